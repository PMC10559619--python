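"""File-format I/O for the pipeline.

All coordinate conventions are converted here and nowhere else:
VCF and SNV records are 1-based; BEDPE and copy-number segments are
0-based half-open. In-memory objects always carry the convention of
their type (``SnvCall.pos`` 1-based, ``CopySegment`` 0-based).

BEDPE columns (tab-separated, no header):
chromA startA endA chromB startB endB name mapq strand strand type caller
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variants import CopySegment, GeneCopyNumber, Impact, SnvCall, SvCall, SvType

# ---------------------------------------------------------------------------
# VCF (SNVs)
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: 'Allele | Annotation | Annotation_Impact | Gene_Name'">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: Sequence[SnvCall], path: str | Path) -> None:
    """Write SNV calls as a minimal VCF v4.2 with ANN impact/gene info."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt)):
            info = f"ANN={c.alt}|variant|{c.impact.value}|{c.gene}"
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n")


def read_vcf_snvs(
    path: str | Path, sample: str = "", caller: str = ""
) -> list[SnvCall]:
    """Read SNVs from a VCF v4.2, parsing the ANN impact field if present.

    Multi-allelic records are split into one call per ALT allele; non-SNV
    alleles (indels) are skipped.
    """
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        ann = rec.INFO.get("ANN")
        impact, gene = Impact.MODIFIER, ""
        if ann:
            fields = str(ann).split(",")[0].split("|")
            if len(fields) >= 3 and fields[2] in Impact.__members__:
                impact = Impact(fields[2])
            if len(fields) >= 4:
                gene = fields[3]
        for alt in rec.ALT:
            if len(rec.REF) != 1 or len(alt) != 1:
                continue
            out.append(
                SnvCall(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    impact=impact,
                    gene=gene,
                    sample=sample,
                    caller=caller,
                )
            )
    return out


# ---------------------------------------------------------------------------
# BEDPE (SVs)
# ---------------------------------------------------------------------------

def write_bedpe(calls: Sequence[SvCall], path: str | Path) -> None:
    """Write SV calls as BEDPE (0-based half-open single-base intervals)."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            fh.write(
                "\t".join(
                    [
                        c.chromA,
                        str(c.posA - 1),
                        str(c.posA),
                        c.chromB,
                        str(c.posB - 1),
                        str(c.posB),
                        c.sample or f"sv{i}",
                        str(c.mapq),
                        "+",
                        "+",
                        c.type.value,
                        c.caller,
                    ]
                )
                + "\n"
            )


def read_bedpe(path: str | Path) -> list[SvCall]:
    """Read SV calls from BEDPE written by :func:`write_bedpe`."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            chrom_a, _, end_a, chrom_b, _, end_b = f[:6]
            pos_a, pos_b = int(end_a), int(end_b)
            sv_type = SvType(f[10])
            out.append(
                SvCall(
                    type=sv_type,
                    chromA=chrom_a,
                    posA=pos_a,
                    chromB=chrom_b,
                    posB=pos_b,
                    length=0 if sv_type is SvType.TRA else pos_b - pos_a,
                    mapq=int(f[7]),
                    sample=f[6],
                    caller=f[11] if len(f) > 11 else "",
                )
            )
    return out


# ---------------------------------------------------------------------------
# Segments / gene copy number / gene breaks
# ---------------------------------------------------------------------------

def write_segments(segments: Sequence[CopySegment], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.sample, s.chrom, s.start, s.end, s.log2_ratio) for s in segments],
        columns=["sample", "chrom", "start", "end", "log2_ratio"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> list[CopySegment]:
    df = pd.read_csv(path, sep="\t")
    return [
        CopySegment(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            log2_ratio=float(r.log2_ratio),
            sample=str(r.sample),
        )
        for r in df.itertuples()
    ]


def write_gene_cn(cn: Sequence[GeneCopyNumber], path: str | Path) -> None:
    """Gene-level CN table: gene, sample, integer_cn, delta."""
    df = pd.DataFrame(
        [(c.gene, c.sample, c.integer_cn, c.delta) for c in cn],
        columns=["gene", "sample", "integer_cn", "delta"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_cn(path: str | Path) -> list[GeneCopyNumber]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneCopyNumber(gene=str(r.gene), sample=str(r.sample), integer_cn=int(r.integer_cn))
        for r in df.itertuples()
    ]


def write_gene_breaks(
    breaks: Iterable[tuple[str, str]], path: str | Path
) -> None:
    pd.DataFrame(list(breaks), columns=["gene", "sample"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_breaks(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(r.gene), str(r.sample)) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            out[fields[0]] = [g for g in fields[2:] if g]
    return out


# ---------------------------------------------------------------------------
# Misc TSVs
# ---------------------------------------------------------------------------

def write_homolog_map(homologs: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        list(homologs.items()), columns=["mouse_symbol", "human_symbol"]
    ).to_csv(path, sep="\t", index=False)


def read_homolog_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["mouse_symbol"].astype(str), df["human_symbol"].astype(str)))
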
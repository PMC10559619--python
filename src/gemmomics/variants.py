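"""Consensus somatic variant logic.

Somatic calls from two independent callers are only trusted where the
callers agree. SNVs must match exactly on (chrom, pos, ref, alt);
structural variants match when both breakpoints agree within a
positional margin (100 bp for copy-number variants and inversions,
1,000 bp for translocations). Consensus calls are then filtered:

* CNV / inversion: length > 10,000 bp, MAPQ >= 60, and no matching
  call in the wildtype (strain background) sample;
* translocation: no length minimum, MAPQ >= 50, and the call must hit
  a gene that an orthogonal copy-number tool also reports as broken in
  the same sample.

Germline subtraction removes tumor calls that are present in the
wildtype strain background (FVB vs the reference strain), leaving
somatic events.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence


class Impact(str, Enum):
    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"
    MODIFIER = "MODIFIER"


class SvType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    TRA = "TRA"


@dataclass(frozen=True)
class SnvCall:
    """A single-nucleotide variant call (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    impact: Impact = Impact.MODIFIER
    gene: str = ""
    sample: str = ""
    caller: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SvCall:
    """A structural-variant call described by a breakpoint pair.

    ``length`` is posB - posA for intrachromosomal events and 0 for
    translocations.
    """

    type: SvType
    chromA: str
    posA: int
    chromB: str
    posB: int
    length: int
    mapq: int
    sample: str = ""
    caller: str = ""
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"MAPQ must be in [0, 60], got {self.mapq}")
        if self.type is not SvType.TRA:
            if self.chromA != self.chromB:
                raise ValueError("non-TRA call must be intrachromosomal")
            if self.posB <= self.posA:
                raise ValueError("non-TRA call requires posB > posA")
            if self.length != self.posB - self.posA:
                raise ValueError("length must equal posB - posA")


@dataclass(frozen=True)
class CopySegment:
    """A copy-number segment (0-based half-open) with log2 ratio."""

    chrom: str
    start: int
    end: int
    log2_ratio: float
    sample: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must be > start")


@dataclass(frozen=True)
class GeneCopyNumber:
    """Integer copy number of one gene in one sample."""

    gene: str
    sample: str
    integer_cn: int

    def __post_init__(self) -> None:
        if self.integer_cn < 0:
            raise ValueError("integer_cn must be >= 0")

    @property
    def delta(self) -> int:
        """Signed change relative to the diploid baseline."""
        return self.integer_cn - 2


# ---------------------------------------------------------------------------
# SNV operations
# ---------------------------------------------------------------------------

def consensus_snvs(
    calls_a: Sequence[SnvCall], calls_b: Sequence[SnvCall]
) -> list[SnvCall]:
    """Intersect two callers' SNV lists on (chrom, pos, ref, alt).

    Annotation (impact, gene) is taken from ``calls_a``. Output is
    sorted by (chrom, pos). Both lists must come from one sample.
    """
    samples = {c.sample for c in calls_a} | {c.sample for c in calls_b}
    if len(samples) > 1:
        raise ValueError(f"mixed-sample input: {sorted(samples)}")
    keys_b = {c.key for c in calls_b}
    seen: set[tuple] = set()
    out = []
    for c in calls_a:
        if c.key in keys_b and c.key not in seen:
            out.append(c)
            seen.add(c.key)
    out.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return out


def subtract_germline(
    somatic: Sequence[SnvCall], germline: Sequence[SnvCall]
) -> list[SnvCall]:
    """Drop somatic calls whose (chrom, pos, ref, alt) is germline.

    Order of the surviving calls is preserved; idempotent.
    """
    germ = {c.key for c in germline}
    return [c for c in somatic if c.key not in germ]


# ---------------------------------------------------------------------------
# SV consensus
# ---------------------------------------------------------------------------

def _match_pairs(
    calls_a: Sequence[SvCall],
    calls_b: Sequence[SvCall],
    margin: int,
) -> list[tuple[int, int]]:
    """Greedy one-to-one breakpoint matching.

    A pair matches when type and chromosomes agree and both breakpoints
    are within ``margin`` bp. Pairs are consumed greedily by smallest
    combined distance |dposA| + |dposB|; ties go to the leftmost
    caller-A call (then leftmost caller-B call).
    """
    candidates = []
    for i, a in enumerate(calls_a):
        for j, b in enumerate(calls_b):
            if a.type is not b.type or a.chromA != b.chromA or a.chromB != b.chromB:
                continue
            da, db = abs(a.posA - b.posA), abs(a.posB - b.posB)
            if da <= margin and db <= margin:
                candidates.append((da + db, a.posA, b.posA, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    return pairs


def _merge_pair(a: SvCall, b: SvCall) -> SvCall:
    """Merged call: caller-A coordinates, conservative (min) MAPQ."""
    return replace(
        a,
        mapq=min(a.mapq, b.mapq),
        genes=a.genes | b.genes,
        caller=f"{a.caller}+{b.caller}" if a.caller or b.caller else "",
    )


def _matches_any(call: SvCall, others: Sequence[SvCall], margin: int) -> bool:
    return any(
        o.type is call.type
        and o.chromA == call.chromA
        and o.chromB == call.chromB
        and abs(o.posA - call.posA) <= margin
        and abs(o.posB - call.posB) <= margin
        for o in others
    )


def consensus_svs(
    calls_a: Sequence[SvCall],
    calls_b: Sequence[SvCall],
    wildtype: Sequence[SvCall] = (),
    kind: str = "CNV",
    margin: int = 100,
    min_length: int = 10_000,
    min_mapq: int = 60,
) -> list[SvCall]:
    """Consensus CNVs (DEL/DUP) or inversions between two callers.

    Matching uses a ``margin`` bp tolerance at both breakpoints; merged
    calls are filtered to length > ``min_length``, MAPQ >= ``min_mapq``
    and no same-type wildtype call matching under the same rule.
    """
    allowed = {"CNV": {SvType.DEL, SvType.DUP}, "INV": {SvType.INV}}[kind.upper()]
    for c in list(calls_a) + list(calls_b) + list(wildtype):
        if c.type not in allowed:
            raise ValueError(f"call type {c.type} inconsistent with kind={kind}")
    merged = [
        _merge_pair(calls_a[i], calls_b[j])
        for i, j in _match_pairs(calls_a, calls_b, margin)
    ]
    out = [
        m
        for m in merged
        if m.length > min_length
        and m.mapq >= min_mapq
        and not _matches_any(m, wildtype, margin)
    ]
    out.sort(key=lambda c: (c.chromA, c.posA, c.posB))
    return out


def consensus_translocations(
    calls_a: Sequence[SvCall],
    calls_b: Sequence[SvCall],
    gene_breaks: Iterable[tuple[str, str]],
    margin: int = 1_000,
    min_mapq: int = 50,
) -> list[SvCall]:
    """Consensus translocations, cross-validated against gene breaks.

    Matching as for CNVs but with a 1,000 bp margin and MAPQ >= 50, no
    length minimum. A merged call is retained only if one of its
    annotated genes appears in ``gene_breaks`` (gene, sample) for the
    same sample — an orthogonal breakpoint line of evidence.
    """
    for c in list(calls_a) + list(calls_b):
        if c.type is not SvType.TRA:
            raise ValueError("consensus_translocations expects TRA calls only")
    breaks: dict[str, set[str]] = defaultdict(set)
    for gene, sample in gene_breaks:
        breaks[sample].add(gene)
    merged = [
        _merge_pair(calls_a[i], calls_b[j])
        for i, j in _match_pairs(calls_a, calls_b, margin)
    ]
    out = [
        m
        for m in merged
        if m.mapq >= min_mapq and m.genes & breaks.get(m.sample, set())
    ]
    out.sort(key=lambda c: (c.chromA, c.posA, c.chromB, c.posB))
    return out


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------

def integer_cn_from_log2(seg: CopySegment, baseline_ploidy: int = 2) -> int:
    """Integer copy number from a segment log2 ratio.

    round(baseline * 2**log2_ratio) with half-up rounding, floored at 0.
    """
    if baseline_ploidy < 1:
        raise ValueError("baseline_ploidy must be >= 1")
    if not math.isfinite(seg.log2_ratio):
        raise ValueError(f"non-finite log2 ratio for {seg}")
    raw = baseline_ploidy * 2.0 ** seg.log2_ratio
    return max(0, math.floor(raw + 0.5))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def conserved_mutations(
    calls_by_sample: Mapping[str, Sequence[SnvCall]],
    groups: Mapping[str, str],
    frac: float = 0.66,
) -> tuple[dict[str, set[str]], dict[frozenset[str], int]]:
    """Per-group conserved, impactful mutated genes plus Venn counts.

    A gene is conserved in a group when >= ``frac`` of the group's
    samples carry at least one MODERATE or HIGH impact call in it.
    Returns ``(per_group_sets, venn)`` where ``venn`` maps each
    non-empty group combination to the number of genes conserved in
    exactly that combination.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    if not groups:
        raise ValueError("no groups given")
    members: dict[str, list[str]] = defaultdict(list)
    for sample, group in groups.items():
        members[group].append(sample)
    for group, samples in members.items():
        if not samples:
            raise ValueError(f"empty group {group!r}")
    conserved: dict[str, set[str]] = {}
    for group, samples in members.items():
        counts: dict[str, int] = defaultdict(int)
        for sample in samples:
            hit = {
                c.gene
                for c in calls_by_sample.get(sample, [])
                if c.gene and c.impact in (Impact.MODERATE, Impact.HIGH)
            }
            for gene in hit:
                counts[gene] += 1
        n = len(samples)
        conserved[group] = {g for g, k in counts.items() if k / n >= frac}
    venn: dict[frozenset[str], int] = {}
    all_genes = set().union(*conserved.values()) if conserved else set()
    for gene in all_genes:
        combo = frozenset(g for g, s in conserved.items() if gene in s)
        venn[combo] = venn.get(combo, 0) + 1
    return conserved, venn


def mutational_burden(
    calls_by_sample: Mapping[str, Sequence[SnvCall]]
) -> dict[str, int]:
    """Total somatic SNV count per sample."""
    return {sample: len(calls) for sample, calls in calls_by_sample.items()}
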
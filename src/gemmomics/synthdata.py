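"""Deterministic synthetic-data generators for every pipeline input.

The generators emulate the statistical structure the analysis assumes:
subtype-structured expression with additive/multiplicative batch
effects, gene-level copy number linearly coupled to expression,
jittered two-caller structural-variant call sets with constructed
false positives and wildtype (strain background) contaminants,
signature-mixture trinucleotide catalogs, and group-structured
exponential survival times.

Every generator is a pure function of ``(config, seed)``: identical
configs produce bit-identical outputs, and each generator returns a
ground-truth sidecar sufficient for parameter-recovery tests.

Default conditions mirror the motivating study design: three
histological subtypes (microacinar, squamous, EMT) with 14 expression
samples each (42 total), conserved whole-block copy-number gains of +2
and +1 in the microacinar-like class, two-caller SV call sets, and
two-arm survival cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .signatures import CHANNELS_96, MutationCatalog, SignatureMatrix
from .survival import SurvivalRecord
from .variants import GeneCopyNumber, Impact, SnvCall, SvCall, SvType

# stream tags: every generator draws from default_rng([seed, TAG])
_TAG_EXPR, _TAG_CN, _TAG_SV, _TAG_SIG, _TAG_CATALOG, _TAG_SURV, _TAG_SNV = range(7)


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([seed, tag])


@dataclass
class SynthConfig:
    """All knobs for the synthetic cohort, with study-shaped defaults."""

    seed: int = 42
    n_genes: int = 500
    n_samples_per_class: dict[str, int] = field(
        default_factory=lambda: {"microacinar": 14, "squamous": 14, "EMT": 14}
    )
    class_means: dict[str, list[float]] | None = None
    noise_sd: float = 1.0
    batch_offsets: dict[str, float] = field(default_factory=lambda: {"b0": 0.0})
    batch_scales: dict[str, float] = field(default_factory=lambda: {"b0": 1.0})
    cn_beta: float = 2.0
    sv_jitter_sd: float = 20.0
    fp_rate: float = 0.1
    signature_mixture: dict[str, float] = field(
        default_factory=lambda: {"SYN-HRD": 0.7, "SYN-CLOCK": 0.3}
    )
    n_mutations: int = 5000
    survival_medians: dict[str, float] = field(
        default_factory=lambda: {"altered": 87.7, "unaltered": 163.5}
    )
    censor_rate: float = 0.3
    # plumbing knobs beyond the headline parameters
    n_informative: int = 24
    cn_block_size: int = 10
    n_cn_varying: int = 30
    cn_baseline_expr: float = 8.0
    n_sv_events: int = 40
    wt_frac: float = 0.2
    n_survival_per_group: int = 500

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.n_samples_per_class or any(
            n <= 0 for n in self.n_samples_per_class.values()
        ):
            raise ValueError("n_samples_per_class must be positive")
        if self.noise_sd < 0 or self.sv_jitter_sd < 0:
            raise ValueError("scale parameters must be >= 0")
        if any(s <= 0 for s in self.batch_scales.values()):
            raise ValueError("batch scales must be > 0")
        if not 0 <= self.fp_rate <= 1 or not 0 <= self.censor_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.signature_mixture:
            total = sum(self.signature_mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"signature mixture must sum to 1, got {total}")
        if any(m <= 0 for m in self.survival_medians.values()):
            raise ValueError("survival medians must be > 0")
        if set(self.batch_offsets) != set(self.batch_scales):
            raise ValueError("batch_offsets and batch_scales must share keys")
        if self.class_means is None:
            self.class_means = _default_class_means(
                list(self.n_samples_per_class), self.n_informative
            )
        lengths = {len(v) for v in self.class_means.values()}
        if len(lengths) != 1:
            raise ValueError("all class mean vectors must have equal length")
        if lengths.pop() > self.n_genes:
            raise ValueError("more informative genes than genes")

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    # -- derived layout --------------------------------------------------
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"Gene{str(i).zfill(width)}" for i in range(1, self.n_genes + 1)]

    def sample_layout(self) -> pd.DataFrame:
        """Sample metadata: class in declaration order, batches cycled
        within class so classes stay balanced across batches."""
        batch_names = list(self.batch_offsets)
        rows = []
        for cls, n in self.n_samples_per_class.items():
            for i in range(n):
                rows.append((f"{cls}_{i + 1}", cls, batch_names[i % len(batch_names)]))
        return pd.DataFrame(rows, columns=["sample", "group", "batch"]).set_index(
            "sample"
        )


def _default_class_means(classes: Sequence[str], n_informative: int) -> dict:
    """Block-structured class means: each class elevated (mean 3) on its
    own slice of the informative genes, baseline 0 elsewhere."""
    k = len(classes)
    per = max(1, n_informative // k)
    means = {}
    for j, cls in enumerate(classes):
        v = np.zeros(n_informative)
        v[j * per : (j + 1) * per] = 3.0
        means[cls] = v.tolist()
    return means


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def gen_expression(cfg: SynthConfig) -> ExpressionMatrix:
    """Subtype-structured expression with batch location/scale effects.

    Sample value = scale_b * (class_mean + noise) + offset_b, so batches
    shift means additively and inflate variances multiplicatively.
    """
    rng = _rng(cfg.seed, _TAG_EXPR)
    layout = cfg.sample_layout()
    genes = cfg.gene_names()
    n_inf = len(next(iter(cfg.class_means.values())))
    values = np.zeros((cfg.n_genes, len(layout)))
    for j, (sample, row) in enumerate(layout.iterrows()):
        mu = np.zeros(cfg.n_genes)
        mu[:n_inf] = cfg.class_means[row["group"]]
        eps = rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes) if cfg.noise_sd else 0.0
        scale = cfg.batch_scales[row["batch"]]
        offset = cfg.batch_offsets[row["batch"]]
        values[:, j] = scale * (mu + eps) + offset
    df = pd.DataFrame(values, index=genes, columns=list(layout.index))
    return ExpressionMatrix(df, layout[["group", "batch"]])


def informative_genes(cfg: SynthConfig) -> list[str]:
    """Ground-truth sidecar: the class-informative gene symbols."""
    n_inf = len(next(iter(cfg.class_means.values())))
    return cfg.gene_names()[:n_inf]


# ---------------------------------------------------------------------------
# Copy number coupled to expression
# ---------------------------------------------------------------------------

@dataclass
class CnExpressionTruth:
    """Sidecar for the CN/expression generator."""

    conserved: pd.DataFrame  # gene, group, delta (conserved events)
    varying_genes: list[str]
    constant_genes: list[str]


def gen_cn_and_expression(
    cfg: SynthConfig,
) -> tuple[list[GeneCopyNumber], ExpressionMatrix, CnExpressionTruth]:
    """Integer copy number with subtype-conserved events, coupled to
    expression as baseline + cn_beta * (CN - 2) + noise.

    Gene layout: one conserved block per class (all of the class's
    samples share the same gain/loss, deltas cycling +2, +1, -1), then
    ``n_cn_varying`` genes with per-sample random CN in {1, 2, 3}, then
    constant diploid genes.
    """
    if not np.isfinite(cfg.cn_beta):
        raise ValueError("cn_beta must be finite")
    rng = _rng(cfg.seed, _TAG_CN)
    layout = cfg.sample_layout()
    genes = cfg.gene_names()
    classes = list(cfg.n_samples_per_class)
    deltas = [2, 1, -1]

    n_samples = len(layout)
    cn = np.full((cfg.n_genes, n_samples), 2, dtype=int)
    conserved_rows = []
    cursor = 0
    for k, cls in enumerate(classes):
        delta = deltas[k % len(deltas)]
        block = genes[cursor : cursor + cfg.cn_block_size]
        members = np.flatnonzero((layout["group"] == cls).to_numpy())
        for g in block:
            gi = genes.index(g)
            cn[gi, members] = int(np.clip(2 + delta, 0, 4))
            conserved_rows.append((g, cls, delta))
        cursor += cfg.cn_block_size

    varying = genes[cursor : cursor + cfg.n_cn_varying]
    group_members = {
        cls: np.flatnonzero((layout["group"] == cls).to_numpy()) for cls in classes
    }
    for g in varying:
        gi = genes.index(g)
        # balanced per-group delta pattern (~1/3 gain, ~1/3 loss, rest
        # neutral) so a varying gene can never look group-conserved
        for members in group_members.values():
            m = len(members)
            third = max(1, m // 3)
            pattern = np.array([1] * third + [-1] * third + [0] * (m - 2 * third))
            cn[gi, members] = 2 + rng.permutation(pattern)
    constant = genes[cursor + cfg.n_cn_varying :]

    noise = (
        rng.normal(0.0, cfg.noise_sd, size=cn.shape) if cfg.noise_sd else 0.0
    )
    expr_values = cfg.cn_baseline_expr + cfg.cn_beta * (cn - 2) + noise
    expr = ExpressionMatrix(
        pd.DataFrame(expr_values, index=genes, columns=list(layout.index)),
        layout[["group", "batch"]],
    )
    cn_records = [
        GeneCopyNumber(gene=genes[i], sample=layout.index[j], integer_cn=int(cn[i, j]))
        for i in range(cfg.n_genes)
        for j in range(n_samples)
    ]
    truth = CnExpressionTruth(
        conserved=pd.DataFrame(conserved_rows, columns=["gene", "group", "delta"]),
        varying_genes=list(varying),
        constant_genes=list(constant),
    )
    return cn_records, expr, truth


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

@dataclass
class SvSimResult:
    """Two jittered call sets, the wildtype set, and the ground truth."""

    caller_a: list[SvCall]
    caller_b: list[SvCall]
    wildtype: list[SvCall]
    truth: pd.DataFrame  # event_id, type, chromA, posA, chromB, posB, in_wildtype
    gene_breaks: list[tuple[str, str]]  # populated for translocations


_CHROMS = [f"chr{i}" for i in range(1, 20)]
_SLOT_BP = 3_000_000  # truth/FP slots are 3 Mb apart: no cross-matching possible


def gen_sv_callsets(
    cfg: SynthConfig, kind: str = "CNV", sample: str = "tumor1"
) -> SvSimResult:
    """Emit a ground-truth SV set into two call sets with breakpoint jitter.

    Truth events sit on a 3 Mb coordinate grid, so distinct events (and
    the caller-private false positives, which occupy disjoint grid
    slots per caller) can never match under a <=1 kb rule. A leading
    fraction ``wt_frac`` of truth events is duplicated into the
    wildtype set at identical coordinates. Lengths are drawn in
    [20 kb, 1 Mb] and MAPQ is 60 so truth events survive the consensus
    filters unless wildtype-matched.
    """
    rng = _rng(cfg.seed, _TAG_SV)
    kind = kind.upper()
    n = cfg.n_sv_events
    n_fp = int(round(cfg.fp_rate * n))

    def slot_pos(slot: int) -> tuple[str, int]:
        chrom = _CHROMS[slot % len(_CHROMS)]
        base = (slot // len(_CHROMS) + 1) * _SLOT_BP
        return chrom, base

    truth_rows = []
    gene_breaks: list[tuple[str, str]] = []
    truth_calls: list[SvCall] = []
    for i in range(n):
        chrom_a, pos_a = slot_pos(i)
        if kind == "TRA":
            chrom_b, pos_b = slot_pos(i + n + 2 * n_fp)  # different region
            length, mapq, sv_type = 0, 55, SvType.TRA
            genes = frozenset({f"BreakGene{i + 1}"})
            gene_breaks.append((f"BreakGene{i + 1}", sample))
        else:
            sv_type = (
                SvType.INV if kind == "INV" else (SvType.DEL, SvType.DUP)[i % 2]
            )
            length = int(rng.integers(20_000, 1_000_000))
            chrom_b, pos_b = chrom_a, pos_a + length
            mapq, genes = 60, frozenset()
        truth_calls.append(
            SvCall(
                type=sv_type,
                chromA=chrom_a,
                posA=pos_a,
                chromB=chrom_b,
                posB=pos_b,
                length=length,
                mapq=mapq,
                sample=sample,
                caller="truth",
                genes=genes,
            )
        )
        truth_rows.append(
            (i, sv_type.value, chrom_a, pos_a, chrom_b, pos_b, i < int(cfg.wt_frac * n))
        )

    def jitter(call: SvCall, caller: str) -> SvCall:
        if cfg.sv_jitter_sd == 0:
            da = db = 0
        else:
            da = int(round(rng.normal(0, cfg.sv_jitter_sd)))
            db = int(round(rng.normal(0, cfg.sv_jitter_sd)))
        pos_a = max(1, call.posA + da)
        pos_b = max(1, call.posB + db)
        if call.type is not SvType.TRA and pos_b <= pos_a:
            pos_b = pos_a + 1
        return SvCall(
            type=call.type,
            chromA=call.chromA,
            posA=pos_a,
            chromB=call.chromB,
            posB=pos_b,
            length=0 if call.type is SvType.TRA else pos_b - pos_a,
            mapq=call.mapq,
            sample=call.sample,
            caller=caller,
            genes=call.genes,
        )

    def false_positive(slot: int, caller: str) -> SvCall:
        chrom_a, pos_a = slot_pos(slot)
        if kind == "TRA":
            chrom_b, pos_b = slot_pos(slot + 3 * n + 4 * n_fp)
            return SvCall(
                type=SvType.TRA, chromA=chrom_a, posA=pos_a, chromB=chrom_b,
                posB=pos_b, length=0, mapq=55, sample=sample, caller=caller,
            )
        sv_type = SvType.INV if kind == "INV" else (SvType.DEL, SvType.DUP)[slot % 2]
        length = int(rng.integers(20_000, 1_000_000))
        return SvCall(
            type=sv_type, chromA=chrom_a, posA=pos_a, chromB=chrom_a,
            posB=pos_a + length, length=length, mapq=60, sample=sample, caller=caller,
        )

    caller_a = [jitter(c, "callerA") for c in truth_calls]
    caller_b = [jitter(c, "callerB") for c in truth_calls]
    caller_a += [false_positive(n + k, "callerA") for k in range(n_fp)]
    caller_b += [false_positive(n + n_fp + k, "callerB") for k in range(n_fp)]
    n_wt = int(cfg.wt_frac * n)
    wildtype = [
        SvCall(
            type=c.type, chromA=c.chromA, posA=c.posA, chromB=c.chromB, posB=c.posB,
            length=c.length, mapq=c.mapq, sample="wildtype", caller="wt",
            genes=c.genes,
        )
        for c in truth_calls[:n_wt]
    ]
    truth = pd.DataFrame(
        truth_rows,
        columns=["event_id", "type", "chromA", "posA", "chromB", "posB", "in_wildtype"],
    )
    return SvSimResult(caller_a, caller_b, wildtype, truth, gene_breaks)


# ---------------------------------------------------------------------------
# SNV call sets
# ---------------------------------------------------------------------------

@dataclass
class SnvSimResult:
    caller_a: list[SnvCall]
    caller_b: list[SnvCall]
    germline: list[SnvCall]
    truth_shared: list[SnvCall]  # consensus calls not in the germline set


def gen_snv_callsets(
    seed: int,
    n_shared: int = 50,
    n_private_a: int = 30,
    n_private_b: int = 20,
    n_germline: int = 10,
    sample: str = "tumor1",
) -> SnvSimResult:
    """Two SNV call sets with planted shared, private, and germline calls.

    Shared calls appear in both callers; the first ``n_germline`` of
    them are duplicated into the germline set (and so should vanish
    after subtraction). Private calls occupy disjoint positions.
    """
    rng = _rng(seed, _TAG_SNV)
    bases = ["A", "C", "G", "T"]
    total = n_shared + n_private_a + n_private_b
    positions = rng.permutation(np.arange(1, 10 * total + 1) * 97)[:total]

    def make(pos: int, idx: int, caller: str) -> SnvCall:
        ref = bases[idx % 4]
        alt = bases[(idx + 1 + int(pos) % 3) % 4]
        if alt == ref:
            alt = bases[(idx + 2) % 4]
        impact = [Impact.LOW, Impact.MODERATE, Impact.HIGH][idx % 3]
        return SnvCall(
            chrom=f"chr{1 + idx % 19}", pos=int(pos), ref=ref, alt=alt,
            impact=impact, gene=f"Gene{idx % 40}", sample=sample, caller=caller,
        )

    shared_a = [make(positions[i], i, "callerA") for i in range(n_shared)]
    shared_b = [
        SnvCall(**{**asdict(c), "impact": c.impact, "caller": "callerB"})
        for c in shared_a
    ]
    priv_a = [
        make(positions[n_shared + i], n_shared + i, "callerA")
        for i in range(n_private_a)
    ]
    priv_b = [
        make(positions[n_shared + n_private_a + i], n_shared + n_private_a + i, "callerB")
        for i in range(n_private_b)
    ]
    germline = [
        SnvCall(**{**asdict(c), "sample": "wildtype", "caller": "germline"})
        for c in shared_a[:n_germline]
    ]
    truth = shared_a[n_germline:]
    return SnvSimResult(shared_a + priv_a, shared_b + priv_b, germline, truth)


# ---------------------------------------------------------------------------
# Mutation catalogs and signatures
# ---------------------------------------------------------------------------

def gen_signature_matrix(names: Sequence[str], seed: int = 42) -> SignatureMatrix:
    """Synthetic, well-separated signature profiles.

    Each signature concentrates 70% of its mass on six channels
    disjoint from every other signature's dominant channels (so
    mixtures are identifiable), with the remaining 30% uniform.
    """
    if 6 * len(names) > 96:
        raise ValueError("at most 16 synthetic signatures supported")
    rng = _rng(seed, _TAG_SIG)
    order = rng.permutation(96)
    rows = {}
    for k, name in enumerate(names):
        profile = np.full(96, 0.3 / 96)
        dominant = order[6 * k : 6 * (k + 1)]
        mass = rng.dirichlet(np.ones(6) * 5.0) * 0.7
        profile[dominant] += mass
        rows[name] = profile / profile.sum()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(CHANNELS_96))
    df.index.name = "signature"
    return SignatureMatrix(df)


def gen_mutation_catalog(
    cfg: SynthConfig,
    sigs: SignatureMatrix | None = None,
    n_samples: int = 1,
) -> tuple[MutationCatalog, SignatureMatrix]:
    """Multinomial catalog draws from the configured signature mixture."""
    if sigs is None:
        sigs = gen_signature_matrix(sorted(cfg.signature_mixture), seed=cfg.seed)
    unknown = set(cfg.signature_mixture) - set(sigs.names)
    if unknown:
        raise ValueError(f"mixture references unknown signatures: {sorted(unknown)}")
    rng = _rng(cfg.seed, _TAG_CATALOG)
    p = np.zeros(96)
    for name, w in cfg.signature_mixture.items():
        p += w * sigs.profiles.loc[name].to_numpy()
    p = p / p.sum()
    rows = {
        f"tumor{i + 1}": rng.multinomial(cfg.n_mutations, p) for i in range(n_samples)
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(CHANNELS_96))
    df.index.name = "sample"
    return MutationCatalog(df), sigs


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def gen_survival(cfg: SynthConfig) -> list[SurvivalRecord]:
    """Exponential event times (rate ln2 / median) per group with
    independent exponential censoring tuned to the target censor rate."""
    rng = _rng(cfg.seed, _TAG_SURV)
    records = []
    for group, median in cfg.survival_medians.items():
        lam = np.log(2.0) / median
        t_event = rng.exponential(1.0 / lam, size=cfg.n_survival_per_group)
        if cfg.censor_rate >= 1.0:
            for i, t in enumerate(t_event):
                records.append(
                    SurvivalRecord(f"{group}_{i + 1}", float(t), 0, group)
                )
            continue
        if cfg.censor_rate > 0:
            mu = lam * cfg.censor_rate / (1.0 - cfg.censor_rate)
            t_cens = rng.exponential(1.0 / mu, size=cfg.n_survival_per_group)
        else:
            t_cens = np.full(cfg.n_survival_per_group, np.inf)
        for i, (te, tc) in enumerate(zip(t_event, t_cens)):
            t, ev = (te, 1) if te <= tc else (tc, 0)
            records.append(SurvivalRecord(f"{group}_{i + 1}", float(t), ev, group))
    return records


# ---------------------------------------------------------------------------
# Homolog map
# ---------------------------------------------------------------------------

def gen_homolog_map(
    genes: Sequence[str], mapped_frac: float = 1.0, seed: int = 42
) -> dict[str, str]:
    """Mouse-to-human style symbol map (upper-cased target symbols).

    A deterministic ``mapped_frac`` leading fraction of genes gets a
    mapping; the rest are left unmapped.
    """
    k = int(round(mapped_frac * len(genes)))
    return {g: g.upper() for g in list(genes)[:k]}
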
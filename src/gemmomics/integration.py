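"""Copy-number / expression integration.

Correlation between integer copy number and expression is computed per
gene across samples with Kendall's tau-b and Pearson's r. Only genes
with a discrete copy-number change (at least one sample at +/- 1 from
the diploid baseline) get a defined correlation; genes with constant
copy number are flagged undefined. Flags are inclusive: tau >= 0.3 and
r >= 0.7 are "significant" in the sense used for downstream tracks.

The integrative gene set crosses differential expression between
groups with conserved copy-number events, then maps the survivors
through a mouse-to-human homolog table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .expression import ExpressionMatrix
from .variants import GeneCopyNumber

TAU_THRESHOLD = 0.3
PEARSON_THRESHOLD = 0.7


@dataclass(frozen=True)
class CorrelationRecord:
    """Per-gene CN/expression correlation with significance flags."""

    gene: str
    tau: float | None
    pearson_r: float | None
    n: int

    @property
    def tau_significant(self) -> bool:
        return self.tau is not None and self.tau >= TAU_THRESHOLD

    @property
    def r_significant(self) -> bool:
        return self.pearson_r is not None and self.pearson_r >= PEARSON_THRESHOLD

    @property
    def defined(self) -> bool:
        return self.tau is not None or self.pearson_r is not None


@dataclass(frozen=True)
class DeResult:
    """Per-gene two-sided t-test result; log_fc = mean_a - mean_b."""

    gene: str
    log_fc: float
    t_stat: float
    p_value: float


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Kendall's tau-b with tie corrections; None when a vector is all-tied."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return None
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def correlate_cn_expression(
    cn: Sequence[GeneCopyNumber], expr: ExpressionMatrix
) -> list[CorrelationRecord]:
    """Correlate integer CN with expression per gene over shared samples.

    Genes with no sample at |delta| >= 1 (no discrete change) emit
    undefined records.
    """
    cn_df = pd.DataFrame(
        [(c.gene, c.sample, c.integer_cn) for c in cn],
        columns=["gene", "sample", "integer_cn"],
    ).pivot_table(index="gene", columns="sample", values="integer_cn")
    shared = [s for s in expr.samples if s in cn_df.columns]
    if not shared:
        raise ValueError("no shared samples between CN table and expression")
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    out = []
    for gene in cn_df.index:
        if gene not in expr.values.index:
            continue
        cn_vec = cn_df.loc[gene, shared].to_numpy(dtype=float)
        if np.isnan(cn_vec).any():
            mask = ~np.isnan(cn_vec)
        else:
            mask = np.ones(len(shared), dtype=bool)
        cn_vec = cn_vec[mask]
        ex_vec = expr.values.loc[gene, shared].to_numpy(dtype=float)[mask]
        n = int(mask.sum())
        if n < 3 or not np.any(np.abs(cn_vec - 2) >= 1) or np.unique(cn_vec).size == 1:
            out.append(CorrelationRecord(gene=gene, tau=None, pearson_r=None, n=n))
            continue
        tau = kendall_tau_b(cn_vec, ex_vec)
        if np.unique(ex_vec).size == 1:
            r = None
        else:
            r = float(stats.pearsonr(cn_vec, ex_vec).statistic)
        out.append(CorrelationRecord(gene=gene, tau=tau, pearson_r=r, n=n))
    return out


def correlation_frame(records: Sequence[CorrelationRecord]) -> pd.DataFrame:
    """Tabular view of correlation records (TSV-ready)."""
    return pd.DataFrame(
        [
            (
                r.gene,
                np.nan if r.tau is None else r.tau,
                np.nan if r.pearson_r is None else r.pearson_r,
                r.n,
                r.tau_significant,
                r.r_significant,
            )
            for r in records
        ],
        columns=["gene", "tau", "pearson_r", "n", "tau_significant", "r_significant"],
    )


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def differential_expression(
    expr: ExpressionMatrix, group_a: str, group_b: str
) -> list[DeResult]:
    """Per-gene pooled-variance two-sided Student's t-test of a vs b."""
    sa = expr.samples_in_group(group_a)
    sb = expr.samples_in_group(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("both groups need >= 2 samples")
    a = expr.values[sa].to_numpy(dtype=float)
    b = expr.values[sb].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    out = []
    for gene, l, ti, pi in zip(expr.genes, lfc, t, p):
        if np.isnan(ti):  # zero variance in both groups
            ti, pi = (0.0, 1.0) if np.isclose(l, 0.0) else (np.inf, 0.0)
        out.append(DeResult(gene=gene, log_fc=float(l), t_stat=float(ti), p_value=float(pi)))
    return out


# ---------------------------------------------------------------------------
# Integrative gene set
# ---------------------------------------------------------------------------

def conserved_cn_genes(
    cn: Sequence[GeneCopyNumber],
    groups: Mapping[str, str],
    frac: float = 0.66,
) -> set[str]:
    """Genes in a conserved same-sign CN event in >= frac of some group.

    A gene qualifies when, within at least one group, the fraction of
    samples with delta >= +1 (or, separately, <= -1) is >= ``frac``.
    """
    df = pd.DataFrame(
        [(c.gene, c.sample, c.delta) for c in cn],
        columns=["gene", "sample", "delta"],
    )
    df["group"] = df["sample"].map(groups)
    df = df.dropna(subset=["group"])
    out: set[str] = set()
    group_sizes = pd.Series(list(groups.values())).value_counts()
    for (gene, group), sub in df.groupby(["gene", "group"]):
        n = int(group_sizes.get(group, 0))
        if n == 0:
            continue
        gains = int((sub["delta"] >= 1).sum())
        losses = int((sub["delta"] <= -1).sum())
        if gains / n >= frac or losses / n >= frac:
            out.add(gene)
    return out


def integrative_gene_set(
    de: Sequence[DeResult],
    cn: Sequence[GeneCopyNumber],
    groups: Mapping[str, str],
    homologs: Mapping[str, str],
    p_cut: float = 0.05,
    frac: float = 0.66,
) -> set[str]:
    """DE genes residing in conserved CN events, mapped to homologs.

    ``de`` may pool the results of several pairwise contrasts; a gene
    qualifies if it is significant (p < p_cut) in at least one of them
    and lies in a conserved copy-number event. Unmapped genes are
    dropped (with a warning when the map is empty).
    """
    de_genes = {r.gene for r in de if r.p_value < p_cut}
    cn_genes = conserved_cn_genes(cn, groups, frac=frac)
    qualifying = de_genes & cn_genes
    if not homologs:
        warnings.warn("empty homolog map: all genes dropped", stacklevel=2)
        return set()
    return {homologs[g] for g in qualifying if g in homologs}


# ---------------------------------------------------------------------------
# Clustering / PCA summaries
# ---------------------------------------------------------------------------

def ward_cluster(
    matrix: np.ndarray | pd.DataFrame, axis: str = "rows"
) -> tuple[np.ndarray, list[int]]:
    """Ward-linkage agglomerative clustering on Euclidean distance.

    Returns the scipy linkage matrix and the deterministic leaf order.
    ``axis='columns'`` clusters columns instead of rows.
    """
    arr = np.asarray(matrix, dtype=float)
    if axis == "columns":
        arr = arr.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    if np.isnan(arr).any():
        raise ValueError("matrix contains NaN")
    linkage = hierarchy.linkage(arr, method="ward")
    leaves = list(hierarchy.leaves_list(linkage))
    return linkage, leaves


def pca_2d(
    matrix: np.ndarray | pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-component PCA on standardized features.

    Rows are items, columns are features; features are standardized to
    zero mean and unit variance first. Zero-variance features are
    dropped with a warning. Returns (scores items x 2, explained
    variance fractions length 2).
    """
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    arr = np.asarray(matrix, dtype=float)
    if arr.shape[0] < 3 or arr.shape[1] < 2:
        raise ValueError("need >= 3 items and >= 2 features")
    keep = arr.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance feature(s)", stacklevel=2
        )
    arr = arr[:, keep]
    z = StandardScaler().fit_transform(arr)
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(z)
    return scores, pca.explained_variance_ratio_.copy()
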
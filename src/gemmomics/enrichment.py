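"""Single-sample gene set enrichment (ssGSEA) and pathway statistics.

For one sample, genes are ranked by descending expression (ties broken
by gene symbol, so scoring is deterministic). Walking down the ranked
list, in-set genes add a weight proportional to |rank statistic|^alpha
(normalized over the in-set genes) and out-of-set genes subtract
1/(N - m). The enrichment score is the running sum integrated over all
positions, so coordinate up-regulation of the whole set near the top
of the ranking produces a large positive score.

At alpha = 0 the score depends on the expression only through ranks.
The default alpha = 0.75 is the weighting conventionally used for
single-sample scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix


@dataclass
class GeneSetCollection:
    """Named gene sets (order-preserving)."""

    sets: dict[str, list[str]]

    def restrict_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect each set with an expression universe, dropping empties."""
        uni = set(universe)
        restricted = {
            name: [g for g in genes if g in uni] for name, genes in self.sets.items()
        }
        return GeneSetCollection({n: g for n, g in restricted.items() if g})

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        from .io import read_gmt

        return cls(read_gmt(path))


@dataclass
class EnrichmentMatrix:
    """Gene sets x samples ssGSEA scores."""

    scores: pd.DataFrame
    normalized: bool = False
    meta: pd.DataFrame | None = field(default=None)

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)

    def samples_in_group(self, group: str) -> list[str]:
        if self.meta is None:
            raise ValueError("no sample metadata attached")
        return list(self.meta.index[self.meta["group"] == group])


def ssgsea_score(
    expr_column: pd.Series | Mapping[str, float],
    gene_set: Iterable[str],
    alpha: float = 0.75,
) -> float:
    """Integrated running-sum enrichment score of one set in one sample."""
    if not isinstance(expr_column, pd.Series):
        expr_column = pd.Series(dict(expr_column))
    genes = expr_column.index
    in_set = set(gene_set) & set(genes)
    if not in_set:
        raise ValueError("gene set has empty intersection with the universe")
    order = sorted(genes, key=lambda g: (-expr_column[g], g))
    values = expr_column.loc[order].to_numpy(dtype=float)
    member = np.array([g in in_set for g in order])
    n, m = len(order), len(in_set)

    weights = np.abs(values) ** alpha
    in_total = weights[member].sum()
    if in_total == 0:  # all-zero rank statistic for in-set genes: equal weights
        step_in = np.where(member, 1.0 / m, 0.0)
    else:
        step_in = np.where(member, weights / in_total, 0.0)
    step_out = 0.0 if n == m else 1.0 / (n - m)
    walk = np.where(member, step_in, -step_out)
    return float(np.cumsum(walk).sum())


def ssgsea_matrix(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.75,
    normalize: bool = False,
) -> EnrichmentMatrix:
    """Score every (set, sample) pair; optionally rescale globally.

    Sets with empty intersection against the expression universe are
    skipped with a warning (missing rows, not NaNs). Normalization
    divides all scores by the global (max - min) of the matrix.
    """
    restricted = sets.restrict_to(expr.genes)
    skipped = set(sets.sets) - set(restricted.sets)
    if skipped:
        warnings.warn(f"skipping sets with empty intersection: {sorted(skipped)}",
                      stacklevel=2)
    rows = {}
    for name, genes in restricted.sets.items():
        gene_set = set(genes)
        rows[name] = [
            ssgsea_score(expr.values[s], gene_set, alpha=alpha) for s in expr.samples
        ]
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=expr.samples)
    scores.index.name = "gene_set"
    if normalize and not scores.empty:
        span = float(scores.to_numpy().max() - scores.to_numpy().min())
        if span > 0:
            scores = scores / span
    return EnrichmentMatrix(scores=scores, normalized=normalize, meta=expr.meta.copy())


def pathway_volcano(
    em: EnrichmentMatrix,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
    lfc_cut: float = 0.4,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-set mean difference (a - b) and two-sided t-test p-value.

    A set is significant when |delta| >= lfc_cut and p <= p_cut.
    ``group_a``/``group_b`` may be group names (resolved through the
    attached metadata) or explicit sample lists; one group may pool
    several subtypes by passing their samples together.
    """
    sa = em.samples_in_group(group_a) if isinstance(group_a, str) else list(group_a)
    sb = em.samples_in_group(group_b) if isinstance(group_b, str) else list(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("both groups need >= 2 samples")
    a = em.scores[sa].to_numpy(dtype=float)
    b = em.scores[sb].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    delta = a.mean(axis=1) - b.mean(axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    df = pd.DataFrame(
        {
            "set": em.set_names,
            "delta": delta,
            "p": p,
            "significant": (np.abs(delta) >= lfc_cut) & (p <= p_cut),
        }
    )
    return df
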
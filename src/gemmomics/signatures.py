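"""Trinucleotide mutation catalogs and signature exposure refitting.

A mutation catalog collapses each SNV into one of 96 channels:
6 pyrimidine-reference substitution classes (C>A, C>G, C>T, T>A, T>C,
T>G) times 16 flanking-base contexts. Purine-reference substitutions
are reverse-complemented first, so ``G>T`` at context ``AGA`` becomes
``C>A`` at ``TCT``.

Exposure refitting expresses one tumor's catalog as a nonnegative
mixture of known signature profiles. Signatures are added by forward
selection: at each step the candidate whose inclusion (with a
nonnegative, sum-at-most-one weight fit) most reduces the squared
reconstruction error joins the model; selection stops when the error
improvement falls below a tolerance. Weights below a cutoff are
discarded, the survivors refit once, and the result renormalized to
sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .variants import SnvCall

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = ("C", "T")
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channels in COSMIC lexicographic order, A[C>A]A ... T[T>G]T.
CHANNELS_96: tuple[str, ...] = tuple(
    sorted(
        f"{five}[{sub}]{three}"
        for sub in _SUBSTITUTIONS
        for five in "ACGT"
        for three in "ACGT"
    )
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_for(ref: str, alt: str, context: str) -> str:
    """The 96-channel label for a substitution in a trinucleotide context.

    ``context`` is the reference trinucleotide centered on the variant.
    """
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    if ref not in _PYRIMIDINES:
        context = _revcomp(context)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in _CHANNEL_INDEX:
        raise ValueError(f"invalid channel {label!r}")
    return label


@dataclass
class MutationCatalog:
    """Samples x 96 integer mutation counts (fixed channel order)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if tuple(self.counts.columns) != CHANNELS_96:
            raise ValueError("catalog columns must be the 96 channels in order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def row(self, sample: str) -> np.ndarray:
        return self.counts.loc[sample].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationCatalog":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class SignatureMatrix:
    """Signatures x 96 probability profiles; each row sums to one."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        if tuple(self.profiles.columns) != CHANNELS_96:
            raise ValueError("signature columns must be the 96 channels in order")
        arr = self.profiles.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("signature entries must be >= 0")
        sums = arr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each signature row must sum to 1 +/- 1e-6")

    @property
    def names(self) -> list[str]:
        return list(self.profiles.index)

    def matrix(self) -> np.ndarray:
        return self.profiles.to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.profiles.to_csv(path, sep="\t", index_label="signature")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class SignatureExposure:
    """Refit mixture weights for one sample.

    ``sse_path`` records the SSE after each accepted forward-selection
    step (non-increasing by construction).
    """

    sample: str
    weights: dict[str, float]
    residual_sse: float
    sse_path: list[float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sse_path is None:
            self.sse_path = []


# ---------------------------------------------------------------------------
# Catalog construction
# ---------------------------------------------------------------------------

def catalog_from_snvs(
    snvs_by_sample: Mapping[str, Sequence[SnvCall]],
    context_source: Mapping[tuple[str, int], str],
) -> MutationCatalog:
    """Collapse per-sample SNVs into a 96-channel catalog.

    ``context_source`` maps (chrom, pos) to the reference trinucleotide
    centered on the position; missing contexts raise with the offending
    positions listed.
    """
    missing = [
        (c.chrom, c.pos)
        for calls in snvs_by_sample.values()
        for c in calls
        if (c.chrom, c.pos) not in context_source
    ]
    if missing:
        raise KeyError(f"missing trinucleotide context for positions: {missing[:10]}")
    rows = {}
    for sample, calls in snvs_by_sample.items():
        counts = np.zeros(96, dtype=int)
        for c in calls:
            label = channel_for(c.ref, c.alt, context_source[(c.chrom, c.pos)])
            counts[_CHANNEL_INDEX[label]] += 1
        rows[sample] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(CHANNELS_96))
    df.index.name = "sample"
    return MutationCatalog(df)


# ---------------------------------------------------------------------------
# Exposure refitting
# ---------------------------------------------------------------------------

def _fit_weights(target: np.ndarray, profiles: np.ndarray) -> tuple[np.ndarray, float]:
    """Nonnegative least squares with the weights constrained to sum <= 1.

    Any solver meeting the residual tolerance is acceptable; this uses
    unconstrained NNLS first and falls back to an SLSQP solve when the
    simplex constraint binds.
    """
    w, _ = optimize.nnls(profiles.T, target)
    if w.sum() > 1.0:
        k = profiles.shape[0]
        res = optimize.minimize(
            lambda v: float(np.sum((profiles.T @ v - target) ** 2)),
            x0=w / w.sum(),
            jac=lambda v: 2.0 * (profiles @ (profiles.T @ v - target)),
            bounds=[(0.0, 1.0)] * k,
            constraints=[{"type": "ineq", "fun": lambda v: 1.0 - v.sum()}],
            method="SLSQP",
            options={"maxiter": 200, "ftol": 1e-12},
        )
        w = np.clip(res.x, 0.0, None)
    sse = float(np.sum((profiles.T @ w - target) ** 2))
    return w, sse


def refit_exposures(
    catalog_row: np.ndarray | Sequence[float],
    sigs: SignatureMatrix,
    cutoff: float = 0.06,
    tol: float = 1e-3,
    sample: str = "",
) -> SignatureExposure:
    """Forward-selection signature refit of one catalog row.

    The row is normalized to channel frequencies; signatures are added
    greedily while each addition improves the SSE by at least ``tol``.
    Weights below ``cutoff`` are discarded, survivors refit once, and
    the retained weights renormalized to sum to 1.
    """
    row = np.asarray(catalog_row, dtype=float)
    if row.shape != (96,):
        raise ValueError("catalog row must have 96 channels")
    total = row.sum()
    if total <= 0:
        raise ValueError("cannot refit a zero-count catalog row")
    target = row / total
    profiles = sigs.matrix()
    names = sigs.names

    selected: list[int] = []
    sse = float(np.sum(target**2))  # empty model reconstructs nothing
    sse_path = [sse]
    while len(selected) < len(names):
        best = None
        for k in range(len(names)):
            if k in selected:
                continue
            trial = selected + [k]
            w, trial_sse = _fit_weights(target, profiles[trial])
            if best is None or trial_sse < best[1]:
                best = (trial, trial_sse, w)
        assert best is not None
        if sse - best[1] < tol:
            break
        selected, sse, weights = best
        sse_path.append(sse)

    if not selected:
        return SignatureExposure(
            sample=sample, weights={}, residual_sse=sse, sse_path=sse_path
        )

    # discard sub-cutoff weights and refit once over the survivors
    survivors = [k for k, w in zip(selected, weights) if w >= cutoff]
    if not survivors:
        survivors = [selected[int(np.argmax(weights))]]
    w, sse = _fit_weights(target, profiles[survivors])
    keep = w > 0
    survivors = [k for k, m in zip(survivors, keep) if m]
    w = w[keep]
    w = w / w.sum()
    out = {names[k]: float(wk) for k, wk in sorted(zip(survivors, w))}
    return SignatureExposure(
        sample=sample, weights=out, residual_sse=sse, sse_path=sse_path
    )


def refit_catalog(
    catalog: MutationCatalog,
    sigs: SignatureMatrix,
    cutoff: float = 0.06,
    tol: float = 1e-3,
) -> list[SignatureExposure]:
    """Refit every sample in a catalog."""
    return [
        refit_exposures(catalog.row(s), sigs, cutoff=cutoff, tol=tol, sample=s)
        for s in catalog.samples
    ]


def exposures_to_frame(exposures: Sequence[SignatureExposure]) -> pd.DataFrame:
    """Samples x signatures weight table (absent weights are 0)."""
    names = sorted({n for e in exposures for n in e.weights})
    df = pd.DataFrame(
        [[e.weights.get(n, 0.0) for n in names] for e in exposures],
        index=[e.sample for e in exposures],
        columns=names,
    )
    df.index.name = "sample"
    return df
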
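"""Within-gene cross-assay correlation evidence.

For each gene the two assays' time-courses are correlated against each
other — the *within-gene* sense: one gene, two modalities, correlation over
time — yielding a coefficient r_g and a two-sided P-value p_g^{XY}.

Replicates are either averaged per (gene, time) before correlating
(``replicate_handling="mean"``, the default, giving n = T + 1 paired
points) or all paired (time, replicate) cells are correlated directly
(``"concat"``, which requires equal replicate counts in the two assays).

Pearson P-values use the exact t transform t = r * sqrt((n-2)/(1-r^2)) on
n - 2 df.  Spearman P-values are exact (full permutation enumeration of the
rank-correlation null) for n <= 8 with untied ranks, otherwise the t
approximation on the rank correlation is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .core import AssayPair, ValidationError

__all__ = ["AssociationResult", "within_gene_correlation"]

#: Largest n for which the Spearman null is enumerated exactly (n! permutations).
SPEARMAN_EXACT_MAX_N = 8


@dataclass
class AssociationResult:
    """Per-gene correlation coefficients and P-values (p_g^XY)."""

    gene_ids: list[str]
    per_gene_r: np.ndarray
    per_gene_p: np.ndarray
    method: str
    replicate_handling: str
    n_effective: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.per_gene_r, dtype=float)
        p = np.asarray(self.per_gene_p, dtype=float)
        finite = np.isfinite(r)
        if finite.any() and np.abs(r[finite]).max() > 1 + 1e-12:
            raise ValidationError("|r| > 1 encountered")
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("correlation P-values outside [0, 1]")
        self.per_gene_r = r
        self.per_gene_p = p

    def per_gene_series(self) -> pd.Series:
        return pd.Series(
            self.per_gene_p, index=pd.Index(self.gene_ids, name="gene_id"),
            name="p_xy",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "r": self.per_gene_r,
                "p_xy": self.per_gene_p,
                "method": self.method,
                "n_effective": self.n_effective,
            }
        )


def _rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r per row of two equally shaped (G, n) matrices."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", Xc, Yc)
    den = np.sqrt(
        np.einsum("ij,ij->i", Xc, Xc) * np.einsum("ij,ij->i", Yc, Yc)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _pearson_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided P from the exact t transform of Pearson r on n-2 df."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.ones_like(r)
    ok = np.isfinite(r) & (n >= 3)
    dfree = n[ok] - 2
    rr = np.clip(r[ok], -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt(dfree / (1.0 - rr**2))
    pv = 2.0 * stats.t.sf(np.abs(t), dfree)
    pv[np.abs(rr) == 1.0] = 0.0
    p[ok] = np.clip(pv, 0.0, 1.0)
    return p


@lru_cache(maxsize=8)
def _spearman_null_abs_r(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (untied ranks)."""
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(permutations(range(n))), dtype=np.intp)
    ranks = base[perms]  # (n!, n)
    mean = (n + 1) / 2.0
    var = np.sum((base - mean) ** 2)
    num = (ranks - mean) @ (base - mean)
    return np.sort(np.abs(num / var))


def _spearman_exact_p(rho: float, n: int) -> float:
    """Two-sided exact permutation P for untied Spearman rho."""
    null = _spearman_null_abs_r(n)
    thresh = abs(rho) - 1e-12
    count = null.size - np.searchsorted(null, thresh, side="left")
    return float(count) / null.size


def _rank_rows(M: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, M)


def within_gene_correlation(
    pair: AssayPair,
    method: str = "spearman",
    replicate_handling: str = "mean",
) -> AssociationResult:
    """Correlate each gene's course in assay X with its course in assay Y.

    Genes where either side has zero variance get r = NaN and P = 1 (no
    correlation evidence, by the documented degenerate rule).
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if replicate_handling == "mean":
        X = np.nanmean(pair.x.values, axis=2)  # (G, T+1)
        Y = np.nanmean(pair.y.values, axis=2)
    elif replicate_handling == "concat":
        if pair.x.n_replicates != pair.y.n_replicates:
            raise ValidationError(
                "replicate_handling='concat' requires equal replicate "
                f"counts (got {pair.x.n_replicates} and {pair.y.n_replicates})"
            )
        G = pair.x.n_genes
        X = pair.x.values.reshape(G, -1)
        Y = pair.y.values.reshape(G, -1)
    else:
        raise ValidationError(
            f"unknown replicate_handling {replicate_handling!r}"
        )
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValidationError(
            "correlation requires complete courses after replicate handling"
        )
    n = X.shape[1]
    if n < 3:
        raise ValidationError("need at least 3 paired points per gene")

    degenerate = (np.ptp(X, axis=1) == 0) | (np.ptp(Y, axis=1) == 0)

    if method == "pearson":
        r = _rowwise_pearson(X, Y)
        p = _pearson_p(r, np.full(len(r), n))
    else:
        RX = _rank_rows(X)
        RY = _rank_rows(Y)
        r = _rowwise_pearson(RX, RY)
        p = _pearson_p(r, np.full(len(r), n))
        if n <= SPEARMAN_EXACT_MAX_N:
            # exact enumeration gene-by-gene where ranks are untied
            untied = np.array(
                [
                    len(set(RX[g])) == n and len(set(RY[g])) == n
                    for g in range(len(r))
                ]
            )
            for g in np.flatnonzero(untied & ~degenerate & np.isfinite(r)):
                p[g] = _spearman_exact_p(float(r[g]), n)

    r = np.where(degenerate, np.nan, r)
    p = np.where(degenerate, 1.0, p)
    return AssociationResult(
        gene_ids=list(pair.gene_ids),
        per_gene_r=r,
        per_gene_p=np.clip(p, 0.0, 1.0),
        method=method,
        replicate_handling=replicate_handling,
        n_effective=np.full(len(r), n, dtype=int),
    )
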
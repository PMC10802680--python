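"""Evidence combination, gene ranking, and selection rules.

Per gene, three P-values are combined: p_x and p_y (differential
expression in each assay) and p_xy (cross-assay within-gene correlation).

* **Edgington's method** sums them, S_g = p_x + p_y + p_xy, and ranks by the
  smallest sum.  The sum of k independent Uniform(0,1) variables follows
  the Irwin--Hall distribution, whose CDF turns S_g into a combined
  P-value; this is a strictly monotone transform of the sum for fixed k, so
  ranking by either is identical.  The sum is sensitive to any single large
  P-value: one p near 1 pushes S_g above 1 no matter how small the others
  are, which is the property that screens out genes that are flat in an
  assay or discordant across assays.
* **Fisher's method** uses X = -2 * sum(ln p), referred to chi-square with
  2k degrees of freedom.  It is dominated by the smallest P-value, so a
  single tiny p can carry a gene regardless of the other evidence.

The two selection rules are top-n on the ranked list (the method's own
rule) and the commonDE baseline G_tau = {g : p_x < tau_x and p_y < tau_y}
(strict inequalities), which ignores correlation entirely.

Combined P-values assume the three inputs are independent; for correlated
inputs they remain monotone evidence scores rather than calibrated
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, factorial, fsum

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .de_tests import DEResult, P_FLOOR

__all__ = [
    "GeneEvidence",
    "SelectionResult",
    "edgington_sum",
    "irwin_hall_cdf",
    "edgington_combined_p",
    "fisher_combined",
    "build_evidence",
    "rank_genes",
    "select_top_n",
    "select_commonDE",
    "commonDE_tau_for_size",
]

EVIDENCE_COLUMNS = [
    "gene_id", "p_x", "p_y", "p_xy", "r",
    "s_edgington", "p_edgington", "s_fisher", "p_fisher", "rank",
]


@dataclass
class GeneEvidence:
    """Per-gene evidence table.

    Wraps a DataFrame with columns ``gene_id, p_x, p_y, p_xy, r,
    s_edgington, p_edgington, s_fisher, p_fisher`` (plus ``rank`` once
    ranked).  Row order is the stable input gene order until
    :func:`rank_genes` reorders it.
    """

    table: pd.DataFrame
    ranked_by: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in EVIDENCE_COLUMNS[:-1] if c not in self.table.columns]
        if missing:
            raise ValidationError(f"evidence table missing columns: {missing}")
        for col in ("p_x", "p_y", "p_xy"):
            bad = ~self.table[col].between(0.0, 1.0)
            if bad.any():
                g = self.table.loc[bad, "gene_id"].iloc[0]
                raise ValidationError(
                    f"{col} outside [0, 1] for gene {g}"
                )
        nn = self.table[["p_x", "p_y", "p_xy", "s_edgington"]].isna().any(axis=1)
        if nn.any():
            g = self.table.loc[nn, "gene_id"].iloc[0]
            raise ValidationError(f"missing evidence fields for gene {g}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SelectionResult:
    """An ordered gene selection plus the rule and evidence behind it."""

    method: str
    parameters: dict
    selected_gene_ids: list[str]
    evidence: pd.DataFrame

    def __len__(self) -> int:
        return len(self.selected_gene_ids)


def _check_unit(p, name: str) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValidationError(f"{name} must lie in [0, 1]")
    return arr


def edgington_sum(*p_values) -> np.ndarray | float:
    """Sum of k >= 2 P-values (elementwise over arrays), S = sum_i p_i."""
    if len(p_values) < 2:
        raise ValidationError("edgington_sum needs at least 2 P-values")
    arrs = [_check_unit(p, f"p[{i}]") for i, p in enumerate(p_values)]
    total = np.add.reduce(np.broadcast_arrays(*arrs))
    return float(total) if np.ndim(total) == 0 else total


def irwin_hall_cdf(s, k: int):
    """CDF of the sum of k independent Uniform(0,1) variables.

    P(U_1 + ... + U_k <= s) = (1/k!) * sum_{j=0..floor(s)}
    (-1)^j C(k,j) (s-j)^k.  Evaluated directly for s <= k/2 and by the
    reflection 1 - F(k - s) above, so the symmetry F(s) + F(k - s) = 1
    holds exactly in floating point.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    s_arr = np.asarray(s, dtype=float)
    if ((s_arr < 0) | (s_arr > k)).any():
        raise ValidationError(f"sum statistic outside [0, {k}]")

    def _lower(v: float) -> float:
        # direct alternating series; v <= k/2 keeps the terms benign
        terms = [
            (-1) ** j * comb(k, j) * (v - j) ** k
            for j in range(int(np.floor(v)) + 1)
        ]
        return fsum(terms) / factorial(k)

    def _one(v: float) -> float:
        if v == k / 2.0:
            return 0.5
        if v < k / 2.0:
            return min(max(_lower(v), 0.0), 1.0)
        return 1.0 - min(max(_lower(k - v), 0.0), 1.0)

    out = np.vectorize(_one, otypes=[float])(s_arr)
    return float(out) if np.ndim(s) == 0 else out


def edgington_combined_p(s, k: int = 3):
    """Edgington combined P-value: the Irwin--Hall CDF at the sum.

    For s <= 1 this is the closed form s^k / k!.
    """
    return irwin_hall_cdf(s, k)


def fisher_combined(*p_values):
    """Fisher's method: X = -2 * sum(ln p), P = chi2.sf(X, 2k).

    Zero P-values are floored at ``P_FLOOR`` before the log (a zero would
    give an infinite statistic); the floor corresponds to the smallest
    P-value the pipeline ever writes.
    Returns ``(statistic, combined_p)`` elementwise.
    """
    if len(p_values) < 2:
        raise ValidationError("fisher_combined needs at least 2 P-values")
    arrs = [_check_unit(p, f"p[{i}]") for i, p in enumerate(p_values)]
    floored = [np.maximum(a, P_FLOOR) for a in arrs]
    stat = -2.0 * np.add.reduce(
        np.broadcast_arrays(*[np.log(a) for a in floored])
    )
    p = stats.chi2.sf(stat, 2 * len(p_values))
    if np.ndim(stat) == 0:
        return float(stat), float(p)
    return stat, p


def build_evidence(
    de_x: DEResult, de_y: DEResult, assoc
) -> GeneEvidence:
    """Join the three evidence sources into one per-gene table."""
    if de_x.gene_ids != de_y.gene_ids or de_x.gene_ids != list(assoc.gene_ids):
        raise ValidationError(
            "DE and association results must share an identical gene list"
        )
    p_x = np.asarray(de_x.per_gene_p, dtype=float)
    p_y = np.asarray(de_y.per_gene_p, dtype=float)
    p_xy = np.asarray(assoc.per_gene_p, dtype=float)
    s_edg = edgington_sum(p_x, p_y, p_xy)
    p_edg = edgington_combined_p(s_edg, k=3)
    s_fis, p_fis = fisher_combined(p_x, p_y, p_xy)
    table = pd.DataFrame(
        {
            "gene_id": de_x.gene_ids,
            "p_x": p_x,
            "p_y": p_y,
            "p_xy": p_xy,
            "r": np.asarray(assoc.per_gene_r, dtype=float),
            "s_edgington": s_edg,
            "p_edgington": p_edg,
            "s_fisher": s_fis,
            "p_fisher": p_fis,
        }
    )
    return GeneEvidence(table=table)


def rank_genes(evidence: GeneEvidence, method: str = "edgington") -> GeneEvidence:
    """Rank genes by combined evidence, smallest (most significant) first.

    Sort key: ``s_edgington`` (method="edgington") or ``p_fisher``
    (method="fisher"); ties broken by smaller ``p_xy``, then gene_id.
    Ranks 1..G are assigned in the sorted order.
    """
    if method == "edgington":
        key = "s_edgington"
    elif method == "fisher":
        key = "p_fisher"
    else:
        raise ValidationError(f"unknown ranking method {method!r}")
    tbl = (
        evidence.table.sort_values(
            [key, "p_xy", "gene_id"], kind="mergesort"
        )
        .reset_index(drop=True)
        .copy()
    )
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    return GeneEvidence(table=tbl, ranked_by=method)


def select_top_n(ranked: GeneEvidence, n: int) -> SelectionResult:
    """The n genes with the smallest combined summary (rank order)."""
    if "rank" not in ranked.table.columns or ranked.table["rank"].isna().any():
        raise ValidationError("select_top_n requires a ranked evidence table")
    G = len(ranked)
    if not 1 <= n <= G:
        raise ValidationError(f"n must be in [1, {G}], got {n}")
    sel = ranked.table.nsmallest(n, "rank")
    return SelectionResult(
        method=f"mintde_{ranked.ranked_by or 'edgington'}",
        parameters={"n": int(n)},
        selected_gene_ids=list(sel["gene_id"]),
        evidence=sel.reset_index(drop=True),
    )


#: The top-n sweep reported by the evaluation workflow.
TOP_N_SWEEP = (10, 20, 50, 100, 200, 500, 1000, 2000)


def select_commonDE(
    de_x: DEResult, de_y: DEResult, tau_x: float, tau_y: float
) -> SelectionResult:
    """commonDE baseline: genes with p_x < tau_x AND p_y < tau_y (strict).

    Selected genes are ordered by max(p_x, p_y) ascending, so truncating
    the list is equivalent to tightening a shared threshold.
    """
    if not (0 < tau_x <= 1) or not (0 < tau_y <= 1):
        raise ValidationError("thresholds must lie in (0, 1]")
    if de_x.gene_ids != de_y.gene_ids:
        raise ValidationError("commonDE requires identical gene sets")
    p_x = np.asarray(de_x.per_gene_p, dtype=float)
    p_y = np.asarray(de_y.per_gene_p, dtype=float)
    keep = (p_x < tau_x) & (p_y < tau_y)
    tbl = pd.DataFrame(
        {
            "gene_id": np.asarray(de_x.gene_ids)[keep],
            "p_x": p_x[keep],
            "p_y": p_y[keep],
            "p_max": np.maximum(p_x, p_y)[keep],
        }
    ).sort_values(["p_max", "gene_id"], kind="mergesort")
    return SelectionResult(
        method="commonDE",
        parameters={"tau_x": float(tau_x), "tau_y": float(tau_y)},
        selected_gene_ids=list(tbl["gene_id"]),
        evidence=tbl.drop(columns="p_max").reset_index(drop=True),
    )


def commonDE_tau_for_size(
    de_x: DEResult, de_y: DEResult, n: int
) -> float:
    """Shared threshold tau whose commonDE selection has exactly n genes.

    Mirrors choosing tau to hit a target selection size: tau is placed just
    above the n-th smallest max(p_x, p_y) (strict-< semantics).
    """
    p_max = np.maximum(
        np.asarray(de_x.per_gene_p, float), np.asarray(de_y.per_gene_p, float)
    )
    order = np.sort(p_max)
    if not 1 <= n <= len(order):
        raise ValidationError(f"n must be in [1, {len(order)}]")
    nth = order[n - 1]
    above = order[n] if n < len(order) else 1.0
    tau = nth + 0.5 * (above - nth) if above > nth else np.nextafter(nth, 1.0)
    return float(min(tau, 1.0))
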
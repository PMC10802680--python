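"""Evaluation statistics for gene selections.

Implements the benchmark summaries used to compare selection rules:

* per-gene **range**, max - min of the LFC over all (time, replicate)
  cells — large for genuinely differentially expressed genes;
* per-gene **coefficient of variation** across replicates, averaged over
  post-baseline timepoints — small for genes whose replicates agree;
* **pseudo-assay** construction, splitting one assay's biological
  replicates into two disjoint groups that act as a known-concordant assay
  pair for method evaluation;
* **selection recovery** against planted truth (sensitivity, specificity,
  precision).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AssayPair, TimeCourseAssay, ValidationError

__all__ = [
    "gene_range",
    "gene_cv",
    "pseudo_assay_split",
    "selection_recovery",
]

#: Timepoint replicate means closer to zero than this are excluded from CV
#: (the ratio sd/mean blows up as the mean crosses zero on the LFC scale).
MEAN_FLOOR_DEFAULT = 1e-8


def gene_range(assay: TimeCourseAssay) -> pd.Series:
    """range(x_g) = max over (t, b) minus min over (t, b), baseline included."""
    vals = assay.values
    rng = np.nanmax(vals, axis=(1, 2)) - np.nanmin(vals, axis=(1, 2))
    return pd.Series(rng, index=assay.gene_index(), name="range")


def gene_cv(
    assay: TimeCourseAssay, mean_floor: float = MEAN_FLOOR_DEFAULT
) -> pd.DataFrame:
    """Replicate coefficient of variation per gene.

    cv(x_g) = average over post-baseline timepoints of sd(x_tg)/mean(x_tg),
    with sd the population (1/B) standard deviation over replicates and
    mean the replicate mean.  Timepoints with |mean| < ``mean_floor`` are
    excluded from the average and counted in ``n_excluded_timepoints``; a
    gene with every timepoint excluded gets CV = NaN.

    Returns a frame with columns ``cv`` and ``n_excluded_timepoints``.
    """
    vals = assay.values
    G, nt, B = vals.shape
    if B < 2:
        raise ValidationError("CV needs at least 2 replicates")
    post = vals[:, 1:, :]  # baseline excluded, per the printed formula
    mean = np.nanmean(post, axis=2)
    sd = np.sqrt(np.nanmean((post - mean[:, :, None]) ** 2, axis=2))
    include = np.abs(mean) >= mean_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(include, sd / mean, np.nan)
    n_inc = include.sum(axis=1)
    with np.errstate(invalid="ignore"):
        cv = np.where(n_inc > 0, np.nansum(ratio, axis=1) / n_inc, np.nan)
    return pd.DataFrame(
        {
            "cv": cv,
            "n_excluded_timepoints": (nt - 1) - n_inc,
        },
        index=assay.gene_index(),
    )


def pseudo_assay_split(
    assay: TimeCourseAssay,
    group_a: list[str],
    group_b: list[str],
) -> AssayPair:
    """Split one assay's replicates into two disjoint pseudo-assays.

    The two halves behave as an assay pair with known concordance (they are
    biological replicates of the same courses), suitable as input to the
    full pipeline for benchmarking.
    """
    ga = [str(r) for r in group_a]
    gb = [str(r) for r in group_b]
    if not ga or not gb:
        raise ValidationError("both replicate groups must be nonempty")
    if set(ga) & set(gb):
        raise ValidationError(
            f"replicate groups overlap: {sorted(set(ga) & set(gb))}"
        )
    known = set(assay.replicate_ids)
    unknown = [r for r in ga + gb if r not in known]
    if unknown:
        raise ValidationError(f"unknown replicate labels: {unknown}")
    pos = {r: i for i, r in enumerate(assay.replicate_ids)}

    def _sub(group: list[str], suffix: str) -> TimeCourseAssay:
        idx = [pos[r] for r in group]
        return TimeCourseAssay(
            assay_name=f"{assay.assay_name}_{suffix}",
            gene_ids=list(assay.gene_ids),
            times=assay.times.copy(),
            replicate_ids=list(group),
            values=assay.values[:, :, idx],
            missing_policy=assay.missing_policy,
        )

    return AssayPair(x=_sub(ga, "a"), y=_sub(gb, "b"))


def selection_recovery(
    selected_gene_ids,
    truth: pd.DataFrame,
    positive_classes,
) -> dict:
    """Confusion-matrix rates of a selection against planted truth.

    ``truth`` must have columns ``gene_id`` and ``gene_class``; genes whose
    class is in ``positive_classes`` are the positives.  Returns
    sensitivity, specificity and precision (NaN when undefined, e.g.
    precision of an empty selection).
    """
    if not {"gene_id", "gene_class"}.issubset(truth.columns):
        raise ValidationError("truth needs gene_id and gene_class columns")
    universe = set(truth["gene_id"])
    selected = set(map(str, selected_gene_ids))
    stray = selected - universe
    if stray:
        raise ValidationError(
            f"selection contains genes outside the truth universe: "
            f"{sorted(stray)[:5]}"
        )
    positive = set(
        truth.loc[truth["gene_class"].isin(set(positive_classes)), "gene_id"]
    )
    tp = len(selected & positive)
    fp = len(selected - positive)
    fn = len(positive - selected)
    tn = len(universe) - tp - fp - fn
    return {
        "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
        "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
        "precision": tp / (tp + fp) if (tp + fp) else np.nan,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }
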
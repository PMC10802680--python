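"""Per-assay differential-expression evidence.

Two routes to a per-gene DE P-value for a time-course assay measured in LFC
against the baseline time point:

* **Pairwise route** — for each post-baseline time t, a two-sided
  equal-variance two-sample t-test of the baseline replicates against the
  replicates at t.  The per-gene residual variance is pooled across all
  time-point groups of that gene (the model assumes one sigma_g^2 per gene,
  so the pooled estimate has (T+1)(B-1) degrees of freedom; at T=1 this is
  exactly the textbook pooled two-sample t with 2B-2 df).  Optionally the
  variance is shrunk across genes by the empirical-Bayes scheme of
  :func:`fit_moderation`, which adds the prior degrees of freedom d0 to the
  t reference distribution.  The per-gene summary p_g is the minimum of the
  per-timepoint P-values.
* **Spline route** — per gene, an ordinary-least-squares fit of all
  (T+1)*B replicate values on an intercept plus a cubic B-spline basis of
  time with ``spline_df`` columns, summarized by the F-test of the joint
  null that every spline coefficient is zero.

Degenerate inputs follow a documented continuity rule: identical constant
groups give P = 1 (no evidence), zero residual variance with a nonzero
signal gives P = 0.  P-values written to files or fed into log-based
combination are floored at :data:`P_FLOOR`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.interpolate import BSpline

from .core import TimeCourseAssay, ValidationError

__all__ = [
    "DEResult",
    "ModerationFit",
    "pairwise_timepoint_tests",
    "fit_moderation",
    "spline_f_test",
    "P_FLOOR",
]

#: Smallest P-value ever written to output files (Fisher's method needs
#: log p, so exact zeros are floored here).
P_FLOOR = 1e-300

#: Default number of spline basis columns ("spline of order 5").
SPLINE_DF_DEFAULT = 5


@dataclass
class DEResult:
    """Differential-expression P-values for one assay.

    ``per_timepoint_p`` is a ``(G, T)`` array for the pairwise methods
    (columns are the post-baseline times) and ``None`` for the spline
    method.  ``per_gene_p`` is the min-P summary (pairwise) or the F-test
    P-value (spline).  ``statistics`` holds the t statistics (pairwise,
    ``(G, T)``) or F statistics (spline, ``(G,)``); ``df_used`` the matching
    degrees of freedom.
    """

    assay_name: str
    gene_ids: list[str]
    method: str
    per_gene_p: np.ndarray
    per_timepoint_p: np.ndarray | None = None
    tested_times: np.ndarray | None = None
    statistics: np.ndarray | None = None
    df_used: np.ndarray | None = None
    moderation: "ModerationFit | None" = None

    def __post_init__(self) -> None:
        self.per_gene_p = np.asarray(self.per_gene_p, dtype=float)
        if not ((self.per_gene_p >= 0) & (self.per_gene_p <= 1)).all():
            raise ValidationError("per-gene P-values outside [0, 1]")
        if self.per_timepoint_p is not None:
            ptp = np.asarray(self.per_timepoint_p, dtype=float)
            if not ((ptp >= 0) & (ptp <= 1)).all():
                raise ValidationError("per-timepoint P-values outside [0, 1]")
            self.per_timepoint_p = ptp

    def per_gene_series(self) -> pd.Series:
        return pd.Series(
            self.per_gene_p, index=pd.Index(self.gene_ids, name="gene_id"),
            name=f"p_{self.assay_name}",
        )

    def to_frame(self) -> pd.DataFrame:
        """Table matching the on-disk layout for this result."""
        df = pd.DataFrame({"gene_id": self.gene_ids})
        df["assay"] = self.assay_name
        df["method"] = self.method
        if self.per_timepoint_p is not None:
            for j, t in enumerate(self.tested_times):
                df[f"p_t{t:g}"] = np.maximum(self.per_timepoint_p[:, j], P_FLOOR)
        if self.method == "spline" and self.statistics is not None:
            df["f_stat"] = self.statistics
        df["p_gene"] = np.maximum(self.per_gene_p, P_FLOOR)
        return df


@dataclass
class ModerationFit:
    """Empirical-Bayes variance moderation parameters.

    ``d0`` is the prior degrees of freedom (``inf`` when the observed
    variance dispersion is at or below the pure-F expectation), ``s0_sq``
    the prior variance, and ``posterior_s_sq`` the per-gene shrunken
    variance (d0*s0^2 + df*s_g^2) / (d0 + df).
    """

    d0: float
    s0_sq: float
    posterior_s_sq: np.ndarray
    df: float

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValidationError("d0 must be nonnegative")
        if not self.s0_sq > 0:
            raise ValidationError("s0_sq must be positive")


def _trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_moderation(sample_vars: np.ndarray, df: float) -> ModerationFit:
    """Estimate (d0, s0^2) by moment-matching log sample variances.

    Under the hierarchical model s_g^2 | sigma_g^2 ~ sigma_g^2 * chi2_df/df
    with 1/sigma_g^2 ~ (1/s0^2) * chi2_d0/d0, the marginal of s_g^2 is a
    scaled F(df, d0).  Matching the mean and variance of log s_g^2 against
    digamma/trigamma moments yields the standard empirical-Bayes estimates;
    d0 is recovered through a trigamma inverse.  Genes with nonpositive
    sample variance are excluded from fitting but still shrunken.
    """
    sv = np.asarray(sample_vars, dtype=float)
    if df <= 0:
        raise ValidationError("residual df must be positive")
    ok = np.isfinite(sv) & (sv > 0)
    if ok.sum() < 2:
        raise ValidationError(
            "need at least 2 genes with positive sample variance"
        )
    z = np.log(sv[ok])
    if np.ptp(z) == 0.0:
        # all variances identical: no dispersion at all, so the prior is a
        # point mass at the common value (the chi2 bias correction assumes
        # sampling noise that is evidently absent here)
        s0_sq = float(sv[ok][0])
        return ModerationFit(
            d0=np.inf, s0_sq=s0_sq,
            posterior_s_sq=_posterior_var(sv, df, np.inf, s0_sq), df=df,
        )
    # e_g is log s_g^2 corrected for the chi2_df sampling bias
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(
            np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    posterior = _posterior_var(sv, df, d0, s0_sq)
    return ModerationFit(d0=d0, s0_sq=s0_sq, posterior_s_sq=posterior, df=df)


def _posterior_var(
    sample_vars: np.ndarray, df: float, d0: float, s0_sq: float
) -> np.ndarray:
    sv = np.where(np.isfinite(sample_vars) & (sample_vars > 0), sample_vars, 0.0)
    if np.isinf(d0):
        return np.full_like(sv, s0_sq)
    if d0 == 0:
        return sv.copy()
    return (d0 * s0_sq + df * sv) / (d0 + df)


def pairwise_timepoint_tests(
    assay: TimeCourseAssay,
    moderate: bool = False,
    d0_override: float | None = None,
) -> DEResult:
    """Per-timepoint two-sample tests of each time t > baseline vs baseline.

    Uses the per-gene residual variance pooled over all time-point groups
    (equal-variance model, one sigma_g per gene).  With ``moderate=True``
    the pooled variances are shrunk across genes via :func:`fit_moderation`
    and the t reference gains d0 degrees of freedom.  ``d0_override`` forces
    a fixed prior df (0 disables shrinkage exactly; ``inf`` pins every
    variance at s0^2), mainly for diagnostics.

    The per-gene summary is the minimum P-value over the T contrasts.
    """
    vals = assay.values
    G, nt, B = vals.shape
    if B < 2:
        raise ValidationError(
            "variance not estimable: need at least 2 replicates"
        )
    means = np.nanmean(vals, axis=2)  # (G, nt)
    counts = np.sum(~np.isnan(vals), axis=2)  # (G, nt)
    if (counts < 2).any():
        g, t = map(int, np.argwhere(counts < 2)[0])
        raise ValidationError(
            f"variance not estimable for gene {assay.gene_ids[g]} at time "
            f"{assay.times[t]:g}: fewer than 2 replicates present"
        )
    resid = vals - means[:, :, None]
    ss = np.nansum(resid**2, axis=(1, 2))  # (G,)
    df_resid = (counts - 1).sum(axis=1).astype(float)  # (G,)
    s2 = ss / df_resid

    if moderate:
        df_common = float(np.median(df_resid))
        if d0_override is not None:
            if d0_override == 0:
                s0 = float(np.mean(s2[s2 > 0])) if (s2 > 0).any() else 1.0
                mod = ModerationFit(
                    d0=0.0, s0_sq=s0,
                    posterior_s_sq=s2.copy(), df=df_common,
                )
            elif np.isinf(d0_override):
                s0 = fit_moderation(s2, df_common).s0_sq
                mod = ModerationFit(
                    d0=np.inf, s0_sq=s0,
                    posterior_s_sq=np.full_like(s2, s0), df=df_common,
                )
            else:
                s0 = fit_moderation(s2, df_common).s0_sq
                mod = ModerationFit(
                    d0=float(d0_override), s0_sq=s0,
                    posterior_s_sq=_posterior_var(
                        s2, df_common, float(d0_override), s0
                    ),
                    df=df_common,
                )
        else:
            mod = fit_moderation(s2, df_common)
        use_s2 = mod.posterior_s_sq
        df_t = df_resid + (0.0 if np.isinf(mod.d0) else mod.d0)
        df_is_inf = np.isinf(mod.d0)
        method = "pairwise_moderated"
    else:
        mod = None
        use_s2 = s2
        df_t = df_resid
        df_is_inf = False
        method = "pairwise"

    delta = means[:, 1:] - means[:, [0]]  # (G, T)
    n_base = counts[:, [0]].astype(float)
    n_t = counts[:, 1:].astype(float)
    se = np.sqrt(use_s2[:, None] * (1.0 / n_base + 1.0 / n_t))

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = delta / se
        # degenerate cells: zero variance
        zero_se = se == 0
        tstat = np.where(zero_se & (delta == 0), 0.0, tstat)
        tstat = np.where(zero_se & (delta != 0), np.sign(delta) * np.inf, tstat)

    if df_is_inf:
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_t[:, None])
    p = np.where(zero_se & (delta == 0), 1.0, p)
    p = np.where(zero_se & (delta != 0), 0.0, p)
    p = np.clip(p, 0.0, 1.0)

    return DEResult(
        assay_name=assay.assay_name,
        gene_ids=list(assay.gene_ids),
        method=method,
        per_gene_p=p.min(axis=1),
        per_timepoint_p=p,
        tested_times=assay.times[1:].copy(),
        statistics=tstat,
        df_used=np.broadcast_to(df_t[:, None], p.shape).copy(),
        moderation=mod,
    )


def bspline_design(times: np.ndarray, df: int, degree: int = 3) -> np.ndarray:
    """Cubic B-spline basis of time with ``df`` columns (no intercept).

    Interior knots sit at quantiles of the distinct observed times; the
    full clamped basis has df + 1 columns summing to one, so the first is
    dropped in favour of the model intercept.
    """
    t = np.asarray(times, dtype=float)
    uniq = np.unique(t)
    n_inner = df - degree
    if n_inner < 0:
        raise ValidationError(
            f"spline_df={df} too small for degree-{degree} basis"
        )
    inner = (
        np.quantile(uniq, np.linspace(0, 1, n_inner + 2)[1:-1])
        if n_inner > 0
        else np.array([])
    )
    knots = np.r_[[uniq[0]] * (degree + 1), inner, [uniq[-1]] * (degree + 1)]
    basis = BSpline.design_matrix(t, knots, degree).toarray()
    return basis[:, 1:]


def spline_f_test(
    assay: TimeCourseAssay, spline_df: int = SPLINE_DF_DEFAULT
) -> DEResult:
    """Whole-course F-test per gene against a flat trajectory.

    OLS of all (T+1)*B replicate values on intercept + B-spline basis of
    time; per-gene P is the F(spline_df, N - spline_df - 1) tail of the
    joint null that all spline coefficients vanish.  A gene that is exactly
    constant gives the 0/0 form and returns P = 1; an exact spline fit with
    signal returns P = 0.
    """
    vals = assay.values
    G, nt, B = vals.shape
    if nt <= spline_df:
        raise ValidationError(
            f"need more distinct times ({nt}) than spline_df ({spline_df})"
        )
    if np.isnan(vals).any():
        raise ValidationError(
            "spline_f_test requires complete data (missing cells present)"
        )
    n_obs = nt * B
    df2 = n_obs - spline_df - 1
    if df2 < 1:
        raise ValidationError(
            f"insufficient residual df: N={n_obs}, spline_df={spline_df}"
        )
    t_long = np.repeat(assay.times, B)
    X = np.column_stack([np.ones(n_obs), bspline_design(t_long, spline_df)])
    Y = vals.reshape(G, n_obs).T  # (N, G)
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    centered = Y - Y.mean(axis=0)
    rss0 = np.einsum("ij,ij->j", centered, centered)
    model_ss = np.maximum(rss0 - rss, 0.0)

    scale = np.maximum(rss0, 1.0)  # relative tolerance for exact fits
    tol = np.finfo(float).eps * n_obs * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = (model_ss / spline_df) / (rss / df2)
    p = stats.f.sf(fstat, spline_df, df2)
    flat = rss0 <= tol  # constant gene: 0/0
    exact = (rss <= tol) & ~flat  # perfect fit with signal
    fstat = np.where(flat, 0.0, fstat)
    p = np.where(flat, 1.0, p)
    p = np.where(exact, 0.0, p)
    p = np.clip(p, 0.0, 1.0)
    return DEResult(
        assay_name=assay.assay_name,
        gene_ids=list(assay.gene_ids),
        method="spline",
        per_gene_p=p,
        per_timepoint_p=None,
        tested_times=None,
        statistics=fstat,
        df_used=np.full(G, float(df2)),
        moderation=None,
    )


def sidak_adjust_minp(min_p: np.ndarray, n_tests: int) -> np.ndarray:
    """Optional Sidak adjustment 1 - (1 - min_p)^T for the min-P summary.

    Off by default throughout the pipeline; the raw minimum matches the
    method's printed definition.
    """
    return 1.0 - (1.0 - np.asarray(min_p, dtype=float)) ** n_tests
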
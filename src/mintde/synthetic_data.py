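"""Synthetic paired time-course assays with planted truth.

The generator emulates the shape of a paired transcriptome/proteome
embryogenesis time-course — by default 14 time points (hourly for the
first six hours, then every two hours to twenty) with four biological
replicates per assay — under the additive noise model

    x_tg(b) = mu_tg + eps,   eps ~ N(0, sigma_g^2),

where mu_tg is a smooth per-gene mean trajectory with mu = 0 at baseline
(LFC convention) and sigma_g is a per-gene replicate noise scale, shared
between the two assays.

Gene classes plant the structure the ranking methods are meant to
distinguish:

=========================  ==========================================
class                      meaning
=========================  ==========================================
null                       flat in both assays (noise only)
de_x_only                  strong trajectory in X, flat in Y
de_y_only                  strong trajectory in Y, flat in X
de_both_uncorrelated       strong but independent trajectories
de_both_correlated         one shared trajectory, strong in both
correlated_moderate_de     shared trajectory, strong in X but only
                           moderate amplitude in Y — concordant across
                           assays yet weakly differentially expressed
                           in one of them, the case a per-assay
                           threshold intersection misses
=========================  ==========================================

Correlated classes share one template (sign-flipped half the time, so the
target correlation is +1 or -1); the uncorrelated-DE class draws an
independent random smooth curve per assay (random weights over the
template library) because any fixed template pair would itself be strongly
(anti)correlated.  All draws come from a single seeded generator stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import AssayPair, TimeCourseAssay, ValidationError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_pair",
    "default_paper_shape",
    "GENE_CLASSES",
    "CORRELATED_CLASSES",
]

GENE_CLASSES = (
    "null",
    "de_x_only",
    "de_y_only",
    "de_both_uncorrelated",
    "de_both_correlated",
    "correlated_moderate_de",
)

#: Classes planted with a shared cross-assay trajectory (|target r| = 1).
CORRELATED_CLASSES = ("de_both_correlated", "correlated_moderate_de")

#: Hourly sampling for six hours post-baseline, then every two hours to 20.
EMBRYOGENESIS_TIMES = (
    0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0
)


@dataclass
class SimulationConfig:
    """Parameters of the paired-assay simulator.

    ``sigma`` is the replicate noise sd in LFC units; with
    ``sigma_gene_varying=True`` each gene's variance is drawn from a
    scaled inverse-chi-square prior (sigma^2 * d0 / chi2_d0, d0 =
    ``sigma_prior_df``), exercising variance moderation.  Amplitudes are
    peak |LFC| of the planted trajectories.
    """

    G: int = 2000
    times: tuple = EMBRYOGENESIS_TIMES
    B_x: int = 4
    B_y: int = 4
    sigma: float = 0.5
    sigma_gene_varying: bool = False
    sigma_prior_df: float = 8.0
    class_fractions: dict = field(
        default_factory=lambda: {
            "null": 0.85,
            "de_x_only": 0.03,
            "de_y_only": 0.03,
            "de_both_uncorrelated": 0.03,
            "de_both_correlated": 0.03,
            "correlated_moderate_de": 0.03,
        }
    )
    amplitude_strong: float = 3.0
    amplitude_moderate: float = 1.5
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.G < 1 or self.B_x < 1 or self.B_y < 1:
            raise ValidationError("G, B_x, B_y must be >= 1")
        if len(self.times) < 2 or not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be >= 2 strictly increasing values")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.amplitude_strong <= 0 or self.amplitude_moderate <= 0:
            raise ValidationError("amplitudes must be positive")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown gene classes: {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.class_fractions.values()):
            raise ValidationError("class fractions must be nonnegative")
        return self

    def to_json(self) -> str:
        d = asdict(self)
        d["times"] = list(d["times"])
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Planted per-gene ground truth.

    ``table`` columns: gene_id, gene_class, amplitude_x, amplitude_y,
    template, target_r.
    """

    table: pd.DataFrame
    config: SimulationConfig

    def genes_of(self, *classes: str) -> list[str]:
        sel = self.table["gene_class"].isin(set(classes))
        return list(self.table.loc[sel, "gene_id"])


# -- trajectory template library -------------------------------------------
# Each template maps normalized time u in [0, 1] to a curve with f(0) = 0
# and max |f| = 1, so amplitude scales are peak LFC.

def _sigmoid_rise(u: np.ndarray) -> np.ndarray:
    raw = 1.0 / (1.0 + np.exp(-12.0 * (u - 0.5)))
    return (raw - raw[0]) / (raw[-1] - raw[0])


def _transient_pulse(u: np.ndarray) -> np.ndarray:
    raw = np.exp(-(((u - 0.4) / 0.15) ** 2))
    raw = raw - raw[0]
    return raw / np.max(np.abs(raw))


def _monotone_decay(u: np.ndarray) -> np.ndarray:
    raw = -(1.0 - np.exp(-3.0 * u)) / (1.0 - np.exp(-3.0))
    return raw / np.max(np.abs(raw))


TEMPLATES = {
    "sigmoid_rise": _sigmoid_rise,
    "transient_pulse": _transient_pulse,
    "monotone_decay": _monotone_decay,
}
TEMPLATE_NAMES = tuple(TEMPLATES)


def _template_matrix(times: np.ndarray) -> np.ndarray:
    u = (times - times[0]) / (times[-1] - times[0])
    return np.stack([TEMPLATES[name](u) for name in TEMPLATE_NAMES])


def _random_smooth_curve(rng: np.random.Generator, tmpl: np.ndarray) -> np.ndarray:
    """Random unit-peak smooth curve: N(0,1) mix over the template library."""
    while True:
        w = rng.standard_normal(len(tmpl))
        curve = w @ tmpl
        peak = np.max(np.abs(curve))
        if peak > 1e-8:
            return curve / peak


def simulate_pair(config: SimulationConfig) -> tuple[AssayPair, SyntheticTruth]:
    """Draw one paired synthetic dataset plus its planted truth.

    Fully reproducible from ``config.seed``; the same config yields
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.times, dtype=float)
    G, nt = config.G, len(times)
    tmpl = _template_matrix(times)

    classes = rng.choice(
        list(config.class_fractions),
        size=G,
        p=list(config.class_fractions.values()),
    )
    gene_ids = [f"g{i:05d}" for i in range(G)]

    if config.sigma_gene_varying:
        d0 = config.sigma_prior_df
        sigma_g = config.sigma * np.sqrt(d0 / rng.chisquare(d0, size=G))
    else:
        sigma_g = np.full(G, config.sigma)

    mu_x = np.zeros((G, nt))
    mu_y = np.zeros((G, nt))
    amp_x = np.zeros(G)
    amp_y = np.zeros(G)
    template = np.full(G, "flat", dtype=object)
    target_r = np.zeros(G)

    for g in range(G):
        cls = classes[g]
        if cls == "null":
            continue
        if cls in ("de_x_only", "de_y_only"):
            name = TEMPLATE_NAMES[rng.integers(len(TEMPLATE_NAMES))]
            curve = tmpl[TEMPLATE_NAMES.index(name)]
            template[g] = name
            if cls == "de_x_only":
                amp_x[g] = config.amplitude_strong
                mu_x[g] = amp_x[g] * curve
            else:
                amp_y[g] = config.amplitude_strong
                mu_y[g] = amp_y[g] * curve
        elif cls == "de_both_uncorrelated":
            template[g] = "random_mix"
            amp_x[g] = amp_y[g] = config.amplitude_strong
            mu_x[g] = amp_x[g] * _random_smooth_curve(rng, tmpl)
            mu_y[g] = amp_y[g] * _random_smooth_curve(rng, tmpl)
        else:  # shared-template correlated classes
            name = TEMPLATE_NAMES[rng.integers(len(TEMPLATE_NAMES))]
            curve = tmpl[TEMPLATE_NAMES.index(name)]
            template[g] = name
            sign = 1.0 if rng.random() < 0.5 else -1.0
            target_r[g] = sign
            amp_x[g] = config.amplitude_strong
            amp_y[g] = (
                config.amplitude_strong
                if cls == "de_both_correlated"
                else config.amplitude_moderate
            )
            mu_x[g] = amp_x[g] * curve
            mu_y[g] = sign * amp_y[g] * curve

    noise_x = rng.standard_normal((G, nt, config.B_x)) * sigma_g[:, None, None]
    noise_y = rng.standard_normal((G, nt, config.B_y)) * sigma_g[:, None, None]
    x = TimeCourseAssay(
        assay_name="assay_x",
        gene_ids=gene_ids,
        times=times,
        replicate_ids=[str(b) for b in range(1, config.B_x + 1)],
        values=mu_x[:, :, None] + noise_x,
    )
    y = TimeCourseAssay(
        assay_name="assay_y",
        gene_ids=gene_ids,
        times=times,
        replicate_ids=[str(b) for b in range(1, config.B_y + 1)],
        values=mu_y[:, :, None] + noise_y,
    )
    truth = SyntheticTruth(
        table=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "gene_class": classes,
                "amplitude_x": amp_x,
                "amplitude_y": amp_y,
                "template": template,
                "target_r": target_r,
            }
        ),
        config=config,
    )
    return AssayPair(x=x, y=y), truth


def default_paper_shape(seed: int = 0) -> SimulationConfig:
    """The default study shape: G=2000 genes, 14 time points, 4 replicates."""
    return SimulationConfig(seed=seed).validate()
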
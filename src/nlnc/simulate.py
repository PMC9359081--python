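"""Synthetic cohorts with the statistical structure the screen assumes.

Each cohort contains:

* a tumour-purity confounder ``p ~ Beta(5, 2)`` loading positively on every
  gene, so that naive lncRNA–mRNA correlations are inflated and the
  purity-adjusted partial correlation has something to fix;
* a latent pathway factor ``F ~ N(0, 1)`` shared by a "Notch module" of
  mRNAs (loading 1) and by the planted driver lncRNAs (loading ``w``);
* non-driver lncRNAs and background mRNAs that see only purity and noise;
* proportional-hazards survival driven by a subset of the driver lncRNAs
  (Weibull baseline, independent uniform censoring calibrated to a target
  censoring fraction).

The driver loading ``w`` is calibrated analytically so that the *population*
partial correlation between a driver lncRNA and any Notch-module mRNA given
purity equals ``driver_effect``: with noise variance ``s^2`` the partial
correlation is ``w / sqrt((w^2 + s^2)(1 + s^2))``, hence

    w = driver_effect * s * sqrt(1 + s^2) / sqrt(1 - driver_effect^2 * (1 + s^2)),

which requires ``|driver_effect| < 1/sqrt(1 + s^2)``.

Planted log-hazard coefficients are per-standard-deviation effects: the
linear predictor is ``sum_j beta_j * z_j`` over the standardized expression
of the prognostic lncRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ExpressionMatrix, GeneSetCollection

__all__ = ["SimulationConfig", "GroundTruth", "Cohort", "simulate_cohort", "simulate_multi_cohort"]

# Weibull scale such that the baseline median event time is ~3 time units
# (shape 1.5): median = scale * ln(2)^(1/shape).
_DEFAULT_SHAPE = 1.5
_DEFAULT_SCALE = 3.0 / math.log(2.0) ** (1.0 / _DEFAULT_SHAPE)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults describe a mid-sized bulk cohort: 300 samples, 300 mRNAs with a
    30-gene pathway module, 300 lncRNAs of which 30 are drivers
    (partial correlation 0.5 with the module given purity) and 6 of those
    are prognostic, 30% censoring.
    """

    n_samples: int = 300
    n_mrna: int = 300
    n_lncrna: int = 300
    notch_set_size: int = 30
    n_driver_lnc: int = 30
    driver_effect: float = 0.5
    purity_loading: float = 3.0
    n_prognostic_lnc: int = 6
    beta: Sequence[float] | None = None  # default: alternating +/-0.8
    baseline_shape: float = _DEFAULT_SHAPE
    baseline_scale: float = _DEFAULT_SCALE
    censoring_rate: float = 0.3
    noise_sd: float = 1.0
    seed: int = 20220725

    def __post_init__(self) -> None:
        if self.n_driver_lnc > self.n_lncrna:
            raise ValueError("n_driver_lnc must be <= n_lncrna")
        if self.n_prognostic_lnc > self.n_driver_lnc:
            raise ValueError("n_prognostic_lnc must be <= n_driver_lnc")
        if self.notch_set_size > self.n_mrna:
            raise ValueError("notch_set_size must be <= n_mrna")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1); with uniform "
                             "censoring any value in that range is reachable")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.beta is None:
            self.beta = [0.8 * (-1) ** j for j in range(self.n_prognostic_lnc)]
        self.beta = list(map(float, self.beta))
        if len(self.beta) != self.n_prognostic_lnc:
            raise ValueError("beta must have one entry per prognostic lncRNA")

    @property
    def driver_loading(self) -> float:
        """Latent-factor loading that realises the target partial correlation."""
        r, s = self.driver_effect, self.noise_sd
        if r == 0:
            return 0.0
        bound = 1.0 / math.sqrt(1.0 + s**2)
        if abs(r) >= bound:
            raise ValueError(
                f"driver_effect {r} unreachable at noise_sd {s}; |effect| must be < {bound:.3f}"
            )
        return r * s * math.sqrt(1 + s**2) / math.sqrt(1 - r**2 * (1 + s**2))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, for recovery testing."""

    driver_lnc_ids: list[str]
    prognostic_betas: dict[str, float]
    notch_gene_ids: list[str]
    purity: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not set(self.prognostic_betas) <= set(self.driver_lnc_ids):
            raise ValueError("prognostic lncRNAs must be a subset of the drivers")

    def notch_collection(self) -> GeneSetCollection:
        return GeneSetCollection({"NOTCH": list(self.notch_gene_ids)},
                                 {"NOTCH": "planted pathway module"})


@dataclass
class Cohort:
    expression: ExpressionMatrix
    purity: pd.Series
    clinical: pd.DataFrame
    truth: GroundTruth


def _calibrate_uniform_censoring(event_times: np.ndarray, rate: float) -> float:
    """Upper bound ``c`` of a Uniform(0, c) censoring law achieving the target
    expected censoring fraction on the realised event times.

    With C ~ U(0, c), P(censored) = E[min(T, c)] / c, which decreases from 1
    to 0 in c; solved by bisection.
    """
    def frac(c: float) -> float:
        return float(np.mean(np.minimum(event_times, c)) / c) - rate

    lo = float(event_times.min()) * 1e-6
    hi = float(event_times.max())
    while frac(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("censoring_rate unreachable on these event times")
    return brentq(frac, lo, hi)


def simulate_cohort(config: SimulationConfig, sample_prefix: str = "S") -> Cohort:
    """Draw one cohort (expression, purity, clinical, ground truth).

    Fully reproducible from ``config.seed``; gene identities are fixed by the
    configuration (Notch module = first ``notch_set_size`` mRNAs, drivers =
    first ``n_driver_lnc`` lncRNAs, prognostic = first ``n_prognostic_lnc``
    drivers).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    s = config.noise_sd

    samples = [f"{sample_prefix}{i:04d}" for i in range(1, n + 1)]
    mrna_ids = [f"M{i:04d}" for i in range(1, config.n_mrna + 1)]
    lnc_ids = [f"L{i:04d}" for i in range(1, config.n_lncrna + 1)]
    notch_ids = mrna_ids[: config.notch_set_size]
    driver_ids = lnc_ids[: config.n_driver_lnc]
    prog_ids = driver_ids[: config.n_prognostic_lnc]

    purity = rng.beta(5.0, 2.0, size=n)
    factor = rng.standard_normal(n)
    w = config.driver_loading

    base_m = rng.normal(5.0, 1.0, size=config.n_mrna)
    mrna = (
        base_m[:, None]
        + config.purity_loading * purity[None, :]
        + s * rng.standard_normal((config.n_mrna, n))
    )
    mrna[: config.notch_set_size] += factor[None, :]

    base_l = rng.normal(5.0, 1.0, size=config.n_lncrna)
    lnc = (
        base_l[:, None]
        + config.purity_loading * purity[None, :]
        + s * rng.standard_normal((config.n_lncrna, n))
    )
    lnc[: config.n_driver_lnc] += w * factor[None, :]

    values = pd.DataFrame(
        np.vstack([mrna, lnc]), index=mrna_ids + lnc_ids, columns=samples
    )
    biotype = pd.Series(
        ["mRNA"] * config.n_mrna + ["lncRNA"] * config.n_lncrna,
        index=mrna_ids + lnc_ids,
    )
    expr = ExpressionMatrix(values, biotype)

    # Proportional-hazards survival on standardized prognostic lncRNAs.
    lp = np.zeros(n)
    for gid, b in zip(prog_ids, config.beta):
        x = values.loc[gid].to_numpy()
        lp += b * (x - x.mean()) / x.std()
    u = rng.uniform(size=n)
    event_t = config.baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / config.baseline_shape)

    if config.censoring_rate > 0:
        c_max = _calibrate_uniform_censoring(event_t, config.censoring_rate)
        censor_t = rng.uniform(0.0, c_max, size=n)
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
    else:
        time, event = event_t, np.ones(n, dtype=int)

    clinical = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": np.round(rng.normal(65.0, 10.0, size=n), 1),
            "sex": rng.choice(["F", "M"], size=n),
        },
        index=pd.Index(samples, name="sample_id"),
    )

    purity_s = pd.Series(purity, index=samples, name="purity")
    truth = GroundTruth(
        driver_lnc_ids=driver_ids,
        prognostic_betas=dict(zip(prog_ids, config.beta)),
        notch_gene_ids=notch_ids,
        purity=purity_s,
    )
    return Cohort(expr, purity_s, clinical, truth)


def simulate_multi_cohort(
    config: SimulationConfig,
    n_cohorts: int,
    effect_jitter: float = 0.0,
) -> list[Cohort]:
    """Independent cohorts sharing planted gene identities.

    Per-cohort seeds derive from the master seed; sample ids are disjoint
    (``C1_``, ``C2_``, ... prefixes).  Planted hazard-coefficient signs are
    identical across cohorts; magnitudes are jittered multiplicatively by a
    uniform factor in ``[1 - effect_jitter, 1 + effect_jitter]``.
    """
    if n_cohorts < 1:
        raise ValueError("n_cohorts must be >= 1")
    if not 0 <= effect_jitter < 1:
        raise ValueError("effect_jitter must lie in [0, 1)")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n_cohorts + 1) >> 1
    jitter_rng = np.random.default_rng(int(child_seeds[-1]))
    base_beta = np.asarray(config.beta, dtype=float)
    cohorts = []
    for c in range(n_cohorts):
        beta_c = base_beta * (1.0 + jitter_rng.uniform(-effect_jitter, effect_jitter, size=base_beta.shape))
        cfg = SimulationConfig(**{**config.to_dict(), "beta": list(beta_c), "seed": int(child_seeds[c])})
        cohorts.append(simulate_cohort(cfg, sample_prefix=f"C{c + 1}_S"))
    return cohorts
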
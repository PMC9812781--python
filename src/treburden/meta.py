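"""Fixed-effect meta-analysis and case-control burden power simulation.

``meta_fixed`` pools per-study log odds ratios with inverse-variance
weights (the METAL-style fixed-effect estimator): w_i = 1/se_i^2,
beta = sum(w_i b_i)/sum(w_i), se = (sum w_i)^(-1/2).  Heterogeneity
(Cochran's Q, I^2) is reported but never switches the model.

``power_sim`` estimates the power of the carrier burden test by Monte
Carlo: control carriers ~ Binomial(n_controls, p0), case carriers ~
Binomial(n_cases, p1) with odds(p1) = GRR * odds(p0), each replicate tested
two-sided on the carrier-proportion difference (unpooled Wald z — the
normal-approximation test whose closed form the simulation is validated
against).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import ConfigError


@dataclass
class StudyEffect:
    """One cohort's burden-test summary statistic on the log-OR scale."""

    name: str
    beta: float
    se: float
    n_cases: int | None = None
    n_controls: int | None = None


@dataclass
class MetaResult:
    beta: float
    se: float
    z: float
    p: float
    q: float
    i2: float
    n_studies: int


def meta_fixed(effects: Sequence[StudyEffect]) -> MetaResult:
    """Inverse-variance-weighted fixed-effect pooled estimate."""
    if not effects:
        raise ConfigError("effects: need at least one study")
    beta = np.array([e.beta for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ConfigError("se: every study standard error must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    z = pooled / pooled_se
    p = float(2 * sps.norm.sf(abs(z)))
    q = float(np.sum(w * (beta - pooled) ** 2))
    df = len(effects) - 1
    i2 = float(max(0.0, (q - df) / q)) if q > 0 and df > 0 else 0.0
    return MetaResult(pooled, pooled_se, float(z), p, q, i2, len(effects))


@dataclass
class PowerResult:
    power: float
    mc_se: float
    params: dict = field(default_factory=dict)


def _case_carrier_prob(carrier_freq: float, grr: float) -> float:
    odds0 = carrier_freq / (1.0 - carrier_freq)
    odds1 = grr * odds0
    p1 = odds1 / (1.0 + odds1)
    if p1 >= 1.0:
        raise ConfigError("grr/carrier_freq: implied case carrier probability >= 1")
    return p1


def analytic_power(
    n_cases: int, n_controls: int, carrier_freq: float, grr: float, alpha: float
) -> float:
    """Closed-form two-proportion normal-approximation power (two-sided)."""
    p0 = carrier_freq
    p1 = _case_carrier_prob(p0, grr)
    delta = p1 - p0
    se1 = np.sqrt(p1 * (1 - p1) / n_cases + p0 * (1 - p0) / n_controls)
    zc = sps.norm.isf(alpha / 2)
    return float(
        sps.norm.sf(zc - delta / se1) + sps.norm.cdf(-zc - delta / se1)
    )


def power_sim(
    n_cases: int,
    n_controls: int,
    carrier_freq: float,
    grr: float,
    alpha: float = 1e-5,
    reps: int = 10000,
    seed: int = 0,
) -> PowerResult:
    """Monte Carlo power of the carrier burden test.

    Parameters mirror the study design: number of cases/controls, the
    aggregate carrier probability in controls, the genotypic relative risk
    (modelled as an odds ratio on carrier status), and the type-I error
    level.  Power is the fraction of replicates whose two-sided test of the
    carrier-proportion difference rejects at ``alpha``; the Monte Carlo
    standard error is sqrt(power (1-power) / reps).
    """
    if min(n_cases, n_controls, reps) <= 0:
        raise ConfigError("n_cases, n_controls, reps: must be positive")
    if not 0 < carrier_freq < 1:
        raise ConfigError("carrier_freq: must lie in (0, 1)")
    if grr <= 0:
        raise ConfigError("grr: must be positive")
    if not 0 < alpha < 1:
        raise ConfigError("alpha: must lie in (0, 1)")
    p0 = carrier_freq
    p1 = _case_carrier_prob(p0, grr)
    rng = np.random.default_rng(seed)
    a = rng.binomial(n_cases, p1, size=reps)
    c = rng.binomial(n_controls, p0, size=reps)
    ph1 = a / n_cases
    ph0 = c / n_controls
    var = ph1 * (1 - ph1) / n_cases + ph0 * (1 - ph0) / n_controls
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(ph1 - ph0) / np.sqrt(var)
    z = np.where(np.isfinite(z), z, 0.0)  # degenerate replicate: never rejects
    zc = sps.norm.isf(alpha / 2)
    power = float(np.mean(z > zc))
    mc_se = float(np.sqrt(power * (1 - power) / reps))
    return PowerResult(
        power=power,
        mc_se=mc_se,
        params={
            "n_cases": n_cases,
            "n_controls": n_controls,
            "carrier_freq": carrier_freq,
            "grr": grr,
            "alpha": alpha,
            "reps": reps,
            "seed": seed,
        },
    )
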
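"""Closed-form population quantities implied by the structural model.

Under balanced allocation the welfare score in each arm is Gaussian,

    W | A = a  ~  Normal(gamma0 + gamma1*a + gamma2*mu_L,
                         sqrt(gamma2^2 * sigma_L^2 + sigma_W^2)),

so the population analogue of "censor everything below the q-th welfare
percentile of all animals" is the q-quantile of the equal 50/50 mixture
of the two arm distributions. Solving ``(F0(t) + F1(t)) / 2 = q`` for the
threshold ``t`` and evaluating each arm's CDF there gives the arm-specific
attrition probabilities — identical for both arms only when the treatment
has no welfare side effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .scm import SEVERITY_GAMMA1, StructuralParams, default_params

__all__ = [
    "ArmAttrition",
    "expected_outcome_mean",
    "population_attrition",
    "attrition_table",
]

_ROOT_XTOL = 1e-12  # absolute tolerance of the threshold root-find


@dataclass(frozen=True)
class ArmAttrition:
    """Arm-specific attrition probabilities and the welfare cutoff that yields them."""

    p_treated: float
    p_control: float
    threshold: float

    def rounded_percent(self) -> tuple[int, int]:
        """(treated, control) as integer percent, half away from zero."""
        return (
            int(np.floor(self.p_treated * 100 + 0.5)),
            int(np.floor(self.p_control * 100 + 0.5)),
        )


def expected_outcome_mean(params: StructuralParams) -> float:
    """Population mean of the final infarct volume under balanced allocation.

    ``E[Y] = beta0 + beta1/2 + beta2*mu_L``; with a null treatment effect
    this reduces to ``beta0 + beta2*mu_L`` (200 mm³ at the defaults).
    """
    return params.beta0 + params.beta1 * 0.5 + params.beta2 * params.mu_L


def arm_welfare_distribution(params: StructuralParams, arm: int) -> tuple[float, float]:
    """Mean and standard deviation of the welfare score in one arm."""
    mean = params.gamma0 + params.gamma1 * arm + params.gamma2 * params.mu_L
    sd = float(np.hypot(params.gamma2 * params.sigma_L, params.sigma_W))
    return mean, sd


def population_attrition(params: StructuralParams, attrition_q: float) -> ArmAttrition:
    """Arm-specific attrition probabilities at total attrition ``attrition_q``.

    The welfare cutoff ``t`` solves the equal-mixture quantile equation
    ``(F_control(t) + F_treated(t)) / 2 = attrition_q`` by bracketed root
    search; each arm's attrition probability is its CDF at ``t``.
    """
    if not 0.0 < attrition_q < 1.0:
        raise ValueError(f"attrition_q must lie strictly in (0, 1), got {attrition_q}")
    m0, s = arm_welfare_distribution(params, 0)
    m1, _ = arm_welfare_distribution(params, 1)
    if s == 0.0:
        raise ValueError("degenerate welfare distribution: gamma2*sigma_L and sigma_W both zero")

    def mixture_cdf_minus_q(t: float) -> float:
        return 0.5 * norm.cdf(t, m0, s) + 0.5 * norm.cdf(t, m1, s) - attrition_q

    center = 0.5 * (m0 + m1)
    lo, hi = center - 10.0 * s - abs(m0 - m1), center + 10.0 * s + abs(m0 - m1)
    t = brentq(mixture_cdf_minus_q, lo, hi, xtol=_ROOT_XTOL)
    return ArmAttrition(
        p_treated=float(norm.cdf(t, m1, s)),
        p_control=float(norm.cdf(t, m0, s)),
        threshold=float(t),
    )


def attrition_table(
    attrition_levels: tuple[float, ...] = (0.10, 0.25, 0.50),
    severities: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Arm-specific attrition for every severity × total-attrition combination.

    One row per combination with the analytic probabilities as integer
    percentages, in severity-block order (minor → moderate → major).
    """
    severities = dict(SEVERITY_GAMMA1) if severities is None else severities
    rows = []
    for severity, gamma1 in severities.items():
        params = default_params(gamma1)
        for q in attrition_levels:
            att = population_attrition(params, q)
            treated_pct, control_pct = att.rounded_percent()
            rows.append(
                {
                    "severity": severity,
                    "total_attrition_pct": int(round(q * 100)),
                    "treated_pct": treated_pct,
                    "control_pct": control_pct,
                }
            )
    return pd.DataFrame(rows)
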
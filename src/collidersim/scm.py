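"""Linear-Gaussian structural causal model for a two-arm preclinical experiment.

The generative model describes a randomized stroke experiment in rats
(middle cerebral artery occlusion). Each animal carries

* ``A`` — treatment arm (1 treated, 0 control), balanced allocation;
* ``L`` — initial infarct volume in mm³, drawn ``Normal(mu_L, sigma_L)``;
* ``W`` — a welfare score on an arbitrary scale (lower is worse),
  ``W = gamma0 + gamma1*A + gamma2*L + eps_W``;
* ``Y`` — final infarct volume in mm³,
  ``Y = beta0 + beta1*A + beta2*L + eps_Y``;
* ``S`` — survival status: animals whose welfare falls below a
  within-cohort percentile are censored (``S = 0``) before outcome
  assessment.

``W`` is a collider on the path ``A -> W <- L -> Y``; censoring on low
welfare conditions on a child of that collider and is what makes the
complete-case (naive) treatment-effect estimate biased even under a true
null effect (``beta1 = 0``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StructuralParams",
    "Scenario",
    "AnimalCohort",
    "SEVERITY_GAMMA1",
    "ATTRITION_LEVELS",
    "default_params",
    "generate_cohort",
    "apply_attrition",
    "censoring_count",
    "severity_label",
    "attrition_label",
    "TiedWelfareWarning",
]

#: Side-effect severity labels and the treatment-on-welfare coefficient each implies.
SEVERITY_GAMMA1 = {"minor": -1.0, "moderate": -3.0, "major": -6.0}

#: Attrition-level labels and the nominal censored fraction each implies.
ATTRITION_LEVELS = {"low": 0.10, "moderate": 0.25, "high": 0.50}


class TiedWelfareWarning(UserWarning):
    """Welfare ties at the censoring threshold; falling back to rank censoring."""


def severity_label(gamma1: float) -> str:
    """Map a treatment-on-welfare coefficient to its severity label."""
    for label, value in SEVERITY_GAMMA1.items():
        if gamma1 == value:
            return label
    return "custom"


def attrition_label(attrition_q: float) -> str:
    """Map a nominal censored fraction to its attrition label."""
    for label, value in ATTRITION_LEVELS.items():
        if attrition_q == value:
            return label
    return "custom"


@dataclass(frozen=True)
class StructuralParams:
    """Coefficients and noise scales of the two structural equations.

    Parameters
    ----------
    beta0, beta1, beta2
        Outcome equation ``Y = beta0 + beta1*A + beta2*L + eps_Y``:
        intercept (mm³), treatment effect (mm³), and infarct-growth
        slope (mm³ final per mm³ initial).
    gamma0, gamma1, gamma2
        Welfare equation ``W = gamma0 + gamma1*A + gamma2*L + eps_W``:
        intercept, treatment side effect, and effect of initial volume
        on welfare (welfare units per mm³).
    sigma_Y, sigma_W
        Standard deviations of the independent Gaussian errors
        ``eps_Y`` (mm³) and ``eps_W`` (welfare units).
    mu_L, sigma_L
        Mean and standard deviation of the initial infarct volume (mm³).
    """

    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 8.0
    gamma0: float = 0.0
    gamma1: float = -1.0
    gamma2: float = -1.0
    sigma_Y: float = 10.0
    sigma_W: float = 2.0
    mu_L: float = 25.0
    sigma_L: float = 5.0

    def __post_init__(self) -> None:
        for name in ("sigma_Y", "sigma_W", "sigma_L"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be a finite non-negative number, got {value!r}")
        for name in ("beta0", "beta1", "beta2", "gamma0", "gamma1", "gamma2", "mu_L"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def default_params(gamma1: float) -> StructuralParams:
    """Default structural parameters of the simulation study.

    Returns the null-effect configuration (``beta1 = 0``) with
    ``beta2 = 8``, ``gamma2 = -1``, noise scales 10 and 2, and
    ``L ~ Normal(25, 5)``; only the treatment side effect ``gamma1``
    is caller-chosen.
    """
    if not np.isfinite(gamma1):
        raise ValueError("gamma1 must be finite")
    return StructuralParams(gamma1=float(gamma1))


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid.

    ``n_total`` animals split evenly between arms, side-effect severity
    ``gamma1`` (one of −1/−3/−6 in the standard grid), and nominal
    censored fraction ``attrition_q`` (the welfare-percentile level).
    """

    n_total: int
    gamma1: float
    attrition_q: float
    severity: str = field(default="")
    attrition: str = field(default="")

    def __post_init__(self) -> None:
        if self.n_total <= 0 or self.n_total % 2 != 0:
            raise ValueError(f"n_total must be a positive even integer, got {self.n_total}")
        if not 0.0 < self.attrition_q < 1.0:
            raise ValueError(f"attrition_q must lie strictly in (0, 1), got {self.attrition_q}")
        if not self.severity:
            object.__setattr__(self, "severity", severity_label(self.gamma1))
        elif self.severity in SEVERITY_GAMMA1 and SEVERITY_GAMMA1[self.severity] != self.gamma1:
            raise ValueError(
                f"severity label {self.severity!r} inconsistent with gamma1={self.gamma1}"
            )
        if not self.attrition:
            object.__setattr__(self, "attrition", attrition_label(self.attrition_q))
        elif self.attrition in ATTRITION_LEVELS and ATTRITION_LEVELS[self.attrition] != self.attrition_q:
            raise ValueError(
                f"attrition label {self.attrition!r} inconsistent with attrition_q={self.attrition_q}"
            )

    @property
    def n_per_arm(self) -> int:
        return self.n_total // 2

    @property
    def scenario_id(self) -> str:
        return f"n{self.n_total}_{self.severity}_q{int(round(self.attrition_q * 100))}"


@dataclass
class AnimalCohort:
    """Per-animal records of one simulated experiment (parallel arrays)."""

    arm: np.ndarray            # 0 control / 1 treated
    initial_volume: np.ndarray  # L, mm³
    welfare: np.ndarray         # W, arbitrary units
    final_volume: np.ndarray    # Y, mm³
    survived: np.ndarray        # S, 1 until censoring marks 0

    def __post_init__(self) -> None:
        n = len(self.arm)
        for name in ("initial_volume", "welfare", "final_volume", "survived"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from arm length {n}")

    @property
    def n_total(self) -> int:
        return len(self.arm)

    def to_dataframe(
        self,
        scenario_id: str | None = None,
        replication: int | None = None,
        seed: int | None = None,
    ) -> pd.DataFrame:
        """Tidy per-animal table (one row per animal)."""
        frame = pd.DataFrame(
            {
                "animal_id": np.arange(self.n_total),
                "arm": self.arm.astype(int),
                "initial_volume_mm3": self.initial_volume,
                "welfare": self.welfare,
                "final_volume_mm3": self.final_volume,
                "survived": self.survived.astype(int),
            }
        )
        if scenario_id is not None:
            frame["scenario_id"] = scenario_id
        if replication is not None:
            frame["replication"] = replication
        if seed is not None:
            frame["seed"] = seed
        return frame


def balanced_arms(n_total: int) -> np.ndarray:
    """Deterministic balanced allocation: first half control, second half treated.

    The estimators are exchangeable in animal order, so the fixed layout
    is without loss of generality and guarantees equal arm sizes in every
    replication.
    """
    half = n_total // 2
    return np.repeat([0, 1], half).astype(np.int8)


def generate_batch(
    scenario: Scenario,
    params: StructuralParams,
    rng: np.random.Generator,
    reps: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``reps`` independent cohorts at once.

    Returns ``(A, L, W, Y)`` where ``A`` has shape ``(n_total,)`` (the
    allocation is the same deterministic pattern in every replication)
    and ``L``, ``W``, ``Y`` have shape ``(reps, n_total)``. This is the
    single source of truth for the structural equations; everything
    downstream (single-cohort generation, the Monte Carlo grid) calls it.
    """
    n = scenario.n_total
    A = balanced_arms(n)
    L = rng.normal(params.mu_L, params.sigma_L, size=(reps, n))
    eps_W = rng.normal(0.0, params.sigma_W, size=(reps, n))
    eps_Y = rng.normal(0.0, params.sigma_Y, size=(reps, n))
    W = params.gamma0 + params.gamma1 * A + params.gamma2 * L + eps_W
    Y = params.beta0 + params.beta1 * A + params.beta2 * L + eps_Y
    return A, L, W, Y


def generate_cohort(
    scenario: Scenario,
    params: StructuralParams,
    rng: np.random.Generator,
) -> AnimalCohort:
    """Generate one uncensored cohort from the structural equations."""
    A, L, W, Y = generate_batch(scenario, params, rng, reps=1)
    return AnimalCohort(
        arm=A.copy(),
        initial_volume=L[0],
        welfare=W[0],
        final_volume=Y[0],
        survived=np.ones(scenario.n_total, dtype=np.int8),
    )


def censoring_count(n_total: int, attrition_q: float) -> int:
    """Number of animals censored for continuous welfare scores.

    The threshold is the type-7 empirical quantile (linear interpolation
    at index ``h = (n-1)q + 1``); with continuous data the count strictly
    below it is ``floor(h)``, or ``h - 1`` when ``h`` is an integer (the
    quantile then coincides with an order statistic, which survives).
    """
    if not 0.0 < attrition_q < 1.0:
        raise ValueError(f"attrition_q must lie strictly in (0, 1), got {attrition_q}")
    h = (n_total - 1) * attrition_q + 1.0
    h_floor = int(np.floor(h))
    return h_floor - 1 if h == h_floor else h_floor


def survival_mask(W: np.ndarray, attrition_q: float) -> np.ndarray:
    """Vectorized censoring rule over a ``(reps, n)`` welfare matrix.

    An animal is censored when its welfare lies strictly below the
    within-replication type-7 quantile at level ``attrition_q``. Welfare
    ties at the threshold (measure-zero under the Gaussian model, but
    possible in degenerate zero-noise configurations) trigger a fallback
    to stable-rank censoring of the ``censoring_count`` lowest scores,
    with a warning.
    """
    if not 0.0 < attrition_q < 1.0:
        raise ValueError(f"attrition_q must lie strictly in (0, 1), got {attrition_q}")
    W = np.atleast_2d(W)
    n = W.shape[1]
    threshold = np.quantile(W, attrition_q, axis=1, method="linear")
    survive = W >= threshold[:, None]
    k = censoring_count(n, attrition_q)
    tied = (n - survive.sum(axis=1)) != k
    if np.any(tied):
        warnings.warn(
            "welfare ties at the censoring threshold; using stable-rank censoring",
            TiedWelfareWarning,
            stacklevel=2,
        )
        for i in np.nonzero(tied)[0]:
            order = np.argsort(W[i], kind="stable")
            survive[i] = True
            survive[i, order[:k]] = False
    return survive


def apply_attrition(cohort: AnimalCohort, attrition_q: float) -> AnimalCohort:
    """Censor animals below the within-cohort welfare percentile.

    Returns a new cohort with ``survived`` set to 0 for censored animals;
    all other fields are unchanged. Deterministic given the cohort.
    """
    if not np.all(cohort.survived == 1):
        raise ValueError("cohort has already been censored (survived must be all 1)")
    survive = survival_mask(cohort.welfare, attrition_q)[0]
    return replace(cohort, survived=survive.astype(np.int8))
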
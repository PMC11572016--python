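"""Three treatment-effect estimators for a censored two-arm cohort.

* **oracle** — difference in mean final infarct volume between arms using
  every animal, censored or not. Unobservable in practice (the outcome of
  an animal lost before assessment is never measured) but unbiased, and
  therefore the benchmark.
* **naive** — the same difference restricted to survivors (complete-case
  analysis). Biased in favor of the treatment when the treatment harms
  welfare, because survival selection makes surviving treated animals
  systematically milder cases.
* **adjusted** — ordinary least squares of final volume on intercept,
  treatment and initial volume among survivors; the treatment coefficient
  is the estimate. Conditioning on the initial volume closes the open
  collider path, so this is unbiased under the linear model.

A negative estimate means an apparently beneficial treatment (smaller
final infarct). Estimates that cannot be computed (an empty arm among
survivors, or an unidentifiable regression) are returned as NaN with the
corresponding computability flag set to False — incomputability is a data
condition, not an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scm import AnimalCohort

__all__ = [
    "EstimateRecord",
    "estimate_oracle",
    "estimate_naive",
    "estimate_adjusted",
    "estimate_all",
    "records_to_frame",
]

# |R_ii| below this (relative to the largest diagonal) marks a rank-deficient fit.
_RANK_TOL = 1e-9


@dataclass(frozen=True)
class EstimateRecord:
    """Per-replication estimates with computability flags and survivor counts."""

    oracle: float
    naive: float
    adjusted: float
    naive_computable: bool
    adjusted_computable: bool
    survivors_treated: int
    survivors_control: int

    def __post_init__(self) -> None:
        if np.isnan(self.naive) == self.naive_computable:
            raise ValueError("naive must be NaN exactly when naive_computable is False")
        if np.isnan(self.adjusted) == self.adjusted_computable:
            raise ValueError("adjusted must be NaN exactly when adjusted_computable is False")
        if np.isnan(self.oracle):
            raise ValueError("oracle estimate can never be missing")


def estimate_oracle(cohort: AnimalCohort) -> float:
    """Difference in mean outcome between arms over all animals."""
    treated = cohort.arm == 1
    if not treated.any() or treated.all():
        raise ValueError("oracle estimate needs at least one animal in each arm")
    return float(cohort.final_volume[treated].mean() - cohort.final_volume[~treated].mean())


def estimate_naive(cohort: AnimalCohort) -> float:
    """Difference in mean outcome between arms among survivors; NaN if an arm is empty."""
    alive = cohort.survived == 1
    treated = cohort.arm == 1
    if not (alive & treated).any() or not (alive & ~treated).any():
        return float("nan")
    return float(
        cohort.final_volume[alive & treated].mean()
        - cohort.final_volume[alive & ~treated].mean()
    )


def estimate_adjusted(cohort: AnimalCohort) -> float:
    """Treatment coefficient of OLS ``Y ~ 1 + A + L`` among survivors.

    NaN when the fit is not identifiable: fewer than three survivors, an
    empty arm, or a rank-deficient design (initial volume constant within
    arms). Solved by QR (``numpy.linalg.lstsq``), no regularization.
    """
    alive = cohort.survived == 1
    A = cohort.arm[alive].astype(float)
    L = cohort.initial_volume[alive]
    Y = cohort.final_volume[alive]
    n = A.size
    if n < 3 or A.sum() == 0 or A.sum() == n:
        return float("nan")
    X = np.column_stack([np.ones(n), A, L])
    if np.linalg.matrix_rank(X) < 3:
        return float("nan")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return float(coef[1])


def estimate_all(cohort: AnimalCohort) -> EstimateRecord:
    """All three estimates for one censored cohort."""
    alive = cohort.survived == 1
    treated = cohort.arm == 1
    naive = estimate_naive(cohort)
    adjusted = estimate_adjusted(cohort)
    return EstimateRecord(
        oracle=estimate_oracle(cohort),
        naive=naive,
        adjusted=adjusted,
        naive_computable=not np.isnan(naive),
        adjusted_computable=not np.isnan(adjusted),
        survivors_treated=int((alive & treated).sum()),
        survivors_control=int((alive & ~treated).sum()),
    )


def batch_estimates(
    A: np.ndarray,
    L: np.ndarray,
    Y: np.ndarray,
    survive: np.ndarray,
) -> dict[str, np.ndarray]:
    """Vectorized estimators over ``(reps, n)`` replication matrices.

    ``A`` is the shared ``(n,)`` allocation vector. Returns arrays of
    length ``reps``: ``oracle``, ``naive``, ``adjusted`` (NaN where not
    computable), the two computability flags, and survivor counts per arm.

    The adjusted fit runs as a stacked QR decomposition: non-survivor
    rows of the design matrix and response are zeroed, which leaves the
    least-squares solution of the survivor subset unchanged (zero rows
    contribute zero residual regardless of the coefficients).
    """
    treated = A == 1
    reps, n = L.shape
    n_half = int(treated.sum())

    oracle = Y[:, treated].mean(axis=1) - Y[:, ~treated].mean(axis=1)

    surv_t = (survive & treated).sum(axis=1)
    surv_c = (survive & ~treated).sum(axis=1)
    naive_ok = (surv_t > 0) & (surv_c > 0)
    sum_t = np.where(survive & treated, Y, 0.0).sum(axis=1)
    sum_c = np.where(survive & ~treated, Y, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        naive = sum_t / surv_t - sum_c / surv_c
    naive = np.where(naive_ok, naive, np.nan)

    # Stacked design (reps, n, 3) with censored rows zeroed out.
    mask = survive.astype(float)
    X = np.empty((reps, n, 3))
    X[:, :, 0] = mask
    X[:, :, 1] = mask * treated
    X[:, :, 2] = mask * L
    y_masked = np.where(survive, Y, 0.0)
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diagonal(R, axis1=1, axis2=2))
    full_rank = diag.min(axis=1) > _RANK_TOL * np.maximum(diag.max(axis=1), 1.0)
    adj_ok = naive_ok & (surv_t + surv_c >= 3) & full_rank
    # Guard singular systems with the identity; those rows are masked to NaN.
    R_safe = np.where(adj_ok[:, None, None], R, np.eye(3))
    rhs = np.einsum("rnk,rn->rk", Q, y_masked)
    coef = np.linalg.solve(R_safe, rhs[..., None])[..., 0]
    adjusted = np.where(adj_ok, coef[:, 1], np.nan)

    return {
        "oracle": oracle,
        "naive": naive,
        "adjusted": adjusted,
        "naive_computable": naive_ok,
        "adjusted_computable": adj_ok,
        "survivors_treated": surv_t,
        "survivors_control": surv_c,
        "n_per_arm": np.full(reps, n_half),
    }


def records_to_frame(
    estimates: dict[str, np.ndarray],
    scenario_id: str,
) -> pd.DataFrame:
    """Tidy per-replication table from a :func:`batch_estimates` result."""
    reps = len(estimates["oracle"])
    return pd.DataFrame(
        {
            "scenario_id": scenario_id,
            "replication": np.arange(reps),
            "oracle": estimates["oracle"],
            "naive": estimates["naive"],
            "adjusted": estimates["adjusted"],
            "naive_computable": estimates["naive_computable"],
            "adjusted_computable": estimates["adjusted_computable"],
            "survivors_treated": estimates["survivors_treated"],
            "survivors_control": estimates["survivors_control"],
        }
    )
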
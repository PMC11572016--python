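"""Monte Carlo grid: run scenarios, summarize estimates, write tables.

The standard grid crosses total sample size {10, 20, 50}, side-effect
severity {minor, moderate, major} and nominal attrition {10%, 25%, 50%}
— 27 scenarios, each replicated 10,000 times. Every replication draws a
cohort from the structural model, censors on welfare, and computes the
oracle/naive/adjusted estimates; a scenario is summarized by the mean and
2.5th/97.5th percentiles of the non-missing estimates per approach, with
incomputable replications counted separately.

Randomness policy: one root seed per run; each scenario derives its own
``SeedSequence(root_seed, spawn_key=(scenario_index,))`` substream from
its position in the canonical grid order, so results are independent of
execution order and a single scenario rerun standalone reproduces its
grid row bit for bit.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import batch_estimates, records_to_frame
from .scm import (
    ATTRITION_LEVELS,
    SEVERITY_GAMMA1,
    Scenario,
    StructuralParams,
    default_params,
    generate_batch,
    survival_mask,
)

__all__ = [
    "GridConfig",
    "ApproachSummary",
    "ScenarioSummary",
    "default_grid",
    "scenario_rng",
    "run_scenario",
    "run_grid",
    "quantile_interpolated",
    "summaries_to_frame",
    "write_summary_table",
    "load_config",
]

logger = logging.getLogger("collidersim")

_APPROACHES = ("oracle", "naive", "adjusted")


@dataclass(frozen=True)
class GridConfig:
    """Scenario grid, replication count, seeding, and output options."""

    n_totals: tuple[int, ...] = (10, 20, 50)
    gamma1_levels: tuple[float, ...] = (-1.0, -3.0, -6.0)
    attrition_levels: tuple[float, ...] = (0.10, 0.25, 0.50)
    reps: int = 10_000
    root_seed: int = 0
    out_path: str | None = None
    out_format: str = "csv"
    write_rounded: bool = True

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")
        for name in ("n_totals", "gamma1_levels", "attrition_levels"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        if self.out_format not in ("csv", "json"):
            raise ValueError(f"out_format must be 'csv' or 'json', got {self.out_format!r}")

    @property
    def n_scenarios(self) -> int:
        return len(self.n_totals) * len(self.gamma1_levels) * len(self.attrition_levels)


@dataclass(frozen=True)
class ApproachSummary:
    """Across-replication summary of one estimator in one scenario."""

    mean: float
    p2_5: float
    p97_5: float
    n_missing: int


@dataclass(frozen=True)
class ScenarioSummary:
    """One grid row: scenario identifiers plus the three approach summaries."""

    n_total: int
    severity: str
    attrition_q: float
    reps: int
    oracle: ApproachSummary
    naive: ApproachSummary
    adjusted: ApproachSummary
    scenario_index: int = field(default=-1)

    @property
    def attrition_pct(self) -> int:
        return int(round(self.attrition_q * 100))


def default_grid(config: GridConfig | None = None) -> list[Scenario]:
    """Scenarios in canonical order: n ascending, then attrition, then severity.

    Severity runs minor → moderate → major within each attrition block,
    matching the layout of the study's summary table.
    """
    config = config or GridConfig()
    severity_order = sorted(config.gamma1_levels, reverse=True)  # minor (−1) first
    return [
        Scenario(n_total=n, gamma1=g1, attrition_q=q)
        for n, q, g1 in itertools.product(
            sorted(config.n_totals), sorted(config.attrition_levels), severity_order
        )
    ]


def scenario_rng(root_seed: int, scenario_index: int) -> np.random.Generator:
    """Independent substream for one scenario, keyed by grid position."""
    return np.random.default_rng(
        np.random.SeedSequence(root_seed, spawn_key=(scenario_index,))
    )


def quantile_interpolated(values: Sequence[float], p: float) -> float:
    """Linear-interpolation sample quantile at index ``h = (m-1)p + 1``.

    The same convention (R type 7) used for the censoring threshold;
    applied to the non-missing estimates when summarizing a scenario.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take a quantile of an empty list")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"quantile level must lie in [0, 1], got {p}")
    srt = np.sort(arr)
    h = (arr.size - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, arr.size - 1)
    return float(srt[lo] + (h - lo) * (srt[hi] - srt[lo]))


def _summarize(values: np.ndarray, reps: int) -> ApproachSummary:
    finite = values[~np.isnan(values)]
    n_missing = reps - finite.size
    if finite.size == 0:
        return ApproachSummary(float("nan"), float("nan"), float("nan"), n_missing)
    return ApproachSummary(
        mean=float(finite.mean()),
        p2_5=quantile_interpolated(finite, 0.025),
        p97_5=quantile_interpolated(finite, 0.975),
        n_missing=n_missing,
    )


def run_scenario(
    scenario: Scenario,
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
    params: StructuralParams | None = None,
    scenario_index: int = -1,
    return_records: bool = False,
) -> ScenarioSummary | tuple[ScenarioSummary, pd.DataFrame]:
    """Simulate one scenario: generate, censor, estimate, summarize.

    All replications are drawn and estimated in vectorized batches. With
    ``return_records=True`` the tidy per-replication estimate table is
    returned alongside the summary.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = rng if rng is not None else np.random.default_rng()
    params = params if params is not None else default_params(scenario.gamma1)
    start = time.perf_counter()
    A, L, W, Y = generate_batch(scenario, params, rng, reps=reps)
    survive = survival_mask(W, scenario.attrition_q)
    est = batch_estimates(A, L, Y, survive)
    summary = ScenarioSummary(
        n_total=scenario.n_total,
        severity=scenario.severity,
        attrition_q=scenario.attrition_q,
        reps=reps,
        oracle=_summarize(est["oracle"], reps),
        naive=_summarize(est["naive"], reps),
        adjusted=_summarize(est["adjusted"], reps),
        scenario_index=scenario_index,
    )
    logger.info(
        "scenario %s: reps=%d naive_missing=%d adjusted_missing=%d elapsed=%.2fs",
        scenario.scenario_id,
        reps,
        summary.naive.n_missing,
        summary.adjusted.n_missing,
        time.perf_counter() - start,
    )
    if return_records:
        return summary, records_to_frame(est, scenario.scenario_id)
    return summary


def run_grid(
    config: GridConfig | None = None,
    return_records: bool = False,
) -> list[ScenarioSummary] | tuple[list[ScenarioSummary], pd.DataFrame]:
    """Run every scenario of the grid on independent substreams.

    Returns the summaries in canonical order (27 rows at the defaults);
    with ``return_records=True`` also the concatenated per-replication
    estimates of all scenarios.
    """
    config = config or GridConfig()
    summaries: list[ScenarioSummary] = []
    record_frames: list[pd.DataFrame] = []
    for index, scenario in enumerate(default_grid(config)):
        rng = scenario_rng(config.root_seed, index)
        result = run_scenario(
            scenario,
            reps=config.reps,
            rng=rng,
            scenario_index=index,
            return_records=return_records,
        )
        if return_records:
            summary, records = result
            record_frames.append(records)
        else:
            summary = result
        summaries.append(summary)
    pooled = pooled_missing_fraction(summaries)
    logger.info("grid complete: %d scenarios, pooled missing fraction %.4f", len(summaries), pooled)
    if return_records:
        return summaries, pd.concat(record_frames, ignore_index=True)
    return summaries


def pooled_missing_fraction(summaries: Sequence[ScenarioSummary], approach: str = "naive") -> float:
    """Fraction of scenario-replications with an incomputable estimate."""
    total = sum(s.reps for s in summaries)
    missing = sum(getattr(s, approach).n_missing for s in summaries)
    return missing / total


def summaries_to_frame(summaries: Sequence[ScenarioSummary]) -> pd.DataFrame:
    """Flatten summaries into the tabular layout (one row per scenario)."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "n_total": s.n_total,
            "attrition_pct": s.attrition_pct,
            "severity": s.severity,
            "reps": s.reps,
        }
        for approach in _APPROACHES:
            a: ApproachSummary = getattr(s, approach)
            row[f"{approach}_mean"] = a.mean
            row[f"{approach}_p2_5"] = a.p2_5
            row[f"{approach}_p97_5"] = a.p97_5
            row[f"{approach}_n_missing"] = a.n_missing
        rows.append(row)
    return pd.DataFrame(rows)


def write_summary_table(
    summaries: Sequence[ScenarioSummary],
    path: str | Path,
    fmt: str = "csv",
    write_rounded: bool = True,
) -> Path:
    """Write the scenario summary table, full precision plus a rounded view.

    The rounded companion (``*_rounded.csv``) formats every estimate to
    one decimal, matching how such tables are conventionally printed.
    """
    if not summaries:
        raise ValueError("no summaries to write")
    path = Path(path)
    frame = summaries_to_frame(summaries)
    try:
        if fmt == "csv":
            frame.to_csv(path, index=False)
        elif fmt == "json":
            path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except OSError as exc:
        raise OSError(f"cannot write summary table to {path}: {exc}") from exc
    if write_rounded:
        rounded = frame.copy()
        for col in rounded.columns:
            if col.endswith(("_mean", "_p2_5", "_p97_5")):
                rounded[col] = rounded[col].map(lambda v: f"{v:.1f}")
        rounded.to_csv(path.with_name(path.stem + "_rounded.csv"), index=False)
    return path


def load_config(path: str | Path, **overrides) -> GridConfig:
    """Load a :class:`GridConfig` from JSON or plain ``key = value`` text.

    Keyword overrides (e.g. from CLI flags) take precedence over file
    values. List-valued fields accept JSON arrays or comma-separated
    scalars.
    """
    path = Path(path)
    text = path.read_text()
    raw: dict[str, object]
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        raw = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            raw[key] = value
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = GridConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, object] = {}
    for key, value in raw.items():
        if key in ("n_totals", "gamma1_levels", "attrition_levels") and isinstance(value, str):
            value = [part.strip() for part in value.split(",") if part.strip()]
        if key == "n_totals":
            kwargs[key] = tuple(int(v) for v in value)  # type: ignore[union-attr]
        elif key in ("gamma1_levels", "attrition_levels"):
            kwargs[key] = tuple(float(v) for v in value)  # type: ignore[union-attr]
        elif key in ("reps", "root_seed"):
            kwargs[key] = int(value)  # type: ignore[arg-type]
        elif key == "write_rounded":
            kwargs[key] = value if isinstance(value, bool) else str(value).lower() in ("1", "true", "yes")
        else:
            kwargs[key] = value
    return GridConfig(**kwargs)  # type: ignore[arg-type]
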
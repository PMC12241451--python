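"""Multi-season scenario runs and their summary statistics.

Summaries follow the conventions of the snow-loss experiment: simulate 20
seasons (120 active-month steps), then report the mean, sample standard
deviation and extrema of the six monthly totals of the final season, the
first month from which the population stays below the quasi-extinction
threshold, and the percent growth statistic

    lambda = (Nbar_last - Nbar_first) / Nbar_first * 100,

where ``Nbar_j`` is the mean of season ``j``'s six monthly totals.  The
deterministic model never reaches exactly zero from a positive state with
positive survival, so extinction is declared when the total drops below
one individual (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cold import ScenarioSpec
from .model import (
    SCALAR_PARAMS,
    Mode,
    ModelParameters,
    MonthlyState,
    SimulationResult,
    simulate,
)

__all__ = [
    "ScenarioSummary",
    "season_mean",
    "lambda_growth",
    "time_to_extinction",
    "run_scenario",
    "sensitivity_oat",
]

DEFAULT_N_SEASONS = 20
DEFAULT_EXTINCTION_THRESHOLD = 1.0


@dataclass(frozen=True)
class ScenarioSummary:
    """Summary statistics of one scenario run (final-season conventions)."""

    scenario: str
    mean_final: float
    sd_final: float
    min_final: float
    max_final: float
    time_to_extinction: int | None
    lambda_pct: float | None
    d_w: float
    n_seasons: int

    def __post_init__(self) -> None:
        if not self.min_final <= self.mean_final <= self.max_final:
            raise ValueError("final-season mean must lie between min and max")

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "mean_final": self.mean_final,
            "sd_final": self.sd_final,
            "min_final": self.min_final,
            "max_final": self.max_final,
            "time_to_extinction_months": self.time_to_extinction,
            "lambda_pct": self.lambda_pct,
            "d_w": self.d_w,
            "n_seasons": self.n_seasons,
        }


def season_mean(result: SimulationResult, j: int) -> float:
    """Mean of the six monthly totals of season ``j``."""
    return float(np.mean([s.total for s in result.season_states(j)]))


def lambda_growth(
    result: SimulationResult,
    j_first: int = 1,
    j_last: int | None = None,
) -> float | None:
    """Percent change in mean seasonal population size, first to last season.

    Returns ``None`` when the first-season mean is zero (the rate is then
    undefined, not infinite).
    """
    if j_last is None:
        j_last = result.n_seasons
    n_first = season_mean(result, j_first)
    n_last = season_mean(result, j_last)
    if n_first == 0.0:
        return None
    return (n_last - n_first) / n_first * 100.0


def time_to_extinction(
    result: SimulationResult,
    threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
) -> int | None:
    """First month step from which totals stay below ``threshold`` forever.

    Steps are 1-based active months, ``t = (j - 1) * 6 + i``; returns
    ``None`` if the population never (permanently) falls below the
    threshold within the simulated horizon.
    """
    totals = result.totals
    alive = np.flatnonzero(totals >= threshold)
    if alive.size == 0:
        return 1
    last_alive = int(alive[-1])
    if last_alive == totals.size - 1:
        return None
    return last_alive + 2  # next step, converted to 1-based


def run_scenario(
    spec: ScenarioSpec,
    params: ModelParameters,
    initial_state: MonthlyState,
    n_seasons: int = DEFAULT_N_SEASONS,
    mode: Mode = "literal",
    threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
) -> tuple[ScenarioSummary, SimulationResult]:
    """Simulate one scenario and summarise it.

    The scenario's adjusted winter survival overrides ``params.d_w``; all
    other demographic rates are untouched.  Returns both the summary and
    the full trajectory.
    """
    d_w = spec.winter_survival()
    result = simulate(initial_state, params.with_winter_survival(d_w), n_seasons, mode)
    finals = np.array([s.total for s in result.season_states(n_seasons)])
    summary = ScenarioSummary(
        scenario=spec.name,
        mean_final=float(finals.mean()),
        sd_final=float(finals.std(ddof=1)),
        min_final=float(finals.min()),
        max_final=float(finals.max()),
        time_to_extinction=time_to_extinction(result, threshold),
        lambda_pct=lambda_growth(result, 1, n_seasons),
        d_w=d_w,
        n_seasons=n_seasons,
    )
    return summary, result


def _mean_final(result: SimulationResult) -> float:
    return season_mean(result, result.n_seasons)


def sensitivity_oat(
    params: ModelParameters,
    initial_state: MonthlyState,
    perturbation: float = 0.10,
    n_seasons: int = DEFAULT_N_SEASONS,
    mode: Mode = "literal",
) -> pd.DataFrame:
    """One-at-a-time sensitivity of the final-season mean to each rate.

    Each scalar parameter is moved down and up by ``perturbation``
    (relative), clipped to [0, 1] where necessary (recorded in the
    ``clipped`` column), and the elasticity

        (R_high - R_low) / R_base  /  ((p_high - p_low) / p_base)

    is computed by central difference.  Parameters at zero get the low and
    high responses but an elasticity of NaN (no proportional change is
    defined at zero).
    """
    if not 0.0 < perturbation < 1.0:
        raise ValueError("perturbation must be a relative step in (0, 1)")
    base_result = simulate(initial_state, params, n_seasons, mode)
    r_base = _mean_final(base_result)

    rows = []
    for name in SCALAR_PARAMS:
        p0 = getattr(params, name)
        lo_raw, hi_raw = p0 * (1 - perturbation), p0 * (1 + perturbation)
        lo, hi = max(lo_raw, 0.0), min(hi_raw, 1.0)
        clipped = (lo != lo_raw) or (hi != hi_raw)
        r_lo = _mean_final(simulate(initial_state, replace(params, **{name: lo}), n_seasons, mode))
        r_hi = _mean_final(simulate(initial_state, replace(params, **{name: hi}), n_seasons, mode))
        if p0 > 0 and r_base != 0 and hi > lo:
            elasticity = ((r_hi - r_lo) / r_base) / ((hi - lo) / p0)
        elif r_base != 0 and r_hi == r_lo:
            elasticity = 0.0
        else:
            elasticity = float("nan")
        rows.append(
            {
                "parameter": name,
                "baseline": p0,
                "low": lo,
                "high": hi,
                "response_base": r_base,
                "response_low": r_lo,
                "response_high": r_hi,
                "elasticity": elasticity,
                "clipped": clipped,
            }
        )
    return pd.DataFrame(rows)
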
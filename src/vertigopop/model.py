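"""Deterministic seasonal stage-structured population model.

The model tracks a *Vertigo moulinsiana* population through five stages —
eggs (``E``), juveniles (``J``) and three adult age classes (``N1``: newly
matured before their first overwintering, ``N2``: after one overwintering,
``N3``: after two) — over a sequence of seasons.  A season is the six-month
activity window May..October, indexed ``i = 1..6``; the December..May
overwintering period is compressed into a single transition that promotes
juveniles to age-1 adults and each adult class to the next, all thinned by
the winter survival probability ``d_w``.  Age-3 adults do not survive a
third winter and eggs never overwinter.

States are expected counts (real-valued): the recursion is linear, so it
propagates expectations of the underlying individual-level process exactly.

Two bookkeeping modes govern mid-season maturation (months 5 and 6, when a
fraction ``a`` of the cohort hatched three months earlier matures):

* ``"literal"`` — the juvenile pool loses ``(1 - a) * J(i-3) * d_j`` while
  age-1 adults gain ``a * J(i-3) * d_j``; exactly the published recursion.
* ``"corrected"`` — the juvenile pool loses only the maturing fraction
  ``a * J(i-3) * d_j``, so individuals are conserved.

Literal mode can, for extreme egg-laying schedules, drive the juvenile pool
negative; such values are clamped to zero and every clamp is recorded as a
diagnostic rather than silently absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "MODES",
    "MONTHS_PER_SEASON",
    "ModelParameters",
    "MonthlyState",
    "Diagnostic",
    "SimulationResult",
    "lay_eggs",
    "update_juveniles",
    "update_adults",
    "overwinter",
    "simulate",
]

MONTHS_PER_SEASON = 6
MATURATION_LAG = 3
MODES = ("literal", "corrected")

Mode = Literal["literal", "corrected"]

#: names of the scalar probability/ratio parameters, all constrained to [0, 1]
SCALAR_PARAMS = ("d_a1", "d_a2", "d_a3", "d_j", "d_e", "d_w", "a")


def _as_schedule(values, name: str) -> tuple[float, ...]:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (MONTHS_PER_SEASON,):
        raise ValueError(
            f"{name} must have exactly {MONTHS_PER_SEASON} monthly values, "
            f"got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be element-wise non-negative")
    return tuple(float(v) for v in arr)


@dataclass(frozen=True)
class ModelParameters:
    """Demographic rates and egg-laying schedules of the seasonal model.

    Parameters
    ----------
    d_a1, d_a2, d_a3
        Monthly survival probabilities of adults in age classes 1-3.
    d_j
        Monthly survival probability of juveniles.
    d_e
        Egg hatching ratio: fraction of eggs laid in month ``i-1`` that
        hatch in month ``i``.
    d_w
        Winter survival probability, applied to juveniles and all adult
        classes during the overwintering transition.
    a
        Recruitment ratio: fraction of a juvenile cohort maturing within
        its season of hatching (months 5-6); the remainder matures after
        overwintering.
    e1, e2, e3
        Per-capita monthly egg-laying schedules for adult age classes 1-3,
        six values each (month 1 = May .. month 6 = October).  ``e3``
        defaults to zero: age-3 adults appear in the life-cycle diagram as
        potential layers but contribute no eggs in the published recursion.
    """

    d_a1: float
    d_a2: float
    d_a3: float
    d_j: float
    d_e: float
    d_w: float
    a: float
    e1: tuple[float, ...]
    e2: tuple[float, ...]
    e3: tuple[float, ...] = (0.0,) * MONTHS_PER_SEASON

    def __post_init__(self) -> None:
        for name in SCALAR_PARAMS:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and np.isfinite(value)):
                raise ValueError(f"parameter {name} must be a finite number")
            if not 0.0 <= value <= 1.0:
                raise ValueError(
                    f"parameter {name}={value} out of range [0, 1]"
                )
        for name in ("e1", "e2", "e3"):
            object.__setattr__(self, name, _as_schedule(getattr(self, name), name))

    def egg_rate(self, age_class: int, i: int) -> float:
        """Per-capita laying rate of ``age_class`` (1-3) in month ``i`` (1-6)."""
        _check_month(i)
        schedule = (self.e1, self.e2, self.e3)[age_class - 1]
        return schedule[i - 1]

    def with_winter_survival(self, d_w: float) -> "ModelParameters":
        """Copy of the parameter set with ``d_w`` replaced (scenario override)."""
        return replace(self, d_w=d_w)


def _check_month(i: int) -> None:
    if not (isinstance(i, (int, np.integer)) and 1 <= i <= MONTHS_PER_SEASON):
        raise ValueError(f"month index must be in 1..{MONTHS_PER_SEASON}, got {i!r}")


@dataclass(frozen=True)
class MonthlyState:
    """Population state in one month: expected abundances per stage.

    ``E`` is the number of eggs laid *this* month; ``J`` the juveniles
    present; ``N1``..``N3`` the adults per age class.  ``season`` (j >= 1)
    and ``month`` (i in 1..6) locate the state in time.  The recursion
    produces ``J = 0`` in every month-1 state it builds (nothing hatches
    over winter); a user-supplied initial state may carry juveniles.
    """

    season: int
    month: int
    E: float = 0.0
    J: float = 0.0
    N1: float = 0.0
    N2: float = 0.0
    N3: float = 0.0

    def __post_init__(self) -> None:
        if self.season < 1:
            raise ValueError(f"season index must be >= 1, got {self.season}")
        _check_month(self.month)
        for name in ("E", "J", "N1", "N2", "N3"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"abundance {name}={value} must be finite and >= 0")

    @property
    def total(self) -> float:
        """Total individuals: juveniles plus adults, eggs excluded."""
        return self.J + self.N1 + self.N2 + self.N3

    @property
    def step(self) -> int:
        """Global 1-based month step ``(season - 1) * 6 + month``."""
        return (self.season - 1) * MONTHS_PER_SEASON + self.month

    def scaled(self, c: float) -> "MonthlyState":
        """State with every abundance multiplied by ``c >= 0``."""
        if c < 0:
            raise ValueError("scale factor must be >= 0")
        return replace(
            self, E=c * self.E, J=c * self.J, N1=c * self.N1, N2=c * self.N2,
            N3=c * self.N3,
        )


@dataclass(frozen=True)
class Diagnostic:
    """A recorded numerical event (currently only negative-value clamps)."""

    season: int
    month: int
    kind: str
    value: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.kind} at season {self.season} month {self.month}: "
            f"{self.value:.6g} clamped to 0"
        )


def lay_eggs(state: MonthlyState, params: ModelParameters) -> float:
    """Eggs laid in the state's month by the adults present in it.

    ``E(i,j) = N1(i,j) e1(i) + N2(i,j) e2(i) + N3(i,j) e3(i)`` — the third
    term is zero under the default schedule.
    """
    i = state.month
    return (
        state.N1 * params.egg_rate(1, i)
        + state.N2 * params.egg_rate(2, i)
        + state.N3 * params.egg_rate(3, i)
    )


def update_juveniles(
    history: Sequence[MonthlyState],
    params: ModelParameters,
    i: int,
    mode: Mode = "literal",
    diagnostics: list[Diagnostic] | None = None,
) -> float:
    """Juveniles present in month ``i`` of the current season.

    ``history`` holds the season's states for months ``1..i-1`` in order.
    Month 1 has no juveniles (eggs do not overwinter and nothing hatches in
    May); from month 2 the pool is last month's survivors plus hatchlings
    from last month's eggs; in months 5 and 6 the cohort hatched three
    months earlier leaves via maturation, with the outflow depending on the
    bookkeeping ``mode`` (see module docstring).

    A negative result (possible in literal mode) is clamped to zero; the
    clamp is appended to ``diagnostics`` when a list is provided.
    """
    _check_month(i)
    _check_mode(mode)
    if i == 1:
        return 0.0
    if len(history) < i - 1:
        raise ValueError(
            f"need states for months 1..{i - 1}, got {len(history)}"
        )
    prev = history[i - 2]
    hatched = prev.E * params.d_e
    # month 2 reduces to E(1)*d_e alone in every model-generated season,
    # since overwintering leaves J(1) = 0; carrying prev.J survivors here
    # also handles a user-supplied initial state with juveniles.
    value = prev.J * params.d_j + hatched
    if i >= MONTHS_PER_SEASON - 1:  # months 5 and 6: maturation outflow
        lagged = history[i - 1 - MATURATION_LAG]
        outflow_fraction = (1.0 - params.a) if mode == "literal" else params.a
        value -= outflow_fraction * lagged.J * params.d_j
    if value < 0.0:
        if diagnostics is not None:
            season = prev.season
            diagnostics.append(Diagnostic(season, i, "negative_juveniles", value))
        value = 0.0
    return value


def update_adults(
    history: Sequence[MonthlyState],
    params: ModelParameters,
    i: int,
) -> tuple[float, float, float]:
    """Adults ``(N1, N2, N3)`` in month ``i`` (within-season months 2..6).

    Each class survives from the previous month at its own rate; in months
    5 and 6, age class 1 additionally receives the maturing fraction
    ``a * J(i-3) * d_j`` of the juvenile cohort hatched three months
    earlier.  Month 1 is produced by :func:`overwinter`, not here.
    """
    if not 2 <= i <= MONTHS_PER_SEASON:
        raise ValueError(f"within-season adult update needs month 2..6, got {i}")
    if len(history) < i - 1:
        raise ValueError(f"need states for months 1..{i - 1}, got {len(history)}")
    prev = history[i - 2]
    n1 = prev.N1 * params.d_a1
    if i >= MONTHS_PER_SEASON - 1:
        lagged = history[i - 1 - MATURATION_LAG]
        n1 += params.a * lagged.J * params.d_j
    n2 = prev.N2 * params.d_a2
    n3 = prev.N3 * params.d_a3
    return n1, n2, n3


def overwinter(final_state: MonthlyState, params: ModelParameters) -> MonthlyState:
    """Overwintering transition: month-6 state -> month-1 state of next season.

    Surviving juveniles mature into age class 1, each adult class advances
    one class, all thinned by ``d_w``; age-3 adults are removed (there is
    no fourth class) and unhatched eggs are discarded.  Eggs of the new
    month are laid afresh by the overwintered adults.
    """
    if final_state.month != MONTHS_PER_SEASON:
        raise ValueError(
            f"overwinter expects a month-{MONTHS_PER_SEASON} state, "
            f"got month {final_state.month}"
        )
    state = MonthlyState(
        season=final_state.season + 1,
        month=1,
        J=0.0,
        N1=final_state.J * params.d_w,
        N2=final_state.N1 * params.d_w,
        N3=final_state.N2 * params.d_w,
    )
    return replace(state, E=lay_eggs(state, params))


@dataclass(frozen=True)
class SimulationResult:
    """Full trajectory of a deterministic run.

    ``states`` covers seasons ``1..n_seasons`` with six monthly states
    each; ``totals[t]`` is juveniles + adults at step ``t`` (0-based over
    the flattened trajectory); ``diagnostics`` lists clamping events.
    """

    states: tuple[MonthlyState, ...]
    parameters: ModelParameters
    mode: Mode
    diagnostics: tuple[Diagnostic, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.states) % MONTHS_PER_SEASON != 0 or not self.states:
            raise ValueError("trajectory must cover whole seasons")

    @property
    def n_seasons(self) -> int:
        return len(self.states) // MONTHS_PER_SEASON

    @property
    def totals(self) -> np.ndarray:
        """Array of total individuals per step (eggs excluded)."""
        return np.array([s.total for s in self.states])

    def season_states(self, j: int) -> tuple[MonthlyState, ...]:
        """The six monthly states of season ``j`` (1-based)."""
        if not 1 <= j <= self.n_seasons:
            raise ValueError(
                f"season {j} outside simulated range 1..{self.n_seasons}"
            )
        lo = (j - 1) * MONTHS_PER_SEASON
        return self.states[lo : lo + MONTHS_PER_SEASON]

    def to_frame(self):
        """Trajectory as a DataFrame: season,month,step,E,J,N1,N2,N3,N_total."""
        import pandas as pd

        return pd.DataFrame(
            {
                "season": [s.season for s in self.states],
                "month": [s.month for s in self.states],
                "step": [s.step for s in self.states],
                "E": [s.E for s in self.states],
                "J": [s.J for s in self.states],
                "N1": [s.N1 for s in self.states],
                "N2": [s.N2 for s in self.states],
                "N3": [s.N3 for s in self.states],
                "N_total": [s.total for s in self.states],
            }
        )


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"bookkeeping mode must be one of {MODES}, got {mode!r}")


def simulate(
    initial_state: MonthlyState,
    params: ModelParameters,
    n_seasons: int,
    mode: Mode = "literal",
) -> SimulationResult:
    """Run the model for ``n_seasons`` seasons of six months each.

    ``initial_state`` must be a month-1 state; its eggs are recomputed from
    its adults (month-1 eggs are always laid by the adults present, they
    cannot be carried in from outside the season).  Within each season,
    months 2..6 apply the juvenile and adult updates followed by egg
    laying; seasons are joined by :func:`overwinter`.
    """
    if n_seasons < 1:
        raise ValueError(f"n_seasons must be >= 1, got {n_seasons}")
    if initial_state.month != 1:
        raise ValueError("initial state must be a month-1 state")
    _check_mode(mode)

    diagnostics: list[Diagnostic] = []
    first = replace(initial_state, season=1, E=0.0)
    first = replace(first, E=lay_eggs(first, params))

    states: list[MonthlyState] = []
    season_start = first
    for j in range(1, n_seasons + 1):
        season: list[MonthlyState] = [season_start]
        for i in range(2, MONTHS_PER_SEASON + 1):
            J = update_juveniles(season, params, i, mode, diagnostics)
            n1, n2, n3 = update_adults(season, params, i)
            state = MonthlyState(season=j, month=i, J=J, N1=n1, N2=n2, N3=n3)
            state = replace(state, E=lay_eggs(state, params))
            season.append(state)
        states.extend(season)
        if j < n_seasons:
            season_start = overwinter(season[-1], params)

    return SimulationResult(
        states=tuple(states),
        parameters=params,
        mode=mode,
        diagnostics=tuple(diagnostics),
    )
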
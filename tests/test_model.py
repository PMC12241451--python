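"""Unit tests of the deterministic core: single-step hand arithmetic,
structural zeros and the overwintering transition."""

import dataclasses

import numpy as np
import pytest

from vertigopop import (
    ModelParameters,
    MonthlyState,
    lay_eggs,
    overwinter,
    simulate,
    update_adults,
    update_juveniles,
)


def make_params(**kw):
    base = dict(
        d_a1=0.9, d_a2=0.9, d_a3=0.9, d_j=0.9, d_e=0.8, d_w=0.7, a=0.1,
        e1=(5, 5, 5, 5, 0, 0), e2=(5, 5, 5, 5, 0, 0),
    )
    base.update(kw)
    return ModelParameters(**base)


def state(i=1, j=1, **kw):
    return MonthlyState(season=j, month=i, **kw)


class TestLayEggs:
    @pytest.mark.parametrize(
        "n1,n2,e1i,e2i,expected",
        [
            (10, 0, 5, 0, 50),     # single-class laying, checked by hand
            (0, 0, 5, 5, 0),       # empty population lays nothing
            (4, 6, 2, 3, 26),      # 4*2 + 6*3
        ],
    )
    def test_hand_examples(self, n1, n2, e1i, e2i, expected):
        p = make_params(e1=(e1i,) * 4 + (0, 0), e2=(e2i,) * 4 + (0, 0))
        assert lay_eggs(state(i=1, N1=n1, N2=n2), p) == expected

    def test_age3_lay_nothing_by_default(self):
        p = make_params()
        assert lay_eggs(state(i=2, N3=1000), p) == 0

    def test_age3_schedule_used_when_configured(self):
        p = make_params(e3=(2, 0, 0, 0, 0, 0))
        assert lay_eggs(state(i=1, N3=10), p) == 20

    def test_no_laying_in_months_5_6_by_default(self):
        p = make_params()
        s = state(i=5, N1=100, N2=100)
        assert lay_eggs(s, p) == 0


class TestUpdateJuveniles:
    def test_month_one_is_always_empty(self):
        p = make_params()
        assert update_juveniles([], p, 1) == 0.0

    def test_month_two_hatches_month_one_eggs(self):
        p = make_params(d_e=0.8)
        history = [state(i=1, E=50)]
        assert update_juveniles(history, p, 2) == pytest.approx(40.0)

    def test_month_five_literal_mode(self):
        # J(4)=100, J(2)=30, E(4)=0, d_j=0.9, a=0.1:
        # 100*0.9 - 0.9*30*0.9 = 65.7 (hand arithmetic)
        p = make_params(d_j=0.9, a=0.1)
        history = [state(i=1), state(i=2, J=30), state(i=3, J=60),
                   state(i=4, J=100, E=0)]
        got = update_juveniles(history, p, 5, mode="literal")
        assert got == pytest.approx(65.7)

    def test_month_five_corrected_mode_subtracts_maturing_fraction(self):
        # corrected: 100*0.9 - 0.1*30*0.9 = 87.3
        p = make_params(d_j=0.9, a=0.1)
        history = [state(i=1), state(i=2, J=30), state(i=3, J=60),
                   state(i=4, J=100, E=0)]
        got = update_juveniles(history, p, 5, mode="corrected")
        assert got == pytest.approx(87.3)

    def test_full_recruitment_matches_plain_branch(self):
        # with a=1 the (1-a) outflow vanishes in literal mode
        p = make_params(a=1.0)
        history = [state(i=1), state(i=2, J=30), state(i=3, J=60),
                   state(i=4, J=100, E=20)]
        literal = update_juveniles(history, p, 5, mode="literal")
        plain = history[3].J * p.d_j + history[3].E * p.d_e
        assert literal == pytest.approx(plain)

    def test_negative_intermediate_clamped_and_logged(self):
        # huge lagged cohort, tiny current pool -> literal mode goes negative
        p = make_params(a=0.0, d_j=0.9)
        history = [state(i=1), state(i=2, J=1000), state(i=3, J=10),
                   state(i=4, J=1, E=0)]
        diagnostics = []
        got = update_juveniles(history, p, 5, mode="literal",
                               diagnostics=diagnostics)
        assert got == 0.0
        assert len(diagnostics) == 1
        assert diagnostics[0].kind == "negative_juveniles"

    def test_invalid_month_rejected(self):
        with pytest.raises(ValueError, match="month"):
            update_juveniles([], make_params(), 7)


class TestUpdateAdults:
    def test_pure_survival_month(self):
        p = make_params(d_a1=0.875)
        history = [state(i=1), state(i=2, N1=100)]
        n1, n2, n3 = update_adults(history, p, 3)
        assert n1 == pytest.approx(87.5)

    def test_recruitment_month(self):
        # N1 = 50*0.9 + 0.125*40*0.8 = 49 (hand arithmetic)
        p = make_params(d_a1=0.9, d_j=0.8, a=0.125)
        history = [state(i=1), state(i=2, J=40), state(i=3),
                   state(i=4, N1=50)]
        n1, _, _ = update_adults(history, p, 5)
        assert n1 == pytest.approx(49.0)

    def test_zero_propagates(self):
        p = make_params()
        history = [state(i=1), state(i=2), state(i=3, N2=0, N3=0)]
        _, n2, n3 = update_adults(history, p, 4)
        assert n2 == 0 and n3 == 0

    def test_month_one_not_handled_here(self):
        with pytest.raises(ValueError):
            update_adults([], make_params(), 1)


class TestOverwinter:
    def test_juveniles_mature_through_winter(self):
        p = make_params(d_w=0.7)
        nxt = overwinter(state(i=6, J=100), p)
        assert nxt.N1 == pytest.approx(70.0)
        assert nxt.month == 1 and nxt.J == 0.0

    def test_classes_advance_one_step(self):
        p = make_params(d_w=0.5)
        nxt = overwinter(state(i=6, J=10, N1=20, N2=40, N3=80), p)
        assert (nxt.N1, nxt.N2, nxt.N3) == (5.0, 10.0, 20.0)

    def test_zero_winter_survival_empties_population(self):
        p = make_params(d_w=0.0)
        nxt = overwinter(state(i=6, J=100, N1=100, N2=100, N3=100), p)
        assert nxt.total == 0.0

    def test_age_three_adults_removed(self):
        p = make_params(d_w=1.0)
        nxt = overwinter(state(i=6, N3=500), p)
        assert nxt.total == 0.0

    def test_unhatched_eggs_discarded(self):
        p = make_params(d_w=1.0)
        nxt = overwinter(state(i=6, E=1000), p)
        assert nxt.total == 0.0 and nxt.E == 0.0

    def test_overwintered_adults_lay_fresh_eggs(self):
        p = make_params(d_w=1.0, e1=(5, 0, 0, 0, 0, 0))
        nxt = overwinter(state(i=6, J=10), p)
        assert nxt.E == pytest.approx(50.0)


class TestSimulate:
    def test_empty_state_stays_empty(self, params):
        res = simulate(MonthlyState(season=1, month=1), params, 3)
        assert np.all(res.totals == 0)

    def test_doubling_initial_state_doubles_everything(self, params,
                                                       initial_state):
        res1 = simulate(initial_state, params, 5)
        res2 = simulate(initial_state.scaled(2.0), params, 5)
        # scaling by a power of two is exact in binary floating point
        for s1, s2 in zip(res1.states, res2.states):
            for f in ("E", "J", "N1", "N2", "N3"):
                assert getattr(s2, f) == 2.0 * getattr(s1, f)

    def test_zero_winter_survival_extinct_from_month_seven(self, initial_state):
        p = make_params(d_w=0.0)
        res = simulate(initial_state, p, 3)
        assert np.all(res.totals[6:] == 0)
        assert np.all(res.totals[:6] > 0)

    def test_month_one_juveniles_zero_after_first_season(self, params,
                                                         initial_state):
        res = simulate(initial_state, params, 6)
        for j in range(2, 7):
            assert res.season_states(j)[0].J == 0.0

    def test_eggs_zero_in_months_5_6_under_default_schedule(self, params,
                                                            initial_state):
        res = simulate(initial_state, params, 4)
        for s in res.states:
            if s.month in (5, 6):
                assert s.E == 0.0

    def test_trajectory_covers_all_months(self, params, initial_state):
        res = simulate(initial_state, params, 7)
        assert len(res.states) == 42
        assert [s.step for s in res.states] == list(range(1, 43))

    def test_invalid_parameters_rejected_before_running(self):
        with pytest.raises(ValueError, match="d_w"):
            make_params(d_w=1.3)

    def test_non_month1_initial_state_rejected(self, params):
        with pytest.raises(ValueError, match="month-1"):
            simulate(MonthlyState(season=1, month=3), params, 2)


class TestModelParameters:
    def test_schedule_length_enforced(self):
        with pytest.raises(ValueError, match="e1"):
            make_params(e1=(1, 2, 3))

    def test_negative_schedule_rejected(self):
        with pytest.raises(ValueError, match="e2"):
            make_params(e2=(1, -1, 0, 0, 0, 0))

    def test_frozen(self):
        p = make_params()
        with pytest.raises(dataclasses.FrozenInstanceError):
            p.d_w = 0.5
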
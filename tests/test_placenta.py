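import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placigg.parameters import SUBCLASSES
from placigg.placenta import (
    HIERARCHY,
    Species,
    baseline_species,
    competition_experiment,
    fm_hierarchy_holds,
    placental_rhs,
    simulate,
    subclass_entropy,
)
from placigg.receptors import Receptor, make_schedule, schedules_from_parameters


class TestRhs:
    def test_zero_state_is_absorbing(self, params):
        sched = schedules_from_parameters(params)
        species = [
            Species(sp.name, sp.kon_fcrn, sp.kon_fcgr2b, sp.k_off, 0.0)
            for sp in baseline_species(params)
        ]
        y0 = np.zeros(7 * 4)
        dy = placental_rhs(10.0, y0, params, sched, species)
        np.testing.assert_array_equal(dy, 0.0)

    def test_fetal_igg1_rising_at_term(self, params, baseline_sim):
        sched = baseline_sim.schedules
        dy = placental_rhs(40.0, baseline_sim.y[:, -1], params, sched,
                           baseline_sim.species)
        d_fetal_igg1 = dy.reshape(4, 7)[0, 6]
        assert d_fetal_igg1 > 0


class TestMassBalance:
    def test_moles_conserved_without_degradation(self, params):
        p0 = replace(params, k_deg=1e-30, delta_Ab=1e-30)
        res = simulate(p0, deplete_maternal=True)
        moles = res.total_moles()
        drift = (moles.max() - moles.min()) / moles[0]
        assert drift < 1e-8

    def test_degradation_loses_moles(self, params):
        res = simulate(params, deplete_maternal=True)
        moles = res.total_moles()
        assert moles[-1] < moles[0]


class TestSimulate:
    def test_subclass_transfer_hierarchy(self, baseline_sim):
        fm = baseline_sim.fm_at_end()
        assert fm_hierarchy_holds(fm, baseline_sim.species_names, HIERARCHY)

    def test_zero_maternal_igg_gives_zero_fetal(self, params):
        p0 = replace(params, igg0=np.zeros(4))
        res = simulate(p0)
        np.testing.assert_array_equal(res.fetal, 0.0)

    def test_halving_receptors_reduces_transfer(self, params, baseline_sim):
        halved = params.with_free_values({
            name: getattr(params, name) / 2
            for name in ("FcRnSTBtotal_end", "FcgRIIbECtotal_end", "FcRnECtotal_end")
        })
        res = simulate(halved)
        assert res.total_fetal()[-1] < baseline_sim.total_fetal()[-1]

    @pytest.mark.parametrize("name, direction", [
        ("k_trans", +1),
        ("FcRnSTBtotal_end", +1),
        ("FcgRIIbECtotal_end", +1),
        ("FcRnECtotal_end", +1),
        ("V_F", -1),
        ("V_EC", -1),
        ("V_STB", -1),
        ("V_STR", -1),
    ])
    def test_local_monotonicity_within_ranges(self, params, ranges, name, direction):
        """Term fetal IgG rises with transfer capacity and falls with the
        diluting volumes across each parameter's calibrated range."""
        lo, hi = ranges.bounds[name]
        f_lo = simulate(params.with_free_values({name: lo})).total_fetal()[-1]
        f_hi = simulate(params.with_free_values({name: hi})).total_fetal()[-1]
        assert direction * (f_hi - f_lo) > 0

    def test_trajectory_invariants_hold(self, baseline_sim):
        baseline_sim.validate()  # non-negativity and bound <= scheduled total
        assert baseline_sim.y.min() >= -1e-12

    def test_tolerance_refinement_stable(self, params, baseline_sim):
        fine = simulate(params, rtol=1e-10, atol=1e-14)
        rel = abs(fine.total_fetal()[-1] - baseline_sim.total_fetal()[-1])
        assert rel / fine.total_fetal()[-1] < 1e-3

    def test_weekly_output_grid(self, baseline_sim):
        assert baseline_sim.t[0] == 0.0
        assert baseline_sim.t[-1] == 40.0
        assert np.all(np.diff(baseline_sim.t) <= 1.0 + 1e-9)

    def test_fm_ratio_matches_fetal_over_maternal(self, baseline_sim, params):
        np.testing.assert_allclose(
            baseline_sim.fm_at_end(),
            baseline_sim.fetal_at_end() / params.igg0,
        )


class TestEntropy:
    def test_uniform_distribution_is_maximal(self):
        assert subclass_entropy([2.0, 2.0, 2.0, 2.0]) == pytest.approx(math.log(4))

    def test_degenerate_distribution_is_zero(self):
        assert subclass_entropy([5.0, 0.0, 0.0, 0.0]) == 0.0

    def test_mixed_distribution(self):
        assert subclass_entropy([2.0, 1.0, 1.0, 0.0]) == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            subclass_entropy([0.0, 0.0, 0.0, 0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            subclass_entropy([1.0, -1.0, 0.0, 0.0])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1e3), min_size=4, max_size=4))
    def test_bounds_and_scale_invariance(self, concs):
        c = np.array(concs)
        e = subclass_entropy(c)
        assert 0.0 <= e <= math.log(4) + 1e-12
        assert subclass_entropy(10.0 * c) == pytest.approx(e, rel=1e-9)


@pytest.fixture(scope="module")
def sweep(params):
    grid = params.FcgRIIbECtotal_end * np.array([1.0, 100.0])
    return competition_experiment(params, R2b_sweep=grid)


class TestCompetition:
    def test_isolated_transfer_beats_mixed(self, sweep):
        assert np.all(sweep["isolated"] + 1e-12 >= sweep["mixed"])

    def test_competition_vanishes_when_all_receptors_in_excess(self, params):
        # Competition requires a limiting shared pool; scaling every
        # receptor total far above the ligand load removes it.  (Scaling
        # FcgRIIb alone does not: the STB FcRn pool stays limiting.)
        sat = params.with_free_values({
            name: getattr(params, name) * 100
            for name in ("FcRnSTBtotal_end", "FcgRIIbECtotal_end", "FcRnECtotal_end")
        })
        out = competition_experiment(
            sat, R2b_sweep=np.array([sat.FcgRIIbECtotal_end])
        )
        rel = out["delta"][0] / out["isolated"][0]
        assert np.all(rel < 0.05)

    def test_empty_grid_rejected(self, params):
        with pytest.raises(ValueError):
            competition_experiment(params, R2b_sweep=np.array([]))


def test_hierarchy_ties_fail():
    assert not fm_hierarchy_holds(
        [1.0, 0.5, 1.0, 0.7], ["IgG1", "IgG2", "IgG3", "IgG4"], HIERARCHY
    )
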
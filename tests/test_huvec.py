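from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import fsolve

from placigg.huvec import (
    AnalysisError,
    HuvecParameters,
    closed_form_complex,
    competition_curve,
    find_saturation_point,
    huvec_rhs,
    mg_ml_to_nM,
    simulate_huvec,
)


@pytest.fixture(scope="module")
def hp():
    return HuvecParameters()


class TestRhs:
    def test_zero_igg_is_stationary(self, hp):
        y = np.array([0.0, 0.0, hp.FcRn0, 0.0, 0.0, 0.0, 0.0])
        np.testing.assert_array_equal(huvec_rhs(0.0, y, hp), 0.0)

    def test_receptor_pool_conserved_in_rhs(self, hp):
        """d([FcRn]+[C1]+[C4])/dt vanishes: receptor recycles on transcytosis."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.uniform(0, 1000, size=7)
            dy = huvec_rhs(0.0, y, hp)
            assert dy[2] + dy[3] + dy[4] == pytest.approx(0.0, abs=1e-9)

    def test_receptor_conservation_along_trajectory(self, hp):
        sol = simulate_huvec(hp, mg_ml_to_nM(0.1), mg_ml_to_nM(0.2))
        total = sol.y[2] + sol.y[3] + sol.y[4]
        np.testing.assert_allclose(total, hp.FcRn0, rtol=1e-7)

    def test_langmuir_equilibrium_without_transcytosis(self):
        p = HuvecParameters(k_trans=1e-12)
        igg4 = 1e5  # large excess keeps free IgG ~ total
        sol = simulate_huvec(p, 0.0, igg4, duration_min=30.0)
        expect = p.FcRn0 * igg4 / (p.KD4 + igg4)
        assert sol.y[4, -1] == pytest.approx(expect, rel=1e-2)


class TestClosedForm:
    def test_no_ligand_no_complex(self, hp):
        assert closed_form_complex(0.0, 500.0, hp.FcRn0, hp.KD4, hp.KD1) == 0.0

    def test_saturation_limit(self, hp):
        c4 = closed_form_complex(1e12, 0.0, hp.FcRn0, hp.KD4, hp.KD1)
        assert c4 == pytest.approx(hp.FcRn0, rel=1e-6)

    def test_symmetry_with_equal_affinity_and_dose(self, hp):
        c_a = closed_form_complex(300.0, 300.0, hp.FcRn0, 50.0, 50.0)
        c_b = closed_form_complex(300.0, 300.0, hp.FcRn0, 50.0, 50.0)
        assert c_a == c_b

    def test_against_brute_force_quasi_steady_state(self, hp):
        """Numerically solve the coupled complex balance (both complexes plus
        receptor conservation) and compare with the closed form."""
        rng = np.random.default_rng(1)
        for _ in range(1000):
            igg1, igg4 = rng.uniform(1.0, 5e4, size=2)
            r0 = rng.uniform(10.0, 5e3)
            kd1, kd4 = rng.uniform(5.0, 500.0, size=2)

            def balance(c):
                c1, c4 = c
                free = r0 - c1 - c4
                return [c1 * kd1 - igg1 * free, c4 * kd4 - igg4 * free]

            c1, c4 = fsolve(balance, [r0 / 3, r0 / 3], xtol=1e-12)
            assert closed_form_complex(igg4, igg1, r0, kd4, kd1) == pytest.approx(
                c4, rel=1e-9, abs=1e-9
            )
        # companion symmetry: the same call with roles swapped gives C1
            assert closed_form_complex(igg1, igg4, r0, kd1, kd4) == pytest.approx(
                c1, rel=1e-9, abs=1e-9
            )

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=0, max_value=1e5),
        st.floats(min_value=0, max_value=1e5),
        st.floats(min_value=1e-3, max_value=1e4),
    )
    def test_complex_bounded_by_receptor(self, igg4, igg1, r0):
        c4 = closed_form_complex(igg4, igg1, r0, 50.0, 12.5)
        assert 0.0 <= c4 <= r0

    def test_negative_inputs_rejected(self, hp):
        with pytest.raises(ValueError):
            closed_form_complex(-1.0, 0.0, hp.FcRn0, hp.KD4, hp.KD1)
        with pytest.raises(ValueError):
            closed_form_complex(1.0, 0.0, hp.FcRn0, -5.0, hp.KD1)


class TestSaturation:
    def test_matches_receptor_capacity(self, hp):
        """The dose-response breakpoint sits near the apical concentration
        stoichiometrically matching the FcRn pool (~0.33 mg/ml)."""
        out = find_saturation_point(hp)
        assert out["saturation_mg_ml"] == pytest.approx(0.33, abs=0.05)

    def test_no_transcytosis_is_degenerate(self):
        p = HuvecParameters(k_trans=0.0)
        with pytest.raises(AnalysisError):
            find_saturation_point(p)

    def test_more_receptor_delays_saturation(self, hp):
        doubled = replace(hp, FcRn0=2 * hp.FcRn0)
        base = find_saturation_point(hp)["saturation_mg_ml"]
        high = find_saturation_point(
            doubled, sweep_mg_ml=np.arange(0.05, 2.0, 0.04)
        )["saturation_mg_ml"]
        assert high > base

    def test_non_increasing_grid_rejected(self, hp):
        with pytest.raises(ValueError):
            find_saturation_point(hp, sweep_mg_ml=np.array([0.5, 0.4, 0.6]))


@pytest.fixture(scope="module")
def curve(hp):
    return competition_curve(hp, igg1_sweep_mg_ml=np.arange(0.0, 0.61, 0.02))


class TestCompetitionCurve:
    def test_igg1_free_point_matches_pure_run(self, hp, curve):
        sol = simulate_huvec(hp, 0.0, mg_ml_to_nM(0.2))
        assert curve["igg4_transcytosed_nM"][0] == pytest.approx(
            sol.y[6, -1], rel=1e-9
        )

    def test_igg4_transcytosis_non_increasing_in_igg1(self, curve):
        diffs = np.diff(curve["igg4_transcytosed_nM"])
        assert np.all(diffs <= 1e-9 * curve["igg4_transcytosed_nM"][0])

    def test_onset_near_receptor_capacity(self, curve):
        assert curve["onset_total_mg_ml"] == pytest.approx(0.33, abs=0.05)


class TestDataIO:
    def _synthetic_timecourse(self, hp, tmp_path):
        """Synthetic replicate-level time-course shaped like assay exports."""
        import pandas as pd

        rows = []
        for c4 in (0.125, 0.5):
            sol = simulate_huvec(hp, 0.0, mg_ml_to_nM(c4), 120.0,
                                 t_eval=np.array([15.0, 30.0, 60.0, 120.0]))
            for rep in (1, 2, 3):
                for t, v in zip(sol.t, sol.y[6]):
                    rows.append({
                        "t_min": t, "apical_igg1_mg_ml": 0.0,
                        "apical_igg4_mg_ml": c4, "replicate": rep,
                        "basolateral_igg4_nM": v,
                    })
        path = tmp_path / "transcytosis.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    def test_reader_validates_columns(self, tmp_path):
        import pandas as pd

        bad = tmp_path / "bad.csv"
        pd.DataFrame({"t_min": [15.0]}).to_csv(bad, index=False)
        from placigg.huvec import read_transcytosis_csv

        with pytest.raises(ValueError):
            read_transcytosis_csv(bad)

    def test_refit_recovers_transcytosis_rate(self, hp, tmp_path):
        from placigg.huvec import read_transcytosis_csv, refit_transcytosis

        df = read_transcytosis_csv(self._synthetic_timecourse(hp, tmp_path))
        start = replace(hp, k_trans=2 * hp.k_trans)
        fit = refit_transcytosis(df, start=start, free=("k_trans",))
        assert fit.k_trans == pytest.approx(hp.k_trans, rel=1e-3)
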
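"""SRK/T engine: frozen worked examples, oracle equivalence, and the
formula's structural properties (self-consistency, monotonicity in power,
near-continuity at the long-eye breakpoint)."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from iolsvr import srkt
from iolsvr.exceptions import (
    InvalidConfigError,
    InvalidInputError,
)
from srkt_stepwise import (
    oracle_chain,
    oracle_emmetropia_power,
    oracle_refraction,
)
from conftest import random_physiological_eyes


class TestElementaryMaps:
    @pytest.mark.parametrize(
        "cr, expected",
        [(7.63, 44.2333), (337.5, 1.0), (6.72, 50.2232)],
    )
    def test_keratometry_examples(self, cr, expected):
        assert srkt.keratometry_from_radius(cr) == pytest.approx(expected, abs=1e-3)

    def test_keratometry_rejects_nonpositive_radius(self):
        with pytest.raises(InvalidInputError):
            srkt.keratometry_from_radius(0.0)

    @pytest.mark.parametrize(
        "a, expected",
        [(119.21, 5.71991), (68.747 / 0.62467, 0.0), (118.26, 5.12647)],
    )
    def test_acd_constant_examples(self, a, expected):
        assert srkt.acd_constant_from_a(a) == pytest.approx(expected, abs=1e-4)

    def test_acd_constant_rejects_out_of_range(self):
        with pytest.raises(InvalidInputError):
            srkt.acd_constant_from_a(109.0)

    @pytest.mark.parametrize(
        "axl, expected, tol",
        [
            (24.0, 24.0, 0.0),       # identity branch
            (26.0, 25.1228, 1e-3),
            (30.5, 26.814575, 1e-4),  # hand-evaluated quadratic
        ],
    )
    def test_corrected_axial_length(self, axl, expected, tol):
        assert srkt.corrected_axial_length(axl) == pytest.approx(expected, abs=tol or 1e-12)

    def test_lcor_breakpoint_gap(self):
        """The published quadratic is near- but not exactly continuous at
        24.2 mm; the measured gap is about 0.023 mm."""
        below = srkt.corrected_axial_length(24.2)
        above = srkt.corrected_axial_length(np.nextafter(24.2, 25.0))
        gap = abs(float(below) - float(above))
        assert gap == pytest.approx(0.022668, abs=1e-4)
        assert gap < 0.03


class TestFormulaChain:
    def test_worked_chain(self):
        res = srkt.srkt_chain(24.0, 7.63, 119.21)
        assert res.h == pytest.approx(3.589, abs=0.005)
        assert res.elp == pytest.approx(5.973, abs=0.005)
        assert res.lopt == pytest.approx(24.17, abs=0.005)
        assert res.rethick == pytest.approx(0.65696 - 0.02029 * 24.0, abs=1e-12)

    def test_worked_refraction_and_power(self):
        ref = srkt.predicted_refraction(24.0, 7.63, 119.21, 19.5)
        assert ref == pytest.approx(-0.199, abs=0.01)
        assert srkt.emmetropia_power(24.0, 7.63, 119.21) == pytest.approx(
            19.19, abs=0.05
        )

    def test_corneal_height_clamp(self):
        # a huge keratometry drives Cw^2/4 past r^2; H must clamp to r
        res = srkt.srkt_chain(30.0, 4.0, 119.0, srkt.SRKTConstants())
        assert bool(res.clamped.any())
        assert float(res.h) == pytest.approx(4.0)

    def test_oracle_equivalence_chain_and_refraction(self):
        """Implementation vs the independently coded stepwise oracle,
        1e-9 D on 1000 random physiological inputs."""
        eyes = random_physiological_eyes(1000, seed=42)
        rng = np.random.default_rng(43)
        powers = rng.uniform(5.0, 30.0, len(eyes))
        got = srkt.predicted_refraction(
            eyes[:, 0], eyes[:, 1], eyes[:, 2], powers
        )
        want = np.array(
            [oracle_refraction(*e, p) for e, p in zip(eyes, powers)]
        )
        assert np.max(np.abs(got - want)) < 1e-9

        chain = srkt.srkt_chain(eyes[:, 0], eyes[:, 1], eyes[:, 2])
        for i in (0, 123, 999):
            ref = oracle_chain(*eyes[i])
            for key, val in ref.items():
                assert getattr(chain, key)[i] == pytest.approx(val, abs=1e-9)

    def test_self_consistency_and_monotonicity(self):
        """REF(P_emme) = 0 to 1e-9, and REF strictly decreasing in power on
        a dense grid, for 1000 random eyes."""
        eyes = random_physiological_eyes(1000, seed=7)
        p_emme = srkt.emmetropia_power(eyes[:, 0], eyes[:, 1], eyes[:, 2])
        ref_at_emme = srkt.predicted_refraction(
            eyes[:, 0], eyes[:, 1], eyes[:, 2], p_emme
        )
        assert np.max(np.abs(ref_at_emme)) < 1e-9

        grid = np.linspace(0.0, 40.0, 161)
        refs = srkt.predicted_refraction(
            eyes[:, 0][:, None], eyes[:, 1][:, None], eyes[:, 2][:, None],
            grid[None, :],
        )
        assert np.all(np.diff(refs, axis=1) < 0)

    def test_emmetropia_power_oracle_and_monotone_in_a(self):
        eyes = random_physiological_eyes(200, seed=9)
        got = srkt.emmetropia_power(eyes[:, 0], eyes[:, 1], eyes[:, 2])
        want = [oracle_emmetropia_power(*e) for e in eyes]
        assert np.allclose(got, want, atol=1e-9)
        # raising A at fixed biometry raises the emmetropia power
        a_sweep = np.linspace(118.0, 120.0, 21)
        p_sweep = srkt.emmetropia_power(24.0, 7.63, a_sweep)
        assert np.all(np.diff(p_sweep) > 0)

    def test_aphakic_limit(self):
        # P = 0 removes the lens terms from the vergence expression
        c = srkt.DEFAULT_CONSTANTS
        chain = srkt.srkt_chain(24.0, 7.63, 119.21)
        x1 = c.na * 7.63 - c.ncm1 * chain.lopt
        aphakic = 1000.0 * c.na * x1 / (c.na * (c.vertex * x1 + chain.lopt * 7.63))
        assert srkt.predicted_refraction(24.0, 7.63, 119.21, 0.0) == pytest.approx(
            float(aphakic), abs=1e-12
        )


class TestPowerSelection:
    def test_exact_grid_member_recovers_itself(self):
        target = float(srkt.predicted_refraction(24.0, 7.63, 119.21, 19.5))
        assert srkt.select_iol_power(24.0, 7.63, 119.21, target) == 19.5

    def test_plano_target_matches_brute_force(self):
        grid = np.round(np.arange(5.0, 30.0001, 0.5), 10)
        refs = srkt.predicted_refraction(24.0, 7.63, 119.21, grid)
        dist = np.abs(refs - 0.0)
        best = dist.min()
        candidates = grid[dist <= best + 1e-12]
        chosen = srkt.select_iol_power(24.0, 7.63, 119.21, 0.0)
        assert chosen in candidates
        assert chosen == candidates.max()  # tie toward the higher power
        assert chosen in (19.0, 19.5)

    def test_unreachable_target_clamps_to_grid_edge(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="iolsvr.srkt"):
            p = srkt.select_iol_power(24.0, 7.63, 119.21, 20.0)
        assert p == 5.0  # hyperopic target far beyond range -> minimum power
        assert any("out of achievable range" in r.message for r in caplog.records)

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidConfigError):
            srkt.select_iol_power(24.0, 7.63, 119.21, 0.0, power_min=10.0,
                                  power_max=5.0)

    @given(
        st.floats(21.0, 30.0),
        st.floats(6.8, 8.5),
        st.floats(118.0, 120.0),
        st.floats(-3.0, 1.0),
    )
    def test_selected_power_is_on_grid(self, axl, cr, a, target):
        p = srkt.select_iol_power(axl, cr, a, target)
        assert 5.0 <= p <= 30.0
        assert (p * 2) == int(p * 2)


def test_eye_record_invariants():
    with pytest.raises(InvalidInputError):
        srkt.EyeRecord("e1", axl=-1.0, cr=7.6)
    with pytest.raises(InvalidInputError):
        srkt.EyeRecord("e2", axl=24.0, cr=7.6, a_constant=130.0)
    with pytest.raises(InvalidInputError):
        srkt.EyeRecord("e3", axl=24.0, cr=7.6, iol_power=45.0)
    rec = srkt.EyeRecord("e4", axl=24.0, cr=7.63, a_constant=119.21)
    assert rec.eye_id == "e4"


def test_predict_cohort_appends_columns(small_cohort):
    out = srkt.predict_cohort(small_cohort)
    assert {"srkt_pred_d", "emme_power_d"} <= set(out.columns)
    assert "srkt_pred_d" not in small_cohort.columns  # input not mutated
    i = 17
    row = small_cohort.iloc[i]
    assert out["srkt_pred_d"].iloc[i] == pytest.approx(
        oracle_refraction(row.axl_mm, row.cr_mm, row.a_constant, row.iol_power_d),
        abs=1e-9,
    )
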
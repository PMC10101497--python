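"""Constant-dose experiments: scans, thresholds, contours, sensitivity."""

import numpy as np
import pytest

from cycleopt import (DoseSchedule, contour_map, min_constant_dose,
                      percent_peak_decrease, scan_monotherapy,
                      sensitivity_cycle_length)


@pytest.fixture(scope="module")
def estrogen_scan(reference):
    params, state = reference
    grid = np.arange(0.0, 150.1, 5.0)  # coarsened grid for the unit suite
    return scan_monotherapy("estrogen", grid, params, state, step=0.02)


@pytest.fixture(scope="module")
def progesterone_scan(reference):
    params, state = reference
    grid = np.arange(0.0, 4.01, 0.1)
    return scan_monotherapy("progesterone", grid, params, state, step=0.02)


class TestEstrogenScan:
    def test_zero_dose_is_ovulatory(self, estrogen_scan):
        assert not estrogen_scan.anovulatory[0]
        assert estrogen_scan.p4_max[0] > 5.0

    def test_max_p4_nonincreasing(self, estrogen_scan):
        """Raising the constant estrogen dose never raises the P4 peak,
        up to the anovulation threshold (deep-suppression profiles ripple
        at the fraction-of-a-ng level beyond it)."""
        flags = estrogen_scan.anovulatory
        stop = int(np.argmax(flags)) + 1 if flags.any() else len(flags)
        p4 = estrogen_scan.p4_max[:stop]
        assert np.all(np.diff(p4) <= 1e-6)

    def test_anovulatory_set_contiguous(self, estrogen_scan):
        """The anovulatory estrogen doses form one contiguous interval.
        (At the top of the scan range the exogenous estradiol itself
        approaches the LH-synthesis threshold and a weak non-ovulatory
        LH excursion re-appears, so the set is an interval rather than a
        half-line.)"""
        flags = estrogen_scan.anovulatory
        assert flags.any()
        idx = np.flatnonzero(flags)
        assert np.all(np.diff(idx) == 1)
        # P4 suppression itself is monotone: once below the 5 ng/mL
        # criterion, larger doses keep it below
        p4_ok = estrogen_scan.p4_max < 5.0
        first = int(np.argmax(p4_ok))
        assert p4_ok[first:].all()

    def test_high_dose_suppresses_lh(self, estrogen_scan):
        assert estrogen_scan.lh_max[-1] < 0.5 * estrogen_scan.lh_max[0]


class TestProgesteroneScan:
    def test_anovulatory_set_is_interval(self, progesterone_scan):
        """The anovulatory progesterone doses form a contiguous interval:
        above it, the exogenous contribution itself pushes P4 back over
        5 ng/mL."""
        flags = progesterone_scan.anovulatory
        assert flags.any()
        idx = np.flatnonzero(flags)
        assert np.all(np.diff(idx) == 1)

    def test_p4_rises_again_at_high_dose(self, progesterone_scan, reference):
        """Large exogenous P4 re-raises max P4 (non-monotone response)."""
        flags = progesterone_scan.anovulatory
        hi = progesterone_scan.doses > progesterone_scan.doses[flags].max()
        if hi.any():
            assert (progesterone_scan.p4_max[hi] >= 5.0).all()


class TestMinConstantDose:
    def test_estrogen_threshold_consistent_with_scan(self, reference,
                                                     estrogen_scan):
        params, state = reference
        dose, total = min_constant_dose("estrogen", params, state,
                                        resolution=0.01, step=0.02)
        assert total == pytest.approx(dose * 28.0)
        flags = estrogen_scan.anovulatory
        first = estrogen_scan.doses[int(np.argmax(flags))]
        assert first - 5.0 <= dose <= first + 1e-9

    def test_threshold_dose_sits_at_the_boundary(self, reference):
        """Max P4 just below 5 at the refined dose, above 5 slightly under
        it (the operational optimum at the anovulation boundary)."""
        from cycleopt import cycle_metrics, simulate
        params, state = reference
        dose, _ = min_constant_dose("estrogen", params, state,
                                    resolution=0.01, step=0.02)
        above = simulate(params, DoseSchedule.constant(e2exo=dose), state,
                         horizon=28.0, step=0.02)
        m_above = cycle_metrics(above, window=(0, 28))
        assert m_above.anovulatory
        assert m_above.peaks["P4"] < 5.0
        below = simulate(params, DoseSchedule.constant(e2exo=dose - 0.5),
                         state, horizon=28.0, step=0.02)
        assert not cycle_metrics(below, window=(0, 28)).anovulatory

    def test_degenerate_params_anovulatory_at_zero(self, reference):
        """With recruitment disabled there are no follicles, no ovulation:
        dose 0 already qualifies."""
        params, state = reference
        p = params.replace(b=0.0, c1=1e-300)
        dose, total = min_constant_dose("estrogen", p, state, step=0.02)
        assert dose == 0.0 and total == 0.0

    def test_no_dose_in_range_raises(self, reference):
        params, state = reference
        with pytest.raises(ValueError):
            min_constant_dose("estrogen", params, state, dose_max=1.0,
                              step=0.02)


class TestPercentDecrease:
    def test_zero_dose_gives_zero_decrease(self, reference):
        params, state = reference
        dec = percent_peak_decrease(DoseSchedule.zero(), params, state,
                                    step=0.02)
        # the treatment window is one cycle of the same periodic solution
        assert all(abs(v) < 3.0 for v in dec.values())

    def test_moderate_doses_suppress_peaks(self, reference):
        """Sub-threshold monotherapy doses reduce every hormone peak, more
        strongly under progesterone for LH."""
        params, state = reference
        dec_e2 = percent_peak_decrease(DoseSchedule.constant(e2exo=20.0),
                                       params, state, step=0.02)
        dec_p4 = percent_peak_decrease(DoseSchedule.constant(p4exo=1.4),
                                       params, state, step=0.02)
        assert all(v > 0 for v in dec_e2.values())
        assert all(v > 0 for v in dec_p4.values())
        assert dec_p4["LH"] > dec_e2["LH"]


@pytest.fixture(scope="module")
def grid(reference):
    params, state = reference
    return contour_map(np.arange(0.0, 121.0, 10.0),
                       np.arange(0.0, 4.01, 0.4), params, state,
                       step=0.05)


class TestContour:
    def test_origin_matches_normal_cycle(self, grid):
        assert grid.max_p4[0, 0] > 5.0
        assert not grid.anovulation_mask[0, 0]

    def test_combination_beats_monotherapy(self, grid, reference,
                                           estrogen_scan, progesterone_scan):
        """Some combination with BOTH components strictly below their
        monotherapy thresholds is anovulatory (combined administration
        enhances effectiveness)."""
        e2_flags = estrogen_scan.anovulatory
        e2_thr = estrogen_scan.doses[int(np.argmax(e2_flags))]
        p4_thr = progesterone_scan.anovulatory_doses().min()
        found = False
        for j, p4d in enumerate(grid.p4_grid):
            for i, e2d in enumerate(grid.e2_grid):
                if (grid.anovulation_mask[j, i] and 0 < e2d < e2_thr
                        and 0 < p4d < p4_thr):
                    found = True
        assert found

    def test_level_curves_nested(self, grid):
        """The k=3 region lies strictly inside the k=5 region: at equal
        P4exo the k=3 curve needs at least as much estrogen."""
        c3 = grid.level_curve(3.0)
        c5 = grid.level_curve(5.0)
        if len(c3) and len(c5):
            for e2_3, p4d in c3:
                match = c5[np.isclose(c5[:, 1], p4d)]
                if len(match):
                    assert e2_3 >= match[0, 0] - 1e-6

    def test_boundary_slope_negative(self, grid):
        slope, rng = grid.boundary_slope(e2_max=35.0)
        assert slope < 0


class TestSensitivity:
    def test_zero_perturbation_zero_estimate(self, reference):
        df = sensitivity_cycle_length(reference[0], 0.0, names=("Km_LH",))
        assert df["dT_dlogp"].iloc[0] == 0.0

    def test_km_lh_lengthens_cycle(self, reference):
        """Raising the E2 half-saturation of LH synthesis postpones the
        surge, lengthening the cycle: positive sensitivity, and among the
        larger ones."""
        params, state = reference
        df = sensitivity_cycle_length(
            params, 0.02, names=("Km_LH", "alpha_LH", "k4", "e1"),
            history=state)
        row = df[df["parameter"] == "Km_LH"].iloc[0]
        assert row["defined"]
        assert row["dT_dlogp"] > 0
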
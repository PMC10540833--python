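"""Recovery of OCR, LPR and GAG synthesis rates from raw traces."""

import numpy as np
import pytest

from discregen.flux_estimation import (
    EstimationError,
    FluxTrace,
    SpheroidAssay,
    StandardCurve,
    estimate_gag_synthesis_rate,
    estimate_lpr,
    estimate_ocr,
    remove_outliers,
)
from discregen.synthetic import GeneratorSpec, default_standard_curve, generate_flux_trace

NOISELESS = GeneratorSpec(seed=1, o2_mmhg_sd=0.0, ph_sd=0.0)


def make_pair(true_ocr=12.0, true_lpr=70.0, n_cells=2000.0, transient=0.0, spec=NOISELESS):
    trace, blank, truth = generate_flux_trace(
        spec, true_ocr=true_ocr, true_lpr=true_lpr, n_cells=n_cells,
        transient_amplitude_mmhg=transient)
    return trace, blank, truth


class TestOcr:
    def test_noiseless_exact_recovery(self):
        trace, blank, truth = make_pair()
        ocr, flagged = estimate_ocr(trace, blank, truth["n_cells"])
        assert not flagged
        assert ocr == pytest.approx(truth["true_ocr"], rel=1e-9)

    def test_flat_trace_zero(self):
        trace, blank, _ = make_pair(true_ocr=0.0)
        ocr, _ = estimate_ocr(trace, blank, 2000.0)
        assert ocr == pytest.approx(0.0, abs=1e-12)

    def test_pre_cutoff_points_ignored(self):
        trace, blank, truth = make_pair()
        o2 = trace.o2_mmhg.copy()
        o2[trace.time_min < 10.0] += 40.0  # arbitrary pre-plateau garbage
        perturbed = FluxTrace(time_min=trace.time_min, o2_mmhg=o2, ph=trace.ph)
        a, _ = estimate_ocr(trace, blank, truth["n_cells"])
        b, _ = estimate_ocr(perturbed, blank, truth["n_cells"])
        assert a == pytest.approx(b, rel=1e-12)

    def test_positive_slope_flagged(self):
        t = np.linspace(0, 30, 8)
        rising = FluxTrace(time_min=t, o2_mmhg=150 + t, ph=np.full_like(t, 7.3))
        blank = FluxTrace(time_min=t, o2_mmhg=np.full_like(t, 150.0),
                          ph=np.full_like(t, 7.3), is_blank=True)
        ocr, flagged = estimate_ocr(rising, blank, 1000.0)
        assert flagged and ocr < 0

    def test_short_trace_rejected(self):
        t = np.array([0.0, 5.0])
        tr = FluxTrace(time_min=t, o2_mmhg=np.array([150.0, 149.0]),
                       ph=np.array([7.3, 7.3]))
        with pytest.raises(EstimationError):
            estimate_ocr(tr, tr, 1000.0)


class TestLpr:
    def test_noiseless_exact_recovery(self):
        curve = default_standard_curve()
        trace, blank, truth = make_pair()
        lpr = estimate_lpr(trace, blank, curve, truth["n_cells"])
        assert lpr == pytest.approx(truth["true_lpr"], rel=1e-9)

    def test_constant_ph_zero(self):
        trace, blank, _ = make_pair(true_lpr=0.0)
        lpr = estimate_lpr(trace, blank, default_standard_curve(), 2000.0)
        assert lpr == pytest.approx(0.0, abs=1e-9)

    def test_blank_drift_cancels(self):
        curve = default_standard_curve()
        trace, blank, truth = make_pair()
        drift = 0.004 * trace.time_min
        trace_d = FluxTrace(time_min=trace.time_min, o2_mmhg=trace.o2_mmhg,
                            ph=trace.ph + drift)
        blank_d = FluxTrace(time_min=blank.time_min, o2_mmhg=blank.o2_mmhg,
                            ph=blank.ph + drift, is_blank=True)
        a = estimate_lpr(trace, blank, curve, truth["n_cells"])
        b = estimate_lpr(trace_d, blank_d, curve, truth["n_cells"])
        assert a == pytest.approx(b, rel=1e-9)

    def test_ph_outside_curve_domain_rejected(self):
        curve = StandardCurve(lactate_mm=np.array([0.0, 2.0]),
                              ph_measured=np.array([7.6, 7.48]))
        t = np.linspace(0, 30, 8)
        tr = FluxTrace(time_min=t, o2_mmhg=np.full_like(t, 150.0),
                       ph=np.linspace(7.6, 6.0, 8))
        blank = FluxTrace(time_min=t, o2_mmhg=np.full_like(t, 150.0),
                          ph=np.full_like(t, 7.6), is_blank=True)
        with pytest.raises(EstimationError, match="outside calibrated"):
            estimate_lpr(tr, blank, curve, 1000.0)

    def test_timestamp_shift_invariance(self):
        """Shifting t0 within the pre-cutoff region leaves estimates unchanged
        (the linear tail carries the same slope)."""
        curve = default_standard_curve()
        trace, blank, truth = make_pair()
        sh = FluxTrace(time_min=trace.time_min + 3.0, o2_mmhg=trace.o2_mmhg,
                       ph=trace.ph)
        bsh = FluxTrace(time_min=blank.time_min + 3.0, o2_mmhg=blank.o2_mmhg,
                        ph=blank.ph, is_blank=True)
        assert estimate_lpr(sh, bsh, curve, truth["n_cells"]) == pytest.approx(
            estimate_lpr(trace, blank, curve, truth["n_cells"]), rel=1e-6)


class TestGagRate:
    def test_hand_arithmetic_oracle(self):
        # 1.0 ug over 14 days by 1e4 cells -> 1e6 pg / (1e4 * 14) pg/cell/day
        assay = SpheroidAssay(gag_ug=1.0, cells=1e4, days=14.0)
        assert estimate_gag_synthesis_rate(assay) == pytest.approx(
            1.0e6 / (1e4 * 14.0), rel=1e-12)

    def test_zero_gag(self):
        assert estimate_gag_synthesis_rate(
            SpheroidAssay(gag_ug=0.0, cells=1e4, days=14.0)) == 0.0

    def test_pooling_invariance(self):
        single = SpheroidAssay(gag_ug=0.5, cells=5e3, days=14.0, pooled_n=1)
        pooled = SpheroidAssay(gag_ug=2.0, cells=2e4, days=14.0, pooled_n=4)
        assert estimate_gag_synthesis_rate(single) == pytest.approx(
            estimate_gag_synthesis_rate(pooled), rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(EstimationError):
            SpheroidAssay(gag_ug=1.0, cells=0.0, days=14.0)
        with pytest.raises(EstimationError):
            SpheroidAssay(gag_ug=1.0, cells=1e4, days=0.0)


class TestOutliers:
    def test_homogeneous_kept(self, rng):
        vals = 10.0 + 0.05 * rng.standard_normal(12)
        res = remove_outliers(vals)
        assert not res.flags.any()
        assert np.array_equal(res.kept, vals)

    def test_gross_outlier_flagged(self, rng):
        vals = 10.0 + 0.05 * rng.standard_normal(12)
        vals[4] = 10.0 + 10 * 0.05 * 10  # ~10 sigma away
        res = remove_outliers(vals)
        # robust-z oracle on the same data: the planted point is the only one
        # with |z| > 5 under median/MAD
        med = np.median(vals)
        mad = 1.4826 * np.median(np.abs(vals - med))
        oracle = np.abs(vals - med) / mad > 5
        assert res.flags[4]
        assert set(np.nonzero(res.flags)[0]) <= set(np.nonzero(oracle)[0]) | {4}

    def test_order_preserving_subset(self, rng):
        vals = rng.normal(5.0, 0.2, size=15)
        vals[0] = 50.0
        res = remove_outliers(vals)
        kept_expected = vals[~res.flags]
        assert np.array_equal(res.kept, kept_expected)

    def test_too_few_passthrough_with_warning(self):
        with pytest.warns(UserWarning, match="outlier screen skipped"):
            res = remove_outliers([1.0, 2.0, 3.0])
        assert res.warned
        assert len(res.kept) == 3


class TestRecoveryUnderNoise:
    def test_median_relative_error_under_default_noise(self):
        """Across 200 synthetic traces at generator-default noise, median
        relative error of OCR and LPR stays below 5%."""
        spec = GeneratorSpec(seed=42)
        rng = spec.rng()
        curve = default_standard_curve()
        errs_ocr, errs_lpr = [], []
        for _ in range(200):
            trace, blank, truth = generate_flux_trace(
                spec, true_ocr=12.0, true_lpr=70.0, n_cells=5000.0, rng=rng)
            ocr, _ = estimate_ocr(trace, blank, truth["n_cells"])
            lpr = estimate_lpr(trace, blank, curve, truth["n_cells"])
            errs_ocr.append(abs(ocr - truth["true_ocr"]) / truth["true_ocr"])
            errs_lpr.append(abs(lpr - truth["true_lpr"]) / truth["true_lpr"])
        assert np.median(errs_ocr) < 0.05
        assert np.median(errs_lpr) < 0.05
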
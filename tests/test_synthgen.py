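"""Synthetic generator: bolus, tissue forward model, rendering, phantom,
cohort."""

import numpy as np
import pytest
from scipy import special

from dscmicro.protocol import AcquisitionProtocol
from dscmicro.curves import ConcentrationCurve
from dscmicro.synthgen import (
    PhantomSpec, CohortDesign, TISSUE_CLASSES,
    make_aif, make_tissue_curve, render_dual_echo_signal,
    make_cohort, discrete_residue,
)
from dscmicro.kinetics import signal_to_delta_r2


class TestMakeAif:
    def test_peak_at_mode(self, protocol):
        aif = make_aif(1.0, 10.0, 3.0, 1.5, protocol)
        # gamma-variate mode is t0 + r*b = 14.5 s; grid has 1.5-s steps
        assert aif.peak_time == pytest.approx(14.5, abs=protocol.tr / 2)
        assert np.all(aif.values >= 0)
        assert np.all(aif.values[protocol.times <= 10.0] == 0)

    def test_t0_beyond_window_gives_zero_curve(self, protocol):
        aif = make_aif(1.0, protocol.duration - 1e-9, 3.0, 1.5, protocol)
        assert np.all(aif.values == 0)

    def test_integral_matches_closed_form(self):
        # fine grid so truncation is negligible; closed-form area of the
        # gamma-variate is A * b**(r+1) * Gamma(r+1)
        p = AcquisitionProtocol(tr=0.05, te_gre=0.04, n_dynamics=4000,
                                baseline_frames=10)
        amp, r, b = 2.0, 3.0, 1.5
        aif = make_aif(amp, 5.0, r, b, p)
        expected = amp * b ** (r + 1) * special.gamma(r + 1)
        assert np.trapezoid(aif.values, p.times) == pytest.approx(
            expected, rel=5e-3)

    @pytest.mark.parametrize("r,b", [(0.0, 1.0), (-1.0, 1.0), (3.0, 0.0)])
    def test_invalid_shape_scale_rejected(self, protocol, r, b):
        with pytest.raises(ValueError):
            make_aif(1.0, 10.0, r, b, protocol)


class TestTissueCurve:
    def test_zero_flow_gives_zero_curve(self, protocol, aif):
        tc = make_tissue_curve(aif, 0.0, 3.0, 1.5, protocol)
        assert np.all(tc.values == 0)

    @staticmethod
    def _closed_form(p, amp, t0, r, b, beta, cbf):
        # alpha=1 makes R(t) = exp(-t/beta); the convolution of the
        # gamma-variate bolus with an exponential has a closed form via
        # the lower incomplete gamma function — an independent oracle.
        k = 1.0 / b - 1.0 / beta
        tt = np.clip(p.times - t0, 0.0, None)
        conv = (amp * np.exp(-tt / beta) * special.gammainc(r + 1, k * tt)
                * special.gamma(r + 1) / k ** (r + 1))
        return (cbf / 60.0) * conv

    def test_exponential_residue_matches_closed_form_convolution(self):
        amp, t0, r, b = 2.0, 3.0, 3.0, 1.5
        beta, cbf = 4.0, 60.0
        errs = []
        for tr in (0.04, 0.02, 0.01):
            p = AcquisitionProtocol(tr=tr, te_gre=0.04,
                                    n_dynamics=int(40 / tr),
                                    baseline_frames=10)
            aif = make_aif(amp, t0, r, b, p)
            tc = make_tissue_curve(aif, cbf, 1.0, beta, p)
            expected = self._closed_form(p, amp, t0, r, b, beta, cbf)
            errs.append(np.max(np.abs(tc.values - expected))
                        / expected.max())
        # fine-grid agreement with the continuous convolution, and
        # first-order convergence of the discretization toward it
        assert errs[-1] < 2e-3
        assert errs[1] < 0.6 * errs[0] and errs[2] < 0.6 * errs[1]

    def test_tracer_mass_conservation(self, protocol, aif):
        # area(Ct)/area(AIF) = cbv = cbf*mtt/60 on the default coarse grid
        cbf, alpha, beta = 24.0, 4.0, 1.0
        tc = make_tissue_curve(aif, cbf, alpha, beta, protocol)
        cbv = cbf * alpha * beta / 60.0
        assert tc.area() / aif.area() == pytest.approx(cbv, rel=0.01)

    def test_discrete_residue_area_equals_mtt(self, protocol):
        r = discrete_residue(protocol.times, protocol.tr, 3.0, 1.5)
        assert protocol.tr * r.sum() == pytest.approx(4.5, rel=1e-6)
        assert r[0] <= 1.0 and np.all(np.diff(r) <= 1e-12)

    def test_timebase_mismatch_rejected(self, protocol, aif):
        other = AcquisitionProtocol(tr=2.0, te_gre=0.04, n_dynamics=80,
                                    baseline_frames=10)
        with pytest.raises(ValueError):
            make_tissue_curve(aif, 20.0, 3.0, 1.5, other)


class TestRenderDualEcho:
    def test_zero_concentration_constant_signal(self, protocol):
        conc = ConcentrationCurve(np.zeros(80), protocol.times)
        r = render_dual_echo_signal(conc, protocol, s0=500.0)
        assert np.all(r.gre == 500.0)
        assert np.all(r.se == 500.0)

    def test_roundtrip_identity(self, protocol, aif):
        tc = make_tissue_curve(aif, 24.0, 3.0, 1.5, protocol)
        r = render_dual_echo_signal(tc, protocol)
        inv = signal_to_delta_r2(r.gre, 0.040, protocol.baseline_frames,
                                 protocol.times)
        assert np.max(np.abs(inv.values - tc.values)) < 1e-10

    def test_roundtrip_with_leakage(self, protocol, aif):
        tc = make_tissue_curve(aif, 24.0, 3.0, 1.5, protocol)
        from scipy.integrate import cumulative_trapezoid
        r = render_dual_echo_signal(tc, protocol, kapp=0.01,
                                    leak_reference=tc)
        inv = signal_to_delta_r2(r.gre, 0.040, protocol.baseline_frames,
                                 protocol.times)
        expected = tc.values - 0.01 * cumulative_trapezoid(
            tc.values, protocol.times, initial=0.0)
        # baseline offset: leak term is zero during baseline so S0 is exact
        assert np.max(np.abs(inv.values - expected)) < 1e-10

    def test_noise_determinism(self, protocol, aif):
        tc = make_tissue_curve(aif, 24.0, 3.0, 1.5, protocol)
        r1 = render_dual_echo_signal(tc, protocol, noise_sigma=5.0, rng=42)
        r2 = render_dual_echo_signal(tc, protocol, noise_sigma=5.0, rng=42)
        r3 = render_dual_echo_signal(tc, protocol, noise_sigma=5.0, rng=43)
        assert np.array_equal(r1.gre, r2.gre)
        assert not np.array_equal(r1.gre, r3.gre)

    def test_excessive_lag_rejected(self, protocol, aif):
        tc = make_tissue_curve(aif, 24.0, 3.0, 1.5, protocol)
        with pytest.raises(ValueError):
            render_dual_echo_signal(tc, protocol, lag=protocol.duration)


class TestMakePhantom:
    def test_ground_truth_invariants(self, small_phantom_noiseless):
        t = small_phantom_noiseless.truth
        flowing = t.cbf > 0
        # central volume theorem holds exactly
        np.testing.assert_allclose(t.cbv[flowing],
                                   t.cbf[flowing] * t.mtt[flowing] / 60.0,
                                   rtol=1e-12)
        # leakage confined to the lesion class by default
        assert np.all(t.kapp[~t.mask("lesion")] == 0)
        assert np.all(t.kapp[t.mask("lesion")] > 0)
        # exactly one artery voxel, with the earliest and tallest bolus
        assert int(t.mask("artery").sum()) == 1
        # elevated heterogeneity where expected
        assert t.rth[t.mask("perilesional")].mean() > t.rth[t.mask("NAWM")].mean()

    def test_protocol_matches_3t_acquisition(self, small_phantom_noiseless):
        p = small_phantom_noiseless.protocol
        assert p.n_dynamics == 80
        assert p.tr == 1.5
        assert p.te_gre == 0.040

    def test_noiseless_phantom_voxels_invert_exactly(
            self, small_phantom_noiseless):
        from scipy.integrate import cumulative_trapezoid
        study = small_phantom_noiseless
        p, t = study.protocol, study.truth
        leak_cum = cumulative_trapezoid(study.leak_reference.values,
                                        p.times, initial=0.0)
        for idx in [tuple(i) for i in
                    np.argwhere(t.tissue_class > TISSUE_CLASSES["background"])][::9]:
            if t.mask("artery")[idx]:
                continue
            alpha = (t.mtt[idx] / t.cth[idx]) ** 2
            beta = t.cth[idx] ** 2 / t.mtt[idx]
            expected = make_tissue_curve(
                study.aif_true, t.cbf[idx], alpha, beta, p
            ).values - t.kapp[idx] * leak_cum
            inv = signal_to_delta_r2(study.signal_gre[idx], p.te_gre,
                                     p.baseline_frames, p.times)
            assert np.max(np.abs(inv.values - expected)) < 1e-10

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(shape=(1, 1, 1))


class TestMakeCohort:
    def test_schema_and_visit_ordering(self):
        df = make_cohort(CohortDesign(seed=3))
        assert {"subject", "group", "visit_day", "rth", "va", "kapp"} <= set(df.columns)
        for _, sub in df.groupby("subject"):
            assert np.all(np.diff(sub["visit_day"].to_numpy()) > 0)

    def test_hem_subjects_have_no_secular_trend(self):
        # pooled over seeds, the regression of RTH on visit day in HEM is
        # consistent with zero slope
        from scipy import stats
        days, vals = [], []
        for s in range(20):
            df = make_cohort(CohortDesign(seed=s))
            hem = df[df.group == "HEM"]
            days.extend(hem.visit_day)
            vals.extend(hem.rth)
        r = stats.linregress(days, vals)
        assert r.pvalue > 0.01
        assert abs(r.slope) * 730 < 0.05  # < 0.05 RTH units over 2 years

    def test_treatment_moves_rth_down_and_va_up(self):
        df = make_cohort(CohortDesign(seed=5))
        gt = df[df.group == "GT"]
        pre = gt[gt.visit_day == 0]
        post = gt[gt.visit_day == 730]
        assert post.rth.mean() < pre.rth.mean()
        assert post.va.mean() > pre.va.mean()
        assert post.kapp.mean() < pre.kapp.mean()

    def test_deterministic_by_seed(self):
        a = make_cohort(CohortDesign(seed=9))
        b = make_cohort(CohortDesign(seed=9))
        assert a.equals(b)

    def test_negative_group_size_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(n_gt=-1)

    def test_nonincreasing_visits_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(visit_days=(0.0, 45.0, 45.0))
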
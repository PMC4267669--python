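"""Core decomposition: aberrant signal, window, models, NNLS fit, QC."""

import itertools

import numpy as np
import pytest

import indelscope as ix
from indelscope.decomp import aberrant_signal, default_window, quality_check

from conftest import run_mixture


def _site(cut, length=800):
    return ix.BreakSite(cut_index=cut, strand="forward", guide_start=cut - 17, alignment_score=40)


def _offset(k=0):
    return ix.OffsetAlignment(offset=k, alignment_score=0)


class TestAberrantSignal:
    def test_pure_reference_row_is_zero(self):
        sig = ix.SignalMatrix(np.array([[1.0, 0, 0, 0]]))
        assert aberrant_signal(sig, "A")[0] == 0.0

    def test_uniform_row_is_three_quarters(self):
        sig = ix.SignalMatrix(np.full((1, 4), 0.25))
        assert aberrant_signal(sig, "G")[0] == pytest.approx(0.75)

    def test_n_reference_and_masked_positions_are_nan(self):
        sig = ix.SignalMatrix(np.full((2, 4), 0.25), mask=np.array([False, True]))
        vals = aberrant_signal(sig, "NA")
        assert np.isnan(vals).all()

    def test_fully_shifted_sample_saturates_near_75_percent(self):
        """A sample consisting 100% of a frameshifted allele shares only
        chance base identity with the control, so the mean aberrant
        signal downstream of the cut approaches 75%."""
        rng = np.random.default_rng(12)
        seq = ix.random_sequence(800, rng)
        # downstream bases replaced by an independent random sequence
        shifted = seq[:400] + ix.random_sequence(400, rng)
        params = ix.TraceParams(noise_cv=0.0, crosstalk=0.0)
        sample_sig = ix.normalize(ix.render_trace(shifted, params))
        vals = aberrant_signal(sample_sig, seq)
        mean_post = np.nanmean(vals[400:])
        assert mean_post == pytest.approx(0.75, abs=0.05)


class TestDefaultWindow:
    def test_default_rule(self):
        win = default_window(_site(200), _offset(0), 700, 700, 10)
        assert (win.left, win.right) == (215, 685)

    def test_larger_indel_range_shrinks_window(self):
        win = default_window(_site(200), _offset(0), 700, 700, 15)
        assert (win.left, win.right) == (220, 680)

    def test_offset_moves_sample_end_into_control_frame(self):
        win = default_window(_site(200), _offset(+50), 700, 700, 10)
        assert win.right == 700 - 50 - 15

    def test_short_reads_raise(self):
        with pytest.raises(ix.WindowError):
            default_window(_site(200), _offset(0), 240, 240, 10)

    def test_window_barely_below_minimum_raises(self):
        # width must reach 10*(2n+1)/4 positions
        with pytest.raises(ix.WindowError):
            default_window(_site(200), _offset(0), 265, 265, 10)


class TestBuildModels:
    def _signal(self, seq):
        params = ix.TraceParams(noise_cv=0.0, crosstalk=0.0)
        return ix.normalize(ix.render_trace(seq, params))

    def test_wild_type_column_is_unshifted_window(self):
        rng = np.random.default_rng(13)
        sig = self._signal(ix.random_sequence(100, rng))
        win = ix.DecompositionWindow(20, 80)
        models = ix.build_models(sig, win, 5)
        col0 = models.matrix[:, models.indel_labels.tolist().index(0)]
        np.testing.assert_array_equal(col0, sig.fractions[20:80].T.ravel())

    def test_deletion_column_shifts_left(self):
        rng = np.random.default_rng(14)
        sig = self._signal(ix.random_sequence(100, rng))
        win = ix.DecompositionWindow(20, 80)
        models = ix.build_models(sig, win, 5)
        col = models.matrix[:, models.indel_labels.tolist().index(-1)]
        np.testing.assert_array_equal(col, sig.fractions[21:81].T.ravel())

    def test_insertion_column_shifts_right(self):
        rng = np.random.default_rng(15)
        sig = self._signal(ix.random_sequence(100, rng))
        win = ix.DecompositionWindow(20, 80)
        models = ix.build_models(sig, win, 5)
        col = models.matrix[:, models.indel_labels.tolist().index(+2)]
        np.testing.assert_array_equal(col, sig.fractions[18:78].T.ravel())

    def test_periodic_sequence_duplicates_columns(self):
        """On a period-3 control, the -3 model equals the wild-type model:
        the degenerate case repetitive targets produce."""
        sig = self._signal("ACG" * 40)
        win = ix.DecompositionWindow(10, 100)
        models = ix.build_models(sig, win, 3)
        labels = models.indel_labels.tolist()
        np.testing.assert_array_equal(
            models.matrix[:, labels.index(-3)], models.matrix[:, labels.index(0)]
        )

    def test_insufficient_control_length_raises(self):
        rng = np.random.default_rng(16)
        sig = self._signal(ix.random_sequence(50, rng))
        with pytest.raises(ValueError):
            ix.build_models(sig, ix.DecompositionWindow(10, 48), 5)


class TestDecompose:
    def test_self_decomposition(self, amplicon, noiseless_params):
        seq, guide, cut = amplicon
        report = run_mixture(
            seq, guide, cut, [(0, 1.0)], noiseless_params, noiseless_params
        )
        res = report.result
        assert res.r_squared > 0.999
        assert res.percentage(0) == pytest.approx(100.0, abs=0.1)
        assert all(
            res.percentage(k) < 0.1 for k in res.indel_labels if k != 0
        )

    def test_noiseless_70_30_mixture(self, amplicon, noiseless_params):
        seq, guide, cut = amplicon
        report = run_mixture(
            seq, guide, cut, [(0, 0.7), (-1, 0.3)], noiseless_params, noiseless_params
        )
        res = report.result
        assert res.percentage(0) == pytest.approx(70.0, abs=0.1)
        assert res.percentage(-1) == pytest.approx(30.0, abs=0.1)
        assert res.total_efficiency == pytest.approx(30.0, abs=0.1)

    def test_five_component_mixture_recovered(self, amplicon, noiseless_params):
        seq, guide, cut = amplicon
        spectrum = [(0, 0.5), (-8, 0.125), (-3, 0.125), (1, 0.125, "T"), (6, 0.125, "ACGTAC")]
        report = run_mixture(
            seq, guide, cut, spectrum, noiseless_params, noiseless_params
        )
        res = report.result
        for entry in spectrum:
            size, weight = entry[0], entry[1]
            assert res.percentage(size) == pytest.approx(100 * weight, abs=0.5)
            assert res.p_value(size) < 1e-6
        others = [k for k in res.indel_labels if k not in {0, -8, -3, 1, 6}]
        assert all(res.percentage(k) < 0.1 for k in others)

    def test_percentage_sum_equals_r_squared(self, amplicon):
        """Conservation: rescaled percentages sum to 100 * R^2 exactly."""
        seq, guide, cut = amplicon
        noisy = ix.TraceParams(seed=21)
        report = run_mixture(
            seq, guide, cut, [(0, 0.6), (-2, 0.25), (1, 0.15, "C")],
            ix.TraceParams(seed=20), noisy,
        )
        res = report.result
        assert res.percentages.sum() == pytest.approx(100 * res.r_squared, abs=1e-6)
        assert np.all(res.coefficients >= 0)
        assert np.all(res.percentages >= 0)

    def test_masked_positions_are_dropped(self, amplicon, noiseless_params):
        """Signal dropout inside the window must not perturb the fit."""
        seq, guide, cut = amplicon
        control = ix.render_trace(seq, noiseless_params)
        mut = ix.apply_indel(seq, ix.IndelSpec(-1, cut))
        sample = ix.mix_traces([(seq, 0.7), (mut, 0.3)], noiseless_params)
        sample.peaks[cut + 40: cut + 45] = 0.0  # dead stretch
        report = ix.analyze(control, sample, guide)
        assert report.result.percentage(-1) == pytest.approx(30.0, abs=0.1)

    def test_window_shift_stability(self, amplicon):
        """Moving the window by +/-10 positions barely changes the result
        on clean synthetic data."""
        seq, guide, cut = amplicon
        control = ix.render_trace(seq, ix.TraceParams(seed=30))
        mut = ix.apply_indel(seq, ix.IndelSpec(-2, cut))
        sample = ix.mix_traces([(seq, 0.75), (mut, 0.25)], ix.TraceParams(seed=31))
        default = ix.analyze(control, sample, guide).result.window
        # shrink the reference window so +/-10 shifts stay inside the trace
        ref = (default.left + 12, default.right - 12)
        base = ix.analyze(control, sample, guide, window_override=ref).result
        for shift in (-10, 10):
            res = ix.analyze(
                control, sample, guide,
                window_override=(ref[0] + shift, ref[1] + shift),
            ).result
            for k in res.indel_labels:
                assert abs(res.percentage(k) - base.percentage(k)) < 2.0

    def test_repetitive_control_flags_singularity(self):
        """Duplicate model columns from a periodic control attach a
        warning and suppress the affected p-values."""
        seq = "ACG" * 300
        params = ix.TraceParams(noise_cv=0.0, crosstalk=0.0)
        sig = ix.normalize(ix.render_trace(seq, params))
        win = ix.DecompositionWindow(100, 300)
        models = ix.build_models(sig, win, 3)
        res = ix.decompose(sig, models, _offset(0))
        assert res.warnings
        assert np.isnan(res.p_value(-3)) and np.isnan(res.p_value(0))

    def test_forward_reverse_strand_concordance(self, amplicon):
        """Sequencing the opposite strand gives the mirrored experiment;
        the recovered spectrum should agree within 1 point."""
        from Bio.Seq import reverse_complement

        seq, guide, cut = amplicon
        spectrum = {0: 0.6, -3: 0.2, 1: 0.2}
        components = [
            (seq, 0.6),
            (ix.apply_indel(seq, ix.IndelSpec(-3, cut)), 0.2),
            (ix.apply_indel(seq, ix.IndelSpec(1, cut, "G")), 0.2),
        ]
        fwd_control = ix.render_trace(seq, ix.TraceParams(seed=40))
        fwd_sample = ix.mix_traces(components, ix.TraceParams(seed=41))
        fwd = ix.analyze(fwd_control, fwd_sample, guide).result

        rc_components = [(reverse_complement(s), w) for s, w in components]
        rc_control = ix.render_trace(reverse_complement(seq), ix.TraceParams(seed=42))
        rc_sample = ix.mix_traces(rc_components, ix.TraceParams(seed=43))
        rev = ix.analyze(rc_control, rc_sample, guide).result

        for k in spectrum:
            assert abs(fwd.percentage(k) - rev.percentage(k)) < 1.0
            assert fwd.percentage(k) == pytest.approx(100 * spectrum[k], abs=1.0)


class TestNnlsGridOracle:
    def test_matches_simplex_grid_search(self):
        """On tiny instances whose true solution lies on the simplex, the
        NNLS fit agrees with an exhaustive grid search (step 1e-3)."""
        from scipy.optimize import nnls

        rng = np.random.default_rng(50)
        for trial in range(3):
            w = 10
            m = rng.uniform(0, 1, size=(w, 2))
            c_true = np.array([0.617, 0.383])
            y = m @ c_true
            coef, _ = nnls(m, y)

            grid = np.arange(0, 1.0 + 1e-9, 1e-3)
            c0 = grid[:, None]
            c1 = 1.0 - c0
            resid = ((c0 * m[:, 0][None, :] + c1 * m[:, 1][None, :] - y) ** 2).sum(axis=1)
            best = grid[int(np.argmin(resid))]
            assert abs(coef[0] - best) < 2e-3
            assert abs(coef[1] - (1 - best)) < 2e-3

    def test_three_column_grid_search(self):
        from scipy.optimize import nnls

        rng = np.random.default_rng(51)
        m = rng.uniform(0, 1, size=(12, 3))
        c_true = np.array([0.25, 0.5, 0.25])
        y = m @ c_true
        coef, _ = nnls(m, y)

        step = 5e-3  # coarser grid: 3-simplex enumeration
        best, best_r = None, np.inf
        for a in np.arange(0, 1 + 1e-9, step):
            for b in np.arange(0, 1 - a + 1e-9, step):
                c = np.array([a, b, 1 - a - b])
                r = ((m @ c - y) ** 2).sum()
                if r < best_r:
                    best, best_r = c, r
        np.testing.assert_allclose(coef, best, atol=6e-3)


class TestQualityCheck:
    def _clean_report(self, amplicon, noiseless_params):
        seq, guide, cut = amplicon
        return run_mixture(
            seq, guide, cut, [(0, 1.0)], noiseless_params, noiseless_params
        )

    def test_clean_self_decomposition_no_warnings(self, amplicon, noiseless_params):
        report = self._clean_report(amplicon, noiseless_params)
        assert quality_check(report.profile, report.result) == []

    def test_low_r_squared_warns(self, amplicon, noiseless_params):
        report = self._clean_report(amplicon, noiseless_params)
        report.result.r_squared = 0.85
        warnings = quality_check(report.profile, report.result)
        assert any("R^2" in w for w in warnings)

    def test_noisy_baseline_warns(self, amplicon):
        """15% simulated baseline noise trips the pre-break background rule."""
        seq, guide, cut = amplicon
        report = run_mixture(
            seq, guide, cut, [(0, 1.0)],
            ix.TraceParams(noise_cv=0.0, crosstalk=0.0),
            ix.TraceParams(noise_cv=0.0, crosstalk=0.3),  # heavy leak = background
        )
        # crosstalk 0.3 puts 30% of signal off-channel: background >= 10%
        warnings = quality_check(report.profile, report.result)
        assert any("background" in w for w in warnings)

    def test_misplaced_cut_site_warns(self, amplicon, noiseless_params):
        """High reported editing with no aberrant-signal rise at the cut
        signals a misalignment."""
        report = self._clean_report(amplicon, noiseless_params)
        report.result.percentages = report.result.percentages.copy()
        labels = report.result.indel_labels
        report.result.percentages[labels == -5] = 40.0  # fake editing, flat profile
        warnings = quality_check(report.profile, report.result)
        assert any("rise" in w for w in warnings)
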
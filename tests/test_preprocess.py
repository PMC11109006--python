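"""Alignment, denoising/binning, coefficient normalization, baselines."""

import numpy as np
import pandas as pd
import pytest

from qlcis import (
    FrameStack,
    align_stack,
    apply_coefficients,
    denoise_and_bin,
    empty_well_coefficients,
    subtract_baseline,
)
from qlcis.preprocess import QUADRANTS, wells_from_table


def textured_frame(rng, shape=(64, 64)):
    """A frame with enough structure for registration."""
    base = rng.random(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return base + 5 * np.exp(-((yy - 30) ** 2 + (xx - 20) ** 2) / 50.0)


def make_stack(frames, interval=1.0, pixel=1.0):
    return FrameStack(data={"IL-5": np.asarray(frames, dtype=float)},
                      frame_interval=interval, time_unit="h", pixel_size_um=pixel)


class TestAlignStack:
    def test_driftless_stack_zero_shifts(self, rng):
        f = textured_frame(rng)
        stack = make_stack([f] * 6)
        _, shifts, conf = align_stack(stack, "IL-5")
        assert shifts == [(0, 0)] * 6
        assert all(conf)

    def test_injected_shift_recovered(self, rng):
        """A frame displaced by (+3, -2) receives the (-3, +2) correction."""
        f = textured_frame(rng)
        frames = [f.copy() for _ in range(6)]
        frames[5] = np.roll(f, shift=(3, -2), axis=(0, 1))
        aligned, shifts, conf = align_stack(make_stack(frames), "IL-5")
        assert shifts[5] == (-3, 2)
        # interior pixels restored exactly; border marked invalid (NaN)
        a = aligned.data["IL-5"][5]
        assert np.isnan(a).any()
        inner = np.s_[5:-5, 5:-5]
        np.testing.assert_allclose(a[inner], f[inner])

    def test_pure_noise_low_confidence(self):
        rng = np.random.default_rng(0)
        frames = [rng.standard_normal((64, 64)) for _ in range(4)]
        _, shifts, conf = align_stack(make_stack(frames), "IL-5")
        assert shifts[1:] == [(0, 0)] * 3
        assert not any(conf[1:])

    def test_featureless_frames_zero_shift_flagged(self, rng):
        frames = [textured_frame(rng)] + [np.zeros((64, 64))] * 3
        _, shifts, conf = align_stack(make_stack(frames), "IL-5")
        assert shifts[1:] == [(0, 0)] * 3
        assert not any(conf[1:])

    def test_single_frame_rejected(self, rng):
        with pytest.raises(ValueError):
            align_stack(make_stack([textured_frame(rng)]), "IL-5")


class TestDenoiseAndBin:
    def test_constant_stack_becomes_zero(self):
        stack = make_stack(np.full((7, 20, 20), 3.3))
        out = denoise_and_bin(stack, median_window=5, bin_factor=5)
        assert np.all(out.data["IL-5"] == 0.0)

    def test_impulse_noise_removed_by_median(self):
        frames = np.zeros((7, 10, 10))
        frames[3, 4, 4] = 100.0  # single-frame impulse
        out = denoise_and_bin(make_stack(frames), median_window=5, bin_factor=1)
        assert np.all(out.data["IL-5"] == 0.0)

    def test_binning_conserves_gaussian_integral(self):
        """Mean binning x area equals the unbinned sum to 1e-6 relative."""
        yy, xx = np.mgrid[:40, :40]
        g = np.exp(-((yy - 20.3) ** 2 + (xx - 17.8) ** 2) / (2 * 4.0**2))
        frames = np.stack([np.zeros_like(g)] + [g] * 4)
        out = denoise_and_bin(make_stack(frames), median_window=1, bin_factor=5)
        binned = out.data["IL-5"][2]
        assert binned.shape == (8, 8)
        assert np.sum(binned) * 25 == pytest.approx(np.sum(g), rel=1e-6)

    def test_pixel_size_scales(self):
        out = denoise_and_bin(make_stack(np.zeros((5, 10, 10)), pixel=0.65),
                              median_window=3, bin_factor=5)
        assert out.pixel_size_um == pytest.approx(3.25)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            denoise_and_bin(make_stack(np.zeros((6, 10, 10))), median_window=4)

    def test_window_longer_than_stack_rejected(self):
        with pytest.raises(ValueError):
            denoise_and_bin(make_stack(np.zeros((3, 10, 10))), median_window=5)

    def test_offset_commutes_with_alignment_chain(self, rng):
        """Adding a global constant before or after processing is equivalent."""
        frames = rng.random((6, 20, 20))
        out1 = denoise_and_bin(make_stack(frames + 7.0), 3, 2).data["IL-5"]
        out2 = denoise_and_bin(make_stack(frames), 3, 2).data["IL-5"]
        np.testing.assert_allclose(out1, out2, atol=1e-12)


def make_table(intensity_fn, n_frames=5, chambers=(1, 2), wells_per_stratum=3,
               channel="IL-5"):
    """Small long-format table; half the wells in each stratum are empty."""
    rows = []
    for ch in chambers:
        for q in QUADRANTS:
            for w in range(wells_per_stratum * 2):
                wid = f"c{ch}{q}w{w}"
                empty = w < wells_per_stratum
                for f in range(n_frames):
                    rows.append((wid, ch, q, f, float(f), channel,
                                 intensity_fn(ch, q, f, w, empty),
                                 0 if empty else 1))
    return pd.DataFrame(rows, columns=["well_id", "chamber", "quadrant", "frame",
                                       "time", "channel", "mean_intensity",
                                       "cell_count"])


class TestEmptyWellCoefficients:
    def test_uniform_wells_give_unit_coefficients(self):
        df = make_table(lambda ch, q, f, w, e: 100.0)
        coeffs = empty_well_coefficients(df)
        np.testing.assert_allclose(coeffs["coefficient"], 1.0)

    def test_bright_chamber_exactly_removed(self):
        """A x2 brighter chamber gets coefficient 2 and corrects to parity."""
        df = make_table(lambda ch, q, f, w, e: 100.0 * (2 if ch == 2 else 1))
        coeffs = empty_well_coefficients(df)
        grand = 100.0 * 1.5
        c1 = coeffs[coeffs["chamber"] == 1]["coefficient"]
        c2 = coeffs[coeffs["chamber"] == 2]["coefficient"]
        np.testing.assert_allclose(c1, 100.0 / grand)
        np.testing.assert_allclose(c2, 200.0 / grand)
        corrected = apply_coefficients(df, coeffs)
        per_chamber = corrected.groupby("chamber")["corrected_intensity"].mean()
        assert per_chamber[1] == pytest.approx(per_chamber[2])

    def test_idempotent(self):
        """Normalizing an already-normalized table changes nothing."""
        rng = np.random.default_rng(2)
        factors = {}

        def drift(ch, q, f, w, e):
            key = (ch, q, f)
            factors.setdefault(key, rng.uniform(0.5, 2.0))
            return 100.0 * factors[key]

        df = make_table(drift)
        corrected = apply_coefficients(df, empty_well_coefficients(df))
        df2 = df.copy()
        df2["mean_intensity"] = corrected["corrected_intensity"]
        corrected2 = apply_coefficients(df2, empty_well_coefficients(df2))
        np.testing.assert_allclose(corrected2["corrected_intensity"],
                                   corrected["corrected_intensity"], rtol=1e-12)

    def test_random_drift_flattens_empty_wells(self):
        rng = np.random.default_rng(3)
        factors = {}

        def drift(ch, q, f, w, e):
            key = (ch, q, f)
            factors.setdefault(key, rng.uniform(0.5, 2.0))
            return 100.0 * factors[key] + rng.normal(0, 0.1)

        df = make_table(drift, wells_per_stratum=10)
        corrected = apply_coefficients(df, empty_well_coefficients(df))
        emp = corrected[corrected["cell_count"] == 0]
        grand = emp["corrected_intensity"].mean()
        resid = emp.groupby(["chamber", "quadrant", "frame"])["corrected_intensity"].mean()
        assert np.max(np.abs(resid / grand - 1.0)) < 0.01

    def test_missing_stratum_falls_back_to_chamber(self):
        df = make_table(lambda ch, q, f, w, e: 100.0)
        # remove all empty wells of one stratum
        drop = (df["chamber"] == 1) & (df["quadrant"] == "upper_left") & (df["cell_count"] == 0)
        df = df[~drop]
        with pytest.warns(UserWarning, match="chamber-level"):
            coeffs = empty_well_coefficients(df)
        assert not coeffs["coefficient"].isna().any()

    def test_no_empty_wells_rejected(self):
        df = make_table(lambda ch, q, f, w, e: 100.0)
        df["cell_count"] = 1
        with pytest.raises(ValueError):
            empty_well_coefficients(df)


class TestSubtractBaseline:
    def _corrected(self, df):
        return apply_coefficients(df, empty_well_coefficients(df))

    def test_typical_well_uses_own_initial(self):
        df = make_table(lambda ch, q, f, w, e: 100.0 + (0.0 if e else f * 2.0))
        traces, modes = subtract_baseline(self._corrected(df), 1.0, "h")
        assert set(modes["baseline_mode"]) == {"own_initial"}
        key = next(k for k in traces)
        np.testing.assert_allclose(traces[key].values,
                                   np.arange(5) * 2.0, atol=1e-9)

    def test_outlier_initial_uses_empty_well_baseline(self):
        def f_int(ch, q, f, w, e):
            base = 100.0
            if not e and w == 5 and ch == 1 and q == "upper_left":
                base += 500.0  # autofluorescent contaminant
            return base + (0.0 if e else f * 2.0)

        df = make_table(f_int, wells_per_stratum=4)
        traces, modes = subtract_baseline(self._corrected(df), 1.0, "h")
        flagged = modes[modes["baseline_mode"] == "empty_well"]
        assert list(flagged["well_id"]) == ["c1upper_leftw5"]
        # the contaminated well's CSS rides on its (constant) contamination,
        # not on a doubled baseline
        tr = traces[("c1upper_leftw5", "IL-5")]
        np.testing.assert_allclose(np.diff(tr.values), 2.0, atol=1e-6)

    def test_degenerate_iqr_keeps_own_initial(self):
        df = make_table(lambda ch, q, f, w, e: 100.0)
        traces, modes = subtract_baseline(self._corrected(df), 1.0, "h")
        assert set(modes["baseline_mode"]) == {"own_initial"}
        for tr in traces.values():
            np.testing.assert_allclose(tr.values, 0.0, atol=1e-9)

    def test_noise_free_chain_is_identity_minus_initial(self):
        """Drift-free, noise-free: the chain only removes the initial frame."""
        df = make_table(lambda ch, q, f, w, e: 50.0 + (0 if e else 3.0 * f**0.5))
        traces, _ = subtract_baseline(self._corrected(df), 1.0, "h")
        expected = 3.0 * np.sqrt(np.arange(5))
        for tr in traces.values():
            np.testing.assert_allclose(tr.values, expected, atol=1e-9)


class TestWellRecords:
    def test_records_from_table(self):
        df = make_table(lambda ch, q, f, w, e: 100.0)
        recs = wells_from_table(df)
        assert len(recs) == len(df["well_id"].unique())
        empties = [r for r in recs if r.empty]
        assert len(empties) == len(recs) // 2
        assert all(len(r.traces["IL-5"]) == 5 for r in recs)
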
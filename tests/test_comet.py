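"""Kymograph comet analysis: tip lines, aligned averaging, superaveraging,
comet area, dual-colour distances, tip-relative averaging, line scans."""

import warnings

import numpy as np
import pytest

from ebtip import comet, simgen
from ebtip.containers import CometProfile, GrowthPhase, Kymograph, TipFit


def clean_kymo(speed=20.0, duration=60.0, noise=0.0, seed=0, offset=0.0,
               delay=0.0):
    cfg = simgen.SimKymoConfig(growth_speed_nm_s=speed, duration_s=duration,
                               noise_sd=noise, seed=seed,
                               channel_offsets_nm=(offset,),
                               channel_delay_s=delay)
    return simgen.simulate_kymograph(cfg)[0]


class TestTipLine:
    def test_slope_matches_growth_speed(self):
        line = comet.detect_tip_line(clean_kymo())
        assert line.accepted
        assert line.slope_px_per_row == pytest.approx(20.0 / 81.0, abs=0.01)

    def test_bright_artefact_excluded_by_confidence_band(self):
        kymo = clean_kymo()
        ref = comet.detect_tip_line(kymo)
        dirty = Kymograph(kymo.data.copy(), kymo.pixel_nm, kymo.line_interval_s)
        row = 30
        tip_col = int(round(ref.position_px(row)))
        dirty.data[row, tip_col + 10] = 10.0  # spot 10 px ahead of the tip
        line = comet.detect_tip_line(dirty)
        assert line.accepted
        assert line.slope_px_per_row == pytest.approx(ref.slope_px_per_row,
                                                      abs=0.005)
        assert line.intercept_px == pytest.approx(ref.intercept_px, abs=0.3)

    def test_shuffled_rows_rejected(self, rng):
        kymo = clean_kymo()
        shuffled = Kymograph(rng.permutation(kymo.data, axis=0),
                             kymo.pixel_nm, kymo.line_interval_s)
        assert not comet.detect_tip_line(shuffled).accepted

    def test_too_few_rows_rejected(self):
        kymo = Kymograph(np.ones((3, 50)))
        with pytest.raises(ValueError, match="5"):
            comet.detect_tip_line(kymo)


class TestAlignAndAverage:
    def test_static_comet_profile_normalised(self):
        kymo = clean_kymo(speed=0.0)
        line = comet.detect_tip_line(kymo)
        prof = comet.align_and_average_comet(kymo, line)
        assert prof.intensity.max() == pytest.approx(1.0)
        ahead = prof.position_nm <= -15 * 81.0
        assert abs(prof.intensity[ahead].mean()) < 1e-9
        assert prof.spacing_nm == pytest.approx(8.1)

    def test_constant_background_removed(self):
        kymo = clean_kymo(speed=0.0)
        shifted = Kymograph(kymo.data + 0.2, kymo.pixel_nm, kymo.line_interval_s)
        line = comet.detect_tip_line(shifted)
        prof = comet.align_and_average_comet(shifted, line)
        assert prof.intensity.max() == pytest.approx(1.0)
        ahead = prof.position_nm <= -15 * 81.0
        assert abs(prof.intensity[ahead].mean()) < 1e-9

    def test_averaging_beats_noise(self, rng):
        # with N rows of i.i.d. noise the averaged profile converges to the
        # noise-free one at ~1/sqrt(N)
        noisy = clean_kymo(noise=0.1, seed=5, duration=60.0)
        clean = clean_kymo(noise=0.0, duration=60.0)
        line = comet.detect_tip_line(clean)
        p_noisy = comet.align_and_average_comet(noisy, line)
        p_clean = comet.align_and_average_comet(clean, line)
        common = np.intersect1d(np.round(p_noisy.position_nm, 3),
                                np.round(p_clean.position_nm, 3))
        yn = p_noisy.intensity[np.isin(np.round(p_noisy.position_nm, 3), common)]
        yc = p_clean.intensity[np.isin(np.round(p_clean.position_nm, 3), common)]
        assert np.sqrt(np.mean((yn - yc) ** 2)) < 0.05

    def test_shift_equivariance(self):
        # translating the comet by k pixels moves the tip-line intercept by
        # k and leaves the aligned profile unchanged
        kymo = clean_kymo(speed=0.0)
        k = 4
        shifted = Kymograph(np.roll(kymo.data, k, axis=1), kymo.pixel_nm,
                            kymo.line_interval_s)
        l0 = comet.detect_tip_line(kymo)
        l1 = comet.detect_tip_line(shifted)
        assert l1.intercept_px - l0.intercept_px == pytest.approx(k, abs=0.01)
        p0 = comet.align_and_average_comet(kymo, l0)
        p1 = comet.align_and_average_comet(shifted, l1)
        # compare around the comet (np.roll wraps the faint far tail, so the
        # extreme positions differ by construction, not by alignment)
        sel0 = np.abs(p0.position_nm) <= 1200.0
        sel1 = np.abs(p1.position_nm) <= 1200.0
        assert np.allclose(p0.intensity[sel0], p1.intensity[sel1], atol=1e-9)


class TestSuperaverage:
    @staticmethod
    def triangle_profile(shift_px=0):
        x = np.arange(-60, 140) * 8.1
        y = np.clip(1.0 - np.abs(x - 200.0) / 400.0, 0.0, None)
        return CometProfile(x + shift_px * 8.1, y)

    def test_shifted_copies_average_to_original(self):
        profiles = [self.triangle_profile(s) for s in (0, 5, -3)]
        avg = comet.superaverage(profiles)
        single = comet.superaverage([self.triangle_profile()])
        common = np.intersect1d(np.round(avg.position_nm, 3),
                                np.round(single.position_nm, 3))
        a = avg.intensity[np.isin(np.round(avg.position_nm, 3), common)]
        b = single.intensity[np.isin(np.round(single.position_nm, 3), common)]
        assert np.allclose(a, b, atol=1e-12)

    def test_single_profile_identity(self):
        p = self.triangle_profile()
        avg = comet.superaverage([p])
        assert np.allclose(avg.intensity, p.intensity)

    def test_profile_below_half_max_excluded(self):
        weak = CometProfile(np.arange(10) * 8.1, np.full(10, np.nan))
        good = self.triangle_profile()
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            avg = comet.superaverage([good, weak])
        assert any("half-maximum" in str(w.message) for w in rec)
        assert avg.n == good.n


class TestCometArea:
    @staticmethod
    def exponential_profile(decay=300.0, amplitude=1.0):
        x = np.arange(-100, 300) * 8.1
        y = np.where(x >= 0.0, amplitude * np.exp(-np.clip(x, 0, None) / decay), 0.0)
        return CometProfile(x, y)

    def test_analytic_area_of_exponential(self):
        out = comet.comet_area(self.exponential_profile())
        assert out["area_nm"] == pytest.approx(300.0, rel=0.02)
        assert out["decay_nm"] == pytest.approx(300.0, rel=0.02)

    def test_area_linear_in_amplitude(self):
        a1 = comet.comet_area(self.exponential_profile(amplitude=1.0))
        a2 = comet.comet_area(self.exponential_profile(amplitude=2.0))
        assert a2["area_nm"] == pytest.approx(2 * a1["area_nm"], rel=1e-6)

    def test_tail_area_linear_in_decay_length(self):
        a1 = comet.comet_area(self.exponential_profile(decay=300.0))
        a2 = comet.comet_area(self.exponential_profile(decay=600.0))
        t1 = a1["tail_amplitude"] * a1["decay_nm"]
        t2 = a2["tail_amplitude"] * a2["decay_nm"]
        assert t2 == pytest.approx(2 * t1, rel=0.02)

    def test_no_decay_crossing_rejected(self):
        flat = CometProfile(np.arange(50) * 8.1, np.ones(50))
        with pytest.raises(ValueError, match="crossing"):
            comet.comet_area(flat)


class TestDualColour:
    @staticmethod
    def pair(offset_nm, noise=0.0, seed=0, delay=0.5):
        cfg = simgen.SimKymoConfig(channel_offsets_nm=(0.0, offset_nm),
                                   channel_delay_s=delay, noise_sd=noise,
                                   duration_s=40.0, seed=seed)
        return simgen.simulate_kymograph(cfg)

    def test_identical_channels_give_zero(self):
        # truly simultaneous identical channels, no sequential correction
        ka, kb = self.pair(0.0, delay=0.0)
        d, _, _ = comet.dual_colour_peak_distance(ka, kb, trim=False)
        assert d.distance_nm == pytest.approx(0.0, abs=1e-9)

    def test_known_offset_recovered(self):
        ka, kb = self.pair(32.0, noise=0.05, seed=3)
        d, _, _ = comet.dual_colour_peak_distance(ka, kb)
        assert d.distance_nm == pytest.approx(32.0, abs=8.1)
        assert d.growth_speed_nm_s == pytest.approx(20.0, rel=0.05)

    def test_omitting_trim_biases_by_half_frame(self):
        # 20 nm/s comet imaged 0.5 s apart: skipping the interpolate/trim
        # correction shifts the apparent distance by ~10 nm
        ka, kb = self.pair(32.0)
        d_corr, _, _ = comet.dual_colour_peak_distance(ka, kb)
        d_raw, _, _ = comet.dual_colour_peak_distance(ka, kb, trim=False)
        bias = d_raw.distance_nm - d_corr.distance_nm
        assert 4.0 <= abs(bias) <= 16.0

    def test_channel_swap_negates_distance(self):
        ka, kb = self.pair(81.0, delay=0.0)
        d_ab, _, _ = comet.dual_colour_peak_distance(ka, kb, trim=False)
        d_ba, _, _ = comet.dual_colour_peak_distance(kb, ka, trim=False)
        assert d_ab.distance_nm == pytest.approx(-d_ba.distance_nm, abs=1e-9)
        assert d_ab.distance_nm == pytest.approx(81.0, abs=8.1)

    def test_shape_mismatch_rejected(self):
        ka, kb = self.pair(0.0)
        with pytest.raises(ValueError, match="shape"):
            comet.dual_colour_peak_distance(
                ka, Kymograph(kb.data[:, :-2], kb.pixel_nm))

    def test_superaveraged_distance(self):
        pas, pbs = [], []
        for seed in range(5):
            ka, kb = self.pair(150.0, noise=0.05, seed=seed)
            _, pa, pb = comet.dual_colour_peak_distance(ka, kb)
            pas.append(pa)
            pbs.append(pb)
        d = comet.superaveraged_peak_distance(pas, pbs)
        assert d == pytest.approx(150.0, abs=8.1)


class TestTipRelativeAverage:
    @staticmethod
    def scene(distance_nm, v=20.0, n=41, pixel_nm=81.0, n_cols=80,
              delay=0.5, noise=0.0, seed=0):
        """MT tip at mu(t) = 1000 + v t; EB channel imaged ``delay`` seconds
        *before* the MT channel (sequential acquisition order matching the
        mu - delay * v reference) with a Gaussian comet ``distance_nm``
        behind the tip."""
        rng = np.random.default_rng(seed)
        x = (np.arange(n_cols) + 0.5) * pixel_nm
        tips, eb = [], []
        for f in range(n):
            mu = 1000.0 + v * f
            tips.append(TipFit(f, mu, 130.0, 1.0, 0.0, 0.01, accepted=True))
            tip_in_eb_frame = 1000.0 + v * (f - delay)
            peak = tip_in_eb_frame - distance_nm
            row = np.exp(-0.5 * ((x - peak) / 130.0) ** 2)
            if noise:
                row = row + rng.normal(0.0, noise, row.size)
            eb.append(row)
        phase = GrowthPhase(0.0, float(n - 1), v, 1.0, kept=True)
        return tips, phase, np.asarray(eb), pixel_nm

    def test_zero_speed_zero_distance(self):
        tips, phase, eb, px = self.scene(0.0, v=0.0)
        phase = GrowthPhase(0.0, 40.0, 0.0, 1.0, kept=True)
        prof, dists = comet.tip_relative_average(
            tips, phase, eb, px, indices=list(range(len(tips))))
        peak_pos = prof.position_nm[np.argmax(prof.intensity)]
        assert peak_pos == pytest.approx(0.0, abs=8.0)
        assert np.median(dists) == pytest.approx(0.0, abs=8.0)

    def test_known_distance_recovered(self):
        tips, phase, eb, px = self.scene(150.0)
        prof, dists = comet.tip_relative_average(tips, phase, eb, px)
        peak_pos = prof.position_nm[np.argmax(prof.intensity)]
        assert peak_pos == pytest.approx(150.0, abs=8.0)
        assert np.median(dists) == pytest.approx(150.0, abs=8.0)

    def test_median_fit_agrees_with_argmax_under_noise(self):
        tips, phase, eb, px = self.scene(150.0, noise=0.05, seed=4)
        prof, dists = comet.tip_relative_average(tips, phase, eb, px)
        peak_pos = prof.position_nm[np.argmax(prof.intensity)]
        assert np.median(dists) == pytest.approx(peak_pos, abs=16.0)

    def test_no_accepted_timepoints_rejected(self):
        tips, phase, eb, px = self.scene(150.0)
        for tip in tips:
            tip.accepted = False
        with pytest.raises(ValueError, match="accepted"):
            comet.tip_relative_average(tips, phase, eb, px)


class TestCellLinescans:
    @staticmethod
    def scan(shift_px=0, offset_px=0, n=200, pixel_nm=5.0):
        """Three-channel line scan; EB2 offset by ``offset_px`` pixels."""
        x = np.arange(n, dtype=float)
        def peak(c):
            return np.exp(-0.5 * ((x - c) / 12.0) ** 2)
        c0 = 80.0 + shift_px
        return {"EB1": peak(c0), "EB3": peak(c0), "EB2": peak(c0 + offset_px)}

    def test_random_shifts_average_to_original(self):
        scans = [self.scan(s) for s in (0, 7, -4, 11)]
        out = comet.align_cell_linescans(scans, mode="fixed", pixel_nm=5.0)
        single = comet.align_cell_linescans([self.scan()], mode="fixed",
                                            pixel_nm=5.0)
        for ch in ("EB1", "EB2", "EB3"):
            common = np.intersect1d(out[ch].position_nm,
                                    single[ch].position_nm)
            a = out[ch].intensity[np.isin(out[ch].position_nm, common)]
            b = single[ch].intensity[np.isin(single[ch].position_nm, common)]
            assert np.allclose(a, b, atol=1e-9)

    def test_channel_offset_preserved_in_average(self):
        # EB2 placed 145 nm from EB1/EB3 in every scan (29 px at 5 nm/px)
        scans = [self.scan(s, offset_px=29) for s in (0, 5, -8)]
        out = comet.align_cell_linescans(scans, mode="fixed", pixel_nm=5.0)
        p1 = out["EB1"].position_nm[np.argmax(out["EB1"].intensity)]
        p2 = out["EB2"].position_nm[np.argmax(out["EB2"].intensity)]
        assert p2 - p1 == pytest.approx(145.0, abs=5.0)

    def test_live_mode_single_scan_identity(self):
        out = comet.align_cell_linescans([self.scan()], mode="live",
                                         pixel_nm=5.0)
        assert out["EB3"].intensity.max() == pytest.approx(1.0)

    def test_flat_reference_channel_excluded(self):
        bad = {"EB1": np.ones(200), "EB3": np.ones(200), "EB2": np.ones(200)}
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            out = comet.align_cell_linescans([self.scan(), bad], mode="fixed",
                                             pixel_nm=5.0)
        assert any("half-maximum" in str(w.message) for w in rec)
        assert out["EB1"].n == 1
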
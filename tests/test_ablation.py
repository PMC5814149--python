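"""Laser-ablation pipeline: differentials, wave fits, minus-end recovery."""

import math

import numpy as np
import pytest

from monoaster import ablation as ab
from monoaster.filaments import FilamentSet, count_severed_minus_ends
from monoaster.synthdata import Optics, sample_monopole


def _stack_from_frames(frames, optics, cut_idx=1):
    return ab.ImageStack(frames=frames, pixel_size=optics.pixel_size,
                         frame_interval=optics.frame_interval,
                         center=optics.center, cut_time_index=cut_idx)


@pytest.fixture
def tiny_optics():
    return Optics(size=256, pixel_size=0.35, noise="none", frame_interval=0.5,
                  background=5.0)


class TestDifferentialIntensity:
    def test_static_movie_gives_zero(self, tiny_optics):
        frames = np.full((8, 32, 32), 3.0)
        stack = ab.ImageStack(frames=frames, pixel_size=0.35, frame_interval=0.5,
                              center=(16, 16), cut_time_index=2)
        diff, times = ab.differential_intensity(stack, 1.0)
        assert np.allclose(diff, 0.0)
        assert len(times) == 4

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = rng.random((6, 16, 16))
        b = rng.random((6, 16, 16))
        mk = lambda f: ab.ImageStack(frames=f, pixel_size=0.5, frame_interval=1.0,
                                     center=(8, 8), cut_time_index=0)
        da, _ = ab.differential_intensity(mk(a), 2.0)
        db, _ = ab.differential_intensity(mk(b), 2.0)
        dab, _ = ab.differential_intensity(mk(a + b), 2.0)
        assert np.allclose(dab, da + db)

    def test_delta_t_validation(self):
        stack = ab.ImageStack(frames=np.zeros((4, 8, 8)), pixel_size=0.5,
                              frame_interval=0.5, center=(4, 4), cut_time_index=0)
        with pytest.raises(ValueError):
            ab.differential_intensity(stack, 0.7)  # not a multiple
        with pytest.raises(ValueError):
            ab.differential_intensity(stack, 10.0)  # longer than movie


class TestAngularIntegrate:
    def test_single_pixel_ring_mass(self):
        frame = np.zeros((64, 64))
        frame[32, 52] = 1.0  # 20 px from center
        stack = ab.ImageStack(frames=frame[None] + 0.0, pixel_size=0.5,
                              frame_interval=1.0, center=(32.0, 32.0),
                              cut_time_index=0)
        x, prof = ab.angular_integrate(frame[None], stack, bin_width=0.5)
        mass = prof[0] * 0.5
        assert mass.sum() == pytest.approx(1.0)
        assert x[np.argmax(mass)] == pytest.approx(10.0, abs=0.5)

    def test_rotation_invariance(self, control_params, tiny_optics):
        from monoaster.synthdata import render

        fs = sample_monopole(control_params, 5000, seed=8, x_max=35.0)
        frame = render(fs, tiny_optics) - tiny_optics.background
        stack = _stack_from_frames(frame[None], tiny_optics, cut_idx=0)
        x, p0 = ab.angular_integrate(frame[None], stack, bin_width=1.0)
        _, p90 = ab.angular_integrate(np.rot90(frame)[None].copy(), stack, bin_width=1.0)
        sel = (x > 3) & (x < 30)
        rel = p90[0][sel] / p0[0][sel] - 1.0
        assert np.abs(rel).max() < 0.02

    def test_center_outside_frame_rejected(self):
        stack = ab.ImageStack(frames=np.zeros((1, 8, 8)), pixel_size=0.5,
                              frame_interval=1.0, center=(20.0, 4.0),
                              cut_time_index=0)
        with pytest.raises(ValueError):
            ab.angular_integrate(np.zeros((1, 8, 8)), stack)


class TestFitWave:
    def test_exact_gaussian_recovered(self):
        x = np.arange(0.25, 40.0, 0.5)
        times = np.array([1.0, 2.0, 3.0])
        amp = 7.0 / (2.0 * math.sqrt(2 * math.pi))  # area 7, sigma 2
        profiles = np.stack([amp * np.exp(-0.5 * ((x - c) / 2.0) ** 2)
                             for c in (15.0, 14.0, 13.0)])
        cut = ab.CutSpec(geometry="circle", radius=16.0, delta_t=1.0)
        track = ab.fit_wave(x, profiles, times, cut, bin_width=0.5)
        assert track.accepted.all()
        assert np.allclose(track.centers, [15.0, 14.0, 13.0], atol=1e-3)
        assert np.allclose(track.areas, 7.0, rtol=1e-3)

    def test_merged_peaks_flagged(self):
        x = np.arange(0.25, 40.0, 0.5)
        two = (np.exp(-0.5 * ((x - 12.0) / 1.0) ** 2)
               + np.exp(-0.5 * ((x - 17.5) / 1.0) ** 2))
        profiles = np.stack([two, two, two])
        cut = ab.CutSpec(geometry="circle", radius=20.0, delta_t=1.0)
        track = ab.fit_wave(x, profiles, np.array([1.0, 2.0, 3.0]), cut)
        assert any("merged" in msg for _, msg in track.flags)

    def test_no_peak_is_no_wave(self):
        x = np.arange(0.25, 40.0, 0.5)
        profiles = np.zeros((4, len(x)))
        cut = ab.CutSpec(geometry="circle", radius=16.0, delta_t=1.0)
        track = ab.fit_wave(x, profiles, np.arange(4.0), cut)
        assert not track.has_wave


class TestVelocity:
    def test_two_perfect_frames_exact_slope(self):
        track = ab.WaveTrack(times=np.array([1.0, 3.0]),
                             centers=np.array([15.0, 13.88]),
                             sigmas=np.ones(2), areas=np.ones(2),
                             accepted=np.ones(2, dtype=bool), r_cut=16.0)
        vel = ab.depolymerization_velocity(track)
        assert vel.v_um_per_s == pytest.approx(0.56)
        assert vel.v_um_per_min == pytest.approx(33.6)

    def test_stationary_peak_velocity_zero(self):
        track = ab.WaveTrack(times=np.arange(5.0),
                             centers=np.full(5, 10.0) + np.array([0, 1e-3, -1e-3, 0, 0]),
                             sigmas=np.ones(5), areas=np.ones(5),
                             accepted=np.ones(5, dtype=bool), r_cut=16.0)
        vel = ab.depolymerization_velocity(track)
        assert vel.v_um_per_s < 1e-3


class TestSimulateCut:
    def test_single_filament_geometry(self, tiny_optics):
        """Minus at 5, length 20, cut at 19: constant wave until d=14, front r-v_d t."""
        fs = FilamentSet(minus_pos=np.array([5.0]), length=np.array([20.0]),
                         angles=np.array([0.7]))
        cut = ab.CutSpec(geometry="circle", radius=19.0, delta_t=1.0)
        v_d = 0.7
        stack = ab.simulate_cut(fs, cut, v_d, tiny_optics, seed=0)
        diff, times = ab.differential_intensity(stack, 1.0)
        x, profs = ab.angular_integrate(diff, stack, bin_width=0.5)
        track = ab.fit_wave(x, profs, times, cut, bin_width=0.5)
        m = track.accepted
        # front position: r - v_d * t
        expect = 19.0 - v_d * track.times[m]
        assert np.allclose(track.centers[m], expect, atol=0.4)
        # area constant while the fragment spans more than one window
        areas = track.areas[m]
        d = v_d * (track.times[m] - track.times[m][0])
        plateau = areas[d < 12.0]
        assert plateau.std() / plateau.mean() < 0.05
        # and the wave dies once the front passes the minus end (d > 14)
        assert track.areas[~m].max(initial=0.0) <= 0.05 * areas.max()

    def test_intensity_conservation(self, control_params, tiny_optics):
        """Non-overlapping differentials sum to severed length x scale."""
        fs = sample_monopole(control_params, 2000, seed=11, x_max=38.0)
        cut = ab.CutSpec(geometry="circle", radius=14.0, delta_t=1.0)
        stack = ab.simulate_cut(fs, cut, 0.56, tiny_optics, seed=0)
        k = int(round(1.0 / tiny_optics.frame_interval))
        diff, _ = ab.differential_intensity(stack, 1.0)
        total = diff[::k].sum()
        severed = fs.spanning(14.0)
        expected = (14.0 - fs.minus_pos[severed]).sum() * tiny_optics.intensity_per_um
        assert total == pytest.approx(expected, rel=0.01)

    def test_no_spanning_filaments_warns(self, tiny_optics):
        fs = FilamentSet(minus_pos=np.array([1.0]), length=np.array([2.0]),
                         angles=np.array([0.0]))
        cut = ab.CutSpec(geometry="circle", radius=20.0, delta_t=1.0)
        with pytest.warns(UserWarning, match="no filament spans"):
            stack = ab.simulate_cut(fs, cut, 0.56, tiny_optics, seed=0)
        diff, _ = ab.differential_intensity(stack, 1.0)
        assert np.abs(diff).max() < 1e-9


class TestAreaDecay:
    def _analyze(self, fs, r, optics, v_d=0.56, delta_t=1.0):
        cut = ab.CutSpec(geometry="circle", radius=r, delta_t=delta_t)
        stack = ab.simulate_cut(fs, cut, v_d, optics, seed=0)
        return ab.analyze_cut_movie(stack, cut)

    def test_central_minus_ends_give_flat_decay(self, tiny_optics):
        rng = np.random.default_rng(3)
        n = 600
        fs = FilamentSet(minus_pos=np.full(n, 0.8), length=rng.exponential(25.0, n) + 16.0,
                         angles=rng.uniform(0, 2 * np.pi, n))
        _, _, est = self._analyze(fs, 14.0, tiny_optics)
        assert abs(est.slope_at_cut) < 0.01  # per µm; essentially flat

    def test_amplitude_linearity(self, control_params, tiny_optics):
        fs1 = sample_monopole(control_params, 2000, seed=13, x_max=38.0)
        fs2 = FilamentSet(minus_pos=np.tile(fs1.minus_pos, 2),
                          length=np.tile(fs1.length, 2),
                          angles=np.concatenate([fs1.angles,
                                                 (fs1.angles + 1.1) % (2 * np.pi)]))
        _, _, e1 = self._analyze(fs1, 14.0, tiny_optics)
        _, _, e2 = self._analyze(fs2, 14.0, tiny_optics)
        assert e2.n_c_at_cut / e1.n_c_at_cut == pytest.approx(2.0, rel=0.1)
        assert e2.per_area_value / e1.per_area_value == pytest.approx(2.0, rel=0.1)

    def test_pipeline_counts_match_oracle(self, control_params, tiny_optics):
        fs = sample_monopole(control_params, 8000, seed=17, x_max=38.0)
        _, _, est = self._analyze(fs, 15.0, tiny_optics, delta_t=2.0)
        edges = np.arange(0.0, 15.0 - 0.56 * 2.0, 3.0)
        oracle = count_severed_minus_ends(fs, 15.0, edges)
        pipe = ab.minus_end_counts(est, edges, tiny_optics.intensity_per_um)
        big = oracle >= 100
        assert big.any()
        assert np.abs(pipe[big] / oracle[big] - 1.0).max() < 0.05


class TestAssembleProfile:
    def _fake_estimate(self, r, value):
        return ab.NucleationEstimate(
            r_cut=r, d=np.zeros(1), t_window_start=np.zeros(1),
            area=np.ones(1), area_norm=np.ones(1),
            decay_length=5.0, area_at_cut=1.0, slope_at_cut=-0.2,
            fluorescence_at_cut=value * 0.2 * 2 * math.pi * r / 0.2,
            n_c_at_cut=value * 2 * math.pi * r, per_area_value=value,
            v_d=0.56, delta_t=2.0,
        )

    def test_duplicate_estimates_have_zero_sd(self):
        ests = [self._fake_estimate(10.0, 3.0) for _ in range(4)]
        prof = ab.assemble_nucleation_profile(ests)
        assert prof.sd[0] == 0.0

    def test_single_radius_warns(self):
        ests = [self._fake_estimate(10.0, 3.0), self._fake_estimate(10.0, 4.0)]
        with pytest.warns(UserWarning, match="single radius"):
            prof = ab.assemble_nucleation_profile(ests)
        assert len(prof.x) == 1

    def test_binning_and_ordering(self):
        ests = [self._fake_estimate(r, v) for r, v in
                [(8.0, 5.0), (9.0, 4.0), (20.0, 1.0), (21.0, 1.2)]]
        prof = ab.assemble_nucleation_profile(ests, bin_width=5.0)
        assert np.all(np.diff(prof.x) > 0)
        assert prof.values[0] > prof.values[-1]


class TestLengthDistribution:
    def test_delta_lengths_flagged_non_exponential(self, tiny_optics):
        rng = np.random.default_rng(5)
        n = 4000
        ests = []
        for i, r in enumerate((10.0, 12.0, 14.0, 16.0)):
            fs = FilamentSet(minus_pos=rng.uniform(0.0, 8.0, n),
                             length=np.full(n, 10.0),
                             angles=rng.uniform(0, 2 * np.pi, n))
            cut = ab.CutSpec(geometry="circle", radius=r, delta_t=1.0)
            stack = ab.simulate_cut(fs, cut, 0.56, tiny_optics, seed=i)
            _, _, est = ab.analyze_cut_movie(stack, cut)
            ests.append(est)
        lf = ab.length_distribution(ests, tiny_optics.intensity_per_um, y_band=(2.0, 7.0))
        assert lf.non_exponential_flag

    def test_insufficient_radii_rejected(self):
        with pytest.raises(ValueError):
            ab.length_distribution([], 100.0)


class TestLineCut:
    def test_two_waves_recovered(self):
        """Synthetic bipolar cut: two Gaussians travelling toward the poles."""
        x = np.arange(-30.0, 30.0, 0.5)
        times = np.arange(1.0, 9.0)
        v = 0.5
        profs = np.stack([
            np.exp(-0.5 * ((x - (-5.0 - v * t)) / 1.5) ** 2)
            + np.exp(-0.5 * ((x - (5.0 + v * t)) / 1.5) ** 2)
            for t in times
        ])
        cut = ab.CutSpec(geometry="line", offset=0.0, delta_t=1.0)
        left, right = ab.analyze_line_cut_profiles(x + 0.0, profs, times, cut)
        for tr in (left, right):
            assert tr.has_wave
            vel = ab.depolymerization_velocity(tr)
            assert vel.v_um_per_s == pytest.approx(v, rel=0.05)
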
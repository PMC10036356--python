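"""Localization, linking, track filtering and drift correction."""

import numpy as np
import pandas as pd
import pytest

from mucorheo.errors import InvalidInputError
from mucorheo.synthetic_data import (
    FluidModel,
    RenderParams,
    TrajectoryParams,
    render_image_stack,
    simulate_fbm_tracks,
)
from mucorheo.tracking import (
    ImageStack,
    bandpass_filter,
    drift_correct,
    filter_tracks,
    link_trajectories,
    locate_beads,
)
from mucorheo.trajectories import TrajectorySet

PX = 0.1625


def _static_stack(points_px, shape=(64, 64), n_frames=1, **render_kw):
    rows = [
        (i, t, x * PX, y * PX)
        for i, (x, y) in enumerate(points_px)
        for t in range(n_frames)
    ]
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
    ts = TrajectorySet(df, 1 / 60)
    kw = dict(poisson_noise=False, shape_yx=shape)
    kw.update(render_kw)
    return render_image_stack(ts, RenderParams(**kw), seed=1)


class TestBandpass:
    def test_constant_image_maps_to_zero(self):
        stack = ImageStack(np.full((2, 32, 32), 55.0), PX, 60)
        out = bandpass_filter(stack, 1.0, 7)
        assert np.allclose(out.frames, 0.0)

    def test_peak_location_preserved(self):
        stack = _static_stack([(20, 30)])
        out = bandpass_filter(stack, 1.0, 7)
        y, x = np.unravel_index(np.argmax(out.frames[0]), (64, 64))
        assert (y, x) == (30, 20)

    def test_noise_variance_reduced(self, rng):
        noise = rng.poisson(100, (1, 64, 64)).astype(float)
        stack = ImageStack(noise, PX, 60)
        out = bandpass_filter(stack, 1.0, 7)
        assert out.frames.var() < noise.var()

    def test_invalid_scales_rejected(self):
        stack = ImageStack(np.zeros((1, 8, 8)), PX, 60)
        with pytest.raises(InvalidInputError):
            bandpass_filter(stack, 4.0, 7)


class TestLocate:
    def test_blank_frame_no_detections(self):
        stack = ImageStack(np.zeros((1, 32, 32)), PX, 60)
        assert len(locate_beads(stack, 7)) == 0

    def test_subpixel_bias_below_005_px(self):
        """Noiseless rendered spots across sub-pixel phases: bias < 0.05 px."""
        worst = 0.0
        for fx in (0.0, 0.2, 0.3, 0.5, 0.7):
            for fy in (0.0, 0.3, 0.7):
                x, y = 20 + fx, 30 + fy
                stack = _static_stack([(x, y)], background_counts=100)
                bp = bandpass_filter(stack, 1.0, 7)
                det = locate_beads(bp, 7, min_mass=100)
                det = det.loc[[det["mass"].idxmax()]]
                worst = max(worst, abs(det.x.iloc[0] - x), abs(det.y.iloc[0] - y))
        assert worst < 0.05

    def test_noisy_rmse_below_02_px(self):
        """Poisson noise at peak SNR >= 10: localization RMSE < 0.2 px."""
        errs = []
        for seed in range(15):
            stack = _static_stack(
                [(20.3, 30.7)],
                poisson_noise=True,
                peak_counts=1500,
                background_counts=100,
            )
            # re-render with a different noise realization
            ts = TrajectorySet(
                pd.DataFrame(
                    {
                        "track_id": [0],
                        "frame": [0],
                        "x_um": [20.3 * PX],
                        "y_um": [30.7 * PX],
                    }
                ),
                1 / 60,
            )
            stack = render_image_stack(
                ts,
                RenderParams(peak_counts=1500, background_counts=100, shape_yx=(64, 64)),
                seed=seed,
            )
            bp = bandpass_filter(stack, 1.0, 7)
            det = locate_beads(bp, 7, min_mass=100)
            det = det.loc[[det["mass"].idxmax()]]
            errs.append((det.x.iloc[0] - 20.3, det.y.iloc[0] - 30.7))
        assert np.sqrt(np.mean(np.square(errs))) < 0.2

    def test_two_separated_spots_two_detections(self):
        stack = _static_stack([(15, 15), (35, 35)])
        det = locate_beads(stack, 7, min_mass=100)
        assert len(det) == 2


class TestLinking:
    def test_one_detection_per_frame_single_track(self):
        det = pd.DataFrame(
            {"frame": range(10), "x": np.linspace(5, 6, 10), "y": 5.0}
        )
        ts = link_trajectories(det, PX, 60, search_radius_px=2)
        assert ts.n_tracks == 1
        assert len(ts.data) == 10

    def test_well_separated_parallel_tracks_recovered_exactly(self):
        rng = np.random.default_rng(8)
        n_frames = 60
        truth = {}
        rows = []
        for b in range(5):
            x = 10.0 + 20 * b + np.cumsum(rng.normal(0, 0.3, n_frames))
            y = 50.0 + np.cumsum(rng.normal(0, 0.3, n_frames))
            truth[b] = np.column_stack([x, y])
            for t in range(n_frames):
                rows.append((t, x[t], y[t]))
        det = pd.DataFrame(rows, columns=["frame", "x", "y"])
        det = det.sample(frac=1.0, random_state=1)  # permutation-invariance
        ts = link_trajectories(det, PX, 60, search_radius_px=5)
        assert ts.n_tracks == 5
        recovered = sorted(
            (xy[0, 0] / PX, xy) for _, _, xy in ts.iter_tracks()
        )
        for b, (_, xy) in enumerate(recovered):
            assert np.allclose(xy / PX, truth[b])

    def test_gap_longer_than_memory_starts_new_track(self):
        frames = [0, 1, 2, 6, 7]  # gap of 3 > memory 2
        det = pd.DataFrame({"frame": frames, "x": 5.0, "y": 5.0})
        ts = link_trajectories(det, PX, 60, search_radius_px=2, memory=2)
        assert ts.n_tracks == 2

    def test_gap_within_memory_bridged(self):
        frames = [0, 1, 2, 4, 5]
        det = pd.DataFrame({"frame": frames, "x": 5.0, "y": 5.0})
        ts = link_trajectories(det, PX, 60, search_radius_px=2, memory=2)
        assert ts.n_tracks == 1

    def test_no_detection_duplicated(self):
        # two tracks converging on one detection: it is used once
        det = pd.DataFrame(
            {"frame": [0, 0, 1], "x": [5.0, 6.0, 5.5], "y": [5.0, 5.0, 5.0]}
        )
        ts = link_trajectories(det, PX, 60, search_radius_px=2)
        sizes = ts.track_lengths()
        assert sorted(sizes.tolist()) == [1, 2]


class TestFilterTracks:
    def test_min_length_one_is_identity(self, gel_tracks):
        out = filter_tracks(gel_tracks, 1)
        assert out.data.equals(gel_tracks.data)

    def test_counting(self):
        rows = []
        for tid, length in enumerate((5, 50, 500)):
            for t in range(length):
                rows.append((tid, t, 0.0, 0.0))
        ts = TrajectorySet(
            pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"]), 1 / 60
        )
        assert filter_tracks(ts, 60).n_tracks == 1
        assert filter_tracks(ts, 501).n_tracks == 0


class TestDriftCorrect:
    def _tracks(self, rng, n_beads=6, n_frames=80):
        rows = []
        for b in range(n_beads):
            xy = np.cumsum(rng.normal(0, 0.05, (n_frames, 2)), axis=0)
            for t in range(n_frames):
                rows.append((b, t, xy[t, 0], xy[t, 1]))
        return TrajectorySet(
            pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"]), 1 / 60
        )

    def test_uniform_drift_cancels(self, rng):
        ts = self._tracks(rng)
        v = np.array([0.03, -0.02])
        drifted = ts.data.copy()
        drifted["x_um"] += v[0] * drifted["frame"]
        drifted["y_um"] += v[1] * drifted["frame"]
        ts_d = TrajectorySet(drifted, 1 / 60)
        a = drift_correct(ts)
        b = drift_correct(ts_d)
        assert np.allclose(
            a.data[["x_um", "y_um"]].to_numpy(),
            b.data[["x_um", "y_um"]].to_numpy(),
            atol=1e-10,
        )

    def test_idempotent(self, rng):
        ts = self._tracks(rng)
        once = drift_correct(ts)
        twice = drift_correct(once)
        assert np.allclose(
            once.data[["x_um", "y_um"]].to_numpy(),
            twice.data[["x_um", "y_um"]].to_numpy(),
            atol=1e-12,
        )

    def test_mean_displacement_zero_after_correction(self, rng):
        ts = drift_correct(self._tracks(rng))
        wide_x = ts.data.pivot(index="frame", columns="track_id", values="x_um")
        assert np.allclose(np.diff(wide_x.to_numpy(), axis=0).mean(axis=1), 0, atol=1e-12)

    def test_single_track_warns_and_passes_through(self):
        df = pd.DataFrame(
            {"track_id": 0, "frame": range(5), "x_um": 1.0, "y_um": 2.0}
        )
        ts = TrajectorySet(df, 1 / 60)
        with pytest.warns(UserWarning):
            out = drift_correct(ts)
        assert out.data.equals(ts.data)


class TestEndToEnd:
    def test_video_tracking_reproduces_generator_msd(self):
        """simulate -> render -> locate -> link MSD within 10% for lags <= 1 s."""
        from mucorheo.microrheology import msd_ensemble, msd_track, subsample_loglog

        fluid = FluidModel(alpha=0.1856, eta_1hz=0.05)
        params = TrajectoryParams(
            n_beads=12,
            n_frames=240,
            localization_sigma_um=0.0,
            start_box=((3.0, 30.0), (3.0, 30.0)),
        )
        truth = simulate_fbm_tracks(fluid, params, seed=21)
        stack = render_image_stack(
            truth, RenderParams(peak_counts=8000, shape_yx=(220, 220)), seed=22
        )
        bp = bandpass_filter(stack, 1.0, 7)
        det = locate_beads(bp, 7, min_mass=2000)
        ts = link_trajectories(det, PX, 60, search_radius_px=5, memory=2)
        ts = filter_tracks(ts, 200)
        assert ts.n_tracks >= 10

        def ensemble(t):
            return subsample_loglog(
                msd_ensemble(
                    [msd_track(f, xy, t.frame_interval_s) for _, f, xy in t.iter_tracks()]
                )
            )

        got, want = ensemble(ts), ensemble(truth)
        sel = got.lags <= 1.0
        ref = np.interp(got.lags[sel], want.lags, want.msd)
        assert np.abs(got.msd[sel] / ref - 1).max() < 0.10
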
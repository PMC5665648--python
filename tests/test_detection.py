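"""Spot detection and fitting: oracles, significance, recall/precision."""

from dataclasses import replace

import numpy as np
import pytest

from escrtdyn.detection import detect_candidates, detect_frame, fit_spot
from escrtdyn.detection import test_significance as amplitude_significance
from escrtdyn.geometry import PointSpreadFunction
from escrtdyn.render import expected_unit_amplitude, render_volume_series
from escrtdyn.synthetic import EmitterTruth, Scene
from tests.conftest import single_emitter_series


def _synthetic_gaussian_frame(shape, center, amplitude, background, psf,
                              voxel_size):
    """Noise-free sampled Gaussian (the fit's own model) for exact oracles."""
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    sz, sy, sx = psf.sigmas_voxels(voxel_size)
    g = np.exp(-((xx - center[2]) ** 2 + (yy - center[1]) ** 2) / (2 * sx ** 2)
               - (zz - center[0]) ** 2 / (2 * sz ** 2))
    return background + amplitude * g


class TestDetectCandidates:
    def test_blank_frame_yields_nothing(self, psf, voxel_size):
        assert detect_candidates(np.zeros((16, 32, 32)), psf, voxel_size) == []

    def test_single_spot_single_candidate(self, psf, voxel_size):
        frame = _synthetic_gaussian_frame((16, 32, 32), (8, 16.3, 15.7),
                                          100.0, 10.0, psf, voxel_size)
        cands = detect_candidates(frame, psf, voxel_size)
        assert len(cands) == 1
        assert np.all(np.abs(np.array(cands[0]) - (8, 16, 16)) <= 1)

    def test_two_well_separated_spots(self, psf, voxel_size):
        # 10x the lateral PSF sigma apart -> exactly two candidates
        frame = _synthetic_gaussian_frame((16, 40, 40), (8, 14, 14),
                                          100.0, 10.0, psf, voxel_size)
        frame += _synthetic_gaussian_frame((16, 40, 40), (8, 14, 25.3),
                                           80.0, 0.0, psf, voxel_size)
        assert len(detect_candidates(frame, psf, voxel_size)) == 2


class TestFitSpot:
    def test_noiseless_recovery(self, psf, voxel_size):
        # amplitude and background within 1%, position within 0.05 voxel
        center = (8.0, 16.32, 15.68)
        frame = _synthetic_gaussian_frame((16, 32, 32), center, 100.0, 10.0,
                                          psf, voxel_size)
        fit = fit_spot(frame, (8, 16, 16), psf, voxel_size)
        assert fit.converged
        assert fit.amplitude == pytest.approx(100.0, rel=0.01)
        assert fit.local_background == pytest.approx(10.0, rel=0.01)
        vz, vy, vx = voxel_size
        fitted_vox = fit.position / np.array([vx, vy, vz])
        np.testing.assert_allclose(fitted_vox, np.array(center)[::-1],
                                   atol=0.05)

    def test_flat_background_not_significant(self, psf, voxel_size, geom_small,
                                             camera, egfp):
        rng = np.random.default_rng(0)
        vol, _ = single_emitter_series(geom_small, camera, psf, egfp, 1, 1,
                                       rng)
        # fit far away from the emitter on pure background
        frame = np.clip(vol.data[0] - camera.offset, 0, None)
        fit = fit_spot(frame, (4, 8, 40), psf, voxel_size)
        assert abs(fit.amplitude) < 3 * fit.residual_sd
        accepted, p = amplitude_significance(fit)
        assert fit.snr < 2.0 or not accepted

    def test_point_emitter_sigma_close_to_psf(self, psf, voxel_size,
                                              geom_small, camera, egfp):
        rng = np.random.default_rng(1)
        vol, pos = single_emitter_series(geom_small, camera, psf, egfp, 40, 6,
                                         rng)
        sigs = []
        for t in range(6):
            frame = np.clip(vol.data[t] - camera.offset, 0, None)
            fits = detect_frame(frame, psf, voxel_size, frame_index=t)
            sigs.extend(f.fitted_sigmas[0] for f in fits)
        assert np.median(sigs) == pytest.approx(psf.sigma_xy, rel=0.15)


class TestSignificance:
    def test_zero_amplitude_gives_half_p(self, psf, voxel_size):
        frame = _synthetic_gaussian_frame((16, 32, 32), (8, 16, 16), 0.0,
                                          10.0, psf, voxel_size)
        rng = np.random.default_rng(0)
        frame = frame + rng.normal(0, 1.0, frame.shape)
        fit = fit_spot(frame, (8, 16, 16), psf, voxel_size,
                       refine_sigmas=False)
        fit.amplitude = 0.0
        accepted, p = amplitude_significance(fit, alpha=0.05)
        assert p == pytest.approx(0.5)
        assert not accepted

    def test_closed_form_matches_residual_permutation(self, voxel_size):
        """The t-test p-value agrees with a brute-force permutation null of
        the amplitude-at-fixed-position estimate on a ~100-voxel window."""
        from scipy import stats as sps

        psf_small = PointSpreadFunction(sigma_xy=55.0, sigma_z=150.0)
        rng = np.random.default_rng(5)
        shape = (7, 4, 4)                     # 112-voxel window
        frame = 10.0 + rng.normal(0.0, 2.0, shape)
        zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape],
                                 indexing="ij")
        sz, sy, sx = psf_small.sigmas_voxels(voxel_size)
        g = np.exp(-((xx - 1.5) ** 2 + (yy - 1.5) ** 2) / (2 * sx ** 2)
                   - (zz - 3.0) ** 2 / (2 * sz ** 2)).ravel()
        frame = frame + 1.2 * g.reshape(shape)  # weak spot -> intermediate p
        y = frame.ravel()
        design = np.column_stack([g, np.ones_like(g)])

        def amp(values):
            coef, res, *_ = np.linalg.lstsq(design, values, rcond=None)
            return coef[0]

        a_obs = amp(y)
        resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        dof = len(y) - 2
        s2 = resid @ resid / dof
        cov = np.linalg.inv(design.T @ design) * s2
        t = a_obs / np.sqrt(cov[0, 0])
        p_closed = float(sps.t.sf(t, dof))

        n_perm = 3000
        perms = np.array([amp(rng.permutation(y)) for _ in range(n_perm)])
        p_perm = np.mean(perms >= a_obs)
        assert abs(p_closed - p_perm) < 0.02

    def test_three_molecule_spots_mostly_accepted(self, geom_small, camera,
                                                  psf, egfp, voxel_size):
        rng = np.random.default_rng(2)
        vol, pos = single_emitter_series(geom_small, camera, psf, egfp, 3, 30,
                                         rng)
        n_acc = 0
        for t in range(30):
            frame = np.clip(vol.data[t] - camera.offset, 0, None)
            fits = detect_frame(frame, psf, voxel_size, frame_index=t)
            n_acc += any(np.linalg.norm(f.position - pos[t][::-1]) < 300
                         for f in fits)
        assert n_acc >= 27  # >= 90% detection of 3-eGFP spots


class TestDetectFrame:
    def test_eight_separated_emitters_all_found(self, geom_small, camera, psf,
                                                egfp, voxel_size):
        vz, vy, vx = voxel_size
        nz, ny, nx = geom_small.volume_shape
        centers_vox = [(5, 10, 10), (5, 10, 38), (5, 38, 10), (5, 38, 38),
                       (11, 10, 24), (11, 38, 24), (11, 24, 10), (11, 24, 38)]
        ems = []
        for i, c in enumerate(centers_vox):
            p = np.array([[c[0] * vz, c[1] * vy, c[2] * vx]])
            ems.append(EmitterTruth(i, "I", p, {"eGFP": np.array([6])}, 0, 1))
        scene = Scene(cell_bounds=(nz * vz, ny * vy, nx * vx), emitters=ems,
                      n_frames=1, frame_interval=850.0)
        rng = np.random.default_rng(3)
        g = replace(geom_small, n_volumes=1)
        vols, _ = render_volume_series(scene, g, camera, {"eGFP": egfp},
                                       psf, rng)
        frame = np.clip(vols["eGFP"].data[0] - camera.offset, 0, None)
        fits = detect_frame(frame, psf, voxel_size)
        assert len(fits) == 8

    def test_empty_frames_false_positive_rate(self, geom_small, camera, psf,
                                              egfp, voxel_size):
        # Monte-Carlo: acceptance rate per candidate stays below alpha
        vz, vy, vx = voxel_size
        nz, ny, nx = geom_small.volume_shape
        scene = Scene(cell_bounds=(nz * vz, ny * vy, nx * vx), emitters=[],
                      n_frames=30, frame_interval=850.0)
        rng = np.random.default_rng(4)
        g = replace(geom_small, n_volumes=30)
        vols, _ = render_volume_series(scene, g, camera, {"eGFP": egfp},
                                       psf, rng)
        n_cand = n_acc = 0
        for t in range(30):
            frame = np.clip(vols["eGFP"].data[t] - camera.offset, 0, None)
            n_cand += len(detect_candidates(frame, psf, voxel_size))
            n_acc += len(detect_frame(frame, psf, voxel_size, frame_index=t))
        assert n_cand >= 10          # the candidate stage stays permissive
        assert n_acc / n_cand <= 0.05

    def test_duplicate_candidates_merge_to_one(self, psf, voxel_size):
        frame = _synthetic_gaussian_frame((16, 32, 32), (8, 16, 16), 300.0,
                                          10.0, psf, voxel_size)
        rng = np.random.default_rng(5)
        frame = frame + rng.normal(0, 2.0, frame.shape)
        fits = detect_frame(frame, psf, voxel_size)
        assert len(fits) == 1


@pytest.fixture(scope="module")
def rendered_population(geom_small, camera, psf, egfp):
    """Many isolated emitters of several brightnesses, fit per frame."""
    results = {}
    rng = np.random.default_rng(9)
    for n_mol in (3, 12, 24, 60):
        amps, errs, found, spurious, frames = [], [], 0, 0, 0
        for rep in range(4):
            vol, pos = single_emitter_series(geom_small, camera, psf,
                                             egfp, n_mol, 15, rng)
            for t in range(15):
                frame = np.clip(vol.data[t] - camera.offset, 0, None)
                fits = detect_frame(frame, psf, geom_small.voxel_size(),
                                    frame_index=t)
                frames += 1
                best = None
                for f in fits:
                    d = np.linalg.norm(f.position - pos[t][::-1])
                    if d < 300 and (best is None
                                    or f.amplitude > best.amplitude):
                        best = f
                spurious += len(fits) - (best is not None)
                if best is not None:
                    found += 1
                    amps.append(best.amplitude)
                    errs.append(best.position - pos[t][::-1])
        results[n_mol] = dict(amps=np.array(amps),
                              errs=np.array(errs), found=found,
                              spurious=spurious, frames=frames)
    return results


class TestQuantificationQuality:
    """Recall/precision, localization and amplitude bias on rendered scenes."""

    def test_recall_and_precision(self, rendered_population):
        for n_mol, r in rendered_population.items():
            assert r["found"] / r["frames"] >= 0.9
            precision = r["found"] / max(r["found"] + r["spurious"], 1)
            assert precision >= 0.95

    def test_localization_rmse(self, rendered_population):
        # <= 0.25 voxel laterally for >= 10-molecule emitters
        errs = rendered_population[12]["errs"]
        rmse_xy = np.sqrt(np.mean(errs[:, :2] ** 2, axis=0))
        assert np.all(rmse_xy <= 0.25 * 97.7)

    def test_amplitude_unbiased(self, rendered_population, geom_small, camera,
                                psf, egfp):
        unit = expected_unit_amplitude(geom_small, camera, egfp, psf)
        for n_mol, r in rendered_population.items():
            amps = r["amps"]
            se = amps.std() / np.sqrt(len(amps))
            bias = amps.mean() - n_mol * unit
            # unbiased within 5% (plus Monte-Carlo error of this sample)
            assert abs(bias) <= 0.05 * n_mol * unit + 3 * se
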
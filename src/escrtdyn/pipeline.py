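"""End-to-end orchestration: simulate -> prep -> detect -> track -> calibrate
-> analyze -> report.

Each stage reads the previous stage's artifacts from a run directory and
writes its own, embedding the config hash so any output can be traced to
the exact configuration and seed that produced it. The CLI in
:mod:`escrtdyn.cli` is a thin wrapper over these functions; they are
equally usable from Python.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .calibration import CalibrationCurve, fit_single_molecule_mixture
from .detection import SpotFit, detect_frame
from .geometry import (AcquisitionGeometry, CameraModel, default_camera,
                       default_egfp, default_geometry, default_mcherry,
                       default_psf)
from .io import (RunConfig, config_hash, read_volume_series, write_tables,
                 write_volume_series, tracks_to_table)
from .render import generate_calibration_field, render_volume_series
from .tracking import classify_tracks, filter_valid, link_tracks
from .trace_analysis import (cohort_curves, cross_correlate, extract_trace,
                             fit_biexponential, fit_max_mixture,
                             summarize_event)
from .volume_prep import deskew, flatfield_correct, subtract_offset

__all__ = ["build_models", "stage_simulate", "stage_prep", "stage_detect",
           "stage_track", "stage_calibrate", "stage_analyze", "stage_report",
           "run_all", "MissingArtifact"]


class MissingArtifact(FileNotFoundError):
    """A stage was run before the stage that produces its input."""


def build_models(cfg: RunConfig):
    geom = default_geometry(**cfg.geometry)
    cam = default_camera(**cfg.camera)
    psf = default_psf(**cfg.psf)
    return geom, cam, psf


def _stamp(outdir: Path, stage: str, cfg: RunConfig, extra: dict | None = None):
    meta = {"stage": stage, "config_hash": config_hash(cfg),
            "seed": cfg.seed}
    if extra:
        meta.update(extra)
    (outdir / f"{stage}.meta.json").write_text(json.dumps(meta, indent=1))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifact(
            f"missing artifact {path.name}; run the '{producer}' stage first")
    return path


def stage_simulate(cfg: RunConfig, outdir: str | Path) -> dict:
    """Generate a ground-truth scene and render raw (skewed) volumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geom, cam, psf = build_models(cfg)
    rng = np.random.default_rng(cfg.seed)
    sc = dict(cfg.scene)
    channel = sc.pop("channel", "eGFP")
    params_map = {"Snf7": synthetic.snf7_params, "Vps24": synthetic.vps24_params,
                  "Vps4": synthetic.vps4_params}
    protein = sc.pop("protein", "Snf7")
    trace_params = {channel: params_map[protein]()}
    scene = synthetic.build_scene(geom, trace_params, rng, **sc)
    fluor = {channel: default_egfp(channel_name=channel)}
    vols, truth = render_volume_series(scene, geom, cam, fluor, psf, rng,
                                       skewed=True)
    paths = {}
    for ch, vol in vols.items():
        paths[ch] = write_volume_series(vol, outdir / f"raw_{ch}.tif")
    truth.to_csv(outdir / "ground_truth.csv", index=False)
    _stamp(outdir, "simulate", cfg, {"channels": list(vols)})
    return {"volumes": paths, "truth": outdir / "ground_truth.csv"}


def stage_prep(cfg: RunConfig, outdir: str | Path) -> dict:
    """Offset-subtract, flat-field and deskew the raw volumes."""
    outdir = Path(outdir)
    _require(outdir / "simulate.meta.json", "simulate")
    geom, cam, _ = build_models(cfg)
    out = {}
    for raw in sorted(outdir.glob("raw_*.tif")):
        vol = read_volume_series(raw)
        vol = subtract_offset(vol, cam.offset)
        profile = np.ones(vol.data.shape[2:])
        vol = flatfield_correct(vol, profile)
        if not vol.deskewed:
            vol = deskew(vol)
        ch = raw.stem.removeprefix("raw_")
        out[ch] = write_volume_series(vol, outdir / f"prep_{ch}.tif")
    _stamp(outdir, "prep", cfg)
    return out


def stage_detect(cfg: RunConfig, outdir: str | Path) -> Path:
    """Detect and fit spots in every frame of each prepped channel."""
    outdir = Path(outdir)
    meta = json.loads(_require(outdir / "prep.meta.json", "prep").read_text())
    del meta
    _, _, psf = build_models(cfg)
    alpha = cfg.detection.get("alpha", 0.05)
    rows = []
    for prep in sorted(outdir.glob("prep_*.tif")):
        vol = read_volume_series(prep)
        if not vol.deskewed:
            raise ValueError(f"{prep.name} is not deskewed; run 'prep' first")
        ch = prep.stem.removeprefix("prep_")
        vs = vol.voxel_size()
        for t in range(vol.n_frames):
            for f in detect_frame(vol.data[t], psf, vs, alpha=alpha,
                                  frame_index=t):
                rows.append(dict(channel=ch, frame=t,
                                 x_nm=f.position[0], y_nm=f.position[1],
                                 z_nm=f.position[2],
                                 x_sd_nm=f.position_sd[0],
                                 y_sd_nm=f.position_sd[1],
                                 z_sd_nm=f.position_sd[2],
                                 amplitude=f.amplitude,
                                 amplitude_sd=f.amplitude_sd,
                                 local_background=f.local_background,
                                 residual_sd=f.residual_sd,
                                 sigma_xy_nm=f.fitted_sigmas[0],
                                 sigma_z_nm=f.fitted_sigmas[2],
                                 p_value=f.p_value, dof=f.dof))
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "detections.csv", index=False, float_format="%.9g")
    _stamp(outdir, "detect", cfg, {"n_detections": len(df)})
    return outdir / "detections.csv"


def _detections_to_frames(df: pd.DataFrame, n_frames: int) -> list[list[SpotFit]]:
    frames: list[list[SpotFit]] = [[] for _ in range(n_frames)]
    for _, r in df.iterrows():
        s = SpotFit(frame=int(r.frame),
                    position=np.array([r.x_nm, r.y_nm, r.z_nm]),
                    position_sd=np.array([r.x_sd_nm, r.y_sd_nm, r.z_sd_nm]),
                    amplitude=r.amplitude, amplitude_sd=r.amplitude_sd,
                    local_background=r.local_background,
                    local_background_sd=0.0, residual_sd=r.residual_sd,
                    fitted_sigmas=np.array([r.sigma_xy_nm, r.sigma_xy_nm,
                                            r.sigma_z_nm]),
                    p_value=r.p_value, accepted=True, converged=True,
                    dof=int(getattr(r, "dof", 0)))
        frames[s.frame].append(s)
    return frames


def stage_track(cfg: RunConfig, outdir: str | Path) -> dict:
    """Link detections, apply validity filters, classify tracks."""
    outdir = Path(outdir)
    det_path = _require(outdir / "detections.csv", "detect")
    df = pd.read_csv(det_path)
    geom, _, psf = build_models(cfg)
    tc = cfg.tracking
    n_frames = geom.n_volumes
    bounds = (geom.planes_per_volume * geom.z_step,
              geom.volume_shape[1] * geom.pixel_size_xy,
              geom.volume_shape[2] * geom.pixel_size_xy)
    results = {}
    for ch, sub in df.groupby("channel"):
        frames = _detections_to_frames(sub, n_frames)
        tracks = link_tracks(frames,
                             max_displacement=tc.get("max_displacement", 800.0),
                             max_gap=tc.get("max_gap", 2))
        valid, persistent, rejected = filter_valid(
            tracks, bounds, n_frames,
            border_margin=tc.get("border_margin", 1500.0),
            min_frames=tc.get("min_frames", 3))
        classify_tracks(valid + persistent, psf)
        table = tracks_to_table(tracks)
        status = {tr.track_id: "valid" for tr in valid}
        status.update({tr.track_id: "persistent" for tr in persistent})
        status.update({tr.track_id: "rejected" for tr in rejected})
        table["status"] = table["track_id"].map(status)
        p = outdir / f"tracks_{ch}.csv"
        table.to_csv(p, index=False, float_format="%.9g")
        results[ch] = dict(path=p, n_valid=len(valid),
                           n_persistent=len(persistent),
                           n_rejected=len(rejected))
    _stamp(outdir, "track", cfg, {ch: {k: (str(v) if isinstance(v, Path) else v)
                                       for k, v in r.items()}
                                  for ch, r in results.items()})
    return results


def calibrate_from_field(cfg: RunConfig, rng: np.random.Generator,
                         ) -> CalibrationCurve:
    """Build the default synthetic calibration field and fit the mixture.

    The field is imaged at a longer exposure than the cell movies (3x by
    default, configurable as ``calibration.exposure``): single fluorophores
    are then far enough above the EMCCD quantization noise that the
    amplitude distribution is close to Gaussian. The fitted unit is
    rescaled linearly back to the imaging exposure (the calibration-curve
    contract), so the returned curve can be applied to spot amplitudes
    as-is.
    """
    from dataclasses import replace

    geom, cam, psf = build_models(cfg)
    cal_cfg = cfg.calibration
    cal_exposure = cal_cfg.get("exposure", 3.0 * geom.exposure_per_plane)
    geom_cal = replace(
        geom, exposure_per_plane=cal_exposure,
        frame_interval=max(geom.frame_interval,
                           geom.planes_per_volume * cal_exposure))
    vol, truth = generate_calibration_field(
        cal_cfg.get("n_emitters", 300), geom_cal, cam, default_egfp(), rng,
        psf=psf)
    vs = vol.voxel_size()
    amps = []
    for t in range(min(2, vol.n_frames)):   # pre-bleach frames only
        frame = np.clip(vol.data[t] - cam.offset, 0, None)
        for f in detect_frame(frame, psf, vs, alpha=cfg.detection.get("alpha", 0.05),
                              frame_index=t):
            amps.append(f.amplitude)
    cal = fit_single_molecule_mixture(np.asarray(amps),
                                      K_max=cal_cfg.get("K_max", 4),
                                      exposure_reference=cal_exposure)
    return CalibrationCurve(
        unit_intensity=cal.unit_at(geom.exposure_per_plane),
        unit_intensity_sd=cal.unit_sd_at(geom.exposure_per_plane),
        exposure_reference=geom.exposure_per_plane,
        n_samples=cal.n_samples, mixture=cal.mixture)


def stage_calibrate(cfg: RunConfig, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 101)
    cal = calibrate_from_field(cfg, rng)
    payload = dict(unit_intensity=cal.unit_intensity,
                   unit_intensity_sd=cal.unit_intensity_sd,
                   exposure_reference=cal.exposure_reference,
                   n_samples=cal.n_samples,
                   mixture_K=cal.mixture.K if cal.mixture else None,
                   config_hash=config_hash(cfg))
    p = outdir / "calibration.json"
    p.write_text(json.dumps(payload, indent=1))
    _stamp(outdir, "calibrate", cfg)
    return p


def _load_calibration(outdir: Path) -> CalibrationCurve:
    meta = json.loads(_require(outdir / "calibration.json", "calibrate").read_text())
    return CalibrationCurve(unit_intensity=meta["unit_intensity"],
                            unit_intensity_sd=meta["unit_intensity_sd"],
                            exposure_reference=meta["exposure_reference"],
                            n_samples=meta["n_samples"])


def stage_analyze(cfg: RunConfig, outdir: str | Path) -> dict:
    """Traces, summaries, lifetime fit, cohorts for every tracked channel."""
    outdir = Path(outdir)
    cal = _load_calibration(outdir)
    geom, _, psf = build_models(cfg)
    results = {}
    all_traces = {}
    for tp in sorted(outdir.glob("tracks_*.csv")):
        ch = tp.stem.removeprefix("tracks_")
        df = pd.read_csv(tp)
        usable = df[df.status.isin(["valid", "persistent"])]
        from .tracking import Track
        traces = []
        for tid, sub in usable.groupby("track_id"):
            sub = sub.sort_values("frame")
            spots = _detections_to_frames(sub, geom.n_volumes)
            flat = [s for fr in spots for s in fr]
            tr = Track(int(tid), flat)
            if sub.status.iloc[0] == "persistent":
                tr.flags.add("persistent")
            tr.class_label = sub.class_label.iloc[0]
            traces.append(extract_trace(tr, cal, ch, geom.frame_interval))
        summaries = [summarize_event(t) for t in traces]
        write_tables(outdir / f"analysis_{ch}", traces=traces,
                     summaries=summaries)
        lifetimes = np.array([s.lifetime for s in summaries if not s.censored])
        res = dict(n_traces=len(traces),
                   n_productive=sum(s.productive for s in summaries))
        if len(lifetimes) >= 100:
            fit = fit_biexponential(lifetimes, min_observable=3.0,
                                    n_boot=50, seed=cfg.seed)
            res["lifetime_fit"] = dict(w=fit.w, tau1=fit.tau1, tau2=fit.tau2)
        maxima = np.array([s.max_accumulation for s in summaries])
        if len(maxima) >= 200:
            mm = fit_max_mixture(maxima, K=2, seed=cfg.seed)
            res["max_mode"] = dict(mean=float(mm.means[0]), sd=float(mm.sds[0]))
        all_traces[ch] = traces
        results[ch] = res
    if len(all_traces) == 2:
        (ch_a, tr_a), (ch_b, tr_b) = all_traces.items()
        ids_b = {t.track_id: t for t in tr_b}
        pairs = [(a, ids_b[a.track_id]) for a in tr_a if a.track_id in ids_b]
        if pairs:
            try:
                cc = cross_correlate([p[0] for p in pairs], [p[1] for p in pairs],
                                     max_lag=cfg.analysis.get("max_lag", 6),
                                     min_lifetime=cfg.analysis.get("min_lifetime_cc", 11.0))
                results["cross_correlation"] = dict(
                    lags=cc.lags.tolist(),
                    intensity=cc.cc_intensity.tolist(),
                    derivative=cc.cc_derivative.tolist(),
                    n=cc.n_traces)
            except ValueError:
                pass
    (outdir / "analysis.json").write_text(json.dumps(results, indent=1, default=str))
    _stamp(outdir, "analyze", cfg)
    return results


def stage_report(cfg: RunConfig, outdir: str | Path) -> Path:
    """Histograms and cohort/correlation figures mirroring the trace stats."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    _require(outdir / "analyze.meta.json", "analyze")
    geom, _, _ = build_models(cfg)
    report = {}
    for adir in sorted(outdir.glob("analysis_*")):
        ch = adir.name.removeprefix("analysis_")
        summ = pd.read_csv(adir / "summaries.csv")
        if summ.empty:
            continue
        fig, axes = plt.subplots(1, 2, figsize=(8, 3))
        live = summ[~summ.censored]
        axes[0].hist(live.lifetime_s, bins=15, density=True, alpha=0.7)
        axes[0].set_xlabel("lifetime (s)")
        axes[0].set_ylabel("probability density")
        ax2 = axes[0].twinx()
        xs = np.sort(live.lifetime_s.to_numpy())
        if len(xs):
            ax2.plot(xs, np.arange(1, len(xs) + 1) / len(xs), "k:")
        axes[1].hist(summ.max_accumulation, bins=15, density=True, alpha=0.7,
                     color="tab:green")
        axes[1].set_xlabel("max accumulation (molecules)")
        fig.tight_layout()
        fig.savefig(outdir / f"report_{ch}.png", dpi=110)
        plt.close(fig)
        report[ch] = dict(n_events=int(len(live)),
                          median_lifetime=float(live.lifetime_s.median())
                          if len(live) else None,
                          median_max=float(summ.max_accumulation.median()))
    p = outdir / "report.json"
    p.write_text(json.dumps({"config_hash": config_hash(cfg),
                             "channels": report}, indent=1))
    _stamp(outdir, "report", cfg)
    return p


def run_all(cfg: RunConfig, outdir: str | Path) -> dict:
    stage_simulate(cfg, outdir)
    stage_prep(cfg, outdir)
    stage_detect(cfg, outdir)
    stage_track(cfg, outdir)
    stage_calibrate(cfg, outdir)
    results = stage_analyze(cfg, outdir)
    stage_report(cfg, outdir)
    return results
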
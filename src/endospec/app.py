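"""Pipeline orchestration and command-line interface.

`run_pipeline` ties the stages together on a phantom scene: generate ->
calibrate -> enhance -> reconstruct -> QC, with every artifact written next
to an archived copy of the run configuration and a structured log.  The
`endospec` CLI exposes the stages as subcommands.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import click
import numpy as np
import imageio.v3 as iio
import tifffile
import yaml

from . import enhance, optics_qc, phantom, spectral, stereo3d
from .errors import EndospecError, ParameterError
from .rig import CameraRig
from .spectral import ANALYSIS_RANGE_NM, BandDefinition, DEFAULT_BANDS

__all__ = ["RunConfig", "run_pipeline", "main"]

log = logging.getLogger("endospec")


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable configuration of one reproducible run."""

    seed: int = 0
    band_choice: float = 420.0  # nm; deep blue separates cholesteatoma best
    threshold: float | str = "auto"
    specular_i_threshold: float = 0.8
    specular_s_threshold: float = 0.1
    mask_specular: bool = True
    denoise_cutoff: float = 0.25
    # phantom scene
    shape: tuple[int, int] = (160, 512)
    cholesteatoma_fraction: float = 0.3
    base_distance_mm: float = 40.0
    relief_amplitude_mm: float = 0.4
    noise_read_sigma: float = 0.0
    # disparity estimation
    disparity_iterations: int = 10
    disparity_window: int = 9
    # rig: inline defaults unless a calibration profile path is given
    rig_path: str | None = None
    output_dir: str = "endospec_run"

    def validate(self) -> None:
        lo, hi = ANALYSIS_RANGE_NM
        if not lo <= self.band_choice <= hi:
            raise ParameterError(
                f"band_choice {self.band_choice:g} nm outside supported range {lo:g}-{hi:g} nm"
            )
        if isinstance(self.threshold, str):
            if self.threshold != "auto":
                raise ParameterError("threshold must be a scalar in [0,1] or 'auto'")
        elif not 0.0 <= float(self.threshold) <= 1.0:
            raise ParameterError("threshold must lie in [0, 1]")
        for name in ("specular_i_threshold", "specular_s_threshold"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if min(self.shape) < 32:
            raise ParameterError("shape must be at least 32x32")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "shape" in data:
            data["shape"] = tuple(data["shape"])
        return cls(**data)


def _png8(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)


def save_calibration_frames(frames: phantom.CalibrationFrames, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "dark.tiff", frames.dark.astype(np.float32))
    entries = []
    for band, white in frames.white.items():
        name = f"white_{int(round(band.center_nm)):03d}.tiff"
        tifffile.imwrite(directory / name, white.astype(np.float32))
        entries.append(
            {"file": name, "center_nm": band.center_nm, "fwhm_nm": band.fwhm_nm,
             "relative_radiance": band.relative_radiance}
        )
    manifest = directory / "calibration.json"
    manifest.write_text(json.dumps({"dark": "dark.tiff", "white": entries}, indent=2))
    return manifest


def load_calibration_frames(manifest_path) -> phantom.CalibrationFrames:
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    directory = manifest_path.parent
    dark = tifffile.imread(directory / meta["dark"]).astype(float)
    white = {}
    for entry in meta["white"]:
        band = BandDefinition(
            center_nm=float(entry["center_nm"]),
            fwhm_nm=float(entry.get("fwhm_nm", 20.0)),
            relative_radiance=float(entry.get("relative_radiance", 1.0)),
        )
        white[band] = tifffile.imread(directory / entry["file"]).astype(float)
    return phantom.CalibrationFrames(dark=dark, white=white)


def run_pipeline(config: RunConfig) -> dict:
    """Execute phantom -> spectral -> enhance -> stereo3d -> optics_qc.

    Returns a dict of artifact paths and per-stage statistics.  The config is
    validated before any work; artifacts are stamped with the config hash.
    """
    config.validate()
    rig = CameraRig.load(config.rig_path) if config.rig_path else CameraRig()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_yaml(out / "run_config.yaml")
    artifacts: dict = {"config_hash": chash}
    stats: dict = {}

    def stage(name):
        log.info("stage=%s config=%s", name, chash)
        return time.perf_counter()

    try:
        # ---- phantom -------------------------------------------------------
        t0 = stage("phantom")
        scene_cfg = phantom.SceneConfig(
            seed=config.seed,
            shape=config.shape,
            cholesteatoma_fraction=config.cholesteatoma_fraction,
            base_distance_mm=config.base_distance_mm,
            relief_amplitude_mm=config.relief_amplitude_mm,
        )
        scene = phantom.make_scene(scene_cfg)
        noise = (
            phantom.NoiseModel(read_sigma=config.noise_read_sigma, seed=config.seed)
            if config.noise_read_sigma > 0
            else None
        )
        render = phantom.render_sequence(scene, rig, DEFAULT_BANDS, noise=noise)
        calib = phantom.render_calibration_frames(DEFAULT_BANDS, config.shape)
        seq_dir = out / "sequences"
        artifacts["left_manifest"] = str(spectral.save_sequence(render.left, seq_dir))
        artifacts["right_manifest"] = str(spectral.save_sequence(render.right, seq_dir))
        artifacts["calibration"] = str(save_calibration_frames(calib, out / "calibration"))
        tifffile.imwrite(out / "true_disparity.tiff", render.true_disparity.astype(np.float32))
        iio.imwrite(out / "labels_left.png", render.labels["left"].astype(np.uint8))
        stats["phantom"] = {
            "seconds": time.perf_counter() - t0,
            "cholesteatoma_fraction": scene.cholesteatoma_fraction(),
        }

        # ---- spectral ------------------------------------------------------
        t0 = stage("spectral")
        band = render.left.band(config.band_choice)
        raw = spectral.select_analysis_channel(render.left.narrowband[band], band)
        refl = spectral.flat_field_correct(raw, calib.dark, calib.white[band], band=band)
        spectral.save_reflectance(refl, out / "reflectance.tiff")
        artifacts["reflectance"] = str(out / "reflectance.tiff")
        stats["spectral"] = {"seconds": time.perf_counter() - t0,
                             "valid_fraction": float(refl.valid_mask.mean())}

        # ---- enhance -------------------------------------------------------
        t0 = stage("enhance")
        denoised = enhance.fourier_denoise(refl.values, cutoff=config.denoise_cutoff)
        tissue = enhance.compute_tissue_map(np.clip(denoised, 0, 1), None, t=config.threshold)
        overlay = enhance.compose_overlay(
            render.left,
            tissue,
            mask_specular=config.mask_specular,
            i_threshold=config.specular_i_threshold,
            s_threshold=config.specular_s_threshold,
        )
        iio.imwrite(out / "overlay.png", _png8(overlay.rgb))
        tifffile.imwrite(out / "overlay.tiff",
                         np.round(np.clip(overlay.rgb, 0, 1) * 65535).astype(np.uint16))
        iio.imwrite(out / "specular_mask.png", _png8(overlay.specular_mask.astype(float)))
        artifacts["overlay"] = str(out / "overlay.png")
        stats["enhance"] = {
            "seconds": time.perf_counter() - t0,
            "threshold_used": tissue.threshold_used,
            "tissue_pixel_fraction": float(np.mean(tissue.values > 0)),
            "specular_pixel_fraction": float(overlay.specular_mask.mean()),
        }

        # ---- stereo3d ------------------------------------------------------
        t0 = stage("stereo3d")
        left_bb, right_bb = stereo3d.rectify_pair(
            render.left.broadband, render.right.broadband, rig
        )
        d_lo = rig.disparity_for_depth(config.base_distance_mm + config.relief_amplitude_mm + 1)
        d_hi = rig.disparity_for_depth(config.base_distance_mm - config.relief_amplitude_mm - 1)
        disparity = stereo3d.estimate_disparity(
            left_bb,
            right_bb,
            search_range=int(np.ceil(d_hi - d_lo)) + 4,
            min_disparity=int(np.floor(d_lo)) - 2,
            iterations=config.disparity_iterations,
            window=config.disparity_window,
            seed=config.seed,
        )
        tifffile.imwrite(out / "disparity.tiff", disparity.values.astype(np.float32))
        cloud = stereo3d.triangulate(disparity, rig)
        cloud = stereo3d.attach_spectral(cloud, overlay, tissue)
        stereo3d.write_ply(cloud, out / "pointcloud.ply")
        artifacts["pointcloud"] = str(out / "pointcloud.ply")
        artifacts["disparity"] = str(out / "disparity.tiff")
        stats["stereo3d"] = {
            "seconds": time.perf_counter() - t0,
            "valid_disparity_fraction": float(disparity.valid.mean()),
            "points": len(cloud),
        }

        # ---- optics_qc -----------------------------------------------------
        t0 = stage("optics_qc")
        # Synthetic QC: blue bands rendered with a stronger chart blur than the
        # rest, mimicking the wavelength-dependent sharpness of endoscope optics.
        freqs = tuple(400.0 / p for p in (4, 6, 8, 10, 12, 16, 20, 28, 40))
        sigma_by_band = {"white": 0.003}
        for b in DEFAULT_BANDS:
            sigma_by_band[f"{b.center_nm:g}"] = 0.003 + 0.004 * max(0.0, (470 - b.center_nm) / 70)
        reports = {}
        for label, sigma in sigma_by_band.items():
            chart = phantom.render_chart("line_bars", freqs, blur_sigma=sigma,
                                         pixel_pitch=0.0025)
            pairs = optics_qc.measure_modulation(chart)
            reports[label] = optics_qc.mtf_crossings(pairs, band_label=label)
        groups = {
            "blue_400_460": tuple(f"{b.center_nm:g}" for b in DEFAULT_BANDS if b.center_nm <= 460),
            "rest_480_plus": tuple(f"{b.center_nm:g}" for b in DEFAULT_BANDS if b.center_nm > 460),
        }
        summary = optics_qc.summarize(reports, groups)
        optics_qc.write_reports_csv(summary, out / "qc_mtf.csv", out / "qc_summary.json")
        artifacts["qc_csv"] = str(out / "qc_mtf.csv")
        stats["optics_qc"] = {"seconds": time.perf_counter() - t0,
                              "group_averages": summary.formatted()}
    except EndospecError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise EndospecError(f"pipeline stage failed: {exc}") from exc

    (out / "run_log.json").write_text(
        json.dumps({"config_hash": chash, "stats": stats, "artifacts": artifacts}, indent=2)
    )
    artifacts["log"] = str(out / "run_log.json")
    artifacts["stats"] = stats
    return artifacts


# ------------------------------------------------------------------------ CLI

@click.group()
def main() -> None:
    """Multispectral stereo-endoscopy toolkit."""
    logging.basicConfig(level=logging.INFO, format="%(message)s")


@main.command("run")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML run configuration; defaults are used when omitted.")
@click.option("--seed", type=int, default=None)
@click.option("--out", "output_dir", type=click.Path(), default=None)
def cli_run(config_path, seed, output_dir):
    """Run the full phantom demo pipeline."""
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    if output_dir is not None:
        cfg = replace(cfg, output_dir=output_dir)
    artifacts = run_pipeline(cfg)
    click.echo(json.dumps({k: v for k, v in artifacts.items() if k != "stats"}, indent=2))


@main.command("phantom")
@click.option("--seed", type=int, default=0)
@click.option("--shape", nargs=2, type=int, default=(160, 512))
@click.option("--fraction", type=float, default=0.3, help="Cholesteatoma area fraction.")
@click.option("--out", "output_dir", type=click.Path(), required=True)
def cli_phantom(seed, shape, fraction, output_dir):
    """Generate a phantom scene and write stereo sequences + ground truth."""
    scene = phantom.make_scene(
        phantom.SceneConfig(seed=seed, shape=tuple(shape), cholesteatoma_fraction=fraction)
    )
    rig = CameraRig()
    render = phantom.render_sequence(scene, rig)
    out = Path(output_dir)
    left = spectral.save_sequence(render.left, out / "sequences")
    right = spectral.save_sequence(render.right, out / "sequences")
    save_calibration_frames(
        phantom.render_calibration_frames(DEFAULT_BANDS, scene.shape), out / "calibration"
    )
    tifffile.imwrite(out / "true_disparity.tiff", render.true_disparity.astype(np.float32))
    iio.imwrite(out / "labels_left.png", render.labels["left"].astype(np.uint8))
    rig.save(out / "rig.json")
    click.echo(f"left manifest: {left}\nright manifest: {right}")


@main.command("enhance")
@click.option("--seq", "manifest", type=click.Path(exists=True), required=True)
@click.option("--calibration", type=click.Path(exists=True), required=True)
@click.option("--band", type=float, default=420.0)
@click.option("--threshold", default="auto")
@click.option("--mask-specular/--no-mask-specular", default=True)
@click.option("--out", "output_dir", type=click.Path(), required=True)
def cli_enhance(manifest, calibration, band, threshold, mask_specular, output_dir):
    """Compute the augmented overlay for one sequence."""
    seq = spectral.load_sequence(manifest)
    calib = load_calibration_frames(calibration)
    band_def = seq.band(band)
    raw = spectral.select_analysis_channel(seq.narrowband[band_def], band_def)
    refl = spectral.flat_field_correct(raw, calib.dark, calib.white[band_def], band=band_def)
    denoised = np.clip(enhance.fourier_denoise(refl.values), 0, 1)
    t = threshold if threshold == "auto" else float(threshold)
    tissue = enhance.compute_tissue_map(denoised, None, t=t)
    overlay = enhance.compose_overlay(seq, tissue, mask_specular=mask_specular)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "overlay.png", _png8(overlay.rgb))
    iio.imwrite(out / "specular_mask.png", _png8(overlay.specular_mask.astype(float)))
    click.echo(f"threshold used: {tissue.threshold_used:.4f}")


@main.command("reconstruct")
@click.option("--left", "left_manifest", type=click.Path(exists=True), required=True)
@click.option("--right", "right_manifest", type=click.Path(exists=True), required=True)
@click.option("--calib", "rig_path", type=click.Path(exists=True), required=True)
@click.option("--search-range", type=int, default=64)
@click.option("--min-disparity", type=int, default=0)
@click.option("--seed", type=int, default=0)
@click.option("--out", "output_dir", type=click.Path(), required=True)
def cli_reconstruct(left_manifest, right_manifest, rig_path, search_range, min_disparity,
                    seed, output_dir):
    """Rectify, match and triangulate a stereo sequence pair to a PLY cloud."""
    rig = CameraRig.load(rig_path)
    left = spectral.load_sequence(left_manifest)
    right = spectral.load_sequence(right_manifest)
    lb, rb = stereo3d.rectify_pair(left.broadband, right.broadband, rig)
    disparity = stereo3d.estimate_disparity(
        lb, rb, search_range=search_range, min_disparity=min_disparity, seed=seed
    )
    cloud = stereo3d.triangulate(disparity, rig)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "disparity.tiff", disparity.values.astype(np.float32))
    stereo3d.write_ply(cloud, out / "pointcloud.ply")
    click.echo(f"valid disparity fraction: {float(disparity.valid.mean()):.3f}; "
               f"{len(cloud)} points")


@main.command("measure")
@click.option("--disparity", "disparity_path", type=click.Path(exists=True), required=True)
@click.option("--calib", "rig_path", type=click.Path(exists=True), required=True)
@click.option("--pixel-a", nargs=2, type=int, required=True)
@click.option("--pixel-b", nargs=2, type=int, required=True)
def cli_measure(disparity_path, rig_path, pixel_a, pixel_b):
    """Metric point-to-point distance between two pixels of a disparity map."""
    rig = CameraRig.load(rig_path)
    values = tifffile.imread(disparity_path).astype(float)
    cloud = stereo3d.triangulate(stereo3d.DisparityMap(values=values), rig)
    mm = stereo3d.measure_distance(cloud, tuple(pixel_a), tuple(pixel_b))
    click.echo(f"{mm:.4f} mm")


@main.command("qc")
@click.option("--sigma", "sigmas", type=float, multiple=True, default=(0.004, 0.006),
              help="Gaussian PSF sigma(s) in mm to evaluate.")
@click.option("--pixel-pitch", type=float, default=0.0025)
@click.option("--out", "output_dir", type=click.Path(), required=True)
def cli_qc(sigmas, pixel_pitch, output_dir):
    """Measure MTF50/MTF10 of synthetic charts at the given blur levels."""
    freqs = tuple(1.0 / (p * pixel_pitch) for p in (4, 6, 8, 10, 12, 16, 20, 28, 40))
    reports = {}
    for sigma in sigmas:
        chart = phantom.render_chart("line_bars", freqs, blur_sigma=sigma,
                                     pixel_pitch=pixel_pitch)
        label = f"sigma_{sigma:g}"
        reports[label] = optics_qc.mtf_crossings(
            optics_qc.measure_modulation(chart), band_label=label
        )
    summary = optics_qc.summarize(reports, {"all": tuple(reports)})
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    optics_qc.write_reports_csv(summary, out / "qc_mtf.csv", out / "qc_summary.json")
    for label, r in reports.items():
        click.echo(f"{label}: MTF50 {r.mtf50:.2f} lp/mm, MTF10 {r.mtf10:.2f} lp/mm")


if __name__ == "__main__":
    main()
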
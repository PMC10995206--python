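"""File I/O, fixture generation and the end-to-end pipeline driver.

Frame stacks travel as multi-page TIFF with a JSON grid sidecar;
detections, tracks and ground truth as headered CSV (comma separator,
'.' decimal, UTF-8, LF endings) so runs are bit-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import ImagingConfig, RunConfig, SimulationParams, stage_rng
from .decode import DecodeModel, Localization, localize_stack, output_to_fine
from .metrics import evaluate_frames
from .ncc import NccParams, fit_psf_template, ncc_localize_stack
from .noise import NoiseModel
from .preprocess import PreprocessParams, preprocess_stack
from .reconstruct import accumulate_density, directional_map
from .simulator import FrameStack, GroundTruth, simulate_sequence
from .templates import TemplateBank, fit_template_moments, make_gaussian_template
from .tracking import track_localizations

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------

def save_stack(stack: FrameStack, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32))
    meta = dataclasses.asdict(stack.grid)
    meta["fov_fine"] = list(stack.grid.fov_fine)
    meta["stage"] = stack.stage
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    stage = meta.pop("stage", "input")
    meta["fov_fine"] = tuple(meta["fov_fine"])
    return FrameStack(np.asarray(data, dtype=np.float64),
                      ImagingConfig(**meta), stage)


def save_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    df = pd.DataFrame(gt.to_records(),
                      columns=["frame", "id", "row_fine", "col_fine", "brightness"])
    df.to_csv(path, index=False, lineterminator="\n")


def load_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path)
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    gt = GroundTruth([[] for _ in range(n_frames)])
    for row in df.itertuples(index=False):
        gt.frames[int(row.frame)].append(
            (int(row.id), float(row.row_fine), float(row.col_fine),
             float(row.brightness)))
    return gt


DETECTION_COLUMNS = ["frame", "row", "col", "brightness", "prob",
                     "sigma_row", "sigma_col", "sigma_I"]


def save_detections(locs: list[Localization], path: str | Path) -> None:
    df = pd.DataFrame([(p.frame, p.row, p.col, p.brightness, p.prob,
                        p.sigma_row, p.sigma_col, p.sigma_I) for p in locs],
                      columns=DETECTION_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def load_detections(path: str | Path) -> list[Localization]:
    df = pd.read_csv(path)
    return [Localization(int(r.frame), float(r.row), float(r.col),
                         float(r.brightness), float(r.prob),
                         float(r.sigma_row), float(r.sigma_col),
                         float(r.sigma_I))
            for r in df.itertuples(index=False)]


def save_tracks(tracks, path: str | Path) -> None:
    rows = [(t.id, p.frame, p.row, p.col, p.brightness)
            for t in tracks for p in t.points]
    pd.DataFrame(rows, columns=["track_id", "frame", "row", "col", "brightness"]) \
        .to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------

def gaussian_bank(n: int = 32, sigma_axial=(1.5, 3.0), sigma_lateral=(1.5, 3.0),
                  side: int = 21, mu_imax: float = 1.0, sigma_imax: float = 0.2,
                  seed: int = 0) -> TemplateBank:
    """Bank of bivariate-Gaussian templates with widths drawn uniformly
    from the given ranges (the parametric stand-in for learned templates)."""
    rng = np.random.default_rng(seed)
    temps = [make_gaussian_template(rng.uniform(*sigma_axial),
                                    rng.uniform(*sigma_lateral), side)
             for _ in range(n)]
    return TemplateBank(temps, mu_imax=mu_imax, sigma_imax=sigma_imax,
                        source="gaussian")


_PROFILES = {
    # fov_fine, n_frames, concentration, n_templates
    "tiny": dict(fov=(32, 32), n_frames=60, concentration=0.12, n_templates=8),
    "desk": dict(fov=(80, 80), n_frames=500, concentration=0.05, n_templates=32),
}


def make_fixtures(profile: str, seed: int, out_dir: str | Path) -> dict:
    """Generate a self-contained fixture directory (stack + GT + bank)."""
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile '{profile}'")
    spec = _PROFILES[profile]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = ImagingConfig(fov_fine=spec["fov"])
    params = SimulationParams(concentration_per_lambda2=spec["concentration"])
    bank = gaussian_bank(spec["n_templates"], seed=seed)
    nm = NoiseModel.constant(0.1 * params.mu_imax, cfg.fov_input)
    stack, gt = simulate_sequence(cfg, params, bank, nm, spec["n_frames"],
                                  seed=seed)
    save_stack(stack, out_dir / "stack.tif")
    save_ground_truth(gt, out_dir / "ground_truth.csv")
    bank.save(out_dir / "bank.npz")
    manifest = dict(profile=profile, seed=seed, n_frames=spec["n_frames"],
                    concentration=spec["concentration"])
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------

def _provenance(config: RunConfig, stage_seeds: dict) -> dict:
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    return dict(config_hash=hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
                seeds=stage_seeds, version=__version__,
                numpy=np.__version__)


def pipeline_run(config: RunConfig, stack: FrameStack,
                 method: str = "ncc", model: DecodeModel | None = None,
                 bank: TemplateBank | None = None,
                 gt: GroundTruth | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """preprocess -> localize -> track -> reconstruct (-> evaluate).

    Returns the artifact dictionary; if ``out_dir`` is given every
    artifact is also written beside a provenance record.
    """
    cfg = stack.grid
    pp = PreprocessParams(svd_low_cut=config.svd_low_cut,
                          threshold=config.threshold)
    pre = preprocess_stack(stack, pp)
    if method == "ncc":
        if bank is None:
            bank = gaussian_bank(seed=config.seed)
        tpl = fit_psf_template(bank, side=None)
        # NCC operates on the input grid; shrink the template accordingly
        d = cfg.downsample
        sr, sc, _ = fit_template_moments(tpl.patch)
        side = max(5, int(np.ceil(5 * max(sr, sc) / d)) | 1)
        tpl_in = make_gaussian_template(max(sr / d, 0.5), max(sc / d, 0.5), side)
        locs = ncc_localize_stack(pre, NccParams(tpl_in, config.ncc_threshold))
    elif method == "decode":
        if model is None:
            raise ValueError("decode method requires a trained model")
        locs = localize_stack(model, pre, p_thresh=config.p_thresh,
                              uncertainty_reject_frac=config.uncertainty_reject_frac)
    else:
        raise ValueError(f"unknown localization method '{method}'")
    # convert output-grid detections to fine-grid coordinates
    fine_locs = []
    for p in locs:
        r, c = output_to_fine(p.row, p.col, cfg)
        fine_locs.append(dataclasses.replace(p, row=r, col=c))
    tracks = track_localizations(fine_locs, cfg,
                                 max_gap=config.max_gap,
                                 max_angle_deg=config.max_angle_deg,
                                 min_persistence=config.min_persistence)
    ulm = accumulate_density(tracks, cfg)
    direction = directional_map(tracks, cfg)
    artifacts = dict(localizations=fine_locs, tracks=tracks, ulm=ulm,
                     direction=direction)
    if gt is not None:
        pred_by_frame: dict[int, list] = {}
        for p in fine_locs:
            pred_by_frame.setdefault(p.frame, []).append((p.row, p.col))
        pred = {t: np.asarray(v) for t, v in pred_by_frame.items()}
        frames = sorted(set(range(len(gt.frames))))
        artifacts["evaluation"] = evaluate_frames(
            pred, gt, frames, radius=5.0 * cfg.downsample)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_detections(fine_locs, out_dir / "detections.csv")
        save_tracks(tracks, out_dir / "tracks.csv")
        tifffile.imwrite(out_dir / "ulm_density.tif",
                         ulm.density.astype(np.float32))
        tifffile.imwrite(out_dir / "ulm_direction.tif",
                         direction.astype(np.float32))
        (out_dir / "ulm_grid.json").write_text(
            json.dumps(dict(pixel_um=ulm.pixel_um)))
        if "evaluation" in artifacts:
            artifacts["evaluation"].to_csv(out_dir / "evaluation.csv",
                                           index=False, lineterminator="\n")
        prov = _provenance(config, dict(master=config.seed))
        (out_dir / "provenance.json").write_text(json.dumps(prov, indent=2))
    return artifacts
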
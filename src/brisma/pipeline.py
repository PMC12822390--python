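"""Batch pipeline: manifest in, per-sample fits and condition summaries out.

Orchestrates the stages over a dataset tree as produced by
:func:`brisma.synthetic.make_dataset` (or an equivalently laid-out real
dataset): per-condition reference sets under ``refs/<condition>/``, a
kappa-calibration set of known-composition Raman spectra under
``calibration/``, and a manifest CSV naming the per-sample files.

Per-sample failures are logged and recorded; the run only aborts on
manifest-level errors.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brillouin import BrillouinDHOModel, normalize_to_controls
from .biphasic import CompositionModel, calibrate_kappa
from .composition import SpheroidCompositionModel
from .exceptions import BrismaError, ManifestError
from .io import read_image, read_manifest, read_spectrum
from .morphometry import classify_zone, nucleus_shapes
from .raman import BandWindows, RamanReferences, ch_oh_ratio

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("brisma.pipeline")


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline run (echoed to the output)."""

    manifest: str = "manifest.csv"
    refs_dir: str = "refs"
    calibration_dir: str = "calibration"
    output_dir: str = "results"
    exclusion_ghz: float = 2.0
    ch_window: tuple[float, float] = (2800.0, 3020.0)
    oh_window: tuple[float, float] = (3020.0, 3700.0)
    knot_spacing: float = 50.0
    w_cell: float = 0.70
    w_ecm: float = 1.0
    phi_ecm_calibration: float = 0.0  # known composition of the calibration set
    k_sd: float = 2.0
    zone_band: float | None = None
    min_nucleus_area: int = 20
    normalization_batch_key: str = "objective"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ManifestError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ch_window", "oh_window"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["ch_window"] = list(d["ch_window"])
        d["oh_window"] = list(d["oh_window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _load_refs(refdir: Path) -> RamanReferences:
    return RamanReferences(
        pdms=read_spectrum(refdir / "pdms.txt", "raman"),
        medium=read_spectrum(refdir / "medium.txt", "raman"),
        offchip=read_spectrum(refdir / "offchip.txt", "raman"),
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage over a manifest; returns the results directory."""
    manifest_path = Path(config.manifest)
    records = read_manifest(manifest_path)
    if not records:
        raise ManifestError(f"{manifest_path}: empty manifest")
    base = manifest_path.parent
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("brisma %s: %d samples from %s", __version__, len(records), manifest_path)

    windows = BandWindows(ch_window=config.ch_window, oh_window=config.oh_window)
    comp = CompositionModel(w_cell=config.w_cell, w_ecm=config.w_ecm)

    # kappa calibration from the known-composition Raman set
    kappa = None
    caldir = base / config.calibration_dir
    if caldir.exists():
        cal_refs = _load_refs(caldir)
        cal_specs = sorted(caldir.glob("*_raman.txt"))
        ratios = []
        for p in cal_specs:
            try:
                ratios.append(
                    ch_oh_ratio(read_spectrum(p, "raman"), cal_refs, windows=windows).ratio
                )
            except BrismaError as exc:
                logger.warning("calibration spectrum %s failed: %s", p.name, exc)
        if ratios:
            kappa = calibrate_kappa(float(np.mean(ratios)), config.phi_ecm_calibration, comp)
            logger.info("kappa calibrated on %d spectra: %.4f", len(ratios), kappa)
    if kappa is not None:
        comp = CompositionModel(w_cell=config.w_cell, w_ecm=config.w_ecm, kappa=kappa)

    refs_cache: dict[str, RamanReferences] = {}
    rows = []
    for rec in records:
        row: dict = {"sample_id": rec.sample_id, "condition": rec.condition, "objective": rec.objective}
        try:
            if rec.brillouin_path:
                spec = read_spectrum(rec.brillouin_path, "brillouin")
                res = BrillouinDHOModel(spec, exclusion=config.exclusion_ghz).fit()
                row.update(
                    omega_b=res.omega_b,
                    gamma=res.gamma,
                    se_omega=res.fit.se_omega,
                    recenter_offset=res.fit.recenter_offset,
                )
            if rec.raman_path and kappa is not None:
                refdir = base / config.refs_dir / rec.condition
                if rec.condition not in refs_cache:
                    refs_cache[rec.condition] = _load_refs(refdir)
                model = SpheroidCompositionModel(
                    read_spectrum(rec.raman_path, "raman"),
                    refs_cache[rec.condition],
                    composition=comp,
                    windows=windows,
                )
                cres = model.fit()
                row.update(
                    ratio=cres.ratio,
                    phi_ecm=cres.phi_ecm,
                    phi_cell=cres.phi_cell,
                    alpha_pdms=cres.raman.alpha_pdms,
                    alpha_medium=cres.raman.alpha_medium,
                )
            if rec.image_path:
                labels = read_image(rec.image_path)
                shapes, _ = nucleus_shapes(labels, min_area=config.min_nucleus_area)
                mask_path = Path(rec.image_path.replace("_labels.tif", "_mask.tif"))
                if mask_path.exists():
                    shapes = classify_zone(shapes, read_image(mask_path), band=config.zone_band)
                    for zone in ("center", "periphery"):
                        zs = [s.aspect_ratio for s in shapes if s.zone == zone]
                        row[f"ar_{zone}"] = float(np.mean(zs)) if zs else np.nan
                row["ar_mean"] = float(np.mean([s.aspect_ratio for s in shapes]))
                row["n_nuclei"] = len(shapes)
            row["status"] = "ok"
        except BrismaError as exc:
            logger.error("sample %s failed: %s", rec.sample_id, exc)
            row["status"] = f"error: {exc}"
        rows.append(row)

    df = pd.DataFrame(rows)
    if "omega_b" in df.columns and (df["condition"] == "control").any():
        ok = df["status"] == "ok"
        try:
            df.loc[ok, "omega_b_norm"] = normalize_to_controls(
                df.loc[ok, "omega_b"].to_numpy(),
                df.loc[ok, "condition"].to_numpy(),
                df.loc[ok, config.normalization_batch_key].to_numpy(),
            )
        except ValueError as exc:
            logger.warning("normalization skipped: %s", exc)
    df.to_csv(outdir / "results.csv", index=False)

    numeric = [c for c in df.columns if df[c].dtype.kind == "f"]
    summary = df[df["status"] == "ok"].groupby("condition")[numeric].agg(["mean", "std", "count"])
    summary.to_csv(outdir / "summary.csv")
    (outdir / "kappa.json").write_text(json.dumps({"kappa": kappa}))
    logger.info("wrote %s", outdir / "results.csv")
    logger.removeHandler(handler)
    handler.close()
    return outdir
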
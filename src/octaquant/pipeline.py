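"""Per-eye orchestration and cohort-level runs.

``process_eye`` takes calibrated SVC/DVC angiograms and produces the
per-eye result: FAZ geometry per plexus, the four (region x plexus)
microvascular profiles, and optional thickness sectors. ``run_eye`` is the
file-based wrapper (image + sidecar in, CSV rows out); ``run_cohort``
drives a manifest of eyes and hands the resulting tidy table to the
statistics layer. Eyes whose FAZ cannot be segmented are excluded with a
machine-readable reason, mirroring the exclusion of unusable acquisitions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


import pandas as pd

from . import io as oio
from .errors import InputError, OctaquantError, SegmentationFailure
from .faz import build_regions, segment_faz
from .metrics import DEFAULT_BOX_LADDER, DEFAULT_LACUNARITY_BOX_PX, compute_profile
from .preprocess import (
    DEFAULT_ADAPTIVE_OFFSET,
    DEFAULT_ADAPTIVE_WINDOW_UM,
    DEFAULT_CALIBER_FLOOR_UM,
    DEFAULT_MEDIAN_RADIUS_UM,
    DEFAULT_TOPHAT_RADIUS_UM,
    binarize_adaptive,
    clean_vessel_mask,
    crop_scan_region,
    enhance_contrast,
    load_enface,
    remove_large_vessels,
    rescale_isotropic,
    segment_large_vessels,
)
from .stats import adjusted_comparison, diagnostic_model
from .thickness import locate_fovea, resample_grid, sector_means
from .types import FazSegmentation, IsotropicAngiogram

logger = logging.getLogger("octaquant")

__all__ = ["PipelineConfig", "EyeResult", "process_eye", "run_eye", "run_cohort"]


@dataclass
class PipelineConfig:
    """Every tunable knob of the pipeline; round-trips losslessly via JSON."""

    median_radius_um: float = DEFAULT_MEDIAN_RADIUS_UM
    tophat_radius_um: float = DEFAULT_TOPHAT_RADIUS_UM
    adaptive_window_um: float = DEFAULT_ADAPTIVE_WINDOW_UM
    adaptive_offset: float = DEFAULT_ADAPTIVE_OFFSET
    caliber_floor_um: float = DEFAULT_CALIBER_FLOOR_UM
    clean_close_radius_um: float = 2.0
    clean_min_object_px: int = 50
    clean_max_hole_px: int = 30
    faz_gauss_sigma_um: float = 5.0
    faz_canny_low_q: float = 0.70
    faz_canny_high_q: float = 0.90
    faz_close_radius_um: float = 12.0
    faz_open_radius_um: float = 30.0
    box_ladder: tuple = DEFAULT_BOX_LADDER
    lacunarity_box_px: int = DEFAULT_LACUNARITY_BOX_PX
    gee_adjust: tuple = ("age", "sex", "hypertension")
    seed: int = 0

    def to_json(self, path=None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        try:
            is_file = Path(str(source)).exists()
        except OSError:  # e.g. a JSON string too long for a file name
            is_file = False
        text = Path(str(source)).read_text() if is_file else str(source)
        d = json.loads(text)
        d["box_ladder"] = tuple(d.get("box_ladder", DEFAULT_BOX_LADDER))
        d["gee_adjust"] = tuple(d.get("gee_adjust", ("age", "sex", "hypertension")))
        return cls(**d)


@dataclass
class EyeResult:
    """Everything measured for one eye."""

    subject_id: str
    eye: str
    faz: dict  # plexus -> FazSegmentation
    profiles: list  # list[MicrovascularProfile]
    sectors: list = field(default_factory=list)  # list[SectorThickness]
    flags: list = field(default_factory=list)

    def to_wide_row(self) -> dict:
        """One tidy eye-level row with descriptive metric column names."""
        row: dict = {"subject_id": self.subject_id, "eye": self.eye}
        for plexus, seg in self.faz.items():
            p = plexus.lower()
            row[f"faz_area_mm2_{p}"] = seg.area_mm2
            row[f"faz_circularity_{p}"] = seg.circularity
            row[f"faz_centroid_x_um_{p}"] = seg.centroid_um[0]
            row[f"faz_centroid_y_um_{p}"] = seg.centroid_um[1]
        for pr in self.profiles:
            key = f"{pr.region}_{pr.plexus.lower()}"
            row[f"perfusion_density_{key}"] = pr.perfusion_density
            row[f"skeleton_density_{key}"] = pr.skeleton_density
            row[f"vessel_perimeter_index_{key}"] = pr.vessel_perimeter_index
            row[f"vessel_diameter_um_{key}"] = pr.mean_vessel_diameter
            row[f"fractal_dimension_{key}"] = pr.fractal_dimension
            row[f"lacunarity_{key}"] = pr.lacunarity
        for sec in self.sectors:
            lay = sec.layer.lower().replace("-", "_").replace("/", "_")
            row[f"thickness_fovea_um_{lay}"] = sec.foveal_mean_um
            row[f"thickness_parafovea_um_{lay}"] = sec.parafoveal_mean_um
        return row


def _prep(img: IsotropicAngiogram, cfg: PipelineConfig):
    enhanced = enhance_contrast(img, cfg.median_radius_um, cfg.tophat_radius_um)
    binarized = binarize_adaptive(enhanced, cfg.adaptive_window_um, cfg.adaptive_offset)
    binarized = clean_vessel_mask(
        binarized, cfg.clean_close_radius_um, cfg.clean_min_object_px, cfg.clean_max_hole_px
    )
    return enhanced, binarized


def process_eye(
    svc: IsotropicAngiogram,
    dvc: IsotropicAngiogram,
    config: Optional[PipelineConfig] = None,
    thickness_maps: Optional[dict] = None,
) -> EyeResult:
    """Full per-eye analysis on calibrated angiograms.

    Raises :class:`SegmentationFailure` if the DVC FAZ cannot be found;
    callers driving a cohort catch it and record the exclusion.
    """
    cfg = config or PipelineConfig()
    if svc.meta.plexus != "SVC" or dvc.meta.plexus != "DVC":
        raise InputError("process_eye expects (SVC, DVC) angiograms in that order")
    t0 = time.perf_counter()
    flags: list[str] = []

    _, svc_bin = _prep(svc, cfg)
    _, dvc_bin = _prep(dvc, cfg)
    # large-vessel Otsu runs on the raw calibrated image: the top-hat in the
    # enhancement chain suppresses structures wider than ~2x its radius,
    # which is exactly the arterioles/venules being segmented here
    large = segment_large_vessels(svc, cfg.caliber_floor_um)
    svc_micro = remove_large_vessels(svc_bin, large)

    faz_kw = dict(
        gauss_sigma_um=cfg.faz_gauss_sigma_um,
        canny_low_q=cfg.faz_canny_low_q,
        canny_high_q=cfg.faz_canny_high_q,
        close_radius_um=cfg.faz_close_radius_um,
        open_radius_um=cfg.faz_open_radius_um,
    )
    faz_dvc = segment_faz(dvc, tophat_radius_um=cfg.tophat_radius_um, **faz_kw)
    faz: dict[str, FazSegmentation] = {"DVC": faz_dvc}
    try:
        faz["SVC"] = segment_faz(
            dataclasses.replace(svc, meta=svc.meta.replace(plexus="DVC")),
            tophat_radius_um=cfg.tophat_radius_um, **faz_kw,
        )
    except (SegmentationFailure, InputError) as exc:
        flags.append(f"svc_faz_failed: {exc}")

    regions = build_regions(faz_dvc.centroid_um, dvc.shape)
    if regions.clipped:
        flags.append("parafovea_clipped")
    profiles = compute_profile(
        svc_micro, dvc_bin, regions,
        box_sizes=tuple(cfg.box_ladder), lacunarity_box_px=cfg.lacunarity_box_px,
    )

    sectors = []
    if thickness_maps:
        if "Retina" not in thickness_maps:
            raise InputError("thickness maps must include the Retina layer")
        center = locate_fovea(thickness_maps["Retina"])
        for layer, m in thickness_maps.items():
            res = resample_grid(m)
            sectors.append(sector_means(res, center))
    logger.info(
        "eye %s/%s processed in %.1fs (flags: %s)",
        svc.meta.subject_id, svc.meta.eye, time.perf_counter() - t0, flags or "none",
    )
    return EyeResult(
        subject_id=svc.meta.subject_id, eye=svc.meta.eye,
        faz=faz, profiles=profiles, sectors=sectors, flags=flags,
    )


def _load_iso(image_path, sidecar_path) -> IsotropicAngiogram:
    meta = oio.read_sidecar(sidecar_path)
    img = load_enface(image_path, meta)
    if meta.crop_box is not None:
        img = crop_scan_region(img)
    return rescale_isotropic(img)


def run_eye(
    svc_image, svc_sidecar, dvc_image, dvc_sidecar,
    config: Optional[PipelineConfig] = None,
    thickness_tsvs: Optional[dict] = None,
) -> EyeResult:
    """File-based per-eye run: images + sidecars (+ thickness TSVs) in."""
    for name, p in (("SVC image", svc_image), ("DVC image", dvc_image)):
        if p is None or not Path(p).exists():
            raise InputError(f"missing input: {name} ({p})")
    svc = _load_iso(svc_image, svc_sidecar)
    dvc = _load_iso(dvc_image, dvc_sidecar)
    maps = None
    if thickness_tsvs:
        maps = {layer: oio.read_thickness_tsv(p) for layer, p in thickness_tsvs.items()}
    return process_eye(svc, dvc, config, maps)


_COVARIATE_COLS = ("group", "age", "sex", "hypertension", "MoCA", "UPDRS_III",
                   "disease_duration")


def run_cohort(manifest: pd.DataFrame, config: Optional[PipelineConfig] = None,
               out_dir=None) -> dict:
    """Process every eye in a manifest, then run the statistics layer.

    Manifest columns: subject_id, eye, svc_image, svc_sidecar, dvc_image,
    dvc_sidecar, plus covariates (group, age, sex, hypertension, ...).
    Returns a dict with the eye-level metrics table, the comparison table,
    and the exclusion list; writes CSVs plus the resolved config if
    ``out_dir`` is given.
    """
    cfg = config or PipelineConfig()
    rows, exclusions = [], []
    for _, rec in manifest.iterrows():
        try:
            res = run_eye(rec["svc_image"], rec["svc_sidecar"],
                          rec["dvc_image"], rec["dvc_sidecar"], cfg)
        except SegmentationFailure as exc:
            exclusions.append({"subject_id": rec["subject_id"], "eye": rec["eye"],
                               "reason_code": "faz_segmentation_failure",
                               "detail": str(exc)})
            continue
        except OctaquantError as exc:
            exclusions.append({"subject_id": rec["subject_id"], "eye": rec["eye"],
                               "reason_code": "input_error", "detail": str(exc)})
            continue
        row = res.to_wide_row()
        for c in _COVARIATE_COLS:
            if c in rec.index:
                row[c] = rec[c]
        rows.append(row)
    metrics = pd.DataFrame(rows)
    out: dict = {"metrics": metrics, "exclusions": pd.DataFrame(exclusions)}

    if "group" in metrics.columns and metrics["group"].nunique() == 2:
        if metrics.groupby("group")["subject_id"].nunique().min() >= 2:
            out["comparison"] = compare_metrics(metrics, adjust=cfg.gee_adjust)
            out["diagnostics"] = _safe_diagnostic_table(metrics)
    if "subgroup" in metrics.columns and metrics["subgroup"].nunique() == 2:
        if metrics.groupby("subgroup")["subject_id"].nunique().min() >= 2:
            out["subgroup_comparison"] = compare_metrics(
                metrics, group_col="subgroup", adjust=cfg.gee_adjust
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out_dir / "eye_metrics.csv", index=False)
        out["exclusions"].to_csv(out_dir / "exclusions.csv", index=False)
        if "comparison" in out:
            out["comparison"].to_csv(out_dir / "group_comparison.csv", index=False)
        if "diagnostics" in out and len(out["diagnostics"]):
            out["diagnostics"].to_csv(out_dir / "diagnostic_auc.csv", index=False)
        if "subgroup_comparison" in out:
            out["subgroup_comparison"].to_csv(
                out_dir / "subgroup_comparison.csv", index=False
            )
        cfg.to_json(out_dir / "resolved_config.json")
    return out


def _safe_diagnostic_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Single-predictor diagnostic models vs the null; failures recorded."""
    skip = {"subject_id", "eye", *(_COVARIATE_COLS)}
    preds = [c for c in metrics.columns
             if c not in skip and pd.api.types.is_numeric_dtype(metrics[c])
             and metrics[c].dropna().nunique() > 1]
    rows = []
    for pred in preds:
        try:
            _, roc, summary = diagnostic_model(metrics, [pred])
            rows.append({"predictor": pred,
                         **{k: v for k, v in summary.items()
                            if not isinstance(v, tuple)},
                         "auc_ci_low": roc.ci_low, "auc_ci_high": roc.ci_high})
        except OctaquantError as exc:
            rows.append({"predictor": pred, "error": str(exc)})
    return pd.DataFrame(rows)


def compare_metrics(metrics: pd.DataFrame, group_col: str = "group",
                    adjust=("age", "sex", "hypertension")) -> pd.DataFrame:
    """Comparison table: one row per metric column, GEE-based p-values."""
    skip = {"subject_id", "eye", *(_COVARIATE_COLS)}
    cols = [c for c in metrics.columns
            if c not in skip and pd.api.types.is_numeric_dtype(metrics[c])]
    rows = []
    for c in cols:
        if metrics[c].dropna().nunique() < 2:
            continue
        try:
            rows.append(adjusted_comparison(metrics, c, group_col=group_col,
                                            adjust=tuple(adjust)))
        except OctaquantError as exc:
            rows.append({"outcome": c, "error": str(exc)})
    return pd.DataFrame(rows)


def diagnostic_table(metrics: pd.DataFrame, predictors: list[str],
                     **kw) -> pd.DataFrame:
    """One diagnostic logistic-GEE model per predictor, vs the null model."""
    rows = []
    for pred in predictors:
        _, roc, summary = diagnostic_model(metrics, [pred], **kw)
        rows.append({"predictor": pred, **{k: v for k, v in summary.items()
                                           if not isinstance(v, tuple)},
                     "auc_ci_low": roc.ci_low, "auc_ci_high": roc.ci_high})
    return pd.DataFrame(rows)
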
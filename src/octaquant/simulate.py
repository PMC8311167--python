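"""Synthetic angiograms, thickness maps and two-eye cohorts with known truth.

Nothing here tries to be biophysically faithful; the generators exist so
that every pipeline stage can be validated against exact ground truth:

* angiograms: branching capillary trees grown from peripheral seeds toward
  the rim of a clean avascular ellipse (the FAZ), closed by a terminal
  capillary arcade along the rim, rendered as tubes with a soft (Gaussian)
  cross profile over a dim background and multiplicative gamma speckle.
  The SVC additionally carries a few large (>30 um) vessels.
* thickness maps: per-layer smooth sheets with a Gaussian foveal pit at a
  known center; the total-retina map is the exact sum of its layers.
* cohorts: two eyes per subject with a shared subject-level random effect,
  which induces exchangeable inter-eye correlation rho; group means and
  SDs default to the reference clinical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw

from .morpho import dilate_disk

from . import refcohort
from .errors import ParameterError
from .faz import build_regions
from .types import AcquisitionMeta, IsotropicAngiogram, ThicknessMap

__all__ = [
    "AngiogramSpec",
    "AngiogramTruth",
    "ThicknessSpec",
    "CohortSpec",
    "generate_angiogram",
    "generate_thickness_map",
    "generate_cohort",
    "reference_cohort_spec",
]


# ---------------------------------------------------------------------------
# angiograms
# ---------------------------------------------------------------------------

@dataclass
class AngiogramSpec:
    """Geometry and texture of one synthetic eye (both plexuses).

    Defaults mirror the acquisition this pipeline targets: a ~2.9 mm field
    at 1 um/px, a FAZ of ~0.5 mm^2, capillaries of 8-12 um caliber, denser
    in the deep plexus, and 2-4 large vessels (>30 um) in the superficial
    plexus only.
    """

    field_um: int = 2940
    faz_axes_um: tuple[float, float] = (450.0, 354.0)  # semi-axes; pi*a*b ~ 0.5 mm^2
    center_offset_um: tuple[float, float] = (0.0, 0.0)
    n_trees: dict = field(default_factory=lambda: {"SVC": 70, "DVC": 110})
    branches_per_tree: int = 3
    capillary_diameter_um: tuple[float, float] = (8.0, 12.0)
    n_large_vessels: tuple[int, int] = (2, 4)
    large_vessel_diameter_um: tuple[float, float] = (32.0, 48.0)
    background_level: float = 40.0
    vessel_level: float = 150.0
    large_vessel_level: float = 240.0  # arterioles/venules: stronger flow signal
    profile_sigma_um: float = 1.5
    speckle_shape: float = 4.0

    def __post_init__(self) -> None:
        a, b = self.faz_axes_um
        if max(a, b) * 2 >= self.field_um:
            raise ParameterError("FAZ does not fit inside the field")
        if self.capillary_diameter_um[0] < 6.0:
            raise ParameterError("capillary diameters must be >= 6 um")

    @property
    def faz_area_mm2(self) -> float:
        a, b = self.faz_axes_um
        return float(np.pi * a * b * 1e-6)


@dataclass
class AngiogramTruth:
    """Exact ground truth for one synthetic eye."""

    faz_axes_um: tuple[float, float]
    faz_area_mm2: float
    center_um: tuple[float, float]
    centerlines: dict  # plexus -> list of (polyline ndarray (n,2) xy um, diameter um)
    vessel_masks: dict  # plexus -> bool raster (SVC includes large vessels)
    svc_micro_mask: np.ndarray
    large_vessel_mask: np.ndarray
    true_perfusion: dict  # (plexus, region) -> area fraction (SVC = micro only)
    seed: int


def _midpoint_path(p0, p1, rng, levels: int = 4, jitter: float = 0.16) -> np.ndarray:
    """Fractal polyline from p0 to p1 by recursive midpoint displacement."""
    pts = np.array([p0, p1], dtype=float)
    for _ in range(levels):
        mids = (pts[:-1] + pts[1:]) / 2.0
        seg = pts[1:] - pts[:-1]
        norm = np.column_stack([-seg[:, 1], seg[:, 0]])
        ln = np.hypot(seg[:, 0], seg[:, 1])[:, None]
        norm = np.divide(norm, ln, out=np.zeros_like(norm), where=ln > 0)
        mids = mids + norm * (rng.normal(size=(len(mids), 1)) * jitter * ln)
        out = np.empty((len(pts) + len(mids), 2))
        out[0::2] = pts
        out[1::2] = mids
        pts = out
    return pts


def _tree_polylines(rng, field: int, center, faz_axes, branches: int) -> list[np.ndarray]:
    """One capillary tree: a trunk from the periphery to the FAZ rim + branches."""
    a, b = faz_axes
    cx, cy = center
    side = rng.integers(4)
    t = rng.uniform(0, field)
    seed_pt = [(t, 0.0), (t, field - 1.0), (0.0, t), (field - 1.0, t)][side]
    th = rng.uniform(0, 2 * np.pi)
    target = (cx + (a + 6) * np.cos(th), cy + (b + 6) * np.sin(th))
    trunk = _midpoint_path(seed_pt, target, rng)
    polys = [trunk]
    for _ in range(branches):
        i = rng.integers(len(trunk) // 5, len(trunk) - 1)
        start = trunk[i]
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(150, 500)
        end = start + length * np.array([np.cos(ang), np.sin(ang)])
        end = np.clip(end, 0, field - 1)
        polys.append(_midpoint_path(start, end, rng, levels=3))
    return polys


def _faz_ring(rng, center, faz_axes, n: int = 240) -> np.ndarray:
    """Terminal capillary arcade: a jittered closed loop hugging the FAZ rim."""
    a, b = faz_axes
    cx, cy = center
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    jit = ndi.gaussian_filter1d(rng.normal(scale=4.0, size=n), 3, mode="wrap")
    pts = np.column_stack(
        [cx + (a + 5 + jit) * np.cos(th), cy + (b + 5 + jit) * np.sin(th)]
    )
    return np.vstack([pts, pts[:1]])


def _rasterize(polys_diams, shape) -> np.ndarray:
    """Render (polyline, diameter) tubes: draw centerlines, dilate per caliber."""
    mask = np.zeros(shape, dtype=bool)
    by_r: dict[int, np.ndarray] = {}
    for poly, d in polys_diams:
        r = max(int(round(d / 2)), 1)
        canvas = by_r.setdefault(r, np.zeros(shape, dtype=bool))
        p = np.clip(np.rint(poly), 0, np.array(shape)[::-1] - 1).astype(int)
        for (x0, y0), (x1, y1) in zip(p[:-1], p[1:]):
            rr, cc = draw.line(y0, x0, y1, x1)
            canvas[rr, cc] = True
    for r, canvas in by_r.items():
        mask |= dilate_disk(canvas, r)
    return mask


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    h, w = shape
    cx, cy = center
    a, b = axes
    yy, xx = np.ogrid[:h, :w]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def generate_angiogram(
    spec: AngiogramSpec, seed: int, subject_id: str = "sim", eye: str = "OD",
    plexuses: tuple[str, ...] = ("SVC", "DVC"),
) -> tuple[dict[str, IsotropicAngiogram], AngiogramTruth]:
    """Render SVC and DVC angiograms plus exact truth, deterministically.

    Capillary trees are drawn from independent substreams spawned from
    ``seed``, so increasing ``n_trees`` extends the vessel set without
    perturbing the trees already present (monotone density response).
    """
    field = spec.field_um
    shape = (field, field)
    center = (field / 2 + spec.center_offset_um[0], field / 2 + spec.center_offset_um[1])
    faz = _ellipse_mask(shape, center, spec.faz_axes_um)
    rng = np.random.default_rng([seed, 9001])

    images: dict[str, IsotropicAngiogram] = {}
    centerlines: dict[str, list] = {}
    vessel_masks: dict[str, np.ndarray] = {}
    large_mask = np.zeros(shape, dtype=bool)
    svc_micro = np.zeros(shape, dtype=bool)

    for pi, plexus in enumerate(("SVC", "DVC")):
        if plexus not in plexuses:
            continue
        polys_diams = []
        for i in range(spec.n_trees[plexus]):
            trng = np.random.default_rng([seed, pi, i])
            d = trng.uniform(*spec.capillary_diameter_um)
            for poly in _tree_polylines(
                trng, field, center, spec.faz_axes_um, spec.branches_per_tree
            ):
                polys_diams.append((poly, d))
        ring_rng = np.random.default_rng([seed, pi, 777])
        polys_diams.append((_faz_ring(ring_rng, center, spec.faz_axes_um),
                            np.mean(spec.capillary_diameter_um)))
        micro = _rasterize(polys_diams, shape) & ~faz

        if plexus == "SVC":
            lv_rng = np.random.default_rng([seed, 5, 0])
            n_lv = int(lv_rng.integers(spec.n_large_vessels[0], spec.n_large_vessels[1] + 1))
            lv_polys = []
            for _ in range(n_lv):
                d = lv_rng.uniform(*spec.large_vessel_diameter_um)
                x0 = lv_rng.uniform(0.1, 0.9) * field
                x1 = np.clip(x0 + lv_rng.normal(scale=0.2 * field), 0, field - 1)
                poly = _midpoint_path((x0, 0.0), (x1, field - 1.0), lv_rng, levels=3, jitter=0.10)
                if lv_rng.random() < 0.5:
                    poly = poly[:, ::-1]  # vertical -> horizontal course
                lv_polys.append((poly, d))
            large_mask = _rasterize(lv_polys, shape) & ~faz
            full = micro | large_mask
            svc_micro = micro & ~large_mask
            centerlines[plexus] = [(p, d) for p, d in polys_diams] + lv_polys
        else:
            full = micro
            centerlines[plexus] = polys_diams
        vessel_masks[plexus] = full

        soft = ndi.gaussian_filter((micro & ~large_mask if plexus == "SVC" else micro).astype(float),
                                   spec.profile_sigma_um)
        img = spec.background_level + spec.vessel_level * soft
        if plexus == "SVC" and large_mask.any():
            soft_lv = ndi.gaussian_filter(large_mask.astype(float), spec.profile_sigma_um)
            img = img + spec.large_vessel_level * soft_lv
        speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, size=shape)
        img = np.clip(img * speckle, 0, 255).astype(np.uint8)
        meta = AcquisitionMeta(
            subject_id=subject_id, eye=eye, plexus=plexus,
            scale_x_um=1.0, scale_y_um=1.0, field_label=f"synthetic seed={seed}",
        )
        images[plexus] = IsotropicAngiogram(pixels=img, meta=meta)

    regions = build_regions(center, shape)
    true_perfusion = {}
    truth_maps = [("SVC", svc_micro)] if "SVC" in vessel_masks else []
    if "DVC" in vessel_masks:
        truth_maps.append(("DVC", vessel_masks["DVC"]))
    for plexus, m in truth_maps:
        for rname, rmask in (("fovea", regions.fovea_mask), ("parafovea", regions.parafovea_mask)):
            true_perfusion[(plexus, rname)] = float((m & rmask).sum() / rmask.sum())

    truth = AngiogramTruth(
        faz_axes_um=spec.faz_axes_um,
        faz_area_mm2=spec.faz_area_mm2,
        center_um=(float(center[0]), float(center[1])),
        centerlines=centerlines,
        vessel_masks=vessel_masks,
        svc_micro_mask=svc_micro,
        large_vessel_mask=large_mask,
        true_perfusion=true_perfusion,
        seed=seed,
    )
    return images, truth


# ---------------------------------------------------------------------------
# thickness maps
# ---------------------------------------------------------------------------

@dataclass
class ThicknessSpec:
    """Per-layer sheets with a Gaussian foveal pit (negative depth = bump).

    The raster mimics a 20-degree macular cube: dense A-scans along x,
    sparse B-scans along y, over a 6 x 6 mm area.
    """

    extent_mm: float = 6.0
    n_ascans: int = 512
    n_bscans: int = 25
    center_mm: tuple[float, float] = (3.0, 3.0)
    pit_sigma_mm: float = 0.35
    noise_um: float = 1.0
    noise_sigma_mm: float = 0.3
    #: layer -> (base thickness um, pit depth um)
    layers: dict = field(default_factory=lambda: {
        "mRNFL": (30.0, 25.0),
        "GCIPL": (95.0, 58.0),
        "INL": (40.0, 19.0),
        "OPL-ONL": (105.0, -12.0),
        "ELM-IS/OS": (44.0, -5.0),
    })

    def __post_init__(self) -> None:
        for layer, (base, depth) in self.layers.items():
            if depth >= base:
                raise ParameterError(f"pit depth >= central thickness for {layer}")


def generate_thickness_map(spec: ThicknessSpec, seed: int) -> dict[str, ThicknessMap]:
    """Per-layer maps plus their exact sum as the total-retina map."""
    sx = spec.extent_mm / (spec.n_ascans - 1)
    sy = spec.extent_mm / (spec.n_bscans - 1)
    xs = np.arange(spec.n_ascans) * sx
    ys = np.arange(spec.n_bscans) * sy
    r2 = (ys[:, None] - spec.center_mm[1]) ** 2 + (xs[None, :] - spec.center_mm[0]) ** 2
    pit = np.exp(-r2 / (2 * spec.pit_sigma_mm**2))
    rng = np.random.default_rng([seed, 42])
    out: dict[str, ThicknessMap] = {}
    total = np.zeros_like(pit)
    for layer, (base, depth) in spec.layers.items():
        vals = base - depth * pit
        if spec.noise_um > 0:
            raw = rng.normal(size=vals.shape)
            smooth = ndi.gaussian_filter(raw, (spec.noise_sigma_mm / sy, spec.noise_sigma_mm / sx))
            sd = smooth.std()
            if sd > 0:
                vals = vals + spec.noise_um * smooth / sd
        vals = np.maximum(vals, 0.0)
        total += vals
        out[layer] = ThicknessMap(layer, vals, sx, sy)
    out["Retina"] = ThicknessMap("Retina", total, sx, sy)
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Two-eye cohort with exchangeable within-subject correlation.

    Each metric value is ``group_mean + sqrt(rho)*sd*Z_subject +
    sqrt(1-rho)*sd*Z_eye`` so the marginal SD is the group SD and the
    inter-eye correlation is exactly ``rho``. Covariates are drawn once per
    subject; eyes drop out independently with ``missing_eye_p``.
    """

    n_per_group: dict
    metric_means: dict  # metric -> {group: mean}
    metric_sds: dict  # metric -> {group: sd}
    rho: float = 0.5
    missing_eye_p: float = 0.1
    covariates: dict = field(default_factory=lambda: refcohort.COVARIATE_REFERENCE)

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ParameterError("rho must lie in [0, 1)")
        if not (0.0 <= self.missing_eye_p < 1.0):
            raise ParameterError("missing_eye_p must lie in [0, 1)")
        for metric, sds in self.metric_sds.items():
            for g, sd in sds.items():
                if sd <= 0:
                    raise ParameterError(f"non-positive SD for {metric}/{g}")


def reference_cohort_spec(rho: float = 0.5, missing_eye_p: float = 0.1) -> CohortSpec:
    """Cohort spec parameterized by the reference clinical summaries."""
    means: dict = {}
    sds: dict = {}
    for (metric, plexus), row in refcohort.FOVEAL_REFERENCE.items():
        name = f"{metric}_{plexus.lower()}"
        means[name] = {g: row[g][0] for g in ("PD", "control")}
        sds[name] = {g: row[g][1] for g in ("PD", "control")}
    n = {g: refcohort.COVARIATE_REFERENCE[g]["n"] for g in ("PD", "control")}
    return CohortSpec(n_per_group=n, metric_means=means, metric_sds=sds,
                      rho=rho, missing_eye_p=missing_eye_p)


def generate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """One tidy eye-level table: one row per retained eye."""
    rng = np.random.default_rng([seed, 7])
    rows = []
    sid = 0
    for group, n in spec.n_per_group.items():
        cov = spec.covariates.get(group, {})
        for _ in range(n):
            sid += 1
            age = rng.normal(*cov.get("age", (65.0, 8.0)))
            sex = "F" if rng.random() < cov.get("female_p", 0.5) else "M"
            ht = bool(rng.random() < cov.get("hypertension_p", 0.2))
            moca = rng.normal(*cov.get("moca", (25.0, 3.0)))
            updrs = rng.normal(*cov["updrs_iii"]) if cov.get("updrs_iii") else np.nan
            dur = max(rng.normal(*cov["duration"]), 0.1) if cov.get("duration") else np.nan
            subj_z = {m: rng.normal() for m in spec.metric_means}
            for eye in ("OD", "OS"):
                eye_vals = {}
                for m in spec.metric_means:
                    mu = spec.metric_means[m][group]
                    sd = spec.metric_sds[m][group]
                    z = np.sqrt(spec.rho) * subj_z[m] + np.sqrt(1 - spec.rho) * rng.normal()
                    eye_vals[m] = mu + sd * z
                keep = rng.random() >= spec.missing_eye_p
                if keep:
                    rows.append({
                        "subject_id": f"S{sid:04d}", "eye": eye, "group": group,
                        "age": age, "sex": sex, "hypertension": ht,
                        "MoCA": moca, "UPDRS_III": updrs, "disease_duration": dur,
                        **eye_vals,
                    })
    return pd.DataFrame(rows)
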
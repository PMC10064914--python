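"""Synthetic inputs for the QA pipeline, at two levels.

**Metric level** (`generate_cohort_metrics`): per-eye quadrant VLD/PD values
for a three-group cohort (contralateral controls, non-ischemic CRVO,
ischemic CRVO).  Each eye has a group base level plus an eye-level random
effect; quadrant values are depressed by capillary-dropout deficits.  A
deficit is a product ``S_eye * J_metric * severity * w_q`` where the
Dirichlet weights ``w`` spread one eye's total dropout unevenly across
quadrants -- the unevenness, not the amount, is what generates quadrant
asymmetry, mirroring the finding that no particular quadrant is
preferentially affected.  QA of an eye is therefore exactly
``S * J * severity * (max w - min w)``: zero severity, or a perfectly even
spread, gives QA = 0.

Default severities are calibrated so group QA means and SDs approximate the
published cohort statistics (QA(VLD) 3.459/3.141/4.875, QA(PD)
0.072/0.062/0.109 for control/non-ischemic/ischemic), with group sizes
27/21/10 eyes.

**Image level** (`generate_angiogram`): small en-face angiograms with a
known vessel raster (branching arcades plus a capillary mesh), per-quadrant
segment-wise capillary dropout, a point-spread blur and additive speckle,
retaining ground-truth quadrant metrics so the image pipeline can be
validated end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from .etdrs_grid import QUADRANTS, ImageCalibration, build_etdrs_grid, quadrant_of_point
from .qa_stats import GROUPS, METRICS, EyeRecord
from .vessel_metrics import EnFaceAngiogram, QuadrantMetrics, quadrant_metrics_from_binary

__all__ = [
    "CohortSpec",
    "SceneConfig",
    "AngiogramScene",
    "generate_roster",
    "generate_cohort_metrics",
    "generate_angiogram",
]

#: E[max w - min w] for w ~ Dirichlet(1,1,1,1) (range of uniform spacings):
#: E[max] = (1/4)(1 + 1/2 + 1/3 + 1/4), E[min] = 1/16.
E_RANGE_DIRICHLET1 = 25.0 / 48.0 - 1.0 / 16.0  # = 0.4583...

#: Published group QA means used as calibration targets for the default
#: severities (severity = target mean / E[range of allocation weights]).
QA_CALIBRATION_TARGETS = {
    "vld": {"control": 3.459, "non_ischemic": 3.141, "ischemic": 4.875},
    "pd": {"control": 0.072, "non_ischemic": 0.062, "ischemic": 0.109},
}


def _default_severity() -> dict[str, dict[str, float]]:
    return {
        m: {g: QA_CALIBRATION_TARGETS[m][g] / E_RANGE_DIRICHLET1 for g in GROUPS}
        for m in METRICS
    }


def _default_base_level() -> dict[str, dict[str, float]]:
    # Chosen so observed quadrant means (base - severity/4 on average) land in
    # realistic ranges: VLD ~18.5/17.5/13 mm^-1 and PD ~0.40/0.38/0.28 for
    # control / non-ischemic / ischemic.
    return {
        "vld": {"control": 20.4, "non_ischemic": 19.2, "ischemic": 15.7},
        "pd": {"control": 0.44, "non_ischemic": 0.41, "ischemic": 0.34},
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings for a metric-level cohort.

    ``concentration`` controls how unevenly one eye's dropout spreads over
    the four quadrants (Dirichlet concentration; 1 = exchangeable/uniform
    simplex, ``inf`` = perfectly even, hence QA = 0).  ``severity_shape``
    and ``jitter_shape`` are Gamma shapes (unit mean) of the eye-level and
    metric-level severity multipliers; together with the allocation spread
    they set the QA coefficient of variation (~0.50 at the defaults, as in
    the published groups).
    """

    n_control: int = 27
    n_non_ischemic: int = 21
    n_ischemic: int = 10
    base_level: dict = field(default_factory=_default_base_level)
    eye_re_sd: dict = field(default_factory=lambda: {"vld": 1.0, "pd": 0.02})
    dropout_severity: dict = field(default_factory=_default_severity)
    severity_shape: float = 18.0
    jitter_shape: float = 18.0
    concentration: float = 1.0
    ischemic_quadrant_effects: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_non_ischemic, self.n_ischemic) < 0:
            raise ValueError("eye counts must be non-negative")
        for m in METRICS:
            for g in GROUPS:
                if self.dropout_severity[m][g] < 0:
                    raise ValueError("severity parameters must be >= 0")
            if self.dropout_severity[m]["ischemic"] < self.dropout_severity[m]["non_ischemic"]:
                raise ValueError("ischemic severity must be >= non-ischemic severity")
        if not (self.concentration > 0):
            raise ValueError("concentration must be positive (may be inf)")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "control": self.n_control,
            "non_ischemic": self.n_non_ischemic,
            "ischemic": self.n_ischemic,
        }


def generate_roster(spec: CohortSpec) -> pd.DataFrame:
    """Patient/eye assignment table (patient_id, eye_id, group, laterality).

    Emulates the paired contralateral-control design: CRVO patients
    contribute one diseased eye and, where available, their fellow eye as a
    control.  One ischemic patient is monocular (no fellow), one
    non-ischemic patient has bilateral CRVO, and one control eye belongs to
    a patient whose diseased eye is not in the cohort; remaining controls
    are fellows.  At the default 27/21/10 eye counts this yields 58 eyes
    from 31 patients.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    pat_counter = 0

    def new_patient() -> str:
        nonlocal pat_counter
        pat_counter += 1
        return f"P{pat_counter:03d}"

    def add_eye(pid: str, group: str, lat: str) -> None:
        rows.append(
            {"patient_id": pid, "eye_id": f"{pid}-{lat}", "group": group, "laterality": lat}
        )

    def pick_lat() -> str:
        return "OD" if rng.random() < 0.5 else "OS"

    fellows: list[tuple[str, str]] = []  # (patient_id, free laterality)

    # Ischemic patients, one eye each; the first is monocular (no fellow).
    for i in range(spec.n_ischemic):
        pid = new_patient()
        lat = pick_lat()
        add_eye(pid, "ischemic", lat)
        if i > 0:
            fellows.append((pid, "OD" if lat == "OS" else "OS"))

    # Non-ischemic: one bilateral patient when there are >= 2 eyes.
    n_non_patients = spec.n_non_ischemic - 1 if spec.n_non_ischemic >= 2 else spec.n_non_ischemic
    for i in range(n_non_patients):
        pid = new_patient()
        lat = pick_lat()
        add_eye(pid, "non_ischemic", lat)
        if i == 0 and spec.n_non_ischemic >= 2:
            add_eye(pid, "non_ischemic", "OD" if lat == "OS" else "OS")  # bilateral
        else:
            fellows.append((pid, "OD" if lat == "OS" else "OS"))

    # Controls: one orphan control patient first (diseased eye excluded
    # upstream), then contralateral fellows, then extra patients if needed.
    n_controls_left = spec.n_control
    if n_controls_left > 0 and (spec.n_ischemic or spec.n_non_ischemic):
        add_eye(new_patient(), "control", pick_lat())
        n_controls_left -= 1
    for pid, lat in fellows[:n_controls_left]:
        add_eye(pid, "control", lat)
    n_controls_left -= min(len(fellows), n_controls_left)
    for _ in range(n_controls_left):
        add_eye(new_patient(), "control", pick_lat())

    return pd.DataFrame(rows, columns=["patient_id", "eye_id", "group", "laterality"])


def generate_cohort_metrics(spec: CohortSpec) -> list[EyeRecord]:
    """Draw one cohort of per-eye quadrant metrics.

    Per eye: ``value[m][q] = base[m][group] + re[m] - S * J[m] *
    severity[m][group] * w[q]`` with ``S ~ Gamma(severity_shape)`` (unit
    mean, shared by both metrics), ``J[m] ~ Gamma(jitter_shape)`` (unit
    mean, per metric), ``w ~ Dirichlet(concentration * 1_4)`` (shared: both
    metrics see the same spatial dropout pattern).  PD is clipped to [0, 1]
    and VLD to >= 0.  Pure function of (spec, spec.seed).
    """
    roster = generate_roster(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    records: list[EyeRecord] = []
    inj = spec.ischemic_quadrant_effects or {}
    for row in roster.itertuples(index=False):
        if math.isinf(spec.concentration):
            w = np.full(4, 0.25)
        else:
            w = rng.dirichlet(np.full(4, spec.concentration))
        s_eye = rng.gamma(spec.severity_shape, 1.0 / spec.severity_shape)
        values: dict[str, dict[str, float]] = {}
        for m in METRICS:
            jitter = rng.gamma(spec.jitter_shape, 1.0 / spec.jitter_shape)
            base = spec.base_level[m][row.group] + rng.normal(0.0, spec.eye_re_sd[m])
            sev = spec.dropout_severity[m][row.group]
            vals = base - s_eye * jitter * sev * w
            if row.group == "ischemic" and m in inj:
                for q, shift in inj[m].items():
                    vals[QUADRANTS.index(q)] += shift
            lo, hi = (0.0, 1.0) if m == "pd" else (0.0, np.inf)
            values[m] = {q: float(np.clip(vals[i], lo, hi)) for i, q in enumerate(QUADRANTS)}
        records.append(
            EyeRecord(
                patient_id=row.patient_id,
                eye_id=row.eye_id,
                group=row.group,
                laterality=row.laterality,
                metrics=QuadrantMetrics(vld=values["vld"], pd=values["pd"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Image-level generator


@dataclass(frozen=True)
class SceneConfig:
    """Settings for one synthetic en-face angiogram.

    The vessel pattern is a handful of branching arcades radiating from the
    fovea plus a dense mesh of short capillary segments; per-quadrant
    dropout removes whole capillary segments (not pixels), mimicking
    capillary non-perfusion.  ``capillary_density`` is segments per mm^2,
    calibrated so healthy scenes land near PD ~0.35 and VLD ~17 mm^-1 in
    the parafoveal ring.
    """

    size_px: int = 245
    scan_width_mm: float = 3.0
    laterality: str = "OD"
    n_arcades: int = 6
    capillary_density: float = 125.0
    capillary_length_mm: tuple[float, float] = (0.073, 0.171)
    vessel_width_mm: float = 0.025
    faz_radius_mm: float = 0.25
    dropout: Mapping[str, float] | None = None
    noise_level: float = 0.08
    psf_sigma_px: float = 0.7

    def __post_init__(self) -> None:
        if self.dropout is not None:
            for q, f in dict(self.dropout).items():
                if q not in QUADRANTS:
                    raise ValueError(f"unknown quadrant {q!r} in dropout config")
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"dropout fraction for {q!r} outside [0, 1]: {f}")

    @property
    def pixel_size_mm(self) -> float:
        return self.scan_width_mm / self.size_px

    def calibration(self) -> ImageCalibration:
        c = (self.size_px - 1) / 2.0
        return ImageCalibration(
            width_px=self.size_px,
            height_px=self.size_px,
            pixel_size_mm=self.pixel_size_mm,
            fovea_center=(c, c),
            laterality=self.laterality,
        )


@dataclass(frozen=True)
class AngiogramScene:
    """Ground truth retained by the image generator."""

    vessel_raster: np.ndarray  # post-dropout, noise-free truth
    true_quadrant_metrics: QuadrantMetrics
    dropout_config: dict[str, float]
    noise_level: float
    seed: int


def _draw_thick_line(
    canvas: np.ndarray, r0: int, c0: int, r1: int, c1: int, width_px: int = 2
) -> None:
    """Line of approximately ``width_px`` pixels (sideways-shifted copies)."""
    rr, cc = skdraw.line(r0, c0, r1, c1)
    h, w = canvas.shape
    sideways = (1, 0) if abs(c1 - c0) >= abs(r1 - r0) else (0, 1)
    for k in range(width_px):
        r, c = rr + sideways[0] * k, cc + sideways[1] * k
        keep = (r >= 0) & (r < h) & (c >= 0) & (c < w)
        canvas[r[keep], c[keep]] = True


def _draw_arcades(canvas: np.ndarray, cfg: SceneConfig, rng: np.random.Generator) -> None:
    h, w = canvas.shape
    c = (cfg.size_px - 1) / 2.0
    ps = cfg.pixel_size_mm
    for k in range(cfg.n_arcades):
        theta = 2 * np.pi * (k + rng.random()) / cfg.n_arcades
        r_mm = cfg.faz_radius_mm + 0.05
        pts = []
        while r_mm < cfg.scan_width_mm * 0.75:
            pts.append((c + r_mm / ps * math.cos(theta), c + r_mm / ps * math.sin(theta)))
            r_mm += rng.uniform(0.12, 0.22)
            theta += rng.normal(0.0, 0.18)
        width_px = max(2, round(1.5 * cfg.vessel_width_mm / ps))
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            _draw_thick_line(
                canvas, int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)), width_px
            )


def generate_angiogram(
    config: SceneConfig | None = None, seed: int = 0
) -> tuple[EnFaceAngiogram, AngiogramScene]:
    """Synthesize one angiogram with retained ground truth.

    Capillary segments falling in quadrant ``q`` of the parafoveal ring are
    removed independently with probability ``dropout[q]``; arcades are never
    dropped.  Intensity = truth convolved with a small Gaussian point
    spread, plus additive speckle.  Bit-identical for identical
    (config, seed).
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    calib = cfg.calibration()
    dropout = {q: 0.0 for q in QUADRANTS}
    if cfg.dropout:
        dropout.update(cfg.dropout)

    arcades = np.zeros((cfg.size_px, cfg.size_px), dtype=bool)
    _draw_arcades(arcades, cfg, rng)

    capillaries = np.zeros_like(arcades)
    area_mm2 = cfg.scan_width_mm**2
    n_seg = rng.poisson(cfg.capillary_density * area_mm2)
    c = (cfg.size_px - 1) / 2.0
    lo, hi = cfg.capillary_length_mm
    cap_width_px = max(1, round(cfg.vessel_width_mm / cfg.pixel_size_mm))
    for _ in range(n_seg):
        x = rng.uniform(0, cfg.size_px - 1)
        y = rng.uniform(0, cfg.size_px - 1)
        if math.hypot(x - c, y - c) * cfg.pixel_size_mm < cfg.faz_radius_mm:
            continue  # foveal avascular zone
        length = rng.uniform(lo, hi) / cfg.pixel_size_mm
        ang = rng.uniform(0, np.pi)
        # segment-wise dropout keyed on the midpoint's quadrant
        q = quadrant_of_point(calib, x, y)
        if q != "outside" and rng.random() < dropout[q]:
            continue
        dx, dy = length / 2 * math.cos(ang), length / 2 * math.sin(ang)
        r0, c0 = int(round(y - dy)), int(round(x - dx))
        r1, c1 = int(round(y + dy)), int(round(x + dx))
        r0, r1 = np.clip([r0, r1], 0, cfg.size_px - 1)
        c0, c1 = np.clip([c0, c1], 0, cfg.size_px - 1)
        _draw_thick_line(capillaries, r0, c0, r1, c1, cap_width_px)

    truth = arcades | capillaries
    grid = build_etdrs_grid(calib)
    true_metrics = quadrant_metrics_from_binary(truth, grid)

    blurred = ndimage.gaussian_filter(truth.astype(float), cfg.psf_sigma_px)
    if blurred.max() > 0:
        blurred /= blurred.max()
    noisy = np.clip(blurred + cfg.noise_level * rng.standard_normal(blurred.shape), 0.0, None)
    img = EnFaceAngiogram(pixels=noisy * 255.0, calib=calib, signal_strength=10)
    scene = AngiogramScene(
        vessel_raster=truth,
        true_quadrant_metrics=true_metrics,
        dropout_config=dropout,
        noise_level=cfg.noise_level,
        seed=seed,
    )
    return img, scene
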
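"""ETDRS parafoveal-ring quadrant geometry on calibrated en-face images.

The parafoveal inner ring of the ETDRS grid is the annulus between 0.5 mm
and 1.5 mm from the fovea center (inner diameter 1 mm, outer diameter 3 mm).
It is split into four quadrants -- superior, inferior, nasal, temporal --
by the two 45-degree diagonals through the center.  Which image side is
nasal depends on laterality: for a right eye (OD) displayed with row 0 as
superior retina, nasal retina is on the image left; for a left eye (OS) it
is on the image right.

All geometry uses a pixel-center rule: a pixel belongs to the annulus iff
the distance from its center to the fovea center satisfies
``inner_radius_mm <= r < outer_radius_mm``.  This makes the four quadrant
masks an exact partition of the annulus, which downstream density
normalisations rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "QUADRANTS",
    "PIXEL_SIZE_3MM_245",
    "ImageCalibration",
    "ETDRSGrid",
    "GridError",
    "build_etdrs_grid",
    "quadrant_of_point",
]

#: Fixed quadrant order used everywhere (tables, tie-breaks, label rasters).
QUADRANTS = ("superior", "inferior", "nasal", "temporal")

#: Pixel pitch of a 3 x 3 mm scan sampled at 245 x 245 A-scans (~12.2 um).
PIXEL_SIZE_3MM_245 = 3.0 / 245.0

INNER_RADIUS_MM = 0.5
OUTER_RADIUS_MM = 1.5

_ORIENTATIONS = ("row0-superior", "row0-inferior")


class GridError(ValueError):
    """Raised when a grid cannot be constructed on the given calibration."""


@dataclass(frozen=True)
class ImageCalibration:
    """Physical calibration of an en-face angiogram raster.

    Parameters
    ----------
    width_px, height_px
        Raster dimensions in pixels.
    pixel_size_mm
        Isotropic physical size of one pixel, mm.  Anisotropic pixels are
        rejected: pass a scalar only.
    fovea_center
        ``(x, y)`` pixel coordinates of the fovea (may be fractional).
    laterality
        ``"OD"`` (right eye) or ``"OS"`` (left eye).
    """

    width_px: int
    height_px: int
    pixel_size_mm: float = PIXEL_SIZE_3MM_245
    fovea_center: tuple[float, float] = None  # type: ignore[assignment]
    laterality: str = "OD"

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if np.ndim(self.pixel_size_mm) != 0:
            raise ValueError(
                "pixel_size_mm must be a scalar; anisotropic pixels are not supported"
            )
        if not np.isfinite(self.pixel_size_mm) or self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive and finite")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")
        if self.fovea_center is None:
            object.__setattr__(
                self,
                "fovea_center",
                ((self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0),
            )
        cx, cy = self.fovea_center
        if not (0 <= cx <= self.width_px - 1 and 0 <= cy <= self.height_px - 1):
            raise ValueError(f"fovea_center {self.fovea_center} outside image bounds")

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape as ``(height, width)`` (numpy convention)."""
        return (self.height_px, self.width_px)

    def to_dict(self) -> dict:
        return {
            "width_px": self.width_px,
            "height_px": self.height_px,
            "pixel_size_mm": float(self.pixel_size_mm),
            "fovea_center": [float(self.fovea_center[0]), float(self.fovea_center[1])],
            "laterality": self.laterality,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ImageCalibration":
        return cls(
            width_px=int(d["width_px"]),
            height_px=int(d["height_px"]),
            pixel_size_mm=float(d["pixel_size_mm"]),
            fovea_center=tuple(d["fovea_center"]),
            laterality=str(d["laterality"]),
        )


def _anatomic_offsets(
    dx_mm: np.ndarray, dy_mm: np.ndarray, laterality: str, orientation: str
) -> tuple[np.ndarray, np.ndarray]:
    """Map image-space offsets (x right, y down) to anatomic (h toward nasal,
    v toward superior) offsets."""
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    v = -dy_mm if orientation == "row0-superior" else dy_mm
    h = -dx_mm if laterality == "OD" else dx_mm
    return h, v


def _classify(h: np.ndarray, v: np.ndarray) -> dict[str, np.ndarray]:
    """Quadrant membership in the anatomic frame.

    Boundaries lie on the diagonals |h| == |v|.  A point exactly on a
    boundary is assigned to the vertical wedge of the adjacent pair
    (superior or inferior).  This tie-break is deterministic and symmetric
    under horizontal and vertical mirroring, so quadrant labels are exact
    under the horizontal-flip + laterality-toggle involution and OD/OS
    grids on the same image are pure relabelings of each other; 90-degree
    rotational symmetry holds up to the boundary pixels only (<0.3% of the
    annulus at 245 x 245).
    """
    return {
        "superior": (v > 0) & (v >= h) & (v >= -h),
        "inferior": (v < 0) & (-v >= h) & (-v >= -h),
        "nasal": (h > v) & (h > -v),
        "temporal": (-h > v) & (-h > -v),
    }


@dataclass(frozen=True)
class ETDRSGrid:
    """Boolean quadrant masks of the parafoveal ring on one raster."""

    masks: dict[str, np.ndarray]
    calib: ImageCalibration
    orientation: str = "row0-superior"
    inner_radius_mm: float = INNER_RADIUS_MM
    outer_radius_mm: float = OUTER_RADIUS_MM

    @property
    def annulus(self) -> np.ndarray:
        out = np.zeros(self.calib.shape, dtype=bool)
        for m in self.masks.values():
            out |= m
        return out

    def area_mm2(self, quadrant: str) -> float:
        """Quadrant area = pixel count x pixel area (mm^2)."""
        px = float(self.calib.pixel_size_mm)
        return int(self.masks[quadrant].sum()) * px * px

    def label_raster(self) -> np.ndarray:
        """uint8 raster: 0 = outside, 1..4 = quadrants in QUADRANTS order."""
        out = np.zeros(self.calib.shape, dtype=np.uint8)
        for i, q in enumerate(QUADRANTS, start=1):
            out[self.masks[q]] = i
        return out

    def export(self, png_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the label raster as PNG plus a JSON calibration sidecar."""
        import imageio.v3 as iio

        png_path = Path(png_path)
        iio.imwrite(png_path, self.label_raster())
        if sidecar_path is None:
            sidecar_path = png_path.with_suffix(".json")
        meta = self.calib.to_dict()
        meta.update(
            orientation=self.orientation,
            inner_radius_mm=self.inner_radius_mm,
            outer_radius_mm=self.outer_radius_mm,
            labels={str(i): q for i, q in enumerate(QUADRANTS, start=1)},
        )
        Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def build_etdrs_grid(
    calib: ImageCalibration, orientation: str = "row0-superior"
) -> ETDRSGrid:
    """Construct the four parafoveal quadrant masks for a calibrated image.

    Raises
    ------
    GridError
        If any annulus pixel would fall outside the raster (the 3 mm ring
        does not fit around the fovea center), reporting how many.
    """
    cx, cy = calib.fovea_center
    ps = float(calib.pixel_size_mm)
    r_out_px = OUTER_RADIUS_MM / ps

    # Count ring pixels that an unbounded raster would contain but this one
    # does not: evaluate the annulus over the ring's bounding box.
    x_lo, x_hi = int(np.floor(cx - r_out_px)), int(np.ceil(cx + r_out_px))
    y_lo, y_hi = int(np.floor(cy - r_out_px)), int(np.ceil(cy + r_out_px))
    yy, xx = np.mgrid[y_lo : y_hi + 1, x_lo : x_hi + 1]
    r_mm = np.hypot((xx - cx) * ps, (yy - cy) * ps)
    in_ann = (r_mm >= INNER_RADIUS_MM) & (r_mm < OUTER_RADIUS_MM)
    outside = in_ann & ~(
        (xx >= 0) & (xx < calib.width_px) & (yy >= 0) & (yy < calib.height_px)
    )
    n_out = int(outside.sum())
    if n_out:
        raise GridError(
            f"parafoveal ring exceeds image bounds: {n_out} ring pixels fall "
            f"outside the {calib.width_px}x{calib.height_px} raster"
        )

    yy, xx = np.mgrid[0 : calib.height_px, 0 : calib.width_px]
    dx = (xx - cx) * ps
    dy = (yy - cy) * ps
    r_mm = np.hypot(dx, dy)
    ann = (r_mm >= INNER_RADIUS_MM) & (r_mm < OUTER_RADIUS_MM)
    h, v = _anatomic_offsets(dx, dy, calib.laterality, orientation)
    wedges = _classify(h, v)
    masks = {q: wedges[q] & ann for q in QUADRANTS}
    return ETDRSGrid(masks=masks, calib=calib, orientation=orientation)


def quadrant_of_point(
    calib: ImageCalibration,
    x_px: float,
    y_px: float,
    orientation: str = "row0-superior",
) -> str:
    """Quadrant label of a single point, or ``"outside"`` the ring.

    Consistent with :func:`build_etdrs_grid` for every pixel center.
    """
    ps = float(calib.pixel_size_mm)
    cx, cy = calib.fovea_center
    dx = np.asarray((x_px - cx) * ps)
    dy = np.asarray((y_px - cy) * ps)
    r = np.hypot(dx, dy)
    if not (INNER_RADIUS_MM <= r < OUTER_RADIUS_MM):
        return "outside"
    h, v = _anatomic_offsets(dx, dy, calib.laterality, orientation)
    for q, member in _classify(h, v).items():
        if bool(member):
            return q
    return "outside"  # unreachable for r > 0; r == 0 is excluded by the ring
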
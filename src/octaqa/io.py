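"""File formats: grayscale rasters with JSON calibration sidecars, and the
tidy CSV interchange tables.

CSV schemas are versioned in a leading comment line so downstream readers
can detect drift; pandas skips it via ``comment='#'``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .etdrs_grid import QUADRANTS, ImageCalibration
from .qa_stats import EyeRecord
from .vessel_metrics import EnFaceAngiogram, QuadrantMetrics

__all__ = [
    "load_angiogram",
    "save_angiogram",
    "write_metrics_csv",
    "read_metrics_csv",
    "METRICS_CSV_COLUMNS",
]

METRICS_CSV_HEADER = "# octaqa quadrant-metrics table v1"
METRICS_CSV_COLUMNS = ["patient_id", "eye_id", "laterality", "group", "quadrant", "vld", "pd"]


def _sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(".json")


def save_angiogram(
    img: EnFaceAngiogram, image_path: str | Path, sidecar_path: str | Path | None = None
) -> None:
    """Write the raster as 16-bit PNG/TIFF plus a JSON calibration sidecar."""
    image_path = Path(image_path)
    px = img.pixels
    scale = px.max() if px.max() > 0 else 1.0
    iio.imwrite(image_path, np.round(px / scale * 65535).astype(np.uint16))
    meta = img.calib.to_dict()
    meta["intensity_scale"] = float(scale)
    if img.signal_strength is not None:
        meta["signal_strength"] = int(img.signal_strength)
    Path(sidecar_path or _sidecar_path(image_path)).write_text(json.dumps(meta, indent=2))


def load_angiogram(
    image_path: str | Path, sidecar_path: str | Path | None = None
) -> EnFaceAngiogram:
    """Read a grayscale PNG/TIFF and its JSON calibration sidecar."""
    image_path = Path(image_path)
    sidecar_path = Path(sidecar_path or _sidecar_path(image_path))
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing calibration sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    calib = ImageCalibration.from_dict(meta)
    px = np.asarray(iio.imread(image_path), dtype=float)
    if px.ndim == 3:  # collapse accidental RGB
        px = px.mean(axis=2)
    scale = float(meta.get("intensity_scale", 1.0))
    if px.max() > 0:
        px = px / 65535.0 * scale if px.max() > 255 else px
    return EnFaceAngiogram(
        pixels=px, calib=calib, signal_strength=meta.get("signal_strength")
    )


def write_metrics_csv(records: Iterable[EyeRecord], path: str | Path) -> None:
    """Tidy long table: one row per eye x quadrant, columns vld and pd."""
    from .cohort_analysis import records_to_long

    df = records_to_long(list(records))[METRICS_CSV_COLUMNS]
    path = Path(path)
    with path.open("w") as fh:
        fh.write(METRICS_CSV_HEADER + "\n")
        df.to_csv(fh, index=False)


def read_metrics_csv(path: str | Path) -> list[EyeRecord]:
    """Inverse of :func:`write_metrics_csv` (round-trip exact on values)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = set(METRICS_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metrics CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"metrics CSV {path} contains no rows")
    records: list[EyeRecord] = []
    for eye_id, sub in df.groupby("eye_id", sort=False):
        if sorted(sub["quadrant"]) != sorted(QUADRANTS):
            raise ValueError(f"eye {eye_id!r} does not have exactly the four quadrants")
        by_q = sub.set_index("quadrant")
        records.append(
            EyeRecord(
                patient_id=str(sub["patient_id"].iloc[0]),
                eye_id=str(eye_id),
                group=str(sub["group"].iloc[0]),
                laterality=str(sub["laterality"].iloc[0]),
                metrics=QuadrantMetrics(
                    vld={q: float(by_q.loc[q, "vld"]) for q in QUADRANTS},
                    pd={q: float(by_q.loc[q, "pd"]) for q in QUADRANTS},
                ),
            )
        )
    return records
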
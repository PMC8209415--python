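"""Geometric dose impact of a measured distortion field.

This module isolates the purely geometric component of the dose effect of
MRI distortion: how the mean dose of a region of interest changes when the
region is displaced by the measured displacement field on a fixed dose
grid.  Treatment-planning physics (IMRT optimization, electron-return
effects, electron-density assignment) is deliberately out of scope; any
externally computed dose grid on the image geometry can be supplied.

The ROI layout follows the phantom study: a 2 x 2 cm central square plus
1 x 1 cm squares at 5, 10, 15 and 17 cm from the centre at the mark-point
angles (clockwise from +y), dropping positions lost to the stability cut —
4, 4, 3 and 2 squares respectively, 14 in total — plus a whole-phantom
region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.special import expit

from .distortion import DistortionModel, displacement_at
from .phantom import PhantomSpec, build_phantom
from .protocols import ScanProtocol

__all__ = [
    "SquareROI",
    "PhantomROI",
    "DoseGrid",
    "default_rois",
    "synthetic_dose",
    "mean_dose",
    "dose_change_rate",
    "dose_table",
    "field_from_model",
    "field_from_correspondences",
]

# displacement field: (x_mm, y_mm) arrays -> (dx_mm, dy_mm)
Field = Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class SquareROI:
    name: str
    cx_mm: float
    cy_mm: float
    half_mm: float

    def sample_points(self, spacing_mm: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Midpoint-rule sample grid; exact for linear dose fields."""
        n = max(4, int(np.ceil(2 * self.half_mm / spacing_mm)))
        step = 2 * self.half_mm / n
        c = -self.half_mm + step / 2 + step * np.arange(n)
        X, Y = np.meshgrid(self.cx_mm + c, self.cy_mm + c)
        return X.ravel(), Y.ravel()


@dataclass(frozen=True)
class PhantomROI:
    """Whole-phantom region: the cut disc of the grid area."""

    name: str
    radius_mm: float
    cut_offset_mm: float

    def sample_points(self, spacing_mm: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
        c = np.arange(-self.radius_mm + spacing_mm / 2, self.radius_mm, spacing_mm)
        X, Y = np.meshgrid(c, c)
        keep = (np.hypot(X, Y) <= self.radius_mm) & (Y >= -self.cut_offset_mm)
        return X[keep], Y[keep]


@dataclass
class DoseGrid:
    """A 2D transverse dose plane on the image geometry."""

    dose_gy: np.ndarray
    pixel_size_mm: float
    origin_mm: np.ndarray  # (x, y) of pixel (row 0, col 0) centre
    prescription_gy: float = 50.0

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if (self.dose_gy < 0).any():
            raise ValueError("dose must be non-negative")

    def sample(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        """Bilinear dose lookup at physical points."""
        col = (np.asarray(x_mm) - self.origin_mm[0]) / self.pixel_size_mm
        row = (np.asarray(y_mm) - self.origin_mm[1]) / self.pixel_size_mm
        eps = 1e-9
        if (
            (col < -0.5 - eps).any()
            or (row < -0.5 - eps).any()
            or (col > self.dose_gy.shape[1] - 0.5 + eps).any()
            or (row > self.dose_gy.shape[0] - 0.5 + eps).any()
        ):
            raise ValueError("sample points fall outside the dose grid")
        return ndi.map_coordinates(
            self.dose_gy, np.stack([row, col]), order=1, mode="nearest"
        )


_SQUARE_ANGLES = {
    "p1": (0.0, 90.0, 180.0, 270.0),
    "p2": (0.0, 90.0, 180.0, 270.0),
    "p3": (0.0, 90.0, 270.0),  # 180-degree position lost to the cut
    "p4": (0.0, 90.0),  # edge points; the cut side is unavailable
}
_SQUARE_RADII = {"p1": 50.0, "p2": 100.0, "p3": 150.0, "p4": 170.0}


def default_rois(spec: PhantomSpec | None = None) -> list:
    """The 14 square ROIs plus the whole-phantom region."""
    spec = spec or build_phantom()
    rois: list = [SquareROI("p", 0.0, 0.0, 10.0)]
    for ring in ("p1", "p2", "p3", "p4"):
        r = _SQUARE_RADII[ring]
        for i, a in enumerate(_SQUARE_ANGLES[ring], start=1):
            t = np.radians(a)
            rois.append(
                SquareROI(f"{ring.upper()}-{i}", r * np.sin(t), r * np.cos(t), 5.0)
            )
    rois.append(
        PhantomROI(
            "whole_phantom",
            radius_mm=spec.grid_inner_radius_mm,
            cut_offset_mm=spec.cut_chord_offset_mm,
        )
    )
    return rois


def synthetic_dose(
    protocol: ScanProtocol,
    prescription_gy: float = 50.0,
    target_radius_mm: float = 190.0,
    penumbra_mm: float = 15.0,
) -> DoseGrid:
    """Rotationally symmetric plateau dose with a sigmoidal penumbra.

    Dose is ``prescription * sigmoid((target_radius - r) / (penumbra / 8))``:
    flat at the prescription inside the target, monotonically falling
    through the penumbra, negligible far outside.  Deterministic.
    """
    if prescription_gy <= 0 or target_radius_mm <= 0 or penumbra_mm <= 0:
        raise ValueError("dose parameters must be positive")
    m = protocol.matrix
    px = protocol.pixel_size_mm
    c = (np.arange(m) - (m - 1) / 2) * px
    X, Y = np.meshgrid(c, c)
    r = np.hypot(X, Y)
    dose = prescription_gy * expit((target_radius_mm - r) / (penumbra_mm / 8.0))
    return DoseGrid(
        dose_gy=dose,
        pixel_size_mm=px,
        origin_mm=np.array([c[0], c[0]]),
        prescription_gy=prescription_gy,
    )


def mean_dose(grid: DoseGrid, roi) -> float:
    """Area-weighted mean dose over the ROI (midpoint quadrature on the
    bilinearly interpolated grid)."""
    x, y = roi.sample_points()
    return float(grid.sample(x, y).mean())


def dose_change_rate(grid: DoseGrid, roi, field: Field) -> float:
    """Percent change of the ROI mean dose under the displacement field.

    Every sample point of the ROI is displaced by the field before the dose
    lookup, so the rate captures exactly the geometric effect:
    ``100 * |mean(displaced) - mean(reference)| / mean(reference)``.
    """
    x, y = roi.sample_points()
    ref = float(grid.sample(x, y).mean())
    if ref == 0:
        raise ValueError("reference mean dose is zero")
    dx, dy = field(x, y)
    moved = float(grid.sample(x + dx, y + dy).mean())
    return 100.0 * abs(moved - ref) / ref


def zero_field(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.zeros_like(x), np.zeros_like(y)


def field_from_model(model: DistortionModel, protocol: ScanProtocol, z_mm: float = 0.0) -> Field:
    """In-plane displacement field of a parametric model at a fixed z."""

    def field(x, y):
        pts = np.column_stack(
            [np.asarray(x, dtype=float).ravel(), np.asarray(y, dtype=float).ravel(),
             np.full(np.asarray(x).size, z_mm)]
        )
        d = displacement_at(model, protocol, pts)
        return d[:, 0].reshape(np.shape(x)), d[:, 1].reshape(np.shape(x))

    return field


def field_from_correspondences(corr: pd.DataFrame) -> Field:
    """Linear interpolant of a measured displacement field.

    Built from matched control points (reference x, y; test x1, y1); zero
    outside the convex hull of the measurements.
    """
    from scipy.interpolate import LinearNDInterpolator

    pts = corr[["x", "y"]].to_numpy()
    dx = (corr["x1"] - corr["x"]).to_numpy()
    dy = (corr["y1"] - corr["y"]).to_numpy()
    fx = LinearNDInterpolator(pts, dx, fill_value=0.0)
    fy = LinearNDInterpolator(pts, dy, fill_value=0.0)

    def field(x, y):
        return fx(x, y), fy(x, y)

    return field


def dose_table(grid: DoseGrid, rois: Sequence, field: Field) -> pd.DataFrame:
    """Reference/displaced mean dose and change rate per ROI."""
    rows = []
    for roi in rois:
        x, y = roi.sample_points()
        ref = float(grid.sample(x, y).mean())
        dx, dy = field(x, y)
        moved = float(grid.sample(x + dx, y + dy).mean())
        rows.append(
            {
                "roi": roi.name,
                "reference_dose_gy": ref,
                "displaced_dose_gy": moved,
                "change_pct": 100.0 * abs(moved - ref) / ref if ref else np.nan,
            }
        )
    return pd.DataFrame(rows)
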
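"""Automatic control-point extraction from transverse phantom slices.

Grid intersections are the only repeated cross-shaped feature in the
phantom, so they are located by normalized cross-correlation with a cross
template whose arms span one cell.  Taking the absolute correlation makes
the detector contrast-agnostic: it works identically on the CT-role
rendering (walls bright) and the T2-role rendering (walls dark).  Peaks are
refined to sub-pixel precision by upsampling a local patch of the response
and fitting a quadratic to the maximum.

The central diamond marker is located the same way with a diamond template;
its position anchors the translation-only centre registration between the
reference and test images (valid because distortion vanishes at the
isocenter, where the marker is aligned).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import match_template, peak_local_max

from .phantom import NodeLattice, PhantomSpec
from .protocols import ScanProtocol
from .simulate import ImageVolume

__all__ = [
    "DetectedPoint",
    "CenterNotFoundError",
    "GridNotDetectedError",
    "find_center_marker",
    "detect_nodes",
    "match_nodes",
    "detect_slice",
]


class CenterNotFoundError(RuntimeError):
    """No diamond-like response above threshold."""


class GridNotDetectedError(RuntimeError):
    """Too few grid crossings found to form a lattice."""


@dataclass(frozen=True)
class DetectedPoint:
    x_mm: float
    y_mm: float
    z_mm: float
    response: float
    slice_index: int


def _template_grid(n_px: int, px: float, ss: int = 4) -> tuple[np.ndarray, np.ndarray]:
    half = (n_px - 1) / 2
    c = (np.arange(n_px * ss) / ss - half - 0.5 + 0.5 / ss) * px
    return np.meshgrid(c, c)


def _cross_template(spec: PhantomSpec, px: float) -> np.ndarray:
    """Cross with arm half-length cell_pitch/2 and arm width = wall."""
    arm = spec.cell_pitch_mm / 2
    n = 2 * int(round(arm / px)) + 1
    X, Y = _template_grid(n, px, ss=4)
    w = spec.wall_thickness_mm / 2
    cross = ((np.abs(X) <= w) & (np.abs(Y) <= arm)) | (
        (np.abs(Y) <= w) & (np.abs(X) <= arm)
    )
    ss = 4
    return cross.astype(float).reshape(n, ss, n, ss).mean(axis=(1, 3))


def _diamond_template(spec: PhantomSpec, px: float) -> np.ndarray:
    half = spec.diamond_halfwidth_mm
    n = 2 * int(round(1.4 * half / px)) + 1
    X, Y = _template_grid(n, px, ss=4)
    diamond = (np.abs(X) + np.abs(Y)) <= half
    ss = 4
    return diamond.astype(float).reshape(n, ss, n, ss).mean(axis=(1, 3))


def _quadratic_peak_2d(patch: np.ndarray) -> tuple[float, float]:
    """Sub-sample offset of the extremum of a 3x3 patch around its centre."""

    def axis_offset(m1: float, c: float, p1: float) -> float:
        denom = m1 - 2 * c + p1
        if denom == 0:
            return 0.0
        off = 0.5 * (m1 - p1) / denom
        return float(np.clip(off, -0.5, 0.5))

    dr = axis_offset(patch[0, 1], patch[1, 1], patch[2, 1])
    dc = axis_offset(patch[1, 0], patch[1, 1], patch[1, 2])
    return dr, dc


def _refine_peak(resp: np.ndarray, row: int, col: int, upsample: int) -> tuple[float, float]:
    """Sub-pixel peak location (row, col) in original pixel units."""
    if upsample <= 1:
        r0, c0 = row, col
        if 0 < row < resp.shape[0] - 1 and 0 < col < resp.shape[1] - 1:
            dr, dc = _quadratic_peak_2d(resp[row - 1 : row + 2, col - 1 : col + 2])
            return row + dr, col + dc
        return float(row), float(col)
    h = 3
    r0 = max(row - h, 0)
    c0 = max(col - h, 0)
    patch = resp[r0 : row + h + 1, c0 : col + h + 1]
    up = ndi.zoom(patch, upsample, order=3, grid_mode=True, mode="nearest")
    rr, cc = np.unravel_index(np.argmax(up), up.shape)
    rr = int(np.clip(rr, 1, up.shape[0] - 2))
    cc = int(np.clip(cc, 1, up.shape[1] - 2))
    dr, dc = _quadratic_peak_2d(up[rr - 1 : rr + 2, cc - 1 : cc + 2])
    # grid_mode zoom maps original index i to i * upsample + (upsample - 1) / 2
    row_f = r0 + (rr + dr - (upsample - 1) / 2) / upsample
    col_f = c0 + (cc + dc - (upsample - 1) / 2) / upsample
    return row_f, col_f


def _response(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    ncc = match_template(img, template, pad_input=True, mode="constant")
    return np.abs(ncc)


def _slice_geometry(volume_or_image, protocol: ScanProtocol, slice_index: int):
    if isinstance(volume_or_image, ImageVolume):
        vol = volume_or_image
        img = vol.data[slice_index]
        x0, y0 = vol.origin_mm[0], vol.origin_mm[1]
        px = vol.pixel_size_mm
        z = vol.slice_z_mm(slice_index)
    else:
        img = np.asarray(volume_or_image)
        px = protocol.pixel_size_mm
        m = img.shape
        x0 = -(m[1] - 1) / 2 * px
        y0 = -(m[0] - 1) / 2 * px
        z = 0.0
    return img, px, x0, y0, z


def find_center_marker(
    image,
    spec: PhantomSpec,
    protocol: ScanProtocol,
    slice_index: int = 0,
    threshold: float = 0.45,
    upsample: int = 4,
) -> DetectedPoint:
    """Locate the central diamond marker at sub-pixel precision.

    ``image`` may be a 2D array (assumed centred on the FOV) or an
    :class:`ImageVolume` with ``slice_index``.

    Raises
    ------
    CenterNotFoundError
        If the best diamond response falls below ``threshold``.
    """
    img, px, x0, y0, z = _slice_geometry(image, protocol, slice_index)
    resp = _response(img, _diamond_template(spec, px))
    row, col = np.unravel_index(np.argmax(resp), resp.shape)
    if resp[row, col] < threshold:
        raise CenterNotFoundError(
            f"best diamond response {resp[row, col]:.3f} below {threshold}"
        )
    rf, cf = _refine_peak(resp, int(row), int(col), upsample)
    return DetectedPoint(
        x_mm=x0 + cf * px,
        y_mm=y0 + rf * px,
        z_mm=z,
        response=float(resp[row, col]),
        slice_index=slice_index,
    )


def detect_nodes(
    image,
    spec: PhantomSpec,
    protocol: ScanProtocol,
    upsample: int = 4,
    slice_index: int = 0,
    threshold: float = 0.25,
) -> list[DetectedPoint]:
    """Detect grid crossings in one transverse slice.

    Local maxima of the absolute cross-template correlation, with
    non-maximum suppression within half a cell pitch, refined to sub-pixel.
    Crossings whose template window exits the image are skipped.

    Raises
    ------
    GridNotDetectedError
        When fewer than 9 crossings are found.
    """
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    img, px, x0, y0, z = _slice_geometry(image, protocol, slice_index)
    template = _cross_template(spec, px)
    resp = _response(img, template)
    min_dist = max(1, int(round(0.45 * spec.cell_pitch_mm / px)))
    border = template.shape[0] // 2
    peaks = peak_local_max(
        resp,
        min_distance=min_dist,
        threshold_abs=threshold,
        exclude_border=border,
    )
    points = []
    for row, col in peaks:
        rf, cf = _refine_peak(resp, int(row), int(col), upsample)
        points.append(
            DetectedPoint(
                x_mm=x0 + cf * px,
                y_mm=y0 + rf * px,
                z_mm=z,
                response=float(resp[row, col]),
                slice_index=slice_index,
            )
        )
    if len(points) < 9:
        raise GridNotDetectedError(f"only {len(points)} grid crossings found")
    return points


def match_nodes(
    detected: list[DetectedPoint],
    lattice: NodeLattice,
    center: DetectedPoint,
    gate_mm: float | None = None,
) -> pd.DataFrame:
    """Pair lattice nodes with detected points after centre registration.

    Detected coordinates are translated so the detected centre marker maps
    to (0, 0); each lattice node is then paired to the nearest detected
    point within ``gate_mm`` (default: half the cell pitch), one-to-one,
    greedily by ascending pair distance.

    Returns a DataFrame with one row per *lattice node*:
    ``node_id, x, y, x_det, y_det, pair_dist, matched`` — unmatched nodes
    keep NaN detected coordinates.
    """
    if gate_mm is None:
        gate_mm = lattice.pitch_mm / 2
    det = np.array([[p.x_mm - center.x_mm, p.y_mm - center.y_mm] for p in detected])
    n_nodes = lattice.n_nodes
    out = pd.DataFrame(
        {
            "node_id": np.arange(n_nodes),
            "x": lattice.nodes[:, 0],
            "y": lattice.nodes[:, 1],
            "x_det": np.full(n_nodes, np.nan),
            "y_det": np.full(n_nodes, np.nan),
            "pair_dist": np.full(n_nodes, np.nan),
        }
    )
    if len(det):
        tree = cKDTree(det)
        pairs = tree.query_ball_point(lattice.nodes, r=gate_mm)
        cand = [
            (float(np.hypot(*(det[j] - lattice.nodes[i]))), i, j)
            for i, js in enumerate(pairs)
            for j in js
        ]
        cand.sort()
        used_nodes: set[int] = set()
        used_det: set[int] = set()
        for dist, i, j in cand:
            if i in used_nodes or j in used_det:
                continue
            used_nodes.add(i)
            used_det.add(j)
            out.loc[i, ["x_det", "y_det", "pair_dist"]] = (det[j, 0], det[j, 1], dist)
    out["matched"] = out["pair_dist"].notna()
    return out


def detect_slice(
    volume: ImageVolume,
    slice_index: int,
    spec: PhantomSpec,
    protocol: ScanProtocol,
    lattice: NodeLattice,
    upsample: int = 4,
) -> pd.DataFrame:
    """Convenience: centre + crossings + matching for one slice.

    The centre-marker position is appended as a detected point for the
    (0, 0) node, since the solid diamond hides that crossing.
    """
    center = find_center_marker(volume, spec, protocol, slice_index=slice_index)
    points = detect_nodes(
        volume, spec, protocol, upsample=upsample, slice_index=slice_index
    )
    near_center = [
        p for p in points if np.hypot(p.x_mm - center.x_mm, p.y_mm - center.y_mm)
        < lattice.pitch_mm / 2
    ]
    points = [p for p in points if p not in near_center] + [center]
    matched = match_nodes(points, lattice, center)
    matched["z"] = volume.slice_z_mm(slice_index)
    matched["slice_index"] = slice_index
    return matched
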
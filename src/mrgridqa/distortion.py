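"""Parametric geometric-distortion fields.

The displacement seen in an MR image is modelled as the sum of two
system-dependent terms:

* **gradient nonlinearity (GNL)** — a smooth polynomial displacement field
  ``d_gnl(x, y, z)`` in mm, one polynomial per output axis, that vanishes at
  the isocenter and grows with distance from it;
* **B0 inhomogeneity** — a smooth off-resonance map ``dB0(x, y, z)`` in Hz
  that shifts image content along the frequency-encode axis by
  ``dB0 / pixel_bandwidth`` pixels, i.e. by
  ``dB0 / bw * pixel_size`` mm.

Both terms are zero at the isocenter, which is where the phantom's diamond
marker is aligned; that is what makes translation-only centre registration
of the measured images valid.

Polynomials are stored as ``{(i, j, k): coeff}`` monomial maps for
``x**i * y**j * z**k``; this keeps the field analytic so ground-truth
displacements are exact at any point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .protocols import ScanProtocol

__all__ = [
    "DistortionModel",
    "displacement_at",
    "zero_model",
    "radial_model",
]

Poly = Dict[Tuple[int, int, int], float]


def _eval_poly(poly: Poly, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    out = np.zeros(np.broadcast(x, y, z).shape, dtype=float)
    for (i, j, k), c in poly.items():
        if c == 0.0:
            continue
        term = c
        if i:
            term = term * x**i
        if j:
            term = term * y**j
        if k:
            term = term * z**k
        out += term
    return out


@dataclass(frozen=True)
class DistortionModel:
    """GNL polynomials per output axis plus a B0 off-resonance polynomial.

    ``seed`` controls only the reproducibility of rendering noise; the field
    itself is deterministic.
    """

    gnl: Dict[str, Poly] = field(default_factory=dict)
    b0_hz: Poly = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for axis, poly in self.gnl.items():
            if axis not in ("x", "y", "z"):
                raise ValueError(f"unknown gnl axis {axis!r}")
            if poly.get((0, 0, 0), 0.0) != 0.0:
                raise ValueError("gnl displacement must vanish at the isocenter")
        if self.b0_hz.get((0, 0, 0), 0.0) != 0.0:
            raise ValueError("B0 map must vanish at the isocenter")

    @property
    def is_zero(self) -> bool:
        return all(
            all(c == 0.0 for c in poly.values()) for poly in self.gnl.values()
        ) and all(c == 0.0 for c in self.b0_hz.values())

    def scaled(self, factor: float) -> "DistortionModel":
        """Scale every GNL coefficient (B0 untouched)."""
        return DistortionModel(
            gnl={
                ax: {p: c * factor for p, c in poly.items()}
                for ax, poly in self.gnl.items()
            },
            b0_hz=dict(self.b0_hz),
            seed=self.seed,
        )


def displacement_at(
    model: DistortionModel,
    protocol: ScanProtocol,
    points,
) -> np.ndarray:
    """Displacement (dx, dy, dz) in mm at one or more (x, y, z) points.

    The B0 term acts along the protocol's frequency-encode axis only and
    scales inversely with pixel bandwidth:
    ``d_b0 = dB0(p) / bw * pixel_size``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    d = np.zeros_like(pts)
    for idx, axis in enumerate("xyz"):
        poly = model.gnl.get(axis)
        if poly:
            d[:, idx] += _eval_poly(poly, x, y, z)
    if model.b0_hz:
        shift_mm = (
            _eval_poly(model.b0_hz, x, y, z)
            / protocol.pixel_bandwidth_hz_per_px
            * protocol.pixel_size_mm
        )
        d[:, "xy".index(protocol.freq_encode_axis)] += shift_mm
    return d if np.asarray(points).ndim > 1 else d[0]


def zero_model(seed: int = 0) -> DistortionModel:
    """The null field: a perfectly faithful scanner."""
    return DistortionModel(gnl={}, b0_hz={}, seed=seed)


def radial_model(
    max_gnl_mm: float,
    r_ref_mm: float = 170.0,
    cubic_fraction: float = 0.7,
    b0_max_hz: float = 0.0,
    dz_max_mm: float = 0.0,
    z_half_mm: float = 110.0,
    seed: int = 0,
) -> DistortionModel:
    """Odd-order radially growing GNL field plus a quadratic B0 map.

    The in-plane GNL displacement points radially outward with magnitude

        |d|(r) = max_gnl_mm * (w3 * u**3 + w5 * u**5),   u = r / r_ref_mm,

    with ``w3 = cubic_fraction`` and ``w5 = 1 - w3``, so the maximum in-plane
    displacement at ``r = r_ref_mm`` equals ``max_gnl_mm`` exactly.  Written
    per axis this is the degree-5 odd polynomial
    ``d_x = a3 * x * r**2 + a5 * x * r**4`` (r taken in-plane), and likewise
    for y, so it is representable exactly in the monomial map.

    ``dz_max_mm`` adds a through-plane term ``dz = dz_max * (z/z_half) * u**2``
    reaching ``dz_max_mm`` at (r_ref, z_half).  ``b0_max_hz`` adds an
    off-resonance map ``dB0 = b0_max_hz * u**2``.
    """
    w3 = cubic_fraction
    w5 = 1.0 - cubic_fraction
    a3 = max_gnl_mm * w3 / r_ref_mm**3
    a5 = max_gnl_mm * w5 / r_ref_mm**5
    gnl: Dict[str, Poly] = {}
    for axis, lead in (("x", (1, 0)), ("y", (0, 1))):
        i0, j0 = lead
        poly: Poly = {
            # a3 * v * (x^2 + y^2)
            (i0 + 2, j0 + 0, 0): a3,
            (i0 + 0, j0 + 2, 0): a3,
            # a5 * v * (x^2 + y^2)^2
            (i0 + 4, j0 + 0, 0): a5,
            (i0 + 0, j0 + 4, 0): a5,
            (i0 + 2, j0 + 2, 0): 2 * a5,
        }
        gnl[axis] = poly
    if dz_max_mm:
        cz = dz_max_mm / (z_half_mm * r_ref_mm**2)
        gnl["z"] = {(2, 0, 1): cz, (0, 2, 1): cz}
    b0: Poly = {}
    if b0_max_hz:
        cb = b0_max_hz / r_ref_mm**2
        b0 = {(2, 0, 0): cb, (0, 2, 0): cb}
    return DistortionModel(gnl=gnl, b0_hz=b0, seed=seed)
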
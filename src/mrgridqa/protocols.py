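"""Scanner acquisition protocols.

Each protocol captures the geometry-relevant acquisition parameters of one
scanner: square field of view, in-plane matrix, pixel bandwidth (which sets
the off-resonance displacement per Hz), slice thickness and the
frequency-encode axis.  Presets mirror the three systems the phantom was
scanned on: the Elekta Unity MR-Linac (1.5 T), a GE Signa HDe (1.5 T) and a
GE Discovery 750 (3.0 T).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["ScanProtocol", "protocol_preset", "PRESETS"]


@dataclass(frozen=True)
class ScanProtocol:
    name: str
    fov_mm: float
    matrix: int
    pixel_bandwidth_hz_per_px: float
    slice_thickness_mm: float
    n_slices: int
    freq_encode_axis: str = "x"

    def __post_init__(self) -> None:
        if self.fov_mm <= 0 or self.matrix <= 0:
            raise ValueError("fov_mm and matrix must be positive")
        if self.pixel_bandwidth_hz_per_px <= 0:
            raise ValueError("pixel bandwidth must be positive")
        if self.freq_encode_axis not in ("x", "y"):
            raise ValueError("freq_encode_axis must be 'x' or 'y'")

    @property
    def pixel_size_mm(self) -> float:
        return self.fov_mm / self.matrix

    def replace(self, **kw) -> "ScanProtocol":
        return dataclasses.replace(self, **kw)


# The Unity acquisition is a 3D series without a meaningful 2D slice
# thickness; it is emulated as contiguous 1.6 mm partitions.  Default slice
# counts are the largest multiple of 30 that fits the 220 mm phantom, since
# the layer-tracking rule expects a multiple of 30 layers.
PRESETS = {
    "unity": ScanProtocol(
        name="unity",
        fov_mm=537.6,
        matrix=1008,
        pixel_bandwidth_hz_per_px=1033.0,
        slice_thickness_mm=1.6,
        n_slices=120,
    ),
    "ge_hde": ScanProtocol(
        name="ge_hde",
        fov_mm=480.0,
        matrix=512,
        pixel_bandwidth_hz_per_px=195.31,
        slice_thickness_mm=5.0,
        n_slices=30,
    ),
    "ge_750": ScanProtocol(
        name="ge_750",
        fov_mm=500.0,
        matrix=512,
        pixel_bandwidth_hz_per_px=195.31,
        slice_thickness_mm=3.0,
        n_slices=60,
    ),
}


def protocol_preset(name: str, **overrides) -> ScanProtocol:
    """Return a scanner preset by name, optionally overriding fields."""
    try:
        proto = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown protocol {name!r}; known: {sorted(PRESETS)}"
        ) from None
    return proto.replace(**overrides) if overrides else proto
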
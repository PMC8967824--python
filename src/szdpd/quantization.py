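"""Lossy m/z quantization at a fixed decimal precision.

A centroided m/z axis is stored as unsigned integers ``round_half_up(mz * 10**dp)``
with ``dp`` decimal places; 4 dp corresponds to roughly 1 ppm mass accuracy for
a 10 Da reference, 5 dp to 0.1 ppm.  Rounding is half-up on the *shortest
decimal representation* of each float (the number a user sees when the value is
printed), which makes the mapping deterministic and independent of binary
representation artifacts.  The inverse mapping divides by the scale, so the
absolute reconstruction error is bounded by ``0.5 * 10**-dp`` relative to the
printed decimal value (at most one float ulp more relative to the binary
double).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import ConfigError, InvalidInputError, UnsortedInputError

__all__ = ["PrecisionConfig", "quantize_mz", "dequantize_mz", "sort_spectrum"]

_PPM_LABELS = {4: "1 ppm", 5: "0.1 ppm", 6: "0.01 ppm"}


@dataclass(frozen=True)
class PrecisionConfig:
    """Decimal precision for integer m/z storage.

    Parameters
    ----------
    decimal_places : int
        Number of decimal places preserved; one of 4, 5 or 6.
    """

    decimal_places: int = 5
    scale: int = field(init=False)
    ppm_label: str = field(init=False)

    def __post_init__(self) -> None:
        if self.decimal_places not in (4, 5, 6):
            raise ConfigError(
                f"decimal_places must be 4, 5 or 6, got {self.decimal_places!r}"
            )
        object.__setattr__(self, "scale", 10**self.decimal_places)
        object.__setattr__(self, "ppm_label", _PPM_LABELS[self.decimal_places])


def _decimal_half_up(x: float, scale: int) -> int:
    # exact decimal arithmetic on the shortest repr of the float
    return int(
        (Decimal(repr(float(x))) * scale).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    )


def quantize_mz(mz, cfg: PrecisionConfig) -> np.ndarray:
    """Convert a non-decreasing float m/z array to scaled unsigned integers.

    Values are multiplied by ``cfg.scale`` and rounded half-up.  The bulk of
    the array goes through a vectorized float64 path; elements whose scaled
    value lands within a few ulp of a half-way point are re-rounded with exact
    decimal arithmetic so the result always matches the printed-decimal rule.

    Raises
    ------
    InvalidInputError
        If any value is negative, NaN or infinite (the offending index is named).
    UnsortedInputError
        If the input is not non-decreasing.
    """
    a = np.asarray(mz, dtype=np.float64)
    if a.ndim != 1:
        raise InvalidInputError(f"m/z array must be 1-D, got shape {a.shape}")
    if a.size == 0:
        return np.empty(0, dtype=np.uint64)
    bad = ~np.isfinite(a) | (a < 0)
    if bad.any():
        i = int(np.argmax(bad))
        raise InvalidInputError(f"non-finite or negative m/z {a[i]!r} at index {i}")
    if a.size > 1 and np.any(np.diff(a) < 0):
        i = int(np.argmax(np.diff(a) < 0))
        raise UnsortedInputError(
            f"m/z array decreases at index {i + 1} ({a[i + 1]!r} < {a[i]!r}); "
            "sort with sort_spectrum first"
        )
    scale = cfg.scale
    y = a * scale
    shifted = y + 0.5
    q = np.floor(shifted)
    # half-way ambiguity: the float product may sit a few ulp on the wrong
    # side of an integer boundary; re-round those exactly
    near = np.abs(shifted - np.round(shifted)) <= 8 * np.spacing(np.maximum(shifted, 1.0))
    if near.any():
        idx = np.nonzero(near)[0]
        q[idx] = [_decimal_half_up(a[i], scale) for i in idx]
    return q.astype(np.uint64)


def dequantize_mz(q, cfg: PrecisionConfig) -> np.ndarray:
    """Map quantized integers back to float m/z (divide by the scale)."""
    a = np.asarray(q, dtype=np.uint64)
    return a.astype(np.float64) / cfg.scale


def sort_spectrum(mz, intensity):
    """Stable-sort an (m/z, intensity) pair list by m/z.

    Returns new arrays; ties keep their original relative order so repeated
    centroids stay deterministic.
    """
    m = np.asarray(mz, dtype=np.float64)
    i = np.asarray(intensity, dtype=np.float64)
    if m.shape != i.shape or m.ndim != 1:
        raise InvalidInputError(
            f"m/z and intensity must be 1-D arrays of equal length, got {m.shape} and {i.shape}"
        )
    order = np.argsort(m, kind="stable")
    return m[order], i[order]
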
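"""Suitability-to-resistance conversion.

Movement resistance is derived from habitat suitability ``h`` in [0, 1] by
the negative-exponential transform

    R(h) = 100 - 99 * (1 - exp(-c * h)) / (1 - exp(-c))

so that perfectly suitable habitat has resistance 1, wholly unsuitable
habitat 100, and the exponent magnitude ``c`` controls how quickly
resistance falls as suitability rises.  Small ``c`` (e.g. 0.25) keeps the
transform near-linear — a species reluctant to leave suitable habitat
experiences strong resistance at intermediate suitability — while large
``c`` (4, 8, ...) drops resistance sharply, modelling vagile species that
move readily through moderately suitable land.  As c -> 0 the transform
approaches the linear map 100 - 99*h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import Raster

__all__ = ["SpeciesMovementProfile", "suitability_to_resistance", "ALLOWED_EXPONENTS"]

#: Exponent magnitudes in routine use; other positive values are accepted
#: via ``strict=False``.
ALLOWED_EXPONENTS = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)


@dataclass
class SpeciesMovementProfile:
    """Species identifier plus the resistance-transform exponent magnitude."""

    species_id: str
    c: float
    strict: bool = True

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("exponent magnitude c must be positive")
        if self.strict and self.c not in ALLOWED_EXPONENTS:
            raise ValueError(f"exponent {self.c} not in allowed set {ALLOWED_EXPONENTS}")


def suitability_to_resistance(h: Raster, profile: SpeciesMovementProfile) -> Raster:
    """Apply the negative-exponential transform to a suitability surface.

    ``h`` must lie in [0, 1] (nodata cells pass through unchanged); output
    lies in [1, 100] and is strictly decreasing in ``h``.
    """
    vals = np.asarray(h.values, dtype=float)
    valid = h.valid_mask()
    hv = vals[valid]
    if hv.size and (hv.min() < 0 or hv.max() > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    c = profile.c
    out = np.full(vals.shape, float(h.nodata))
    out[valid] = 100.0 - 99.0 * (1.0 - np.exp(-c * hv)) / (1.0 - np.exp(-c))
    return h.copy_with(out)
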
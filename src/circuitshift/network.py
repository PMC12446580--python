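"""Scenario comparison and connectivity-network classification.

Per-species normalised current maps are stacked (summed) into an
all-species connectivity surface per climate scenario.  Scenario surfaces
are compared on a common scale by *relative standardisation*: every
scenario is converted to z-units of the reference (current-climate)
surface,

    z_i = (v_i - xbar) / sigma_x

with ``xbar`` and ``sigma_x`` the reference surface's mean and standard
deviation (population denominator), so the reference itself standardises
to mean 0, sd 1, and a future cell value of +2 reads as "two reference
standard deviations above the contemporary average".

The connectivity network is built from each scenario's top decile of
standardised connectivity: cells in the top decile of all three periods
are *permanent* connectivity; cells in the decile of two consecutive
periods (current & 2050, or 2050 & 2090) are *stepping stones*; decile
cells of a single period, or of current & 2090 only (no pathway through
2050), are *impermanent* and excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .circuit import CurrentMap
from .raster import Raster

__all__ = [
    "StandardisedSurface",
    "SummaryStats",
    "NetworkClass",
    "NetworkClassMap",
    "stack_species",
    "relative_standardise",
    "summary_stats",
    "surface_correlation",
    "top_decile_mask",
    "classify_network",
]


class NetworkClass(IntEnum):
    """Integer codes for the network classification raster."""

    NONE = 0
    PERMANENT = 1
    STEPPING_C50 = 2
    STEPPING_5090 = 3
    IMPERMANENT = 4


@dataclass
class StandardisedSurface:
    """A connectivity surface in z-units of the reference scenario."""

    z: Raster
    reference_mean: float
    reference_sd: float
    scenario: str = "current"


@dataclass
class SummaryStats:
    """Moment-based summary of a surface (population moments, excess kurtosis)."""

    min: float
    max: float
    range: float
    mean: float
    sd: float
    variance: float
    skewness: float
    kurtosis: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "Min": self.min,
                "Max": self.max,
                "Range": self.range,
                "Mean": self.mean,
                "Standard deviation": self.sd,
                "Variance": self.variance,
                "Skewness": self.skewness,
                "Kurtosis": self.kurtosis,
            }
        )


def stack_species(maps: list[CurrentMap | Raster]) -> Raster:
    """Cell-wise sum of species connectivity maps; nodata propagates."""
    if not maps:
        raise ValueError("need at least one map")
    rasters = [m.raster if isinstance(m, CurrentMap) else m for m in maps]
    ref = rasters[0]
    for r in rasters[1:]:
        if not r.same_geometry(ref):
            raise ValueError("species maps have mismatched geometries")
    total = np.zeros(ref.shape)
    invalid = np.zeros(ref.shape, dtype=bool)
    for r in rasters:
        invalid |= ~r.valid_mask()
        total += np.where(r.valid_mask(), r.values.astype(float), 0.0)
    total[invalid] = ref.nodata
    return ref.copy_with(total)


def _ref_moments(reference: Raster | tuple[float, float]) -> tuple[float, float]:
    if isinstance(reference, Raster):
        vals = reference.valid_values().astype(float)
        return float(vals.mean()), float(vals.std())  # population sd
    mean, sd = reference
    return float(mean), float(sd)


def relative_standardise(
    surface: Raster, reference: Raster | tuple[float, float], scenario: str = "current"
) -> StandardisedSurface:
    """Express ``surface`` in z-units of the reference surface.

    ``reference`` is either the reference-scenario raster or a
    ``(mean, sd)`` pair (population sd).  Standardising the reference by
    itself yields mean 0 and sd 1 exactly.
    """
    mean, sd = _ref_moments(reference)
    if sd <= 0:
        raise ValueError("reference surface is constant (sd = 0)")
    vals = np.asarray(surface.values, dtype=float)
    valid = surface.valid_mask()
    z = np.where(valid, (vals - mean) / sd, surface.nodata)
    return StandardisedSurface(z=surface.copy_with(z), reference_mean=mean, reference_sd=sd, scenario=scenario)


def summary_stats(z: StandardisedSurface | Raster) -> SummaryStats:
    """Min/max/range, mean, sd, variance, skewness and excess kurtosis.

    Population (N-denominator) moments; kurtosis is excess (normal = 0).
    """
    raster = z.z if isinstance(z, StandardisedSurface) else z
    vals = raster.valid_values().astype(float)
    if vals.size < 2:
        raise ValueError("need at least 2 valid cells")
    m = vals.mean()
    d = vals - m
    m2 = np.mean(d**2)
    m3 = np.mean(d**3)
    m4 = np.mean(d**4)
    sd = math.sqrt(m2)
    return SummaryStats(
        min=float(vals.min()),
        max=float(vals.max()),
        range=float(vals.max() - vals.min()),
        mean=float(m),
        sd=float(sd),
        variance=float(m2),
        skewness=float(m3 / m2**1.5) if m2 > 0 else 0.0,
        kurtosis=float(m4 / m2**2 - 3.0) if m2 > 0 else 0.0,
    )


def surface_correlation(a: Raster, b: Raster) -> float:
    """Pearson correlation between two surfaces over jointly valid cells."""
    if a.shape != b.shape:
        raise ValueError("surfaces must share geometry")
    mask = a.valid_mask() & b.valid_mask()
    if mask.sum() < 2:
        raise ValueError("need at least 2 jointly valid cells")
    va = a.values[mask].astype(float)
    vb = b.values[mask].astype(float)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("constant surface: correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def top_decile_mask(z: StandardisedSurface | Raster, decile: float = 0.9) -> Raster:
    """Binary mask of the top ``1 - decile`` fraction of cells by value.

    Exactly ``ceil((1 - decile) * N)`` valid cells are selected — the
    highest-valued ones, with ties broken by row-major cell order — so
    every scenario's mask covers the same amount of space.
    """
    raster = z.z if isinstance(z, StandardisedSurface) else z
    valid = raster.valid_mask()
    n = int(valid.sum())
    if n == 0:
        raise ValueError("all-nodata surface")
    k = math.ceil((1 - decile) * n)
    flat_idx = np.nonzero(valid.ravel())[0]
    vals = raster.values.ravel()[flat_idx].astype(float)
    # primary: value descending; secondary: row-major position ascending
    order = np.lexsort((flat_idx, -vals))
    chosen = flat_idx[order[:k]]
    mask = np.zeros(raster.shape[0] * raster.shape[1], dtype=np.int32)
    mask[chosen] = 1
    out = mask.reshape(raster.shape)
    return Raster(out, cell_size=raster.cell_size, origin=raster.origin, nodata=-9999)


@dataclass
class NetworkClassMap:
    """Per-cell network class labels (see :class:`NetworkClass`)."""

    raster: Raster

    def network_mask(self) -> np.ndarray:
        """Cells belonging to the connectivity network (permanent + stepping stones)."""
        v = self.raster.values
        return np.isin(v, [NetworkClass.PERMANENT, NetworkClass.STEPPING_C50, NetworkClass.STEPPING_5090])

    def class_counts(self) -> dict[str, int]:
        v = self.raster.values
        return {cls.name.lower(): int(np.sum(v == cls)) for cls in NetworkClass}

    def legend(self) -> dict[int, str]:
        return {int(cls): cls.name.lower() for cls in NetworkClass}


def classify_network(mask_current: Raster, mask_2050: Raster, mask_2090: Raster) -> NetworkClassMap:
    """Classify cells from the three scenarios' top-decile masks.

    Truth table over (current, 2050, 2090) membership:
    (1,1,1) permanent; (1,1,0) stepping stone current & 2050;
    (0,1,1) stepping stone 2050 & 2090; (0,0,0) none; everything else —
    single-period cells and current & 2090 without 2050 — impermanent.
    """
    if not (mask_current.same_geometry(mask_2050) and mask_current.same_geometry(mask_2090)):
        raise ValueError("masks have mismatched geometries")
    a = np.asarray(mask_current.values) == 1
    b = np.asarray(mask_2050.values) == 1
    c = np.asarray(mask_2090.values) == 1
    out = np.full(a.shape, int(NetworkClass.IMPERMANENT), dtype=np.int32)
    out[a & b & c] = NetworkClass.PERMANENT
    out[a & b & ~c] = NetworkClass.STEPPING_C50
    out[~a & b & c] = NetworkClass.STEPPING_5090
    out[~a & ~b & ~c] = NetworkClass.NONE
    raster = Raster(out, cell_size=mask_current.cell_size, origin=mask_current.origin, nodata=-9999)
    return NetworkClassMap(raster=raster)
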
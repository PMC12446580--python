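"""Zonal reporting: ranking zones, protected-area overlap and landcover tallies.

The classified connectivity network is summarised against three reporting
rasters: zone partitions (ranked by the proportion of each zone inside
the network), a binary protected-area mask (how much of the network is
already protected), and categorical landcover (what the network is made
of, inside and outside protection).  Areas are cell counts times the
cell area, reported in hectares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import NetworkClassMap
from .raster import Raster

__all__ = ["rank_zones", "protected_overlap", "landcover_tally"]


def _cell_area_ha(raster: Raster) -> float:
    return raster.cell_size**2 / 1e4


def _network_mask(network: NetworkClassMap, reference: Raster) -> np.ndarray:
    if network.raster.shape != reference.shape:
        raise ValueError("network and reporting raster have mismatched geometries")
    return network.network_mask()


def rank_zones(network: NetworkClassMap, zones: Raster) -> pd.DataFrame:
    """Per-zone network area and dense rank by proportion of zone area.

    Returns columns ``zone_id, zone_area_ha, network_area_ha, proportion,
    rank`` with rank 1 the highest proportion; tied proportions share a
    rank (dense ranking).
    """
    net = _network_mask(network, zones)
    cell_ha = _cell_area_ha(zones)
    zvals = np.asarray(zones.values)
    zvalid = zones.valid_mask()
    ids = np.unique(zvals[zvalid]).astype(int)
    rows = []
    for zid in ids:
        in_zone = (zvals == zid) & zvalid
        zone_cells = int(in_zone.sum())
        net_cells = int((in_zone & net).sum())
        rows.append(
            {
                "zone_id": zid,
                "zone_area_ha": zone_cells * cell_ha,
                "network_area_ha": net_cells * cell_ha,
                "proportion": net_cells / zone_cells if zone_cells else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    table["rank"] = table["proportion"].rank(method="dense", ascending=False).astype(int)
    return table.sort_values(["rank", "zone_id"]).reset_index(drop=True)


def protected_overlap(network: NetworkClassMap, protected: Raster) -> tuple[float, float, float]:
    """Split the network by the protection mask.

    Returns ``(inside_ha, outside_ha, inside_fraction)``.  An empty
    network yields fraction 0 with a warning.
    """
    import warnings

    net = _network_mask(network, protected)
    cell_ha = _cell_area_ha(protected)
    prot = np.asarray(protected.values) == 1
    inside = int((net & prot).sum())
    outside = int((net & ~prot).sum())
    total = inside + outside
    if total == 0:
        warnings.warn("empty connectivity network: protected fraction undefined, reporting 0", stacklevel=2)
        return 0.0, 0.0, 0.0
    return inside * cell_ha, outside * cell_ha, inside / total


def landcover_tally(network: NetworkClassMap, landcover: Raster, protected: Raster) -> pd.DataFrame:
    """Cross-tabulate network cells by landcover class and protection flag.

    Returns columns ``landcover_class, area_outside_ha, area_inside_ha``
    (hectares); rows sum to the total network area.
    """
    net = _network_mask(network, landcover)
    if landcover.shape != protected.shape:
        raise ValueError("landcover and protected rasters have mismatched geometries")
    cell_ha = _cell_area_ha(landcover)
    lc = np.asarray(landcover.values)
    prot = np.asarray(protected.values) == 1
    lvalid = landcover.valid_mask()
    classes = np.unique(lc[lvalid]).astype(int)
    rows = []
    for cls in classes:
        in_cls = (lc == cls) & lvalid & net
        rows.append(
            {
                "landcover_class": cls,
                "area_outside_ha": int((in_cls & ~prot).sum()) * cell_ha,
                "area_inside_ha": int((in_cls & prot).sum()) * cell_ha,
            }
        )
    return pd.DataFrame(rows)
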
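"""Zone selectivity via the Vanderploeg–Scavia electivity index.

For each zone ``i`` with observed use ``r_i`` (proportion of location fixes
in the zone) and expected use ``p_i`` (the zone's share of the surface
area), the selectivity coefficient is

    W_i = (r_i / p_i) / sum_j (r_j / p_j),

and the electivity index

    E*_i = (W_i - 1/n) / (W_i + 1/n),

with ``n`` the number of zones.  E* is 0 for use proportional to
availability, -1 for total avoidance, and approaches (1 - 1/n)/(1 + 1/n)
for exclusive use of a single zone; zones with positive E* are read as
preferred.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import SurfacePoint, ZonePartition, point_in_zone

__all__ = [
    "ZeroAvailabilityError",
    "electivity_index",
    "mean_electivity",
    "selectivity_weights",
    "zone_use",
]


class ZeroAvailabilityError(ValueError):
    """A zone with zero expected use must be removed before analysis."""


def selectivity_weights(r: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Selectivity coefficients W_i = (r_i/p_i) / sum_j(r_j/p_j).

    ``r`` and ``p`` are matching vectors of observed and expected use
    proportions (each summing to 1).  Unused zones get W = 0; zones with
    zero availability are illegal.
    """
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if r.shape != p.shape:
        raise ValueError(f"r and p differ in length: {r.shape} vs {p.shape}")
    if np.any(p <= 0):
        raise ZeroAvailabilityError(
            "every zone must have positive expected use; drop empty zones first"
        )
    if not (np.isclose(r.sum(), 1.0) and np.isclose(p.sum(), 1.0)):
        raise ValueError("r and p must each sum to 1")
    if np.any(r < 0):
        raise ValueError("observed proportions must be non-negative")
    ratio = r / p
    return ratio / ratio.sum()


def electivity_index(W: np.ndarray, n_zones: int) -> np.ndarray:
    """Elementwise E* = (W_i - 1/n) / (W_i + 1/n)."""
    if n_zones < 2:
        raise ValueError(f"need at least 2 zones, got {n_zones}")
    W = np.asarray(W, dtype=float)
    inv_n = 1.0 / n_zones
    return (W - inv_n) / (W + inv_n)


def zone_use(
    points: list[SurfacePoint], zones: ZonePartition
) -> pd.DataFrame:
    """Per-zone use table (r, p, W, E*) for one subject's location fixes.

    ``p`` comes from the zone polygons' share of the partition area; ``r``
    from a spatial join of the fixes.  Zones never used keep a row with
    r = 0, W = 0, E* = -1.
    """
    if len(points) == 0:
        raise ValueError("no location fixes supplied")
    names = zones.names
    p_map = zones.area_proportions()
    counts = dict.fromkeys(names, 0)
    for pt in points:
        counts[point_in_zone(pt, zones)] += 1
    r = np.array([counts[n] for n in names], dtype=float)
    r /= r.sum()
    p = np.array([p_map[n] for n in names])
    W = selectivity_weights(r, p)
    E = electivity_index(W, zones.n_zones)
    return pd.DataFrame(
        {"zone": names, "r": r, "p": p, "W": W, "E_star": E}
    )


def mean_electivity(per_subject: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Across-subject mean and SD of E* per zone.

    ``per_subject`` maps subject id to a :func:`zone_use` table; each
    subject's E* enters the zone mean with equal weight.
    """
    if len(per_subject) == 0:
        raise ValueError("need at least one subject table")
    stacked = pd.concat(
        [df.assign(subject_id=sid) for sid, df in per_subject.items()],
        ignore_index=True,
    )
    out = (
        stacked.groupby("zone", sort=False)["E_star"]
        .agg(mean_E_star="mean", sd_E_star="std", n_subjects="size")
        .reset_index()
    )
    # preserve partition zone order
    order = per_subject[next(iter(per_subject))]["zone"].tolist()
    return out.set_index("zone").loc[order].reset_index()
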
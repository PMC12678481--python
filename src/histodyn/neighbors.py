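"""Local nuclear-density analysis (the local N/C-ratio proxy).

The number of neighbors within a fixed radius of each nucleus at its
minimum-volume frame operationalizes the local nuclear-to-cytoplasmic
ratio.  Sub-cortical "edge" nuclei, centred below the cortical sheet, are
identified from their Z coordinates: they contribute to the neighbor counts
of others but are excluded from downstream curve averaging.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import AnalysisParams
from .quantify import ImportCurve, import_curves, initial_import_rate

__all__ = ["count_neighbors", "filter_edge_nuclei", "neighbor_profiles",
           "bin_and_average", "BinnedCurves"]


def count_neighbors(positions: np.ndarray, radius: float = 20.0) -> np.ndarray:
    """Neighbors within ``radius`` (3-D Euclidean, inclusive boundary).

    ``positions`` is (n, 3); returns the integer count of *other* nuclei at
    distance <= radius for each nucleus.  Duplicate coordinates count
    normally; a single nucleus has count 0.
    """
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("positions must be (n, 3)")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(pts) == 1:
        return np.zeros(1, dtype=np.int64)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=radius, return_length=True)
    return (counts - 1).astype(np.int64)


def filter_edge_nuclei(z: np.ndarray, z_threshold: float = 2.0) -> np.ndarray:
    """Flag nuclei lying more than ``z_threshold`` below the cortical plane.

    The cortical plane is the median Z of the cohort; only the downward
    deviation flags a nucleus (edge nuclei sit lower in the embryo).
    """
    z = np.asarray(z, dtype=float)
    return z < np.median(z) - z_threshold


def neighbor_profiles(table: pd.DataFrame, cycle: int,
                      params: AnalysisParams = AnalysisParams(),
                      ) -> pd.DataFrame:
    """Per-nucleus neighbor count at minimum volume, with edge flag.

    Uses each nucleus's position at its minimum-volume frame (searched in
    the early interphase).  Returns (nucleus_id, cycle, neighbor_count,
    is_edge, bin_id); ``bin_id`` defaults to the raw count.
    """
    sub = table[(table["cycle"] == cycle) & (table["phase"] == "interphase")]
    if sub.empty:
        raise ValueError(f"cycle NC{cycle} not present")
    rows = []
    for nid, grp in sub.groupby("nucleus_id"):
        grp = grp.sort_values("frame")
        n_search = max(1, int(np.ceil(params.t0_search_fraction * len(grp))))
        i0 = int(np.argmin(grp["volume"].to_numpy()[:n_search]))
        r = grp.iloc[i0]
        rows.append({"nucleus_id": int(nid), "x": r["x"], "y": r["y"],
                     "z": r["z"]})
    prof = pd.DataFrame(rows)
    pos = prof[["x", "y", "z"]].to_numpy()
    prof["neighbor_count"] = count_neighbors(pos, params.neighbor_radius)
    prof["is_edge"] = filter_edge_nuclei(prof["z"].to_numpy(),
                                         params.z_edge_threshold)
    prof["cycle"] = cycle
    prof["bin_id"] = prof["neighbor_count"]
    return prof[["nucleus_id", "cycle", "neighbor_count", "is_edge", "bin_id"]]


class BinnedCurves:
    """Weighted per-bin mean import curves plus per-bin initial slopes."""

    def __init__(self, curves: pd.DataFrame, slopes: pd.DataFrame):
        self.curves = curves  # columns: bin, time, mean, weight, n
        self.slopes = slopes  # columns: bin, n, initial_slope


def bin_and_average(curves: list[ImportCurve], profiles: pd.DataFrame,
                    params: AnalysisParams = AnalysisParams(),
                    bin_width: int = 1) -> BinnedCurves:
    """Bin non-edge import curves by neighbor count and average per bin.

    Curves are already aligned at their individual T0; each distinct
    neighbor count (optionally coarsened by ``bin_width``) forms one bin
    whose mean curve carries the member count as weight.  All curves are
    re-normalized so the weighted grand mean of per-nucleus maxima equals 1.
    Also computes the initial import slope of each bin's mean curve.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    prof = profiles.set_index("nucleus_id")
    members: dict[int, list[ImportCurve]] = {}
    for c in curves:
        if c.nucleus_id not in prof.index:
            raise ValueError(f"nucleus {c.nucleus_id} has no neighbor profile")
        row = prof.loc[c.nucleus_id]
        if bool(row["is_edge"]):
            continue
        b = int(row["neighbor_count"]) // bin_width * bin_width
        members.setdefault(b, []).append(c)
    if not members:
        raise ValueError("no non-edge curves to average")
    all_kept = [c for cs in members.values() for c in cs]
    grand = float(np.mean([c.values.max() for c in all_kept]))
    curve_rows = []
    slope_rows = []
    for b in sorted(members):
        cs = [c.scaled(1.0 / grand) for c in members[b]]
        length = max(len(c.values) for c in cs)
        times = max(cs, key=lambda c: len(c.times)).times
        stack = np.full((len(cs), length), np.nan)
        for i, c in enumerate(cs):
            stack[i, :len(c.values)] = c.values
        mean = np.nanmean(stack, axis=0)
        n_at = np.sum(~np.isnan(stack), axis=0)
        for t, m, k in zip(times, mean, n_at):
            curve_rows.append({"bin": b, "time": float(t), "mean": float(m),
                               "weight": len(cs), "n": int(k)})
        mean_curve = ImportCurve(nucleus_id=-1, cycle=cs[0].cycle,
                                 times=times, values=mean, mode=cs[0].mode)
        try:
            slope = initial_import_rate(mean_curve, params)
        except ValueError:
            slope = np.nan
        slope_rows.append({"bin": b, "n": len(cs), "initial_slope": slope})
    return BinnedCurves(pd.DataFrame(curve_rows), pd.DataFrame(slope_rows))


def binned_import_analysis(table: pd.DataFrame, cycle: int, channel: str,
                           params: AnalysisParams = AnalysisParams(),
                           bin_width: int = 1) -> BinnedCurves:
    """Convenience: profiles + curves + binning for one cycle and channel."""
    profiles = neighbor_profiles(table, cycle, params)
    curves = import_curves(table, cycle, channel, params)
    return bin_and_average(curves, profiles, params, bin_width)


__all__.append("binned_import_analysis")
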
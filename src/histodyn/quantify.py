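"""Per-cycle quantifications of tracked nuclei.

Operates on the long-format TrackTable (one row per nucleus per frame) and
reproduces the core measurements of the live-imaging pipeline: mitotic
chromatin totals, interphase nuclear concentration shortly before NEB,
per-nucleus nuclear import curves aligned at minimum volume, initial import
rates, embryo region definitions and cell-cycle durations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import AnalysisParams

__all__ = [
    "CycleSummary",
    "ImportCurve",
    "channels_of",
    "metaphase_frames",
    "mitotic_chromatin_totals",
    "interphase_concentration",
    "import_curves",
    "initial_import_rate",
    "define_regions",
    "cycle_durations",
    "normalize_durations",
]

logger = logging.getLogger(__name__)

INTERPHASE = "interphase"
MITOSIS = "mitosis"


def channels_of(table: pd.DataFrame) -> list[str]:
    """Channel names present in a TrackTable (from ``total_*`` columns)."""
    return [c[len("total_"):] for c in table.columns if c.startswith("total_")]


@dataclass(frozen=True)
class CycleSummary:
    """Per-cycle aggregates of a per-nucleus measurement.

    ``per_nucleus`` has columns (cycle, nucleus_id, value, normalized);
    ``per_cycle`` has (cycle, mean, normalized_mean, n).  Values are divided
    by the reference-cycle mean, so the reference cycle's normalized mean is
    exactly 1.
    """

    kind: str
    channel: str
    per_nucleus: pd.DataFrame
    per_cycle: pd.DataFrame
    reference_cycle: int
    reference_value: float

    def normalized_mean(self, cycle: int) -> float:
        row = self.per_cycle.loc[self.per_cycle["cycle"] == cycle]
        if row.empty:
            raise KeyError(f"cycle NC{cycle} not present in summary")
        return float(row["normalized_mean"].iloc[0])

    def renormalized(self) -> "CycleSummary":
        """Normalize again against the reference cycle (idempotent)."""
        pn = (self.per_nucleus[["cycle", "nucleus_id", "normalized"]]
              .rename(columns={"normalized": "value"}))
        return _summarize(self.kind, self.channel, pn, self.reference_cycle)


@dataclass(frozen=True)
class ImportCurve:
    """One nucleus's aligned, normalized total-intensity trace for a cycle.

    ``times`` are seconds relative to T0, the minimum-volume frame (searched
    in the early interphase); ``values`` run from T0 through the last
    interphase frame.
    """

    nucleus_id: int
    cycle: int
    times: np.ndarray
    values: np.ndarray
    mode: str
    neighbor_count: int | None = None

    def scaled(self, factor: float) -> "ImportCurve":
        return replace(self, values=self.values * factor)


def _summarize(kind: str, channel: str, per_nucleus: pd.DataFrame,
               reference_cycle: int) -> CycleSummary:
    if per_nucleus.empty:
        raise ValueError(f"{kind}: no usable nuclei found")
    ref = per_nucleus.loc[per_nucleus["cycle"] == reference_cycle, "value"]
    if ref.empty:
        raise ValueError(f"{kind}: reference cycle NC{reference_cycle} missing")
    ref_mean = float(ref.mean())
    if ref_mean <= 0:
        raise ValueError(f"{kind}: non-positive reference mean")
    per_nucleus = per_nucleus.assign(normalized=per_nucleus["value"] / ref_mean)
    per_cycle = (per_nucleus.groupby("cycle", as_index=False)
                 .agg(mean=("value", "mean"), n=("value", "size")))
    per_cycle["normalized_mean"] = per_cycle["mean"] / ref_mean
    return CycleSummary(kind=kind, channel=channel, per_nucleus=per_nucleus,
                        per_cycle=per_cycle, reference_cycle=reference_cycle,
                        reference_value=ref_mean)


def metaphase_frames(table: pd.DataFrame) -> pd.DataFrame:
    """Designated metaphase frame per (nucleus, cycle): midpoint of mitosis.

    Returns rows (nucleus_id, cycle, frame, t).  Nuclei with no mitosis rows
    (arrest) are absent.
    """
    mit = table[table["phase"] == MITOSIS]
    rows = []
    for (nid, cyc), grp in mit.groupby(["nucleus_id", "cycle"]):
        frames = np.sort(grp["frame"].to_numpy())
        f = int(frames[len(frames) // 2])
        t = float(grp.loc[grp["frame"] == f, "t"].iloc[0])
        rows.append({"nucleus_id": nid, "cycle": cyc, "frame": f, "t": t})
    return pd.DataFrame(rows, columns=["nucleus_id", "cycle", "frame", "t"])


def mitotic_chromatin_totals(table: pd.DataFrame, channel: str,
                             params: AnalysisParams = AnalysisParams(),
                             ) -> CycleSummary:
    """Total chromatin intensity per nucleus at metaphase, NC-normalized.

    Per nucleus, the total intensity at its designated metaphase frame; per
    cycle the mean; everything divided by the reference-cycle mean.  Cycles
    with zero mitotic nuclei (e.g. arrest) are omitted with a logged note.
    """
    meta = metaphase_frames(table)
    if meta.empty:
        raise ValueError("table contains no mitosis-phase rows")
    present = set(meta["cycle"].unique())
    all_cycles = set(table["cycle"].unique())
    for cyc in sorted(all_cycles - present):
        logger.info("NC%d has no mitotic nuclei; omitted from chromatin totals",
                    cyc)
    merged = meta.merge(table[["nucleus_id", "frame", f"total_{channel}"]],
                        on=["nucleus_id", "frame"], how="left")
    per_nucleus = merged.rename(columns={f"total_{channel}": "value"})[
        ["cycle", "nucleus_id", "value"]]
    return _summarize("mitotic_chromatin_total", channel, per_nucleus,
                      params.reference_cycle)


def interphase_concentration(table: pd.DataFrame, channel: str,
                             params: AnalysisParams = AnalysisParams(),
                             ) -> CycleSummary:
    """Mean nuclear intensity ``neb_lookback`` s before NEB, NC-normalized.

    NEB is taken as the end of a nucleus's last interphase frame; the
    measurement frame sits ``neb_lookback`` seconds earlier.  Nuclei with
    fewer than two interphase frames are excluded with a warning.
    """
    frame_interval = _frame_interval(table)
    back = max(1, int(round(params.neb_lookback / frame_interval))) - 1
    rows = []
    skipped = 0
    for (nid, cyc), grp in table.groupby(["nucleus_id", "cycle"]):
        inter = grp[grp["phase"] == INTERPHASE].sort_values("frame")
        if len(inter) < 2:
            skipped += 1
            continue
        if not (grp["phase"] == MITOSIS).any():
            continue  # NEB not observed (arrest / truncated track)
        idx = max(0, len(inter) - 1 - back)
        rows.append({"cycle": cyc, "nucleus_id": nid,
                     "value": float(inter[f"mean_{channel}"].iloc[idx])})
    if skipped:
        logger.warning("%d nuclei excluded from concentration analysis "
                       "(<2 interphase frames)", skipped)
    return _summarize("interphase_concentration", channel,
                      pd.DataFrame(rows, columns=["cycle", "nucleus_id", "value"]),
                      params.reference_cycle)


def _frame_interval(table: pd.DataFrame) -> float:
    t = np.sort(table["t"].unique())
    if len(t) < 2:
        raise ValueError("table has fewer than two frames")
    return float(np.min(np.diff(t)))


def _t0_index(inter: pd.DataFrame, search_fraction: float) -> int:
    n = len(inter)
    n_search = max(1, int(np.ceil(search_fraction * n)))
    vols = inter["volume"].to_numpy()[:n_search]
    return int(np.argmin(vols))  # argmin takes the earliest tie


def import_curves(table: pd.DataFrame, cycle: int, channel: str,
                  params: AnalysisParams = AnalysisParams(),
                  mode: str = "mean_max_size_per_cycle",
                  ) -> list[ImportCurve]:
    """Aligned, normalized total-intensity traces for every nucleus of a cycle.

    Each trace is shifted so that T0 (the minimum-volume frame, searched in
    the first ``t0_search_fraction`` of the interphase, earliest tie wins)
    maps to time 0 and runs through the last interphase frame.

    Normalization modes
    -------------------
    ``mean_max_size_per_cycle``
        Divide by the within-cycle mean of each nucleus's intensity at its
        maximum-volume frame, so that mean equals 1.
    ``max_of_reference_cycle``
        Divide by the same statistic computed on the reference cycle.
    """
    if mode not in ("mean_max_size_per_cycle", "max_of_reference_cycle"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    sub = table[table["cycle"] == cycle]
    if sub.empty:
        raise ValueError(f"cycle NC{cycle} not present in table")
    curves = []
    maxima = []
    for nid, grp in sub.groupby("nucleus_id"):
        inter = grp[grp["phase"] == INTERPHASE].sort_values("frame")
        if len(inter) < 2:
            continue
        i0 = _t0_index(inter, params.t0_search_fraction)
        t = inter["t"].to_numpy()
        y = inter[f"total_{channel}"].to_numpy()
        imax = int(np.argmax(inter["volume"].to_numpy()))
        maxima.append(float(y[imax]))
        curves.append(ImportCurve(nucleus_id=int(nid), cycle=cycle,
                                  times=t[i0:] - t[i0], values=y[i0:],
                                  mode=mode))
    if not curves:
        raise ValueError(f"no usable nuclei in cycle NC{cycle}")
    if mode == "mean_max_size_per_cycle":
        norm = float(np.mean(maxima))
    else:
        ref = import_curves(table, params.reference_cycle, channel, params,
                            mode="mean_max_size_per_cycle")
        ref_max = [float(c.values.max()) for c in ref]
        # recover the raw reference maxima: unnormalized stat of ref cycle
        ref_sub = table[table["cycle"] == params.reference_cycle]
        raw = []
        for nid, grp in ref_sub.groupby("nucleus_id"):
            inter = grp[grp["phase"] == INTERPHASE].sort_values("frame")
            if len(inter) < 2:
                continue
            imax = int(np.argmax(inter["volume"].to_numpy()))
            raw.append(float(inter[f"total_{channel}"].to_numpy()[imax]))
        del ref, ref_max
        norm = float(np.mean(raw))
    if norm <= 0:
        raise ValueError("non-positive normalization constant")
    return [c.scaled(1.0 / norm) for c in curves]


def initial_import_rate(curve: ImportCurve,
                        params: AnalysisParams = AnalysisParams()) -> float:
    """OLS slope of the first ``slope_window`` points of an aligned curve.

    Units: normalized a.u. per second.  Raises if the curve is shorter than
    the window, naming the offending nucleus.
    """
    w = params.slope_window
    if len(curve.values) < w:
        raise ValueError(
            f"nucleus {curve.nucleus_id} (NC{curve.cycle}): curve has "
            f"{len(curve.values)} points, fewer than slope_window={w}")
    t = np.asarray(curve.times[:w], dtype=float)
    y = np.asarray(curve.values[:w], dtype=float)
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def define_regions(table: pd.DataFrame, scenario: str = "control",
                   params: AnalysisParams = AnalysisParams(),
                   pole: str = "anterior") -> pd.DataFrame:
    """Assign each nucleus to an embryo region.

    Control embryos: a ``middle`` box centred on the midline of the long
    (x) axis and a ``pole`` box with one edge at the chosen embryo tip, both
    of side ``region_box_px`` x pixel size; everything else is ``other``.

    shkl embryos: ``low_density`` is exactly the lineage that performs the
    partial extra NC14 division; ``high_density`` is a same-sized box centred
    on the densest NC11 location (peak fixed-radius neighbor count);
    remainder ``other``.  Raises if no NC14 rows exist.
    """
    pos = (table.groupby("nucleus_id")
           .agg(x=("x", "mean"), y=("y", "mean"), cycle=("cycle", "first"),
                parent_id=("parent_id", "first"))
           .reset_index())
    box = params.region_box_um
    if scenario != "shkl":
        xmin, xmax = float(pos["x"].min()), float(pos["x"].max())
        xmid = 0.5 * (xmin + xmax)
        region = np.full(len(pos), "other", dtype=object)
        region[np.abs(pos["x"] - xmid) <= box / 2.0] = "middle"
        if pole == "anterior":
            region[pos["x"] <= xmin + box] = "pole"
        else:
            region[pos["x"] >= xmax - box] = "pole"
        return pos.assign(region=region)[["nucleus_id", "region"]]

    nc14_ids = set(table.loc[table["cycle"] >= 14, "nucleus_id"].unique())
    if not nc14_ids:
        raise ValueError("shkl table has no NC14 nuclei; low-density region "
                         "is undefined")
    parent_of = dict(zip(pos["nucleus_id"], pos["parent_id"]))
    low = set()
    for nid in nc14_ids:
        cur = nid
        while cur in parent_of and cur not in low:
            low.add(cur)
            cur = parent_of.get(cur, -1)
            if cur < 0:
                break
    nc11 = pos[pos["cycle"] == 11]
    if nc11.empty:
        nc11 = pos[pos["cycle"] == pos["cycle"].min()]
    pts = nc11[["x", "y"]].to_numpy()
    counts = cKDTree(pts).query_ball_point(pts, r=params.neighbor_radius,
                                           return_length=True) - 1
    peak = pts[int(np.argmax(counts))]
    in_box = ((np.abs(pos["x"] - peak[0]) <= box / 2.0)
              & (np.abs(pos["y"] - peak[1]) <= box / 2.0))
    region = np.full(len(pos), "other", dtype=object)
    region[in_box.to_numpy()] = "high_density"
    region[pos["nucleus_id"].isin(low).to_numpy()] = "low_density"
    return pos.assign(region=region)[["nucleus_id", "region"]]


def cycle_durations(table: pd.DataFrame) -> pd.DataFrame:
    """Metaphase-to-metaphase cycle durations.

    The metaphase time of a cycle is the mean over nuclei of their designated
    metaphase frames; duration(NC k) = t_meta(k+1) - t_meta(k).  Cycles
    without a following metaphase are skipped with a warning.  If the table
    has an ``embryo`` column, durations are computed per embryo.
    """
    def _one(tab: pd.DataFrame) -> pd.DataFrame:
        meta = metaphase_frames(tab)
        if meta.empty:
            return pd.DataFrame(columns=["cycle", "duration"])
        t_meta = meta.groupby("cycle")["t"].mean()
        rows = []
        for cyc in sorted(t_meta.index):
            if cyc + 1 in t_meta.index:
                rows.append({"cycle": cyc,
                             "duration": float(t_meta[cyc + 1] - t_meta[cyc])})
            else:
                logger.warning("NC%d has no following metaphase; duration "
                               "skipped", cyc)
        return pd.DataFrame(rows, columns=["cycle", "duration"])

    if "embryo" in table.columns:
        parts = []
        for emb, tab in table.groupby("embryo"):
            d = _one(tab)
            d.insert(0, "embryo", emb)
            parts.append(d)
        return pd.concat(parts, ignore_index=True)
    return _one(table)


def normalize_durations(durations: pd.DataFrame, control_nc11_mean: float,
                        params: AnalysisParams = AnalysisParams(),
                        ) -> pd.DataFrame:
    """Scale all same-batch durations so control NC11 maps to the reference.

    The factor ``nc11_reference_duration / control_nc11_mean`` (10 min
    convention) is applied to every duration, removing day-to-day
    temperature variability.
    """
    if control_nc11_mean <= 0:
        raise ValueError("control NC11 mean duration must be positive")
    factor = params.nc11_reference_duration / control_nc11_mean
    out = durations.copy()
    out["duration_scaled"] = out["duration"] * factor
    return out
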
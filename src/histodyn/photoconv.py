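"""Photoconversion analyses: export assay, free fraction, bleach check.

A green-to-red photoconverted nucleus reports on two quantities the green
channel cannot separate: nuclear export (red should stay constant during
interphase if export is negligible) and the unbound "free" pool (red that
disperses at NEB instead of staying on mitotic chromatin was never
incorporated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConversionSeries", "extract_conversion_series", "export_assay",
           "free_fraction", "BleachAssessment", "photobleach_check"]

logger = logging.getLogger(__name__)

NEGLIGIBLE_EXPORT_PER_MIN = 0.01   # |rate| below 1 %/min counts as negligible
NEGLIGIBLE_BLEACH_RATIO = 0.95     # retention ratio above this is negligible


@dataclass(frozen=True)
class ConversionSeries:
    """Red-channel time series of one photoconverted nucleus.

    ``t``/``red_total`` span from conversion through (at least) the first
    post-NEB mitotic frame; ``phase`` marks interphase vs mitosis rows.
    """

    nucleus_id: int
    t_conv: float
    t: np.ndarray
    red_total: np.ndarray
    phase: np.ndarray
    background: float = 0.0

    @property
    def neb_index(self) -> int | None:
        mit = np.nonzero(self.phase == "mitosis")[0]
        return int(mit[0]) if len(mit) else None


def extract_conversion_series(table: pd.DataFrame, channel: str,
                              nucleus_id: int, t_conv: float,
                              background: float = 0.0) -> ConversionSeries:
    """Pull the red time series of a converted nucleus from a TrackTable."""
    col = f"red_{channel}"
    if col not in table.columns:
        raise ValueError(f"table has no red channel for {channel!r}")
    sub = (table[(table["nucleus_id"] == nucleus_id) & (table["t"] >= t_conv)]
           .sort_values("frame"))
    if sub.empty:
        raise ValueError(f"nucleus {nucleus_id} has no frames at t >= {t_conv:g}")
    return ConversionSeries(
        nucleus_id=nucleus_id, t_conv=t_conv,
        t=sub["t"].to_numpy(dtype=float),
        red_total=sub[col].to_numpy(dtype=float),
        phase=sub["phase"].to_numpy(), background=background)


def export_assay(series: ConversionSeries) -> tuple[float, bool]:
    """Nuclear export rate from the post-conversion red signal.

    OLS slope of red total vs time over the interphase frames after
    conversion, expressed as fraction of the initial post-conversion red per
    minute.  Returns (rate_per_min, negligible); export is negligible when
    |rate| < 1 %/min.  The fit window is truncated at NEB.
    """
    inter = series.phase == "interphase"
    neb = series.neb_index
    if neb is not None:
        inter = inter & (np.arange(len(series.t)) < neb)
    t = series.t[inter]
    y = series.red_total[inter] - series.background
    if len(t) < 5:
        raise ValueError("need >= 5 interphase frames after conversion")
    y0 = float(y[0])
    if y0 <= 0:
        raise ValueError("non-positive initial red signal")
    slope, _ = np.polyfit(t, y, 1)
    rate_per_min = float(slope) * 60.0 / y0
    return rate_per_min, abs(rate_per_min) < NEGLIGIBLE_EXPORT_PER_MIN


def free_fraction(series: ConversionSeries, post_neb_frame: int = 0) -> float:
    """Fraction of converted histone not retained on chromatin after NEB.

    free = 1 - red_on_chromatin(first post-NEB mitotic frame)
               / red_total(last pre-NEB frame), clipped to [0, 1].
    Bound red stays on the mitotic chromatin while free red disperses, so
    the chromatin-retained ratio at NEB measures the bound share directly.
    ``post_neb_frame`` selects a later mitotic frame if desired.
    """
    neb = series.neb_index
    if neb is None:
        raise ValueError("series contains no post-NEB mitotic frame")
    if neb == 0:
        raise ValueError("series has no pre-NEB frame")
    pre = float(series.red_total[neb - 1]) - series.background
    if pre <= 0:
        raise ValueError("pre-NEB red total is not above background; "
                         "conversion uninformative")
    idx = neb + post_neb_frame
    if idx >= len(series.red_total):
        raise ValueError("requested post-NEB frame beyond series end")
    post = float(series.red_total[idx]) - series.background
    frac = 1.0 - post / pre
    if frac < 0.0 or frac > 1.0:
        logger.info("free fraction %.3f outside [0,1]; clipped (noise)", frac)
    return float(np.clip(frac, 0.0, 1.0))


@dataclass(frozen=True)
class BleachAssessment:
    """Outcome of the parallel-embryo photobleaching comparison.

    Each condition's NC13 total is normalized to its own NC10 value; the
    bleach ratio compares the continuously imaged sub-region against the
    unimaged comparator (parallel embryo, falling back to the area outside
    the sub-region).
    """

    imaged_retention: float
    outside_retention: float | None
    parallel_retention: float | None
    bleach_ratio: float
    negligible: bool
    note: str = ""


def photobleach_check(imaged_nc10: float, imaged_nc13: float,
                      parallel_nc10: float | None = None,
                      parallel_nc13: float | None = None,
                      outside_nc10: float | None = None,
                      outside_nc13: float | None = None) -> BleachAssessment:
    """Compare imaged vs unimaged totals at matched stages (NC10, NC13).

    bleach ratio = (imaged NC13/NC10) / (comparator NC13/NC10); a ratio of
    1 means imaging caused no extra signal loss.  Negligible when the ratio
    is >= 0.95.  With no comparator available a partial report is returned
    with a warning.
    """
    if imaged_nc10 <= 0:
        raise ValueError("imaged NC10 total must be positive")
    imaged = imaged_nc13 / imaged_nc10
    outside = (outside_nc13 / outside_nc10
               if outside_nc10 and outside_nc13 else None)
    parallel = (parallel_nc13 / parallel_nc10
                if parallel_nc10 and parallel_nc13 else None)
    comparator = parallel if parallel is not None else outside
    note = ""
    if comparator is None:
        logger.warning("no unimaged comparator; reporting raw retention only")
        note = "no comparator; ratio is raw imaged retention"
        ratio = imaged
    else:
        if comparator <= 0:
            raise ValueError("comparator retention must be positive")
        ratio = imaged / comparator
    return BleachAssessment(
        imaged_retention=imaged, outside_retention=outside,
        parallel_retention=parallel, bleach_ratio=float(ratio),
        negligible=ratio >= NEGLIGIBLE_BLEACH_RATIO, note=note)
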
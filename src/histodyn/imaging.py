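"""Segmentation and division-aware tracking of 3D+t image stacks.

A deliberately simple desk-scale stage: global threshold segmentation
(Otsu or fixed) with 26-connected components, then greedy mutual-nearest-
neighbor frame-to-frame linking with an explicit division rule.  It is not
a general-purpose tracker; it is adequate for sparse, slowly moving nuclei
such as the rendered synthetic stacks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy.spatial.distance import cdist
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import expand_labels

from .render import ImagingParams

__all__ = ["LabeledObject", "segment_frame", "segment_stack", "track_objects",
           "read_tiff", "read_ilastik_csv", "ILASTIK_DEFAULT_COLUMNS"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledObject:
    """One segmented nucleus in one frame.

    Coordinates are micrometres (x, y, z) at voxel centres, origin at the
    stack corner; volume = voxel count x voxel volume; intensity statistics
    are computed on the raw (pre-threshold) voxels.
    """

    frame: int
    label: int
    x: float
    y: float
    z: float
    size_in_pixels: int
    volume: float
    total_intensity: float
    mean_intensity: float


def segment_frame(frame3d: np.ndarray, params: ImagingParams = ImagingParams(),
                  threshold_method: str = "otsu", threshold: float | None = None,
                  min_size: int = 30, frame_index: int = 0,
                  support_fraction: float = 0.02, expand_um: float = 3.0,
                  ) -> list[LabeledObject]:
    """Segment one 3-D frame into labeled objects.

    ``threshold_method`` is ``"otsu"`` or ``"fixed"`` (requires
    ``threshold``).  Connected components (26-connectivity) smaller than
    ``min_size`` voxels are discarded.  Because a hard threshold clips the
    dim rim of a nucleus, each core label is expanded by up to
    ``expand_um`` onto surrounding voxels still above
    ``support_fraction x threshold``; all statistics (size, volume,
    centroid, intensities) are computed on that support so per-object
    totals track the underlying signal.  An all-background frame returns
    an empty list.
    """
    img = np.asarray(frame3d)
    if threshold_method == "otsu":
        if img.max() <= img.min():
            return []
        thr = threshold_otsu(img)
    elif threshold_method == "fixed":
        if threshold is None:
            raise ValueError("fixed thresholding requires `threshold`")
        thr = threshold
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    core = sk_label(img > thr, connectivity=3)
    keep = np.zeros_like(core)
    for prop in regionprops(core):
        if prop.area >= min_size:
            keep[core == prop.label] = prop.label
    if not keep.any():
        return []
    spacing = (params.z_step, params.pixel_size, params.pixel_size)
    expanded = expand_labels(keep, distance=expand_um, spacing=spacing)
    support = np.where(img > support_fraction * thr, expanded, 0)
    support = np.where(keep > 0, keep, support)  # cores always belong
    out = []
    for prop in regionprops(support, intensity_image=img):
        cz, cy, cx = prop.centroid  # voxel indices (z, y, x)
        out.append(LabeledObject(
            frame=frame_index, label=int(prop.label),
            x=(cx + 0.5) * params.pixel_size,
            y=(cy + 0.5) * params.pixel_size,
            z=(cz + 0.5) * params.z_step,
            size_in_pixels=int(prop.area),
            volume=float(prop.area) * params.voxel_volume,
            total_intensity=(total := float(
                prop.image_intensity[prop.image].sum())),
            mean_intensity=total / int(prop.area),
        ))
    out.sort(key=lambda o: o.label)
    return out


def segment_stack(stack: np.ndarray, params: ImagingParams = ImagingParams(),
                  **kw) -> list[list[LabeledObject]]:
    """Segment every frame of a (T, Z, Y, X) stack."""
    return [segment_frame(stack[t], params, frame_index=t, **kw)
            for t in range(stack.shape[0])]


def track_objects(frames: list[list[LabeledObject]], max_disp: float = 10.0,
                  frame_interval: float = 45.0, start_cycle: int = 10,
                  channel: str = "ch0") -> pd.DataFrame:
    """Link per-frame objects into division-aware tracks (a TrackTable).

    Greedy mutual-nearest-neighbor linking within ``max_disp`` um.  When
    exactly two objects at t+1 claim the same object at t (post-mitosis),
    the parent track ends and both daughters start new tracks with
    ``parent_id`` set and the cycle index incremented.  Unlinked objects
    start fresh tracks.  Ambiguities resolve by distance, then label order,
    so tracking is deterministic.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    rows: list[dict] = []
    next_id = 0
    current: dict[int, tuple[int, int, int]] = {}  # label -> (track, parent, cycle)

    def emit(obj: LabeledObject, track: int, parent: int, cycle: int) -> None:
        rows.append({
            "nucleus_id": track, "parent_id": parent, "cycle": cycle,
            "frame": obj.frame, "t": obj.frame * frame_interval,
            "x": obj.x, "y": obj.y, "z": obj.z, "volume": obj.volume,
            f"total_{channel}": obj.total_intensity,
            f"mean_{channel}": obj.mean_intensity,
            "phase": "interphase",
        })

    for t, objs in enumerate(frames):
        if t == 0:
            for o in objs:
                current[o.label] = (next_id, -1, start_cycle)
                emit(o, next_id, -1, start_cycle)
                next_id += 1
            continue
        prev_objs = frames[t - 1]
        new_current: dict[int, tuple[int, int, int]] = {}
        if prev_objs and objs:
            p = np.array([[o.x, o.y, o.z] for o in prev_objs])
            q = np.array([[o.x, o.y, o.z] for o in objs])
            d = cdist(p, q)
            # each new object claims its nearest predecessor within range
            claims: dict[int, list[int]] = {}
            for j in range(len(objs)):
                i = int(np.argmin(d[:, j]))
                if d[i, j] <= max_disp:
                    claims.setdefault(i, []).append(j)
            assigned: set[int] = set()
            for i, js in sorted(claims.items()):
                js = sorted(js, key=lambda j: (d[i, j], objs[j].label))
                track, parent, cycle = current[prev_objs[i].label]
                if len(js) == 1:
                    j = js[0]
                    if int(np.argmin(d[i, :])) == j:  # mutual nearest
                        new_current[objs[j].label] = (track, parent, cycle)
                        assigned.add(j)
                else:
                    for j in js[:2]:  # division: two daughters, new ids
                        new_current[objs[j].label] = (next_id, track, cycle + 1)
                        next_id += 1
                        assigned.add(j)
            for j in range(len(objs)):
                if j not in assigned and objs[j].label not in new_current:
                    new_current[objs[j].label] = (next_id, -1, start_cycle)
                    next_id += 1
        else:
            for o in objs:
                new_current[o.label] = (next_id, -1, start_cycle)
                next_id += 1
        for o in objs:
            track, parent, cycle = new_current[o.label]
            emit(o, track, parent, cycle)
        current = new_current
    return pd.DataFrame(rows)


def read_tiff(path) -> np.ndarray:
    """Read a multi-page TIFF written by :func:`histodyn.render.write_tiff`."""
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        arr = arr[None]
    return arr


#: Best-effort default mapping from ilastik "tracking with learning" CSV
#: exports onto the TrackTable schema.  Column names vary by ilastik
#: version; override entries as needed.
ILASTIK_DEFAULT_COLUMNS: dict[str, str] = {
    "frame": "frame",
    "nucleus_id": "trackId",
    "parent_id": "parentTrackId",
    "x": "Center_of_the_object_0",
    "y": "Center_of_the_object_1",
    "z": "Center_of_the_object_2",
    "size_in_pixels": "Size_in_pixels_0",
    "total_intensity": "Total_Intensity_0",
    "mean_intensity": "Mean_Intensity_0",
}


def read_ilastik_csv(path, channel: str = "ch0",
                     column_map: dict[str, str] | None = None,
                     params: ImagingParams = ImagingParams(),
                     frame_interval: float = 45.0,
                     coordinates_in_pixels: bool = True) -> pd.DataFrame:
    """Map an ilastik object/tracking CSV export onto the TrackTable schema.

    ``column_map`` maps TrackTable fields to the export's column names (see
    :data:`ILASTIK_DEFAULT_COLUMNS`).  Pixel coordinates and sizes are
    converted to micrometres via ``params``.
    """
    cmap = dict(ILASTIK_DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    missing = [v for k, v in cmap.items()
               if v not in raw.columns and k not in ("parent_id", "z")]
    if missing:
        raise ValueError(f"ilastik export lacks expected columns {missing}; "
                         "pass a column_map")
    out = pd.DataFrame()
    out["nucleus_id"] = raw[cmap["nucleus_id"]].astype(int)
    out["parent_id"] = (raw[cmap["parent_id"]].astype(int)
                        if cmap["parent_id"] in raw.columns else -1)
    out["frame"] = raw[cmap["frame"]].astype(int)
    out["t"] = out["frame"] * frame_interval
    sx = params.pixel_size if coordinates_in_pixels else 1.0
    sz = params.z_step if coordinates_in_pixels else 1.0
    out["x"] = raw[cmap["x"]].astype(float) * sx
    out["y"] = raw[cmap["y"]].astype(float) * sx
    out["z"] = (raw[cmap["z"]].astype(float) * sz
                if cmap["z"] in raw.columns else 0.0)
    size = raw[cmap["size_in_pixels"]].astype(float)
    out["volume"] = size * params.voxel_volume
    out[f"total_{channel}"] = raw[cmap["total_intensity"]].astype(float)
    out[f"mean_{channel}"] = raw[cmap["mean_intensity"]].astype(float)
    out["cycle"] = raw["cycle"].astype(int) if "cycle" in raw.columns else -1
    out["phase"] = raw["phase"] if "phase" in raw.columns else "interphase"
    return out
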
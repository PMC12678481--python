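"""Deterministic tabular report bundles.

``make_report`` writes one CSV per analysis product plus a JSON manifest.
Same inputs produce byte-identical files, so bundles can be diffed across
runs and seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import SimConfig
from .io import write_table
from .quantify import CycleSummary
from .stats import AnovaResult

__all__ = ["make_report"]


def _as_frame(product) -> pd.DataFrame:
    if isinstance(product, pd.DataFrame):
        return product
    if isinstance(product, CycleSummary):
        return product.per_cycle.assign(kind=product.kind,
                                        channel=product.channel)
    if isinstance(product, AnovaResult):
        return product.table.reset_index(names="effect")
    raise TypeError(f"cannot serialise report product of type {type(product)!r}")


def make_report(products: dict[str, object], outdir,
                config: SimConfig | None = None) -> Path:
    """Write each named product as ``<name>.csv`` plus ``manifest.json``.

    ``products`` maps table names to DataFrames, CycleSummaries or
    AnovaResults.  Returns the manifest path.  Empty input yields an empty
    bundle with a manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(products):
        frame = _as_frame(products[name])
        path = outdir / f"{name}.csv"
        write_table(frame, path, config=config)
        entries.append({"name": name, "file": path.name, "rows": len(frame)})
    manifest = outdir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"tables": entries}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
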
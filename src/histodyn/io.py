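"""CSV round-tripping for TrackTables and analysis products.

Every file carries a single ``#``-prefixed header comment recording the
package version, seed and a config hash, so outputs are traceable and
byte-identical across reruns with the same inputs.
"""

from __future__ import annotations

import hashlib
import io as _io
import json

import pandas as pd

from . import __version__
from .config import SimConfig

__all__ = ["write_table", "read_table", "config_hash"]


def config_hash(config: SimConfig | None) -> str:
    if config is None:
        return "none"
    blob = json.dumps(config.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(seed, cfg_hash) -> str:
    return (f"# histodyn v{__version__} seed={seed} config={cfg_hash}\n")


def write_table(df: pd.DataFrame, path, config: SimConfig | None = None,
                seed: int | None = None) -> None:
    """Write a DataFrame as CSV with a provenance comment line."""
    if seed is None and config is not None:
        seed = config.seed
    with open(path, "w") as fh:
        fh.write(_header(seed, config_hash(config)))
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines skipped)."""
    with open(path) as fh:
        text = fh.read()
    return pd.read_csv(_io.StringIO(text), comment="#")
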
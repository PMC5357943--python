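"""Shared helpers: reproducible seed streams and annotated table output."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a single master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def config_hash(params: Mapping[str, Any]) -> str:
    """Short stable hash of a parameter mapping, for output provenance lines."""
    blob = json.dumps({k: repr(v) for k, v in sorted(params.items())}, sort_keys=True)
    return hashlib.md5(blob.encode()).hexdigest()[:10]


def table_header(meta: Mapping[str, Any] | None = None) -> str:
    from switchnet import __version__

    meta = dict(meta or {})
    parts = [f"switchnet v{__version__}"]
    parts += [f"{k}={v}" for k, v in meta.items()]
    return "# " + " | ".join(parts)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, Any] | None = None,
    index: bool = False,
) -> Path:
    """Write a TSV with a ``#`` provenance header line (version, config, seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(table_header(meta) + "\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (skips ``#`` header lines)."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
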
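"""Shared helpers: TSV output with provenance headers, window iteration."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterator

import pandas as pd

from vectorpop._version import __version__


def write_tsv(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> Path:
    """Write a DataFrame as TSV with a comment header recording version and parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# vectorpop={__version__}"]
    for key, val in (params or {}).items():
        lines.append(f"# {key}={val}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def snp_windows(n_sites: int, window_size: int, step: int | None = None) -> Iterator[tuple[int, int, bool]]:
    """Yield (start, stop, flagged) half-open site-index windows.

    Full windows advance by ``step`` (default: non-overlapping). A trailing
    partial window is kept, flagged, if it spans at least half a window,
    and silently dropped otherwise.
    """
    if window_size < 2:
        raise ValueError(f"window_size must be >= 2, got {window_size}")
    step = window_size if step is None else step
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    start = 0
    while start + window_size <= n_sites:
        yield start, start + window_size, False
        start += step
    if start < n_sites and (n_sites - start) >= window_size / 2:
        yield start, n_sites, True
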
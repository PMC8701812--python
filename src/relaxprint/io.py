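"""Schema-checked CSV table IO with a fixed, locale-independent dialect.

All tables are comma-separated UTF-8 with LF line endings and "." decimal
points, written at 12 significant digits (lossless for every quantity the
pipeline produces at that precision).
"""

from __future__ import annotations

import hashlib
import io as _io

import pandas as pd

from .errors import SchemaError

__all__ = ["read_table", "write_table", "file_sha256"]

_FLOAT_FORMAT = "%.12g"


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a DataFrame as CSV in the package dialect."""
    text = df.to_csv(index=index, float_format=_FLOAT_FORMAT, lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)


def read_table(path, required_columns=(), index_col=None) -> pd.DataFrame:
    """Read a CSV table, checking required columns are present.

    Parsing is locale-independent: "." is always the decimal separator,
    regardless of the environment's LC_NUMERIC.
    """
    df = pd.read_csv(path, index_col=index_col, float_precision="round_trip")
    present = set(df.columns) | ({df.index.name} if df.index.name else set())
    missing = [c for c in required_columns if c not in present]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def file_sha256(path) -> str:
    """Hex SHA-256 of a file's bytes (for run manifests)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
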
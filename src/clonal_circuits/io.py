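"""Readers and writers for pair tables, cell tables, counts and configs.

Tables travel as delimited text (tab by default; comma autodetected) with a
one-line header; count matrices as matrix-market sparse files with gene and
cell TSV sidecars; configuration as JSON or YAML.  All distances in files
are micrometres.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .config import RELATIONS, normalize_layer
from .connectivity import PAIR_COLUMNS

REQUIRED_PAIR_COLUMNS = [
    "pre_layer",
    "post_layer",
    "relation",
    "connected",
    "tangential_um",
    "vertical_um",
    "euclidean_um",
]


class SchemaError(ValueError):
    """Malformed table: missing columns or invalid values, with row numbers."""


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a delimited table, accepting both tab and comma dialects."""
    return pd.read_csv(path, sep=None, engine="python")


def read_pair_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a pair-test table.

    Normalizes layer aliases ("L23" -> "L2/3"), coerces the boolean flags,
    and reports offending data rows by number (1-based, excluding the
    header) for invalid layer, relation or rostrocaudal values.
    """
    df = _read_delimited(path)
    missing = [c for c in REQUIRED_PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pair table {path} missing columns: {missing}")
    for col in ("pre_layer", "post_layer"):
        normalized = []
        for i, tok in enumerate(df[col]):
            try:
                normalized.append(normalize_layer(tok))
            except ValueError as exc:
                raise SchemaError(f"{path} row {i + 1}, column {col}: {exc}") from exc
        df[col] = normalized
    bad = ~df["relation"].isin(RELATIONS)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise SchemaError(
            f"{path} row {row}: invalid relation {df['relation'].iloc[row - 1]!r}"
        )
    df["connected"] = df["connected"].astype(int).astype(bool)
    if "bidirectional_tested" not in df.columns:
        df["bidirectional_tested"] = False
    df["bidirectional_tested"] = df["bidirectional_tested"].astype(int).astype(bool)
    if "rostrocaudal" not in df.columns:
        df["rostrocaudal"] = 3
    rc = df["rostrocaudal"].astype(int)
    bad = ~rc.between(1, 5)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise SchemaError(f"{path} row {row}: rostrocaudal outside 1..5")
    df["rostrocaudal"] = rc
    if "clone_id" not in df.columns:
        df["clone_id"] = -1
    cols = PAIR_COLUMNS + (["pair_id"] if "pair_id" in df.columns else [])
    return df[cols]


def write_pair_table(pairs: pd.DataFrame, path: str | Path) -> None:
    """Write a pair table as TSV (booleans as 0/1; lossless float repr)."""
    out = pairs.copy()
    for col in ("connected", "bidirectional_tested"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    out = cells.copy()
    out["tdtomato"] = out["tdtomato"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    df = _read_delimited(path)
    df["tdtomato"] = df["tdtomato"].astype(int).astype(bool)
    return df


def write_counts_mtx(
    counts: np.ndarray, genes: list[str], cell_ids: list, prefix: str | Path
) -> None:
    """Write a cells x genes count matrix as MTX plus TSV sidecars.

    Produces ``<prefix>.mtx`` (genes x cells, the conventional orientation),
    ``<prefix>.genes.tsv`` and ``<prefix>.cells.tsv``.
    """
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix) + ".mtx", scipy.sparse.csr_matrix(counts.T))
    pd.Series(genes).to_csv(str(prefix) + ".genes.tsv", sep="\t", index=False, header=False)
    pd.Series(cell_ids).to_csv(str(prefix) + ".cells.tsv", sep="\t", index=False, header=False)


def read_counts_mtx(prefix: str | Path):
    """Read back a matrix written by :func:`write_counts_mtx`.

    Returns (counts cells x genes, genes, cell ids).
    """
    prefix = Path(prefix)
    mat = scipy.io.mmread(str(prefix) + ".mtx").toarray().T
    genes = pd.read_csv(str(prefix) + ".genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(str(prefix) + ".cells.tsv", sep="\t", header=None)[0].tolist()
    return mat, genes, cells


def load_config_file(path: str | Path) -> dict:
    """Load a JSON or YAML configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dict for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON output (sorted keys, no timestamps)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
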
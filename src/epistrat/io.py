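"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as TSV (genes in rows, header = sample ids) or
as a MatrixMarket triplet (.mtx plus row/column name files); gene sets as
GMT; clinical tables, annotations and labels as TSV; run metadata as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .errors import DataContractError

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_matrix_market", "write_matrix_market",
    "read_gmt", "write_gmt",
    "read_table", "write_table",
    "read_json", "write_json",
]


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise DataContractError("duplicate gene or sample identifiers")
    return df


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix_market(prefix: str | Path) -> pd.DataFrame:
    """Read ``<prefix>.mtx`` with ``<prefix>.rows.txt``/``.cols.txt``."""
    prefix = Path(prefix)
    mat = sio.mmread(prefix.with_suffix(".mtx"))
    rows = prefix.parent.joinpath(prefix.name + ".rows.txt").read_text().split()
    cols = prefix.parent.joinpath(prefix.name + ".cols.txt").read_text().split()
    dense = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
    if dense.shape != (len(rows), len(cols)):
        raise DataContractError("matrix dimensions do not match the name files")
    return pd.DataFrame(dense, index=rows, columns=cols)


def write_matrix_market(df: pd.DataFrame, prefix: str | Path) -> None:
    prefix = Path(prefix)
    sio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(df.to_numpy()))
    prefix.parent.joinpath(prefix.name + ".rows.txt").write_text(
        "\n".join(map(str, df.index)) + "\n")
    prefix.parent.joinpath(prefix.name + ".cols.txt").write_text(
        "\n".join(map(str, df.columns)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:  # name + description; member list may be empty
            raise DataContractError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "") -> None:
    lines = ["\t".join([name, description, *genes]) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
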
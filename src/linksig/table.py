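"""The per-pair score table and its TSV round trip.

A :class:`ScoreTable` holds one row per candidate pair (canonical
lexicographic order) with the common-neighbor count, any computed
similarity measures, and — once the degree-preserving null model has been
run — the sampled mean/deviation, z-score, empirical p-value and z* rank.
Metadata (graph mode, ranked side, null-model population size, sampler
settings) travels with the table and is echoed as ``#`` comment lines in
the TSV so every output is reproducible from its header.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph import canonical_pair

KEY_COLUMNS = ("node_u", "node_v", "n_common")

__all__ = ["ScoreTable", "write_scores", "read_scores"]


class ScoreTable:
    """Scores of all candidate pairs of one graph.

    Wraps a :class:`pandas.DataFrame` whose first columns are
    ``node_u``, ``node_v`` (canonical pair order) and ``n_common``,
    followed by one column per measure/statistic. Lookups are symmetric
    in the pair. Undefined values (e.g. a Pearson coefficient with zero
    variance) are stored as NaN and sort below all defined values in any
    ranking.
    """

    def __init__(self, df: pd.DataFrame, meta: dict | None = None) -> None:
        for col in KEY_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"score table lacks required column {col!r}")
        df = df.copy()
        # normalize pair order, then sort rows canonically
        flip = df["node_u"] > df["node_v"]
        if flip.any():
            u = df.loc[flip, "node_u"].copy()
            df.loc[flip, "node_u"] = df.loc[flip, "node_v"]
            df.loc[flip, "node_v"] = u
        df = df.sort_values(["node_u", "node_v"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(subset=["node_u", "node_v"]).any():
            raise ValueError("duplicate candidate pairs in score table")
        self.df = df
        self.meta: dict = dict(meta or {})
        self._row: dict[tuple[str, str], int] = {
            (u, v): i for i, (u, v) in enumerate(zip(df["node_u"], df["node_v"]))
        }

    # -- access ----------------------------------------------------------

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.df["node_u"], self.df["node_v"]))

    @property
    def measures(self) -> list[str]:
        return [c for c in self.df.columns if c not in KEY_COLUMNS]

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self._row

    def row_of(self, u: str, v: str) -> int:
        pair = canonical_pair(u, v)
        try:
            return self._row[pair]
        except KeyError:
            raise KeyError(f"pair {pair!r} is not a candidate pair") from None

    def lookup(self, u: str, v: str, column: str) -> float:
        """Symmetric lookup of one value; NaN marks an undefined score."""
        return self.df.at[self.row_of(u, v), column]

    def values(self, column: str) -> np.ndarray:
        if column not in self.df.columns:
            raise KeyError(f"unknown column {column!r}")
        return self.df[column].to_numpy()

    def add_column(self, name: str, values: Sequence[float]) -> None:
        if len(values) != len(self.df):
            raise ValueError("column length does not match number of pairs")
        self.df[name] = values

    def nodes(self) -> list[str]:
        return sorted(set(self.df["node_u"]) | set(self.df["node_v"]))

    def pairs_of(self, node: str) -> list[tuple[int, str]]:
        """(row index, partner) for every candidate pair containing ``node``."""
        out: list[tuple[int, str]] = []
        for i, (u, v) in enumerate(zip(self.df["node_u"], self.df["node_v"])):
            if u == node:
                out.append((i, v))
            elif v == node:
                out.append((i, u))
        return out


def write_scores(table: ScoreTable, path: str) -> None:
    """Write a ScoreTable as TSV: ``#`` metadata lines, header, data rows.

    Floats are written with 17 significant digits so a write→read round
    trip preserves values exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(table.meta):
            fh.write(f"# {key}={table.meta[key]}\n")
        fh.write("\t".join(table.df.columns) + "\n")
        for row in table.df.itertuples(index=False):
            fields = [repr(v) if isinstance(v, float) else str(v) for v in row]
            fh.write("\t".join(fields) + "\n")


def read_scores(path: str) -> ScoreTable:
    """Read a TSV written by :func:`write_scores`."""
    meta: dict = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if header is None:
                header = line.split("\t")
            else:
                rows.append(line.split("\t"))
    if header is None:
        raise ValueError(f"{path}: no header line found")
    df = pd.DataFrame(rows, columns=header)
    if len(df):
        df["n_common"] = df["n_common"].astype(int)
        for col in df.columns:
            if col in ("node_u", "node_v", "n_common"):
                continue
            try:
                df[col] = df[col].astype(np.int64)
            except ValueError:
                df[col] = df[col].astype(float)
    else:
        df["n_common"] = df["n_common"].astype(int)
        for col in df.columns:
            if col not in ("node_u", "node_v", "n_common"):
                df[col] = df[col].astype(float)
    return ScoreTable(df, meta=meta)
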
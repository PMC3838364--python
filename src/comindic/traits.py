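"""Mixed-type species trait tables and Gower dissimilarity.

Trait matrices for community originality mix quantitative measurements
(e.g. maximum body length), ordinal scores, and nominal or binary
categories (e.g. parental care, rheophily).  Gower's coefficient is the
standard dissimilarity for such data: each trait contributes a value in
[0, 1] (range-normalized absolute difference for ordered traits, simple
mismatch for categorical ones) and traits with a missing value in either
species are dropped pairwise from the average.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAIT_KINDS = ("quantitative", "ordinal", "nominal", "binary")
ORDERED_KINDS = ("quantitative", "ordinal")


class TraitTableError(ValueError):
    """Invalid trait table or schema."""


@dataclass
class TraitTable:
    """Species x traits matrix with per-column type declarations.

    Parameters
    ----------
    data:
        DataFrame indexed by species id.  Missing values are NaN/None.
    kinds:
        Mapping from column name to one of ``TRAIT_KINDS``.
    """

    data: pd.DataFrame
    kinds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.data.index
        if len(idx) == 0:
            raise TraitTableError("trait table has no species")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise TraitTableError(f"duplicate species id(s): {dup}")
        undeclared = [c for c in self.data.columns if c not in self.kinds]
        if undeclared:
            raise TraitTableError(
                f"column(s) without a declared trait kind: {undeclared}"
            )
        extra = [c for c in self.kinds if c not in self.data.columns]
        if extra:
            raise TraitTableError(f"schema declares unknown column(s): {extra}")
        for col, kind in self.kinds.items():
            if kind not in TRAIT_KINDS:
                raise TraitTableError(
                    f"column {col!r}: unknown trait kind {kind!r} "
                    f"(expected one of {TRAIT_KINDS})"
                )
            vals = self.data[col]
            if vals.isna().all():
                raise TraitTableError(f"column {col!r} has no non-missing value")
            if kind in ORDERED_KINDS:
                try:
                    self.data[col] = pd.to_numeric(vals)
                except (ValueError, TypeError) as exc:
                    raise TraitTableError(
                        f"column {col!r} declared {kind} but not numeric: {exc}"
                    ) from None

    @property
    def species_ids(self) -> list:
        return list(self.data.index)

    @property
    def trait_names(self) -> list:
        return list(self.data.columns)

    def subset(self, species: Sequence) -> "TraitTable":
        """Restrict to the given species (order preserved)."""
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise TraitTableError(f"unknown species id(s): {missing}")
        return TraitTable(self.data.loc[list(species)].copy(), dict(self.kinds))


def read_trait_table(
    path,
    schema: Mapping[str, str],
    missing_token: str = "NA",
    delimiter: str | None = None,
    species_column: str | None = None,
) -> TraitTable:
    """Read a delimited trait table with a header row and a species-id column.

    ``schema`` maps every trait column to its kind; ``missing_token`` cells
    become missing values.  The species-id column defaults to the first
    column of the file.
    """
    df = pd.read_csv(
        path,
        sep=delimiter,
        engine="python" if delimiter is None else "c",
        na_values=[missing_token],
        keep_default_na=False,
        dtype=object,
    )
    if species_column is None:
        species_column = df.columns[0]
    if species_column not in df.columns:
        raise TraitTableError(f"species column {species_column!r} not in file")
    ids = df[species_column]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].unique().tolist()
        raise TraitTableError(f"duplicate species id(s): {dup}")
    df = df.set_index(species_column)
    df.index.name = "species"
    return TraitTable(df, dict(schema))


def read_schema(path) -> dict:
    """Read a ``trait=kind`` sidecar schema file (one entry per line)."""
    kinds: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise TraitTableError(
                    f"{path}:{lineno}: expected 'trait=kind', got {line!r}"
                )
            key, _, kind = line.partition("=")
            kinds[key.strip()] = kind.strip()
    return kinds


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with ordered labels."""

    labels: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.d.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if np.isnan(self.d).any():
            raise ValueError("distance matrix contains undefined entries")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (self.d < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if not df.index.equals(df.columns):
            raise ValueError("row and column labels differ")
        return cls(list(df.index), df.to_numpy(dtype=float))


def _per_trait_dissimilarity(col: pd.Series, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (s, delta): per-pair dissimilarity and comparability mask."""
    if kind in ORDERED_KINDS:
        x = col.to_numpy(dtype=float)
        ok = ~np.isnan(x)
        rng = np.nanmax(x) - np.nanmin(x) if ok.any() else 0.0
        diff = np.abs(x[:, None] - x[None, :])
        if rng > 0:
            s = diff / rng
        else:
            warnings.warn(
                f"trait {col.name!r} has zero range; contributes 0 to Gower",
                stacklevel=3,
            )
            s = np.zeros_like(diff)
        delta = ok[:, None] & ok[None, :]
        s = np.where(delta, s, 0.0)
    else:
        vals = col.to_numpy(dtype=object)
        ok = ~pd.isna(vals)
        eq = vals[:, None] == vals[None, :]
        s = np.where(eq, 0.0, 1.0)
        delta = ok[:, None] & ok[None, :]
        s = np.where(delta, s, 0.0)
    return s, delta


def gower_distance(
    table: TraitTable, weights: Mapping[str, float] | None = None
) -> DistanceMatrix:
    """Gower (1971) dissimilarity with pairwise deletion of missing values.

    d(i, j) = sum_k w_k delta_ijk s_ijk / sum_k w_k delta_ijk, where
    delta_ijk is 1 iff trait k is non-missing for both species, s_ijk is
    the range-normalized absolute difference (ordered traits) or the 0/1
    mismatch (categorical traits).  A species pair with no comparable
    trait raises an error rather than being silently imputed.
    """
    cols = table.trait_names
    if weights is None:
        w = {c: 1.0 for c in cols}
    else:
        w = dict(weights)
        missing = [c for c in cols if c not in w]
        if missing:
            raise TraitTableError(f"no weight for trait(s): {missing}")
        bad = [c for c in cols if not w[c] > 0]
        if bad:
            raise TraitTableError(f"non-positive weight for trait(s): {bad}")

    n = len(table.species_ids)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in cols:
        s, delta = _per_trait_dissimilarity(table.data[col], table.kinds[col])
        num += w[col] * s
        den += w[col] * delta
    if (den == 0).any():
        ii, jj = np.nonzero(den == 0)
        pairs = [
            (table.species_ids[i], table.species_ids[j])
            for i, j in zip(ii, jj)
            if i < j
        ]
        raise TraitTableError(
            f"species pair(s) share no comparable trait: {pairs}"
        )
    d = num / den
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # symmetrize away float noise
    return DistanceMatrix(table.species_ids, d)


def write_distance_csv(dm: DistanceMatrix, path) -> None:
    dm.to_frame().to_csv(path, index_label="species")


def read_distance_csv(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    df.columns.name = None
    df.index.name = None
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DistanceMatrix.from_frame(df)
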
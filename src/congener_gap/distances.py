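"""Uncorrected pairwise p-distances over an alignment.

The p-distance between two aligned sequences is the fraction of differing
positions among their pairwise-comparable sites.  Sites where either sequence
carries a gap, an N or any IUPAC ambiguity code are excluded for that pair
("pairwise deletion"); ambiguity codes are treated as missing rather than as
partial matches, which keeps distances order-independent and conservative.

Because comparable-site sets differ between pairs, p-distance with pairwise
deletion is not a metric — the triangle inequality can fail — so no metric
property is assumed anywhere downstream.

Distances are computed on the four canonical bases only.  The full matrix is
built with one-hot matrix products, which keeps the 3573-sequence study-scale
computation in the minutes range on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd

from .io import Alignment, TaxonIdentity

__all__ = [
    "DistanceMatrix",
    "SpeciesPairSummary",
    "UndefinedDistanceError",
    "p_distance",
    "distance_matrix",
    "species_pair_summary",
    "max_intraspecific",
    "format_percent",
]

_BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}


class UndefinedDistanceError(ValueError):
    """Two sequences share no comparable sites."""


def _encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8: 1-4 for ACGT, 0 for any excluded site."""
    arr = np.zeros(len(seq), dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Uncorrected p-distance and comparable-site count for one pair.

    Raises :class:`UndefinedDistanceError` when no site is comparable.
    """
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length: {len(a)} vs {len(b)}")
    ea = _encode(a.upper())
    eb = _encode(b.upper())
    comparable = (ea > 0) & (eb > 0)
    m = int(comparable.sum())
    if m == 0:
        raise UndefinedDistanceError("no comparable sites between the two sequences")
    mismatches = int(np.count_nonzero(ea[comparable] != eb[comparable]))
    return mismatches / m, m


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair comparable-site counts.

    ``d[i, j]`` is NaN for pairs without comparable sites; ``m[i, j]`` is the
    number of sites the pair was compared on.
    """

    labels: list[str]
    d: np.ndarray
    m: np.ndarray
    identities: list[TaxonIdentity]

    def __post_init__(self) -> None:
        self._index = {label: i for i, label in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self._index[label]

    def records_of_species(self, species_key: str) -> list[int]:
        return [
            i
            for i, ident in enumerate(self.identities)
            if ident.species_key == species_key
        ]

    def species_keys(self, include_qualified: bool = False) -> list[str]:
        seen: dict[str, None] = {}
        for ident in self.identities:
            if ident.is_qualified and not include_qualified:
                continue
            seen.setdefault(ident.species_key, None)
        return list(seen)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        """Off-diagonal pairs with no comparable sites."""
        ii, jj = np.where(np.isnan(self.d))
        return [
            (self.labels[i], self.labels[j]) for i, j in zip(ii, jj) if i < j
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def write_phylip(self, path) -> None:
        """Square PHYLIP distance format (names truncated to 10 characters)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, label in enumerate(self.labels):
                row = " ".join(f"{x:.6f}" for x in np.nan_to_num(self.d[i]))
                fh.write(f"{label[:10]:<10} {row}\n")


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """Full symmetric p-distance matrix for an alignment.

    Pairs with zero comparable sites get d = NaN (and m = 0); callers decide
    how to treat them.  Uses one-hot products: for valid-site indicators V and
    per-base indicators A_b, comparable counts are V·Vᵀ and match counts are
    Σ_b A_b·A_bᵀ.
    """
    if len(alignment) < 2:
        raise ValueError("distance_matrix needs at least 2 records")
    n = len(alignment)
    length = alignment.n_columns
    codes = np.zeros((n, length), dtype=np.uint8)
    for i, rec in enumerate(alignment):
        codes[i] = _encode(rec.sequence)
    valid = (codes > 0).astype(np.int32)
    m = valid @ valid.T
    matches = np.zeros((n, n), dtype=np.int64)
    for code in range(1, 5):
        indicator = (codes == code).astype(np.int32)
        matches += indicator @ indicator.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(m > 0, (m - matches) / np.maximum(m, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        labels=alignment.labels(),
        d=d,
        m=m,
        identities=[rec.identity for rec in alignment],
    )


@dataclass(frozen=True)
class SpeciesPairSummary:
    species_a: str
    species_b: str
    min_dist: float
    mean_dist: float
    max_dist: float
    n_pairs: int


def species_pair_summary(
    sp_a: str, sp_b: str, matrix: DistanceMatrix
) -> SpeciesPairSummary:
    """Min/mean/max p-distance over all cross-species record pairs."""
    idx_a = matrix.records_of_species(sp_a)
    idx_b = matrix.records_of_species(sp_b)
    if not idx_a:
        raise KeyError(f"species '{sp_a}' has no records in the matrix")
    if not idx_b:
        raise KeyError(f"species '{sp_b}' has no records in the matrix")
    block = matrix.d[np.ix_(idx_a, idx_b)]
    values = block[~np.isnan(block)]
    if values.size == 0:
        raise UndefinedDistanceError(
            f"no defined distances between '{sp_a}' and '{sp_b}'"
        )
    return SpeciesPairSummary(
        species_a=sp_a,
        species_b=sp_b,
        min_dist=float(values.min()),
        mean_dist=float(values.mean()),
        max_dist=float(values.max()),
        n_pairs=int(values.size),
    )


def max_intraspecific(sp: str, matrix: DistanceMatrix) -> Optional[float]:
    """Maximum within-species p-distance, or None for singletons."""
    idx = matrix.records_of_species(sp)
    if len(idx) < 2:
        return None
    block = matrix.d[np.ix_(idx, idx)]
    upper = block[np.triu_indices(len(idx), k=1)]
    values = upper[~np.isnan(upper)]
    if values.size == 0:
        return None
    return float(values.max())


def format_percent(distance: float, decimals: int = 1) -> str:
    """Render a p-distance as percent, rounding half-up (0.0225 -> '2.3')."""
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(repr(distance)) * 100).quantize(quantum, rounding=ROUND_HALF_UP)
    return str(value)
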
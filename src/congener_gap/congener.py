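"""Morphologically calibrated closest-congener distance statistics.

The idea: instead of a universal species-delimitation threshold, summarise —
per genus and geographic distribution class — the distance from each
morphologically uncontroversial "reference" species (confidence group 1) to
its closest congener.  Confidence group 2 species may serve as congeners but
never contribute their own rows; group 3 (species complexes, candidate new
species) is excluded entirely.

Distribution groups stratify species by the maximum linear extent of their
range: ISL for island taxa, C1 for narrow continental endemics (≤ 50 km),
C2 for medium ranges, C3 for large ranges; the C2/C3 cutoff is
subfamily-specific (500 km for Cryptorhynchinae, 2000 km for Apioninae and
Ceutorhynchinae, reflecting the far larger ranges typical of the latter two).

The species-to-species distance is the minimum over all cross-specimen pairs,
which matches the closest-pair reporting convention of barcode-gap analyses
and is the conservative choice for flagging potential synonyms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, format_percent, species_pair_summary
from .io import TaxonAnnotation

__all__ = [
    "DISTRIBUTION_GROUPS",
    "RANGE_CUTOFFS_KM",
    "assign_distribution_group",
    "select_statistics_set",
    "closest_congener",
    "congener_table",
    "CongenerStatRow",
    "GenusTableRow",
    "genus_distribution_table",
    "genus_table_frame",
    "leave_one_out",
    "LeaveOneOutResult",
]

logger = logging.getLogger(__name__)

DISTRIBUTION_GROUPS = ("ISL", "C1", "C2", "C3")

# Narrow-endemic cutoff, and subfamily-specific medium/large cutoff (km).
C1_CUTOFF_KM = 50.0
RANGE_CUTOFFS_KM: Mapping[str, float] = {
    "Cryptorhynchinae": 500.0,
    "Apioninae": 2000.0,
    "Ceutorhynchinae": 2000.0,
}


def assign_distribution_group(annotation: TaxonAnnotation) -> str:
    """Distribution group of one species: island flag first, then range size.

    Boundary convention: C1 = (0, 50], C2 = (50, U], C3 = (U, inf) with U the
    subfamily cutoff — "up to 50 km" includes the endpoint.
    """
    try:
        upper = RANGE_CUTOFFS_KM[annotation.subfamily]
    except KeyError:
        raise ValueError(
            f"no distribution-group cutoffs defined for subfamily "
            f"'{annotation.subfamily}' (species '{annotation.species_key}')"
        ) from None
    if annotation.island:
        return "ISL"
    if annotation.range_km <= C1_CUTOFF_KM:
        return "C1"
    if annotation.range_km <= upper:
        return "C2"
    return "C3"


def select_statistics_set(
    annotations: Mapping[str, TaxonAnnotation],
) -> tuple[set[str], set[str]]:
    """Split annotated species into (reference_set, congener_set).

    Reference species are confidence group 1; the congener pool is groups
    1 and 2.  Group 3 takes no part in the statistics.
    """
    reference = {k for k, a in annotations.items() if a.confidence_group == 1}
    congeners = {k for k, a in annotations.items() if a.confidence_group in (1, 2)}
    if not reference:
        logger.warning("no confidence-group-1 species: reference set is empty")
    return reference, congeners


@dataclass(frozen=True)
class CongenerStatRow:
    reference_species: str
    genus: str
    distribution_group: str
    closest_congener: str
    min_dist: float
    tied_congeners: tuple[str, ...] = ()


def _genus_of(
    species_key: str,
    annotations: Mapping[str, TaxonAnnotation],
    genus_aliases: Optional[Mapping[str, str]] = None,
) -> str:
    genus = annotations[species_key].genus
    if genus_aliases:
        genus = genus_aliases.get(genus, genus)
    return genus


def closest_congener(
    ref: str,
    matrix: DistanceMatrix,
    annotations: Mapping[str, TaxonAnnotation],
    congener_set: set[str],
    genus_aliases: Optional[Mapping[str, str]] = None,
    tie_tol: float = 0.0,
) -> Optional[CongenerStatRow]:
    """Closest congener of a reference species by minimum cross-pair distance.

    Candidates are congener-pool species of the same (possibly aliased) genus
    present in the matrix.  Ties within ``tie_tol`` are recorded; the
    lexicographically first tied species is reported.  Returns None (with a
    logged reason) when the genus has no other congener in the dataset.
    """
    genus = _genus_of(ref, annotations, genus_aliases)
    candidates = sorted(
        sp
        for sp in congener_set
        if sp != ref
        and sp in annotations
        and _genus_of(sp, annotations, genus_aliases) == genus
        and matrix.records_of_species(sp)
    )
    if not matrix.records_of_species(ref):
        logger.info("reference species '%s' has no records in the matrix", ref)
        return None
    if not candidates:
        logger.info(
            "reference species '%s' (genus %s) has no congener in the dataset",
            ref,
            genus,
        )
        return None
    dists = {
        sp: species_pair_summary(ref, sp, matrix).min_dist for sp in candidates
    }
    best = min(dists.values())
    tied = tuple(sp for sp in candidates if dists[sp] <= best + tie_tol)
    return CongenerStatRow(
        reference_species=ref,
        genus=genus,
        distribution_group=assign_distribution_group(annotations[ref]),
        closest_congener=tied[0],
        min_dist=best,
        tied_congeners=tied,
    )


def congener_table(
    matrix: DistanceMatrix,
    annotations: Mapping[str, TaxonAnnotation],
    genus_aliases: Optional[Mapping[str, str]] = None,
) -> list[CongenerStatRow]:
    """One closest-congener row per reference species present in the matrix."""
    reference, congeners = select_statistics_set(annotations)
    rows = []
    for ref in sorted(reference):
        row = closest_congener(ref, matrix, annotations, congeners, genus_aliases)
        if row is not None:
            rows.append(row)
    return rows


@dataclass(frozen=True)
class GenusTableRow:
    genus: str
    distribution_group: str
    min_of_min: float  # p-distance in [0, 1]
    avg_of_min: float
    n_reference_species: int


def genus_distribution_table(rows: Sequence[CongenerStatRow]) -> list[GenusTableRow]:
    """Aggregate per-species minima into genus × distribution-group cells.

    Each cell reports the minimum and the arithmetic mean of the per-species
    closest-congener distances; empty cells are omitted.
    """
    cells: dict[tuple[str, str], list[float]] = {}
    for row in rows:
        cells.setdefault((row.genus, row.distribution_group), []).append(row.min_dist)
    out = []
    for (genus, group), values in sorted(cells.items()):
        out.append(
            GenusTableRow(
                genus=genus,
                distribution_group=group,
                min_of_min=min(values),
                avg_of_min=float(np.mean(values)),
                n_reference_species=len(values),
            )
        )
    return out


def genus_table_frame(rows: Sequence[GenusTableRow]) -> pd.DataFrame:
    """Wide per-genus table with one min/avg percent column pair per group."""
    genera = sorted({r.genus for r in rows})
    by_cell = {(r.genus, r.distribution_group): r for r in rows}
    data: dict[str, list] = {"genus": genera}
    for group in DISTRIBUTION_GROUPS:
        mins, avgs = [], []
        for genus in genera:
            cell = by_cell.get((genus, group))
            mins.append(format_percent(cell.min_of_min) if cell else "")
            avgs.append(format_percent(cell.avg_of_min) if cell else "")
        data[f"{group}_min"] = mins
        data[f"{group}_avg"] = avgs
    return pd.DataFrame(data)


@dataclass
class LeaveOneOutResult:
    excluded: str
    rows: list[CongenerStatRow]
    genus_table: list[GenusTableRow]
    changed: list[tuple[str, Optional[CongenerStatRow], Optional[CongenerStatRow]]] = field(
        default_factory=list
    )

    def delta_frame(self) -> pd.DataFrame:
        data = []
        for ref, before, after in self.changed:
            data.append(
                {
                    "reference_species": ref,
                    "closest_before": before.closest_congener if before else "",
                    "min_dist_before": format_percent(before.min_dist) if before else "",
                    "closest_after": after.closest_congener if after else "",
                    "min_dist_after": format_percent(after.min_dist) if after else "",
                }
            )
        return pd.DataFrame(
            data,
            columns=[
                "reference_species",
                "closest_before",
                "min_dist_before",
                "closest_after",
                "min_dist_after",
            ],
        )


def leave_one_out(
    excluded: str,
    baseline_rows: Sequence[CongenerStatRow],
    matrix_without: DistanceMatrix,
    annotations: Mapping[str, TaxonAnnotation],
    genus_aliases: Optional[Mapping[str, str]] = None,
) -> LeaveOneOutResult:
    """Recompute all statistics with one species' records removed.

    ``matrix_without`` is the distance matrix of the alignment restricted to
    the remaining records (distances among remaining records are unchanged by
    the removal, so recomputing or slicing are equivalent).  The delta lists
    every reference species whose closest congener or minimum distance
    changed; removing a species can only increase remaining minima.
    """
    if excluded not in annotations:
        raise KeyError(f"unknown species '{excluded}'")
    remaining = {k: v for k, v in annotations.items() if k != excluded}
    rows = congener_table(matrix_without, remaining, genus_aliases)
    table = genus_distribution_table(rows)
    before = {r.reference_species: r for r in baseline_rows}
    after = {r.reference_species: r for r in rows}
    changed = []
    for ref in sorted(set(before) | set(after)):
        if ref == excluded:
            continue
        b, a = before.get(ref), after.get(ref)
        if b is None and a is None:
            continue
        if (
            b is None
            or a is None
            or b.closest_congener != a.closest_congener
            or b.min_dist != a.min_dist
        ):
            changed.append((ref, b, a))
    return LeaveOneOutResult(
        excluded=excluded, rows=rows, genus_table=table, changed=changed
    )
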
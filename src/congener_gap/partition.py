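"""Single-threshold MOTU partitioning and concordance with morphospecies.

Threshold-based species delimitation groups sequences into molecular
operational taxonomic units (MOTUs) by single linkage: two records share a
MOTU iff they are connected by a chain of pairwise p-distances at or below
the threshold.  The concordance evaluation then asks, for each
morphologically delimited species, whether its record set coincides exactly
with one MOTU (one-to-one; no split, no lump) and counts the failures in
taxa and in sequences.

This evaluates *given* thresholds; searching for thresholds (ABGD/ASAP style
recursive partitioning) is a separate problem.  Partitions produced by an
external delimitation program can be read in and scored with the same
concordance metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix

__all__ = [
    "Partition",
    "ConcordanceReport",
    "single_linkage_partition",
    "concordance",
    "threshold_sweep",
    "read_partition_tsv",
    "write_partition_tsv",
]


@dataclass
class Partition:
    """A MOTU assignment: disjoint record-label sets covering all records."""

    threshold: float
    motus: list[frozenset[str]]
    linkage: str = "single"

    @property
    def n_motus(self) -> int:
        return len(self.motus)

    def motu_of(self) -> dict[str, int]:
        return {label: i for i, motu in enumerate(self.motus) for label in motu}


def single_linkage_partition(matrix: DistanceMatrix, threshold: float) -> Partition:
    """Connected components of the graph with edges d <= threshold.

    Requires a complete matrix on the records being partitioned: pairs with
    undefined distances are an error (listing them) because connectivity
    through such a pair is undecidable.
    """
    undefined = matrix.undefined_pairs()
    if undefined:
        shown = ", ".join(f"{a}~{b}" for a, b in undefined[:5])
        raise ValueError(
            f"{len(undefined)} record pair(s) have undefined distances "
            f"(no comparable sites): {shown}"
        )
    adjacency = csr_matrix(matrix.d <= threshold)
    n_comp, assignment = connected_components(adjacency, directed=False)
    motus: list[set[str]] = [set() for _ in range(n_comp)]
    for label, comp in zip(matrix.labels, assignment):
        motus[comp].add(label)
    return Partition(threshold=threshold, motus=[frozenset(m) for m in motus])


@dataclass(frozen=True)
class ConcordanceReport:
    threshold: Optional[float]
    n_morphospecies: int
    n_motus: int
    n_wrong_taxa: int
    n_wrong_seqs: int
    n_total_seqs: int

    @property
    def pct_wrong_seqs(self) -> int:
        """Percent of sequences in wrongly assigned taxa, to whole percent (half-up)."""
        if self.n_total_seqs == 0:
            return 0
        frac = Decimal(self.n_wrong_seqs) * 100 / Decimal(self.n_total_seqs)
        return int(frac.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def concordance(
    partition: Partition,
    species_of: Mapping[str, str],
    seq_count_mode: str = "affected_taxa",
) -> ConcordanceReport:
    """Compare a MOTU partition against the morphospecies grouping.

    A morphospecies is correctly assigned iff its record set equals exactly
    one MOTU.  ``n_wrong_taxa`` counts morphospecies failing this test.

    ``seq_count_mode`` selects the sequence-level bookkeeping:

    - ``"affected_taxa"`` (default): every sequence of a wrongly assigned
      morphospecies counts as wrong;
    - ``"misplaced"``: only sequences outside their morphospecies' plurality
      MOTU count, i.e. the records one would have to move to repair splits
      (a pure lump contributes no misplaced sequences under this mode).
    """
    if seq_count_mode not in ("affected_taxa", "misplaced"):
        raise ValueError(f"unknown seq_count_mode '{seq_count_mode}'")
    members: dict[str, set[str]] = {}
    for label in (lab for motu in partition.motus for lab in motu):
        sp = species_of[label]
        members.setdefault(sp, set()).add(label)
    motu_sets = {frozenset(m) for m in partition.motus}
    motu_index = partition.motu_of()
    n_wrong_taxa = 0
    n_wrong_seqs = 0
    for sp, records in members.items():
        if frozenset(records) in motu_sets:
            continue
        n_wrong_taxa += 1
        if seq_count_mode == "affected_taxa":
            n_wrong_seqs += len(records)
        else:
            motus_hit: dict[int, int] = {}
            for label in records:
                motus_hit[motu_index[label]] = motus_hit.get(motu_index[label], 0) + 1
            n_wrong_seqs += len(records) - max(motus_hit.values())
    n_total = sum(len(m) for m in partition.motus)
    return ConcordanceReport(
        threshold=partition.threshold,
        n_morphospecies=len(members),
        n_motus=partition.n_motus,
        n_wrong_taxa=n_wrong_taxa,
        n_wrong_seqs=n_wrong_seqs,
        n_total_seqs=n_total,
    )


@dataclass
class SweepResult:
    reports: list[ConcordanceReport]

    @property
    def best_by_taxa(self) -> ConcordanceReport:
        return min(self.reports, key=lambda r: (r.n_wrong_taxa, r.threshold))

    @property
    def best_by_seqs(self) -> ConcordanceReport:
        return min(self.reports, key=lambda r: (r.pct_wrong_seqs, r.threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": [r.threshold for r in self.reports],
                "n_motus": [r.n_motus for r in self.reports],
                "n_morphospecies": [r.n_morphospecies for r in self.reports],
                "n_wrong_taxa": [r.n_wrong_taxa for r in self.reports],
                "n_wrong_seqs": [r.n_wrong_seqs for r in self.reports],
                "pct_wrong_seqs": [r.pct_wrong_seqs for r in self.reports],
            }
        )


def threshold_sweep(
    matrix: DistanceMatrix,
    species_of: Mapping[str, str],
    thresholds: Sequence[float],
    seq_count_mode: str = "affected_taxa",
) -> SweepResult:
    """Concordance report for each threshold, with the sweep's argmins."""
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    reports = []
    for t in thresholds:
        part = single_linkage_partition(matrix, t)
        reports.append(concordance(part, species_of, seq_count_mode))
    return SweepResult(reports=reports)


def write_partition_tsv(partition: Partition, path) -> None:
    rows = sorted(
        (label, i) for i, motu in enumerate(partition.motus) for label in motu
    )
    pd.DataFrame(rows, columns=["record_id", "motu_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_partition_tsv(path, threshold: Optional[float] = None) -> Partition:
    """Read an externally produced partition (record_id TAB motu_id) for scoring."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"record_id", "motu_id"} <= set(df.columns):
        raise ValueError("partition file needs columns record_id, motu_id")
    groups: dict[str, set[str]] = {}
    for rec, motu in zip(df["record_id"], df["motu_id"]):
        groups.setdefault(motu, set()).add(rec)
    return Partition(
        threshold=threshold if threshold is not None else float("nan"),
        motus=[frozenset(g) for g in groups.values()],
        linkage="external",
    )
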
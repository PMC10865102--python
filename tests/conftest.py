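"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive algorithms (per-site double loops,
transitive closure by repeated squaring, exhaustive set comparison) and
third-party codon tables so they stay independent of the implementation
paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from congener_gap import SimConfig, simulate_dataset
from congener_gap.io import Alignment, SequenceRecord, parse_label


# ---------------------------------------------------------------- oracles

VALID_BASES = set("ACGT")


def oracle_p_distance(a: str, b: str) -> tuple[float | None, int]:
    """Naive per-site p-distance with pairwise deletion."""
    m = 0
    diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in VALID_BASES and y in VALID_BASES:
            m += 1
            if x != y:
                diff += 1
    return (diff / m if m else None), m


def oracle_components(n: int, edges: set[tuple[int, int]]) -> list[frozenset[int]]:
    """Connected components by boolean transitive closure (repeated squaring)."""
    reach = np.eye(n, dtype=bool)
    for i, j in edges:
        reach[i, j] = reach[j, i] = True
    while True:
        nxt = reach | (reach @ reach)
        if np.array_equal(nxt, reach):
            break
        reach = nxt
    comps = []
    seen: set[int] = set()
    for i in range(n):
        if i in seen:
            continue
        comp = frozenset(np.nonzero(reach[i])[0].tolist())
        seen |= comp
        comps.append(comp)
    return comps


def oracle_concordance(
    motus: list[frozenset[str]], species_of: dict[str, str]
) -> tuple[int, int]:
    """(wrong taxa, wrong seqs) by exhaustive species-vs-MOTU set comparison."""
    species_sets: dict[str, set[str]] = {}
    for label, sp in species_of.items():
        species_sets.setdefault(sp, set()).add(label)
    wrong_taxa = 0
    wrong_seqs = 0
    for sp, recs in species_sets.items():
        if not any(frozenset(recs) == motu for motu in motus):
            wrong_taxa += 1
            wrong_seqs += len(recs)
    return wrong_taxa, wrong_seqs


def oracle_stop_codons(sequence: str, frame: int) -> list[int]:
    """Stop-codon scan using Biopython's invertebrate mitochondrial table."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id
    from Bio.Data.IUPACData import ambiguous_dna_values

    stops = set(unambiguous_dna_by_id[5].stop_codons)
    seq = sequence.upper()
    hits = []
    for idx in range((len(seq) - frame) // 3):
        codon = seq[frame + 3 * idx : frame + 3 * idx + 3]
        expansions = [
            "".join(c)
            for c in itertools.product(*(ambiguous_dna_values[b] for b in codon))
        ]
        if all(e in stops for e in expansions):
            hits.append(idx)
    return hits


def random_aligned_pair(
    rng: np.random.Generator, length: int = 60, gap_rate: float = 0.1
) -> tuple[str, str]:
    alphabet = np.array(list("ACGT-NRY"))
    probs = np.array([0.21, 0.21, 0.21, 0.21, gap_rate, 0.04, 0.01, 0.01])
    probs = probs / probs.sum()
    a = "".join(rng.choice(alphabet, size=length, p=probs))
    b = "".join(rng.choice(alphabet, size=length, p=probs))
    return a, b


def toy_alignment(spec: dict[str, list[str]]) -> Alignment:
    """Build an alignment from {species_key: [sequences]} with scheme labels."""
    records = []
    counter = 0
    for species_key, seqs in spec.items():
        for seq in seqs:
            counter += 1
            label = f"{species_key}_{counter:04d}-TOY"
            records.append(
                SequenceRecord(
                    raw_label=label, sequence=seq, identity=parse_label(label)
                )
            )
    return Alignment(records)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def small_dataset():
    """A seeded synthetic library shared by read-only tests."""
    return simulate_dataset(SimConfig(seed=11, n_genera=8, species_per_genus_mean=4.0))


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    from congener_gap import distance_matrix

    return distance_matrix(small_dataset.alignment)
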
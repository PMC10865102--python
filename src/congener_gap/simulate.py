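"""Synthetic barcode datasets with known ground truth.

The generator emulates the statistical structure of a curated CO1 barcode
library: a genus-structured alignment of 658 nt sequences, species with
configurable within- and between-species divergence, a realistic
specimens-per-species distribution (many singletons, a heavy tail of densely
sampled species) and a matching per-species annotation table.

Substitution model
------------------
Per genus, a random ancestor sequence is drawn; each species founder derives
from it by independent per-site substitution with probability
``inter_divergence`` (the substituted base is uniform over the three other
bases); each specimen derives from its founder the same way with probability
``intra_divergence``.  Because every substitution step acts as
``(1-u)·I + u·(J-I)/3`` on the base distribution, the expected p-distance
between two sequences connected by steps ``u_1, ..., u_k`` has the closed
form

    E[d] = 3/4 · (1 - prod_i (1 - 4 u_i / 3)),

which makes oracle tests exact: conspecific specimens are two ``intra``
steps apart, congeneric specimens two ``inter`` plus two ``intra`` steps.

All randomness flows through one seeded generator; the draw order is fixed
(per genus: species count, then per species its specimen count, annotation
fields, founder and specimen mutations), so a seed fully determines the
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io import (
    Alignment,
    SequenceRecord,
    TaxonAnnotation,
    parse_label,
)

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "expected_p_distance",
    "simulate_dataset",
    "inject_numt",
    "make_gap_scenario",
    "species_of_alignment",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic barcode library.

    Divergences are per-site substitution probabilities per step, not
    expected p-distances; use :func:`expected_p_distance` to convert.
    Defaults mirror a densely sampled weevil-style library: 658 nt
    barcodes, ~43% of species sampled once (≈16% of sequences), a
    heavy-tailed specimen count giving a handful of deeply sampled species,
    and founder divergence giving congeneric expected p-distances near 10%.
    """

    seed: int = 0
    n_genera: int = 20
    species_per_genus_mean: float = 5.0  # zero-truncated Poisson
    species_per_genus_fixed: Optional[int] = None  # pin the count for experiments
    # Specimens per species: a three-part mixture — singletons, shallowly
    # sampled species (2-3 specimens) and deeply sampled ones (6+).  The
    # defaults reproduce a densely collected library: ~16% of sequences are
    # singletons and the median sequence sits in a species with ~6 specimens.
    singleton_prob: float = 0.43  # probability a species is sampled once
    deep_species_prob: float = 0.30  # of non-singletons: deeply sampled
    deep_extra_mean: float = 2.3  # deep sizes are 6 + Poisson(this)
    shallow_geom_p: float = 0.77  # shallow sizes are 2 + Geometric(p) - 1
    max_specimens: int = 60
    seq_length: int = 658
    intra_divergence: float = 0.005
    inter_divergence: float = 0.055
    confidence_group_probs: tuple[float, float, float] = (0.6, 0.25, 0.15)
    island_fraction: float = 0.35
    range_km_log_mean: float = 5.0  # lognormal parameters for continental ranges
    range_km_log_sigma: float = 1.8
    subfamily: str = "Cryptorhynchinae"
    gap_rate: float = 0.0
    ambiguity_rate: float = 0.0
    # Keep frame-0 free of stop codons so sequences are coding-plausible and
    # planted pseudogene signals are the only QC flags.
    avoid_stop_codons: bool = True

    def validate(self) -> None:
        if self.n_genera <= 0:
            raise ValueError("n_genera must be positive")
        if self.seq_length <= 0:
            raise ValueError("seq_length must be positive")
        for name in ("intra_divergence", "inter_divergence", "singleton_prob",
                     "island_fraction", "gap_rate", "ambiguity_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if abs(sum(self.confidence_group_probs) - 1.0) > 1e-9:
            raise ValueError("confidence_group_probs must sum to 1")


def expected_p_distance(*steps: float) -> float:
    """Expected p-distance between two sequences joined by substitution steps.

    Each ``step`` is a per-site substitution probability along the path
    between the two sequences (e.g. founder→specimen twice for a
    conspecific pair).
    """
    prod = 1.0
    for u in steps:
        prod *= 1.0 - 4.0 * u / 3.0
    return 0.75 * (1.0 - prod)


@dataclass
class SimulatedDataset:
    alignment: Alignment
    annotations: dict[str, TaxonAnnotation]
    truth: pd.DataFrame
    config: SimConfig


def _letter_suffix(index: int, width: int = 3) -> str:
    chars = []
    for _ in range(width):
        index, rem = divmod(index, 26)
        chars.append(_LETTERS[rem])
    return "".join(reversed(chars))


def _mutate(seq: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-site substitution to a uniformly chosen different base."""
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.size) < prob)[0]
    if hit.size:
        # shift by 1..3 positions in base order => uniform over the other three
        shift = rng.integers(1, 4, size=hit.size)
        idx = np.searchsorted(_BASES, out[hit])
        out[hit] = _BASES[(idx + shift) % 4]
    return out


def _strip_stops(seq: np.ndarray) -> np.ndarray:
    """Repair frame-0 stop codons (TAA/TAG -> TCA/TCG) in place.

    Only the middle base of an offending codon is touched, so no repair can
    create a new stop and a single pass suffices.
    """
    for start in range(0, seq.size - 2, 3):
        codon = seq[start : start + 3].tobytes()
        if codon in (b"TAA", b"TAG"):
            seq[start + 1] = ord("C")
    return seq


def _degrade(seq: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.gap_rate > 0:
        mask = rng.random(seq.size) < config.gap_rate
        seq = np.where(mask, ord("-"), seq).astype(np.uint8)
    if config.ambiguity_rate > 0:
        mask = rng.random(seq.size) < config.ambiguity_rate
        seq = np.where(mask, ord("N"), seq).astype(np.uint8)
    return seq


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate an alignment + annotations + truth table from a config.

    Labels follow the default scheme (``Genus_epithet_NNNN-SYN``).  The truth
    table records, per species, the closed-form expected p-distance to a
    conspecific specimen and to the nearest congener's specimens.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    annotations: dict[str, TaxonAnnotation] = {}
    truth_rows = []
    specimen_counter = 0
    expected_intra = expected_p_distance(
        config.intra_divergence, config.intra_divergence
    )
    expected_inter = expected_p_distance(
        config.inter_divergence,
        config.inter_divergence,
        config.intra_divergence,
        config.intra_divergence,
    )
    for g in range(config.n_genera):
        genus = "Gen" + _letter_suffix(g).capitalize()
        ancestor = rng.choice(_BASES, size=config.seq_length)
        if config.species_per_genus_fixed is not None:
            n_species = config.species_per_genus_fixed
        else:
            n_species = 0
            while n_species == 0:  # zero-truncated Poisson
                n_species = int(rng.poisson(config.species_per_genus_mean))
        for s in range(n_species):
            epithet = "sim" + _letter_suffix(s)
            species_key = f"{genus}_{epithet}"
            if rng.random() < config.singleton_prob:
                n_specimens = 1
            elif rng.random() < config.deep_species_prob:
                n_specimens = min(
                    6 + int(rng.poisson(config.deep_extra_mean)), config.max_specimens
                )
            else:
                n_specimens = min(
                    2 + int(rng.geometric(config.shallow_geom_p)) - 1,
                    config.max_specimens,
                )
            group = int(
                rng.choice((1, 2, 3), p=config.confidence_group_probs)
            )
            island = bool(rng.random() < config.island_fraction)
            range_km = float(
                rng.lognormal(config.range_km_log_mean, config.range_km_log_sigma)
            )
            founder = _mutate(ancestor, config.inter_divergence, rng)
            for _ in range(n_specimens):
                specimen_counter += 1
                specimen = _mutate(founder, config.intra_divergence, rng)
                if config.avoid_stop_codons:
                    specimen = _strip_stops(specimen)
                specimen = _degrade(specimen, config, rng)
                label = f"{genus}_{epithet}_{specimen_counter:04d}-SYN"
                records.append(
                    SequenceRecord(
                        raw_label=label,
                        sequence=specimen.tobytes().decode(),
                        identity=parse_label(label),
                    )
                )
            annotations[species_key] = TaxonAnnotation(
                species_key=species_key,
                genus=genus,
                subfamily=config.subfamily,
                confidence_group=group,
                island=island,
                range_km=range_km,
            )
            truth_rows.append(
                {
                    "species_key": species_key,
                    "genus": genus,
                    "n_specimens": n_specimens,
                    "confidence_group": group,
                    "n_congeners": n_species - 1,
                    "expected_intra_dist": expected_intra,
                    "expected_nearest_congener_dist": expected_inter,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(
        alignment=Alignment(records),
        annotations=annotations,
        truth=truth,
        config=config,
    )


def species_of_alignment(alignment: Alignment) -> dict[str, str]:
    """Mapping record label -> species key (morphospecies assignment)."""
    return {rec.raw_label: rec.identity.species_key for rec in alignment}


def inject_numt(
    alignment: Alignment, record_label: str, seed: int, frame: int = 0
) -> tuple[Alignment, int]:
    """Replace one random in-frame codon of a record with TAA.

    Returns the modified alignment and the 0-based codon index that was
    overwritten (in ungapped coordinates of the given frame).  Used to plant
    pseudogene signals for QC testing.
    """
    labels = alignment.labels()
    if record_label not in labels:
        raise KeyError(f"record '{record_label}' not in alignment")
    rng = np.random.default_rng(seed)
    new_records = []
    codon_index = -1
    for rec in alignment:
        if rec.raw_label != record_label:
            new_records.append(rec)
            continue
        # map ungapped positions back to alignment columns
        cols = [i for i, c in enumerate(rec.sequence) if c != "-"]
        n_codons = (len(cols) - frame) // 3
        if n_codons < 1:
            raise ValueError(f"record '{record_label}' has no complete codon")
        codon_index = int(rng.integers(0, n_codons))
        target = cols[frame + 3 * codon_index : frame + 3 * codon_index + 3]
        seq = list(rec.sequence)
        for col, base in zip(target, "TAA"):
            seq[col] = base
        new_records.append(
            SequenceRecord(
                raw_label=rec.raw_label,
                sequence="".join(seq),
                identity=rec.identity,
            )
        )
    return Alignment(new_records), codon_index


def make_gap_scenario(
    g_lo: float = 0.02,
    g_hi: float = 0.08,
    config: Optional[SimConfig] = None,
    max_tries: int = 20,
) -> SimulatedDataset:
    """Dataset with a planted barcoding gap, verified by direct scan.

    Rejection-samples datasets until every within-species distance is
    <= ``g_lo`` and every between-species distance is >= ``g_hi``.  The
    default config uses low within-species and high founder divergence so
    the gap almost always holds on the first draw.
    """
    from .distances import distance_matrix

    if g_lo >= g_hi:
        raise ValueError("g_lo must be below g_hi")
    if config is None:
        config = SimConfig(
            n_genera=6,
            species_per_genus_mean=4.0,
            intra_divergence=0.002,
            inter_divergence=0.08,
            confidence_group_probs=(1.0, 0.0, 0.0),
        )
    for attempt in range(max_tries):
        dataset = simulate_dataset(replace(config, seed=config.seed + attempt))
        matrix = distance_matrix(dataset.alignment)
        keys = np.array([ident.species_key for ident in matrix.identities])
        same = keys[:, None] == keys[None, :]
        iu = np.triu_indices(len(keys), k=1)
        intra = matrix.d[iu][same[iu]]
        inter = matrix.d[iu][~same[iu]]
        if (intra.size == 0 or np.nanmax(intra) <= g_lo) and (
            inter.size == 0 or np.nanmin(inter) >= g_hi
        ):
            return dataset
    raise RuntimeError(
        f"no gapped dataset found in {max_tries} tries for g_lo={g_lo}, g_hi={g_hi}"
    )
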
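"""Input/output for barcode alignments, taxon annotations and report tables.

Alignments are FASTA files whose record labels encode the taxon identity of
each voucher specimen.  The default label grammar is

    Genus_epithet[_subepithet]_specimenID[_accession]
    Genus_cf_epithet_specimenID[_accession]
    Genus_sp_specimenID[_accession]

e.g. ``Acalles_pilula_1234-PST_MG000001``.  The grammar is configurable via
:class:`LabelScheme` because curated barcode releases each ship their own
naming convention.

Annotations are a tab-separated table with one row per species carrying the
curation metadata used by the statistics: genus, subfamily, confidence group,
island flag and maximum linear distribution range in km.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "LabelScheme",
    "DEFAULT_LABEL_SCHEME",
    "TaxonIdentity",
    "SequenceRecord",
    "Alignment",
    "TaxonAnnotation",
    "LabelParseError",
    "AlignmentError",
    "AnnotationError",
    "parse_label",
    "read_alignment",
    "write_alignment",
    "read_annotations",
    "write_annotations",
    "dataset_summary",
]

# Aligned nucleotides: canonical bases, IUPAC ambiguity codes, gap, N.
ALLOWED_CHARS = frozenset("ACGTURYSWKMBDHVN-")

KNOWN_SUBFAMILIES = ("Cryptorhynchinae", "Apioninae", "Ceutorhynchinae")


class LabelParseError(ValueError):
    """A record label does not match the configured naming scheme."""


class AlignmentError(ValueError):
    """The input does not form a valid alignment."""


class AnnotationError(ValueError):
    """The annotation table is malformed."""


@dataclass(frozen=True)
class LabelScheme:
    """Regular expression with named groups describing the label grammar.

    Required groups: ``genus``, ``species``.  Optional groups:
    ``subspecies``, ``qualifier`` (cf/sp), ``specimen_id``, ``accession``.
    """

    pattern: str
    name: str = "custom"

    def __post_init__(self) -> None:
        compiled = re.compile(self.pattern)
        groups = set(compiled.groupindex)
        missing = {"genus", "species"} - groups
        if missing:
            raise ValueError(f"label scheme lacks required groups: {sorted(missing)}")
        object.__setattr__(self, "_compiled", compiled)

    @property
    def regex(self) -> re.Pattern:
        return self._compiled  # type: ignore[attr-defined]


#: Default scheme: Genus_epithet[_subepithet|_cf_epithet|_sp]_specimenID[_accession]
DEFAULT_LABEL_SCHEME = LabelScheme(
    pattern=(
        r"^(?P<genus>[A-Z][A-Za-z]*)"
        r"(?:_(?P<qualifier>cf|sp))?"
        r"(?:_(?P<species>[a-z][a-z0-9]*))?"
        r"(?:_(?P<subspecies>[a-z][a-z0-9]*))?"
        r"_(?P<specimen_id>[0-9]+-[A-Za-z]+)"
        r"(?:_(?P<accession>[A-Z]{1,2}[0-9]{5,8}))?$"
    ),
    name="default",
)


@dataclass(frozen=True)
class TaxonIdentity:
    """Parsed taxon identity of one sequenced voucher specimen."""

    genus: str
    species_epithet: Optional[str]
    subspecies_epithet: Optional[str] = None
    qualifier: Optional[str] = None  # "cf" or "sp"
    specimen_id: Optional[str] = None
    accession: Optional[str] = None

    @property
    def is_qualified(self) -> bool:
        """True for open-nomenclature records (cf./sp.) excluded from species counts."""
        return self.qualifier is not None

    @property
    def species_key(self) -> str:
        """Genus + species epithet; subspecies collapse into the parent species."""
        if self.species_epithet is None:
            return f"{self.genus}_{self.qualifier or 'sp'}"
        return f"{self.genus}_{self.species_epithet}"


@dataclass(frozen=True)
class SequenceRecord:
    raw_label: str
    sequence: str
    identity: TaxonIdentity

    @property
    def ungapped_length(self) -> int:
        return len(self.sequence) - self.sequence.count("-")


@dataclass
class Alignment:
    """An ordered collection of equal-length aligned sequence records."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if self.records:
            n = len(self.records[0].sequence)
            for rec in self.records:
                if len(rec.sequence) != n:
                    raise AlignmentError(
                        f"record '{rec.raw_label}' has length {len(rec.sequence)}, "
                        f"expected {n}"
                    )

    @property
    def n_columns(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def labels(self) -> list[str]:
        return [rec.raw_label for rec in self.records]

    def subset(self, keep: Iterable[str]) -> "Alignment":
        """New alignment restricted to the given raw labels, preserving order."""
        wanted = set(keep)
        return Alignment([r for r in self.records if r.raw_label in wanted])

    def drop_species(self, species_key: str) -> "Alignment":
        """New alignment with every record of one species removed."""
        return Alignment(
            [r for r in self.records if r.identity.species_key != species_key]
        )


@dataclass(frozen=True)
class TaxonAnnotation:
    """Per-species curation metadata driving the statistics."""

    species_key: str
    genus: str
    subfamily: str  # one of KNOWN_SUBFAMILIES or "other"
    confidence_group: int  # 1 reference, 2 congener-only, 3 excluded
    island: bool
    range_km: float

    def __post_init__(self) -> None:
        if self.confidence_group not in (1, 2, 3):
            raise AnnotationError(
                f"species '{self.species_key}': confidence_group must be 1, 2 or 3, "
                f"got {self.confidence_group}"
            )
        if self.range_km < 0:
            raise AnnotationError(
                f"species '{self.species_key}': range_km must be non-negative"
            )


def parse_label(raw_label: str, scheme: LabelScheme = DEFAULT_LABEL_SCHEME) -> TaxonIdentity:
    """Parse one FASTA record label into a :class:`TaxonIdentity`.

    Raises :class:`LabelParseError` if the label does not match the scheme,
    or if a qualifier-free label has no species epithet.
    """
    match = scheme.regex.match(raw_label)
    if match is None:
        raise LabelParseError(
            f"label '{raw_label}' does not match scheme '{scheme.name}'"
        )
    groups = match.groupdict()
    qualifier = groups.get("qualifier")
    species = groups.get("species")
    if species is None and qualifier is None:
        raise LabelParseError(
            f"label '{raw_label}' has no species epithet and no cf/sp qualifier"
        )
    return TaxonIdentity(
        genus=match.group("genus"),
        species_epithet=species,
        subspecies_epithet=groups.get("subspecies"),
        qualifier=qualifier,
        specimen_id=groups.get("specimen_id"),
        accession=groups.get("accession"),
    )


def _validate_sequence(label: str, seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - ALLOWED_CHARS
    if bad:
        raise AlignmentError(
            f"record '{label}' contains invalid characters: {sorted(bad)}"
        )
    return seq


def read_alignment(
    path: str | Path, scheme: LabelScheme = DEFAULT_LABEL_SCHEME
) -> Alignment:
    """Read an aligned FASTA file with structured labels.

    All records must share one length; sequences are stored uppercase with
    U mapped to T.  Input order is preserved.
    """
    records: list[SequenceRecord] = []
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        label = bio_rec.id
        seq = _validate_sequence(label, str(bio_rec.seq))
        identity = parse_label(label, scheme)
        records.append(SequenceRecord(raw_label=label, sequence=seq, identity=identity))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return Alignment(records)


def write_alignment(alignment: Alignment, path: str | Path, wrap: int = 80) -> None:
    """Write an alignment as FASTA with fixed-width line wrapping."""
    bio_records = [
        _BioSeqRecord(Seq(rec.sequence), id=rec.raw_label, description="")
        for rec in alignment
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(bio_records)


ANNOTATION_COLUMNS = [
    "species_key",
    "genus",
    "subfamily",
    "confidence_group",
    "island",
    "range_km",
]

_TRUE_STRINGS = {"true", "1", "yes", "y"}
_FALSE_STRINGS = {"false", "0", "no", "n"}


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise AnnotationError(f"cannot interpret '{value}' as a boolean island flag")


def read_annotations(path: str | Path) -> dict[str, TaxonAnnotation]:
    """Read the per-species annotation table (TSV with header row).

    Returns a mapping species_key -> :class:`TaxonAnnotation`.  Unknown
    subfamilies are carried through as ``"other"``; duplicate species keys
    and missing columns are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"annotation table missing columns: {missing}")
    dupes = df["species_key"][df["species_key"].duplicated()].tolist()
    if dupes:
        raise AnnotationError(f"duplicate species_key entries: {sorted(set(dupes))}")
    annotations: dict[str, TaxonAnnotation] = {}
    for row in df.itertuples(index=False):
        subfamily = row.subfamily if row.subfamily in KNOWN_SUBFAMILIES else "other"
        try:
            group = int(row.confidence_group)
        except (TypeError, ValueError):
            raise AnnotationError(
                f"species '{row.species_key}': confidence_group "
                f"'{row.confidence_group}' is not an integer"
            ) from None
        ann = TaxonAnnotation(
            species_key=row.species_key,
            genus=row.genus,
            subfamily=subfamily,
            confidence_group=group,
            island=_parse_bool(row.island),
            range_km=float(row.range_km),
        )
        annotations[ann.species_key] = ann
    return annotations


def write_annotations(
    annotations: dict[str, TaxonAnnotation] | Sequence[TaxonAnnotation],
    path: str | Path,
) -> None:
    rows = (
        list(annotations.values())
        if isinstance(annotations, dict)
        else list(annotations)
    )
    df = pd.DataFrame(
        {
            "species_key": [a.species_key for a in rows],
            "genus": [a.genus for a in rows],
            "subfamily": [a.subfamily for a in rows],
            "confidence_group": [a.confidence_group for a in rows],
            "island": [a.island for a in rows],
            "range_km": [a.range_km for a in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SummaryReport:
    n_sequences: int
    n_species: int
    n_qualified_sequences: int
    n_singleton_species: int
    median_specimens_per_species: float
    specimens_per_species: dict[str, int] = field(repr=False, default_factory=dict)


def dataset_summary(alignment: Alignment) -> SummaryReport:
    """Dataset composition: sequence, species and singleton counts.

    Species are counted on genus + epithet; open-nomenclature records
    (cf./sp.) are excluded from species counts, and subspecies collapse
    into their parent species.
    """
    counts: dict[str, int] = {}
    n_qualified = 0
    for rec in alignment:
        if rec.identity.is_qualified:
            n_qualified += 1
            continue
        key = rec.identity.species_key
        counts[key] = counts.get(key, 0) + 1
    n_species = len(counts)
    singletons = sum(1 for v in counts.values() if v == 1)
    median = float(statistics.median(counts.values())) if counts else 0.0
    return SummaryReport(
        n_sequences=len(alignment),
        n_species=n_species,
        n_qualified_sequences=n_qualified,
        n_singleton_species=singletons,
        median_specimens_per_species=median,
        specimens_per_species=counts,
    )
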
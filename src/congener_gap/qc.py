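"""Quality screening of barcode sequences.

Nuclear copies of mitochondrial genes (NUMTs) co-amplify with the true CO1
barcode and typically reveal themselves through in-frame stop codons, since
pseudogenes are released from coding constraint.  This module scans each
record's reading frame for stop codons under the invertebrate mitochondrial
genetic code (where TAA and TAG are the only stops; AGA/AGG encode serine,
unlike the standard code) and keeps per-record length accounting against the
full 658 nt barcode and the 500 nt minimum accepted by reference databases.

Screening flags records; it never removes them.  Whether a flagged record is
excluded is a curatorial decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable

import pandas as pd

from .io import Alignment

__all__ = [
    "INVERTEBRATE_MITO_STOPS",
    "STANDARD_STOPS",
    "FULL_BARCODE_LENGTH",
    "MIN_BARCODE_LENGTH",
    "find_stop_codons",
    "qc_screen",
    "RecordQC",
    "QCReport",
]

FULL_BARCODE_LENGTH = 658
MIN_BARCODE_LENGTH = 500

# NCBI translation table 5 (invertebrate mitochondrial): TGA = Trp, AGA/AGG = Ser.
INVERTEBRATE_MITO_STOPS = frozenset({"TAA", "TAG"})
# NCBI translation table 1, for comparison/screening of contaminants.
STANDARD_STOPS = frozenset({"TAA", "TAG", "TGA"})

_STOP_SETS = {
    "invert-mito": INVERTEBRATE_MITO_STOPS,
    "standard": STANDARD_STOPS,
}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _resolutions(codon: str) -> Iterable[str]:
    sets = [_IUPAC.get(base) for base in codon]
    if any(s is None for s in sets):
        raise ValueError(f"codon '{codon}' contains a non-IUPAC character")
    return ("".join(bases) for bases in product(*sets))


def find_stop_codons(sequence: str, frame: int = 0, code: str = "invert-mito") -> list[int]:
    """Return 0-based codon indices of stop codons in the given frame.

    The sequence must be ungapped.  A codon containing ambiguity codes counts
    as a stop only if *every* resolution of the ambiguity is a stop (e.g.
    ``TAR`` is a stop under the invertebrate mitochondrial code, ``TAN`` is
    not).  An incomplete terminal codon is ignored.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    try:
        stops = _STOP_SETS[code]
    except KeyError:
        raise ValueError(f"unknown genetic code '{code}'") from None
    seq = sequence.upper()
    if "-" in seq:
        raise ValueError("find_stop_codons expects an ungapped sequence")
    hits: list[int] = []
    n_codons = (len(seq) - frame) // 3
    for idx in range(n_codons):
        codon = seq[frame + 3 * idx : frame + 3 * idx + 3]
        if codon in stops:
            hits.append(idx)
        elif not set(codon) <= {"A", "C", "G", "T"}:
            if all(res in stops for res in _resolutions(codon)):
                hits.append(idx)
    return hits


@dataclass(frozen=True)
class RecordQC:
    raw_label: str
    ungapped_length: int
    is_full_length: bool
    below_min_length: bool
    stop_codon_positions: tuple[int, ...]

    @property
    def flagged_numt(self) -> bool:
        return len(self.stop_codon_positions) > 0


@dataclass
class QCReport:
    records: list[RecordQC]
    frame: int
    code: str

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_full_length(self) -> int:
        return sum(1 for r in self.records if r.is_full_length)

    @property
    def n_shorter(self) -> int:
        return sum(1 for r in self.records if not r.is_full_length)

    @property
    def n_below_min(self) -> int:
        return sum(1 for r in self.records if r.below_min_length)

    @property
    def flagged(self) -> list[RecordQC]:
        return [r for r in self.records if r.flagged_numt]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "record": [r.raw_label for r in self.records],
                "ungapped_length": [r.ungapped_length for r in self.records],
                "full_length": [r.is_full_length for r in self.records],
                "below_min_length": [r.below_min_length for r in self.records],
                "n_stop_codons": [len(r.stop_codon_positions) for r in self.records],
                "stop_codon_positions": [
                    ",".join(map(str, r.stop_codon_positions)) for r in self.records
                ],
                "flagged_numt": [r.flagged_numt for r in self.records],
            }
        )


def qc_screen(alignment: Alignment, frame: int = 0, code: str = "invert-mito") -> QCReport:
    """Screen every record of an alignment for NUMT signals and length classes.

    The reading frame is a dataset property (barcodes are primer-trimmed, so
    the frame depends on the trimming) and must be supplied by the caller.
    Gaps are removed before codon scanning.
    """
    rows: list[RecordQC] = []
    for rec in alignment:
        ungapped = rec.sequence.replace("-", "")
        stops = find_stop_codons(ungapped, frame=frame, code=code)
        rows.append(
            RecordQC(
                raw_label=rec.raw_label,
                ungapped_length=len(ungapped),
                is_full_length=len(ungapped) == FULL_BARCODE_LENGTH,
                below_min_length=len(ungapped) < MIN_BARCODE_LENGTH,
                stop_codon_positions=tuple(stops),
            )
        )
    return QCReport(records=rows, frame=frame, code=code)
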
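"""Streaming paired-FASTQ ingest for 10x 3' amplicon libraries.

R1 carries the cell barcode followed by the UMI (16 + 12 nt under the v3
chemistry, a 28 bp read); R2 is the amplicon cDNA read (nominally 91 bp).
Records are streamed pairwise — no whole-file buffering — and barcodes may
optionally be corrected against a whitelist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "ChemistrySpec",
    "ReadObservation",
    "Whitelist",
    "IngestCounters",
    "IngestError",
    "parse_read_pairs",
    "correct_barcode",
]


class IngestError(RuntimeError):
    """Fatal FASTQ pairing or format error."""


@dataclass(frozen=True)
class ChemistrySpec:
    """Barcode/UMI layout of R1 (10x 3' v3: 16 nt barcode + 12 nt UMI)."""

    barcode_len: int = 16
    umi_len: int = 12

    def __post_init__(self) -> None:
        if self.barcode_len < 1 or self.umi_len < 1:
            raise ValueError("barcode_len and umi_len must be >= 1")

    @property
    def r1_min_len(self) -> int:
        return self.barcode_len + self.umi_len


@dataclass(frozen=True)
class ReadObservation:
    """One read pair after barcode/UMI extraction."""

    read_id: str
    barcode: str
    umi: str
    cdna: str


class Whitelist:
    """Set of valid cell barcodes.

    Entries may carry a trailing GEM-well suffix (``-1`` style); it is
    stripped on load.
    """

    def __init__(self, barcodes) -> None:
        cleaned = {bc.split("-")[0] for bc in barcodes if bc.strip()}
        if not cleaned:
            raise ValueError("whitelist must be non-empty")
        lengths = {len(bc) for bc in cleaned}
        if len(lengths) != 1:
            raise ValueError(f"whitelist entries have mixed lengths {sorted(lengths)}")
        self.barcodes: frozenset[str] = frozenset(cleaned)
        self.entry_len: int = lengths.pop()

    def __contains__(self, bc: str) -> bool:
        return bc in self.barcodes

    def __len__(self) -> int:
        return len(self.barcodes)

    @classmethod
    def load(cls, path) -> "Whitelist":
        with open(path) as fh:
            return cls(line.strip() for line in fh)


@dataclass
class IngestCounters:
    """Read-pair accounting; yielded + rejected always equals total."""

    total_pairs: int = 0
    yielded: int = 0
    rejected_short_r1: int = 0
    rejected_n_in_barcode_umi: int = 0
    rejected_empty_cdna: int = 0

    @property
    def rejected(self) -> int:
        return (
            self.rejected_short_r1
            + self.rejected_n_in_barcode_umi
            + self.rejected_empty_cdna
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "total_pairs": self.total_pairs,
            "yielded": self.yielded,
            "rejected_short_r1": self.rejected_short_r1,
            "rejected_n_in_barcode_umi": self.rejected_n_in_barcode_umi,
            "rejected_empty_cdna": self.rejected_empty_cdna,
        }


def parse_read_pairs(
    r1_path,
    r2_path,
    chem: ChemistrySpec = ChemistrySpec(),
    counters: IngestCounters | None = None,
) -> Iterator[ReadObservation]:
    """Stream paired FASTQ records, extracting barcode and UMI from R1.

    Yields one :class:`ReadObservation` per accepted pair; rejected pairs
    (short R1, N in barcode/UMI, empty R2) are counted in ``counters``.
    Files may be plain or gzip-compressed.

    Raises
    ------
    IngestError
        If R1 and R2 have unequal record counts (reported with the record
        index at which one file ended).
    """
    if counters is None:
        counters = IngestCounters()
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        it1, it2 = iter(f1), iter(f2)
        index = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                break
            if rec1 is None or rec2 is None:
                which = "R1" if rec1 is None else "R2"
                raise IngestError(
                    f"record count mismatch: {which} exhausted at pair index {index}"
                )
            index += 1
            counters.total_pairs += 1
            r1_seq = rec1.sequence.upper()
            if len(r1_seq) < chem.r1_min_len:
                counters.rejected_short_r1 += 1
                continue
            barcode = r1_seq[: chem.barcode_len]
            umi = r1_seq[chem.barcode_len : chem.barcode_len + chem.umi_len]
            if "N" in barcode or "N" in umi:
                counters.rejected_n_in_barcode_umi += 1
                continue
            cdna = (rec2.sequence or "").upper()
            if not cdna:
                counters.rejected_empty_cdna += 1
                continue
            counters.yielded += 1
            yield ReadObservation(read_id=rec1.name, barcode=barcode, umi=umi, cdna=cdna)


def correct_barcode(bc: str, wl: Whitelist, max_hamming: int = 0) -> str | None:
    """Match a barcode against the whitelist, optionally rescuing 1-mismatch
    barcodes when the rescue is unambiguous.

    Returns the (possibly corrected) barcode, or ``None`` to signal discard.
    With ``max_hamming=1``, a barcode at Hamming distance 1 from exactly one
    whitelist entry is corrected to it; two or more equidistant candidates
    are ambiguous and discarded.
    """
    if len(bc) != wl.entry_len:
        return None
    if bc in wl:
        return bc
    if max_hamming < 1:
        return None
    candidate: str | None = None
    bases = "ACGT"
    for i, orig in enumerate(bc):
        prefix, suffix = bc[:i], bc[i + 1 :]
        for b in bases:
            if b == orig:
                continue
            alt = prefix + b + suffix
            if alt in wl:
                if candidate is not None:
                    return None  # ambiguous rescue
                candidate = alt
    return candidate
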
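"""UMI consensus calling and per-cell genotype assignment.

Reads sharing one (cell barcode, UMI) pair are PCR copies of a single
cDNA molecule, so their allele evidence is collapsed into one UMI call.
A UMI is filtered when its matched-read depth is below five reads, or
when it carries both wildtype and mutant (or two distinct mutant)
sequences; a surviving UMI reports its unanimous allele.  A cell is
assigned mutant or wildtype status from its called UMIs, the assignment
being confident when supported by at least two UMIs.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable

from scfishhook.amplicon import WILDTYPE
from scfishhook.ingest import ReadObservation
from scfishhook.matcher import MatchResult

__all__ = [
    "UmiParams",
    "UmiGroup",
    "UmiCall",
    "CellGenotype",
    "RunSummary",
    "group_by_umi",
    "call_umi",
    "genotype_cell",
    "genotype_cells",
    "summarize_run",
]


@dataclass(frozen=True)
class UmiParams:
    """Filtering thresholds: >=5 reads per UMI, >=2 UMIs per confident call."""

    min_reads_per_umi: int = 5
    min_umis_per_call: int = 2

    def __post_init__(self) -> None:
        if self.min_reads_per_umi < 1 or self.min_umis_per_call < 1:
            raise ValueError("UMI thresholds must be >= 1")


@dataclass
class UmiGroup:
    """Matched-read allele tallies for one (barcode, UMI) molecule."""

    barcode: str
    umi: str
    tallies: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.tallies.values())


@dataclass(frozen=True)
class UmiCall:
    """Consensus outcome for one UMI group after coverage/conflict filters."""

    barcode: str
    umi: str
    status: str  # "called" | "filtered_low_coverage" | "filtered_conflict"
    allele: str | None  # set iff called
    depth: int


@dataclass(frozen=True)
class CellGenotype:
    """Final per-barcode assignment with its supporting UMI tallies."""

    barcode: str
    umi_counts: dict[str, int]
    status: str  # "mutant" | "wildtype" | "unassigned"
    assigned_variant: str | None  # set iff mutant
    confident: bool


def group_by_umi(
    matches: Iterable[tuple[ReadObservation, MatchResult]],
) -> list[UmiGroup]:
    """Group matched reads by (barcode, UMI) and tally allele identities.

    Only unambiguously matched reads reach this stage.  Output is sorted by
    barcode then UMI, so grouping is independent of input order.
    """
    tallies: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for obs, match in matches:
        tallies[(obs.barcode, obs.umi)][match.allele_id] += 1
    return [
        UmiGroup(barcode=bc, umi=umi, tallies=dict(tallies[(bc, umi)]))
        for bc, umi in sorted(tallies)
    ]


def call_umi(group: UmiGroup, params: UmiParams = UmiParams()) -> UmiCall:
    """Apply the coverage filter, then the conflict filter, then call.

    A group below ``min_reads_per_umi`` total depth is filtered for low
    coverage (checked first, so a shallow mixed group reports low coverage);
    a group mixing wildtype with a variant, or two distinct variants, is
    conflict-filtered; otherwise the unanimous allele is called.
    """
    if not group.tallies:
        raise ValueError("empty UMI group")
    depth = group.depth
    if depth < params.min_reads_per_umi:
        status, allele = "filtered_low_coverage", None
    elif len(group.tallies) > 1:
        status, allele = "filtered_conflict", None
    else:
        status, allele = "called", next(iter(group.tallies))
    return UmiCall(barcode=group.barcode, umi=group.umi, status=status, allele=allele, depth=depth)


def genotype_cell(calls: list[UmiCall], params: UmiParams = UmiParams()) -> CellGenotype:
    """Assign wildtype/mutant status to one cell from its UMI calls.

    A cell is mutant when some variant has at least ``min_umis_per_call``
    called UMIs (the most-supported variant is assigned; an exact tie
    between distinct variants is unassigned).  It is wildtype when the
    wildtype UMI count reaches the threshold and no variant UMI exists at
    all.  Cells with both mutant and wildtype UMIs above threshold are
    mutant — heterozygous tumor cells express both alleles.  ``confident``
    records whether the supporting count met the threshold.
    """
    barcodes = {c.barcode for c in calls}
    if len(barcodes) > 1:
        raise ValueError(f"calls span multiple barcodes: {sorted(barcodes)}")
    if not calls:
        raise ValueError("no UMI calls supplied")
    barcode = calls[0].barcode
    counts: Counter = Counter()
    for c in calls:
        if c.status == "called":
            counts[c.allele] += 1
    n_wt = counts.get(WILDTYPE, 0)
    variant_counts = {a: n for a, n in counts.items() if a != WILDTYPE}
    best_n = max(variant_counts.values(), default=0)
    if best_n >= params.min_umis_per_call:
        top = sorted(a for a, n in variant_counts.items() if n == best_n)
        if len(top) > 1:
            status, assigned, confident = "unassigned", None, False
        else:
            status, assigned, confident = "mutant", top[0], True
    elif n_wt >= params.min_umis_per_call and best_n == 0:
        status, assigned, confident = "wildtype", None, True
    else:
        status, assigned, confident = "unassigned", None, False
    return CellGenotype(
        barcode=barcode,
        umi_counts=dict(counts),
        status=status,
        assigned_variant=assigned,
        confident=confident,
    )


def genotype_cells(calls: list[UmiCall], params: UmiParams = UmiParams()) -> list[CellGenotype]:
    """Genotype every barcode present in ``calls``, sorted by barcode."""
    by_barcode: dict[str, list[UmiCall]] = defaultdict(list)
    for c in calls:
        by_barcode[c.barcode].append(c)
    return [genotype_cell(by_barcode[bc], params) for bc in sorted(by_barcode)]


@dataclass
class RunSummary:
    """Deterministic counters over a genotyping run."""

    cells_by_status: dict[str, int]
    cells_by_variant: dict[str, int]
    umis_by_status: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "cells_by_status": dict(sorted(self.cells_by_status.items())),
            "cells_by_variant": dict(sorted(self.cells_by_variant.items())),
            "umis_by_status": dict(sorted(self.umis_by_status.items())),
        }


def summarize_run(
    genotypes: list[CellGenotype], calls: list[UmiCall] | None = None
) -> RunSummary:
    """Tally cells by status and assigned variant, and UMIs by call status."""
    cells_by_status = {"mutant": 0, "wildtype": 0, "unassigned": 0}
    cells_by_variant: Counter = Counter()
    for g in genotypes:
        cells_by_status[g.status] += 1
        if g.assigned_variant is not None:
            cells_by_variant[g.assigned_variant] += 1
    umis_by_status = {"called": 0, "filtered_low_coverage": 0, "filtered_conflict": 0}
    for c in calls or []:
        umis_by_status[c.status] += 1
    return RunSummary(
        cells_by_status=cells_by_status,
        cells_by_variant=dict(cells_by_variant),
        umis_by_status=umis_by_status,
    )
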
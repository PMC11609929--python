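"""Seeded synthetic amplicon sequencing runs.

Generates paired FASTQ (R1 = barcode + UMI, R2 = amplicon cDNA windows)
plus a per-cell truth table, emulating a 10x 3' v3 nested-PCR amplicon
library: per-cell genotype truth, a configurable number of UMIs per cell
and reads per UMI, uniform per-base substitution sequencing error on R2,
and ambient reads carrying random non-whitelist barcodes.

All reads of one UMI share a single amplicon window (they are PCR copies
of one molecule); the window is drawn uniformly among placements that
fully contain the cell allele's probe window, mirroring the matcher's
full-containment rule.  Mutant cells emit mutant-allele molecules only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from scfishhook.amplicon import (
    AmpliconReference,
    DesignParams,
    Fishhook,
    VariantSpec,
    WILDTYPE,
    build_fishhooks,
)

__all__ = ["SimParams", "CellTruth", "SimResult", "simulate_run", "write_truth_table"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic run.

    ``umis_per_cell`` and ``reads_per_umi`` are either a fixed integer or a
    ``(mean, dispersion)`` tuple for negative-binomial counts (dispersion is
    the NB size parameter; smaller = more overdispersed), truncated at 1.
    ``mutant_fraction`` maps variant_id to the proportion of cells carrying
    it; the remainder of cells are wildtype.  ``ambient_fraction`` is the
    proportion of all emitted reads given fresh random non-whitelist
    barcodes.
    """

    n_cells: int
    mutant_fraction: dict[str, float] = field(default_factory=dict)
    umis_per_cell: int | tuple[float, float] = 3
    reads_per_umi: int | tuple[float, float] = 6
    error_rate: float = 0.0
    ambient_fraction: float = 0.0
    r1_len: int = 28
    r2_len: int = 91
    barcode_len: int = 16
    umi_len: int = 12
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        total = sum(self.mutant_fraction.values())
        if any(f < 0 or f > 1 for f in self.mutant_fraction.values()) or total > 1 + 1e-9:
            raise ValueError("mutant fractions must lie in [0,1] and sum to <= 1")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must lie in [0,1]")
        if not 0 <= self.ambient_fraction < 1:
            raise ValueError("ambient_fraction must lie in [0,1)")
        if self.r1_len < self.barcode_len + self.umi_len:
            raise ValueError("r1_len must cover barcode + UMI")


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one simulated cell."""

    barcode: str
    true_status: str  # WILDTYPE or variant_id
    n_umis: int
    n_reads: int


@dataclass
class SimResult:
    """Paths and truth produced by one simulated run."""

    r1_path: Path
    r2_path: Path
    truth: list[CellTruth]
    n_ambient_reads: int

    @property
    def total_reads(self) -> int:
        return sum(t.n_reads for t in self.truth) + self.n_ambient_reads


def _draw_counts(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, int):
        return np.full(n, spec, dtype=np.int64)
    mean, dispersion = spec
    if mean <= 0 or dispersion <= 0:
        raise ValueError("count distribution mean and dispersion must be > 0")
    p = dispersion / (dispersion + mean)
    counts = rng.negative_binomial(dispersion, p, size=n)
    return np.maximum(counts, 1)


def _random_seqs(n: int, length: int, rng: np.random.Generator) -> list[str]:
    if n == 0:
        return []
    arr = _BASES[rng.integers(0, 4, size=(n, length))]
    return [row.tobytes().decode() for row in arr]


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    if hit.any():
        idx = np.nonzero(hit)[0]
        # substitute with a uniformly chosen *different* base
        shifts = rng.integers(1, 4, size=idx.size)
        current = np.searchsorted(_BASES, arr[idx])
        arr[idx] = _BASES[(current + shifts) % 4]
    return arr.tobytes().decode()


def _open_out(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def simulate_run(
    ref: AmpliconReference,
    variants: list[VariantSpec],
    params: SimParams,
    out_dir,
    design: DesignParams = DesignParams(),
    gzip_output: bool = False,
) -> SimResult:
    """Generate an R1/R2 FASTQ pair and truth table for one synthetic run.

    Deterministic for a fixed ``params.rng_seed``: identical parameters
    yield byte-identical files.  Raises ``ValueError`` when the geometry is
    infeasible (R2 shorter than the probe window).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if params.r2_len < design.probe_len:
        raise ValueError(
            f"r2_len {params.r2_len} cannot contain a {design.probe_len} nt probe window"
        )
    if params.r2_len > len(ref.sequence):
        raise ValueError("r2_len exceeds amplicon length")
    rng = np.random.default_rng(params.rng_seed)
    hooks = build_fishhooks(ref, variants, design)
    mut_hook: dict[str, Fishhook] = {
        fh.variant_id: fh for fh in hooks if fh.allele_class == "mutant"
    }

    # deterministic genotype assignment: exact counts per variant, shuffled
    statuses = []
    for vid in sorted(params.mutant_fraction):
        statuses.extend([vid] * round(params.mutant_fraction[vid] * params.n_cells))
    if len(statuses) > params.n_cells:
        raise ValueError("mutant fractions allocate more cells than n_cells")
    statuses.extend([WILDTYPE] * (params.n_cells - len(statuses)))
    rng.shuffle(statuses)

    # unique cell barcodes
    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < params.n_cells:
        for bc in _random_seqs(params.n_cells - len(barcodes), params.barcode_len, rng):
            if bc not in seen:
                seen.add(bc)
                barcodes.append(bc)
    whitelist = set(barcodes)

    umi_counts = _draw_counts(params.umis_per_cell, params.n_cells, rng)

    # per-variant mutated amplicon copies
    mutated: dict[str, str] = {}
    for vid, fh in mut_hook.items():
        s = list(ref.sequence)
        for off in fh.discriminating_offsets:
            s[fh.amplicon_start + off] = fh.sequence[off]
        mutated[vid] = "".join(s)

    reads: list[tuple[str, str, str]] = []  # (barcode, umi, r2 sequence)
    truth: list[CellTruth] = []
    amplicon_len = len(ref.sequence)
    # wildtype molecules are drawn around a uniformly chosen probe locus
    wt_loci = sorted({fh.amplicon_start for fh in mut_hook.values()})
    for bc, status, n_umis in zip(barcodes, statuses, umi_counts):
        n_umis = int(n_umis)
        read_counts = _draw_counts(params.reads_per_umi, n_umis, rng)
        cell_reads = 0
        template = ref.sequence if status == WILDTYPE else mutated[status]
        for n_reads in read_counts:
            umi = _random_seqs(1, params.umi_len, rng)[0]
            if status == WILDTYPE:
                locus = wt_loci[int(rng.integers(0, len(wt_loci)))]
            else:
                locus = mut_hook[status].amplicon_start
            lo = max(0, locus + design.probe_len - params.r2_len)
            hi = min(locus, amplicon_len - params.r2_len)
            window_start = int(rng.integers(lo, hi + 1))
            molecule = template[window_start : window_start + params.r2_len]
            for _ in range(int(n_reads)):
                reads.append((bc, umi, _apply_errors(molecule, params.error_rate, rng)))
            cell_reads += int(n_reads)
        truth.append(CellTruth(barcode=bc, true_status=status, n_umis=n_umis, n_reads=cell_reads))

    n_cell_reads = len(reads)
    n_ambient = 0
    if params.ambient_fraction > 0 and n_cell_reads > 0:
        n_ambient = round(
            n_cell_reads * params.ambient_fraction / (1 - params.ambient_fraction)
        )
        for _ in range(n_ambient):
            while True:
                bc = _random_seqs(1, params.barcode_len, rng)[0]
                if bc not in whitelist:
                    break
            umi = _random_seqs(1, params.umi_len, rng)[0]
            window_start = int(rng.integers(0, amplicon_len - params.r2_len + 1))
            molecule = ref.sequence[window_start : window_start + params.r2_len]
            reads.append((bc, umi, _apply_errors(molecule, params.error_rate, rng)))

    order = rng.permutation(len(reads))
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    r1_path = out_dir / f"sim_R1{suffix}"
    r2_path = out_dir / f"sim_R2{suffix}"
    pad = "A" * (params.r1_len - params.barcode_len - params.umi_len)
    q1 = "I" * params.r1_len
    q2 = "I" * params.r2_len
    with _open_out(r1_path) as f1, _open_out(r2_path) as f2:
        for rank, i in enumerate(order):
            bc, umi, r2_seq = reads[i]
            rid = f"simread:{rank}"
            f1.write(f"@{rid}\n{bc}{umi}{pad}\n+\n{q1}\n")
            f2.write(f"@{rid}\n{r2_seq}\n+\n{q2}\n")
    return SimResult(r1_path=r1_path, r2_path=r2_path, truth=truth, n_ambient_reads=n_ambient)


def write_truth_table(truth: list[CellTruth], path) -> None:
    """Write the per-cell truth table TSV."""
    with open(path, "w") as fh:
        fh.write("barcode\ttrue_status\tn_umis\tn_reads\n")
        for t in truth:
            fh.write(f"{t.barcode}\t{t.true_status}\t{t.n_umis}\t{t.n_reads}\n")
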
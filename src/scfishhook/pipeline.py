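"""End-to-end genotyping runs: file loading, stage wiring, outputs.

A run reads the amplicon reference (FASTA), the hotspot variant table
(TSV), paired FASTQ inputs and an optional barcode whitelist; it builds
the probe set, matches every read, collapses evidence by UMI, genotypes
each cell and writes deterministic TSV/JSON outputs plus a manifest
recording every parameter and input checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from Bio import SeqIO

from scfishhook.amplicon import (
    AmpliconReference,
    DesignParams,
    Fishhook,
    VariantSpec,
    VariantValidationError,
    WILDTYPE,
    build_fishhooks,
    validate_probe_set,
)
from scfishhook.genotyper import (
    CellGenotype,
    UmiCall,
    UmiParams,
    call_umi,
    genotype_cells,
    group_by_umi,
    summarize_run,
)
from scfishhook.ingest import (
    ChemistrySpec,
    IngestCounters,
    Whitelist,
    correct_barcode,
    parse_read_pairs,
)
from scfishhook.matcher import MatchCounters, MatcherParams, build_seed_index, match_read

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunResult",
    "load_reference",
    "load_variant_table",
    "load_whitelist",
    "write_probe_set",
    "run_genotype",
]


def load_reference(path, cds_offset: int | None = None, target_codons=(12, 61)) -> AmpliconReference:
    """Load a single-record amplicon FASTA.

    ``cds_offset`` may be given explicitly or embedded in the FASTA header
    description as ``cds_offset=<int>`` (``codons=<lo>-<hi>`` likewise).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record in {path}, found {len(records)}")
    rec = records[0]
    for token in rec.description.split():
        if token.startswith("cds_offset=") and cds_offset is None:
            cds_offset = int(token.split("=", 1)[1])
        if token.startswith("codons="):
            lo, hi = token.split("=", 1)[1].split("-")
            target_codons = (int(lo), int(hi))
    if cds_offset is None:
        raise ValueError(
            "cds_offset not given and not found in FASTA header "
            "(expected a 'cds_offset=<int>' token in the description)"
        )
    return AmpliconReference(
        name=rec.id,
        sequence=str(rec.seq).upper(),
        cds_offset=cds_offset,
        target_codons=tuple(target_codons),
    )


def load_variant_table(path) -> list[VariantSpec]:
    """Parse the hotspot variant TSV (``variant_id codon ref_codon alt_codon``).

    Comment lines (``#``) are skipped; malformed rows raise with their line
    number; variants changing sequence length (indels) are rejected.
    """
    variants: list[VariantSpec] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                header_seen = True
                if fields[0] == "variant_id":
                    continue
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}")
            vid, codon_s, ref_c, alt_c = (f.strip() for f in fields)
            try:
                codon = int(codon_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: codon {codon_s!r} is not an integer") from None
            if len(ref_c) != len(alt_c):
                raise ValueError(
                    f"{path}:{lineno}: {vid}: ref/alt length change (indel) not supported"
                )
            try:
                variants.append(
                    VariantSpec(variant_id=vid, codon=codon, ref_codon=ref_c.upper(), alt_codon=alt_c.upper())
                )
            except VariantValidationError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not variants:
        raise ValueError(f"{path}: no variants parsed (at least one is required)")
    return variants


def load_whitelist(path) -> Whitelist:
    """Load a plain-text barcode whitelist (GEM-well suffixes stripped)."""
    return Whitelist.load(path)


def write_probe_set(fishhooks: list[Fishhook], path) -> None:
    with open(path, "w") as fh:
        fh.write("fishhook_id\tvariant_id\tallele_class\tamplicon_start\tdiscriminating_offsets\tsequence\n")
        for p in fishhooks:
            offs = ",".join(str(o) for o in p.discriminating_offsets)
            fh.write(
                f"{p.fishhook_id}\t{p.variant_id}\t{p.allele_class}\t{p.amplicon_start}\t{offs}\t{p.sequence}\n"
            )


@dataclass
class RunConfig:
    """All inputs and parameters of one genotyping run."""

    reference: Path
    variants: Path
    r1: Path
    r2: Path
    out_dir: Path
    whitelist: Path | None = None
    whitelist_max_hamming: int = 0
    cds_offset: int | None = None
    design: DesignParams = field(default_factory=DesignParams)
    matcher: MatcherParams = field(default_factory=MatcherParams)
    umi: UmiParams = field(default_factory=UmiParams)
    chemistry: ChemistrySpec = field(default_factory=ChemistrySpec)
    write_match_log: bool = False


@dataclass
class RunResult:
    genotypes: list[CellGenotype]
    calls: list[UmiCall]
    summary: dict
    out_dir: Path


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_umi_calls(calls: list[UmiCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("barcode\tumi\tstatus\tallele\tdepth\n")
        for c in calls:
            fh.write(f"{c.barcode}\t{c.umi}\t{c.status}\t{c.allele or '.'}\t{c.depth}\n")


def _write_genotypes(genotypes: list[CellGenotype], variant_ids: list[str], path) -> None:
    variant_cols = sorted(variant_ids)
    with open(path, "w") as fh:
        header = ["barcode", "status", "assigned_variant", "confident", "n_wildtype_umis"]
        header += [f"n_{v}_umis" for v in variant_cols]
        fh.write("\t".join(header) + "\n")
        for g in genotypes:
            row = [
                g.barcode,
                g.status,
                g.assigned_variant or ".",
                str(g.confident).lower(),
                str(g.umi_counts.get(WILDTYPE, 0)),
            ]
            row += [str(g.umi_counts.get(v, 0)) for v in variant_cols]
            fh.write("\t".join(row) + "\n")


def run_genotype(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write outputs under ``config.out_dir``.

    Outputs: ``probe_set.tsv``, ``umi_calls.tsv``, ``cell_genotypes.tsv``,
    ``summary.json``, ``run_manifest.json`` and optionally
    ``match_log.tsv``.  Identical inputs and configuration produce
    byte-identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage=design loading reference and variants")
    ref = load_reference(config.reference, cds_offset=config.cds_offset)
    variants = load_variant_table(config.variants)
    hooks = build_fishhooks(ref, variants, config.design)
    hazards = validate_probe_set(hooks, config.matcher.max_mismatch)
    if hazards:
        logger.warning("probe set has %d cross-locus ambiguity hazards", len(hazards))
    write_probe_set(hooks, out_dir / "probe_set.tsv")
    index = build_seed_index(hooks, config.matcher)

    wl: Whitelist | None = None
    if config.whitelist is not None:
        wl = load_whitelist(config.whitelist)
        logger.info("stage=ingest whitelist of %d barcodes", len(wl))
    else:
        logger.warning("no whitelist supplied; raw barcodes pass through uncorrected")

    ingest_counters = IngestCounters()
    match_counters = MatchCounters()
    barcode_discarded = 0
    matches = []
    match_log_rows: list[str] = []
    for obs in parse_read_pairs(config.r1, config.r2, config.chemistry, ingest_counters):
        barcode = obs.barcode
        if wl is not None:
            corrected = correct_barcode(barcode, wl, config.whitelist_max_hamming)
            if corrected is None:
                barcode_discarded += 1
                continue
            if corrected != barcode:
                obs = type(obs)(obs.read_id, corrected, obs.umi, obs.cdna)
        result = match_read(obs.cdna, index, config.matcher, obs.read_id, match_counters)
        if result is None:
            continue
        matches.append((obs, result))
        if config.write_match_log:
            match_log_rows.append(
                f"{obs.read_id}\t{obs.barcode}\t{obs.umi}\t{result.fishhook_id}\t"
                f"{result.allele_class}\t{result.mismatches}\t{result.read_offset}\t{result.orientation}"
            )

    groups = group_by_umi(matches)
    calls = [call_umi(g, config.umi) for g in groups]
    called = [c for c in calls if c.status == "called"]
    genotypes = genotype_cells(called, config.umi)
    summary = summarize_run(genotypes, calls).as_dict()
    summary["ingest"] = ingest_counters.as_dict()
    summary["match"] = match_counters.as_dict()
    summary["barcode_discarded"] = barcode_discarded
    summary["n_umi_groups"] = len(groups)
    summary["n_probe_hazards"] = len(hazards)

    _write_umi_calls(calls, out_dir / "umi_calls.tsv")
    _write_genotypes(genotypes, [v.variant_id for v in variants], out_dir / "cell_genotypes.tsv")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if config.write_match_log:
        with open(out_dir / "match_log.tsv", "w") as fh:
            fh.write("read_id\tbarcode\tumi\tfishhook_id\tallele_class\tmismatches\tread_offset\torientation\n")
            for row in match_log_rows:
                fh.write(row + "\n")

    manifest = {
        "inputs": {
            "reference": {"path": str(config.reference), "sha256": _sha256(config.reference)},
            "variants": {"path": str(config.variants), "sha256": _sha256(config.variants)},
            "r1": {"path": str(config.r1), "sha256": _sha256(config.r1)},
            "r2": {"path": str(config.r2), "sha256": _sha256(config.r2)},
            "whitelist": (
                {"path": str(config.whitelist), "sha256": _sha256(config.whitelist)}
                if config.whitelist
                else None
            ),
        },
        "parameters": {
            "design": asdict(config.design),
            "matcher": asdict(config.matcher),
            "umi": asdict(config.umi),
            "chemistry": asdict(config.chemistry),
            "whitelist_max_hamming": config.whitelist_max_hamming,
            "cds_offset": config.cds_offset,
            "write_match_log": config.write_match_log,
        },
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return RunResult(genotypes=genotypes, calls=calls, summary=summary, out_dir=out_dir)
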
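"""Default KRAS target: canonical coding sequence around codons 12-61.

The amplicon emulates the first-round (nest 1) PCR product covering the
KRAS mutational region, codons 12 through 61, with enough flanking coding
sequence on both sides for full-length 38-mer probes centered on codon 12
and codon 61.  The sequence below is the canonical human KRAS coding
sequence for codons 1-75 (protein MTEYKLVVVG AGGVGKSALT ...); codon 12 is
GGT (Gly), codon 13 GGC (Gly), codon 61 CAA (Gln).
"""

from __future__ import annotations

from scfishhook.amplicon import AmpliconReference, VariantSpec

__all__ = [
    "KRAS_AMPLICON_SEQ",
    "default_reference",
    "default_variants",
    "write_default_inputs",
]

# Human KRAS CDS, codons 1-75 (225 nt).
KRAS_AMPLICON_SEQ = (
    "ATGACTGAATATAAACTTGTGGTAGTTGGAGCT"  # codons 1-11
    "GGTGGC"                             # codons 12-13 (G12, G13)
    "GTAGGCAAGAGTGCCTTGACGATACAGCTAATTCAGAATCATTTTGTGGACGAA"
    "TATGATCCAACAATAGAGGATTCCTACAGGAAGCAAGTAGTAATTGATGGAGAA"
    "ACCTGTCTCTTGGATATTCTCGACACAGCA"
    "GGTCAA"                             # codons 60-61 (G60, Q61)
    "GAGGAGTACAGTGCAATGAGGGACCAGTACATGAGGACTGGG"  # codons 62-75
)

# codon 12 starts at CDS position 3*(12-1) = 33
_CDS_OFFSET_CODON12 = 33

_HOTSPOTS: tuple[tuple[str, int, str, str], ...] = (
    ("G12D", 12, "GGT", "GAT"),
    ("G12V", 12, "GGT", "GTT"),
    ("G12C", 12, "GGT", "TGT"),
    ("G12R", 12, "GGT", "CGT"),
    ("G13D", 13, "GGC", "GAC"),
    ("Q61H", 61, "CAA", "CAC"),
    ("Q61R", 61, "CAA", "CGA"),
)


def default_reference() -> AmpliconReference:
    """The default KRAS codon 12-61 amplicon reference."""
    return AmpliconReference(
        name="KRAS_codons12-61",
        sequence=KRAS_AMPLICON_SEQ,
        cds_offset=_CDS_OFFSET_CODON12,
        target_codons=(12, 61),
    )


def default_variants() -> list[VariantSpec]:
    """The default KRAS hotspot substitution panel (G12/G13/Q61)."""
    return [VariantSpec(*row) for row in _HOTSPOTS]


def write_default_inputs(fasta_path, variants_path) -> None:
    """Write the default reference FASTA and hotspot variant TSV to disk."""
    ref = default_reference()
    with open(fasta_path, "w") as fh:
        fh.write(f">{ref.name} cds_offset={ref.cds_offset} codons={ref.target_codons[0]}-{ref.target_codons[1]}\n")
        for i in range(0, len(ref.sequence), 60):
            fh.write(ref.sequence[i : i + 60] + "\n")
    with open(variants_path, "w") as fh:
        fh.write("variant_id\tcodon\tref_codon\talt_codon\n")
        for row in _HOTSPOTS:
            fh.write("\t".join(str(x) for x in row) + "\n")
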
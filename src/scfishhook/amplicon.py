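"""Amplicon reference model and fishhook probe construction.

A *fishhook* is a fixed-length probe (38 nt by default) carrying either a
hotspot variant's alternate bases or the matched reference bases, used to
capture allele-specific reads from targeted amplicon sequencing.  Each
hotspot substitution yields a mutant probe and a paired wildtype probe
occupying the same amplicon window; the positions where the pair differ
are the *discriminating offsets* — the allele-informative bases.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "WILDTYPE",
    "AmpliconReference",
    "VariantSpec",
    "DesignParams",
    "Fishhook",
    "ProbeHazard",
    "build_fishhooks",
    "validate_probe_set",
    "DesignError",
    "VariantValidationError",
]

#: Reserved allele label for wildtype evidence, distinct from any variant id.
WILDTYPE = "WILDTYPE"

_ACGT = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class DesignError(ValueError):
    """Probe construction cannot satisfy its geometric constraints."""


class VariantValidationError(ValueError):
    """A variant specification is inconsistent with the reference."""


@dataclass(frozen=True)
class AmpliconReference:
    """The amplified target region and its codon coordinate system.

    Parameters
    ----------
    name : str
        Reference record name.
    sequence : str
        Amplicon nucleotide sequence, strictly A/C/G/T.
    cds_offset : int
        0-based position in ``sequence`` of the first base of the first
        codon in ``target_codons``.
    target_codons : tuple[int, int]
        Inclusive range of protein codon numbers covered by the assay;
        the KRAS hotspot assay targets codons 12 through 61.
    """

    name: str
    sequence: str
    cds_offset: int
    target_codons: tuple[int, int] = (12, 61)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("amplicon sequence must be non-empty")
        bad = set(self.sequence) - _ACGT
        if bad:
            raise ValueError(f"amplicon sequence contains non-ACGT characters: {sorted(bad)}")
        lo, hi = self.target_codons
        if lo > hi:
            raise ValueError(f"target_codons low {lo} > high {hi}")
        if self.cds_offset < 0:
            raise ValueError("cds_offset must be >= 0")
        span_end = self.cds_offset + 3 * (hi - lo + 1)
        if span_end > len(self.sequence):
            raise ValueError(
                f"codon span ends at {span_end} but amplicon is only {len(self.sequence)} nt"
            )

    def codon_start(self, codon: int) -> int:
        """0-based amplicon position of the first base of ``codon``."""
        lo, hi = self.target_codons
        if not lo <= codon <= hi:
            raise ValueError(f"codon {codon} outside target range {lo}..{hi}")
        return self.cds_offset + 3 * (codon - lo)

    def codon_sequence(self, codon: int) -> str:
        start = self.codon_start(codon)
        return self.sequence[start : start + 3]


@dataclass(frozen=True)
class VariantSpec:
    """One hotspot substitution, expressed as a codon change (e.g. G12D)."""

    variant_id: str
    codon: int
    ref_codon: str
    alt_codon: str

    def __post_init__(self) -> None:
        for label, cod in (("ref_codon", self.ref_codon), ("alt_codon", self.alt_codon)):
            if len(cod) != 3 or set(cod) - _ACGT:
                raise VariantValidationError(
                    f"{self.variant_id}: {label} {cod!r} must be 3 nt of A/C/G/T"
                )
        if self.ref_codon == self.alt_codon:
            raise VariantValidationError(f"{self.variant_id}: ref and alt codons are identical")
        if not self.variant_id:
            raise VariantValidationError("variant_id must be non-empty")

    def validate_against(self, ref: AmpliconReference) -> None:
        """Check codon range membership and reference-codon agreement."""
        lo, hi = ref.target_codons
        if not lo <= self.codon <= hi:
            raise VariantValidationError(
                f"{self.variant_id}: codon {self.codon} outside target range {lo}..{hi}"
            )
        observed = ref.codon_sequence(self.codon)
        if observed != self.ref_codon:
            raise VariantValidationError(
                f"{self.variant_id}: ref_codon {self.ref_codon} does not match reference "
                f"codon {self.codon} ({observed})"
            )

    @property
    def changed_indices(self) -> tuple[int, ...]:
        """Within-codon indices (0..2) where ref and alt codons differ."""
        return tuple(i for i in range(3) if self.ref_codon[i] != self.alt_codon[i])


@dataclass(frozen=True)
class DesignParams:
    """Probe design parameters; the assay uses 38-mer fishhooks."""

    probe_len: int = 38

    def __post_init__(self) -> None:
        if self.probe_len < 2:
            raise ValueError("probe_len must be >= 2")


@dataclass(frozen=True)
class Fishhook:
    """A fixed-length allele-specific probe placed on the amplicon.

    ``allele_id`` is the collapsed allele identity used by the matcher and
    the UMI tally: the variant id for a mutant probe, :data:`WILDTYPE` for
    any wildtype probe.  Wildtype probes of variants sharing a codon may be
    sequence-identical; collapsing their identity keeps such reads
    unambiguous.
    """

    fishhook_id: str
    variant_id: str
    allele_class: str  # "wildtype" | "mutant"
    sequence: str
    amplicon_start: int
    discriminating_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.allele_class not in ("wildtype", "mutant"):
            raise ValueError(f"invalid allele_class {self.allele_class!r}")
        if not self.discriminating_offsets:
            raise ValueError("discriminating_offsets must be non-empty")

    @property
    def allele_id(self) -> str:
        return self.variant_id if self.allele_class == "mutant" else WILDTYPE


def _window_start(positions: tuple[int, ...], probe_len: int, amplicon_len: int) -> int:
    """Center rule: place the probe window centered on the differing base(s),
    clamped so the window stays within the amplicon at full length."""
    center = (min(positions) + max(positions)) // 2
    start = center - (probe_len - 1) // 2
    start = max(0, min(start, amplicon_len - probe_len))
    return start


def build_fishhooks(
    ref: AmpliconReference,
    variants: list[VariantSpec],
    params: DesignParams = DesignParams(),
) -> list[Fishhook]:
    """Construct one mutant probe and one paired wildtype probe per variant.

    The probe window is centered on the variant's differing base(s); at the
    amplicon edges the window is clamped inward so it always keeps full
    length.  Paired probes share the window and differ exactly at the
    discriminating offsets.

    Raises
    ------
    VariantValidationError
        If a variant's ref codon disagrees with the reference sequence.
    DesignError
        If a full-length probe window cannot contain the variant bases.
    """
    if not variants:
        raise ValueError("variants list must be non-empty")
    if params.probe_len > len(ref.sequence):
        raise DesignError(
            f"probe_len {params.probe_len} exceeds amplicon length {len(ref.sequence)}"
        )
    seen: set[str] = set()
    hooks: list[Fishhook] = []
    for var in variants:
        if var.variant_id in seen:
            raise VariantValidationError(f"duplicate variant_id {var.variant_id}")
        seen.add(var.variant_id)
        var.validate_against(ref)
        codon_start = ref.codon_start(var.codon)
        diff_positions = tuple(codon_start + i for i in var.changed_indices)
        start = _window_start(diff_positions, params.probe_len, len(ref.sequence))
        end = start + params.probe_len
        if not all(start <= p < end for p in diff_positions):
            raise DesignError(
                f"{var.variant_id}: probe window [{start},{end}) cannot contain "
                f"variant positions {diff_positions}"
            )
        wt_seq = ref.sequence[start:end]
        offsets = tuple(p - start for p in diff_positions)
        mut_bases = list(wt_seq)
        for off, idx in zip(offsets, var.changed_indices):
            mut_bases[off] = var.alt_codon[idx]
        mut_seq = "".join(mut_bases)
        hooks.append(
            Fishhook(
                fishhook_id=f"{var.variant_id}:mut",
                variant_id=var.variant_id,
                allele_class="mutant",
                sequence=mut_seq,
                amplicon_start=start,
                discriminating_offsets=offsets,
            )
        )
        hooks.append(
            Fishhook(
                fishhook_id=f"{var.variant_id}:wt",
                variant_id=var.variant_id,
                allele_class="wildtype",
                sequence=wt_seq,
                amplicon_start=start,
                discriminating_offsets=offsets,
            )
        )
    return hooks


@dataclass(frozen=True)
class ProbeHazard:
    """Two probes at different loci confusable under the mismatch budget."""

    fishhook_id_a: str
    fishhook_id_b: str
    hamming: int


def validate_probe_set(fishhooks: list[Fishhook], max_mismatch: int = 2) -> list[ProbeHazard]:
    """Report pairs of probes whose full-length sequences are within
    ``max_mismatch`` Hamming distance.

    Same-locus pairs (equal ``amplicon_start``) are intentional allele
    alternatives — the mutant/wildtype pair of one variant, or probes of
    variants sharing a codon — and are distinguished downstream by the
    discriminant-exact rule, so they are not reported.  A non-empty report
    flags probes at *different* loci that the matcher could confuse.
    """
    if not fishhooks:
        raise ValueError("probe set must be non-empty")
    hazards: list[ProbeHazard] = []
    for i, a in enumerate(fishhooks):
        for b in fishhooks[i + 1 :]:
            if a.amplicon_start == b.amplicon_start:
                continue
            if len(a.sequence) != len(b.sequence):
                continue
            d = sum(x != y for x, y in zip(a.sequence, b.sequence))
            if d <= max_mismatch:
                hazards.append(ProbeHazard(a.fishhook_id, b.fishhook_id, d))
    return hazards
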
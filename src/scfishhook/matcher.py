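"""Seed-and-extend fishhook matching.

Every overlapping 6-mer of every probe is indexed exactly; a read (and,
by default, its reverse complement) is scanned for exact seed hits, each
hit nominating a full-length ungapped probe placement.  A placement is
scored by Hamming mismatches over the whole probe and accepted when the
count is at most ``max_mismatch`` (two by default) and, under the
discriminant-exact rule, the read agrees verbatim with the probe at every
allele-informative position.  The best accepted placement wins; equal-score
candidates with conflicting allele identities make the read ambiguous.

The seed search is lossless for the default geometry: two mismatches over
a 38-mer always leave at least one clean 6-mer (pigeonhole), so every
placement within the mismatch budget is nominated by some exact seed.
"""

from __future__ import annotations

from dataclasses import dataclass

from scfishhook.amplicon import Fishhook, reverse_complement

__all__ = [
    "MatcherParams",
    "SeedIndex",
    "MatchResult",
    "MatchCounters",
    "build_seed_index",
    "match_read",
]

_ACGTN = frozenset("ACGTN")


@dataclass(frozen=True)
class MatcherParams:
    """Seed-and-extend parameters (defaults: 6-mer seed, 2 mismatches)."""

    seed_len: int = 6
    max_mismatch: int = 2
    require_discriminant_exact: bool = True
    search_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if self.seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


class SeedIndex:
    """Exact k-mer index over every overlapping seed of every probe."""

    def __init__(self, fishhooks: list[Fishhook], seed_len: int) -> None:
        if not fishhooks:
            raise ValueError("no probes to index")
        lengths = {len(fh.sequence) for fh in fishhooks}
        if len(lengths) != 1:
            raise ValueError(f"probes of unequal length: {sorted(lengths)}")
        self.probe_len = lengths.pop()
        if seed_len >= self.probe_len:
            raise ValueError("seed_len must be < probe length")
        self.seed_len = seed_len
        self.fishhooks = list(fishhooks)
        self._by_id = {fh.fishhook_id: fh for fh in fishhooks}
        if len(self._by_id) != len(fishhooks):
            raise ValueError("duplicate fishhook_id in probe set")
        index: dict[str, list[tuple[str, int]]] = {}
        for fh in fishhooks:
            seq = fh.sequence
            for off in range(self.probe_len - seed_len + 1):
                index.setdefault(seq[off : off + seed_len], []).append((fh.fishhook_id, off))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All (fishhook_id, offset-within-probe) occurrences of ``kmer``."""
        return self._index.get(kmer, [])

    def probe(self, fishhook_id: str) -> Fishhook:
        return self._by_id[fishhook_id]

    def items(self):
        return self._index.items()

    def __len__(self) -> int:
        return len(self._index)


def build_seed_index(fishhooks: list[Fishhook], params: MatcherParams = MatcherParams()) -> SeedIndex:
    """Index every overlapping ``seed_len``-mer of every probe."""
    return SeedIndex(fishhooks, params.seed_len)


@dataclass(frozen=True)
class MatchResult:
    """Best accepted fishhook placement for one read."""

    read_id: str
    fishhook_id: str
    variant_id: str
    allele_id: str  # collapsed allele identity: variant_id or WILDTYPE
    allele_class: str
    mismatches: int
    read_offset: int
    orientation: str  # "forward" | "reverse"


@dataclass
class MatchCounters:
    """Per-read match outcome accounting."""

    reads_seen: int = 0
    matched: int = 0
    no_match: int = 0
    ambiguous: int = 0
    rejected_bad_chars: int = 0
    too_short: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "reads_seen": self.reads_seen,
            "matched": self.matched,
            "no_match": self.no_match,
            "ambiguous": self.ambiguous,
            "rejected_bad_chars": self.rejected_bad_chars,
            "too_short": self.too_short,
        }


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def match_read(
    cdna: str,
    index: SeedIndex,
    params: MatcherParams = MatcherParams(),
    read_id: str = "",
    counters: MatchCounters | None = None,
) -> MatchResult | None:
    """Find the best fishhook placement on a read via seed-and-extend.

    Every exact seed hit on the read (and its reverse complement when
    enabled) nominates a full-containment probe placement; placements are
    deduplicated and scored by full-probe Hamming distance.  Acceptance
    requires ``mismatches <= max_mismatch`` and, with
    ``require_discriminant_exact``, exact agreement at all discriminating
    offsets.  Ties at the minimal mismatch count are broken by orientation
    (forward first), then smaller read offset, then fishhook id — but only
    when all tied candidates share one allele identity; otherwise the read
    is ambiguous and ``None`` is returned.
    """
    if counters is not None:
        counters.reads_seen += 1
    cdna = cdna.upper()
    if set(cdna) - _ACGTN:
        if counters is not None:
            counters.rejected_bad_chars += 1
        return None
    L = index.probe_len
    if len(cdna) < L:
        if counters is not None:
            counters.too_short += 1
        return None

    orientations = [("forward", cdna)]
    if params.search_reverse_complement:
        orientations.append(("reverse", reverse_complement(cdna)))

    k = index.seed_len
    candidates: dict[tuple[str, str, int], int] = {}
    for orient, seq in orientations:
        n = len(seq)
        for i in range(n - k + 1):
            for fh_id, probe_off in index.lookup(seq[i : i + k]):
                read_off = i - probe_off
                if read_off < 0 or read_off + L > n:
                    continue
                key = (orient, fh_id, read_off)
                if key in candidates:
                    continue
                probe = index.probe(fh_id)
                window = seq[read_off : read_off + L]
                mm = _hamming(probe.sequence, window)
                if mm > params.max_mismatch:
                    continue
                if params.require_discriminant_exact and any(
                    window[off] != probe.sequence[off] for off in probe.discriminating_offsets
                ):
                    continue
                candidates[key] = mm

    if not candidates:
        if counters is not None:
            counters.no_match += 1
        return None

    best_mm = min(candidates.values())
    tied = [key for key, mm in candidates.items() if mm == best_mm]
    alleles = {index.probe(fh_id).allele_id for _, fh_id, _ in tied}
    if len(alleles) > 1:
        if counters is not None:
            counters.ambiguous += 1
        return None
    orient, fh_id, read_off = min(
        tied, key=lambda key: (key[0] != "forward", key[2], key[1])
    )
    probe = index.probe(fh_id)
    if counters is not None:
        counters.matched += 1
    return MatchResult(
        read_id=read_id,
        fishhook_id=fh_id,
        variant_id=probe.variant_id,
        allele_id=probe.allele_id,
        allele_class=probe.allele_class,
        mismatches=best_mm,
        read_offset=read_off,
        orientation=orient,
    )
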
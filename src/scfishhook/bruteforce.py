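"""Exhaustive reference matcher for validating the seed-and-extend search.

Slides every probe over every offset of each read and of its reverse
complement, counts Hamming mismatches over the full probe, and applies
the same acceptance and tie rules as :func:`scfishhook.matcher.match_read`
— but with no seed index at all, so any disagreement between the two
paths exposes a defect in the seeded search (or a violation of the
pigeonhole guarantee that a within-budget placement always contains a
clean seed).

Kept deliberately independent of the matcher's code path: placement
enumeration and scoring are vectorised over numpy byte arrays rather
than walking a k-mer index.
"""

from __future__ import annotations

import numpy as np

from scfishhook.amplicon import Fishhook, reverse_complement
from scfishhook.matcher import MatcherParams, MatchResult

__all__ = ["brute_force_match", "brute_force_match_many"]

_ACGTN = frozenset("ACGTN")


def _encode(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def brute_force_match_many(
    reads: list[str],
    fishhooks: list[Fishhook],
    params: MatcherParams = MatcherParams(),
) -> list[MatchResult | None]:
    """Match every read by exhaustive all-offsets, both-strands scanning."""
    out: list[MatchResult | None] = [None] * len(reads)
    probe_len = len(fishhooks[0].sequence)
    if any(len(fh.sequence) != probe_len for fh in fishhooks):
        raise ValueError("probes of unequal length")
    probes = _encode([fh.sequence for fh in fishhooks])
    disc = [np.array(fh.discriminating_offsets, dtype=np.intp) for fh in fishhooks]

    # group reads by length so each group is one rectangular array
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        r = r.upper()
        if len(r) < probe_len or set(r) - _ACGTN:
            continue
        by_len.setdefault(len(r), []).append(i)

    orientations = ["forward"]
    if params.search_reverse_complement:
        orientations.append("reverse")

    for length, idxs in by_len.items():
        fwd = [reads[i].upper() for i in idxs]
        seq_sets = {"forward": _encode(fwd)}
        if params.search_reverse_complement:
            seq_sets["reverse"] = _encode([reverse_complement(s) for s in fwd])
        # candidates[j] collects accepted placements of read idxs[j]
        candidates: dict[int, list[tuple[int, str, int, int]]] = {}
        for orient in orientations:
            arr = seq_sets[orient]
            windows = np.lib.stride_tricks.sliding_window_view(arr, probe_len, axis=1)
            for p, fh in enumerate(fishhooks):
                mm = (windows != probes[p]).sum(axis=2)
                ok = mm <= params.max_mismatch
                if params.require_discriminant_exact:
                    ok &= (windows[:, :, disc[p]] == probes[p][disc[p]]).all(axis=2)
                for j, off in zip(*np.nonzero(ok)):
                    candidates.setdefault(int(j), []).append(
                        (int(mm[j, off]), orient, int(off), p)
                    )
        for j, cands in candidates.items():
            best = min(c[0] for c in cands)
            tied = [c for c in cands if c[0] == best]
            alleles = {fishhooks[p].allele_id for _, _, _, p in tied}
            if len(alleles) > 1:
                continue
            _, orient, off, p = min(
                tied,
                key=lambda c: (c[1] != "forward", c[2], fishhooks[c[3]].fishhook_id),
            )
            fh = fishhooks[p]
            out[idxs[j]] = MatchResult(
                read_id="",
                fishhook_id=fh.fishhook_id,
                variant_id=fh.variant_id,
                allele_id=fh.allele_id,
                allele_class=fh.allele_class,
                mismatches=best,
                read_offset=off,
                orientation=orient,
            )
    return out


def brute_force_match(
    cdna: str, fishhooks: list[Fishhook], params: MatcherParams = MatcherParams()
) -> MatchResult | None:
    """Exhaustive match of a single read."""
    return brute_force_match_many([cdna], fishhooks, params)[0]
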
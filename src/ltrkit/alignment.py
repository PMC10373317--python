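"""Shared pairwise-alignment parameters.

The detector's identity filter and the dating module's divergence both use
the same banded-free global alignment (match +1, mismatch -1, gap open -4,
gap extend -1), so the two statistics are mutually consistent.
"""

from __future__ import annotations

from Bio import Align

MATCH = 1
MISMATCH = -1
GAP_OPEN = -4
GAP_EXTEND = -1


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = make_aligner()


def align_pair(a: str, b: str):
    """Best global alignment of two sequences (first optimum)."""
    return _ALIGNER.align(a, b)[0]


def global_identity(a: str, b: str) -> float:
    """Identity = matches / alignment columns, gap columns included."""
    aln = align_pair(a, b)
    counts = aln.counts()
    total = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / total if total else 0.0


def aligned_site_stats(a: str, b: str) -> tuple[int, int]:
    """(mismatches, aligned_sites) over gap-free, N-free alignment columns."""
    aln = align_pair(a, b)
    mismatches = 0
    sites = 0
    blocks_a, blocks_b = aln.aligned
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        for i in range(ea - sa):
            ca, cb = a[sa + i], b[sb + i]
            if ca == "N" or cb == "N":
                continue
            sites += 1
            if ca != cb:
                mismatches += 1
    return mismatches, sites
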
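"""Structural detection of intact LTR retrotransposons.

An intact element is recognised purely from sequence structure: two
near-identical long terminal repeats (>= 90% identity, each 100-7000 bp)
separated by an internal region, bounded by the TG...CA terminal
dinucleotides and flanked by an exact 4-6 bp target-site duplication (TSD).
Detection proceeds seed -> chain -> extend -> validate:

1. exact k-mer seed matches on the same strand are grouped by diagonal;
2. seeds on one diagonal are chained (max gap between seeds 50 bp);
3. chains are extended outward by an ungapped X-drop scan to maximal
   near-identical blocks;
4. candidate pairs passing length/identity filters are validated for
   micro-structure (terminal motifs + TSD), with a small boundary
   adjustment scan so that a few bp of extension slop never costs a
   structurally perfect element.

Superfamily classification uses the canonical Pol domain orders:
Copia = GAG-PR-INT-RT-RH, Gypsy = GAG-PR-RT-RH-INT.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .alignment import global_identity
from .core_io import GenomicInterval, Genome

logger = logging.getLogger("ltrkit")

COPIA_LINEAGES = frozenset(
    {"Ale", "Alesia", "Angela", "Bianca", "Ikeros", "Ivana", "SIRE", "TAR", "Tork"}
)
GYPSY_LINEAGES = frozenset(
    {"Athila", "CRM", "Galadriel", "Ogre", "Reina", "Retand", "Tekay"}
)

COPIA_ORDER = ("INT", "RT", "RH")
GYPSY_ORDER = ("RT", "RH", "INT")
CORE_DOMAINS = frozenset(COPIA_ORDER)


@dataclass
class DetectorParams:
    """Tunable structural-detection parameters (defaults follow the
    standard LTR length/identity criteria; seeding and extension knobs are
    this detector's own)."""

    k: int = 20                    # exact seed length
    max_chain_gap: int = 50        # bp between consecutive seeds in a chain
    min_ltr: int = 100
    max_ltr: int = 7000
    min_internal: int = 200
    max_internal: int = 15000
    min_identity: float = 0.90
    xdrop: int = 12                # ungapped extension drop-off
    xdrop_mismatch: int = -2
    wiggle: int = 20               # micro-structure boundary adjustment, bp
    strict: bool = True            # require terminal motif AND TSD
    motif: tuple[str, str] = ("TG", "CA")
    tsd_min: int = 4
    tsd_max: int = 6
    max_kmer_occ: int = 100        # ignore ultra-repetitive seeds
    allow_nested: bool = False

    @property
    def min_span(self) -> int:
        return self.min_ltr + self.min_internal

    @property
    def max_span(self) -> int:
        return self.max_ltr + self.max_internal


@dataclass(frozen=True)
class DomainHit:
    """One protein-domain hit inside an element's internal region."""

    element_id: str
    domain: str
    start: int
    end: int
    lineage: str | None = None


@dataclass(frozen=True)
class CandidatePair:
    """An LTR pair candidate before micro-structure validation.

    Both blocks have equal length (ungapped diagonal model); ``diag`` is
    the offset between the 5' and 3' copies.
    """

    seq_id: str
    start: int      # 5' LTR start
    end: int        # 5' LTR end (exclusive)
    diag: int       # ltr3.start - ltr5.start
    identity: float

    @property
    def ltr5(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.start, self.end)

    @property
    def ltr3(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.start + self.diag,
                               self.end + self.diag)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end + self.diag


@dataclass
class IntactLTRRT:
    """A validated intact LTR retrotransposon."""

    element_id: str
    element_interval: GenomicInterval
    ltr5: GenomicInterval
    ltr3: GenomicInterval
    internal: GenomicInterval
    tsd: str | None
    terminal_motif_ok: bool
    ltr_identity: float
    superfamily: str = "Unknown"
    lineage: str | None = None
    lineage_conflict: bool = False

    def __post_init__(self) -> None:
        if not (self.ltr5.end <= self.internal.start
                <= self.internal.end <= self.ltr3.start):
            raise ValueError(f"{self.element_id}: inconsistent sub-intervals")
        if not 0.0 <= self.ltr_identity <= 1.0:
            raise ValueError(f"{self.element_id}: identity outside [0,1]")

    @property
    def length(self) -> int:
        return self.element_interval.length


# ---------------------------------------------------------------------------
# seed -> chain -> extend
# ---------------------------------------------------------------------------

def _xdrop_extend(seq: str, diag: int, left: int, right: int,
                  params: DetectorParams) -> tuple[int, int]:
    """Extend the ungapped block [left, right) on ``diag`` both ways.

    Compares seq[x] with seq[x + diag]; returns the maximal-scoring
    extension endpoints (match +1, mismatch ``xdrop_mismatch``, stop when
    the running score falls ``xdrop`` below its maximum).
    """
    n = len(seq)
    mm = params.xdrop_mismatch

    # ties prefer the farther endpoint: a neutral stretch just inside the
    # true boundary must not truncate the block
    score, best, best_x = 0, 0, left
    x = left - 1
    while x >= 0 and x + diag < n:
        score += 1 if seq[x] == seq[x + diag] and seq[x] != "N" else mm
        if score >= best:
            best, best_x = score, x
        if score < best - params.xdrop:
            break
        x -= 1
    new_left = best_x

    score, best, best_x = 0, 0, right
    x = right
    while x + diag < n:
        score += 1 if seq[x] == seq[x + diag] and seq[x] != "N" else mm
        if score >= best:
            best, best_x = score, x + 1
        if score < best - params.xdrop:
            break
        x += 1
    return new_left, best_x


def find_ltr_pairs(sequence: str, params: DetectorParams | None = None,
                   seq_id: str = "seq") -> list[CandidatePair]:
    """Find candidate LTR pairs in one sequence.

    Returns candidates sorted by position; overlap resolution happens in
    :func:`detect_elements`.
    """
    params = params or DetectorParams()
    k = params.k
    n = len(sequence)
    if n < 2 * params.min_ltr + params.min_internal:
        return []

    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        kmer = sequence[i:i + k]
        if "N" not in kmer:
            index[kmer].append(i)

    by_diag: dict[int, list[int]] = defaultdict(list)
    for positions in index.values():
        m = len(positions)
        if m < 2 or m > params.max_kmer_occ:
            continue
        for ai in range(m - 1):
            for bi in range(ai + 1, m):
                d = positions[bi] - positions[ai]
                if params.min_span <= d <= params.max_span:
                    by_diag[d].append(positions[ai])

    seen: set[tuple[int, int, int]] = set()
    candidates: list[CandidatePair] = []
    for diag, starts in by_diag.items():
        starts.sort()
        chain_start = prev = starts[0]
        chains = []
        for s in starts[1:]:
            if s - prev > params.max_chain_gap:
                chains.append((chain_start, prev + k))
                chain_start = s
            prev = s
        chains.append((chain_start, prev + k))
        for left, right in chains:
            left, right = _xdrop_extend(sequence, diag, left, right, params)
            key = (diag, left, right)
            if key in seen:
                continue
            seen.add(key)
            length = right - left
            internal = diag - length
            if not (params.min_ltr <= length <= params.max_ltr):
                continue
            if not (params.min_internal <= internal <= params.max_internal):
                continue
            ident = global_identity(sequence[left:right],
                                    sequence[left + diag:right + diag])
            if ident >= params.min_identity:
                candidates.append(
                    CandidatePair(seq_id, left, right, diag, ident)
                )
    candidates.sort(key=lambda c: (c.start, c.diag))
    return candidates


# ---------------------------------------------------------------------------
# micro-structure validation
# ---------------------------------------------------------------------------

def validate_element(pair: CandidatePair, sequence: str,
                     params: DetectorParams | None = None,
                     element_id: str = "element",
                     ) -> tuple[IntactLTRRT | None, str]:
    """Validate a candidate pair's micro-structure.

    Scans boundary adjustments (dl, dr) within ``params.wiggle`` bp,
    nearest first, for a placement where both LTRs carry the terminal
    motif (5' starts TG, 3' ends CA) and an exact 4-6 bp TSD flanks the
    element (longest first).  Returns (element, "ok") or (None, reason).
    """
    params = params or DetectorParams()
    s = sequence
    n = len(s)
    d = pair.diag
    m5, m3 = params.motif

    if pair.start - params.tsd_max - params.wiggle < 0 or \
            pair.end + d + params.tsd_max + params.wiggle > n:
        return None, "edge"

    w = params.wiggle
    offsets = sorted(
        ((dl, dr) for dl in range(-w, w + 1) for dr in range(-w, w + 1)),
        key=lambda o: (abs(o[0]) + abs(o[1]), abs(o[0]), o[0], o[1]),
    )
    best_lenient: tuple[int, int, str] | None = None
    for dl, dr in offsets:
        start = pair.start + dl          # element / 5'LTR start
        l5_end = pair.end + dr           # 5'LTR end
        l3_start = start + d
        end = l5_end + d                 # element / 3'LTR end
        length = l5_end - start
        if not (params.min_ltr <= length <= params.max_ltr):
            continue
        motif_ok = (
            s[start:start + 2] == m5
            and s[l3_start:l3_start + 2] == m5
            and s[l5_end - 2:l5_end] == m3
            and s[end - 2:end] == m3
        )
        tsd = None
        for tk in range(params.tsd_max, params.tsd_min - 1, -1):
            left_flank = s[start - tk:start]
            right_flank = s[end:end + tk]
            if "N" not in left_flank and left_flank == right_flank:
                tsd = left_flank
                break
        if tsd is None:
            continue
        if motif_ok:
            return _build(pair, start, l5_end, tsd, True, element_id), "ok"
        if best_lenient is None:
            best_lenient = (start, l5_end, tsd)
    if not params.strict and best_lenient is not None:
        start, l5_end, tsd = best_lenient
        return _build(pair, start, l5_end, tsd, False, element_id), "ok"
    return None, ("no_motif" if best_lenient is not None else "no_tsd")


def _build(pair: CandidatePair, start: int, l5_end: int, tsd: str,
           motif_ok: bool, element_id: str) -> IntactLTRRT:
    d = pair.diag
    sid = pair.seq_id
    return IntactLTRRT(
        element_id=element_id,
        element_interval=GenomicInterval(sid, start, l5_end + d),
        ltr5=GenomicInterval(sid, start, l5_end),
        ltr3=GenomicInterval(sid, start + d, l5_end + d),
        internal=GenomicInterval(sid, l5_end, start + d),
        tsd=tsd,
        terminal_motif_ok=motif_ok,
        ltr_identity=round(pair.identity, 4),
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _dedupe_hits(hits: list[DomainHit]) -> list[DomainHit]:
    seen: set[str] = set()
    out = []
    for h in sorted(hits, key=lambda h: h.start):
        if h.domain in seen:
            logger.warning("duplicate domain %s in %s; using first occurrence",
                           h.domain, h.element_id)
            continue
        seen.add(h.domain)
        out.append(h)
    return out


def classify_superfamily(domain_hits: list[DomainHit]) -> str:
    """Copia / Gypsy / Unknown from the order of the INT, RT, RH domains.

    The observed order of whichever core domains are present is checked
    against both canonical orders; exactly one consistent order decides,
    fewer than two core domains or an ambiguous order gives Unknown.
    """
    core = [h.domain for h in _dedupe_hits(domain_hits)
            if h.domain in CORE_DOMAINS]
    if len(core) < 2:
        return "Unknown"

    def consistent(canonical: tuple[str, ...]) -> bool:
        ranks = [canonical.index(d) for d in core]
        return ranks == sorted(ranks)

    copia, gypsy = consistent(COPIA_ORDER), consistent(GYPSY_ORDER)
    if copia and not gypsy:
        return "Copia"
    if gypsy and not copia:
        return "Gypsy"
    return "Unknown"


def assign_lineage(superfamily: str,
                   domain_hits: list[DomainHit]) -> tuple[str | None, bool]:
    """Majority lineage label across the element's domain hits.

    Returns (lineage, conflict); conflict is set when the winning label is
    illegal for the assigned superfamily.  Ties and unlabeled hits give
    (None, False).
    """
    labels = [h.lineage for h in domain_hits if h.lineage]
    if not labels:
        return None, False
    counts = Counter(labels).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return None, False
    lineage = counts[0][0]
    legal = {"Copia": COPIA_LINEAGES, "Gypsy": GYPSY_LINEAGES}.get(superfamily)
    conflict = legal is not None and lineage not in legal
    return lineage, conflict


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def detect_elements(genome: Genome, params: DetectorParams | None = None,
                    domain_hits: list[DomainHit] | None = None,
                    ) -> list[IntactLTRRT]:
    """Detect, validate and classify intact elements genome-wide.

    Overlapping candidates are resolved greedily by descending identity
    then element length; an accepted element masks its span unless
    ``params.allow_nested``.  Domain hits, when supplied, are matched to
    elements by overlap of the hit coordinates with the internal region
    (hits whose ``element_id`` matches are always used).
    """
    params = params or DetectorParams()
    elements: list[IntactLTRRT] = []
    for seq_id in genome:
        seq = genome[seq_id]
        candidates = find_ltr_pairs(seq, params, seq_id=seq_id)
        candidates.sort(key=lambda c: (-c.identity, -(c.end - c.start + c.diag),
                                       c.start))
        accepted_spans: list[tuple[int, int]] = []
        for cand in candidates:
            s, e = cand.span
            if not params.allow_nested and any(
                s < ae and as_ < e for as_, ae in accepted_spans
            ):
                continue
            element, reason = validate_element(cand, seq, params)
            if element is None:
                logger.debug("candidate %s:%d-%d rejected: %s",
                             seq_id, s, e, reason)
                continue
            accepted_spans.append(
                (element.element_interval.start, element.element_interval.end)
            )
            elements.append(element)
    elements.sort(key=lambda el: (el.element_interval.seq_id,
                                  el.element_interval.start))
    for i, el in enumerate(elements, 1):
        el.element_id = f"LTRRT_{i:04d}"

    if domain_hits is not None:
        by_id: dict[str, list[DomainHit]] = defaultdict(list)
        for h in domain_hits:
            by_id[h.element_id].append(h)
        for el in elements:
            hits = by_id.get(el.element_id)
            if hits is None:
                hits = _hits_by_overlap(el, domain_hits)
            el.superfamily = classify_superfamily(hits)
            el.lineage, el.lineage_conflict = assign_lineage(el.superfamily, hits)
    return elements


def _hits_by_overlap(element: IntactLTRRT,
                     domain_hits: list[DomainHit]) -> list[DomainHit]:
    """Domain hits whose genomic coordinates fall inside the internal region."""
    internal = element.internal
    out = []
    for h in domain_hits:
        if h.start >= internal.start and h.end <= internal.end:
            out.append(
                DomainHit(element.element_id, h.domain,
                          h.start - internal.start, h.end - internal.start,
                          h.lineage)
            )
    return out
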
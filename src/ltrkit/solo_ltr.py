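"""Solo-LTR detection and solo:intact (S/I) ratio analyses.

A solo LTR is the scar left when unequal recombination between the two
LTRs of an intact element deletes the internal region and one LTR: a
repeat-library hit that covers an LTR consensus well (identity > 0.80,
coverage >= 0.80 by default), lies away from any intact element or
annotated internal region, and is flanked by an exact 4-6 bp target-site
duplication found by scanning the 6-bp flanks longest-first.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .core_io import Genome, GenomicInterval, RepeatHit
from .ltr_detect import IntactLTRRT


@dataclass
class SoloParams:
    min_identity: float = 0.80      # strict > on comparison
    min_coverage: float = 0.80      # fraction of consensus length covered
    exclusion_margin: int = 100     # bp around intact elements / internals
    tsd_min: int = 4
    tsd_max: int = 6
    tsd_slack: int = 0              # allowed offset of the TSD from the hit edge


@dataclass(frozen=True)
class SoloLTR:
    interval: GenomicInterval
    consensus_id: str
    identity: float
    consensus_coverage: float
    tsd: str

    def __post_init__(self) -> None:
        if not 4 <= len(self.tsd) <= 6:
            raise ValueError(f"TSD length {len(self.tsd)} outside [4,6]")


@dataclass(frozen=True)
class SoloIntactRatio:
    genome_id: str
    n_solo: int
    n_intact: int

    @property
    def ratio(self) -> float:
        if self.n_intact == 0:
            return float("nan")
        return self.n_solo / self.n_intact

    @property
    def defined(self) -> bool:
        return self.n_intact > 0


def _find_tsd(seq: str, start: int, end: int, params: SoloParams) -> str | None:
    """Exact TSD anchored at the hit boundaries, longest-first (6,5,4)."""
    for off_l in range(params.tsd_slack + 1):
        for off_r in range(params.tsd_slack + 1):
            a, b = start - off_l, end + off_r
            for tk in range(params.tsd_max, params.tsd_min - 1, -1):
                if a - tk < 0 or b + tk > len(seq):
                    continue
                left = seq[a - tk:a]
                if "N" not in left and left == seq[b:b + tk]:
                    return left
    return None


def detect_solo_ltrs(repeat_hits: list[RepeatHit],
                     intact_elements: list[IntactLTRRT],
                     genome: Genome,
                     consensus_lengths: dict[str, int],
                     params: SoloParams | None = None,
                     ) -> tuple[list[SoloLTR], list[tuple[RepeatHit, str]]]:
    """Apply the solo-LTR rule to a repeat hit table.

    Returns (solos, rejected) where rejected pairs each discarded hit with
    its reason (low_identity, low_coverage, near_internal, edge, no_tsd).
    The procedure is per-hit and order-independent.
    """
    params = params or SoloParams()
    exclusion: list[GenomicInterval] = []
    for el in intact_elements:
        exclusion.append(el.element_interval)
        exclusion.append(el.internal)

    solos: list[SoloLTR] = []
    rejected: list[tuple[RepeatHit, str]] = []
    for hit in repeat_hits:
        if not hit.identity > params.min_identity:
            rejected.append((hit, "low_identity"))
            continue
        clen = consensus_lengths.get(hit.consensus_id)
        if clen is None:
            rejected.append((hit, "unknown_consensus"))
            continue
        coverage = hit.consensus_coverage(clen)
        if coverage < params.min_coverage:
            rejected.append((hit, "low_coverage"))
            continue
        iv = hit.interval
        near = any(
            iv.seq_id == ex.seq_id and iv.distance(ex) <= params.exclusion_margin
            for ex in exclusion
        )
        if near:
            rejected.append((hit, "near_internal"))
            continue
        seq = genome[iv.seq_id]
        if iv.start - params.tsd_max < 0 or iv.end + params.tsd_max > len(seq):
            rejected.append((hit, "edge"))
            continue
        tsd = _find_tsd(seq, iv.start, iv.end, params)
        if tsd is None:
            rejected.append((hit, "no_tsd"))
            continue
        solos.append(SoloLTR(iv, hit.consensus_id, hit.identity, coverage, tsd))
    return solos, rejected


def si_ratio(solos: list[SoloLTR] | int, intacts: list[IntactLTRRT] | int,
             genome_id: str = "genome") -> SoloIntactRatio:
    """Solo : intact count ratio for one genome (NaN-flagged at 0 intact)."""
    n_solo = solos if isinstance(solos, int) else len(solos)
    n_intact = intacts if isinstance(intacts, int) else len(intacts)
    return SoloIntactRatio(genome_id, n_solo, n_intact)


def correlate(x_values, y_values) -> tuple[float, float]:
    """Pearson correlation with a two-sided p from t with n-2 df."""
    import numpy as np

    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
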
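"""Insertion-time estimation from inter-LTR divergence.

Both LTRs of an element are identical at insertion, so the nucleotide
divergence K between the 5' and 3' LTR measures twice the time since
insertion: T = K / (2 r), with r the substitution rate per site per year
(default 1.3e-8).  The raw mismatch fraction p is corrected for multiple
hits with Jukes-Cantor: K = -(3/4) ln(1 - 4p/3); the uncorrected p can be
used instead via ``correction="none"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import aligned_site_stats
from .ltr_detect import IntactLTRRT

DEFAULT_RATE = 1.3e-8  # substitutions / site / year
SATURATION_P = 0.75    # JC69 undefined at and beyond this mismatch fraction
MIN_ALIGNED_SITES = 50


@dataclass(frozen=True)
class AgeEstimate:
    element_id: str
    raw_mismatch_fraction: float
    K: float                     # corrected divergence, substitutions/site
    T: float                     # insertion time, million years
    aligned_sites: int
    flags: tuple[str, ...] = ()


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a raw mismatch fraction."""
    if not 0.0 <= p < SATURATION_P:
        raise ValueError(f"mismatch fraction {p} outside [0, {SATURATION_P})")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ltr_divergence(ltr5_seq: str, ltr3_seq: str,
                   correction: str = "jc69") -> tuple[float, float, int, tuple[str, ...]]:
    """Divergence between the two LTRs of one element.

    Globally aligns the sequences; columns containing a gap or an N are
    excluded.  Returns (raw p, K, aligned_sites, flags); K is NaN when the
    alignment is saturated (p >= 0.75).
    """
    if not ltr5_seq or not ltr3_seq:
        raise ValueError("empty LTR sequence")
    mismatches, sites = aligned_site_stats(ltr5_seq, ltr3_seq)
    flags: list[str] = []
    if sites < MIN_ALIGNED_SITES:
        flags.append("short_alignment")
    if sites == 0:
        return float("nan"), float("nan"), 0, tuple(flags)
    p = mismatches / sites
    if correction == "none":
        k = p
    elif p >= SATURATION_P:
        flags.append("saturated")
        k = float("nan")
    else:
        k = jukes_cantor(p)
    return p, k, sites, tuple(flags)


def insertion_time(K: float, r: float = DEFAULT_RATE) -> float:
    """Insertion time in million years: T = K / (2 r) / 1e6."""
    if K < 0:
        raise ValueError(f"negative divergence {K}")
    if r <= 0:
        raise ValueError(f"non-positive rate {r}")
    return K / (2.0 * r) / 1e6


def date_elements(elements: list[IntactLTRRT], genome,
                  r: float = DEFAULT_RATE,
                  correction: str = "jc69") -> list[AgeEstimate]:
    """Estimate the insertion time of every element from its genome sequence."""
    out = []
    for el in elements:
        seq = genome[el.element_interval.seq_id]
        p, k, sites, flags = ltr_divergence(
            seq[el.ltr5.start:el.ltr5.end],
            seq[el.ltr3.start:el.ltr3.end],
            correction=correction,
        )
        t = insertion_time(k, r) if not math.isnan(k) else float("nan")
        out.append(AgeEstimate(el.element_id, p, k, t, sites, flags))
    return out


def age_summary(ages: list[AgeEstimate],
                lineages: dict[str, str | None] | None = None,
                bin_width: float = 0.1,
                recent_cutoff: float = 0.5) -> dict:
    """Per-genome (and optionally per-lineage) insertion-time distributions.

    Reports mean, median, a histogram at ``bin_width``-MY bins, and the
    fraction of elements no older than ``recent_cutoff`` MY (the
    recent-amplification statistic).
    """
    dated = [a for a in ages if not math.isnan(a.T)]
    if not dated:
        raise ValueError("no dated elements")

    def stats(subset: list[AgeEstimate]) -> dict:
        ts = np.array([a.T for a in subset])
        edges = np.arange(0.0, ts.max() + bin_width, bin_width)
        if len(edges) < 2:
            edges = np.array([0.0, bin_width])
        hist, _ = np.histogram(ts, bins=edges)
        return {
            "n": len(ts),
            "mean": float(ts.mean()),
            "median": float(np.median(ts)),
            "fraction_recent": float((ts <= recent_cutoff).mean()),
            "hist_edges": edges.tolist(),
            "hist_counts": hist.tolist(),
        }

    out = {"genome": stats(dated)}
    if lineages:
        per_lineage: dict[str, list[AgeEstimate]] = {}
        for a in dated:
            lin = lineages.get(a.element_id)
            if lin:
                per_lineage.setdefault(lin, []).append(a)
        out["by_lineage"] = {lin: stats(sub) for lin, sub in
                             sorted(per_lineage.items())}
    return out


def ages_to_frame(ages: list[AgeEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "element_id": [a.element_id for a in ages],
            "p": [a.raw_mismatch_fraction for a in ages],
            "K": [a.K for a in ages],
            "T_MY": [a.T for a in ages],
            "aligned_sites": [a.aligned_sites for a in ages],
            "flags": [",".join(a.flags) for a in ages],
        }
    ).set_index("element_id")
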
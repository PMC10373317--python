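"""Transcriptional-activity calls and DNA-methylation metaprofiles.

An intact element is called transcriptionally active when its mean CPM
across replicates exceeds 1 (strict inequality).  Methylation is
summarised per sequence context (CG / CHG / CHH) as the weighted level
sum(meth) / sum(meth + unmeth) in 20 upstream 100-bp bins, 20
proportionally scaled body bins and 20 downstream 100-bp bins, pooled over
the elements of each (context, lineage, activity) stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CytosineCall, GeneModel, Genome, GenomicInterval, RepeatHit
from .ltr_detect import IntactLTRRT

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class ProfileParams:
    flank_bp: int = 2000
    flank_bins: int = 20
    body_bins: int = 20
    min_coverage: int = 4     # per-cytosine total count to be included


@dataclass(frozen=True)
class ActivityCall:
    element_id: str
    cpm_per_sample: tuple[float, ...]
    mean_cpm: float
    active: bool


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each column scaled by its library size."""
    libsizes = counts.sum(axis=0)
    if (libsizes <= 0).any():
        bad = libsizes[libsizes <= 0].index.tolist()
        raise ValueError(f"zero library size in samples {bad}")
    return counts.div(libsizes, axis=1) * 1e6


def call_activity(cpm_matrix: pd.DataFrame,
                  threshold: float = 1.0) -> list[ActivityCall]:
    """Active <=> mean CPM across replicates strictly exceeds ``threshold``."""
    if cpm_matrix.shape[1] < 1:
        raise ValueError("need at least one sample")
    out = []
    for fid, row in cpm_matrix.iterrows():
        mean = float(row.mean())
        out.append(
            ActivityCall(str(fid), tuple(float(v) for v in row),
                         mean, mean > threshold)
        )
    return out


def compare_active_silent(elements: list[IntactLTRRT],
                          ages: dict[str, float],
                          activity: dict[str, bool]) -> pd.DataFrame:
    """Length and age of active vs silent elements, Welch t-test per trait.

    ``ages`` maps element_id to insertion time (MY); ``activity`` maps
    element_id to the activity call.  Returns one row per trait with group
    means/medians, t and p.
    """
    groups: dict[bool, list[IntactLTRRT]] = {True: [], False: []}
    for el in elements:
        if el.element_id in activity:
            groups[activity[el.element_id]].append(el)
    if len(groups[True]) < 2 or len(groups[False]) < 2:
        raise ValueError("need >= 2 elements per activity group")

    rows = []
    for trait, getter in (
        ("length_bp", lambda el: float(el.length)),
        ("age_MY", lambda el: ages.get(el.element_id, float("nan"))),
    ):
        vals = {
            label: np.array([getter(el) for el in groups[flag]])
            for label, flag in (("active", True), ("silent", False))
        }
        vals = {k: v[~np.isnan(v)] for k, v in vals.items()}
        t, p = stats.ttest_ind(vals["active"], vals["silent"], equal_var=False)
        rows.append(
            {
                "trait": trait,
                "n_active": len(vals["active"]),
                "n_silent": len(vals["silent"]),
                "active_mean": float(vals["active"].mean()),
                "active_median": float(np.median(vals["active"])),
                "silent_mean": float(vals["silent"].mean()),
                "silent_median": float(np.median(vals["silent"])),
                "t_statistic": float(t),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


# ---------------------------------------------------------------------------
# metaprofiles
# ---------------------------------------------------------------------------

def _feature_bins(interval: GenomicInterval, pos: int,
                  params: ProfileParams) -> tuple[str, int] | None:
    """Map a genomic position to (region, bin) for one feature, or None.

    Bins are half-open; upstream/downstream are fixed 100-bp bins spanning
    exactly ``flank_bp``; the body is split into ``body_bins``
    proportional bins (nearest-assignment for very short bodies).
    """
    start, end = interval.start, interval.end
    fb, nb = params.flank_bp, params.flank_bins
    if start - fb <= pos < start:
        return "upstream", (pos - (start - fb)) * nb // fb
    if start <= pos < end:
        return "body", min((pos - start) * params.body_bins // (end - start),
                           params.body_bins - 1)
    if end <= pos < end + fb:
        return "downstream", (pos - end) * nb // fb
    return None


def metaprofile(calls: list[CytosineCall],
                features: list[tuple[str, GenomicInterval, str, str]],
                params: ProfileParams | None = None) -> pd.DataFrame:
    """Pooled weighted-methylation metaprofile.

    ``features`` rows are (feature_id, interval, lineage, activity_label).
    Cytosine calls from both strands are pooled; calls with total coverage
    below ``params.min_coverage`` are excluded.  Returns a tidy frame with
    columns context, lineage, activity, region, bin, meth, total, level,
    n_cytosines; bins with no covered cytosine have level = NaN.
    """
    params = params or ProfileParams()
    by_seq: dict[str, list[CytosineCall]] = {}
    for c in calls:
        if c.coverage >= params.min_coverage:
            by_seq.setdefault(c.seq_id, []).append(c)
    for seq_calls in by_seq.values():
        seq_calls.sort(key=lambda c: c.pos)
    positions = {sid: np.array([c.pos for c in cl])
                 for sid, cl in by_seq.items()}

    nbins = {"upstream": params.flank_bins, "body": params.body_bins,
             "downstream": params.flank_bins}
    acc: dict[tuple, np.ndarray] = {}

    def stratum_arrays(key):
        if key not in acc:
            acc[key] = np.zeros((3, sum(nbins.values())), dtype=np.int64)
        return acc[key]

    region_offset = {"upstream": 0, "body": params.flank_bins,
                     "downstream": params.flank_bins + params.body_bins}

    for _fid, interval, lineage, activity in features:
        sid = interval.seq_id
        if sid not in by_seq:
            continue
        pos = positions[sid]
        lo = np.searchsorted(pos, interval.start - params.flank_bp)
        hi = np.searchsorted(pos, interval.end + params.flank_bp)
        for c in by_seq[sid][lo:hi]:
            hit = _feature_bins(interval, c.pos, params)
            if hit is None:
                continue
            region, b = hit
            arr = stratum_arrays((c.context, lineage, activity))
            col = region_offset[region] + b
            arr[0, col] += c.meth_count
            arr[1, col] += c.unmeth_count
            arr[2, col] += 1

    rows = []
    for (context, lineage, activity), arr in sorted(acc.items()):
        for region in ("upstream", "body", "downstream"):
            off = region_offset[region]
            for b in range(nbins[region]):
                meth = int(arr[0, off + b])
                unmeth = int(arr[1, off + b])
                total = meth + unmeth
                rows.append(
                    {
                        "context": context,
                        "lineage": lineage,
                        "activity": activity,
                        "region": region,
                        "bin": b,
                        "meth": meth,
                        "total": total,
                        "level": meth / total if total else float("nan"),
                        "n_cytosines": int(arr[2, off + b]),
                    }
                )
    return pd.DataFrame(rows)


def element_profile_features(elements: list[IntactLTRRT],
                             activity: dict[str, bool] | None = None,
                             ) -> list[tuple[str, GenomicInterval, str, str]]:
    """Adapt elements to metaprofile feature rows."""
    rows = []
    for el in elements:
        label = "all"
        if activity is not None:
            flag = activity.get(el.element_id)
            label = "active" if flag else "silent"
        rows.append((el.element_id, el.element_interval,
                     el.lineage or "unassigned", label))
    return rows


def region_level(calls: list[CytosineCall], interval: GenomicInterval,
                 context: str, min_coverage: int = 4) -> float:
    """Weighted methylation level of one region in one context."""
    meth = total = 0
    for c in calls:
        if (c.seq_id == interval.seq_id and interval.start <= c.pos < interval.end
                and c.context == context and c.coverage >= min_coverage):
            meth += c.meth_count
            total += c.coverage
    return meth / total if total else float("nan")


def gene_vs_ltr_profile(calls: list[CytosineCall], genes: list[GeneModel],
                        elements: list[IntactLTRRT],
                        params: ProfileParams | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The same body +- flank metaprofile for genes and for elements."""
    if not genes:
        raise ValueError("empty gene set")
    gene_features = [(g.gene_id, g.interval, "gene", "all") for g in genes]
    ltr_features = [(el.element_id, el.element_interval, "LTR-RT", "all")
                    for el in elements]
    return (metaprofile(calls, gene_features, params),
            metaprofile(calls, ltr_features, params))


# ---------------------------------------------------------------------------
# flank TE density
# ---------------------------------------------------------------------------

def flank_te_density(elements: list[IntactLTRRT],
                     repeat_hits: list[RepeatHit],
                     flank_bp: int = 2000) -> pd.DataFrame:
    """Per lineage, the fraction of element-flanking bases covered by TEs.

    Both 2-kb flanks of every element are pooled per lineage; a base
    counts as covered when it lies in >= 1 repeat hit outside the
    element's own span.
    """
    hits_by_seq: dict[str, list[tuple[int, int]]] = {}
    for h in repeat_hits:
        hits_by_seq.setdefault(h.interval.seq_id, []).append(
            (h.interval.start, h.interval.end)
        )

    covered: dict[str, int] = {}
    totals: dict[str, int] = {}
    for el in elements:
        lineage = el.lineage or "unassigned"
        iv = el.element_interval
        flanks = [(max(0, iv.start - flank_bp), iv.start), (iv.end, iv.end + flank_bp)]
        for fs, fe in flanks:
            if fe <= fs:
                continue
            mask = np.zeros(fe - fs, dtype=bool)
            for hs, he in hits_by_seq.get(iv.seq_id, []):
                # a hit inside the element's own span never reaches the flank
                a, b = max(hs, fs), min(he, fe)
                if a < b:
                    mask[a - fs:b - fs] = True
            covered[lineage] = covered.get(lineage, 0) + int(mask.sum())
            totals[lineage] = totals.get(lineage, 0) + (fe - fs)
    rows = [
        {"lineage": lin, "flank_bases": totals[lin],
         "covered_bases": covered[lin],
         "density": covered[lin] / totals[lin]}
        for lin in sorted(totals)
    ]
    return pd.DataFrame(rows).set_index("lineage")
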
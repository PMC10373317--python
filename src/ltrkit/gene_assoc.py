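"""LTR-RT / gene association and expression comparison.

An element is associated with a gene when it overlaps (by >= 1 bp) the
gene's exons, introns, promoter (5 kb upstream of the TSS, strand-aware)
or downstream region (5 kb past the TTS).  One category is reported per
(gene, element) pair with precedence exon > intron > promoter >
downstream: evidence inside the gene body outranks flanking evidence.
Expression of each associated gene group is compared against the whole
gene set with a Welch t-test on log2(TPM + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneModel, GenomicInterval
from .ltr_detect import IntactLTRRT

CATEGORIES = ("promoter", "exon", "intron", "downstream")
PRECEDENCE = ("exon", "intron", "promoter", "downstream")


@dataclass(frozen=True)
class GeneAssociation:
    gene_id: str
    element_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"invalid category {self.category!r}")


@dataclass(frozen=True)
class ExpressionComparison:
    category: str
    n_genes: int
    group_mean_log2: float
    background_mean_log2: float
    t_statistic: float
    p_value: float
    direction: str  # higher / lower / ns


def gene_regions(gene: GeneModel, promoter_bp: int = 5000,
                 downstream_bp: int = 5000) -> dict[str, list[GenomicInterval]]:
    """Strand-aware region decomposition of one gene.

    The promoter is the ``promoter_bp`` window upstream of the TSS and the
    downstream region the window past the TTS; neither extends into the
    gene's own body, and both are clipped at position 0.
    """
    iv = gene.interval
    if gene.strand == "+":
        prom = (max(0, iv.start - promoter_bp), iv.start)
        down = (iv.end, iv.end + downstream_bp)
    else:
        prom = (iv.end, iv.end + promoter_bp)
        down = (max(0, iv.start - downstream_bp), iv.start)
    regions: dict[str, list[GenomicInterval]] = {
        "exon": list(gene.exons),
        "intron": list(gene.introns),
        "promoter": [],
        "downstream": [],
    }
    if prom[0] < prom[1]:
        regions["promoter"] = [GenomicInterval(iv.seq_id, *prom, gene.strand)]
    if down[0] < down[1]:
        regions["downstream"] = [GenomicInterval(iv.seq_id, *down, gene.strand)]
    return regions


def associate(elements: list[IntactLTRRT], genes: list[GeneModel],
              promoter_bp: int = 5000,
              downstream_bp: int = 5000) -> list[GeneAssociation]:
    """Classify every (gene, element) overlap into one category.

    An element may associate with several genes; each (gene, element) pair
    yields at most one record, chosen by precedence exon > intron >
    promoter > downstream.
    """
    out: list[GeneAssociation] = []
    for gene in genes:
        regions = gene_regions(gene, promoter_bp, downstream_bp)
        for el in elements:
            span = el.element_interval
            for category in PRECEDENCE:
                if any(span.overlaps(r) for r in regions[category]):
                    out.append(GeneAssociation(gene.gene_id, el.element_id,
                                               category))
                    break
    return out


def tpm(counts: pd.DataFrame, feature_lengths: dict[str, int] | pd.Series,
        ) -> pd.DataFrame:
    """Transcripts per million: per-kilobase rates rescaled to sum to 1e6."""
    lengths = pd.Series(feature_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise ValueError(f"missing lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("non-positive feature length")
    rates = counts.div(lengths / 1e3, axis=0)
    totals = rates.sum(axis=0)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"zero total rate in samples {bad}")
    return rates.div(totals, axis=1) * 1e6


def compare_expression(associations: list[GeneAssociation],
                       tpm_table: pd.DataFrame,
                       category: str,
                       alpha: float = 0.05) -> ExpressionComparison:
    """Welch t-test of one associated gene group against the whole gene set.

    TPM is averaged across replicate columns, then log2(TPM + 1)
    transformed.  The background is the entire gene set, group members
    included.  ``direction`` is the sign of the group-minus-background
    mean difference when p < alpha, else "ns".
    """
    if category not in CATEGORIES:
        raise ValueError(f"invalid category {category!r}")
    group_ids = sorted({a.gene_id for a in associations
                        if a.category == category})
    group_ids = [g for g in group_ids if g in tpm_table.index]
    if len(group_ids) < 2:
        raise ValueError(f"fewer than 2 genes in category {category!r}")
    mean_tpm = tpm_table.mean(axis=1)
    log_all = np.log2(mean_tpm + 1.0)
    log_group = log_all.loc[group_ids]
    t_stat, p = stats.ttest_ind(log_group, log_all, equal_var=False)
    diff = float(log_group.mean() - log_all.mean())
    if p < alpha:
        direction = "higher" if diff > 0 else "lower"
    else:
        direction = "ns"
    return ExpressionComparison(
        category=category,
        n_genes=len(group_ids),
        group_mean_log2=float(log_group.mean()),
        background_mean_log2=float(log_all.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        direction=direction,
    )


def associations_to_frame(associations: list[GeneAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.gene_id, a.element_id, a.category) for a in associations],
        columns=["gene_id", "element_id", "category"],
    )
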
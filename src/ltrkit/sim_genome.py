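"""Synthetic genomes with planted LTR retrotransposons and full ground truth.

The generator plants, into a random background sequence:

* intact elements — TSD + 5'LTR (TG...CA) + internal region carrying
  ordered 30-bp domain sentinels (Copia: GAG-PR-INT-RT-RH; Gypsy:
  GAG-PR-RT-RH-INT) + 3'LTR + the same TSD.  The two LTRs start as exact
  copies and receive independent per-site substitutions so that the
  expected pairwise divergence equals 2 r T for the planted age T (the
  terminal TG/CA dinucleotides are exempt, standing in for the selective
  constraint that keeps them intact in vivo);
* solo LTRs — a single LTR copy flanked by an exact TSD, plus a class
  whose flanks are deliberately TSD-free;
* truncated LTR fragments covering < 80% of their consensus;
* gene models with exon/intron structure;

and emits every downstream input: repeat-hit and domain-hit tables, a
combined gene + element count table whose active elements have CPM > 1 by
construction, and a strand- and context-resolved cytosine report drawn
binomially around per-class methylation means.  Every planted feature is
recorded in a truth registry for recovery tests.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    CytosineCall,
    GeneModel,
    Genome,
    GenomicInterval,
    RepeatHit,
    write_cx_report,
    write_counts,
    write_fasta,
    write_gff3_genes,
    write_repeat_hits,
)
from .ltr_detect import COPIA_LINEAGES, COPIA_ORDER, GYPSY_LINEAGES, GYPSY_ORDER, DomainHit

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Fixed 30-bp sentinel motifs standing in for the protein-coding domains,
# so that superfamily classification is testable without profile searches.
DOMAIN_MOTIFS = {
    "GAG": "ATGGCTAAGGCAGATTCCGATCTACGGAAG",
    "PR":  "TGTCCGATTACCAGTTCAGGCTAGATCCAA",
    "INT": "GGACTTCAAGATCCGTTAGCTGAACCGTAT",
    "RT":  "CATCGGAGTTCAAGCCTAGGTAACGATCTG",
    "RH":  "TACGGTTCAGATCCAGCTTAGGAATCCGAC",
}


@dataclass
class MethylationParams:
    """Per-context methylation means (CG, CHG, CHH) by element class."""

    silent: tuple[float, float, float] = (0.85, 0.70, 0.10)
    active: tuple[float, float, float] = (0.45, 0.30, 0.06)
    background: float = 0.05
    coverage_mean: float = 20.0

    def class_means(self, active: bool) -> dict[str, float]:
        vals = self.active if active else self.silent
        return dict(zip(("CG", "CHG", "CHH"), vals))


@dataclass
class SimConfig:
    genome_length: int = 2_000_000
    seq_id: str = "chr1"
    n_intact: int = 50
    n_solo: int = 30
    n_solo_without_tsd: int = 10
    n_truncated: int = 10
    n_genes: int = 30
    ltr_length_range: tuple[int, int] = (800, 1500)
    internal_length_range: tuple[int, int] = (2000, 8000)
    gene_length_range: tuple[int, int] = (1500, 4000)
    age_range: tuple[float, float] = (0.1, 3.0)        # million years
    solo_divergence_range: tuple[float, float] = (0.0, 0.10)
    substitution_rate: float = 1.3e-8                  # /site/year
    tsd_length_range: tuple[int, int] = (4, 6)
    active_fraction: float = 0.3
    n_samples: int = 2
    methylation: MethylationParams = field(default_factory=MethylationParams)
    cx_flank: int = 2200          # emit cytosine calls within features +- this
    spacing: int = 500            # minimum gap between planted features
    edge_margin: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ltr_length_range
        if not 100 <= lo <= hi <= 7000:
            raise ValueError("ltr_length_range must lie within [100, 7000]")
        tlo, thi = self.tsd_length_range
        if not 4 <= tlo <= thi <= 6:
            raise ValueError("tsd_length_range must lie within [4, 6]")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction outside [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        meth = raw.pop("methylation", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if meth:
            cfg.methylation = MethylationParams(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in meth.items()}
            )
        return cfg


@dataclass
class PlantedFeature:
    feature_id: str
    kind: str                       # intact / solo / solo_no_tsd / truncated / gene
    interval: GenomicInterval       # feature span, TSD excluded
    tsd: str | None = None
    age: float | None = None        # million years
    divergence: float | None = None  # expected substitutions/site between LTRs
    lineage: str | None = None
    superfamily: str | None = None
    active: bool | None = None
    consensus_id: str | None = None
    ltr5: GenomicInterval | None = None
    ltr3: GenomicInterval | None = None


@dataclass
class SimTruth:
    features: list[PlantedFeature]

    def of_kind(self, kind: str) -> list[PlantedFeature]:
        return [f for f in self.features if f.kind == kind]

    @property
    def intact(self) -> list[PlantedFeature]:
        return self.of_kind("intact")

    @property
    def solos(self) -> list[PlantedFeature]:
        return self.of_kind("solo")

    @property
    def solos_without_tsd(self) -> list[PlantedFeature]:
        return self.of_kind("solo_no_tsd")

    @property
    def genes(self) -> list[PlantedFeature]:
        return self.of_kind("gene")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.features:
            rows.append(
                {
                    "feature_id": f.feature_id,
                    "kind": f.kind,
                    "seq_id": f.interval.seq_id,
                    "start": f.interval.start,
                    "end": f.interval.end,
                    "tsd": f.tsd or "",
                    "age_MY": f.age if f.age is not None else np.nan,
                    "divergence": f.divergence if f.divergence is not None else np.nan,
                    "lineage": f.lineage or "",
                    "superfamily": f.superfamily or "",
                    "active": "" if f.active is None else str(f.active),
                    "consensus_id": f.consensus_id or "",
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SimulatedData:
    config: SimConfig
    genome: Genome
    genes: list[GeneModel]
    repeat_hits: list[RepeatHit]
    domain_hits: list[DomainHit]
    counts: pd.DataFrame
    cx_calls: list[CytosineCall]
    consensi: dict[str, str]
    truth: SimTruth

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        join = lambda name: os.path.join(outdir, name)  # noqa: E731
        write_fasta(self.genome, join("genome.fa"))
        write_gff3_genes(self.genes, join("genes.gff3"))
        write_repeat_hits(self.repeat_hits, join("repeats.tsv"))
        write_domain_hits(self.domain_hits, join("domains.tsv"))
        write_counts(self.counts, join("counts.tsv"))
        write_cx_report(self.cx_calls, self.genome, join("genome.CX_report.txt"))
        write_fasta(self.consensi, join("ltr_consensi.fa"))
        self.truth.to_frame().to_csv(join("truth.tsv"), sep="\t", index=False)


def write_domain_hits(hits: list[DomainHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.element_id}\t{h.domain}\t{h.start + 1}\t{h.end}\t"
                     f"{h.lineage or ''}\n")


def read_domain_hits(path) -> list[DomainHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            hits.append(DomainHit(f[0], f[1], int(f[2]) - 1, int(f[3]),
                                  f[4] or None if len(f) > 4 else None))
    return hits


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, length)]


def mutate(seq: np.ndarray, prob: float, rng: np.random.Generator,
           protect_ends: int = 0) -> np.ndarray:
    """Independent per-site substitutions (always to a different base)."""
    out = seq.copy()
    hit = rng.random(len(seq)) < prob
    if protect_ends:
        hit[:protect_ends] = False
        hit[len(seq) - protect_ends:] = False
    idx = np.flatnonzero(hit)
    if len(idx):
        # map current base to one of the 3 alternatives
        lookup = np.zeros(256, dtype=np.int64)
        for i, b in enumerate(BASES):
            lookup[b] = i
        cur = lookup[out[idx]]
        out[idx] = BASES[(cur + rng.integers(1, 4, len(idx))) % 4]
    return out


def make_ltr_pair(rng: np.random.Generator, length: int, divergence: float,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ancestral, copy5, copy3): copies each mutated at divergence/2.

    The ancestral LTR starts TG and ends CA; those four sites are exempt
    from mutation so planted elements keep their terminal motifs.
    """
    anc = random_seq(rng, length)
    anc[0:2] = np.frombuffer(b"TG", dtype=np.uint8)
    anc[-2:] = np.frombuffer(b"CA", dtype=np.uint8)
    c5 = mutate(anc, divergence / 2.0, rng, protect_ends=2)
    c3 = mutate(anc, divergence / 2.0, rng, protect_ends=2)
    return anc, c5, c3


def simulate_ltr_pairs(n: int, ltr_length: int, age_range: tuple[float, float],
                       r: float = 1.3e-8, seed: int = 0,
                       ) -> list[tuple[float, str, str]]:
    """Standalone LTR pairs for dating studies: (age_MY, seq5, seq3)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        age = rng.uniform(*age_range)
        d = 2.0 * r * age * 1e6
        _, c5, c3 = make_ltr_pair(rng, ltr_length, d)
        out.append((age, c5.tobytes().decode(), c3.tobytes().decode()))
    return out


def _make_internal(rng: np.random.Generator, length: int, superfamily: str,
                   ) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    """Internal region with ordered domain sentinels; returns (seq, hits)."""
    seq = random_seq(rng, length)
    order = ("GAG", "PR") + (COPIA_ORDER if superfamily == "Copia" else GYPSY_ORDER)
    hits = []
    motif_len = 30
    n_dom = len(order)
    for i, dom in enumerate(order):
        start = (i + 1) * length // (n_dom + 2)
        motif = np.frombuffer(DOMAIN_MOTIFS[dom].encode(), dtype=np.uint8)
        seq[start:start + motif_len] = motif
        hits.append((dom, start, start + motif_len))
    return seq, hits


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _place(rng: np.random.Generator, length: int, occupied: list[tuple[int, int]],
           genome_length: int, spacing: int, margin: int) -> int:
    for _ in range(2000):
        start = int(rng.integers(margin, genome_length - margin - length))
        if all(start - spacing >= e or start + length + spacing <= s
               for s, e in occupied):
            occupied.append((start, start + length))
            return start
    raise ValueError(
        "cannot place requested features without overlap; "
        "increase genome_length or reduce feature counts"
    )


def _break_accidental_tsds(seq: bytearray, start: int, end: int,
                           tsd_len: int, rng: np.random.Generator) -> None:
    """Ensure no flank match longer than the planted TSD (or any, if 0)."""
    for _ in range(3):  # mutations can in principle create new matches
        changed = False
        for tk in range(6, tsd_len, -1):
            if start - tk < 0 or end + tk > len(seq):
                continue
            if seq[start - tk:start] == seq[end:end + tk]:
                old = seq[start - tk]
                choices = [b for b in b"ACGT" if b != old]
                seq[start - tk] = choices[int(rng.integers(0, 3))]
                changed = True
        if not changed:
            return


def simulate_genome(config: SimConfig | None = None) -> SimulatedData:
    """Generate one synthetic genome with its complete truth registry."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_length
    sid = cfg.seq_id
    seq = bytearray(random_seq(rng, L).tobytes())

    occupied: list[tuple[int, int]] = []
    truth: list[PlantedFeature] = []
    repeat_hits: list[RepeatHit] = []
    domain_hits: list[DomainHit] = []
    consensi: dict[str, str] = {}

    copia_lin = sorted(COPIA_LINEAGES)
    gypsy_lin = sorted(GYPSY_LINEAGES)

    n_active = int(round(cfg.n_intact * cfg.active_fraction))
    active_flags = np.array([True] * n_active +
                            [False] * (cfg.n_intact - n_active))
    rng.shuffle(active_flags)

    # ---- intact elements -------------------------------------------------
    for i in range(cfg.n_intact):
        ltr_len = int(rng.integers(cfg.ltr_length_range[0],
                                   cfg.ltr_length_range[1] + 1))
        int_len = int(rng.integers(cfg.internal_length_range[0],
                                   cfg.internal_length_range[1] + 1))
        age = float(rng.uniform(*cfg.age_range))
        div = 2.0 * cfg.substitution_rate * age * 1e6
        tsd_len = int(rng.integers(cfg.tsd_length_range[0],
                                   cfg.tsd_length_range[1] + 1))
        tsd = random_seq(rng, tsd_len)
        superfamily = "Copia" if rng.random() < 0.5 else "Gypsy"
        lineage = (copia_lin if superfamily == "Copia" else gypsy_lin)[
            int(rng.integers(0, len(copia_lin if superfamily == "Copia"
                                    else gypsy_lin)))
        ]
        anc, c5, c3 = make_ltr_pair(rng, ltr_len, div)
        internal, dom_local = _make_internal(rng, int_len, superfamily)

        cassette = np.concatenate([tsd, c5, internal, c3, tsd])
        start = _place(rng, len(cassette), occupied, L, cfg.spacing,
                       cfg.edge_margin)
        seq[start:start + len(cassette)] = cassette.tobytes()
        el_start = start + tsd_len                 # element span excludes TSD
        el_end = el_start + ltr_len + int_len + ltr_len
        _break_accidental_tsds(seq, el_start, el_end, tsd_len, rng)

        fid = f"sim_intact_{i + 1:03d}"
        cons_id = f"consLTR_{fid}"
        consensi[cons_id] = anc.tobytes().decode()
        ltr5 = GenomicInterval(sid, el_start, el_start + ltr_len)
        ltr3 = GenomicInterval(sid, el_end - ltr_len, el_end)
        truth.append(
            PlantedFeature(
                feature_id=fid, kind="intact",
                interval=GenomicInterval(sid, el_start, el_end),
                tsd=tsd.tobytes().decode(), age=age, divergence=div,
                lineage=lineage, superfamily=superfamily,
                active=bool(active_flags[i]), consensus_id=cons_id,
                ltr5=ltr5, ltr3=ltr3,
            )
        )
        for iv, ident in ((ltr5, 1.0 - div / 2), (ltr3, 1.0 - div / 2)):
            repeat_hits.append(
                RepeatHit(iv, cons_id, 0, ltr_len, max(0.0, ident))
            )
        int_start = el_start + ltr_len
        for dom, ds, de in dom_local:
            domain_hits.append(
                DomainHit(fid, dom, int_start + ds, int_start + de, lineage)
            )

    # ---- solo LTRs (with and without TSD) --------------------------------
    for i in range(cfg.n_solo + cfg.n_solo_without_tsd):
        with_tsd = i < cfg.n_solo
        ltr_len = int(rng.integers(cfg.ltr_length_range[0],
                                   cfg.ltr_length_range[1] + 1))
        div = float(rng.uniform(*cfg.solo_divergence_range))
        anc, copy, _ = make_ltr_pair(rng, ltr_len, div * 2.0)
        tsd_len = int(rng.integers(cfg.tsd_length_range[0],
                                   cfg.tsd_length_range[1] + 1))
        tsd = random_seq(rng, tsd_len)
        if with_tsd:
            cassette = np.concatenate([tsd, copy, tsd])
            start = _place(rng, len(cassette), occupied, L, cfg.spacing,
                           cfg.edge_margin)
            seq[start:start + len(cassette)] = cassette.tobytes()
            s0 = start + tsd_len
            e0 = s0 + ltr_len
            _break_accidental_tsds(seq, s0, e0, tsd_len, rng)
            fid = f"sim_solo_{i + 1:03d}"
            kind, tsd_str = "solo", tsd.tobytes().decode()
        else:
            start = _place(rng, ltr_len, occupied, L, cfg.spacing,
                           cfg.edge_margin)
            seq[start:start + ltr_len] = copy.tobytes()
            s0, e0 = start, start + ltr_len
            _break_accidental_tsds(seq, s0, e0, 0, rng)  # no match at any k
            fid = f"sim_solo_notsd_{i - cfg.n_solo + 1:03d}"
            kind, tsd_str = "solo_no_tsd", None
        cons_id = f"consLTR_{fid}"
        consensi[cons_id] = anc.tobytes().decode()
        iv = GenomicInterval(sid, s0, e0)
        truth.append(
            PlantedFeature(fid, kind, iv, tsd=tsd_str, divergence=div,
                           consensus_id=cons_id)
        )
        repeat_hits.append(
            RepeatHit(iv, cons_id, 0, ltr_len, max(0.0, 1.0 - div))
        )

    # ---- truncated fragments --------------------------------------------
    for i in range(cfg.n_truncated):
        ltr_len = int(rng.integers(cfg.ltr_length_range[0],
                                   cfg.ltr_length_range[1] + 1))
        anc, copy, _ = make_ltr_pair(rng, ltr_len, 0.04)
        frac = float(rng.uniform(0.3, 0.6))
        flen = max(60, int(ltr_len * frac))
        off = int(rng.integers(0, ltr_len - flen + 1))
        frag = copy[off:off + flen]
        start = _place(rng, flen, occupied, L, cfg.spacing, cfg.edge_margin)
        seq[start:start + flen] = frag.tobytes()
        _break_accidental_tsds(seq, start, start + flen, 0, rng)
        fid = f"sim_trunc_{i + 1:03d}"
        cons_id = f"consLTR_{fid}"
        consensi[cons_id] = anc.tobytes().decode()
        iv = GenomicInterval(sid, start, start + flen)
        truth.append(PlantedFeature(fid, "truncated", iv, consensus_id=cons_id))
        repeat_hits.append(RepeatHit(iv, cons_id, off, off + flen, 0.98))

    # ---- genes -----------------------------------------------------------
    genes: list[GeneModel] = []
    for i in range(cfg.n_genes):
        glen = int(rng.integers(cfg.gene_length_range[0],
                                cfg.gene_length_range[1] + 1))
        start = _place(rng, glen, occupied, L, cfg.spacing, cfg.edge_margin)
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(200, glen - 200, 100),
                                  size=2 * (n_ex - 1), replace=False))
        bounds = [0, *cuts.tolist(), glen]
        exons = []
        for j in range(0, len(bounds) - 1, 2):
            exons.append(GenomicInterval(sid, start + bounds[j],
                                         start + bounds[j + 1], strand))
        gid = f"sim_gene_{i + 1:03d}"
        gene = GeneModel(
            gene_id=gid,
            interval=GenomicInterval(sid, start, start + glen, strand),
            exons=tuple(exons), mrna_id=f"{gid}.1",
        )
        genes.append(gene)
        truth.append(PlantedFeature(gid, "gene", gene.interval))

    genome = Genome({sid: seq.decode()})

    counts = _simulate_counts(cfg, rng, truth, genes)
    cx_calls = _simulate_methylome(cfg, rng, genome, truth)

    repeat_hits.sort(key=lambda h: (h.interval.seq_id, h.interval.start))
    truth.sort(key=lambda f: f.interval.start)
    genes.sort(key=lambda g: g.interval.start)
    return SimulatedData(
        config=cfg, genome=genome, genes=genes, repeat_hits=repeat_hits,
        domain_hits=domain_hits, counts=counts, cx_calls=cx_calls,
        consensi=consensi, truth=SimTruth(truth),
    )


def _simulate_counts(cfg: SimConfig, rng: np.random.Generator,
                     truth: list[PlantedFeature],
                     genes: list[GeneModel]) -> pd.DataFrame:
    """Combined gene + element count table, library size exactly 1e6.

    With a 1e6 library, CPM equals the raw count, so planted active
    elements (counts >= 2) sit strictly above the CPM > 1 rule and silent
    ones (counts <= 1) at or below it, in every replicate.
    """
    lib = 1_000_000
    rows: dict[str, np.ndarray] = {}
    for f in truth:
        if f.kind != "intact":
            continue
        if f.active:
            target = rng.uniform(5.0, 100.0)
            counts = rng.poisson(target, cfg.n_samples) + 2
        else:
            counts = rng.integers(0, 2, cfg.n_samples)
        rows[f.feature_id] = counts.astype(np.int64)
    for g in genes:
        rows[g.gene_id] = rng.integers(50, 2000, cfg.n_samples).astype(np.int64)
    filler = lib - sum(rows.values(), np.zeros(cfg.n_samples, dtype=np.int64))
    if (filler <= 0).any():
        raise ValueError("library budget exceeded; reduce feature counts")
    rows["sim_gene_filler"] = filler
    samples = [f"rep{i + 1}" for i in range(cfg.n_samples)]
    return pd.DataFrame(rows, index=samples).T


def _simulate_methylome(cfg: SimConfig, rng: np.random.Generator,
                        genome: Genome,
                        truth: list[PlantedFeature]) -> list[CytosineCall]:
    """Binomially sampled cytosine calls within features +- cx_flank."""
    sid = cfg.seq_id
    seq = genome[sid]
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(codes)

    windows = []
    for f in truth:
        windows.append((max(0, f.interval.start - cfg.cx_flank),
                        min(n, f.interval.end + cfg.cx_flank)))
    windows.sort()
    merged: list[list[int]] = []
    for s, e in windows:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    # per-position methylation mean: background, overridden inside elements
    mean_by_ctx = {ctx: np.full(n, cfg.methylation.background)
                   for ctx in ("CG", "CHG", "CHH")}
    for f in truth:
        if f.kind in ("intact", "solo", "solo_no_tsd", "truncated"):
            means = cfg.methylation.class_means(bool(f.active))
            for ctx, m in means.items():
                mean_by_ctx[ctx][f.interval.start:f.interval.end] = m

    C, G, A_ = ord("C"), ord("G"), ord("A")
    calls: list[CytosineCall] = []
    for ws, we in merged:
        w = codes[ws:we]
        pos = np.arange(ws, we)
        # plus strand: C at p; context from p+1, p+2
        is_c = w == C
        full1 = codes[np.minimum(pos + 1, n - 1)]
        full2 = codes[np.minimum(pos + 2, n - 1)]
        ctx_plus = np.where(full1 == G, 0, np.where(full2 == G, 1, 2))
        # minus strand: G at p; context from p-1, p-2
        is_g = w == G
        back1 = codes[np.maximum(pos - 1, 0)]
        back2 = codes[np.maximum(pos - 2, 0)]
        ctx_minus = np.where(back1 == C, 0, np.where(back2 == C, 1, 2))

        ctx_names = np.array(["CG", "CHG", "CHH"])
        for strand, sel, ctx_idx in (("+", is_c, ctx_plus),
                                     ("-", is_g, ctx_minus)):
            p_sel = pos[sel]
            cidx = ctx_idx[sel]
            if not len(p_sel):
                continue
            cov = rng.poisson(cfg.methylation.coverage_mean, len(p_sel))
            means = np.empty(len(p_sel))
            for k, ctx in enumerate(ctx_names):
                m = cidx == k
                means[m] = mean_by_ctx[ctx][p_sel[m]]
            meth = rng.binomial(cov, means)
            for j in range(len(p_sel)):
                calls.append(
                    CytosineCall(sid, int(p_sel[j]), strand,
                                 str(ctx_names[cidx[j]]),
                                 int(meth[j]), int(cov[j] - meth[j]))
                )
    calls.sort(key=lambda c: (c.seq_id, c.pos, c.strand))
    return calls


# ---------------------------------------------------------------------------
# controls and auxiliary simulators
# ---------------------------------------------------------------------------

def shuffle_background(genome: Genome, seed: int = 0) -> Genome:
    """Per-sequence base shuffle: identical composition, no structure."""
    rng = np.random.default_rng(seed)
    out = {}
    for sid, s in genome.items():
        arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
        rng.shuffle(arr)
        out[sid] = arr.tobytes().decode()
    return Genome(out)


def simulate_association_expression(
    n_background: int = 600,
    n_promoter: int = 200,
    n_intron: int = 200,
    promoter_shift: float = -2.0,
    intron_shift: float = 2.0,
    n_samples: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, list]:
    """TPM table plus associations with planted expression shifts.

    Background gene log2-TPM is normal(4, 1.5); promoter-associated genes
    are shifted by ``promoter_shift`` and intron-associated genes by
    ``intron_shift`` (log2 units).  Returns (tpm_table, associations).
    """
    from .gene_assoc import GeneAssociation

    rng = np.random.default_rng(seed)
    ids, shifts = [], []
    for grp, count, shift in (("bg", n_background, 0.0),
                              ("prom", n_promoter, promoter_shift),
                              ("intr", n_intron, intron_shift)):
        for i in range(count):
            ids.append(f"{grp}_gene_{i + 1:04d}")
            shifts.append(shift)
    shifts = np.array(shifts)
    data = {}
    for s in range(n_samples):
        log2 = rng.normal(4.0 + shifts, 1.5)
        data[f"rep{s + 1}"] = np.maximum(0.0, 2.0 ** log2 - 1.0)
    table = pd.DataFrame(data, index=ids)
    assoc = []
    for i, gid in enumerate(ids):
        if gid.startswith("prom"):
            assoc.append(GeneAssociation(gid, f"el_p{i}", "promoter"))
        elif gid.startswith("intr"):
            assoc.append(GeneAssociation(gid, f"el_i{i}", "intron"))
    return table, assoc
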
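"""Readers, writers and domain containers for every external format the pipeline touches.

All coordinates held in memory are 0-based, half-open intervals.  GFF3 and
Bismark CX reports are 1-based on disk; the conversion happens exactly once,
inside the reader or writer, never in analysis code.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("ltrkit")

VALID_STRANDS = ("+", "-", ".")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval.

    ``strand`` is "+", "-" for stranded features (genes) and "." for
    repeats, whose two LTRs lie on the same strand regardless of
    orientation.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int:
        """Gap between two intervals on the same sequence; 0 if they touch or overlap."""
        if self.seq_id != other.seq_id:
            raise ValueError("distance undefined across sequences")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass(frozen=True)
class RepeatHit:
    """A repeat-library match on the genome (RepeatMasker-style)."""

    interval: GenomicInterval
    consensus_id: str
    consensus_start: int  # 0-based on the consensus
    consensus_end: int    # exclusive
    identity: float       # fraction in [0, 1]

    def __post_init__(self) -> None:
        if not 0 <= self.consensus_start < self.consensus_end:
            raise ValueError("invalid consensus coordinates")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0,1]")

    def consensus_coverage(self, consensus_length: int) -> float:
        return (self.consensus_end - self.consensus_start) / consensus_length


@dataclass(frozen=True)
class CytosineCall:
    """One cytosine's bisulfite evidence (one strand, one position)."""

    seq_id: str
    pos: int          # 0-based
    strand: str       # "+" or "-"
    context: str      # CG / CHG / CHH
    meth_count: int
    unmeth_count: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.context not in ("CG", "CHG", "CHH"):
            raise ValueError(f"invalid context {self.context!r}")
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError("negative counts")

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its canonical transcript (longest mRNA)."""

    gene_id: str
    interval: GenomicInterval          # gene span, stranded
    exons: tuple[GenomicInterval, ...]  # sorted by start
    mrna_id: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(
                    f"exon {ex.start}-{ex.end} outside gene {self.gene_id}"
                )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.interval.seq_id, a.end, b.start, self.strand)
                )
        return tuple(out)

    @property
    def tss(self) -> int:
        """Transcription start site, 0-based position of the first transcribed base."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


@dataclass
class Genome:
    """Uppercased sequences plus a soft-mask bitmap of the original case."""

    sequences: dict[str, str]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, seq_id: str) -> str:
        return self.sequences[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.sequences

    def __iter__(self):
        return iter(self.sequences)

    def items(self):
        return self.sequences.items()

    def length(self, seq_id: str) -> int:
        return len(self.sequences[seq_id])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are uppercased; lowercase (soft-masked) positions are kept in
    a boolean bitmap per sequence.  Duplicate ids and empty files are
    errors.
    """
    sequences: dict[str, str] = {}
    masks: dict[str, np.ndarray] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        raw = str(rec.seq)
        codes = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
        masks[rec.id] = (codes >= 97) & (codes <= 122)  # a-z
        sequences[rec.id] = raw.upper()
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(sequences, masks)


def write_fasta(genome: Genome | dict[str, str], path: str | os.PathLike,
                width: int = 60) -> None:
    seqs = genome.sequences if isinstance(genome, Genome) else genome
    with open(path, "w") as fh:
        for seq_id, seq in seqs.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# gene GFF3
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3, one canonical transcript per gene.

    The canonical transcript is the longest mRNA (span length); ties go to
    the mRNA that appears first in the file.  Introns are derived later
    from exon gaps.  Coordinates are converted from GFF3 1-based closed to
    0-based half-open.
    """
    db = gffutils.create_db(
        str(path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            logger.warning("gene %s has no mRNA children; skipped", gene.id)
            continue
        # longest span wins; ties -> first occurrence in file (line number)
        canonical = max(
            mrnas, key=lambda m: (m.end - m.start + 1, -m.file_order
                                  if hasattr(m, "file_order") else 0)
        )
        best_len = canonical.end - canonical.start + 1
        for m in mrnas:  # first-in-file tiebreak
            if m.end - m.start + 1 == best_len:
                canonical = m
                break
        exons = []
        for ex in db.children(canonical, featuretype="exon", order_by="start"):
            if ex.start - 1 < canonical.start - 1 or ex.end > canonical.end:
                raise ValueError(
                    f"exon {ex.start}-{ex.end} outside mRNA {canonical.id}"
                )
            exons.append(
                GenomicInterval(ex.seqid, ex.start - 1, ex.end, canonical.strand)
            )
        if not exons:
            raise ValueError(f"mRNA {canonical.id} of gene {gene.id} has no exons")
        genes.append(
            GeneModel(
                gene_id=gene.id,
                interval=GenomicInterval(
                    gene.seqid, gene.start - 1, gene.end, gene.strand
                ),
                exons=tuple(sorted(exons, key=lambda e: e.start)),
                mrna_id=canonical.id,
            )
        )
    return genes


def write_gff3_genes(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.seq_id}\tltrkit\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )
            mid = g.mrna_id or f"{g.gene_id}.1"
            fh.write(
                f"{iv.seq_id}\tltrkit\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={mid};Parent={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exons, 1):
                fh.write(
                    f"{iv.seq_id}\tltrkit\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{iv.strand}\t.\tID={mid}.exon{i};Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# Bismark CX report
# ---------------------------------------------------------------------------

def derive_context(seq: str, pos: int, strand: str) -> str | None:
    """Cytosine context (CG/CHG/CHH) from the reference, or None if underivable.

    On "+" the cytosine is seq[pos]; on "-" it is the complement of a G at
    seq[pos] and the context reads leftward.  Positions too close to the
    sequence edge, or with N in the context window, return None.
    """
    n = len(seq)
    if strand == "+":
        if pos < 0 or pos >= n or seq[pos] != "C":
            return None
        b1 = seq[pos + 1] if pos + 1 < n else None
        b2 = seq[pos + 2] if pos + 2 < n else None
        if b1 == "G":
            return "CG"
        if b1 is None or b1 == "N":
            return None
        if b2 == "G":
            return "CHG"
        if b2 is None or b2 == "N":
            return None
        return "CHH"
    else:
        if pos < 0 or pos >= n or seq[pos] != "G":
            return None
        b1 = seq[pos - 1] if pos - 1 >= 0 else None
        b2 = seq[pos - 2] if pos - 2 >= 0 else None
        if b1 == "C":
            return "CG"
        if b1 is None or b1 == "N":
            return None
        if b2 == "C":
            return "CHG"
        if b2 is None or b2 == "N":
            return None
        return "CHH"


def read_cx_report(path: str | os.PathLike, genome: Genome) -> list[CytosineCall]:
    """Read a Bismark CX-style report, validating contexts against the genome.

    Columns: seq_id, 1-based position, strand, meth count, unmeth count,
    context, trinucleotide.  Zero-coverage rows are retained; coverage
    filters are applied downstream.  A context that contradicts the
    reference is an error naming the position.
    """
    calls: list[CytosineCall] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected >=6 columns")
            seq_id, pos1, strand, meth, unmeth, context = parts[:6]
            pos = int(pos1) - 1
            if seq_id not in genome:
                raise ValueError(f"{path}:{ln}: unknown sequence {seq_id!r}")
            expected = derive_context(genome[seq_id], pos, strand)
            if expected is not None and expected != context:
                raise ValueError(
                    f"{path}:{ln}: context {context} at {seq_id}:{pos1}({strand}) "
                    f"contradicts reference-derived {expected}"
                )
            calls.append(
                CytosineCall(seq_id, pos, strand, context, int(meth), int(unmeth))
            )
    return calls


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def write_cx_report(calls: list[CytosineCall], genome: Genome,
                    path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c in calls:
            seq = genome[c.seq_id]
            if c.strand == "+":
                tri = seq[c.pos:c.pos + 3].ljust(3, "N")
            else:
                tri = seq[max(0, c.pos - 2):c.pos + 1][::-1].translate(
                    _COMPLEMENT
                ).ljust(3, "N")
            fh.write(
                f"{c.seq_id}\t{c.pos + 1}\t{c.strand}\t{c.meth_count}\t"
                f"{c.unmeth_count}\t{c.context}\t{tri}\n"
            )


# ---------------------------------------------------------------------------
# repeat hit tables
# ---------------------------------------------------------------------------

def read_repeat_hits(path: str | os.PathLike) -> list[RepeatHit]:
    """Read repeat-library hits; dialect auto-detected.

    Two dialects are accepted: the classic RepeatMasker ``.out`` layout
    (3-line header, whitespace-delimited, percent divergence) and a
    headerless TSV with columns seq_id, start (1-based), end, strand,
    consensus_id, consensus_start (1-based), consensus_end, identity
    (fraction).
    """
    with open(path) as fh:
        first = fh.readline()
    if first.split()[:2] in (["SW", "perc"], ["score", "div"]) or \
            first.lstrip().startswith("SW"):
        return _read_rm_out(path)
    return _read_hits_tsv(path)


def _read_hits_tsv(path) -> list[RepeatHit]:
    hits = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            hits.append(
                RepeatHit(
                    interval=GenomicInterval(f[0], int(f[1]) - 1, int(f[2]), f[3]),
                    consensus_id=f[4],
                    consensus_start=int(f[5]) - 1,
                    consensus_end=int(f[6]),
                    identity=float(f[7]),
                )
            )
    return hits


def _read_rm_out(path) -> list[RepeatHit]:
    hits = []
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[3:]:  # classic 3-line header
        f = line.split()
        if not f:
            continue
        divergence = float(f[1])
        seq_id, qbeg, qend = f[4], int(f[5]), int(f[6])
        orient, name = f[8], f[9]
        if orient == "+":
            strand, rbeg, rend = "+", int(f[11]), int(f[12])
        else:  # 'C' lines carry (left) in col 11, begin/end swapped
            strand = "-"
            rend = int(f[12])
            rbeg = int(f[13])
        hits.append(
            RepeatHit(
                interval=GenomicInterval(seq_id, qbeg - 1, qend, strand),
                consensus_id=name,
                consensus_start=min(rbeg, rend) - 1,
                consensus_end=max(rbeg, rend),
                identity=(100.0 - divergence) / 100.0,
            )
        )
    return hits


def write_repeat_hits(hits: list[RepeatHit], path: str | os.PathLike) -> None:
    """Write hits in the headerless TSV dialect."""
    with open(path, "w") as fh:
        for h in hits:
            iv = h.interval
            fh.write(
                f"{iv.seq_id}\t{iv.start + 1}\t{iv.end}\t{iv.strand}\t"
                f"{h.consensus_id}\t{h.consensus_start + 1}\t{h.consensus_end}\t"
                f"{h.identity:.4f}\n"
            )


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature x sample count table (TSV, first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dups}")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return df


def write_counts(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# element GFF3 (intact LTR-RT annotations)
# ---------------------------------------------------------------------------

def write_elements_gff3(elements, path: str | os.PathLike) -> None:
    """Write intact elements as GFF3: one LTR_retrotransposon parent with
    two long_terminal_repeat children and, when a TSD was found, two
    target_site_duplication children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in elements:
            iv = el.element_interval
            attrs = [f"ID={el.element_id}"]
            attrs.append(f"superfamily={el.superfamily}")
            if el.lineage:
                attrs.append(f"lineage={el.lineage}")
            attrs.append(f"ltr_identity={el.ltr_identity:.4f}")
            attrs.append(f"motif={'TGCA' if el.terminal_motif_ok else 'none'}")
            if el.lineage_conflict:
                attrs.append("lineage_conflict=1")
            if el.tsd:
                attrs.append(f"tsd={el.tsd}")
            fh.write(
                f"{iv.seq_id}\tltrkit\tLTR_retrotransposon\t{iv.start + 1}\t"
                f"{iv.end}\t.\t.\t.\t{';'.join(attrs)}\n"
            )
            for tag, child in (("ltr5", el.ltr5), ("ltr3", el.ltr3)):
                if child.start < iv.start or child.end > iv.end:
                    raise ValueError(
                        f"child {tag} outside parent for {el.element_id}"
                    )
                fh.write(
                    f"{iv.seq_id}\tltrkit\tlong_terminal_repeat\t"
                    f"{child.start + 1}\t{child.end}\t.\t.\t.\t"
                    f"ID={el.element_id}.{tag};Parent={el.element_id}\n"
                )
            if el.tsd:
                k = len(el.tsd)
                for tag, s, e in (
                    ("tsd5", iv.start - k, iv.start),
                    ("tsd3", iv.end, iv.end + k),
                ):
                    fh.write(
                        f"{iv.seq_id}\tltrkit\ttarget_site_duplication\t"
                        f"{s + 1}\t{e}\t.\t.\t.\t"
                        f"ID={el.element_id}.{tag};Parent={el.element_id}\n"
                    )


def read_elements_gff3(path: str | os.PathLike):
    """Read back elements written by :func:`write_elements_gff3`."""
    from .ltr_detect import IntactLTRRT  # local import: avoid cycle

    parents: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            seq_id, _, ftype, start1, end1, _, _, _, attr_s = \
                line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in attr_s.split(";") if kv)
            start, end = int(start1) - 1, int(end1)
            if ftype == "LTR_retrotransposon":
                eid = attrs["ID"]
                parents[eid] = {
                    "seq_id": seq_id, "start": start, "end": end,
                    "attrs": attrs, "ltrs": [],
                }
                order.append(eid)
            elif ftype == "long_terminal_repeat":
                parents[attrs["Parent"]]["ltrs"].append((start, end))
            elif ftype == "target_site_duplication":
                pass  # redundant with the tsd attribute
    elements = []
    for eid in order:
        p = parents[eid]
        ltrs = sorted(p["ltrs"])
        if len(ltrs) != 2:
            raise ValueError(f"element {eid} has {len(ltrs)} LTR children")
        (l5s, l5e), (l3s, l3e) = ltrs
        a = p["attrs"]
        elements.append(
            IntactLTRRT(
                element_id=eid,
                element_interval=GenomicInterval(p["seq_id"], p["start"], p["end"]),
                ltr5=GenomicInterval(p["seq_id"], l5s, l5e),
                ltr3=GenomicInterval(p["seq_id"], l3s, l3e),
                internal=GenomicInterval(p["seq_id"], l5e, l3s),
                tsd=a.get("tsd"),
                terminal_motif_ok=a.get("motif") == "TGCA",
                ltr_identity=float(a.get("ltr_identity", "1")),
                superfamily=a.get("superfamily", "Unknown"),
                lineage=a.get("lineage"),
                lineage_conflict=a.get("lineage_conflict") == "1",
            )
        )
    return elements


def write_elements_bed(elements, path: str | os.PathLike) -> None:
    """Optional BED6 export of element spans."""
    with open(path, "w") as fh:
        for el in elements:
            iv = el.element_interval
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{el.element_id}\t"
                f"{int(round(el.ltr_identity * 1000))}\t.\n"
            )
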
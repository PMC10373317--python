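# Methods

## Coordinate conventions

All in-memory coordinates are 0-based, half-open; GFF3 and CX reports are
1-based on disk and converted exactly once, inside the readers/writers.
Gene models are reduced to one canonical transcript each — the longest
mRNA, ties resolved to the first in file — and introns are the gaps
between sorted exons. Zero-coverage cytosines are retained on read;
coverage filtering happens only at the methylation-level computation, so
the filter is a single configurable point (`ProfileParams.min_coverage`,
default 4 reads).

## Structural detection

An intact LTR retrotransposon is called from sequence alone, in four
stages:

1. **Seeding.** Exact 20-mer matches on the forward strand (both LTRs of
   one element lie on the same strand) are grouped by diagonal
   (3′-start − 5′-start), keeping diagonals between 300 bp
   (min LTR 100 + min internal 200) and 22,000 bp (max LTR 7,000 + max
   internal 15,000). Seeds occurring more than 100 times are skipped as
   low-complexity.
2. **Chaining.** Seeds on one diagonal are merged into chains whenever
   consecutive seeds lie within 50 bp.
3. **Extension.** Each chain is extended outward by an ungapped X-drop
   scan (match +1, mismatch −2, drop-off 12; score ties prefer the
   farther endpoint so neutral stretches inside the repeat do not
   truncate the block). Blocks must be 100–7,000 bp with an internal
   distance of 200–15,000 bp, and the two copies must reach ≥ 90 %
   identity under a global alignment (match +1, mismatch −1, gap open −4,
   gap extend −1; identity = matches / alignment columns, gaps included).
4. **Micro-structure validation.** Boundary offsets (dl, dr) within
   ±20 bp of the extension estimate are scanned nearest-first for a
   placement where both LTRs start `TG`, both end `CA`, and an identical
   4–6 bp target-site duplication (TSD; longest first, exact match)
   flanks the element. Strict mode (default) requires motif **and** TSD;
   lenient mode accepts TSD alone. Elements without room for a flank are
   rejected as `edge`.

The ±20 bp adjustment window exists because X-drop endpoints carry a few
bp of slop on divergent copies (mismatch clusters at the repeat boundary
shift the score maximum); when motif + TSD are found the reported
boundaries come from the micro-structure, not the extension, and are
exact. Overlapping candidates are resolved greedily by descending
identity, then length; accepted elements mask their span
(`--allow-nested` disables masking). Reported identity is rounded to
10⁻⁴, which is also the precision the GFF3 round-trip preserves.

Superfamily follows the canonical Pol domain orders — *Copia*
GAG-PR-INT-RT-RH, *Gypsy* GAG-PR-RT-RH-INT. The observed order of
whichever core domains (INT, RT, RH) are present is checked against both
canonical orders; exactly one consistent order decides, otherwise
`Unknown` (this generalises cleanly to partial domain sets: INT before RT
is Copia-only evidence, RT before RH is consistent with both). Lineage is
the majority label over the element's domain hits; a winner illegal for
the assigned superfamily (e.g. Athila under Copia) sets a conflict flag
rather than being silently dropped.

## Insertion-time estimation

The two LTRs are globally aligned with the same scoring as the detector,
so identity and divergence are mutually consistent. Columns containing a
gap or N are excluded; the raw mismatch fraction p is corrected for
multiple hits with Jukes–Cantor, K = −(3/4) ln(1 − 4p/3), and
T = K/(2r)/10⁶ MY with r = 1.3 × 10⁻⁸ site⁻¹ yr⁻¹ by default (overridable
— a single rate across taxa is itself an approximation). JC69 was chosen
because it is invertible (clean oracles), standard for LTR dating, and
differs from raw p by < 0.7 percentage points at K ≤ 0.10;
`correction="none"` / `--no-correction` reproduces raw-p behaviour.
Alignments with p ≥ 0.75 are flagged `saturated` (K undefined) and those
with fewer than 50 gap-free columns `short_alignment`. Age summaries
report mean, median, 0.1-MY histograms and the fraction of elements
≤ 0.5 MY old.

## Solo LTRs

A repeat-library hit is a solo LTR when: identity > 0.80 (strict
inequality); it covers ≥ 80 % of its LTR consensus ("exactly covered"
cannot literally mean 100 % on real hits, so coverage is a configurable
fraction); it lies more than 100 bp (configurable margin) from any intact
element or annotated internal region; and an identical flank pair of
length 6, then 5, then 4 is anchored exactly at the hit boundaries. A
`--tsd-slack` option (default 0) allows the TSD to sit a few bp off the
boundary. Hits failing these rules are returned with a reason
(`low_identity`, `low_coverage`, `near_internal`, `edge`, `no_tsd`), which
also serves as the truncated/other bucket. The procedure is per-hit and
order-independent. S/I ratios are flagged undefined at zero intact
elements; Pearson correlations use the exact t(n−2) two-sided p.

## Gene association and expression

Promoter = 5 kb upstream of the TSS, downstream = 5 kb past the TTS, both
strand-aware and never extending into the same gene's body; exons come
from the canonical transcript and introns from its gaps. An element
overlapping ≥ 1 bp of a region is associated; one category per
(gene, element) pair with precedence exon > intron > promoter >
downstream, on the grounds that inside-gene evidence outranks flanking
evidence. TPM is per-kilobase rate rescaled to 10⁶ per sample; replicate
TPMs are averaged, log2(TPM+1) transformed, and each category's genes are
compared against the entire gene set (group included) with a Welch
t-test; direction is the sign of the mean difference at p < 0.05. No
multiple-testing correction is applied across the four categories.

## Activity and methylation

CPM is count / library size × 10⁶ over the full count table (the library
includes genes, matching read-counting over a whole alignment). An
element is active when its mean CPM across replicates strictly exceeds 1;
the threshold is the standard expressed/not-expressed rule, the
mean-of-replicates aggregation is this package's choice. Active and
silent groups are contrasted on length and age with Welch t-tests.

Metaprofiles use the weighted methylation level Σmeth/Σ(meth+unmeth) —
robust to coverage heterogeneity, unlike mean-of-site-fractions — over
20 × 100 bp upstream bins, 20 proportionally scaled body bins and
20 × 100 bp downstream bins (half-open; a position belongs to exactly one
bin, verified by a conservation test). Cytosines below the coverage floor
are excluded; bins with no covered cytosine are reported missing (NaN),
never 0. Both strands pool into the position's context; profiles are
unstranded because elements carry strand ".". Strata are
(context × lineage × activity); overlapping elements contribute
independently. The same binning is applied to gene bodies for the
gene-vs-LTR contrast, and flank TE density is the fraction of the pooled
±2 kb flanks covered by ≥ 1 repeat annotation, per lineage.

## The synthetic-data generator

The generator emulates the *inputs* of the analysis, not reads: features
are planted into an i.i.d. uniform background and every downstream file
is emitted directly (repeat hits, domain hits, counts, cytosine calls).
Defaults: 2 Mb genome; 50 intact elements (LTRs 800–1,500 bp, internal
2–8 kb, ages uniform 0.1–3.0 MY), 30 TSD-bearing solos, 10 TSD-less
solos, 10 truncated fragments (30–60 % of consensus), 30 genes with 2–4
exons; features ≥ 500 bp apart and ≥ 5 kb from sequence ends.

Key modelling choices:

* **Divergence.** Each LTR copy receives independent per-site
  substitutions with probability d/2, d = 2rT for the planted age, with
  no back-mutation bookkeeping — so the age estimator is validated in the
  regime K ≤ 0.10 where the discrepancy is second-order (the exact
  expected pairwise mismatch is 2q(1−q) + (2/3)q², q = d/2, about
  d − 0.58 d²). The terminal TG/CA dinucleotides are exempt from
  mutation, standing in for the selective constraint that keeps termini
  functional; without it a planted "intact" element could fail its own
  defining motif.
* **TSDs** are drawn uniformly from {A,C,G,T}ᵏ, k uniform on 4–6, and
  duplicated exactly (no decay model). After planting, flanking
  background bases are adjusted so no *longer* accidental duplication
  exists (and none at all for the TSD-less class), keeping detected TSDs
  byte-identical to truth.
* **Domains** are fixed 30-bp sentinel motifs per domain name, placed in
  the superfamily's canonical order and emitted as a domain-hit table
  with genomic coordinates and a lineage label — classification is
  testable without any profile-HMM machinery.
* **Each planted feature gets its own consensus family**, so
  inter-element seed matches cannot masquerade as LTR pairs; solo
  detection receives the per-family consensus FASTA.
* **Counts.** Library size is exactly 10⁶ per replicate (a filler gene
  absorbs the remainder), so CPM equals the raw count: active elements
  get counts ≥ 2 in every replicate, silent ones 0–1, putting truth
  strictly on the correct side of the CPM > 1 rule.
* **Methylation.** Per-cytosine coverage is Poisson (mean 20) and
  methylated counts binomial around class means — silent bodies
  mCG/mCHG/mCHH = 0.85/0.70/0.10, active 0.45/0.30/0.06, background 0.05.
  These are free simulation parameters whose direction (silent > active
  in all contexts) mirrors the biology being modelled; they are not
  measurements. Cytosine calls are emitted within planted features
  ± 2.2 kb rather than genome-wide: the reader accepts any positional
  subset and the omitted background adds nothing to recovery tests while
  dominating file size.

What the generator does **not** model — and what passing tests therefore
do not show about real data: indel evolution and alignment ambiguity,
nested-insertion stratigraphy, TSD decay, GC/composition bias and
repetitive background, read-level noise (counts and cytosine calls are
feature/site-level), and mappability artefacts. Recovery being exact here
demonstrates the rules are implemented correctly, not that real genomes
yield clean calls.

## Numerical and degenerate-input policy

Determinism: one `numpy` Generator seeded from the config drives every
draw; outputs are written in sorted order, so identical seeds give
byte-identical bundles (tested). Degenerate cases are errors, not
silence: zero library sizes, all-zero TPM samples, genes without exons,
empty gene sets, groups too small to test, negative divergence. Bodies
shorter than the bin count fall back to nearest-bin assignment. Features
at sequence edges lose only their absent flank bins (methylation) or are
rejected with reason `edge` (detection, solo calling).

## Problem sizes

The bundled checks run on a 2-Mb genome with 50 planted elements
(detection, classification, activity, methylation), 200 standalone LTR
pairs (dating), and a 1.2-Mb genome with 30 + 10 solos and 20 intact
elements (solo rule); the whole verification suite completes in about a
minute on one CPU. Larger genomes scale linearly in sequence length for
seeding and in candidate count for validation.
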
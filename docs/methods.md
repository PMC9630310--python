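# Methods

This note records the models implemented in crisprkit, the conventions and
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the known limitations. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and nuclease conventions

All arithmetic is 0-based, half-open on the plus strand; 1-based inclusive
coordinates appear only in exported GFF3 and VCF text. The representative
coordinate of a target site is the first nucleotide of the PAM read 5'→3'
on the strand carrying the protospacer: for a 3'-PAM nuclease on the plus
strand this is the PAM interval start; on the minus strand it is the
highest plus-strand position of the PAM interval. PAM-free use (Cas13
family without a PFS constraint) is treated as a zero-length 3' PAM, so the
representative coordinate is the base immediately 3' of the protospacer and
every downstream formula is unchanged.

A nuclease is a declarative record: target type (DNA/RNA), PAM side, a list
of IUPAC PAM patterns with tolerance weights in [0, 1] (at least one
pattern has weight 1 and defines the canonical PAM), spacer length, and a
cut offset. Shipped defaults (`src/crisprkit/data/*.json`) are editable
configuration, not code: SpCas9 (NGG weight 1, NAG weight 0.26, 20-nt
spacer, cut offset −4), AsCas12a (TTTV, 5' PAM, 23-nt spacer, offset +21),
CasRx (RNA-targeting, PFS-free, 23-nt spacer, no defined cut site).

**Cut sites.** A blunt cut is a boundary between two bases; the reported
cut site is the base on the lower-coordinate side of that boundary. With
`cut_offset = o` this is `pam + o` on the plus strand and `pam − o − 1` on
the minus strand, which places the cut at the homologous protospacer
position on either strand (SpCas9: between protospacer positions 17 and 18).
An undefined offset (catalytically dead applications) yields an explicit
"no cut site" marker, and annotations then fall back to the representative
coordinate.

Mismatch positions are always indexed 1..L from the PAM-distal end of the
protospacer — the indexing convention of the published mismatch-weight
tables — so for 5'-PAM nucleases position 1 is the 3'-most protospacer base.

## Spacer discovery

`find_spacers` reports one guide for every position where a PAM pattern
with weight above a configurable floor matches and the full protospacer
fits inside the sequence (no partial guides at sequence ends). DNA
nucleases are scanned on both strands by scanning the reverse complement
and mirroring coordinates; RNA nucleases scan the given (transcript) strand
only, and their spacer is the reverse complement of the protospacer.
The contract is exhaustiveness: the test suite checks set equality against
an independent sliding-window scan for 3'-PAM, 5'-PAM and PAM-free
nucleases.

Sequence features are computed on the spacer alone (GC fraction, TTTT
transcription-termination signal, maximum homopolymer run) except
restriction-site scanning, which includes user-supplied cloning-vector
flanks on both strands. The hairpin flag uses a deliberate placeholder
rule — two disjoint substrings of length ≥ 5 (configurable) that are
reverse complements — because no thermodynamic criterion is part of the
model; it is monotone under appending a prefix's reverse complement, which
the suite asserts. Optical-pooled-screening collisions report guide pairs
whose first `cycles` bases (default 12) differ in fewer than `min_hamming`
(default 2) positions; both defaults are configurable since the constraint,
not the numbers, is the specified part.

## Off-target search

`find_alignments` enumerates every subject window within a Hamming bound of
any spacer (no DNA/RNA bulges), subject to a PAM mode: `canonical_only`
(weight-1 patterns), `any_pam` (weight > 0), or `ignore_pam` (PAM-agnostic).
The engine is a pigeonhole seed-and-verify scan: a window with ≤ m
mismatches must contain one of m+1 equal partitions of the query verbatim,
so exact partition occurrences nominate candidates which are verified
base-by-base with early exit. Correctness is defined as set equality with a
naive all-windows Hamming oracle (an independent numpy implementation in
the test suite), asserted over twenty seeded 50-guide × 100-kb fixtures in
all PAM modes, together with strand closure under reverse complement.

The iterative variant aligns at 0 mismatches first and escalates the
allowance one level at a time, continuing only for guides whose cumulative
hit count has not exceeded a threshold (default 100, configurable — the
strategy, not the number, is the specified part). Escalation counts are
cumulative across levels. Guides that never hit the threshold get hit sets
identical to the exhaustive search; stopped guides record the level and
carry explicit "not computed" markers for the levels above it, so a guide
landing in a repeat element cannot silently masquerade as clean.

Hit context labels evaluate the highest-priority genic feature at the cut
site: CDS > 5'/3' UTR > non-coding exon > intron > intergenic, using
interval trees over the gene model.

## Scoring

* CFD: product of w_p(x_RNA, x_DNA) over mismatched positions; an optional
  PAM factor multiplies in when the weight table carries PAM weights (the
  bare formula omits it). A missing table entry is a configuration error
  naming the (position, RNA base, DNA base) triple — never a silent 1.
* MIT: (∏ c_p) · 1/(((L−d)/L)·4+1) · 1/m², with L = 19 by default and d the
  mean pairwise distance between mismatch positions. Conventions for the
  degenerate cases: m = 0 returns 1.0; at m = 1 the distance term is
  undefined and the distance factor is set to 1 (equivalently d = L).
* Specificity: 1/(1 + ΣC_i) over every putative off-target except the
  primary on-target; additional perfect-complementarity loci enter with
  C = 1 (forced by the anchor value 0.5 for a guide with two on-targets).
* Composite on-target score: per method, guides rank ascending so the best
  raw score takes the largest rank, ties average; each method's ranks are
  rescaled so its maximum equals the global maximum rank before averaging,
  keeping methods with missing values comparable. Larger composite = better
  guide; machine-learned scoring models themselves are out of scope, so the
  score columns are user-supplied.
* Frameshift proportion: probability mass of an indel-length distribution
  on lengths not divisible by 3 (2/3 under a uniform distribution — the
  chance level). The trained indel-spectrum predictor is out of scope; only
  the proportion semantics are implemented.

## CFD-CasRx weight estimation

Position-wise mismatch tolerance weights for an RNA-targeting nuclease are
estimated from a single-mismatch (SM) tiling screen: compute ΔLFC = LFC_SM −
LFC_PM against each guide's perfect-match parent, fit a LOESS curve of ΔLFC
against spacer position, evaluate it at each position, and convert to
relative activity against the PM median LFC, clamped to [0, 1]:

    weight(p) = clamp((median_PM + fit(p)) / median_PM, 0, 1).

The sign convention is that of an enrichment (FACS) screen: positive LFC
means activity. The LOESS span defaults to 0.25 with the standard
robustness iterations; a local-linear smoother has a small downward-curvature
bias where the weight profile bottoms out, which is the dominant residual in
the parameter-recovery tests. Predicted LFC of a mismatched guide is the
parent PM LFC times the product of the weights at its mismatched positions.

## Base-editing model

A base editor is a nuclease plus a window of per-position editing
probabilities q(p, nuc_u, nuc_e) indexed on the editing strand
(protospacer or opposite). Rows must sum to 1 over outcomes including
identity; editors supplied with off-diagonal weights only are completed by
assigning the residual to identity, because the allele likelihood is a
product of per-position outcome probabilities and needs a full
distribution. Only positions with an off-diagonal outcome for the observed
wildtype base branch the enumeration; alleles below `min_score` (default
1e-4) are dropped after the product is formed, so the untruncated
enumeration always sums to 1 (asserted over random editor matrices).

Consequences map window positions into the spliced CDS of a gene-model
transcript (canonical by default): each changed codon is classified and the
allele takes the most consequential label, nonsense > missense > silent;
edits entirely outside the CDS are "none". Splice-site disruption and
indel outcomes are not modelled. Per-guide mutation-type scores sum the
member-allele likelihoods, so silent + missense + nonsense + none-mass = 1
on an untruncated enumeration.

The shipped BE4max definition carries the editor's window geometry with
synthetic placeholder C→T probabilities (peak at protospacer position 6);
the numbers are meant to be replaced by experimentally derived weights and
are marked as such in the file.

## Annotation

* Gene annotation: a transcript is targeted when the protospacer interval
  overlaps its exons; `pct_cds` is 100 · (spliced-CDS index of the cut + 1)
  / CDS length on the gene's canonical transcript (and per targeted
  transcript); `isoform_fraction` is targeted isoforms over all isoforms of
  the gene. For transcriptome-designed RNA-targeting guides, an isoform
  counts as targeted when its sequence contains the protospacer verbatim.
* The downstream in-frame ATG flag is a minimal, configurable
  translation-reinitiation heuristic (any in-frame ATG at least
  `atg_min_offset` codons 3' of the cut codon in the same CDS, default 0);
  it stands in for published reinitiation rules that are referenced but not
  restated in the model this package implements.
* TSS annotation: strand-aware signed distance from the cut to the nearest
  TSS (negative = upstream); the activation window default is 75–150 nt
  upstream. No silent default is applied for interference-style windows —
  the window is explicit configuration.
* SNP annotation flags any variant whose reference span intersects the
  protospacer-plus-PAM interval.
* Conservation is the arithmetic mean of a per-base track over an 18-nt
  window centred on the cut site ([cut − 9, cut + 9)); missing bases are
  excluded from the mean, not imputed as zero, and a fully missing window
  yields NaN.
* Allele injection replaces SNV positions with the major or minor allele
  judged by the alternate-allele frequency (AF > 0.5 means ALT is major;
  ties keep REF in major mode and inject ALT in minor mode). Indels are
  excluded with a warning; a REF base disagreeing with the genome is a hard
  error naming the record. Output length always equals input length.

All annotation steps are additive: pre-existing guide fields are never
modified.

## Ranking

Rounds for Cas9-class nucleases: (1) unique target — exactly one
0-mismatch alignment — and no 1–2-mismatch off-targets cutting in coding
regions; (2) fewer than 5 one-or-two-mismatch off-targets (all such
off-targets counted, not only coding ones); (3) remainder; (4) overrides
applied after binning — common-SNP overlap, TTTT stretch, or GC outside
[20%, 80%] — so an otherwise perfect guide with a polyT lands in round 4.
Within a round, guides are tiered by cut-within-first-85%-of-canonical-CDS,
then conservation > 0, then ordered by the composite on-target rank over
user-supplied score columns, falling back to the specificity score and
finally the guide id, which makes the order a deterministic total order
(asserted stable under input permutation). The CasRx-class ranking replaces
rounds 1–2 by isoform coverage ≥ 75% / ≥ 50% with a clean 1–2-mismatch
off-target profile, and orders within rounds by a supplied on-target score.

## Synthetic data generators

The generators exist so every pipeline stage can be exercised against known
truth with no downloads; all are seeded and byte-reproducible.

* Genomes: i.i.d. bases at configurable GC (default 0.41, human-like), with
  guide target sites planted at recorded non-overlapping loci — for each
  guide one copy per requested mismatch count (default one each at 0–3),
  with a concrete canonical PAM, on a random strand for DNA nucleases. The
  truth table closes the loop: the search must recover exactly the planted
  rows.
* Gene models: evenly spaced genes with nested isoforms sharing an exon
  grid (isoform 0 canonical and longest), CDS trimmed to a multiple of 3,
  alternating strands; emitted as GTF with a `canonical` tag.
* Variants: uniform-random SNVs at a density per kb with AF ~ U(0.01, 0.99).
* Conservation: piecewise-constant segments with Normal(0, 1) levels,
  mimicking a signed base-wise conservation score.
* Screens: PM guides draw LFC ~ Normal(2.0, 0.2) truncated positive; each
  SM guide takes a random PM parent and position and draws
  LFC = w(p)·LFC_PM + Normal(0, 0.05); DM guides multiply two weights. The
  default truth profile w(p) = 0.35 + 0.55·cos²(π(p−1)/(L−1)) is smooth
  with mid-spacer mismatches costing the most activity. Parent
  heterogeneity enters the ΔLFC differences scaled by (w − 1) and does not
  cancel, so the default spreads are chosen to keep the position-level
  standard error of the recovered weight near a third of the 0.05 recovery
  tolerance — the small-noise regime the estimator is designed for.

What the fixtures do not emulate: real base composition beyond GC content,
repeat families beyond exact planted repeats, chromatin context, sequencing
error, guide-specific efficacy covariates. Passing tests therefore
demonstrate correctness of the arithmetic and search contracts, not
predictive performance on real screens.

Problem sizes in the default test run — twenty 50-guide × 100-kb search
fixtures, 500-guide SM screens, 100 random editor matrices — were chosen so
the whole suite completes in well under a minute of search time while still
exercising every code path at non-trivial scale.

## Numerical and degenerate-input choices

* Probability rows and indel distributions validate to 1 within 1e-9.
* Composite ranks break ties by average rank; ranking order ties break by
  guide id.
* An all-missing score column is dropped with a warning; all columns
  missing is an error.
* `max_mismatches` greater than the spacer length, RNA nucleases asked for
  a double-strand search, non-positive OPS cycles, and editing windows
  outside the supplied context are usage errors, not silent clamps.
* Sequences shorter than protospacer + PAM yield empty results, not errors.
* Guides whose protospacer contains an ambiguity code are not emitted.

## Limitations

* Hamming-distance off-targets only; no bulge alignment, no external
  aligner wrappers, no BAM/CRAM subjects.
* No machine-learned on-target or off-target models; the corresponding
  table columns are user-supplied inputs.
* The hairpin rule and the reinitiation (downstream ATG) rule are
  documented placeholders, configurable but deliberately simple.
* Published CFD/MIT weight constants are not bundled; the formulas are
  validated against synthetic tables and users supply published tables as
  TSV/JSON resources.
* Remote annotation services, genome-browser visualisation and lift-over
  are out of scope.
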
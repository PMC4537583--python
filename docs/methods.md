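# Methods

## The TS score

The Time-course Switch score compares two non-negative expression profiles
(FPKM per stage) by stacking them as the rows of X ∈ ℝ^(2×T) and computing

TS = 2 · (1 − s₁ / (s₁ + s₂)),

where s₁ ≥ s₂ ≥ 0 are the singular values of X.  The geometry: s₁ captures
the dominant shared direction of the two profiles, s₂ the residual.  If the
minor profile is any scalar multiple of the primary, X has rank 1, s₂ = 0 and
TS = 0; TS = 1 requires orthogonal profiles of equal Euclidean norm.  Since
s₁ ≥ s₂ always, TS ∈ [0, 1].  The score is symmetric in its rows, invariant
to a common positive rescaling, non-decreasing in the angle between profiles
at fixed norms, and non-decreasing in the norm ratio at a fixed angle —
i.e. it rewards *both* shape divergence and magnitude balance, which is what
distinguishes a plausible functional switch from low-level noise that a
shape-only measure (1 − Pearson) would top-rank.

Profiles enter the SVD as raw FPKM vectors.  No log transform or per-row
normalisation is applied by default because magnitude sensitivity is the
score's purpose; a `log1p` option exists for heavy-tailed data.  A pair in
which both profiles are entirely zero has no defined score and raises an
error rather than returning 0 — such pairs indicate a missing upstream
expression filter.  Numerically the score uses LAPACK's SVD; the test oracle
instead takes square roots of the closed-form eigenvalues of the 2×2 Gram
matrix XXᵀ.  The two routes agree to ~1e−14 on generic profile pairs; the
closed form loses relative accuracy as s₂ → 0 (cancellation in the 2×2
determinant), so the degenerate near-rank-1 regime is compared at 1e−8
absolute rather than 1e−10.

## Isoform designation

A gene enters the analysis as a *multi-protein gene* if, after discarding
transcripts never expressed strictly above 1 FPKM in any stage, at least two
distinct protein sequences remain.  Mean expression is the unweighted
arithmetic mean over all stages of the retained transcript's full vector;
stages are an ordered categorical axis with no interpolation.  The primary
isoform is the transcript with the highest mean, the secondary is the
highest-mean transcript with a different protein, minors are all transcripts
with a different protein.  Protein identity is exact string equality of the
supplied protein sequences (or keys) — no alignment-based fuzziness.  Ties
in mean expression are broken lexicographically by transcript id, making
designation deterministic and order-invariant.  A gene's reported TS score
is the primary–secondary pair's; all primary–minor pairs can be scored on
request.  The High-TS call is strict (TS > 0.5).

## Splice-event classification

Coordinates are GTF-style: 1-based, inclusive, kept so internally (this is
stated explicitly to avoid half-open drift at interval arithmetic).  For a
primary/minor pair on the same gene, seqname and strand:

- **exon gain** — a minor exon sharing ≥ 1 base with no primary exon;
- **intron retention** — a minor exon whose interval contains a primary
  intron (intron between consecutive exons (a₁,a₂),(b₁,b₂) is (a₂+1,b₁−1));
  one read-through exon spanning several introns yields one event per
  covered intron.

Containment is pure: the retained-intron test does not additionally require
the minor exon to extend beyond both flanking primary exons.  Exon *loss* is
the same computation with the roles swapped (`--symmetric`).  Conservation
flags: an event matches a Conservation Index record by exact coordinates
first, else by maximal overlap (annotation versions shift exon bounds);
`conserved` is true iff CI ≥ cutoff (default 5, the valley between the two
modes of the CI distribution), and stays unset — not false — when no record
matches, keeping "not conserved" distinct from "not measured".  The cutoff
comparison is inclusive and configurable.

## Resnik GO semantic similarity

IC(t) = −ln(n_t / N) with n_t the number of genes annotated to t or any
descendant (true-path propagation) and N the number of genes with ≥ 1
annotation in the namespace — IC is a probability within the annotated
corpus, not the genome.  Resnik similarity of two terms is the maximum IC
over their common ancestors; gene-pair GOSS is the maximum over the genes'
term pairs, computed equivalently (and faster) as the maximum IC over the
intersection of the genes' propagated ancestor sets.  Natural log is the
default base, making the pipeline cutoffs interpretable (GOSS > 6 ⇔ shared
ancestor covering < e⁻⁶ ≈ 0.25 % of the corpus; 2.5 ⇔ < 8.2 %); the base is
configurable, and the cutoffs are configuration rather than constants since
absolute IC depends on the annotation snapshot.  Only `is_a` edges are
traversed by default (`part_of` optional).  NOT-qualified and ND-evidence
annotations are removed on load.  Cross-namespace term comparison is an
error; gene GOSS is computed per namespace, and the TAPAS pipeline uses the
biological-process branch only, where co-expression is most likely to
reflect shared annotation.

## TAPAS

Per query isoform: (1) members are all transcripts of *other* genes with
Pearson r strictly > 0.7 against the query profile (raw FPKM, consistent
with the TS decision; constant profiles are skipped); (2) a functional link
is recorded to each member gene with an experimental PPI edge, STRING
score > 800 (strict), or gene-pair GOSS > 6 (strict) to the query gene —
any link resolves the cluster `linked`; (3) otherwise the k = 20
most-similar members whose genes carry BP annotations are taken (each
foreign gene counted once at its best-correlated isoform), and the
arithmetic mean of gene-gene GOSS over all unordered pairs of those member
genes — the query's own gene never among them — decides `goss_pass`
(mean ≥ 2.5, boundary inclusive) versus `discarded`.  Fewer than two
annotated member genes cannot form a pair and discard with reason
"insufficient annotation".  Reported network edges run query ↔ member
(the network characterises the query); member–member links are not emitted.
Raising the similarity threshold can only shrink clusters and raising the
mean cutoff can only demote verdicts, so both filters are monotone.

Validation compares, per cluster, the mean GOSS between member genes and
the query's parent gene across three groups: clusters kept (`linked` or
`goss_pass`), discarded clusters, and seeded random-membership controls of
matched sizes drawn from the annotated corpus; the summary reports group
medians and a one-sided Mann–Whitney p-value for kept > random.

## Statistics

Fisher's exact test is the one-sided hypergeometric tail in the enrichment
direction; empty-margin tables return p = 1 with a warning.  The one-sided
Mann–Whitney test uses exact tie-aware enumeration when min(n,m) ≤ 8 and
n+m ≤ 20 — so small-sample results are checkable against brute force — and
the tie-corrected normal approximation with continuity correction above
that.  With ties, the exact tail at the distribution's centre includes the
atom P(U = centre), so two identical small samples score slightly above 0.5
(the all-values-identical boundary returns exactly 0.5 with a warning).
BH correction is the standard step-up.  GO enrichment tests one-sided
over-representation per term after propagation, skipping terms with fewer
than 10 background annotations, with BH over tested terms.

The permutation null shuffles per-gene TS scores while event annotations
stay fixed; the empirical p is (r+1)/(n_perm+1), never zero, and the test
direction is configurable per event kind (enrichment for exon gain, deficit
for intron retention).  Bias-control matching pairs each case gene with the
unused control gene at minimum Euclidean distance between gene-level
profiles (per-stage sum of all isoform FPKMs — the standard aggregation);
cases are processed in descending total expression with lexicographic ties,
each control used at most once, so the pairing is injective and each step
greedy-optimal.  Stratified re-tests restrict the 2×2 universe by label
flags (singleton-only, domain-class exclusion, age classes); external gene
properties (essentiality, domains, motifs, ages) are consumed as label
tables, not regenerated.

## Synthetic data

The expression simulator emulates staged developmental RNA-seq: 30 ordered
stages (twelve 2-h embryonic windows, larval, white-prepupa, pupal, adult),
Gaussian-bump primary profiles (amplitude 30–100 FPKM, width 1.5–3 stages),
and one minor isoform per gene from three archetypes: **switch** (bump in
the opposite half of the series, 0.6–1.0× the primary's amplitude — a
planted high-TS case), **replica** (0.2–0.8× scalar copy — TS exactly 0
before noise) and **noise** (flat 1.1–1.8 FPKM, just above the expression
filter — low TS because of the magnitude imbalance).  Defaults: 100 genes,
20 % switch / 40 % replica / 40 % noise.  Noise is multiplicative
log-normal (default σ = 0.3), preserving non-negativity with
magnitude-proportional spread as in real FPKM estimates.  What this does
*not* emulate: stage-autocorrelated library effects, isoform-assignment
ambiguity from shared exons, annotation errors, or multimodal profiles — so
passing tests demonstrate correctness of the scoring machinery under the
planted model, not detection performance on real quantification output.

The gene-model simulator plants exactly one event per non-decoy minor (an
exon strictly inside a primary intron, or two exons merged across one
intron) and boundary-shift decoys (≤ 10 bp extension into an intron) that
must yield no event; constructions guarantee no accidental second event, so
precision and recall against truth are exactly 1.  The GO simulator builds
per-module root→mid→deep chains with module genes annotated at the deep
term (pairwise GOSS = −ln(module size / corpus), known in closed form) and
decoy/filler genes at the root (GOSS 0); the corpus is padded with filler
genes so deep-term IC (≈ 3.2 at the default 7-gene terms in a 166-gene
corpus) sits clearly above the 2.5 fallback cutoff.  The end-to-end TAPAS
scenario spaces module bumps so the maximum cross-module profile correlation
(~0.37) stays far below the 0.7 clustering threshold, alternates modules
with and without interaction edges (exercising both the `linked` and the
fallback `goss_pass` routes), gives query genes a broad primary with a dip
over the module window (so the primary never joins any cluster), and plants
decoy queries tracking root-only-annotated genes that must be discarded.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible.
The shipped verification uses 1000 random profile pairs for the TS oracle,
500 random gene models for the event classifier, 100 random DAGs (≤ 50
terms, ≤ 100 genes) for the Resnik oracle, the 5-module TAPAS scenario, 200
replicate seeds × 99 permutations for the permutation-null uniformity (KS)
check, and 100-gene expression simulations for detection power — sizes at
which the exhaustive oracles are exact and the whole suite runs in seconds.

## Known limitations

- The two-row TS score is defined only for isoform pairs; no multi-isoform
  generalisation is attempted.
- Event classification knows gains, losses and intron retention; alternative
  transcription initiation/termination and splice-site shifts are out of
  scope, as is read alignment/quantification upstream of the FPKM matrix.
- GOSS cutoffs (6, 2.5) are calibrated to a corpus's annotation density and
  should be revisited for corpora far from ~10⁴ annotated genes.
- The Mann–Whitney asymptotic path is a normal approximation; exact p-values
  are only guaranteed in the small-sample regime stated above.
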
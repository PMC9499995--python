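# Methods

## Panel design

The spike-in panel is the full factorial grid of fragment length
(80, 160, 320 bp), G+C content (35, 50, 65%) and CpG fraction (1 CpG
per 80, 40, 20 bp) — 27 combinations, each realised as a methylated
and an unmethylated fragment. CpG fractions were chosen so the CpG
count is an integer at every length (80 bp fragments carry 1/2/4 CpGs,
160 bp 2/4/8, 320 bp 4/8/16). The 320 bp / 65% G+C combinations fold
too readily for synthesis; they are replaced in the final design by
second alternates of (35%, 1/80), (50%, 1/40) and (50%, 1/20), keeping
18 sequences in the 320 bp class. Two 160 bp / 35% / 1-in-20 fragments
failed synthesis and are carried in the grid with `synthesis_ok=False`,
so both the 54- and the 52-fragment views are reproducible.

Sequences are sampled from a first-order Markov chain whose transition
matrix is tuned to the target base composition, with the C→G
transition pinned so the expected CpG-per-bp rate matches the spec;
rejection sampling then enforces the *exact* G+C base count and exact
CpG dinucleotide count. Exactness is a deliberate tightening — it
makes every generated sequence re-measurable against its
specification, at the cost of a few hundred rejected draws per
fragment (budget 100,000 attempts; infeasible specs, e.g. more CpGs
than available G+C bases, fail fast with the violated constraint).
Candidates are screened two ways:

* **Hairpin screen.** A dynamic program finds the longest perfect
  inverted-repeat stem (reverse-complement self-match with a loop of
  ≥ 3 unpaired nt); candidates with a stem of ≥ 10 bp are rejected.
  This replaces thermodynamic folding with an oracle-verifiable
  structural proxy: long perfect stems are the dominant
  synthesis-blocking structure.
* **Genome-uniqueness screen.** A candidate fails if it shares any
  25-mer with a user-supplied reference (both strands); 25 matching
  bases approximates an alignment bit score of 50. The screen is
  pluggable so an aligner-based screen can be substituted.

Molecular mass is computed from base composition for both strands
(average dNMP residue masses, −61.96 g/mol end correction per strand).
Equimolar pool amounts support two schemes: `global` (every fragment
the same molar amount) and `per-length-pool` (total mass split equally
across the three length pools, fragments equimolar within a pool —
the panel's documented pooling). How total mass splits across pools
is not specified anywhere; equal mass per pool was chosen and is the
only free choice in the scheme. 1 ng of a fragment of mass M g/mol is
1e3/M pmol; a 0.01 ng pool puts individual fragments at roughly
0.4–4 × 10⁻⁶ pmol.

## Counting

Aligned paired-end records (SAM/BAM via pysam) against a composite
reference (spike-in contigs + genome) are filtered pairwise: a pair is
dropped when either mate is unmapped, has mapping quality < 20, or
mean base quality < 40 (thresholds configurable; "mean base quality"
is our reading of a per-read Phred cutoff). Survivors become fragments
spanning the outer mate coordinates. PCR duplicates are collapsed by
exact (contig, start, end, UMI) identity — no error-tolerant UMI
clustering; with 5 nt of UMI per read (10 nt per fragment) exact
collapse loses little. Coordinates are 0-based half-open internally.

Genomic signal is summarised on a 300 bp half-open tiling; a trailing
partial window is kept and flagged. Window annotations (G+C, CpG
fraction, minimum overlapping mappability) are computed from the
reference sequence and a bedGraph track; windows without a mappability
record score 0. Because the tiling is regular, window overlap is
computed arithmetically (`pos // 300`) rather than with a generic
interval engine.

## Quantification

The 5-term model is fit by least squares (numpy `lstsq`) with an
explicit rank check — a rank-deficient design (e.g. six spike-ins
sharing one length) raises instead of being silently pseudo-inverted.
At least 6 training spike-ins are required (one more than the number
of terms). By default only methylated spike-ins train the model:
unmethylated fragment counts reflect non-specific binding, not the
amount→count response; a flag includes them. An optional per-length
weight vector supports emphasising 160 bp fragments. The cube-root
transform of CpG fraction is applied symmetrically at fit and predict
time.

Two prediction modes exist:

* **Fragment mode** (default in `quantify_sample`): genomic fragments
  with identical coordinates form a group; x_reads is the group size
  and x_len/x_GC/x_CpGfraction come from the reference sequence under
  the fragment. Each group's η is distributed to windows as
  η′ = (ℓ/ℓ*)·η. This follows the per-fragment formulation literally
  and recovers simulated per-window truth at r > 0.99 at the default
  depth.
* **Window mode** (`quantify_window_counts`): x_reads is the window's
  total deduplicated count, x_len the window size, and the window's
  own annotations are the covariates. Because depth enters only
  through β_reads·x_reads — and β_reads shrinks as spike-in counts
  grow — this mode cancels per-batch efficiency and is the one used
  for batch-effect assessment.

The identity link can produce negative η; raw and zero-clamped values
are both emitted.

## Filtering

Windows are removed for: overlap (≥ 1 bp) with simple repeats,
overlap with a blacklist, minimum mappability ≤ 0.5 (inclusive), and
between-replicate standard deviation of molar amount ≥ 0.05 pmol
(inclusive). The surviving set is order-independent; the per-criterion
attribution applies the criteria in the order repeats → blacklist →
mappability → SD, each counting only windows not already removed.
Replicate SD uses the sample (n−1) denominator — with two replicates,
|a−b|/√2 — configurable via `ddof` since the convention is not
universal.

## QC

Methylation specificity is Σ methylated counts / Σ all spike-in
counts on deduplicated fragments; its complement estimates
non-specific binding. Alternative-fragment consistency compares the
two same-property 320 bp alternates: the within-alternative range is
[min, max] over all individual replicate counts of both alternates;
the between-alternatives value is the absolute difference of the two
alternates' replicate means (the signless reading of "range between
the means"). Between-alternatives can never exceed the
within-alternative width, since means lie inside the envelope.

## Validation

**Held-out accuracy.** For each training size 6–25, 100 random subsets
of the (by default methylated, n = 26) spike-ins train the model and
the held-out spike-ins are predicted; the mean absolute error against
known amounts is recorded. Draws use independent seeded substreams
(`SeedSequence([seed, size, iteration])`) so any cell is reproducible
in isolation; rank-deficient draws are redrawn within the iteration's
stream. With noiseless amounts the MAE is identically zero (the model
class contains the truth).

**Batch assessment.** The samples × windows matrix is centered
(no scaling) and decomposed by SVD; zero-variance windows are dropped
with a log line. For each principal component and each categorical
variable, a one-way ANOVA of PC scores by variable level gives F
(no second factor is specified per test, so the per-test design is
one-way). F converts to Cohen's d as d = √(F(n₁+n₂)/(n₁n₂)) for two
levels; for k > 2 levels η² = F·df₁/(F·df₁+df₂), f = √(η²/(1−η²)),
d = 2f. All (PC, variable) p-values of one assessment form a single
Holm-Bonferroni family. The Holm step-down is implemented directly
(sorted p·(m−i), monotone enforcement, cap at 1) and cross-checked
against statsmodels in the tests.

## Simulator

The simulator defines the study conditions used by the tests:

* **Spike-in counts.** Expected methylated count ∝ known amount ×
  length weight × exp(gc_slope·GC + cpg_slope·∛CpGfraction), scaled so
  the methylated total equals the configured depth (default 100,000
  deduplicated fragments). Length weights default to
  {80: 0.6, 160: 1.0, 320: 0.4}, favouring 160 bp as size selection
  does. Unmethylated fragments get a flat expectation — non-specific
  rate (default 0.03) × mean methylated expectation — independent of
  properties, so default specificity is ≈ 1/1.03 ≈ 0.97. Realised
  counts multiply the expectation by mean-one lognormal noise
  (CV default 0.10; Poisson optional) and round. The log-linear bias
  is a test harness — recoverable by the linear model only
  approximately — not a claim about immunoprecipitation chemistry.
* **Known amounts.** The nominal pool is equimolar per length pool at
  0.01 ng; a fixed, seed-derived lognormal jitter (CV 0.15) emulates
  per-fragment concentration measurement of one physical pool, shared
  by every sample of a study. This within-class amount variation is
  what identifies β_reads; an exactly equimolar pool (`amount_cv=0`)
  is used where the experiment calls for it.
* **Genomic samples.** A toy genome (default 2 chromosomes × 25
  windows of 300 bp) carries a latent per-window methylated amount: a
  lognormal field whose log is smoothed over adjacent windows
  (methylation is regionally correlated), with ~10% fully
  unmethylated windows. Fragments are drawn per window proportional
  to its amount (Poisson), with cfDNA-like lengths
  (normal(166, 30) clipped to [80, 320]) placed within the window, so
  the per-window truth is exactly what the pipeline should recover.
  Each fragment carries a 10 nt UMI (5 nt per read); PCR duplicates
  spawn as D ~ Geometric(mean = r) extra copies sharing coordinates
  and UMI, so dedup removes an expected r/(1+r) of records (⅓ at
  r = 0.5). Records can be written as paired-end SAM against the
  composite reference to exercise the real readers.
* **Batch studies.** 3 labs × 5 patients by default; each patient's
  window truth is shared across labs, each lab applies a multiplicative
  efficiency (defaults 1.0/2.0/0.5) to both spike-in and genomic depth
  and carries filler/adapter labels. Because the spike-ins scale with
  the lab's efficiency, window-mode quantification cancels it; the
  batch-associated Cohen's d of molar amounts is strictly smaller than
  that of raw counts in the bundled assessments.

What the simulator does **not** emulate: fragment-end motifs and
nucleosome positioning, chromosome-scale methylation domains, mapping
ambiguity and alignment error, UMI sequencing errors, adapter/filler
chemistry. Passing tests therefore demonstrate the pipeline's
statistical machinery under its stated assumptions, not performance on
real plasma data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 52 spike-ins,
toy genomes of 30–50 windows, depths of 5,000–100,000 fragments,
15-sample batch studies — sizes chosen so the full suite completes in
about a minute while every code path (including SAM round-trips) is
exercised. Coefficient recovery on noiseless data is asserted to
1e-8; mass conservation to 1e-9 relative; Holm and overlap
distribution against brute-force oracles to 1e-12 relative. Ties in
the hairpin DP resolve to the longest usable stem; degenerate inputs
(constant matrices, single-level variables, zero spike-in totals)
raise or return missing-with-warning rather than guessing.

## Known limitations

* Exact-match UMI collapse slightly overcounts molecules under
  sequencing error and undercounts at extreme depth (UMI saturation).
* The Gaussian identity-link model can predict negative amounts;
  both raw and clamped values are reported, and the choice of which to
  analyse is the user's.
* Fragment-mode quantification tracks relative window amounts well but
  inherits the intercept's scale; window mode is preferred when
  cross-batch comparability matters.
* The per-test ANOVA is one-way; variables correlated with each other
  (e.g. filler and adapter following lab) are assessed marginally.
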
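# Methods

This note documents the models, parameter choices and known limitations of
`txpred`.  It is written for users who need to judge what the package's
results do and do not demonstrate.

## Transcript representation and validation

A gene is a `TranscriptRecord` of three segments (5'UTR, ORF, 3'UTR) over
the DNA alphabet (U is mapped to T on input, sequences uppercased).  Strict
validation requires a non-empty ORF whose length is divisible by 3, that
starts with ATG and ends with TAA/TAG/TGA; permissive mode downgrades
violations to warnings and truncates a trailing partial codon.  Empty UTRs
are legal — segment features on empty segments take documented defaults so
the feature count never varies across genes.  All coordinates are 0-based
half-open internally; 1-based only in files (the PARS TSV).

PPR and RL are always derived, never read: PPR = PA/mRNA and RL = RD×mRNA
(`rl_definition="total_ribosomes"` switches to RD×mRNA×ORF-codon-count).
Both are monotone proxies for protein output per message and total
ribosome engagement; keeping the definitions single-sourced and switchable
makes the assumption auditable.

## Feature catalogue

Features are named `<scope>.<family>.<detail>` and carry the segment scope
that drives segment-restricted predictors (the TRANSCRIPT scope admits all
features).  The catalogue size (~4,321 in scheme A) is a *property* of the
configured families — dominated by the 3,721 codon pairs and 400
amino-acid pairs — not a hard-coded constant.

Conventions that matter:

- ATG counting is an overlapping step-1 scan.
- A uORF is an ATG in the 5'UTR with an in-frame stop still inside the
  5'UTR (a config flag allows the stop inside the ORF instead).  A sORF is
  an alternative ATG at ORF offset > 0 in frame +1/+2 with an in-frame stop
  within the ORF; in-frame (F0) alternative ATGs are counted as such.
- "Distance" features default to segment length + 1 when no ATG exists — a
  sentinel larger than any real distance (recorded as −1 in the catalogue
  TSV, since the actual default is per-gene).
- Start-context scores use a window of 6 nt upstream + 3 nt downstream of
  the ATG (Kozak-like; the ATG itself is excluded).  Positions outside the
  transcript contribute 0.  Scores are log-odds against the pooled
  background of the PSSM training windows, pseudocount 1.
- Frequency families (codons, amino acids, both pair families) are each
  normalized to sum to 1 over the gene's sense codons; internal stops are
  counted and logged but excluded from sense usage.

## Adaptation indices and the two inference schemes

tAI weights follow the standard parameterization: W_c = Σ over decoding
anticodons of (1 − s) × gene copies, with the Watson–Crick cognate plus one
wobble alternative per codon third base and s = 0.41 (G:U), 0.28 (I:C),
0.9999 (I:A), 0.68 (U:G); weights are max-normalized and zero weights are
imputed with the geometric mean of the non-zero ones so logs stay defined.
The bundled copy-number table is a representative budding-yeast-like
complement intended for synthetic studies; supply a measured table for real
data.  The gene index (tAI and CAI alike) is the geometric mean of weights
over the ORF's sense codons, so it is order-invariant and bounded in (0,1].

**Scheme A (expression-free).**  All parameters derive from the transcripts
alone: tAI from tRNA copy numbers; the CAI reference set and the
context-PSSM training set are the top 10% of genes ranked by tAI, a
transcript-only proxy for high expression (ties break by gene id; at least
10 genes are always taken).  Scheme-A constructors have no parameter that
could carry expression data — the separation is structural, and tested.

**Scheme B (mRNA-optimized).**  Inside each jackknife replicate, using the
train tercile only: codon weights are re-estimated by deterministic
coordinate ascent on the 61 log-weights maximizing the Spearman correlation
between gene index and train mRNA (steps 0.4/0.2/0.1/0.05 coarse-to-fine,
because a rank objective is piecewise constant and small steps alone stall
on plateaus; fixed codon order; stop when a full sweep accepts nothing, cap
200 sweeps — seedless and reproducible); the CAI reference and the context
PSSM are rebuilt from the top train-tercile mRNA genes.  The TASEP feature
is kept scheme-A-only: re-simulating every gene per replicate would cost
orders of magnitude more than every other scheme-B recomputation combined,
for a feature whose scheme-B variant is already largely captured by the
re-optimized tAI it would be built from.  A leakage guard raises if any
held-out gene id reaches the optimizer.

## Folding engine

The default engine maximizes total weighted base pairing (GC = 3, AU = 2,
GU = 1, minimum hairpin loop 3) by a Nussinov-style dynamic program; the
score is the negated pair weight so more structure reads as more negative,
matching the folding-energy sign convention.  Pair counts come from one
optimal traceback.  The engine is exact: tests compare it against
exhaustive enumeration of all nested structures for every sequence up to
12 nt.  A thermodynamic minimum-free-energy provider can be plugged in
behind the same `(seq) -> (score, n_basepairs)` signature; the regression
layer is agnostic to the backend.  Default windows: last 40 nt of the
5'UTR, first/last 90 nt of the ORF, first 40 nt of the 3'UTR (score, pair
count, score per nt), and 40-nt sliding windows at step 10 over the first
300 nt of the ORF (score only).  Windows are clipped to segment bounds;
empty windows emit defaults.  PARS features (mean, max, mean expPARS with
expPARS_i = exp(PARS_i), exponentiated per nucleotide before averaging) use
the same boundary windows; records without a profile emit defaults (0, 0,
1) so the catalogue stays rectangular.

## TASEP simulator

Ribosomes are particles of footprint ℓ codons (default 9) on the ORF codon
lattice.  Initiation at rate α (default 0.1) requires the first ℓ sites
free; a ribosome at site i advances at the site's hop rate when site i+ℓ is
free (or beyond the lattice); termination from the last site at rate β
(default 10).  Hop rates are the codon adaptation weights rescaled to mean
1, so α ≈ 0.1 puts the system in the initiation-limited regime while slow
codon clusters near the start can still queue ribosomes back onto the
initiation region.  The simulation is a continuous-time Gillespie process
(numba kernel); the current J is terminations per unit time after burn-in,
with a batch-means standard error (20 batches).  Fewer than 100
terminations flags the estimate low-confidence.  Default horizons are 10⁵
burn-in + 10⁶ sampled events; feature extraction and tests use the "fast"
profile (10⁴ + 6×10⁴ events, ≈10 ms per 500-codon gene), whose Monte-Carlo
noise is part of the feature's documented behavior.  Per-gene seeds are
CRC32(gene_id) XOR the run seed, so results are reproducible without
global-ordering effects.  For lattices of ≤ 10 sites with ℓ = 1 an exact
solver builds the full 2ⁿ-state generator and solves the stationary linear
system; it is the oracle for the Monte-Carlo estimator (and is itself
checked against the closed-form single-site current αβ/(α+β) and an
independent symbolic solve of the two-site chain).

## Regression

Tercile splits are balanced to within one gene (remainder to train, then
test), sampled independently per replicate from a seeded generator.
Features are z-scored on train statistics; train-constant columns are
excluded from candidacy in that replicate.  Greedy selection scores each
candidate by the training correlation of the refit model and stops when the
test correlation fails to improve by ε = 0 (any non-improvement stops; the
cap is 30 features, further capped at train-size − 2).  Ties break toward
the earlier catalogue position.  For the linear model the per-step argmax
is computed by projecting candidates and residual onto the orthogonal
complement of the selected set — mathematically identical to refitting
every candidate, and asserted equal to the naive loop in tests; MARS uses
the literal refit loop.  A variant selecting by test-set correlation exists
behind `select_on="test"` for sensitivity analysis.  Targets are
log-transformed before any correlation (expression spans decades);
Spearman scoring is available by config.  OLS uses the minimum-norm
solution on singular designs with a logged warning.  MARS: forward pass
adds mirrored hinge pairs at observed-value knots (up to 32 quantiles per
variable), interaction degree ≤ 2; backward pass prunes by GCV with
C(M) = M + 3(M−1)/2.

The family's median predictor is the member with the median validation
correlation (lower median for even family sizes, so it is always an actual
member); prevalence is the count of replicates selecting each feature.
Everything downstream of (data, config, seed) is deterministic — the grid
summary TSV is byte-identical across repeat runs.

## Synthetic data generator

The generator emulates: log-normal segment lengths (means 82.33 / 1490.8 /
133.62 nt, log-sd 0.45); per-gene GC content uniform in [0.30, 0.50];
per-gene codon bias of uniform-random strength (temperature 0–2) toward the
tAI weights plus a GC tilt, which produces a realistic spread of tAI/CAI
and TASEP currents; uORFs injected into 35% of sufficiently long leaders
(with `uorf_prob=0`, leader ATGs are scrubbed so uORF counts are zero by
construction); and an optional synthetic PARS profile — smoothed noise on
top of the predicted pairing of 40-nt chunks, labelled synthetic because it
mimics only the local correlation of measured structure scores, not their
experimental error model.

Expression is planted: latent = Σ coefficient × z-scored feature over the
planted model; log mRNA / log PA / log RD = (1.0 / 1.3 / 0.7) × latent +
independent per-gene Gaussian noise calibrated so corr(latent, log
target)² equals the configured R² (default 0.5).  Noise is keyed by gene id
so permuting input order permutes rows only.  PPR and RL are derived by the
same code path as real data; consequently RL inherits the signal twice
(validation correlations ≈ 0.8) while PPR keeps only the 0.3 × latent scale
difference (r ≈ 0.2), which is below what greedy selection can separate
from 4,300 competing candidates at n = 1000 — PPR families scoring near
zero on synthetic data is expected behavior, not a defect.

The default planted model spans three segments and five families
(first-ATG distance in the 5'UTR, leucine usage, a mid-ORF folding window,
3'UTR folding pair count, TASEP current), chosen after inspecting the
generator's feature correlation structure so that no planted feature has a
catalogue proxy above |r| ≈ 0.8; coefficients (1.0–1.2) weight features
with stronger proxies up so each feature's residual signal is comparable.
This matters because the strict test-improvement stopping rule only admits
features with detectable *unique* signal.  An ORF-only planted variant
supports segment-contrast studies.

What passing synthetic tests does **not** show: the generator has no
phylogenetic structure, no correlated measurement error across targets, no
amino-acid-level selection, and UTR composition is independent of the ORF
— real transcriptomes violate all four, so recovered prevalences and
correlations on real data will be lower and more confounded than the
planted-recovery results here.

## Problem sizes and runtime choices

Recovery studies use the standard 1000-gene profile with 20-replicate
families; unit fixtures use 50 genes; the scheme-separation sign test uses
240 genes × 20 tercile replicates with the optimizer capped at 30 sweeps;
the segment-contrast study uses 400 genes × 10 replicates.  These sizes
give comfortably converged statistics for every quantity reported while
keeping a full verification run in the minutes range on one CPU; all are
plain config values that scale up freely.

## Known limitations

- The base-pairing engine maximizes pair weight, not free energy; absolute
  scores are not kcal/mol (the sign convention matches, by design).
- tAI wobble handling uses the four standard pairing classes only; no
  species-specific curation (e.g. the shared Ile/Met CAT anticodon).
- The TASEP feature at fast horizons carries Monte-Carlo noise of a few
  percent relative; increase the horizons for production feature tables.
- Scheme-B optimization is a local hill climb on a rank objective;
  different step ladders can reach different local optima (deterministic
  given config).
- The greedy + tercile-stopping procedure controls overfitting but is not
  a consistency-guaranteed selector; prevalence ranks are descriptive.
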
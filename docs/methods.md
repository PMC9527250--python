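# Methods

This note documents the models, parameter choices and numerical
conventions behind `sedadna`, and what the synthetic-data tests do and
do not demonstrate about real sediment-core data.

## Damage model

Ancient DNA accumulates cytosine deamination at fragment termini. For a
double-stranded library this is read as C→T substitutions at the 5′ end
and the complementary G→A at the 3′ end. The generator flips each C at
5′ position *i* with probability `d5 · r^i` (0-based) and each G at
position *j* from the 3′ end with the same law; a `single_stranded`
flag switches to C→T at both ends. An optional background channel flips
every base to one of the other three with probability ε. Defaults:
`r = 0.5` (the per-position geometric decay of the terminal signal),
ε = 0 in the generator's damage model (sequencing error is applied
separately, at 10⁻³ per base, to every read including contaminants),
and a damage amplitude that ramps linearly with sample age from
`d5 = 0.03` at the surface to `0.33` at 400 ka, matching the span of
damage proportions a down-core marine record shows (a few percent near
the mudline to roughly a third in the deepest samples).

The authentication side mirrors the generator without sharing code with
it. Substitution spectra `f5[i]` count C→T mismatches among alignment
columns with reference C at 5′ position *i* (analogously `f3` for G→A
from the 3′ end), over the first/last 20 positions; read positions
aligned to a reference gap are excluded from the denominators. The
decay fit solves least squares for `f5[i] ≈ d·r^i + ε` under the box
constraints d ∈ [0,1], r ∈ (0,1), ε ≥ 0 (SciPy trust-region reflective,
tolerances 10⁻¹⁴ so noiseless spectra invert to ~10⁻⁷). An all-zero
spectrum returns `d = 0` with the decay ratio flagged undefined rather
than an arbitrary r.

A single read is called **ancient** when its best surviving hit carries
at least one C→T mismatch within the first `k_terminal = 5` read
positions or one G→A within the last 5 — the de-facto read-level
criterion of the HOPS/MaltExtract tool family, whose exact rule the
original toolchain does not restate; the window is configurable. Reads
failing the stringent gate (identity < 0.95 or gap fraction > 0.1) are
**rejected** and excluded from damage-proportion denominators; everything
else is **default**. Per-(sample, taxon) proportions under 50 retained
reads are flagged low-confidence but still reported, down to
single-read groups. With ε = 0 the classifier's sensitivity has the
closed form `1 − Π (1 − d5·r^pos)` over the terminal C (5′) and G (3′)
positions of the source fragment; the test suite checks this, and
extends it exactly for ε > 0 (a damaged base leaves the T state with
probability ε; an undamaged one enters it with ε/3).

## Alignment and assignment

Semiglobal alignment: the read aligns end-to-end against a local window
of the reference (no read clipping), scored +1 match / −1 mismatch / −2
per gap column (linear). The dynamic program is exact and unbanded (a
numba kernel); seeding only selects *which* references are aligned —
every reference sharing ≥ 1 exact 12-mer with the read on either strand
— so whenever the true source shares an intact seed the seeded best
score equals an exhaustive search. Reads ≥ 25 bp with at most one
substitution per 13 bp window always retain a seed (pigeonhole). Ties
in the traceback prefer diagonal moves, then read-gaps, then
reference-gaps, and the leftmost maximal end column, making output
deterministic. Only the forward strand is indexed; queries are searched
as-is and reverse-complemented and the better strand kept, which halves
the index at the cost of one extra query pass.

Mismatch coordinates are reported 0-based from the read's 5′ end in
read orientation; minus-strand hits have both bases complemented before
recording, so template-strand deamination surfaces with the expected
polarity regardless of orientation. Percent identity is
matches/columns over all alignment columns including gaps (a
gap-excluding variant is available).

Hit filtering keeps alignments with identity ≥ 0.95 inside a score
window of 10% below the best hit. The 10% window is the long-standing
default of the naive-LCA tool family; the identity threshold follows
standard marker-gene practice for this workflow. Assignment drops hits
whose taxon is a strict ancestor of another hit's taxon (the
more-specific-match rule) and places the read on the LCA of the rest.
`min_support_percent` (percent units, default 0 = off) re-assigns taxa
whose per-sample share of assigned reads falls below the threshold one
level up, in a single pass against the raw shares — no cascade; with
the default 0 the profile equals the raw assignment counts.

Rank projection maps each profile column to its ancestor at the
requested rank; taxa assigned above that rank (or on lineages that skip
it) are kept in an explicit "not further classified" bucket under their
deepest ancestor above the rank, so projection conserves per-sample
totals exactly.

## Control subtraction

Two modes, both auditable via the subtraction report: `remove_taxon`
(default) zeroes every taxon seen with ≥ 1 read in any in-scope
control — the conservative reading of subtracting control-identified
species — and `subtract_counts` reduces each sample by the
per-taxon *maximum* across in-scope controls, floored at zero (the
maximum, rather than the sum, avoids over-penalising taxa measured in
several controls). Scope is per-site by default, since controls are
collected per site. `remove_taxon` is idempotent; `subtract_counts` is
deliberately not (applying it twice subtracts twice), which is why the
pipeline applies subtraction exactly once and records it in the report.

## Tracer QC

Blank correction subtracts the run's mean blank from every measurement,
floored at zero (concentrations are physical); a state flag prevents
accidental double correction. The detection limit is 3 × SD of the
blanks — **sample** SD (n−1), a documented, configurable convention —
with a fallback to 3 × SD of the lowest standard's replicates when the
blanks are all identical (typically all zero). Standard nominal
concentrations are multiplied by the 0.88 measurable-stereoisomer
fraction before the calibration line is fitted. Values below the limit
are rejected (reported below-limit); surviving periphery / centre
values set the per-sample flags, and centre detections carry an
explicit caution note. The generator treats sub-floor material as
reading exactly zero on the instrument — only genuinely tracer-bearing
measurements carry noise — which is what makes clean/periphery/centre
verdicts exactly recoverable whenever injected separations exceed a few
blank SDs.

## Statistics

Marker-gene (SSU/LSU) profiles are analysed as relative abundances
without rarefaction, to keep every read available for damage analysis;
rarefaction (exact multivariate-hypergeometric subsampling without
replacement, deterministic per seed) is provided for single-copy-gene
style analyses, with the depth chosen as the smallest marker-bearing
library. The 1%-mean-abundance rule for pooling rare taxa uses the
unweighted mean of per-sample fractions, with ≥ kept at the boundary.
Correlations are Pearson on raw values (Spearman by flag for skewed
covariates), pairwise-complete, skipping pairs with < 3 complete
observations or constant columns; mudline and eukaryote-free samples
are dropped before correlation. Recovery of a configured correlation
target ρ is judged against the Fisher-z 95% interval
`tanh(atanh ρ ± 1.96/√(n−3))`.

## Synthetic cores: what they do and do not show

The generator's defaults are the study conditions the package is tested
under: 12 down-core samples (0.5–392 ka) plus mudline and air /
extraction-blank / drill-fluid controls, 5000 reads per sample in the
headline scenario, a diatom fraction stepping from 0.08 to 0.50 at
14.5 ka, fungal contaminants at 5% of sample libraries and 100% of
control libraries (always undamaged — modern fungi are a routine
component of sediment records), lognormal fragment lengths with mode
56 bp and a hard 20 bp floor, and random 400 bp marker references per
taxon for SSU and LSU (one taxon is LSU-only, so a merged database
demonstrably detects more than either marker alone). Geochemical
covariates (ammonium, alkalinity, phosphate, sulfate, temperature,
silicon, δ¹⁸O, pH, salinity) are generated by a Gaussian copula against
the per-sample damage amplitude with targets matching the correlations
such records report (0.56, 0.52, 0.44, −0.42, 0.31, 0.26, 0.32, 0.09,
−0.15 respectively).

Passing these tests shows the *chain* is correct — filters, aligner,
LCA, subtraction, damage estimation and statistics recover known
inputs. It does not show robustness to features the generator omits:
platform-specific error profiles, indels and fragmentation biases,
chimeric reads, conserved regions shared across real taxa (random
references make cross-taxon misalignment essentially impossible),
database incompleteness, or community structure beyond fixed mixing
proportions.

## Problem sizes and other choices

Tests and the acceptance script run at desk scale, chosen so each
property is measured with comfortable statistical room: 50 000 reads
for damage recovery (binomial 3σ ≈ 0.6%), 12 × 2000 reads for the
damage–age trend, 1000 instances for each oracle comparison, 12 × 5000
reads for the end-to-end transition scenario, 1000 seeds for
rarefaction expectations. Reference length defaults to 400 bp (a
desk-scale stand-in for marker-gene reference fragments). The
`dedupe` step is scoped per library, not across the pooled run (the
narrower, safer reading). Reads shorter than the seed length return no
hits with a warning; reads too short to hold a single complexity
window pass the complexity filter with a warning rather than being
silently destroyed.

Known limitations: no adapter trimming or paired-end merging (simulated
reads carry none), no E-value statistics or protein-space alignment, no
statistical decontamination beyond control subtraction, no Bayesian
damage models with indel terms, and the pipeline's file-based stages
assume the simulator's directory layout for their inputs.
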
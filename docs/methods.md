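# Methods

## Quantifying methylated fractions from fragment ends

DpnI cuts GATC sites methylated on both adenines, leaving blunt ends
between the A and the T; some molecules lose the terminal A or T.  For a
GATC with bases g, a, t, c (0-based, half-open coordinates; the cut falls
at coordinate g+2), the left half-site counts fragments ending at g+1 or
g+2 and divides by the protection-side coverage of the G — fragments with
`start ≤ g` and `end ≥ g+2`.  A fragment that ends *on* the G is a cut
diagnostic, not evidence of protection, so it is excluded from the
denominator; a blunt-cut left fragment (end g+2) still covers the G and
is included, which makes the ratio equal the per-molecule methylation
probability exactly when no ends are trimmed.  The right half-site
mirrors this around the C.  End trimming deflates the denominator
slightly, so pooled ratios above 1 are clipped with a warning.

Half-sites whose adjacent motif site is closer than 200 bp are discarded:
the inter-site fragment that would diagnose them is short enough to be
lost during library preparation.  The distance is measured between motif
start positions, modularly on circular sequences (mtDNA, plasmid).  The
two half-site ratios are pooled as (sum of valid numerators)/(sum of
valid denominators), weighting each strand's evidence by its coverage
rather than averaging two ratios of unequal precision.  A site with no
valid half-site, or zero pooled coverage, is dropped.

## First-order rate estimation

`ln(1 − f)` is regressed on time (natural log, ordinary least squares;
`k = −slope`).  Fractions above 0.99 carry almost no rate information:
they are capped at 0.99 and, past the first capped observation, removed
entirely rather than retained at the cap.  A site needs at least 3 usable
observations (two for slope and intercept, one more for R² to be
meaningful); otherwise it is flagged unestimable and excluded downstream.
Any t = 0 observation is included; the intercept absorbs pre-induction
background.  On noise-free exponential data the estimator is exact to
machine precision, which the tests assert directly.

Two reference modes normalize rates across strains.  The mitochondrial
reference (Dam mode default) is the median of per-site mtDNA rate
constants; a `median_trajectory` variant fits the per-timepoint median
mtDNA fraction instead, and the two agree on kinetically homogeneous
mtDNA.  The genome-median reference (CpG mode) fits the per-timepoint
median fraction over every site of every sequence, including mtDNA and
the plasmid when present.  Normalized rates are invariant under global
rate scaling.

## Decaying sine wave fit

The phasing profile is built per integer dyad-relative offset as the
plain mean of normalized rates over all contributing (gene, site) pairs;
a site inside two genes' windows contributes once per gene.  The model
`A·e^(−λx)·sin(ωx+θ) + kx + b` is fit to the **raw** per-offset means
over x ∈ [−50, 1000] (1051 points) by bounded trust-region least squares
with an analytic Jacobian.  Smoothing (21-bp centered box, edge-shrunk
symmetrically so locally linear profiles are reproduced exactly) is
applied only to the exported display profile — pre-smoothing would bias
the fitted amplitude downward.

Constraints: A ≥ 0, λ ∈ [0, 0.1] per bp, period 2π/ω ∈ [120, 220] bp
(brackets all plausible yeast nucleosome repeat lengths), θ ∈ (−π, π],
slope and baseline free.  The fit is multi-started from a fixed grid of
periods (140–200 bp, step 5) crossed with four phases (−π/2, 0, π/2, π),
with slope/baseline initialized from a linear detrend; the lowest-SSR
start wins and the grid search stops early once the residual is at
rounding level.  No randomness anywhere, so fits are bit-reproducible.
A flat profile (zero variance) short-circuits to an A = 0 solution with
a warning.

Derived descriptors: spacing = 2π/ω; decay per period = e^(−λ·spacing)
(reported as 1 when A = λ = 0); slope per kb = 1000k; adjusted mean rate
= curve mean over the 1051 integer offsets; adjusted
R² = 1 − (SSR/SST)(N−1)/(N−7) for the six model parameters, so a perfect
fit scores exactly 1.

## Per-gene rates and quintiles

Because motif sites sample the oscillating landscape unevenly, a gene's
plain mean rate is biased by where its sites happen to fall.  The bias is
estimated from the population fit: per gene, the mean of the fitted curve
at the gene's own site offsets minus the population adjusted mean; the
unbiased rate is the raw mean minus this bias, i.e. the gene's mean
deviation from the curve anchored at the population mean, which makes
quintile means directly comparable to the population descriptor.  Genes
need at least 5 sites in the window to be ranked (below that the mean
deviation is noise-dominated; exposed as a flag).  Ranked genes are
sorted ascending (ties broken by gene id, so the split is deterministic)
and divided into five groups whose sizes differ by at most one, Q1
slowest; the phasing model is then refit on each quintile's combined
profile.

## tRNA transcription-factor regions

With the TSS as +1 (1-based, gene-oriented), TFIIIB occupies −56..−13
(44 bp for every gene) and TFIIIC −2..gene end +10, excluding the intron
if present; the Pol III terminator's protection is subsumed in the +10 bp
extension.  Internally these are converted to 0-based half-open genomic
intervals (e.g. TFIIIB on a plus-strand gene with TSS t is
[t−56, t−12)); minus-strand genes are mirrored.  Class kinetics are
summarized as per-class median normalized rates and the TFIIIC/TFIIIB
and intron/TFIIIB ratios, optionally alongside first-order fits to the
class-median fraction trajectories.

The TSS-aligned rate map over intronless tRNA genes uses the TSS frame up
to offset +99 — offsets at or past a gene's own length are skipped, so
the 72–99 zone is covered only by longer-than-nominal genes and is masked
when fewer than 10 genes contribute (an SD over fewer genes is not
meaningful) — and a downstream frame from +100, anchored at each gene's
own end (+100 maps to 28 bp past the end of a nominal 72-bp gene).

## Synthetic data generator

The generator emulates the study conditions, not yeast sequence: genes
occupy fixed non-overlapping 2.6-kb slots on both strands (half minus
strand, seeded arrangement), each with a +1 dyad 60 bp downstream of its
TSS, a promoter NDR at dyad-relative −180..−80, and motif sites placed at
a jittered mean interval (256 bp for GATC, 16 bp for CG).  The slot width
guarantees that no site inside one gene's fitting window also falls in
another's, so round-trip recovery is exact by construction.  An 85.8-kb
circular mtDNA carries one uniform rate (the internal control), and a
6.3-kb plasmid can be included for CpG mode.

True rates are the control rate times a landscape factor: the decaying
sine curve at the site's offset for genic sites (window-edge value past
+1000 — the model is never extrapolated), 1.5× for NDR sites (promoter
NDRs methylate fastest, faster than mtDNA), exactly 1× for mtDNA, and
1× for all remaining background (typical chromatin methylates at the
reference rate; this also makes the genome-median reference identify the
generator's control rate exactly, mirroring the convention that the
median site defines 1).  tRNA subregions use factors 1.3/1.95/2.6
(TFIIIB : TFIIIC : intron = 1 : 1.5 : 2).  A landscape that is
non-positive anywhere on the fit window raises a configuration error
rather than being silently floored.  The default landscape is the
wild-type descriptor set (spacing 166.3 bp, amplitude 0.39, decay 0.86,
slope −0.12/kb, adjusted mean 0.80); the baseline parameter for a target
adjusted mean is solved in closed form since the model is linear in it.

Time courses are exact exponentials (default induction timepoints 30,
60, 120, 240 min; control rate 0.005/min, chosen so the slowest sites
rise measurably by 30 min while the fastest stay below the 0.99
saturation cap at 240 min) with optional binomial sampling noise at a
configurable per-site molecule coverage.  Fragment simulation models
only DpnI cuts (between A and T of methylated sites, each site
independently Bernoulli with its current fraction), one-base end
trimming at a configurable share of cut ends, and probabilistic loss of
sub-200-bp fragments; sonication breakpoints are not modelled because
the counting rule never uses them.  Circular molecules are linearized at
the origin for fragment emission.

What passing the round trips shows — and does not.  Noise-free synthetic
recovery demonstrates that the estimator chain is unbiased and
self-consistent at the study's geometry, not that real data would yield
these parameters: real genomes have overlapping and divergent genes,
sequence-dependent site spacing, coverage heterogeneity, replication and
cell-cycle effects, and mappability artifacts, none of which are
emulated.  The binomial-noise and fragment paths exercise sampling error
and the counting rule, but not alignment error.

## Problem sizes

The shipped round-trip scenarios use 2000-gene genomes (about 21,000
GATC or 340,000 CG sites), which the full pipeline processes in seconds
to tens of seconds; they are scale models of the 5398-gene analysis, and
the recovered descriptors are independent of the seed because the
kinetics are noise-free.

## Known limitations

Single-exponential kinetics only (no mixtures, no error propagation from
rate fits into the sine fit); no bootstrap uncertainty on fitted
parameters; fragment input is interval-level (no BAM parsing, duplicate
marking or mapping-quality filtering); sites shared by overlapping genes
are intentionally double-counted per gene; the per-gene deviation mean is
site-weighted, not offset-binned.
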
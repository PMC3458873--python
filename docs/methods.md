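# Methods

`clinescan` asks a single question of a multi-locus transect: can loci under
diversifying selection be told apart from loci whose geographic gradients are
a residue of demographic history?  It answers it with four connected pieces:
per-locus cline detection, a genome-wide coincidence/concordance ("Co-Co")
outlier analysis, an FST-outlier scan against a coalescent island-model null,
and a neutral secondary-contact simulation study that serves as the sceptic's
baseline.

## Data model

The universal container (`ClineDataset`) is populations x loci allele
*counts*.  Counts are canonical; published frequency tables without sample
sizes are converted assuming 40 allele copies (20 diploids) per site — the
same convention as the Hardy-Weinberg genotype synthesis — with
largest-remainder rounding so counts sum exactly to n.  Missing data are
encoded as zero sampled copies, never as NaN frequencies.  mtDNA is carried
as haploid counts in the same structure.  GenePop is read in both 2- and
3-digit dialects and always written 3-digit.

## Cline model and fitting

For each locus a single *focal allele* is modelled against latitude.  For
multi-allelic loci the focal allele maximises the binarised (allele vs rest)
Weir-Cockerham theta computed over northern (> 42 N) plus southern (< 34 N)
sites, ignoring the central region; biallelic loci tie exactly and take the
first allele (downstream results are reflection-invariant, see below).

Three nested models of frequency vs latitude:

* horizontal: p(lat) = p0 (1 parameter);
* twice-broken-stick: flat plateaus p_south / p_north outside two break
  latitudes, linear in between (4 parameters — the two break coordinates);
  midpoint = mean of the breaks, slope = delta-p over the break span;
* logistic (4-parameter sigmoid), kept only as a cross-check because its
  unsupervised optimisation fails on flat or edge-truncated data.

Two objectives are available and the choice matters:

* `binomial` (default for empirical count data): the exact binomial
  log-likelihood of the counts, with predicted frequencies clamped to
  [1e-6, 1 - 1e-6].  Correct weighting when sampling noise dominates.
* `gaussian`: the variance-profiled normal likelihood of the observed
  frequencies (equivalently least squares).  For data whose among-site
  scatter is dominated by genetic drift rather than sampling — notably the
  simulated stepping-stone demes — the binomial model mistakes that
  overdispersion itself for spatial signal (flat-but-drifting loci are
  declared clinal almost always); the least-squares criterion instead
  measures improvement relative to the total scatter and is the appropriate
  yardstick.  The simulation-study classifiers default to it.

Optimisation is multi-start: all ordered pairs of nine latitude quantiles
seed the breaks, plateau frequencies start at the data means on either side,
and the three best starts are refined by Nelder-Mead in a transformed space
enforcing break order, a window one degree beyond the sampled range (so edge
clines are representable) and frequencies in (0, 1).  Ties within 1e-8
log-likelihood resolve to the smaller |slope|.  A minimum break separation
of 0.01 degrees keeps slopes finite; fits pinned to it are flagged
"step_like".  Loci with fewer than five assayed sites or fewer than three
distinct latitudes are excluded with a logged reason.

Fitting is made *exactly* reflection-symmetric (x -> n - x flips the slope
sign and preserves log-likelihood, midpoint and |slope| bit-for-bit) by
canonically orienting the data before optimisation and mirroring the result
back; this also guarantees biallelic loci give identical screens whichever
allele is focal.

### The clinality test

A locus is clinal when the broken-stick fit beats the horizontal fit.  For
the binomial objective the statistic 2*delta-loglik is referred to
chi-square with 3 df — the nominal choice; because the two break positions
are unidentified under the null, the realised type-I error is inflated to
roughly 8-10% at alpha = 0.05 (measured on flat panels; the test suite
brackets it at [0.01, 0.12]).  For the gaussian objective we use the exact
equivalent F-test, F = (RSS_h/RSS_bs - 1)(m - 4)/3 against F(3, m - 4),
since with the residual variance estimated from m ~ 40 sites the chi-square
reference is additionally anticonservative.  Co-Co inclusion further
requires a significant one-sided Mantel test (999 seeded permutations,
alpha = 0.05) of the locus's pairwise Weir-Cockerham FST matrix against
absolute latitude difference (the transect is effectively one-dimensional;
great-circle distance is available).  Benjamini-Hochberg adjustment across
loci is exposed but off by default — the screen is nominal, as in the
original analysis.

## Co-Co plot

Clinal, Mantel-passing loci are embedded at (midpoint, log|slope|); the
natural log of |slope| undoes the right-skew of raw slopes.  A 2-D Gaussian
product-kernel density is estimated with per-axis bandwidths chosen by
least-squares cross-validation (statsmodels `KDEMultivariate`, diagonal
bandwidth matrix) with a normal-reference plug-in fallback when the CV
objective degenerates.  The grid extends four bandwidths beyond the data so
at least 99.9% of the kernel mass is on the grid.

Envelope levels at 75/95/99% follow the kernel-smoothing convention of
density quantiles *at the sample points*: the 95% level is the 5th
percentile of the estimated density over the loci, so the envelope contains
~95% of loci by construction (5% +- 3 flagged on homogeneous Gaussian
clouds).  The literal probability-mass HDR of the estimated density is also
available (`points=None`); kernel smoothing makes that variant cover ~99% of
its own sample, which is why it is not the flagging default.  Outliers are
loci below the 95% level (99% also reported) — clines significantly displaced
in location or steepness from the genomic consensus.

## FST-outlier scan

The null is a finite island model: 100 demes, 11 sampled with 40 gene copies
each, infinite-alleles mutation, migration calibrated so the mean
Weir-Cockerham theta across replicate loci equals a target (0.33, the
system-wide differentiation of the empirical transect).  The coalescent core
is an in-package event-driven structured coalescent exploiting deme
exchangeability (lineages carry only a deme label; pairs sharing a deme
coalesce at rate 1/Ne, lineages emigrate at total rate m to a uniform other
deme).  It is validated in the tests against an independent coalescent
simulator (msprime) and the island-model closed form
FST = 1/(1 + 4Nm (d/(d-1))^2).  Infinite-alleles mutation is realised
branch-wise: a branch mutates with probability 1 - exp(-mu L) and gives its
subtree a fresh allele, which reproduces the allelic partition exactly
(interior multiple hits are invisible).  Per-locus scaled mutation rates are
drawn log-uniformly (pooled theta in [0.05, 8] by default) so the null spans
the heterozygosity axis; the conditioning on He makes the envelope
insensitive to this distribution.  Monomorphic draws are rejected.

Calibration bisects log-m from the closed-form start until the pilot mean
FST (2,000 replicates by default, common random numbers) is within 0.01 of
target.  The envelope is built from 25 equal-count He bins: two-sided 95%
and 99% conditional quantiles plus the median, smoothed by a 3-bin running
median with quantile order restored afterwards.  Empirical loci are placed
in their He bin (nearest bin outside the support); `outlier_high` means FST
above the upper envelope, and the empirical p is the fraction of null pairs
in the bin with FST at or above the observed value.  Pooled-sample expected
heterozygosity is used throughout, matching the fdist convention.

## Secondary-contact simulations

The neutral baseline mimics a Pleistocene split with Holocene secondary
contact (constant total Ne = 100,000 throughout): a single ancestor splits
100,000 generations ago into two isolated relicts (Ne 50,000); 10,000
generations ago each expands instantaneously into 20 stepping-stone demes
(Ne 2,500; 40 demes in one chain, contact between demes 20 and 21) linked to
immediate neighbours at a constant scaled rate to the present.  Genealogies
come from msprime; each locus receives one segregating site placed uniformly
on the total branch length (fixed-S = 1, the SNP convention), with
monomorphic draws rejected and counted.

Migration is parameterised ms-style: `four_n_m` = 4 N0 m with N0 the single
reference size of the simulation, i.e. the total (= ancestral) Ne of
100,000 — not the per-deme Ne.  This is the natural reading of a coalescent
command line in which every rate is scaled by one N0, and it is the
parameterisation under which the neutral baseline reproduces the reported
behaviour (percent clinal ~ 36-50% rising gently with dispersal; under a
per-deme scaling the fractions are 10-25 points higher and nearly flat).

`percent_clinal` applies the broken-stick vs horizontal screen (gaussian
objective, F reference, alpha = 0.05) with the deme index as the spatial
coordinate.  The study runner reports per-condition means and SDs over
replicates, pools the clinal fits into a Co-Co cloud with slope signs
normalised (higher frequency to the left), and can push every simulated
locus through the FST-outlier test — the demonstration that neutral
secondary contact is flagged as "selection" far above the nominal rate.

## Synthetic transect generator

For pipeline testing with known truth: 10-80 sites on 30-45 degrees N (half
spread over the range, half packed within 3 degrees of 40 N, mimicking the
denser sampling around the cline), a chosen fraction of loci clinal with
logistic (default; stresses the broken-stick approximation) or stepped
shape, midpoints drawn in [38, 42], frequency differences in [0.4, 0.9],
random direction, flat loci at uniform(0.05, 0.95), binomial sampling at 40
copies per site.  What it deliberately does not emulate: drift
autocorrelation among sites, linkage between loci, ascertainment bias of
marker panels, or missing-data structure — so passing recovery tests show
correctness of the estimators under sampling noise, not robustness to every
property of real compilations (the secondary-contact simulator supplies the
drift-structured case).

## Problem sizes and numerical choices

Defaults follow the study design: island null 50,000 replicates; simulation
study 300 loci x 10 replicates per condition.  The test suite and the
acceptance script use desk-scale versions chosen to keep a full run on one
CPU comfortable: a 5,000-replicate null with a 1,500-replicate calibration
pilot, and 5 replicates x 300 loci per dispersal condition; tolerances on
stochastic checks account for these sizes (e.g. envelope stability is
checked at 5,000 vs 2,000 pairs at 0.08 FST rather than the 0.03 quoted for
50,000 vs 5,000).  Seeds thread through numpy `SeedSequence` everywhere;
identical seeds give bit-identical outputs.  Optimiser tolerances: the
clinality LRT clamps log-likelihood differences at -5e-7 (beyond which an
optimiser failure is raised); KDE grids default to 256 x 256; density mass
on the grid is within 1e-3 of 1.

## Known limitations

* The clinality screen's realised type-I error (~8-10%) exceeds the nominal
  5% because the break positions are unidentified under the null; all
  downstream percentages inherit this, as does any analysis using the same
  unsupervised screen.
* The island-model null assumes exchangeable demes; the secondary-contact
  analysis exists precisely because that assumption fails on stepped clines.
* The logistic fit is a diagnostic, not a production model; it flags rather
  than raises on failure.
* Multi-allelic loci are reduced to one focal allele; joint multi-allele
  cline surfaces are out of scope.
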
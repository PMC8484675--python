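# Methods

## Spike-in calibration model

Each sequencing library receives five synthetic standard DNAs at known
concentrations x = (100, 50, 25, 12.5, 2.5) copies/µl. The model is that
within a library, expected reads are proportional to input copies:
E[y_k] = β·x_k with a library-specific β (reads per copy/µl). We estimate
β by least squares through the origin, β̂ = Σx_k y_k / Σx_k², which is also
the maximum-likelihood slope under homoscedastic Gaussian error and an
excellent approximation to the Poisson MLE at these read depths. Fit
quality is the uncentered R² = 1 − RSS/Σy²; the centred version can go
negative for a no-intercept fit and is not used. A library whose standards
all receive zero reads is *flagged* (slope 0) and excluded from
quantification rather than raising, so one failed library never aborts a
run; a configurable R² floor (default 0.7, the weakest fit one still sees
in practice on real ladders) flags but keeps marginal libraries.

Fish OTU reads convert as copies/µl = reads/β̂, and to water concentration
as copies/ml = copies/µl × elution volume (µl) / filtered volume (ml).
Both volumes travel with each sample's metadata (defaults 100 µl and
2000 ml) rather than being hard-coded, because the effective filtered
volume is a property of the sampling, not of the algorithm. Field blanks
are calibrated but never quantified; their fish reads are expressed as a
percentage of the mean positive-sample copy yield, which is the natural
run-level contamination metric. The method deliberately does not correct
for amplification-efficiency differences *between* species — the standards
share primer-binding sites with the targets, so the calibration is
per-library, not per-taxon — and cross-species copy comparisons should be
read with that caveat.

## OTU screening

Screens run in a fixed order: (1) assignment filters — drop OTUs whose
best database hit is not a bony fish, shark or ray, has identity < 98.5 %
(an exact 98.5 % hit is kept), or aligns over ≤ 150 bp (the amplicon is
~172 bp, so genuine amplicons comfortably exceed this); (2) taxonomy
collapsing — multi-species hits within a genus become "Genus spp." unless
the regional checklist holds exactly one species of that genus, which is
then assigned at species rank; multi-genus hits fall to the shared family
when a genus→family map is supplied; (3) the noise filter — per sample,
any fish OTU with reads strictly below 0.05 % of that sample's total fish
reads is zeroed (at a 100,000-read sample: 49 reads removed, 50 kept).
Standards are excluded from the denominator by default because they are
carrier, not biological signal; a flag includes them for sensitivity
analysis. The filter is single-pass and provably idempotent — removing
sub-threshold counts only lowers the total, so surviving OTUs remain above
the recomputed threshold — with an iterative variant behind a flag;
(4) contaminant removal — taxa that cannot occur in the study region and
are common food items (default blocklist: sockeye salmon, Alaska pollock,
Atlantic horse mackerel) are dropped entirely. Zeroed cells keep their
row/column ids until an explicit prune, so table shapes stay aligned
through the pipeline, and every dropped OTU carries a reason code in the
audit table.

## Detection-rate accounting

The reference is a set-net catch record of (classification, rank, biomass).
Records above species rank cannot be scored and are excluded, as are
species belonging to marker-indistinguishable pairs (the chub/blue
mackerel pair: detectable only as "Scomber spp."). A species counts as
detected if its exact name, or a "Genus spp." label covering its genus, is
among the metabarcoding labels; higher-rank labels vouch for no particular
species. An optional biomass floor (e.g. 10 kg/month) restricts the
denominator to non-trivially caught species *after* the rank and ambiguity
exclusions and never alters per-species detection flags. With the floor
active the report carries an explicit biomass-exclusion count so the
denominator identity stays checkable.

## Acoustics

Backscatter arrives as a ping × depth grid of volume backscattering
strength S_V in dB re 1 m⁻¹. Cells within 1 m of the per-ping bottom are
invalidated (acoustic dead zone), along with any supplied instrument or
bubble masks. A −70 dB threshold then separates fish echoes from
background: valid cells below it are set to linear zero — *not* treated as
missing — while an exact −70 dB cell is kept. Station summaries are
arithmetic means of linear S_V = 10^(dB/10) over valid cells in the
half-open ten-minute window after the station's sampling time. Averaging
must happen in the linear domain (dB are log-powers; averaging them biases
low), and counting thresholded zeros is what allows a station mean to fall
below 10⁻⁷, as sparse echograms genuinely do. A depth-band argument
optionally restricts the mean to the sampled layer; the default averages
the full valid column.

## Spatial models

Responses are OTU richness (Poisson, log link), strictly positive copy
concentrations (gamma, log link), and zero-containing concentrations
(gamma hurdle: logistic presence × gamma magnitude on positives, joint
log-likelihood the sum of the parts). Gamma coefficients come from IRLS —
they do not depend on the shape — after which the shape is profiled by a
1-D ML optimisation, giving a full likelihood for information criteria;
coefficient covariance is the inverse Fisher information (XᵀX)⁻¹/α. BIC is
k·ln(n) − 2ℓ with the shape counted in k (and, for the hurdle, k summed
over components). The candidate set is hierarchical: {1; cov; depth;
cov+depth; cov+depth+cov×depth}, with the hurdle's binomial component
intercept-only by default (mirroring how sparse presence patterns rarely
support more) and optionally mirroring the gamma terms.

Distance enters as log(distance_m + 0.1): the +0.1 m offset keeps the reef
station (0 m) finite while anchoring the intercept at log(0.1). Signed
east/west distances are stored but models use absolute distance, pooling
the two transect arms. Echo intensity enters as log10 of linear S_V since
station means span about three decades; a raw-linear option exists. Depth
is coded with bottom as the reference level, so reported effects are
middle-vs-bottom. The pseudo-R² is the squared Pearson correlation between
observed and fitted responses — simple, family-agnostic, and adequate for
comparing fits descriptively.

Station effects are screened by likelihood-ratio tests (chi-square,
levels − 1 df, shapes profiled under both hypotheses). Pairwise follow-ups
use Wald z statistics on the linear-predictor scale with single-step
max-|z| adjustment: the contrasts' correlation matrix induces a
multivariate normal whose max-|Z| null distribution is evaluated by seeded
Monte Carlo (default 10⁵ draws); Holm is available as a deterministic
fallback. With two levels the adjusted p equals the unadjusted p exactly.

## Community analysis

Bray–Curtis dissimilarity BC(x, y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) is computed on copy
numbers as-is: the spike-in calibration already makes samples comparable,
so no relative-abundance standardisation is applied by default (sqrt and
Wisconsin options exist). An all-zero pair has undefined BC and is set to
0 with a warning. BC is invariant under *joint* rescaling of both samples
but not under rescaling one of a pair — a property the tests assert in
both directions. Ordination is non-metric MDS (SMACOF with isotonic
regression on dissimilarity ranks), best of 50 seeded random starts,
reporting Kruskal stress-1 with centred coordinates. PERMANOVA uses
Anderson's pseudo-F from the among/within partition of squared
dissimilarities, with free permutation of labels and
p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1); reef-vs-surrounding and
middle-vs-bottom are tested as two one-factor analyses (a two-factor call
is a matter of passing a different grouping). The permutation engine is
in-package so every p-value is exactly reproducible from a seed; the test
suite cross-checks its pseudo-F against an independent implementation.

## Synthetic survey generator

The generator emulates the survey's statistical structure: stations at 0
(focal reef), ±150/500/750 m and a second reef at 220 m; two depth layers
× two replicates per station plus one field blank (33 libraries). True
concentration of species i in sample s is baseline_i ×
exp(−decay·reefassoc_i·log(d_s+0.1)) × a depth-preference multiplier ×
lognormal noise; reads are Poisson(slope_s × copies/µl) with slope_s drawn
lognormal (median 200 reads per copy/µl, log-sd 0.5 — every library
amplifies differently, which is precisely what the calibration corrects),
and standards are Poisson(slope_s × ladder). A multinomial option instead
conditions on a fixed per-sample total (default 65,000 reads) to stress
compositional distortion; Poisson is the default because it keeps the
standards' linearity assumption exact. Defaults: 20 species with lognormal
baselines (log-mean log 2.5 copies/ml, chosen so the synthetic survey's
mean total eDNA lands at the tens-of-copies/ml scale typical of such
surveys), 70 % of species reef-associated with coefficients U(0, 1.5),
decay 0.3 per log-metre, depth preferences middle/bottom/none with
probabilities 0.2/0.5/0.3 and strength e^±0.6, concentration noise log-sd
0.5. Species 0 and 1 share a genus and collapse onto a single OTU — the
built-in marker-indistinguishable pair. Echograms put each station's mean
dB at gain + 10·log10(total density) with Gaussian dB noise; the catch
record draws biomass proportional to summed density with lognormal error
and includes genus/family-rank records. Everything derives from one
`numpy` Generator seeded by the config, so bundles are bitwise
reproducible.

What the generator does *not* emulate: sequence-level artefacts (chimeras,
index hopping), species-specific amplification bias, eDNA transport and
degradation dynamics, tide/current structure, or acoustic beam physics.
Passing tests therefore demonstrate that the *analysis* is correct under
the stated stochastic model, not that field data meet that model.

## Synthetic reference fixture

The published survey's supplementary catch table is not redistributed;
`qmiseq/synthetic_refs.py` holds a synthetic fixture reproducing its
*accounting structure* (41 classifications = 38 species + 1 genus + 2
families; the mackerel pair; 21/36 detected overall; 14 species under
10 kg; 17/22 detected at the 10 kg floor) plus the printed sequencing
totals. The detection-rate and read-fraction results computed from it are
exact arithmetic on those counts, not re-derivations from raw reads.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen for tight-but-fast Monte Carlo:
coefficient-recovery runs use n = 500 with 100 replicates; type-I-error
calibration uses 500 null datasets (LRT: 8 stations × 25; PERMANOVA: 32
samples, 199 permutations); the acceptance script's PERMANOVA uses 999
permutations. The gamma-shape profile optimises over log α in [−6, 12];
NMDS uses 50 starts, ε = 10⁻⁹, max 300 iterations. Ties and boundaries are
resolved as stated above (identity = 98.5 % kept; alignment = 150 bp
dropped; noise threshold strict-<; −70 dB kept). Degenerate inputs —
all-zero standards, all-zero samples, empty detection denominators, fully
masked echo windows, hurdle responses with no zeros or no positives —
return flagged results or documented fallbacks rather than exceptions.

## Known limitations

Single-step contrast p-values are Monte-Carlo estimates (seeded, so
reproducible, but with ~10⁻³ resolution at the default draw count). The
hurdle's two components are fitted independently, which is exact for the
separable likelihood but means no cross-component covariance is reported.
LRT p-values rely on chi-square asymptotics; at very small per-station
replication they can drift from nominal (the calibration simulations use
25 per station, where coverage is nominal). The generator's Poisson read
model understates overdispersion seen in some real libraries; the
multinomial mode is a partial stress test, not a full PCR-noise model.
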
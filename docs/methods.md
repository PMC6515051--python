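# Methods

## The model of a paranome's age distribution

Within one genome, duplicate gene pairs arise continuously from small-scale
duplications (SSD) and episodically from whole-genome duplications (WGD).
Treating the synonymous divergence Ks of a pair as its age, the SSD
background is approximately exponential (young pairs are common, old ones
increasingly lost) and a WGD appears as a burst of pairs of similar age —
approximately Gaussian on the ln(Ks) scale. The analysis therefore models
the observed (redundancy-corrected, range-filtered) log-Ks values as a
finite Gaussian mixture and asks whether any component is a credible WGD
peak. A peak at mean Ks converts to an absolute age through the clock
identity T = Ks/(2r), r being the synonymous substitution rate per site per
year; the factor 2 accounts for divergence accumulating along both
descendant lineages.

## Homology search and family construction

All-vs-all protein comparison uses exact local alignment (Smith–Waterman
under BLOSUM62 with BLAST-style affine gaps, open 11 / extend 1 — a gap of
length g costs 11+g) rather than a heuristic search engine. Significance is
scored with the Karlin–Altschul expectation E = K·m·n·e^(−λS) using the
published gapped constants λ = 0.267, K = 0.041 and a database-style n (the
total residue count of the searched set), which reproduces default-BLASTP
decision behaviour. Two tiers of thresholds apply: hits at E ≤ 1e-5 define
family membership (families are connected components of the hit graph,
i.e. single linkage — the simplest reading of clustering a similarity
graph); pairs feeding the age distribution additionally require aligned
length strictly greater than 100 residues and E strictly below 1e-15. Both
are exposed in the configuration.

Because exact alignment of every pair scales quadratically, `all_vs_all`
by default restricts the aligner to candidate pairs sharing at least two
distinct protein 5-mers (a deterministic screen, computed from an inverted
k-mer index; buckets above 500 members are ignored as low-complexity). At
the divergences that can pass the E-value thresholds, homologous pairs
share dozens of 5-mers, so the screen is effectively lossless there —
`prefilter=None` runs the exact quadratic search, and a test asserts that
the two modes agree on simulated paranomes. Alignment itself is delegated
to Biopython's `PairwiseAligner`; tie-breaking among co-optimal tracebacks
follows that library's deterministic order.

## Ks estimation

**NG86 counting.** Synonymous/nonsynonymous sites are counted per codon as
the per-position fraction of *viable* single-base changes that are
synonymous; mutations creating stop codons are excluded from the
opportunity space, so the site normalisation matches the 61-sense-codon
state space of the ML model and the simulator (variants that count stop
changes as nonsynonymous opportunities give Ks a few percent lower on
stop-adjacent codons). Differences at multi-hit codons are averaged over
all mutational orderings, excluding pathways that pass through a stop codon
(all orderings are used in the rare case that every pathway is blocked).
Proportions are corrected for multiple hits with Jukes–Cantor,
Ks = −(3/4)·ln(1 − (4/3)pS); pS ≥ 3/4 is reported as saturated.

**GY94 maximum likelihood.** The production estimator maximises the
pairwise likelihood Σ ln(π_x · P_xy(t)) over (t, κ, ω) under the
Goldman–Yang codon model: single-nucleotide exchanges at rate
π_target · κ^[transition] · ω^[nonsynonymous], F3×4 equilibrium frequencies
estimated jointly from the two sequences (with a half-count pseudo-count
per base per position so frequencies stay positive), and the generator
scaled to one expected substitution per codon per unit t. Optimisation is
L-BFGS-B on the log-parameters with bounds t ∈ [1e-6, 50], κ ∈ [0.1, 20],
ω ∈ [1e-4, 10], started from the NG86 estimate (κ start 2); if the
optimiser fails to improve on the start, the NG86 estimate is returned
flagged. Ks and Ka are decomposed from t by Yang's flux convention:
dS = t·ρS/(3ρS¹), where ρS is the synonymous fraction of the substitution
flux at the estimate and ρS¹ the same quantity at ω = 1 (so 3ρS¹ is the
number of synonymous sites per codon). A branch length at its upper bound
marks the pair saturated. Transition probabilities use the symmetrised
spectral decomposition of the reversible generator; rows are clipped and
renormalised against round-off.

## Redundancy correction (node weighting)

An n-member family offers n(n−1)/2 pairwise Ks values but represents only
n−1 duplication events. Family members are clustered by average-linkage
hierarchical clustering on their pairwise Ks (all within-family pairs are
estimated for this, not only those passing the retention gate; pairs with
saturated or failed estimates enter the distance matrix at a large fill
value and are excluded from weighting). Each internal node of the
resulting tree is one duplication event; each pair is assigned to the node
joining its two members and the pairs of a node share total weight 1
(weight = 1/(pairs at the node)) — exactly, which the tests assert. The
retention gate and the Ks ∈ [0.1, 5] filter (both endpoints inclusive, so
results are bit-reproducible) then subset rows without reweighting. A flat
1/(pairs-per-family) weighting is available as a comparison mode, as is a
"nearest window boundary" variant of the peak representative-pair rule
(default: nearest the fitted peak mean, ties to the smaller Ks).

## Mixture modelling

Gaussian mixtures on ln(Ks) are fit by observation-weighted EM with
unequal per-component variances (variance floor 1e-6; a tied-variance mode
is available, with BIC then charging 2k instead of 3k−1 free parameters). Initialisation is a
weighted quantile partition plus seeded weighted k-means++ restarts; every
start runs at most 300 iterations and the best is polished until the
relative log-likelihood change falls below 1e-8 or 2000 iterations are
reached. Each k in 1..10 is fit and the fit maximising
BIC = 2·logL − (3k−1)·ln(n) is kept (larger is better; n is the effective
sample size, the sum of observation weights). Component summaries
back-transform the log-mean (mean Ks = exp(μ)) and report the log-scale
variance alongside a derived Ks-scale variance, since a log-scale fit can
be summarised either way. 95% CIs come from seeded bootstrap resampling
(indices drawn with probability proportional to weight; each resample
refit with k fixed, warm-started from the point estimate with a relaxed
tolerance of 1e-6 and 500 iterations, components matched by nearest mean);
more than 20% non-converged refits flags the CI unstable. Components with
mean Ks in [0.5, 2.0] and proportion ≥ 0.1 are labelled candidate-WGD;
components above Ks 2 are reported but never labelled WGD, because high-Ks
structure is dominated by saturation and stochastic loss.

## Dating and distribution comparison

`age_from_ks` and `rate_from_age` implement T = Ks/(2r) and r = Ks/(2T);
ages are reported rounded to the nearest Myr and rates to two decimals in
10⁻⁹/site/year units, matching conventional reporting precision. The
average plant rate 6.1×10⁻⁹ is provided as a constant. CI endpoints of a
peak mean are propagated through the same formula. Two age distributions
are compared by a two-sided Wilcoxon signed-rank test on their paired
per-bin relative frequencies over the shared 0.1-wide grid (binning being
the only pairing structure two paranomes share); zero differences are
dropped, the null is enumerated exactly up to 25 non-zero pairs and
approximated normally (with continuity correction) beyond.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
realised as actual sequences. Each family draws its size from
{2: 0.7, 3: 0.2, 4: 0.1}; its size−1 duplication events are independently
SSD (Ks ~ Exponential(rate 2.5), i.e. mean background age Ks 0.4) or WGD
(Ks ~ exp(Normal(ln 1.2, 0.15)), fraction 0.4 of events by default). The
events define a random ultrametric tree (heights in Ks/2 units, each event
splitting a uniformly chosen lineage), and codon sequences (300 codons by
default) evolve along it under GY94 with κ = 2, ω = 0.2 and a slightly
AT-rich F3×4 composition — per-site transition probabilities from the
matrix exponential, so no stop codon can ever arise and branch lengths are
exact. Branch lengths are scaled through the model's synonymous flux, so
the generator and the ML estimator share one definition of Ks; a tip pair's
expected synonymous divergence equals the Ks its joining event was drawn
at, which the truth table records together with the event's origin.

The background decay rate is calibrated so that an SSD-only paranome
cannot mimic a WGD: with rate 2.5 under a tenth of background pairs lie
beyond Ks 0.9, so a mixture fit of a pure background leaves no component
of proportion ≥ 0.1 inside the peak window — the generator's own negative
control. Shallower backgrounds (mean Ks ≳ 0.5) place a legitimate
shoulder component of the smooth exponential inside [0.9, 1.5], which is a
property of approximating a smooth density by Gaussians, not a detection
of anything.

What the generator does *not* emulate: assembly artifacts and fragmented
transcripts, allelic/homoeolog redundancy, rate variation among lineages
or sites, codon-usage differences between genes, and gene loss biased by
function. Passing tests therefore demonstrate the correctness and
statistical behaviour of the machinery under the stated model, not the
quality of any particular real transcriptome.

## Problem sizes and numerical choices in the tests

The test-suite simulations use the sizes at which the checked properties
stabilise while keeping the suite quick: 500-codon pairs with 50 replicates
per level for estimator recovery, 2000-family populations for the
positive/negative mixture controls (ground-truth Ks for the negative
control, full sequence pipeline for the positive one), and n = 8364 for
refits of the published diploid mixture. Exhaustive oracles (alignment-path
enumeration, Wilcoxon sign enumeration) run at the small sizes where
enumeration is feasible (≤ 6 residues, ≤ 12 pairs). Degenerate inputs are
handled explicitly: all-equal mixture data forces k = 1 at the variance
floor; an empty filtered distribution skips the mixture stage; a family
whose pairs are all saturated contributes nothing to the distribution;
all-zero Wilcoxon differences report p = 1 with a warning.

## Known limitations

Pairwise (not family-wise) likelihood; no rate heterogeneity across sites
or branches; no ortholog-based cross-species Ks correction; single-linkage
families can chain distinct families through promiscuous domains in real
data; the Karlin–Altschul constants are the published gapped BLOSUM62
values rather than being re-estimated per dataset; Ks saturation above ~2
makes old peaks unreliable (hence the labelling rule and the 0.1–5 working
range).
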
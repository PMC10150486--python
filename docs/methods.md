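# Methods

## Signature-SNV scoring

For every biallelic site the sink's reference/alternative read counts
(*n*, *m*) are evaluated under two hypotheses per candidate source *i*:

* **H1** — source *i* alone explains the sink: θ̂ = pᵢ, the source's
  reference-allele frequency (ref reads / depth).
* **H2** — the other sources jointly explain it: θ̂ = Σ_{j≠i} αⱼ pⱼ with α
  on the simplex (αⱼ ∈ [0, 1], Σ αⱼ = 1).

Both are scored with the binomial log-likelihood
LL(θ̂) = n·log θ̂ + m·log(1 − θ̂); the per-source log-likelihood ratio is
l₁ − l₂ and the site's signature score is the maximum over sources.

**Closed-form H2 fit.** LL is concave in θ, and as α ranges over the
simplex θ = Σ αⱼ pⱼ sweeps exactly the interval [min pⱼ, max pⱼ]. The
constrained optimum is therefore θ* = clip(n/(n+m), min pⱼ, max pⱼ),
attained by a mixture of the two extreme sources. This replaces an
iterative constrained optimiser with an exact, deterministic expression;
the test suite verifies it against both an exhaustive simplex grid search
(step 10⁻³, agreement < 10⁻⁴ log-units on random sites) and a sequential
least-squares optimiser.

**Conventions and edge cases.**

* p and θ refer to the *reference* allele; the LL formula pairs θ with the
  reference count n, which fixes the orientation.
* Frequencies are clipped to [10⁻⁶, 1 − 10⁻⁶] before logarithms, so every
  score is finite even for fixed sources opposing the sink's reads.
* A source participates at a site only if its depth passes the coverage
  minimum there. If a single source passes, H2 is undefined and l₂ = 0, so
  the score reduces to l₁ — such sites score very high when the source
  matches the sink.
* Coverage filter: sink depth ≥ `min_site_depth` (default 10; 5 is the
  documented low-coverage setting for environmental data) and at least one
  source at depth ≥ the same minimum; a sink-biallelic site additionally
  needs ≥ 2 reads on each allele.

**Selection.** Scores are grouped per (species, contig) into 200-kb windows
(window index = ⌊(position − 1)/window⌋); a site is selected when its score
strictly exceeds the window mean plus 2 population standard deviations.
Strictness means an all-equal window (SD 0) selects nothing, including
singleton windows. A global-threshold variant is available as a flag.
Sites carrying an allele present in the sink but absent from every covered
source are always selected ("rescue", toggleable): they are the footprint
of an unknown source. Both the per-window statistic and the rescue default
reflect one reading of an ambiguous original description; the flags expose
the alternative readings.

## Contribution estimation (EM)

Features are either the two allele counts of every signature SNV or species
pseudo-counts (relative abundances × a nominal read total, species absent
from the sink excluded). The model is

x ~ Multinomial(N, Σₖ αₖ γₖ),  k = 1 … J+1,

with the J known sources' own counts yⱼ ~ Multinomial(Nⱼ, γⱼ) entering the
joint likelihood, so γⱼ is informed by the source sample and by the sink
reads attributed to it (M-step γⱼ ∝ yⱼ + zⱼ); the unknown source's γ comes
from its E-step share alone (γ_u ∝ z_u). The joint log-likelihood is
asserted non-decreasing at every iteration; convergence is a relative
log-likelihood change below 10⁻⁶ (default), capped at 1000 iterations.

**Why estimation is staged.** The unknown component makes the likelihood
degenerate: a free distribution fitted from the sink alone can reproduce
the sink exactly, so the global optimum is always "everything is unknown",
and an EM started from a dense (e.g. uniform) unknown distribution drifts
steadily toward it, absorbing sampling noise along the way. The estimator
therefore proceeds in stages:

1. **Known-only fit.** Contributions over the J known sources alone
   (plug-in profiles γⱼ = yⱼ/Nⱼ, restricted to features where some known
   source has counts) — a non-degenerate fit.
2. **Residual seed.** The unknown's distribution is seeded with the
   positive residual of the sink over that fit, soft-thresholded at half a
   binomial standard error per feature. Pure sampling noise also leaves
   mass after thresholding (per feature, mean ≈ 0.1978 and SD ≈ 0.4128
   noise SDs), so an unknown component is introduced only when the seed
   total exceeds the no-unknown null's mean by two null SDs, and the null
   mean is then subtracted. Zeros in the seed are fixed points of the
   unknown's M-step, so the unknown can only ever claim features the known
   sources genuinely fail to explain. The full (J+1)-component EM then
   runs from uniform contributions.
3. **Species-level reattribution** (SNV features only). Stage 2 credits
   the unknown only for reads on alleles absent from every known source,
   yet a source mixing into a species contributes at *all* of that
   species' sites. At sites where the unknown is identifiable (seeded
   sites) its local mixing share is read off the E-step assignment; the
   per-species share is taken as the 0.75 quantile over those sites
   (sites seeded by global misfit rather than private alleles sit below
   the private-allele cluster, so the upper quartile lands on the
   cluster) and extrapolated over each species' read share. The unknown's
   total becomes Σ_c (species read share) × (local share), never below
   stage 2's direct claim, with the known sources rescaled
   proportionally. The half-SE threshold and the quantile were calibrated
   on mixture scenarios spanning feature sparsity, depth and unknown
   size, separate from the benchmark suite.

Degenerate duplicated sources make α non-identifiable; the estimator
reports the fixed point reached from its deterministic start. Optional
random restarts redraw the starting contributions. Rarefaction to the
minimum sample depth is available but off by default. A nominal total of
10⁴ reads converts relative species abundances to pseudo-counts for
species-level tracking.

## Strain-sharing baselines

Both baselines operate on allele-count panels, so they re-specify the
original read-level tools' logic at the count level.

**popANI.** Sites covered ≥ 5× in both samples are compared; an allele is
detected when it has ≥ 1 read and ≥ 5% within-sample frequency; a site is a
population substitution when the detected-allele sets are disjoint.
Per-contig popANI = 1 − substitutions/compared; the species value is the
unweighted mean over contigs; species with no compared site are omitted.
Sink and source are called "same strain" for a species at popANI ≥ 99.999%,
and the per-source sharing estimate is the fraction of species (with a
defined value) called shared.

**Private marker alleles.** An allele is considered in a sample when site
depth ≥ 30 and it carries ≥ 10% of reads; it is absent from a sample when
it has < 3 reads (the documented fixed ceiling, 10% × 30; a
depth-proportional alternative is a flag). A considered focal allele absent
from partner and every background sample is a focal-only marker; one
considered in both focal and partner and absent from all background is
shared. Total sharing = shared/(focal + partner + shared markers); a
species shares a strain at ≥ 5%. Pooled proportions sum numerators and
denominators across species.

## The transmission simulator

The generator emulates the count-level signature of mixing sequencing reads
from real source samples; it produces allele-count panels directly rather
than reads, which is the level every estimator here consumes.

* **Communities.** A base species profile is drawn log-normal(σ = 1.5)
  across 20 species and perturbed per source by log-normal(σ = 0.6),
  mimicking hosts from one cohort: heavy-tailed abundances with shared
  structure.
* **Strains.** Each species contributes 2000 biallelic sites placed
  uniformly on a 1-Mb contig (so five 200-kb selection windows). Every
  site has an ancestral reference frequency q ~ U(0.05, 0.95) and an
  ancestral genotype ~ Bernoulli(q); each source redraws the genotype
  independently at a divergence fraction (0.3) of sites, is polymorphic
  (frequency U(0.2, 0.8)) at a 0.1 fraction, and carries N(0, 0.02)
  frequency noise — mostly clonal strains, related but distinguishable.
  Site density follows the regime where a single species' variant sites
  number in the thousands; divergence/polymorphism set to 0 reproduce
  identical sources as a degenerate check.
* **Depths.** Per-sample site depth ~ Poisson(50 × relative species
  abundance × number of species), so a sample's depth profile tracks its
  community composition.
* **Transmission.** Per (source, species), a probability is drawn from a
  Beta with mean equal to the species' abundance in that source ("high"
  mode) or 0.1 × it ("low"), variance 0.1; one Bernoulli draw per source,
  and any success transmits the species from all sources carrying it.
  Infeasible Beta variances (v ≥ μ(1−μ), frequent at small μ) are clamped
  to 95% of the bound, keeping the mean exact. Masks are redrawn until at
  least one species is transmitted — an empty sink is not a trackable
  instance.
* **The sink.** One contributing source is withheld as the unknown. Each
  source's abundances are renormalised over its transmitted species, so
  every source supplies in expectation exactly its configured share of
  sink reads — the count-level equivalent of pooling a fixed proportion of
  reads per source sample. Per-site sink depth ~ Poisson(50 × mixture
  species weight); reads are allocated to sources multinomially
  (∝ proportion × renormalised abundance) and carry the reference allele
  binomially at the source's site frequency. The truth manifest records
  configured proportions, the transmission mask and realised read
  fractions.
* **Mixing proportions.** Benchmark replicates draw the unknown share
  uniformly from [0.10, 0.90] and split the remainder across 2–9 known
  sources by a shifted Dirichlet honouring a 1% floor, alternating high
  and low transmission.

## What the simulations do and do not show

The generator reproduces the features the estimators actually consume:
biallelic count panels with abundance-scaled coverage, mostly clonal
per-host strains with shared ancestry, per-species transmission, and a
ground-truth simplex including a genuinely held-out source. It does not
model read-level artefacts (mapping bias, duplicated regions, chimeric
reads), multi-allelic sites, strain mixtures drifting within a host over
time, or horizontal gene transfer. Passing the benchmark shows the
selection + EM machinery recovers mixing proportions under faithful
count-level conditions; it does not certify performance on real read
mappings.

Two benchmark observations deserve note. Species-level tracking performs
poorly here because every simulated sample carries all species — there is
almost no species presence/absence signal, only abundance shape — which
exaggerates (but points the same way as) the finding that SNV features
outperform species features precisely when species composition is
uninformative. And the marker-allele baseline's correlation is modest at
this scale because its 30-read site threshold discards most sites of
low-abundance species; both baselines are included as comparators, not as
tuned competitors.

## Numerical choices

* Frequency/θ clipping 10⁻⁶; EM responsibilities guard zero mixtures;
  log-likelihood monotonicity asserted at 10⁻⁸ relative tolerance.
* Window statistics use the population (not sample) standard deviation.
* Best-source ties resolve to the lowest index; windowed selection is
  strict (>), so constant windows select nothing.
* MIDAS frequency × depth products round half-to-even; the native TSV
  carries explicit integer counts to avoid rounding ambiguity.
* Multi-allelic or malformed rows are rejected at read time with a
  warning; a missing sample-site is depth 0, not an error.
* All stochastic components take explicit seeds; identical inputs and
  seeds reproduce identical outputs byte for byte.

## Known limitations

* The EM's unknown component is identified through model structure, not
  the likelihood optimum (which is degenerate); very smooth, heavily
  overlapping sources can still hide a small unknown inside the known
  hull, biasing it low.
* popANI and marker-allele logic are count-level re-specifications of
  tools that natively work from read alignments; absolute agreement with
  those tools on real data is not claimed.
* Coordinates are 1-based and sites biallelic throughout; multi-allelic
  sites are rejected rather than decomposed.
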
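# Methods and design notes

## The setting

A base population descended from 19 inbred founder accessions is subjected
to truncation selection for a quantitative trait (shoot branching) over 10
generations: each generation 40 of 200 individuals are chosen as parents,
randomly paired into 20 disjoint crosses, and each cross contributes 10
progeny. Pool sequencing of the final generation yields, per 200 kb
sliding window (100 kb step), the estimated frequencies of the 19 founder
haplotypes. Selection is detected as local collapses of haplotype
diversity against the genome-wide background.

## Statistics

**Expected heterozygosity.** For a window with founder-haplotype
frequencies p₁…p₁₉, He = 1 − Σ pᵢ²: the probability that two randomly
sampled haplotypes differ. With 19 equifrequent haplotypes He = 18/19 ≈
0.947, the theoretical maximum; a hard sweep drives it towards 0.

**Collapsed statistics.** He is insensitive to sweeps in which several
haplotypes rise together. He12 (and He123, He1234) sort the frequencies
descending and treat the top k as one allele:
He(k) = 1 − (Σ_{i≤k} p(i))² − Σ_{i>k} p(i)². The top-k mass enters as a
squared sum, and the remaining squared frequencies are also subtracted,
so k = 1 reduces exactly to He and He(k) is non-increasing in k.

**Breeder's equation.** Per generation, the selection differential S is
the mean trait of the chosen parents minus the population mean; the
response R is the selected population's mean minus its paired control's
(the control absorbs shared environmental drift). The realised
heritability is the zero-intercept least-squares slope of R on cumulative
S: h² = Σ cumSₜRₜ / Σ cumSₜ². Uncertainty comes from resampling
generations (the (cumSₜ, Rₜ) pairs) with replacement, 1000 times, and
taking the central 95% interval. Bootstrapping generations rather than
individuals matches the unit at which the regression has independent
information. Realised heritability estimates the heritability expressed
under the experiment's conditions and is noisy at 10 generations.

**Vargha–Delaney A.** A(x, y) = [#(x>y) + ½#(x=y)] / (n_x n_y), computed
from rank sums; 0.5 under no effect, and A(x,y) + A(y,x) = 1.

**Inbreeding.** F of an individual equals the kinship of its parents,
computed by the recursive additive-relationship construction on a
generation-ordered pedigree: founders unrelated and non-inbred;
kinship(a,a) = (1+F_a)/2; an individual's kinship with anyone earlier is
the mean of its parents' kinships. One known parent is treated as paired
with an unrelated phantom.

**Gene-drop nulls.** For each of n independent loci (default 1000), every
founder receives two alleles i.i.d. uniform over the 19 states ("equal
starting frequency" read as equal expected frequency, the same convention
as the simulator's founder initialisation), alleles are transmitted by
fair Mendelian sampling down the fixed pedigree, and He is computed from
the final generation's pooled 2N genes. The resulting distribution is the
population-specific neutral expectation; scans are z-scaled by its mean
and SD, with windows below z = −4 flagged. The closed-form counterpart is
H_t = H₀(1 − 1/2N)ᵗ; with H₀ = 18/19, N = 40 breeding parents and t = 10
it gives 0.835.

**Thresholds and intervals.** The empirical threshold takes each
directionally selected population's 1% percentile of window values
(linear interpolation between order statistics) and combines populations
by the median; a pooled-percentile variant is provided. Windows below
threshold form runs; runs on one chromosome within 400 kb edge-to-edge
(four consecutive sliding windows) are merged; intervals overlapping the
1 Mb centromeric mask are flagged and optionally dropped (haplotype
frequency estimates are unreliable there). Merging is idempotent.

**SNP |AFC| scans.** A SNP carried by s of the 19 founders starts at
frequency s/19; |AFC| is the absolute difference between that and the
observed pooled final-generation frequency, averaged per window. Outlier
windows exceed the 99% percentile of the track; empty windows are missing
and excluded.

## The simulator

Five chromosomes carry (303, 195, 233, 184, 268) loci — one per scan
window — each with 19 allele states. Founders are sampled i.i.d. uniform
per locus, so generation-0 LD is zero by construction (a deliberate
simplification: the real population inherits founder LD blocks). Meiosis
draws Poisson(2) crossovers per chromosome, placed on distinct
inter-locus gaps chosen uniformly (a repeated gap would self-cancel),
alternating parental haplotypes from a random start.

The trait is Normal(μ, 1) with μ = effect × (advantageous-allele dose
summed over trait loci, 0–2 copies per locus): strictly additive per
copy, no dominance or epistasis, noise redrawn each generation. Trait
loci are placed deterministically — one per chromosome at the central
locus for ≤ 5 loci, otherwise round-robin at equally spaced interior
positions. Advantageous alleles at a locus (states 1…a of 19) are
interchangeable and share one effect. Selection regimes: directional
(top 40), stabilising (closest to the generation mean), random; ties
break at random. No mutation is modelled: over 10 generations new
mutations contribute negligibly. Realised heritability of a simulated
population uses R_t = mean(t) − mean(0); the environmental noise is
mean-zero by construction, so the generation-0 mean plays the role the
control population plays in the glasshouse.

One experiment at the default size runs in ~0.5 s, so the behavioural
test batteries (100-seed dichotomy runs, a 4 × 6 × 20 parameter grid)
complete in minutes.

## Synthetic fixtures: what they emulate, and what not

**Haplotype-frequency tables.** Window background vectors are Dirichlet
draws centred on 1/19, blended over a 4-window moving span (the
autocorrelation that 200 kb/100 kb overlapping windows impose) and
renormalised; the pre-smoothing concentration is chosen so the
post-smoothing marginal has a requested effective concentration c, for
which E[He] = (18/19)·c/(c+1). Three calibrations are provided:
`concentration_for_mean_he` inverts that identity; the generic default
(c ≈ 7.4) matches the neutral drift expectation 0.835 after 10
generations with 40 parents; `DIRECTIONAL_CONCENTRATION` (mean He 0.767,
founder diversity scaled by 1−F at F ≈ 0.19) and `CONTROL_CONCENTRATION`
(mean He 0.852, F ≈ 0.10) reflect that directional selection co-selects
siblings and roughly doubles inbreeding relative to random controls.
These choices reproduce the observed detectability structure: a
one-haplotype sweep at 0.8 (He ≈ 0.36) falls below the directional 1%
tail, a two-haplotype sweep at 0.45 + 0.45 (He ≈ 0.59) does not but its
He12 ≈ 0.19 does, and control-background genomes scanned at a
directional-population threshold yield ≪ 1 false interval on average.
Injected sweeps set a founder subset (1–4 founders) to a target total
frequency, split equally, with the remaining founders rescaled. The
fixtures do not emulate centromeric estimation bias, coverage
heterogeneity or founder-specific mapping bias.

**Phenotypes.** An infinitesimal model: breeding values are transmitted
as the mid-parent value plus segregation noise, and the segregation
variance is sized each generation to restore the additive variance to its
base value (floored at the classical Va/2). The restoration is
deliberate: under truncation selection a fixed-Va/2 model lets
between-family variance erode (the Bulmer effect), so the realised slope
would systematically estimate a quantity below the declared truth and
"true h²" would be ill-defined as a recovery target. Environmental noise
is sized so narrow-sense heritability equals the requested value; a
shared seasonal shift per generation (SD 1 branch) is absorbed by the
paired control, and a per-population batch effect (SD 1 branch) supplies
the independent generation-level scatter that glasshouse experiments
show and that the generation bootstrap resamples. Branch counts are the
latent values rounded and floored at zero (baseline 5, phenotypic SD 2
branches, giving selection differentials of ~1–3 branches at intensity
~1.4). Flowering days are decorative draws with 5% missingness to
exercise missing-data paths. Not emulated: seasonality-linked variance
cycles, zero-inflation beyond the floor, GxE.

**Pedigrees.** Experiment-shaped (20 disjoint pairs × 10 progeny,
census 200). A sibling-enrichment parameter ≥ 0 biases parent choice
towards families with a high random family value, mimicking the extra
inbreeding of directional selection; at 0 the choice is uniform. The
monogamous equal-contribution structure drifts slightly slower than the
idealised 1/(2·40) rate per generation (mean F ≈ 0.09 vs 0.11 at
generation 10); `make_wright_fisher_pedigree` provides the idealised
variant for which the closed-form decay is exact.

**SNPs.** Positions uniform per chromosome; ~50% of carrier sets are
private (size 1), the rest uniform sizes 2–9; observed frequencies are
the carrier founders' summed haplotype frequency in the containing
window plus N(0, 0.01) noise, so SNP and haplotype fixtures share one
latent truth and the |AFC| and He scans can be cross-validated.

## Numerical and interface conventions

Coordinates are 0-based half-open internally and in BED output; 1-based
inclusive frequency tables are accepted with a read dialect flag. Window
frequency rows are renormalised when within 1e-3 of summing to 1 and
rejected otherwise (haplotype-frequency inference emits near- but not
exactly normalised rows). Founder columns are fixed alphabetically.
Sample SDs use the n−1 denominator; the MAD is reported raw (no 1.4826
factor). Quantiles interpolate linearly between order statistics.
Missing windows propagate as missing and never enter percentiles.
Degenerate gene-drop nulls (SD = 0) are flagged rather than silently
z-scaled. All stochastic components take explicit seeds or generators;
identical seed and configuration give bit-identical results.

## Known limitations

- Founder initialisation without LD makes simulated sweep signals more
  local than real ones, where long founder haplotype blocks extend the
  footprint.
- The family-mean plasticity estimator replaces a random-slope mixed
  model; it is the quantity actually compared between populations but
  does not partition within-family variance.
- Realised heritability from 10 generations is intrinsically noisy; the
  bootstrap interval quantifies generation-level scatter, not drift of
  the whole trajectory.
- The gene-drop null treats loci as unlinked; observed windows are
  autocorrelated, so null SDs are exact per window but neighbouring
  windows' z-scores are not independent.
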
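# Methods

`pinepop` implements a multilocus population-genetic analysis for small sets
of sequenced gene fragments from closely related taxa — the design used in
candidate-gene studies of conifers, where haploid megagametophyte sequencing
yields phased sequences for tens of loci across a few taxa and many
populations.  This note documents the models, the parameter choices, the
numerical decisions and the known limitations.

## Data model

A study is a set of per-locus haploid multiple alignments over
`A C G T - N` (IUPAC ambiguity codes become `N` on input), a sample table
(taxon / population / optional regional group per sample), an optional
aligned outgroup row per locus, and optional coding-interval annotation.
Coordinates are 0-based half-open internally and 1-based in reports and VCF
output.

Variant tables treat an alignment column with two or more distinct called
bases as a SNP; a maximal run of gap columns sharing one presence/absence
pattern collapses to a single indel polymorphism.  Indels count in the
polymorphic-site total and in haplotype definitions but are excluded from
per-site statistics (pi, theta per bp), which matches the usual
"total mutations vs. sites" split of sequence-polymorphism software.  Sites
with more than two alleles are retained for per-site diversity (computed as
the mean pairwise difference over alleles) and reduced to major-vs-rest only
where a method requires biallelic input (r², the outlier scans).  Missing
data are handled by pairwise deletion wherever a pairwise quantity is
computed.  Singletons are sites whose minor allele is carried by exactly one
sample, irrespective of derived state; derived-singleton counts are
available after outgroup polarization, which assigns the ancestral state
only when the outgroup carries one of the segregating alleles.

## Diversity and the multilocus theta posterior

Per-site pi is the mean per-site pairwise difference over called pairs;
Watterson's theta is `S / (a_{n-1} L)`; haplotype diversity and its SD
follow Nei's unbiased estimators.  Silent sites are noncoding columns plus
the Nei–Gojobori synonymous-site fraction of coding codons evaluated on the
group consensus (codons containing gaps, `N` or stops are skipped); the
silent/total split is available whenever annotation is supplied.

The multilocus theta estimate is Bayesian: one per-site theta shared across
loci, scaled by each locus's length.  The likelihood of the segregating-site
count uses the closed-form alternating-sum distribution of S under the
neutral coalescent for n ≤ 60 and S ≤ 500 (its float64 cancellation error,
about n digits, is far below posterior Monte-Carlo noise; an independent
geometric-convolution form verifies it in the tests) and a Monte-Carlo
likelihood with common tree-length draws otherwise.  The sampler is a
Metropolis walk on log10(theta) against a likelihood cached on a 2001-point
grid over the uniform log-prior range [1e-5, 1e-1]; acceptance rate and an
autocorrelation-based effective sample size are reported, with a warning
below ESS 200.  Default chain: 5000 burn-in, 100 000 samples; scaled-down
chains (≥ ~20 000 samples) give indistinguishable medians for study-sized
data and are used in the worked examples.

## Coalescent engine

All null distributions come from an in-package coalescent with ms-style
scaling: time in units of 4N generations (pair coalescence rate 2 within a
deme), locus-total theta = 4Nμ and rho = 4Nc, migration M = 4Nm moving each
lineage at rate M/2.  Demographies: panmictic, finite-island (each deme of
size N, so a d-deme island model totals dN), and population splits expressed
as scheduled backward-time deme merges, optionally with migration restricted
to groups of demes (populations within one taxon).  Mutation is
infinite-sites with either fixed-theta (Poisson on total tree length) or
fixed-S conditioning (exactly S mutations placed proportional to branch
length).  Intralocus recombination uses the Hudson ancestral recombination
graph via msprime, with the package's scaling mapped onto msprime's
(haploid samples, population size 1/2), guarded to n ≤ 30 and rho ≤ 50.

Two compiled (numba) fast paths exist for the simulation-heavy consumers:
a panmictic simulator returning (S, theta_pi, theta_L, F, k) per replicate,
and an island-model single-SNP simulator that skips migrations of lone
lineages into empty demes — an exact aggregation, since demes are
exchangeable and such moves change nothing.  Both are validated
distributionally against the pure-Python engine in the test suite.

## Neutrality tests

Tajima's D uses the 1989 variance constants (n = 3 is degenerate: the
statistic is identically 0/0 and is reported as 0).  Fay & Wu's H is
reported normalized following Zeng et al. (2006), `(theta_pi - theta_L)`
over its estimated SD, alongside the unnormalized `theta_pi - theta_H`; only
polarized biallelic sites enter.  The Ewens–Watterson statistic is haplotype
homozygosity F with the Ewens-sampling-formula null conditional on (n, k),
drawn by Chinese-restaurant rejection at the theta matching E[K] = k (the
conditional law is theta-free, so this is exact).

P-values are empirical, `(b+1)/(B+1)`, one-sided in the selection
directions: D low, H low, F high.  Per-locus nulls default to fixed-S
conditioning; the compound tests condition on fixed theta at the locus's
Watterson estimate, the convention of the software they reproduce, with
fixed-S available.  The compound HEW (H & EW) and DHEW (D, H & EW) tests
simulate the joint null once per conditioning, convert each replicate's
components to empirical p-values against the same bank, and set the
component threshold alpha' to the alpha-quantile of the per-replicate
maximum component p — the largest threshold whose compound size does not
exceed alpha.  Because the components are jointly required and positively
correlated, alpha' typically exceeds alpha.  Null banks are cached per
(n, conditioning) and seeded deterministically from a master seed.

The multilocus Tajima test compares the observed mean D with the mean of
independently simulated per-locus fixed-S nulls.  The HKA test uses the
one-population-plus-outgroup-sequence design:
`E[S_i] = theta_i a_{n_i-1}`, `Var = E[S_i] + theta_i² b_{n_i-1}`,
`E[D_i] = theta_i (T+1)`, `Var = E[D_i] + theta_i²`; (T, theta_i) minimize
the X² of observed against expected (moment solution as the optimizer
start, per-locus 1-D profile minimization inside a bounded search over T),
and p comes from chi-square with L−1 degrees of freedom.  Multi-sequence
outgroups are reduced to mean divergence.  S=0 loci are excluded from
per-locus tests but kept in HKA unless divergence is also zero.

## Differentiation

AMOVA follows the squared-pairwise-difference variance partition with two-
or three-level hierarchies and the standard permutation schemes (samples
among populations for Phi_ST; samples among populations within groups for
Phi_SC; whole populations among groups for Phi_CT).  Pairwise F_ST between
groups is the same Phi_ST machinery on each pair — the Arlequin-style
convention rather than Weir–Cockerham, chosen for comparability with the
study design this package addresses.  Per-SNP F_ST is the closed-form
haploid one-level partition from allele counts and equals the full AMOVA on
the same data to 1e-10 (tested).  S_nn follows Hudson (2000), nearest
neighbours by minimum distance with ties split equally.  PCoA is Gower
double-centering with eigendecomposition; negative eigenvalues are reported
and excluded from the variance percentages.  The haplotype network is the
union of all minimum spanning trees (Kruskal by weight class, keeping every
co-minimal edge evaluated against the components at its class start).

## Outlier scans

The FDIST-style scan simulates single-SNP loci under a 100-deme finite
island model with the observed group sample sizes, one mutation per
genealogy placed proportional to branch length.  Migration is calibrated by
bisection so the simulated weighted (ratio-of-sums) multilocus F_ST matches
the observed value; the naive mean of per-SNP ratios is near zero or
negative for weakly differentiated data and is not used.  One round of
trimming removes SNPs flagged at the 99% level from the target estimate and
recalibrates, so strong outliers do not inflate the neutral envelope.

Conditioning on heterozygosity is exact where possible: with complete data
H_e is a bijection of the folded allele count, so the equal-H_e block of
simulated loci is the exact conditional null; a sliding window (≥500
simulated loci) is the fallback for sparse classes.  Because the
conditional F_ST null is heavily discrete, the reported p is the exact-size
randomized tie-broken empirical p-value (uniform under the null); the
conservative non-randomized value is reported as `p_upper`.  Flags at
p ≤ 0.05 and p ≤ 0.01 correspond to the 95% and 99% conditional envelopes.
Measured island-null flag rates are 0.044–0.057 and 0.0075–0.012 across
seeds.

The Bayesian scan decomposes `logit(F_ST^{ij}) = alpha_i + beta_j`
(locus effect, population effect) with beta-binomial allele counts, uniform
ancestral frequencies, alpha ~ N(0,1), beta ~ N(−1, 1.8²), and
reversible-jump toggling of each alpha with prior odds 10 for neutrality.
SNPs at pooled minor-allele frequency ≤ 0.05 are excluded.  Updates are
vectorized across SNPs; a beta move re-evaluates only its own population's
likelihood column.  Pilot runs tune random-walk widths toward 25–45%
acceptance.  Output is the posterior inclusion probability per SNP, the
posterior mean alpha over included iterations, and local-FDR q-values (the
cumulative mean of 1 − inclusion probability in decreasing-probability
order), with decisions at q < 0.05.  Storey FDR control uses the
single-lambda pi0 estimate (`lambda = 0.15` by default) and step-up
q-values.

## Evidence synthesis

Per gene and taxon, six evidence codes are collected: (1) significant
between-taxon F_ST (p < 0.01), (2) significant among-population F_ST within
the taxon, (3) significant S_nn, (4) SNPs above the 99% between-taxon
envelope, (5) outlier SNPs within the taxon (95% envelope), (6) significant
HEW and/or DHEW (p < 0.05).  A candidate gene requires, within one taxon,
code 6 AND (1 or 4) AND (2, 3 or 5) — neutrality deviation plus
between-taxon divergence plus a within-taxon signature.  Genes with any
signal in more than one taxon are listed separately.  Every flag carries a
provenance string naming the underlying test row, and the assembly is a
pure function of its inputs.

## The synthetic-study generator

The generator emulates the target design: three taxa with 79/24/50 haploid
samples over 8/3/5 populations (regional groups for the large taxon), 79
nuclear fragments averaging ~420 bp (~33 kbp total), three non-recombining
mtDNA fragments, and a deep outgroup per locus.  Populations are island
demes within their taxon (M = 25, within-taxon population F_ST a few
percent); taxa merge backward at 0.005 and 0.01 in 4N units with no
migration between taxa; the outgroup lineage joins at 2.7.  Per-site theta
is log-normal(ln 0.0035, 0.55), spanning the observed per-locus range with
mean pi near 0.004.  mtDNA uses reduced theta (0.001/site), lower
within-taxon migration and a 4× deeper time scale (smaller organellar Ne),
which partitions the mtDNA haplotypes between taxa more strongly than the
nuclear data — as in the real system.  A fifth of nuclear loci receive one
short (2–4 bp) indel polymorphism so the indel pathway is exercised
end-to-end.

These defaults were tuned once, against the published regime, and frozen:
shared polymorphic sites between the large taxa ≈ 59–60%, mean net
divergence ~5e-5 (well under 0.001), outgroup net divergence ≈ 0.022–0.024,
mean pi ≈ 0.0039, haplotype diversity ≈ 0.62, mtDNA ≈ 12 SNPs and ~20
haplotypes.  Two consequences are deliberate and should be kept in mind
when reading synthetic results:

* **Shared polymorphism vs. taxon F_ST trade off.**  Under a neutral
  equilibrium split, ~60% shared polymorphism forces very recent splits,
  which caps between-taxon F_ST near 0.01–0.03 — the published 0.08–0.15
  alongside 59–69% sharing reflects non-equilibrium history the generator
  does not model.  The generator follows its two stated targets (sharing
  and net divergence).
* **No demographic growth.**  The constant-size coalescent centres
  multilocus Tajima's D at zero; the consistently negative D of the real
  data (range-expansion signal) is not emulated.  Passing synthetic tests
  therefore validates the statistics and their calibration, not a claim
  that the generator reproduces every feature of the real data.

Selection injection is post-hoc with exact truth labels: `divergent` shifts
derived-allele frequencies in a target taxon by delta (carriers changed
only by the count difference, so delta = 0 is the identity); `sweep_like`
replaces a fraction of a taxon's polymorphic columns with star-tree-like
columns (singletons, occasionally near-fixed derived alleles), which drives
D and H negative and homozygosity up.  Both are stylized stand-ins for
forward simulation, chosen for speed and exact truth.

## Numerical and testing choices

* Empirical p-values use `(b+1)/(B+1)` everywhere, so zero is never
  reported; the FDIST scan additionally randomizes ties (see above).
* All randomness flows through explicit seeds; null banks and the
  acceptance script derive sub-seeds deterministically from one master
  seed, and every simulation count is recorded in the result objects.
* Replicate counts: the API defaults carry the reference settings
  (1000 permutations, 10 000 compound-test simulations, 20 000 envelope
  replicates, 100 000 posterior samples).  The test suite and the worked
  examples run scaled-down counts (hundreds to a few thousand replicates,
  ≥2000 where a size is being estimated) — the package's choice of
  problem size for its own verification, at which every calibration band
  checked is stable across seeds.
* The r²-based rho fit recovers the presence and ordering of recombination
  (Spearman > 0.8 across a rho grid) but its absolute level is biased
  upward at modest locus counts, a known property of moment fits to the
  Hill–Weir curve under informative-site conditioning; rho and rho/theta
  should be read comparatively.
* FDIST-style scans assume the island null; applied to data from a
  hierarchical split-plus-island history the 95% flag rate runs mildly
  liberal (~0.07 where the matched-model rate is ~0.05), the classic
  robustness caveat for this family of scans.

## Limitations

Beyond the generator caveats above: no codon-model or gamma-corrected
distances (Jukes–Cantor only, per the target design); no model-based
admixture clustering (PCoA/F_ST views stand in); the HKA implementation is
the classic single-population design, not the multi-species variant;
between-locus LD is never used; and the BayeScan-style sampler is a
faithful but compact implementation — for very large SNP panels the
original tool's adaptive proposals will mix better.
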
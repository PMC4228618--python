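# Methods

This note records the statistical definitions, conventions and numerical
choices behind `haplopop`, and what the synthetic-data generator does and
does not emulate.

## Data model

The universal input is a haploid individuals × loci matrix of positive
integer allele codes (microsatellite fragment sizes, or arbitrary codes)
with `0` reserved for missing calls, plus per-individual stratification
labels (host tree, infructescence age class). Null alleles are treated
operationally as amplification failures, i.e. missing calls; no
maximum-likelihood null-frequency estimation is attempted. Loci whose
missing-call proportion exceeds a threshold (default **0.10**) are dropped
before analysis. The threshold is a conventional cutoff: in marker panels
of this kind the observed proportions cluster either at a few percent
(sporadic dropout) or above ~35% (systematic nulls), so any value between
separates the two regimes; 0.10 is configurable.

Missing data are handled by **pairwise (per-locus) deletion** throughout:
each locus keeps its own non-missing sample size n.

## Diversity

For allele frequencies p_i over the n non-missing calls at a locus:

* gene diversity h = 1 − Σp_i²;
* unbiased expected heterozygosity H_E = h·n/(n−1). The correction uses
  the haploid sample count n (individuals), not 2n: each individual
  contributes one allele.
* effective allele number N_e = 1/(1−h), equal to the allele count exactly
  when alleles are equifrequent.

Cross-locus summaries are reported as unweighted locus means ± SEM
(sample SD/√L). Group comparisons of per-locus indices (N_a, N_e, H_E,
private alleles) use Student's equal-variance two-sample t-test by default
(Welch available), treating loci as sampling units.

## Genotypic diversity

Individuals are grouped into multilocus genotypes by exact equality across
retained loci. **Missing matches nothing**, including another missing
call: an individual with any missing call is an unmatchable singleton.
This can never merge genotypes spuriously; the number of affected
individuals is logged. With f_x the number of genotypes occurring x times
in n individuals:

* G = 1/Σ[f_x(x/n)²] (inverse Simpson; effective genotype number);
* Ĝ = 100·G/N, the percentage of the sample-size maximum;
* E₅ = (G−1)/(e^{H'}−1), with H' the **natural-log** Shannon index (the
  convention E₅ inherits from its Simpson/Shannon effective-number
  definition); a single-genotype census is 0/0 and is returned as 1 by the
  equifrequency limit.

Genotype accumulation curves average distinct-genotype counts over random
locus subsets (default 100 per panel size), with an exhaustive option for
small panels.

## Linkage disequilibrium

Over all P = n(n−1)/2 individual pairs, m_{p,j} indicates a mismatch at
locus j (missing scores 0, tied with "equal", keeping the pairwise
distance additive over loci; affected pair counts are logged). With V_O
the variance of the pair distances and V_E = Σ_j var_j:

* I_A = V_O/V_E − 1;
* r̄_d = (V_O − V_E)/(2Σ_{j<k}√(var_j·var_k)) ∈ [−1, 1].

All variances are **population variances over the pair set**; mixing
variance conventions changes r̄_d, so this one is fixed. The permutation
null shuffles the non-missing calls of each locus independently among
their positions (missingness pattern preserved per locus), breaking
between-locus associations while preserving allele frequencies. The
p-value is one-sided upper-tail with the +1 correction,
(1 + #{r̄_d^perm ≥ r̄_d^obs})/(R+1); ties count as extreme. Default
R = 1000.

## Differentiation

Nei–Chesser small-sample estimators in haploid form (observed-
heterozygosity terms vanish; sample sizes count individuals):

* Ĥ_S = [ñ/(ñ−1)]·(1 − mean_k Σ p̂²_{ik}), ñ the harmonic mean
  subpopulation sample size at the locus;
* Ĥ_T = 1 − Σp̄_i² + Ĥ_S/(ñ·s), p̄ the **unweighted** mean of
  subpopulation frequency vectors.

Unweighted means follow Nei & Chesser's convention and keep unequal
samples from distorting the total; a consequence tested explicitly is that
duplicating the whole subpopulation panel leaves the uncorrected
diversities unchanged (merging a single pair of identical subpopulations,
by contrast, moves the unweighted mean and is *not* an invariant of this
dialect). Subpopulations with fewer than two non-missing calls at a locus
are excluded there, with s adjusted and logged.

Derived statistics: G_ST = (Ĥ_T − Ĥ_S)/Ĥ_T from the multilocus means;
N_m = 0.5(1−G_ST)/G_ST (reported infinite when G_ST ≤ 0); Δ_T = 1/(1−Ĥ_T),
Δ_S = 1/(1−Ĥ_S), their ratio and inverse; Jost's
D = [(H_T−H_S)/(1−H_S)]·[s/(s−1)] — from uncorrected diversities for D and
from the estimators for D_est(hap). The s/(s−1) factor uses the number of
subpopulations (the symbol n in the original formulation of D collides
with sample size; it is housed as s here). Raw, possibly negative
D_est(hap) is preserved in machine output and floored at 0 only in
rendered tables.

θ = (Q−q)/(1−q) pools identical-pair frequencies across loci and pairs
(Q within subpopulations, q between), rather than averaging per-locus
ratios — the dialect of the classic multilocus implementation. Note Q
excludes self-pairs, so under exact panmixia θ is slightly negative at
finite n, vanishing asymptotically.

## AMOVA

Squared distance between two haploids = number of mismatching loci (each
differing locus contributes 1), computed over co-typed loci without
rescaling. Sums of squares follow the Excoffier identity (SS of a set =
sum of squared pairwise distances / set size) over the nested hierarchy
groups ⊃ subpopulations ⊃ individuals; variance components solve the
expected-mean-square equations with the standard unequal-size
coefficients. Degrees of freedom are g−1, s−g, N−s; empty strata are
dropped before df computation. Negative components are reported as
computed and floored at 0 only in the rendered % column. Permutation
schemes per level: individuals among subpopulations regardless of groups
(Φ_ST), individuals among subpopulations within groups (Φ_SC), whole
subpopulations among groups (Φ_CT); p = (1 + #{≥ obs})/(R+1), default
R = 10,000 (reducible for testing).

## Minimum spanning network

The network is the union of all minimum spanning trees: edges processed in
ascending weight; within a weight class an edge is kept iff its endpoints
lie in different components as of the class start; components merge after
the class. An edge lies in *every* MST iff, contracting class-start
components, it is a bridge with no parallel kept edge; this is exported as
the `in_all_msts` flag. Inferred intermediate haplotypes are not
synthesized — that is a different algorithm (median-joining) — edge
weights carry the distance instead. Output ordering is deterministic
(nodes lexicographic, edges by weight then endpoints).

## Island-model simulator

Haploid Wright–Fisher demes; each offspring draws its source deme (own
with probability 1−m, else a uniform other deme), then either copies one
parent's full genotype (probability = clonality c) or inherits every locus
from an independently drawn parent — free recombination, appropriate for
unlinked markers and matching the null hypothesis of the r̄_d test.
Mutation is stepwise, ±1 repeat unit with equal probability (default
5×10⁻⁴ per locus per generation), keeping allele counts in the range
typical of microsatellite panels. Null-allele injection masks whole allele
classes in size-biased order until a per-locus target fraction is reached
(a true null tracks a primer-site mutation carried by an allele lineage);
a uniform missing-at-random mask can be added.

The survey-shaped preset emulates a 92-isolate, 12-locus survey across 11
trees × 2 age classes with one empty stratum (21 occupied subpopulations):
demes of census size 100 under m = 0.25 (Nm ≫ 1, effectively panmictic),
60 generations from founding spectra of 4–12 alleles per locus
(flat-Dirichlet frequencies), then per-stratum samples of 4–5 isolates.
Calibration across seeds places the median mean H_E near 0.74 (band
0.65–0.80) with ≥95% unique multilocus genotypes.

What the generator does **not** emulate: allele-size homoplasy structure
beyond the stepwise walk, linkage between markers, selection, demographic
change, spatially explicit dispersal (deme exchangeability is assumed),
and genotyping error other than dropout. Passing tests therefore
demonstrate correct statistical behavior under an idealized island model,
not the full complexity of field data.

## Problem sizes and test design

Property tests verify estimators against independent brute-force oracles
(pair enumeration, exhaustive spanning-tree enumeration, symbolic/linear
EMS solves) on exhaustive small instances, and regime signatures on
simulations: the panmixia checks use 22 demes of 200 at m = 0.3 (Nm = 60,
the order of the gene-flow regime where Jost's D falls below 0.02 — note
D ≈ G_ST/(1−H_S) amplifies small G_ST roughly four-fold at H_E ≈ 0.74, so
Nm ≥ 10 alone leaves equilibrium D near 0.1); the clonality power check
uses single demes of 92 at c = 1; monotonicity of G_ST in migration uses
8 demes of 12 over m ∈ {0, 0.01, 0.1, 0.3}; the equilibrium band check
uses 22 demes of 4 at m = 0.25 against G_ST ≈ 1/(1+2Nm). Permutation
replicates in tests are 99–199; library defaults remain 1000 (LD) and
10,000 (AMOVA).

## Known limitations

* H_E at loci retained with a few missing calls uses the per-locus
  non-missing n; panels computed with a fixed nominal n may differ in the
  third decimal.
* θ, G_ST and D_est(hap) are point estimates without bootstrap intervals
  (per-locus SEMs are reported instead).
* GenePop round trips encode the composite `tree:age_class` key in the
  individual label (the format carries only one stratification factor);
  CSV is the canonical two-factor format.
* The MSN tie rule is the union-of-all-MSTs construction; other network
  programs may break ties differently.
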
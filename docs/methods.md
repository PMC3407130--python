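# Methods

This note documents the models, numerical conventions and design choices
behind `ytopo`, and what the synthetic-data generator does and does not
emulate.

## Haplogroup model

The binary-marker phylogeny is a single rooted tree; ROOT is virtual and
collects profiles ancestral at every typed marker (label `Y*`). A call
is the deepest marker whose entire ancestor path is derived. Untyped
markers inside a derived chain are tolerated — the deeper derived marker
confirms the lineage — but when the deep markers themselves are untyped
the call truncates at the last confirmed derived marker. A derived
marker beneath a typed-ancestral ancestor, or derived markers on two
incompatible branches, make the profile *inconsistent*; the error lists
the conflicting marker pairs rather than guessing. A star is appended
exactly when the terminal marker has typed children and all of them are
ancestral; an untyped sub-marker therefore blocks the paragroup claim.

The shipped 27-marker tree follows the standard Y phylogeny for this
panel (E: M96 > M78; F: M89 > G/I/J/K; G: M201 > P15; I: M170 >
M253/P37/M223; K: M9 > L-M20, T-M70, P-M45; P > Q-M242, R-M173; R1a:
SRY_10831_ > M17; R1b: M343 > M269 > L23 > M412 > L11 > {U106, S116 >
{U152, M529}}). The recurrent assay SRY_10831_ is encoded at a single
position (the R1a branch, its second mutation event); profiles
contradicting that placement are reported inconsistent instead of being
resolved by back-mutation logic. A consequence worth stating: with the
deepest-derived calling rule, the number of theoretically
distinguishable haplo/paragroups is exactly one per marker position plus
the root paragroup — 28 for 27 single-placement markers, independent of
topology. (Placing the recurrent assay at both of its mutation events
would add one more by splitting the root paragroup.)

Close paternal relatives are collapsed before frequency work: records
sharing an identical haplogroup call, an identical full STR profile and
the same declared descent group keep only the lexicographically smallest
id. Records without a descent group are never collapsed. The operation
is idempotent.

## Frequency tables and tests

Per group, counts become relative frequencies with modified-Wald
(add-2-successes/add-2-failures) 95% intervals: p̃ = (x+2)/(n+4),
p̃ ± 1.96·√(p̃(1−p̃)/(n+4)), clamped to [0, 1]. Frequencies below the
informative threshold (default 5%; *exactly* 5% still counts as
informative) are flagged. Report-table rounding is one decimal, half
away from zero. Group contrasts use Fisher's exact test (two-sided,
hypergeometric-enumeration semantics; delegated to scipy and verified
against full enumeration for every table with total ≤ 40 in the test
suite). Multiple-testing correction offers BH step-up, BY (default — the
FDR variant that stays valid under arbitrary dependence, which is the
conservative choice for haplogroup counts that share one denominator)
and Bonferroni, via statsmodels.

## Y-STR preprocessing

DYS389II is a concatenated read containing DYS389I, so DYS389b =
DYS389II − DYS389I is derived first (missing if either side is missing;
non-positive differences are an error, not data). Numeric haplotypes
live on a fixed 15-locus panel (DYS385 removed, DYS389b in place of
DYS389II). Partial repeats convert as x.y → x + y/u with u the repeat
unit length (DYS392 is a trinucleotide, DYS438 penta-, DYS448 hexa-, the
rest tetra-); y ≥ u is an error. Loci observed duplicated are missing in
every computation. Pairwise statistics run over the intersection of
non-missing loci without rescaling. On the 17-locus panel DYS385 is
compared as an unordered pair under the pairing that minimizes the
number of differing positions ({11,14} vs {11,15} = 1 difference,
{11,14} vs {12,15} = 2). "Multi-step neighbor" means an absolute
difference of ≥ 2 repeat units at a compared locus — the natural cutoff
contrasting with single-step mutation, fixed here because no explicit
threshold is conventional.

Diversity: H = n(1 − Σp²)/(n−1) over haplotype frequencies (unbiased
gene diversity applied to whole haplotypes), D = k/n. The dispersion
contrast between two groups is a label permutation test on the absolute
difference of group mean pairwise statistics with P = (b+1)/(m+1); a
Welch t-test on the per-pair values is available for comparison but the
permutation test is primary because pair values within a group are not
independent.

## ΦST (AMOVA)

Two-level decomposition from squared inter-haplotype distances (default
metric: sum of squared repeat-length differences, which is what the
repeat-block conversion exists for; count-of-differing-loci available as
a sensitivity check): SS_total = (1/2N)ΣΣd², SS_within =
Σ_k (1/2n_k)ΣΣ_within d², variance components via MS_among/(K−1),
MS_within/(N−K) and n′ = (N − Σn_k²/N)/(K−1), ΦST = σ²_a/(σ²_a +
MS_within). Negative estimates are reported as computed (an unbiased
estimator fluctuates below zero under the null); a display clamp exists
in the pipeline's PCoA embedding only. Permutation P shuffles
individuals across groups, (b+1)/(m+1), with the default 5,000
permutations for pairwise distances.

## Shannon mutual information

ˢH_UA = H_pooled − Σ_k (n_k/N)·H_k with plug-in entropies in nats. The
default treats the whole haplotype as one allele; a per-locus-averaged
mode exists because group-comparison software in this field computes
per-locus. The two modes are not comparable with each other — use one
consistently. The quantity is ≥ 0 and equals 0 exactly when the
empirical distributions coincide.

## PCoA

Gower double-centering of −½D², symmetric eigendecomposition,
coordinates = eigenvectors scaled by √λ for positive eigenvalues
(threshold max(1e-8, 1e-8·λ₁)). Negative eigenvalues (non-Euclidean
input, e.g. ΦST matrices) are reported but excluded from variance
fractions, which are relative to the positive-eigenvalue total. The
implementation is deliberately self-contained and is cross-checked
against scikit-bio's PCoA in the tests.

## Spatial autocorrelation

Squared genetic distances between individuals are Gower-centered into C;
geographic separation between individuals is the road distance between
their municipalities at the configured generation level (0 within a
municipality — road distances, because straight lines are meaningless
across alpine ridges; the matrix is an input, no geodesy is done).
Pairs are binned by the even-pair-count scheme by default (k = 6 classes;
the class count is a package choice, no canonical value exists), with
ties broken by stable pair order and larger classes first; fixed km
edges are supported. Per class, r(h) = Σ_{x≠y∈h} c_xy / Σ_x m_x(h)·c_xx.
The null distribution relocates individuals by permutation (default
9,999) giving a 95% envelope and one-sided P per class (sign-mirrored
for negative r); bootstrap resampling of pairs within a class (default
9,999) gives CIs. Overall significance uses ω = Σ_h r(h)², P =
(b+1)/(m+1) against the joint permutation replicates. The ω statistic is
this package's documented choice of heterogeneity test; it is
seed-reproducible and replayable from the stored replicate matrix.

## Toponym density and regionalization

Density per grid cell center = points of one etymon class within a
*closed* disc of radius R (default 10 km), divided by πR². Cell size
defaults to 1 km — well below R, so surfaces are stable; the grid covers
the point bounding box expanded by R. Region classification compares the
Romance and Slavic surfaces at each municipality: A if Romance exceeds
Slavic by more than the margin, B for the reverse; ties fall back to a
fixed municipality→region table when provided and are otherwise flagged
unresolved. The original study assigned regions by expert inspection of
the maps; the explicit rule (margin + fallback) makes that step
auditable. Germanic-class points never enter the classifier.

## Synthetic-data generator

The generator's defaults are the study conditions: 29 municipalities in
two spatial clusters ~50 km apart edge-to-edge region A to region B
centers, sample sizes summing to 35 (region A) and 235 (region B) with
one dominant town of 99, plus 17 planted paternal relatives (287 drawn →
270 retained); 853 pasture-name points at 606/145/102
(Germanic/Slavic/Romance ≈ 71/17/12%), Germanic uniform over the study
box, Slavic/Romance as Gaussian clusters (σ = 6 km) around region-B/-A
municipalities; haplogroup founder frequencies per region including
region-restricted clades (R-M17 at 16% in B, absent in A; R-S116* B-only;
E-M96* A-only); per-locus per-generation stepwise mutation rate μ =
2×10⁻³ (the typical Y-STR rate) over G = 50 generations — roughly the
~1,500-year depth of the settlement history being emulated, which
produces within-haplogroup mean pairwise differences of a few loci,
matching the observed order of magnitude. Mutations are symmetric
single-step by default; a two-step jump option (p = 0.05) exists to
exercise the multi-step statistic. Founder haplotypes are the modal
Yfiler-like base vector plus a label-seeded offset of up to ±3 repeats
per locus, overridable for controlled-divergence experiments.

Migration: grandfathers sit at their sampled home municipality; each
generation step moves with probability 0.3 to a municipality chosen with
exponentially distance-decaying weight (scale 10 km road distance).
This keeps migration mostly local — a few percent of lineages cross
regions over two generations — consistent with the short documented
migration distances in this kind of study population. Road distances
are Euclidean × 1.4 (a valley-network detour factor; no road graph is
simulated). SNP profiles are generated noiselessly from the true
haplogroup.

What the generator does **not** emulate: deep coalescent structure
within haplogroups (founder + star-shaped descent only), genotyping
error, null/duplicated-allele chemistry, surname evolution, real
municipality geography or road networks. Tests passing on synthetic data
therefore demonstrate the statistics' correctness and calibration under
a known truth, not the historical conclusions themselves.

## Numerical conventions

Permutation P values always use (b+1)/(m+1). Comparisons against
observed statistics carry a 1e-12 slack so exact ties count as
"at least as extreme". All stochastic stages take explicit seeds; a
pipeline run is byte-reproducible given config + inputs. Distance-matrix
symmetry is enforced on read by averaging when the asymmetry is within
0.1 km and rejecting otherwise. Missing table values are empty cells or
`NA`; an explicit allele 0 is rejected as an error rather than silently
treated as missing.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the statistics at the
study's own scale where that is cheap (270-record studies, 853-point
densities) and at reduced permutation/replicate counts where full-scale
resampling adds nothing to the property under test (e.g. 199-permutation
nulls across 200 replicates for calibration checks, 999 permutations in
the acceptance script's end-to-end run). The defaults wired into
`AnalysisConfig` remain the full 5,000/9,999 resampling counts.

## Known limitations

* The fixed-table region fallback ships without a canonical table; real
  municipality assignments must be supplied by the user.
* ΦST assumes the squared-distance metric captures mutational distance;
  for strongly non-stepwise loci the count metric may be preferable.
* The ω overall test and the even-pair-count class scheme are package
  choices where the field's software leaves the construction unstated;
  both are documented and reproducible rather than canonical.
* Haplogroup calling does not model back-mutation or marker recurrence
  beyond the single-placement convention described above.
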
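# Methods

## The DDAG model

All models scored by this package are *direct DAGs* (DDAGs): Bayesian
networks over n ternary SNP variables and one binary disease variable D in
which the only edges point from SNPs into D. A DDAG is identified with D's
parent set, so the model space has 2^n members and exhaustive scoring of all
parent sets of size k_min..k_max is feasible for the panel sizes the package
targets (counts are exact integers via `count_parent_sets`). The DDAG
restriction encodes the working assumption that we care about SNP–phenotype
dependence, not about dependencies among SNPs; correlations between SNPs
(linkage disequilibrium) are *not* modelled.

Sufficient statistics for a family are the counts s_jk of child state k
under joint parent state j; joint states are indexed in mixed radix with the
lowest SNP column index most significant, a fixed convention that makes
every reported score reproducible bit for bit.

## Scoring criteria

**Bayesian (K2, BDeu).** The marginal likelihood of one family under
Dirichlet priors is computed in natural-log space through log-gamma
functions (the underlying product over states underflows for realistic m).
K2 sets every pseudo-count to 1; BDeu(α) sets a_jk = α/(r·q), which makes
Markov-equivalent structures score equally and gives α the interpretation of
a prior equivalent sample size. Two independent oracles certify the
implementation in the test suite: the sequential (prequential)
Dirichlet-multinomial predictive product, and the fact that the marginal
likelihoods of the two-family SNP→D network sum to exactly 1 over the space
of all possible datasets of a given size.

Because every SNP is a root node in a DDAG, a SNP family's term is the same
number in every model, and the sum of all n SNP terms is a model-independent
constant. Model comparison therefore uses the disease family alone. This is
not merely an optimisation: adding root-family terms only for the k parent
SNPs would charge each parent roughly its m·H(SNP) data cost (about 10^3
nats at m = 1600), a spurious penalty that no epistatic signal could
overcome and that would force every criterion to select single-SNP models.

**MDL.** score = structure penalty (bits) + m·H(D | parents) encoding bits,
estimated from the data; lower is better. The binary disease node has 3^k
free parameters, each ternary SNP has 2. Penalty variants:

| variant  | disease term            | per-parent-SNP term (version 2) |
|----------|-------------------------|---------------------------------|
| `suzuki` | (3^k/2)·log2 m          | (2/2)·log2 m                    |
| `aic`    | 3^k                     | 2                               |
| `epi`    | (3^k/2)·log2(m/3^k)     | (2/2)·log2 m × 2 parameters → log2 m |
| `none`   | 0                       | 0                               |

The `epi` (BNMBL) penalty prices each disease parameter at the *expected
per-cell sample size* m/3^k instead of m, the refinement that adapts MDL to
the exponentially growing joint parent state space. When m < 3^k the
disease term goes negative; the package permits this but emits a
`RuntimeWarning`. Version 1 includes only the disease-node penalty (the SNP
penalties are constant when all n SNPs are considered part of the model);
version 2 adds the k parent SNPs' parameter bits. The version split affects
penalties only — all variants and versions encode the data identically,
through the disease family. The `aic` penalty is implemented as Σ d_i (one
bit-unit per free parameter); its upstream printed form was not available,
so this standard form is adopted deliberately.

**MML** is implemented as the K2 score converted to log2 units minus
(d/2)·log2 m penalties (version 1: disease node only; version 2: plus the
parent SNPs) — i.e. K2 with an explicit structure penalty. The MML-minus-K2
offset is a closed form checked exactly in the tests.

**Ranking.** Exhaustive search orders models by the criterion's orientation
with deterministic tie-breaks: smaller parent set first, then lexicographic.
Scoring is vectorised per subset size and shares the sufficient statistics
across criteria, so multi-criterion sweeps cost little more than one; the
ranking is independent of batching.

## Two-stage anchored screen

For panels too large for direct exhaustive search, stage 1 scores every
2-parent model pairing a fixed anchor locus (e.g. a known risk factor) with
one other SNP and keeps the non-anchor members of the `top_m` best pairs;
stage 2 exhaustively scores all 1..k_max-parent models over the retained
pool plus the anchor. The same criterion is used in both stages by default.

## Simulator

`build_pure_epistasis_model` constructs 3×3 penetrance tables f with
*exactly* zero marginal effects: the deviation e = f − K is drawn from the
orthonormal basis of the 4-dimensional null space of the six
Hardy–Weinberg-weighted marginal constraints, then rescaled so the
broad-sense heritability

    h² = Σ_ab p_a p_b (f_ab − K)² / (K(1−K))

hits its target exactly (this variance-ratio definition for a dichotomous
penetrance model is the standard one and is adopted explicitly). Draws whose
rescaled table would leave [0, 1] are rejected and redrawn. The prevalence K
is chosen per draw from a fixed grid as the feasible value closest to 0.5:
high-heritability targets at rare alleles (h² = 0.4 at MAF 0.2) are
infeasible at K = 0.5 but straightforward away from it. Construction is
deterministic given the seed, and infeasible targets raise an error naming
the best attainable value.

The default study grid crosses seven heritabilities (0.01, 0.025, 0.05,
0.10, 0.20, 0.30, 0.40) with two minor allele frequencies (0.2, 0.4), 18
noise SNPs, 1:1 case-control ratio, and sample sizes 200–1600. The exact
penetrance tables of the original benchmark collection are not public, so
the generator reproduces the *design parameters*, not those tables;
experiment outcomes therefore replicate orderings and shapes, not exact
counts.

Sampling is retrospective and exact: case genotype pairs come from
P(a,b | case) ∝ p_a p_b f_ab, controls from p_a p_b (1 − f_ab), so the
requested case/control counts hold by construction (no rejection step).
Noise SNPs are independent Hardy–Weinberg draws (MAF defaulting to the
functional MAF), and the two functional columns are placed at
seed-randomised positions reported as ground truth. Features of real data
the simulator does **not** emulate: linkage disequilibrium, genotyping
error, missingness, covariates and population structure — passing tests
certify behaviour under the idealised design only.

## Evaluation harness

A criterion *correctly learns* a dataset when its top-ranked parent set
equals the generating pair exactly; *recall* is |S∩T|/|S| against the
top-ranked model only. Paired criteria are compared by the McNemar
chi-square test on the discordant counts; the continuity correction is
applied by default (the choice is exposed), and the corrected p agrees with
the exact binomial sign test to <0.02 for b+c ≥ 30 in seeded sweeps. Marker
reports count how many of the top-n models intersect a marker set and how
many distinct markers appear, mirroring candidate-gene follow-up.

## MDR baseline

The comparison method is a deliberately minimal re-implementation of
Multifactor Dimensionality Reduction at the standard settings (10-fold
stratified CV, exhaustive 1..4-SNP combinations): training cells are
labelled high-risk when the case:control ratio reaches the overall ratio
(ties high; empty cells low; case-only cells high), and combinations are
ranked by held-out balanced accuracy, then CV consistency (folds won in the
within-fold training comparison), then size, then lexicographic order. Fold
assignment is seeded but keyed to a canonical row ordering, so results
depend on the data multiset, not on file row order. Permutation testing and
covariate handling are out of scope.

## Problem sizes and numerical choices

The shipped experiments run at desk scale, chosen so the full suite and the
reproduction script each finish in minutes on one core: the criterion
comparison uses 100 datasets (50 in the script) at n = 1600, h² = 0.4,
MAF 0.4 — the easiest study condition, where the directional orderings
(BDeu α=15 accuracy ≥ K2; recall at α=162 ≥ α=3) are expected to hold or
tie at ceiling — and the prior-strength sweep uses 50 datasets at n = 400,
h² = 0.1, MAF 0.4, a regime weak enough that α visibly controls selected
model size. Empty parent-state cells are handled naturally everywhere
(Dirichlet marginals through pseudo-counts; zero encoding bits under MDL);
q > m families are permitted. Scores are float64 throughout; counts are
exact integers.

## Known limitations

- Only DDAG structures are scored; SNP–SNP edges, structure priors other
  than uniform, and heuristic/MCMC search are out of scope.
- No missing-genotype support: rows must be complete.
- The simulator's zero-marginal constraint is exact; generators that allow
  approximately-zero marginals will produce slightly different data.
- MDR cell-tie conventions follow the standard published description; exact
  parity with any particular external implementation is not guaranteed.
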
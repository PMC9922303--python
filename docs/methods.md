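# Methods

## The model

`groupacc` tests whether a *group* of short genomic elements (typically
ChIP-seq peaks bound by one transcription factor) has evolved at an
elevated substitution rate on a chosen *foreground* lineage of a species
tree, relative to the remaining *background* branches. Pooling
information across a group is what makes *weak* acceleration detectable:
a 20% rate increase is invisible in a single 200 bp element but obvious
in the concatenation of hundreds.

All inference is anchored on a **reference model**: a fixed rooted
topology with branch lengths (expected substitutions per site), a
general time-reversible (GTR) substitution model (six exchangeabilities,
one fixed to 1; four stationary frequencies), and discrete-Gamma
among-site rate variation with K = 4 equal-probability categories whose
rates are bin means of Gamma(α, α), so the mean relative rate is exactly
1. The reference model is fitted by maximum likelihood to the
concatenation of *all* elements, on the assumption that most elements
are not accelerated; every subsequent test holds it fixed and estimates
only branch-length *scale factors*:

* **H0** — one global scale r applied to every branch;
* **Ha** — a foreground scale r1 (the clade's stem branch plus every
  branch inside the clade) and a background scale r2.

The group-level statistic is 2(log L(Ha) − log L(H0)), referred to
chi-square with 1 degree of freedom; a group is called accelerated when
the test rejects *and* r1 > r2. P-values across groups are
Bonferroni-adjusted. Likelihoods are computed by the pruning algorithm
with site-pattern compression; gaps, Ns, and partial IUPAC ambiguity
codes are marginalized as missing data (partially ambiguous codes sum
over their consistent states), and rate categories are mixed per column.

### Element-level inference and the mixture model

To estimate *how many* elements in a significant group are accelerated,
the same LRT is applied to each element separately. Per-element
chi-square p-values are unreliable at element scale (tens of
substitutions), so empirical p-values come from a group-calibrated
parametric bootstrap: the group's H0 fit supplies a global scale, B null
alignments are simulated under that calibrated model with lengths
resampled from the group's own element lengths, and
p = (1 + #{null ≥ observed}) / (1 + B). The pseudocount keeps p > 0,
which the mixture density below requires.

The group's p-values are then fitted with a beta-uniform mixture,

    f(x | a, λ) = λ + (1 − λ) a x^(a−1),   0 < a ≤ 1, 0 ≤ λ ≤ 1,

whose value at 1, π_ub = λ + (1 − λ)a, upper-bounds the fraction of
p-values generated under the null; 1 − π_ub is a conservative lower
bound on the accelerated fraction and (1 − π_ub)·n the implied
accelerated-element count. A 95% confidence interval for π_ub maps the
joint likelihood region {(a*, λ*): 2(l(â, λ̂) − l(a*, λ*)) ≤ χ²₂,0.95 =
5.991} through π*_ub = λ* + (1 − λ*)a*. The joint 2-df construction is
used as given; a 1-df profile would be narrower.

### Locating the rate shift

Rejecting H0 with a focal-tip foreground (e.g. human) does not say
*when* the acceleration happened. The lineage scan fits Ha once per
candidate foreground — the focal tip alone, then each monophyletic clade
containing it, excluding the whole tree (with every branch foreground,
r1 and r2 are not jointly identifiable) — and ranks candidates by
BIC = −2l + k·log(n) with k = 2 and n the number of alignment columns.
The best fit is the *minimum* BIC, with ties broken toward the smaller
(tip-ward) clade as the more parsimonious explanation. On the bundled
10-taxon tree a human focal tip yields exactly 7 candidates.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_species` | 5 | informative column: unambiguous A/C/G/T in ≥ 5 taxa |
| `min_informative` | 50 | minimum informative columns per element |
| `b_replicates` | 10 000 | bootstrap replicates per group |
| `k_categories` | 4 | discrete-Gamma categories |
| scale bounds | [1e−4, 1e3] | box for all scale optimizations |
| `element_length` | 200 bp | simulator default (median element length) |

## The synthetic-data generator

`simulator` draws each column i.i.d.: a Gamma category (uniform over the
K categories), a root base from the stationary frequencies, then
evolution down the tree with P(branch · scale · rate). Three scenarios
reproduce the ways group data depart from the null: (1) every element
fully accelerated; (2) a fraction L of each element's columns
accelerated (placed contiguously at the element start — placement is
irrelevant to an i.i.d.-column likelihood but contiguity mimics a
motif); (3) a fraction M of elements accelerated. Eight cases name the
accelerated lineage: human; Hominini; African apes + human; great apes +
human; and the controls chimp, gorilla, orangutan, macaque. One RNG
stream per element is derived from (seed, element index), so growing a
group never perturbs existing elements.

The bundled fixture is a 10-taxon primate tree (human, chimp, gorilla,
orangutan, macaque, baboon, marmoset, tarsier, mouse_lemur, bushbaby)
with hand-set branch lengths at plausible neutral primate depths (total
tree length ≈ 0.65 substitutions/site, human terminal 0.0066). The
fixture GTR uses a transition/transversion asymmetry typical of
mammalian noncoding DNA (AG and CT roughly four-fold the transversions)
with mildly AT-rich composition, and α = 1.5 — moderate rate variation,
between the strong heterogeneity of coding DNA (α < 0.5) and rate
homogeneity. The generator emulates independent, indel-free, fully
observed columns; real alignments add alignment error, indels, missing
species, GC-biased gene conversion, and within-element rate
autocorrelation, none of which is simulated. Passing tests therefore
validate the inference machinery under its own model assumptions, not
robustness to alignment artifacts.

## Numerical choices

* Transition matrices come from one symmetrized eigendecomposition of Q
  per model (exact for reversible models), so each likelihood
  evaluation builds all branch-by-category matrices with two small
  matrix products; partial likelihoods are rescaled per node to avoid
  underflow.
* H0 scale: 15-point log-spaced grid on [1e−4, 1e3], then bounded Brent
  refinement in the bracketing interval. Hitting a grid end is reported
  as non-convergence (e.g. an invariant alignment drives r to the lower
  bound).
* Ha scales: L-BFGS-B on (log r1, log r2) started at the H0 scale, with
  extra starts at half and twice it for group-level fits (the surface
  can be flat in r1 when the foreground is short). Element-level fits
  use the single start — the bootstrap applies the identical optimizer
  to observed and null elements, so any small optimization bias cancels
  in the empirical p-value. The alternative log-likelihood is floored
  at the null's (the models are nested), and negative LRT statistics
  from round-off are clipped to 0.
* Reference-model fitting cycles coordinate blocks (branch lengths |
  GTR | α) until the log-likelihood improves by < 1e−3.
* BUM fitting seeds L-BFGS-B from the top points of a 50×50 grid (the
  surface has a boundary ridge at λ → 1); the CI uses a 200×200 grid
  with 4× refinement around the retained region's boundary.
* BIC ties resolve to the first (smallest) candidate clade via stable
  argmin.

## Validation design and problem sizes

The validation suite runs every method at desk scale: the pruning
engine is checked to 1e−9 against exhaustive enumeration over internal
states on all 124 rooted binary topologies with ≤ 5 tips; null
calibration uses 500 elements × 100 bp with B = 999; fold recovery uses
300 elements × 200 bp at folds 1.2–5; mis-specification controls run
200 replicate groups of 20 elements × 100 bp per control case; the
mixture analysis uses 500 elements × 200 bp per M cell; the lineage
scan uses 10 replicates of 300 elements × 200 bp. These sizes were
chosen as the smallest at which the statistical properties under test
are clearly resolved.

## Known limitations

* **Per-element chi-square is conservative at short lengths.** With a
  human-only foreground a 100 bp element carries < 1 expected
  foreground substitution; the chi-square rejection rate runs at
  2–3% for a nominal 5%. This is precisely why element-level inference
  uses the bootstrap, whose p-values are uniform under the null.
* **Bootstrap resolution bounds the mixture's accuracy in
  strong-signal regimes.** Empirical p-values cannot go below
  1/(B + 1); when the foreground signal is strong, accelerated
  elements pile up at that floor, and the x^(a−1) term of the mixture
  fits the atom, so π̂_ub loses its upper-bound property and
  (1 − π̂_ub)·n can *over*-count (observed: ≈ +37% at a true fraction
  of 0.2 with fold 3 on Hominini, B = 999). Conversely, with weak
  signal the estimate is the conservative lower bound it is designed to
  be and undershoots large true fractions. Counts are therefore most
  trustworthy at moderate signal, and raising B tightens the floor.
* The fitted group fold under partial acceleration converges to the
  weighted average L·f + (1 − L) (or M·f + (1 − M)), not to the raw
  fold f; `weighted_fold_estimate` exists to move between the two
  scales.
* The two-class scaling cannot represent more than one rate shift per
  tree, and the scan's nested candidates assume the shift happened on
  the focal tip's own history.
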
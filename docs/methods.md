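# Methods

This note documents the models implemented in `pedconnect`, the parameters
that matter, the numerical choices, and what the synthetic-data generators do
and do not establish.

## Pedigree model

A pedigree is a table of animals with sire/dam links, sex, birth year and
flock.  Internally animals are held in a canonical topological order
(parents before offspring, ties broken lexicographically by id, so parsing
is invariant to input row order) with integer parent indices; −1 denotes an
unknown parent.  Unknown parents are treated as unrelated, non-inbred
founders everywhere.  No unknown-parent groups are fitted: the intended
mitigation for missing ancestry is the pedigree-quality gating of the
reference population, not genetic groups, and the two should not be mixed
silently.

Parents referenced without a row of their own become founder placeholder
records (sex inferred from the role).  Cycles, dual-role parents (an id used
as both sire and dam), sex-inconsistent parents and selfing are validation
*errors* (sheep are dioecious); offspring born no later than a parent is a
*warning* only, because historic data contain year gaps and year-windowed
analyses simply exclude animals with unknown years.

## Quality metrics

For animal *i* and generation *g* there are 2^g ancestor slots; an ancestor
occupying several slots (inbreeding loops) counts once per slot.

* completeness a_g = known slots / 2^g;
* NEG = Σ_g (known slots at g)·(1/2)^g, computed with no depth cap by a
  single topological pass NEG_i = Σ_{known parents p} (1 + NEG_p)/2;
* NFG = largest g with every slot known up to g; NMG = longest known path;
* PCI = harmonic mean of the side completenesses C_f and C_m, where the
  parent occupies generation 1 of its side and its own ancestors shift one
  generation deeper; C = (1/d)Σ_{i≤d} a_i with **d = 5 generations by
  default** (configurable, `--pci-depth`).  The depth is a convention — the
  index family does not fix it — so it is exposed rather than hidden.  A
  missing parent gives side completeness 0 and hence PCI = 0.

Distribution tables use left-closed bins (last bin closed), percentages
rounded to 2 decimals per row, and a cumulative column that accumulates the
rounded values, so its last entry is 100 only up to rounding — matching how
such tables are conventionally printed.

## Relatedness

F is computed by the Meuwissen–Luo ancestor traversal (exact, O(ancestors)
per animal, inbreeding-aware Mendelian sampling variances
d_i = 0.5 − 0.25(F_s + F_d), with 0.75 − 0.25F_p / 1 for one/no known
parent).  A⁻¹ is assembled sparsely by the Henderson/Quaas rules with those
d_i.  Kinship submatrices are obtained by solving A⁻¹x = e_j with one sparse
LU factorisation per query set and halving: exact to solver precision,
O(n·|subset|) memory, and equal to the tabular recursion (which the test
suite keeps as an independent oracle).  The kinship matrix is symmetrised
after the solves to remove round-off asymmetry (~1e−16).

The generation interval is the mean mid-parent age over offspring with both
parental birth years known (default); a four-pathway variant (mean of
parent-age means within sire/dam × son/daughter pathways) is available
because the two conventions differ in unbalanced data.

## Effective population size

The per-pair rate of coancestry increase is
ΔC_ij = 1 − (1 − C_ij)^(2/(g_i + g_j)) with g the *equivalent complete
generations* (NEG) of each member — NEG is used for g even when the
reference population is gated on NFG, because the rate normalisation is
defined in terms of equivalent generations.  Ne = 1/(2·mean ΔC) over all
unordered distinct pairs; self-pairs are excluded; members with NEG = 0
carry no rate information (the exponent is undefined) and are dropped from
the pair set, while the window's mean F averages over *all* members.
mean ΔC = 0 reports Ne = ∞ rather than failing.

Sliding windows have a fixed calendar length (default 4 years ≈ one
generation interval), slide by a configurable step, and are labelled with a
1-based generation index that is also the trend regressor — making the ΔNe
and ΔF slopes per-generation rates rather than per-year ones.  Trends are
ordinary least squares with the two-sided t test on n − 2 df; a perfectly
collinear series returns SE = 0 with p = 0 (p = 1 when the line is flat),
and fewer than 3 usable windows yields no trend.  Windows whose gated
membership is too small are reported as NaN rows and skipped by the
regression.

## Connectedness

Animal model y = Xb + Zu + e with one fixed-effect level per management
unit and **no separate intercept** — the fixed block is then full rank and
the coefficient matrix positive definite, so no identifiability constraint
is needed; a test verifies that the animal block C²² agrees with a dense
pseudoinverse of a deliberately rank-deficient system (redundant intercept).
All pedigree animals occupy the random block whether or not they carry
records, so non-recorded relatives transmit links.  Repeated records per
animal are allowed; no permanent-environment effect is fitted, a documented
simplification (connectedness here characterises the design, not the full
evaluation model).

Variance parameters default to h² = 0.3 (λ = (1 − h²)/h² ≈ 2.33) and
σe² = 1, so PEVD is reported in σe² units; any apparent [0, 1] range of
PEVD is parameterisation-dependent, not intrinsic.  Both are configurable
and echoed in output headers/manifests.

With P = C²²σe² over the distinct recorded animals and unit index sets S_i:

* **PEVD_ind(i,j)** = mean over S_i×S_j of PEV_k + PEV_l − 2·PEC_kl;
* **PEVD_group(i,j)** = 1'P_ii1/n_i² + 1'P_jj1/n_j² − 2·1'P_ij1/(n_i n_j),
  the exact prediction error variance of the difference of unit-mean EBVs.
  This uses a minus sign on the PEC term — the only reading that is a
  variance and vanishes for a unit against itself — and keeps the
  within-unit PEC terms that a loose "mean PEV + mean PEV − 2 mean PEC"
  reading would drop;
* **CD(i,j)** = 1 − λ·Σ(C²²_kk + C²²_ll − 2C²²_kl)/Σ(K_kk + K_ll − 2K_kl)
  over cross pairs, K = 2·kinship the relationship matrix (identically
  1 − ΣPEVD/(σu²ΣK-terms); the suite checks both routes agree to 1e−10).
  Same-animal pairs contribute zero to both sums; units that are literal
  clones of one another have zero relationship variance and are rejected;
* **r(i,j)** = 1'P_ij1/√(1'P_ii1·1'P_jj1): the correlation of unit-mean
  prediction errors, with diagonal exactly 1 and entries in [−1, 1].
  Benchmarks: r̄ ≥ 0.05 "good", ≥ 0.10 "superior", else insufficient for
  unbiased across-unit ranking.

Per-unit and overall summaries average off-diagonal entries only (diagonal
self-pairs are computed but describe within-unit quantities).  PEV/PEC are
obtained by sparse-LU column solves of the coefficient matrix for the
recorded animals; for structurally disconnected units the solves cannot
propagate across components, so cross-unit PEC is *exactly* zero, not
merely small.

## Synthetic data

**Flock scenario** (defaults are the stated world): 14 performance-recorded
flocks of 30 ewes + 2 breeding rams over 12 years; ewes lamb with
probability 0.9/year; a lamb's sire comes from another (uniformly chosen)
flock with probability `migration_rate` (default 0.1); breeders enter at
age 2 and are culled with hazard 1/(mean_parent_age − 1), putting the
generation interval near the 3.8-year target (realised ≈ 3.7); parent links
of cohorts older than 4 years are deleted with probability growing 8 % per
year of age (capped 0.9), reproducing the steep completeness decay of
recently established recording.  Records go to ewes of the recorded flocks
born in the last 5 years.  What the generator does **not** emulate:
selection (rams are drawn uniformly), phenotypes and genetic trend, flock
size heterogeneity, and the ~100 non-recorded flocks of a real breed —
green tests therefore establish the correctness of the estimators under the
stated structure, not breed-specific magnitudes.

**Idealized scenario**: discrete generations, constant census N, equal sex
ratio, each offspring drawing sire and dam uniformly (Poisson-equivalent
family sizes); realised Ne ≈ N.  Because the population is dioecious, mean
inbreeding follows the coancestry of the *previous* generation: the exact
recursion for this mating system agrees with 1 − (1 − 1/2N)^(t−1)
(founders = generation 0) to ~1e−3, and the tests use that lagged closed
form, comparing at the trajectory level (per-seed mean deviation vs its
across-seed standard error) because within-seed deviations share one drift
path and per-generation SE estimates from 5 seeds are unstable.

All draws flow through a single `numpy.random.Generator`; the same seed
gives byte-identical output.

## Known limitations

* No genomic (SNP) relationships or genomic connectedness.
* No unknown-parent groups; severely incomplete pedigrees must be handled
  by gating, not grouping.
* Kinship queries are dense in the subset size (fine to a few thousand
  animals per reference population).
* The connectedness model fits a single trait with unit fixed effects only;
  contemporary-group structures finer than the flock are not expressed.
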
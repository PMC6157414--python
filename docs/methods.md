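# Methods

## Model and estimation

The pipeline fits the single-trait animal model `y = Xb + Z1 a + Z2 w + e`
with a correlated additive effect (`Var(a) = H σ²ₐ`), an i.i.d. full-sib
family effect capturing shared rearing environment (`Var(w) = I σ²_w`),
and i.i.d. residuals. Fixed effects are treated as categorical with
reference-level (drop-first) coding plus an intercept; a rank check rejects
confounded factor sets. The animal vector spans the whole pedigree, so
animals without phenotypes (e.g. non-genotyped ancestors) contribute
through the relationship structure and receive GEBVs.

### Relationship matrices

* **A** — tabular method over the topologically ordered pedigree.
* **F** — Meuwissen–Luo ancestor recursion; equals `diag(A) − 1` exactly,
  and feeds the Mendelian-sampling variances `Dᵢ = 0.5 − 0.25(F_s + F_d)`
  (unknown parents enter as F = −1) of Henderson's sparse A⁻¹ rules.
* **G** — `Z D Z′ / k`, `Z = M − 2p` centered at the observed ("current")
  post-QC allele frequencies, `D` the per-SNP weights rescaled to mean 1
  each iteration so that `k = Σ 2pq·d` stays on the unweighted Σ2pq scale
  across weight iterations, keeping λₐ comparable between iterations. No
  base-population frequency estimation is attempted.
* **Blending** — `G_b = 0.95·G + 0.05·A22` by default. Centering at
  observed frequencies puts the all-ones vector in G's null space, so
  unblended G is always singular in practice; blending (not scale-tuning)
  restores invertibility. α is config-exposed.
* **H⁻¹** — `A⁻¹ + [0 0; 0 G_b⁻¹ − A22⁻¹]`, stored sparse with a dense
  correction confined to the genotyped block. With `G := A22` this
  collapses to `A⁻¹` and the whole fit reduces to pedigree BLUP, which the
  test suite checks to 1e-8.

Dense Cholesky factorizations are used for the genotyped-block inverses
(intended scale: up to a few thousand genotyped animals); only A⁻¹ and H⁻¹
are sparse.

### REML

Variance components (σ²ₐ, σ²_w, σ²ₑ) are estimated by average-information
REML on the phenotyped animals' covariance `V = σ²ₐ K + σ²_w Z2Z2′ + σ²ₑ I`
with `K` the phenotyped block of `H = (H⁻¹)⁻¹`. Each round takes a Newton
step with the AI matrix; the step is halved (up to 5 times) if it would
leave the positive orthant or decrease the restricted likelihood, components
driven non-positive are pinned at a floor of 1e-10·var(y), and if no AI
step is acceptable the round falls back to the EM fixed point
`θᵢ ← θᵢ·(y′PVᵢPy)/tr(PVᵢ)`, which preserves positivity and does not
decrease the likelihood. Convergence: max relative change < 1e-8 or 50
rounds; components pinned at the boundary are excluded from the convergence
check (their relative change never settles). Initial values are equal
thirds of the phenotypic variance. Components are estimated once, on the
iteration-1 (flat-weight) relationship matrices, and held fixed across
weight iterations; per-iteration re-estimation is available but off by
default.

An identifiability caveat found while validating the null behaviour: with a
single record per animal and only full-sib families of unrelated parents,
the additive covariance K is exactly collinear with the family-plus-residual
structure (`K = 0.5·J_fam + 0.5·I` on such data) and σ²ₐ cannot be
separated. Null-recovery experiments therefore use two-generation
pedigrees, where cross-generation relatedness identifies the component.

### Association scan

Per iteration: back-solve `û = D Z′ G_b⁻¹ â_g / k` (same Z, D, k, G as the
fit — with unblended G this reproduces `Z û = â_g` exactly), update weights
`dⱼ = ûⱼ²·2pⱼqⱼ` rescaled to mean 1 (raw weights are logged; an all-zero
raw vector falls back to flat weights), rebuild G/H⁻¹, re-solve. Two
iterations by default; iteration 1 is bit-identical to standard ssGBLUP.

Windows are index-based runs of 50 adjacent SNPs (never base-pair spans),
sliding by 1 SNP, confined within chromosomes; a chromosome shorter than
the window yields one shorter window flagged as a tail. A window's
percentage is `Var_i(Σⱼ z_ij ûⱼ) / σ̂²ₐ × 100`; the alternative denominator
`Var(total DGV)` is selectable (`denominator="dgv"`) and self-normalizes —
one genome-wide window is exactly 100%. Ranking sorts by percentage with
ties broken by (chromosome, start position); windows at or above 1% are
flagged.

## Quality control

Filter order is fixed and logged: SNP call rate → animal call rate → MAF →
HWE, each recomputed on the surviving matrix, and the pass is idempotent.
Keeps: call rate ≥ 0.90 on both axes (inclusive boundary), MAF strictly
> 0.05, HWE deviation strictly < 0.15. The HWE statistic is the
heterozygote-frequency deviation `|obs_het − 2p(1−p)|` — the standard
chip-QC reading; a literal "observed minus expected allele frequency" is
degenerate because the expected frequency is estimated from the same
counts. Missing genotypes are mean-imputed to 2p after QC, which leaves
column means unchanged so imputed cells contribute nothing to the centered
Z.

## The synthetic population

The generator emulates the statistical structure of a two-year-class
growth-selected trout line; defaults (all config-exposed):

| parameter | default | rationale |
|---|---|---|
| families × offspring | 98 × 4, 2 generations | ~784 phenotyped fish in ~196 families, matching the ~878 fish / ~197 family scale |
| SNPs | 10 chromosomes × 500 | scaled-down stand-in for the ~35K post-QC panel |
| trait mean / SD | 48.91 / 2.42 | fillet yield, percent of body weight |
| h² / c² | 0.40 / 0.10 | moderate heritability plus tank common environment; h² is a chosen default, varied in tests, not an assertion about the real trait |
| founder LD | copy-probability 0.7 Markov chain | enough local LD for 50-SNP windows to localize QTL |
| founder frequencies | logit-AR(1), sd 1.7, autocorrelation 0.98 | mean founder MAF ≈ 0.25; high adjacent-allele correlation forces nearby marginals to be similar, hence the slow drift |
| QTL | 2 × 10% of σ²ₐ, MAF ≥ 0.10 | "a few large QTL" architecture; the MAF floor keeps planted QTL from being removed by the MAF filter, which would void recovery experiments |
| harvest groups | 5, cycling within family | one fish per family per weekly slaughter group; fixed-effect spread 0.2·σ_p |
| missing rate | 1%, uniform | applied after truth recording, so truth is complete |

Mechanics: discrete generations; the previous generation is shuffled and
split into disjoint sire/dam pairs (no selfing, no parent reuse within a
generation); gametes recombine under the Haldane model (Poisson crossovers)
with genetic positions given by physical order scaled to the chromosome
length in Morgans. The additive target is σ²ₐ = h²·σ²_p: each major QTL is
scaled on the phenotyped animals' realized genotype variance to its
configured share, and the remaining share is spread as random-sign
equal-variance effects over all other polymorphic SNPs (polygenic
background). With shares summing to 1 there is no background and the true
breeding value is exactly the centered-QTL dot product; `n_qtl = 0` means
no genetic signal at all. All draws flow from named sub-streams of one
seed, so stages can be re-run independently and outputs are byte-identical
under a fixed seed.

What the simulator does *not* model — and hence what passing tests do not
show about real data: selection and non-random mating across generations,
genotyping error, ascertainment bias of chip SNPs toward the phenotyped
line, sex effects/neomales, non-uniform missingness, and coalescent-shaped
LD decay (the Markov founder LD is locally calibrated but has no long-range
structure).

## Validation experiments and their sizes

Chosen to run comfortably on one CPU while leaving sampling noise small
relative to the assertion bands:

* **REML recovery** — 10 seeds, 150 families × 10 offspring (1500
  genotyped+phenotyped), h² 0.4 / c² 0.1, 2000 SNPs; mean σ̂²ₐ/σ²ₐ is
  asserted within [0.85, 1.15].
* **Null additive shrinkage** — 5 seeds, two-generation pedigree, no
  genetic signal; σ̂²ₐ ≤ 0.05·σ̂²ₑ expected in ≥ 4/5.
* **QTL window recovery** — 10 seeds, 200 families × 5 (1000 animals),
  2000 SNPs, two 10% QTL, 2 iterations. Overlapping ranked windows are
  reduced to non-overlapping peaks (greedy by rank); both QTL are expected
  inside top-3 peaks in ≥ 9/10 seeds, and the mean containing-window
  percentage within 10 ± 5.
* **Null window calibration** — same scale, no large-effect QTL (the 98%
  polygenic remainder spread genome-wide). The *unweighted* pass stays
  below 5% max window share (measured 2.0–3.6% over 10 seeds). The
  weighted second iteration inflates null noise peaks to ~6–11%: iterated
  û²-weighting amplifies whatever the first pass ranked highest, signal or
  noise. Both numbers are reported; window percentages from weighted
  iterations should be compared against a weighted-null reference rather
  than the nominal 1% threshold. A fully null genome (h² ≈ 0) is not used
  for calibration because REML pins σ̂²ₐ at the boundary and a percentage
  of a near-zero variance is meaningless.

## Numerical choices and degenerate inputs

* Matrices exposed as symmetric are symmetrized after construction
  (tolerance 1e-10 in tests); SPD inverses go through Cholesky with an
  explicit error advising a smaller blend α on singularity.
* MME solved by sparse LU by default; Jacobi-preconditioned CG (relative
  tolerance 1e-10) agrees to 1e-8 and is available for larger systems.
* Ties in window ranking: lower (chromosome, position) first. Tail windows
  are emitted and flagged, not dropped.
* A SNP with no observed calls gets frequency NaN and is removed by the
  call-rate filter; `'0'` is reserved for unknown parents and rejected as
  an animal id; an empty post-QC panel raises rather than propagating an
  empty matrix.
* PED/MAP import counts the file's minor allele (lexicographic tie-break),
  stores the allele pair in the map, and is stable under re-export from
  the first import onward.

## Known limitations

Desk scale only: dense genotyped-block algebra and a dense REML V limit
practical size to a few thousand genotyped animals (no APY/metafounders/
unknown-parent groups). Variance components are not re-estimated between
weight iterations by default. Window percentages are descriptive variance
shares, not calibrated p-values — the null-calibration experiment above is
the package's own guidance on interpreting them.
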
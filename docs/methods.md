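# Methods

## Model and procedure

The package implements constrained ordination of a species × traits matrix.
Writing **Y** for the column-centered (optionally standardized) response and
**X** for a centered explanatory matrix, the RDA fit is the orthogonal
projection **Ŷ** = **Q**ₓ**Q**ₓ′**Y**, where **Q**ₓ is an orthonormal basis
of the column span of **X**. Total inertia is Σⱼ var(yⱼ) (denominator n − 1);
explained inertia is the same functional of **Ŷ**; canonical eigenvalues are
the squared singular values of **Ŷ**/√(n − 1) and sum to the explained
inertia. With covariables **W** (partial RDA), **Y** and **X** are first
residualized on **W**'s span.

Three conventions that matter and how they are fixed here:

- **Explained fractions of partial fits are reported against the original
  total inertia**, not the conditioned inertia. This makes the variance
  partition additive: A + B + C + U = 1 exactly, and the unique fractions
  from the three-fit route (R_joint − R_eco, R_joint − R_phylo) equal the
  partial-RDA fractions; the code asserts this identity at 1e-8 on every
  partition call.
- **Rank deficiency.** Categorical variables keep all k dummy levels (so
  every category has its own triplot arrow); the engine works through an SVD
  basis with singular values truncated at 1e-8 relative to the largest.
  Residualized constraint blocks are truncated relative to the
  *pre-residualization* scale — otherwise a constraint lying numerically
  inside the covariable span resurfaces as rank-1 noise and breaks the
  partition identities.
- **Degrees of freedom.** The pseudo-F uses q = numerical rank of the
  (residualized) constraints and df = n − q − q_W − 1, with the residual
  inertia taken on the conditioned response.

## Permutation tests

p-values follow the (hits + 1)/(m + 1) convention, hits counting permuted
statistics ≥ the observed one (ties detected at relative 1e-9). For
conditioned terms the default scheme permutes residuals of the reduced
(covariable-only) model and adds them back to its fitted values; unrestricted
raw-row permutation is available as a configuration option. Every test is
seeded; forward selection gives each step, and the marginal clade table each
column, an order-independent substream derived from the run seed.

**Mid-p and discrete nulls.** With n species, the permutation null of a
single-species indicator takes only n distinct values, so the smallest
attainable p is 1/n — at n = 17 that is 0.059, above a strict 0.05 cutoff no
matter how extreme the species is. Selection decisions therefore default to
the mid-p variant (ties counted half), which is asymptotically identical to
the +1 rule for continuous statistics and ≈ 1/(2n) in the fully tied case.
Reported p-values always keep the +1 convention;
`selection_rule="p_value"` restores the strict rule.

## Trait coding

Reproductive frequency (RF) is the proportion of reproductive mature females
in the breeding season; RF ≤ 0.5 codes a biennial cycle, otherwise annual.
Mean fecundity (MF) is the mean count of oviductal eggs plus embryos; absent
counts leave MF missing, never zero. Reproductive potential is RP = MF × RF,
classified low (< 5), medium ([5, 10] — the closed interval keeps the rule
total where the verbal definition leaves the boundaries open), high (> 10).
The response matrix codes MF numerically and mode, frequency and RP as full
dummy blocks; frequency may instead enter as numeric RF
(`frequency_coding="numeric"`). Default scaling is `correlation`
(standardized columns) because MF's numeric scale otherwise dominates the
dummies; `covariance` (centering only) is retained as the variance–covariance
convention of the classical analyses, and is what best reproduces the
packaged worked example. The packaged table keeps one internally
inconsistent printed category (RP of *Erythrolamprus poecilogyrus*) as
printed, flagged `rp_class_consistent=False`.

## Clade candidates

Clade indicator columns come from the internal nodes of a rooted tree, with
the all-species root excluded (constant after centering) and `min_size`
filtering. The fixture analysis uses `labelled_only` candidates — the named
tribes and genera — with `min_size=1` so the monotypic tribe Hydrodynastini
(a labelled unifurcation in the fixture Newick) is admitted; without it no
single-species group can ever be a candidate variable. The fixture tree
encodes only groupings that are certain (six tribes, multi-species genera,
Hydrodynastini sister to Pseudoboini) over a root polytomy; any other
backbone can be supplied as a Newick file.

## Forward selection and Table-style reporting

Selection is greedy on added explained inertia, ties broken by column label;
each step's conditional test conditions on the already-selected columns.
Both the per-step sequential contributions (which telescope exactly to the
selected model's fit) and the marginal per-clade table (each clade fit
alone) are reported: for near-disjoint clades the two nearly coincide on the
first step but differ later, and published tables in this literature print
the sequential ones.

## Synthetic data

`generate_dataset` draws a Yule tree (dendropy's birth–death simulator with
death rate 0), evolves latent traits as
z = a·BM_std + b·eco_std + noise_sd·ε, with the Brownian and category-effect
components standardized across species so latent variance shares are
a² : b² : noise_sd². Observables mimic the empirical table: MF and RF are
affine transforms of latents (rounded, clipped to their domains), mode is a
median threshold of a latent, RP follows the derivation rule, the driving
ecological category becomes substrate use, and habitat is an inert i.i.d.
classification. Category assignment is either i.i.d. or phylogenetically
clustered (contiguous blocks of the tree's leaf order), the latter inducing
the ecology–phylogeny shared variance the empirical data show. Defaults
(n = 24 species, a = 1, b = 0.5, noise 0.5, three categories, clustered)
give a clearly phylogeny-dominated regime comparable to the worked example.

What the simulator does *not* emulate: Markov-process character evolution
(categorical traits are thresholded latents), non-ultrametric trees,
rate shifts, and sampling error in the per-species trait estimates. Passing
recovery tests therefore show that the pipeline attributes variance correctly
when its additive-signal assumptions hold, not that those assumptions hold
for any particular empirical community.

## Problem sizes used in the test suite

Exactness checks run on 50 random 12 × 4 instances against an independent
per-column least-squares oracle (tolerance 1e-10) and against R vegan on the
fixture. Calibration uses 500 null replicates at 199 permutations
(Kolmogorov distance < 0.08); recovery uses 30 replicates per weight level at
n = 24 and 199 permutations. The full fixture analysis runs its permutation
tests at 9999, matching the published setting.

## Known limitations

- The published community analysis contains internal inconsistencies (its
  printed F statistics and explained percentages cannot all be produced by
  any single least-squares coding of the printed table); the package
  reproduces the selection path, the sequential clade contributions and the
  qualitative partition, but three printed percentages differ by 3–7 points
  under every documented coding. The acceptance script reports the computed
  values, not the printed ones.
- No chi-square (CCA) ordination, detrending, phylogenetic GLS or
  eigenvector alternatives; membership coding ignores branch lengths by
  design.
- Forward selection inherits the usual selection-bias caveat: p-values of
  later steps are conditional on earlier data-driven choices.
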
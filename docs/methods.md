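# Methods

## Model and pipeline

The package discovers miRNA–mRNA regulatory modules as *collective group
relationships* (COREs). The underlying model is that miRNAs act in cohesive
groups that jointly regulate groups of mRNAs, so module structure should be
visible simultaneously in (a) the bipartite pattern of expression
correlations between the two sides and (b) the joint linear association of
the two groups' expression profiles. The pipeline operationalizes this in
two stages on top of a pre-processing step:

1. **Weights.** W[i, j] = |PCC| between miRNA i and mRNA j across the n
   matched samples ("abs" mode; "neg_abs" keeps only anti-correlated
   edges). A cutoff η zeroes entries below it; surviving entries keep their
   magnitude. Binarizing instead would discard the very information the
   weighted formulation exists to keep. PCC is computed with the n−1
   (sample-covariance) divisor; the divisor cancels in the ratio.
   A zero-variance feature has no defined PCC; its weights are set to 0
   with a warning rather than aborting, so heavily filtered inputs and
   parameter sweeps do not crash.
2. **Collaboration.** v_ij = (Σ_k w_ik w_jk)² / (Σ_k w_ik · Σ_k w_jk),
   applied to rows of W for the miRNA-side matrix S and to rows of Wᵀ for
   the mRNA-side matrix T. The formula is implemented literally as stated;
   for binary W it equals |N(i)∩N(j)|²/(|N(i)||N(j)|) ≤ 1, while for
   weighted W values above 1 are possible and only non-negativity is
   asserted. The diagonal is defined as 0, so total-collaboration sums
   (used for seeding order) exclude self-scores. If either row sum is 0 the
   score is 0: isolated features become singleton groups that the size
   filters discard.
3. **Grouping.** Greedy overlapping neighborhood expansion maximizing
   cs(C) = w_int/(w_int + w_ext + α|C|), adapted from the ClusterONE
   protein-complex algorithm. Seeds are taken in descending
   total-collaboration order, skipping vertices already covered by a grown
   group (coverage accrues even if that group is later size-filtered).
   Growth applies the single strictly-improving move with the largest gain;
   the seed is never removable (guaranteeing termination and coverage);
   ties prefer additions over removals, then the lexicographically smallest
   ID. Grown groups outside [min_size, max_size] are discarded; overlapping
   groups with ω(A,B) = |A∩B|²/(|A||B|) ≥ merge_overlap are merged (union,
   cohesiveness recomputed) to a fixpoint. Merging only grows groups, so
   only max_size is re-checked afterwards; an over-cap merged group is
   dropped and logged. Output order: cohesiveness descending, ties by
   smallest member.
4. **CORE scoring.** Every (miRNA group, mRNA group) pair is scored by its
   first canonical correlation on the expression submatrices; pairs with
   r ≥ ρ become COREs, ranked by r (ties: larger total size, then member
   lexicographic). A group may appear in several COREs. A pair whose CCA
   fails (singular covariance under the classical solver) is skipped, not
   fatal.

## Parameters

| parameter | default | meaning |
|---|---|---|
| η (`eta`) | 0.5 (sweep 0–1 step 0.05) | magnitude cutoff on \|PCC\| weights; unitless correlation scale |
| weights mode | `abs` | `neg_abs` restricts to anti-correlated (repression-like) edges |
| α (`alpha`) | 2.0 | cohesiveness penalty per member, modeling undetected interactions |
| θ_m (`min_mirnas`) | 3 | minimum miRNA group size (avoids star structures) |
| θ_g (`min_mrnas`) / `max_mrnas` | 5 / 500 | mRNA group size bounds (smaller groups uninformative, larger ones unwieldy); miRNA groups uncapped by default, configurable per side |
| ω (`merge_overlap`) | 0.8 | overlap score at or above which two groups merge |
| `min_density` | None | optional density floor on groups, off by default |
| ρ (`rho`) | 0.50 | minimum first canonical correlation for a CORE |
| CCA method | `sparse_pmd` | `classical` and `ridge_regularized` available |
| sparse penalties | 0.3 · √dim | ℓ1 bounds on the PMD coefficient vectors, clamped to [1, √dim] |

α = 2 is used uniformly: it is the one value stated for the comparison
configuration, and a single consistent default (user-overridable) is
preferable to an undocumented per-dataset choice. The merge rule and
ω = 0.8 follow ClusterONE, the algorithm this stage adapts. ρ, θ_m, θ_g and
the mRNA cap are the published operating points of the method.

## Canonical correlation solvers

Features are standardized to zero mean, unit variance (n−1 divisor) before
any solver; classical CCA is invariant to this, and it puts the sparse
solver's identity-approximation of the variance matrices on the right
scale.

- **classical** — r = largest singular value of
  Σ_XX^{−1/2} Σ_XY Σ_YY^{−1/2}. Requires n > |C_x| + |C_y| and invertible
  covariances; a singular covariance raises an error naming the regularized
  alternatives. For 1×1 "groups" this reduces to |PCC| (used as a test
  oracle; the pipeline itself requires ≥ 2 features per group).
- **ridge_regularized** — same construction on Σ + reg·I (reg = 0.1 on the
  correlation scale); the reported r is the empirical correlation of the
  resulting variates, clipped to [0, 1].
- **sparse_pmd** (default) — rank-1 penalized matrix decomposition of
  K = X_s Y_sᵀ: maximize u′Kv under ‖u‖₂ ≤ 1, ‖v‖₂ ≤ 1 and ℓ1 bounds
  c = penalty·√dim, by alternating soft-thresholded updates with a binary
  search on the threshold. Initialization is the leading singular-vector
  pair of K with a fixed sign convention, making the iteration
  deterministic. Chosen as default because mRNA groups (up to hundreds of
  genes) routinely exceed the sample count, where classical CCA is
  ill-posed. Only the first canonical correlation is reported; higher
  variates are not computed.

Numerical conventions: correlations are clipped to [−1, 1] against rounding;
r is clipped to [0, 1]; the cohesiveness of a set with zero denominator
(possible only at α = 0) is defined as 0; the PMD inner loop stops at a
relative change of 1e−9 or 100 iterations.

## Synthetic data

The generator plants rank-1 modules in Gaussian noise: each module draws one
latent factor per sample; member miRNAs load +m on it and member mRNAs −m
("anti", reflecting repression) or random ±m ("mixed", exercising the
absolute-value weighting). All features receive i.i.d. noise (sd 0.5 by
default); non-members are pure noise. The default scenario — 60 samples,
30 miRNAs × 200 mRNAs, two disjoint modules of (4, 20) and (5, 30) with
unit loading — gives within-module |PCC| ≈ m²/(m² + sd²) = 0.8 against a
background of ≈ 1/√n, a separation comparable to the strong co-expression
structure in differentially-expressed cancer panels, at a size small enough
that the full multi-seed test battery runs in seconds.

What the generator does *not* emulate: empirical expression distributions
(heavy tails, batch structure), correlated noise between modules, many weak
overlapping modules, or realistic target-network sparsity. Passing the
planted-recovery tests therefore demonstrates that the implementation
correctly extracts the structure its model class assumes — not that the
method will resolve modules in any particular real dataset.

## Design choices on genuinely open points

- The η cutoff is applied after the abs/neg_abs transform (the weights
  matrix is derived first, then thresholded and consumed).
- Seeding uses all not-yet-covered vertices in total-collaboration order;
  the ranking's role in seeding is inherited from ClusterONE's
  uncovered-vertex strategy.
- Expression values are treated as given (no log/linear detection); sample
  matching is exact string equality; missing values are rejected, never
  imputed.
- Standardization before CCA is always on (documented above) since the
  alternative is scale-dependent in the sparse solver.
- Wall-clock timing is logged but is not part of any data model or output
  contract (hardware-dependent).

## Limitations

- Weighted collaboration scores are unbounded above; cohesiveness remains
  in [0, 1] but cross-dataset comparison of raw scores is not meaningful.
- The greedy clustering finds local cohesiveness maxima; no global
  optimality is claimed (the exact-recovery tests cover planted,
  well-separated structure).
- Sparse-CCA penalties are heuristic defaults (0.3·√dim), exposed in
  configuration; no data-driven penalty selection is performed.
- No significance testing: both η and ρ filter by magnitude, not p-value.
- Dense matrix algebra throughout; intended scale is up to a few thousand
  features per side.
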
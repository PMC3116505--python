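# Methods

`darffc` analyzes a binary transcriptional connection matrix `M` (genes in
rows, transcription factors in columns, `M[i,j] = 1` iff TF *j* has a
predicted binding site upstream of gene *i*). Every TF is encoded by one of
the gene rows, so autoregulation is observable as the diagonal entry of a
TF's own row. This note records the models, conventions and numerical
choices, and what the synthetic studies do and do not show.

## Circuit census

A feedforward circuit (FFC) is an ordered triple (X, Y, Z): TF X targets TF
Y and both target gene Z, with Z distinct from the genes encoding X and Y.
Counting conventions:

- **Ordered pairs.** If X→Y and Y→X both exist, (X, Y, Z) and (Y, X, Z) are
  two circuits. The census is purely combinatorial; no exclusion rule is
  applied to mutual edges.
- **Target kind.** Z is a `TF` target when its gene is in the TF-gene set,
  otherwise an `effecter` (terminal) target. The TF-gene set defaults to
  the genes encoding the matrix's TF columns and can be extended with any
  further TF-annotated gene IDs (`tf_gene_ids=`), since a genome typically
  contains more TF genes than the matrix has columns.
- **Coherence.** Each edge is signed by its regulator's global mode
  (+ activator, − repressor). The sign of the direct X→Z path equals the
  product of signs along X→Y→Z exactly when Y is an activator, so
  coherent ⇔ Y activates; type 1 ⇔ X activates. Circuits containing a
  bimodal or mode-unspecified TF are excluded from mode-dependent counts
  (their per-connection signs are unknowable) and retained in
  mode-independent ones; the excluded number is reported.
- **Autoregulation configuration.** From the diagonal flags of X and Y:
  double / intermediary-only / originating-only / none. The combined
  scheme is the (mode pair) × (autoconfig) × (target kind) product; its
  (NN, double, effecter) cell is the DAR-FFC (double-autorepression FFC).
- **Backbones.** The ordered TF→TF edge X→Y, censused irrespective of
  shared targets, under the autoconfig and combined splits; backbones are
  classified by TF-level modes.

Counts are computed by matrix algebra (per-pair common-target counts from
`Mᵀ M` restricted by target kind and sign, with the two self-row exclusion
terms subtracted) and are verified against brute-force triple enumeration
in the test-suite for random networks up to 8 TFs × 25 genes.

## Null model

Degree-preserving randomization by 2×2 checkerboard swaps: draw distinct
columns (a, b) and distinct rows (m, n); if `M[m,a] = M[n,b] = 1` and
`M[n,a] = M[m,b] = 0`, complement the submatrix. A *step* counts one
attempted draw, applied or not — the draw-check-swap loop is the unit the
step budget controls. Row and column sums are conserved exactly (integer
equality, asserted in tests). Diagonal entries are not protected: self-edges
shuffle like any others, which is what gives the autoregulation count a
non-degenerate null distribution.

Defaults are 500 000 steps per matrix and ensembles of 1000 — the regime at
which the changed-entry convergence curve (`convergence_curve`) plateaus
for a matrix of ~5000 × ~80 at realistic density. Synthetic studies in the
tests and the acceptance script use matrices of 16 TFs × 120 genes with
5000 steps and ensembles of 25–60, the same plateau criterion applied at
that scale. Per-matrix seeds derive from a master seed via a counter
(`SeedSequence([seed, i])`); all randomization is bit-reproducible.

## Ensemble statistics

Per category: Z = (real − mean_null)/sd_null with the sample sd (n−1); at
n = 1000 the n vs n−1 choice is far below reporting precision. P is the
standard-normal tail in the direction of the deviation (1 − Φ(Z) for
Z ≥ 0, Φ(Z) otherwise), so P(Z) = P(−Z) and the sign of Z distinguishes
motifs from antimotifs. Zero-variance categories are flagged as degenerate
(Z, P = NaN) rather than dropped or given a pseudo-sd. No multiple-testing
correction is applied — categories are few, structured and reported raw.

## GO enrichment

Redundant counting throughout: every (gene, term) record counts, and an
effecter targeted by k DAR connections contributes its annotations k times
to the target-side totals (`target_frequencies` accepts a multiset).
Background r_g = F_g/E over the effecter universe; f_g ~ Binomial(D, r_g)
under the null; P_g is the inclusive upper tail P(K ≥ f_g), computed via
the regularized incomplete beta (`scipy.stats.binom.sf`), accurate far
below 1e−40. The inclusive tail is the standard enrichment convention and
gives P = 1 at f = 0; the strict tail P(K > f) is available via
`inclusive=False`. Filters: global lists drop terms with F_g ≤ 0.1% of E;
per-connection lists drop F_g ≤ 0.05% of E or P ≥ 0.01. Ties in the
P-ascending ranking break by descending f_g then term ID, making output
deterministic. Terms are opaque labels — no GO-DAG propagation.

## DAR connections and higher-order structure

A DAR connection is an ordered pair of autoregulated repressors with the
X→Y edge present and ≥ 1 jointly targeted effecter. Higher-order DAR-FFCs
are feedforward triangles among these connections; by default all three
triangle edges must themselves be DAR connections (the triangles live
inside the connection graph). The looser reading — the X→Y leg only needs
to be a plain matrix edge, while both target-sharing legs are DAR
connections — is available via `xy_edge="matrix"`; the two readings differ
only when a TF-TF edge lacks shared effecter targets. Roles follow from
the triangle (out-degree-2 node = X, in-degree-2 = Z); a hub is a TF in
≥ 2 higher-order circuits, always in role X.

## Mode perturbation

The perturbation unit is the *connection*: among present edges of moded
TFs, `round(p · n_signed)` are selected uniformly without replacement from
the joint pool (per-mode pools via `pool="per_mode"`) and sign-flipped.
Circuits are re-classified from the signs of their two regulator→target
edges, which coincides with the TF-level scheme when no edge is flipped;
the same stored selection is applied to each null matrix's edges (edges
absent from the real matrix inherit their TF-level sign), so real and null
counts face the same perturbation. Proportion 0 therefore reproduces the
unperturbed Z bit-for-bit — asserted in tests.

## Synthetic data

The generator emulates the features the pipeline is sensitive to: TF genes
among the rows, heavy-tailed TF out-degrees (discretized log-normal, mean
0.12 × n_genes, σ = 0.8 by default — a broad, dense regime comparable to a
conserved-binding-site matrix), independent per-TF modes, Bernoulli
autoregulation, planted DAR connections (both diagonals set, X→Y edge,
`targets_per` common non-TF targets) and Zipf-weighted annotations
(Poisson 2.5 terms/gene, ~a curated-annotation density) with planted terms
at `multiplier ×` background rate among chosen targets. Planted quantities
are lower bounds on censused ones — background edges can create more.

It does **not** emulate: correlated TF families or co-binding, promoter
sequence or binding-site structure, in-degree heterogeneity beyond what
uniform target choice induces, or GO-DAG structure. Passing synthetic
tests therefore demonstrates correctness of the counting, null model,
statistics and recovery behavior under known truth — not that any
particular biological network exhibits these motifs.

## Numerical and degenerate-input choices

- All RNG is `numpy.random.Generator`; every stochastic API takes a seed
  and composite seeds use `SeedSequence` counters.
- Binary matrices are `uint8`; census products use `int64` (exact).
- `z_score` raises on sd = 0 rather than returning ±inf;
  `summarize_ensemble` converts this to a degenerate flag.
- Empty annotation files parse to empty tables; a target set with no
  annotations yields D = 0 and P = 1 everywhere.
- `randomize(steps=0)` is the identity; negative steps are an error.

## Known limitations

- The normal approximation for P is inherited from the ensemble-Z design;
  empirical-percentile P values are not offered.
- The swap chain's mixing is assessed by the changed-entry plateau, a
  practical but not rigorous diagnostic.
- Per-edge mode perturbation leaves backbone categories classified at the
  TF level (perturbation targets circuit classification only).
- The exact supplementary-table dialects are reconstructed from their
  descriptions; the readers accept a symbol→gene-ID map to absorb layout
  differences.
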
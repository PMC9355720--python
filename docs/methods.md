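# Methods

## Problem and model

Given a binary matrix `Y` (rows: lncRNAs, columns: diseases) of curated
associations and a disease ontology in which every disease carries one or
more dot-separated hierarchical tree numbers, the package scores all
lncRNA–disease pairs so that plausible but unrecorded associations rank
high. The method is guilt-by-association: it assumes that lncRNAs whose
known disease sets are semantically close tend to share further diseases,
and that association evidence diffuses smoothly over both similarity
networks. Zeros in `Y` are treated as *unknown*, never as verified
negatives.

The package enforces one orientation everywhere — lncRNAs are rows,
diseases are columns — at the type level (`AssociationMatrix`,
`ScoreMatrix`). All stages are deterministic; randomness exists only in
the synthetic-data generator and the fold split.

## Disease semantic similarity

Each disease's DAG is the prefix closure of its tree numbers: code
`C04.588.894` yields ancestors `C04` and `C04.588`, with edges from each
prefix to its extension. A disease with several tree numbers gets the
union of the closures (one multi-rooted DAG whose leaf node may have
several parents). Codes owned by another dataset disease are identified
with that disease; remaining codes are anonymous terms that still count in
contribution sums and corpus frequencies.

Three contribution recursions are available (`contribution_variant`):

- `SV1`: fixed decay `α` per edge; the contribution of term `t` is the
  maximum over all downward paths to the disease of `α^(path length)`.
- `SV2`: pure information content `−log(Dags(t)/D)` (natural log), where
  `Dags(t)` counts the disease DAGs containing `t` and `D` is the number
  of diseases in the loaded dataset.
- `SV3` (default): per-edge factor `α + β(t)` with
  `β(t) = (max_k Dags(k) − Dags(t))/D`, so rare terms decay less.

Two deliberate readings are exposed as knobs rather than hard-coded:
`β` is evaluated at the node being scored (a flag moves it to the child),
and `D` is the dataset's disease count — the corpus the implementation can
actually see — rather than a full ontology release. Contributions are not
clamped when `α + β(t) ≥ 1`; the similarity ratio stays in `[0, 1]`
regardless, because the shared-term mass never exceeds the total mass.

The recursions are implemented as memoized sweeps over the DAG and are
tested against a brute-force enumeration of all downward paths.

## lncRNA functional similarity

`S_l(u,v)` is the best-match-average of `S_d` between the two disease
groups `DG(u)`, `DG(v)` read from `Y`. Inside cross-validation the groups
come from the *fold-masked* matrix: recomputing `S_l` per fold costs a few
tens of milliseconds at this scale and removes the feature-leakage path
that would otherwise inflate AUC (the package keeps a deliberate-leakage
switch purely to demonstrate the effect, and the acceptance suite checks
that the leaky variant scores higher). lncRNAs left with no associations
after masking get a zero similarity row/column and a unit diagonal.

## Walks and smoothing

Both walks start at `P⁰ = Y` and iterate a linear restart recursion with
the similarity matrix applied on the matching axis. Design choices:

- Similarity matrices are used raw — no row-stochastic normalization. The
  iteration is then not a Markov chain, but AUC is invariant to the overall
  score scale, and with `γ = 0.001` the map is strongly contractive for any
  similarity matrix at these sizes (`γ·ρ(S) ≪ 1`).
- The step counts are fixed integers (`n_l = 31`, `n_d = 1` by default),
  not convergence tolerances.
- The default `γ = 0.001` makes the propagation term small relative to the
  `(1−γ)Y` restart; this is kept as-is. Known pairs therefore score ≈ 1
  and novel candidates are ranked among themselves by the propagated mass.

Each network's normalized Laplacian `L = M^{-1/2}(M−S)M^{-1/2}` (with `M`
the diagonal of row sums; PSD by construction) defines the smoothing
kernel `K = S(S + ηLS)^{-1}`. For invertible `S` this collapses to
`(I + ηL)^{-1}`, the closed-form minimizer of
`‖P − F‖²_F + η·tr(FᵀLF)` — a mild graph low-pass filter; `η = 0` gives
the identity. Kernels are computed by linear solve, validated by the
residual `‖K(S+ηLS) − S‖ ≤ 1e-8·‖S‖`, and an exactly singular system
(possible for degenerate similarity structure, e.g. duplicated rows) is
re-solved with a logged ridge `ε = 1e-10·tr(S)/n` rather than failing.

The kernels act *cross-space* by default: the disease kernel smooths the
lncRNA-walk scores along the disease axis (`P_l ← P_l K_dᵀ`) and the
lncRNA kernel smooths the disease-walk scores (`P_d ← K_l P_d`). This is
the one dimensionally consistent reading of the smoothing step that
preserves the intended pairing of kernels with the opposite walk; a flag
(`cross_space_smoothing=False`) switches to same-space pairing for
sensitivity analysis. Likewise, whether smoothing happens inside every
walk iteration or once at the end is genuinely open; both are implemented
(`smoothing_mode="per_step"` default, `"final"`), and with `n_d = 1` they
coincide on the disease side. The final score is the elementwise mean of
the two smoothed matrices.

## Parameters

| name | default | meaning |
|---|---|---|
| `alpha` | 0.5 | semantic decay per ontology edge, in (0,1) |
| `gamma` | 0.001 | walk restart weight, in (0,1) |
| `n_l`, `n_d` | 31, 1 | walk step counts (lncRNA / disease network) |
| `eta_l`, `eta_d` | 0.01 | Laplacian-RLS trade-offs, ≥ 0 |
| `contribution_variant` | SV3 | semantic recursion (SV1/SV2 for ablation) |
| `smoothing_mode` | per_step | kernel applied every step vs once at the end |
| `cross_space_smoothing` | True | opposite-space kernel pairing |

Defaults follow the settings under which the method was originally tuned
on curated association data.

## Evaluation protocol

Folds partition the *positive pairs* uniformly at random (sizes within 1),
deterministically per seed. Per fold: mask the fold's positives, recompute
`S_l`, predict, then compute AUC of the held-out positives against all
pairs that are 0 in the full matrix (the standard all-unknowns negative
set for this literature; the negative-set definition is a convention, not
a ground truth). The headline number is the mean of per-fold AUCs; the
pooled-score AUC is reported alongside. AUC is the Mann–Whitney statistic
(ties half-credit), computed by scikit-learn and checked in the tests
against O(n²) pair counting.

## Synthetic benchmark

`simulate.FixtureSpec` plants recoverable structure: diseases and lncRNAs
are split into matched blocks; block members share an ancestor prefix in a
generated code hierarchy (so `S_d` correlates with block membership), and
associations are Bernoulli — `density_in` within matched blocks,
`density_out` elsewhere. One integer seed drives ontology and associations
through independent derived streams, so densities can change without
altering the ontology. All-zero rows/columns are redrawn once and then
accepted.

`default_paperlike_spec()` mirrors the shape of curated lncRNA–disease
resources: 80 lncRNAs × 150 diseases, 5 blocks, `density_in = 0.25`,
`density_out = 0.01`, giving ≈ 700 expected positives (~6% density). The
acceptance benchmark additionally uses a stronger planting
(`density_in = 0.5`, `density_out = 0.02`) averaged over 10 generator
seeds; these sizes keep the whole acceptance run under a minute on one
CPU while leaving the Monte-Carlo spread of the mean AUC near 0.005.

What the generator does *not* emulate: the real ontology's depth and
fan-out heterogeneity, literature-driven annotation bias (well-studied
lncRNAs have systematically larger disease groups), and overlapping or
hierarchical disease modules. Passing the planted-signal benchmark shows
the pipeline recovers block-structured association signal through its own
similarity computations; it does not certify performance on any real
database snapshot, and AUC values on real data will differ.

## Numerical notes

- All linear systems use LAPACK solves; explicit inverses appear only in
  test oracles.
- Ranking output breaks score ties by ascending lncRNA name, so reports
  are byte-stable across runs.
- Matrix TSVs are written at full float precision (round-trip to 1e-12);
  the human-facing ranking table rounds to 6 significant digits.
- Walk convergence to the resolvent fixed point `(1−γ)(I−γS)^{-1}Y` is
  guaranteed only when `γ·ρ(S) < 1`; the fixed-point helper checks this
  and exists mainly as a test oracle.

## Limitations

- Transductive: scores exist only for the lncRNAs and diseases present in
  the input; there is no out-of-sample `predict(X)`.
- Disease similarity depends entirely on tree-number placement; diseases
  with poor ontology coverage get near-zero similarity and effectively
  fall back to the restart term.
- The dataset-local `D` in the information-content terms makes `SV2`/`SV3`
  values dataset-size dependent; comparisons across datasets of very
  different sizes should use `SV1`.
- No sparse-matrix paths: the implementation targets the ~10² × 10² scale
  of curated association resources.
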
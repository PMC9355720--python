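# birwrls

Link prediction for lncRNA–disease associations: which long noncoding RNAs
are likely involved in which diseases, given a sparse list of curated
associations and a disease ontology?

The package is aimed at computational biologists doing network-based
candidate prioritization. It scores every lncRNA–disease pair by composing
four stages:

1. **Disease semantic similarity** `S_d`. Each disease's hierarchy DAG is
   rebuilt from its dot-separated tree numbers (prefix truncation gives
   ancestors). A term `t` contributes to disease `A` via the recursion
   `SV_A(A) = 1`, `SV_A(t) = (α + β(t)) · max_{t' ∈ children(t)} SV_A(t')`,
   where `β(t) = (max_k Dags(k) − Dags(t)) / D` rewards rare (specific)
   terms. Then `S_d(A,B) = Σ_{t ∈ T_A ∩ T_B} (SV_A(t)+SV_B(t)) / (SV(A)+SV(B))`.
   The plain fixed-decay variant (`β ≡ 0`) and a pure information-content
   variant are selectable.
2. **lncRNA functional similarity** `S_l`: best-match-average of disease
   similarities between the two lncRNAs' known disease sets,
   `S_l(u,v) = (Σ_{d∈DG(u)} max_{d'∈DG(v)} S_d(d,d') + Σ_{d∈DG(v)} max_{d'∈DG(u)} S_d(d,d')) / (|DG(u)|+|DG(v)|)`.
3. **Unbalanced bi-random walk**: two independent restart iterations on the
   association matrix `Y`, `P ← γ S_l P + (1−γ) Y` (n_l steps) and
   `P ← γ P S_d + (1−γ) Y` (n_d steps), with different step counts per
   network (defaults n_l = 31, n_d = 1, γ = 0.001).
4. **Laplacian-RLS smoothing and fusion**: each similarity network yields a
   normalized Laplacian `L = M^{-1/2}(M−S)M^{-1/2}` and a kernel
   `K = S (S + η L S)^{-1}` (the closed-form Laplacian-regularized
   least-squares smoother); kernels are applied to the walk scores and the
   two smoothed matrices are averaged into the final score `P`.

Evaluation is 5-fold cross-validated AUC over the known positives, with the
lncRNA similarity recomputed per fold from the masked matrix so held-out
associations never leak into the features. A synthetic-data module
generates planted-block ontologies and association matrices shaped like
curated resources (~80 lncRNAs × ~150 diseases, ~700 associations), so
everything runs and is tested fully offline.

## Worked example

```python
from birwrls import BiRandomWalkRLS, make_folds, cross_validate
from birwrls.simulate import default_paperlike_spec, generate_dataset

records, Y = generate_dataset(default_paperlike_spec(seed=1))   # 681 positives
model = BiRandomWalkRLS().fit(Y, diseases=records)
print(model.rank("disease 000", k=5))

plan = make_folds(Y, n_folds=5, seed=42)
res = cross_validate(records, Y, plan=plan)
print(f"mean AUC {res.mean_auc:.4f}")
```

prints

```
   rank   lncRNA     score  known_flag
0     1  lnc-010  0.993121           1
1     2  lnc-012  0.992374           1
2     3  lnc-003  0.003035           0
3     4  lnc-002  0.002880           0
4     5  lnc-004  0.002861           0
mean AUC 0.8052
```

The two known partners of `disease 000` rank first with scores near 1
(dominated by the `(1−γ)Y` restart term); the best novel candidates are
lncRNAs from the same planted block, whose scores come entirely from
similarity propagation and kernel smoothing. The mean AUC says that a held-
out true association outranks a random unknown pair about 81% of the time
on this moderately noisy synthetic dataset.

The same pipeline is scriptable from the shell:

```sh
birwrls simulate --seed 7 --out-dir fixtures/
birwrls predict --diseases fixtures/diseases.tsv --associations fixtures/associations.tsv --out scores.tsv
birwrls cv      --diseases fixtures/diseases.tsv --associations fixtures/associations.tsv --folds 5 --seed 42 --out cv.tsv
birwrls rank    --scores scores.tsv --associations fixtures/associations.tsv --disease "disease 000" --k 30 --out top30.tsv
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter meanings and
defaults, the design of the synthetic benchmark, and known limitations.
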
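# Methods

## Model

GrwLDA scores every lncRNA–disease pair on a heterogeneous network built from
three blocks: an lncRNA functional-similarity network `LL`, a disease
semantic-similarity network `DD`, and the bipartite known-association matrix
`AS` (rows lncRNAs, columns diseases). Its core assumption is guilt by
association in both directions: functionally similar lncRNAs associate with
phenotypically similar diseases, and vice versa.

### Disease semantic similarity

A disease is located in the MeSH hierarchy by one or more dot-delimited tree
numbers. Ancestors are obtained by prefix truncation (`C04.588.274` →
`C04.588` → `C04`), and the union over all of the disease's codes forms its
DAG. Contributions are

```
DT_D(t) = 1                                         if t is one of D's own positions
DT_D(t) = max { Δ · DT_D(t') : t' child of t }      otherwise
```

with decay factor Δ; a term reachable along several paths keeps the maximum,
and a position that is simultaneously an ancestor of another position keeps
its unit contribution (the max rule again). The semantic value is
`T(D) = Σ_t DT_D(t) ≥ 1`, and

```
DD(A, B) = Σ_{t ∈ V(A) ∩ V(B)} (DT_A(t) + DT_B(t)) / (T(A) + T(B)).
```

`DD` is symmetric, bounded by [0, 1], 1 for identical DAGs and 0 for disjoint
ones. Δ defaults to 0.5, the customary value for this family of DAG measures;
it is exposed everywhere as `decay` / `delta`.

### lncRNA functional similarity

With `D(u)` the disease group of lncRNA *u* (the nonzero entries of its `AS`
row), the group-wise (LNCSIM) measure is the best-match average

```
S(d, G)  = max_{d' ∈ G} DD(d, d')
LL(u, v) = [ Σ_{d ∈ D(u)} S(d, D(v)) + Σ_{d ∈ D(v)} S(d, D(u)) ]
           / ( |D(u)| + |D(v)| ).
```

When either group is empty the measure is undefined; we define `LL = 0`
there, *including the diagonal* of an empty-profile lncRNA: an lncRNA with no
known disease carries no functional evidence at all. This choice has a
far-reaching consequence for novel-lncRNA evaluation (below).

### Propagation

`LL`, `DD`, `AS`, `ASᵀ` are column-normalized (zero columns stay zero) into
`WL`, `WD`, `WA1`, `WA2`. For disease *j*:

1. Laplacian smoothing: `LPd(j) = (1−α)(I − α·WD)⁻¹ d(j)` spreads the
   indicator `d(j)` over the disease network so that connected diseases
   receive similar relevance. The matrix-inverse form is the standard graph
   regularization score and is guaranteed nonnegative for column-stochastic
   `WD` and α < 1; the plain product `(1−α)(I − α·WD) d(j)` — which produces
   negative off-diagonal entries and therefore cannot seed a probability
   vector — is retained behind `laplacian_form="literal"` for fidelity
   experiments, with a sign-agnostic sum normalization.
2. Seed: `pl⁰_j = WA1·LPd(j) + WA1(:, j)`, column-normalized. The first term
   reaches lncRNAs of *similar* diseases — this is what gives an isolated
   disease (all-zero `AS` column) a nonzero seed; the second doubles the
   weight of disease *j*'s own known lncRNAs. An all-zero seed is legal
   (entity disconnected from everything) and yields an all-zero score column
   rather than an error.
3. Walk: `pl^{t+1} = (1−γ)·WL·pl^t + γ·pl⁰_j` until the L1 change between
   successive vectors is ≤ `tol` (non-strict comparison; default 1e-6, cap
   `max_iter = 1000`); the steady state column is `S1(·, j)`. Because the
   update is a convex combination under a column-stochastic matrix, a seed
   summing to 1 keeps total mass 1 throughout.

The disease-side walk mirrors this with `WL`/`WD` swapped, balance β and
seeds `pd⁰_i = WA2·LPl(i) + WA2(:, i)`, giving `S2`. The final score is the
blend `FS = η·S1 + (1−η)·S2`, exactly linear in η.

Since all seeds are linear in the indicator, the per-entity walks are run as
one matrix iteration over all columns simultaneously (stopping when the worst
column has converged); a closed-form engine `γ(I − (1−γ)W)⁻¹P⁰` is available
via `engine="solve"` and the iterative default is tested against it.

### Parameters

| name | default | meaning |
|------|---------|---------|
| γ (`gamma`) | 0.9 | restart probability of both walks |
| α (`alpha`) | 0.1 | disease-side Laplacian balance |
| β (`beta`) | 0.1 | lncRNA-side Laplacian balance |
| η (`eta`) | 0.7 | weight of the lncRNA-side walk in `FS` |
| Δ (`delta`/`decay`) | 0.5 | DAG contribution decay |
| `tol` | 1e-6 | L1 convergence threshold |
| `max_iter` | 1000 | iteration cap (exceeding it raises, carrying the residual) |

The γ/α/β/η defaults are the operating point commonly reported as optimal for
this model family; a large γ keeps the steady state close to the seeds, so
the Laplacian seed construction — not long-range diffusion — carries most of
the signal.

## Evaluation protocol

Three leave-one-out masking modes:

* `overall` — each known association is zeroed in turn (one cell);
* `novel_lncrna` — the lncRNA's entire row is zeroed;
* `isolated_disease` — the disease's entire column is zeroed.

Because `LL` is *derived from* `AS`, reusing the unmasked `LL` inside a fold
leaks the held-out evidence. By default `LL` is therefore recomputed from the
masked matrix in every fold; `static_ll=True` restores the naive variant, and
both are reported side by side by the acceptance script.

Negative scores (never-known pairs): in `overall` mode they are computed once
under the full model — a single-cell-masked model differs from it in one cell
only, and recomputing all ~8.6k negatives per positive would be quadratic
without changing the comparison. In the row/column modes, each entity's
knowns *and* unknowns are scored from the same masked run — the run that
would rank candidates for that entity if it were genuinely novel or isolated.
Scoring masked positives against full-model negatives instead systematically
inflates the isolated-disease AUC, because the normalized isolated seed
spreads unit mass over the whole neighborhood while the full model
concentrates it on known partners; the per-run convention removes this
artifact and preserves the expected ordering (overall ≥ novel, isolated).

A consequence of the leakage-free default worth stating plainly: under
recomputed `LL`, a fully masked lncRNA has an empty profile, zero similarity
to everything and no path into the network, so every `novel_lncrna` score is
exactly 0 and the AUC degenerates to 0.5. This is the honest answer — with
association-derived functional similarity there is *no* independent evidence
about a truly novel lncRNA. Nonzero novel-lncRNA performance requires the
static-similarity protocol, which is what published evaluations of this model
family implicitly use.

ROC points come from a sweep over all distinct scores; the AUC (trapezoidal)
equals the Mann–Whitney statistic with 0.5 credit for ties and is verified
against brute-force concordant-pair counting. AUPR uses the step-wise
(non-interpolated) rule. Repeated k-fold CV partitions the association cells
(k = 5, 10 repetitions by default, seed mandatory); within each repetition
the folds' held-out scores are pooled against the negatives for one AUC per
repetition. Ranked prediction tables exclude known pairs and break ties by
ascending identifier.

## Synthetic benchmark

The generator emulates the statistical shape of the curated benchmark: 78
lncRNAs × 113 diseases and exactly 210 associations (6 co-module blocks × 33
in-block associations + 12 uniformly sprinkled cross-block noise links).
Diseases of a block share a depth-3 tree-number prefix under a common root,
each disease adding one unique leaf segment (tree depth 4, a realistic MeSH
descriptor depth); this yields mean within-block `DD` ≈ 0.47 versus ≈ 0.07
between blocks. A round-robin pass inside each block guarantees every lncRNA
and every disease at least one association, so the written edge list parses
back to exactly the configured counts. One integer seed drives three
deterministic substreams (tree numbers, in-block placement, noise), so
outputs are reproducible and independent of one another.

What the generator does *not* emulate: the long-tailed degree distribution of
real association databases (a handful of famous lncRNAs carry dozens of
links), name/descriptor curation noise, correlated ascertainment bias between
similar diseases, and DAGs with multiple tree numbers per disease. Passing
the planted-signal tests therefore shows the pipeline recovers block-structured
signal under the stated noise — not that real-data AUCs are reproduced.

A label-permutation null (`permute_labels`) reassigns the 210 cells uniformly
at random, destroying the block signal; the overall LOOCV AUC on permuted
data sits at chance (≈ 0.5), confirming the evaluation itself does not leak.

## Numerical choices and degenerate inputs

* Convergence uses the L1 norm with a non-strict (≤) threshold.
* `(I − αW)` is solved directly (LAPACK); it is nonsingular for α < 1 and
  column-stochastic `W`.
* Zero columns/rows propagate as zeros everywhere rather than raising, so
  whole-matrix prediction never aborts on disconnected entities.
* Ties in rankings break by ascending identifier; ties in metrics get 0.5
  credit (AUC) / step-wise handling (AUPR).
* γ = 1 is allowed as a degenerate case (the walk returns its seed).

## Limitations

* Functional similarity comes only from shared disease associations, so
  predictions are biased toward well-annotated regions of the association
  matrix, and truly novel lncRNAs are out of reach under the leakage-free
  protocol (see above).
* The η-blend is linear; no attempt is made at a single unified walk.
* The synthetic benchmark's block structure is cleaner than real data; the
  absolute AUC values on it are not comparable to values on curated corpora.
* DAGs are built from tree-number prefixes alone; semantic relations not
  expressed in the tree numbering (e.g. MeSH "see also") are ignored.
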
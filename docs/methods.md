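# Methods

## Model

The package assumes a linear latent-activity model of transcriptional
regulation. A prior network records which genes each transcription factor
(TF) is believed to regulate; stacking it as a genes × TFs matrix P, the
(transformed) expression matrix X (genes × samples) is modeled as X ≈ P A,
where A (TFs × samples) is the unobserved TF activity. Activities are
estimated by the Moore–Penrose pseudoinverse, Â = pinv(P) X, with singular
values below 1e−10 · σ_max treated as zero. Before inversion a TF's edge
onto its own gene is removed — a TF that "explains" its own transcript
carries no information about its protein-level activity and corrupts the
estimate. A TF with no usable prior targets falls back to its own
expression row when measured (tagged `expression_fallback`), and is dropped
otherwise. Activities are deliberately left unstandardized here; each
regression engine standardizes its own design matrix, which keeps the
activity estimator a pure linear map (it is exactly linear in X, a property
the tests exercise).

Each gene is then regressed on the activities with sparse model selection.
All engines report, for every selected TF j, the explained-variance score
d_j = max(0, 1 − RSS_full / RSS_−j) from an OLS refit of the selected
support, so edge scores are comparable across engines.

### BBSR

Candidates for a gene are the TFs with a prior edge to it, ordered by CLR
(the context likelihood of relatedness: mutual information between target
and regressor, z-scored against the row and column MI distributions and
combined as sqrt(max(0,z_r)² + max(0,z_c)²)), truncated to nK = 10; if
fewer, the highest-CLR non-prior TFs fill the remaining slots, so genes
held out of the prior still receive data-driven candidates. MI uses 10
equal-width bins per variable over its observed range, natural logs, and a
zero-MI convention for constant variables. All 2^k subsets are enumerated
and scored by BIC_m = n ln(max(RSS_m, 1e−10)/n) + ln(n) Σ_{j∈m} w_j, where
the per-predictor penalty weights w_j default to 1 and can be set below 1
for prior-supported predictors (`prior_penalty_weight`). This weighted-BIC
scheme stands in for a full Zellner g-prior: in the equal-weight case the
selection is identical, and it is verifiable against a brute-force oracle,
which the test suite does on hundreds of random instances. Ties prefer
fewer predictors, then the lexicographically first subset.

### StARS-LASSO

The lasso objective is (1/2n)‖y − Xβ‖² + λ‖β‖₁ (solved by coordinate
descent via scikit-learn). The penalty grid has 20 log-spaced points from
λ_max = max_j |x_jᵀy|/n down to 0.01 λ_max — wide enough to bracket empty
through dense models. For each of 20 subsamples of ⌈0.63 n⌉ samples drawn
without replacement, the support along the grid is recorded; with selection
frequency θ_jλ, the instability D(λ) = mean_j 2θ(1−θ) is monotonized by a
running maximum from the largest λ down, and λ* is the smallest grid value
with D̄ ≤ 0.05 (λ_max if none qualifies). These are the classic stability
selection defaults. The prior is not used to mask predictors in this
engine — it acts only through the activity estimates — so every TF is a
potential regulator of every gene (except a TF for its own gene, excluded
in all engines). Within a workflow run the subsample index sets are drawn
once per bootstrap and shared by all genes; this keeps runs deterministic
and independent of worker count, and lets the per-subsample Gram matrices
be computed once.

### AMuSR

For K tasks the per-gene coefficients W (predictors × tasks) decompose as
W = B + S with objective

    Σ_k (1/2n_k)‖y_k − X_k(b_k + s_k)‖²
      + λ_B Σ_j max_k |B_jk| + λ_S Σ_{j,k} w_jk |S_jk|.

The ℓ1/ℓ∞ penalty on B makes its support row-structured (a predictor is
shared by all tasks or by none); S absorbs task-specific deviations, with
adaptive weights w_jk = ρ < 1 on prior-supported (TF, task) pairs
(`prior_penalty_weight`; the shared component B is deliberately not
reweighted, since task-specific priors should not bias the shared
structure). Optimization alternates exact block-coordinate updates in
covariance space: entrywise soft-thresholding for S and, for each row of B,
the weighted ℓ∞ prox min Σ_k c_k/2 (b_k − a_k)² + λ_B max_k |b_k|, solved
by clamping coordinates at a common cap found by a sorted water-filling
scan. Every update minimizes its block exactly, so the objective is
monotonically nonincreasing; iteration stops at a relative decrease below
1e−4 or 200 iterations. Penalties are selected on a one-dimensional grid:
λ_B over 20 log-spaced values from the smallest value zeroing both B and S
down to 1% of it, with λ_S = λ_B/√K coupled, scored by
EBIC = Σ_k [n_k ln(RSS_k/n_k) + df_k ln n_k + 2γ df_k ln p] with γ = 1;
the one-dimensional grid keeps the selection brute-force checkable, and
fits are warm-started along the grid. With K = 1 and B forced empty the
engine reduces exactly to the ℓ1 solver (verified to 1e−6).

## Preprocessing and controls

Raw counts can be filtered by the "1 count per N cells" rule: threshold
T = max(1, ⌊n_samples/N⌋) with N = 20 by default (T = 2217 at 44,343
cells); transformed by the Freeman–Tukey transform sqrt(x+1) + sqrt(x) − 1
(the zero-preserving form, chosen because scRNA-seq matrices are
zero-inflated) or log2(x+1); and depth-normalized so each cell's total
equals the median cell total (all-zero cells are left unchanged; the median
is taken over all cells including empty ones).

Two negative controls calibrate the no-signal floor. The noise control
replaces expression with per-gene draws N(μ_i, σ_i) from the observed gene
means and standard deviations; negatives are clipped to zero and each cell
is rescaled multiplicatively to its original total (clip-then-rescale is
the simplest scheme satisfying the per-cell-sum constraint; the choice is
recorded in run metadata). The shuffle control permutes the prior's gene
labels, preserving TF out-degrees and the in-degree multiset exactly.
`add_random_prior_edges` adds round(fraction × n_edges) false edges at
uniform empty cells for robustness sweeps.

## Ensembling and evaluation

Within each (task, bootstrap) edge set, edges are ranked by score (average
ranks on ties); any universe pair a set does not score receives the worst
rank U = |TFs| × |genes|, which — unlike ranking by per-set edge count —
keeps confidences comparable across sets of different density. Rank sums
over M sets map to confidence = 1 − (rank_sum − M)/(M(U−1)), an affine map
with best-everywhere ↦ 1 and never-scored ↦ 0, invariant to any monotone
transform of within-set scores and to the order of the sets.

Cross-validation holds out a uniform 20% of the genes that have at least
one prior edge: their prior columns are zeroed before inference and scoring
restricts to edges into them. Scoring builds the universe (gold TFs) ×
(gold genes ∩ restriction) — genes absent from the gold standard are
unknowable and excluded; gold-standard genes absent from expression are
dropped with a logged count. Edges are swept by descending confidence with
equal-confidence edges treated as one block (block precision makes AUPR
deterministic and fair under permutation of ties); universe pairs the
network never scored are appended as a final all-tied block so they count
toward recall. AUPR is the block-wise sum Σ ΔR · P; the random baseline is
P/U, the expected precision of a random ranking. MCC (0 when any
confusion-matrix marginal is empty) and F1 are computed at every block
boundary, and `threshold_max_mcc` returns the largest confidence achieving
the maximum — the network-sizing heuristic that maximizes overlap with a
reference network without an arbitrary precision target. Maximum F1 gives
a less conservative network (true negatives do not enter it) and is
provided under the same sweep contract.

## Synthetic data

The generator mirrors the engines' assumptions — which is the point: it
measures whether the machinery recovers structure under its own model, not
whether the model matches real biology. `generate_truth` places each
TF → gene edge independently with the requested sparsity, with coefficients
±Uniform(0.5, 2); TFs are the first genes of the namespace and carry no
incoming edges, because their expression rows are set to their own activity
(plus noise), keeping X = WᵀA self-consistent and exercising the
expression-fallback path. Continuous mode adds N(0, σ) noise; count mode
draws Poisson counts with rates exp(0.5 · signal) scaled to a mean depth of
2000 per cell — sparse enough to exercise the count filter. Degraded
priors keep a uniform fraction of true edges and add false ones; kept
edges carry the true coefficient's sign by default, as curated priors in
this field record activation versus repression. The sign matters
mechanically: the activity estimator pseudoinverts the prior, and
discarding signs makes opposite-sign targets cancel, roughly halving
held-out AUPR on the standard instance. An unsigned variant
(`signed=False`) is available. Multi-task families share a uniformly
chosen core of round(shared_fraction × edges) edges; each task resamples
the remaining edge mass at fresh empty cells.

What the synthetic data does not emulate: nonlinear and combinatorial
regulation, RNA decay dynamics, doublets/ambient RNA, batch effects within
a task, and realistic TF-TF correlation structure. Passing tests therefore
demonstrate correctness of the machinery and its statistical behavior
under the linear model, not performance on real tissues.

## Problem sizes and numerical choices

The acceptance checks run at deliberate desk scale: the standard recovery
instance is 200 genes × 20 TFs × 500 samples (sparsity 0.05, noise sd 0.5,
80% of true edges kept in the prior, 20% gene holdout, 2 replicates ×
1 bootstrap), and the multi-task comparison uses 3 tasks × 150 samples on
100 genes × 20 TFs over 5 seeds. Defaults for real runs are larger
(5 bootstraps, 10 replicates). Degenerate inputs are handled explicitly:
RSS is floored at 1e−10 inside logs; zero-variance responses yield empty
models; singular candidate subsets are skipped; constant variables have
zero MI; zero-total cells pass through depth normalization untouched. All
sorted outputs break ties lexicographically, every random decision derives
from the run seed (sub-seeds via CRC32 of labeled strings), and bootstrap
draws index positions after a canonical sample-id sort, so results are
byte-identical across reruns, worker counts, and input orderings.

## Known limitations

- StARS with few predictors (≲ 10 TFs) is extremely conservative: a single
  flickering predictor contributes 0.5/p to the mean instability, which
  alone can exceed the 0.05 target, collapsing models to near-empty. Use
  BBSR or AMuSR for very small regulator panels.
- The pseudoinverse activity estimator degrades when the prior is unsigned
  but true effects have mixed signs (see above), and when prior columns are
  nearly collinear.
- Rank combination assumes a shared universe; tasks with different gene
  sets are harmonized to the union before combining, so a gene absent from
  a task contributes worst ranks for that task rather than being treated
  as missing.
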
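# Methods

## Problem and model

`lpnmf` predicts missing links in a bipartite lncRNA–protein interaction
network. The observed data are a binary matrix `A` (rows lncRNAs, columns
proteins) plus heterogeneous side information: nucleotide and amino-acid
sequences, an lncRNA expression profile over tissues, and protein GO
annotations on an ontology DAG. The model assumes (i) interactions are
generated by low-dimensional non-negative latent factors, `A ≈ UVᵀ`;
(ii) each feature view is linearly related to the latent space through a
non-negative projection (`FLᵢPLᵢᵀ ≈ U`); and (iii) entities that are
similar — by sequence, expression, annotation, or interaction profile —
have nearby latent vectors (graph Laplacian regularization). Observed
interactions are experimentally verified and are therefore up-weighted
relative to unobserved pairs through the importance matrix `C`
(`C_ij = δ` where `A_ij = 1`, else 1).

The training objective and its block-coordinate solver (multiplicative
sweeps for `U`, `V` and the projections; closed-form simplex updates for
the view weights) are stated in the README. Two deliberate reproductions
of the printed update rules are worth flagging:

- The denominator of the `U`/`V` updates uses `(C ⊙ UVᵀ)V` rather than
  the exact gradient `(C ⊙ C ⊙ UVᵀ)V` of the weighted square loss. The
  printed form is implemented verbatim; for moderate `δ` the difference
  only rescales the pull toward observed entries. The consequence is that
  the sweep is not guaranteed monotone in the objective; empirically the
  trace is monotone after the first few iterations (this is asserted, to
  1e-6 relative tolerance, in the test suite).
- The interaction-existence test used by the importance matrix and by the
  cold-start completion reads the *binary* training matrix `A`, not the
  completed `Ā`; `Ā` is only the reconstruction target.

## Pipeline order

1. **Features.** lncRNA: tissue expression row, PseKNC (k = 3, λ = 10,
   w = 0.05) and PCPseDNC (λ = 10, w = 0.05); protein: APseAAC (λ = 15,
   w = 0.05) and CTriad (343 class-triad frequencies, min–max rescaled).
   High-dimensional descriptors are PCA-reduced (components explaining
   95% variance, capped at 200, deterministic sign convention); every
   view is column-wise min–max normalized so the solver sees entries in
   [0, 1]. Constant columns map to zero (the normalization formula is
   0/0 there; zeros keep the matrix finite without dropping columns).
   The pseudo-composition tier correlations use property tables shipped
   as package data: the unified nearest-neighbor thermodynamic scales
   (ΔG°₃₇, ΔH°, ΔS°) for the 16 DNA dinucleotides, and consensus
   hydrophobicity plus Hopp–Woods hydrophilicity for the 20 residues,
   each z-normalized across the alphabet before use.
2. **Interaction completion (WKNNP).** Each row (column) of the training
   matrix is replaced by a convex combination of its K = ⌈0.3N⌉ most
   similar rows (columns), the t-th neighbor weighted by
   `0.8^(t−1) · s_t` and normalized by the summed weights;
   `Ā = max(A, (row + column completions)/2)`, so completion never
   erases a known interaction. The neighbor metric is the kernel
   neighborhood similarity of the raw interaction profiles themselves:
   the completion runs before any profile-derived network exists, and
   profiles are the one signal guaranteed to reflect the network being
   completed.
3. **Similarity networks.** lncRNA side: d2* (k = 6, order-0 background
   from each sequence's own base composition) plus KSNS over expression,
   PseKNC, PCPseDNC and the completed profile; protein side: GO semantic
   similarity plus KSNS over APseAAC, CTriad and the completed profile.
   GO term similarity uses the graph-based S-value recursion
   (`S_A(A) = 1`, `S_A(parent) = max w_e · S_A(child)`, `w = 0.8` for
   is_a and 0.6 for part_of) and best-match averaging over the proteins'
   term sets; unannotated proteins get zero similarity to all others.
4. **Fusion.** Each network is row-normalized into a transition matrix,
   smoothed by a random walk with restart (restart probability 0.5,
   iterated to an L1 change below 1e-9), averaged across networks,
   symmetrized, min–max rescaled to [0, 1], diagonal set to 1. This is a
   deliberately simplified diffusion-and-average fusion; the
   dimension-reduction/log-transform stages of heavier fusion schemes
   are omitted.
5. **Solve, complete, score.** The fused networks are sparsified to
   K = ⌈0.3N⌉ neighborhoods (an OR rule, hence symmetric) for the
   Laplacians, the solver runs to a relative objective change below
   1e-6 (at most 500 sweeps), interaction-free entities borrow latent
   vectors from their K = max(5, ⌊0.1N⌋) most similar interacting
   neighbors (similarity-weighted, normalized), and `Ȳ = ŨṼᵀ`.

Inside cross-validation, steps 2–5 are recomputed per fold from the
masked training matrix only; the feature views and the sequence/GO
networks of step 1/3 do not depend on `A` and are computed once.

## Parameters

| parameter | default | role |
|---|---|---|
| η | 5 | projection index; sharpens the view weighting (η→1 puts all mass on the best view) |
| µ | 100 | ℓ₁,₂ penalty on projections (row-sparse projections) |
| λ | 1 | neighborhood Laplacian regularizer |
| γ | 1 | Frobenius shrinkage of `U`, `V` |
| δ | 2 | importance of observed interactions (δ = 1 treats known and unknown pairs alike) |
| d | 100 | latent dimension, capped at min(N_l, N_p) |
| K (sparsify/WKNNP) | ⌈0.3N⌉ | neighborhood size, adaptive to sample count |
| K (cold start) | max(5, ⌊0.1N⌋) | donors for latent completion |
| KSNS penalty | 10 | ridge on non-neighbor reconstruction weights |
| KSNS bandwidth | median pairwise squared distance | Gaussian kernel scale |

All solver defaults (η, µ, λ, γ, δ, d) are the tuned operating point of
the method on its benchmark corpora; the descriptor parameters (k, λ, w)
are the conventional values for those descriptors. Everything is exposed
through `Hyperparams` and the YAML config.

## Numerical choices

- Multiplicative-update denominators are floored at 1e-12; zero factor
  entries are fixed points of the update and stay zero.
- View weights with numerically zero residual (< 1e-12) receive the
  entire mass, split uniformly among zero-residual views — the closed
  form's η-limit.
- KSNS per-sample weights are found by projected gradient descent with
  exact Euclidean projection onto the simplex (step 1/(2‖G‖₂), change
  tolerance 1e-8). A multiplicative-update-with-renormalization scheme
  was tried first and rejected: its fixed point satisfies a
  multiplicative Lagrange condition, not the KKT conditions of the
  constrained quadratic program, and it disagreed with an exact QP
  solver by up to 0.07 per weight.
- K-nearest selection everywhere breaks ties by ascending index
  (stable sort); an entity is never its own neighbor.
- d2* terms for k-mers with zero background probability in either
  sequence are skipped (they are 0·0/0 limits); the statistic is clipped
  to [0, 1].
- Random initialization draws every matrix from one seeded generator in
  a fixed order (U, V, PL₁…, PP₁…), so fits are bit-reproducible.
- Degenerate inputs: constant feature columns normalize to zero;
  all-identical KSNS samples fall back to a uniform kernel; an all-zero
  interaction matrix is valid input (pure cold start) but latent
  completion requires at least one interacting entity per side.

## Synthetic data: what it emulates and what it does not

`generate_fixture` produces a complete dataset with a *planted* truth:
`U_true, V_true ~ U(0,1)` of rank `d_true`, interactions set to 1 on the
top `density` fraction of `U_true V_trueᵀ`, optional independent entry
flips, and a recorded hold-out subset of positives. Default study
conditions: 40 lncRNAs × 12 proteins, rank 4, density 0.15 (the density
of the denser public lncRNA–protein benchmark), no noise, 24 tissues, a
30-term single-rooted ontology, 15% of positives held out. Sequences are
uniform random over their alphabets, expression is i.i.d. log-normal,
and annotations are uniform term draws.

This emulates the *formats* and the low-rank interaction structure the
solver targets, but deliberately not the biology: in real data, sequence,
expression and annotation similarity carry information about
interactions, whereas in the fixture they are independent of the planted
truth by construction. Consequently 8 of the 9 similarity networks the
pipeline fuses are pure noise on synthetic data, and the only exploitable
signal is the interaction profile itself. Passing tests on this fixture
therefore demonstrate correctness of the machinery (formats, formulas,
invariants, leakage-free evaluation, cold-start plumbing) and
above-chance recovery from profile structure — they do not demonstrate,
and cannot bound, the accuracy attainable on real data where the side
information is informative. The measured ceiling is correspondingly
modest: on the default fixture, cross-validated AUPR over known pairs is
roughly 0.13–0.19 against a chance level of ~0.03, and direct
profile-propagation baselines reach ~0.3–0.7 on the same protocol.

## Evaluation protocols

Three 5-fold protocols, each repeated over five fixed seeds
(101, 103, 107, 109, 113 by default): CV over known pairs (each fold's
test set is its fifth of the positives plus *all* unknown pairs), CV over
lncRNA rows, and CV over protein columns (zeroed rows/columns become the
test instances). Metrics: AUPR by step-interpolated precision–recall
integration (the primary metric under heavy class imbalance), AUC as the
tie-averaged rank statistic, and F1 reported as the maximum over all
score-induced thresholds together with the achieving threshold (the
operating threshold is otherwise undefined for a ranking method). The
hit rate of a protein is the fraction of its true test lncRNAs appearing
among its top-n ranked candidates.

## Known limitations

- The printed multiplicative updates are not provably monotone (see
  above); monotonicity is monitored, not proven.
- The fusion step is a simplified diffusion scheme, not a faithful
  reimplementation of heavier network-fusion algorithms.
- Feature descriptors follow the standard constructions but are not
  bit-compatible with the repDNA/protr reference packages (different
  property tables).
- Latent completion can only help cold entities whose fused similarity
  to interacting entities is informative; with uninformative side data
  it dilutes rather than sharpens predictions.
- The evaluation assumes unobserved pairs are negatives, the standard
  (and biased) convention for this problem.
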
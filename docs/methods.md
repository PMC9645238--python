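# Methods

## Model

`asmatch` estimates the pairwise alignment distance of two nucleotide
sequences without aligning them.  A sequence S = s_1…s_L is mapped to an
embedding u ∈ R^N_{≥0}; the estimate for a pair is the cosine distance of
the two embeddings.  The map is a bank of N learnable *patterns* scored
against the sequence by a smoothed approximate-string-matching (ASM)
dynamic program:

* each pattern is an M×4 real matrix P = [p_1 … p_M]ᵀ over the one-hot
  alphabet (columns A, C, G, T); the reward for pairing pattern position
  m with sequence position ℓ is p_m·s_ℓᵀ;
* the (M+1)×(L+1) scoring matrix follows the classic infix-search
  recursion — free start (first row 0), pattern-deletion boundary
  F(m,0) = −m·g — with interior cells

      F(m,ℓ) = max_γ( F(m−1,ℓ−1) + p_m·s_ℓᵀ,  F(m−1,ℓ) − g,  F(m,ℓ−1) − g ),

  where g > 0 is a learnable gap penalty shared by all patterns and
  max_γ(a) = γ·log Σ_j exp(a_j/γ) is the smoothed maximum (a smooth upper
  bound of the hard max, within γ·log J of it, exact as γ→0);
* the pattern's score v_n is the **hard** maximum of the last row (free
  end), and u = ReLU(v + b) with a learnable bias b ∈ R^N.

Variable-length input is handled natively: the DP consumes whatever L it
is given, and the embedding dimension is always N.

Training is Siamese: the two sequences of a pair pass through the same
parameters Θ = (P_1…P_N, g, b), and Θ minimizes the mean squared error
between cosine embedding distances d_e and Needleman–Wunsch alignment
distances d_a over a training set of pairs.

## Alignment ground truth

d_a is computed from the optimal affine-gap global alignment (Gotoh) at
match 2, mismatch −3, gap open −5, gap extend −2; a gap run of length k
costs open + (k−1)·extend.  The NW score itself is not bounded or
comparable across lengths, so the distance is the standard p-distance
over the alignment: d_a = 1 − (identical columns)/(alignment length),
which lies in [0, 1] like the cosine distance.  A column counts as
identical only when both residues are the same unambiguous base.  The
alignment is delegated to Bio.Align.PairwiseAligner; its traceback
enumeration is deterministic, so d_a is reproducible even between
co-optimal alignments.

## Gradients

The loss is differentiable in Θ except through two argmax choices that
are treated as fixed per forward pass (a subgradient): the last-row
argmax defining v, and the choice of the best-matched window.  The window
S̃ — the stretch of sequence consumed by backtracking from the last-row
argmax with ties broken diagonal > up > left — is the only part of the
input that determines v, so gradients are computed on a small
differentiable NW matrix F̃ over S̃ alone (both boundaries penalized,
−m·g and −ℓ·g), at cost O(M·L̃) instead of O(M·L) per pattern:

* ∂F̃(m,ℓ)/∂p_m = w_diag(m,ℓ)·s̃_ℓ, where w_diag, w_up, w_left are the
  softmax weights of a cell's three branch values (they sum to 1);
* ∂F̃(M,L̃)/∂F̃(m,ℓ) is accumulated backward through each cell's three
  downstream neighbours, seeded with 1 at (M, L̃);
* ∂F̃/∂g is accumulated forward, seeding boundaries with −m and −ℓ and
  weighting the two gap branches by (child − 1) and the diagonal branch
  by (child).

An empty window (the optimum deletes the whole pattern) contributes zero
pattern gradient and ∂v/∂g = −M, the all-gap limit.

The windowed gradient is an approximation to the gradient of the full
smoothed DP: paths outside the chosen window carry weight e^{−Δ/γ} where
Δ is their score deficit.  At the default γ = 0.1 the end-to-end
agreement with central finite differences of the exact loss is ~1e−4
normwise on random instances; at γ ≳ 0.5 the approximation loosens by
design (the tests quantify both regimes).  Within the window the
analytic recursions agree with finite differences to ~1e−10.

## Numerical implementation

The training-time forward pass runs in the exponent domain: with
E = exp(F/γ) the smoothed-max recursion becomes the multiply–add

    E(m,ℓ) = E(m−1,ℓ−1)·e^{r/γ} + e^{−g/γ}·(E(m−1,ℓ) + E(m,ℓ−1)),

evaluated anti-diagonal by anti-diagonal over all (sequence, pattern)
slots of a mini-batch at once, with each anti-diagonal rescaled by its
maximum and the log-scale tracked per sequence (exact up to rounding, as
in scaled HMM forward passes).  Because a reward can only take one value
per IUPAC code, rewards are read from a 16×M×N table rather than a dense
tensor.  When |reward|/γ or g/γ exceeds the float64 exponent range
(γ ≲ 2e−3 at unit rewards) the implementation falls back to a log-domain
log-sum-exp path.  A pure-numpy per-pattern reference implementation of
every recursion is kept alongside the kernels and the test suite asserts
agreement between the two paths to 1e−9.

Other numerical choices:

* cosine distance is guarded as 1 − u_1·u_2/((‖u_1‖+ε)(‖u_2‖+ε)) with
  ε = 1e−8; two zero embeddings are at distance 1;
* all backtracking tie-breaks are fixed (diagonal > up > left; last-row
  argmax takes the smallest column), so runs are bit-reproducible;
* g is floor-clamped at 1e−3 after each optimizer step to stay positive;
* the per-batch objective is the *mean* of squared errors (not the sum),
  so the learning-rate scale is independent of batch size; the optimum
  is unchanged.

## Training defaults

| parameter | default | note |
|---|---|---|
| patterns N | 300 | published operating point; error flattens above 300 |
| pattern length M | 20 | published operating point |
| smoothing γ | 0.1 | not stated in the original description; recorded in the model file |
| optimizer | Adam (β₁ 0.9, β₂ 0.999) | learning rate 1e−4, 200 epochs |
| batch size | 32 pairs | unstated originally; configurable |
| init | patterns i.i.d. U(−½, ½), g = 1, b = 0 | see below |

Pattern initialization is zero-mean.  An all-positive init (e.g.
U(0, 1)) makes every pattern score close to the same large positive
value for every sequence, so all embeddings start nearly parallel and
cosine distances sit orders of magnitude below the d_a targets; at small
learning rates the optimizer cannot bridge that scale gap within a
desk-scale epoch budget (measured: the loss stays within 10% of its
starting value).  Zero-mean rewards give spread-out scores from the
start, which is the standard motivation for zero-mean filter
initialization.

## Synthetic data

The generator emulates amplicon-like divergence: an ancestral i.i.d.
uniform sequence radiates serially into family ancestors (one mutation
step per family: 5% substitutions, 1% insertion and deletion events per
position), and each ancestor spawns members at strain-level divergence
(3% substitutions, 0.5% indels).  Indel run lengths are geometric
(success ½) capped at 5 — short indels dominate real amplicon
divergence.  Serial radiation makes clades nested, so pairwise d_a
covers a graded spectrum (roughly 0.03–0.5 at the default desk scale)
rather than collapsing onto within/between levels; this mirrors the
continuous distance clouds of real 16S data.  One master seed is split
into per-family child streams, so adding families never perturbs earlier
ones.

What the generator does **not** emulate: sequencing-error profiles
(Illumina/PacBio), chimeras, primer artifacts, compositional bias, or
conserved/variable region structure within the gene.  Passing the
desk-scale tests therefore shows that the architecture and training
machinery recover alignment distances under realistic substitution/indel
divergence — not that a model trained here transfers to any particular
real dataset; real use requires training on pairs drawn from the target
data, as the published full-scale protocol does.

## Desk-scale protocol sizes

The validation protocol (tests and `scripts/acceptance.py`) uses sizes
chosen to exercise every code path in minutes on one CPU: 10 families ×
20 members of length ~150 nt, 2,000 training pairs, 60 epochs, N = 50,
M = 12, 1,000 held-out pairs (disjoint from training), 50 taxonomy
queries, and 500/200/100-instance randomized oracle and gradient checks.
The published full-scale setting (5 million training pairs, N = 300,
M = 20, 200 epochs) is out of scope here.

## Known limitations

* The windowed gradient ignores the sensitivity of the window choice
  itself; near window ties the gradient is discontinuous (shared with
  the underlying method).
* The exponent-domain kernel requires M·max|reward|/γ within float64
  exponent range; extreme parameter magnitudes fall back to a slower
  path.
* MRE excludes zero-distance pairs (relative error undefined there); the
  excluded count is reported alongside.
* Embedding-based taxonomy is scored against the NW best hit, i.e. it
  measures concordance with an exhaustive alignment search, not against
  an external taxonomy.
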
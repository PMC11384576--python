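# Methods

`hpagtwr` implements a two-part analysis: (i) a **health policy attention
(HPA) index** computed from government documents as the share of total term
frequency contributed by a curated health lexicon, times 100; and (ii) a
**geographically and temporally weighted regression (GTWR)** of that index
on socioeconomic covariates, with spatial diagnostics. Because the original
corpora (Chinese municipal government work reports) and statistical-yearbook
covariates are not redistributable, the package ships a synthetic-data
generator that emulates the study design — 323 cities observed 2018–2021 —
with fully known ground truth, so every stage is testable end to end.

## The attention index

A document is a bag of tokens. Given a lexicon L,

    HPA = 100 · #{token occurrences in L} / #{all token occurrences}.

Occurrences, not unique types, are counted in both numerator and
denominator; no stop words are removed, so the denominator is the full
document as tokenized. The score is therefore invariant to token order and
to duplicating the document, and lies in [0, 100]. Multiple documents for
one (city, year) are pooled (token counts concatenated) before scoring.
Tokenization defaults to lowercasing + whitespace splitting; a segmenter
callable can be injected for languages without whitespace word boundaries.
Whether punctuation or numerals should be excluded from the denominator is
left to the tokenizer: the scorer counts every token it receives.

## Lexicon construction

The lexicon starts from a small seed set of health words and is expanded
distributionally. A CBOW (continuous bag-of-words) word-embedding model —
predict the center word from the average of its context vectors, trained
with negative sampling — is fit to a corpus; every non-seed vocabulary word
is scored by its **maximum** cosine similarity to any in-vocabulary seed
(max rather than mean: a word strongly tied to a single health seed is
health-related even if unrelated to the others). Candidates are ranked by
(score desc, word asc) — the lexicographic tie-break makes rankings
reproducible and top-k results prefix-monotone — truncated to `top_k`
and to `score ≥ min_similarity`, then filtered by an explicit **accept
list** that stands in for expert review. The final lexicon is
seeds ∪ accepted, with per-word provenance retained.

The CBOW trainer is a compact single-threaded numpy implementation
(vocabulary ordered by frequency then lexicographically; input vectors
initialised uniform(−0.5/d, 0.5/d), output vectors zero; unigram^0.75
negative-sampling distribution; learning rate decaying linearly from 0.025
to 1e-4). Sequential single-threaded updates make training bit-reproducible
for a fixed seed — the reason multithreading is deliberately absent.
Defaults (dim 100, window 5, 20 epochs, min_count 5, 5 negatives) are
ordinary word2vec practice and are exposed in the config.

## The regression model

Each observation i (a city-year) has planar coordinates (u_i, v_i) in km,
year t_i, response y_i (HPA percent) and covariates x_ik. The model lets
all coefficients vary over space and time:

    y_i = β0(u_i, v_i, t_i) + Σ_k βk(u_i, v_i, t_i) x_ik + ε_i.

At each focal observation the coefficients are estimated by weighted least
squares, β̂(i) = (XᵀW_iX)⁻¹XᵀW_i y, with diagonal weights from a kernel on
the squared spacetime distance

    d²_ST(i, j) = λ_s [(u_i−u_j)² + (v_i−v_j)²] + μ_t (t_i−t_j)².

The additive combination with scale weights (λ_s, μ_t) is the standard way
to put km² and years² on one axis. Defaults: λ_s = 1 and μ_t = τ², where τ
is the median nearest-neighbour distance between distinct cities — one year
of separation then weighs like one typical inter-city hop. Both are
configurable; analyses that probe *temporal* shifts (e.g. a step at a
pandemic year) should scale μ_t up — the package's step-recovery study uses
μ_t = 9τ², without which CV smooths across years and attenuates the step.
Years enter as raw integers, centered before distance computation (pairwise
differences are unchanged; centering only keeps magnitudes small).

Kernels: Gaussian w = exp(−d²/h²) (default, always positive) or bisquare
(compact support). The bandwidth h applies to the combined distance.

### Bandwidth selection

h is chosen by leave-one-out cross-validation: the focal observation's own
weight is set to zero and Σ_i (y_i − ŷ_{≠i})² minimised, either over an
explicit grid or by golden-section search on an assumed-unimodal CV curve
(`tol` controls the bracket width). Ties break toward the larger h — the
smoother, better-conditioned model. A singular local fit during CV yields a
logged +∞ sentinel so the search can pass through degenerate candidates; if
no candidate is finite a bandwidth error is raised.

### Fit statistics

The hat diagonal uses the local-smoother convention
s_ii = w_ii · x_iᵀ(XᵀW_iX)⁻¹x_i, and trace(S) = Σ s_ii is the effective
number of parameters. The corrected AIC follows the GWR convention

    AICc = n·ln(σ̂²) + n·ln(2π) + n·(n + tr S)/(n − 2 − tr S),  σ̂² = RSS/n,

and adjusted R² uses trace(S) in its degrees of freedom. The OLS baseline
(statsmodels under the hood) reports the same AICc formula with tr S = k+1,
so the two criteria are directly comparable and the GTWR fit converges to
the OLS values in the flat-kernel limit h → ∞ (verified to 1e-6/1e-3 in the
tests). RSS is floored at the smallest positive float before the log so
exact zero-noise fits do not produce −∞ with a warning.

### Numerical choices

* `fit_local` solves the weighted system via QR on √w-scaled rows; the
  batched whole-panel solver forms XᵀW_iX explicitly (an einsum over the
  weight matrix) and screens reciprocal condition numbers.
* Reciprocal condition < 1e-10 → a singularity error naming the focal
  observation; trace(S) ≥ n−2 → a bandwidth-too-small error.
* Coordinates are synthetic projected planar km. No CRS is claimed; kernel
  distances require a metric plane, which lon/lat is not.

## Diagnostics

**Moran's I** with permutation inference justifies the spatial model:
I = (n/S0)·Σ w_ij z_i z_j / Σ z_i², with p = (1 + #extreme)/(1 + n_perm)
over random relabelings (default 999, seeded; smallest attainable p is
1/(n_perm+1)). Default weights: k-nearest (k = 5) symmetrized by union and
row-standardized, applied to city-level mean HPA — the aggregation and
scheme are configurable since reasonable analyses differ here.
Inverse-distance weights with a cutoff are also provided (with cutoff equal
to the lattice step they reproduce rook contiguity, which the tests use for
the checkerboard closed form I = −1 and the null expectation −1/(n−1)).

**Nonstationarity screen**: a covariate's coefficient is flagged as
genuinely varying when the interquartile range of its n local estimates
exceeds twice the OLS standard error of the global coefficient (plus a
1e-10 absolute floor so exactly-fit zero-variance designs are not flagged
on round-off). Quantiles everywhere are linear-interpolation (type 7).

**Reporting tables**: per-variable AVG/MIN/LQ/MED/UQ/MAX over local
coefficients, and period-averaged coefficients around a split year
(default 2020) with change ≡ during − before.

## The synthetic-data generator

The generator emulates the study conditions, not any real dataset:

* **Grid**: n cities uniform on [0, extent]² (defaults 323 cities,
  1000 km); the "capital" (political center) is the city nearest the
  centroid and anchors radial coefficient surfaces.
* **Covariates**: nine variables matching the study's printed moments
  (means, SDs, ranges) via truncated-normal draws; the city-type indicator
  is Bernoulli(0.8869). Draws are iid across observations — real covariates
  are strongly autocorrelated within a city over years, which the generator
  does not emulate.
* **Surfaces**: closed-form coefficient fields — constant, linear in
  (u, v, t), radial decay from the capital, or a step at a pandemic year —
  plus Gaussian noise (default 0.05 percent points for the nine-covariate
  demo; 0.25 for the three-covariate recovery benchmark whose coefficient
  surfaces are order one). The balanced 4-year panel reflects the study
  frame; an unbalanced option is not provided.
* **Corpora**: documents with an exact planted health-token share, so
  scoring round-trips to the target within 100/(2·doc_length); the default
  5000-token documents (long annual reports) bound quantization at 0.01
  percent points. A separate co-occurrence generator plants seeds/synonyms
  in shared context templates and distractors in disjoint ones, giving the
  embedding stage a corpus with known distributional ground truth.

Tokens are opaque ASCII strings; no attempt is made to mimic Chinese
morphology or real report structure. Passing tests therefore demonstrate
the correctness of the algorithms under the stated model, not performance
on real government text.

## Study sizes used in tests and the acceptance script

Unit tests run on 10–80-city panels; the recovery and model-comparison
studies use the full 323 × 4 frame (n = 1292, 3 covariates). The embedding
recovery study uses 20 replicates of a 500-sentence corpus at dim 50. These
sizes give stable statistics while keeping the whole suite fast on a single
core.

## Known limitations

* λ_s/μ_t are not jointly cross-validated with h; only h is searched.
* No mixed (partially stationary) GTWR, no spatial-lag/error models, and no
  adaptive (k-nearest) bandwidth — the fixed Gaussian kernel is the default
  analysis.
* The CBOW trainer is built for small corpora (10⁴–10⁵ tokens); it is
  quadratic in nothing but far slower per token than optimized C
  implementations, and subsampling of frequent words is not implemented.
* Moran's I inference assumes exchangeability under the null; covariate-
  conditional autocorrelation is not tested.
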
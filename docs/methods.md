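# Methods

## Model

The package learns a directed acyclic graph (DAG) over n continuous
variables from m joint observations, assuming each variable is
generated by an additive noise model (ANM)

    X_i = F_i(X_{P_i}) + E_i,

where P_i is the parent set of X_i in the DAG, F_i is the causal
function, and the noise E_i is independent of the parents. Under the
causal Markov and faithfulness assumptions the joint density factorizes
over the graph, and the log-likelihood of the data equals the
log-likelihood of the noise values e_{j,i} = o_{j,i} − F_i(o_{j,P_i})
under the noise densities. Likelihood alone cannot distinguish DAGs in
the same Markov equivalence class; the functional form plus
non-Gaussian noise restores identifiability of edge directions, which
is why the synthetic benchmarks default to uniform noise.

## Score

Each node contributes a local score

    L'_i = Σ_j log p̂_i(e_{j,i}) − d_i · ln(m) / 2,

where p̂_i is a Gaussian-kernel density estimate of the residuals and
d_i is the number of fitted regression coefficients (intercept
included; d_i = 1 for a parentless node, k+1 for a linear fit with k
parents, the basis size for polynomial families). The BIC-style penalty
d_i·ln(m)/2 guards against redundant parents at finite m. The
functional causal likelihood (FCL) of a structure is the sum of local
scores; the improved score (IFCL) raises every local score by an
adjustment threshold α ≥ 0:

    total_ifcl = total_fcl + n·α.

The constant shift matters through the search acceptance rule, not
through the ranking of complete structures.

## Search

Hill climbing over DAGs with single-edge moves (add, delete, reverse;
changed nodes {to} or, for reversals, {from, to}). A candidate is
accepted iff its iteration likelihood L_B* exceeds the running adjusted
likelihood L̄_B, which reduces algebraically to

    Σ (local-score gains over changed nodes) > (#changed) · α,

i.e. α is a per-refitted-node acceptance margin. Reversals require the
margin on the two changed nodes jointly. The running total threshold
α_k starts at n·α and decreases by (#changed)·α at each accepted move.
Selection is best-improvement with ties broken by a fixed lexicographic
move order (add < delete < reverse, then edge), making the search fully
deterministic given (data, α, family, initial graph); the `seed`
argument exists only for interface uniformity. The default initial
graph is empty. Termination is guaranteed: every accepted move strictly
increases total_fcl, which is bounded above for fixed data. As a
consequence the search always returns *some* structure — with a very
large α it returns the (possibly empty) initial graph rather than
failing.

An exhaustive enumeration of all labelled DAGs (1, 3, 25, 543, 29281
for n = 1..5) provides a global-optimum oracle; local scores are
precomputed once per (node, parent set) so enumeration dominates the
cost. It is used in tests to confirm the greedy search attains the
global maximum on strong-signal 3-node problems.

All mechanism fits are memoized by (node, parent set, family): local
scores do not depend on the rest of the graph, so a single cache serves
an entire search, the exhaustive oracle, and a whole α sweep on the
same data.

## Noise density estimation

Residual densities use a Gaussian kernel with Silverman's rule-of-thumb
bandwidth h = 0.9·min(sd, IQR/1.34)·m^(−1/5), floored at 1e−3 times the
residual scale (1e−3 absolutely when the residuals are numerically
constant) so degenerate fits still yield finite log-densities.
Evaluation is done in log space with a chunked log-sum-exp; no
in-sample point can underflow to −∞. The default evaluates the KDE at
the same residuals it was fitted on, mirroring the definition of the
score; because in-sample KDE likelihood is optimistically biased, a
leave-one-out mode (`loo=True`, excluding the kernel centered on the
evaluated point) is available throughout. Sanity anchor: for m = 5000
standard-normal residuals the in-sample mean log-density falls within
0.05 of the differential entropy −½ln(2π) − ½ ≈ −1.4189.

## Regression families

The causal functions default to ordinary least squares linear
regression (`linear`); `poly2`/`poly3` use a full polynomial basis
(powers and cross terms) with d_i equal to the basis size. A
rank-deficient design (e.g. duplicated parent columns) raises a
numerical error rather than silently fitting.

## Preprocessing

Tables are read from delimited text with a header. The pipeline is:
drop the outcome/class column; recode exact zeros as missing in
user-listed columns (Pima-style files encode unmeasured glucose, blood
pressure, skinfold, insulin and BMI as 0); mean-impute missing cells
(column means over observed values, computed on the raw scale);
Z-score each column with the sample (m−1) standard deviation; replace
cells with |z| > zmax (default 3) by the column mean, i.e. 0. The
replacement step runs after standardization, so column moments may
drift slightly from (0, 1) afterwards; counts of imputed and replaced
cells are reported per column. Constant or fully missing columns are
errors, not silent drops.

The Pearson screen (all n(n−1)/2 pairs, two-sided P values from the t
distribution on m−2 df) is exploratory metadata: pairs with |r| below
the cutoff (default 0.1, applied to the absolute value) are flagged as
lacking a linear relationship. By default the screen does not constrain
the search; an optional mode restricts candidate edge additions to the
retained skeleton.

## Synthetic benchmark

`sample_anm` generates data from a known DAG in topological order:
linear (Σ c_k·x_k) or quadratic (Σ c_k·(x_k + x_k²/2)) mechanisms with
coefficient magnitudes drawn from [0.5, 0.95] — bounded away from zero
so the signal is detectable at sample sizes of 500–5000 — and uniform
(default half-width 0.5), Laplace, or Gaussian noise. Output is
Z-scored, mirroring the real-data preprocessing. Recovery is quantified
by structural Hamming distance (edge insertions/deletions/reversals
over unordered pairs), skeleton and directed precision/recall, and
counts of reversed and redundant edges.

What the generator does not emulate: latent confounders, selection
bias, measurement error, discrete or mixed-type variables,
heteroscedastic noise, and the particular marginal distributions of
clinical variables. Passing recovery tests therefore demonstrate the
correctness of the score and search on data satisfying the model's own
assumptions, not field performance on epidemiological tables.

## Scale of α, and what validation covers

The score here is a raw sum over all m samples, so a genuine edge is
typically worth tens to hundreds of nats and the practically
interesting α range scales accordingly (the examples sweep α up to a
few hundred on m = 2000). Implementations that normalize the likelihood
per sample (total magnitudes of order −8 rather than −10⁴) compress the
same margins into an α band of roughly 0.05–0.18; α values are
therefore not transferable across the two conventions, and this package
reports the normalized total/(n·m) alongside raw totals for
comparability. Over the 0.05–0.18 band on raw sums, sparsification is
limited to knife-edge spurious edges whose net gain lies within that
band of zero; the validated trend is the weak inequality (edge count
non-increasing in α).

Validation problem sizes (unit + acceptance suites, and
`scripts/acceptance.py`): 3-node chains at m = 1000–2000 (100 seeds)
for oracle equivalence and directed recovery; 4-node random DAGs at
m = 200–500 for the score identities, α = 0 identity, and margin
nesting (≥1000 triples); 6-node/6-edge graphs at m = 2000 (20 seeds)
for the α sparsification trend; m = 5000 for the KDE anchor. Larger
problems run fine but add nothing to the properties checked.

## Known limitations

- With Gaussian noise and linear mechanisms the edge direction is not
  identifiable; only skeleton-level recovery should be expected.
- In-sample KDE likelihood is upward-biased and mildly favors complex
  parent sets; the BIC penalty compensates in practice, and the
  leave-one-out mode exists for users who want the unbiased variant.
- Greedy search can stop in a local maximum; the exhaustive oracle is
  limited to n ≤ 5, and enumeration at n = 5 is slow (about 10⁶
  candidate parent-set assignments).
- The likelihood totals depend on the regression family and KDE
  bandwidth convention; totals from other ANM implementations are not
  directly comparable.
- The search cannot "fail to find a structure": with unreachable
  margins it returns the initial graph.
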
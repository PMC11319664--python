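# Methods

## Model

`isingspikes` fits the pairwise maximum-entropy model of binary neural
activity.  A raster assigns each unit `i` and time bin `t` a spin
`s_i(t) ∈ {−1, +1}` (+1 = spike).  The observed constraints are the
time-averaged activities `⟨s_i⟩ = (1/M) Σ_t s_i(t)` and the connected
pairwise correlations `C_ij = ⟨s_i s_j⟩ − ⟨s_i⟩⟨s_j⟩`, both with the
population `1/M` normalization.  The distribution of maximum entropy
consistent with these constraints is the Boltzmann distribution
`P({s}) ∝ exp(−H/T)` of the Ising Hamiltonian

    H = − Σ_i h_i s_i − Σ_{i>j} J_ij s_i s_j ,      k_B = 1,

with local fields `h_i`, symmetric zero-diagonal couplings `J_ij`, and
an arbitrary operating temperature `T_o` (1 by convention; only `h/T`
and `J/T` are identifiable, so `T_o` just fixes the parameter scale).

## Inference

Parameters are found by Boltzmann-machine moment matching: starting
from `h = 0`, `J = 0` at iteration `n = 1`,

    J_ij(n+1) = J_ij(n) − η(n) [C_ij^model − C_ij^obs]
    h_i(n+1)  = h_i(n)  − η(n) [⟨s_i⟩^model − ⟨s_i⟩^obs]

with the learning rate `η(n) = η₀ / n^0.4`.  This is gradient descent
on the KL divergence between data and model, so the matched moments are
the unique maximum-entropy fixed point.  Defaults: `η₀ = 0.05` (stable
for ±1-scale moments up to N = 60 units) and an 80,000-iteration
budget, with an optional early stop on the maximum moment mismatch.

Model moments per iteration come from one of two interchangeable
back ends:

* **Monte Carlo** (`gradient_mode="monte_carlo"`, any N): single-spin-flip
  Metropolis dynamics — a sweep is N proposed flips at uniformly random
  sites, acceptance `min(1, e^{−ΔH/T})`; a Glauber heat-bath rule and a
  sequential site order are available behind the same interface.  Each
  iteration's chain is warm-started from the previous iteration's last
  configuration (default budget 100 equilibration sweeps + 1,000
  retained samples per iteration).  Proposal energy changes are
  evaluated directly from the current configuration through the local
  field `h_i + Σ_j J_ij s_j`, so there is no incremental energy
  bookkeeping that could drift; a test asserts this identity against
  full energy recomputation.
* **Exact enumeration** (`gradient_mode="exact"`, N ≤ 20): Boltzmann
  weights over all 2^N states with log-sum-exp stabilization.  This is
  also the oracle that Monte Carlo estimates are validated against.

Units that never or always fire (`|⟨s_i⟩| = 1`) make the matched field
diverge; `fit_ising` refuses them by default, or clamps the mean to
`±(1 − 1/M)` with a warning when asked (`clamp_degenerate`, the
default in the scikit-learn estimator wrapper `PairwiseMaxEntIsing`).

All chains are seeded explicitly; every fit, sweep and report is
bit-reproducible for fixed seeds.

## Validation statistics

* **P(K)**: the distribution of the number of simultaneously firing
  units per bin, fitted by nonlinear least squares to
  `p(K) = α e^{−βK}` over the populated bins (log-linear fit
  available).  Because α and β are estimated from the same sample and K
  is discrete, the KS p-value uses a parametric bootstrap (default
  1,000 replicates; parameters re-estimated per replicate).  On rasters
  generated by the package's own Ising ground truth this test often
  rejects — the model's true P(K) is only approximately exponential and
  M = 20,000 bins give the KS test high power; that is the expected
  behavior, not a defect.
* **Triplets**: the three-point statistic is the connected third
  central moment `T_ijk = ⟨(s_i−⟨s_i⟩)(s_j−⟨s_j⟩)(s_k−⟨s_k⟩)⟩` over
  `i<j<k` (the standard choice in pairwise-MaxEnt spike analyses; the
  definition is a single swappable function).  Since the learner never
  sees triplets, agreement between model and observed triplets is a
  genuine generalization test.  The mean relative error
  `⟨(T^model − T^obs)/T^obs⟩` is ill-defined at `T^obs ≈ 0`, so triples
  with `|T^obs| < ε` (default `ε = 10⁻³`) are excluded and counted.
  For display, paired triplets are sorted by observed value and split
  into equal-count quantile bins (default 100; populations differ by at
  most one, so every bin is populated); equal-width binning is an
  option.
* **Parameter distributions**: fields and upper-triangle couplings are
  summarized by mean, SD and sample skewness; couplings get a
  maximum-likelihood Gaussian fit with a one-sample KS test (parameters
  estimated from the data, which makes the test conservative).

## Thermodynamics

For a configuration, `M = (1/N) Σ_i s_i` and `E = H/N` per spin (the
per-spin energy is sometimes written without the Hamiltonian's minus
signs; only Var(E) enters the observables below, so the sign convention
is immaterial and we report the Hamiltonian per spin).  The
fluctuation-dissipation observables are, exactly as printed and in the
per-spin convention (no factor of N; `extensive=True` restores the
textbook convention):

    C(T)  = (⟨E²⟩ − ⟨E⟩²) / T²        specific heat
    χ(T)  = (⟨M²⟩ − ⟨M⟩²) / T         susceptibility

Temperature sweeps default to the grid T ∈ [0.5, 2.0] in steps of 0.02
with a fresh random chain per temperature ("independent"); ascending /
descending modes warm-start from the neighboring temperature for the
hysteresis check, which flags any M(T) discrepancy above 3 combined
standard errors between protocols (absence of hysteresis is the
second-order-transition signature).  Standard errors come from
independent replicate chains, which also absorb autocorrelation.  The
peak temperature `T_c*` is the grid argmax refined by a quadratic fit
through the three surrounding points (exact for parabolic peaks); a
boundary maximum triggers a warning since the peak is not bracketed.

**Zero-field caveat.**  For models with `h = 0` the ordered phase is
two-fold degenerate and the plain Var(M) is dominated by inter-well
flips: exactly (by enumeration, or the magnetization-sector sum for
uniform couplings) it grows monotonically as T decreases, so it has no
interior peak at small N.  `abs_magnetization=True` substitutes |M|,
the standard finite-size treatment; with it the uniform ferromagnet
`J_ij = J0/(N−1)` at N = 30 has its exact susceptibility peak at
T ≈ 0.85 J0, i.e. shifted below the mean-field transition
`T_c = J0·N/(N−1)` by the expected O(N^{−1/2}) amount.  Tests compare
Monte Carlo peaks against this exact finite-size location rather than
the infinite-N formula.  Learned culture-like models have strong fields
and never need the flag.

## Synthetic data

The generator emulates the statistical shape of multielectrode culture
recordings (default 60 units × 20,000 bins):

* couplings `J_ij ~ Normal(0, j_sigma)` symmetrized, zero diagonal,
  default `j_sigma = 1.2/√N`;
* fields `h_i = h_location − h_scale · LogNormal(0, h_skew)` — mostly
  negative and left-skewed (defaults −0.6, 0.6, 0.6), giving sparse
  firing and an exponentially decaying P(K);
* rasters sampled from the ground-truth model by Metropolis at T = 1,
  with 5 sweeps between retained states to suppress chain
  autocorrelation (experimental time series are not MC output, so
  residual autocorrelation would be a modeling artifact), plus an
  independent-Bernoulli null generator.

At the default `j_sigma` the model has no spontaneous order at T = 1
(the random field dominates), while its crossover — the specific-heat
peak — sits above T = 1 (≈ 1.2–1.4 at N = 12–24), mirroring inferred
culture models whose `T_c*` exceeds the operating temperature.  With
zero-centered Gaussian couplings the susceptibility of this
random-field model has no interior peak on [0.5, 2] at desk-scale N
(weakly polarized units dominate Var(M) at low T); the crossover is
therefore read from C(T).

What passing tests on this generator do **not** show: real recordings
have temporal structure (bursts, refractoriness, avalanches) that the
equilibrium generator lacks, their correlation distributions are
positively skewed in a sample-specific way, and N = 60 systems carry
sample-to-sample variability that desk-scale N = 12–30 checks only
sketch.

## Test and report scales

Checks run at sizes chosen so the whole suite stays at desk scale:
oracle equivalence and exact-gradient recovery at N = 6 (and N = 3
state-frequency detailed balance), end-to-end Monte Carlo recovery at
N = 15 with M = 20,000 bins, triplet generalization at N = 12
(220 triples), the shuffle control at N = 24, thermodynamic closed
forms at N ≤ 10 and the ferromagnet check at N = 30.  For the recovery
check the generator uses `j_sigma = 0.6/√N` (safely paramagnetic at
T = 1) and moderate sparsity (`h_location = −0.3`, `h_scale = 0.3`,
`h_skew = 0.5`, mean activity ≈ −0.5): at M = 20,000 the
coupling-estimation noise that leaks into the fields is the binding
accuracy limit, and very sparse units simply do not carry enough
pairwise signal for any estimator — with heavier sparsity even the
exact-gradient solution's field correlation degrades.  The triplet
check keeps sparser fields (−0.4/0.4/0.6) and `j_sigma = 0.8/√N`,
where the triplet signal itself is the quantity of interest.

## Known limitations

* Moment matching with Monte Carlo gradients inherits gradient noise;
  the decaying learning rate averages it but the final parameters
  retain O(η·SE) jitter.  Exact gradients remove this for N ≤ 20.
* The relative-triplet-error statistic is dominated by near-guard
  denominators; the Pearson correlation and the binned comparison are
  the more stable summaries.
* No regularization is applied; for undersampled rasters (M small
  relative to N²) the inverse problem will overfit sampling noise in
  the covariances.
* Cluster Monte Carlo algorithms are deliberately absent: frustrated
  couplings make them inapplicable.
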
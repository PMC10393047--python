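# Methods

`edmnet` reconstructs directed species-interaction networks from quantitative
eDNA time series and asks how interaction strength responds to temperature.
The pipeline has five stages — community simulation, spike-in quantification,
state-space reconstruction with transfer-entropy causality tests, multiview
distance regularized S-map interaction strengths, and gamma-family
temperature-sensitivity models. This note records the models, the estimator
choices, and the limits of what the synthetic validation can show.

## 1. Synthetic community model

The simulator exists so that every inference stage can be checked against
analytic truth. The latent dynamic is a temperature-modulated discrete-time
Ricker map,

    x_{i,t+1} = x_{i,t} exp( r_i + beta_i*Ts_t
                             - sum_j a_ij (1 + gamma_ij*Ts_t) x_{j,t}
                             + eps_{i,t} ),

with `Ts` the standardized water temperature, `a_ii > 0` self-limitation
(the diagonal equals `r_i`, putting the single-species equilibrium at 1),
`beta_i` the growth-rate response to temperature, `gamma_ij` the
dimensionless slope of each coupling against temperature, and `eps`
Gaussian process noise on the log scale (default SD 0.05 per half-month
step). The Ricker form was chosen because it is bounded below by zero, is
the canonical overcompensating fish stock–recruitment map, and has a
closed-form one-step Jacobian,

    dx_{i,t+1}/dx_{j,t} = exp(g_i) * (delta_ij - x_i a_ij (1 + gamma_ij Ts)),

which serves as the ground-truth "interaction strength at time t"
(`jacobian_oracle`; verified against central finite differences to 1e-6
relative in the tests). Temperature enters both growth and coupling so the
headline phenomenon — temperature-dependent interaction strength — is
present by construction and recoverable in principle.

Defaults mirror a multi-site half-monthly coastal survey: 11 sites on a
4 °C latitudinal gradient, ~50 half-monthly occasions (period 24 steps/year,
seasonal amplitude 4.5 °C, weather noise 0.5 °C), 50 species, growth rates
U(2.7, 3.2) (chaotic regime), exact connectance `round(C·n(n-1))` with
signed magnitudes U(0.05, 0.35). Two adjustments keep species-rich
communities realistic rather than explosive: magnitudes are damped by
`min(1, 1.5/sqrt(nC))` — the classic complexity–stability trade-off — and
signs favour competition 70/30 (unchecked mutualistic feedback in a Ricker
community diverges almost surely). Candidate parameter sets are
rejection-sampled: a burn-in under forcing and process noise at least as
harsh as a real run must stay below 10^4 (two noise realizations); the
hard divergence abort in `simulate_abundance` sits two orders higher.

Observation layer: reads per sample are multinomial with probabilities
proportional to latent abundance above a detection floor (default 1e-4 of
the equilibrium scale), total 20,000 reads (a typical rarefied depth); the
spike-in species' absolute concentration is measured with mean-one
lognormal error (CV 0.1). In `simulate_dataset` the spike species is given
sub-critical, uncoupled dynamics (r = 1.6): an internal standard is by
definition a species detected in essentially every sample, and a chaotic
crasher cannot play that role. Salinity, wave height, and tide level are
inert AR(1) covariates — present so conditioning code paths see realistic
nuisance variables, but never driving dynamics.

Noise streams are keyed by `(seed, site, species_id)`, which makes the
decoupling property exact: removing uncoupled species leaves the remaining
trajectories bit-identical.

## 2. Spike-in quantification and standardization

Reads are converted to copies/µL per sample via
`conversion = spike_reads / spike_copies`; zeros in either spike quantity
are replaced by configurable minima before forming the ratio. The shipped
constants (0.346 copies/µL, 12 reads) are the reference field calibration
for a seabream spike-in; on synthetic data the recommended setting is
`"auto"`, which recomputes the minima as the observed nonzero minima — the
same way the field constants were derived. Copies are depth-invariant by
construction (scaling all reads in a sample cancels), monotone in reads,
and only defined up to the spike's units — which is irrelevant downstream
because every series is standardized.

Species are ranked by detection frequency (ties: total reads, then id) and
the top *n* (50 at field scale) retained. Per species, site series are
concatenated in fixed site order and standardized to mean 0 / SD 1 over the
merged series (a per-site option exists but is off). The merged panel
records segment boundaries; no delay vector, target, or neighbour lookup
ever crosses one. Missing sampling occasions stay `NaN` and simply drop the
embeddings that touch them; nothing is imputed, and half-monthly gaps are
treated as one nominal step.

## 3. State-space primitives

Time-delay embeddings use E lags spaced tau (default 1) plus optional
contemporaneous conditioning coordinates. Nearest-neighbour regression uses
exponential simplex weights `w_i = exp(-d_i/d_1)`; zero-distance ties give
weight 1 to exact matches with an epsilon-floor decay for the rest, and
distance ties resolve to the earlier time index, so results are
deterministic across platforms. The Theiler exclusion window defaults to 0.

Conditional predictive densities are Gaussian, centred on the leave-one-out
k-NN prediction with LOO residual variance; transfer entropy is the mean
log-likelihood ratio of a full and a reduced model, which reduces to
`0.5*log(vr/vf)`.

**Embedding dimension.** E is selected from the effect series' own one-step
predictability: starting at E=1, the E-lag model is compared with the best
accepted smaller model, stepping up while the gain is statistically clear
(contribution bootstrap, alpha 0.05) and stopping at the first unclear
step; conditioning variables sit in both models. Both nested models share
the same neighbour count (the larger model would otherwise smooth over more
neighbours and fake a gain — with per-model k, iid noise steps to E=2 about
40% of the time). Including the candidate cause in both nested models was
tried and rejected: on a deterministic coupled map the cause coordinate
makes every E look sufficient, collapsing the selection to E=1 and the
causality test to nothing.

## 4. Causality detection (conditional TE / cross mapping)

For an ordered pair (cause y, effect x) the full model embeds the effect
{x_t, ..., x_{t-(E-1)tau}} and cross-maps the cause at lag tp (scanned 0 to
-6, i.e. up to three months back at half-monthly sampling); the reduced
model drops the most recent coordinate. Information flow y→x appears as a
positive log-likelihood ratio: the effect's attractor reconstructs its
drivers, and the freshest coordinate is what carries them.

**Clarity.** The raw ratio is not centred under the null (the two models
differ in dimension and neighbour smoothing), so significance is assessed
against a **rotation null**: the cause series is circularly shifted by
`n_boot` (default 1000, tests use 200) random offsets, preserving the
serial dependence of both series while destroying their alignment. Because
the effect-side geometry is fixed, each rotation's TE is a cheap linear
operation on the rotated target vector. The reported p-value is
selection-adjusted for the lag scan: the fraction of rotations whose *best*
lag reaches the observed best TE. Per-lag rotation p-values choose the
retained lag (largest TE among clear lags, else largest overall). Measured
on 200 independent AR(1) pairs this yields 14 rejections at alpha 0.05 and
a uniform p-value distribution; on unidirectionally coupled logistic maps
(coupling 0.3, T=200) the true direction is clear in 20/20 seeds and the
false direction in 0/20.

**Conditioning.** Environmental variables with a statistically clear
influence on the effect (each tested as a cause of the effect series, fixed
order: temperature, salinity, wave, tide; constant covariates skipped) are
conditioned on by **partialling out**: both series are replaced by their
residuals from a LOO k-NN regression on the conditioning variables at lags
0–2 (k ~ sqrt(T)), and the rotation test runs on the residuals. Conditioning
through a single contemporaneous z_t coordinate was tried first and left
the shared-driver false-positive rate at 13–18%: a common driver influences
the *target's* time, not the state vector's, and no instantaneous
coordinate can absorb a distributed-lag response. Removal-by-residualization
brings the conditioned rate to ~6–8% while the unconditioned rate on the
same communities is ~15–20%. Two caveats are worth knowing: (i) for
overcompensating (2-cycle) dynamics a shared noisy driver acts by *phase
entrainment*, a dependence conditioning cannot remove even in principle —
the shared-driver validation therefore uses the temperature-tracking regime
(r < 2) on log abundances, where the multiplicative temperature effect is
additive; (ii) a rotation ensemble is a single-realization surrogate and
slightly understates between-realization variance, so residual
miscalibration of a point or two per hundred remains.

`conditional_te` keeps the literal drop-one-coordinate estimator (with the
marginal density as the reduced model at E=1) for transparency and for the
oracle cross-checks; its raw value carries a model-complexity offset
(about -0.25 at E=1 against the marginal), identical in both directions,
so directional *differences* are centred — the discretized plug-in TE
comparison in the tests uses exactly that.

## 5. Interaction strengths (MDR S-map)

Per target species the coordinate set is: its own optimal-E lags, each
statistically clear cause at its retained lag (an edge at tp means
cause_{t+tp} influences effect_t; predicting effect_{t*+1} the cause is
read at `t* + min(tp+1, 0)`, so tp=-1 lands on the Jacobian-aligned
contemporaneous coordinate and tp=0 never peeks at the future), and its
clear environmental conditionals at lag 0.

Neighbourhoods come from the **multiview distance**: all (or up to 2000
sampled) coordinate subsets of size `ceil(sqrt(#coords))` containing at
least one target lag are ranked by LOO simplex forecast correlation; the
top `ceil(sqrt(#views))` are kept, each view's pairwise Euclidean distances
are normalized by their own off-diagonal mean, and the normalized distances
are averaged. At each target point a locally weighted ridge regression
(weights `exp(-theta*d/dbar)`, intercept unpenalized, own point excluded)
yields the coefficients read as interaction strengths IS_j(t*). One
(theta, lambda) pair per target is chosen by LOO forecast error over
theta in {0, 0.5, 1, 2, 4} and lambda in {0, 1e-3, 1e-2, 1e-1, 1};
singular local designs are retried at the largest penalty and otherwise
skipped with a warning count. Libraries pool all sites; vectors never span
site boundaries, which also enforces the per-edge record bound of
time points − E + 1.

Validation: on a globally linear VAR(1) (spectral radius ~0.7, T=300,
theta=0) the median coefficients recover the transition matrix to within
0.025 with all signs correct; on 5-species temperature-modulated Ricker
communities (T=200, 20 seeds) the median per-edge Spearman correlation
between |IS_j(t)| and the analytic |Jacobian_ij(t)| is ~0.6.

## 6. Temperature sensitivity

Cross-species IS records become |IS| observations — one in-row for the
receiving species and one out-row for the giving species per edge and time
point — joined with that sample's temperature, species richness (species
with positive copies), and total eDNA copies. The community-level model is
a gamma-family, log-link regression with an unpenalized cubic B-spline
smooth of the predictor (df 5; knots at quantiles) and fixed per-site and
per-species intercepts standing in for random intercepts (no gamma-family
mixed GAM exists in the Python stack; with a handful of sites and tens of
species the fixed/random distinction is immaterial for the smooth).
Zero strengths are floored at half the smallest positive value (gamma
support is positive) with the count reported.

Because |IS| observations are serially and cross-edge dependent (parallel
edges at one time share the community state), the nominal Wald F-test of
the spline block is anti-conservative (20–50% null clarity in our
experiments, depending on the covariance correction attempted). The
community-level clarity p-value therefore comes from a **within-site
rotation null of the predictor series** (default 200 rotations): the
response and its dependence structure stay fixed, the predictor's time
course is circularly shifted per site, and the spline-block Wald statistic
is re-computed per rotation. Under independence this is exchangeable by
construction; measured null clarity is 4/60 communities at alpha 0.05.
Species-level fits (site intercepts only, df 4, run separately per species
with a 30-row floor; smaller species reported as skipped) keep the
model-based p-value — they feed a stringent highlight threshold
(p < 1e-4) rather than a calibrated community claim — and classify each
species as increasing / decreasing / non-monotone from the fitted curve at
the 5th vs 95th predictor percentile (endpoint difference at least half the
curve's range; otherwise non-monotone).

On ring communities whose received edges carry gamma = +0.6 for half the
species and -0.6 for the rest (2 sites x 100 steps, 20 seeds), the sign
class is recovered for ~91% of species.

For network visualization, clear edges at or above the 0.8 quantile of the
clear-edge TE distribution are flagged as retained (ties retained).

## 7. Validation scale, and what it does not show

All validation runs at desk scale: pairs and small communities (2–8
species), 1–2 sites, 100–300 time points, 150–200 rotation/bootstrap
draws, 20–60 seeds per experiment — sizes chosen so the full suite runs in
minutes while leaving the measured rates interpretable against binomial
intervals. The generator emulates seasonality, site structure, multinomial
read sampling, spike-in measurement error, detection floors, and
temperature-modulated couplings. It does not emulate eDNA transport and
degradation, species-specific PCR amplification bias (beyond what
standardization cancels), taxonomic misassignment, or observation-driven
missingness; passing these tests shows the estimators recover truth under
the stated generative model, not that field inferences are correct. The
field-scale defaults (11 sites x 50 steps x 50 species) run the simulator
in under a second, but an all-pairs scan at that scale is a
2450-test computation and is deliberately not part of the test suite.
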
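# Methods

## Model

The package implements a nine-state ODE model of de novo pyrimidine
biosynthesis in *E. coli*, in mM and seconds. The state is
(cap, casp, dho, oro, omp, ump, udp, utp, ctp); ATP and IMP are external
pools held constant during integration (chemostat conditions). The rate laws
are the *reduced* forms: each generalized constant kⱼ absorbs the enzyme
concentration, its catalytic constant and the saturation terms of external
substrates (bicarbonate, glutamine, aspartate, PRPP, quinones, ATP where it
acts as co-substrate). The unreduced enzyme-level laws, with explicit enzyme
concentrations and further modifiers (ornithine, GTP), are out of scope; the
reduction is the model's own premise and the printed kⱼ values are its
parameters.

Eight negative feedback loops act on five enzymes:

| loop | signal | target | form |
|------|--------|--------|------|
| 1 | UMP | V₁ CPSase | Hill term (ump/K_UMP1)^h_UMP1 in a shared denominator |
| 8 | UDP | V₁ | Hill term, shared denominator |
| 3 | UTP | V₁ | Hill term, shared denominator |
| 4 | CTP | V₂ ATCase | partial inhibitor (δ_CTP2 < 1) in the occupancy ratio |
| 5 | UTP | V₂ | partial inhibitor, CTP·UTP synergy via ω₂ |
| 2 | ORO | V₄ DHO dehydrogenase | product-inhibition term oro/Ki_ORO4 |
| 6 | UTP | V₇ UMP kinase | mixed competitive/noncompetitive, weight r |
| 7 | CTP | V₉ CTP synthetase | product term ctp/K_CTP9 multiplying Km^h |

### Typeset-grouping choices

The source equations are printed with flattened parenthesization; the
groupings adopted here are fixed by three requirements: every kⱼ is the
uninhibited V_max limit of its law, the V₇ law reduces to the textbook
competitive form at r = 0 and the textbook noncompetitive form at r = 1, and
all inhibition terms are dimensionless occupancies. Concretely: V₁'s four
regulator terms add in one shared denominator; V₄'s dimensionless k₄ divides
the whole product denominator, so sgn V₄ = sgn(k₄f·dho/Km − k₄r·oro/Km); in
V₇ the weights (1−r) and r sit inside the Hill powers and one shared
exponent h_UTP7 serves both branches; V₁'s activation constant (numerator,
`Ka_IMP1`) and inhibition constant (denominator, `K_IMP1`) are distinct
symbols.

## Parameters, units, calibration

All parameters live in `pyrdyn.params.PARAMETER_TABLE` with value, units and
provenance; YAML configs can override any subset. The generalized constants
are literature values of the reduced model:

k₁ = 0.012, k₂ = 0.31, k₃ = 0.351, k₄f = 1.27, k₄r = 0.225, k₄ = 12.28
(dimensionless), k₅ = 3.9, k₅,prpp = 7.5 (dimensionless), k₆ = 0.73,
k₇ = 0.393, k₈ = 0.11, k₉ = 1.74·10⁻⁵ — mM/s where dimensional.

The affinity constants, Hill exponents and outflow constants of the reduced
model are not available as published numbers; they are package defaults on
physiological scales (metabolite pools 0.01–1 mM; outflows ~10⁻³ 1/s, the
turnover of nucleotide pools by nucleic-acid synthesis, a hundredfold faster
than chemostat dilution at 0.1 h⁻¹). They were calibrated **once**, by
fixed-point eigenvalue screening over a coarse grid followed by simulation,
to make the model realize the documented regime dichotomy simultaneously:

1. the default set is steady under both strains' ATP/IMP pools, with UMP and
   UTP the only large pools and low CTP;
2. the oscillation-regime set (k₂ = 0.0031, k₃ = 0.00351, k₉ = 1.74·10⁻⁴,
   h_UMP1 = 2.1, r = 1) yields a sustained limit cycle (period ≈ 2.1·10³ s);
3. the same set with h_UMP1 = 1 or with r = 0 is steady;
4. on the Hill grid, the noncompetitive mechanism (r = 1) opens an
   oscillatory region and the competitive one (r = 0) does not;
5. the open-loop chain (all inhibition constants → ∞) is steady everywhere.

The calibrated values are K_UMP1 = 0.05, Km_UMP7 = 0.05, K_UTP71 = 0.2,
K_UTP72 = 1.0, h_UTP7 = 4, K_UTP1 = 0.3, d_ATP2 = 2.0, Km_CAP2 = 0.5 mM,
k₁₀ = 2·10⁻³ 1/s. Mechanistically the oscillation is a relaxation cycle on
the UMP/UTP pair: at r = 1 the UTP level caps UMP-kinase *capacity*
(V_max suppression), so when influx approaches that capacity UMP integrates
upward and shuts carbamoyl-phosphate synthetase through loop 1; the slow
stages (small k₂, k₃) delay the response, and the UTP pool (τ = 1/k₁₀ = 500 s)
provides the second slow variable. At r = 0 the same UTP signal only
inflates the apparent Km, capacity stays at k₇ ≫ flux, UMP relaxes quickly,
and the loop is stable — which is why the oscillatory region of the regime
map grows dramatically with r. The ATP activation of ATCase (d_ATP2 = 2) and
the UTP loop on CPSase (K_UTP1 = 0.3) keep the r = 0 plane steady rather
than letting CAP or CASP grow without bound when k₂, k₃ are small.

## Simulator

`integrate` uses LSODA (stiff-capable, automatic switching) at
rtol = 10⁻⁸ / atol = 10⁻¹² with a 30-s reporting grid (defaults; horizon
2·10⁵ s). Negative components from solver undershoot are clipped to zero
before rate evaluation. `find_steady_state` integrates in chunks with early
exit, Newton-refines the endpoint to ‖dx/dt‖∞ < 10⁻¹⁰ mM/s, and returns
`None` when the trajectory does not converge (e.g. a limit cycle), when root
refinement fails or leaves the non-negative orthant, or when the refined
point is linearly unstable — the last guard prevents reporting the unstable
focus inside a limit cycle as a steady state.

## Regime classification

The oscillation detector is a deterministic periodogram-plus-envelope test
(the Bayesian spectral machinery it stands in for is used here only as an
oscillation detector, so any consistent detector preserves the regime-map
topology). Per channel, after discarding a 50% burn-in: (i) span ≤ 10⁻⁶ of
the channel's full-record scale → steady; (ii) a dominantly monotone window
is "steady" if its tail has settled (tail span < 1% of window span), else
undetermined (transit or divergence); (iii) otherwise the detrended signal
must put ≥ 40% of its variance into the dominant periodogram line and that
line must exceed 10× the median power; (iv) a candidate line counts as
*sustained* only if ≥ 3 periods are observed, successive-maxima spacings
have CV ≤ 0.35, and the envelope (median of maxima, on a period/6-smoothed
copy) decays < 5% per period — otherwise the channel is a damped transient
(steady) or inconclusive. All thresholds are relative, making the call
invariant to rescaling concentrations and changing the time unit. Period is
the mean successive-maxima spacing; amplitude is half peak-to-trough over
the last three periods. Validated at ≥ 95% (measured: 100%) accuracy on a
200-signal labelled suite of noisy sinusoids, damped sinusoids, noisy
constants and relaxation waves.

## Regime mapping, bisection, sensitivities

`scan_hill_space` replaces (h_UMP1, h_UDP1, h_UTP1) ∈ [1, 10] and
r ∈ [0, 1] on a grid (step 1 for the full map, step 3 for quick runs),
simulates each point from the empty pathway and classifies it; points whose
trajectory settles onto a stable fixed point take a fast early-exit path.
Solver failures are logged and labelled undetermined. Boundary location uses
plain bisection on the classification outcome (`bisect_label_boundary`);
an undetermined midpoint is resolved toward the oscillatory side so the
bracket around the two decided endpoint labels stays valid. Branch-following
continuation is out of scope — boundary location is what the regime maps
need. The bisection is validated against the supercritical Hopf normal form
(critical point μ = 0, known in closed form).

`sensitivity_rank` reports max-norm normalized steady-state sensitivities
|∂ ln xᵢ / ∂ ln pⱼ| by central finite differences (default relative step
5%), clamped to each parameter's admissible domain (r ≤ 1, Hill ≥ 1;
one-sided at the edges); parameters whose perturbed model loses its steady
state get NaN and sort last.

## Fitting

The objective is the sum over datasets and observed metabolites of squared
log-residuals between the model's steady state under that dataset's ATP/IMP
pools and the observations, with one multiplicative normalization
coefficient per dataset. The first dataset is the reference (coefficient 1);
the others' coefficients are profiled out in closed form (the geometric-mean
matcher exp(−mean log-residual)), which keeps absolute concentrations
identifiable while absorbing systematic between-strain measurement scales.
Log-space residuals are used because the pools span four orders of
magnitude. A dataset with no steady state contributes an infinite penalty.
Optimization is `scipy.optimize.differential_evolution` in log₁₀-parameter
space (Sobol initialization, immediate updating, optional L-BFGS-B polish),
seeded for reproducibility. Inside the optimizer loop, steady states are
obtained by Newton refinement from per-dataset fixed points of the base
parameters, accepted only if linearly stable, with the trajectory-based
finder as fallback — this assumes the stable fixed point near the hint is
the one reached from the empty pathway, which holds throughout the steady
regime explored by the bounds used here.

### Identifiability of k₂

At steady state the chain is feed-forward: the flux F and every downstream
pool solve a subsystem that does not contain k₂, and carbamoyl phosphate —
the one pool k₂ sets, via x₁ = V₂⁻¹(F) — is not among the observable
metabolites (casp, dho, ump, udp, utp, ctp). k₂ is therefore structurally
non-identifiable from steady-state tables of those metabolites: the
objective is flat in k₂ over the entire region where a steady state exists
(verified numerically: objective ~10⁻³⁰ at k₂ off by 5×). The
recovery experiments reflect this: k₃, k₉ and h_UMP1 recover with median
errors of 1–3% at 10% measurement noise (multi-seed study in
`examples/recovery_study.py`), while recovered k₂ wanders across its search
bounds. The same argument makes k₃'s sensitivity signature purely local to
casp (∂ ln casp/∂ ln k₃ = −k₃/(k₃ − F)), which the test suite uses as an
analytic oracle. Identifying k₂ would require either measuring carbamoyl
phosphate (chemically unstable, rarely measured) or non-steady-state data.

## Synthetic data

`make_steady_datasets` emulates the two-strain chemostat design: dataset 0
uses ATP = 0.33, IMP = 0.098 mM (BW25113-like), dataset 1 ATP = 9.6,
IMP = 0.27 mM (NCM3722-like); each table is the model's steady state under
its pools × a systematic scale factor (default 1 and 2, emulating the
between-strain measurement differences the normalization coefficients exist
to absorb) × median-unbiased lognormal noise (default CV 10%). What the
generator does *not* emulate: real measurement error structure (correlated
biases, detection limits), biological replication, any mismatch between the
model family and the true pathway, or chemostat growth dynamics (dilution
enters only through the outflow constants). Passing recovery tests therefore
demonstrate the estimator's correctness and the observables' information
content under the model's own assumptions — not robustness to model
misspecification.

`make_labelled_trajectories` draws sinusoids (period 200–5000 s, noise up to
10% of amplitude), damped sinusoids (≥ 15% amplitude loss per period),
noisy constants and skewed relaxation waves, each on a 30-s grid long enough
for ≥ 10 periods. `make_oscillatory_base` is deterministic and returns the
published oscillation-regime constants joined with the calibrated defaults.
`hopf_normal_form_trajectory` integrates dx/dt = μx − ωy − x(x²+y²),
dy/dt = ωx + μy − y(x²+y²) as the closed-form bisection benchmark.

## SBML

`export_sbml` writes SBML L3V1 directly (lxml): nine species, boundary
species for ATP/IMP, all 49 parameters, and 13 reactions whose kinetic laws
are generated from an independent sympy definition of the rate laws and
serialized as content MathML. `integrate_sbml` rebuilds the ODEs from the
document alone (MathML → sympy → lambdify) and reproduces the native
simulation to < 10⁻⁶ relative; because writer and native model implement the
laws separately, the round trip doubles as a formula cross-check.

## Problem sizes and numerical choices

Default test/acceptance problem sizes were chosen as the smallest that make
each property unambiguous: horizons of 2·10⁵ s (≈ 100 oscillation periods),
a coarse Hill step of 3 with r ∈ {0, 1} for regime-map counts (the full
step-1, 11-level-r map is available through the same API), 200 signals for
classifier validation, two datasets × six metabolites for fitting, and
differential-evolution budgets of ~40–60 generations with populations of
8–12 per free parameter set. Ties and degenerate inputs: negative
concentrations are clipped at zero before rate evaluation; the all-zero
state is a valid initial condition (V₁ > 0 there); an exactly-constant
channel classifies steady without spectral analysis; bisection treats an
undetermined midpoint as oscillatory-side.

## Known limitations

- The affinity/Hill defaults are calibrated package values, not measured
  constants; trajectories are structurally, not numerically, comparable to
  any particular published figure.
- The classifier detects sustained single-line oscillations; quasiperiodic
  or chaotic regimes would be labelled undetermined (none arise on the
  explored grids).
- With oscillation-regime rate constants and weak feedback the open chain
  can lose its steady state (CAP grows without bound since intermediates
  have no dilution term); such grid points are honestly labelled
  undetermined rather than steady.
- k₂ cannot be estimated from the supported observables (see above).
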
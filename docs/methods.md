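# Methods

## Model

An irreversible covalent inhibitor engages its target in two steps: a
reversible, affinity-driven association forming the non-covalent encounter
complex, then irreversible bond formation,

```
E + I  <==[k_on / k_off]==>  EI  --[k_inact]-->  EI*
```

Applying the steady-state approximation to `EI` and assuming
pseudo-first-order conditions (`[I] >> [E]0`, so free inhibitor is not
depleted), the covalent occupancy follows a single exponential,

```
[EI*]/[E]0 = 1 - exp(-k_obs t),     k_obs = k_inact [I] / (K_I + [I])
```

with `K_I = (k_off + k_inact)/k_on`. The three reportable constants are
`k_inact` (s^-1, intrinsic warhead reactivity in its protein context),
`K_I` (M, non-covalent affinity) and their ratio `k_eff = k_inact/K_I`
(M^-1 s^-1), the standard potency metric for irreversible inhibitors.

The package works in strict SI units internally (M, s); unit conversion
(nM/µM, min/h) happens once, in the I/O layer. Occupancies are fractions.

## Two-step estimation (`kinact.fitting`)

Stage 1: for each inhibitor concentration, occupancy-vs-time points are
fitted with the constrained one-phase association `Y = 1 - exp(-k_obs t)`
(floor fixed at 0, plateau at 1; a single point inverts in closed form).
Stage 2: the `([I], k_obs)` points are fitted with the hyperbolic model
`k_obs = k_inact [I]/(K_I + [I])`, initialized at `k_inact = max(k_obs)` and
`K_I =` the concentration nearest half-max. Replicate experiments contribute
separate `k_obs` points at each concentration.

Numerical choices:

* Positivity is enforced by optimizing in log parameters with a
  trust-region least-squares solver (`scipy.optimize.least_squares`, cost
  tolerance 1e-10, at most 1000 iterations). Residuals are unweighted by
  default (1/SE² weighting is an option).
* Standard errors are symmetric approximations from the local covariance at
  the optimum, mapped back to the natural scale by the delta method; the
  `k_eff` error uses the full 2x2 covariance.
* Occupancy exactly 1 is clamped to `1 - 1e-6` before any log-based
  initialization.
* Identifiability guards: a fitted `K_I` more than 10x above the top dose
  means the data never left the linear regime — the fit is demoted to
  "keff-only" and `k_eff` is reported from the through-origin
  (Lineweaver-Burk-style) regression `k_obs = k_eff [I]`, which is the
  stable estimator there. A fitted `K_I` below a tenth of the lowest dose
  means plateau-only data: "kinact-only". These mirror, at full design
  scale, the scenario logic of the two-point triage.

`CovalentKineticsModel(data).fit()` wraps both stages behind a
model/results interface; the results object carries estimates, standard
errors, per-concentration `k_obs` diagnostics and a `summary()` table.

## ODE simulator (`kinact.simulate`)

The four-species mass-action system (dE, dI, dEI, dEI*/dt) is integrated
without any steady-state shortcut, so inhibitor depletion is represented
faithfully. The system is stiff (species at 1e-10 M, rates spanning
decades): a BDF solver with `rtol = 1e-8` and `atol = 1e-16 M` is used —
default tolerances would swamp the signal. Trajectories verify mass
conservation (`E + EI + EI* = E0` to 1e-6 relative) and monotone EI* on
construction, and solver failure raises with diagnostics rather than
returning NaNs.

The default in-silico panel is nine log-spaced concentrations from 1e-9 to
1e-5 M at `E0 = 1e-10 M`, integrated to 86,400 s. The sampling grid is the
union of 30 log-spaced and 30 uniform times: the log half resolves fast
kinetics (`k_obs` near `k_inact`, saturating within minutes), the uniform
half anchors slow approaches to plateau. When extracting `k_obs` from a
trajectory, samples inside the pre-steady-state transient
(`t < 5/(k_on I + k_off + k_inact)`) are excluded — the single-exponential
law only holds after the non-covalent complex equilibrates, and including
the transient biases `k_obs` downward by several percent. With these
choices the two-step fit recovers generating parameters to within ~4%
across `K_I` from 10 nM to 10 µM and `k_inact` from 1e-4 to 1e-2 s^-1; the
residual error at the high-affinity/low-dose corner is physical inhibitor
depletion (`I0` only 10x `E0` at the lowest dose), not estimator bias.

The closed form is exact only without depletion; `Trajectory.
closed_form_divergence()` reports the post-transient deviation as a
diagnostic. The steady-state error itself scales as
`(k_obs/relax)·(1-occ)/occ` with `relax = k_on[I]+k_off+k_inact`, so
agreement is ~1% past half-maximal occupancy and improves from there.

## Occupancy pipeline (`kinact.occupancy`)

Channel-to-channel pulldown variation is removed by dividing every channel
by an internal reference analyte enriched equally everywhere (default id
`ACC1`, the endogenous biotinylated carboxylase captured in streptavidin
pulldowns); if absent, total-intensity normalization is the fallback, with
a warning. Occupancy anchors to the two controls:
`occupancy = 1 - (A - A_sat)/(A_dmso - A_sat)` — the DMSO control defines
0% inhibitor occupancy, the saturating pre-incubation control defines the
background floor (100%). Occupancies outside [0, 1] are clamped with
`clamped_low`/`clamped_high` flags (noise around the controls; downstream
log transforms need finite inputs); analytes whose controls do not separate
(`A_dmso - A_sat <= 0`) carry no competable signal and are flagged
`unquantifiable`; single-PSM analytes are fitted but flagged
`low_evidence` when PSM counts are supplied. Off-target ranking scores each
analyte by `-log2(A_sat/A_dmso)`.

## Two-point triage (`kinact.triage`)

For screens measuring each fragment-analyte pair at two doses and one time,
each competition ratio converts to occupancy and then to
`k_obs = -ln(1-occ)/t`, and three candidate models are fitted: linear
through the origin (`k_eff` only; K=1), hyperbolic (full model; K=2) and
constant (plateau; K=1). Pairs with no competition at either dose
(mean occupancy <= 0 at both) are classed "zero" without fitting. Selection
uses `AIC = n ln(RSS/n) + 2K` (and BIC with `K ln n`) under Gaussian iid
residuals, with `RSS/n` floored at 1e-30 so perfect interpolants stay
finite; ties resolve to the simpler model. `n` counts every replicate point
(2 doses x R replicates). With a single replicate the hyperbola
interpolates exactly and can still lose on the complexity penalty — the
intended Occam behavior. Pairs whose mean `k_obs` does not increase with
dose are already on the plateau and are routed to the constant candidate
only.

Scenario readouts: linear gives `k_eff` only; hyperbolic gives `k_inact`,
`K_I` and `k_eff`; constant gives `k_inact` plus the concavity bound
`K_I <= min(dose)/2` (the saturation curve is concave, so a flat pair
implies half the lower dose already exceeds `K_I`) and hence
`k_eff >= k_inact/(min(dose)/2)`. The bound uses the lower of the two
doses — the concavity argument supports the tighter choice.

Two CR orientations exist in practice and both are supported explicitly:
`treated_over_dmso` (occupancy `1 - CR`; no competition shows CR >= 1,
matching the zero-model rule) and `dmso_over_treated` (occupancy
`1 - 1/CR`; used by the single-dose converter below). The orientation is a
required, explicit config choice rather than a guess.

## Single-dose CR conversion (`kinact.abpp`)

Competitive cysteine-profiling screens report one CR per fragment-site at a
single dose and time. Assuming fragments sharing a warhead class share
intrinsic reactivity, shipped class-median `k_inact` values
(chloroacetamide 0.0092 s^-1, acrylamide 0.0025 s^-1, curated from public
covalent-kinetics databases and treated as constants) close the system:
`occupancy = 1 - 1/CR`, `k_obs = -ln(1-occ)/t`,
`K_I = k_inact [I]/k_obs - [I]`, with defaults `t = 7200 s`,
`[I] = 2.5e-5 M`. CRs at or below the cutoff (default 2) are skipped as
below the reliable-competition window. When the implied `k_obs` reaches the
class `k_inact`, no finite `K_I` exists — the site is reactivity-limited
and only the bound `K_I <= [I]` is reported.

Ligand efficiency is `LE = -RT ln(K_I)/N` with `R = 1.987e-3
kcal mol^-1 K^-1`, `T = 298.15 K`, and `N` the heavy-atom count (the field
convention; an all-atom count can be supplied instead). The sign convention
makes sub-molar binders score positive — the free-energy-per-atom form
`-ΔG/N` — which we adopt as the internally consistent reading of the
quantity. `LLE = -log10(K_I) - clogP`; clogP is consumed as data, with
optional on-the-fly Crippen computation from SMILES via RDKit (an extra,
never a hard dependency).

## Synthetic experiments (`kinact.synthetic`)

The generator inverts the occupancy pipeline: treated-channel intensity is
`baseline * ((1-occ)(1-bg) + bg) * noise` with occupancy from the closed
form, occupancy 0 in the DMSO control and exactly 1 for true targets in the
saturation control. The uniform residual background `bg` (default 1%)
stands in for nonspecific pulldown and keeps saturation intensities finite;
being uniform it cancels exactly in control normalization, so the noise-free
roundtrip is exact to machine precision. Noise is multiplicative log-normal
on intensities (reporter-ion noise is scale-dependent), parameterized by
its CV through `cv² = exp(σ²) - 1`, mean-one, and deterministic given the
seed. The default cv of 0.05 sits below the <10% replicate CVs of
well-behaved multiplexed screens.

Defaults emulate a benchmark kinase-inhibitor experiment: design presets of
5 doses x 3 times (25-400 nM or 12.5-200 nM; 2/4/6 min) plus the two
controls; target kinetics log-uniform over `K_I` 30-300 nM and `k_inact`
0.01-0.05 s^-1 (the range measured for clinical covalent kinase inhibitors
against their on- and off-targets); non-targets have `k_inact = 0`.

What the generator does **not** emulate: reporter-ion ratio compression,
co-isolation interference, missing values, peptide-to-protein rollup, or
any upstream search-engine behavior. Passing tests therefore demonstrate
correctness of the kinetic estimation given occupancy-faithful intensities,
not robustness to MS acquisition artifacts.

## Problem sizes used in validation

The shipped validation runs are sized for interactive use: nine-dose ODE
panels (~60 time samples each), a 300-analyte synthetic proteome with 10
targets for the end-to-end pipeline, 100-200 seeded pairs per regime for
the triage recovery study, and 200 replicate fits for the noise-consistency
check. All complete in seconds.

## Known limitations

* The closed form (and hence the estimator) assumes no inhibitor depletion;
  designs where doses approach the target concentration will bias `K_I`
  upward. The simulator quantifies this but the estimator does not correct
  for it.
* Two-point kinetic estimates are intrinsically fragile: with `n = 2R`
  points and up to two parameters, scenario misassignment near `K_I` is
  possible, and uncertainty estimates are not meaningful at that size.
* The zero-model rule (no competition at both doses) classifies a true
  non-binder correctly only ~25% of the time under symmetric multiplicative
  noise, since each dose's mean CR falls on the no-competition side of 1
  with probability ~1/2; the rest land in the constant model with near-zero
  `k_inact`. This is a property of the rule itself.
* Warhead-class `k_inact` medians carry survivorship and curation biases;
  converted `K_I` values rank fragments within a class more reliably than
  they compare across classes.
* Reversible-covalent inhibitors, two-site binding, and multi-target
  competition for a shared inhibitor pool are out of scope.
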
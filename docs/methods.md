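# Methods

## The system

`chaoscope` studies engineered three-strain bacterial communities grown in
a chemostat. Each strain may carry up to three genetic parts: a quorum
sensing (QS) synthase producing a diffusible signal (A1 or A2), a
bacteriocin expression cassette (B1, B2 or B3) whose promoter is induced or
repressed by one of the QS signals, and a sensitivity determinant making
the strain killable by one bacteriocin. A *model* is an assignment of such
parts to the three strains plus a map saying which QS species drives each
bacteriocin. The package asks: which of these topologies, and which
parameter regions within them, produce oscillations and deterministic
chaos — and how can an operator steer a running community between those
regimes?

## Model space

Strain configurations are tuples (sensitivity, QS, bacteriocin, regulation
mode); the regulation flag is canonicalised when no bacteriocin is carried,
leaving 84 unique strains. Models are permutation-deduplicated triples of
distinct strains (strains are exchangeable a priori: they share identical
parameter priors) combined with every assignment of a regulating QS (drawn
from the QS species present in the model) to every bacteriocin present.
Four cleanup rules remove redundant systems: duplicate strains, regulators
absent from the system, sensitivities to absent bacteriocins, and
bacteriocins that kill nobody. Under these conventions the three-strain
space contains 34 831 models. The regulator assignment and the
ordered-versus-unordered choice are genuinely open — the part options alone
do not determine them — so they are recorded in
`ModelSpace.enumeration_convention`; alternative conventions (per-cassette
regulators, system-level regulation modes, label-symmetry reduction) give
counts from roughly 1 400 to 200 000, and none of the ~400 variants we
enumerated reproduces the externally reported count of 4 182 for this
space, which appears to depend on unpublished details of the original
enumeration code. The reference four-part topology (one QS produced by
strain 1 inducing B1, made by strains 1 and 2 and killing strain 1 only,
and B2, made and felt by strain 3) is located structurally, never by
index.

## Dynamics

State variables are strain densities `N_x` (OD), substrate `S` (M), and
rescaled bacteriocin/QS concentrations `B_z`, `A_y` (physical molar
concentration divided by `C_B = C_A = 1e-9`; `C_N = 1e9` cells/OD converts
densities to cell numbers). The rescaling keeps every state O(1)–O(100).
The equations are

    dN_x/dt = N_x mu_x(S) − N_x Σ_z ω(B_z C_B) − N_x D
    dS/dt   = D (S0 − S) − Σ_x mu_x(S) N_x C_N / γ
    dB_z/dt = Σ_x kB_{x,z}(A_{r(z)} C_A) N_x C_N / C_B − D B_z
    dA_y/dt = Σ_{x∈prod(y)} kA_y N_x C_N / C_A − D A_y

with Monod growth `mu(S) = mu_max S/(K+S)`, Hill killing
`ω(B) = ω_max B^{n_ω}/(K_ω^{n_ω}+B^{n_ω})` applied only to sensitive
strains, and induced/repressed Hill forms for the per-cell bacteriocin
expression rate `kB`. Dimensional analysis fixes the production terms as
*divisions* by the scale factors (production per cell times cell number,
re-expressed in scaled units); with the shipped parameter set this places
the QS and bacteriocin concentrations at the half-maximum constants of
their response functions, which is what makes the regulation dynamically
active. Strain densities enter the field linearly and unclamped so the
linearisation at boundary fixed points is exact; only inputs to fractional
powers are floored at zero against solver round-off.

Integration uses LSODA (stiff-capable, adaptive) at absolute tolerance
1e-9 and relative tolerance 1e-4, over 5000 h with 1 h output spacing, and
stops early (terminal event) when any strain drops below the extinction
threshold of 1e-5 OD. Integrator failures surface as a `failed`
termination that batch drivers treat as maximal distance. A compiled
(numba) evaluation path accelerates the inner loop roughly four-fold; it
is verified against the pure-numpy reference field to 1e-12 relative and
falls back to numpy when unavailable.

## Lyapunov exponents

The primary estimator is the dual-orbit method: after a transient equal to
the first 10% of the horizon, a companion orbit displaced by
`delta0 = 1e-10` (on the first strain density by default) is co-integrated
with the reference orbit — as one joint system, so both share solver step
sizes — and after every renormalisation interval `dt` the base-2 log of the
separation growth (Euclidean norm over *all* state variables) is
accumulated and the companion is pulled back to `delta0` along the current
separation direction. The exponent is the average `lambda1 = S/n` in bits
per step.

The renormalisation interval is not dictated by the method; the package
default is `dt = 2 h`, calibrated so that both published chaos
classifications hold simultaneously — the reference community vector above
the community threshold 0.003 bits/step and the four-species gLV attractor
above the gLV threshold 0.015 bits/step — and so that the community
classification is robust to the initial separation (1e-9…1e-11) and to a
tenfold tolerance tightening. At `dt = 1 h` the reference vector measures
~0.0027 bits/step, marginally below threshold, and its classification
flips with `delta0`; we treat that as a mis-calibrated scale rather than
evidence against chaos.

A tangent-space (variational/Benettin) estimator integrating `v' = J(y)v`
with per-step renormalisation serves as an independent cross-check; the
two agree within 5% on the Lorenz system and the gLV attractor at the
horizons used in the tests (1000 and 10 000 time units — this attractor
mixes slowly, so short averages fluctuate by more than the tolerance).

An important numerical caveat: the reference community vector is
*transiently* chaotic in this implementation. The tolerance-converged
plain trajectory (identical under LSODA and BDF down to rtol 1e-10) leaves
the chaotic saddle within a few hundred hours and settles onto a small
limit cycle around the unstable coexistence point (strains 2 and 3 cycling
with ~0.1 OD peak-to-trough, strain 1 at ~0.003). The dual-orbit
estimator, whose stepped orbit shadows the saddle, classifies the vector
as chaotic robustly. Consequences: statements tied to the *plain*
trajectory (per-strain oscillation prescreen at the reference point;
absence of chaos when perturbing the initial N2/N3/A1) do not all
reproduce, while every lambda-based result does. Escape times from
chaotic saddles are exquisitely sensitive to integrator details, so
published trajectory-level observations at matched parameters should be
expected to vary between implementations.

## Behaviour objectives

Oscillation statistics per strain signal: the dominant period `T` from the
peak of the mean-removed Fourier magnitude spectrum (no windowing; the
simplest spectral estimate), the expected peak count `p = t/T`, and
peak-to-trough amplitudes computed by pairing consecutive gradient-sign
extrema — one amplitude per cycle, so a clean oscillator yields `A_K ≈ p`
amplitudes above the threshold `K = 0.05`. (Overlapping extremum
differences would double-count and make the second distance reject perfect
oscillators.) The distance triple is `d_o1 = |T − t/2|` (zeroed when
`T < t/2`), `d_o2 = |A_K − p|`, `d_o3 = |A_F − K|` (zeroed when above
`K`), combined across strains by componentwise maximum — all three strains
must oscillate — with final thresholds (2.0, 2.5, 20.0). Extinct or failed
simulations receive a sentinel distance of 1e6, beyond any threshold. The
`d_o3` zeroing rule makes that component almost never binding; it is
implemented as stated.

The chaos objective uses the single distance `d_C1 = 1/(1 + lambda1)`
(final threshold 0.997, equivalent to `lambda1 > 0.003`; negative
distances are hard rejections), preceded by a cheap prescreen that rejects
extinctions and any particle whose trajectory shows fewer than two
above-threshold oscillations in *some* strain.

Behaviour classification for scans: extinction dominates;
`lambda1 > 0.003` is chaotic; exponents inside the ±0.003 noise band count
as oscillatory when at least one strain still shows two sizeable
amplitudes over the final half of the signal (community limit cycles often
involve one strain at small amplitude, so the all-strain rule would leave
the oscillatory class empty); everything else is stable.

## ABC SMC

Particles are (model, parameter vector) pairs drawn from a uniform model
prior and per-parameter uniform priors; ranges spanning three or more
decades (QS/bacteriocin production and affinity constants, the killing
half-max) are sampled log10-uniformly, the rest linearly, as recorded per
run. Generation 0 accepts every particle with finite distances; the next
threshold is the per-component lower alpha-quantile (default
`alpha = 0.5`) of the accepted distances, floored at the final threshold,
which marks the final generation. Perturbation uses a componentwise
uniform kernel of half-width 0.1 prior range on the sampling scale
(out-of-support proposals redrawn) plus a model-switch move with
probability 0.1; weights follow the importance ratio
`pi(theta)/Σ_j w_j K(theta|theta_j)` with the sum restricted to same-model
particles of the previous population (parameter spaces differ between
models), and generation-0 weights equal one. Independent repeats pool
their final populations; the model posterior is the weighted mass per
model with its standard deviation across repeats.

The full prior table is the default study condition. Because a direct
chaos search from the full prior has an acceptance rate near zero on a
workstation (297 of 300 prior draws go extinct before 2000 h), the
scaled-down model-selection demonstrations use a shipped *desk-scale*
prior: the same table with the widest ranges narrowed to the neighbourhood
of the known chaotic operating point (dilution 0.1–0.3/h, QS production
within a factor of five of the reference rate, expression rates
1e-17–1e-15 M/h, regulation affinities 1e-9–1e-7 M, growth rates 1–3/h).
Under it, a population-10, three-repeat, 1500 h run over the reference
topology plus four structural neighbours converges to the final threshold
in about two minutes and concentrates ~70% of the posterior mass on the
reference topology.

## Steady states

For the reference topology the washout state and both unkilled-survivor
states have closed-form coordinates and eigenvalues; the self-killing
survivor state solves a scalar growth-versus-killing balance, monotone in
substrate, bracketed on (0, S0) and solved by Brent's method — the root
exists exactly when the dilution rate is below that strain's washout
limit. The interior coexistence state is found by damped Newton iteration
from the post-transient trajectory mean (random restarts on failure), and
all stability verdicts come from the eigenvalues of a
Richardson-extrapolated central-difference Jacobian (plain central
differences are not accurate enough along the substrate axis, whose Monod
curvature scale is the half-saturation constant ~4e-5). Closed-form and
numerical spectra agree to 1e-6 relative in the tests. Necessary
conditions for coexistence — the middle strain's growth rate wedged
between a washout/killing lower bound and its competitors' rates — are
evaluated with margins.

## Scans and ramps

Grid, sensitivity and bifurcation scans override one or two entries of a
flat input vector (parameters plus initial state), re-simulate, estimate
the exponent and classify each cell. Bifurcation summaries collect
post-transient peak levels of one strain, deduplicated at 1e-4. Real-time
ramps make the dilution rate or a QS production rate a piecewise-linear
function of time *inside* the vector field — one continuous integration,
as in an operator retuning a running reactor — rather than a chain of
restarts. Default grids in the examples and tests are coarse (a handful
of cells along each axis) to keep workstation runtimes in minutes; the
transition orderings they probe (QS rate up: stable → oscillatory →
chaotic → extinct; dilution up from the chaotic point: chaotic →
oscillatory → extinct) are insensitive to the grid resolution, though the
fine structure near the chaos boundary contains interleaved windows.

## Random forest

Labelled input vectors (oscillatory vs chaotic) are balanced by
subsampling the larger class, split 50/50 into train and test, and fed to
a scikit-learn random forest with the entropy criterion (importances are
then information gains in bits; 2000 trees at full scale, fewer in unit
tests). Feature importances are reported as the per-feature mean impurity
decrease with its standard deviation across trees — large spreads flag
redundant features — in raw and normalised form.

## What the synthetic signals do and do not show

The fixture generator produces sines, damped sines, multi-tone sums,
constants and Lorenz trajectories with analytically known periods,
amplitude counts and exponent signs; they validate the spectral, peak and
Lyapunov machinery independently of the community model. They do not
emulate demographic noise, measurement noise, uneven sampling or
non-stationary drifts, so passing tests certify the deterministic
pipeline, not robustness to experimental data artefacts.

## Known limitations

* The two calibration gaps inherited from the source material — the exact
  enumeration convention behind the published 4 182 model count and the
  renormalisation interval behind the published exponent thresholds — are
  resolved here by explicit convention objects and by the two-inequality
  calibration described above, respectively.
* Transient-versus-sustained chaos at matched parameters is
  integrator-sensitive; only exponent-based classifications should be
  compared across implementations.
* Steady-state formulas beyond the generic root-finder are specific to the
  reference topology.
* The desk-scale prior is a reduced-compute study condition; posterior
  probabilities obtained under it are not comparable to full-prior runs.
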
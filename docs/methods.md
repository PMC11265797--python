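# Methods

This note records the models, conventions and numerical choices behind
`altaccess`, and what its synthetic validation does and does not
establish.

## Scope and design

The package implements the *analysis* layer of a conformational
free-energy study of an alternating-access transporter: everything that
happens after an MD engine has produced CV time series, protonation
traces, or per-window work values. No MD engine is run; instead a
Brownian-dynamics sampler on analytic surfaces supplies inputs whose
ground truth is known, which turns every estimator into a testable
recovery problem.

## Units and constants

Internal units are nm (gate CVs), ps (time), kcal/mol (energies), K
(temperature, default 310 K). kB = 1.987204259e-3 kcal/mol/K, so kT at
310 K is 0.61603 kcal/mol and RT ln 10 — the free energy of one pKa
unit — is 1.41847 kcal/mol. External force constants arrive in
kJ/mol/(CV unit)² and are converted with 1 kcal = 4.184 kJ exactly.

## Gate collective variables

The two gates of an MFS transporter are tracked as centre-of-mass
distances between residue groups: the extracellular gate by the
"tips" (extracellular helix ends) and the intracellular gate by the
"bases" of the N- and C-terminal six-helix bundles. The built-in
definitions carry fixed residue intervals in rat PepT2 numbering, six
12-residue intervals per group (72 residues/group), evaluated over Cα
atoms. COM is mass-weighted; over a single atom type this equals the
geometric mean, so the choice only matters for custom groups. Tip and
base groups of the same bundle may share residues (120–121, 227–228);
disjointness is enforced only within one CV definition.

Contact fractions use a minimum-distance criterion with a default
0.4 nm cutoff — a common salt-bridge criterion between polar heavy
atoms; the cutoff is configurable because no single value is canonical.

## Synthetic sampler

The sampler is overdamped Langevin (Euler–Maruyama):
`x ← x − ∇(U+bias)/γ·dt + √(2kT·dt/γ)·ξ`, with friction γ in 1/ps and
unit effective mass. Inertia is omitted deliberately: WHAM and the
titration/alchemical estimators consume equilibrium distributions, not
kinetics. Discretisation inflates the sampled variance of a harmonic
mode of stiffness k by `1/(1 − k·dt/(2γ))`; campaign defaults keep
`k_max·dt/γ ≤ 0.02` so the bias stays below one percent. The first 10%
of steps are discarded as burn-in (configurable); a per-step displacement
above 1 CV unit aborts with a stability error. All randomness flows from
explicit seeds.

Stock surfaces: a harmonic well, a quartic double well
`U = h((x−c)²−a²)²/a⁴` (default barrier h = 3 kcal/mol, minima at
0.35/0.85 nm), and a 2D Gaussian-basin mixture with a weak harmonic
confinement (k = 1 kcal/mol/unit²) that keeps the unbiased density
normalisable. The default three-basin mixture (depths 9.303/5.705/7.296,
widths 0.265/0.301/0.346, centres −1/0/+1 on the first CV) was solved
once, by least squares on its 1D section, to plant basins near
(0, +3, +2) kcal/mol with saddles near +6 and +5 — the energy scale of a
transporter's conformational landscape. These are fixtures with a
realistic scale, not claims about any protein; the exact planted values
used by the tests are read off the analytic surface itself.

## WHAM

Binned WHAM solves
`P(b) = N(b) / Σ_j N_j exp(β(f_j − b_j(b)))`,
`f_j = −kT ln Σ_b P(b) exp(−β b_j(b))`
for pooled windows, each entering with its own harmonic bias — so
heterogeneous force constants, replicate pooling, and two-tier designs
need no special handling. The solver first minimises the equivalent
convex negative log-likelihood with L-BFGS (analytic gradient), then
polishes by direct iteration until `max|Δβf| < 1e-7` (cap 1e5
iterations) — tighter than statistical noise at any scale used here.
Bins with zero pooled counts are undefined (+∞) and carry zero
probability through projection. Disconnected window-histogram components
trigger a warning naming the components, since relative free energies
between them are meaningless. Replica-exchange structure in the input is
ignored: samples are treated as window-labelled equilibrium draws, the
standard WHAM treatment of replica-exchange umbrella data.

Grid choice is the one numerically delicate point: because the bias is
evaluated at bin centres, the bin width must stay comparable to the
thermal width `√(kT/k)` of the stiffest window, and auto-ranged grids
put their outermost bins in barely-sampled territory. The canonical
protocols therefore fix their analysis grids explicitly (72 bins over
the covered range in 1D; 64×48 for the two-tier 2D design, where 48×48
leaves a visible discretisation bias from the stiff tier).

Projection to 1D is Boltzmann reweighting
`F₁(x) = −kT ln Σ_y exp(−βF₂(x,y))Δy` over defined bins. Profiles are
defined only up to additive constants; alignment is by least-squares
offset against a reference curve over co-defined bins (equivalently the
mean difference), or by zeroing the mean over a stated CV region.
Convergence bands repeat the full pipeline on per-window time fractions
(first 40%, last 40%, 100% — truncation acts per window on the time
axis), align each to the 100% curve, and take the per-bin min/max
envelope; the 100% curve lies inside by construction, and only relative
energies are meaningful.

Basin/barrier readout finds interior local minima (optionally after a
moving-average smooth) and reports saddles between adjacent minima.
A prominence filter (`min_prominence`, default off; 0.5 kcal/mol in the
canonical analyses) drops minima whose relief over the lower flanking
saddle is below threshold — statistical jitter otherwise reads as
basins.

## Second-CV optimisation

Independent transition-path replicates disagree along slow degrees of
freedom orthogonal to the main gating motion. PCA (plain SVD; optional
iterative Kabsch superposition to the mean shape when frames are 3N
Cartesian coordinates) supplies a basis; the replicate-separation metric

`M = 2/(Nrep(Nrep−1)) Σ_{i<j} Σ_n log d²(n,i,j)`

is maximised over weights on PCs 2–16 by differential evolution
(bounds ±1 per weight, population 15, tolerance 1e-7, seeded). Two
readings of d² ship: projection onto the single combined direction
`d² = (v·ΔX)²` (default — matches the "projection along a combination"
description) and a per-PC weighted sum `d² = Σ_k w_k²(Δp_k)²`; both are
tested and neither is asserted as uniquely correct. Squared distances
are floored at 1e-12 before the log, else coincident frames give −∞.
Scaling the weights shifts the metric by a constant (log identity), so
the search is over directions; weights are normalised afterwards and
the sign canonicalised (largest-magnitude weight positive — the metric
is even in w). No weight can land on PC 1 by construction.

## Titration

Convention fixed once: the *deprotonated* fraction rises with pH,
`f = 1/(1+10^{n(pKa−pH)})`, Hill coefficient n = 1 by default
(single-site residues; n is fittable for coupled-site synthetics). The
pKa is constrained to [min pH − 2, max pH + 2]; traces saturated at
every pH raise an unidentifiability error, and saturated *chunks* in the
chunked estimator are skipped and counted rather than clamped — clamping
would fabricate histogram mass at the pH-range edges. Replicate
statistics use the sample SD (n−1); a single replicate reports SD as
missing. Synthetic traces are two-state Markov chains with exact
stationary Hill fractions and a prescribed autocorrelation time (chain
eigenvalue `exp(−1/τ)`), started from stationarity.

## Free-energy estimators and cycles

BAR solves the Bennett self-consistent equation by bracketing root
search; its SD is the standard asymptotic estimator from the Fermi-weight
fluctuations in both ensembles. One-sided data falls back to exponential
averaging with a warning. TI integrates mean ∂H/∂λ by trapezoid with
SEMs propagated through the quadrature weights.

The Boresch term is the stiff-restraint analytic result for one
distance, two angles and three dihedrals,

`ΔG_release = −kT ln[8π²V° √(Πk) / (r₀² sinθ_A sinθ_B (2πkT)³)]`,

with V° = 1.660539 nm³ (1 M standard state), validated against a
six-coordinate configurational-integral oracle (quadrature with the
r² sinθ Jacobian) rather than trusted as transcribed; the regression
test pins the validated value. Sign conventions are centralised in one
table in `thermo.py`: affinities are reported as positive magnitudes,
`affinity = Σ(complex legs) + ΔG_release − Σ(ligand legs)`, protonation
edges are `RT ln10·(pH − pKa)`, and cycle residuals are oriented sums
with root-sum-square SDs. Cycle loop closure is validated on state
labels before any arithmetic.

The shipped λ-schedule preset (restraint switch-on through 13 uneven
points, coulomb at 0.1 spacing, van der Waals at 0.05 spacing) is
campaign metadata, not something the estimators require.

## What the synthetic world does not establish

Green tests show the estimators are correct on data satisfying their own
assumptions: equilibrium, window-labelled, uncorrelated-enough samples;
stationary protonation chains; Gaussian work distributions. They say
nothing about force-field accuracy, about hysteresis from imperfect CVs
in real sampling, about the membrane artifacts of hybrid-solvent
constant-pH methods, or about equilibration of real trajectories —
convergence bands measure internal consistency, not truth. Known
limitations: binned (not binless) WHAM with centre-evaluated biases, so
grids must resolve the stiffest windows; no decorrelation-aware
uncertainty on PMFs; no periodic CVs (distances and PC projections are
aperiodic); the Boresch formula assumes the stiff-restraint Gaussian
regime.
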
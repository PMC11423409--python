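# Methods

## The reference landscape

The synthetic ground truth for all free-energy work is a radial potential

U(r) = A·exp(−(r − R)/λ) − Σⱼ Dⱼ·exp(−(r − μⱼ)²/2σⱼ²)

with an exponential repulsive wall (A = 500 kJ/mol, R = 0.22 nm,
λ = 0.012 nm) and three Gaussian wells at μ = 0.32, 0.37 and 0.52 nm
(σ = 0.015, 0.013, 0.05 nm) representing the bidentate (BDP), monodentate
(MDP) and solvent-shared (SSP) Ca²⁺–sulfur binding modes. The well depths
are not free parameters: they are solved at construction (by root-finding
on a 10⁻⁴ nm grid search of the analytic extrema) so that

- U(BDP) − U(SSP) = +7.0 kJ/mol (inside the reported 6–9 kJ/mol range),
- U(MDP) − U(SSP) = +2.0 kJ/mol (inside the reported 1–3.5 kJ/mol range),
- the maximum between the MDP and SSP minima sits exactly 10.0 kJ/mol
  above SSP (the reported ≈10 kJ/mol barrier).

The construction is rejected if the BDP feature degenerates into a shoulder
(argmin pinned to the search-window edge), which guards the solver against
a spurious second root. The well *shapes* (widths, wall) are package
choices — only the stated energy differences and approximate positions are
constrained by the reference data — so a green recovery test establishes
estimator correctness, not anything about the true molecular curve shape.
The wall position/softness were chosen so that the integrator stiffness
βκD·dt stays ≪ 1 everywhere profiles are scored (see below); the MDP width
must stay below ~0.015 nm or its tail would undercut the shallow BDP dip
and turn it into a window-edge artifact.

## Umbrella-window generation

Windows are overdamped (inertia-free) Langevin trajectories of a single
particle in 3D under U(|x|) + k/2(|x| − r₀)². Only the stationary
distribution matters for validating histogram reweighting, and sampling in
3D produces the radial r² Jacobian physically, so the volume-entropy
correction is genuinely exercised rather than injected by hand.

The update uses the Leimkuhler–Matthews discretization

x_{n+1} = x_n − βD∇U(x_n)·dt + √(2D·dt)·(ξ_n + ξ_{n+1})/2

which samples the configurational distribution with O(dt²) accuracy at the
cost of plain Euler–Maruyama. Defaults: D = 0.1 nm²/ps, T = 300 K,
dt = 1×10⁻⁴ ps, 2×10⁴ equilibration steps, sampling stride 50 steps.
Rationale: the in-window relaxation time is τ = kT/(kD) (≈0.005 ps at
k = 5000 kJ/mol/nm², i.e. ~50 steps), so a 2×10⁵-step window carries
~2000 effective samples; a naive Euler step this long would bias the
stationary density in the stiff wall/well regions, which the
Leimkuhler–Matthews noise averaging suppresses. The stride equals τ so the
stored samples are approximately independent — this keeps the
within-window bootstrap honest (bootstrap resampling assumes exchangeable
samples; storing every 10th step instead underestimates profile errors
~3×). A runtime check rejects configurations with βκD·dt > 1, where κ is
the largest curvature of the total potential within 10 kT of the biased
minimum. Trajectories that reach |x| < 10⁻⁴ nm or NaN abort with advice to
reduce the timestep.

All generators (windows, ideal-gas frames, cluster fixtures) are pure
functions of their parameters and a seed; per-window seeds are derived
from the set seed by a fixed affine rule.

## WHAM

Standard self-consistent iteration on a shared bin grid (default width
0.005 nm), vectorized over windows × bins; convergence when
max|ΔFᵢ| < 10⁻⁷ kJ/mol (max 10⁵ iterations). Unoccupied bins are reported
as NaN — never silently zero — and samples outside the grid are counted in
the profile metadata. Non-convergence is flagged in the returned solution
and warned about, never silently returned as good. The fixed point is
independent of the iteration start (tested against random offsets).

The 2D solver is the same fixed point over flattened (r₁, r₂) bins with
separable harmonic biases; its volume-entropy correction is the sum of the
two independent 1D corrections, and tail alignment uses the occupied cells
farthest out in r₁ + r₂ (the sampled grid may stop short of the nominal
corner).

Alignment conventions: `ssp_minimum` subtracts the minimum over
0.45–0.65 nm (the solvent-shared basin, extended slightly for robustness);
`large_distance` subtracts the mean of the last 3 occupied bins. The
profile only determines differences, so both are pure shifts.

Error estimators: `segment_error` splits every window into n contiguous
blocks (default 5), rebuilds the full corrected/aligned profile per block
index, and reports the per-bin standard deviation across blocks — note
this measures the noise of a 1/n-length dataset, so it sits ~√n above the
full-profile error. `bootstrap_error` resamples each window with
replacement (same length; default 100 replicates, seeded). No
autocorrelation correction is applied anywhere (known limitation); the
stride choice above is what keeps the bootstrap approximately calibrated.

## Binding modes

`locate_mode_extrema` does bin-level argmin searches in fixed windows
(BDP 0.28–0.35, MDP 0.35–0.45, SSP 0.45–0.65 nm; overridable) with no
smoothing — reproducibility over aesthetics. A window whose argmin is not
a bracketed local minimum (monotone stretch, or a dip at the edge of the
sampled profile) is reported as not found rather than guessed. The barrier
is the maximum of G between the MDP and SSP minima. Frame classification
counts anion oxygens within 0.335 nm of the cation (minimum image):
≥2 → BDP, 1 → MDP, 0 → SSP; the ≥2 bucket deliberately absorbs
pathological >2 coordination seen with overpolarizing models.

## Structure observables

RDFs use minimum-image distances in orthorhombic boxes and exact shell
volumes (4π/3)(r₊³ − r₋³), so an ideal gas gives g = 1 bin by bin;
same-species RDFs exclude the self pair and use (N−1)/V as the target
density. Coordination numbers integrate 4πρ∫g r²dr by trapezoid on a grid
closed at 0 and at r_cut (interpolated) so no partial shell is dropped.
Cluster analysis builds a molecule contact graph (any inter-molecule
particle pair within the 0.35 nm cutoff, all particles by default — an
optional species subset supports heavy-atom-only contact) and takes
connected components; cations are excluded from connectivity by default
(clusters are defined over saccharide–saccharide contacts), with a
bridging-inclusive mode available. Triclinic boxes are out of scope.

## Composition bookkeeping

`composition_report` converts (n_solute, box edge) to molarity via
Avogadro's number and checks declared formal charges: the benchmark box of
16 disaccharides (−2 each: carboxyl + sulfate/sulfamate) and 16 Ca²⁺ in a
4 nm cube gives 0.415 M ≈ 0.4 M and zero net charge.

## What the synthetic world does and does not establish

The generator reproduces: biased sampling statistics with realistic
correlation times, the radial Jacobian, multi-window overlap structure,
and hand-constructable aggregation geometries. It does not contain
explicit water, electrostatics, force-field energetics, or any molecular
detail — a green test establishes that the estimators (WHAM, corrections,
alignments, error bars, RDF/cluster machinery) are correct and internally
consistent at desk scale, not that any particular force field is accurate.
Ideal-gas frames validate RDF normalization only; cluster fixtures are
constructions, labelled as such.

## Numerical conventions

Energies kJ/mol with k_B = 0.0083144626 kJ/mol/K; distances nm internally
(Å accepted on input with an explicit `angstrom` unit tag); times ps.
Charges in e, written to 4 decimal places. Pipeline tables are TSV with 6
significant digits, making reruns under a fixed config + seed
byte-identical. Published charge presets pin the sulfur verbatim (0.7850 e
for sulfamate, 1.00 e for sulfate sites) because the −0.75 group total is
enforced over link atoms that the published table does not print; for
user-defined groups the absorber-balance rule makes the group total exact
by construction.
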
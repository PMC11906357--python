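# Methods

`icmsort` models and quantifies the spatial segregation of the two inner-cell-mass
(ICM) lineages of the early mouse blastocyst — epiblast (EPI) and primitive
endoderm (PrE) — from their initial salt-and-pepper mixture to the final
configuration in which PrE forms a surface monolayer at the ICM–fluid interface.
It has four scientific layers: a Poissonian cellular Potts simulator, statistics
over fate-labelled 3D trajectories, scalar operators for image-derived
measurements, and a spherical-cap model of monolayer feasibility across embryo
sizes and species. A fifth layer of seeded synthetic generators provides inputs
with the statistical structure each stage assumes, so the whole pipeline is
testable without image data.

## Cellular Potts model with Poissonian kinetics

Cells are Moore-connected domains of 1 μm³ voxels in a closed box with a frozen
one-voxel medium shell (isolated-ICM geometry). The energy is

    E = Σ_ij J_ij / 2 + (κ/2) Σ_c (V_c − V̄_c)² + ε N_ECM

where the first sum runs over Moore-neighbour voxel pairs of differing label with
contact coefficients J by type pair (medium, EPI, PrE, ECM), the volume
constraint applies to cells only (no perimeter term: the actomyosin cortex, not
the model, sets cell area on these timescales), and each extracellular-matrix
(ECM) voxel carries an energy cost ε that drives its decay.

Time is physical: a copy of source type *s* over target type *t* is a Poisson
event with rate

    λ = α(t) · e^(φ(s,t)) · min(1, e^(−ΔE/k_BT)),

integrated by tau-leaping with step dt = 0.1 min — each boundary voxel, visited
in random order, draws one candidate label uniformly from the distinct labels in
its Moore neighbourhood and executes it with probability 1 − e^(−λ·dt). The
Metropolis-shaped acceptance was chosen because it reduces to exact Boltzmann
stationarity when α is uniform and φ = 0, which the test suite verifies on an
enumerable toy system. Moves that would empty a cell or break its Moore
connectivity are rejected; the connectivity test is the local simple-point
criterion (the cell's voxels inside the 26-neighbourhood of the removed voxel
must remain Moore-connected among themselves), which is sufficient for global
connectivity and slightly conservative. ECM and medium regions may fragment
freely.

ECM deposition: when a cell voxel's neighbourhood contains a *different* PrE
cell, the ECM label joins the candidate set, and the active exponent
φ(EPI→ECM) = φ(PrE→ECM) biases the copy. Converting a voxel adjacent to its own
cell's interior creates of order 15 fresh ECM:cell contacts, an intrinsic cost of
tens of k_BT; the default exponent (52 with the default J) largely offsets this,
giving steady deposition at cell–cell contact corners. A saturating exponent
(e.g. 10⁵) is accepted configuration but floods the lattice with matrix.
Destruction is passive: cells and medium overwrite ECM at the unbiased rate, with
−ε favouring decay, so matrix turns over in minutes and its instantaneous
distribution tracks where PrE contacts currently are — which is what produces the
peripheral ECM shift as sorting proceeds.

Growth and division: V̄_c(t) = V̄_c(0) + g·t until V̄ reaches a division target
drawn with replacement from the ten measured mitotic volumes
(2,406.63 … 4,133.67 μm³); the cell then splits along the plane through its
centroid perpendicular to the principal axis of its gyration tensor (documented
tie-break: the x-axis for a degenerate tensor). Daughters inherit the type,
start with V̄ equal to their actual post-split volume, and resample targets.
Discrete plane cuts can strand fragments; these are reassigned so both daughters
stay connected while volumes still sum exactly to the parent's.

### Default parameters and why

No complete numeric parameter set is available for this model variant, so the
shipped defaults are this package's own, constrained by (a) the stated tension ordering
γ_PrE:M < γ_PrE:PrE < γ_EPI:EPI < γ_PrE:EPI < γ_EPI:M and (b) the requirement
that a 30-cell ICM sorts within 8 simulated hours:

| parameter | default | unit | note |
|---|---|---|---|
| J(PrE,M) / J(PrE,PrE) / J(EPI,EPI) / J(PrE,EPI) / J(EPI,M) | 2 / 4 / 5 / 7 / 14 | k_BT per voxel-pair | ordering above; ECM mirrors PrE: J(M,ECM)=J(M,PrE), J(EPI,ECM)=J(EPI,PrE), J(PrE,ECM)=J(PrE,PrE) |
| κ | 1 | k_BT·μm⁻⁶ | ~1-voxel r.m.s. volume fluctuation |
| α | 16 | events·min⁻¹ (all types) | sets the mobility scale; α_ECM = α_PrE |
| φ(cell→ECM) | 52 | dimensionless | offsets the ECM-interface creation cost at J(PrE,ECM)=4 |
| ε | 2 | k_BT per ECM voxel | matrix lifetime of minutes |
| dt | 0.1 | min | as published |
| g | 2 | μm³·min⁻¹ | volume roughly doubles in a ~16 h cycle at ~1,900 μm³ cells |

A softer PrE:PrE contact (≤2) lets PrE flatten into thin enveloping shells; the
configuration is physically sorted (the free surface becomes >95% PrE) but the
centroid-based sorting score saturates near +0.25 because flattened-shell
centroids sit at the same radius as the outermost EPI centroids. The default
J(PrE,PrE) = 4 keeps cells compact and the score discriminating.

### Scaled test geometry

The acceptance-scale simulations use 30 cells in a 10 μm-radius aggregate
(~140 μm³ per cell, about 8× below the measured ~1,900 μm³) so ten 8-hour runs
fit a single-CPU budget; the growth rate is scaled by the same factor
(g = 0.25 μm³·min⁻¹), and division targets are consequently never reached in
those runs — division mechanics are exercised separately at full scale. Energies
are scale-free per contact, so the tension ordering and sorting behaviour carry
over; absolute timescales of sorting do depend on cell size, which is why the
defaults are calibrated at the test scale.

## Trajectory statistics

Radial position is measured from the per-frame geometric centroid (plain mean of
all cell positions); the normalised depth d divides by the per-frame maximum
cell radius (outermost cell ⇒ d = 1), a parameter-free surface proxy. Rolling
averages are centred with a 3-frame default window. The sorting score is the
mean over all (PrE, EPI) pairs of sign(r_PrE − r_EPI): +1 exactly when every PrE
lies strictly outside every EPI, antisymmetric under label exchange, invariant
to common rescaling of radii. Displacement maps bin r(t+1) − r(t) by the step's
starting radius and time (positive = outward). First-passage probabilities scan
each distance-to-lumen trajectory for the first exit of a ±3 μm corridor around
X₀, with successive X₀ samples at least 3 min apart; trajectories that never
exit are censored — counted but excluded from the conditional probability.
Fate-switch detection uses a hysteresis band: a switch requires crossing the
high threshold from below the low one and staying above it for ≥ 2 frames
(defaults: mode midpoint ± 10% of the mode distance, modes from 2-class 1-D
k-means), so single-frame reporter spikes never count.

## Image-derived operators

* **Aspiration tension**: γ = P_c / [2(1/R_p − 1/R_c)]; since 1 Pa = 1 pN·μm⁻²,
  pressures in Pa and radii in μm give γ in pN·μm⁻¹ with no conversion. R_c ≤ R_p
  is rejected as an invalid steady state.
* **Polarization index**: outer-quarter over inner-quarter mean intensity of a
  cell-spanning profile (inner edge at 0, fluid-facing edge at 1).
* **Profiles**: equal-width positional bins (default 20), optional division by
  the maximum bin and centred rolling average; empty bins surface as NaN.
* **Membrane curvature**: for each contour point, the circumscribed circle
  through the points ±10 positions away (cyclic on closed contours); curvature
  1/R in μm⁻¹, exactly 0 for collinear triples (|cross| < 10⁻⁹ × extent²), sign
  positive where the contour is locally convex outward, fixed via the contour
  orientation. Mean error on digitised circles of radius 20–200 px is under 5%.
* **Boundary bins**: six contiguous equal-arc-length intervals anchored with bin
  0 centred on the cavity-facing pole (the point whose direction from the
  centroid best aligns with the cavity axis); argmax ties resolve to the lowest
  index and are flagged.
* **Fate classification**: per channel, log intensity is regressed on imaging
  depth z and the fitted trend subtracted (fluorescence decays with depth);
  2-class k-means (10 restarts, fixed seed) on the corrected (GATA6, NANOG)
  values; the cluster with the higher corrected GATA6 mean is PrE.
* **Shape**: aspect ratio from the second-moments ellipse of the traced polygon
  (exact Green's-theorem moments), circularity 4πA/P² with polygonal perimeter;
  protrusion length and cavity angle from centre→tip and centre→cavity-normal
  segments.
* **Colocalization**: Pearson r over the union of above-threshold voxels;
  Manders M1 = Σ A over B-positive voxels / Σ A and symmetrically M2. A constant
  channel yields a flagged NaN correlation.

## Spherical-cap monolayer model

The ICM is the solid between two spherical caps on a shared base circle of
radius R: the trophectoderm-facing dome of height H minus the fluid-facing cap
of height h. Closed forms: cap volume (πh/6)(3r² + h²), lateral area π(r² + h²).
With PrE fraction f and apical-area percentiles q10 = 157 μm², q90 = 376 μm²,
an ICM of n cells can tile its interface iff

    f·n·q10 ≤ A_interface = π(R² + h²) ≤ f·n·q90,

with A_interface above the band ⇒ gap, below ⇒ multilayer; boundary equalities
count as monolayer (the published inequalities for gap/multilayer are strict).
Convex (human-type) interfaces use the same formulas with h measured toward the
cavity; only the ICM-volume bookkeeping flips the minor-cap sign. The hemisphere
reference curve A = 3^(2/3)(π/2)^(1/3)(cN)^(2/3) is the interface area of a
hemispherical cap on a spherical ICM of volume cN; because it scales like
N^(2/3) against linear PrE-area bounds, monolayer feasibility holds on exactly
one contiguous interval of N — asserted numerically in the tests. The scaling
constants come from through-origin least squares (V = cN and n_pre = f·n_total,
literally as published, not affine fits), defaults c = 1,907 μm³ and f = 0.6
(species scenarios: mouse 0.6, monkey 0.7, human 0.55). Outcome probabilities
are per-size-class relative frequencies with binomial standard errors.

## Synthetic generators: what they emulate, and what a green test does not show

Each generator is a pure function of its spec and seed (byte-identical reruns)
and writes a ground-truth sidecar sufficient to compute every stage's expected
output. Distributional choices the source data do not constrain are: Gaussian
drift–diffusion steps for trajectories (PrE biased outward 0.5 μm/frame at a
20-min frame interval, retention at the surface radius; EPI neutral), binomial
fate counts and Poisson cell counts over size classes, log-normal marker
intensities with exponential depth decay, Gaussian-bump protrusions on circular
contours, and multiplicative Gaussian pressure noise on Young–Laplace records.
The marker generator's default mode separation is 3 s.d. per channel,
representative of the clean GATA6/NANOG bimodality of fixed embryos; at 2 s.d.
the Bayes-optimal error of any classifier already exceeds 5%, so the ≥95%
recovery property is stated — and tested — at the 3 s.d. default. Green tests
establish internal consistency against these stated worlds, not agreement with
microscopy data: real nuclei tracks have correlated, anisotropic motion; real
intensity decay is not exactly exponential; real contours carry tracing noise.

## Numerical choices and degenerate inputs

Rates are computed in log space so saturating exponents never overflow; the
execution probability saturates at 1. Collinearity, degenerate gyration
tensors, zero-area contours, inverted hysteresis thresholds, empty histogram
bins, constant colocalization channels, R_c ≤ R_p aspiration readings and
infeasible packings all have explicit, tested behaviours (documented above or
raising named errors) rather than silent defaults. The ECM radial statistic of
a recording window pools per-minute snapshots across the window; the
instantaneous matrix population is small and fast-mixing, so single snapshots
are shot-noise dominated.

## Known limitations

The Metropolis-shaped Poisson-rate functional is one member of a family of
admissible kinetics, and no reference parameter set exists for it, so
quantitative rate-dependent outputs (absolute sorting timescales, ECM turnover
rates) are calibrated, not reproduced. The simulator has no trophectoderm, cavity pressure, or gene
network; fate is fixed at initialisation. Tau-leaping introduces O(dt) bias
relative to exact kinetic Monte Carlo — negligible at dt = 0.1 min for the
default rates, and the Boltzmann test runs at dt = 0.01 accordingly. The local
connectivity test can reject globally safe moves, slightly stiffening cells.
The sorting score is nuclei/centroid-based and undervalues configurations with
strongly flattened surface cells.
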
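# Methods

## Model overview

`vascrad` couples a lattice of discrete cell agents to a continuum oxygen
field (a hybrid cellular automaton). The three ingredients are:

1. **Oxygen transport.** On the non-dimensional lattice (lengths in cell
   diameters, times in cell cycles, oxygen as a fraction of the arterial
   concentration), the field obeys ∂c/∂t = D_c∇²c − f(c) with
   Michaelis–Menten uptake f = μ_i·r_c·c/(c+K_m). Vessels are single
   lattice sites held at c = 1 (Dirichlet); the outer boundary is
   no-flux. The model assumes linear isotropic diffusion, vessels that
   neither move, collapse nor remodel, and *en face* vessel cross
   sections (point sources in the tissue plane).
2. **Cell fates.** Healthy and tumour cells occupy single sites and are
   visited once per automaton step in a fresh uniform-random order (order
   bias is checked statistically in the test suite). Below c_ap a cell
   dies with probability p_d; below c_p, or lacking an eligible Moore
   neighbour, it is quiescent (reversible, division suppressed only);
   otherwise it divides with probability p_H/p_T, placing an identical
   daughter in a uniformly chosen eligible neighbour. Tumour daughters may
   replace (kill) healthy occupants — competition is modelled as
   replacement, not displacement. Daughters act from the following step.
3. **Radiation.** Survival is linear-quadratic with the oxygen
   enhancement ratio applied as α(c) = α_max/OER_α(c),
   β(c) = β_max/OER_β(c)², OER saturating from OER_max (anoxia) down to
   OER_min = 1 (full oxygenation) with half-saturation K_OER. Tissue
   survival is evaluated on the cellular-oxygen histogram (bin width
   Δc = 0.01, survival at bin midpoints), giving expected survivors as
   real numbers; an optional Bernoulli-thinning mode actually removes
   cells for dynamic post-irradiation studies.

## Parameters

Defaults (see `ModelParameters`) are glioblastoma-flavoured estimates:

| symbol | meaning | default | non-dim |
|---|---|---|---|
| D_c | oxygen diffusivity | 1.0e-5 cm²/s | 2.304e4 cycle⁻¹ |
| r_c | maximal uptake | 4.6e-16 mol/cell/s | 51.55 cycle⁻¹ |
| r_p | proliferative surcharge | ×5 | — |
| Δx | cell diameter | 50 µm | 1 |
| τ | cell cycle | 16 h | 1 |
| Δt | oxygen step | 0.25 s | 1/230,400 |
| c_max | arterial oxygen | 5.14e-13 mol/cell (~80 mmHg) | 1 |
| c_ap / c_p | death / quiescence thresholds | — | 0.10 / 0.11 |
| K_m | Michaelis constant | 5.14e-15 mol/cell | 0.01 |
| μ_H, μ_T/μ_H | metabolic constants | 1, 2 | — |
| p_d, p_H, p_T | per-cycle fate probabilities | 0.25, 0.005, 0.01 | — |
| α_max, β_max | LQ constants | 0.3 Gy⁻¹, 0.03 Gy⁻² | — |
| OER_{α,β},max | anoxic enhancement | 1.75, 3.25 | — |
| K_OER | OER half-saturation | 3.28 mmHg | 0.041 |

α_max and β_max are conventional glioma LQ values, exposed as mandatory
configuration fields so users can substitute their own; they only enter
the radiation post-processing. c₀ (initial oxygen) defaults to the
arterial value 1, which relaxes fastest to the quasi-steady field.

**K_OER units.** The OER half-saturation constant is a partial pressure
(≈3 mmHg in the classical radiobiology literature). The package therefore
non-dimensionalises it like every other oxygen quantity:
K_OER,nd = 3.28/80 = 0.041. With the constant left at 3.28 on a [0, 1]
oxygen scale the OER would be nearly flat across the entire physiological
range (1.58–1.75 for α) and the oxygen effect essentially inert, which we
judge unphysical; `rescale_K_OER_by_cmax: false` restores that behaviour
for comparison. The headline qualitative result (the interior peak of
mean survivors across vessel densities) is present under both settings.

**OER functional form.** Two reconstructions are provided:
the default `saturating_decreasing` (OER falls from OER_max to OER_min
with oxygen; α = α_max/OER) and `saturating_increasing` (OER rises from
OER_min to OER_max; α = α_max·OER/OER_max). Both satisfy the same anoxic
and fully-oxygenated limits, which is all the tests assert; the choice
between them only reshapes the transition region around K_OER.

## Numerics

* **Discretisation.** Five-point Laplacian, ghost-node reflection
  (c₋₁ = c₁) at the domain edges, unit lattice spacing. Vessel sites are
  Dirichlet nodes excluded from the update.
* **Quasi-steady coupling.** The oxygen relaxation time across the
  domain (~N²/D_c, a few percent of a cell cycle for N ≈ 100) is far
  shorter than an automaton step, so each step couples to the steady
  field. The default route solves the discrete steady equations by
  damped modified Newton: the per-site quadratic from the
  Michaelis–Menten term is linearised, the sparse Jacobian LU is reused
  across automaton steps while occupancy changes little, and iterations
  stop when the maximum update falls below 10⁻⁶ (Newton updates track the
  remaining error closely). The explicit route (`method="explicit"`,
  steps of 1/230,400 cycle, stability number 0.1 ≤ 0.25) is retained and
  must agree with the direct route to better than 0.1% — in practice
  ~10⁻⁶ — in the cross-validation tests.
* **Degenerate cases.** No vessels and no consumers: the no-flux dynamics
  conserve mean oxygen, so the field flattens to its mean. No vessels
  with consumers: the field decays to zero. Vessels everywhere: the field
  is identically 1. Oxygen is clipped to [0, 1] against round-off only; a
  clip larger than 10⁻⁶ raises a diagnostics warning.
* **Fate updates.** The sequential random-order sweep is compiled with
  numba; all random draws (visit order, death/division, daughter choice)
  are pre-generated from seeded numpy Generators, so every trajectory is
  exactly reproducible from (configuration, master seed) and all
  substreams are derived by hashing (seed, purpose tag, replicate index).
* **Update frequency.** K automaton updates per cell cycle (default 1)
  with exact hazard rescaling 1−(1−p)^K = p_cycle, so per-cycle death and
  division probabilities are invariant to K.
* **Ties and choices.** Daughter sites are chosen uniformly among
  eligible neighbours; the histogram bin of c = 1 clamps to the top bin;
  bin survival uses midpoints (second-order accurate against the
  per-cell oracle, agreement <1% enforced in tests).

## Experiment protocols and the synthetic vessel generator

Vessel patterns are the synthetic data of this package and define the
study conditions:

* **Regular grids** at integer spacings, centred in their tile
  (offset = spacing div 2; the phase is configurable since only the
  density is physically constrained). Realisable regular densities are
  quantised; near-square kx × ky grids (|kx−ky| ≤ 1 by default) refine
  the quantisation, and sweeps always report the realised Θ = v/N².
* **Uniform-random placements** of v distinct sites (complete spatial
  randomness on the lattice), the model of disorganised tumour
  vasculature.
* Clustered-patch and two-point fixtures exist for estimator validation.

The equilibrium protocol steps the automaton until the cell count changes
by <1% for 50 consecutive steps (an empty domain counts as converged;
a 2000-step cap flags non-equilibrated runs, which family summaries
exclude), then records and averages 100 further steps of cellularity and
cellular-oxygen data; the averaged histogram is what gets irradiated.
"Carrying capacity 1" means ≥99.9% of non-vessel sites occupied at
equilibrium; at genuinely supercritical densities no site ever falls
below c_ap, so occupancy is exactly 1 and the threshold only absorbs
stochastic flicker. Cellularity is reported both as cells/N² (vessel
sites in the denominator) and as occupancy of non-vessel sites.

Desk-scale problem sizes (the package's defaults for its own test suite
and acceptance script): 3 automaton seeds per density for the
critical-density search on 100 × 100; 25 replicates per vessel count at
10 counts spanning Θ = 0.001–0.045 on 73 × 73 for the random families;
10 placements each for the irregular-cellularity runs. Production-scale
sweeps (hundreds of replicates per family) use the same code paths with
`n_reps` raised.

What the generator does **not** emulate: vessel calibre or flow
heterogeneity, clustered/inhomogeneous vasculature beyond the test
fixture, angiogenesis or vessel collapse, three-dimensional geometry.
Passing tests therefore demonstrate internal consistency of the model
chain under idealised point-source vasculature, not fidelity to any
particular histological tissue.

## Spatial statistics

Ripley's K uses the translation edge correction, exactly unbiased on a
rectangular window (K̂(r) = |W|/(n(n−1)) Σ_{i≠j} e_ij 1(d_ij ≤ r) with
e_ij = |W|/((a−|Δx|)(b−|Δy|))); an isotropic (circle-fraction) correction
is available as an option and the organisation–outcome correlations are
not sensitive to the choice. L(r) = √(K/π) is evaluated at integer
r = 0…19 cell diameters and averaged into the scalar mean-L summary;
CSR calibration (mean L within 3 standard errors of r over ≥200 random
patterns) is enforced in the acceptance tests. Patterns need at least two
distinct points; degenerate inputs are rejected, and zero-variance
correlation inputs return flagged results rather than silent NaN.

## Known limitations

* The emergent tissue-support scale is set by the ratio D_c/r_c of the
  default constants; the critical regular density for healthy tissue
  computed by this implementation (bracketed by the acceptance script at
  0.0012–0.0016 vessels/site) is roughly half the 0.0027–0.0031 range
  quoted in the glioblastoma modelling literature from which the
  parameter estimates derive, and equilibrium cellularities under sparse
  random vasculature are correspondingly higher. Both integration routes
  agree and satisfy the discrete steady balance exactly, so this is a
  property of the stated constants, not of the numerics; users calibrating
  against tissue data should treat r_c (or equivalently μ_H) as the free
  scale. For the same reason the density at which mean post-irradiation
  survivors peak — an interior maximum the model robustly produces, where
  rising carrying capacity is overtaken by improving oxygenation and by
  vessels displacing cells — is found by the acceptance script at
  Θ ≈ 0.007 rather than the ≈0.01 quoted in that literature.
* Quiescent cells consume at the baseline rate (reduced quiescent
  metabolism is not modelled); the proliferative ×5 surcharge applies to
  a dividing parent for exactly one oxygen solve.
* Radiation is instantaneous thinning: no repair kinetics, repopulation
  between fractions, cell-cycle radiosensitivity, or fractionation
  scheduling.
* The automaton has no cell motility and only two phenotypes.
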
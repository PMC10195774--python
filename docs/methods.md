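# Methods

`terpued` post-processes excited-state trajectory ensembles of the
photochemical electrocyclic ring-opening of α-terpinene
(1-methyl-4-isopropyl-1,3-cyclohexadiene) into the observables of a
megaelectronvolt gas-phase ultrafast electron diffraction (UED) experiment,
and provides a phenomenological surrogate generator so that the whole
pipeline can be exercised, calibrated and tested without ab initio data.

## Structural model

All bookkeeping uses a fixed carbon numbering: the ring is
C1–C3–C4–C5–C9–C6–C1 with reactant double bonds C1=C6 and C9=C5; the σ bond
broken by the ring-opening is C3–C4; the isopropyl group (C2, with methyls
C7/C8) sits on C1 and the methyl reporter C10 on C5. The bond topology is
the *reactant* topology and is never re-perceived from distances during
dynamics, so "the C3–C4 distance" and "third coordination sphere" keep their
meaning after the ring has opened.

Coordination spheres are shortest bond-path lengths in this fixed graph:
sphere 1 pairs are bonded (~1.3–1.5 Å), sphere 2 pairs geminal (~2.5 Å),
sphere 3 pairs sit across a central bond and are bimodal — *cis* conformers
near 3 Å, *trans* conformers near 4 Å. cis/trans labels are assigned by the
sign of the dihedral along a shortest path, evaluated once on a reference
reactant geometry and then propagated, because they describe reactant-frame
conformations rather than per-frame dihedrals.

### Conrotatory angles

Rehybridization of the C3/C4 CH₂ groups is tracked by two plane–plane
coordinates:

* **ɸ (planarization)** — per side, the signed angle between the CH₂ plane
  (carbon plus its two nearest hydrogens within 1.3 Å) and the plane of the
  forming product double bond ((C1,C2,C3) and (C4,C5,C10) respectively).
* **ψ (deplanarization)** — the signed angles of those same substituent
  planes against the least-squares plane of the conjugated diene carbons
  C1, C6, C9, C5 (smallest principal component of the centered coordinates;
  four atoms are generally non-coplanar).

Signs use side axes C3→C1 and C4→C5 and the triple product
n_ref · (n_mov × axis). Reference normals are oriented by the right-hand
circulation of the C1→C6→C9→C5 circuit; orienting by "the side bearing C2"
is numerically ill-defined because C2 lies almost in the ring plane. With
this convention a conrotatory twist of the two terminal groups produces
contributions of equal sign (the sums add), while disrotatory motion
cancels. Both sums are invariant under rigid rotation and translation;
under mirror reflection they change sign, as a chirality-sensitive
coordinate must.

## Diffraction model

Scattering is computed in the independent-atom model (IAM). The rotationally
averaged molecular intensity follows the Debye equation,

    I_mol(s) = Σ_{i≠j} f_i(s) f_j(s) sin(s r_ij)/(s r_ij),

with elastic electron scattering amplitudes from the 5-Gaussian
parameterization of Peng, Ren, Dudarev & Whelan (Acta Cryst. A52, 257,
1996), and the observable is sM(s) = s·I_mol/I_at with
I_at = Σ_i f_i². Pair distribution functions are the damped sine transform

    PDF(r) = ∫ sM(s) sin(sr) exp(−α s²) ds,

evaluated by the trapezoidal rule. Defaults: s ∈ [0.5, 10] Å⁻¹ with
Δs = 0.02 Å⁻¹ (a typical MeV-UED window; the unmeasured region below s_min
is treated as zero), r ∈ [0, 8] Å with Δr = 0.01 Å, and α chosen so that
exp(−α s_max²) = 0.1 — the usual compromise between real-space resolution
and truncation ripple. All are configurable and recorded in artifact
headers. Difference PDFs are ΔPDF = f_exc (PDF_excited − PDF_reference)
with the experimental excitation fraction f_exc = 1.56 % by default. No
inelastic, multiple-scattering or anisotropy corrections are applied.
Hydrogens are included in the IAM sums but contribute weakly; the analysis
of distance distributions is restricted to carbon–carbon pairs.

ccDDF histograms use 0.05 Å bins over [1, 8] Å. Extrema are located on a
Gaussian-smoothed histogram (kernel σ = 2 bins): raw-bin argmaxes are
noise-sensitive. The "gap minimum" of the third sphere is the interior
minimum between the two largest maxima, with plateau centers used when the
smoothed valley is flat.

## Kinetic analysis

Time-dependent ΔPDF amplitude is integrated over three real-space windows,
chosen from the coordination-sphere structure and configurable:
α = [1.2, 1.9] Å (bond rupture), β = [2.2, 3.0] Å (geminal distances),
γ = [3.2, 3.7] Å (the third-sphere cis/trans gap around 3.4 Å). Traces are
convolved with a unit-area Gaussian instrument response (default FWHM
150 fs, replicated-edge padding so constants are preserved) and fit with

    S(t) = B + (A/2)(1 + erf((t − t0)/(√2 w))).

The fit is restricted to an *onset window* (delays ≤ 400 fs by default,
about 2.7× the IRF FWHM past time zero, plus all pre-time-zero points).
The error function is a local model of a signal rise; over a full
picosecond the region traces contain slow drifts from ongoing product
formation, and including them biases the fitted center away from the onset
it is meant to locate. Onset widths are reported both as the Gaussian σ of
the erf and as FWHM = 2.3548 σ.

Uncertainties are nonparametric bootstrap 68 % percentile intervals
(16th–84th), resampling *trajectories* (or experimental scans), never
individual frames, which are serially correlated. Because region traces are
linear in the per-trajectory scattering curves, the pipeline precomputes a
(trajectory × delay × region) tensor once and bootstraps by reweighting.

The C3···C10 reporter dip time is the minimum of the S1-restricted
expectation value, refined to sub-grid resolution by a local parabola and
evaluated only where the S1 population is at least 10 % (late-time S1
remnants are single trajectories and their expectation is noise).

Ring-opening branching is classified at the final frame only (avoiding
transient recrossing): the population-weighted fraction of S0 frames with
C3–C4 > 2.0 Å, a threshold safely beyond the ring-open conical-intersection
region (~2.2 Å) yet below all product values (> 2.5 Å). A
trajectory-counting mode is available.

## Surrogate trajectory generator

The generator emulates the statistical structure of nonadiabatic
wavepacket simulations of this reaction without computing forces:

* **Geometries.** The closed reactant and the open-chain triene products
  (cZc, cZt, tZc, tZt; Z central bond, s-cis ≈ 40° or s-trans 180° terminal
  single-bond conformations) are built with RDKit (ETKDG embedding, MMFF94
  refinement) and relabelled onto the canonical atom order by
  bond-order-aware graph matching. The three stable isopropyl rotamers are
  produced by torsion-restrained relaxation and enter with equal weight by
  default. Builders are deterministic, including across processes.
* **Anchors.** The pericyclic-minimum and ring-open-CI anchors are
  *synthetic constructs*: internal-coordinate edits of the reactant with
  the breaking σ bond set to 1.6 Å and 2.2 Å respectively, the methyl
  bent 60° out of the diene plane, a 12° twist of the diene about its
  central bond, and a 12° conrotatory rotation of both CH₂ groups. The
  methyl tilt is calibrated so the anchor's C3···C10 distance is ≈ 3.55 Å
  (its reactant value is ≈ 3.9 Å). The diene twist matters structurally:
  tilting substituents on a rigid ring alone *shortens* the geminal
  C4···C10 distance and spuriously feeds the β region at early times,
  whereas deplanarization of the conjugated system also stretches the cis
  third-sphere distances and keeps the early signal confined to the γ gap
  — which is exactly the discriminating signature the analysis is built to
  resolve.
* **Dynamics.** Each trajectory starts from a thermally displaced reactant
  (independent Gaussian displacements, σ_C = 0.03 Å, σ_H = 0.06 Å — a
  cheap stand-in for Wigner sampling), relaxes on S1 along an
  internal-coordinate morph toward the pericyclic anchor with a sin²
  progress law peaking at the dip time (default 100 fs, log-normal jitter
  15 % so that the ensemble spreads along the reaction path) and then
  settling, with a damped oscillation, onto a plateau just below the
  anchor — dephasing keeps the first arrival the unique closest approach,
  so the reporter-distance dip time is well defined — hops to S0
  at latency + Exp(τ) (defaults 60 + 120 fs — free parameters shaping a
  plausible S0 rise, not literature values), and then either morphs to a
  uniformly chosen product anchor with an exponential 100 fs ramp
  (probability p_open, default 0.58) or relaxes back toward the reactant
  (150 fs). Morphing interpolates bond lengths, angles and shortest-arc
  dihedrals of a fixed Z-matrix whose construction tree contains the
  breaking C3–C4 bond (the ring closes at the emergent C4–C5 bond, exact
  at every anchor); Cartesian interpolation is avoided because it
  collapses CH₂ groups along curved paths. Native time step 5 fs over
  1 ps, resampled to a 10 fs analysis grid; equal, constant trajectory
  weights.

What the surrogate does **not** emulate: forces, energies, surface
topography, spawning (no spawn-geometry metadata), coherent population
transfer (weights are constant per trajectory; hops are instantaneous),
anharmonic thermal structure, and long-lived hot ground-state motion.
Passing tests on surrogate data therefore validates the *analysis chain* —
observable forward model, region kinetics, fit and bootstrap machinery, and
the recoverability of generator-level truths (branching fraction, dip time,
onset ordering) — not the photochemistry itself.

Spectrum utilities mirror the initial-condition workflow of such studies:
oscillator-strength-scaled Gaussian broadening (0.2 eV FWHM default) and
selection of initial conditions whose red-shifted (0.4 eV) transition
energy lies within 0.3 eV of the 4.65 eV pump.

## Numerical choices and degenerate inputs

* Weighted ensembles are normalized internally; all ensemble statistics are
  invariant to uniform weight rescaling (enforced by tests).
* Expectation values with zero state-filtered population return masked
  points, not exceptions.
* Zero-width bootstrap intervals (degenerate statistics) warn instead of
  failing; the interval is clamped to contain the point estimate.
* Erf fits start from data-driven guesses (edge means for baseline and
  amplitude, half-rise crossing for the center); non-convergence raises a
  fit error carrying the optimizer diagnostics.
* XYZ parsing reports file, frame and line on malformed input. Carbon
  labels come from a sidecar file or, for closed-ring geometries, from
  distance-based template matching against the fixed topology (double bonds
  below 1.42 Å, bonds below 1.75 Å), with the C7/C8 methyl ambiguity
  resolved by a torsion convention shared with the builder.

## Problem sizes

Default analyses use 100-trajectory ensembles (400 for branching-ratio
estimates, matching a binomial 3σ of ±7.4 % at p = 0.58), 21 delay points
at 50 fs spacing for ΔPDFs, 200 bootstrap resamples, and 180-geometry
thermal ensembles (60 per rotamer) for static observables. The onset
ordering study runs 20 independently seeded end-to-end repeats, each also
evaluated with all region boundaries shifted by ±0.2 Å.

## Known limitations

* The IAM ignores inelastic and multiple scattering; absolute ΔPDF
  amplitudes are meaningful only relative to the same model.
* The anchors are plausibility constructs, not stationary points of any
  potential-energy surface; quantities that depend on fine anchor geometry
  (e.g., the exact location of the third-sphere gap minimum) inherit the
  force field's equilibrium structure.
* A single error function cannot represent multi-step kinetics; the onset
  window mitigates but does not remove this model error.
* The fixed Z-matrix is specific to the C10H16 skeleton; other molecules
  would need their own construction tree.
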
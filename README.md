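# terpued

Structural-dynamics analysis of the photochemical electrocyclic
ring-opening of α-terpinene, from excited-state trajectory ensembles to
gas-phase ultrafast electron diffraction (UED) observables.

α-Terpinene (1-methyl-4-isopropyl-1,3-cyclohexadiene) is a substituted
cyclohexadiene whose UV-driven 6π electrocyclic ring-opening passes through
the *pericyclic minimum* — the S₁ critical geometry at which σ-bond
breaking, π-bond alternation and conrotatory CH₂ rehybridization are all
partially advanced. Its methyl and isopropyl substituents act as carbon
reporter groups: their out-of-plane bending during relaxation into the
pericyclic minimum shortens *trans* third-coordination-sphere
carbon–carbon distances (e.g. C3···C10, 3.9 → 3.55 Å by ~100 fs) and is
visible in time-resolved pair distribution functions *before* the C3–C4
σ bond breaks on the ground state. This package implements that complete
analysis chain for simulators and UED experimentalists:

* **Geometry** — fixed C1..C10 topology, coordination spheres, cis/trans
  conformer labels, and the conrotatory planarization/deplanarization
  angles ɸ and ψ.
* **Diffraction** — independent-atom-model sM(s) via the Debye equation,

      sM(s) = s · Σ_{i≠j} f_i f_j sin(s r_ij)/(s r_ij) / Σ_i f_i²,

  damped sine-transform PDFs, and excitation-fraction-scaled ΔPDFs.
* **Distance distributions** — carbon–carbon distance histograms (ccDDF)
  partitioned by coordination sphere, their time differences, and extrema
  (the third sphere is bimodal: cis ≈ 3 Å, trans ≈ 4 Å, gap minimum 3.4 Å).
* **Wavepacket ensembles** — weighted, state-labelled trajectories with
  population traces, coordinate expectation values, 2-D kernel-density
  projections, and the open/closed branching fraction.
* **Kinetics** — α/β/γ region integration, 150 fs Gaussian IRF
  convolution, error-function onset fits
  S(t) = B + (A/2)(1 + erf((t−t₀)/(√2 w))), and trajectory-level bootstrap
  (68 % percentile) uncertainties.
* **Surrogate generator** — a phenomenological trajectory-ensemble
  generator (thermal sampling, S₁ relaxation with methyl out-of-plane
  bending, stochastic internal conversion, tunable 58 % ring-opening
  branching into the cZc/cZt/tZc/tZt triene isomers) used to exercise and
  calibrate the pipeline end to end.

## Worked example

Run the full pipeline on a freshly generated 100-trajectory surrogate
ensemble and write CSV/JSON artifacts to `analysis/`:

```sh
terpued analyze --seed 1 --out analysis
```

prints

```
onset alpha: t0 = 237.3 fs [223.4, 251.5] (68%), width sigma = 119.8 fs
onset beta: t0 = 155.1 fs [143.3, 167.3] (68%), width sigma = 98.0 fs
onset gamma: t0 = 117.2 fs [102.1, 132.2] (68%), width sigma = 113.2 fs
branching fraction: 52.5% [46.5, 57.0] (68%)
C3-C10 S1 dip: 112 fs
```

Reading the output: the γ region (3.2–3.7 Å, the gap between the cis and
trans third-sphere modes) turns on at ~117 fs, *before* the β (155.1 fs)
and α (237.3 fs) regions — the diffraction signature of substituent
out-of-plane bending toward the pericyclic minimum preceding the actual
C3–C4 bond rupture. The branching fraction is the share of ground-state
population that ends ring-opened (this 100-trajectory draw gives
52.5 ± 5 % around the configured 58 %), and the dip is the time at which
the S₁ C3···C10 reporter distance is shortest (configured at 100 fs;
bracketed values are bootstrap 68 % intervals over trajectories).

The same analysis is available as a library:

```python
from terpued import SurrogateParams, generate_ensemble, branching_fraction
ens = generate_ensemble(SurrogateParams(n_traj=400, seed=12))
print(branching_fraction(ens))   # 0.60 for this seed
```

`terpued simulate` writes an ensemble (manifest CSV + multi-frame XYZ) to
disk, `terpued fit` fits an erf onset to any two-column delay trace, and
`terpued report` summarizes a saved `report.json`.

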
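# skindpf

Monte Carlo light transport in layered human skin, built to answer one
question precisely: **how far does detected light actually travel** in
reflection-mode near-infrared spectroscopy (NIRS)?

In scattering tissue the mean optical pathlength ⟨L⟩ of detected photons is
much longer than the source–detector separation *d* (optode spacing), and the
modified Beer–Lambert law must carry the ratio as the **differential
pathlength factor**:

```
A(λ) = ε(λ) · C · d · DPF(λ, d),        DPF(λ, d) = ⟨L(λ, d)⟩ / d
```

Accurate DPF values are what turn a measured attenuation change into a
quantitative chromophore change (hemoglobin, water — and, downstream, skin
glucose sensing in the dermis). `skindpf` estimates DPF(λ, d), per-layer
partial pathlengths, and banana-shaped spatial sensitivity maps for a
seven-layer skin model across the diagnostic window (450–1050 nm) and
separations of 0.5–8 mm, for light (2 % epidermal melanin) and dark (20 %)
skin.

## What is inside

* **Tissue model** — a seven-layer slab (stratum corneum, epidermis,
  papillary dermis, upper blood net dermis, reticular dermis, deep blood net
  dermis, subcutaneous tissue; 2.95 mm total). Layer absorption is a
  volume-fraction blend of water, oxy/deoxyhemoglobin (saturation S = 0.75),
  melanin (μa = 6.6×10¹⁰ λ⁻³·³³ mm⁻¹) and a small baseline; scattering is a
  tabulated spectrum (60.6 mm⁻¹ at 450 nm down to 7.5 mm⁻¹ at 1050 nm) with
  Henyey–Greenstein anisotropy g = 0.9 and refractive index n = 1.37
  throughout. Everything is overridable through a validated YAML schema;
  `skin_2pct.yaml` / `skin_20pct.yaml` ship as packaged fixtures.
* **Transport kernel** — weighted photon packets, exponential free paths,
  per-interaction weight deposit μa/(μa+μs), Henyey–Greenstein scattering,
  unpolarised Fresnel boundaries with total internal reflection, Russian
  roulette, annular-ring detection with per-layer pathlength accounting, and
  an exact energy-conservation ledger. The per-photon loop is numba-compiled
  (~10⁶–10⁷ photons/min/wavelength on one core, wavelength-dependent).
* **Two estimator protocols** — `standard` (μt step sampling,
  absorption-weighted mean paths: the unbiased physical estimator) and
  `scatterpath` (μs-only sampling, unweighted mean of registered paths: the
  scattering-process pathlength convention under which published skin DPF
  tables with very large short-wavelength values are defined; see
  `docs/methods.md`).
* **Analysis** — replicated DPF grids with both replicate SD and
  detection-statistics SE, per-layer pathlength tables, spatial sensitivity
  maps, CSV/JSON writers with full provenance manifests.
* **Independent oracles** (test-only) — a pure-Python scalar random walker,
  the semi-infinite diffusion-theory DPF closed form, and quadrature of the
  Henyey–Greenstein density.

## Worked example

```python
from skindpf import RunConfig, build_default_model, replicate_sweep

model = build_default_model(melanin_fraction=0.02)   # light skin
grid = replicate_sweep(
    model,
    wavelengths=[650.0, 850.0, 1050.0],
    sds=[1.0, 2.0, 4.0],                 # mm
    n_photons=200_000,
    n_replicates=3,
    base_seed=7,
    config_template=RunConfig(step_sampling_mode="scattering",
                              roulette_threshold=0.0),
    weighted=False,                      # scatter-path protocol
)
for i, wl in enumerate(grid.wavelengths):
    for j, d in enumerate(grid.sds):
        print(f"{wl:6.0f} nm  {d:3.1f} mm  DPF = {grid.dpf_mean[i,j]:6.3f}"
              f" ± {grid.dpf_sd[i,j]:5.3f}")
```

prints

```
   650 nm  1.0 mm  DPF =  5.215 ± 0.013
   650 nm  2.0 mm  DPF =  4.972 ± 0.012
   650 nm  4.0 mm  DPF =  4.891 ± 0.033
   850 nm  1.0 mm  DPF =  4.691 ± 0.010
   850 nm  2.0 mm  DPF =  3.964 ± 0.010
   850 nm  4.0 mm  DPF =  3.564 ± 0.031   # falls with d at long wavelengths
  1050 nm  1.0 mm  DPF =  4.418 ± 0.039
  1050 nm  2.0 mm  DPF =  3.386 ± 0.007
  1050 nm  4.0 mm  DPF =  2.763 ± 0.021
```

Each DPF is the mean detected pathlength in a 0.5 mm-wide annulus centred on
*d*, divided by *d*; the ± figure is the standard deviation across the three
independently seeded replicates. Detected 850 nm light at 2 mm spacing thus
travels ≈ 7.9 mm through the skin, with
`grid.mean_path_by_layer` splitting that path over the seven layers (at
1050 nm / 4 mm, 1.77 mm of it lies in the deep blood net dermis — the layer
glucose sensing cares about).

The same sweep from the shell, plus a sensitivity map:

```bash
skindpf dpf-table --wavelengths 650,850,1050 --sds 1,2,4 \
    --photons 200000 --replicates 3 --seed 7 --protocol scatterpath --out out/
skindpf sensitivity-map --wavelength 1050 --sds-at 6 --photons 200000 --out out/
```

The `full` preset (`--preset full`) runs the production protocol
(10⁸ photons × 20 replicates per wavelength); `desk` (default) is a
laptop-scale version of the same sweep.

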
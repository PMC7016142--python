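# condensate-metrics

Quantitative analysis of biomolecular condensates formed by liquid–liquid
phase separation (LLPS), built around the tripartite protein/vesicle
droplet system (an adaptor protein such as SLP65, its multivalent SH3
partner CIN85, and small unilamellar vesicles).  It is aimed at wet-lab
groups who image condensates by confocal microscopy, segment vesicles in
cryo-electron tomograms, or probe droplet interiors by solution NMR, and
who need the downstream numbers — enrichment, phase boundaries, packing
distances, binding signatures — computed reproducibly from those data.

The pipeline covers four analyses plus fully seeded synthetic generators
with known ground truth:

* **Droplet imaging** — intermeans ("default" isodata) thresholding,
  8-connected particle analysis with area and circularity (4πA/P²)
  filters, and the two headline statistics per image: the index of
  dispersion IoD = s²/x̄ of pixel intensities over square ROIs, and the
  partition coefficient P = ⟨I_in⟩/⟨I_out⟩ of the droplet mask.
* **Phase mapping** — dispersed vs phase-separated calls from median ROI
  IoD against a no-droplet reference control, and the transition
  threshold as the monotone frontier along a concentration axis.
* **Vesicle statistics** — surface-to-surface gaps
  g(i,j) = ‖c_i−c_j‖ − r_i − r_j of segmented sphere clouds
  (nearest-neighbour or all-pairs-within-cutoff), radius distributions
  with SEM, and radial density profiles toward the condensate border.
* **NMR** — per-residue peak intensity ratios with SNR-propagated
  uncertainty σ = R·√((σ_n/I_n)² + (σ_d/I_d)²) and
  "broadened-beyond-detection" flagging, single-exponential relaxation
  fits I(t) = A·e^(−Rt), TRACT η_xy = (R_anti − R_trosy)/2, and two-point
  PRE rates Γ₂ = ln(I_dia/I_para)/Δt.

## Worked example

Quantify a synthetic droplet image with a known 10-fold enrichment:

```bash
condensate-metrics simulate image --out img.tif --n-droplets 3 --seed 4
condensate-metrics quantify --image img.tif --roi-side-um 30.816
```

```json
{
  "threshold": 260.4076484425847,
  "n_droplets": 3,
  "median_iod": 0.9997867804537683,
  "partition": 9.293057742631119,
  "inside_mean": 470.2326848249027,
  "outside_mean": 50.600426452506575
}
```

The threshold sits between the ~50-count background and the ~500-count
droplet interiors; the recovered partition coefficient 9.29 is the true
10-fold enrichment attenuated a few percent by PSF blur at the droplet
rims; the median ROI IoD ≈ 1.0 reflects tiles without droplets (Poisson
noise gives IoD ≈ 1; droplet-containing tiles run into the hundreds).

The same works for vesicle clouds — from a CSV of segmented sphere centres
and radii (`x_nm, y_nm, z_nm, radius_nm`):

```bash
condensate-metrics simulate vesicles --out ves.csv --n 500 --seed 2
condensate-metrics vesicle-stats --coords ves.csv --mode nn
```

```json
{
  "gap_mean_nm": 7.261656574832554,
  "gap_sem_nm": 0.19295506742357021,
  "gap_n": 500,
  "n_overlapping": 0,
  "radius_mean_nm": 9.001147182763,
  "radius_sem_nm": 0.045831392548901825,
  "radius_n": 500,
  "innermost_density_per_nm3": 0.0,
  "outermost_density_per_nm3": 2.5097502500415725e-05
}
```

i.e. a mean nearest-neighbour surface gap of 7.26 ± 0.19 nm (mean ± SEM,
n = 500) and a mean radius of 9.00 ± 0.05 nm for this packing (the
innermost shell of the density profile is tiny and happens to hold no
vesicle centre here).  Python
API, multi-stage YAML pipelines (`condensate-metrics run --config
run.yaml`), and the NMR subcommands (`nmr ratio`, `nmr tract`, `nmr pre`)
are documented in the module docstrings; the scientific background and all
defaults are in `docs/methods.md`.

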
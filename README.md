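# filotrack

Single-molecule TIRF analysis of how myosin 10 (M10) reaches filopodial
tips, rebuilt as a tested, reusable pipeline with a synthetic ground-truth
simulator.

Myosin 10 accumulates in a punctum at the tip of filopodia. Live-cell TIRF
imaging of eGFP-tagged molecules shows three movement regimes: fast 3D
diffusion in the cytosol (D_cyto ≈ 5 µm²·s⁻¹), slower 2D diffusion on the
plasma membrane (D_mem ≈ 0.2 µm²·s⁻¹, intermittent binding with rates *f*
and *g*), and directed 1D runs along the filopodial actin bundle
(≈ 1.4 µm·s⁻¹). The raw videos behind those measurements are not public, so
this package pairs every analysis stage with a simulator that generates TIRF
movies with known ground truth — evanescent-field excitation, single-eGFP
photon budgets, EMCCD noise, single-step photobleaching — and demonstrates
that each pipeline stage recovers the values it was pointed at. It is aimed
at people doing single-particle tracking and image-correlation analysis of
live-cell TIRF data, and at anyone who wants a transparent benchmark for
such pipelines.

## What is implemented

| Stage | Module | Core quantity |
| --- | --- | --- |
| Ground-truth simulation | `filotrack.simulate`, `filotrack.render` | 3D/2D/1D kinetic state machine; pixel-integrated Gaussian PSF; `offset + gain·Poisson + read noise` camera |
| Sub-pixel tracking | `filotrack.tracking` | matched-filter detection, 2D Gaussian fits (~30 nm precision), mutual nearest-neighbour linking |
| MSD mobility | `filotrack.msd` | time-averaged MSD; D_lat = ¼ × initial gradient; shape class via MSD = 4D·dtᵅ; stationary cut at 0.02 µm²·s⁻¹ |
| Autocorrelation maps | `filotrack.acf` | per-pixel temporal ACF, τ = 1/e crossing, 8×8 local averaging, empirical τ→D calibration, 2 µm²·s⁻¹ cap |
| Filopodial kinetics | `filotrack.kinetics` | spline straightening (5-px stripe), kymographs, streak velocimetry, 500-ms window velocities, two-Gaussian mixture fit, reduced-n one-tailed Welch test |
| Super-resolution | `filotrack.superres` | 16× localization canvas (6.25 nm pitch, "~6.3 nm"), intensity-scaled kernels (amplitude ∝ I, σ ∝ 1/√I), transverse FWHM profiles |
| Search model | `filotrack.targeting` | f = c·k_on; dwells 1/g and 1/f; explored area D_mem/g; excursion √(D_cyto/f); exponential run survival; Monte-Carlo cross-check |

The reduced-dimensionality targeting model, in the field's notation: a
molecule alternates between membrane-bound 2D episodes (mean dwell
t_mem = 1/g) and cytosolic 3D episodes (mean dwell t_cyto = 1/f, with
f = c·k_on). Each membrane visit explores an area ~ D_mem/g and each
cytosolic hop covers ~ √(D_cyto/f), so rebinding lands on fresh membrane;
the search is fastest when t_cyto/t_mem = D_mem/D_cyto, which the measured
parameter set satisfies exactly (0.04 = 0.04).

## Worked example

```python
>>> from filotrack import model_summary, benchmarks
>>> model_summary()
{'f_per_s': 2.5, 'g_per_s': 0.1, 't_mem_s': 10.0, 't_cyto_s': 0.4,
 'exploration_area_um2': 2.0, 'excursion_length_um': 1.4142135623730951,
 'time_ratio': 0.04, 'D_ratio': 0.04, 'optimality_mismatch': 0.0,
 'run_survival_pct': 0.6737946999085467}
>>> benchmarks.kymograph_velocity_recovery(seed=1)   # truth: 1.4 um/s
1.4006893772783977
>>> benchmarks.dlat_recovery(seed=1)                 # truth: 0.2 um^2/s
0.20741233222843403
```

The first call evaluates the search model at the measured parameters: a
25 nM cytosolic pool rebinding at the diffusion limit gives f = 2.5 s⁻¹,
hence 0.4 s in the cytosol per 10 s on the membrane, ~2 µm² of membrane
explored per visit, and a 0.67 % chance that an exponential 1-µm-mean run
exceeds 5 µm. The other two calls simulate movies/tracks at the reported
mobility values and recover them through the full analysis chain.

The numbered scripts under `analysis/` run the same stages as a narrative
(simulate → track/MSD → mobility map → filopodial kinetics →
super-resolution → search model) and write their tables under `results/`.
`filotrack --help` lists the equivalent shell commands.

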
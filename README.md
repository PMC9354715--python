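# pumpprobe

Analysis pipeline for label-free discrimination of melanin species in uveal
melanoma by femtosecond pump-probe (transient-absorption) microscopy, built
and validated on synthetic tissue phantoms.

Uveal melanoma tissue is dominated by **eumelanin**, while the surrounding
paracancerous choroid predominantly contains **pheomelanin**.  The two
pigments cannot be told apart by conventional histology, but their
picosecond transient-absorption dynamics differ sharply: both show positive
excited-state absorption (ESA) at pump-probe delay τ = 0, but eumelanin
additionally shows a long-lived *negative* ground-state-bleaching (GSB)
component (lifetime ≈ 9.4 ps), whereas the pheomelanin transient (lifetime
< 200 fs) has vanished by τ = 500 fs.  Two delay frames therefore separate
the pigments pixel-by-pixel:

    S_eu = max(−S(500 fs), 0)        S_ph = max(S(0) + S(500 fs), 0)

and the eumelanin/pheomelanin dominance contrast delineates the tumor
margin.  The package implements the full computational chain:

- `pumpprobe.ta_model` — signed multiexponential transient models and their
  analytic convolution with a Gaussian instrument response (EMG/erfc form);
- `pumpprobe.synthetic` — ground-truthed tissue phantoms (tumor/paracancer
  interface, choroid belts, scattered single cells) rendered into noisy
  delay stacks S(x, y, τ) with Beer-Lambert DC transmission;
- `pumpprobe.fitting` — multistart bounded least-squares decay fitting and
  per-pixel pigment classification;
- `pumpprobe.unmixing` — DC normalization and the two-delay separation;
- `pumpprobe.delineation` — margin segmentation and Dice / boundary-distance
  scoring against ground truth;
- `pumpprobe.io`, `pumpprobe.config`, `pumpprobe.cli` — TIFF + JSON-sidecar
  formats, YAML configs, and a `pumpprobe` command with `simulate`,
  `unmix`, `fit`, `delineate` and `run-all` subcommands.

See `docs/methods.md` for the model, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the study end to end
(`python analysis/01_simulate_phantoms.py`, then 02-04).  Characterizing
the two pigment transients (script 02) prints:

```
    pigment  noise_sigma  n_components  tau_fast_ps   A_fast  tau_slow_ps    A_slow
pheomelanin         0.00             1     0.150000 1.000000          NaN       NaN
pheomelanin         0.02             1     0.151082 0.999488          NaN       NaN
  eumelanin         0.00             2     0.150000 1.000000     9.400000 -0.350000
  eumelanin         0.02             2     0.147142 1.001120    10.116023 -0.343147

pheomelanin ESA lifetime 150 fs (< 200 fs); eumelanin GSB lifetime 9.40 ps (~9.4 ps)
```

i.e. the fitter recovers the fast positive ESA lifetime and the slow
negative GSB lifetime exactly on noiseless traces and within a few percent
at 2% noise.  Delineating margins on the noisy 256² phantoms (script 04)
prints:

```
              layout     dice  mean_boundary_distance_um  hausdorff_distance_um
        choroid_belt 0.000000                        inf                    inf
     scattered_cells 0.873529                   0.456285               1.171146
two_region_interface 0.999435                   0.034883               0.828125
```

The tumor/paracancer interface is recovered almost perfectly (Dice 0.999,
mean boundary error well below a pixel); scattered single cells are all
detected with sub-micron boundary accuracy; the choroid-belt phantom
contains no tumor, and its nonzero segmented area (0.4% of pixels, hence
Dice 0 against an empty truth mask) is noise speckle in melanin-free cores
where the dominance fraction is undefined — see the limitations section of
the methods note.

The same chain is available from the shell:

```sh
pumpprobe run-all --seed 0 --out-dir results/run0
```

which writes the stack, pigment maps, red/cyan composite, tumor mask and a
`metrics.json` with the Dice score.

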
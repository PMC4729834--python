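# cytocycle

Label-free cell-cycle analysis for imaging flow cytometry.

Imaging flow cytometers photograph every cell in flow, producing a
brightfield (transmitted light) and a darkfield (90° side scatter) image
per cell alongside any fluorescence channels. `cytocycle` turns those two
label-free channels into cell-cycle readouts, so DNA stains — which cost
fluorescence channels and can perturb live cells — are only needed once,
to annotate a training subset:

* a fixed, versioned **213-feature morphological profile** per cell
  (size/shape + Zernike moments, intensity, radial distribution, Haralick
  texture and granularity; 130 features from the segmented brightfield
  object, 83 from the full darkfield frame);
* **least-squares boosted regression** of DNA content (integrated nuclear
  stain intensity) from the profile, evaluated by stratified 10-fold
  cross-validation (Pearson r between predicted and true intensity);
* **random-undersampling boosted classification** (RUSBoost, a SAMME
  AdaBoost whose stages train on per-stage class-balanced subsamples) of
  the rare mitotic phases — prophase, metaphase, anaphase, telophase —
  against interphase;
* the **Watson pragmatic curve fit**, which deconvolves a DNA-content
  histogram into G1/S/G2M fractions by fitting Gaussians to the outer
  halves of the 2N and 4N peaks and assigning the unexplained counts
  between them to S phase;
* a seeded **synthetic population generator** that emulates the couplings
  the workflow relies on (cell size and darkfield intensity grow with DNA
  content; mitotic morphologies are rare and distinctive; the stain
  channel is stoichiometric), so the entire chain is testable end to end
  without instrument data.

The intended user is a cytometry or image-analysis scientist who wants a
scriptable, fully reproducible implementation of this workflow — either
to run on exported per-cell TIFFs or to study the method itself on
synthetic ground truth.

## Worked example

Train the DNA regressor on a stained synthetic population, apply it to an
*unstained* population treated with a simulated mitotic blocking agent,
and read the G2/M shift off the two predicted DNA distributions:

```python
from cytocycle import demo_block_experiment

res = demo_block_experiment(seed=5, n_cells=800, block_shift=0.15,
                            with_classifier=False)
print({k: round(v, 3) for k, v in res["control_fractions"].items()})
print({k: round(v, 3) for k, v in res["blocked_fractions"].items()})
print(f"delta G2M = {res['delta_g2m']:+.3f}")
```

```
{'G1': 0.524, 'S': 0.241, 'G2M': 0.235}
{'G1': 0.421, 'S': 0.233, 'G2M': 0.346}
delta G2M = +0.111
```

The blocking agent moved 15% of the simulated population into the
G2+mitotic pool; the label-free readout — trained only on the untreated,
stained cells and applied to unstained treated cells — recovers a G2/M
increase of about ten percentage points. The remaining gap is the
regression's shrinkage of extreme DNA values, which compresses distances
between the histogram peaks before the Watson fit.

The `examples/` directory holds one short script per capability
(simulation, profiling, regression, classification, Watson fitting, the
block experiment); each prints the numbers it computes and a line on what
they mean. A thin command line mirrors the library
(`cytocycle simulate|montage|segment|features|train|predict|evaluate|`
`importance|cellcycle|demo-block|run`).

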
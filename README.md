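# chemoscope

Quantitative readouts of chemotactically active *Escherichia coli* from
fluorescence microscopy. The package implements three analysis pipelines and
a synthetic-scene generator that produces every input with ground truth
attached:

1. **Foci kinetics** (`chemoscope.focikinetics`) — CheY~P–CheZ interactions
   visualized by split-eGFP (bimolecular fluorescence complementation) form
   fluorescent foci whose intensity decays under continuous imaging, mostly
   by photobleaching. Per-focus traces are fitted with the second-order decay
   law

   *f*(*t*) = 1 / (*k·t* + 1/*A*₀)

   with rate constant *k* (min⁻¹) and initial fluorescence *A*₀. Traces from
   cells in plain motility buffer define the bleaching baseline
   (AVE_k ± SD_k); a ligand-exposed focus is classified *slower* when
   *k* + SD_k(focus) < AVE_k − SD_k(baseline) — the signature of renewed
   reporter formation in repellent-exposed cells — and *faster* in the mirror
   case. Per-series deviant proportions are compared across conditions with
   a Kruskal–Wallis rank test.

2. **Foci mapping** (`chemoscope.focimap`) — spot detection against each
   cell's local background (score = background-subtracted peak amplitude /
   robust cell-noise SD, retained at score ≥ 10), localization on a
   normalized cell axis (−1/+1 = poles), polar/mid-cell partitioning,
   two-channel (eGFP / FliM-mCherry) colocalization by optimal one-to-one
   matching under a 2-px (120 nm) cutoff, intensity histograms and
   distance-trend slope tests.

3. **pH profiling** (`chemoscope.phratio`) — the pH-sensitive fluorophore
   pHluorin is excited at 386 and 470 nm; its 525-nm emission ratio
   R = I₃₈₆/I₄₇₀ increases linearly with pH between 6 and 8. A linear
   calibration R = a·pH + b fitted on cells at known pH inverts ratio images
   to pH maps. Around a circular attractant source, cell abundance (Sobel
   edge signal) and emission ratio are averaged over successive 25-px (2 µm)
   distance zones parallel to the source border (3 inside + 57 outside by
   default) and aggregated over sides × replicates with a 95% *t*-confidence
   band.

The generators in `chemoscope.synthio` emulate the three experimental
configurations (decay traces with optional renewal, dual-excitation source
scenes with a planted pH field and cell-density profile, and one- or
two-channel foci scenes with planted counts, positions and overlap), all
seeded and bit-reproducible.

## Worked example

```python
import numpy as np
import chemoscope as cs

# simulate buffer and repellent-exposed (renewal) trace populations
buffer_traces, _ = cs.gen_foci_traces(cs.TraceSimSpec(n_traces=60, seed=1))
nickel_traces, _ = cs.gen_foci_traces(
    cs.TraceSimSpec(n_traces=60, condition="nickel", renewal_rate=0.03, seed=2)
)

fits_buf = cs.fit_traces(buffer_traces)
fits_ni = cs.fit_traces(nickel_traces)
baseline = cs.compute_baseline(fits_buf)
print(f"baseline: ave_k={baseline.ave_k:.4f} /min, sd_k={baseline.sd_k:.4f}")

results = [cs.classify_deviance(f, baseline) for f in fits_buf + fits_ni]
props = cs.deviant_proportions(results)
print(props[["prop_slower", "prop_faster"]])
```

prints

```
baseline: ave_k=0.0498 /min, sd_k=0.0088
                  prop_slower  prop_faster
condition series
buffer    0          0.116667         0.05
nickel    0          0.900000         0.00
```

The buffer population sits near its own baseline band (≈10–15% nominally
deviant on either side, as expected from the ±1 SD rule), while renewal at
0.03 AU/min — an effect two buffer SDs strong — pushes 90% of the
repellent-like traces below the band.

The same end-to-end flow is scriptable from the shell:

```bash
chemoscope run --seed 5 --outdir out/        # simulate + analyze + report.json
chemoscope simulate ratio --seed 3 --outdir out/
chemoscope phmap --scene out/ratio --calibration out/ratio/calibration.csv
```

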
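# cardioquant

Quantification pipelines for cardiac cell and embryo imaging, built for
studies of sarco-endoplasmic reticulum (SR/ER) disruption in heart muscle —
e.g. knockdown of an SR-shaping membrane protein that leaves myocytes unable
to contract and embryonic hearts beating out of sync. It packages four
measurements that such a study needs, each testable end-to-end on synthetic
data with closed-form ground truth:

1. **Single-myocyte contractility** from 16-bit time-lapse movies (one frame
   per 40 ms): mean-threshold binarization, Savitzky–Golay outline smoothing
   (order 2, window 75), cell length under the longest-axis line,
   rest-normalization, sixth-order polynomial detrending, and contraction
   events called at fractional shortening FS = (L_rest − L_peak)/L_rest ≥ 5%,
   with frequency f = 1 / mean inter-event period.
2. **Zebrafish chamber rhythm** from atrial/ventricular area-vs-time
   profiles: Gaussian smoothing (σ = 0.2 s), mean normalization, beats
   counted as prominent area maxima over a 15-s window (bpm = count × 4),
   atrioventricular ratio and dyssynchrony (healthy 1:1 vs e.g. 3:1 block),
   and phenotypic penetrance.
3. **Colocalization** of two immunofluorescence channels: Pearson r over a
   cell mask and percent overlap above per-channel Otsu thresholds.
4. **Interactor enrichment** from label-free iBAQ tables: exclude proteins
   detected in ≤ 2 of 8 MS runs, average per condition over detected runs,
   impute 10 for fully undetected condition averages, rank by
   fold change = mean(transfected)/mean(control).

See `docs/methods.md` for the models, parameter rationale, and limitations.

## Worked example

Simulate the contractility study conditions — a 512×512, 20-s movie at 25
frames/s of a 200 × 80 px cell whose long axis shortens by ratio 0.876
(true FS 12.4%) in five pulses ~3.7 s apart, with intensity noise at 2% of
the foreground level — and run the full image pipeline:

```python
from cardioquant import CellMovieSpec, make_cell_movie
from cardioquant.contractility import analyze_stack

spec = CellMovieSpec(seed=7, noise_sd=600.0)
stack, truth = make_cell_movie(spec)
result, trace = analyze_stack(stack)
print(f"events: {result.n_events}")
print(f"mean fractional shortening: {result.mean_amplitude:.2f} %")
print(f"frequency: {result.frequency:.3f} Hz")
```

prints

```
events: 5
mean fractional shortening: 12.14 %
frequency: 0.270 Hz
```

i.e. all five contractions are found, the mean FS per event recovers the
simulated 12.4% within the sub-pixel measurement error of the chord readout,
and the beat frequency matches the simulated 0.27 Hz.

The same works from the shell. An AV-block phenotype (atrium beating every
0.5 s, ventricle every 1.5 s):

```sh
cardioquant simulate-heart --out-dir sim --atrial-period-s 0.5 --ventricular-period-s 1.5
cardioquant analyze-heart --atrium sim/atrium.csv --ventricle sim/ventricle.csv --out-dir rhythm
```

`rhythm/rhythm.json` then reports 30 atrial and 10 ventricular beats in the
15-s window (120 and 40 bpm) and

```json
"av": {"av_ratio": 3.0, "dyssynchronous": true, "label": "3:1"}
```

— a 3:1 atrioventricular block. `cardioquant penetrance --affected 164
--total 410` prints `40.0` (percent of scored embryos showing the
phenotype). Other subcommands: `simulate-cell`, `analyze-cell`, `coloc`,
`enrich`; every run writes JSON/CSV results plus a `manifest.json` with the
parameters and seed, and reruns with the same seed are byte-identical.

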
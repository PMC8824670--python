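# serrsmap

Analysis of hyperspectral Raman maps acquired with surface-enhanced resonance
Raman scattering (SERRS) nanoparticle probes — the kind of data produced when
antibody-functionalized nanoparticles (e.g. targeting EGFR or HER2) are used
to read out tumor surface-marker expression with a mapping Raman microscope.

Each map point is a Raman spectrum (counts/s vs. Raman shift in cm⁻¹) sitting
on a large, smooth fluorescence background. The nanoparticle reporter has a
sharp multi-peak fingerprint whose dominant line is at 950 cm⁻¹; plastic
substrates contribute their own weak lines (main peak at 1020 cm⁻¹). The
package turns such maps into quantitative expression read-outs:

* **Baseline removal** — Whittaker penalized least squares with asymmetric
  reweighting (AsLS): find `z` minimizing `Σᵢ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)²` with
  weights `p` above / `1−p` below the current baseline (defaults λ = 200,
  d = 2, p = 0.001), solved with a banded Cholesky factorization. Negative
  channels after subtraction are rectified to zero by default.
* **Band quantification** — the indicative intensity of a spectrum is the
  mean counts/s over the 950–960 cm⁻¹ band (inclusive edges, channel-centre
  membership); per-point values form an intensity map.
* **ROI statistics** — channel-wise mean spectra over rectangular regions of
  interest, expression classes (`high` > 200 cts/s, `negative` ≤ 75 cts/s,
  `low` in between) and two-sample Student t-tests (pooled variance by
  default, Welch optional) between region point intensities.
* **Calibration / limit of detection** — a Langmuir-type saturating response
  `I(C) = floor + I_max·C/(C + K½)` fitted to a dilution series; the LOD is
  the concentration at which the fitted curve crosses
  `mean_blank + k·sd_blank` (k = 3 by default), by algebraic inversion.
* **Signature matching** — cosine similarity between a (baseline-corrected)
  spectrum and a unit-norm reference fingerprint.
* **Synthetic generator** — seeded, fully deterministic spectra, dilution
  series, and tumor phantoms with aligned ground truth, so the whole pipeline
  can be exercised and validated without instrument data.

## Worked example

Simulate the default three-region tumor phantom (1500 × 900 µm² regions of
high / low / no marker expression, 70 map points each at 150 × 130 µm pitch),
baseline-correct it, and report the ROI statistics:

```sh
serrsmap run --seed 7 --out demo
```

```
ROI report — band 950-960 cm^-1, thresholds high>200 / neg<=75 cts/s

          high: n=  70  indicative=  250.77 cts/s  class=high
           low: n=  70  indicative=   93.92 cts/s  class=low
      negative: n=  70  indicative=   46.97 cts/s  class=negative

  high vs low: t=105.950, df=138, p=4.52e-134 (pooled)
  high vs negative: t=148.650, df=138, p=3.46e-154 (pooled)
  low vs negative: t=72.474, df=138, p=1.01e-111 (pooled)
```

The three indicative intensities land in the three expression regimes
(> 200 cts/s, ~100 cts/s, ~50 cts/s). The ~47 cts/s "negative" value is not
nanoparticle signal: it is the substrate contribution inside the band plus
the positive bias left by rectifying noise after baseline subtraction, which
is why a `t_neg` threshold above that floor is needed. The t-tests compare
the 70 per-point band intensities of one region against another; the tiny
p-values reflect the phantom's well-separated planted levels.

The same steps are available individually (`simulate`, `baseline`, `map`,
`roi`, `classify`, `lod`) and as library functions:

```python
from serrsmap import (GeneratorConfig, simulate_phantom, default_phantom_layout,
                      correct_map, heterogeneity_report)

cfg = GeneratorConfig(seed=7)
regions, rois, extent = default_phantom_layout(cfg)
raw, truth = simulate_phantom(regions, cfg, extent)
report = heterogeneity_report(correct_map(raw), rois)
print(report.to_text())
```

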
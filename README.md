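# arthromri

Evaluation tooling for MRI-based assessment of radiation synovectomy in
hemophilic arthropathy (HA). Recurrent intra-articular bleeding in
hemophilia drives synovial hyperplasia, hemosiderin deposition and
progressive osteochondral damage; radiation synovectomy (intra-articular
β-emitter injection) ablates the hypertrophied synovium, and MRI with the
IPSG (International Prophylaxis Study Group) additive score is the standard
way to quantify the joint's state before and after treatment.

`arthromri` implements, as a tested and fully synthetic-data-driven
pipeline, the comparison of a *Canny-algorithm-based* MRI reading arm
against a conventional reading arm and a pathology reference:

* **Canny edge-detection chain** (`arthromri.edges`): Gaussian smoothing
  `I' = I * G`, Sobel gradients `g = (f'x, f'y)` with magnitude
  `ϑ = sqrt(f'x² + f'y²)`, non-maximum suppression along the 45°-quantised
  gradient direction, and double-threshold hysteresis linking — plus the L2
  approximation degree `‖f − g‖₂` and synovial-contour extraction.
* **Image-quality metrics** (`arthromri.metrics`):
  `MSE = Σ(I−J)²/(mn)`, `PSNR = 10·log10((2^B−1)²/MSE)` in dB, and
  sliding-window SSIM `l·c·s` with uniform H×H windows, sample-(n−1)
  statistics, `C1=(0.01L)²`, `C2=(0.03L)²`, `C3=C2/2`, `L=255`.
* **IPSG scoring** (`arthromri.ipsg`): the 17-point card — effusion,
  synovial hyperplasia and hemosiderin each graded 0–3 (soft-tissue
  subtotal ≤ 9) plus eight binary erosion/cyst/cartilage items
  (osteochondral subtotal ≤ 8) — with area-fraction grade mapping and
  mask-overlap rules.
* **Synthetic data** (`arthromri.phantom`, `arthromri.cohort`): joint
  phantoms with analytically known lesion masks and Rician noise, and a
  146-joint / 60-patient cohort (84 knee, 38 ankle, 10 elbow, 14 hip)
  whose per-lesion grade tables, pre/post synovial volumes and bleed
  counts have known ground truth.
* **Statistics** (`arthromri.stats`): paired t-test, one-way ANOVA and the
  per-score-level detection-rate chi-square, with t/F tail probabilities
  computed by the package's own continued-fraction regularized incomplete
  beta function.
* **Orchestration** (`arthromri.study`, CLI `ha-study`): one seeded config
  runs cohort generation, both processing arms, metrics, scoring and all
  tests, and writes a machine-readable report.

## Worked example

```python
import numpy as np
from arthromri import (CannyParams, canny, default_phantom_spec,
                       extract_synovial_contour, make_phantom, psnr, ssim,
                       total_score)
from arthromri.edges import smooth

ph = make_phantom(default_phantom_spec(seed=42))
print({k: v for k, v in ph.true_grades.as_dict().items() if v})
# {'effusion': 2, 'synovial_hyperplasia': 3, 'hemosiderin': 1}
print(total_score(ph.true_grades))
# (6, 6, 0)            -> total 6 = soft-tissue 6 + osteochondral 0

edge_map = canny(ph.noisy.pixels, CannyParams(delta=1.4))
contour, closed = extract_synovial_contour(edge_map)
print(int(contour.sum()), closed)
# 128 True             -> a closed synovial contour despite the noise

recon = smooth(ph.noisy.pixels, 0.5)  # the Canny-arm reconstruction
print(f"{psnr(ph.clean, ph.noisy):.2f}", f"{ssim(ph.clean, ph.noisy).value:.4f}")
# 26.60 0.6859         -> raw noisy raster vs clean reference
print(f"{psnr(ph.clean, recon):.2f}", f"{ssim(ph.clean, recon).value:.4f}")
# 28.36 0.7769         -> reconstruction: higher PSNR (dB) and SSIM
```

The full study (`run_study(StudyConfig(seed=0))`) reports, among other
things, mean PSNR 26.57 dB / SSIM 0.6871 for the raw arm versus
28.45 dB / 0.7813 for the Canny arm over 20 phantoms, a paired-t of 11.37
(p ≈ 3e-14, n = 42) for the post-surgery synovial-volume reduction
(46 049 → 32 530 mm³), and F = 95.5 (p ≈ 1e-19) for the drop in six-month
bleed counts (4.23 → 1.67).

Command-line equivalents:

```sh
ha-study run --out results/          # whole study, default config
ha-study phantom make --seed 42 --out phantom/
ha-study edges run --in phantom/noisy.png --delta 1.4 --out edges.png
ha-study metrics compare --ref phantom/clean.png --test recon.png
ha-study cohort make --default --out cohort.tsv
ha-study stats run --cohort cohort.tsv --out stats.json
```

## Layout

```
src/arthromri/    raster, phantom, cohort, edges, metrics, ipsg, stats,
                  study, cli
tests/            unit, property and acceptance tests (+ _naive.py oracles)
docs/methods.md   models, parameters, numerical choices, limitations
scripts/          acceptance.py
```
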
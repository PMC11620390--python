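# tilagree

Interpretable inter-observer agreement measures for tumor-infiltrating
lymphocyte (TILs) scoring on histopathological images.

TILs density in tumor stroma is a prognostic biomarker in breast cancer, but
scoring it requires two subjective annotation steps — outlining the stromal
regions and marking individual lymphocytes — and pathologists disagree at
both. `tilagree` quantifies that disagreement at three levels:

* **Stromal segmentation (M_S)** — pixel-wise Fleiss' kappa over N binary
  masks, and **Boundary-Weighted Fleiss' Kappa (BWFK)**, which down-weights
  pixels near annotation boundaries (where honest delineation ambiguity
  lives) via a flattened mean distance transform of the observers' stroma
  boundaries.
* **Lymphocyte detection (M_L)** — the **Distance-Based Cell Agreement
  Algorithm (DBCAA)**: for each annotated center point, count the other
  observers with a point within the expected lymphocyte diameter D_L; no
  ground truth needed.
* **TILs score concordance (M_T)** — the TILs score
  T = (stromal lymphocyte count · 50.3 μm²) / stromal area per observer,
  compared across observers with ICC(2,1) and multi-observer Bland-Altman
  limits of agreement with the mean (LOAM).

The same machinery validates AI systems: a model's masks and points are
simply merged in as one more observer.

## The statistics

With pixels as subjects i = 1..M, categories j ∈ {non-stroma, stroma} and
n_ij observers voting pixel i into category j:

```
κ = (P̄ − P̄e) / (1 − P̄e)
P̄  = (Σi Σj n_ij² − MN) / (MN(N−1)),   P̄e = Σj p_j²,  p_j = Σi n_ij / (MN)
```

BWFK weights each pixel by w′_i = M·w_i / Σ w, where w_i is the mean
distance to the N observers' stroma boundaries, clipped (flattened) at
DT = 100 px, giving

```
P̄ʷ = (Σj Σi w′_i n_ij² − MN) / (MN(N−1)),   p_jʷ = Σi w′_i n_ij / (MN)
```

DBCAA counts, for the k-th point P of observer i,
a_k^i = #{ j ≠ i : min_p∈c_j ‖P − p‖ < D_L }, and scores
M_L = Σ a / ((N−1)·Σ m_i) (max-match normalization; perfect agreement = 1).

## Worked example

```python
from tilagree.synthetic_data import SynthConfig, generate_truth, generate_observers
from tilagree.model import SegmentationAgreement, CellDetectionAgreement

cfg = SynthConfig(height=256, width=256, pixel_size_um=1.0,
                  lymph_density_per_mm2=1500.0, length_scale=25.0,
                  boundary_amplitude_px=5.0, seed=7)
mask, pts = generate_truth(cfg)               # latent stroma + cells
stack, points = generate_observers(mask, pts, cfg)  # 4 noisy observers

print(SegmentationAgreement(stack, dt=100).fit().summary())
print(CellDetectionAgreement(points, pixel_size_um=cfg.pixel_size_um).fit().summary())
```

```
Segmentation agreement
============================================
Image                           synthetic
Observers (N)                   4
Pixels in universe (M)          65536
Fleiss' kappa (FK)              0.975002
  observed agreement Po         0.987607
  expected agreement Pe         0.504253
Boundary-weighted kappa (BWFK)  0.998835
  weighted Po                   0.999422
  weighted Pe                   0.503787
Flattening threshold DT (px)    100
BWFK gain (%)                   2.44439

Cell detection agreement
===================================
Image                  synthetic
Observers (N)          4
Total points (Σm)      411
Match radius D_L (px)  8
Normalization          max_match
Agreement total (ΣA)   1070
DBCAA score            0.867802
```

The four simulated observers disagree only within ±5 px of the true stromal
boundary, so plain kappa (0.975) is dragged down by delineation noise while
BWFK (0.999) recognises the annotations as essentially concordant — a 2.4%
gain. DBCAA reads 0.868: with a 10% miss rate, 5% false positives and 2 px
jitter, roughly 87% of the maximum possible cross-observer matches are
realised.

A command-line interface covers the same ground:

```bash
tilagree simulate --out ds/ --n-images 5 --seed 0
tilagree run-all --manifest ds/manifest.yaml --out report --seed 0
tilagree sensitivity --manifest ds/manifest.yaml --mode mask-shift --seed 0
```

## Acceptance script

`scripts/acceptance.py` regenerates a synthetic multi-observer dataset from
the given seed and runs the complete framework — per-image FK/BWFK/DBCAA,
per-observer TILs scores, ICC, LOAM, the subgroup correlation test and a
mask-shift sensitivity curve — logging the computed values to stderr and
writing the results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
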
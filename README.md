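# faupa

Detection of **functional areas of unitary pooled activity (FAUPAs)** in
BOLD fMRI: contiguous voxel sets whose signal time courses share, up to
amplitude and noise, a single temporal waveform. The package is for
neuroimaging researchers who want a task-free, threshold-free-of-GLM way
to parcel a 4D scan into small, internally coherent functional areas —
and for anyone who wants to study the algorithm's behaviour on synthetic
data with known ground truth.

## Model and algorithm

Inside such an area the voxel course follows

    S_i(t) = C_i · G(t) + δ_i(t)

with a common course G(t), per-voxel amplitude C_i and noise δ_i. The
member correlations R_i (each course against the area mean S̄(t)) have
mean μ and sd σ; without noise every R_i = 1. Detection is a seeded,
iterative correlation-threshold region growing:

* **seed** — a centre voxel with ≥ 4 of its 26 neighbours correlated
  above 0.9; the 4 best form the seed;
* **grow** — threshold an 11×11×11 box at the region's own
  TH1 = μ − 1.645σ against the region mean course, keep the largest
  26-connected cluster, iterate to a stable set (caps: 29 voxels, 20
  iterations);
* **accept** — with TH2 = μ − 2.327σ there is a ≈ 4% chance for a
  conforming voxel to land in (TH2, TH1); the region is accepted iff at
  most 4% of its one-voxel border layer does (L ≤ 0.04·K).

Accepted areas are disjoint, each with a full acceptance record
(R̄, μ, σ, TH1, TH2, K, L) that can be re-verified from its voxel set.
Supporting modules cover preprocessing (Gaussian smoothing by FWHM,
0.009–0.08 Hz zero-phase bandpass, percent signal change), a
border-layer separation t-test, task association via a double-gamma HRF
ideal response, and a synthetic 4D generator with planted clusters for
recovery experiments. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from faupa import (SyntheticSpec, simulate, detect_faupas,
                   separation_tests, recovery_metrics)

spec = SyntheticSpec(n_clusters=10, noise_sd=0.25, rng_seed=42)
volume, truth = simulate(spec)          # 32x32x16 grid, 288 TRs at 2.5 s
faupas, labelmap = detect_faupas(volume)
print(f"detected {len(faupas)} FAUPAs")
for f in faupas[:3]:
    print(f"  id {f.id}: {f.n_voxels} voxels, R_bar={f.r_bar:.4f}, "
          f"TH1={f.th1:.4f}, border L/K={f.border.l_count}/{f.border.k_total}")
rep = recovery_metrics(faupas, truth)
print(f"sensitivity {rep.sensitivity:.2f}, median Dice "
      f"{np.median(rep.dice_values):.2f}, false positives {rep.n_false_positives}")
res = separation_tests(faupas, volume)
print(f"separated: {sum(r.separated for r in res)}/{len(res)} at P<0.05")
```

Output:

```
detected 9 FAUPAs
  id 1: 4 voxels, R_bar=0.9771, TH1=0.9701, border L/K=0/60
  id 2: 9 voxels, R_bar=0.9726, TH1=0.9625, border L/K=0/97
  id 3: 6 voxels, R_bar=0.9778, TH1=0.9688, border L/K=1/42
sensitivity 0.90, median Dice 0.73, false positives 0
separated: 9/9 at P<0.05
```

Nine of the ten planted clusters are recovered (sensitivity 0.90), no
detection lands off the planted truth, every accepted area passes its
4% border criterion (L well under 0.04·K) and separates sharply from its
adjacent layer. The R̄ values near 0.97 show the near-unitary internal
correlation the model demands; the median Dice of 0.73 reflects that the
stable regions are high-correlation *cores* of the planted areas rather
than their full extent (see the operating-characteristics section of
`docs/methods.md`).

The same pipeline is scriptable from the shell:

```
faupa simulate --out run/sim --n-clusters 10 --noise-sd 0.25 --seed 42
faupa detect --in run/sim/bold_raw.nii.gz --mask run/sim/mask.nii.gz \
             --fwhm 0 --out run/detect
faupa separate --in run/sim/bold_pct.nii.gz \
               --labels run/detect/labels.nii.gz --out run/detect
faupa report --dir run/detect
```

Each stage writes a `manifest.json` (version, parameters, seeds, input
hashes); re-running a stage on the same inputs reproduces its tables
bit for bit.

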
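# heartsr

Single-volume super-resolution for 3D whole-heart bSSFP-like magnitude MR
volumes.

3D whole-heart balanced steady-state free precession (WH-bSSFP) imaging
delineates intra-cardiac and vascular anatomy, but acquiring it at high
resolution is slow.  Acquiring at low resolution and restoring the
high-resolution features as a post-processing step — single-volume
super-resolution — recovers most of the lost image quality at a fraction of
the scan time.  `heartsr` implements that framework end to end for
researchers working on MR reconstruction:

* **`heartsr.degrade`** — the synthetic low-resolution simulator: centred
  FFT, retention of the central `round(f·N)` phase/slice k-space lines,
  additional asymmetric partial-Fourier zeroing (retained count
  `round(pf·f·N)`, 6/8 by default), zero-filled inverse FFT, magnitude,
  optional in-plane crop, and min-max normalization to [0, 1].
* **`heartsr.phantom`** — seeded synthetic whole-heart phantoms (bright
  blood pool and vessels, intermediate myocardial shell, dark noisy lung)
  with partial-volume borders, ground-truth region masks and vessel probes,
  so the entire pipeline runs without clinical data.
* **`heartsr.model` / `heartsr.train`** — a 3D residual U-Net
  (3×3×3 convolutions, ReLU, skip connections; output
  `ReLU(input + residual)` ≥ 0) trained with the ℓ¹ loss and Adam
  (lr 10⁻³, batches of two whole volumes), implemented in pure NumPy with
  hand-written backpropagation.
* **`heartsr.metrics`** — SSIM (3D Gaussian window), MSE, the 60-ray vessel
  edge-sharpness metric (mm⁻¹), eSNR (blood/lung), eCNR (blood/myocardium),
  an FWHM vessel calliper and Bland-Altman agreement
  (bias ± 1.96 × SD limits).
* **`heartsr.harness`** — validation summaries, the resolution
  generalisability sweep, and a fully seeded `end_to_end` pipeline with a
  re-runnable manifest.

Volumes travel as NIfTI-1, datasets as HDF5 archives, configs as YAML, and a
`heartsr` CLI (`simulate`, `degrade`, `train`, `apply`, `evaluate`, `sweep`,
`run`) wraps the library.

## Worked example

A desk-scale version of the full study — simulate paired data, train, and
validate on held-out phantoms — runs in a few minutes on one CPU:

```python
import heartsr as h
from heartsr.harness import derive_seeds

seeds = derive_seeds(0)
template = h.default_phantom_spec()            # 48^3 voxels at 1.6 mm
degradation = h.DegradationSpec()              # 50% phase+slice, 6/8 partial Fourier

train_ds = h.make_dataset(template, 8, seeds["data"], degradation, role="train")
test_ds  = h.make_dataset(template, 4, seeds["test"], degradation, role="test")

net, report = h.fit(
    train_ds,
    h.NetworkConfig(levels=2, base_channels=8, seed=seeds["init"]),
    h.TrainConfig(epochs=30, seed=seeds["shuffle"]),
)
s = h.validate(net, test_ds)
print(f"SSIM {s['ssim_lr_mean']:.4f} -> {s['ssim_sr_mean']:.4f}")
print(f"MSE  {s['mse_lr_mean']:.2e} -> {s['mse_sr_mean']:.2e}")
```

Output from this exact run:

```
SSIM 0.7714 -> 0.8071
MSE  1.44e-03 -> 8.50e-04
```

Degrading the phantoms to 50% phase and slice resolution drops the
structural similarity to the ground truth to 0.771; after super-resolution
the held-out mean rises by +0.036 and the mean squared error falls by about
40% — the super-resolution network recovers a substantial part of what the
k-space truncation removed.  The same pipeline is available as
`heartsr run --out runs/demo --seed 0`, which also writes the resolution
sweep and a manifest sufficient to reproduce the run bit-identically.

## Documentation

The model, the simulator conventions, the metric definitions and the design
decisions (with their rationale and known limitations) are documented in
[`docs/methods.md`](docs/methods.md).
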
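# ddrecon — dual-domain accelerated-MRI reconstruction

`ddrecon` is a research toolkit for reconstructing undersampled multi-coil
MRI. Accelerated acquisitions skip phase-encoding (PE) lines of k-space;
the inverse FFT of the incomplete data is a *folded* image contaminated by
aliasing, and reconstruction must disentangle the overlap. The package
implements a hybrid model that works in both domains at once:

* a **Vision-Transformer autoencoder** processes the folded image
  `x ∈ R^{H×W×2C}` (real/imaginary channel pairs of the per-coil
  zero-filled images): patch tokens are encoded by pre-norm self-attention
  blocks (`z_enc = Φ_enc(x)`), decoded by a second transformer, and
  expanded by an upsampling tail into image features
  `I_ViT ∈ R^{H×W×C_ViT}`;
* a **bidirectional recurrent k-space transform** sweeps the W flattened
  k-space columns with two stacked bidirectional gated-recurrent layers
  (hidden width H·d per direction) and reshapes the result into image
  features `I_RNN ∈ R^{H×W×2d}` — a learned, parameter-efficient
  surrogate for the global frequency→image mapping;
* the reconstruction is `ŷ = Conv2D(Concat(I_ViT, I_RNN, x))`, compared
  against the root-sum-of-squares (RSS) reference with an L1 loss.

Three variants isolate the contributions (encoder-only with an MLP head;
encoder–decoder; the full dual-domain model) alongside an optional UNet
baseline. Everything runs on synthetic multi-coil phantom k-space, so no
external data are needed; a reader/writer for fastMRI-layout HDF5
containers is included. Intended users: researchers studying
reconstruction architectures and students who want a transparent,
dependency-light reference implementation (the networks run on a built-in
numpy autodiff engine — no GPU framework required).

## Worked example

Simulate a 4-slice, 2-coil 64×72 phantom volume, undersample it at R=4
with per-slice random masks (6-line ACS block at this width), and score
the zero-filled baseline:

```bash
ddrecon synth --slices 4 --coils 2 --height 64 --width 72 \
              --noise 0.01 --seed 7 --out demo.h5
# -> wrote 4 slices [2x64x72] to demo.h5
ddrecon mask --width 396 --accel 4 --acs 32 --pattern random --seed 1 --out mask.txt
# -> 99/396 lines sampled (R=4, ACS=32)
```

```python
from ddrecon import synthetic_data, train_eval, metrics

vol = synthetic_data.read_dataset("demo.h5")
ds = train_eval.build_dataset(vol, R=4, pattern="random", mask_seed=0)
zf = train_eval.zero_filled(ds)
records = [metrics.evaluate_pair(vol.reference[i], zf[i]) for i in range(vol.n_slices)]
print(metrics.aggregate(records).aggregate())
```

which prints (mean ± std over the 4 slices)

```
nmse_pct: 3.906 +/- 1.225
ssim:     0.513 +/- 0.043
vif:      0.272 +/- 0.067
```

i.e. plain zero-filling at R=4 already retains ~96% of the reference
energy on these smooth phantoms (nMSE 3.9%), but the aliasing destroys
structural similarity (SSIM 0.51) and perceptual fidelity (VIF 0.27).
Training a model (`ddrecon train --variant model3 --data demo.h5 ...`) and
re-evaluating shows how much of that structure a network recovers; the
`ddrecon compare` command runs the full desk-scale three-variant
comparison and tabulates nMSE/SSIM/VIF per undersampling scenario.

The full-scale configuration of the recurrent module is pinned by its
closed-form parameter count:

```bash
ddrecon count-params --variant model3 --scale full
# -> {"birnn": 637102080}
```

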
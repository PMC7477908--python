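# asdlmri — adaptive-size dictionary learning for undersampled MRI

`asdlmri` reconstructs magnetic-resonance images from undersampled k-space
data with patch-based dictionary learning whose dictionary size adapts
online via information-theoretic criteria. It targets the regime of
low-field MRI, where scan time and signal-to-noise ratio are at a premium
and acquiring only a fraction of k-space is attractive — provided the
reconstruction can suppress the resulting aliasing.

## The method

An image `x` is reconstructed from measurements `y = F_u x` (`F_u` =
undersampled Fourier operator on the sampled set Ω) by alternating two
steps of the objective

```
min_{x,D,Γ}  Σ_ij ‖R_ij x − D α_ij‖²  +  v ‖F_u x − y‖²,   ‖α_ij‖₀ ≤ T0
```

1. **Dictionary learning.** Overlapping √m×√m patches `R_ij x` of the
   current estimate are sparse-coded with OMP and the dictionary `D`
   (unit-norm atoms) is updated with approximate K-SVD sweeps. After each
   pass the atoms are sorted by *power* `P(d_j) = ‖x_jᵀ‖₂` (the 2-norm of
   atom j's code row) and nested sub-dictionary sizes `h` are scored with

   ```
   EBIC(h) = 2 log RMSE + (log Q / Q) P + (2N/Q) log C(h, s),
   RMSE = ‖Y − D_h X_h‖_F / √Q,   Q = mN,   P = sN + (m−1)h
   ```

   (an extended renormalized-maximum-likelihood criterion, ERML, is also
   available). The minimizer `n_ITC` drives three update rules: much
   smaller than the current size n → shrink by `e−`; slightly smaller →
   shrink by one; equal → grow by `e+` random atoms. After a fixed search
   phase the size freezes at the last `n_ITC` and a few refinement passes
   polish the atoms.

2. **Reconstruction update.** The patch approximations are averaged back
   into an image whose spectrum `M` is blended with the zero-filled
   measurements `M0` by the closed-form update

   ```
   Fx(k) = M(k)                  k ∉ Ω
   Fx(k) = (M(k) + v·M0(k))/(1+v)   k ∈ Ω
   ```

   and `x` is the inverse FFT of `Fx`.

The dictionary-learning core is also exposed as a scikit-learn-style
estimator, `AdaptiveDictionaryLearning` (fit/transform, `components_`),
which supports complex-valued signals and composes with sklearn
pipelines.

## Worked example

```sh
asdlmri simulate --size 128 --factor 4 --seed 1 --out y.npz --ref-out ref.png
asdlmri recon --kspace y.npz --ref ref.png --out recon.png --log metrics.csv
```

prints, among the per-iteration progress lines,

```
iter   9  n=  78  n_itc=  64  shrink_big
zero-filled PSNR 17.84 dB
final PSNR 23.13 dB  SNR 11.03 dB  HFEN 1.3060
```

i.e. on a 128² Shepp-Logan phantom with a 4× variable-density mask, ten
outer iterations raise PSNR by ≈5 dB over the zero-filled baseline while
the high-frequency error norm (HFEN, the norm of the
Laplacian-of-Gaussian-filtered error, which scores edge fidelity) drops
by more than half; the dictionary meanwhile shrinks from its initial 128
atoms toward the criterion's choice. The same run from Python:

```python
from asdlmri import (PhantomSpec, ReconConfig, generate_phantom,
                     make_sampling_mask, undersample, as_dlmri_reconstruct)

phantom = generate_phantom(PhantomSpec(grid_size=128))
mask = make_sampling_mask(128, 128, 4.0, "variable_density_2d", seed=1)
y = undersample(phantom, mask)
result = as_dlmri_reconstruct(y, ReconConfig(seed=1), reference=phantom)
print(result.per_iteration[-1])   # MetricsReport(psnr_db=23.1, ...)
```

Size recovery on synthetic data with a known ground truth:

```python
from asdlmri import AdaptiveDictionaryLearning, make_synthetic_dl_problem

prob = make_synthetic_dl_problem(m=36, n_true=48, N=500, s=5, seed=0)
est = AdaptiveDictionaryLearning(n_init=80, n_min=36, search_iters=15,
                                 sparsity_cap=5, random_state=0)
est.fit(prob.signals.T)
print(est.n_components_)          # 50 — within one shrink step of 48
```

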
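# Methods

## Model and procedure

The reconstruction treats an image as a field of overlapping √m×√m
patches, each approximately a sparse combination of at most T0 atoms of a
learned dictionary D ∈ C^{m×n}, together with a quadratic k-space data
fidelity on the sampled set Ω weighted by v. The two blocks are
alternated from a zero-filled initialization:

1. patch extraction (stride r, periodic boundary) → OMP sparse coding →
   one approximate K-SVD atom sweep (optionally several per outer
   iteration), with online size adaptation (below);
2. averaging the coded patches back to an image and applying the exact
   least-squares k-space update: keep the current spectrum off Ω, blend
   `(M + v·M0)/(1+v)` on Ω.

With periodic extraction at stride 1 every pixel is covered by exactly m
patches, so the patch-term normal matrix is m·I and the k-space blend is
the exact minimizer of the reconstruction subproblem — this is why
wraparound stride-1 patching is the default and why the aggregate step
divides by the coverage counts.

All Fourier transforms are centered and unitary; Parseval then holds
exactly and v is independent of grid size.

### Size adaptation

After a learning pass, atoms are sorted by power (2-norm of their code
row) and `n_cand` candidate sizes evenly spaced over [max(n_min, m), n]
are scored with EBIC (default) or ERML. Natural logarithms are used
throughout and the log-binomial term goes through log-gamma, so
C(128, 6)-scale terms never overflow. A perfect fit (RMSE = 0) scores
−∞ with a warning, so among perfect candidates the smallest wins; ERML
candidates with Q ≤ P are over-parameterized and score +∞. Ties always
select the smaller size.

Two candidate-scoring modes exist:

* **truncation** (the `select_candidate_size` default): the size-h error
  keeps the existing codes truncated to their top-h rows. It is cheap
  (one matrix product for the whole scan) and is what the nested-model
  reading of the criterion suggests.
* **re-coding** (`recode=True`, used by the size controller): each
  candidate sub-dictionary re-codes the signals with OMP at sparsity s,
  optionally on a seeded subsample of at most `n_eval` columns (default
  512) to bound the cost. This measures what a smaller dictionary could
  actually achieve. The distinction matters: a redundant learned
  dictionary spreads representation power over all atoms, so truncated
  codes charge every dropped atom its full power and the criterion can
  never prefer a smaller size, whereas after re-coding the error curve
  flattens once h suffices and the complexity terms pull the minimizer
  down. Only the re-coding mode makes the controller recover a known
  ground-truth size.

The controller applies the three-rule update (gap > `gap_threshold` →
−e−; 0 < gap ≤ threshold → −1; gap = 0 → +e+ random unit-norm atoms with
zero code rows), never goes below `n_min`, and freezes at the last
`n_ITC` once `search_iters` evaluations have run; `refine_iters` further
passes run at the frozen size. "Much smaller" is undefined in the
underlying three-rule scheme; the threshold defaults to e− itself, the
smallest choice that keeps the two shrink rules distinct.

### Sparse coding

OMP selects the atom with maximal |⟨residual, atom⟩| (conjugation on the
atom side; ties break to the lowest index for determinism) and refits
all selected coefficients by least squares each step, stopping at T0
atoms or at a residual-norm tolerance. The batch coder shares the Gram
matrix across columns and solves stacked small normal systems; it is
verified column-by-column against the single-vector routine. For complex
data the coefficient row refit in the K-SVD sweep is d^H E (the
least-squares solution), and unused atoms are replaced by the currently
worst-represented training column (ties → lowest index).

## Parameters

| parameter | default | meaning |
|---|---|---|
| patch_side (√m) | 6 | patch edge, m = 36 pixel patches |
| stride r | 1 | patch overlap stride (wraparound on) |
| T0 (`sparsity_cap`) | 6 | OMP atoms per patch |
| `code_tol_rms` | 0.05 | per-pixel RMS residual tolerance of patch coding (reconstruction only) |
| s (`itc_sparsity`) | 5 | sparsity in the complexity count P = sN + (m−1)n |
| n_init / n_min / n_cand | 128 / 64 / 20 | initial, minimum, candidate count |
| e− / e+ / gap_threshold | 5 / 5 / 5 | size-update steps |
| search / refine iterations | 20 / 5 | adaptation phase and fixed-size polish |
| outer_iters | 10 | reconstruction alternations |
| v_weight | 1e6 | data-consistency weight (effectively hard for noiseless data) |

`code_tol_rms` deserves a note: with a purely T0-capped code, a learned
dictionary represents the aliasing artifacts as faithfully as the
anatomy and the alternation barely improves on the zero-filled image.
With an error-constrained code at a tolerance near the artifact level,
patches whose content is explained to that tolerance get very short
codes and the incoherent aliasing is rejected — reconstruction then
gains ≈5 dB at 4× on the default phantom. It is the error-form of the
compressed-sensing constraint and plays the role a noise level plays in
dictionary denoising; set it to 0 to recover the purely capped form.
`omp`/`sparse_code_all` themselves default to tol = 0.

The weight relating the two objective terms is deliberately a single
scalar `v`: the formulation's w = λ/δ involves a δ that cannot be
resolved into a formula from the available description, so v is exposed
directly (large for noiseless data, smaller when measurements are
noisy).

Size-recovery experiments code with T0 = s = 5 (the coding cap and the
criterion sparsity are arguably the same quantity; the package exposes
both, defaults 6 and 5).

## Synthetic data

`generate_phantom` renders the classical 10-ellipse Shepp-Logan head
phantom (contrast-modified intensities) on [−1,1]², evaluated at pixel
centers, intensities clipped to [0, 1]. `make_sampling_mask` provides
2-D variable-density masks — polynomial density (1−r)^6 about DC,
clipped to [0,1] after an additive floor (or multiplicative scale)
solved by bisection so the expected fraction is 1/factor, then an
exact-count weighted draw — plus Cartesian random lines and uniform
random masks; DC is always sampled so the zero-filled initialization
keeps the intensity scale. The additive floor matters: without it, at
moderate factors every sample lands near DC, the aliasing degenerates to
a coherent blur and no patch model can undo it; the floor spreads a
uniform budget across high frequencies, which is what makes the
artifacts incoherent and removable (and matches the standard
variable-density construction in this literature).

`make_synthetic_dl_problem` draws a unit-norm Gaussian dictionary and
exactly-s-sparse Gaussian codes (signals = D·X, optional complex
Gaussian noise); `make_incoherent_dictionary` builds dictionaries with a
prescribed coherence bound by alternating projection on the Gram matrix,
used to create regimes where greedy recovery is provably exact
(μ < 1/(2s−1)).

What the synthetic data does *not* emulate: scanner noise statistics of
a real low-field acquisition, coil sensitivities, phase maps, k-space
trajectory imperfections, or anatomy beyond a piecewise-constant
phantom. Passing tests demonstrate correctness of the algorithmic
machinery and the qualitative behavior (artifact suppression, size
recovery, metric trends), not clinical image quality.

## Numerical choices

- OMP batch solves add a 1e−13 ridge to the stacked Gram systems to
  guard against numerically repeated atoms; columns whose residual falls
  below max(tol, 1e−12·‖y‖) deactivate, which also prevents re-selecting
  an atom at an exact fit.
- Atom updates that encounter a numerically zero direction keep the old
  atom instead of dividing by ~0.
- PSNR/SNR/HFEN compare magnitude images; identical images return +inf.
  The HFEN kernel is the 15×15, σ = 1.5 rotationally symmetric LoG,
  mean-subtracted so a constant difference scores exactly 0.
- Phantom rendering, masks, noise, atom spawning and ITC subsampling are
  all seeded; a reconstruction is bit-reproducible from (inputs, config).

## Problem sizes used in the shipped experiments

Reconstruction experiments use 128² phantoms, 10 outer iterations and
one learning pass per outer iteration (~5 s per run); size-recovery
experiments use m = 36, n_true = 48, N = 500, 15 search + 2 refinement
passes over 10 replicates (~12 s). These sizes give stable statistics
while keeping a full test run in minutes.

## Known limitations

- Single-coil, Cartesian 2-D only; no wavelet/TV hybrid regularization.
- The frozen dictionary size is biased a few atoms above the generating
  size (greedy coding benefits from slight redundancy); recovery is
  within one shrink step (±e−) rather than exact.
- With heavily center-weighted masks (the no-floor limit) the method
  cannot recover never-sampled high frequencies; gains then shrink
  toward zero.
- The noisy-measurement path removes noise only partially at large v;
  choosing v for a given noise level is left to the user.
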
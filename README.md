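# gmchaos

Chaos-topology analysis of gray-matter (GM) structural MRI.

`gmchaos` turns a segmented, spatially normalized GM volume (e.g. a
modulated `mwp1*` map at 1.5 mm isotropic resolution) into a **spatial
series** — the per-voxel product of Euclidean distance from the GM
intensity-weighted center of mass and GM intensity, sorted from highest
to lowest and truncated to the top *K* voxels (default *K* = 5 000,
roughly 1% of nonzero GM voxels). Treating this series like a time
series, it estimates the **Largest Lyapunov Exponent** (λ) by Takens
delay embedding and the Rosenstein small-data-set divergence method,
maps localized λ values back into the brain, decomposes the λ series
into spatial scales with a **complex Morlet continuous wavelet
transform** (scalograms), and compares groups with covariate-adjusted
voxel-wise statistics (permutation max-|t| family-wise error control)
and point-by-scale scalogram tests (Benjamini–Hochberg FDR).

It is aimed at researchers studying cortical topology and its group
differences (e.g. psychosis cohorts) who have segmented GM maps and a
covariate table, and at methodologists who want a fully synthetic,
seeded test bed: the package ships a phantom generator that emulates GM
as noisy corrugated spherical shells with controllable surface
complexity, so the entire pipeline is testable without patient data.

## Method sketch

Delay embedding of the series `x_0 … x_{N−1}`:

    X_k = [x_k, x_{k+τ}, …, x_{k+(m−1)τ}],   k = 0 … M−1,  M = N − (m−1)τ

For each state `X_k`, the nearest neighbor `X_j` outside a Theiler
window `|k − j| > w` is tracked while both advance `s` steps; under
exponential divergence `d(s) ≈ d(0)·e^{λ s}`, so λ is the least-squares
slope of the mean log-divergence `⟨ln d(s)⟩` over its initial linear
region. A localized λ(k) is the one-step finite difference of each
reference pair's own log-distance; λ values are scattered back to their
voxels (unselected voxels set to 0) and smoothed with an 8 mm FWHM
Gaussian. The Morlet wavelet `ψ_s(t) = s^{−1/2} π^{−1/4} e^{iω₀t/s}
e^{−(t/s)²/2}` (ω₀ = 6) correlates the λ series at scales 1–100
(configurable); the stored coefficient is the real part, so positive
values are matches with the wavelet shape and negative values
anti-matches.

## Worked example

Simulate a small two-group cohort of corrugated-shell phantoms (group B
has higher surface complexity), run the subject-level chain on one
phantom, then the group analysis:

```sh
$ gmchaos simulate --out-dir demo/cohort --n-per-group 4 --grid 48 --seed 7
wrote 8 phantoms to demo/cohort

$ gmchaos lambda demo/cohort/S004.nii.gz --out-dir demo/lam --K 1000
lambda_global=-0.0009 fit_r2=0.008 (K=1000, m=5, tau=1)

$ gmchaos group demo/cohort --out-dir demo/stats --K 1000 \
      --scale-max 50 --n-perm 200 --covariates age
[joint covariates] clusters=3 significant_scales=[]
```

`lambda_global` is the fitted divergence slope per series step — near 0
here because a sorted weighted-distance series is almost monotone, so
nearby states barely diverge; the localized λ(k) values and their
scalograms, not the global slope, carry the spatial structure.
`clusters=3` counts suprathreshold clusters (uncorrected p < 0.001,
≥ 10 voxels, 26-connectivity) in the voxel-wise group contrast; their
family-wise-corrected p-values are in `demo/stats/corrected_p_map.nii.gz`.
`significant_scales=[]` means no wavelet scale survived FDR at q = 0.05
for this small cohort. Per-subject outputs include the sorted series
(`series.tsv`: rank, voxel index, weighted distance), the divergence
curve (`divergence.tsv`: step, mean log-divergence, pair count), λ maps
as NIfTI, and the scalogram as a `.npy` array.

The first series rows for S004 show the bookkeeping:

```
rank  i   j   k   weighted_distance
0     13  36  26  24.593137430319725
1     14  36  25  24.532600475905767
2     15  36  28  24.380570771019208
```

## Library layout

| module | contents |
|---|---|
| `gmchaos.volume_io` | NIfTI and covariate-table I/O, coordinate contract |
| `gmchaos.spatial_series` | center of mass, weighted-distance map, top-K sorted series |
| `gmchaos.chaos` | delay embedding, Rosenstein divergence, λ estimates and maps |
| `gmchaos.scalogram` | Morlet CWT, per-subject and cohort scalograms |
| `gmchaos.group_stats` | voxel-wise GLM, permutation FWE, BH-FDR, scalogram tests, atlas region means |
| `gmchaos.synthetic` | corrugated-shell phantoms and seeded two-group cohorts |
| `gmchaos.pipeline` / `gmchaos.cli` | orchestration, manifests, `gmchaos` command |

The `manifest.json` written by group runs records every parameter, the
subject list, per-subject λ estimates and the master seed, so any
output is recomputable from the manifest plus the inputs.

See `docs/methods.md` for the model assumptions, parameter defaults,
what the phantom generator does and does not emulate, and known
limitations.
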
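# Methods

## The spatial series

A GM volume is reduced to one scalar sequence in three steps. The
intensity-weighted center of mass is computed in fractional voxel
coordinates and mapped to world mm through the affine. Each voxel's
Euclidean distance (mm, world coordinates — correct for anisotropic
voxels) from that center is multiplied by its GM intensity; intensities
are used as stored, with no rescaling, so modulated maps whose values
exceed 1 are handled as-is. The products are sorted in descending order
and the top *K* retained together with their voxel indices. Ties are
broken by ascending row-major linear index, which makes the series a
deterministic, storage-order-independent function of the volume.
Negative intensities (interpolation ringing in warped maps) are clipped
to zero on read, with the clip count logged.

*K* defaults to 5 000 (about 1% of nonzero GM voxels in a 1.5 mm
whole-brain map); all examples and tests at 48³ phantom scale use
K = 1 000 to keep runtimes in seconds. Selection is per subject: each
subject contributes its own top-K voxel set.

The sorted series is monotone non-increasing, which makes the
"attractor" reading of the subsequent analysis unconventional; the
package implements the sorted form as its primary contract and the
unsorted voxel ordering remains reachable by skipping `sort_and_select`.

## Lyapunov estimation

The series is delay-embedded with dimension `m` and delay `τ`
(`M = N − (m−1)τ` states). Neither parameter has a canonical value for
this kind of data; the defaults are `m = 5`, `τ = 1`, chosen once for
reproducibility and overridable everywhere — the Rosenstein estimator is
documented to be robust to moderate changes in both. The Theiler window
defaults to `τ(m−1)` (the span of one state vector), preventing
trivially overlapping neighbors in a near-monotone series.

For every reference state the nearest neighbor outside the Theiler
window is found by exact (chunked O(M²)) search, ties toward the
smaller index. Pairs are advanced step by step; at step `s` the mean of
`ln‖X_{k+s} − X_{j+s}‖` over surviving pairs forms the divergence
curve. Pairs with exactly zero distance (ties in the sorted series) are
excluded from that step's mean rather than jittered, so no randomness
is injected; the exclusion count is reported. The global λ is the
least-squares slope of the mean curve over a configurable step range
(default steps 1–20 of a 50-step horizon, in units of the state-space
sampling interval `T_step`, default 1). For short analytic benchmarks
(logistic map), the fit range is set to the initial linear region
(steps 0–6) before the curve saturates at the attractor diameter — the
standard way this estimator is applied.

Localized λ(k) is the one-step finite difference of the *k*-th
reference pair's own log-distance, `(ln d_k(1) − ln d_k(0))/T_step`, so
every selected voxel receives its own value; positions whose pair is
undefined (no admissible neighbor, zero distance, or beyond the last
embedded state) are flagged missing and written to the λ map as 0 with
a logged count. For a divergence curve that is exactly linear, the mean
of the localized values equals the global slope. λ maps are smoothed
with a Gaussian kernel parameterized by FWHM in mm (default 8 mm per
axis, the common volumetric-neuroimaging choice; σ = FWHM/√(8 ln 2)
per axis in voxel units), zero-padded at the boundary.

Two invariances are worth stating because they shape what the method
can and cannot see: adding a constant to the series leaves every λ
quantity unchanged (distances are translation invariant), and scaling
the series by c > 0 shifts all log-distances by ln c without changing
any slope. λ is therefore blind to affine changes of the series — only
changes in its *shape* register.

## Scalograms

The λ series (missing values imputed as 0, with a logged count) is
correlated with the complex Morlet wavelet
`ψ_s(t) = s^{−1/2} π^{−1/4} exp(iω₀t/s) exp(−(t/s)²/2)` at integer
scales 1–100 by default (ω₀ = 6, the standard admissible center
frequency; the wavelet is truncated at |t/s| > 8 where the envelope is
below 1e−14). Coefficients are computed by FFT convolution with the
conjugate wavelet and zero-padded boundaries; the stored value is the
real part — signed "match"/"anti-match" with the wavelet shape — with
the modulus available via a flag. Cells within one truncated wavelet
support of either series edge are flagged boundary-affected; interior
coefficients are provably unchanged by further zero padding. For a pure
cosine of period P the peak scale is `P(ω₀ + √(2+ω₀²))/(4π)` (the
Morlet Fourier factor), which the tests verify against direct
inner-product oracles.

## Group statistics

Voxel-wise inference is an OLS GLM per voxel with design
`[intercept, group indicator, covariates…]`; the analysis mask keeps
voxels whose values vary across subjects (exact peak-to-peak test). The
group t statistic and two-sided Student p are reported with
df = n − p. Covariates default to joint adjustment; a
covariates-separately mode repeats the analysis once per covariate.

Family-wise error over voxels is controlled by permutation max-|t|
with Freedman–Lane covariate handling: the response is residualized on
the nuisance design, residuals are permuted (seeded generator), the
nuisance fit is added back, and the full model refitted; the corrected
p of a voxel is the rank of its observed |t| within the permutation
distribution of the volume-wise maximum (the observed statistic is
included, so p ≥ 1/(n_perm+1); default n_perm = 1 000). Random-field
theory is deliberately not used: permutation is exact under
exchangeability and directly testable. Clusters are formed on the
observed uncorrected map at p < 0.001 (two-sided), 26-connectivity,
and filtered at a 10-voxel extent.

Scalogram comparisons run a two-sample t per (point, scale) cell with
Benjamini–Hochberg FDR across the full cell grid (strict threshold
adjusted p < q). The paper trail for this kind of analysis is ambiguous
between correcting across the whole grid and within each scale; the
full grid is the more conservative default and a per-scale variant is
provided. BH is delegated to statsmodels and verified against the
literal step-up definition. Atlas region means average the nonzero λ
map voxels within each integer label.

Two statistical caveats are documented rather than hidden. First,
λ maps are zero-inflated across subjects (each subject's top-K set
differs; unselected voxels are written as 0) and localized λ values are
heavy-tailed log spacing-ratios, so the parametric voxel-wise t-test is
*conservative* on real pipeline maps — measured null rejection ≈ 0.034
at nominal 0.05 over 50 synthetic null cohorts. This is the safe
direction, and the permutation procedure is exact regardless; exact
nominal voxel-wise level should not be expected from the parametric
p-values. Second, BH at q = 0.05 with many true discoveries admits its
nominal share of false cells, so "significant scales" can include
isolated cells outside a true effect band.

## The synthetic phantom

A phantom is a spherical shell: intensity
`exp(−(r − R(θ,φ))²/(2w²))` with angular radius
`R = r0·(1 + a·B(θ,φ))`, where `B` is a unit-variance, band-limited
random field built from real spherical harmonics of degree 1..L with
iid standard-normal coefficients (analytic normalization; the basis
depends only on the grid and is cached, so cohorts generate in
milliseconds per subject). Defaults: 64³ grid at 1.5 mm, r0 = 24 mm (a
quarter of the box extent, leaving headroom for corrugation; scaled
proportionally for other grids), shell width 3 mm (cortical-sheet
scale), band limit L = 6 (primary-folding scale), truncated-Gaussian
non-negative intensity noise with sd 0.02 (modulated GM maps are
heavily denoised, so residual scanner noise is small and anatomical
variation dominates). The corrugation amplitude `a` is the
surface-complexity dial; the default phantom is the uncorrugated
reference shell. Roughness (variance of R over a fixed angular sample)
increases strictly with `a`.

Cohorts draw per-subject surfaces from seeds derived deterministically
from a master seed, jitter each subject's amplitude with a reflected
normal (sd 0.02 — population variability in gyrification), shift group
B's mean amplitude by `group_effect` (default 0.1), and sample
covariates (age, sex, education, smoking, alcohol) independently of
group, so the default cohort has null covariates; an optional confound
mode shifts one covariate in group B.

What the phantom does *not* emulate: real gyral geometry (harmonic
relief is symmetric and band-limited; cortex is sharp-sulcated and
multiscale), tissue-class mixing, registration error, and — critically
— non-affine group differences in the weighted-distance distribution.
Because `R = r0(1 + aB)` is affine in `a`, raising the amplitude mostly
*rescales* the weighted-distance series, and by the invariances above λ
is first-order blind to it. Passing pipeline tests on these phantoms
therefore demonstrates correctness of the machinery and calibration of
the statistics, **not** that a given amplitude difference is clinically
detectable: in the generator's study conditions (amplitude effect 0.1,
8+8 subjects, K = 1 000, scales 1–50, grid-wide FDR) the scalogram
group test detects the effect only when within-group variability is
made unrealistically small. The mean λ of the corrugated group tends
to shift in one direction (75–100% of seeded cohorts across our runs),
but cell-level detection at these sample sizes does not reach
conventional power. A
strong qualitative contrast (smooth reference shells vs corrugated,
with no amplitude jitter or intensity noise) is detected in every
seeded cohort, and is used as the planted-effect check of the group
pipeline.

## Numerical choices

Voxel indices are 0-based; world coordinates go through the affine.
All estimators are deterministic given their inputs; the only random
elements (phantoms, covariates, permutations) use seeded generators,
and identical config + seed reproduces bit-identical arrays and
manifests. Degenerate inputs raise named errors: all-zero volumes
(center of mass), fewer than K positive voxels (selection), series
shorter than the embedding span, constant series (no positive neighbor
distances), rank-deficient designs, and shells that do not fit their
grid. Problem sizes in the tests (48³ phantoms, K = 1 000, 50 null and
20 effect cohorts, n_perm = 200–500) were chosen so the whole suite
completes in a few minutes while keeping ≥10⁴ pooled voxel tests for
calibration checks.
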
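# Methods

This note documents the models, defaults and design choices behind
`raman-mqa`, and what the synthetic validation does and does not demonstrate.

## The measurement model

A confocal Raman cube holds one spectrum per ~450 nm pixel on a shared
wavenumber axis. We model the measured intensity at pixel (x, y) and
wavenumber ν as

    I(x, y, ν) = g(x, y) · Σ_m c_m(x, y) · R_m(ν) + B(x, y, ν) + ε

where g is an unknown per-pixel multiplicative gain (focus, laser power,
local optical coupling), c_m the concentration of metabolite m, R_m its
reference spectrum (band shape × Raman cross-section), B a smooth
fluorescence-like baseline and ε noise. Neither g nor the cross-sections are
identifiable from a single cube, which is why raw intensity is never treated
as abundance. After baseline removal, the band-area ratio

    ΔA = A_metabolite / A_internal_standard

cancels g exactly (both areas are linear functionals of the same pixel's
spectrum) and leaves ΔA ∝ c_metabolite with an unidentified per-metabolite
constant, provided the internal standard's concentration is spatially uniform
and stable across conditions. This proportionality — not absolute
concentration — is the package's quantitative contract, and is asserted in
tests via linear fits across phantom concentration sweeps, never via absolute
equality.

Assumptions: linear mixing (no resonance enhancement at the working
wavelength), a baseline that is smooth relative to band widths, and an
internal-standard band free of strong interfering neighbors.

## Preprocessing

**Wavenumber calibration.** The silicon reference band is located by
quadratic interpolation through the maximum channel and its two neighbors
(exact for a locally parabolic apex), and the rigid offset to the nominal
520 cm⁻¹ position is subtracted from the target axis. Offsets above
15 cm⁻¹ indicate a gross instrument problem and are warned about.

**Cosmic-ray removal (threshold 8, dimensionless).** A channel is repaired
only if it is anomalous in two independent senses: (i) *spatially* — the
minimum absolute difference between the pixel and each of its 8-connected
valid neighbors exceeds the threshold times the pixel's robust noise SD
(estimated as 1.4826·MAD of the spectrum's second difference / √1.5); and
(ii) *spectrally* — the modified z-score of the second difference itself
exceeds the threshold. A cosmic-ray hit (1–2 channels, detector event)
trips both; genuine compartment contrast at a boundary pixel trips neither,
because the pixel still matches its same-compartment neighbors and real
bands are spectrally smooth. We adopted this two-test form after simpler
spatial-only scores (difference from the neighbor median, with global or
per-channel MAD scaling) repaired real bands at the rims of small structures
such as lipid droplets, where most neighbors lie in another compartment.
Flagged runs are replaced by linear interpolation across their endpoints;
unflagged channels are bit-identical to the input. Isolated pixels fall back
to the spectral test alone; a fully-flagged pixel is masked.

**Baseline correction.** Default arPLS (λ = 1e5, ≤ 20 reweighting
iterations): a Whittaker smoother whose weights are a logistic function of
the residual scaled by the noise statistics of the points *below* the current
baseline, so in signal-free regions the baseline runs through the middle of
the noise. Plain AsLS (p = 0.01) is also provided but is not the default: its
baseline hugs the noise floor, leaving a positive ~1σ-per-channel pedestal
that inflated small band areas by up to 15% on phantoms — intolerable for
ratio quantification of weak bands. A degree-3 iteratively clipped polynomial
is available for very smooth backgrounds. Both penalized methods commute with
positive global intensity scaling (their weights depend only on scale-free
residual ratios); equivariance is exact apart from linear-solver round-off.

**Savitzky–Golay smoothing** (window 9 channels, order 3) with truncated
window refit at the edges (scipy's `interp` mode), so no intensity is
invented outside the measured range. Note that at 2 cm⁻¹ sampling SG
flattens sharp band apexes by design; band *areas* are conserved to ≪1%,
which is why quantification integrates areas rather than reading heights.

**PCA denoising** is available but off by default in quantification paths:
low-rank reconstruction can redistribute band area between correlated
channels. Segmentation uses PCA scores internally regardless.

**Stage order** defaults to despike → baseline → smooth: spikes corrupt the
baseline estimate, so despiking first is safer even though acquisition
software commonly lists baseline correction first. The order is fully
configurable, including the instrument-style order.

## Compartmentalization

Clustering runs k-means (k-means++, 10 restarts, seeded) on the top 10 PCA
scores of unit-L2-normalized spectra: normalization makes segmentation
respond to spectral shape rather than brightness, and the PCA projection
suppresses noise dimensions. k is either fixed or chosen as the silhouette
maximum over a scan (ties to smaller k). Cluster mean spectra are arithmetic
means of the *original* spectra, so downstream band areas keep their units.

"Component imaging" (linear unmixing) is re-specified openly as: endmembers
= observed pixel spectra selected by successive simplex-volume maximization
on PCA scores (start from the pixel farthest from the centroid, then
repeatedly add the pixel farthest from the affine hull of the current set),
followed by per-pixel non-negative least squares. Under the pure-pixel
assumption this recovers the true endmembers exactly; because the endmember
sets are nested in the component count, the per-pixel NNLS residual is
provably non-increasing as components are added. This is an approximation of
proprietary component-imaging tools, not a clone.

Cluster annotation matches each cluster's difference peaks (cluster mean
minus the mean of the other clusters, ranked by prominence) against the band
library and votes by compartment class: {1078, 1423} → nucleus;
{1746, 1263, 1656, 3009, 1083} → lipid droplet; {930, 943, 1643, 1379, 1666,
484} → symbiont; {1006} → cytoplasm. All library assignments carry a
"tentatively assigned" note — the tool reports candidates, never identities
— and positions inside the 980 ± 8 cm⁻¹ fixation-artifact window are never
assigned.

## Quantification

Band areas are closed-window trapezoids with linear interpolation at the
exact window bounds; the whole integral is one precomputed dot product per
pixel, so integration is exactly linear in intensity. An optional chord
("local") baseline subtracts the secant through the window endpoints — off
by default because cubes are baseline-corrected globally, on by default for
raw calibration spectra. A peak-height compatibility mode exists; area is
the default because at 3 cm⁻¹ spectral resolution area is far more robust.

Ratio maps are valid where both areas are valid and the denominator exceeds
ε = 1e-6 × max denominator area (prevents blow-up at near-empty pixels
without hiding genuine signal). Negative areas (over-subtraction) are kept,
flagged, and reported — clipping would silently break linearity; statistics
offer an optional clip-at-zero mode.

Internal-standard selection ranks candidate windows by the spatial
coefficient of variation (SD/mean) of their area maps over the cell mask,
ascending; negative-mean candidates are disqualified and ties go to the lower
center. Between-group stability can be checked by comparing candidate CVs
across treatment groups. Compartment statistics report mean, population SD
(so SD = 0 iff all values equal) and n of valid pixels per label; group
comparison is descriptive (mean ± SD) with no bundled hypothesis testing.
Calibration is ordinary least squares of ΔA on the varied analyte's
concentration; R² is snapped to exactly 1 when the residual sum of squares
is below 1e-12 of the total, so collinear input reports perfect linearity
despite float round-off. (The mock design varies the analyte at fixed
internal standard, so the regression is on the analyte's concentration.)

## The phantom generator

The generator is the ground truth for every test. It emulates a bacteriocyte
on a 48×48 grid at 450 nm pixel spacing (any grid ≥ 16×16 works; geometry is
specified in grid fractions): an elliptical cell, a nucleus disc at the
basal pole, three lipid-droplet discs near the nucleus, symbiont strain A on
the outer (apical) side, strain B inward, cytoplasm elsewhere. Out-of-cell
pixels carry baseline and noise only and are masked.

Reference spectra are sums of pseudo-Voigt bands (default σ = 2.5 cm⁻¹,
Gaussian/Lorentzian mixing η = 0.1 — FWHM ≈ 6 cm⁻¹, matching sharp bands at
3 cm⁻¹ instrument resolution) at the library positions, plus 2–4 fixed
"filler" background bands per metabolite placed ≥ 25 cm⁻¹ from every library
center (documented in `data/reference_bands.yaml`) so spectra overlap
realistically without corrupting quantified windows. Two deliberate
omissions at this resolution: the nucleic-acid PO₂⁻ 1078 band is degenerate
with the cholesterol 1083 ± 8 window, so the default nucleus signature uses
deoxyribose 1423 only; and palmitoleic acid's 1656 band sits 2 cm⁻¹ from the
squalene 1666 ± 8 window edge, so its reference uses the 1263 and 3009 bands.
With those windows clean, residual cross-talk (mainly NADH 1114 ↔ glucose
1127, whose windows genuinely overlap) stays below ~7% of a compartment's
ΔA under the default concentration contrasts.

Default compartment concentrations encode only ordinal relations:
nucleus-rich deoxyribose; lipid-droplet triglyceride/palmitoleate/
cholesterol; symbiont lanosterol/squalene with strain A > strain B in
glycogen and NADH; cytoplasmic phenylalanine/glucose/tryptophan; threonine
constant (1.0) across the whole cell. No quantitative contrast between
compartments is claimed as biological truth.

Noise is Gaussian with variance 0.8·signal + 0.2·floor scaled so that the
*mean-signal* SNR equals the `snr` parameter (default 30) — a continuously
tunable stand-in for shot noise, not true Poisson. The baseline is a gentle
quadratic with a smoothly varying spatial amplitude (default 0.3 of unit
band scale); the gain field is smooth with ±15% default variation; cosmic
spikes (default 6 per cube) add 30–60× the pixel's mean intensity at one
channel. Every cube is bit-reproducible from (parameters, seed): the seed
spawns four child streams consumed in the documented order gain → baseline
field → noise → spikes, so disabling one component never changes another.

The de-symbiosis series shrinks the symbiont masks from the inner edge
(stage fractions 1.0/0.5/0.1 by default, tags InS/D4w/D10w) and applies
stage multipliers (cholesterol ×1/1.6/2.4, glucose ×1/1.3/1.8, tryptophan
×1/1.25/1.7) emulating metabolite accumulation after symbiont loss. The mock
calibration series mixes glucose at 6 levels (0.5–5.0) with threonine fixed
at 1.0. Its default SNR of 100 was set once by a seeded sweep over
{50, 100, 150, 200, 300, 500, 800}: 100 is the noisiest level at which at
least 95 of 100 replicates reach R² ≥ 0.9998 (at SNR 50, 92 of 100 do).

**What passing phantom tests does not show about real data:** the phantom
has piecewise-constant concentrations with sharp compartment borders, no
optical point-spread blur or confocal depth sectioning, Gaussian rather than
Poisson noise, per-metabolite reference spectra that are exactly shared
across pixels, and an internal standard that is uniform *by construction*.
Real cells violate all of these to some degree; in particular the uniformity
of any internal-standard band must be re-established empirically (the
CV-ranking report) for each new system, and depth-dependent signal loss is
not corrected.

## Numerical choices and degenerate inputs

- Areas/ratios: ε-floor as above; empty compartments are omitted from tables
  with a warning; masked pixels never contribute to any statistic.
- k-means ties (equal distance) follow scikit-learn's deterministic
  assignment under the fixed seed; silhouette ties go to smaller k;
  internal-standard CV ties go to the lower band center.
- Unmixing with one component reduces to "most extreme pixel" selection;
  degenerate (all-identical) cubes raise a selection error in the k scan.
- AsLS/arPLS solve a pentadiagonal banded system (O(channels) per
  iteration); iteration caps at 20 with convergence on the weight vector.
- Problem sizes: tests and validation use 48×48×1351 cubes (the default
  phantom), 24–32 px grids where statistics allow, 100-replicate calibration
  sweeps — all chosen so the full suite completes in a few minutes on one
  core.

## Known limitations

- Semi-quantitative only: per-metabolite proportionality constants are not
  identified; no absolute concentrations, no cross-metabolite comparisons.
- Window cross-talk between bands closer than ~16 cm⁻¹ (e.g. NADH/glucose)
  biases ΔA by the interferer's relative abundance; the library flags such
  pairs implicitly through window overlap, but no spectral deconvolution is
  attempted.
- The unmixing is linear and unregularized; spatial label smoothing and
  nonlinear mixing are out of scope.
- Instrument response, detector nonlinearity and dark current are assumed
  already corrected upstream; proprietary instrument files are not parsed.
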
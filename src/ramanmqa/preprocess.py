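"""Preprocessing: axis calibration, despiking, baseline, smoothing, denoising.

Stages are individually callable and composed by :func:`run_preprocess` in a
configurable order.  The default order is cosmic-ray removal -> baseline
correction -> Savitzky-Golay smoothing (PCA reconstruction off by default):
spikes corrupt the baseline estimate, so despiking runs first even though
instrument software often lists baseline correction first; the order stays
configurable.

Baseline correction defaults to asymmetric least squares (AsLS), the standard
approach for fluorescence backgrounds under Raman bands: a Whittaker smoother
whose weights penalize points above the running baseline far less (p << 1)
than points below it, iterated until the above/below partition stabilizes.
Because the weights depend only on the *sign* of the residual, the estimated
baseline is exactly scale-equivariant: correcting ``c * S`` gives ``c`` times
the correction of ``S``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.linalg import solve_banded
from scipy.signal import savgol_filter
from sklearn.decomposition import PCA

from .core import HyperCube, Spectrum, WavenumberAxis
from .errors import CalibrationError, ConfigError

__all__ = [
    "PreprocessConfig",
    "AxisCalibration",
    "CrrReport",
    "calibrate_axis",
    "remove_cosmic_rays",
    "correct_baseline",
    "smooth_savitzky_golay",
    "pca_denoise",
    "run_preprocess",
]

logger = logging.getLogger(__name__)

_STAGES = ("crr", "baseline", "sg", "pca")


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for every preprocessing stage.

    ``crr_zscore_threshold``: modified z-score above which a channel is a
    cosmic-ray hit (dimensionless, default 8).  ``asls_lambda`` / ``asls_p``:
    AsLS smoothness weight and asymmetry.  ``sg_window`` / ``sg_order``:
    Savitzky-Golay window (odd channel count) and polynomial order.
    ``pca_variance``: cumulative explained-variance target in (0, 1], or an
    explicit integer component count.  ``stage_order``: which stages run, in
    which order (any subset of crr / baseline / sg / pca).
    """

    crr_zscore_threshold: float = 8.0
    baseline_method: str = "arpls"
    asls_lambda: float = 1e5
    asls_p: float = 0.01
    asls_max_iter: int = 20
    poly_degree: int = 3
    sg_window: int = 9
    sg_order: int = 3
    pca_variance: Union[float, int] = 0.99
    stage_order: tuple[str, ...] = ("crr", "baseline", "sg")

    def __post_init__(self) -> None:
        if self.crr_zscore_threshold <= 0:
            raise ConfigError("crr_zscore_threshold must be positive")
        if self.baseline_method not in ("arpls", "asls", "poly"):
            raise ConfigError("baseline_method must be 'arpls', 'asls' or 'poly'")
        if self.asls_lambda <= 0 or not 0 < self.asls_p < 1:
            raise ConfigError("asls_lambda must be > 0 and asls_p in (0, 1)")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ConfigError("sg_window must be odd and greater than sg_order")
        if isinstance(self.pca_variance, float) and not 0 < self.pca_variance <= 1:
            raise ConfigError("pca_variance must lie in (0, 1] or be an integer count")
        if isinstance(self.pca_variance, int) and self.pca_variance < 1:
            raise ConfigError("explicit PCA component count must be >= 1")
        unknown = set(self.stage_order) - set(_STAGES)
        if unknown or len(set(self.stage_order)) != len(self.stage_order):
            raise ConfigError(f"stage_order must be distinct stages from {_STAGES}")

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        d = dict(d)
        if "stage_order" in d:
            d["stage_order"] = tuple(d["stage_order"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Axis calibration
# ---------------------------------------------------------------------------

#: Silicon's characteristic first-order phonon band, the usual wavenumber
#: calibration reference.
SILICON_REFERENCE_CM1 = 520.0


@dataclass(frozen=True)
class AxisCalibration:
    """Result of rigid axis calibration: detected apex and applied offset."""

    offset: float
    apex_raw: float
    reference_position: float


def detect_apex(
    spectrum: Spectrum, position: float, search_halfwidth: float = 30.0
) -> float:
    """Band apex near ``position`` by quadratic interpolation around the maximum.

    The maximum is located among channels within ``position +-
    search_halfwidth``; the apex is the vertex of the parabola through that
    channel and its two neighbors (exact for a locally quadratic peak).
    """
    x = spectrum.axis.values
    y = spectrum.intensity
    sel = np.where(np.abs(x - position) <= search_halfwidth)[0]
    if sel.size < 3:
        raise CalibrationError(
            f"fewer than 3 channels within {search_halfwidth} cm^-1 of {position}"
        )
    i = sel[np.argmax(y[sel])]
    if i == 0 or i == len(x) - 1:
        raise CalibrationError("reference maximum sits on the axis boundary")
    if y[i] <= y[sel].min():
        raise CalibrationError("no peak found in the calibration search window")
    x3, y3 = x[i - 1 : i + 2], y[i - 1 : i + 2]
    a, b, _ = np.polyfit(x3 - x3[1], y3, 2)
    if a >= 0:
        raise CalibrationError("reference band is not locally concave")
    return float(x3[1] - b / (2.0 * a))


def calibrate_axis(
    target: Union[HyperCube, Spectrum],
    reference: Spectrum,
    reference_position: float = SILICON_REFERENCE_CM1,
    search_halfwidth: float = 30.0,
):
    """Rigidly shift ``target``'s axis so the reference apex maps to its nominal position.

    The silicon reference band is located on the reference spectrum by
    quadratic interpolation; the same offset ``apex - reference_position`` is
    subtracted from the target axis.  Returns ``(calibrated_target,
    AxisCalibration)``.
    """
    apex = detect_apex(reference, reference_position, search_halfwidth)
    offset = apex - reference_position
    if abs(offset) > 15.0:
        warnings.warn(
            f"axis calibration offset {offset:+.2f} cm^-1 exceeds 15 cm^-1", stacklevel=2
        )
    result = AxisCalibration(offset=offset, apex_raw=apex, reference_position=reference_position)
    new_axis = target.axis.shifted(-offset)
    if isinstance(target, Spectrum):
        return Spectrum(new_axis, target.intensity), result
    return target.with_data(target.data, axis=new_axis), result


# ---------------------------------------------------------------------------
# Cosmic-ray removal
# ---------------------------------------------------------------------------


@dataclass
class CrrReport:
    """Despiking audit: every replaced (row, col, channel) and masked pixels."""

    replacements: list[tuple[int, int, int]] = field(default_factory=list)
    masked_pixels: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_replaced(self) -> int:
        return len(self.replacements)


def _neighbor_min_difference(data: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Per-channel minimum |pixel - neighbor| over the 8-connected valid neighbors.

    A cosmic-ray hit deviates from *every* neighbor, so its minimum difference
    is huge; a pixel at a compartment boundary still matches its
    same-compartment neighbors, so genuine band contrast stays small.  NaN
    where a pixel has no valid neighbor.
    """
    h, w, c = data.shape
    stack = np.full((8, h, w, c), np.nan)
    padded = np.full((h + 2, w + 2, c), np.nan)
    padded[1:-1, 1:-1][valid] = data[valid]
    k = 0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            stack[k] = padded[1 + dr : h + 1 + dr, 1 + dc : w + 1 + dc]
            k += 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices -> NaN
        return np.nanmin(np.abs(stack - data), axis=0)


def _modified_zscore(d: np.ndarray) -> np.ndarray:
    """Robust outlier score 0.6745 |d - med| / MAD; infinite where MAD is zero."""
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    dev = np.abs(d - med)
    if mad == 0:
        return np.where(dev > 0, np.inf, 0.0)
    return 0.6745 * dev / mad


def _second_difference(y: np.ndarray) -> np.ndarray:
    d = np.empty_like(y)
    d[1:-1] = y[1:-1] - 0.5 * (y[:-2] + y[2:])
    d[0] = y[0] - y[1]
    d[-1] = y[-1] - y[-2]
    return d


def _interpolate_runs(y: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    good = np.where(~flagged)[0]
    out = y.copy()
    out[flagged] = np.interp(np.where(flagged)[0], good, y[good])
    return out


def remove_cosmic_rays(
    cube: HyperCube, config: Optional[PreprocessConfig] = None
) -> tuple[HyperCube, CrrReport]:
    """Flag and repair cosmic-ray spikes; unflagged channels are never altered.

    Spatial evidence per channel is the *minimum* absolute difference between
    the pixel and its 8-connected valid neighbors: a cosmic-ray hit deviates
    from every neighbor, whereas a pixel at a sharp compartment boundary
    still matches its same-compartment neighbors, so genuine bands at
    boundary pixels are never "repaired".  That evidence is expressed in
    units of the pixel's robust noise SD (estimated from the MAD of the
    spectrum's second difference), and a channel is flagged when this spatial
    score *and* the modified z-score of the second difference itself both
    exceed ``crr_zscore_threshold`` (spikes are 1-2 channels wide, hence
    anomalous in both senses).  Flagged runs are replaced by linear
    interpolation across their ends.  Pixels without valid neighbors
    (single-pixel cubes, isolated pixels) use the spectral score alone.  A
    pixel with every channel flagged is masked instead.
    """
    config = config or PreprocessConfig()
    if cube.n_channels < 2:
        raise ConfigError("cosmic-ray removal needs at least 2 channels")
    thr = config.crr_zscore_threshold
    valid = cube.valid_mask()
    dev = _neighbor_min_difference(cube.data, valid)

    with np.errstate(invalid="ignore", divide="ignore"):
        # spectral score: modified z of the second difference, per pixel
        d2 = np.empty_like(cube.data)
        d2[..., 1:-1] = cube.data[..., 1:-1] - 0.5 * (cube.data[..., :-2] + cube.data[..., 2:])
        d2[..., 0] = cube.data[..., 0] - cube.data[..., 1]
        d2[..., -1] = cube.data[..., -1] - cube.data[..., -2]
        med2 = np.median(d2, axis=-1, keepdims=True)
        dev2 = np.abs(d2 - med2)
        mad2 = np.median(dev2, axis=-1, keepdims=True)
        z_spectral = np.where(
            mad2 > 0, 0.6745 * dev2 / mad2, np.where(dev2 > 0, np.inf, 0.0)
        )

        # spatial score: min |pixel - neighbor| in units of the pixel's robust
        # noise SD (from the second difference: SD(d2) = sqrt(1.5) * SD(noise))
        sigma = 1.4826 * mad2 / np.sqrt(1.5)
        z_spatial = np.where(sigma > 0, dev / sigma, np.where(dev > 0, np.inf, 0.0))

    has_neighbors = np.isfinite(dev).all(axis=-1)
    flags = np.where(
        has_neighbors[..., None],
        (z_spatial > thr) & (z_spectral > thr),
        z_spectral > thr,
    )
    flags &= valid[..., None]

    data = cube.data.copy()
    mask = valid.copy()
    report = CrrReport()
    for r, c in zip(*np.nonzero(flags.any(axis=-1))):
        flagged = flags[r, c]
        if flagged.all():
            mask[r, c] = False
            report.masked_pixels.append((int(r), int(c)))
            warnings.warn(f"all channels flagged at pixel ({r}, {c}); pixel masked", stacklevel=2)
            continue
        data[r, c] = _interpolate_runs(cube.data[r, c], flagged)
        report.replacements.extend((int(r), int(c), int(ch)) for ch in np.where(flagged)[0])
    out = HyperCube(cube.axis, data, pixel_size_nm=cube.pixel_size_nm, mask=mask)
    return out, report


# ---------------------------------------------------------------------------
# Baseline correction
# ---------------------------------------------------------------------------


_ASLS_BANDED_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _asls_penalty_banded(n: int, lam: float) -> np.ndarray:
    """Pentadiagonal lam * D2'D2 in solve_banded layout, cached per (n, lam)."""
    key = (n, lam)
    if key not in _ASLS_BANDED_CACHE:
        from scipy import sparse

        D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
        A0 = (lam * (D.T @ D)).todia()
        banded = np.zeros((5, n))
        for off, vals in zip(A0.offsets, A0.data):
            banded[2 - off, :] = vals
        if len(_ASLS_BANDED_CACHE) > 8:
            _ASLS_BANDED_CACHE.clear()
        _ASLS_BANDED_CACHE[key] = banded
    return _ASLS_BANDED_CACHE[key]


def _asls_baseline(y: np.ndarray, lam: float, p: float, max_iter: int) -> np.ndarray:
    """AsLS baseline via a banded Whittaker solve; weights from residual sign only."""
    n = y.size
    banded0 = _asls_penalty_banded(n, lam)
    w = np.ones(n)
    z = y.copy()
    for _ in range(max_iter):
        ab = banded0.copy()
        ab[2, :] += w
        z = solve_banded((2, 2), ab, w * y)
        if not np.all(np.isfinite(z)):
            raise ConfigError("AsLS baseline solve diverged")
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def _arpls_baseline(y: np.ndarray, lam: float, max_iter: int) -> np.ndarray:
    """arPLS baseline: asymmetric reweighting from the negative-residual noise.

    Unlike plain AsLS, whose baseline hugs the *bottom* of the noise and so
    leaves a positive pedestal on the corrected signal, arPLS weights are a
    logistic function of the residual scaled by the noise statistics of the
    points below the baseline, so in signal-free regions the baseline runs
    through the middle of the noise and band areas carry no additive offset.
    Weights depend only on scale-free residual ratios, so the estimate
    commutes with positive global intensity scaling.
    """
    n = y.size
    banded0 = _asls_penalty_banded(n, lam)
    w = np.ones(n)
    z = y.copy()
    for _ in range(max_iter):
        ab = banded0.copy()
        ab[2, :] += w
        z = solve_banded((2, 2), ab, w * y)
        if not np.all(np.isfinite(z)):
            raise ConfigError("arPLS baseline solve diverged")
        d = y - z
        neg = d[d < 0]
        if neg.size < 2:
            break
        m, s = float(neg.mean()), float(neg.std())
        if s == 0:
            break
        with np.errstate(over="ignore"):
            w_new = 1.0 / (1.0 + np.exp(np.clip(2.0 * (d - (2.0 * s - m)) / s, -500, 500)))
        if np.linalg.norm(w_new - w) / max(np.linalg.norm(w), 1e-300) < 1e-3:
            w = w_new
            break
        w = w_new
    return z


def _poly_baseline(y: np.ndarray, x: np.ndarray, degree: int, n_iter: int = 12) -> np.ndarray:
    """Iterative polynomial baseline: refit after clipping y to the current fit."""
    t = (x - x.mean()) / (x.max() - x.min())
    yy = y.copy()
    fit = np.zeros_like(y)
    for _ in range(n_iter):
        coef = np.polyfit(t, yy, degree)
        fit = np.polyval(coef, t)
        yy = np.minimum(yy, fit)
    return fit


def correct_baseline(
    obj: Union[HyperCube, Spectrum], config: Optional[PreprocessConfig] = None
):
    """Subtract a smooth estimated baseline; returns ``(corrected, baseline)``.

    The stored baseline has the same shape as the input so the subtraction is
    auditable.
    """
    config = config or PreprocessConfig()
    if isinstance(obj, Spectrum):
        n = len(obj.axis)
    else:
        n = obj.n_channels
    if n < 2 * config.sg_window:
        raise ConfigError("baseline correction needs at least 2 x sg_window channels")

    def one(y: np.ndarray, x: np.ndarray, where: str) -> np.ndarray:
        try:
            if config.baseline_method == "arpls":
                return _arpls_baseline(y, config.asls_lambda, config.asls_max_iter)
            if config.baseline_method == "asls":
                return _asls_baseline(y, config.asls_lambda, config.asls_p, config.asls_max_iter)
            return _poly_baseline(y, x, config.poly_degree)
        except ConfigError as exc:
            raise ConfigError(f"baseline estimation failed at {where}: {exc}") from exc

    if isinstance(obj, Spectrum):
        base = one(obj.intensity, obj.axis.values, "spectrum")
        return Spectrum(obj.axis, obj.intensity - base), Spectrum(obj.axis, base)

    baseline = np.zeros_like(obj.data)
    data = obj.data.copy()
    valid = obj.valid_mask()
    x = obj.axis.values
    for r, c in np.argwhere(valid):
        base = one(obj.data[r, c], x, f"pixel ({r}, {c})")
        baseline[r, c] = base
        data[r, c] = obj.data[r, c] - base
    return obj.with_data(data), obj.with_data(baseline)


# ---------------------------------------------------------------------------
# Savitzky-Golay smoothing
# ---------------------------------------------------------------------------


def smooth_savitzky_golay(
    obj: Union[HyperCube, Spectrum], config: Optional[PreprocessConfig] = None
):
    """Savitzky-Golay convolution along the spectral axis.

    Edges are handled by refitting the polynomial on the truncated window
    (scipy's ``interp`` mode) rather than by mirror padding, so no intensity
    is invented outside the measured range.
    """
    config = config or PreprocessConfig()
    n = len(obj.axis) if isinstance(obj, Spectrum) else obj.n_channels
    if config.sg_window > n:
        raise ConfigError(f"sg_window {config.sg_window} exceeds channel count {n}")
    if isinstance(obj, Spectrum):
        return Spectrum(
            obj.axis, savgol_filter(obj.intensity, config.sg_window, config.sg_order, mode="interp")
        )
    smoothed = savgol_filter(obj.data, config.sg_window, config.sg_order, axis=-1, mode="interp")
    return obj.with_data(smoothed)


# ---------------------------------------------------------------------------
# PCA denoising
# ---------------------------------------------------------------------------


def pca_denoise(
    cube: HyperCube, config: Optional[PreprocessConfig] = None
) -> tuple[HyperCube, np.ndarray, int]:
    """Reconstruct valid pixels from the leading principal components.

    Components are retained up to the configured cumulative explained
    variance (or an explicit count).  Returns ``(cube,
    explained_variance_ratio_profile, n_retained)``.  The per-channel mean
    spectrum of the valid pixels is preserved exactly (PCA reconstructs
    around the mean).
    """
    config = config or PreprocessConfig()
    valid = cube.valid_mask()
    X = cube.data[valid]
    max_comp = min(X.shape)
    if isinstance(config.pca_variance, int):
        n_comp = config.pca_variance
        if n_comp > max_comp:
            raise ConfigError(
                f"requested {n_comp} components but only {max_comp} available"
            )
    else:
        n_comp = max_comp
    pca = PCA(n_components=n_comp, svd_solver="auto", random_state=0)
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    if not isinstance(config.pca_variance, int):
        cum = np.cumsum(evr)
        n_comp = int(np.searchsorted(cum, config.pca_variance - 1e-12) + 1)
        n_comp = min(n_comp, len(evr))
        scores[:, n_comp:] = 0.0
    recon = pca.inverse_transform(scores)
    data = cube.data.copy()
    data[valid] = recon
    return cube.with_data(data), evr, int(n_comp)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_preprocess(
    cube: HyperCube, config: Optional[PreprocessConfig] = None
) -> tuple[HyperCube, dict]:
    """Apply the configured stages in order; returns the cube and provenance.

    The provenance dict records the stage order, the parameters used, the
    spike count and masked pixels from despiking, and the PCA component count
    — enough to audit or replay a run.
    """
    config = config or PreprocessConfig()
    provenance: dict = {
        "stage_order": list(config.stage_order),
        "parameters": {
            "crr_zscore_threshold": config.crr_zscore_threshold,
            "baseline_method": config.baseline_method,
            "asls_lambda": config.asls_lambda,
            "asls_p": config.asls_p,
            "sg_window": config.sg_window,
            "sg_order": config.sg_order,
            "pca_variance": config.pca_variance,
        },
        "stages": {},
    }
    for stage in config.stage_order:
        if stage == "crr":
            cube, report = remove_cosmic_rays(cube, config)
            provenance["stages"]["crr"] = {
                "n_replaced": report.n_replaced,
                "masked_pixels": report.masked_pixels,
            }
        elif stage == "baseline":
            cube, _ = correct_baseline(cube, config)
            provenance["stages"]["baseline"] = {"method": config.baseline_method}
        elif stage == "sg":
            cube = smooth_savitzky_golay(cube, config)
            provenance["stages"]["sg"] = {
                "window": config.sg_window,
                "order": config.sg_order,
            }
        elif stage == "pca":
            cube, evr, n_retained = pca_denoise(cube, config)
            provenance["stages"]["pca"] = {
                "n_components": n_retained,
                "explained_variance_ratio": [float(v) for v in evr[:n_retained]],
            }
        logger.info("preprocess stage %s done", stage)
    return cube, provenance
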
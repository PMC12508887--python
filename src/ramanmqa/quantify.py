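"""Band imaging and internal-standard semi-quantification.

Raman intensity depends on per-molecule scattering cross-sections, focus,
laser power and detector gain, so raw band area cannot be compared across
pixels or samples.  The sanctioned normalization is the internal-standard
ratio: integrate a metabolite band area ``A_metabolite`` and divide by the
area of a band whose carrier is uniformly distributed and stable in content
(here the 1341 cm^-1 band, tentatively threonine):

    dA = A_metabolite / A_internal_standard

Any per-pixel multiplicative gain cancels exactly in ``dA``, which is what
makes the result semi-quantitative: proportional to concentration per
metabolite, comparable across pixels, cells and treatment groups, but with an
unidentified per-metabolite constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import AreaMap, HyperCube, PeakWindow, RatioMap, Spectrum
from .errors import ConfigError, FitError, GridError, SelectionError, UsageError
from .multivariate import ClusterResult, kmeans_cluster, select_k, true_component_analysis
from .preprocess import PreprocessConfig, run_preprocess

__all__ = [
    "PeakWindow",
    "CalibrationFit",
    "MqaConfig",
    "MqaResult",
    "integrate_peak",
    "peak_area",
    "ratio_map",
    "select_internal_standard",
    "compartment_stats",
    "fit_calibration",
    "calibration_delta_a",
    "run_mqa",
    "DEFAULT_METABOLITE_WINDOWS",
    "INTERNAL_STANDARD_WINDOW",
]

#: Shipped metabolite integration windows (center +- 8 cm^-1).
DEFAULT_METABOLITE_WINDOWS: dict[str, PeakWindow] = {
    "glycogen": PeakWindow(484.0, 8.0, "glycogen"),
    "nadh": PeakWindow(1114.0, 8.0, "nadh"),
    "squalene": PeakWindow(1666.0, 8.0, "squalene"),
    "lanosterol": PeakWindow(1643.0, 8.0, "lanosterol"),
    "cholesterol": PeakWindow(1083.0, 8.0, "cholesterol"),
    "glucose": PeakWindow(1127.0, 8.0, "glucose"),
    "tryptophan": PeakWindow(1557.0, 8.0, "tryptophan"),
}

#: The default internal-standard band (tentatively threonine).
INTERNAL_STANDARD_WINDOW = PeakWindow(1341.0, 8.0, "threonine")


# ---------------------------------------------------------------------------
# Band integration
# ---------------------------------------------------------------------------


def _endpoint_functional(x: np.ndarray, pos: float) -> np.ndarray:
    """Weights w with w @ intensity = linearly interpolated intensity at pos."""
    w = np.zeros(x.size)
    j = int(np.searchsorted(x, pos))
    if j < x.size and x[j] == pos:
        w[j] = 1.0
        return w
    frac = (pos - x[j - 1]) / (x[j] - x[j - 1])
    w[j - 1] = 1.0 - frac
    w[j] = frac
    return w


def _window_weights(x: np.ndarray, window: PeakWindow, local_baseline: bool) -> np.ndarray:
    """Linear functional w such that ``intensity @ w`` is the window's trapezoid area.

    The window is clipped to the axis range; intensity at the exact clipped
    bounds is obtained by linear interpolation, and if ``local_baseline`` the
    chord joining the two endpoint intensities is subtracted (also a linear
    functional, so the whole integral stays one dot product per pixel).
    """
    lo, hi = max(window.lo, float(x[0])), min(window.hi, float(x[-1]))
    if lo >= hi:
        raise ConfigError(
            f"window [{window.lo}, {window.hi}] lies outside the axis range "
            f"[{x[0]}, {x[-1]}]"
        )
    if int(np.sum((x >= lo) & (x <= hi))) < 2:
        raise ConfigError("window must intersect the axis in at least 2 channels")
    inner = np.where((x > lo) & (x < hi))[0]
    nodes = np.concatenate([[lo], x[inner], [hi]])
    tw = np.zeros(nodes.size)
    d = np.diff(nodes)
    tw[:-1] += d / 2.0
    tw[1:] += d / 2.0
    e_lo = _endpoint_functional(x, lo)
    e_hi = _endpoint_functional(x, hi)
    w = np.zeros(x.size)
    w[inner] += tw[1:-1]
    w += tw[0] * e_lo + tw[-1] * e_hi
    if local_baseline:
        w -= 0.5 * (hi - lo) * (e_lo + e_hi)
    return w


def integrate_peak(
    cube: HyperCube,
    window: PeakWindow,
    local_baseline: bool = False,
    use_height: bool = False,
) -> AreaMap:
    """Per-pixel trapezoidal band area over the closed window.

    ``local_baseline`` subtracts the chord joining the window-endpoint
    intensities first (for cubes that were not globally baseline-corrected).
    ``use_height`` replaces the integral by the maximum in-window intensity
    (above the chord when ``local_baseline``), a compatibility mode for
    peak-intensity imaging.
    """
    x = cube.axis.values
    if use_height:
        lo, hi = max(window.lo, float(x[0])), min(window.hi, float(x[-1]))
        if lo >= hi or int(np.sum((x >= lo) & (x <= hi))) < 2:
            raise ConfigError("window must intersect the axis in at least 2 channels")
        sel = (x >= lo) & (x <= hi)
        seg = cube.data[..., sel]
        if local_baseline:
            e_lo = cube.data @ _endpoint_functional(x, lo)
            e_hi = cube.data @ _endpoint_functional(x, hi)
            frac = (x[sel] - lo) / (hi - lo)
            chord = e_lo[..., None] + (e_hi - e_lo)[..., None] * frac
            seg = seg - chord
        values = seg.max(axis=-1)
    else:
        w = _window_weights(x, window, local_baseline)
        values = cube.data @ w
    return AreaMap(window=window, values=values, valid=cube.valid_mask().copy())


def peak_area(spectrum: Spectrum, window: PeakWindow, local_baseline: bool = False) -> float:
    """Band area of a single spectrum (same rule as :func:`integrate_peak`)."""
    w = _window_weights(spectrum.axis.values, window, local_baseline)
    return float(spectrum.intensity @ w)


# ---------------------------------------------------------------------------
# Ratio maps
# ---------------------------------------------------------------------------


def ratio_map(
    numerator: AreaMap, denominator: AreaMap, epsilon: Optional[float] = None
) -> RatioMap:
    """dA = A_numerator / A_denominator with a validity mask.

    Pixels are valid where both operand areas are valid and the denominator
    exceeds the floor ``epsilon`` (default ``1e-6 x max valid denominator``),
    which prevents ratio blow-up at near-empty pixels.  Negative areas
    (baseline over-subtraction) stay valid but are flagged in ``negative``.
    """
    if numerator.shape != denominator.shape:
        raise GridError(
            f"operand grids differ: {numerator.shape} vs {denominator.shape}"
        )
    den = denominator.values
    if epsilon is None:
        den_valid = den[denominator.valid]
        epsilon = 1e-6 * float(den_valid.max()) if den_valid.size else 0.0
    if epsilon < 0:
        raise ConfigError("epsilon must be >= 0")
    valid = numerator.valid & denominator.valid & (den > epsilon)
    values = np.full(numerator.shape, np.nan)
    values[valid] = numerator.values[valid] / den[valid]
    negative = valid & ((numerator.values < 0) | (den < 0))
    return RatioMap(
        numerator_window=numerator.window,
        denominator_window=denominator.window,
        values=values,
        valid=valid,
        negative=negative,
    )


# ---------------------------------------------------------------------------
# Internal-standard selection
# ---------------------------------------------------------------------------


def select_internal_standard(
    cube: HyperCube,
    candidates: Sequence[PeakWindow],
    cell_mask: Optional[np.ndarray] = None,
) -> tuple[PeakWindow, pd.DataFrame]:
    """Rank candidate bands by spatial coefficient of variation over the cell.

    A usable internal standard must be uniformly distributed and stable in
    content, so the candidate with the lowest CV = SD/mean of its area map
    over the cell mask is chosen (ties to the lower center wavenumber);
    candidates with non-positive mean area are disqualified.  Returns the
    chosen window and the ascending-CV ranking of qualified candidates.
    """
    if not candidates:
        raise SelectionError("no internal-standard candidates supplied")
    mask = cube.valid_mask() if cell_mask is None else (np.asarray(cell_mask, bool) & cube.valid_mask())
    if not mask.any():
        raise SelectionError("cell mask is empty")
    rows = []
    for window in candidates:
        amap = integrate_peak(cube, window)
        vals = amap.values[mask & amap.valid]
        mean = float(vals.mean())
        sd = float(vals.std())
        if mean <= 0:
            continue
        rows.append(
            {
                "label": window.label,
                "center": window.center,
                "half_width": window.half_width,
                "mean": mean,
                "sd": sd,
                "cv": sd / mean,
            }
        )
    if not rows:
        raise SelectionError("every internal-standard candidate was disqualified")
    ranking = pd.DataFrame(rows).sort_values(["cv", "center"], kind="stable").reset_index(drop=True)
    best = ranking.iloc[0]
    chosen = PeakWindow(float(best["center"]), float(best["half_width"]), str(best["label"]))
    return chosen, ranking


# ---------------------------------------------------------------------------
# Compartment statistics
# ---------------------------------------------------------------------------


def _label_array(labels) -> np.ndarray:
    if isinstance(labels, ClusterResult):
        return labels.labels
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return np.where(arr, 0, -1)
    return arr.astype(int)


def compartment_stats(
    ratio: RatioMap, labels, group_tag: str = "", clip_negative: bool = False
) -> pd.DataFrame:
    """Mean, SD and n of valid dA per compartment label.

    ``labels`` is a :class:`~ramanmqa.multivariate.ClusterResult`, an integer
    label map (-1 = unlabeled), or a boolean cell mask.  Invalid ratio pixels
    reduce n and never contribute; labels with zero valid pixels are omitted
    with a warning.  SD is the population SD (ddof=0), so SD = 0 exactly when
    all valid values in a compartment are equal.  ``group_tag`` (e.g. a
    treatment stage) is carried through for cross-group tables.
    """
    lab = _label_array(labels)
    if lab.shape != ratio.shape:
        raise GridError("label map does not align with the ratio grid")
    rows = []
    for value in np.unique(lab[lab >= 0]):
        sel = (lab == value) & ratio.valid
        if not sel.any():
            warnings.warn(f"label {value} has no valid pixels; row omitted", stacklevel=2)
            continue
        vals = ratio.values[sel]
        if clip_negative:
            vals = np.clip(vals, 0.0, None)
        rows.append(
            {
                "group": group_tag,
                "label": int(value),
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std()),
            }
        )
    return pd.DataFrame(rows, columns=["group", "label", "n", "mean", "sd"])


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary least squares of dA on concentration."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def fit_calibration(series: Sequence[tuple[float, float]]) -> CalibrationFit:
    """OLS fit ``dA = slope * concentration + intercept`` with R^2.

    Requires >= 3 points with >= 2 distinct concentrations.  R^2 is snapped
    to exactly 1.0 when the residual sum of squares is below 1e-12 of the
    total, so collinear input reports perfect linearity despite float
    round-off.
    """
    if len(series) < 3:
        raise FitError("calibration needs at least 3 points")
    x = np.asarray([c for c, _ in series], dtype=float)
    y = np.asarray([a for _, a in series], dtype=float)
    if np.unique(x).size < 2:
        raise FitError("calibration needs at least 2 distinct concentrations")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-24 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        if 1.0 - r2 < 1e-12:
            r2 = 1.0
    return CalibrationFit(float(slope), float(intercept), float(r2), int(x.size))


def calibration_delta_a(
    series: Sequence[tuple[float, Spectrum]],
    analyte_window: PeakWindow,
    is_window: PeakWindow = INTERNAL_STANDARD_WINDOW,
    local_baseline: bool = True,
) -> list[tuple[float, float]]:
    """Reduce a (concentration, spectrum) series to (concentration, dA) pairs.

    The chord-type local baseline is on by default because calibration
    spectra are typically used raw, without a global baseline pass.
    """
    out = []
    for conc, spec in series:
        a_num = peak_area(spec, analyte_window, local_baseline)
        a_den = peak_area(spec, is_window, local_baseline)
        if a_den == 0:
            raise FitError(f"internal-standard area is zero at concentration {conc}")
        out.append((float(conc), a_num / a_den))
    return out


# ---------------------------------------------------------------------------
# End-to-end quantification
# ---------------------------------------------------------------------------


@dataclass
class MqaConfig:
    """Configuration of the full semi-quantification workflow."""

    windows: dict[str, PeakWindow] = field(
        default_factory=lambda: dict(DEFAULT_METABOLITE_WINDOWS)
    )
    internal_standard: PeakWindow = INTERNAL_STANDARD_WINDOW
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    k: Optional[int] = 5
    k_range: tuple[int, int] = (2, 8)
    n_pcs: int = 10
    seed: int = 0
    local_baseline: bool = False
    use_peak_height: bool = False
    epsilon: Optional[float] = None
    clip_negative: bool = False
    group_tag: str = ""
    unmix_components: Optional[int] = None


@dataclass
class MqaResult:
    """Results bundle of :func:`run_mqa`."""

    cube: HyperCube
    cluster: ClusterResult
    internal_area: AreaMap
    areas: dict[str, AreaMap]
    ratios: dict[str, RatioMap]
    stats: pd.DataFrame
    provenance: dict
    unmix: Optional[object] = None
    silhouette_profile: Optional[dict[int, float]] = None


def run_mqa(cube: HyperCube, config: Optional[MqaConfig] = None) -> MqaResult:
    """Preprocess, compartmentalize and semi-quantify one hyperspectral cube.

    Pipeline: preprocessing stages -> k-means segmentation (k fixed or chosen
    by silhouette scan) -> optional unmixing -> band integration for the
    internal standard and every configured metabolite window -> dA ratio maps
    -> per-compartment statistics.  The returned ``stats`` table has one row
    per (metabolite, compartment) with columns group, compartment,
    metabolite, n, mean, sd.
    """
    config = config or MqaConfig()
    if not config.windows:
        raise UsageError("MqaConfig.windows must name at least one metabolite window")

    processed, prov = run_preprocess(cube, config.preprocess)

    silhouette_profile = None
    k = config.k
    if k is None:
        k, silhouette_profile = select_k(
            processed, range(config.k_range[0], config.k_range[1] + 1), config.seed, config.n_pcs
        )
    cluster = kmeans_cluster(processed, k, seed=config.seed, n_pcs=config.n_pcs)

    unmix = None
    if config.unmix_components is not None:
        unmix = true_component_analysis(processed, config.unmix_components, seed=config.seed)

    internal_area = integrate_peak(
        processed, config.internal_standard, config.local_baseline, config.use_peak_height
    )
    areas: dict[str, AreaMap] = {}
    ratios: dict[str, RatioMap] = {}
    tables = []
    for name, window in config.windows.items():
        amap = integrate_peak(processed, window, config.local_baseline, config.use_peak_height)
        rmap = ratio_map(amap, internal_area, config.epsilon)
        areas[name] = amap
        ratios[name] = rmap
        table = compartment_stats(rmap, cluster, config.group_tag, config.clip_negative)
        table.insert(2, "metabolite", name)
        tables.append(table)
    stats = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    stats = stats.rename(columns={"label": "compartment"})

    prov = dict(prov)
    prov.update(
        {
            "k": int(k),
            "n_pcs": config.n_pcs,
            "seed": config.seed,
            "internal_standard": {
                "center": config.internal_standard.center,
                "half_width": config.internal_standard.half_width,
                "label": config.internal_standard.label,
            },
            "windows": {
                name: {"center": w.center, "half_width": w.half_width}
                for name, w in config.windows.items()
            },
            "local_baseline": config.local_baseline,
            "use_peak_height": config.use_peak_height,
            "group_tag": config.group_tag,
        }
    )
    return MqaResult(
        cube=processed,
        cluster=cluster,
        internal_area=internal_area,
        areas=areas,
        ratios=ratios,
        stats=stats,
        provenance=prov,
        unmix=unmix,
        silhouette_profile=silhouette_profile,
    )
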
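"""Synthetic single-cell phantom generator with known ground truth.

Emulates a bacteriocyte — a gill epithelial cell hosting methanotrophic
endosymbionts — as imaged by confocal Raman microspectroscopy: an elliptical
cell on a 48x48 grid (450 nm pixel spacing) containing a nucleus disc at the
basal pole, small lipid-droplet discs near the nucleus, two symbiont zones
(strain A on the outer, apical side with elevated glycogen; strain B inward)
and cytoplasm elsewhere.

Per pixel the measured spectrum is

    gain(x, y) * sum_m conc_m(x, y) * ref_m  +  baseline  +  noise  +  spikes

where each reference spectrum ``ref_m`` is a sum of pseudo-Voigt bands at the
metabolite's library positions plus fixed "filler" background bands (shipped
in ``data/reference_bands.yaml``), the baseline is a smooth polynomial with a
spatially varying amplitude, and the noise is heteroscedastic Gaussian with
variance proportional to signal plus a floor (a continuous stand-in for shot
noise).  Cosmic-ray spikes are sparse single-channel additions.

Every cube is bit-reproducible from ``(parameters, seed)``: the seed spawns
four independent child streams drawn in the documented order gain -> baseline
field -> noise -> spikes, so e.g. disabling spikes never changes the noise.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import ndimage

from .core import HyperCube, Spectrum, WavenumberAxis
from .errors import ConfigError

__all__ = [
    "Band",
    "ReferenceSpectrum",
    "PhantomTruth",
    "default_axis",
    "load_band_table",
    "make_reference_spectrum",
    "reference_for",
    "make_cell_phantom",
    "make_desymbiosis_series",
    "make_calibration_series",
    "DEFAULT_CONCENTRATIONS",
    "DEFAULT_CALIBRATION_SNR",
    "COMPARTMENTS",
]

COMPARTMENTS = ("nucleus", "lipid_droplets", "symbiont_a", "symbiont_b", "cytoplasm")

#: Default compartment concentrations (arbitrary units).  Only ordinal
#: relations are meaningful: nucleus rich in deoxyribose; lipid droplets in
#: triglycerides / palmitoleic acid / cholesterol; symbionts in lanosterol and
#: squalene with strain A > strain B glycogen and NADH; cytoplasm in
#: phenylalanine / glucose / tryptophan.  The threonine internal standard is
#: spatially constant over the cell.
DEFAULT_CONCENTRATIONS: dict[str, dict[str, float]] = {
    #                 nucleus lipid  symA  symB  cyto
    "deoxyribose": dict(zip(COMPARTMENTS, (3.0, 0.25, 0.25, 0.25, 0.35))),
    "triglyceride": dict(zip(COMPARTMENTS, (0.2, 3.0, 0.2, 0.2, 0.3))),
    "palmitoleic_acid": dict(zip(COMPARTMENTS, (0.2, 2.5, 0.2, 0.2, 0.3))),
    "cholesterol": dict(zip(COMPARTMENTS, (0.35, 1.8, 0.3, 0.3, 0.5))),
    "phenylalanine": dict(zip(COMPARTMENTS, (0.8, 0.6, 0.5, 0.5, 1.5))),
    "lanosterol": dict(zip(COMPARTMENTS, (0.15, 0.2, 2.0, 1.8, 0.2))),
    "squalene": dict(zip(COMPARTMENTS, (0.15, 0.2, 2.2, 2.0, 0.2))),
    "glycogen": dict(zip(COMPARTMENTS, (0.3, 0.3, 2.8, 0.9, 0.4))),
    "nadh": dict(zip(COMPARTMENTS, (0.35, 0.35, 1.3, 0.75, 0.55))),
    "glucose": dict(zip(COMPARTMENTS, (0.55, 0.45, 0.8, 0.7, 1.0))),
    "tryptophan": dict(zip(COMPARTMENTS, (0.6, 0.5, 0.5, 0.5, 0.9))),
    "threonine": dict(zip(COMPARTMENTS, (1.0, 1.0, 1.0, 1.0, 1.0))),
}

#: Noise level of the simulated mock calibration series (mean-signal SNR).
#: Chosen by the documented replicate sweep (see docs/methods.md): the
#: noisiest level on the sweep grid {50, 100, 150, 200, 300, 500, 800} at
#: which >= 95 of 100 seeded replicates reach the linearity the mock
#: experiment demonstrates (R^2 >= 0.9998).
DEFAULT_CALIBRATION_SNR = 100.0

DEFAULT_CALIBRATION_CONCENTRATIONS = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)


def default_axis(start: float = 400.0, stop: float = 3100.0, step: float = 2.0) -> WavenumberAxis:
    """400-3100 cm^-1 at 2 cm^-1 spacing: covers every library band."""
    return WavenumberAxis(np.arange(start, stop + 0.5 * step, step))


# ---------------------------------------------------------------------------
# Reference spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Band:
    """One pseudo-Voigt band: center (cm^-1), amplitude, width sigma, mixing eta."""

    center: float
    amplitude: float = 1.0
    sigma: float = 2.5
    eta: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigError("band sigma must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ConfigError("band eta must lie in [0, 1]")


def pseudo_voigt(x: np.ndarray, band: Band) -> np.ndarray:
    """Pseudo-Voigt profile: (1 - eta) Gaussian + eta Lorentzian, shared width."""
    d2 = (np.asarray(x, dtype=float) - band.center) ** 2
    g = np.exp(-d2 / (2.0 * band.sigma**2))
    lor = band.sigma**2 / (d2 + band.sigma**2)
    return band.amplitude * ((1.0 - band.eta) * g + band.eta * lor)


@dataclass(frozen=True)
class ReferenceSpectrum:
    """A named metabolite reference rendered as a sum of pseudo-Voigt bands."""

    name: str
    bands: tuple[Band, ...]
    axis: WavenumberAxis
    intensity: np.ndarray

    def as_spectrum(self) -> Spectrum:
        return Spectrum(self.axis, self.intensity)


def make_reference_spectrum(
    bands: Sequence[Band], axis: WavenumberAxis, name: str = ""
) -> ReferenceSpectrum:
    """Render the sum of pseudo-Voigt profiles on ``axis`` (zero bands -> zero)."""
    intensity = np.zeros(len(axis))
    for band in bands:
        intensity += pseudo_voigt(axis.values, band)
    return ReferenceSpectrum(name, tuple(bands), axis, intensity)


def load_band_table() -> dict:
    """Parse the shipped reference band table (library + filler bands)."""
    text = (
        importlib.resources.files("ramanmqa").joinpath("data/reference_bands.yaml").read_text()
    )
    return yaml.safe_load(text)


def _bands_for(name: str, table: dict, include_filler: bool) -> list[Band]:
    shape = table.get("band_shape", {})
    sigma0 = float(shape.get("sigma", 2.5))
    eta0 = float(shape.get("eta", 0.1))
    try:
        spec = table["metabolites"][name]
    except KeyError as exc:
        raise ConfigError(f"unknown metabolite {name!r} in band table") from exc
    groups = [spec.get("bands", [])]
    if include_filler:
        groups.append(spec.get("filler", []))
    bands = []
    for group in groups:
        for b in group:
            bands.append(
                Band(
                    center=float(b["center"]),
                    amplitude=float(b.get("amplitude", 1.0)),
                    sigma=float(b.get("sigma", sigma0)),
                    eta=float(b.get("eta", eta0)),
                )
            )
    return bands


def reference_for(
    name: str, axis: Optional[WavenumberAxis] = None, include_filler: bool = True
) -> ReferenceSpectrum:
    """Reference spectrum of one metabolite from the shipped band table."""
    axis = axis if axis is not None else default_axis()
    return make_reference_spectrum(_bands_for(name, load_band_table(), include_filler), axis, name)


# ---------------------------------------------------------------------------
# Cell geometry
# ---------------------------------------------------------------------------


def _bacteriocyte_masks(shape: tuple[int, int], symbiont_fraction: float) -> dict[str, np.ndarray]:
    """Compartment masks on the pixel grid; disjoint, union = cell mask.

    Geometry is specified in grid fractions so any grid >= 16x16 works: the
    apical (outer) side is at low row indices, the basal pole with the nucleus
    at high row indices, mirroring the polarized bacteriocyte organization.
    """
    h, w = shape
    if h < 16 or w < 16:
        raise ConfigError("phantom grid must be at least 16x16")
    if not 0.0 <= symbiont_fraction <= 1.0:
        raise ConfigError("symbiont_fraction must lie in [0, 1]")
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    cell = ((rr - 0.50 * h) / (0.458 * h)) ** 2 + ((cc - 0.49 * w) / (0.396 * w)) ** 2 <= 1.0

    def disc(r0: float, c0: float, radius: float) -> np.ndarray:
        return (rr - r0 * h) ** 2 + (cc - c0 * w) ** 2 <= (radius * min(h, w)) ** 2

    nucleus = disc(0.73, 0.50, 0.135) & cell
    lipid = np.zeros_like(cell)
    for r0, c0 in ((0.583, 0.292), (0.604, 0.688), (0.8125, 0.3125)):
        lipid |= disc(r0, c0, 0.046)
    lipid &= cell & ~nucleus

    sym_zone = cell & ~nucleus & ~lipid & (rr <= 0.417 * h)
    sym_a = sym_zone & (rr <= 0.25 * h)
    sym_b = sym_zone & ~sym_a

    def shrink(mask: np.ndarray, frac: float) -> np.ndarray:
        # symbionts are lost from the inner (high-row) edge first
        idx = np.argwhere(mask)
        keep = int(round(frac * len(idx)))
        order = np.lexsort((idx[:, 1], idx[:, 0]))  # outermost rows first
        kept = idx[order][:keep]
        out = np.zeros_like(mask)
        out[kept[:, 0], kept[:, 1]] = True
        return out

    if symbiont_fraction < 1.0:
        sym_a = shrink(sym_a, symbiont_fraction)
        sym_b = shrink(sym_b, symbiont_fraction)
    cytoplasm = cell & ~nucleus & ~lipid & ~sym_a & ~sym_b
    return {
        "nucleus": nucleus,
        "lipid_droplets": lipid,
        "symbiont_a": sym_a,
        "symbiont_b": sym_b,
        "cytoplasm": cytoplasm,
    }


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, coarse: int = 6) -> np.ndarray:
    """Smooth zero-mean random field, unit-ish scale, via coarse-grid upsampling."""
    low = rng.standard_normal((coarse, coarse))
    zoom = (shape[0] / coarse, shape[1] / coarse)
    fld = ndimage.zoom(low, zoom, order=3)[: shape[0], : shape[1]]
    return fld / max(np.abs(fld).max(), 1e-12)


def _baseline_profile(axis: WavenumberAxis) -> np.ndarray:
    """Gentle fluorescence-like polynomial background, unit peak scale."""
    t = (axis.values - axis.values[0]) / (axis.values[-1] - axis.values[0])
    return 0.5 + 0.35 * t + 0.15 * t**2


def _noise_sigma(clean: np.ndarray, snr: float, ref_level: float) -> np.ndarray:
    """Heteroscedastic noise SD: variance ~ 0.8 signal + 0.2 floor, SNR at ref level."""
    if not np.isfinite(snr):
        return np.zeros_like(clean)
    rel = np.clip(clean, 0.0, None) / ref_level
    return (ref_level / snr) * np.sqrt(0.8 * rel + 0.2)


# ---------------------------------------------------------------------------
# Phantom truth
# ---------------------------------------------------------------------------


@dataclass
class PhantomTruth:
    """Everything needed to reconstruct a phantom's noiseless ground truth."""

    seed: int
    masks: dict[str, np.ndarray]
    cell_mask: np.ndarray
    concentrations: dict[str, np.ndarray]  # per-metabolite (H, W) fields
    reference_spectra: dict[str, np.ndarray]  # per-metabolite (C,) intensities
    axis: WavenumberAxis
    gain: np.ndarray  # (H, W) multiplicative gain field
    baseline_profile: np.ndarray  # (C,) spectral shape
    baseline_field: np.ndarray  # (H, W) amplitude field
    snr: float
    spikes: list[tuple[int, int, int, float]]  # (row, col, channel, amplitude)
    tag: str = ""

    def labels(self) -> np.ndarray:
        """Compartment label map: indices follow COMPARTMENTS, -1 outside."""
        lab = np.full(self.cell_mask.shape, -1, dtype=int)
        for i, name in enumerate(COMPARTMENTS):
            lab[self.masks[name]] = i
        return lab

    def mixture(self) -> np.ndarray:
        """Pure concentration-weighted mixture, no gain/baseline/noise."""
        names = list(self.concentrations)
        conc = np.stack([self.concentrations[n] for n in names])  # (M, H, W)
        refs = np.stack([self.reference_spectra[n] for n in names])  # (M, C)
        return np.einsum("mhw,mc->hwc", conc, refs)

    def clean(self) -> np.ndarray:
        """Noiseless, spike-free cube data (gain and baseline applied)."""
        return (
            self.gain[..., None] * self.mixture()
            + self.baseline_field[..., None] * self.baseline_profile
        )


def make_cell_phantom(
    shape: tuple[int, int] = (48, 48),
    snr: float = 30.0,
    seed: int = 0,
    *,
    concentrations: Optional[dict[str, dict[str, float]]] = None,
    concentration_multipliers: Optional[dict[str, float]] = None,
    symbiont_fraction: float = 1.0,
    baseline_amplitude: float = 0.3,
    gain_variation: float = 0.15,
    n_spikes: int = 6,
    spike_factor: tuple[float, float] = (30.0, 60.0),
    pixel_size_nm: float = 450.0,
    axis: Optional[WavenumberAxis] = None,
    tag: str = "",
) -> tuple[HyperCube, PhantomTruth]:
    """Generate one bacteriocyte phantom cube plus its ground truth.

    ``snr`` is the mean-signal signal-to-noise ratio inside the cell
    (``np.inf`` for a noiseless cube).  ``concentrations`` maps metabolite ->
    compartment -> level and defaults to :data:`DEFAULT_CONCENTRATIONS`;
    ``concentration_multipliers`` rescales whole metabolite fields (used by
    the de-symbiosis series).  Pixels outside the cell carry baseline and
    noise only and are masked invalid in the returned cube.
    """
    if snr <= 0:
        raise ConfigError("snr must be positive")
    axis = axis if axis is not None else default_axis()
    conc_table = concentrations if concentrations is not None else DEFAULT_CONCENTRATIONS
    table = load_band_table()
    refs: dict[str, np.ndarray] = {}
    for name in conc_table:
        refs[name] = make_reference_spectrum(_bands_for(name, table, True), axis, name).intensity

    masks = _bacteriocyte_masks(shape, symbiont_fraction)
    cell = np.zeros(shape, dtype=bool)
    for m in masks.values():
        cell |= m

    conc_fields: dict[str, np.ndarray] = {}
    for name, per_comp in conc_table.items():
        fld = np.zeros(shape)
        for comp, level in per_comp.items():
            if comp not in masks:
                raise ConfigError(f"unknown compartment {comp!r} for metabolite {name!r}")
            if level < 0:
                raise ConfigError("concentrations must be non-negative")
            fld[masks[comp]] = level
        if concentration_multipliers and name in concentration_multipliers:
            fld = fld * float(concentration_multipliers[name])
        conc_fields[name] = fld

    children = np.random.SeedSequence(seed).spawn(4)
    rng_gain, rng_base, rng_noise, rng_spike = (np.random.default_rng(s) for s in children)

    gain = 1.0 + gain_variation * _smooth_field(shape, rng_gain)
    gain = np.clip(gain, 0.3, None)
    profile = _baseline_profile(axis)
    base_field = baseline_amplitude * (1.0 + 0.2 * _smooth_field(shape, rng_base))

    truth = PhantomTruth(
        seed=seed,
        masks=masks,
        cell_mask=cell,
        concentrations=conc_fields,
        reference_spectra=refs,
        axis=axis,
        gain=gain,
        baseline_profile=profile,
        baseline_field=base_field,
        snr=snr,
        spikes=[],
        tag=tag,
    )

    clean = truth.clean()
    ref_level = float(clean[cell].mean()) if cell.any() else float(clean.mean())
    data = clean + _noise_sigma(clean, snr, max(ref_level, 1e-12)) * rng_noise.standard_normal(
        clean.shape
    )

    if n_spikes > 0:
        cell_idx = np.argwhere(cell)
        pick = rng_spike.choice(len(cell_idx), size=min(n_spikes, len(cell_idx)), replace=False)
        for i in pick:
            r, c = map(int, cell_idx[i])
            ch = int(rng_spike.integers(1, len(axis) - 1))
            amp = float(rng_spike.uniform(*spike_factor) * max(clean[r, c].mean(), 1e-12))
            data[r, c, ch] += amp
            truth.spikes.append((r, c, ch, amp))

    cube = HyperCube(axis, data, pixel_size_nm=pixel_size_nm, mask=cell.copy())
    return cube, truth


#: Per-stage multipliers emulating de-symbiosis: host sterol precursors lose
#: support as symbiont masks shrink while cholesterol, glucose and tryptophan
#: accumulate in the remaining cell.
DEFAULT_STAGE_MULTIPLIERS = (
    {},
    {"cholesterol": 1.6, "glucose": 1.3, "tryptophan": 1.25},
    {"cholesterol": 2.4, "glucose": 1.8, "tryptophan": 1.7},
)

DEFAULT_STAGE_TAGS = ("InS", "D4w", "D10w")


def make_desymbiosis_series(
    fractions: Sequence[float] = (1.0, 0.5, 0.1),
    multipliers: Optional[Sequence[dict[str, float]]] = None,
    snr: float = 30.0,
    seed: int = 0,
    tags: Optional[Sequence[str]] = None,
    **phantom_kwargs,
) -> list[tuple[HyperCube, PhantomTruth]]:
    """Phantom series with shrinking symbiont masks across stages.

    ``fractions`` are the surviving symbiont-pixel fractions per stage and
    must be non-increasing in [0, 1].  All stages share the root seed, so a
    stage with fraction 1 and unit multipliers reproduces
    :func:`make_cell_phantom` exactly.
    """
    fr = [float(f) for f in fractions]
    if any(not 0.0 <= f <= 1.0 for f in fr):
        raise ConfigError("fractions must lie in [0, 1]")
    if any(b > a for a, b in zip(fr, fr[1:])):
        raise ConfigError("fractions must be non-increasing")
    if multipliers is None:
        multipliers = (
            DEFAULT_STAGE_MULTIPLIERS if len(fr) == 3 else tuple({} for _ in fr)
        )
    if len(multipliers) != len(fr):
        raise ConfigError("one multiplier mapping required per stage")
    if tags is None:
        tags = DEFAULT_STAGE_TAGS if len(fr) == 3 else tuple(f"stage{i}" for i in range(len(fr)))
    out = []
    for f, mult, tag in zip(fr, multipliers, tags):
        out.append(
            make_cell_phantom(
                snr=snr,
                seed=seed,
                symbiont_fraction=f,
                concentration_multipliers=dict(mult) if mult else None,
                tag=tag,
                **phantom_kwargs,
            )
        )
    return out


def make_calibration_series(
    analyte: str = "glucose",
    concentrations: Sequence[float] = DEFAULT_CALIBRATION_CONCENTRATIONS,
    is_name: str = "threonine",
    is_concentration: float = 1.0,
    snr: float = DEFAULT_CALIBRATION_SNR,
    seed: int = 0,
    baseline_amplitude: float = 0.2,
    axis: Optional[WavenumberAxis] = None,
) -> tuple[list[tuple[float, Spectrum]], dict]:
    """Mock-sample dilution series: analyte varied, internal standard fixed.

    Each spectrum is ``c * ref_analyte + c_IS * ref_IS + baseline + noise``
    with the heteroscedastic noise model of the cell phantom.  Returns the
    ``(concentration, spectrum)`` pairs plus a truth record.
    """
    conc = [float(c) for c in concentrations]
    if len(conc) < 3:
        raise ConfigError("calibration series needs at least 3 concentrations")
    if snr <= 0:
        raise ConfigError("snr must be positive")
    axis = axis if axis is not None else default_axis()
    table = load_band_table()
    ref_a = make_reference_spectrum(_bands_for(analyte, table, True), axis, analyte).intensity
    ref_is = make_reference_spectrum(_bands_for(is_name, table, True), axis, is_name).intensity
    profile = baseline_amplitude * _baseline_profile(axis)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    series = []
    for c in conc:
        clean = c * ref_a + is_concentration * ref_is + profile
        ref_level = max(float(clean.mean()), 1e-12)
        noisy = clean + _noise_sigma(clean, snr, ref_level) * rng.standard_normal(clean.shape)
        series.append((c, Spectrum(axis, noisy)))
    truth = {
        "analyte": analyte,
        "internal_standard": is_name,
        "is_concentration": is_concentration,
        "concentrations": conc,
        "snr": snr,
        "seed": seed,
        "baseline_amplitude": baseline_amplitude,
    }
    return series, truth
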
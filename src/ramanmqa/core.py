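"""Domain containers and I/O for single-cell Raman hyperspectral data.

The central object is the :class:`HyperCube`: a ``height x width`` raster in
which every pixel holds a full Raman spectrum on one shared
:class:`WavenumberAxis`.  Band-imaging results live in :class:`AreaMap`
(integrated band area per pixel) and :class:`RatioMap` (area divided by the
internal-standard area, the dimensionless quantity written ``dA``).

Grid convention everywhere: 0-based, row-major ``(row, col)`` indices with the
origin at the top-left pixel.  Intensities are arbitrary detector units and
are never rescaled at I/O time; the internal-standard ratio is the only
normalization applied to quantities that leave the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .errors import AxisError, ConfigError, FormatError, GridError, UsageError

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "HyperCube",
    "PeakWindow",
    "AreaMap",
    "RatioMap",
    "read_cube",
    "write_cube",
    "export_map",
    "CLUSTER_PALETTE",
]

#: Composite-image palette: nucleus, lipid droplets, the two symbiont
#: phenotypes, cytoplasm.
CLUSTER_PALETTE: tuple[tuple[float, float, float], ...] = (
    (1.0, 0.0, 0.0),  # red
    (1.0, 1.0, 0.0),  # yellow
    (0.0, 0.8, 0.0),  # green
    (0.0, 1.0, 1.0),  # cyan
    (0.0, 0.0, 1.0),  # blue
)

_MIN_AXIS_LEN = 16


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing Raman-shift axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < _MIN_AXIS_LEN:
            raise AxisError(
                f"axis must be 1-D with >= {_MIN_AXIS_LEN} points, got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise AxisError("axis contains non-finite values")
        if not np.all(np.diff(vals) > 0):
            raise AxisError("axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    def shifted(self, offset: float) -> "WavenumberAxis":
        """Return a rigidly shifted copy (``values + offset``)."""
        return WavenumberAxis(self.values + float(offset))


@dataclass(frozen=True)
class Spectrum:
    """One spectrum: intensity per axis channel, arbitrary units."""

    axis: WavenumberAxis
    intensity: np.ndarray

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "intensity", inten)
        if inten.shape != (len(self.axis),):
            raise AxisError(
                f"intensity length {inten.shape} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(inten)):
            raise FormatError("spectrum contains non-finite intensities")


@dataclass
class HyperCube:
    """Raster of spectra sharing one wavenumber axis.

    ``data`` has shape ``(height, width, channels)``; ``mask`` is a boolean
    ``(height, width)`` array where ``True`` marks a valid pixel (``None``
    means all pixels valid).  ``pixel_size_nm`` is the scan step size.
    """

    axis: WavenumberAxis
    data: np.ndarray
    pixel_size_nm: float = 450.0
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise GridError(f"cube data must be 3-D (row, col, channel), got {self.data.shape}")
        if self.data.shape[2] != len(self.axis):
            raise AxisError(
                f"cube has {self.data.shape[2]} channels but axis has {len(self.axis)}"
            )
        if self.pixel_size_nm <= 0:
            raise ConfigError("pixel_size_nm must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise GridError("mask shape does not match pixel grid")
        finite = np.isfinite(self.data)
        if not finite.all():
            bad = ~finite.all(axis=2)
            if self.mask is None or (bad & self.mask).any():
                raise FormatError("cube contains non-finite intensities at unmasked pixels")

    @property
    def height(self) -> int:
        return int(self.data.shape[0])

    @property
    def width(self) -> int:
        return int(self.data.shape[1])

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[2])

    def valid_mask(self) -> np.ndarray:
        """Boolean (height, width) validity, materializing ``mask=None``."""
        if self.mask is None:
            return np.ones(self.data.shape[:2], dtype=bool)
        return self.mask

    def spectrum_at(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.axis, self.data[row, col])

    def with_data(self, data: np.ndarray, axis: Optional[WavenumberAxis] = None) -> "HyperCube":
        """Copy carrying new intensities (and optionally a new axis)."""
        return HyperCube(
            axis=axis if axis is not None else self.axis,
            data=data,
            pixel_size_nm=self.pixel_size_nm,
            mask=None if self.mask is None else self.mask.copy(),
        )


@dataclass(frozen=True)
class PeakWindow:
    """Closed integration window ``[center - half_width, center + half_width]``.

    Default half-width is 8 cm^-1, the band tolerance used throughout.
    """

    center: float
    half_width: float = 8.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ConfigError("half_width must be positive")

    @property
    def lo(self) -> float:
        return self.center - self.half_width

    @property
    def hi(self) -> float:
        return self.center + self.half_width

    def overlaps(self, other: "PeakWindow") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi


@dataclass
class AreaMap:
    """Per-pixel integrated band area (arbitrary units x cm^-1)."""

    window: PeakWindow
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 2 or self.valid.shape != self.values.shape:
            raise GridError("AreaMap values/valid must be matching 2-D arrays")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class RatioMap:
    """Per-pixel dA = A_metabolite / A_internal_standard (dimensionless).

    ``negative`` flags pixels where either operand area was negative
    (baseline over-subtraction); such pixels stay valid but are reported.
    """

    numerator_window: PeakWindow
    denominator_window: PeakWindow
    values: np.ndarray
    valid: np.ndarray
    negative: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 2 or self.valid.shape != self.values.shape:
            raise GridError("RatioMap values/valid must be matching 2-D arrays")
        if self.negative is not None:
            self.negative = np.asarray(self.negative, dtype=bool)
            if self.negative.shape != self.values.shape:
                raise GridError("RatioMap negative-flag shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Cube I/O
# ---------------------------------------------------------------------------

_DIALECTS = ("long_csv", "wide_csv", "container")


def _apply_nonfinite_policy(data: np.ndarray, mask: Optional[np.ndarray], on_nonfinite: str):
    finite = np.isfinite(data).all(axis=2)
    if finite.all():
        return data, mask
    if on_nonfinite == "error":
        bad = np.argwhere(~finite)[0]
        raise FormatError(
            f"non-finite intensity at pixel (row={bad[0]}, col={bad[1]}); "
            "pass on_nonfinite='mask' to mask such pixels instead"
        )
    if on_nonfinite == "mask":
        mask = finite.copy() if mask is None else (mask & finite)
        data = data.copy()
        data[~finite] = 0.0
        return data, mask
    raise UsageError(f"unknown non-finite policy {on_nonfinite!r} (use 'error' or 'mask')")


def read_cube(path, dialect: str = "container", on_nonfinite: str = "error") -> HyperCube:
    """Read a :class:`HyperCube` from one of the documented dialects.

    ``long_csv``: columns ``row,col,wavenumber,intensity``.
    ``wide_csv``: first column ``wavenumber``, one column ``px_<row>_<col>``
    per pixel.  ``container``: HDF5 with ``/axis``, ``/cube`` and optional
    ``/mask`` datasets.  ``on_nonfinite`` chooses whether NaN/Inf intensities
    abort the read (``"error"``, default) or mask the affected pixel
    (``"mask"``).
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise UsageError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if dialect == "container":
        return _read_container(path, on_nonfinite)
    if dialect == "long_csv":
        return _read_long_csv(path, on_nonfinite)
    return _read_wide_csv(path, on_nonfinite)


def _read_container(path: Path, on_nonfinite: str) -> HyperCube:
    with h5py.File(path, "r") as f:
        for name in ("axis", "cube"):
            if name not in f:
                raise FormatError(f"container missing required dataset '/{name}'")
        axis = np.asarray(f["axis"], dtype=float)
        data = np.asarray(f["cube"], dtype=np.float32).astype(float)
        mask = np.asarray(f["mask"], dtype=bool) if "mask" in f else None
        pixel_size = float(f.attrs.get("pixel_size_nm", 450.0))
    data, mask = _apply_nonfinite_policy(data, mask, on_nonfinite)
    return HyperCube(WavenumberAxis(axis), data, pixel_size_nm=pixel_size, mask=mask)


def _read_long_csv(path: Path, on_nonfinite: str) -> HyperCube:
    df = pd.read_csv(path)
    required = ["row", "col", "wavenumber", "intensity"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"long_csv is missing required column '{col}'")
    axis_vals = np.sort(df["wavenumber"].unique())
    height = int(df["row"].max()) + 1
    width = int(df["col"].max()) + 1
    n_chan = axis_vals.size
    if len(df) != height * width * n_chan:
        raise FormatError(
            f"long_csv has {len(df)} rows; expected {height}x{width}x{n_chan} complete grid"
        )
    order = np.lexsort((df["wavenumber"].values, df["col"].values, df["row"].values))
    data = df["intensity"].values[order].reshape(height, width, n_chan)
    data, mask = _apply_nonfinite_policy(np.asarray(data, dtype=float), None, on_nonfinite)
    return HyperCube(WavenumberAxis(axis_vals), data, mask=mask)


def _read_wide_csv(path: Path, on_nonfinite: str) -> HyperCube:
    df = pd.read_csv(path)
    if df.columns[0] != "wavenumber":
        raise FormatError(
            f"wide_csv first column must be 'wavenumber', got {df.columns[0]!r}"
        )
    axis_vals = df["wavenumber"].values.astype(float)
    if not np.all(np.diff(axis_vals) > 0):
        raise AxisError("wide_csv wavenumber column is not strictly increasing")
    pixels = []
    for name in df.columns[1:]:
        parts = name.split("_")
        if len(parts) != 3 or parts[0] != "px":
            raise FormatError(f"wide_csv pixel column {name!r} is not of the form px_<row>_<col>")
        try:
            pixels.append((int(parts[1]), int(parts[2]), name))
        except ValueError as exc:
            raise FormatError(f"wide_csv pixel column {name!r} has non-integer indices") from exc
    height = max(r for r, _, _ in pixels) + 1
    width = max(c for _, c, _ in pixels) + 1
    if len(pixels) != height * width:
        raise FormatError("wide_csv pixel columns do not form a complete grid")
    data = np.empty((height, width, axis_vals.size), dtype=float)
    for r, c, name in pixels:
        data[r, c] = df[name].values
    data, mask = _apply_nonfinite_policy(data, None, on_nonfinite)
    return HyperCube(WavenumberAxis(axis_vals), data, mask=mask)


def write_cube(cube: HyperCube, path, dialect: str = "container") -> Path:
    """Write ``cube`` in the requested dialect; returns the path written.

    Container storage uses float32 intensities; text dialects use 17
    significant digits so a read-back round-trips within 1e-9 relative.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise UsageError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if path.is_dir():
        raise IOError(f"target path is a directory: {path}")
    if not path.parent.exists():
        raise IOError(f"target directory does not exist: {path.parent}")
    if dialect == "container":
        with h5py.File(path, "w") as f:
            f.create_dataset("axis", data=cube.axis.values.astype(np.float64))
            f.create_dataset("cube", data=cube.data.astype(np.float32))
            if cube.mask is not None:
                f.create_dataset("mask", data=cube.mask.astype(np.uint8))
            f.attrs["pixel_size_nm"] = float(cube.pixel_size_nm)
        return path
    if dialect == "long_csv":
        h, w, n = cube.data.shape
        rows = np.repeat(np.arange(h), w * n)
        cols = np.tile(np.repeat(np.arange(w), n), h)
        wn = np.tile(cube.axis.values, h * w)
        df = pd.DataFrame(
            {"row": rows, "col": cols, "wavenumber": wn, "intensity": cube.data.ravel()}
        )
        df.to_csv(path, index=False, float_format="%.17g")
        return path
    # wide_csv
    h, w, _ = cube.data.shape
    out = {"wavenumber": cube.axis.values}
    for r in range(h):
        for c in range(w):
            out[f"px_{r}_{c}"] = cube.data[r, c]
    pd.DataFrame(out).to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Map export
# ---------------------------------------------------------------------------


def export_map(map_obj, path, format: str = "tiff", cmap: str = "inferno") -> Path:
    """Export an :class:`AreaMap`, :class:`RatioMap` or integer label map.

    ``tiff`` writes lossless 32-bit float (invalid pixels as NaN; label maps
    as int32 with -1 invalid).  ``png`` writes an 8-bit heatmap with invalid
    pixels transparent and a JSON sidecar recording the color scale; label
    maps use the red/yellow/green/cyan/blue compartment palette.  ``csv`` is
    lossless (full float precision, invalid pixels empty).
    """
    import matplotlib

    matplotlib.use("Agg")
    import tifffile

    path = Path(path)
    if format not in ("tiff", "png", "csv"):
        raise UsageError(f"unsupported export format {format!r} (tiff, png or csv)")

    if isinstance(map_obj, (AreaMap, RatioMap)):
        values, valid = map_obj.values, map_obj.valid
        is_labels = False
    else:
        values = np.asarray(map_obj)
        if values.ndim != 2:
            raise GridError("label map must be 2-D")
        is_labels = np.issubdtype(values.dtype, np.integer)
        valid = values >= 0 if is_labels else np.isfinite(values)

    if format == "tiff":
        if is_labels:
            tifffile.imwrite(path, values.astype(np.int32))
        else:
            out = values.astype(np.float32).copy()
            out[~valid] = np.nan
            tifffile.imwrite(path, out)
        return path

    if format == "csv":
        out = values.astype(float).copy()
        out[~valid] = np.nan
        pd.DataFrame(out).to_csv(path, index=False, header=False, float_format="%.17g")
        return path

    # png
    import matplotlib.image as mimg

    h, w = values.shape
    rgba = np.zeros((h, w, 4), dtype=float)
    sidecar: dict = {"shape": [h, w]}
    if is_labels:
        labels = values
        k = int(labels[valid].max()) + 1 if valid.any() else 0
        palette = list(CLUSTER_PALETTE)
        while len(palette) < k:  # extend deterministically past 5 clusters
            cyc = matplotlib.colormaps["tab10"](len(palette) % 10)
            palette.append(tuple(cyc[:3]))
        for lab in range(k):
            sel = valid & (labels == lab)
            rgba[sel, :3] = palette[lab]
            rgba[sel, 3] = 1.0
        sidecar.update({"kind": "labels", "palette": [list(p) for p in palette[:k]]})
    else:
        vmin = float(np.nanmin(values[valid])) if valid.any() else 0.0
        vmax = float(np.nanmax(values[valid])) if valid.any() else 1.0
        span = vmax - vmin if vmax > vmin else 1.0
        norm = np.clip((values - vmin) / span, 0.0, 1.0)
        colors = matplotlib.colormaps[cmap](norm)
        rgba[valid] = colors[valid]
        rgba[valid, 3] = 1.0
        sidecar.update({"kind": "heatmap", "cmap": cmap, "vmin": vmin, "vmax": vmax})
    mimg.imsave(path, rgba)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path
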
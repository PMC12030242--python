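"""Multiband raster containers, I/O, vegetation masking and ROI statistics.

The imaging model is a six-channel multispectral frame camera: blue (450 nm),
green (555 nm), red (660 nm), two red-edge channels (720 and 750 nm) and
near-infrared (840 nm).  Reflectance is dimensionless in [0, 1].  Rasters are
stored as plain multiband TIFF (one page per band, float32, band name in the
page description); masks as single-page uint8 TIFF with 1 = vegetation.

Pixel convention is row-major with 0-based (row, col) indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import EmptyROIError, FormatError

__all__ = [
    "BandInfo",
    "DEFAULT_BANDS",
    "BAND_NAMES",
    "MultispectralImage",
    "ReflectanceRecord",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "vegetation_mask",
    "plot_mean_reflectance",
]


@dataclass(frozen=True)
class BandInfo:
    """One spectral channel of the camera."""

    index: int  # 1-based band number
    name: str
    center_nm: float
    bandwidth_nm: float


#: Camera band set: center wavelength / bandwidth in nm.
DEFAULT_BANDS: tuple[BandInfo, ...] = (
    BandInfo(1, "B", 450.0, 35.0),
    BandInfo(2, "G", 555.0, 25.0),
    BandInfo(3, "R", 660.0, 20.0),
    BandInfo(4, "RE1", 720.0, 10.0),
    BandInfo(5, "RE2", 750.0, 15.0),
    BandInfo(6, "NIR", 840.0, 35.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)

#: Band descriptions written to / expected in TIFF pages.
_TIFF_DESCRIPTIONS = ("B450", "G555", "R660", "RE720", "RE750", "NIR840")

N_BANDS = 6


@dataclass
class MultispectralImage:
    """Reflectance raster of shape (rows, cols, 6) with band metadata."""

    data: np.ndarray
    bands: tuple[BandInfo, ...] = field(default=DEFAULT_BANDS)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.shape[2] != N_BANDS:
            raise FormatError(
                f"expected (rows, cols, {N_BANDS}) array, got {self.data.shape}"
            )
        if len(self.bands) != N_BANDS:
            raise FormatError(f"expected {N_BANDS} band descriptors")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("non-finite reflectance values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def band(self, name: str) -> np.ndarray:
        """Return one band as a 2-D array by its short name (e.g. 'NIR')."""
        for i, b in enumerate(self.bands):
            if b.name == name:
                return self.data[:, :, i]
        raise KeyError(name)


@dataclass
class ReflectanceRecord:
    """Plot-mean reflectance per band, the input of vegetation indices."""

    plot_id: str
    R_B: float
    R_G: float
    R_RED: float
    R_RE1: float
    R_RE2: float
    R_NIR: float

    def as_dict(self) -> dict[str, float]:
        return {
            "R_B": self.R_B,
            "R_G": self.R_G,
            "R_RED": self.R_RED,
            "R_RE1": self.R_RE1,
            "R_RE2": self.R_RE2,
            "R_NIR": self.R_NIR,
        }


def write_image(image: MultispectralImage, path) -> None:
    """Write a six-band image as multipage float32 TIFF, one page per band."""
    with tifffile.TiffWriter(path) as tw:
        for i in range(N_BANDS):
            tw.write(
                image.data[:, :, i].astype(np.float32),
                description=_TIFF_DESCRIPTIONS[i],
                contiguous=False,
            )


def read_image(path) -> MultispectralImage:
    """Read a six-band multipage TIFF written by :func:`write_image`.

    Raises :class:`FormatError` if the file does not contain exactly six
    single-channel pages.
    """
    with tifffile.TiffFile(path) as tf:
        pages = tf.pages
        if len(pages) != N_BANDS:
            raise FormatError(f"{path}: expected {N_BANDS} bands, found {len(pages)}")
        arrs = [p.asarray() for p in pages]
    for a in arrs:
        if a.ndim != 2:
            raise FormatError(f"{path}: band pages must be single-channel")
    data = np.stack(arrs, axis=-1).astype(np.float32)
    return MultispectralImage(data)


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def vegetation_mask(
    image: MultispectralImage,
    method: str = "ndvi-threshold",
    threshold: float = 0.3,
    provided: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean vegetation raster separating canopy from soil/shadow.

    ``method='ndvi-threshold'`` keeps pixels with NDVI = (NIR−R)/(NIR+R)
    above ``threshold`` (default 0.3); ``method='provided-mask'`` passes a
    ground-truth mask through unchanged.
    """
    if method == "provided-mask":
        if provided is None:
            raise ValueError("provided-mask method requires a mask")
        provided = np.asarray(provided, dtype=bool)
        if provided.shape != image.shape:
            raise FormatError("mask shape does not match image shape")
        return provided
    if method != "ndvi-threshold":
        raise ValueError(f"unknown masking method {method!r}")
    nir = image.band("NIR").astype(np.float64)
    red = image.band("R").astype(np.float64)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / denom, 0.0)
    return ndvi > threshold


def plot_mean_reflectance(
    image: MultispectralImage, mask: np.ndarray, plot_id: str = ""
) -> ReflectanceRecord:
    """Arithmetic per-band mean over the masked (vegetation) pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise FormatError("mask shape does not match image shape")
    if not mask.any():
        raise EmptyROIError("vegetation mask is empty")
    means = image.data[mask].mean(axis=0, dtype=np.float64)
    return ReflectanceRecord(plot_id, *[float(m) for m in means])
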
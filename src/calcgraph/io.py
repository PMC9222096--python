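"""Reading, writing and segmenting mammographic images.

Coordinate convention used throughout the package: ``(x, y)`` means
``(column, row)``, 0-based, origin at the top-left corner.  A point ``(x, y)``
therefore indexes ``pixels[y, x]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .exceptions import DegenerateInputError, FormatError

CLASS_NAMES = ("diffuse", "regional", "grouped", "linear", "segmental")


@dataclass
class MammogramImage:
    """A single-frame grayscale mammogram.

    ``pixels`` holds raw stored intensities for integer formats or values in
    ``[0, 1]`` for float data; higher always means brighter (MONOCHROME1 DICOM
    data is inverted on read).
    """

    pixels: np.ndarray
    pixel_spacing: float | None = None
    view: str | None = None
    laterality: str | None = None
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError("pixels must be a non-empty 2D array, got shape "
                              f"{self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise FormatError("pixel intensities must be non-negative")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class BreastMask:
    """Boolean breast-region mask aligned with its image."""

    mask: np.ndarray
    area_fraction: float = field(init=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise FormatError("mask must be 2D")
        self.area_fraction = float(self.mask.mean())


@dataclass
class RoiAnnotation:
    """A labeled region of interest: circle or polygon, pixel coordinates."""

    geometry: dict
    label: str
    image_id: str

    def __post_init__(self):
        if self.label not in CLASS_NAMES:
            raise FormatError(f"label {self.label!r} not one of {CLASS_NAMES}")
        gtype = self.geometry.get("type")
        if gtype not in ("circle", "polygon"):
            raise FormatError(f"unsupported geometry type {gtype!r}")

    def contains(self, x, y):
        if self.geometry["type"] == "circle":
            cx, cy = self.geometry["center"]
            return (x - cx) ** 2 + (y - cy) ** 2 <= self.geometry["radius"] ** 2
        from matplotlib.path import Path as MplPath

        return bool(MplPath(self.geometry["vertices"]).contains_point((x, y)))


def load_annotations(path):
    """Read a JSON list of ``{image_id, geometry, label}`` records."""
    with open(path) as fh:
        records = json.load(fh)
    return [RoiAnnotation(r["geometry"], r["label"], r["image_id"]) for r in records]


def save_annotations(annotations, path):
    records = [
        {"image_id": a.image_id, "geometry": a.geometry, "label": a.label}
        for a in annotations
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


# ---------------------------------------------------------------------------
# image I/O


def _infer_format(path):
    suffix = Path(path).suffix.lower()
    if suffix == ".png":
        return "png"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".dcm", ".dicom"):
        return "dicom"
    raise FormatError(f"cannot infer image format from suffix {suffix!r}")


def read_image(path, fmt=None):
    """Read a single-frame grayscale PNG/TIFF/DICOM mammogram.

    Integer intensities are preserved losslessly.  DICOM images stored as
    MONOCHROME1 (higher = darker) are inverted to ``max_stored - p`` so that
    higher always means brighter.  Color or multi-frame inputs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = fmt or _infer_format(path)
    if fmt == "png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    elif fmt == "tiff":
        import tifffile

        arr = tifffile.imread(path)
    elif fmt == "dicom":
        return _read_dicom(path)
    else:
        raise FormatError(f"unsupported format {fmt!r}")
    if arr.ndim != 2:
        raise FormatError(
            f"expected single-frame grayscale image, got array of shape {arr.shape}")
    return MammogramImage(pixels=arr, source_id=path.stem)


def _read_dicom(path):
    import pydicom

    ds = pydicom.dcmread(path)
    nframes = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if nframes != 1:
        raise FormatError(f"multi-frame DICOM (NumberOfFrames={nframes}) not supported")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise FormatError("color DICOM (SamplesPerPixel>1) not supported")
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise FormatError(f"expected 2D pixel data, got shape {arr.shape}")
    if str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2")) == "MONOCHROME1":
        max_stored = (1 << int(ds.BitsStored)) - 1
        arr = max_stored - arr.astype(np.int64)
    spacing = None
    if getattr(ds, "PixelSpacing", None):
        spacing = float(ds.PixelSpacing[0])
    elif getattr(ds, "ImagerPixelSpacing", None):
        spacing = float(ds.ImagerPixelSpacing[0])
    return MammogramImage(
        pixels=arr,
        pixel_spacing=spacing,
        view=str(getattr(ds, "ViewPosition", "")) or None,
        laterality=str(getattr(ds, "ImageLaterality", "")) or None,
        source_id=str(getattr(ds, "SOPInstanceUID", path.stem)),
    )


def write_image(image, path, fmt=None):
    """Write pixels to PNG (8/16-bit) or TIFF; lossless for integer dtypes.

    Float images in [0, 1] are scaled to 16-bit for PNG and stored natively
    for TIFF.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    arr = image.pixels if isinstance(image, MammogramImage) else np.asarray(image)
    if fmt == "png":
        import imageio.v3 as iio

        if np.issubdtype(arr.dtype, np.floating):
            arr = np.round(np.clip(arr, 0, 1) * 65535).astype(np.uint16)
        iio.imwrite(path, arr)
    elif fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        raise FormatError(f"unsupported output format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# breast segmentation


def segment_breast(image, border_margin=2):
    """Segment the breast by global Otsu thresholding.

    The threshold is computed on the full-image histogram at native bit
    depth; post-processing keeps the largest 8-connected foreground
    component and fills its holes.  A strip of ``border_margin`` pixels
    along each image edge is cleared first so thin border artifacts
    (film edges, labels) cannot seed the component.
    """
    pixels = image.pixels if isinstance(image, MammogramImage) else np.asarray(image)
    if np.unique(pixels).size < 2:
        raise DegenerateInputError("Otsu threshold undefined on a constant image")
    thresh = threshold_otsu(pixels)
    fg = pixels > thresh
    if border_margin > 0:
        fg[:border_margin, :] = False
        fg[-border_margin:, :] = False
        fg[:, :border_margin] = False
        fg[:, -border_margin:] = False
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise DegenerateInputError("no foreground component above Otsu threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    return BreastMask(mask=mask)
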
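"""Volume loading and the slice preprocessing chain for classification.

The chain mirrors standard practice for desktop micro-CT scans of
specimen-in-holder assemblies: segment the bone with Otsu's threshold,
drop disconnected artifacts by keeping the largest 3D connected
component, crop every slice to the volume-level bounding box of the bone,
min–max normalize per volume to [0, 1] and resize to 384×384 with linear
interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .volume import ImageVolume

TARGET_SIZE = 384

_STACK_EXTS = {".bmp", ".png", ".tif", ".tiff"}


@dataclass
class PreparedSlice:
    """One classifier-ready slice: 384×384 pixels in [0, 1]."""

    pixels: np.ndarray
    source_index: int
    z_mm: float

    def __post_init__(self):
        if self.pixels.shape != (TARGET_SIZE, TARGET_SIZE):
            raise ValueError(f"prepared slice must be {TARGET_SIZE}x{TARGET_SIZE}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("prepared slice values must lie in [0,1]")


# --------------------------------------------------------------------------
# readers
# --------------------------------------------------------------------------

def read_volume(path: str | Path, voxel_size_mm: float | None = None,
                fmt: str | None = None) -> ImageVolume:
    """Read a micro-CT volume from a slice directory or a single file.

    Supported inputs: a directory of BMP/PNG/TIFF slices (stacked in
    lexicographic filename order, proximal first), a multipage TIFF, a
    MetaImage ``.mhd`` or a NIfTI ``.nii``/``.nii.gz``.  ``voxel_size_mm``
    is required for formats without spacing metadata (slice stacks and
    plain TIFFs); MetaImage/NIfTI spacing is read from the header when not
    overridden.  Intensities are returned as read, without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffix = path.suffix.lower()
    fmt = fmt or ("stack" if path.is_dir() else suffix.lstrip("."))

    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _STACK_EXTS)
        if not files:
            raise ValueError(f"no image slices found in {path}")
        slices = []
        shape = None
        for f in files:
            img = np.asarray(iio.imread(f))
            if img.ndim == 3:  # collapse RGB(A)
                img = img[..., 0]
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(
                    f"slice {f.name} has shape {img.shape}, expected {shape}"
                )
            slices.append(img)
        if voxel_size_mm is None:
            raise ValueError("voxel_size_mm required for slice stacks")
        return ImageVolume(np.stack(slices), voxel_size_mm)

    if suffix in {".tif", ".tiff"}:
        data = tifffile.imread(path)
        if data.ndim != 3:
            raise ValueError(f"expected a multipage TIFF, got shape {data.shape}")
        if voxel_size_mm is None:
            raise ValueError("voxel_size_mm required for TIFF volumes")
        return ImageVolume(data, voxel_size_mm)

    if suffix == ".mhd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        if voxel_size_mm is None:
            sp = img.GetSpacing()
            if not np.allclose(sp, sp[0]):
                raise ValueError(f"anisotropic spacing {sp}; pass voxel_size_mm")
            voxel_size_mm = float(sp[0])
        return ImageVolume(data, voxel_size_mm)

    if suffix == ".gz" or suffix == ".nii":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj).T  # (x,y,z) → (z,y,x)
        if voxel_size_mm is None:
            zooms = img.header.get_zooms()[:3]
            if not np.allclose(zooms, zooms[0]):
                raise ValueError(f"anisotropic spacing {zooms}; pass voxel_size_mm")
            voxel_size_mm = float(zooms[0])
        return ImageVolume(data, voxel_size_mm)

    raise ValueError(f"unknown volume format: {path}")


def write_volume(path: str | Path, volume: ImageVolume) -> None:
    """Write a volume as multipage TIFF or MetaImage (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, volume.intensities)
    elif path.suffix.lower() == ".mhd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(volume.intensities)
        img.SetSpacing([volume.voxel_size_mm] * 3)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported output format: {path.suffix}")


# --------------------------------------------------------------------------
# segmentation chain
# --------------------------------------------------------------------------

def otsu_threshold(image: np.ndarray) -> np.ndarray:
    """Binary foreground mask by Otsu's method on a 256-bin histogram.

    The threshold maximizes the between-class variance over an exhaustive
    scan of the 256 candidate bin edges; ties break toward the lower
    threshold.  Foreground = values strictly above the threshold.
    """
    image = np.asarray(image)
    vals = image.ravel()
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        raise ValueError("constant image: no Otsu threshold exists")
    hist, edges = np.histogram(vals, bins=256, range=(lo, hi))
    sums, _ = np.histogram(vals, bins=256, range=(lo, hi),
                           weights=vals.astype(float))
    p = hist.astype(float) / hist.sum()
    omega = np.cumsum(p)
    # exact per-bin value sums (not bin centers) so that on integer images
    # the variance scan coincides with the exhaustive integer-threshold scan
    mu = np.cumsum(sums / vals.size)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer
    # foreground: strictly above every value assigned to bins <= k
    return image >= edges[k + 1]


def largest_component(mask: np.ndarray, connectivity: int | None = None) -> np.ndarray:
    """Keep only the largest connected component of a binary mask.

    Default connectivity is full (26 in 3D, 8 in 2D).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask has no largest component")
    if connectivity is None:
        structure = np.ones((3,) * mask.ndim, dtype=int)
    else:
        structure = ndimage.generate_binary_structure(mask.ndim, connectivity)
    lab, nlab = ndimage.label(mask, structure=structure)
    if nlab == 1:
        return mask
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, nlab + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def segment_bone(volume: ImageVolume) -> np.ndarray:
    """Otsu threshold + largest 3D component: the bone mask of a scan."""
    return largest_component(otsu_threshold(volume.intensities))


def bounding_box(mask: np.ndarray) -> tuple[slice, slice, slice]:
    """Volume-level 3D bounding box of a mask as index slices."""
    if not np.asarray(mask).any():
        raise ValueError("cannot bound an empty mask")
    out = []
    for ax in range(3):
        proj = np.any(mask, axis=tuple(i for i in range(3) if i != ax))
        idx = np.where(proj)[0]
        out.append(slice(int(idx[0]), int(idx[-1]) + 1))
    return tuple(out)


def prepare_slices(volume: ImageVolume, mask: np.ndarray | None = None,
                   pad_square: bool = False) -> list[PreparedSlice]:
    """Produce classifier-ready slices from a volume.

    Crops every slice to the volume-level bounding box of the bone mask
    (so slice geometry is mutually consistent), min–max normalizes per
    volume to [0, 1], and resizes to 384×384 with linear interpolation.
    Non-square crops are resized anisotropically by default; set
    ``pad_square=True`` to zero-pad to a square before resizing instead.
    """
    if mask is None:
        mask = segment_bone(volume)
    box = bounding_box(mask)
    cropped = volume.intensities[box].astype(np.float64)
    lo, hi = cropped.min(), cropped.max()
    if hi > lo:
        cropped = (cropped - lo) / (hi - lo)
    else:
        warnings.warn("degenerate normalization: crop is constant, emitting zeros")
        cropped = np.zeros_like(cropped)

    z_offset = box[0].start
    out = []
    for i in range(cropped.shape[0]):
        sl = cropped[i]
        if pad_square and sl.shape[0] != sl.shape[1]:
            side = max(sl.shape)
            padded = np.zeros((side, side))
            oy = (side - sl.shape[0]) // 2
            ox = (side - sl.shape[1]) // 2
            padded[oy:oy + sl.shape[0], ox:ox + sl.shape[1]] = sl
            sl = padded
        if sl.shape != (TARGET_SIZE, TARGET_SIZE):
            sl = _sk_resize(sl, (TARGET_SIZE, TARGET_SIZE), order=1,
                            anti_aliasing=False, preserve_range=True)
        sl = np.clip(sl, 0.0, 1.0)
        src = z_offset + i
        out.append(PreparedSlice(sl, source_index=src,
                                 z_mm=src * volume.voxel_size_mm))
    return out
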
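"""Rigid orientation standardization and VOI extraction.

Alignment maps the first principal axis of the segmented bone to the
global +z axis with the proximal end (the end with the larger
cross-sectional area — the epiphysis) at z = 0, then fixes the in-plane
rotation so the mean tibial-ridge direction — the per-slice furthest
point from the centroid within the proximal 65–75 % segment of the bone
length — points along +x.

VOIs are half-open z-intervals anchored on a transitional landmark
(``[ref + offset, ref + offset + height)``), so adjacent VOIs sharing a
reference never share a slice; slice counts are ``round(height / voxel)``
which at 5 µm makes a 1 mm VOI exactly 200 slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .landmarks import LandmarkSet
from .volume import ImageVolume
from .preprocess import otsu_threshold, largest_component

RIDGE_SEGMENT = (0.65, 0.75)  # fraction of bone length used for ridge detection


@dataclass
class VOISpec:
    """A z-interval anchored on a landmark.

    ``offset_mm`` is signed with distal positive; the interval is
    ``[ref + offset, ref + offset + height)`` except the epiphyseal preset
    which grows proximally: ``[Z_eg - height, Z_eg)``.
    """

    name: str
    reference: str
    offset_mm: float
    height_mm: float
    grows_proximally: bool = False

    def __post_init__(self):
        if not self.height_mm > 0:
            raise ValueError("VOI height must be > 0")

    @classmethod
    def preset(cls, name: str, fixed_offset_mm: float = 0.25) -> "VOISpec":
        """Named presets for the standard compartment VOIs.

        * ``epiphyseal`` — 0.25 mm proximal of Z_eg,
        * ``mixed_primary_secondary`` — 1 mm distal of Z_gp,
        * ``secondary`` — 1 mm distal of Z_ps,
        * ``fixed_offset`` — 1 mm starting ``fixed_offset_mm`` (0.125 or
          0.25) distal of Z_gp, the conventional fixed-offset convention.
        """
        presets = {
            "epiphyseal": cls("epiphyseal", "Z_eg", -0.25, 0.25,
                              grows_proximally=True),
            "mixed_primary_secondary": cls("mixed_primary_secondary", "Z_gp",
                                           0.0, 1.0),
            "secondary": cls("secondary", "Z_ps", 0.0, 1.0),
            "fixed_offset": cls("fixed_offset", "Z_gp", fixed_offset_mm, 1.0),
        }
        if name not in presets:
            raise ValueError(f"unknown VOI preset {name!r}")
        return presets[name]


@dataclass
class AlignmentResult:
    rotation: np.ndarray          # 3x3 orthonormal, det +1
    ridge_angle_deg: float
    aligned_volume: ImageVolume
    aligned_masks: dict


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

def _principal_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cov = np.cov(coords.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 1.05 * evals[-2]:
        raise ValueError(
            "degenerate mask: no unique principal direction "
            f"(eigenvalues {evals})"
        )
    return evecs[:, -1], evals


def align_tibia(volume: ImageVolume, mask: np.ndarray | None = None,
                proximal_is_larger: bool = True) -> AlignmentResult:
    """Standardize the orientation of a tibia scan.

    ``mask`` defaults to Otsu + largest component of the volume.  The
    returned rotation maps original (z, y, x) coordinates into the aligned
    frame; the volume is resampled with linear interpolation, masks with
    nearest-neighbor.
    """
    if mask is None:
        mask = largest_component(otsu_threshold(volume.intensities))
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask).astype(float)
    if len(coords) < 10:
        raise ValueError("mask too small to align")
    centroid = coords.mean(axis=0)
    axis, _ = _principal_axis(coords)

    # sign: proximal end (larger cross-sectional area) toward -infinity on
    # the axis so it ends up at low z
    proj = (coords - centroid) @ axis
    pmin, pmax = proj.min(), proj.max()
    span = pmax - pmin
    # mean cross-sectional area over the terminal 10% of the bone length
    area_lo = (proj < pmin + 0.1 * span).sum()
    area_hi = (proj > pmax - 0.1 * span).sum()
    big_at_hi = area_hi > area_lo
    if big_at_hi == proximal_is_larger:
        axis = -axis

    # rotation taking `axis` to +z (axis order z,y,x => z unit = (1,0,0))
    z_new = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 1.0, 0.0])
    if abs(z_new @ ref) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    y_new = np.cross(z_new, ref)
    y_new /= np.linalg.norm(y_new)
    x_new = np.cross(y_new, z_new)
    R1 = np.stack([z_new, y_new, x_new])  # rows: new axes in old coords
    if np.linalg.det(R1) < 0:
        # keep the transform proper; the y orientation itself is free
        R1 = np.stack([z_new, -y_new, x_new])

    rot_coords = (coords - centroid) @ R1.T

    # ridge: furthest point from the in-plane centroid, per slice of the
    # proximal 65-75% segment of the bone length
    z = rot_coords[:, 0]
    z0, z1 = z.min(), z.max()
    length = z1 - z0
    lo_z = z0 + RIDGE_SEGMENT[0] * length
    hi_z = z0 + RIDGE_SEGMENT[1] * length
    seg = rot_coords[(z >= lo_z) & (z <= hi_z)]
    if len(seg) == 0:
        raise ValueError("empty ridge segment: mask spans too little length")
    angles = []
    for zi in np.unique(np.round(seg[:, 0])):
        sl = seg[np.round(seg[:, 0]) == zi]
        c = sl.mean(axis=0)
        d = sl[:, 1:] - c[1:]
        r = np.sqrt((d ** 2).sum(axis=1))
        # direction of the ridge tip: centroid of the near-maximal points,
        # which is stabler than the single furthest voxel (a bump corner)
        far = d[r >= r.max() - 1.0].mean(axis=0)
        angles.append(np.arctan2(far[0], far[1]))  # (y, x) -> angle from +x
    mean_angle = np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles)))

    # in-plane rotation sending the mean ridge direction to +x
    c, s = np.cos(mean_angle), np.sin(mean_angle)
    R2 = np.array([[1.0, 0.0, 0.0],
                   [0.0, c, -s],
                   [0.0, s, c]])
    R = R2 @ R1

    aligned = _resample(volume.intensities, R, centroid, order=1)
    aligned_mask = _resample(mask.astype(np.uint8), R, centroid, order=0) > 0
    return AlignmentResult(
        rotation=R,
        ridge_angle_deg=float(np.degrees(mean_angle)),
        aligned_volume=ImageVolume(aligned, volume.voxel_size_mm,
                                   meta=dict(volume.meta, aligned=True)),
        aligned_masks={"bone": aligned_mask},
    )


def _resample(arr: np.ndarray, R: np.ndarray, center: np.ndarray,
              order: int) -> np.ndarray:
    """Rotate arr about `center` by R (new = R @ (old - center) + center)."""
    inv = R.T
    offset = center - inv @ center
    return ndimage.affine_transform(arr, inv, offset=offset, order=order,
                                    mode="constant", cval=0.0)


# --------------------------------------------------------------------------
# VOI extraction
# --------------------------------------------------------------------------

def voi_slice_range(spec: VOISpec, landmarks: LandmarkSet,
                    voxel_size_mm: float, n_slices: int) -> tuple[int, int]:
    """Half-open slice-index interval [start, stop) of a VOI."""
    ref = getattr(landmarks, spec.reference, None)
    if ref is None:
        raise ValueError(f"landmark {spec.reference} is absent; cannot "
                         f"extract VOI {spec.name!r}")
    if spec.grows_proximally:
        z_start = ref + spec.offset_mm
    else:
        z_start = ref + spec.offset_mm
    n_voi = int(round(spec.height_mm / voxel_size_mm))
    start = int(round(z_start / voxel_size_mm))
    stop = start + n_voi
    if start < 0 or stop > n_slices:
        raise ValueError(
            f"VOI {spec.name!r} spans slices [{start}, {stop}) but the "
            f"volume has z-range [0, {n_slices}) "
            f"({0.0}-{n_slices * voxel_size_mm} mm)"
        )
    return start, stop


def extract_voi(volume: ImageVolume, landmarks: LandmarkSet, spec: VOISpec,
                masks: dict | None = None):
    """Extract the sub-volume (and any masks) of a VOI.

    Returns ``(sub_volume, sub_masks, (start, stop))`` where the interval
    is half-open in slice indices so adjacent VOIs sharing a reference
    never overlap.
    """
    start, stop = voi_slice_range(spec, landmarks, volume.voxel_size_mm,
                                  volume.n_slices)
    sub = ImageVolume(volume.intensities[start:stop], volume.voxel_size_mm,
                      meta=dict(volume.meta, voi=spec.name,
                                z_start_mm=start * volume.voxel_size_mm))
    sub_masks = {}
    if masks:
        for name, m in masks.items():
            if m.shape != volume.shape:
                raise ValueError(f"mask {name!r} shape {m.shape} does not "
                                 f"match volume {volume.shape}")
            sub_masks[name] = m[start:stop]
    return sub, sub_masks, (start, stop)


# --------------------------------------------------------------------------
# medullary / trabecular masks
# --------------------------------------------------------------------------

def medullary_and_trabecular_masks(
    voi: ImageVolume | np.ndarray,
    external_trabecular: np.ndarray | None = None,
    external_medullary: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Medullary and trabecular masks of a VOI.

    With external masks supplied they are passed through unchanged
    (clipped to the VOI by the caller).  Otherwise a substitute
    threshold-based segmentation is used: Otsu binarization; per slice the
    cortical shell is the bone component(s) touching the outer boundary of
    the filled bone silhouette; medulla = filled silhouette minus cortex;
    trabecular = bone ∩ medulla.  This substitute is NOT equivalent to a
    learned trabecular segmentation — prefer supplying precomputed masks.
    """
    data = voi.intensities if isinstance(voi, ImageVolume) else np.asarray(voi)
    if external_trabecular is not None:
        trab = np.asarray(external_trabecular, dtype=bool)
        if trab.shape != data.shape:
            raise ValueError("external trabecular mask shape mismatch")
        if external_medullary is not None:
            med = np.asarray(external_medullary, dtype=bool)
            if med.shape != data.shape:
                raise ValueError("external medullary mask shape mismatch")
        else:
            med = np.ones_like(trab)
        return med, trab & med

    bone = otsu_threshold(data)
    med = np.zeros_like(bone)
    trab = np.zeros_like(bone)
    struct = np.ones((3, 3), int)
    import warnings as _warnings
    for i in range(data.shape[0]):
        b = bone[i]
        if not b.any():
            raise ValueError(f"slice {i} contains no bone")
        silhouette = ndimage.binary_fill_holes(b)
        boundary = silhouette & ~ndimage.binary_erosion(silhouette)
        lab, _ = ndimage.label(b, structure=struct)
        touching = np.unique(lab[boundary & b])
        cortex = np.isin(lab, touching[touching > 0])
        med_i = silhouette & ~cortex
        if not med_i.any():
            _warnings.warn(f"slice {i}: solid cross-section, empty medulla")
        med[i] = med_i
        trab[i] = b & med_i
    return med, trab
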
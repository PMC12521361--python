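"""Transitional landmark detection from per-slice class probabilities.

The regional probability distribution method: per-slice class
probabilities over the four compartments (epiphyseal bone C=0, growth
plate C=1, primary spongiosa C=2, secondary spongiosa C=3) are median
smoothed along z, and the three transitional landmarks are the first
equality points of adjacent class probabilities in the appropriate scan
direction:

* ``Z_eg``: min z with P(z,0) = P(z,1), scanned proximal→distal,
* ``Z_ps``: first z with P(z,2) = P(z,3), scanned distal→proximal,
* ``Z_gp``: first z with P(z,1) = P(z,2), scanned proximal→distal within
  the interval (Z_eg, Z_ps).

A discrete crossing is the first index pair where the dominant class of
the scan hands over to its successor; the sub-slice position is obtained
by linear interpolation of the probability difference, removing the
half-voxel bias of reporting whole slice indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LandmarkSet:
    """The transitional landmarks of one bone, in mm (z=0 proximal).

    Any landmark may be ``None`` (absent compartment or no crossing
    found); ``Z_gs`` is the growth-plate/secondary fallback interface used
    when the primary spongiosa is absent.
    """

    Z_eg: float | None = None
    Z_gp: float | None = None
    Z_ps: float | None = None
    Z_gs: float | None = None
    absent_compartments: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        vals = [self.Z_eg, self.Z_gp, self.Z_ps]
        if all(v is not None for v in vals):
            if not (self.Z_eg < self.Z_gp < self.Z_ps):
                raise ValueError(
                    f"landmark ordering violated: Z_eg={self.Z_eg}, "
                    f"Z_gp={self.Z_gp}, Z_ps={self.Z_ps}"
                )

    def to_dict(self) -> dict:
        return {
            "Z_eg": self.Z_eg, "Z_gp": self.Z_gp, "Z_ps": self.Z_ps,
            "Z_gs": self.Z_gs,
            "absent": sorted(self.absent_compartments),
        }


@dataclass
class LandmarkConfig:
    """Tunables of the landmark detector.

    ``smoothing_window_mm`` (default 0.05 mm) is the rolling-median window
    applied to the raw probability profile; ``absence_threshold`` is the
    peak probability below which a compartment is declared absent (0.5: a
    compartment must dominate somewhere to count as present).
    """

    smoothing_window_mm: float = 0.05
    absence_threshold: float = 0.5

    def __post_init__(self):
        if not self.smoothing_window_mm > 0:
            raise ValueError("smoothing window must be > 0")
        if not 0 < self.absence_threshold < 1:
            raise ValueError("absence threshold must be in (0,1)")


@dataclass
class ProbabilityProfile:
    """Per-slice class probabilities along z, proximal→distal.

    ``P`` is ``(n_slices, 4)``; each row sums to 1 within 1e-6.
    """

    P: np.ndarray
    voxel_size_mm: float
    smoothed: bool = False

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[1] != 4:
            raise ValueError("profile must be (n_slices, 4)")
        if self.P.shape[0] < 1:
            raise ValueError("profile must contain at least one slice")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    @property
    def n_slices(self) -> int:
        return self.P.shape[0]

    def z_mm(self) -> np.ndarray:
        return np.arange(self.n_slices) * self.voxel_size_mm

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.P, columns=["p0", "p1", "p2", "p3"])
        df.insert(0, "z_mm", self.z_mm())
        df.insert(0, "z_index", np.arange(self.n_slices))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, voxel_size_mm: float | None = None,
                   smoothed: bool = False) -> "ProbabilityProfile":
        if voxel_size_mm is None:
            z = df["z_mm"].to_numpy()
            voxel_size_mm = float(np.diff(z).mean()) if len(z) > 1 else 1.0
        return cls(df[["p0", "p1", "p2", "p3"]].to_numpy(), voxel_size_mm,
                   smoothed=smoothed)


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------

def smooth_profile(profile: ProbabilityProfile,
                   config: LandmarkConfig | None = None) -> ProbabilityProfile:
    """Centered rolling-median smoothing of each class column.

    The window is ``smoothing_window_mm`` converted to slices and forced
    odd (rounded up); edges shrink the window symmetrically.  Because the
    column-wise medians of a row need not sum to one, rows are
    re-normalized after filtering.
    """
    config = config or LandmarkConfig()
    w = int(round(config.smoothing_window_mm / profile.voxel_size_mm))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    half = w // 2
    P = profile.P
    n = P.shape[0]
    out = np.empty_like(P)
    for i in range(n):
        k = min(half, i, n - 1 - i)  # shrink symmetrically at the edges
        out[i] = np.median(P[i - k:i + k + 1], axis=0)
    sums = out.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    out /= sums
    return ProbabilityProfile(out, profile.voxel_size_mm, smoothed=True)


# --------------------------------------------------------------------------
# crossing detection
# --------------------------------------------------------------------------

def _first_crossing(P: np.ndarray, a: int, b: int, idx: np.ndarray,
                    voxel_size_mm: float) -> float | None:
    """First z (mm) along the index sequence ``idx`` where the dominant
    class ``a`` hands over to ``b`` (sign of P[:,a]-P[:,b] flips + → −).

    Sub-slice position by linear interpolation of the difference; an exact
    zero at a slice yields that slice's z.
    """
    D = P[idx, a] - P[idx, b]
    for j in range(len(idx)):
        if D[j] == 0.0:
            return idx[j] * voxel_size_mm
        if j + 1 < len(idx) and D[j] > 0 > D[j + 1]:
            i0, i1 = idx[j], idx[j + 1]
            frac = D[j] / (D[j] - D[j + 1])
            return (i0 + frac * (i1 - i0)) * voxel_size_mm
    return None


def detect_landmarks(profile: ProbabilityProfile,
                     config: LandmarkConfig | None = None) -> LandmarkSet:
    """Detect Z_eg, Z_gp, Z_ps from a smoothed probability profile.

    Raises no error when a crossing is missing — the landmark is simply
    absent in the returned set (with the compartment flagged when its peak
    probability never reaches the absence threshold).  An unsmoothed
    profile triggers a warning; landmark equality points on raw profiles
    are noise-sensitive.
    """
    config = config or LandmarkConfig()
    if not profile.smoothed:
        warnings.warn("detect_landmarks called on an unsmoothed profile",
                      stacklevel=2)
    P = profile.P
    v = profile.voxel_size_mm
    n = profile.n_slices
    fwd = np.arange(n)

    absent = {c for c in range(4) if P[:, c].max() < config.absence_threshold}
    if len(absent) > 2:
        raise ValueError(f"more than two absent compartments: {sorted(absent)}")

    if 2 in absent:
        # primary spongiosa missing: growth plate meets secondary directly
        z_eg = _first_crossing(P, 0, 1, fwd, v)
        z_gs = _first_crossing(P, 1, 3, fwd, v)
        return LandmarkSet(Z_eg=z_eg, Z_gs=z_gs,
                           absent_compartments=frozenset(absent))

    z_eg = _first_crossing(P, 0, 1, fwd, v)
    z_ps = _first_crossing(P, 3, 2, fwd[::-1], v)

    z_gp = None
    if z_eg is not None and z_ps is not None:
        lo = int(np.ceil(z_eg / v))
        hi = int(np.floor(z_ps / v))
        inner = fwd[lo:hi + 1]
        z_gp = _first_crossing(P, 1, 2, inner, v)
    elif z_eg is not None or z_ps is not None:
        z_gp = _first_crossing(P, 1, 2, fwd, v)

    return LandmarkSet(Z_eg=z_eg, Z_gp=z_gp, Z_ps=z_ps,
                       absent_compartments=frozenset(absent))


def detect_absent_compartments(profile: ProbabilityProfile,
                               config: LandmarkConfig | None = None
                               ) -> tuple[set, LandmarkSet]:
    """Absent-compartment set plus the landmark set with fallbacks applied.

    A compartment is absent when its smoothed probability never reaches
    ``absence_threshold`` anywhere along z.  When the primary spongiosa is
    absent, Z_gp/Z_ps are absent and Z_gs (growth-plate/secondary
    interface) is returned instead.
    """
    config = config or LandmarkConfig()
    lms = detect_landmarks(profile, config)
    return set(lms.absent_compartments), lms
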
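"""Skull-based reference frame and petalia component decomposition.

The protrusion of one cerebral hemisphere beyond the other at the frontal
or occipital pole (a *petalia*) is measured here in a reference frame
built from three midsagittal skull landmarks, so that the quantification
is independent of the endocast itself:

* **L1** — the line through glabella (G) and inion (I); its direction is
  the antero-posterior axis (anterior = I -> G).
* **L2** — the perpendicular dropped from basion (B) onto L1; its
  direction (from B towards its foot on L1) is the superior axis.
* The right axis completes the right-handed frame (anterior x superior)
  and is oriented so that a labelled right-side landmark falls on its
  positive side.

The four endocranial pole landmarks (right/left frontal poles RFP/LFP,
right/left occipital poles ROP/LOP) are projected onto L1, onto L2 and
onto the midsagittal plane spanned by L1 and L2.  Signed differences of
the projections of a right/left pole pair give the antero-posterior,
vertical and lateral components of each petalia.

Sign conventions (positive = right asymmetry):

====================  ================================================
frontal AP            right frontal pole more **anterior**
occipital AP          right occipital pole more **posterior**
vertical (both)       right pole more **superior**
lateral (both)        right pole **farther from the midplane**
====================  ================================================

All coordinates are unitless floats interpreted as millimetres.
Endocranial volume (EV) is supplied in cubic centimetres; size-corrected
values are ``x / (EV in mm^3)^(1/3) * 100`` and dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateLandmarksError",
    "OrientationError",
    "MissingVolumeError",
    "SideLabelWarning",
    "LandmarkSet",
    "ReferenceFrame",
    "PetaliaComponents",
    "TRAITS",
    "POLE_POSITIONS",
    "build_reference_frame",
    "ap_component",
    "vertical_component",
    "lateral_component",
    "pole_lateral_position",
    "size_correct",
    "quantify",
    "quantify_cohort",
]

#: Canonical trait order used throughout the package.
TRAITS = (
    "frontal_ap",
    "frontal_vert",
    "frontal_lat",
    "occipital_ap",
    "occipital_vert",
    "occipital_lat",
)

POLE_POSITIONS = ("frontal_pole_pos", "occipital_pole_pos")

#: Absolute tolerance (mm) below which landmark configurations are degenerate.
DEGENERACY_TOL = 1e-6
#: Relative tolerance for orientation (midplane) checks.
ORIENTATION_RTOL = 1e-9


class DegenerateLandmarksError(ValueError):
    """G/I/B configuration does not define the reference frame."""


class OrientationError(ValueError):
    """The orientation hint lies on the midplane; left/right is ambiguous."""


class MissingVolumeError(ValueError):
    """Size correction requested but no endocranial volume is available."""


class SideLabelWarning(UserWarning):
    """A pole labelled right/left falls on the opposite side of the midplane."""


def _as_point(p, name: str = "point") -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} has non-finite coordinates: {a}")
    return a


@dataclass(frozen=True)
class LandmarkSet:
    """One specimen: three skull landmarks, four endocranial poles, metadata.

    Parameters
    ----------
    specimen_id : str
        Unique specimen label.
    G, I, B : array-like, shape (3,)
        Glabella, inion and basion in mm.  Required; they define the frame.
    RFP, LFP, ROP, LOP : array-like or None
        Right/left frontal and occipital poles.  A missing pole (``None``)
        makes the traits of that lobe unavailable for the specimen.
    EV : float or None
        Endocranial volume in cc (> 0 when present).
    group, sex : str
        Group label (e.g. ``"AMH"``) and optional sex.
    """

    specimen_id: str
    G: np.ndarray
    I: np.ndarray
    B: np.ndarray
    RFP: Optional[np.ndarray] = None
    LFP: Optional[np.ndarray] = None
    ROP: Optional[np.ndarray] = None
    LOP: Optional[np.ndarray] = None
    EV: Optional[float] = None
    group: str = ""
    sex: Optional[str] = None

    def __post_init__(self):
        for name in ("G", "I", "B"):
            object.__setattr__(self, name, _as_point(getattr(self, name), name))
        for name in ("RFP", "LFP", "ROP", "LOP"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, _as_point(v, name))
        G, I, B = self.G, self.I, self.B
        gi = np.linalg.norm(G - I)
        if gi <= DEGENERACY_TOL:
            raise DegenerateLandmarksError(
                f"{self.specimen_id!r}: glabella and inion coincide (|G-I|={gi:g} mm)"
            )
        axis = (G - I) / gi
        off_axis = (B - I) - np.dot(B - I, axis) * axis
        if np.linalg.norm(off_axis) <= DEGENERACY_TOL:
            raise DegenerateLandmarksError(
                f"{self.specimen_id!r}: basion lies on the glabella-inion line; "
                "the perpendicular L2 is undefined"
            )
        if self.EV is not None and not self.EV > 0:
            raise ValueError(f"{self.specimen_id!r}: EV must be positive, got {self.EV}")

    @property
    def has_frontal(self) -> bool:
        return self.RFP is not None and self.LFP is not None

    @property
    def has_occipital(self) -> bool:
        return self.ROP is not None and self.LOP is not None

    def orient_hint(self) -> np.ndarray:
        """First available labelled right-side pole, used to orient the frame."""
        if self.RFP is not None:
            return self.RFP
        if self.ROP is not None:
            return self.ROP
        raise DegenerateLandmarksError(
            f"{self.specimen_id!r}: no right-side pole available to orient the frame"
        )

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "LandmarkSet":
        """Return a copy with every landmark mapped through ``x -> R @ x + t``."""
        R = np.asarray(R, float)
        t = np.asarray(t, float)

        def mv(p):
            return None if p is None else R @ p + t

        return replace(
            self,
            G=R @ self.G + t, I=R @ self.I + t, B=R @ self.B + t,
            RFP=mv(self.RFP), LFP=mv(self.LFP), ROP=mv(self.ROP), LOP=mv(self.LOP),
        )


@dataclass(frozen=True)
class ReferenceFrame:
    """Orthonormal skull frame: origin on L1 plus anterior/superior/right axes."""

    origin: np.ndarray
    anterior: np.ndarray
    superior: np.ndarray
    right: np.ndarray

    def coords(self, p) -> np.ndarray:
        """(anterior, superior, right) coordinates of ``p`` relative to origin."""
        d = _as_point(p) - self.origin
        return np.array(
            [np.dot(d, self.anterior), np.dot(d, self.superior), np.dot(d, self.right)]
        )


def build_reference_frame(G, I, B, orient_hint) -> ReferenceFrame:
    """Construct the skull-based frame from glabella, inion and basion.

    ``anterior`` points from inion to glabella along L1; ``origin`` is the
    orthogonal projection of basion onto L1; ``superior`` points from basion
    to the origin along L2; ``right = anterior x superior``, flipped if
    necessary so that ``orient_hint`` (a labelled right-side landmark) has a
    positive right-coordinate.

    Raises
    ------
    DegenerateLandmarksError
        If G and I coincide or B lies on L1 (within ``DEGENERACY_TOL`` mm).
    OrientationError
        If ``orient_hint`` lies on the midplane.
    """
    G, I, B = _as_point(G, "G"), _as_point(I, "I"), _as_point(B, "B")
    hint = _as_point(orient_hint, "orient_hint")

    gi = np.linalg.norm(G - I)
    if gi <= DEGENERACY_TOL:
        raise DegenerateLandmarksError(f"|G-I| = {gi:g} mm is below tolerance")
    anterior = (G - I) / gi

    origin = I + np.dot(B - I, anterior) * anterior
    perp = origin - B
    pn = np.linalg.norm(perp)
    if pn <= DEGENERACY_TOL:
        raise DegenerateLandmarksError(
            f"basion is {pn:g} mm from the G-I line; L2 is undefined"
        )
    superior = perp / pn

    right = np.cross(anterior, superior)
    lat = np.dot(hint - origin, right)
    scale = max(gi, pn)
    if abs(lat) <= ORIENTATION_RTOL * scale:
        raise OrientationError(
            "orientation hint lies on the midplane; cannot orient the right axis"
        )
    if lat < 0:
        right = -right
    return ReferenceFrame(origin=origin, anterior=anterior, superior=superior, right=right)


def ap_component(frame: ReferenceFrame, right_pole, left_pole, lobe: str) -> float:
    """Signed antero-posterior petalia component (mm).

    For the frontal lobe, positive means the right pole projects more
    anteriorly on L1; for the occipital lobe the sign is flipped so that
    positive means the right pole projects more *posteriorly* (the lobe's
    protrusion direction).  A negative occipital value therefore indicates
    a left pole that is more posterior than the right.
    """
    a_r = np.dot(_as_point(right_pole) - frame.origin, frame.anterior)
    a_l = np.dot(_as_point(left_pole) - frame.origin, frame.anterior)
    if lobe == "frontal":
        return float(a_r - a_l)
    if lobe == "occipital":
        return float(a_l - a_r)
    raise ValueError(f"lobe must be 'frontal' or 'occipital', got {lobe!r}")


def vertical_component(frame: ReferenceFrame, right_pole, left_pole) -> float:
    """Signed vertical component (mm): positive = right pole more superior."""
    s_r = np.dot(_as_point(right_pole) - frame.origin, frame.superior)
    s_l = np.dot(_as_point(left_pole) - frame.origin, frame.superior)
    return float(s_r - s_l)


def _lateral_coord(frame: ReferenceFrame, pole) -> float:
    return float(np.dot(_as_point(pole) - frame.origin, frame.right))


def lateral_component(frame: ReferenceFrame, right_pole, left_pole) -> float:
    """Signed lateral component (mm): positive = right pole farther from midplane.

    Emits :class:`SideLabelWarning` when a pole labelled right sits on the
    negative side of the midplane (or a left pole on the positive side),
    which usually indicates swapped labels in the input.
    """
    r_r = _lateral_coord(frame, right_pole)
    r_l = _lateral_coord(frame, left_pole)
    if r_r < 0 or r_l > 0:
        warnings.warn(
            "pole labelled right/left lies on the opposite side of the midplane; "
            "check R/L labels",
            SideLabelWarning,
            stacklevel=2,
        )
    return float(abs(r_r) - abs(r_l))


def pole_lateral_position(frame: ReferenceFrame, right_pole, left_pole) -> float:
    """Mean unsigned distance (mm) of the two poles to the midsagittal plane."""
    return float(
        0.5 * (abs(_lateral_coord(frame, right_pole)) + abs(_lateral_coord(frame, left_pole)))
    )


def size_correct(value: float, EV: Optional[float]) -> float:
    """Size-correct a linear measure: ``value / (EV in mm^3)^(1/3) * 100``.

    ``EV`` is in cc (1 cc = 1000 mm^3); the result is dimensionless and
    invariant under isometric scaling (coordinates x k, EV x k^3).
    """
    if EV is None:
        raise MissingVolumeError("size correction requires an endocranial volume")
    if not EV > 0:
        raise ValueError(f"EV must be positive, got {EV}")
    return float(value) / np.cbrt(EV * 1000.0) * 100.0


@dataclass(frozen=True)
class PetaliaComponents:
    """Six signed petalia components plus the two pole lateral positions.

    Components are in mm when ``size_corrected`` is False and dimensionless
    (per-cube-root-EV x 100) when True.  Traits whose poles are missing are
    NaN.
    """

    frontal_ap: float = np.nan
    frontal_vert: float = np.nan
    frontal_lat: float = np.nan
    occipital_ap: float = np.nan
    occipital_vert: float = np.nan
    occipital_lat: float = np.nan
    frontal_pole_pos: float = np.nan
    occipital_pole_pos: float = np.nan
    size_corrected: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in TRAITS + POLE_POSITIONS}

    def as_array(self) -> np.ndarray:
        """The six signed components in canonical trait order."""
        return np.array([getattr(self, k) for k in TRAITS], dtype=float)

    def corrected(self, EV: Optional[float]) -> "PetaliaComponents":
        """Return a size-corrected copy (see :func:`size_correct`)."""
        if self.size_corrected:
            raise ValueError("components are already size-corrected")
        vals = {k: size_correct(v, EV) if np.isfinite(v) else np.nan
                for k, v in self.as_dict().items()}
        return PetaliaComponents(size_corrected=True, **vals)


def quantify(landmarks: LandmarkSet) -> PetaliaComponents:
    """Decompose a specimen's petalias into signed components (raw mm).

    Frontal traits require both frontal poles and occipital traits both
    occipital poles; missing pairs yield NaN.  Geometry errors are re-raised
    with the specimen id attached.
    """
    try:
        frame = build_reference_frame(
            landmarks.G, landmarks.I, landmarks.B, landmarks.orient_hint()
        )
        out = {}
        if landmarks.has_frontal:
            out["frontal_ap"] = ap_component(frame, landmarks.RFP, landmarks.LFP, "frontal")
            out["frontal_vert"] = vertical_component(frame, landmarks.RFP, landmarks.LFP)
            out["frontal_lat"] = lateral_component(frame, landmarks.RFP, landmarks.LFP)
            out["frontal_pole_pos"] = pole_lateral_position(frame, landmarks.RFP, landmarks.LFP)
        if landmarks.has_occipital:
            out["occipital_ap"] = ap_component(frame, landmarks.ROP, landmarks.LOP, "occipital")
            out["occipital_vert"] = vertical_component(frame, landmarks.ROP, landmarks.LOP)
            out["occipital_lat"] = lateral_component(frame, landmarks.ROP, landmarks.LOP)
            out["occipital_pole_pos"] = pole_lateral_position(frame, landmarks.ROP, landmarks.LOP)
    except (DegenerateLandmarksError, OrientationError) as exc:
        raise type(exc)(f"specimen {landmarks.specimen_id!r}: {exc}") from exc
    return PetaliaComponents(**out)


def quantify_cohort(
    specimens: Iterable[LandmarkSet], size_corrected: bool = True
) -> pd.DataFrame:
    """Quantify many specimens into a cohort table.

    Returns one row per specimen with metadata, the raw components, the pole
    positions and (when ``size_corrected`` and EV is present) size-corrected
    columns prefixed ``rel_``.
    """
    rows = []
    for lm in specimens:
        comp = quantify(lm)
        row = {"specimen_id": lm.specimen_id, "group": lm.group, "sex": lm.sex,
               "EV_cc": lm.EV}
        row.update(comp.as_dict())
        if size_corrected and lm.EV is not None:
            rel = comp.corrected(lm.EV)
            row.update({f"rel_{k}": v for k, v in rel.as_dict().items()})
        elif size_corrected:
            row.update({f"rel_{k}": np.nan for k in TRAITS + POLE_POSITIONS})
        rows.append(row)
    cols = ["specimen_id", "group", "sex", "EV_cc", *TRAITS, *POLE_POSITIONS]
    if size_corrected:
        cols += [f"rel_{k}" for k in TRAITS + POLE_POSITIONS]
    return pd.DataFrame(rows, columns=cols)
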
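"""Local-axis helix analysis: per-residue bending angles and shape classes.

Follows the classic local-axis recipe for helix geometry: a local axis is
fitted to each window of four consecutive CA atoms via the Sugeta-Miyazawa
construction, the angle between consecutive local axes is the bending angle
of the central residue, and the helix is classified from those angles.  A
kink is a bending angle greater than 20 deg but less than 60 deg; angles of
60 deg or more mark an irregular (broken) helix; a helix that never kinks
but turns appreciably is curved; otherwise it is straight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geom
from .errors import ValidationError
from .structure import StructureModel, ca_trace

__all__ = [
    "HelixGeometryReport",
    "local_axes",
    "bending_angles",
    "classify_helix",
    "analyze_helix",
    "KINK_MIN_DEG",
    "KINK_MAX_DEG",
]

KINK_MIN_DEG = 20.0
KINK_MAX_DEG = 60.0
#: max bending angle above which a never-kinked helix is called curved
CURVE_ANGLE_DEG = 3.0
#: net axis turning above which a helix is called curved even if locally straight
CURVE_TURN_DEG = 20.0


@dataclass(frozen=True)
class HelixGeometryReport:
    """Bending-angle profile and shape classification of one helix."""

    bending_angles: tuple[tuple[int, float], ...]  # (seq_id, degrees)
    classification: str
    max_angle: float
    net_turn: float


def local_axes(ca: np.ndarray, window: int = 4) -> np.ndarray:
    """Unit local helix axes over sliding CA windows.

    For the default window of four CAs the axis is the Sugeta-Miyazawa
    direction (cross product of the two difference-of-difference vectors);
    wider windows average the construction over the window.
    """
    ca = np.asarray(ca, dtype=float)
    if window < 4:
        raise ValidationError("window must be >= 4 CA atoms")
    if ca.shape[0] < window:
        raise ValidationError(f"trace of {ca.shape[0]} CAs too short for window {window}")
    u = np.diff(ca, axis=0)          # bond vectors
    v = u[:-1] - u[1:]               # bisector-like, point away from the axis
    raw = np.cross(v[:-1], v[1:])    # one axis per 4-CA window
    norms = np.linalg.norm(raw, axis=1)
    if np.any(norms < 1e-10):
        raise ValidationError("degenerate (collinear) CA geometry in axis window")
    raw /= norms[:, None]
    # orient along the chain
    chain_dir = ca[-1] - ca[0]
    for i in range(raw.shape[0]):
        if raw[i] @ chain_dir < 0:
            raw[i] = -raw[i]
    if window == 4:
        return raw
    per = window - 3  # basic axes per wide window
    out = []
    for s in range(raw.shape[0] - per + 1):
        m = raw[s:s + per].mean(axis=0)
        out.append(m / np.linalg.norm(m))
    return np.array(out)


def bending_angles(axes: np.ndarray, separation: int = 1) -> np.ndarray:
    """Angles (degrees) between local axes `separation` windows apart, in [0, 180).

    With `separation` 1 this is the angle between consecutive overlapping
    windows, which smears a discrete kink across several residues and
    under-reports its magnitude.  Helix analysis therefore compares axes
    whose windows share no CA atoms (separation = window - 1), which
    recovers the geometric inter-segment angle of a sharp kink.
    """
    axes = np.asarray(axes, dtype=float)
    if separation < 1:
        raise ValidationError("separation must be >= 1")
    if axes.shape[0] < separation + 1:
        raise ValidationError("need at least separation + 1 local axes")
    dots = np.clip(np.einsum("ij,ij->i", axes[:-separation], axes[separation:]),
                   -1.0, 1.0)
    ang = np.degrees(np.arccos(dots))
    return np.minimum(ang, np.nextafter(180.0, 0.0))


def classify_helix(angles: np.ndarray,
                   kink_band: tuple[float, float] = (KINK_MIN_DEG, KINK_MAX_DEG),
                   curve_angle: float = CURVE_ANGLE_DEG,
                   curve_turn: float = CURVE_TURN_DEG,
                   net_turn: float | None = None) -> str:
    """Classify a bending-angle profile.

    irregular if any angle reaches the upper kink bound (a break rather than
    a kink); kinked if any angle falls inside the kink band; curved when the
    largest angle exceeds `curve_angle` or the net axis turning exceeds
    `curve_turn`; straight otherwise.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValidationError("no bending angles to classify")
    lo, hi = kink_band
    amax = float(angles.max())
    if amax >= hi:
        return "irregular"
    if amax > lo:
        return "kinked"
    turning = float(net_turn) if net_turn is not None else float(angles.sum())
    if amax > curve_angle or turning > curve_turn:
        return "curved"
    return "straight"


def analyze_helix(model: StructureModel, chain: str | None = None,
                  residue_range: tuple[int, int] | None = None,
                  window: int = 4) -> HelixGeometryReport:
    """Bending-angle report for one helical chain (or residue range)."""
    cid = chain if chain is not None else model.first_chain_id()
    trace = ca_trace(model, cid)
    if residue_range is not None:
        lo, hi = residue_range
        trace = [(s, p) for s, p in trace if lo <= s <= hi]
    if len(trace) < window + 1:
        raise ValidationError("selected trace too short for helix analysis")
    seq_ids = [s for s, _ in trace]
    ca = np.array([p for _, p in trace])
    axes = local_axes(ca, window)
    sep = window
    if axes.shape[0] < sep + 1:
        raise ValidationError("selected trace too short for helix analysis")
    angles = bending_angles(axes, separation=sep)
    # axis i covers CAs i..i+window-1; the angle between axes i and i+sep is
    # assigned to the residue midway between the two windows
    offset = (window - 1 + sep) // 2
    pairs = tuple((seq_ids[i + offset], float(a)) for i, a in enumerate(angles))
    net = float(np.degrees(np.arccos(np.clip(axes[0] @ axes[-1], -1.0, 1.0))))
    cls = classify_helix(angles, net_turn=net)
    return HelixGeometryReport(
        bending_angles=pairs,
        classification=cls,
        max_angle=float(angles.max()),
        net_turn=net,
    )
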
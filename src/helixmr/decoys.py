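"""Synthetic ab initio decoy sets with known ground truth.

Ab initio structure predictors hand the ensemble machinery a pile of
same-sequence models: one dominant, well-converged structural cluster plus
wrong-topology outliers, with positional scatter that grows toward loops and
chain termini.  This module builds such sets deterministically so the
clustering, truncation and scoring stages can be exercised against exact
ground-truth labels.

The ground truth is an up-down bundle of ideal polyalanine helices placed on
a circle with alternating direction and joined by loop residues.  Core
decoys are the truth plus a small per-helix rigid-body jitter and i.i.d.
Gaussian atom noise, inflated in loop/terminal residues; outliers are the
truth with the helices re-ordered on the circle, which guarantees they sit
far outside any subcluster radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from . import geom
from .clustering import DecoySet
from .errors import ValidationError
from .helices import build_ideal_helix
from .structure import Atom, Residue, StructureModel

__all__ = [
    "DecoyGenSpec",
    "generate_ground_truth",
    "generate_decoy_set",
    "residue_labels",
]

#: chain-end window (residues at either terminus) treated as flexible
TERMINAL_WINDOW = 4
#: circle radius for helix placement, Angstroms
BUNDLE_RADIUS = 10.0


@dataclass(frozen=True)
class DecoyGenSpec:
    """Parameters of a synthetic decoy population.

    Noise values are standard deviations (Angstroms) of isotropic Gaussian
    per-atom displacement; `terminal_noise_multiplier` inflates the noise in
    loop and terminal residues to create the variance gradient that
    truncation exploits.
    """

    n_helices: int = 4
    helix_length: int = 20
    loop_length: int = 4
    n_core_decoys: int = 80
    n_outlier_decoys: int = 20
    core_noise: float = 0.5
    terminal_noise_multiplier: float = 4.0
    outlier_noise: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_helices < 1:
            raise ValidationError("need at least one helix")
        if self.helix_length < 2 or self.loop_length < 0:
            raise ValidationError("invalid helix/loop lengths")
        if min(self.n_core_decoys, self.n_outlier_decoys) < 0:
            raise ValidationError("decoy counts must be >= 0")
        if min(self.core_noise, self.outlier_noise) < 0:
            raise ValidationError("noise levels must be >= 0")
        if self.core_noise > self.outlier_noise:
            raise ValidationError("core_noise must not exceed outlier_noise")

    @property
    def n_residues(self) -> int:
        return self.n_helices * self.helix_length + max(0, self.n_helices - 1) * self.loop_length


def residue_labels(spec: DecoyGenSpec) -> list[str]:
    """Per-residue ground-truth labels: 'helix', 'loop' or 'terminal'."""
    labels = []
    for h in range(spec.n_helices):
        labels.extend(["helix"] * spec.helix_length)
        if h < spec.n_helices - 1:
            labels.extend(["loop"] * spec.loop_length)
    n = len(labels)
    w = min(TERMINAL_WINDOW, n)
    for i in range(w):
        labels[i] = "terminal"
        labels[n - 1 - i] = "terminal"
    return labels


def _helix_slots(spec: DecoyGenSpec) -> list[tuple[np.ndarray, int]]:
    """(base point, axial direction sign) for each helix slot on the circle."""
    slots = []
    for h in range(spec.n_helices):
        if spec.n_helices == 1:
            base = np.zeros(3)
        else:
            theta = 2.0 * np.pi * h / spec.n_helices
            base = BUNDLE_RADIUS * np.array([np.cos(theta), np.sin(theta), 0.0])
        slots.append((base, 1 if h % 2 == 0 else -1))
    return slots


def _placed_helix(spec: DecoyGenSpec, slot: tuple[np.ndarray, int],
                  start_seq_id: int) -> list[Residue]:
    """One ideal helix rigidly placed in a bundle slot, axis along +/-z."""
    base, sign = slot
    helix = build_ideal_helix(spec.helix_length, start_seq_id=start_seq_id)
    residues = helix.chains["A"]
    ca = np.array([r.ca.position for r in residues])
    centroid, axis = geom.fit_axis(ca)
    rot = geom.rotation_aligning(axis, np.array([0.0, 0.0, float(sign)]))
    rise = float(np.ptp((ca - centroid) @ axis))
    # centroid on the slot axis, helix spanning z in [0, rise]
    origin = base + np.array([0.0, 0.0, rise / 2.0])
    for r in residues:
        for a in r.atoms:
            a.position = rot @ (a.position - centroid) + origin
    return residues


def _arc_points(a: np.ndarray, b: np.ndarray, n_pts: int, step: float = 3.6) -> np.ndarray:
    """`n_pts` interior points from a to b along a circular arc of roughly
    constant `step` spacing, bowed outward from the origin when the straight
    chord would compress the spacing below peptide geometry."""
    n_gaps = n_pts + 1
    chord = float(np.linalg.norm(b - a))
    desired = step * n_gaps
    if desired <= chord or chord < 1e-9:
        ts = np.linspace(0.0, 1.0, n_gaps + 1)[1:-1]
        return a + ts[:, None] * (b - a)
    # circular arc with chord `chord` and length `desired`:
    # solve sin(t)/t = chord/desired for half-angle t
    f = lambda t: np.sin(t) / t - chord / desired
    t = brentq(f, 1e-6, np.pi - 1e-6)
    radius = chord / (2.0 * np.sin(t))
    mid = 0.5 * (a + b)
    # bow away from the bundle axis (z), orthogonal to the chord;
    # fall back to +x for degenerate midpoints
    chord_dir = (b - a) / chord
    out_dir = mid - np.array([0.0, 0.0, mid[2]])
    out_dir = out_dir - (out_dir @ chord_dir) * chord_dir
    if np.linalg.norm(out_dir) < 1e-6:
        out_dir = np.array([1.0, 0.0, 0.0])
        out_dir = out_dir - (out_dir @ chord_dir) * chord_dir
    out_dir = out_dir / np.linalg.norm(out_dir)
    center = mid - out_dir * radius * np.cos(t)
    u = (a - center) / np.linalg.norm(a - center)
    v_axis = np.cross(np.cross(u, (b - center) / np.linalg.norm(b - center)), u)
    v_axis /= np.linalg.norm(v_axis)
    angles = np.linspace(0.0, 2.0 * t, n_gaps + 1)[1:-1]
    return np.array([center + radius * (np.cos(g) * u + np.sin(g) * v_axis)
                     for g in angles])


def _loop_residues(ca_pts: np.ndarray, before: np.ndarray, after: np.ndarray,
                   start_seq_id: int) -> list[Residue]:
    """Plausible full-atom alanine residues around prescribed loop CA points."""
    residues = []
    ext = np.vstack([before, ca_pts, after])
    for k, ca in enumerate(ca_pts):
        prev_dir = ca - ext[k]
        next_dir = ext[k + 2] - ca
        t = prev_dir + next_dir
        t /= max(np.linalg.norm(t), 1e-9)
        perp = np.cross(t, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(t, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        n_pos = ca - 1.458 * (0.94 * t + 0.34 * perp)
        c_pos = ca + 1.525 * (0.94 * t - 0.34 * perp)
        o_pos = c_pos + 1.231 * perp
        cb_pos = ca + 1.521 * np.cross(t, perp)
        residues.append(Residue(start_seq_id + k, "ALA", [
            Atom("N", "N", n_pos), Atom("CA", "C", ca), Atom("C", "C", c_pos),
            Atom("O", "O", o_pos), Atom("CB", "C", cb_pos),
        ]))
    return residues


def generate_ground_truth(spec: DecoyGenSpec) -> StructureModel:
    """Deterministic up-down helical bundle used as the decoy ground truth."""
    spec.validate()
    slots = _helix_slots(spec)
    helices = []
    seq_id = 1
    for h in range(spec.n_helices):
        residues = _placed_helix(spec, slots[h], seq_id)
        helices.append(residues)
        seq_id += spec.helix_length + (spec.loop_length if h < spec.n_helices - 1 else 0)

    chain: list[Residue] = []
    for h in range(spec.n_helices):
        chain.extend(helices[h])
        if h < spec.n_helices - 1 and spec.loop_length > 0:
            a = helices[h][-1].ca.position
            b = helices[h + 1][0].ca.position
            pts = _arc_points(a, b, spec.loop_length)
            before = helices[h][-2].ca.position if spec.helix_length > 1 else a
            after = helices[h + 1][1].ca.position if spec.helix_length > 1 else b
            start = helices[h][-1].seq_id + 1
            chain.extend(_loop_residues(pts, before, after, start))
    return StructureModel("ground_truth", {"A": chain})


def _apply_noise(model: StructureModel, sigmas: np.ndarray, rng: np.random.Generator) -> None:
    for res, sig in zip(model.chains["A"], sigmas):
        for a in res.atoms:
            a.position = a.position + rng.normal(0.0, sig, 3) if sig > 0 else a.position


def _helix_ranges(spec: DecoyGenSpec) -> list[tuple[int, int]]:
    """Index ranges (start, stop) of helix residues within the chain."""
    ranges = []
    pos = 0
    for h in range(spec.n_helices):
        ranges.append((pos, pos + spec.helix_length))
        pos += spec.helix_length + (spec.loop_length if h < spec.n_helices - 1 else 0)
    return ranges


def generate_decoy_set(spec: DecoyGenSpec) -> DecoySet:
    """Core decoys plus wrong-topology outliers, deterministic given the seed.

    Core decoy model ids carry a ``core_`` prefix and outliers an
    ``outlier_`` prefix so tests can check recovered cluster membership
    against the ground truth.
    """
    spec.validate()
    truth = generate_ground_truth(spec)
    labels = residue_labels(spec)
    rng = np.random.default_rng(spec.seed)
    base_sig = np.array([spec.core_noise if lab == "helix"
                         else spec.core_noise * spec.terminal_noise_multiplier
                         for lab in labels])
    ranges = _helix_ranges(spec)
    slots = _helix_slots(spec)

    decoys = []
    for i in range(spec.n_core_decoys):
        d = truth.copy(model_id=f"core_{i:04d}")
        if spec.core_noise > 0:
            # small per-helix rigid jitter, then per-atom noise
            for (start, stop) in ranges:
                rotvec = rng.normal(0.0, np.radians(2.0) * spec.core_noise, 3)
                shift = rng.normal(0.0, 0.3 * spec.core_noise, 3)
                rot = Rotation.from_rotvec(rotvec).as_matrix()
                seg = d.chains["A"][start:stop]
                pivot = np.mean([r.ca.position for r in seg], axis=0)
                for r in seg:
                    for a in r.atoms:
                        a.position = rot @ (a.position - pivot) + pivot + shift
            _apply_noise(d, base_sig, rng)
        decoys.append(d)

    for i in range(spec.n_outlier_decoys):
        d = truth.copy(model_id=f"outlier_{i:04d}")
        if spec.outlier_noise > 0:
            if spec.n_helices > 1:
                perm = _derangement(spec.n_helices, rng)
                for h, (start, stop) in enumerate(ranges):
                    src_base, src_sign = slots[h]
                    dst_base, dst_sign = slots[perm[h]]
                    delta = dst_base - src_base
                    for r in d.chains["A"][start:stop]:
                        for a in r.atoms:
                            a.position = a.position + delta
            _apply_noise(d, np.full(len(labels), spec.outlier_noise), rng)
        decoys.append(d)

    return DecoySet(decoys, sequence=truth.sequence())


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """A random permutation of range(n) with no fixed point."""
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm
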
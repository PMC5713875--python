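"""Structural quality metrics and the molecular-replacement success classifier.

Implements least-squares rigid superposition (Kabsch), the length-normalised
TM-score with its iterative fragment-seeded maximisation, the RIO
register-overlap count of placed search-model residues against a crystal
structure, and the CC/ACL/R-free success rule applied to externally produced
density-modification and rebuilding statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, ValidationError
from .structure import StructureModel

__all__ = [
    "SuperpositionResult",
    "ModelQuality",
    "RioResult",
    "SolutionAssessment",
    "kabsch",
    "ca_rmsd",
    "tm_score",
    "rio_score",
    "classify_solution",
]

# --------------------------------------------------------------------------
# superposition

@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid map x -> rotation @ x + translation of A onto B."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(a: np.ndarray, b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of point set `a` onto `b` (SVD form).

    Both inputs are (N, 3) with N >= 3; the returned rotation is proper
    (det = +1), with the reflection branch removed in the standard way.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValidationError(f"coordinate sets must share shape (N, 3); got {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    ca_, cb_ = a.mean(axis=0), b.mean(axis=0)
    am, bm = a - ca_, b - cb_
    h = am.T @ bm
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10:
        raise DegenerateGeometryError("collinear point set: rotation is not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cb_ - rot @ ca_
    diff = am @ rot.T - bm
    rmsd = float(np.sqrt((diff ** 2).sum() / a.shape[0]))
    return SuperpositionResult(rot, trans, rmsd)


def ca_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """CA RMSD after optimal superposition."""
    return kabsch(a, b).rmsd


# --------------------------------------------------------------------------
# TM-score

@dataclass(frozen=True)
class ModelQuality:
    """TM-score comparison of a model against a reference."""

    tm_score: float
    aligned_length: int
    rmsd: float


def tm_d0(l_ref: int) -> float:
    """Length-dependent normalisation distance, floored at 0.5 A."""
    return max(0.5, 1.24 * np.cbrt(l_ref - 15.0) - 1.8)


def tm_sum(distances: np.ndarray, d0: float, l_ref: int) -> float:
    """The TM sum: (1/L_ref) * sum_i 1 / (1 + (d_i/d0)^2)."""
    d = np.asarray(distances, dtype=float)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref)


def _lenient_superpose(a: np.ndarray, b: np.ndarray):
    """Least-squares rotation/translation tolerant of collinear subsets.

    Used inside the TM search, where a seed fragment of the reference may be
    (nearly) straight; the rotational ambiguity about the line does not
    change any point-to-line distance, so the TM sum is still well defined.
    """
    ca_, cb_ = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca_).T @ (b - cb_)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, cb_ - rot @ ca_


def _paired_ca(model: StructureModel, reference: StructureModel):
    """CA coordinate pairs matched by (chain-order, residue number)."""
    mod_map = {}
    for cid, residues in model.chains.items():
        for r in residues:
            if r.ca is not None:
                mod_map[(cid, r.seq_id, r.insertion_code)] = r.ca.position
    a, b = [], []
    n_ref = 0
    for cid, residues in reference.chains.items():
        for r in residues:
            if r.ca is None:
                continue
            n_ref += 1
            pos = mod_map.get((cid, r.seq_id, r.insertion_code))
            if pos is None and len(model.chains) == 1 and len(reference.chains) == 1:
                # single-chain comparison tolerates differing chain ids
                pos = mod_map.get((next(iter(model.chains)), r.seq_id, r.insertion_code))
            if pos is not None:
                a.append(pos)
                b.append(r.ca.position)
    return np.array(a), np.array(b), n_ref


def _tm_refine(a: np.ndarray, b: np.ndarray, seed: np.ndarray, d0: float,
               n_norm: int, max_iter: int = 30) -> float:
    """Iteratively refine one seed alignment; returns the best score seen."""
    d0_search = min(max(d0, 4.5), 8.0)
    idx = seed
    best = 0.0
    prev: set[int] = set()
    for _ in range(max_iter):
        if idx.size < 3:
            break
        rot, trans = _lenient_superpose(a[idx], b[idx])
        d = np.linalg.norm(a @ rot.T + trans - b, axis=1)
        best = max(best, tm_sum(d, d0, n_norm))
        cut = d0_search
        sel = np.nonzero(d < cut)[0]
        while sel.size < 3 and cut < 30.0:
            cut += 0.5
            sel = np.nonzero(d < cut)[0]
        if set(sel.tolist()) == prev:
            break
        prev = set(sel.tolist())
        idx = sel
    return best


def tm_score(model: StructureModel, reference: StructureModel) -> ModelQuality:
    """TM-score of `model` against `reference` with residue-number pairing.

    TM = max over superpositions of (1/L_ref) * sum_i 1 / (1 + (d_i/d0)^2)
    with d0 = 1.24 (L_ref - 15)^(1/3) - 1.8, floored at 0.5 A.  The maximum
    is sought by seeding from contiguous fragments at several lengths and
    iterating superposition/selection to convergence, as in the standard
    TM-score procedure.  Residue correspondence is fixed by numbering (same
    sequence); no structural alignment search is performed.
    """
    a, b, l_ref = _paired_ca(model, reference)
    if l_ref == 0:
        raise ValidationError("reference has no CA atoms")
    if a.shape[0] < 3:
        raise ValidationError(
            "models share fewer than 3 residues by numbering; same-sequence input required")
    n = a.shape[0]
    d0 = tm_d0(l_ref)
    if n <= 40:
        # short chains: exhaustive fragment seeding is cheap and removes any
        # dependence on the seed schedule
        lengths = list(range(n, 3, -1))
    else:
        # canonical seed schedule: halve the fragment length down to 4
        lengths = []
        lf = n
        while lf > 4:
            lengths.append(lf)
            lf //= 2
        lengths.append(4)
    best = 0.0
    for lf in lengths:
        if lf > n:
            continue
        for start in range(0, n - lf + 1):
            seed = np.arange(start, start + lf)
            best = max(best, _tm_refine(a, b, seed, d0, l_ref))
    # common-residue RMSD at the global superposition, reported for context
    rmsd = kabsch(a, b).rmsd
    return ModelQuality(tm_score=best, aligned_length=n, rmsd=rmsd)


# --------------------------------------------------------------------------
# RIO

@dataclass(frozen=True)
class RioResult:
    """Register overlap of a placed search model with the crystal structure."""

    in_register: int
    out_of_register: int
    total: int

    @property
    def overlap(self) -> int:
        return self.in_register + self.out_of_register


def rio_score(placed: StructureModel, crystal: StructureModel,
              extra_copies: list[StructureModel] | None = None,
              match_distance: float = 1.5) -> RioResult:
    """Count placed residues overlapping the crystal structure, by register.

    Both models must already sit in the same coordinate frame (no
    superposition is performed): the placed model comes out of molecular
    replacement, and symmetry mates are supplied explicitly via
    `extra_copies`.  A placed residue is overlapped when its CA lies within
    `match_distance` of a crystal CA; overlapped residues are segmented into
    maximal runs in which consecutive placed residues match consecutive
    crystal residues, and only runs of >= 3 residues count.  A run is
    in-register when the placed and crystal residue numbers agree throughout,
    otherwise out-of-register.
    """
    placed_res = [r for r in placed.residues() if r.ca is not None]
    if not placed_res:
        raise ValidationError("placed model has no CA atoms")
    crystal_ca = []  # (copy index, chain id, seq_id, position)
    for ci, xtal in enumerate([crystal] + list(extra_copies or [])):
        for cid, residues in xtal.chains.items():
            for r in residues:
                if r.ca is not None:
                    crystal_ca.append((ci, cid, r.seq_id, r.ca.position))
    if not crystal_ca:
        raise ValidationError("crystal model has no CA atoms")
    tree = cKDTree(np.array([c[3] for c in crystal_ca]))

    matches: list[tuple[int, int, int] | None] = []  # (copy, chain-ordinal, seq) per placed residue
    chain_ord = {cid: i for i, cid in enumerate({c[1]: None for c in crystal_ca})}
    for r in placed_res:
        d, i = tree.query(r.ca.position, distance_upper_bound=match_distance)
        if np.isinf(d):
            matches.append(None)
        else:
            ci, cid, seq, _ = crystal_ca[int(i)]
            matches.append((ci, chain_ord[cid], seq))

    in_reg = out_reg = 0
    run: list[int] = []  # indices into placed_res
    run_step = 0

    def flush() -> None:
        nonlocal in_reg, out_reg
        if len(run) >= 3:
            if all(matches[i][2] == placed_res[i].seq_id for i in run):
                in_reg += len(run)
            else:
                out_reg += len(run)

    for i in range(len(placed_res)):
        m = matches[i]
        if m is None:
            flush()
            run, run_step = [], 0
            continue
        if run:
            pm = matches[run[-1]]
            contiguous = (placed_res[i].seq_id == placed_res[run[-1]].seq_id + 1
                          and m[0] == pm[0] and m[1] == pm[1])
            step = m[2] - pm[2]
            ok = contiguous and step in (1, -1) and (run_step == 0 or step == run_step)
            if ok:
                run.append(i)
                run_step = step
                continue
            flush()
        run, run_step = [i], 0
    flush()
    return RioResult(in_register=in_reg, out_of_register=out_reg, total=len(placed_res))


# --------------------------------------------------------------------------
# success classification

@dataclass(frozen=True)
class SolutionAssessment:
    """Externally measured per-search-model statistics and the success flag.

    shelxe_cc is the density-modification correlation coefficient on the
    percent scale; acl the average traced chain length in residues; rfree
    the free R factor after rebuilding, as a fraction.
    """

    shelxe_cc: float
    acl: float
    rfree: float

    def __post_init__(self) -> None:
        for name in ("shelxe_cc", "acl", "rfree"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValidationError(f"{name} missing or non-finite")
        if not 0.0 <= self.rfree <= 1.0:
            raise ValidationError(f"rfree={self.rfree} outside [0, 1]")
        if self.acl < 0:
            raise ValidationError(f"acl={self.acl} negative")

    @property
    def success(self) -> bool:
        return classify_solution(self)


def classify_solution(a: SolutionAssessment,
                      cc_min: float = 25.00, acl_min: float = 10.00,
                      rfree_max: float = 0.45) -> bool:
    """Success rule for a molecular-replacement solution.

    Success requires a density-modification CC of at least 25.00, an average
    traced chain length strictly greater than 10.00 residues, and a rebuilt
    free R factor of 0.45 or better (i.e. <= 0.45).
    """
    return (a.shelxe_cc >= cc_min) and (a.acl > acl_min) and (a.rfree <= rfree_max)
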
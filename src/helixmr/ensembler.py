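"""Variance-based truncation of a decoy cluster into search ensembles.

The core search-model preparation algorithm: members of the capped top
cluster are superposed on the centroid, per-residue CA variance is measured
across members, residues are ranked by variance and pared away in 20
evenly-spaced size bins, each truncation is subclustered under 1/2/3 A RMSD
radii, and three side-chain treatments are applied.  Each surviving
combination is one search ensemble, named by the quartet
``c<cluster>_t<level>_r<radius>_<mode>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .clustering import DecoyCluster, DecoySet
from .errors import ValidationError
from .scoring import kabsch
from .structure import StructureModel, ca_coords

__all__ = [
    "VarianceProfile",
    "TruncationLevel",
    "Ensemble",
    "EnsembleConfig",
    "per_residue_variance",
    "truncate",
    "subcluster",
    "apply_sidechain_mode",
    "generate_ensembles",
    "SIDECHAIN_MODES",
    "LOW_ROTAMER_RESIDUES",
]

#: side-chain treatments and their tokens in ensemble names
SIDECHAIN_MODES = {"polyalanine": "polyAla", "reliable": "reliable", "allatom": "allatom"}

#: residues whose side chains are kept in 'reliable' mode (<= 3 chi1 rotamers)
LOW_ROTAMER_RESIDUES = frozenset({"ALA", "GLY", "CYS", "PRO", "SER", "THR", "VAL"})

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")


@dataclass(frozen=True)
class VarianceProfile:
    """Per-residue positional variance (A^2) across cluster members."""

    per_residue: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if any(v < 0 for _, v in self.per_residue):
            raise ValidationError("variances must be >= 0")

    def __len__(self) -> int:
        return len(self.per_residue)


@dataclass(frozen=True)
class TruncationLevel:
    """One size bin: the kept lowest-variance residue set."""

    level: int
    kept_residues: frozenset[int]
    fraction: float


@dataclass
class Ensemble:
    """A truncated, subclustered, side-chain-edited search ensemble."""

    cluster_index: int
    truncation_level: int
    subcluster_radius: float
    sidechain_mode: str
    members: list[StructureModel]
    centroid_id: str
    kept_residues: frozenset[int] = field(default_factory=frozenset)

    @property
    def name(self) -> str:
        token = SIDECHAIN_MODES[self.sidechain_mode]
        return (f"c{self.cluster_index}_t{self.truncation_level}"
                f"_r{self.subcluster_radius:g}_{token}")

    @property
    def size(self) -> int:
        return len(self.members)


def per_residue_variance(cluster: DecoyCluster, dset: DecoySet) -> VarianceProfile:
    """Mean squared CA deviation from the across-member mean position.

    Every member is first superposed onto the cluster centroid over all
    shared CA atoms, so rigid-body differences do not contribute.
    """
    if cluster.size < 2:
        raise ValidationError("variance needs at least 2 cluster members")
    members = [dset.by_id(m) for m in cluster.member_ids]
    centroid = dset.by_id(cluster.centroid_id)
    seq_ids = [r.seq_id for r in centroid.residues()]
    ref = ca_coords(centroid)
    aligned = []
    for m in members:
        coords = _member_ca(m, seq_ids)
        sup = kabsch(coords, ref)
        aligned.append(sup.apply(coords))
    arr = np.array(aligned)  # (members, residues, 3)
    mean = arr.mean(axis=0)
    var = ((arr - mean) ** 2).sum(axis=2).mean(axis=0)
    return VarianceProfile(tuple((sid, float(v)) for sid, v in zip(seq_ids, var)))


def _member_ca(model: StructureModel, seq_ids: list[int]) -> np.ndarray:
    by_seq = {r.seq_id: r for r in model.residues()}
    coords = []
    for sid in seq_ids:
        r = by_seq.get(sid)
        if r is None or r.ca is None:
            raise ValidationError(
                f"model {model.model_id!r}: missing CA at shared residue {sid}")
        coords.append(r.ca.position)
    return np.array(coords)


def truncate(profile: VarianceProfile, n_bins: int = 20) -> list[TruncationLevel]:
    """Evenly-spaced size bins over the variance ranking.

    Level k (1-based) keeps the ceil(k*N/n_bins) residues of lowest
    variance; ties at a bin boundary keep the lower residue number first.
    Levels therefore nest and level n_bins keeps everything.
    """
    if len(profile) == 0:
        raise ValidationError("empty variance profile")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    order = sorted(profile.per_residue, key=lambda t: (t[1], t[0]))
    n = len(order)
    levels = []
    for k in range(1, n_bins + 1):
        count = ceil(k * n / n_bins)
        levels.append(TruncationLevel(
            level=k,
            kept_residues=frozenset(sid for sid, _ in order[:count]),
            fraction=count / n,
        ))
    return levels


def truncate_model(model: StructureModel, kept: frozenset[int],
                   model_id: str | None = None) -> StructureModel:
    """Copy of `model` restricted to `kept` residue numbers.

    Retained residues keep their original numbering, so discontiguous
    fragments preserve register for downstream overlap scoring.
    """
    out = StructureModel(model_id or model.model_id, {})
    for cid, residues in model.chains.items():
        sel = [r.copy() for r in residues if r.seq_id in kept]
        if sel:
            out.chains[cid] = sel
    if not out.chains:
        raise ValidationError("truncation removed every residue")
    return out


def _member_rmsd_matrix(members: list[StructureModel]) -> np.ndarray:
    xyz = [ca_coords(m) for m in members]
    n = len(members)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch(xyz[i], xyz[j]).rmsd
    return mat


def subcluster(members: list[StructureModel], radius: float,
               cap: int = 30, rmsd_matrix: np.ndarray | None = None
               ) -> list[StructureModel]:
    """Members within `radius` CA-RMSD of the best-connected member.

    The seed is the member with most neighbours within the radius (ties to
    the lower input index); the seed plus neighbours are returned, capped at
    `cap` models by proximity to the seed.
    """
    if radius <= 0:
        raise ValidationError("radius must be positive")
    if not members:
        return []
    if len(members) == 1:
        return list(members)
    mat = rmsd_matrix if rmsd_matrix is not None else _member_rmsd_matrix(members)
    counts = (mat <= radius).sum(axis=1)
    seed = int(np.argmax(counts))
    neighbours = np.nonzero(mat[seed] <= radius)[0]
    # proximity to seed, ties to lower index; seed itself is at distance 0
    ranked = sorted(neighbours, key=lambda j: (mat[seed, j], j))
    return [members[j] for j in ranked[:cap]]


def apply_sidechain_mode(model: StructureModel, mode: str,
                         low_rotamer: frozenset[str] = LOW_ROTAMER_RESIDUES
                         ) -> StructureModel:
    """One of the three side-chain treatments.

    polyalanine strips every residue to N/CA/C/O/CB; reliable keeps side
    chains only for the low-rotamer residue set; allatom is a plain copy.
    """
    if mode not in SIDECHAIN_MODES:
        raise ValidationError(f"unknown side-chain mode {mode!r}")
    out = model.copy()
    if mode == "allatom":
        return out
    for res in out.residues():
        if mode == "reliable" and res.res_name in low_rotamer:
            continue
        res.atoms = [a for a in res.atoms if a.name in BACKBONE_ATOMS]
    return out


@dataclass(frozen=True)
class EnsembleConfig:
    """Knobs of the factorial ensemble sweep."""

    n_bins: int = 20
    radii: tuple[float, ...] = (1.0, 2.0, 3.0)
    modes: tuple[str, ...] = ("polyalanine", "reliable", "allatom")
    cluster_cap: int = 200
    subcluster_cap: int = 30
    cluster_index: int = 1
    cutoff_range: tuple[float, float] = (0.5, 12.0)
    target_fraction: tuple[float, float] = (0.1, 0.9)
    low_rotamer: frozenset[str] = LOW_ROTAMER_RESIDUES


def generate_ensembles(dset: DecoySet, config: EnsembleConfig = EnsembleConfig(),
                       clusters: list[DecoyCluster] | None = None) -> list[Ensemble]:
    """Full factorial sweep: truncation level x radius x side-chain mode.

    Operates on the capped cluster selected by ``config.cluster_index``
    (clusters are computed here unless supplied).  Within a truncation
    level, a subcluster whose member set duplicates one already emitted at
    that level (for a smaller radius) is dropped; modes multiply the
    surviving (level, radius) pairs.
    """
    from .clustering import cluster_decoys, top_cluster

    if clusters is None:
        clusters = cluster_decoys(dset, config.cutoff_range, config.target_fraction)
    chosen = [c for c in clusters if c.index == config.cluster_index]
    if not chosen:
        raise ValidationError(f"no cluster with index {config.cluster_index}")
    capped = top_cluster([chosen[0]], cap=config.cluster_cap)

    profile = per_residue_variance(capped, dset)
    levels = truncate(profile, config.n_bins)
    members_full = [dset.by_id(m) for m in capped.member_ids]

    ensembles: list[Ensemble] = []
    for lvl in levels:
        truncated = [truncate_model(m, lvl.kept_residues) for m in members_full]
        level_mat = _member_rmsd_matrix(truncated)
        seen: list[frozenset[str]] = []
        for radius in config.radii:
            sub = subcluster(truncated, radius, cap=config.subcluster_cap,
                             rmsd_matrix=level_mat)
            if not sub:
                continue
            key = frozenset(m.model_id for m in sub)
            if key in seen:
                continue
            seen.append(key)
            for mode in config.modes:
                edited = [apply_sidechain_mode(m, mode, config.low_rotamer) for m in sub]
                ensembles.append(Ensemble(
                    cluster_index=capped.index,
                    truncation_level=lvl.level,
                    subcluster_radius=radius,
                    sidechain_mode=mode,
                    members=edited,
                    centroid_id=sub[0].model_id,
                    kept_residues=lvl.kept_residues,
                ))
    return ensembles
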
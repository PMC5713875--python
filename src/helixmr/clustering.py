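"""Structural clustering of ab initio decoy sets and top-cluster selection.

Search-ensemble preparation starts from ~1000 ab initio decoys, takes up to
200 models from the top structural cluster, and feeds them to the
variance-truncation machinery.  The clustering here is a neighbour-count
greedy scheme over the pairwise CA-RMSD matrix with the cutoff auto-adjusted
by bisection, which captures the behaviour of the classic decoy-clustering
programs without claiming bit-compatibility with any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .scoring import kabsch
from .structure import StructureModel, ca_coords

__all__ = [
    "DecoySet",
    "DecoyCluster",
    "pairwise_rmsd_matrix",
    "cluster_decoys",
    "top_cluster",
]


@dataclass
class DecoySet:
    """Same-sequence decoy models, one StructureModel each."""

    decoys: list[StructureModel]
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.decoys and not self.sequence:
            self.sequence = self.decoys[0].sequence()
        counts = {d.n_residues for d in self.decoys}
        if len(counts) > 1:
            raise ValidationError(f"decoys differ in residue count: {sorted(counts)}")

    def __len__(self) -> int:
        return len(self.decoys)

    def by_id(self, model_id: str) -> StructureModel:
        for d in self.decoys:
            if d.model_id == model_id:
                return d
        raise KeyError(model_id)

    def coords(self) -> np.ndarray:
        """(n_decoys, n_residues, 3) stacked CA coordinates."""
        return np.array([ca_coords(d) for d in self.decoys])


@dataclass
class DecoyCluster:
    """One structural cluster: 1-based size rank, centroid and members."""

    index: int
    centroid_id: str
    member_ids: list[str]
    cutoff_used: float
    rmsd_to_centroid: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.centroid_id not in self.member_ids:
            raise ValidationError("centroid must be a cluster member")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValidationError("duplicate member ids in cluster")

    @property
    def size(self) -> int:
        return len(self.member_ids)


def pairwise_rmsd_matrix(dset: DecoySet) -> np.ndarray:
    """Symmetric matrix of CA-RMSD after optimal superposition, zero diagonal."""
    if len(dset) < 2:
        raise ValidationError("need at least 2 decoys for a pairwise matrix")
    xyz = dset.coords()
    n = xyz.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch(xyz[i], xyz[j]).rmsd
            mat[i, j] = mat[j, i] = r
    return mat


def _greedy_clusters(mat: np.ndarray, cutoff: float) -> list[list[int]]:
    """Repeatedly extract the model with most neighbours within cutoff."""
    n = mat.shape[0]
    remaining = list(range(n))
    clusters = []
    while remaining:
        sub = mat[np.ix_(remaining, remaining)]
        counts = (sub <= cutoff).sum(axis=1)  # includes self
        seed_local = int(np.argmax(counts))  # argmax ties -> lowest index
        members_local = np.nonzero(sub[seed_local] <= cutoff)[0]
        members = [remaining[k] for k in members_local]
        seed = remaining[seed_local]
        # seed first, then remaining members in input order
        ordered = [seed] + [m for m in members if m != seed]
        clusters.append(ordered)
        remaining = [r for r in remaining if r not in set(members)]
    return clusters


def _largest_fraction(mat: np.ndarray, cutoff: float) -> float:
    counts = (mat <= cutoff).sum(axis=1)
    return counts.max() / mat.shape[0]


def cluster_decoys(dset: DecoySet,
                   cutoff_range: tuple[float, float] = (0.5, 12.0),
                   target_fraction: tuple[float, float] = (0.1, 0.9),
                   ) -> list[DecoyCluster]:
    """Cluster a decoy set, auto-adjusting the RMSD cutoff by bisection.

    The cutoff is sought within `cutoff_range` so the largest cluster holds a
    fraction of decoys inside `target_fraction` when achievable; otherwise
    the in-range cutoff whose fraction is nearest the band is used.  Clusters
    are extracted greedily (most-neighboured model plus its neighbours),
    ranked by size, with all ties broken toward lower model index.
    """
    if len(dset) == 0:
        raise ValidationError("empty decoy set")
    if len(dset) == 1:
        d = dset.decoys[0]
        return [DecoyCluster(1, d.model_id, [d.model_id], cutoff_used=0.0,
                             rmsd_to_centroid={d.model_id: 0.0})]
    mat = pairwise_rmsd_matrix(dset)
    lo, hi = cutoff_range
    fmin, fmax = target_fraction
    cutoff = None
    best_off = None  # (distance outside band, cutoff)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        frac = _largest_fraction(mat, mid)
        if frac > fmax:
            off = frac - fmax
            hi = mid
        elif frac < fmin:
            off = fmin - frac
            lo = mid
        else:
            cutoff = mid
            break
        if best_off is None or off < best_off[0]:
            best_off = (off, mid)
    if cutoff is None:
        cutoff = best_off[1] if best_off is not None else 0.5 * (lo + hi)

    raw = _greedy_clusters(mat, cutoff)
    raw.sort(key=lambda mem: (-len(mem), min(mem)))
    ids = [d.model_id for d in dset.decoys]
    clusters = []
    for rank, mem in enumerate(raw, start=1):
        seed = mem[0]
        clusters.append(DecoyCluster(
            index=rank,
            centroid_id=ids[seed],
            member_ids=[ids[m] for m in mem],
            cutoff_used=float(cutoff),
            rmsd_to_centroid={ids[m]: float(mat[seed, m]) for m in mem},
        ))
    return clusters


def top_cluster(clusters: list[DecoyCluster], cap: int = 200) -> DecoyCluster:
    """The rank-1 cluster with membership capped to the `cap` models nearest
    the centroid (the centroid itself is always retained)."""
    if not clusters:
        raise ValidationError("no clusters given")
    top = min(clusters, key=lambda c: c.index)
    if top.size <= cap:
        return top
    others = [m for m in top.member_ids if m != top.centroid_id]
    others.sort(key=lambda m: (top.rmsd_to_centroid.get(m, np.inf),
                               top.member_ids.index(m)))
    keep = [top.centroid_id] + others[: cap - 1]
    return DecoyCluster(
        index=top.index,
        centroid_id=top.centroid_id,
        member_ids=keep,
        cutoff_used=top.cutoff_used,
        rmsd_to_centroid={m: top.rmsd_to_centroid[m] for m in keep},
    )
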
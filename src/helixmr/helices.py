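"""Ideal polyalanine alpha-helices built from internal coordinates.

The library used for helix-only molecular replacement holds eight ideal
polyalanine helices of 5-40 residues built with backbone dihedrals
phi = -57.8 deg and psi = -47.0 deg.  Bond lengths and angles are fixed at
standard (Engh/Huber-style) values; only the dihedrals are free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geom
from .errors import ValidationError
from .structure import Atom, Residue, StructureModel

__all__ = [
    "HelixBuildParams",
    "build_ideal_helix",
    "build_bent_helix",
    "helix_library",
    "measure_dihedrals",
    "LIBRARY_LENGTHS",
    "IDEAL_PHI",
    "IDEAL_PSI",
]

IDEAL_PHI = -57.8
IDEAL_PSI = -47.0
LIBRARY_LENGTHS = (5, 10, 15, 20, 25, 30, 35, 40)

# standard backbone geometry (Angstroms / degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
B_CA_CB = 1.521
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.8
A_N_CA_CB = 110.5
T_CB_IMPROPER = 122.6  # torsion N-C-CA-CB for an L-amino acid
CHAIN_BREAK_CN = 2.5  # Angstroms; C-N beyond this is a chain break


@dataclass(frozen=True)
class HelixBuildParams:
    """Dihedral recipe for an ideal helix."""

    n_residues: int
    phi: float = IDEAL_PHI
    psi: float = IDEAL_PSI
    omega: float = 180.0

    def validate(self) -> None:
        if self.n_residues < 2:
            raise ValidationError("an ideal helix needs at least 2 residues")
        for name, v in (("phi", self.phi), ("psi", self.psi), ("omega", self.omega)):
            if not -180.0 < v <= 180.0:
                raise ValidationError(f"{name}={v} outside (-180, 180]")


def build_ideal_helix(params: HelixBuildParams | int,
                      phi: float = IDEAL_PHI, psi: float = IDEAL_PSI,
                      chain_id: str = "A", start_seq_id: int = 1,
                      model_id: str | None = None) -> StructureModel:
    """Build a polyalanine helix (atoms N, CA, C, O, CB) from internal coordinates.

    The first residue sits in a canonical frame at the origin; every interior
    residue measures exactly the requested phi/psi.
    """
    if isinstance(params, int):
        params = HelixBuildParams(params, phi, psi)
    params.validate()
    n = params.n_residues

    # canonical first-residue frame
    n0 = np.zeros(3)
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    ang = np.radians(A_N_CA_C)
    c0 = ca0 + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    backbone: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, n):
        prev = backbone[-1]
        n_i = geom.nerf(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, params.psi)
        ca_i = geom.nerf(prev["CA"], prev["C"], n_i, B_N_CA, A_C_N_CA, params.omega)
        c_i = geom.nerf(prev["C"], n_i, ca_i, B_CA_C, A_N_CA_C, params.phi)
        backbone.append({"N": n_i, "CA": ca_i, "C": c_i})

    residues = []
    for i, bb in enumerate(backbone):
        o_i = geom.nerf(bb["N"], bb["CA"], bb["C"], B_C_O, A_CA_C_O, params.psi + 180.0)
        cb_i = geom.nerf(bb["N"], bb["C"], bb["CA"], B_CA_CB, A_N_CA_CB, T_CB_IMPROPER)
        atoms = [
            Atom("N", "N", bb["N"]),
            Atom("CA", "C", bb["CA"]),
            Atom("C", "C", bb["C"]),
            Atom("O", "O", o_i),
            Atom("CB", "C", cb_i),
        ]
        residues.append(Residue(start_seq_id + i, "ALA", atoms))
    mid = model_id if model_id is not None else f"polyala_helix_{n}"
    return StructureModel(mid, {chain_id: residues})


def build_bent_helix(n_residues: int, bend_angle_deg: float,
                     phi: float = IDEAL_PHI, psi: float = IDEAL_PSI) -> StructureModel:
    """Two ideal helical segments whose axes meet at a controlled angle.

    The downstream half of a straight ideal helix is rotated about a point on
    the fitted helix axis at the junction, about an axis perpendicular to the
    helix axis, so the inter-segment axis angle equals `bend_angle_deg`.
    """
    if n_residues < 8:
        raise ValidationError("a two-segment helix needs at least 8 residues")
    model = build_ideal_helix(HelixBuildParams(n_residues, phi, psi),
                              model_id=f"bent_helix_{bend_angle_deg:g}")
    residues = model.chains["A"]
    ca = np.array([r.ca.position for r in residues])
    centroid, axis = geom.fit_axis(ca)
    half = n_residues // 2
    # pivot: projection of the junction CA onto the helix axis
    junction = ca[half]
    pivot = centroid + ((junction - centroid) @ axis) * axis
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    rot = geom.rotation_about_axis(perp, bend_angle_deg)
    for res in residues[half:]:
        for a in res.atoms:
            a.position = rot @ (a.position - pivot) + pivot
    return model


def helix_library(lengths: tuple[int, ...] = LIBRARY_LENGTHS) -> list[StructureModel]:
    """The ideal-helix search library: one polyalanine helix per length."""
    return [build_ideal_helix(HelixBuildParams(n)) for n in sorted(lengths)]


def measure_dihedrals(model: StructureModel, chain: str | None = None
                      ) -> list[tuple[float | None, float | None]]:
    """Per-residue (phi, psi) in degrees; None where undefined.

    phi is undefined for the first residue, psi for the last; both are
    undefined across a chain break (peptide C-N distance > 2.5 A).
    """
    cid = chain if chain is not None else model.first_chain_id()
    residues = model.chains.get(cid)
    if residues is None:
        raise ValidationError(f"no chain {cid!r}")
    bb = []
    for r in residues:
        atoms = {nm: r.atom(nm) for nm in ("N", "CA", "C")}
        if any(a is None for a in atoms.values()):
            raise ValidationError(
                f"residue {r.seq_id}: incomplete N/CA/C backbone for dihedral measurement")
        bb.append({nm: a.position for nm, a in atoms.items()})

    def linked(i: int) -> bool:
        return np.linalg.norm(bb[i + 1]["N"] - bb[i]["C"]) <= CHAIN_BREAK_CN

    out: list[tuple[float | None, float | None]] = []
    for i in range(len(bb)):
        phi_i = psi_i = None
        if i > 0 and linked(i - 1):
            phi_i = geom.torsion(bb[i - 1]["C"], bb[i]["N"], bb[i]["CA"], bb[i]["C"])
        if i < len(bb) - 1 and linked(i):
            psi_i = geom.torsion(bb[i]["N"], bb[i]["CA"], bb[i]["C"], bb[i + 1]["N"])
        out.append((phi_i, psi_i))
    return out
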
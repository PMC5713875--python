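"""Coordinate I/O and the shared structural data model.

A :class:`StructureModel` is an ordered map of chains, each an ordered list
of residues carrying named atoms with 3-D coordinates in Angstroms.  It is
the universal coordinate object passed between the clustering, truncation
and scoring stages.

Only the PDB coordinate subset (ATOM/TER/END/MODEL records, fixed columns)
is supported; decoy sets are distributed one-file-per-model, so only the
first MODEL block of a multi-model file is read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ChainLookupError,
    EmptyStructureError,
    PdbFormatError,
    ValidationError,
)

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "read_pdb",
    "write_pdb",
    "ca_trace",
]

#: 3-letter codes of the 20 standard amino acids.
STANDARD_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET
       PHE PRO SER THR TRP TYR VAL""".split()
)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


@dataclass
class Atom:
    """A named atom with coordinates in Angstroms."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.name:
            raise ValidationError("atom name must be non-empty")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValidationError(f"atom {self.name}: position must be a finite 3-vector")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy())


@dataclass
class Residue:
    """One residue: author numbering, 3-letter code and an ordered atom list."""

    seq_id: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    def copy(self) -> "Residue":
        return Residue(self.seq_id, self.res_name, [a.copy() for a in self.atoms],
                       self.insertion_code)

    def sort_key(self) -> tuple[int, str]:
        return (self.seq_id, self.insertion_code)


@dataclass
class StructureModel:
    """A protein model: ordered map chain-id -> ordered residue list."""

    model_id: str = "model"
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def residues(self, chain: str | None = None):
        """Iterate residues, over one chain or all chains in order."""
        if chain is not None:
            if chain not in self.chains:
                raise ChainLookupError(f"no chain {chain!r} in model {self.model_id!r}")
            yield from self.chains[chain]
        else:
            for residues in self.chains.values():
                yield from residues

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.residues())

    def first_chain_id(self) -> str:
        if not self.chains:
            raise EmptyStructureError(f"model {self.model_id!r} has no chains")
        return next(iter(self.chains))

    def sequence(self, chain: str | None = None) -> str:
        """1-letter sequence; nonstandard residues map to X."""
        return "".join(AA3_TO_1.get(r.res_name, "X") for r in self.residues(chain))

    def copy(self, model_id: str | None = None) -> "StructureModel":
        return StructureModel(
            model_id if model_id is not None else self.model_id,
            {cid: [r.copy() for r in residues] for cid, residues in self.chains.items()},
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    model_id: str | None = None) -> "StructureModel":
        """Return a rigidly moved copy: x -> rotation @ x + translation."""
        out = self.copy(model_id)
        for res in out.residues():
            for a in res.atoms:
                a.position = rotation @ a.position + translation
        return out


def _parse_atom_line(line: str, lineno: int):
    """Parse one fixed-column ATOM record."""
    if len(line) < 54:
        raise PdbFormatError(f"line {lineno}: ATOM record too short")
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        seq_id = int(line[22:26])
        icode = line[26].strip()
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
    except ValueError as exc:
        raise PdbFormatError(f"line {lineno}: unparseable ATOM record ({exc})") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[:1]
    return name, altloc, seq_id, icode, res_name, occ, xyz, element, chain_id


def read_pdb(path) -> StructureModel:
    """Read the first MODEL block of a PDB file.

    Altloc groups are resolved to the highest-occupancy conformer (ties break
    to the lexicographically first altloc id); HETATM records and hydrogens
    are ignored.
    """
    # chains -> residue key -> (Residue, atom name -> (occ, altloc))
    chains: dict[str, dict[tuple[int, str], Residue]] = {}
    best: dict[tuple[str, int, str, str], tuple[float, str]] = {}
    in_model = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6]
            if rec.startswith("MODEL"):
                in_model += 1
                if in_model > 1:
                    break
            elif rec.startswith("ENDMDL"):
                break
            elif rec == "ATOM  ":
                (name, altloc, seq_id, icode, res_name, occ, xyz, element,
                 chain_id) = _parse_atom_line(raw.rstrip("\n"), lineno)
                if element in ("H", "D"):
                    continue
                resmap = chains.setdefault(chain_id, {})
                key = (seq_id, icode)
                res = resmap.get(key)
                if res is None:
                    res = resmap[key] = Residue(seq_id, res_name, [], icode)
                akey = (chain_id, seq_id, icode, name)
                existing = res.atom(name)
                if existing is None:
                    res.atoms.append(Atom(name, element, xyz))
                    best[akey] = (occ, altloc)
                else:
                    prev_occ, prev_alt = best[akey]
                    if occ > prev_occ or (occ == prev_occ and altloc < prev_alt):
                        existing.position = xyz
                        best[akey] = (occ, altloc)
    if not chains:
        raise EmptyStructureError(f"{path}: no ATOM records found")
    model_id = os.path.splitext(os.path.basename(str(path)))[0]
    return StructureModel(model_id, {cid: list(resmap.values()) for cid, resmap in chains.items()})


def _pdb_body_lines(model: StructureModel) -> list[str]:
    if not model.chains or model.n_atoms == 0:
        raise ValidationError("cannot write an empty model")
    lines: list[str] = []
    serial = 0
    for chain_id, residues in model.chains.items():
        if len(chain_id) != 1:
            raise ValidationError(f"chain id {chain_id!r} must be a single character")
        if not residues:
            raise ValidationError(f"chain {chain_id!r} has no residues")
        for res in residues:
            if not res.atoms:
                raise ValidationError(
                    f"residue {res.res_name} {chain_id}{res.seq_id} has no atoms")
            for a in res.atoms:
                serial += 1
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4.4s} {res.res_name:<3s} {chain_id}"
                    f"{res.seq_id:4d}{res.insertion_code or ' '}   "
                    f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                    f"  1.00  0.00          {a.element:>2.2s}"
                )
        serial += 1
        last = residues[-1]
        lines.append(f"TER   {serial:5d}      {last.res_name:<3s} {chain_id}"
                     f"{last.seq_id:4d}{last.insertion_code or ' '}")
    return lines


def write_pdb(model: StructureModel, path) -> None:
    """Write fixed-column ATOM records, serials from 1, TER per chain, END."""
    lines = _pdb_body_lines(model) + ["END"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_multimodel_pdb(models: list[StructureModel], path) -> None:
    """Write an NMR-style multi-model PDB (MODEL/ENDMDL blocks)."""
    if not models:
        raise ValidationError("no models to write")
    lines: list[str] = []
    for i, m in enumerate(models, start=1):
        lines.append(f"MODEL     {i:4d}")
        lines.extend(_pdb_body_lines(m))
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def ca_trace(model: StructureModel, chain: str) -> list[tuple[int, np.ndarray]]:
    """Ordered (seq_id, CA position) for every residue of `chain` with a CA."""
    if chain not in model.chains:
        raise ChainLookupError(f"no chain {chain!r} in model {model.model_id!r}")
    out = []
    for res in model.chains[chain]:
        ca = res.ca
        if ca is not None:
            out.append((res.seq_id, ca.position))
    return out


def ca_coords(model: StructureModel, chain: str | None = None) -> np.ndarray:
    """(N, 3) array of CA coordinates over one chain or the whole model."""
    pts = [r.ca.position for r in model.residues(chain) if r.ca is not None]
    if not pts:
        raise EmptyStructureError(f"model {model.model_id!r}: no CA atoms")
    return np.array(pts)
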
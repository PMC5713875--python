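"""Residue-contact predictions: parsing, top-L selection, restraints, precision.

Predicted residue-residue contacts arrive as ranked pair lists (CASP RR
style or plain 3-column text).  The top-L pairs (L = sequence length) are
converted into Rosetta AtomPair restraints with the FADE functional form
between C-beta atoms (C-alpha for glycine), and prediction quality is
measured as precision against a structure at an 8 A C-beta-C-beta cutoff,
optionally across an oligomer interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import PdbFormatError, ValidationError
from .structure import StructureModel

__all__ = [
    "ContactPrediction",
    "FadeParams",
    "RestraintSet",
    "parse_contacts",
    "write_contacts",
    "select_top_L",
    "contacts_to_restraints",
    "contact_precision",
    "interface_contacts",
]

logger = logging.getLogger(__name__)

#: minimum |j - i| for an accepted contact
DEFAULT_MIN_SEPARATION = 5
#: C-beta--C-beta distance (A) at or below which a pair is a true contact
CONTACT_CUTOFF = 8.0


@dataclass(frozen=True)
class ContactPrediction:
    """One predicted residue pair with its confidence score."""

    res_i: int
    res_j: int
    confidence: float

    def __post_init__(self) -> None:
        if self.res_i >= self.res_j:
            raise ValidationError(f"contact must have res_i < res_j, got ({self.res_i}, {self.res_j})")
        if self.confidence < 0:
            raise ValidationError("confidence must be >= 0")


@dataclass(frozen=True)
class FadeParams:
    """FADE restraint parameters (bounds and fade zone in A, depth in Rosetta
    energy units).  Defaults follow common contact-restraint practice for
    ab initio folding and are expected to be overridden from config."""

    lower: float = -10.0
    upper: float = 19.0
    fade_zone: float = 10.0
    well_depth: float = -15.00


@dataclass(frozen=True)
class RestraintSet:
    """Atom-pair distance restraints in a named file dialect."""

    restraints: tuple[tuple[str, int, str, int, str, FadeParams], ...]
    format_dialect: str = "rosetta"

    def __len__(self) -> int:
        return len(self.restraints)

    def to_lines(self) -> list[str]:
        lines = [f"# {len(self.restraints)} atom-pair FADE restraints"]
        for atom_i, res_i, atom_j, res_j, func, p in self.restraints:
            lines.append(
                f"AtomPair {atom_i} {res_i} {atom_j} {res_j} {func} "
                f"{p.lower:g} {p.upper:g} {p.fade_zone:g} {p.well_depth:.2f}"
            )
        return lines

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.to_lines()) + "\n")


_RR_HEADERS = ("PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL", "REMARK", "END")


def parse_contacts(path, dialect: str = "casp_rr",
                   min_separation: int = DEFAULT_MIN_SEPARATION) -> list[ContactPrediction]:
    """Parse ranked contact predictions.

    ``casp_rr`` lines are ``i j d_low d_high confidence``; ``3col`` lines are
    ``i j confidence``.  Pairs are normalised to res_i < res_j, duplicates
    collapse to the highest confidence, and pairs closer in sequence than
    `min_separation` are discarded.
    """
    if dialect not in ("casp_rr", "3col"):
        raise ValidationError(f"unknown contact dialect {dialect!r}")
    best: dict[tuple[int, int], float] = {}
    order: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if dialect == "casp_rr":
                if line.split()[0].upper() in _RR_HEADERS:
                    continue
                if line.isalpha():  # wrapped target sequence block
                    continue
            tok = line.split()
            want = 5 if dialect == "casp_rr" else 3
            if len(tok) != want:
                raise PdbFormatError(
                    f"line {lineno}: expected {want} fields for {dialect}, got {len(tok)}")
            try:
                i, j = int(tok[0]), int(tok[1])
                conf = float(tok[-1])
            except ValueError as exc:
                raise PdbFormatError(f"line {lineno}: {exc}") from exc
            if i == j:
                raise PdbFormatError(f"line {lineno}: self-contact ({i}, {j})")
            if i > j:
                i, j = j, i
            if j - i < min_separation:
                continue
            if (i, j) not in best:
                order.append((i, j))
                best[(i, j)] = conf
            else:
                best[(i, j)] = max(best[(i, j)], conf)
    return [ContactPrediction(i, j, best[(i, j)]) for i, j in order]


def write_contacts(contacts: list[ContactPrediction], path,
                   dialect: str = "casp_rr") -> None:
    """Serialise contacts in the given dialect (inverse of parse_contacts)."""
    lines = []
    if dialect == "casp_rr":
        lines.append("PFRMAT RR")
        lines.extend(f"{c.res_i} {c.res_j} 0 8 {c.confidence:g}" for c in contacts)
        lines.append("END")
    elif dialect == "3col":
        lines.extend(f"{c.res_i} {c.res_j} {c.confidence:g}" for c in contacts)
    else:
        raise ValidationError(f"unknown contact dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def select_top_L(contacts: list[ContactPrediction], L: int) -> list[ContactPrediction]:
    """The L highest-confidence pairs (L = target sequence length).

    Ties break to the smaller res_i, then smaller res_j, so selection is
    deterministic.
    """
    if L < 0:
        raise ValidationError("L must be >= 0")
    ranked = sorted(contacts, key=lambda c: (-c.confidence, c.res_i, c.res_j))
    return ranked[:L]


def contacts_to_restraints(contacts: list[ContactPrediction], sequence: str,
                           params: FadeParams = FadeParams()) -> RestraintSet:
    """One FADE AtomPair restraint per contact, C-beta based (C-alpha for Gly).

    `sequence` is the 1-letter target sequence indexed from residue 1.
    """
    restraints = []
    for c in contacts:
        atoms = []
        for res in (c.res_i, c.res_j):
            if not 1 <= res <= len(sequence):
                raise ValidationError(f"contact residue {res} outside sequence of length {len(sequence)}")
            aa = sequence[res - 1]
            if aa not in "ACDEFGHIKLMNPQRSTVWY":
                raise ValidationError(f"unknown residue {aa!r} at position {res}")
            atoms.append("CA" if aa == "G" else "CB")
        restraints.append((atoms[0], c.res_i, atoms[1], c.res_j, "FADE", params))
    return RestraintSet(tuple(restraints), format_dialect="rosetta")


def _contact_atom_map(structure: StructureModel) -> dict[int, np.ndarray]:
    """seq_id -> contact-distance atom position (CB, falling back to CA)."""
    out = {}
    for res in structure.residues():
        atom = res.atom("CB")
        if atom is None or res.res_name == "GLY":
            atom = res.atom("CA") or atom
        if atom is not None:
            out[res.seq_id] = atom.position
    return out


def contact_precision(contacts: list[ContactPrediction], structure: StructureModel,
                      cutoff: float = CONTACT_CUTOFF) -> float:
    """Fraction of predicted pairs realised in `structure` at <= `cutoff` A.

    Distances are C-beta to C-beta (C-alpha for glycine or when C-beta is
    absent).  Pairs referencing residues missing from the structure count as
    false and are reported through the module logger.
    """
    if not contacts:
        raise ValidationError("no contacts to evaluate")
    pos = _contact_atom_map(structure)
    true = 0
    missing = 0
    for c in contacts:
        a, b = pos.get(c.res_i), pos.get(c.res_j)
        if a is None or b is None:
            missing += 1
            continue
        if np.linalg.norm(a - b) <= cutoff:
            true += 1
    if missing:
        logger.warning("%d/%d contact pairs reference residues absent from %s; counted false",
                       missing, len(contacts), structure.model_id)
    return true / len(contacts)


def interface_contacts(contacts: list[ContactPrediction],
                       chain_a: StructureModel, chain_b: StructureModel,
                       cutoff: float = CONTACT_CUTOFF) -> tuple[int, float]:
    """Count predicted pairs realised across an oligomer interface.

    A pair (i, j) is an interface contact when residue i of one protomer and
    residue j of the other lie within `cutoff` (C-beta convention), in either
    direction.  Returns the count and the mean confidence of those pairs
    (0.0 when none).
    """
    if not contacts:
        raise ValidationError("no contacts to evaluate")
    pa = _contact_atom_map(chain_a)
    pb = _contact_atom_map(chain_b)
    found = []
    for c in contacts:
        hit = False
        for m1, m2 in ((pa, pb), (pb, pa)):
            x, y = m1.get(c.res_i), m2.get(c.res_j)
            if x is not None and y is not None and np.linalg.norm(x - y) <= cutoff:
                hit = True
                break
        if hit:
            found.append(c.confidence)
    return len(found), (float(np.mean(found)) if found else 0.0)
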
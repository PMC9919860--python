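"""Molecule containers, SDF I/O and rigid common-core superposition.

Molecules are labeled 3D point sets: each atom carries an element symbol, a
van der Waals class (Tripos-style, e.g. ``C.3``), Cartesian coordinates in
Angstrom and a partial charge in elementary-charge units.  Partial charges are
mandatory because the electrostatic field computation needs them; they travel
in a named SDF property field rather than in the (integer-only) V2000 charge
block.

Alignment of a congeneric series onto a template is done by Kabsch
superposition over an explicit common-core atom mapping supplied by the user;
no substructure search is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from .errors import DegenerateGeometryError, ParameterError, ParseError

_CHARGE_PROP = "PARTIAL_CHARGES"
_VDW_PROP = "VDW_CLASSES"
_PIC50_PROP = "PIC50"


@dataclass
class Molecule:
    """A labeled 3D point set with optional activity.

    Parameters
    ----------
    id : str
        Unique compound identifier within a set.
    elements : list of str
        Element symbol per atom.
    vdw_classes : list of str
        Van der Waals class per atom (keys into the field engine's tables).
    coords : (n_atoms, 3) ndarray
        Cartesian coordinates, Angstrom.
    charges : (n_atoms,) ndarray
        Partial charges, elementary charge units.
    pic50 : float, optional
        -log10(IC50 / M); more positive = more potent.
    """

    id: str
    elements: list[str]
    vdw_classes: list[str]
    coords: np.ndarray
    charges: np.ndarray
    pic50: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ParameterError(
                f"molecule {self.id}: coords shape {self.coords.shape} != ({n}, 3)"
            )
        if self.charges.shape != (n,):
            raise ParameterError(f"molecule {self.id}: one charge per atom required")
        if len(self.vdw_classes) != n:
            raise ParameterError(f"molecule {self.id}: one vdW class per atom required")
        if not np.all(np.isfinite(self.coords)):
            raise ParameterError(f"molecule {self.id}: non-finite coordinates")
        if not np.all(np.isfinite(self.charges)):
            raise ParameterError(f"molecule {self.id}: non-finite charges")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        """Return a copy with coordinates mapped through ``R x + t``."""
        new_coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return replace(self, coords=new_coords)


class MoleculeSet:
    """An ordered collection of molecules with unique ids."""

    def __init__(self, molecules: Iterable[Molecule]):
        self.molecules: list[Molecule] = list(molecules)
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ParameterError(f"duplicate molecule ids: {dupes}")

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self) -> Iterator[Molecule]:
        return iter(self.molecules)

    def __getitem__(self, key: int | str) -> Molecule:
        if isinstance(key, str):
            for m in self.molecules:
                if m.id == key:
                    return m
            raise KeyError(key)
        return self.molecules[key]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    def all_coords(self) -> np.ndarray:
        """Stacked coordinates of every atom in the set."""
        return np.vstack([m.coords for m in self.molecules])


@dataclass
class CoreMapping:
    """Atom index pairs mapping a molecule onto the template's common core."""

    pairs: list[tuple[int, int]]  # (template_atom_index, target_atom_index)
    template_id: str = ""

    def __post_init__(self) -> None:
        if len(self.pairs) < 3:
            raise ParameterError("core mapping needs at least 3 atom pairs")
        t_idx = [p[0] for p in self.pairs]
        m_idx = [p[1] for p in self.pairs]
        if len(set(t_idx)) != len(t_idx) or len(set(m_idx)) != len(m_idx):
            raise ParameterError("duplicate atom indices in core mapping")

    @property
    def template_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def target_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


@dataclass
class SuperpositionResult:
    """Rigid transform minimizing least-squares distance over paired points."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float  # over the mapped atoms, Angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# SDF I/O (RDKit-backed; molecules need not have chemically valid bond graphs)
# ---------------------------------------------------------------------------

def _to_rdkit(mol: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for el in mol.elements:
        rw.AddAtom(Chem.Atom(el))
    m = rw.GetMol()
    conf = Chem.Conformer(mol.n_atoms)
    for i, (x, y, z) in enumerate(mol.coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    m.AddConformer(conf)
    m.UpdatePropertyCache(strict=False)
    m.SetProp("_Name", mol.id)
    m.SetProp(_CHARGE_PROP, " ".join(f"{q:.6f}" for q in mol.charges))
    m.SetProp(_VDW_PROP, " ".join(mol.vdw_classes))
    if mol.pic50 is not None:
        m.SetProp(_PIC50_PROP, f"{mol.pic50:.6f}")
    return m


def write_molecules(mset: MoleculeSet | Sequence[Molecule], path) -> None:
    """Write a molecule set as a V2000 SDF with charges/classes in properties."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    try:
        for mol in mset:
            writer.write(_to_rdkit(mol))
    finally:
        writer.close()


def read_molecules(path, activities=None) -> MoleculeSet:
    """Read a V2000 SDF into a :class:`MoleculeSet`.

    Parameters
    ----------
    path : path-like
        SDF file with per-record ``PARTIAL_CHARGES`` and ``VDW_CLASSES``
        properties (space-separated, one entry per atom).
    activities : pandas.DataFrame, optional
        Table with columns ``id`` and ``pIC50``; joined onto molecules by id.

    Raises
    ------
    ParseError
        On an unparseable record or a record missing the charge property,
        naming the (1-based) record index.
    """
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    act = None
    if activities is not None:
        act = dict(zip(activities["id"].astype(str), activities["pIC50"].astype(float)))
    out: list[Molecule] = []
    for rec, rdmol in enumerate(supplier, start=1):
        if rdmol is None:
            raise ParseError(f"malformed SDF record {rec} in {path}")
        if not rdmol.HasProp(_CHARGE_PROP):
            raise ParseError(
                f"SDF record {rec} is missing the mandatory {_CHARGE_PROP} property"
            )
        n = rdmol.GetNumAtoms()
        charges = np.array([float(v) for v in rdmol.GetProp(_CHARGE_PROP).split()])
        if charges.size != n:
            raise ParseError(f"SDF record {rec}: {charges.size} charges for {n} atoms")
        if rdmol.HasProp(_VDW_PROP):
            classes = rdmol.GetProp(_VDW_PROP).split()
        else:  # fall back to bare element symbols as classes
            classes = [a.GetSymbol() for a in rdmol.GetAtoms()]
        conf = rdmol.GetConformer()
        coords = np.array(
            [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
             for i in range(n)]
        )
        mol_id = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else f"mol{rec}"
        pic50 = None
        if rdmol.HasProp(_PIC50_PROP):
            pic50 = float(rdmol.GetProp(_PIC50_PROP))
        if act is not None and mol_id in act:
            pic50 = act[mol_id]
        out.append(
            Molecule(
                id=mol_id,
                elements=[a.GetSymbol() for a in rdmol.GetAtoms()],
                vdw_classes=classes,
                coords=coords,
                charges=charges,
                pic50=pic50,
            )
        )
    return MoleculeSet(out)


# ---------------------------------------------------------------------------
# Kabsch superposition and set alignment
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Uses the SVD form of the Kabsch algorithm with a determinant correction so
    that only proper rotations (det = +1) are returned; chirality is never
    inverted.  Both point lists must be the same length (>= 3) and
    non-collinear.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ParameterError("mobile and reference must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise ParameterError("at least 3 paired points required")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    scale = max(np.abs(P0).max(), np.abs(Q0).max(), 1.0)
    if (np.linalg.matrix_rank(P0, tol=1e-8 * scale) < 2
            or np.linalg.matrix_rank(Q0, tol=1e-8 * scale) < 2):
        raise DegenerateGeometryError("collinear or coincident points: rotation ill-defined")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def align_set(
    mset: MoleculeSet,
    template: Molecule,
    mappings: dict[str, CoreMapping],
) -> tuple[MoleculeSet, dict[str, float]]:
    """Rigidly superpose every molecule onto the template via its core mapping.

    Returns the aligned set (template molecule unchanged if it maps onto
    itself) and the per-molecule core RMSD in Angstrom.
    """
    missing = [m.id for m in mset if m.id not in mappings]
    if missing:
        raise ParameterError(f"no core mapping for compounds: {missing}")
    aligned: list[Molecule] = []
    rmsds: dict[str, float] = {}
    for mol in mset:
        mp = mappings[mol.id]
        res = kabsch_superpose(
            mol.coords[mp.target_indices], template.coords[mp.template_indices]
        )
        aligned.append(mol.transformed(res.rotation, res.translation))
        rmsds[mol.id] = res.rmsd
    return MoleculeSet(aligned), rmsds


def identity_mappings(mset: MoleculeSet, template: Molecule, n_core: int) -> dict[str, CoreMapping]:
    """Convenience: map the first ``n_core`` atoms of each molecule 1:1 onto
    the template's first ``n_core`` atoms (the layout the synthetic generator
    produces)."""
    pairs = [(i, i) for i in range(n_core)]
    return {m.id: CoreMapping(pairs=list(pairs), template_id=template.id) for m in mset}
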
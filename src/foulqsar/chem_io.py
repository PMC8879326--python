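"""Molecule data model, SDF V2000 I/O, standardization and deduplication.

The in-memory model is deliberately small: an atom is an element symbol, a
3D position, a formal charge and (once assigned) a partial charge; a bond is
an index pair with an order code. Everything heavier — connection-table
parsing, canonical identifiers, SMILES — is delegated to RDKit behind this
module's surface, so the rest of the package never touches an RDKit object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger


RDLogger.DisableLog("rdApp.*")

#: Elements the pipeline is parameterized for.
SUPPORTED_ELEMENTS = frozenset({"H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"})

#: Standard atomic weights (u) for the supported elements.
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "Cl": 35.45, "Br": 79.904, "I": 126.904,
}

#: Usual valences used when filling hydrogens.
STANDARD_VALENCE = {
    "H": 1, "C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

#: Bond-order code for aromatic bonds (SDF V2000 convention).
AROMATIC = 4


class ChemError(ValueError):
    """Base error for molecule handling."""


class SdfParseError(ChemError):
    """Raised when an SDF block cannot be parsed; names the block index."""


class UnsupportedElementError(ChemError):
    """Raised when a structure contains an element outside the supported set."""


@dataclass
class Atom:
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    formal_charge: int = 0
    partial_charge: float | None = None
    #: tetrahedral parity code (RDKit ChiralType value); interpreted relative
    #: to the molecule's stored bond order, so it survives round-trips but is
    #: not meaningful after arbitrary atom/bond reshuffling.
    chiral_tag: int = 0

    def __post_init__(self) -> None:
        if self.element not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(
                f"unsupported element symbol: {self.element!r}"
            )
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ChemError(f"atom coordinates must be a finite 3-vector: {self.coords}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass(frozen=True)
class Bond:
    a1: int
    a2: int
    order: int = 1  # 1, 2, 3 or AROMATIC (4)

    def __post_init__(self) -> None:
        if self.a1 == self.a2:
            raise ChemError(f"bond connects an atom to itself: {self.a1}")
        if self.order not in (1, 2, 3, AROMATIC):
            raise ChemError(f"unsupported bond order code: {self.order}")

    def conventional_order(self) -> float:
        """1, 2, 3, or 1.5 for aromatic."""
        return 1.5 if self.order == AROMATIC else float(self.order)


@dataclass
class Molecule:
    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    source: str = ""
    properties: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n < 1:
            raise ChemError(f"molecule {self.id!r} has no atoms")
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.a1 < n and 0 <= b.a2 < n):
                raise ChemError(f"molecule {self.id!r}: bond index out of range: {b}")
            key = (min(b.a1, b.a2), max(b.a1, b.a2))
            if key in seen:
                raise ChemError(f"molecule {self.id!r}: duplicate bond {key}")
            seen.add(key)

    # -- graph views -------------------------------------------------------
    def graph(self, heavy_only: bool = False) -> nx.Graph:
        """Molecular graph; ``heavy_only`` suppresses hydrogens."""
        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            if heavy_only and a.is_hydrogen:
                continue
            g.add_node(i, element=a.element)
        for b in self.bonds:
            if heavy_only and (
                self.atoms[b.a1].is_hydrogen or self.atoms[b.a2].is_hydrogen
            ):
                continue
            g.add_edge(b.a1, b.a2, order=b.order)
        return g

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]

    def h_count(self, i: int) -> int:
        """Number of hydrogens bonded to atom i."""
        return sum(
            1
            for b in self.bonds
            if (b.a1 == i and self.atoms[b.a2].is_hydrogen)
            or (b.a2 == i and self.atoms[b.a1].is_hydrogen)
        )

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.a1 == i:
                out.append(b.a2)
            elif b.a2 == i:
                out.append(b.a1)
        return out

    def total_formal_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    def molecular_weight(self) -> float:
        return float(sum(ATOMIC_MASS[a.element] for a in self.atoms))

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def copy(self) -> "Molecule":
        return Molecule(
            id=self.id,
            atoms=[replace(a, coords=a.coords.copy()) for a in self.atoms],
            bonds=list(self.bonds),
            source=self.source,
            properties=dict(self.properties),
        )


#: Structural-cluster labels admitted on records (seven scaffold families).
CLUSTER_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII")


@dataclass
class MoleculeRecord:
    molecule: Molecule
    activity: "object | None" = None  # qsar.ActivityRecord, kept untyped to avoid a cycle
    cluster: str | None = None

    def __post_init__(self) -> None:
        if self.cluster is not None and self.cluster not in CLUSTER_LABELS:
            raise ChemError(
                f"cluster label {self.cluster!r} not one of {CLUSTER_LABELS}"
            )


# ---------------------------------------------------------------------------
# RDKit bridge
# ---------------------------------------------------------------------------

_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    AROMATIC: Chem.BondType.AROMATIC,
}
_BOND_CODES = {v: k for k, v in _BOND_TYPES.items()}


def to_rdkit(mol: Molecule, sanitize: bool = True) -> Chem.Mol:
    """Convert to an RDKit Mol, preserving atom order, charges and coordinates."""
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        if a.chiral_tag:
            ra.SetChiralTag(Chem.ChiralType.values[a.chiral_tag])
        rw.AddAtom(ra)
    for b in mol.bonds:
        rw.AddBond(b.a1, b.a2, _BOND_TYPES[b.order])
        if b.order == AROMATIC:
            rw.GetAtomWithIdx(b.a1).SetIsAromatic(True)
            rw.GetAtomWithIdx(b.a2).SetIsAromatic(True)
            rw.GetBondBetweenAtoms(b.a1, b.a2).SetIsAromatic(True)
    m = rw.GetMol()
    conf = Chem.Conformer(len(mol.atoms))
    for i, a in enumerate(mol.atoms):
        conf.SetAtomPosition(i, tuple(float(x) for x in a.coords))
    m.AddConformer(conf)
    if sanitize:
        Chem.SanitizeMol(m)
    return m


def from_rdkit(rdmol: Chem.Mol, mol_id: str = "", source: str = "") -> Molecule:
    """Convert an RDKit Mol (explicit hydrogens as given) to the local model."""
    if rdmol.GetNumConformers() > 0:
        conf = rdmol.GetConformer()
        coords = [conf.GetAtomPosition(i) for i in range(rdmol.GetNumAtoms())]
        coords = [np.array([p.x, p.y, p.z]) for p in coords]
    else:
        coords = [np.zeros(3) for _ in range(rdmol.GetNumAtoms())]
    atoms = []
    for i, ra in enumerate(rdmol.GetAtoms()):
        sym = ra.GetSymbol()
        if sym not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(f"unsupported element symbol: {sym!r}")
        atoms.append(
            Atom(
                sym,
                coords[i],
                formal_charge=ra.GetFormalCharge(),
                chiral_tag=int(ra.GetChiralTag()),
            )
        )
    bonds = []
    for rb in rdmol.GetBonds():
        code = _BOND_CODES.get(rb.GetBondType())
        if code is None:
            if rb.GetBondTypeAsDouble() == 1.5 or rb.GetIsAromatic():
                code = AROMATIC
            else:
                raise ChemError(f"unsupported bond type: {rb.GetBondType()}")
        bonds.append(Bond(rb.GetBeginAtomIdx(), rb.GetEndAtomIdx(), code))
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds, source=source)


def from_smiles(smiles: str, mol_id: str = "") -> Molecule:
    """Parse a SMILES string into a molecule with explicit hydrogens (no 3D).

    Coordinates are all-zero placeholders; run the 3D embedding step before
    computing geometry-dependent descriptors.
    """
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise ChemError(f"could not parse SMILES: {smiles!r}")
    rd = Chem.AddHs(rd)
    return from_rdkit(rd, mol_id=mol_id, source=f"smiles:{smiles}")


# ---------------------------------------------------------------------------
# SDF I/O
# ---------------------------------------------------------------------------

def _split_sdf_blocks(text: str) -> list[str]:
    blocks = []
    current: list[str] = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            blocks.append("\n".join(current) + "\n")
            current = []
        else:
            current.append(line)
    if any(ln.strip() for ln in current):
        blocks.append("\n".join(current) + "\n")
    return blocks


def _parse_data_fields(block: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    lines = block.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(">"):
            lo = line.find("<")
            name = line[lo + 1 :].split(">")[0] if lo != -1 else line[1:].strip()
            vals = []
            i += 1
            while i < len(lines) and lines[i].strip() != "":
                vals.append(lines[i])
                i += 1
            fields[name] = "\n".join(vals)
        i += 1
    return fields


def read_sdf(path) -> list[MoleculeRecord]:
    """Read an MDL SDF (V2000) file into molecule records.

    Data fields (``> <tag>``) are captured as string properties on the
    molecule; ``activity``/``cluster`` interpretation is left to the caller.
    Raises :class:`SdfParseError` naming the 1-based block index on any
    malformed connection table, and rejects V3000 blocks outright.
    """
    with open(path) as fh:
        text = fh.read()
    blocks = _split_sdf_blocks(text)
    records: list[MoleculeRecord] = []
    for bi, block in enumerate(blocks, start=1):
        lines = block.splitlines()
        if len(lines) >= 4 and "V3000" in lines[3]:
            raise SdfParseError(
                f"block {bi}: V3000 connection tables are not supported (V2000 only)"
            )
        rd = Chem.MolFromMolBlock(
            block, sanitize=False, removeHs=False, strictParsing=True
        )
        if rd is None:
            raise SdfParseError(f"block {bi}: malformed V2000 connection table")
        # prefer the sanitized parse when valid: it perceives wedge-bond
        # stereo, which the dedup key's stereo layer needs
        rd_clean = Chem.MolFromMolBlock(block, sanitize=True, removeHs=False)
        if rd_clean is not None and rd_clean.GetNumAtoms() == rd.GetNumAtoms():
            rd = rd_clean
        name = rd.GetProp("_Name").strip() if rd.HasProp("_Name") else ""
        try:
            mol = from_rdkit(rd, mol_id=name or f"mol{bi}", source=f"{path}#{bi}")
        except UnsupportedElementError as exc:
            raise UnsupportedElementError(f"block {bi}: {exc}") from exc
        mol.properties = _parse_data_fields(block)
        records.append(MoleculeRecord(molecule=mol))
    return records


def write_sdf(records: Iterable[MoleculeRecord | Molecule], path) -> None:
    """Write molecules to an MDL SDF V2000 file, preserving data fields."""
    with open(path, "w") as fh:
        for rec in records:
            mol = rec.molecule if isinstance(rec, MoleculeRecord) else rec
            rd = to_rdkit(mol, sanitize=False)
            rd.SetProp("_Name", mol.id)
            try:
                block = Chem.MolToMolBlock(rd, kekulize=False)
            except Exception as exc:  # pragma: no cover - defensive
                raise ChemError(f"could not write molecule {mol.id!r}: {exc}") from exc
            fh.write(block)
            for key, val in mol.properties.items():
                fh.write(f">  <{key}>\n{val}\n\n")
            fh.write("$$$$\n")


def read_activity_csv(path) -> pd.DataFrame:
    """Read an activity CSV (id, smiles, endpoint_type, endpoint_value, units, cluster)."""
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "smiles", "endpoint_type", "endpoint_value", "units"}
    missing = required - set(df.columns)
    if missing:
        raise ChemError(f"activity CSV missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(mol: Molecule) -> Molecule:
    """Keep only the largest connected component (salt/fragment stripping).

    Largest by heavy-atom count; ties broken by total atomic mass, then by the
    lowest original first-atom index. Atom indices are compacted; formal
    charges, coordinates and bond orders are preserved.
    """
    if len(mol.atoms) == 0:
        raise ChemError("cannot standardize an empty molecule")
    g = mol.graph()
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(
        key=lambda comp: (
            -sum(1 for i in comp if not mol.atoms[i].is_hydrogen),
            -sum(ATOMIC_MASS[mol.atoms[i].element] for i in comp),
            comp[0],
        )
    )
    keep = components[0]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [replace(mol.atoms[i], coords=mol.atoms[i].coords.copy()) for i in keep]
    bonds = [
        Bond(remap[b.a1], remap[b.a2], b.order)
        for b in mol.bonds
        if b.a1 in remap and b.a2 in remap
    ]
    return Molecule(
        id=mol.id, atoms=atoms, bonds=bonds, source=mol.source,
        properties=dict(mol.properties),
    )


def add_hydrogens(mol: Molecule) -> Molecule:
    """Fill each heavy atom's valence with explicit hydrogens.

    Target valence is the standard count adjusted by formal charge (e.g. N+
    takes 4 bonds, O- takes 1). New hydrogens are placed at their parent's
    coordinates; run 3D embedding afterwards for real geometry.
    """
    out = mol.copy()
    order_sum = np.zeros(len(out.atoms))
    for b in out.bonds:
        o = b.conventional_order()
        order_sum[b.a1] += o
        order_sum[b.a2] += o
    for i, a in enumerate(list(out.atoms)):
        if a.is_hydrogen:
            continue
        if a.element == "C":
            target = 4 - abs(a.formal_charge)
        elif a.element in ("N", "O", "S", "P"):
            target = STANDARD_VALENCE[a.element] + a.formal_charge
        else:
            target = STANDARD_VALENCE[a.element]
        n_missing = int(round(target - order_sum[i]))
        for _ in range(max(0, n_missing)):
            out.atoms.append(Atom("H", a.coords.copy()))
            out.bonds.append(Bond(i, len(out.atoms) - 1, 1))
    return out


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

KeyProvider = Callable[[Molecule], str]


def _inchi_key(mol: Molecule) -> str:
    return Chem.MolToInchi(to_rdkit(mol, sanitize=True))


def _smiles_key(mol: Molecule) -> str:
    return Chem.MolToSmiles(Chem.RemoveHs(to_rdkit(mol, sanitize=True)))


_KEY_PROVIDERS: dict[str, KeyProvider] = {
    "inchi": _inchi_key,
    "smiles": _smiles_key,
}


def dedup_key(mol: Molecule, provider: str | KeyProvider = "inchi") -> str:
    """Canonical identity key, invariant to atom order, including stereo.

    The default provider is the InChI string (with its stereo layer, so
    enantiomers with specified centers differ while stereo-unspecified
    constitutional duplicates collide). ``provider='smiles'`` uses canonical
    isomeric SMILES — an order of magnitude faster for very large libraries.
    """
    fn = _KEY_PROVIDERS[provider] if isinstance(provider, str) else provider
    return fn(mol)


def deduplicate(
    records: Sequence[MoleculeRecord],
    against: Sequence[MoleculeRecord] | None = None,
    provider: str | KeyProvider = "inchi",
) -> tuple[list[MoleculeRecord], list[str]]:
    """Drop duplicate records by canonical key; first occurrence wins.

    When ``against`` is given, records whose key occurs in that set are also
    dropped (cross-set deduplication of a screening library against a model
    set). Returns the survivors in input order and a plain-text removal log.
    """
    blocked: set[str] = set()
    if against:
        blocked = {dedup_key(r.molecule, provider) for r in against}
    seen: set[str] = set()
    survivors: list[MoleculeRecord] = []
    log: list[str] = []
    for rec in records:
        key = dedup_key(rec.molecule, provider)
        if key in blocked:
            log.append(f"removed {rec.molecule.id}: duplicate of reference set")
        elif key in seen:
            log.append(f"removed {rec.molecule.id}: internal duplicate")
        else:
            seen.add(key)
            survivors.append(rec)
    return survivors, log
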
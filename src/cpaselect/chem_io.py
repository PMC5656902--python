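"""Molecular structure and tabular I/O, plus anchor-atom perception.

Every geometric operation in the package is expressed relative to a handful
of *anchor atoms* of the BINOL-phosphoric-acid scaffold: the phosphorus, the
two acid oxygens (P=O / P-OH), the two aryl-ether oxygens, the two C3/C3'
ring carbons and the first atom of each 3,3' substituent.
:func:`find_catalyst_anchors` locates them from connectivity alone, so SDF,
MOL and (bond-inferred) XYZ inputs are all acceptable.

Coordinates are Å; energies are normalised to kcal/mol on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._params import HARTREE_TO_KCAL
from .errors import AnchorError, EnsembleError, StructureParseError

log = logging.getLogger(__name__)

__all__ = [
    "Molecule3D",
    "CatalystAnchors",
    "AtomMap",
    "read_structure",
    "write_structure",
    "find_catalyst_anchors",
    "read_ensemble_csv",
    "read_atom_map",
]

#: bond-inference criterion for XYZ input: bonded iff d < this factor times
#: the sum of covalent radii.
COVALENT_FACTOR = 1.25


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Molecule3D:
    """Elements, Cartesian coordinates (Å) and connectivity.

    ``bonds`` holds ``(i, j, order)`` with ``order`` 1, 2, 3 or 1.5 for
    aromatic bonds.
    """

    symbols: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    title: str = ""
    charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.symbols) == 0:
            raise StructureParseError("molecule has no atoms")
        if self.coords.shape[0] != len(self.symbols):
            raise StructureParseError("coordinate/element count mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise StructureParseError("non-finite coordinates")
        n = len(self.symbols)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise StructureParseError(f"bond ({i}, {j}) out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def atoms(self) -> list[tuple[str, np.ndarray]]:
        return list(zip(self.symbols, self.coords))

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def heavy_neighbors(self, idx: int) -> list[int]:
        return [j for j in sorted(self.adjacency()[idx]) if self.symbols[j] != "H"]


@dataclass(frozen=True)
class CatalystAnchors:
    """Anchor atoms of a monophosphoric-acid binaphthyl catalyst.

    ``substituent_root_indices`` holds the first heavy atom of each 3,3'
    substituent, or the marker string ``"H"`` for the parent scaffold.
    ``acid_form`` records whether an acidic hydrogen was found ("acid") or
    the structure is the phosphate anion ("anion").
    """

    p_index: int
    acid_o_indices: tuple[int, int]
    ether_o_indices: tuple[int, int]
    c3_indices: tuple[int, int]
    substituent_root_indices: tuple[int | str, int | str]
    acid_form: str = "acid"


@dataclass(frozen=True)
class AtomMap:
    """Named indices required to classify an explicit TS geometry."""

    imine_c: int
    imine_n: int
    n_sub_anchor: int
    c_sub_anchor: int
    anchors: CatalystAnchors

    def validate(self, mol: Molecule3D) -> None:
        named = [self.imine_c, self.imine_n, self.n_sub_anchor, self.c_sub_anchor]
        if len(set(named)) != 4:
            raise AnchorError("atom-map indices must be distinct")
        for i in named:
            if not 0 <= i < mol.n_atoms:
                raise AnchorError(f"atom-map index {i} out of range")
        adj = mol.adjacency()
        if self.imine_n not in adj[self.imine_c]:
            raise AnchorError("imine_c is not bonded to imine_n")


# --------------------------------------------------------------------------
# structure I/O
# --------------------------------------------------------------------------

_BOND_ORDER_FROM_RDKIT = {1.0: 1.0, 2.0: 2.0, 3.0: 3.0, 1.5: 1.5}


def _rdkit_to_molecule(rdmol, title: str = "") -> Molecule3D:
    from rdkit import Chem

    conf = rdmol.GetConformer()
    symbols = [a.GetSymbol() for a in rdmol.GetAtoms()]
    coords = np.array(conf.GetPositions(), dtype=float)
    bonds = []
    for b in rdmol.GetBonds():
        order = b.GetBondTypeAsDouble()
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                      _BOND_ORDER_FROM_RDKIT.get(order, 1.0)))
    charge = Chem.GetFormalCharge(rdmol)
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else title
    return Molecule3D(symbols, coords, bonds, title=name, charge=charge)


def molecule_to_rdkit(mol: Molecule3D):
    """Build an (unsanitised) RDKit molecule carrying the same geometry."""
    from rdkit import Chem
    from rdkit.Chem import Conformer, RWMol

    rw = RWMol()
    for s in mol.symbols:
        rw.AddAtom(Chem.Atom(s))
    order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                 3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    for i, j, o in mol.bonds:
        rw.AddBond(int(i), int(j), order_map.get(o, Chem.BondType.SINGLE))
    conf = Conformer(mol.n_atoms)
    for i, xyz in enumerate(mol.coords):
        conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
    m = rw.GetMol()
    m.AddConformer(conf)
    m.SetProp("_Name", mol.title)
    m.UpdatePropertyCache(strict=False)
    return m


def _infer_bonds(symbols: Sequence[str], coords: np.ndarray) -> list[tuple[int, int, float]]:
    """Distance-based connectivity: bonded iff d < 1.25 (r_cov_i + r_cov_j)."""
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    rcov = np.array([pt.GetRcovalent(s) for s in symbols])
    bonds = []
    n = len(symbols)
    for i in range(n):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        cut = COVALENT_FACTOR * (rcov[i] + rcov[i + 1:])
        for k in np.nonzero(d < cut)[0]:
            bonds.append((i, int(i + 1 + k), 1.0))
    return bonds


def _element_symbols() -> set[str]:
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    return {pt.GetElementSymbol(z) for z in range(1, 119)}


def _parse_xyz(path: Path) -> Molecule3D:
    valid_elements = _element_symbols()
    lines = path.read_text().splitlines()
    if not lines:
        raise StructureParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise StructureParseError(f"{path}, line 1: expected an atom count") from None
    if len(lines) < n + 2:
        raise StructureParseError(f"{path}: truncated XYZ block ({n} atoms declared)")
    title = lines[1].strip() if len(lines) > 1 else ""
    symbols, coords = [], []
    for ln, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise StructureParseError(f"{path}, line {ln}: expected 'El x y z'")
        el = parts[0]
        if el not in valid_elements:
            raise StructureParseError(f"{path}, line {ln}: {el!r} is not an element")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise StructureParseError(f"{path}, line {ln}: non-numeric coordinate") from None
        symbols.append(el)
        coords.append(xyz)
    if n == 0:
        raise StructureParseError(f"{path}: empty molecule")
    coords = np.array(coords)
    return Molecule3D(symbols, coords, _infer_bonds(symbols, coords), title=title)


def read_structure(path: str | Path, format: str | None = None) -> Molecule3D:
    """Read an SDF/MOL/XYZ file into a :class:`Molecule3D`.

    XYZ carries no connectivity, so bonds are inferred from the
    covalent-radius distance criterion.  The format defaults to the file
    extension.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _parse_xyz(path)
    if fmt in ("sdf", "mol"):
        from rdkit import Chem

        rdmol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=False)
        if rdmol is None:
            raise StructureParseError(f"{path}: RDKit could not parse the MOL block")
        if rdmol.GetNumAtoms() == 0:
            raise StructureParseError(f"{path}: empty molecule")
        try:
            Chem.SanitizeMol(rdmol, catchErrors=False)
        except Exception:
            log.warning("%s: sanitisation failed; using raw connectivity", path)
        if rdmol.GetNumConformers() == 0:
            raise StructureParseError(f"{path}: no 3D coordinates")
        return _rdkit_to_molecule(rdmol, title=path.stem)
    raise StructureParseError(f"unknown structure format {fmt!r}")


def write_structure(mol: Molecule3D, path: str | Path, format: str | None = None) -> None:
    """Write SDF/MOL (V2000) or XYZ."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        lines = [str(mol.n_atoms), mol.title]
        for s, (x, y, z) in zip(mol.symbols, mol.coords):
            lines.append(f"{s:<3s} {x:15.8f} {y:15.8f} {z:15.8f}")
        path.write_text("\n".join(lines) + "\n")
        return
    if fmt in ("sdf", "mol"):
        from rdkit import Chem

        block = Chem.MolToMolBlock(molecule_to_rdkit(mol), kekulize=False)
        text = block + "$$$$\n" if fmt == "sdf" else block
        path.write_text(text)
        return
    raise StructureParseError(f"unknown structure format {fmt!r}")


# --------------------------------------------------------------------------
# anchor perception
# --------------------------------------------------------------------------

def _has_path_avoiding(adj: list[set[int]], start: int, goal: int, avoid: int,
                       max_len: int = 8) -> bool:
    """BFS: is there a path start→goal that never visits ``avoid``?"""
    seen = {start, avoid}
    frontier = [start]
    depth = 0
    while frontier and depth < max_len:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v == goal:
                    return True
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
        depth += 1
    return False


def find_catalyst_anchors(mol: Molecule3D) -> CatalystAnchors:
    """Locate P, the acid and ether oxygens, the C3/C3' carbons and the
    3,3'-substituent roots from connectivity.

    The C3 carbon on each naphthol is the ring carbon ortho to the
    ether-bearing carbon that is *not* part of the biaryl linkage; its
    non-ring heavy neighbour (if any) is the substituent root.
    """
    adj = mol.adjacency()
    p_atoms = [i for i, s in enumerate(mol.symbols) if s == "P"]
    if len(p_atoms) != 1:
        raise AnchorError(
            f"not a monophosphoric acid: found {len(p_atoms)} phosphorus atoms")
    p = p_atoms[0]

    oxygens = [i for i in adj[p] if mol.symbols[i] == "O"]
    if len(oxygens) != 4:
        raise AnchorError(
            f"not a monophosphoric acid: P bonded to {len(oxygens)} oxygens, need 4")
    acid_o, ether_o = [], []
    for o in oxygens:
        heavy = [j for j in adj[o] if j != p and mol.symbols[j] != "H"]
        if heavy:
            ether_o.append(o)
        else:
            acid_o.append(o)
    if len(acid_o) != 2 or len(ether_o) != 2:
        raise AnchorError(
            f"expected 2 acid and 2 ether oxygens, found {len(acid_o)}/{len(ether_o)}")

    has_acidic_h = any(
        mol.symbols[j] == "H" for o in acid_o for j in adj[o])
    acid_form = "acid" if has_acidic_h else "anion"
    if acid_form == "anion":
        log.warning("no acidic hydrogen found: treating structure as the "
                    "phosphate anion form")

    # C2 = aryl carbon bonded to each ether oxygen
    c2 = []
    for o in ether_o:
        carbons = [j for j in adj[o] if j != p and mol.symbols[j] == "C"]
        if len(carbons) != 1:
            raise AnchorError(f"ether oxygen {o} is not bonded to exactly one carbon")
        c2.append(carbons[0])

    c3s: list[int] = []
    roots: list[int | str] = []
    for this_c2, other_c2 in ((c2[0], c2[1]), (c2[1], c2[0])):
        ortho = [j for j in adj[this_c2] if mol.symbols[j] == "C"]
        other_ortho = {j for j in adj[other_c2] if mol.symbols[j] == "C"}
        # C1 carries the biaryl bond: it is bonded to an ortho carbon of the
        # other naphthol's C2.
        c1_candidates = [j for j in ortho if adj[j] & other_ortho]
        c3_candidates = [j for j in ortho if j not in c1_candidates]
        if len(c3_candidates) != 1:
            raise AnchorError(
                "ambiguous C3 assignment on carbon "
                f"{this_c2}: candidates {sorted(c3_candidates) or sorted(ortho)}")
        c3 = c3_candidates[0]
        c3s.append(c3)
        heavy = [j for j in adj[c3] if j != this_c2 and mol.symbols[j] != "H"]
        # ring neighbour C4 reaches C2 around the ring without passing C3
        exo = [j for j in heavy if not _has_path_avoiding(adj, j, this_c2, avoid=c3)]
        if len(exo) > 1:
            raise AnchorError(f"C3 atom {c3} bears {len(exo)} exocyclic substituents")
        roots.append(exo[0] if exo else "H")

    return CatalystAnchors(
        p_index=p,
        acid_o_indices=tuple(sorted(acid_o)),
        ether_o_indices=tuple(sorted(ether_o)),
        c3_indices=(c3s[0], c3s[1]),
        substituent_root_indices=(roots[0], roots[1]),
        acid_form=acid_form,
    )


# --------------------------------------------------------------------------
# tabular inputs
# --------------------------------------------------------------------------

def read_ensemble_csv(path: str | Path, energy_unit: str = "kcal_per_mol",
                      temperature: float = 298.15):
    """Read a TS free-energy table (columns: label, pathway, config, energy).

    Energies are converted to kcal/mol and stored relative to the ensemble
    minimum.  Returns a :class:`cpaselect.stereoselectivity.TSEnsemble`.
    """
    from .pathway_model import PathwayLabel
    from .stereoselectivity import TSEnsemble, TSRecord

    if energy_unit not in ("kcal_per_mol", "hartree"):
        raise EnsembleError(f"unknown energy unit {energy_unit!r}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise EnsembleError(f"could not read {path}: {exc}") from exc
    missing = {"label", "pathway", "config", "energy"} - set(df.columns)
    if missing:
        raise EnsembleError(f"{path}: missing columns {sorted(missing)}")
    energies = pd.to_numeric(df["energy"], errors="coerce")
    if energies.isna().any():
        bad = df.loc[energies.isna(), "energy"].iloc[0]
        raise EnsembleError(f"{path}: non-numeric energy {bad!r}")
    scale = HARTREE_TO_KCAL if energy_unit == "hartree" else 1.0
    rel = (energies - energies.min()) * scale
    records = []
    for (_, row), e in zip(df.iterrows(), rel):
        config = str(row["config"]).strip()
        if config not in ("R", "S"):
            raise EnsembleError(f"{path}: unknown product configuration {config!r}")
        records.append(TSRecord(
            label=str(row["label"]),
            pathway=PathwayLabel.parse(str(row["pathway"]).strip()),
            config=config,
            rel_energy=float(e),
        ))
    return TSEnsemble(records=records, temperature=temperature)


def read_atom_map(path: str | Path, mol: Molecule3D) -> AtomMap:
    """Load an atom map (YAML/JSON) and validate it against ``mol``.

    Anchor indices may be given explicitly under ``anchors:``; otherwise they
    are perceived from the structure.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise AnchorError(f"{path}: expected a mapping")
    if "anchors" in data:
        a = data["anchors"]
        anchors = CatalystAnchors(
            p_index=int(a["p_index"]),
            acid_o_indices=tuple(int(i) for i in a["acid_o_indices"]),
            ether_o_indices=tuple(int(i) for i in a["ether_o_indices"]),
            c3_indices=tuple(int(i) for i in a["c3_indices"]),
            substituent_root_indices=tuple(
                i if i == "H" else int(i) for i in a["substituent_root_indices"]),
            acid_form=a.get("acid_form", "acid"),
        )
    else:
        anchors = find_catalyst_anchors(mol)
    amap = AtomMap(
        imine_c=int(data["imine_c"]),
        imine_n=int(data["imine_n"]),
        n_sub_anchor=int(data["n_sub_anchor"]),
        c_sub_anchor=int(data["c_sub_anchor"]),
        anchors=anchors,
    )
    amap.validate(mol)
    return amap
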
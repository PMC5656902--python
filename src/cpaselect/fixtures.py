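"""Deterministic synthetic inputs for every module.

Four fixture families, all generated in code (nothing is downloaded and no
quantum chemistry is run):

* cone toys — sphere arrangements with a closed-form tangent-cone aperture,
  for validating the numeric AREA(θ) search;
* torsion toys — a clash-free diatomic rotor on a phosphoric-acid stub;
* catalyst 3D models — BINOL phosphoric acids with the catalogued 3,3'
  substituents, embedded with seeded ETKDG and UFF-relaxed;
* idealised TS geometries — minimal rigid arrangements whose only contract
  is their Type I/II × E/Z label;
* TS free-energy ensembles with prescribed gaps.

Identical recipe + seed reproduces fixtures bit-for-bit.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from ._params import vdw_radius
from .catalyst_catalog import BACKBONE_SMILES, CATALYST_ALIASES, CATALYST_SMILES
from .chem_io import AtomMap, CatalystAnchors, Molecule3D
from .errors import GeometryError
from .pathway_model import PathwayLabel
from .stereoselectivity import TSEnsemble, TSRecord

__all__ = [
    "make_cone_toy",
    "make_torsion_toy",
    "make_catalyst_3d",
    "make_ts_fixture",
    "make_two_state_ensemble",
    "analytic_tangent_theta",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20170914


# --------------------------------------------------------------------------
# cone toys
# --------------------------------------------------------------------------

def analytic_tangent_theta(center: np.ndarray, radius: float,
                           apex: np.ndarray, axis: np.ndarray) -> float:
    """Closed-form maximal aperture for a single obstructing sphere:
    θ = α − arcsin(r/d), the angle to the sphere's tangent cone."""
    v = np.asarray(center, float) - np.asarray(apex, float)
    d = float(np.linalg.norm(v))
    if d <= radius:
        raise GeometryError("sphere contains the apex: aperture undefined")
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    alpha = math.degrees(math.acos(float(np.clip(v.dot(axis) / d, -1, 1))))
    return alpha - math.degrees(math.asin(radius / d))


def make_cone_toy(obstructions: list[tuple[tuple[float, float, float], str]],
                  apex: tuple[float, float, float] = (0.0, 0.0, 0.0),
                  axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
                  max_theta: float = 179.0,
                  ) -> tuple[Molecule3D, CatalystAnchors, float]:
    """A minimal scaffold plus obstructing atoms, with the analytic aperture.

    ``obstructions`` is a list of (xyz, element) pairs; each element's Bondi
    radius is the sphere radius.  The scaffold (P apex, two acid oxygens
    placed so the binding-face axis points along ``axis``, two ether oxygens
    and two C3 carbons behind the apex) sits within any remote cutoff
    ≥ 2 Å and therefore never obstructs.  Returns (molecule, anchors,
    analytic θ) where the analytic value is the minimum single-sphere
    tangent aperture, clipped to ``max_theta``.
    """
    apex = np.asarray(apex, float)
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise GeometryError("zero axis")
    axis = axis / n
    # orthonormal frame
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis.dot(ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = np.cross(axis, ref)
    perp /= np.linalg.norm(perp)

    symbols = ["P", "O", "O", "O", "O", "C", "C"]
    coords = [
        apex,
        apex + 1.0 * axis + 0.5 * perp,   # acid oxygens: midpoint on the axis
        apex + 1.0 * axis - 0.5 * perp,
        apex - 1.0 * axis + 0.5 * perp,   # ether oxygens behind
        apex - 1.0 * axis - 0.5 * perp,
        apex - 1.5 * axis + 0.9 * perp,   # stand-in C3 carbons
        apex - 1.5 * axis - 0.9 * perp,
    ]
    bonds = [(0, 1, 2.0), (0, 2, 1.0), (0, 3, 1.0), (0, 4, 1.0),
             (3, 5, 1.0), (4, 6, 1.0)]

    thetas = []
    for xyz, element in obstructions:
        r = vdw_radius(element)
        thetas.append(analytic_tangent_theta(np.asarray(xyz), r, apex, axis))
        symbols.append(element)
        coords.append(np.asarray(xyz, float))
    if not obstructions:
        raise GeometryError("cone toy needs at least one obstructing sphere")
    analytic = min(max_theta, max(0.0, min(thetas)))
    mol = Molecule3D(symbols, np.array(coords), bonds, title="cone toy")
    anchors = CatalystAnchors(p_index=0, acid_o_indices=(1, 2),
                              ether_o_indices=(3, 4), c3_indices=(5, 6),
                              substituent_root_indices=("H", "H"),
                              acid_form="anion")
    return mol, anchors, analytic


# --------------------------------------------------------------------------
# torsion toy
# --------------------------------------------------------------------------

def make_torsion_toy(arm_length: float = 6.0
                     ) -> tuple[Molecule3D, CatalystAnchors]:
    """A diatomic rotor on a long arm, far from every other atom.

    The "substituent" is a C-O diatomic at the end of a linear arm attached
    to a C3 stand-in, so the rigid scan should be essentially flat: any
    barrier comes purely from the (negligible) long-range tail of the
    steric potential.
    """
    symbols = ["P", "O", "O", "O", "O", "C", "C", "C", "O"]
    coords = np.array([
        [0.0, 0.0, 0.0],
        [0.8, 0.8, 1.0], [-0.8, -0.8, 1.0],     # acid O
        [1.0, 0.0, -1.0], [-1.0, 0.0, -1.0],    # ether O
        [2.2, 0.0, -1.5], [-2.2, 0.0, -1.5],    # C3 stand-ins
        [2.2 + arm_length, 0.0, -1.5],          # rotor carbon
        [2.2 + arm_length + 0.8, 1.05, -1.5],   # rotor oxygen, off-axis
    ])
    bonds = [(0, 1, 2.0), (0, 2, 1.0), (0, 3, 1.0), (0, 4, 1.0),
             (3, 5, 1.0), (4, 6, 1.0), (5, 7, 1.0), (7, 8, 1.0)]
    mol = Molecule3D(symbols, coords, bonds, title="torsion toy")
    anchors = CatalystAnchors(p_index=0, acid_o_indices=(1, 2),
                              ether_o_indices=(3, 4), c3_indices=(5, 6),
                              substituent_root_indices=(7, "H"),
                              acid_form="anion")
    return mol, anchors


# --------------------------------------------------------------------------
# catalyst 3D models
# --------------------------------------------------------------------------

def catalyst_smiles(name: str) -> str:
    key = CATALYST_ALIASES.get(name, name)
    if key not in CATALYST_SMILES:
        raise KeyError(
            f"unknown catalyst {name!r}; known: {sorted(CATALYST_SMILES)} "
            f"plus aliases {sorted(CATALYST_ALIASES)}")
    return BACKBONE_SMILES.replace("{R}", CATALYST_SMILES[key])


@lru_cache(maxsize=32)
def make_catalyst_3d(name: str, seed: int = DEFAULT_SEED) -> Molecule3D:
    """Embed a catalogued catalyst (or any backbone-substituent name) in 3D.

    Uses seeded ETKDG embedding followed by a UFF relaxation; identical
    name + seed gives identical coordinates.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    from .chem_io import _rdkit_to_molecule

    smiles = catalyst_smiles(name)
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:  # pragma: no cover - registry is curated
        raise ValueError(f"bad construction SMILES for {name!r}")
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        raise RuntimeError(f"3D embedding failed for {name!r}")
    AllChem.UFFOptimizeMolecule(rdmol, maxIters=2000)
    mol = _rdkit_to_molecule(rdmol, title=name)
    return mol


# --------------------------------------------------------------------------
# TS geometry fixtures
# --------------------------------------------------------------------------

def make_ts_fixture(orientation: str, config: str,
                    dihedral: float | None = None
                    ) -> tuple[Molecule3D, AtomMap]:
    """Minimal rigid TS geometry with a known Type I/II × E/Z label.

    The catalyst frame is a seven-atom phosphoric-acid stub whose
    binding-face normal points along +z (with a small −y tilt); the imine
    sits above it.  The N-substituent anchor is placed below (Type I) or
    above (Type II) the 3,3' front plane, and on the opposite (E) or same
    (Z) side of the C=N axis as the C-substituent anchor.  ``dihedral``
    overrides the C-substituent twist for edge-case tests (e.g. exactly
    90°).
    """
    label = PathwayLabel(orientation, config)
    frame_symbols = ["P", "O", "O", "O", "O", "C", "C"]
    frame_coords = [
        [0.0, 0.0, 0.0],
        [1.2, 0.0, 1.0], [-1.2, 0.0, 1.0],     # acid O (binding face +z)
        [1.2, 0.0, -1.0], [-1.2, 0.0, -1.0],   # ether O
        [3.5, 2.0, 0.5], [-3.5, 2.0, 0.5],     # C3 carbons -> front plane
    ]
    n_pos = np.array([0.0, -0.5, 3.2])
    c_pos = np.array([1.3, -0.5, 3.2])
    down = np.array([0.0, 0.0, -1.2])
    up = np.array([0.0, 0.0, 1.2])

    n_perp = down if label.orientation == "I" else up
    if label.config == "E":
        c_perp = -n_perp  # opposite sides of the C=N axis
    else:
        c_perp = n_perp
    if dihedral is not None:
        # rotate the C-substituent perpendicular component about the C=N
        # (x) axis to the requested dihedral relative to the N-substituent
        phi = math.radians(dihedral)
        ny, nz = n_perp[1], n_perp[2]
        c_perp = np.array([0.0,
                           ny * math.cos(phi) - nz * math.sin(phi),
                           ny * math.sin(phi) + nz * math.cos(phi)])
    n_sub = n_pos + np.array([-0.7, 0.0, 0.0]) + n_perp
    c_sub = c_pos + np.array([0.7, 0.0, 0.0]) + c_perp

    symbols = frame_symbols + ["N", "C", "C", "C"]
    coords = np.array(frame_coords + [n_pos, c_pos, n_sub, c_sub])
    bonds = [(0, 1, 2.0), (0, 2, 1.0), (0, 3, 1.0), (0, 4, 1.0),
             (3, 5, 1.0), (4, 6, 1.0),
             (7, 8, 2.0), (7, 9, 1.0), (8, 10, 1.0)]
    mol = Molecule3D(symbols, coords, bonds, title=f"TS fixture {label}")
    anchors = CatalystAnchors(p_index=0, acid_o_indices=(1, 2),
                              ether_o_indices=(3, 4), c3_indices=(5, 6),
                              substituent_root_indices=("H", "H"),
                              acid_form="anion")
    amap = AtomMap(imine_c=8, imine_n=7, n_sub_anchor=9, c_sub_anchor=10,
                   anchors=anchors)
    return mol, amap


def reflect_substrate_through_front_plane(mol: Molecule3D, amap: AtomMap
                                          ) -> Molecule3D:
    """Mirror the substrate atoms (imine + anchors) through the 3,3' front
    plane, keeping the catalyst frame fixed.  Flips Type I <-> II while
    preserving the E/Z label."""
    from .pathway_model import front_plane_normal

    normal = front_plane_normal(mol, amap.anchors)
    p = mol.coords[amap.anchors.p_index]
    coords = mol.coords.copy()
    for i in (amap.imine_c, amap.imine_n, amap.n_sub_anchor, amap.c_sub_anchor):
        v = coords[i] - p
        coords[i] = p + v - 2.0 * v.dot(normal) * normal
    return Molecule3D(list(mol.symbols), coords, list(mol.bonds),
                      title=mol.title + " (mirrored substrate)",
                      charge=mol.charge)


# --------------------------------------------------------------------------
# ensembles
# --------------------------------------------------------------------------

def make_two_state_ensemble(ddg: float, temperature: float = 298.15,
                            low_pathway: str = "II_Z",
                            high_pathway: str = "I_Z",
                            low_config: str = "S",
                            positive_config: str = "R") -> TSEnsemble:
    """Two competing TSs separated by ``ddg`` kcal/mol.

    Defaults encode the transfer-hydrogenation scenario: the lower TS is the
    Type II pathway leading to the negatively-signed enantiomer.
    """
    high_config = "R" if low_config == "S" else "S"
    records = [
        TSRecord("TS1", PathwayLabel.parse(low_pathway), low_config, 0.0),
        TSRecord("TS2", PathwayLabel.parse(high_pathway), high_config, float(ddg)),
    ]
    return TSEnsemble(records=records, temperature=temperature,
                      positive_config=positive_config)
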
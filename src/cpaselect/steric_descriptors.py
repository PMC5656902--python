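"""The two catalyst steric parameters: AREA(θ) and the biaryl rotation barrier.

AREA(θ) quantifies the *remote* steric environment as the half-aperture (in
degrees) of the widest cone, anchored at the phosphorus and opening over the
substrate-binding face, that stays clear of every van-der-Waals-inflated atom
lying beyond a distance cutoff from the apex.  A large θ means an open
remote environment (the parent 3,3'-H catalyst), a small θ a congested one
(3,3'-SiPh3).

The *proximal* steric demand is quantified as the barrier of a rigid-rotor
torsion scan about the C3-Cipso bond, evaluated with a deterministic
pairwise steric potential (capped 12-6 Lennard-Jones by default; any
conformational energy function may be supplied).

Neither descriptor aims to reproduce literature magnitudes computed with
QM-based protocols; they are designed so that *orderings and class
assignments* across catalysts are faithful.  The class thresholds
(θ > 70 large / θ ≤ 36 small; barrier < 3 small / > 26 large, kcal/mol)
follow the screening-table conventions and are applied to catalog values.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np
from scipy.spatial.transform import Rotation

from ._params import lj_well_depth, vdw_radius
from .chem_io import CatalystAnchors, Molecule3D
from .errors import GeometryError

__all__ = [
    "ConeParams",
    "TorsionScan",
    "StericProfile",
    "compute_area_theta",
    "scan_rotation_barrier",
    "classify_catalyst",
    "compute_profile",
    "lj_steric_energy",
]

AREA_LARGE_THRESHOLD = 70.0   # θ strictly above -> large (open)
AREA_SMALL_THRESHOLD = 36.0   # θ at or below -> small
PROXIMAL_SMALL_THRESHOLD = 3.0   # barrier strictly below -> small
PROXIMAL_LARGE_THRESHOLD = 26.0  # barrier strictly above -> large


# --------------------------------------------------------------------------
# parameters and result containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConeParams:
    """Protocol parameters of the AREA(θ) cone search.

    apex: "phosphorus" or "midpoint_ether_oxygens".
    axis_mode: "binding_face" (apex towards the midpoint of the two acid
        oxygens — the direction the substrate approaches from) or
        "away_from_binding_face" (the reverse).
    remote_cutoff: atoms farther than this from the apex count as remote
        obstructions; nearer atoms are proximal and ignored.
    """

    apex: str = "phosphorus"
    axis_mode: str = "binding_face"
    remote_cutoff: float = 4.0
    vdw_radii_set: str = "bondi"
    angular_resolution: float = 0.5
    max_theta: float = 179.0

    def __post_init__(self) -> None:
        if self.apex not in ("phosphorus", "midpoint_ether_oxygens"):
            raise ValueError(f"unknown apex {self.apex!r}")
        if self.axis_mode not in ("binding_face", "away_from_binding_face"):
            raise ValueError(f"unknown axis_mode {self.axis_mode!r}")
        if self.remote_cutoff <= 0:
            raise ValueError("remote_cutoff must be positive")
        if not 0 < self.angular_resolution <= 5:
            raise ValueError("angular_resolution must be in (0, 5] degrees")


@dataclass
class TorsionScan:
    """A rigid-rotor torsion scan about the C3-Cipso bond.

    ``energies`` is a list of (angle, energy) pairs covering [0, 360) at the
    stated step, normalised so the minimum is zero.
    """

    torsion_atoms: tuple[int, int, int, int]
    step: float
    energies: list[tuple[float, float]]
    mode: str = "rigid"

    def __post_init__(self) -> None:
        e = np.array([v for _, v in self.energies])
        if not np.all(np.isfinite(e)):
            raise ValueError("non-finite scan energies")
        shift = e.min()
        if shift != 0.0:
            self.energies = [(a, v - shift) for a, v in self.energies]

    @property
    def barrier(self) -> float:
        e = [v for _, v in self.energies]
        return max(e) - min(e)

    def plot(self, ax=None):
        """Plot E(φ); requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        angles, energies = zip(*self.energies)
        ax.plot(angles, energies, marker="o")
        ax.set_xlabel("torsion angle φ / degrees")
        ax.set_ylabel("steric energy / kcal mol$^{-1}$")
        return ax


@dataclass
class StericProfile:
    """Computed descriptors and their steric classes for one catalyst."""

    area_theta: float
    rotation_barrier: float
    area_class: str
    proximal_class: str
    params_used: dict
    proximal_class_override: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.area_theta < 180:
            raise ValueError(f"area_theta {self.area_theta} outside (0, 180)")
        if self.rotation_barrier < 0:
            raise ValueError("rotation_barrier must be >= 0")


# --------------------------------------------------------------------------
# AREA(θ)
# --------------------------------------------------------------------------

def _apex_and_axis(mol: Molecule3D, anchors: CatalystAnchors,
                   params: ConeParams) -> tuple[np.ndarray, np.ndarray]:
    X = mol.coords
    if params.apex == "phosphorus":
        apex = X[anchors.p_index]
    else:
        apex = X[list(anchors.ether_o_indices)].mean(axis=0)
    mid_acid = X[list(anchors.acid_o_indices)].mean(axis=0)
    axis = mid_acid - apex
    if params.axis_mode == "away_from_binding_face":
        axis = -axis
    norm = np.linalg.norm(axis)
    if norm < 1e-8:
        raise GeometryError("degenerate cone axis: apex coincides with the "
                            "acid-oxygen midpoint")
    return apex, axis / norm


def _cone_clearance(thetas_deg: np.ndarray, d: np.ndarray, alpha_deg: np.ndarray
                    ) -> np.ndarray:
    """Distance from each sphere centre to the solid cone, for each aperture.

    Returns an array of shape (len(thetas), len(d)).  The solid cone has its
    apex at the origin; a centre at distance d and polar angle alpha from the
    axis is inside for alpha <= theta (clearance 0), faces the lateral
    surface for alpha - theta < 90 degrees, and otherwise is closest to the
    apex itself.
    """
    diff = np.radians(alpha_deg)[None, :] - np.radians(thetas_deg)[:, None]
    lateral = d[None, :] * np.sin(diff)
    clearance = np.where(diff <= 0, 0.0,
                         np.where(diff < np.pi / 2, lateral, d[None, :]))
    return clearance


def compute_area_theta(mol: Molecule3D, anchors: CatalystAnchors,
                       params: ConeParams | None = None) -> float:
    """Maximal clear cone half-aperture θ (degrees) over the binding face.

    The search walks a θ grid at ``angular_resolution`` and returns the
    largest aperture whose cone interior is not entered by any
    vdW-inflated remote atom (all atoms farther than ``remote_cutoff``
    from the apex, substituent and backbone alike).
    """
    params = params or ConeParams()
    apex, axis = _apex_and_axis(mol, anchors, params)
    v = mol.coords - apex
    d = np.linalg.norm(v, axis=1)
    remote = d > params.remote_cutoff
    if not np.any(remote):
        warnings.warn("no remote atoms: returning the configured maximum "
                      f"aperture {params.max_theta} degrees", stacklevel=2)
        return params.max_theta
    d = d[remote]
    radii = np.array([vdw_radius(s, params.vdw_radii_set)
                      for s, m in zip(mol.symbols, remote) if m])
    cosa = np.clip(v[remote].dot(axis) / d, -1.0, 1.0)
    alpha = np.degrees(np.arccos(cosa))

    thetas = np.arange(params.angular_resolution,
                       params.max_theta + 1e-9, params.angular_resolution)
    clearance = _cone_clearance(thetas, d, alpha)
    feasible = np.all(clearance >= radii[None, :] - 1e-9, axis=1)
    if not np.any(feasible):
        # even the narrowest grid cone is obstructed
        return float(thetas[0])
    return float(min(thetas[feasible].max(), params.max_theta))


# --------------------------------------------------------------------------
# rotation barrier
# --------------------------------------------------------------------------

def _graph_distances_leq2(mol: Molecule3D) -> set[tuple[int, int]]:
    """Atom pairs separated by one or two bonds (to be excluded from the
    nonbonded sum), as ordered tuples (i < j)."""
    adj = mol.adjacency()
    excl: set[tuple[int, int]] = set()
    for i in range(mol.n_atoms):
        for j in adj[i]:
            excl.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    excl.add((min(i, k), max(i, k)))
    return excl


def lj_steric_energy(mol: Molecule3D, coords: np.ndarray, *,
                     cap: float = 25.0,
                     _cache: dict = {}) -> float:
    """Capped 12-6 Lennard-Jones nonbonded energy (kcal/mol).

    Pairs separated by fewer than three bonds are excluded; each pair
    contribution is clamped at ``cap`` so that the hard-sphere clashes of a
    rigid scan stay finite.  This is the default, deterministic steric
    energy of :func:`scan_rotation_barrier`.
    """
    key = id(mol)
    if key not in _cache:
        n = mol.n_atoms
        iu, ju = np.triu_indices(n, k=1)
        excl = _graph_distances_leq2(mol)
        mask = np.array([(int(i), int(j)) not in excl for i, j in zip(iu, ju)])
        iu, ju = iu[mask], ju[mask]
        r0 = np.array([vdw_radius(s) for s in mol.symbols])
        eps = np.array([lj_well_depth(s) for s in mol.symbols])
        _cache.clear()  # keep only the most recent molecule
        _cache[key] = (iu, ju, r0[iu] + r0[ju], np.sqrt(eps[iu] * eps[ju]))
    iu, ju, r0_ij, eps_ij = _cache[key]
    dvec = coords[iu] - coords[ju]
    dist = np.maximum(np.linalg.norm(dvec, axis=1), 1e-3)
    x6 = (r0_ij / dist) ** 6
    e = eps_ij * (x6 * x6 - 2.0 * x6)
    return float(np.minimum(e, cap).sum())


def _substituent_atoms(mol: Molecule3D, c3: int, root: int) -> list[int]:
    """Atoms on the substituent side of the C3-root bond (BFS from root,
    never crossing back through C3).  Raises if the bond closes a ring."""
    adj = mol.adjacency()
    seen = {c3, root}
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w == c3 and u != root:
                    raise GeometryError(
                        "C3-substituent bond is part of a ring and not rotatable")
                if w not in seen:
                    seen.add(w)
                    nxt.append(w)
        frontier = nxt
    seen.discard(c3)
    return sorted(seen)


def scan_rotation_barrier(mol: Molecule3D, anchors: CatalystAnchors,
                          step: float = 10.0,
                          energy_fn: Callable[[Molecule3D, np.ndarray], float] | None = None,
                          torsion_v2: float = 0.0) -> TorsionScan:
    """Rigid-rotor scan of the C3-Cipso torsion; barrier = max E - min E.

    Each 3,3' substituent is rotated in turn about its C3-root axis with the
    rest of the molecule (including the other substituent) held fixed; the
    scan of the more hindered substituent is returned.  A hydrogen
    substituent has no rotor: the barrier is 0 by convention.

    ``torsion_v2`` adds an intrinsic 2-fold torsional term
    V2/2 (1 - cos 2Δφ) on top of the steric energy (0 by default, so a
    clash-free rotor scans flat).
    """
    if energy_fn is None:
        energy_fn = lj_steric_energy
    adj = mol.adjacency()
    best: TorsionScan | None = None
    for c3, root in zip(anchors.c3_indices, anchors.substituent_root_indices):
        if root == "H":
            continue
        moved = _substituent_atoms(mol, c3, root)
        axis = mol.coords[root] - mol.coords[c3]
        norm = np.linalg.norm(axis)
        if norm < 1e-8:
            raise GeometryError("zero-length C3-substituent bond")
        axis = axis / norm
        pivot = mol.coords[c3]
        # torsion atom metadata: ring neighbour of C3, C3, root, a neighbour
        # of the root (the root itself for a terminal rotor)
        c2 = next(i for i in adj[c3] if i != root and mol.symbols[i] != "H")
        fourth = next((i for i in sorted(adj[root]) if i != c3), root)
        angles = np.arange(0.0, 360.0, step)
        energies = []
        for phi in angles:
            rot = Rotation.from_rotvec(np.radians(phi) * axis).as_matrix()
            coords = mol.coords.copy()
            coords[moved] = (coords[moved] - pivot) @ rot.T + pivot
            e = energy_fn(mol, coords)
            if torsion_v2:
                e += 0.5 * torsion_v2 * (1.0 - np.cos(2.0 * np.radians(phi)))
            energies.append((float(phi), float(e)))
        scan = TorsionScan(torsion_atoms=(c2, c3, int(root), int(fourth)),
                           step=step, energies=energies)
        if best is None or scan.barrier > best.barrier:
            best = scan
    if best is None:
        # parent catalyst: both substituents are hydrogen
        import logging
        logging.getLogger(__name__).info(
            "3,3' substituents are hydrogen: rotation barrier is 0 by convention")
        angles = np.arange(0.0, 360.0, step)
        c3 = anchors.c3_indices[0]
        c2 = next(iter(adj[c3]))
        best = TorsionScan(torsion_atoms=(c2, c3, c3, c3), step=step,
                           energies=[(float(a), 0.0) for a in angles])
    return best


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def classify_catalyst(area_theta: float, rotation_barrier: float,
                      override: str | None = None) -> tuple[str, str]:
    """Bin (θ, barrier) into (area_class, proximal_class).

    Strict inequalities at the 70/36 and 3/26 thresholds put boundary
    catalysts (Ph at θ=70, the 3,5-tBu2-4-OMe aryl at θ=35) in the
    medium/small bins, consistent with their screening-table placement.
    ``override`` replaces the proximal class for silyl/alkyl 3,3' groups
    whose up-and-towards arm acts as proximal bulk even though the C-C
    rotation barrier is small.
    """
    if not (np.isfinite(area_theta) and np.isfinite(rotation_barrier)):
        raise ValueError("descriptors must be finite")
    if area_theta > AREA_LARGE_THRESHOLD:
        area_class = "large"
    elif area_theta <= AREA_SMALL_THRESHOLD:
        area_class = "small"
    else:
        area_class = "medium"
    if rotation_barrier < PROXIMAL_SMALL_THRESHOLD:
        proximal_class = "small"
    elif rotation_barrier > PROXIMAL_LARGE_THRESHOLD:
        proximal_class = "large"
    else:
        proximal_class = "medium"
    if override is not None:
        if override not in ("small", "medium", "large"):
            raise ValueError(f"unknown proximal class override {override!r}")
        proximal_class = override
    return area_class, proximal_class


def compute_profile(mol: Molecule3D, anchors: CatalystAnchors,
                    cone_params: ConeParams | None = None,
                    step: float = 10.0,
                    proximal_class_override: str | None = None) -> StericProfile:
    """Convenience: both descriptors plus their classes, with provenance."""
    cone_params = cone_params or ConeParams()
    theta = compute_area_theta(mol, anchors, cone_params)
    scan = scan_rotation_barrier(mol, anchors, step=step)
    area_class, proximal_class = classify_catalyst(
        theta, scan.barrier, override=proximal_class_override)
    params_used = {
        "cone": asdict(cone_params),
        "scan_step": step,
        "scan_mode": scan.mode,
        "acid_form": anchors.acid_form,
        "thresholds": {
            "area_large": AREA_LARGE_THRESHOLD,
            "area_small": AREA_SMALL_THRESHOLD,
            "proximal_small": PROXIMAL_SMALL_THRESHOLD,
            "proximal_large": PROXIMAL_LARGE_THRESHOLD,
        },
    }
    return StericProfile(area_theta=theta, rotation_barrier=scan.barrier,
                         area_class=area_class, proximal_class=proximal_class,
                         params_used=params_used,
                         proximal_class_override=proximal_class_override)
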
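"""Transition-state pathway taxonomy for bifunctional CPA-imine catalysis.

A phosphoric acid activates the imine through its P-OH and the nucleophile
through its P=O, which leaves four diastereomeric arrangements: the imine
N-substituent pointing away from (Type I) or towards (Type II) the front of
the 3,3' groups, combined with an *E* or *Z* C=N configuration.  This module
represents reactions declaratively (:class:`ReactionSpec`), infers the
operative pathway from substrate features, and assigns a pathway label to an
explicit TS geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import total_ordering

import numpy as np

from .chem_io import AtomMap, Molecule3D
from .errors import GeometryError

__all__ = ["PathwayLabel", "ReactionSpec", "infer_pathway", "classify_ts_geometry"]

_ORIENTATIONS = ("I", "II")
_CONFIGS = ("E", "Z")


@total_ordering
@dataclass(frozen=True)
class PathwayLabel:
    """One of the four TS pathways: Type I/II x E/Z."""

    orientation: str
    config: str

    def __post_init__(self) -> None:
        if self.orientation not in _ORIENTATIONS:
            raise ValueError(f"orientation must be I or II, got {self.orientation!r}")
        if self.config not in _CONFIGS:
            raise ValueError(f"config must be E or Z, got {self.config!r}")

    @classmethod
    def parse(cls, token: str) -> "PathwayLabel":
        try:
            orientation, config = token.split("_")
            return cls(orientation, config)
        except ValueError:
            raise ValueError(
                f"unknown pathway token {token!r}; expected one of "
                "I_E, I_Z, II_E, II_Z") from None

    def __str__(self) -> str:
        return f"{self.orientation}_{self.config}"

    def _key(self) -> tuple[int, int]:
        return (_ORIENTATIONS.index(self.orientation), _CONFIGS.index(self.config))

    def __lt__(self, other: "PathwayLabel") -> bool:
        return self._key() < other._key()


@dataclass(frozen=True)
class ReactionSpec:
    """Declarative features of an imine + nucleophile combination.

    ``displaced_bulk`` is the size class of the substituent on the carbon
    bearing the heteroatom that hydrogen-bonds to the phosphoryl oxygen; it
    is required exactly when the nucleophile is displaced.  Cyclic imines
    are locked in the *Z* configuration.
    """

    imine_cyclic: bool
    n_substituent_size: str  # "large" | "small"
    accessible_configs: frozenset = frozenset({"E"})
    nucleophile_kind: str = "symmetrical"  # "symmetrical" | "displaced"
    displaced_bulk: str | None = None  # "small" | "large"
    declared_pathway: PathwayLabel | None = None
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "accessible_configs",
                           frozenset(self.accessible_configs))
        if not self.accessible_configs:
            raise ValueError("accessible_configs must not be empty")
        if not self.accessible_configs <= {"E", "Z"}:
            raise ValueError(f"unknown configs {set(self.accessible_configs)}")
        if self.n_substituent_size not in ("large", "small"):
            raise ValueError("n_substituent_size must be 'large' or 'small'")
        if self.nucleophile_kind not in ("symmetrical", "displaced"):
            raise ValueError("nucleophile_kind must be 'symmetrical' or 'displaced'")
        if self.imine_cyclic and self.accessible_configs != {"Z"}:
            raise ValueError("cyclic imines are locked Z: accessible_configs must be {'Z'}")
        if (self.nucleophile_kind == "displaced") != (self.displaced_bulk is not None):
            raise ValueError("displaced_bulk is required iff the nucleophile is displaced")
        if self.displaced_bulk not in (None, "small", "large"):
            raise ValueError("displaced_bulk must be 'small' or 'large'")

    @classmethod
    def from_dict(cls, data: dict) -> "ReactionSpec":
        declared = data.get("declared_pathway")
        return cls(
            imine_cyclic=bool(data["imine_cyclic"]),
            n_substituent_size=data["n_substituent_size"],
            accessible_configs=frozenset(data.get("accessible_configs", ["E"])),
            nucleophile_kind=data.get("nucleophile_kind", "symmetrical"),
            displaced_bulk=data.get("displaced_bulk"),
            declared_pathway=PathwayLabel.parse(declared) if declared else None,
            name=data.get("name", ""),
        )


def infer_pathway(spec: ReactionSpec) -> PathwayLabel:
    """Infer the operative pathway from substrate features.

    Large N-substituents favour Type I, small ones Type II; the imine reacts
    through *Z* whenever that configuration is accessible (cyclic imines
    always, acyclic ones when declared so), otherwise through *E*.  An
    explicitly declared pathway overrides the inference.
    """
    if spec.declared_pathway is not None:
        return spec.declared_pathway
    orientation = "I" if spec.n_substituent_size == "large" else "II"
    config = "Z" if "Z" in spec.accessible_configs else "E"
    return PathwayLabel(orientation, config)


# --------------------------------------------------------------------------
# geometric classification
# --------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees) about the p1-p2 axis."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
        raise GeometryError("dihedral undefined: collinear atoms")
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1.dot(n2)
    y = m1.dot(n2)
    return float(np.degrees(np.arctan2(y, x)))


def front_plane_normal(mol: Molecule3D, anchors) -> np.ndarray:
    """Unit normal of the 3,3' front plane, oriented towards the binding face.

    The plane passes through phosphorus and the two C3 carbons; the normal is
    oriented towards the midpoint of the two acid oxygens (where the
    substrate binds).
    """
    X = mol.coords
    p = X[anchors.p_index]
    c3a, c3b = (X[i] for i in anchors.c3_indices)
    n = np.cross(c3a - p, c3b - p)
    norm = np.linalg.norm(n)
    if norm < 1e-8:
        raise GeometryError("front plane degenerate: P and C3 carbons collinear")
    n = n / norm
    mid_acid = X[list(anchors.acid_o_indices)].mean(axis=0)
    if n.dot(mid_acid - p) < 0:
        n = -n
    return n


def classify_ts_geometry(mol: Molecule3D, amap: AtomMap) -> PathwayLabel:
    """Assign a Type I/II x E/Z label to an explicit TS geometry.

    The C=N configuration comes from the anchor-atom dihedral (|phi| >= 90
    degrees is *E*, ties inclusive); this is a geometric surrogate, not a CIP
    assignment.  Orientation is Type I when the N-substituent points away
    from the binding face, i.e. when (n_sub_anchor - imine_n) has negative
    projection on the front-plane normal of :func:`front_plane_normal`.
    """
    amap.validate(mol)
    X = mol.coords
    dih = _dihedral(X[amap.c_sub_anchor], X[amap.imine_c],
                    X[amap.imine_n], X[amap.n_sub_anchor])
    config = "E" if abs(dih) >= 90.0 else "Z"
    normal = front_plane_normal(mol, amap.anchors)
    proj = float((X[amap.n_sub_anchor] - X[amap.imine_n]).dot(normal))
    orientation = "I" if proj < 0 else "II"
    return PathwayLabel(orientation, config)
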
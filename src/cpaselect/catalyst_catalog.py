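"""Packaged catalyst screens and class-wise reaction summaries.

Two datasets ship with the package and are verified against embedded
checksums on load:

* ``catalyst_screens.csv`` — per-catalyst rows of three literature screens
  (a transfer hydrogenation of cyclic imines, a Friedel–Crafts indole
  addition, and an enamide addition), each with the printed AREA(θ),
  rotation barrier and signed ee.  Negative ee means the opposite
  enantiomer is formed.
* ``reaction_summaries.csv`` — reaction classes with the best ee reached by
  catalysts of each steric class (AREA(θ) classes for acyclic screens,
  rotation-barrier classes for the cyclic/Type II screens), together with a
  declarative transcription of each reaction's substrate features.

Catalysts that recur across screens with slightly different printed
descriptor values (e.g. the 9-anthryl barrier) are kept per-table and never
merged.  Curated SMILES for building 3D models of the catalysts are an
artifact addition, not printed data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import CpaError
from .pathway_model import ReactionSpec

__all__ = [
    "CatalogEntry",
    "ReactionSummaryRow",
    "load_catalog",
    "query_catalyst",
    "summary_rows_for_table",
    "best_class_per_row",
    "CATALYST_SMILES",
    "CATALYST_ALIASES",
]

_SHA256 = {
    "catalyst_screens.csv":
        "1383e53ae9eb18bf0c4dfaa3b1736b96ef034d702d5c5119b502a8e3c735c45b",
    "reaction_summaries.csv":
        "12038bbe7d332d2e7fee153542306638a770f44610bcd25d6e2835082caf5dd5",
}

#: Curated construction SMILES (artifact additions).  ``{R}`` marks the two
#: 3,3' attachment points on the BINOL phosphoric acid backbone.
BACKBONE_SMILES = "O=P1(O)Oc2c({R})cc3ccccc3c2-c2c(O1)c({R})cc1ccccc21"

CATALYST_SMILES = {
    "H": "[H]",
    "Ph": "c4ccccc4",
    "4-PhC6H4": "c4ccc(-c5ccccc5)cc4",
    "3,5-(CF3)2C6H4": "c4cc(C(F)(F)F)cc(C(F)(F)F)c4",
    "2-naphthyl": "c4ccc5ccccc5c4",
    "1-naphthyl": "c4cccc5ccccc45",
    "9-anthryl": "c4c5ccccc5cc5ccccc45",
    "9-phenanthryl": "c4cc5ccccc5c5ccccc45",
    "3,5-(tBu)2-4-OMeC6H3": "c4cc(C(C)(C)C)c(OC)c(C(C)(C)C)c4",
    "3,5-(tBu)2C6H4": "c4cc(C(C)(C)C)cc(C(C)(C)C)c4",
    "2,4,6-(iPr)3C6H3": "c4c(C(C)C)cc(C(C)C)cc4C(C)C",
    "SiPh3": "[Si](c4ccccc4)(c4ccccc4)c4ccccc4",
    "4-NO2C6H4": "c4ccc([N+](=O)[O-])cc4",
}

CATALYST_ALIASES = {
    "TRIP": "2,4,6-(iPr)3C6H3",
    "TIPSY": "SiPh3",
}


@dataclass(frozen=True)
class CatalogEntry:
    """One printed row of a catalyst screen."""

    catalyst_name: str
    area_theta: float
    rotation_barrier: float
    ee_percent: float
    source_table: int
    mechanism: str | None = None           # "I" | "II" where printed
    proximal_class_override: str | None = None
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not -100 <= self.ee_percent <= 100:
            raise CpaError(f"ee {self.ee_percent} outside [-100, 100]")


@dataclass(frozen=True)
class ReactionSummaryRow:
    """One reaction class with its per-steric-class best ee values.

    ``axis`` says which steric classes the table's columns bin by:
    "area" (AREA(θ) large/medium/small) or "proximal" (rotation-barrier
    small/medium/large).  Missing (unprinted) cells are absent from
    ``ee_by_class``, never stored as 0.
    """

    reaction_name: str
    mechanism_label: str   # I_E | I_Z | I_EZ | I_II_E | II_E
    ee_by_class: dict
    source_table: int
    axis: str
    reaction: ReactionSpec | None = None
    nu_carbon_substituent: str | None = None

    def __post_init__(self) -> None:
        if self.axis not in ("area", "proximal"):
            raise CpaError(f"unknown class axis {self.axis!r}")
        if len(self.ee_by_class) < 1:
            raise CpaError(f"row {self.reaction_name!r} has no populated class")

    @property
    def ambiguous_mechanism(self) -> bool:
        """Mixed printed labels (Type I E/Z, Type I/II E) that cannot be
        attributed to a single pathway."""
        return self.mechanism_label in ("I_EZ", "I_II_E")


def _read_verified(name: str) -> pd.DataFrame:
    data = (resources.files("cpaselect") / "data" / name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _SHA256[name]:
        raise CpaError(f"packaged dataset {name} failed its checksum "
                       f"({digest[:12]}... != {_SHA256[name][:12]}...)")
    from io import BytesIO
    return pd.read_csv(BytesIO(data))


def load_catalog() -> tuple[list[CatalogEntry], list[ReactionSummaryRow]]:
    """Load both packaged datasets, verifying their checksums."""
    screens = _read_verified("catalyst_screens.csv")
    entries = []
    for _, r in screens.iterrows():
        name = str(r["catalyst_name"])
        entries.append(CatalogEntry(
            catalyst_name=name,
            area_theta=float(r["area_theta"]),
            rotation_barrier=float(r["rotation_barrier"]),
            ee_percent=float(r["ee_percent"]),
            source_table=int(r["source_table"]),
            mechanism=None if pd.isna(r["mechanism"]) else str(r["mechanism"]),
            proximal_class_override=(None if pd.isna(r["proximal_class_override"])
                                     else str(r["proximal_class_override"])),
            smiles=CATALYST_SMILES.get(name),
        ))

    summaries = _read_verified("reaction_summaries.csv")
    rows = []
    for _, r in summaries.iterrows():
        ee_by_class = {}
        for cls in ("small", "medium", "large"):
            v = r[f"ee_{cls}"]
            if not pd.isna(v):
                ee_by_class[cls] = float(v)
        bulk = None if pd.isna(r["displaced_bulk"]) else str(r["displaced_bulk"])
        spec = ReactionSpec(
            imine_cyclic=bool(r["imine_cyclic"]),
            n_substituent_size=str(r["n_substituent_size"]),
            accessible_configs=frozenset(str(r["accessible_configs"]).split("|")),
            nucleophile_kind=str(r["nucleophile_kind"]),
            displaced_bulk=bulk,
            name=str(r["reaction_name"]),
        )
        rows.append(ReactionSummaryRow(
            reaction_name=str(r["reaction_name"]),
            mechanism_label=str(r["mechanism_label"]),
            ee_by_class=ee_by_class,
            source_table=int(r["source_table"]),
            axis=str(r["axis"]),
            reaction=spec,
            nu_carbon_substituent=(None if pd.isna(r["nu_carbon_substituent"])
                                   else str(r["nu_carbon_substituent"])),
        ))
    return entries, rows


def query_catalyst(name: str, table: int | None = None) -> list[CatalogEntry]:
    """Entries for a catalyst by canonical name or alias (TRIP, TIPSY)."""
    canonical = CATALYST_ALIASES.get(name, name)
    entries, _ = load_catalog()
    hits = [e for e in entries if e.catalyst_name == canonical
            and (table is None or e.source_table == table)]
    return hits


def summary_rows_for_table(table: int) -> list[ReactionSummaryRow]:
    _, rows = load_catalog()
    return [r for r in rows if r.source_table == table]


def best_class_per_row(row: ReactionSummaryRow, tolerance: float = 0.0) -> set[str]:
    """Steric classes whose |ee| is within ``tolerance`` points of the row
    maximum |ee|."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    best = max(abs(v) for v in row.ee_by_class.values())
    return {c for c, v in row.ee_by_class.items() if abs(v) >= best - tolerance}
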
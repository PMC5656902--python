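"""The eight-outcome decision tree mapping a reaction to catalyst sterics.

The qualitative selection model distinguishes reactions by four substrate
factors — N-substituent size, imine configuration, imine cyclicity and the
bulk of a displaced nucleophile — giving eight outcomes that collapse onto
four catalyst requirements:

====  ===========================================================  ==================
leaf  condition                                                    (proximal, AREA)
====  ===========================================================  ==================
1     Type I *E*, symmetrical nucleophile                          (large, medium)
2     Type I *E*, displaced nucleophile                            (large, small)
3     Type I *Z*, acyclic imine                                    (large, small)
4     Type I *Z*, cyclic imine, symmetrical nucleophile            (large, any)
5     Type I *Z*, cyclic imine, displaced nucleophile              (large, small)
6     Type II *E*, small displaced nucleophile                     (large, medium)
7     Type II *E*, large displaced nucleophile                     (small, medium)
8     Type II *Z* (cyclic imine)                                   (large, medium)
====  ===========================================================  ==================

Leaf 6 follows the computational evidence (medium AREA(θ): a Type II *E*
catalyst must differentiate Type II from Type I, which very small-AREA
catalysts cannot) rather than the one contradictory prose sentence
suggesting small AREA; the deviation is documented in the methods note.
Acyclic Type II *Z* has no literature precedent and raises an explicit
error.  TRIP suits every leaf except 7 — reactions of large displaced
nucleophiles need 2,6-unsubstituted (small-proximal) catalysts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .catalyst_catalog import (CatalogEntry, ReactionSummaryRow,
                               best_class_per_row, load_catalog)
from .errors import NoLiteraturePrecedentError
from .pathway_model import PathwayLabel, ReactionSpec, infer_pathway
from .steric_descriptors import classify_catalyst

__all__ = ["Requirement", "Recommendation", "recommend", "enumerate_leaves",
           "concordance_report"]

TRIP_WARNING = ("TRIP should be avoided here: reactions of large displaced "
                "nucleophiles with imines proceed through Type II *E* "
                "pathways that large proximal sterics destabilise; prefer a "
                "2,6-unsubstituted aryl catalyst such as phenyl.")


@dataclass(frozen=True)
class Requirement:
    """Required catalyst steric classes for one decision-tree leaf."""

    proximal: str   # "large" | "small" | "any"
    area: str       # "medium" | "small" | "any"
    leaf_id: int
    rationale: str

    def matches(self, proximal_class: str, area_class: str) -> bool:
        ok_p = self.proximal == "any" or proximal_class == self.proximal
        ok_a = self.area == "any" or area_class == self.area
        return ok_p and ok_a


@dataclass(frozen=True)
class Recommendation:
    """A requirement plus the catalog catalysts that satisfy it."""

    requirement: Requirement
    pathway: PathwayLabel
    shortlist: list[CatalogEntry]
    warnings: list[str] = field(default_factory=list)


_LEAVES = {
    1: Requirement("large", "medium", 1,
                   "Type I *E* with a symmetrical nucleophile: large proximal "
                   "sterics suppress Type II; medium AREA(θ) keeps the *E* "
                   "approach selective without blocking it."),
    2: Requirement("large", "small", 2,
                   "Type I *E* with a displaced nucleophile: large proximal "
                   "sterics suppress Type II and small AREA(θ) removes the "
                   "competing arrangements of the displaced binding mode."),
    3: Requirement("large", "small", 3,
                   "Type I *Z* with an acyclic imine: large proximal sterics "
                   "suppress Type II and small AREA(θ) disfavours the "
                   "competing Type I *E* pathway."),
    4: Requirement("large", "any", 4,
                   "Type I *Z*, cyclic imine, symmetrical nucleophile: the "
                   "imine cannot isomerise and the nucleophile adds in line, "
                   "so only proximal sterics act on the TS; any AREA(θ) "
                   "works."),
    5: Requirement("large", "small", 5,
                   "Type I *Z*, cyclic imine, displaced nucleophile: the "
                   "competing Type II TS tilts into the remote region, so "
                   "both large proximal sterics and small AREA(θ) are "
                   "needed."),
    6: Requirement("large", "medium", 6,
                   "Type II *E* with a small displaced nucleophile: large "
                   "proximal sterics disfavour Type I *E*; AREA(θ) must be "
                   "medium — large enough to discriminate the pathways, "
                   "small enough not to destabilise Type II itself."),
    7: Requirement("small", "medium", 7,
                   "Type II *E* with a large displaced nucleophile: bulk on "
                   "the nucleophile's binding carbon already fills the front "
                   "pocket, so small proximal sterics are essential and "
                   "medium AREA(θ) carries the discrimination."),
    8: Requirement("large", "medium", 8,
                   "Type II *Z* (cyclic imine): the tilted Type II "
                   "disposition engages both regions, so large proximal "
                   "sterics and medium AREA(θ) are required."),
}

#: (condition pattern, requirement) for each of the eight outcomes.  The
#: pattern fields mirror ReactionSpec; None means "any value".
_LEAF_PATTERNS = [
    ({"pathway": "I_E", "nucleophile_kind": "symmetrical"}, _LEAVES[1]),
    ({"pathway": "I_E", "nucleophile_kind": "displaced"}, _LEAVES[2]),
    ({"pathway": "I_Z", "imine_cyclic": False}, _LEAVES[3]),
    ({"pathway": "I_Z", "imine_cyclic": True,
      "nucleophile_kind": "symmetrical"}, _LEAVES[4]),
    ({"pathway": "I_Z", "imine_cyclic": True,
      "nucleophile_kind": "displaced"}, _LEAVES[5]),
    ({"pathway": "II_E", "nucleophile_kind": "displaced",
      "displaced_bulk": "small"}, _LEAVES[6]),
    ({"pathway": "II_E", "nucleophile_kind": "displaced",
      "displaced_bulk": "large"}, _LEAVES[7]),
    ({"pathway": "II_Z", "imine_cyclic": True}, _LEAVES[8]),
]


def enumerate_leaves() -> list[tuple[dict, Requirement]]:
    """The eight decision-tree leaves as (condition pattern, requirement)."""
    return list(_LEAF_PATTERNS)


def _leaf_for(spec: ReactionSpec, pathway: PathwayLabel) -> Requirement:
    if pathway.orientation == "II" and pathway.config == "Z" and not spec.imine_cyclic:
        raise NoLiteraturePrecedentError(
            "acyclic imines are not known to react through Type II *Z* "
            "pathways; no recommendation can be made")
    if str(pathway) == "I_E":
        return _LEAVES[1] if spec.nucleophile_kind == "symmetrical" else _LEAVES[2]
    if str(pathway) == "I_Z":
        if not spec.imine_cyclic:
            return _LEAVES[3]
        return _LEAVES[4] if spec.nucleophile_kind == "symmetrical" else _LEAVES[5]
    if str(pathway) == "II_E":
        if spec.nucleophile_kind == "displaced" and spec.displaced_bulk == "large":
            return _LEAVES[7]
        # small displaced nucleophiles; symmetrical nucleophiles (outside
        # the eight catalogued outcomes) behave like small in-line donors
        # and are routed to the same requirement
        return _LEAVES[6]
    return _LEAVES[8]  # II_Z, cyclic


def _entry_classes(entry: CatalogEntry) -> tuple[str, str]:
    return classify_catalyst(entry.area_theta, entry.rotation_barrier,
                             override=entry.proximal_class_override)


def recommend(spec: ReactionSpec,
              catalog: list[CatalogEntry] | None = None) -> Recommendation:
    """Map a reaction to its leaf and shortlist matching catalog catalysts.

    The shortlist groups catalog entries by catalyst name, keeps those whose
    steric classes (with silyl/alkyl proximal overrides honoured) satisfy
    the requirement, and ranks by the best |ee| evidence across the
    screens, ties alphabetical.
    """
    pathway = infer_pathway(spec)
    requirement = _leaf_for(spec, pathway)
    if catalog is None:
        catalog, _ = load_catalog()

    by_name: dict[str, list[CatalogEntry]] = {}
    for e in catalog:
        by_name.setdefault(e.catalyst_name, []).append(e)
    matching = []
    for name, entries in by_name.items():
        area_class, proximal_class = _entry_classes(entries[0])
        if requirement.matches(proximal_class, area_class):
            evidence = max(abs(e.ee_percent) for e in entries)
            matching.append((name, evidence, entries[0]))
    matching.sort(key=lambda t: (-t[1], t[0]))
    shortlist = [e for _, _, e in matching]

    warns = []
    if requirement.leaf_id == 7:
        warns.append(TRIP_WARNING)
    return Recommendation(requirement=requirement, pathway=pathway,
                          shortlist=shortlist, warnings=warns)


def concordance_report(tolerance: float = 10.0,
                       rows: list[ReactionSummaryRow] | None = None) -> pd.DataFrame:
    """Compare each packaged reaction summary against its recommendation.

    For every summary row the recommended steric class along the row's class
    axis is checked against the classes achieving the row's best |ee|
    (within ``tolerance`` ee points).  Rows with mixed printed mechanisms
    are reported but excluded from the verdict.  The frame carries
    per-row verdicts; ``.attrs`` holds the overall concordant fraction and
    the exception list at the requested and at zero tolerance.
    """
    if rows is None:
        _, rows = load_catalog()
    records = []
    for row in rows:
        rec: dict = {
            "source_table": row.source_table,
            "reaction": row.reaction_name,
            "mechanism": row.mechanism_label,
            "axis": row.axis,
        }
        if row.ambiguous_mechanism or row.reaction is None:
            rec.update(recommended=None, best_classes=None, concordant=None,
                       note="excluded: ambiguous printed mechanism")
            records.append(rec)
            continue
        recommendation = recommend(row.reaction, catalog=[])
        req = recommendation.requirement
        wanted = req.area if row.axis == "area" else req.proximal
        best = best_class_per_row(row, tolerance)
        best0 = best_class_per_row(row, 0.0)
        concordant = wanted == "any" or wanted in best
        rec.update(recommended=wanted,
                   best_classes=",".join(sorted(best)),
                   concordant=bool(concordant),
                   note="" if wanted == "any" or wanted in best0
                        else "not the strict row maximum")
        records.append(rec)
    columns = ["source_table", "reaction", "mechanism", "axis",
               "recommended", "best_classes", "concordant", "note"]
    df = pd.DataFrame.from_records(records, columns=columns)
    judged = df[df["concordant"].notna()]
    df.attrs["tolerance"] = tolerance
    df.attrs["n_judged"] = int(len(judged))
    df.attrs["fraction_concordant"] = (
        float(judged["concordant"].mean()) if len(judged) else float("nan"))
    df.attrs["exceptions"] = sorted(
        judged.loc[judged["concordant"] == False, "reaction"])  # noqa: E712
    # strict exceptions: rows whose recommended class misses the tolerance-0 maximum
    strict = judged[(judged["note"] == "not the strict row maximum")
                    | (judged["concordant"] == False)]  # noqa: E712
    df.attrs["exceptions_tolerance_0"] = sorted(strict["reaction"])
    return df
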
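"""Boltzmann/Curtin-Hammett enantioselectivity from TS free-energy ensembles.

Under Curtin-Hammett control the product ratio is set by the relative free
energies of the competing diastereomeric transition states:

    w_i = exp(-dG_i / RT) / sum_j exp(-dG_j / RT)
    ee  = 100 * (sum of weights of the positive-convention records
                 - sum of the others)

For a two-state ensemble this reduces to ee = 100 tanh(ddG / 2RT).  The gas
constant is R = 1.987204e-3 kcal/mol/K; energies are kcal/mol relative to
the ensemble minimum and temperatures are Kelvin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._params import R_KCAL
from .errors import EnsembleError
from .pathway_model import PathwayLabel

__all__ = [
    "TSRecord",
    "TSEnsemble",
    "SelectivityResult",
    "predict_ee",
    "ddg_from_ee",
    "dominant_mechanism",
]


@dataclass(frozen=True)
class TSRecord:
    """One transition state: label, pathway, product configuration and
    free energy (kcal/mol, relative)."""

    label: str
    pathway: PathwayLabel
    config: str  # "R" | "S"
    rel_energy: float

    def __post_init__(self) -> None:
        if self.config not in ("R", "S"):
            raise EnsembleError(f"config must be R or S, got {self.config!r}")
        if not np.isfinite(self.rel_energy):
            raise EnsembleError("non-finite energy")


@dataclass
class TSEnsemble:
    """A labelled set of competing TSs at a temperature.

    ``positive_config`` is the sign convention: the product configuration
    that carries positive ee.  Energies are re-referenced to the minimum on
    construction, so ``min(rel_energy) == 0`` always holds.
    """

    records: list[TSRecord]
    temperature: float = 298.15
    positive_config: str = "R"

    def __post_init__(self) -> None:
        if not self.records:
            raise EnsembleError("ensemble has no records")
        if self.temperature <= 0:
            raise EnsembleError(f"temperature must be positive, got {self.temperature}")
        if self.positive_config not in ("R", "S"):
            raise EnsembleError("positive_config must be 'R' or 'S'")
        emin = min(r.rel_energy for r in self.records)
        if emin != 0.0:
            self.records = [
                TSRecord(r.label, r.pathway, r.config, r.rel_energy - emin)
                for r in self.records
            ]

    @property
    def rel_energies(self) -> np.ndarray:
        return np.array([r.rel_energy for r in self.records])


@dataclass(frozen=True)
class SelectivityResult:
    """Predicted ee (signed %), Boltzmann weights, dominant pathway, and the
    free-energy gap between the best TSs of the two configurations
    (positive when the positive-convention configuration is favoured;
    None when only one configuration is present)."""

    ee: float
    weights: np.ndarray
    dominant_pathway: PathwayLabel
    delta_delta_g: float | None


def predict_ee(ensemble: TSEnsemble) -> SelectivityResult:
    """Boltzmann-weight the ensemble and predict the enantiomeric excess."""
    E = ensemble.rel_energies
    w = np.exp(-E / (R_KCAL * ensemble.temperature))
    w = w / w.sum()
    pos = np.array([r.config == ensemble.positive_config for r in ensemble.records])
    ee = 100.0 * (w[pos].sum() - w[~pos].sum())

    # dominant pathway: the largest-weight record; break exact weight ties by
    # pathway order (I < II, E < Z)
    order = sorted(range(len(w)), key=lambda i: (-w[i], ensemble.records[i].pathway))
    dominant = ensemble.records[order[0]].pathway

    e_pos = E[pos].min() if pos.any() else None
    e_neg = E[~pos].min() if (~pos).any() else None
    ddg = (e_neg - e_pos) if (e_pos is not None and e_neg is not None) else None
    return SelectivityResult(ee=float(ee), weights=w, dominant_pathway=dominant,
                             delta_delta_g=ddg)


def ee_from_ddg(ddg: float, temperature: float) -> float:
    """Two-state closed form: ee = 100 tanh(ddG / 2RT)."""
    if temperature <= 0:
        raise EnsembleError("temperature must be positive")
    return 100.0 * float(np.tanh(ddg / (2.0 * R_KCAL * temperature)))


def ddg_from_ee(ee: float, temperature: float) -> float:
    """Invert the two-state relation: ddG = RT ln((1+|ee|/100)/(1-|ee|/100)).

    Returns the (unsigned) free-energy gap in kcal/mol.
    """
    if temperature <= 0:
        raise EnsembleError("temperature must be positive")
    e = abs(ee) / 100.0
    if e >= 1.0:
        raise EnsembleError("|ee| must be < 100 %: the two-state gap is unbounded")
    return R_KCAL * temperature * float(np.log((1.0 + e) / (1.0 - e)))


def dominant_mechanism(ensemble: TSEnsemble) -> PathwayLabel:
    """Pathway of the minimum-energy record.

    Exact energy ties between different pathways are broken by pathway order
    (I before II, E before Z) with a warning.
    """
    emin = min(r.rel_energy for r in ensemble.records)
    lowest = [r for r in ensemble.records if r.rel_energy == emin]
    pathways = sorted({r.pathway for r in lowest})
    if len(pathways) > 1:
        warnings.warn(
            f"exact energy tie between pathways {[str(p) for p in pathways]}; "
            f"reporting {pathways[0]}", stacklevel=2)
    return pathways[0]
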
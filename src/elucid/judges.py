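"""Fitness evaluators: NMR-shift agreement, NP-likeness, anti-Bredt veto.

Each candidate constitution is scored by up to three judges:

* the NMR judge back-calculates every carbon's shift from the HOSE
  index, assigns carbons to experimental peaks within attached-hydrogen
  classes (from DEPT 90/135), awards ``P_max`` points per carbon whose
  predicted shift falls within the confidence limit of its assigned
  peak, and normalizes by ``carbon_count * P_max``;
* the NP judge maps the raw natural-product-likeness score linearly
  onto [0, 1] using the trained model's recorded extremes;
* the anti-Bredt judge flags bridgehead double bonds whose rings all
  have seven or fewer atoms.

The combined fitness is ``NMRcost_norm / 1 + NPcost_norm / 2`` (NMR
agreement weighted twice as strongly as NP-likeness); a higher total is
better.  An anti-Bredt violation vetoes the candidate (total 0) unless
a softer multiplicative penalty is configured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from scipy.optimize import linear_sum_assignment

from .chem_graph import MolecularGraph
from .hose_index import PredictedShift, ShiftIndex, predict_shift
from .np_model import DegenerateModelError, FragmentModel, np_raw_score

__all__ = [
    "SpectrumError",
    "JudgeError",
    "Peak",
    "Spectrum",
    "JudgeConfig",
    "FitnessRecord",
    "assign_peaks",
    "nmr_judge",
    "np_judge",
    "antibredt_judge",
    "total_cost",
    "evaluate",
]


class SpectrumError(ValueError):
    """Spectrum inconsistent with the problem formula."""


class JudgeError(ValueError):
    """Judge applied to an inapplicable problem."""


@dataclass(frozen=True)
class Peak:
    """One experimental 13C resonance.

    ``n_h`` is the attached-hydrogen count from DEPT 90/135 and
    ``multiplicity`` the number of equivalent carbons under the peak.
    """

    shift: float
    n_h: int
    multiplicity: int = 1


@dataclass
class Spectrum:
    """Experimental 13C peak list; the elucidation constraint."""

    peaks: List[Peak]

    @property
    def carbon_total(self) -> int:
        return sum(p.multiplicity for p in self.peaks)

    def validate(self, formula: Dict[str, int]) -> None:
        n_c = formula.get("C", 0)
        if self.carbon_total != n_c:
            raise SpectrumError(
                f"peaks cover {self.carbon_total} carbons but formula has {n_c}"
            )
        for p in self.peaks:
            if not np.isfinite(p.shift):
                raise SpectrumError(f"non-finite shift {p.shift}")
            if not 0 <= p.n_h <= 3:
                raise SpectrumError(f"attached-H count {p.n_h} out of range 0-3")
            if p.multiplicity < 1:
                raise SpectrumError(f"multiplicity {p.multiplicity} < 1")
        h_attached = sum(p.n_h * p.multiplicity for p in self.peaks)
        if h_attached > formula.get("H", 0):
            raise SpectrumError(
                f"peaks attach {h_attached} hydrogens but formula has "
                f"{formula.get('H', 0)}"
            )


@dataclass
class JudgeConfig:
    """Judge weights and modes.

    The default weights (NMR 1, NP 1/2) weight candidates more for NMR
    agreement and less for NP-likeness; ``mode`` selects whether the NP
    judge participates.  ``bredt_penalty=0`` is a hard veto; a value in
    (0, 1) multiplies the total instead.
    """

    mode: str = "nmr_np"  # "nmr_np" | "nmr_only"
    p_max: float = 100.0
    nmr_weight: float = 1.0
    np_weight: float = 0.5
    antibredt: bool = True
    bredt_penalty: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("nmr_np", "nmr_only"):
            raise ValueError(f"unknown judge mode {self.mode!r}")


@dataclass(frozen=True)
class FitnessRecord:
    """Per-candidate cost breakdown; ``total`` is the fitness (higher wins)."""

    nmr_score: float
    nmr_norm: float
    np_score: Optional[float]
    np_norm: Optional[float]
    bredt_violation: bool
    total: float


# ---------------------------------------------------------------------------
# Peak assignment (Eq 1 presupposes a pairing; this makes it deterministic)
# ---------------------------------------------------------------------------

_MISMATCH = 1.0e6
_DEV_SCALE = 1.0e-4  # keeps total deviations < 1, strictly secondary to matches


def assign_peaks(
    predictions: Sequence[Tuple[PredictedShift, int]],
    spectrum: Spectrum,
) -> List[Tuple[int, Optional[int], bool]]:
    """Assign candidate carbons to experimental peaks.

    ``predictions[k]`` is (predicted shift, attached-H count) for carbon
    *k* of the candidate.  Pairing is restricted to equal attached-H
    classes; within each class an optimal bipartite assignment maximizes
    the number of within-CL matches, ties broken by minimum total
    absolute deviation.  Returns (carbon position, peak index or None,
    matched) triples.  Carbons in excess of their class's peak capacity
    stay unassigned (scored zero, candidate not rejected).
    """
    slots: Dict[int, List[int]] = {}
    for p_idx, peak in enumerate(spectrum.peaks):
        slots.setdefault(peak.n_h, []).extend([p_idx] * peak.multiplicity)

    result: List[Tuple[int, Optional[int], bool]] = []
    by_class: Dict[int, List[int]] = {}
    for k, (_, n_h) in enumerate(predictions):
        by_class.setdefault(n_h, []).append(k)

    for n_h, carbon_idx in sorted(by_class.items()):
        class_slots = slots.get(n_h, [])
        if not class_slots:
            result.extend((k, None, False) for k in carbon_idx)
            continue
        cost = np.empty((len(carbon_idx), len(class_slots)))
        for r, k in enumerate(carbon_idx):
            pred = predictions[k][0]
            for c, p_idx in enumerate(class_slots):
                peak = spectrum.peaks[p_idx]
                if pred.fallback:
                    cost[r, c] = _MISMATCH
                else:
                    dev = abs(pred.delta - peak.shift)
                    cost[r, c] = dev * _DEV_SCALE + (0.0 if dev <= pred.cl else _MISMATCH)
        rows, cols = linear_sum_assignment(cost)
        assigned = {}
        for r, c in zip(rows, cols):
            assigned[carbon_idx[r]] = (class_slots[c], bool(cost[r, c] < _MISMATCH))
        for k in carbon_idx:
            if k in assigned:
                p_idx, ok = assigned[k]
                result.append((k, p_idx, ok))
            else:
                result.append((k, None, False))
    result.sort(key=lambda t: t[0])
    return result


# ---------------------------------------------------------------------------
# Judges
# ---------------------------------------------------------------------------


def nmr_judge(
    g: MolecularGraph,
    spectrum: Spectrum,
    index: ShiftIndex,
    config: JudgeConfig,
) -> Tuple[float, float]:
    """Score 13C agreement: P_max per carbon matched within its CL.

    Returns (raw score, normalized score = raw / (carbon_count * P_max)).
    Carbons whose shift cannot be predicted at any height score zero.
    """
    carbons = g.carbons()
    if not carbons:
        raise JudgeError("candidate has no carbon atoms; NMR judge inapplicable")
    predictions = [(predict_shift(index, g, i), g.hydrogens[i]) for i in carbons]
    assignment = assign_peaks(predictions, spectrum)
    matched = sum(1 for _, _, ok in assignment if ok)
    raw = matched * config.p_max
    return raw, raw / (len(carbons) * config.p_max)


def np_judge(
    g: MolecularGraph, model: FragmentModel, config: JudgeConfig
) -> Tuple[float, float]:
    """Normalize the raw NP-likeness score onto [0, 1] via the model extremes."""
    if model.min_score >= model.max_score:
        raise DegenerateModelError("model min >= max; cannot normalize")
    raw = np_raw_score(model, g)
    norm = (raw - model.min_score) / (model.max_score - model.min_score)
    return raw, min(1.0, max(0.0, norm))


def antibredt_judge(g: MolecularGraph) -> bool:
    """True iff the graph contains a forbidden bridgehead double bond.

    A bridgehead is an endpoint atom of a bridge shared by two rings
    (rings with >= 2 common bonds).  A double bond at a bridgehead is a
    violation when every ring through that bond -- through the
    bridgehead itself for an exocyclic double bond -- has <= 7 atoms.
    """
    bridgeheads = _bridgehead_atoms(g)
    if not bridgeheads:
        return False
    for a in bridgeheads:
        for b, order in g.neighbors(a).items():
            if order != 2:
                continue
            sizes = _ring_sizes_through_bond(g, a, b)
            if not sizes:
                sizes = _ring_sizes_through_atom(g, a)
            if sizes and max(sizes) <= 7:
                return True
    return False


def _bridgehead_atoms(g: MolecularGraph) -> set:
    """Endpoint atoms of a bridge: rings sharing >= 2 bonds (SSSR)."""
    mol = g.to_rdkit()
    Chem.GetSymmSSSR(mol)
    info = mol.GetRingInfo()
    bond_rings = [set(r) for r in info.BondRings()]
    bridgeheads: set = set()
    for a in range(len(bond_rings)):
        for b in range(a + 1, len(bond_rings)):
            shared = bond_rings[a] & bond_rings[b]
            if len(shared) < 2:
                continue
            incidence: Dict[int, int] = {}
            for bond_idx in shared:
                bond = mol.GetBondWithIdx(bond_idx)
                for k in (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()):
                    incidence[k] = incidence.get(k, 0) + 1
            bridgeheads.update(k for k, deg in incidence.items() if deg == 1)
    return bridgeheads


def _ring_sizes_through_bond(g: MolecularGraph, u: int, v: int) -> List[int]:
    """Sizes of all simple rings containing bond (u, v)."""
    sizes: List[int] = []

    def dfs(node: int, visited: set) -> None:
        for nbr in g.neighbors(node):
            if nbr == v and node != u:
                sizes.append(len(visited))
            elif nbr not in visited and nbr != v:
                visited.add(nbr)
                dfs(nbr, visited)
                visited.remove(nbr)

    dfs(u, {u})
    return sizes


def _ring_sizes_through_atom(g: MolecularGraph, a: int) -> List[int]:
    sizes: List[int] = []
    for nbr in g.neighbors(a):
        for s in _ring_sizes_through_bond(g, a, nbr):
            sizes.append(s)
    return sizes


def total_cost(
    nmr_norm: float,
    np_norm: Optional[float],
    bredt_violation: bool,
    config: JudgeConfig,
) -> float:
    """Weighted total: NMR / (1/w1) + NP / (1/w2); veto on anti-Bredt hits."""
    total = config.nmr_weight * nmr_norm
    if config.mode == "nmr_np":
        if np_norm is None:
            raise JudgeError("nmr_np mode requires an NP score")
        total += config.np_weight * np_norm
    if bredt_violation and config.antibredt:
        total *= config.bredt_penalty
    return total


def evaluate(
    g: MolecularGraph,
    spectrum: Spectrum,
    index: ShiftIndex,
    model: Optional[FragmentModel],
    config: JudgeConfig,
) -> FitnessRecord:
    """Run all enabled judges and combine into a FitnessRecord."""
    nmr_score, nmr_norm = nmr_judge(g, spectrum, index, config)
    np_score = np_norm = None
    if config.mode == "nmr_np":
        if model is None:
            raise JudgeError("nmr_np mode requires a fragment model")
        np_score, np_norm = np_judge(g, model, config)
    violation = antibredt_judge(g) if config.antibredt else False
    return FitnessRecord(
        nmr_score=nmr_score,
        nmr_norm=nmr_norm,
        np_score=np_score,
        np_norm=np_norm,
        bredt_violation=violation,
        total=total_cost(nmr_norm, np_norm, violation, config),
    )
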
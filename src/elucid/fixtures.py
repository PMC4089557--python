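"""Synthetic reference data: shift sets, NP corpora, closed-loop problems.

Everything the system needs to build and test itself is generated here,
with no external download: a reference set of molecules with per-carbon
13C shifts (standing in for a curated shift-database export), two
deliberately skewed training corpora for the NP-likeness model, and
closed-loop elucidation problems whose spectra are produced by the
package's own predictor on a known answer -- so the answer attains a
normalized NMR score of exactly 1 by construction.

The shift model is additive over the carbon's one-sphere environment
(a base value per neighbour element/bond-order class) plus Gaussian
noise.  It is crude on purpose: the tests assert pipeline behaviour
(indexing, backoff, assignment, search), not chemical accuracy.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

from .chem_graph import (
    GenerationError,
    MolecularGraph,
    from_smiles,
    random_structure,
)
from .hose_index import ShiftIndex, predict_shift
from .judges import Peak, Spectrum

__all__ = [
    "FixtureError",
    "FixtureSpec",
    "NP_SCAFFOLD_SMILES",
    "SYNTHETIC_SCAFFOLD_SMILES",
    "base_shift",
    "make_reference_set",
    "make_np_corpora",
    "make_closed_loop_problem",
]


class FixtureError(ValueError):
    """Fixture construction failed (e.g. unpredictable answer carbon)."""


@dataclass
class FixtureSpec:
    """Parameters of the synthetic data generators.

    ``n_molecules`` molecules per generated set, heavy-atom counts kept
    at or below ``max_heavy`` (the small-natural-product regime the
    system targets), shifts drawn as class base value + N(0, noise_sd)
    ppm.  Everything is deterministic given ``seed``.
    """

    n_molecules: int = 60
    max_heavy: int = 15
    seed: int = 0
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be positive")
        if self.max_heavy < 2 or self.max_heavy > 15:
            raise ValueError("max_heavy must be in 2..15")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


# Hand-curated natural-product-like scaffolds, <= 15 heavy atoms:
# oxygen heterocycles, lactones, polyols, phenolics, terpenoid fragments.
NP_SCAFFOLD_SMILES: Tuple[str, ...] = (
    "C1CCOC1",                    # tetrahydrofuran
    "O=C1CCCO1",                  # gamma-butyrolactone
    "O=C1OC(C)CC1",               # 5-methyl lactone
    "OC1CCCCO1",                  # 2-hydroxy-oxane (lactol)
    "OCC1OC(O)C(O)C1O",           # furanose-like polyol
    "OCC1OC(O)C(O)C(O)C1O",       # pyranose-like polyol
    "CC1=CC(=O)CC(C)(C)C1",       # isophorone (terpenoid ketone)
    "CC1=CCC(CC1)C(C)C",          # terpinene-like
    "CC(C)=CCCC(C)=O",            # methyl-heptenone (acyclic terpenoid)
    "OC1=CC=CC(O)=C1",            # resorcinol
    "COC1=CC=CC(C=O)=C1",         # methoxy-benzaldehyde
    "OC1=CC=C(CC=C)C=C1",         # allyl-phenol
    "O=C1C=COC2=CC=CC=C12",       # chromone
    "O=C1OC2=CC=CC=C2C=C1",       # coumarin
    "CC1CCOC1=O",                 # 3-methyl lactone
    "OCC(O)C(O)CO",               # erythritol
    "CC(O)C1=CC=C(O)C=C1",        # phenolic alcohol
    "O1C=CC2=CC=CC=C12",          # benzofuran
    "OC1CCC2(C)CCCC2C1",          # decalin-ol fragment
    "CC1=CC(C)=CC(O)=C1",         # xylenol
)

# Synthetic-like scaffolds: halogenated, amide/nitrile-rich motifs.
SYNTHETIC_SCAFFOLD_SMILES: Tuple[str, ...] = (
    "ClC1=CC=CC=C1",              # chlorobenzene
    "ClC1=CC=C(Cl)C=C1",          # dichlorobenzene
    "FC1=CC=C(C=C1)C#N",          # fluorobenzonitrile
    "CN(C)C(C)=O",                # dimethylacetamide
    "CC(=O)NC1=CC=CC=C1",         # acetanilide
    "N#CCC#N",                    # malononitrile
    "ClCC(=O)NC",                 # chloroacetamide
    "CN1CCNCC1",                  # N-methylpiperazine
    "FC(F)(F)C1=CC=CC=C1",        # trifluoromethylbenzene
    "ClC(Cl)C1=CC=CC=C1",         # dichloromethylbenzene
    "CSC1=CC=CC=C1",              # thioanisole
    "CN(C)C1=CC=C(C=C1)C#N",      # dimethylamino-benzonitrile
    "BrCC1=CC=CC=C1",             # benzyl bromide
    "CC(C)N(C(C)C)CC#N",          # aminonitrile
    "ClC1=NC=CC=C1",              # chloropyridine
    "CN(C)CC(=O)NC",              # glycinamide motif
)

#: Additive one-sphere shift contributions, ppm, keyed by
#: (neighbour element, bond order).  Chosen to spread the common carbon
#: classes over a plausible 0-200 ppm range (methyl ~15, alcohol carbon
#: ~55, alkene ~70-130, carbonyl ~170-200).
_SHIFT_CONTRIB: Dict[Tuple[str, int], float] = {
    ("C", 1): 10.0, ("C", 2): 60.0, ("C", 3): 85.0,
    ("O", 1): 45.0, ("O", 2): 155.0,
    ("N", 1): 25.0, ("N", 2): 80.0, ("N", 3): 95.0,
    ("S", 1): 15.0,
    ("F", 1): 75.0, ("Cl", 1): 35.0, ("Br", 1): 25.0, ("I", 1): -10.0,
    ("P", 1): 12.0,
}
_SHIFT_BASE = 5.0


def base_shift(g: MolecularGraph, atom: int) -> float:
    """Deterministic noise-free shift of a carbon from its one-sphere class."""
    if g.elements[atom] != "C":
        raise FixtureError(f"atom {atom} is not carbon")
    delta = _SHIFT_BASE
    for nbr, order in g.neighbors(atom).items():
        delta += _SHIFT_CONTRIB.get((g.elements[nbr], order), 20.0)
    return delta


def _np_scaffolds() -> List[MolecularGraph]:
    return [from_smiles(s) for s in NP_SCAFFOLD_SMILES]


def _synthetic_scaffolds() -> List[MolecularGraph]:
    return [from_smiles(s) for s in SYNTHETIC_SCAFFOLD_SMILES]


def _random_np_like(rng: random.Random, max_heavy: int) -> MolecularGraph:
    """Random valid structure from an O-rich CxHyOz formula."""
    for _ in range(50):
        n_c = rng.randint(3, max(3, min(max_heavy - 1, 9)))
        n_o = rng.randint(1, min(3, max_heavy - n_c))
        dbe = rng.randint(0, 2)
        n_h = 2 * n_c + 2 - 2 * dbe
        if n_h < 0:
            continue
        try:
            return random_structure(
                {"C": n_c, "O": n_o, "H": n_h}, rng
            )
        except GenerationError:
            continue
    raise FixtureError("could not generate a random NP-like molecule")


def _random_synthetic_like(rng: random.Random, max_heavy: int) -> MolecularGraph:
    """Random valid structure from an N/halogen-rich formula."""
    for _ in range(50):
        n_c = rng.randint(3, max(3, min(max_heavy - 2, 8)))
        n_n = rng.randint(0, 1)
        n_cl = rng.randint(1, 2)
        dbe = rng.randint(0, 2)
        n_h = 2 * n_c + 2 + n_n - n_cl - 2 * dbe
        if n_h < 0:
            continue
        formula = {"C": n_c, "H": n_h, "Cl": n_cl}
        if n_n:
            formula["N"] = n_n
        try:
            return random_structure(formula, rng)
        except GenerationError:
            continue
    raise FixtureError("could not generate a random synthetic-like molecule")


def make_reference_set(
    spec: FixtureSpec,
    exclude: Optional[Set[str]] = None,
) -> List[Tuple[MolecularGraph, Dict[int, float]]]:
    """Generate (molecule, per-carbon shift) pairs for index building.

    Scaffolds are used first, then random structures; molecules whose
    canonical key is in ``exclude`` are dropped, mirroring the practice
    of cross-checking test structures out of the training index.
    """
    rng = random.Random(spec.seed)
    exclude = exclude or set()
    molecules: List[MolecularGraph] = []
    for g in _np_scaffolds() + _synthetic_scaffolds():
        if len(molecules) >= spec.n_molecules:
            break
        if g.n_atoms <= spec.max_heavy and g.key not in exclude:
            molecules.append(g)
    seen = {g.key for g in molecules} | exclude
    guard = 0
    while len(molecules) < spec.n_molecules and guard < 50 * spec.n_molecules:
        guard += 1
        maker = _random_np_like if rng.random() < 0.6 else _random_synthetic_like
        g = maker(rng, spec.max_heavy)
        if g.key in seen:
            continue
        seen.add(g.key)
        molecules.append(g)
    reference = []
    for g in molecules:
        shifts = {
            i: base_shift(g, i) + rng.gauss(0.0, spec.noise_sd)
            for i in g.carbons()
        }
        reference.append((g, shifts))
    return reference


def make_np_corpora(
    spec: FixtureSpec,
) -> Tuple[List[MolecularGraph], List[MolecularGraph]]:
    """Two corpora with skewed fragment vocabularies (NP-ish vs synthetic-ish)."""
    rng = random.Random(spec.seed + 1)
    np_set = [g for g in _np_scaffolds() if g.n_atoms <= spec.max_heavy]
    syn_set = [g for g in _synthetic_scaffolds() if g.n_atoms <= spec.max_heavy]
    np_keys = {g.key for g in np_set}
    syn_keys = {g.key for g in syn_set}
    guard = 0
    while len(np_set) < spec.n_molecules and guard < 50 * spec.n_molecules:
        guard += 1
        g = _random_np_like(rng, spec.max_heavy)
        if g.key not in np_keys:
            np_keys.add(g.key)
            np_set.append(g)
    guard = 0
    while len(syn_set) < spec.n_molecules and guard < 50 * spec.n_molecules:
        guard += 1
        g = _random_synthetic_like(rng, spec.max_heavy)
        if g.key not in syn_keys:
            syn_keys.add(g.key)
            syn_set.append(g)
    return np_set, syn_set


def make_closed_loop_problem(
    answer: MolecularGraph,
    index: ShiftIndex,
) -> Tuple[Dict[str, int], Spectrum, MolecularGraph]:
    """Build a problem whose spectrum is the index's own prediction of ``answer``.

    Carbons sharing a predicted shift and attached-H count merge into
    one peak with the corresponding multiplicity, so symmetric carbons
    appear as a single resonance.  By construction the answer's
    normalized NMR cost is exactly 1.  Raises :class:`FixtureError` if
    any answer carbon is unpredictable at every height.
    """
    answer.validate()
    peaks: Dict[Tuple[float, int], int] = {}
    for i in answer.carbons():
        pred = predict_shift(index, answer, i)
        if pred.fallback:
            raise FixtureError(
                f"carbon {i} of the answer matches no index entry at any height"
            )
        key = (round(pred.delta, 4), answer.hydrogens[i])
        peaks[key] = peaks.get(key, 0) + 1
    spectrum = Spectrum(
        [Peak(shift, n_h, mult) for (shift, n_h), mult in sorted(peaks.items())]
    )
    formula = answer.element_counts()
    spectrum.validate(formula)
    return formula, spectrum, answer
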
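"""Molecular graphs for constitutional isomer search.

The unit of search is a hydrogen-suppressed connected multigraph of heavy
atoms with integer bond orders (1-3).  Hydrogens are implicit: each heavy
atom carries the number of hydrogens forced by its standard valence, so a
molecular graph together with its element counts fully determines a
constitution.  This module provides the data model, Hill-formula parsing
with a degree-of-unsaturation feasibility check, random structure
generation, the Faulon-style mutation operator used by the evolutionary
search, canonicalization/isomorphism, and molfile/SDF/SMILES I/O (backed
by RDKit).
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import networkx as nx
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "VALENCES",
    "ELEMENT_PRIORITY",
    "FormulaError",
    "InfeasibleFormulaError",
    "GenerationError",
    "MolfileError",
    "UnsupportedFeatureError",
    "MolecularGraph",
    "parse_formula",
    "formula_dbe",
    "format_formula",
    "random_structure",
    "mutate",
    "canonical_key",
    "is_same_constitution",
    "permute_graph",
    "from_smiles",
    "to_smiles",
    "read_molfile",
    "write_sdf",
    "read_sdf",
]

#: Fixed standard valences.  No charges, radicals or hypervalent states:
#: the target chemistry is small neutral natural products.
VALENCES: Dict[str, int] = {
    "C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

#: Priority used when ordering branches in environment codes:
#: carbon first, then O, N, S, P, halogens.
ELEMENT_PRIORITY: Dict[str, int] = {
    el: i for i, el in enumerate(["C", "O", "N", "S", "P", "F", "Cl", "Br", "I"])
}

_HALOGENS = frozenset({"F", "Cl", "Br", "I"})


class FormulaError(ValueError):
    """Malformed or unsupported molecular formula."""


class InfeasibleFormulaError(FormulaError):
    """Formula with negative or fractional degree of unsaturation."""


class GenerationError(RuntimeError):
    """Random structure generation exhausted its retry budget."""


class MolfileError(ValueError):
    """Malformed molfile/SDF input."""


class UnsupportedFeatureError(ValueError):
    """Input uses chemistry outside the supported model (charges, isotopes...)."""


# ---------------------------------------------------------------------------
# Formula handling
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts.

    Raises :class:`FormulaError` for unsupported elements and
    :class:`InfeasibleFormulaError` when the implied degree of
    unsaturation is negative or fractional.
    """
    text = text.strip()
    if not text:
        raise FormulaError("empty formula")
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el != "H" and el not in VALENCES:
            raise FormulaError(f"unsupported element {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    heavy = sum(n for el, n in counts.items() if el != "H")
    if heavy < 1:
        raise InfeasibleFormulaError(f"formula {text!r} has no heavy atom")
    dbe = formula_dbe(counts)
    if dbe < 0 or dbe != int(dbe):
        raise InfeasibleFormulaError(
            f"formula {text!r} infeasible: degree of unsaturation {dbe}"
        )
    return counts


def formula_dbe(counts: Dict[str, int]) -> float:
    """Degree of unsaturation (rings + pi bonds) of a formula.

    DBE = 1 + sum_i n_i (v_i - 2) / 2 over all atoms including hydrogen,
    which for CHNOPS+halogens reduces to C + 1 + (N+P)/2 - (H+X)/2.
    """
    dbe = 1.0
    for el, n in counts.items():
        v = 1 if el == "H" else VALENCES[el]
        dbe += n * (v - 2) / 2.0
    return dbe


def format_formula(counts: Dict[str, int]) -> str:
    """Render element counts in Hill order (C, H, then alphabetical)."""
    parts = []
    for el in ["C", "H"] + sorted(k for k in counts if k not in ("C", "H")):
        n = counts.get(el, 0)
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


# ---------------------------------------------------------------------------
# The molecular graph
# ---------------------------------------------------------------------------


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed molecular multigraph.

    ``elements[i]`` is the element symbol of heavy atom *i*,
    ``hydrogens[i]`` its implicit hydrogen count, and ``adj[i][j]`` the
    integer order (1-3) of the bond between *i* and *j* (stored
    symmetrically).  Instances are treated as immutable once built;
    mutation operators return new graphs.
    """

    elements: List[str]
    hydrogens: List[int]
    adj: Dict[int, Dict[int, int]]
    provenance: Optional[str] = None
    _key: Optional[str] = field(default=None, repr=False, compare=False)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def bonds(self) -> Iterator[Tuple[int, int, int]]:
        """Yield (i, j, order) with i < j."""
        for i in sorted(self.adj):
            for j in sorted(self.adj[i]):
                if i < j:
                    yield i, j, self.adj[i][j]

    def bond_order(self, i: int, j: int) -> int:
        return self.adj.get(i, {}).get(j, 0)

    def neighbors(self, i: int) -> Dict[int, int]:
        return self.adj.get(i, {})

    def heavy_degree(self, i: int) -> int:
        """Sum of incident bond orders (the heavy-atom valence share)."""
        return sum(self.adj.get(i, {}).values())

    def element_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for el in self.elements:
            counts[el] = counts.get(el, 0) + 1
        h = sum(self.hydrogens)
        if h:
            counts["H"] = counts.get("H", 0) + h
        return counts

    def carbons(self) -> List[int]:
        return [i for i, el in enumerate(self.elements) if el == "C"]

    def copy(self, provenance: Optional[str] = None) -> "MolecularGraph":
        return MolecularGraph(
            list(self.elements),
            list(self.hydrogens),
            {i: dict(nbrs) for i, nbrs in self.adj.items()},
            provenance if provenance is not None else self.provenance,
        )

    # -- invariants ---------------------------------------------------------

    def is_connected(self) -> bool:
        n = self.n_atoms
        if n <= 1:
            return True
        seen = {0}
        stack = [0]
        while stack:
            i = stack.pop()
            for j in self.adj.get(i, {}):
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == n

    def validate(self, formula: Optional[Dict[str, int]] = None) -> None:
        """Assert all structural invariants; raise ``ValueError`` on failure."""
        n = self.n_atoms
        if n < 1:
            raise ValueError("graph has no atoms")
        if len(self.hydrogens) != n:
            raise ValueError("hydrogens length mismatch")
        for i, el in enumerate(self.elements):
            if el not in VALENCES:
                raise ValueError(f"unsupported element {el!r} at atom {i}")
            if self.hydrogens[i] < 0:
                raise ValueError(f"negative hydrogen count at atom {i}")
            if self.heavy_degree(i) + self.hydrogens[i] != VALENCES[el]:
                raise ValueError(
                    f"valence violation at atom {i} ({el}): "
                    f"{self.heavy_degree(i)} bond order + {self.hydrogens[i]} H "
                    f"!= {VALENCES[el]}"
                )
        for i, nbrs in self.adj.items():
            for j, order in nbrs.items():
                if i == j:
                    raise ValueError(f"self-loop at atom {i}")
                if not 1 <= order <= 3:
                    raise ValueError(f"bond order {order} out of range on ({i},{j})")
                if self.adj.get(j, {}).get(i) != order:
                    raise ValueError(f"asymmetric bond record ({i},{j})")
        if not self.is_connected():
            raise ValueError("graph is disconnected")
        if formula is not None:
            if self.element_counts() != {k: v for k, v in formula.items() if v}:
                raise ValueError(
                    f"element counts {self.element_counts()} != formula {formula}"
                )

    # -- conversions --------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(self.elements):
            g.add_node(i, element=el, hydrogens=self.hydrogens[i])
        for i, j, order in self.bonds():
            g.add_edge(i, j, order=order)
        return g

    def to_rdkit(self) -> Chem.Mol:
        return _to_rdkit(self)

    @property
    def key(self) -> str:
        """Cached canonical key (see :func:`canonical_key`)."""
        if self._key is None:
            self._key = canonical_key(self)
        return self._key


_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}

# Skip aromaticity perception and kekulization: the internal convention is
# Kekulé bond orders throughout, including in canonical keys.
_SANITIZE_OPS = (
    Chem.SanitizeFlags.SANITIZE_ALL
    ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
    ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
)


def _to_rdkit(g: MolecularGraph) -> Chem.Mol:
    rw = Chem.RWMol()
    for el, nh in zip(g.elements, g.hydrogens):
        atom = Chem.Atom(el)
        atom.SetNumExplicitHs(nh)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j, order in g.bonds():
        rw.AddBond(i, j, _BOND_TYPES[order])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, _SANITIZE_OPS)
    return mol


def _from_rdkit(mol: Chem.Mol, source: str = "rdkit") -> MolecularGraph:
    mol = Chem.Mol(mol)
    for atom in mol.GetAtoms():
        if atom.GetFormalCharge() != 0:
            raise UnsupportedFeatureError(
                f"charged atom {atom.GetSymbol()}{atom.GetFormalCharge():+d} "
                f"(index {atom.GetIdx()}) not supported"
            )
        if atom.GetNumRadicalElectrons() != 0:
            raise UnsupportedFeatureError("radical centres not supported")
        if atom.GetIsotope() != 0:
            raise UnsupportedFeatureError("isotope labels not supported")
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:  # pragma: no cover - rdkit guards
        raise MolfileError(f"cannot kekulize {source}: {exc}") from exc
    heavy = [a for a in mol.GetAtoms() if a.GetSymbol() != "H"]
    index = {a.GetIdx(): k for k, a in enumerate(heavy)}
    elements, hydrogens = [], []
    for a in heavy:
        el = a.GetSymbol()
        if el not in VALENCES:
            raise UnsupportedFeatureError(f"unsupported element {el!r}")
        nh = a.GetTotalNumHs(includeNeighbors=True)
        elements.append(el)
        hydrogens.append(nh)
    adj: Dict[int, Dict[int, int]] = {k: {} for k in range(len(heavy))}
    for b in mol.GetBonds():
        ia, ja = b.GetBeginAtom(), b.GetEndAtom()
        if ia.GetSymbol() == "H" or ja.GetSymbol() == "H":
            continue
        order = int(b.GetBondTypeAsDouble())
        if order not in (1, 2, 3):
            raise UnsupportedFeatureError(f"unsupported bond order {order}")
        i, j = index[ia.GetIdx()], index[ja.GetIdx()]
        adj[i][j] = order
        adj[j][i] = order
    g = MolecularGraph(elements, hydrogens, adj, provenance=source)
    g.validate()
    return g


# ---------------------------------------------------------------------------
# Canonicalization / isomorphism
# ---------------------------------------------------------------------------


def canonical_key(g: MolecularGraph) -> str:
    """Canonical SMILES of the Kekulé structure.

    Two graphs have equal keys iff they are isomorphic as element-labelled,
    bond-order-labelled graphs.  No aromaticity perception is applied, so
    the key is a pure function of the multigraph.
    """
    return Chem.MolToSmiles(_to_rdkit(g))


def is_same_constitution(g1: MolecularGraph, g2: MolecularGraph) -> bool:
    """Element- and bond-order-preserving graph isomorphism (VF2).

    Deliberately routed through networkx rather than the canonical key so
    the two notions of identity cross-check each other.
    """
    if sorted(g1.elements) != sorted(g2.elements) or sorted(g1.hydrogens) != sorted(
        g2.hydrogens
    ):
        return False
    return nx.is_isomorphic(
        g1.to_networkx(),
        g2.to_networkx(),
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )


def permute_graph(g: MolecularGraph, perm: Sequence[int]) -> MolecularGraph:
    """Relabel atoms: new atom ``perm[i]`` is old atom ``i`` (test utility)."""
    n = g.n_atoms
    elements = [""] * n
    hydrogens = [0] * n
    adj: Dict[int, Dict[int, int]] = {k: {} for k in range(n)}
    for i in range(n):
        elements[perm[i]] = g.elements[i]
        hydrogens[perm[i]] = g.hydrogens[i]
    for i, j, order in g.bonds():
        a, b = perm[i], perm[j]
        adj[a][b] = order
        adj[b][a] = order
    return MolecularGraph(elements, hydrogens, adj, provenance=g.provenance)


# ---------------------------------------------------------------------------
# Random structure generation
# ---------------------------------------------------------------------------


def _heavy_atom_list(formula: Dict[str, int]) -> List[str]:
    atoms: List[str] = []
    for el in sorted(formula):
        if el == "H":
            continue
        atoms.extend([el] * formula[el])
    return atoms


def random_structure(
    formula: Dict[str, int],
    rng: random.Random,
    max_tries: int = 1000,
) -> MolecularGraph:
    """Generate a random valid constitution for ``formula``.

    Builds a random spanning tree over the heavy atoms, then distributes
    the remaining bond-order units (new bonds or order increments) until
    the implicit hydrogen total matches the formula.  Retries on dead
    ends up to ``max_tries`` before raising :class:`GenerationError`.
    """
    elements = _heavy_atom_list(formula)
    n = len(elements)
    if n == 0:
        raise InfeasibleFormulaError("no heavy atoms")
    h_total = formula.get("H", 0)
    val_sum = sum(VALENCES[el] for el in elements)
    if (val_sum - h_total) % 2 != 0:
        raise InfeasibleFormulaError(f"odd total valence for H={h_total}")
    order_total = (val_sum - h_total) // 2
    if order_total < n - 1 or (n == 1 and order_total != 0):
        raise InfeasibleFormulaError(
            f"formula needs {order_total} bond-order units for {n} heavy atoms"
        )

    for _ in range(max_tries):
        g = _try_random_structure(elements, order_total, rng)
        if g is not None:
            g.validate(formula)
            return g
    raise GenerationError(
        f"no valid structure found for {format_formula(formula)} "
        f"after {max_tries} attempts"
    )


def _try_random_structure(
    elements: List[str], order_total: int, rng: random.Random
) -> Optional[MolecularGraph]:
    n = len(elements)
    order = list(range(n))
    rng.shuffle(order)
    cap = {i: VALENCES[elements[i]] for i in range(n)}
    adj: Dict[int, Dict[int, int]] = {i: {} for i in range(n)}

    placed = [order[0]]
    for k in range(1, n):
        i = order[k]
        hosts = [j for j in placed if cap[j] >= 1]
        if not hosts:
            return None
        j = rng.choice(hosts)
        adj[i][j] = adj[j][i] = 1
        cap[i] -= 1
        cap[j] -= 1
        placed.append(i)

    for _ in range(order_total - (n - 1)):
        donors = [i for i in range(n) if cap[i] >= 1]
        rng.shuffle(donors)
        placed_unit = False
        for i in donors:
            partners = [
                j
                for j in donors
                if j != i and cap[j] >= 1 and adj[i].get(j, 0) < 3
            ]
            if not partners:
                continue
            j = rng.choice(partners)
            adj[i][j] = adj[j][i] = adj[i].get(j, 0) + 1
            cap[i] -= 1
            cap[j] -= 1
            placed_unit = True
            break
        if not placed_unit:
            return None

    hydrogens = [cap[i] for i in range(n)]
    return MolecularGraph(elements, hydrogens, adj, provenance="random")


# ---------------------------------------------------------------------------
# Mutation (Faulon-style elementary moves)
# ---------------------------------------------------------------------------


def mutate(
    g: MolecularGraph,
    rng: random.Random,
    max_tries: int = 100,
) -> MolecularGraph:
    """One random Faulon-style elementary move on the constitution.

    Conceptually the operator acts on the hydrogen-explicit graph: pick
    two bonds (a,b) and (c,d) on four distinct atoms, decrement both and
    increment (a,c) and (b,d) (or the crossed variant) so every atom's
    total valence is untouched.  On the hydrogen-suppressed graph this
    yields two move types:

    * ``rewire``: both bonds heavy-heavy — transfers one bond-order unit
      between two heavy-atom pairs, preserving every heavy atom's
      bond-order sum;
    * ``hshift``: one chosen bond endpoint is a hydrogen — a heavy bond
      (a,b) loses one order unit, b gains an implicit H, and an H moves
      from some third atom c to create/strengthen bond (a,c).

    Element counts, total hydrogen and total bond order are always
    conserved.  Moves producing disconnected graphs, order > 3 or
    negative hydrogen counts are rejected and retried; after
    ``max_tries`` rejections the input graph is returned unchanged with
    a logged warning.
    """
    bonds = list(g.bonds())
    if not bonds:
        return g
    for _ in range(max_tries):
        if len(bonds) >= 2 and rng.random() < 0.5:
            out = _try_rewire(g, bonds, rng)
        else:
            out = _try_hshift(g, bonds, rng)
        if out is not None:
            return out
    logger.warning(
        "mutation found no applicable move after %d tries; returning input",
        max_tries,
    )
    return g


def _try_rewire(
    g: MolecularGraph, bonds: List[Tuple[int, int, int]], rng: random.Random
) -> Optional[MolecularGraph]:
    (a, b, _), (c, d, _) = rng.sample(bonds, 2)
    if len({a, b, c, d}) < 4:
        return None
    if rng.random() < 0.5:
        b, a = a, b
    if rng.random() < 0.5:
        pairs = ((a, c), (b, d))
    else:
        pairs = ((a, d), (b, c))
    out = g.copy(provenance="mutate:rewire")
    if not _dec_bond(out, a, b) or not _dec_bond(out, c, d):
        return None
    for i, j in pairs:
        if not _inc_bond(out, i, j):
            return None
    if not out.is_connected():
        return None
    out._key = None
    return out


def _try_hshift(
    g: MolecularGraph, bonds: List[Tuple[int, int, int]], rng: random.Random
) -> Optional[MolecularGraph]:
    a, b, _ = bonds[rng.randrange(len(bonds))]
    if rng.random() < 0.5:
        a, b = b, a
    candidates = [
        c for c in range(g.n_atoms) if c != a and c != b and g.hydrogens[c] >= 1
    ]
    if not candidates:
        return None
    c = rng.choice(candidates)
    out = g.copy(provenance="mutate:hshift")
    if not _dec_bond(out, a, b):
        return None
    out.hydrogens[b] += 1
    out.hydrogens[c] -= 1
    if not _inc_bond(out, a, c):
        return None
    if not out.is_connected():
        return None
    out._key = None
    return out


def _dec_bond(g: MolecularGraph, i: int, j: int) -> bool:
    order = g.adj[i].get(j, 0)
    if order < 1:
        return False
    if order == 1:
        del g.adj[i][j]
        del g.adj[j][i]
    else:
        g.adj[i][j] = g.adj[j][i] = order - 1
    return True


def _inc_bond(g: MolecularGraph, i: int, j: int) -> bool:
    if i == j:
        return False
    order = g.adj[i].get(j, 0)
    if order >= 3:
        return False
    g.adj[i][j] = g.adj[j][i] = order + 1
    return True


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def from_smiles(smiles: str) -> MolecularGraph:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MolfileError(f"cannot parse SMILES {smiles!r}")
    return _from_rdkit(mol, source=f"smiles:{smiles}")


def to_smiles(g: MolecularGraph) -> str:
    return canonical_key(g)


def read_molfile(path: str) -> MolecularGraph:
    """Read a V2000 molfile; explicit hydrogens are folded into implicit counts."""
    with open(path) as fh:
        text = fh.read()
    _check_counts_line(text, path)
    mol = Chem.MolFromMolBlock(text, removeHs=True)
    if mol is None:
        raise MolfileError(f"RDKit could not parse molfile {path!r}")
    return _from_rdkit(mol, source=path)


def _check_counts_line(text: str, path: str) -> None:
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileError(f"{path}: truncated molfile (line 4 missing)")
    counts = lines[3]
    try:
        int(counts[0:3])
        int(counts[3:6])
    except (ValueError, IndexError) as exc:
        raise MolfileError(f"{path}: malformed counts line (line 4)") from exc


def write_sdf(
    graphs: Iterable[MolecularGraph],
    path: str,
    properties: Optional[Sequence[Dict[str, object]]] = None,
) -> None:
    """Write graphs to an SDF file, one record per graph.

    ``properties[k]`` (if given) is attached to record *k* as SDF data
    fields; per-carbon shift assignments use ``Shift_atom{i}`` keys.
    """
    graphs = list(graphs)
    if properties is not None and len(properties) != len(graphs):
        raise ValueError("properties length must match number of graphs")
    writer = Chem.SDWriter(path)
    writer.SetKekulize(True)
    try:
        for k, g in enumerate(graphs):
            mol = _to_rdkit(g)
            if properties is not None:
                for key, value in properties[k].items():
                    mol.SetProp(str(key), str(value))
            writer.write(mol)
    finally:
        writer.close()


def read_sdf(path: str) -> List[Tuple[MolecularGraph, Dict[str, str]]]:
    """Read an SDF file; returns (graph, properties) per record."""
    supplier = Chem.SDMolSupplier(path, removeHs=True)
    out: List[Tuple[MolecularGraph, Dict[str, str]]] = []
    for k, mol in enumerate(supplier):
        if mol is None:
            raise MolfileError(f"{path}: unreadable SDF record {k}")
        props = {k2: mol.GetProp(k2) for k2 in mol.GetPropNames()}
        out.append((_from_rdkit(mol, source=f"{path}#{k}"), props))
    return out
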
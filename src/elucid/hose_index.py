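"""HOSE-style atom environments and backed-off 13C shift prediction.

A HOSE code (Hierarchical Organisation of Spherical Environments)
describes an atom's neighbourhood shell by shell out to a stated height.
A shift index maps each code seen in a reference set of assigned spectra
to the mean of its observed shifts and a Student-t 95% confidence limit;
prediction for a query carbon looks its codes up from height 4 down to 1
(longest-match backoff).

The canonical string grammar is this package's own (the historic format
is only loosely specified in the literature); it is documented in
docs/methods.md.  In brief: each node is written ``<bond><element>H<n>``
with bond symbols ``-``/``=``/``#``, children are parenthesised,
comma-separated and ordered by (bond order descending, element priority
C>O>N>S>P>halogens, recursive string).  The code is a pure function of
the rooted h-sphere neighbourhood, independent of atom numbering.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from scipy import stats

from .chem_graph import ELEMENT_PRIORITY, MolecularGraph

logger = logging.getLogger(__name__)

__all__ = [
    "CL_FLOOR_PPM",
    "IndexError_",
    "UnassignedShiftError",
    "hose_code",
    "ShiftIndexEntry",
    "ShiftIndex",
    "PredictedShift",
    "build_index",
    "predict_shift",
]

#: Minimum confidence limit assigned to any index entry, in ppm.
CL_FLOOR_PPM = 5.0

_BOND_SYMBOL = {1: "-", 2: "=", 3: "#"}


class IndexError_(ValueError):
    """Invalid shift-index construction or lookup arguments."""


class UnassignedShiftError(ValueError):
    """A reference molecule carbon is missing its shift assignment."""


# ---------------------------------------------------------------------------
# Environment encoding
# ---------------------------------------------------------------------------


def hose_code(g: MolecularGraph, atom: int, height: int) -> str:
    """Canonical spherical-environment code of ``atom`` up to ``height``.

    Deterministic under graph relabelling: branches are ordered by a
    canonical priority key, so the code depends only on the rooted
    neighbourhood, not on atom indices.
    """
    if not 1 <= height <= 4:
        raise IndexError_(f"height must be in 1..4, got {height}")
    if not 0 <= atom < g.n_atoms:
        raise IndexError_(f"atom index {atom} out of range")
    return _encode(g, atom, height)


def atom_environment(g: MolecularGraph, atom: int, height: int) -> str:
    """Same encoder without the HOSE height restriction (height >= 0)."""
    if height < 0:
        raise IndexError_("height must be non-negative")
    return _encode(g, atom, height)


def _encode(g: MolecularGraph, root: int, height: int) -> str:
    # the root token carries the attached-hydrogen count; deeper nodes
    # are element-only, their hydrogens being implied by the unencoded
    # remainder of their valence (coarse low heights back off gracefully)
    tok = f"{g.elements[root]}H{g.hydrogens[root]}"
    if height == 0:
        return tok
    children = _branches(g, root, root, height)
    return tok + "(" + ",".join(s for _, s in children) + ")" if children else tok


def _branches(
    g: MolecularGraph, node: int, parent: int, depth: int
) -> List[Tuple[tuple, str]]:
    out = []
    for nbr, order in g.neighbors(node).items():
        if nbr == parent:
            continue
        out.append(_branch(g, nbr, node, order, depth - 1))
    out.sort(key=lambda t: t[0])
    return out


def _branch(
    g: MolecularGraph, node: int, parent: int, order: int, depth: int
) -> Tuple[tuple, str]:
    tok = _BOND_SYMBOL[order] + g.elements[node]
    if depth > 0:
        children = _branches(g, node, parent, depth)
        if children:
            tok = tok + "(" + ",".join(s for _, s in children) + ")"
    key = (-order, ELEMENT_PRIORITY[g.elements[node]], tok)
    return key, tok


# ---------------------------------------------------------------------------
# Index construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShiftIndexEntry:
    """Aggregated observations for one (height, code) environment."""

    count: int
    mean: float
    sd: float
    cl: float


@dataclass(frozen=True)
class PredictedShift:
    """Back-calculated shift for one carbon, or a fallback marker."""

    delta: Optional[float]
    cl: Optional[float]
    height: Optional[int]
    fallback: bool = False


@dataclass
class ShiftIndex:
    """Per-height lookup tables HoseCode -> ShiftIndexEntry."""

    tables: Dict[int, Dict[str, ShiftIndexEntry]]
    max_height: int = 4
    source_size: int = 0
    confidence: float = 0.95
    version: str = "1"

    def entry(self, height: int, code: str) -> Optional[ShiftIndexEntry]:
        return self.tables.get(height, {}).get(code)

    def n_entries(self) -> int:
        return sum(len(t) for t in self.tables.values())

    def truncated(self, max_height: int) -> "ShiftIndex":
        """Copy of the index restricted to heights <= ``max_height``."""
        return ShiftIndex(
            {h: dict(t) for h, t in self.tables.items() if h <= max_height},
            max_height=max_height,
            source_size=self.source_size,
            confidence=self.confidence,
        )

    # -- serialization: sorted, versioned TSV for bit-exact reload ---------

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#shift-index\tversion={self.version}\n")
            fh.write(
                f"#max_height={self.max_height}\tsource_size={self.source_size}"
                f"\tconfidence={self.confidence!r}\n"
            )
            fh.write("height\tcode\tcount\tmean\tsd\tcl\n")
            for h in sorted(self.tables):
                for code in sorted(self.tables[h]):
                    e = self.tables[h][code]
                    fh.write(
                        f"{h}\t{code}\t{e.count}\t{e.mean!r}\t{e.sd!r}\t{e.cl!r}\n"
                    )

    @classmethod
    def load(cls, path: str) -> "ShiftIndex":
        tables: Dict[int, Dict[str, ShiftIndexEntry]] = {}
        max_height, source_size, confidence = 4, 0, 0.95
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#max_height="):
                    fields = dict(p.split("=", 1) for p in line[1:].split("\t"))
                    max_height = int(fields["max_height"])
                    source_size = int(fields["source_size"])
                    confidence = float(fields["confidence"])
                    continue
                if line.startswith("#") or line.startswith("height\t") or not line:
                    continue
                h, code, count, mean, sd, cl = line.split("\t")
                tables.setdefault(int(h), {})[code] = ShiftIndexEntry(
                    int(count), float(mean), float(sd), float(cl)
                )
        return cls(tables, max_height=max_height, source_size=source_size,
                   confidence=confidence)


def confidence_limit(
    shifts: Sequence[float], confidence: float = 0.95
) -> float:
    """Student-t confidence half-width with the 5 ppm floor.

    CL = max(floor, (sd / sqrt(n)) * t_{(1+confidence)/2, n-1}) for n >= 2.
    A single observation has no defined standard error, so singleton
    entries take the floor directly.
    """
    n = len(shifts)
    if n < 2:
        return CL_FLOOR_PPM
    sd = statistics.stdev(shifts)
    se = sd / math.sqrt(n)
    t = float(stats.t.ppf((1.0 + confidence) / 2.0, n - 1))
    return max(CL_FLOOR_PPM, se * t)


def build_index(
    reference: Iterable[Tuple[MolecularGraph, Dict[int, float]]],
    max_height: int = 4,
    confidence: float = 0.95,
    strict: bool = False,
) -> ShiftIndex:
    """Build a shift index from (molecule, {carbon index: shift ppm}) pairs.

    Every carbon of every reference molecule contributes one observation
    per height 1..``max_height``.  Molecules with unassigned carbons are
    skipped with a warning (or rejected when ``strict``).
    """
    observations: Dict[int, Dict[str, List[float]]] = {
        h: {} for h in range(1, max_height + 1)
    }
    n_molecules = 0
    for g, shifts in reference:
        carbons = g.carbons()
        missing = [i for i in carbons if i not in shifts]
        if missing:
            msg = f"reference molecule missing shifts for carbons {missing}"
            if strict:
                raise UnassignedShiftError(msg)
            logger.warning("%s; molecule skipped", msg)
            continue
        n_molecules += 1
        for i in carbons:
            for h in range(1, max_height + 1):
                code = hose_code(g, i, h)
                observations[h].setdefault(code, []).append(shifts[i])
    tables: Dict[int, Dict[str, ShiftIndexEntry]] = {}
    for h, by_code in observations.items():
        table: Dict[str, ShiftIndexEntry] = {}
        for code, vals in by_code.items():
            n = len(vals)
            mean = sum(vals) / n
            sd = statistics.stdev(vals) if n >= 2 else 0.0
            table[code] = ShiftIndexEntry(n, mean, sd, confidence_limit(vals, confidence))
        tables[h] = table
    return ShiftIndex(
        tables, max_height=max_height, source_size=n_molecules, confidence=confidence
    )


def predict_shift(index: ShiftIndex, g: MolecularGraph, atom: int) -> PredictedShift:
    """Backed-off lookup: try height 4, then 3, 2, 1; fallback if none match."""
    if g.elements[atom] != "C":
        raise IndexError_(f"atom {atom} is {g.elements[atom]}, not carbon")
    for h in range(index.max_height, 0, -1):
        table = index.tables.get(h)
        if not table:
            continue
        entry = table.get(hose_code(g, atom, h))
        if entry is not None:
            return PredictedShift(entry.mean, entry.cl, h)
    return PredictedShift(None, None, None, fallback=True)
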
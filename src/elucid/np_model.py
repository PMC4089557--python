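"""Fragment-based natural-product-likeness scoring.

Molecules are decomposed into atom-rooted signatures (spherical
environments of height 3 by default).  A model trained on a
natural-product corpus versus a synthetic corpus assigns each signature
the log-odds of its smoothed relative frequency in the two corpora; a
molecule's raw score is the mean contribution over its heavy atoms, so
fragment-rich large molecules are not favoured merely by size.  Higher
scores mean more natural-product-like.  The model also records the
extreme raw scores over its training molecules, which downstream
normalization maps to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

from .chem_graph import MolecularGraph
from .hose_index import atom_environment

__all__ = [
    "TrainingError",
    "DegenerateModelError",
    "atom_signature",
    "FragmentModel",
    "train_fragment_model",
    "np_raw_score",
]


class TrainingError(ValueError):
    """Invalid training input (e.g. an empty corpus)."""


class DegenerateModelError(ValueError):
    """Trained model cannot normalize scores (min == max)."""


def atom_signature(g: MolecularGraph, atom: int, height: int = 3) -> str:
    """Canonical atom-rooted subgraph signature of the given height.

    ``height=0`` degenerates to the element-plus-hydrogen token.
    Symmetric atoms yield equal signatures; the string is independent of
    atom numbering.
    """
    return atom_environment(g, atom, height)


def molecule_signatures(g: MolecularGraph, height: int = 3) -> List[str]:
    return [atom_signature(g, i, height) for i in range(g.n_atoms)]


@dataclass
class FragmentModel:
    """Signature -> log-odds contributions plus training-score extremes."""

    contributions: Dict[str, float]
    min_score: float
    max_score: float
    height: int = 3
    n_np: int = 0
    n_synthetic: int = 0
    version: str = "1"

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#np-fragment-model\tversion={self.version}\n")
            fh.write(
                f"#height={self.height}\tmin={self.min_score!r}"
                f"\tmax={self.max_score!r}\tn_np={self.n_np}"
                f"\tn_synthetic={self.n_synthetic}\n"
            )
            fh.write("signature\tcontribution\n")
            for sig in sorted(self.contributions):
                fh.write(f"{sig}\t{self.contributions[sig]!r}\n")

    @classmethod
    def load(cls, path: str) -> "FragmentModel":
        contributions: Dict[str, float] = {}
        height, mn, mx, n_np, n_syn = 3, 0.0, 0.0, 0, 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#height="):
                    fields = dict(p.split("=", 1) for p in line[1:].split("\t"))
                    height = int(fields["height"])
                    mn = float(fields["min"])
                    mx = float(fields["max"])
                    n_np = int(fields["n_np"])
                    n_syn = int(fields["n_synthetic"])
                    continue
                if line.startswith("#") or line.startswith("signature\t") or not line:
                    continue
                sig, contribution = line.split("\t")
                contributions[sig] = float(contribution)
        return cls(contributions, mn, mx, height=height, n_np=n_np,
                   n_synthetic=n_syn)


def train_fragment_model(
    np_set: Sequence[MolecularGraph],
    synthetic_set: Sequence[MolecularGraph],
    height: int = 3,
    smoothing: float = 1.0,
) -> FragmentModel:
    """Train signature log-odds from the two corpora.

    contribution(s) = ln( p_np(s) / p_syn(s) ) with Laplace-smoothed
    relative frequencies p(s) = (count(s) + smoothing) / (total +
    smoothing * vocabulary), the vocabulary being the union of
    signatures seen in either corpus.  Records min/max raw molecule
    scores over the union of training molecules.
    """
    np_set = list(np_set)
    synthetic_set = list(synthetic_set)
    if not np_set or not synthetic_set:
        raise TrainingError("both training corpora must be non-empty")
    np_counts = _count_signatures(np_set, height)
    syn_counts = _count_signatures(synthetic_set, height)
    vocab = sorted(set(np_counts) | set(syn_counts))
    v = len(vocab)
    np_total = sum(np_counts.values())
    syn_total = sum(syn_counts.values())
    contributions = {
        sig: math.log(
            ((np_counts.get(sig, 0) + smoothing) / (np_total + smoothing * v))
            / ((syn_counts.get(sig, 0) + smoothing) / (syn_total + smoothing * v))
        )
        for sig in vocab
    }
    model = FragmentModel(
        contributions, 0.0, 0.0, height=height,
        n_np=len(np_set), n_synthetic=len(synthetic_set),
    )
    scores = [np_raw_score(model, g) for g in np_set + synthetic_set]
    model.min_score = min(scores)
    model.max_score = max(scores)
    if model.min_score == model.max_score:
        raise DegenerateModelError(
            "training molecules all score identically; cannot normalize"
        )
    return model


def _count_signatures(
    molecules: Iterable[MolecularGraph], height: int
) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for g in molecules:
        for sig in molecule_signatures(g, height):
            counts[sig] = counts.get(sig, 0) + 1
    return counts


def np_raw_score(model: FragmentModel, g: MolecularGraph) -> float:
    """Mean signature contribution per heavy atom; unseen signatures are 0."""
    g.validate()
    total = sum(
        model.contributions.get(sig, 0.0)
        for sig in molecule_signatures(g, model.height)
    )
    return total / g.n_atoms
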
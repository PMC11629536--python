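"""Distribution-learning and property metrics for generated molecule sets.

Conventions follow the standard generative-chemistry benchmark suite:
internal diversity is 1 minus the mean pairwise Tanimoto (first power,
ordered pairs i != j); SNN is the mean nearest-neighbour similarity of each
generated molecule to a reference set; Frag is the cosine similarity of
BRICS fragment count profiles; novelty and uniqueness are set fractions.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from rdkit.Chem import BRICS, QED

from .chemio import Molecule, _mol_from_smiles, fingerprint_matrix, tanimoto_matrix
from .oracles_experts import _sa_scorer


def internal_diversity(molecules: Sequence[Molecule]) -> float:
    """1 - mean pairwise presence-bit Tanimoto over ordered pairs i != j."""
    if len(molecules) < 2:
        return 0.0
    fps = fingerprint_matrix(molecules)
    sim = tanimoto_matrix(fps, fps)
    n = len(molecules)
    off_diag_mean = (sim.sum() - np.trace(sim)) / (n * (n - 1))
    return float(1.0 - off_diag_mean)


def snn(generated: Sequence[Molecule], reference: Sequence[Molecule]) -> float:
    """Mean similarity of each generated molecule to its nearest reference."""
    sim = tanimoto_matrix(fingerprint_matrix(generated), fingerprint_matrix(reference))
    return float(sim.max(axis=1).mean())


def _fragment_counts(molecules: Sequence[Molecule]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for m in molecules:
        for frag in BRICS.BRICSDecompose(_mol_from_smiles(m.smiles)):
            counts[frag] = counts.get(frag, 0) + 1
    return counts


def fragment_similarity(
    generated: Sequence[Molecule], reference: Sequence[Molecule]
) -> float:
    """Cosine similarity between BRICS fragment count profiles."""
    a = _fragment_counts(generated)
    b = _fragment_counts(reference)
    keys = sorted(set(a) | set(b))
    va = np.array([a.get(k, 0) for k in keys], dtype=float)
    vb = np.array([b.get(k, 0) for k in keys], dtype=float)
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    return float(va @ vb / denom) if denom > 0 else 0.0


def novelty(generated: Sequence[Molecule], train: Sequence[Molecule]) -> float:
    """Fraction of generated canonical SMILES absent from the training set."""
    train_smiles = {m.smiles for m in train}
    return float(np.mean([m.smiles not in train_smiles for m in generated]))


def uniqueness(generated: Sequence[Molecule]) -> float:
    """Fraction of distinct canonical SMILES among the generated set."""
    return len({m.smiles for m in generated}) / len(generated)


def mean_sa(molecules: Sequence[Molecule]) -> float:
    scorer = _sa_scorer()
    return float(
        np.mean([scorer.calculateScore(_mol_from_smiles(m.smiles)) for m in molecules])
    )


def mean_qed(molecules: Sequence[Molecule]) -> float:
    return float(np.mean([QED.qed(_mol_from_smiles(m.smiles)) for m in molecules]))
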
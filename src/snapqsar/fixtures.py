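"""Deterministic toy molecules and a separable synthetic benchmark.

The real screening data behind this pipeline is an external download; to keep
every stage testable offline, this module generates idealized molecules with
standard bond lengths and a labeled synthetic dataset whose class signal is a
geometric property — active molecules are long carbon chains (or rings),
inactive ones short chains — so that both the rendered snapshot images and
molecular descriptors carry the signal. Activity scores are assigned 100 for
active and 0 for inactive, so the standard score binarization at 40
reproduces the intended labels; label noise flips scores at a configurable
rate. Everything is reproducible under a seed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .chemio import Molecule
from .evalx import ConfusionMatrix, MetricsReport, metrics
from .splits import LabeledDataset

__all__ = [
    "SyntheticSpec",
    "make_toy_molecule",
    "make_synthetic_dataset",
    "worked_confusion_example",
]

_CC = 1.54  # sp3 C-C bond length, Angstrom
_CH = 1.09
_CC_AROM = 1.39
_TETRA = math.degrees(math.acos(-1.0 / 3.0))  # 109.47


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for the synthetic labeled dataset.

    n_per_class molecules per label; ``signal`` chooses the geometric rule
    ("chain_length": active chains are ``signal_strength`` atoms longer than
    inactive ones; "ring_vs_chain": actives are rings). ``noise_rate`` is the
    probability a molecule's activity score (hence label) is flipped.
    """

    n_per_class: int = 30
    signal: str = "chain_length"
    signal_strength: int = 6
    noise_rate: float = 0.0
    base_chain: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal not in ("chain_length", "ring_vs_chain"):
            raise ValueError(f"unknown signal {self.signal!r}")
        if not (0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must be in [0, 0.5)")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


def make_toy_molecule(kind: str) -> Molecule:
    """Idealized molecule: 'methane', 'benzene', 'chain(k)' or 'tetrahedron'."""
    if kind == "methane":
        return _methane()
    if kind == "benzene":
        return _benzene()
    if kind == "tetrahedron":
        return _tetrahedron()
    m = re.fullmatch(r"chain\((\d+)\)", kind)
    if m:
        k = int(m.group(1))
        if k < 2:
            raise ValueError("chain length must be >= 2")
        return _chain(k)
    raise ValueError(f"unknown toy molecule kind {kind!r}")


def _methane() -> Molecule:
    # C at origin, H at alternating cube corners
    d = _CH / math.sqrt(3.0)
    atoms = [("C", 0.0, 0.0, 0.0)]
    for sx, sy, sz in [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]:
        atoms.append(("H", sx * d, sy * d, sz * d))
    bonds = [(0, i, 1) for i in range(1, 5)]
    return Molecule(id="methane", atoms=atoms, bonds=bonds)


def _benzene() -> Molecule:
    atoms = []
    bonds = []
    r_c = _CC_AROM
    r_h = _CC_AROM + _CH
    for i in range(6):
        a = math.radians(60 * i)
        atoms.append(("C", r_c * math.cos(a), r_c * math.sin(a), 0.0))
    for i in range(6):
        a = math.radians(60 * i)
        atoms.append(("H", r_h * math.cos(a), r_h * math.sin(a), 0.0))
        bonds.append((i, 6 + i, 1))
    for i in range(6):
        bonds.append((i, (i + 1) % 6, 12))
    return Molecule(id="benzene", atoms=atoms, bonds=bonds)


def _tetrahedron() -> Molecule:
    # four carbons at regular tetrahedron vertices, all pairs bonded:
    # a purely geometric probe object for the renderer
    e = _CC / math.sqrt(2.0)
    verts = [(e, e, e), (e, -e, -e), (-e, e, -e), (-e, -e, e)]
    atoms = [("C", *v) for v in verts]
    bonds = [(i, j, 1) for i in range(4) for j in range(i + 1, 4)]
    return Molecule(id="tetrahedron", atoms=atoms, bonds=bonds)


def _chain(k: int, mol_id: str | None = None) -> Molecule:
    """All-carbon zigzag chain with ideal sp3 geometry (heavy atoms only)."""
    half = math.radians(_TETRA / 2.0)
    dx = _CC * math.sin(half)
    dy = _CC * math.cos(half)
    atoms = [("C", i * dx, (i % 2) * dy, 0.0) for i in range(k)]
    bonds = [(i, i + 1, 1) for i in range(k - 1)]
    return Molecule(id=mol_id or f"chain{k}", atoms=atoms, bonds=bonds)


def _ring(k: int, mol_id: str) -> Molecule:
    r = _CC / (2.0 * math.sin(math.pi / k))
    atoms = [
        ("C", r * math.cos(2 * math.pi * i / k), r * math.sin(2 * math.pi * i / k), 0.0)
        for i in range(k)
    ]
    bonds = [(i, (i + 1) % k, 1) for i in range(k)]
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds)


def make_synthetic_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, list[Molecule]]:
    """Generate the separable benchmark: molecules plus scored labels.

    Inactive molecules are chains of ``base_chain`` +/- 1 atoms; active ones
    are ``signal_strength`` atoms longer (or rings of that size for the
    "ring_vs_chain" signal). A small seeded 3D jitter (0.06 A per coordinate)
    individualizes conformers without blurring the class signal. Scores are
    0/100 before noise; noise flips a molecule's score with probability
    ``noise_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    mols: list[Molecule] = []
    ids: list[str] = []
    scores: list[int] = []
    for cls, prefix in ((0, "inact"), (1, "act")):
        for i in range(spec.n_per_class):
            size = spec.base_chain + int(rng.integers(0, 2))
            mol_id = f"{prefix}{i:04d}"
            if cls == 1:
                size += spec.signal_strength
                if spec.signal == "ring_vs_chain":
                    mol = _ring(size, mol_id)
                else:
                    mol = _chain(size, mol_id)
            else:
                mol = _chain(size, mol_id)
            mol.id = mol_id
            jitter = rng.normal(0.0, 0.06, size=(mol.n_atoms, 3))
            mol.atoms = [
                (s, x + jitter[k, 0], y + jitter[k, 1], z + jitter[k, 2])
                for k, (s, x, y, z) in enumerate(mol.atoms)
            ]
            score = 100 * cls
            if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
                score = 100 - score
            mol.activity_score = score
            mol.provenance = {"synthetic": True, "true_class": cls}
            mols.append(mol)
            ids.append(mol_id)
            scores.append(score)
    return LabeledDataset(ids=ids, scores=scores), mols


def worked_confusion_example() -> tuple[list[float], list[int], ConfusionMatrix, MetricsReport]:
    """Fixed TP=3 / FN=1 / TN=4 / FP=2 case with its hand-computed metrics.

    Ten molecule-level predictions at cutoff 0.5 reproduce the counts; the
    returned report carries sensitivity 0.75, specificity 2/3, BAC 0.7083,
    accuracy 0.7, precision 0.6, F 2/3 and MCC 0.4082 (4 d.p.).
    """
    preds = [0.9, 0.8, 0.7, 0.2, 0.1, 0.15, 0.3, 0.25, 0.6, 0.55]
    labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    cm = ConfusionMatrix(tp=3, fn=1, tn=4, fp=2)
    return preds, labels, cm, metrics(cm, cutoff=0.5)
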
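"""Activity labeling and the N = Rt + Rv + 1 group-split design.

qHTS activity scores (0-100) are binarized at 40: scores 40-100 are active,
0-39 inactive. For cross-validation the molecule list is partitioned into
N = Rt + Rv + 1 near-equal groups; each fold designates one group as the
test set and splits the remaining N - 1 groups Rt : Rv into training and
validation. Rotating the test group over folds yields up to N folds
(10 are used by default, matching the published design). Permutation
controls shuffle the labels while preserving class counts.

Splitting is always by molecule: every snapshot image of a molecule inherits
that molecule's group, so there is no image-level leakage across the
train/validation/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVE_THRESHOLD",
    "LabeledDataset",
    "SplitPlan",
    "percent_activity",
    "label_activity",
    "make_split_plan",
    "fold_assignment",
    "permute_labels",
    "experiment_grid",
    "write_manifest",
    "read_manifest",
]

#: Scores >= this are "active".
ACTIVE_THRESHOLD = 40


def percent_activity(v_compound: float, v_dmso: float, v_pos: float) -> float:
    """Concentration-response % Activity = (Vc - Vdmso) / (Vpos - Vdmso) * 100.

    Vdmso and Vpos are the DMSO-only and positive-control medians. The result
    may fall outside [0, 100] for compounds outside the control range.
    """
    denom = v_pos - v_dmso
    if denom == 0:
        raise ZeroDivisionError("positive control equals DMSO control")
    return (v_compound - v_dmso) / denom * 100.0


def label_activity(score: int) -> str:
    """Binarize a 0-100 activity score: active iff score >= 40."""
    if not (0 <= score <= 100):
        raise ValueError(f"activity score {score} outside [0, 100]")
    return "active" if score >= ACTIVE_THRESHOLD else "inactive"


@dataclass
class LabeledDataset:
    """Molecule ids with activity scores and derived binary labels."""

    ids: list[str]
    scores: list[int]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores length mismatch")
        if not self.labels:
            self.labels = [label_activity(s) for s in self.scores]
        if len(self.labels) != len(self.ids):
            raise ValueError("labels length mismatch")

    @property
    def n_active(self) -> int:
        return sum(1 for l in self.labels if l == "active")

    @property
    def n_inactive(self) -> int:
        return len(self.labels) - self.n_active

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class SplitPlan:
    """Assignment of molecules to N = Rt + Rv + 1 groups."""

    rt: int
    rv: int
    assignment: dict[str, int]
    seed: int
    permuted: bool = False

    @property
    def n_groups(self) -> int:
        return self.rt + self.rv + 1

    @property
    def n_folds(self) -> int:
        # published design caps at 10 folds even when N = 11
        return min(10, self.n_groups)

    def group_ids(self, group: int) -> list[str]:
        return [i for i, g in self.assignment.items() if g == group]

    def validate(self) -> None:
        groups = np.array(list(self.assignment.values()))
        if set(np.unique(groups)) != set(range(self.n_groups)):
            raise ValueError("assignment does not cover all groups")
        sizes = np.bincount(groups, minlength=self.n_groups)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("group sizes differ by more than 1")


def make_split_plan(
    ids: Sequence[str],
    rt: int,
    rv: int,
    seed: int,
    labels: Sequence[str] | None = None,
    permuted: bool = False,
) -> SplitPlan:
    """Randomly partition molecules into N = rt + rv + 1 near-equal groups.

    Ids are sorted before the seeded shuffle so the plan is invariant to
    input order. When ``labels`` is given the shuffle-and-deal is done
    within each class (stratification), keeping the class ratio similar in
    every group — the safer default for heavily imbalanced activity data;
    pass ``labels=None`` to switch stratification off.
    """
    if rt < 1 or rv < 1:
        raise ValueError("rt and rv must be >= 1")
    n_groups = rt + rv + 1
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate molecule ids")
    if len(ids) < n_groups:
        raise ValueError(f"need at least {n_groups} molecules, got {len(ids)}")
    rng = np.random.default_rng(seed)

    assignment: dict[str, int] = {}
    if labels is None:
        strata = [sorted(ids)]
    else:
        by_label: dict[str, list[str]] = {}
        for i, l in zip(ids, labels):
            by_label.setdefault(l, []).append(i)
        strata = [sorted(by_label[k]) for k in sorted(by_label)]

    # round-robin deal, continuing the group counter across strata so the
    # overall group sizes stay within 1 of each other
    order = np.concatenate(
        [rng.permutation(len(s)) + sum(len(x) for x in strata[:k]) for k, s in enumerate(strata)]
    ) if strata else np.array([], dtype=int)
    flat = [i for s in strata for i in s]
    pos = 0
    for k in order:
        assignment[flat[int(k)]] = pos % n_groups
        pos += 1

    plan = SplitPlan(rt=rt, rv=rv, assignment=assignment, seed=seed, permuted=permuted)
    plan.validate()
    return plan


def fold_assignment(plan: SplitPlan, fold: int) -> tuple[list[int], list[int], int]:
    """Group indices of (training, validation, test) for one fold.

    The test group is ``fold mod N``; the remaining N - 1 groups, taken in
    cyclic order starting just after the test group, are split Rt : Rv into
    training and validation. The three parts partition all N groups, and
    test groups across folds are pairwise distinct.
    """
    n = plan.n_groups
    if not (0 <= fold < plan.n_folds):
        raise ValueError(f"fold {fold} out of range [0, {plan.n_folds})")
    test = fold % n
    rest = [(test + k) % n for k in range(1, n)]
    return rest[: plan.rt], rest[plan.rt : plan.rt + plan.rv], test


def permute_labels(labels: Sequence, seed: int) -> list:
    """Uniform random permutation of labels; the multiset is preserved."""
    if len(labels) == 0:
        raise ValueError("empty label list")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(labels))
    labels = list(labels)
    return [labels[i] for i in idx]


def experiment_grid(
    angles: Sequence[float], ratios: Sequence[tuple[int, int]]
) -> list[tuple[float, tuple[int, int]]]:
    """Cartesian product of rendering angles and (Rt, Rv) ratios, row-major."""
    if not angles or not ratios:
        raise ValueError("angles and ratios must be non-empty")
    return [(a, tuple(r)) for a in angles for r in ratios]


# ---------------------------------------------------------------------------
# split manifests
# ---------------------------------------------------------------------------

def write_manifest(
    plan: SplitPlan, dataset: LabeledDataset, path: str | Path
) -> Path:
    """CSV manifest: id, score, label, group, and per-fold role columns."""
    path = Path(path)
    rows = []
    score = dict(zip(dataset.ids, dataset.scores))
    label = dict(zip(dataset.ids, dataset.labels))
    fold_roles = {}
    for fold in range(plan.n_folds):
        tra, val, test = fold_assignment(plan, fold)
        roles = {}
        for g in tra:
            roles[g] = "tra"
        for g in val:
            roles[g] = "val"
        roles[test] = "test"
        fold_roles[fold] = roles
    for mol_id in sorted(plan.assignment):
        g = plan.assignment[mol_id]
        row = {
            "id": mol_id,
            "score": score.get(mol_id, ""),
            "label": label.get(mol_id, ""),
            "group": g,
        }
        for fold in range(plan.n_folds):
            row[f"fold{fold}"] = fold_roles[fold][g]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str})
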
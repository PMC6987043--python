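"""End-to-end orchestration: molecules -> snapshots -> splits -> training -> metrics.

Glue for the full image-classification workflow. Each molecule is rendered
once into its rotation-grid snapshot set; a group-split plan assigns
molecules (and therefore all of their images) to training / validation /
test; per fold an image classifier is trained, per-image probabilities on
the test group are aggregated to per-molecule medians, and the shared metric
suite scores the fold. The same plan object drives the descriptor baseline,
so the two routes see identical folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemio import Molecule
from .evalx import (
    MetricsReport,
    aggregate_median,
    confusion_at_cutoff,
    metrics,
    optimal_cutoff,
    roc_auc,
)
from .snapshot import RenderConfig, encode_png, snap_molecule, snapshot_filename
from .splits import LabeledDataset, SplitPlan, fold_assignment, make_split_plan, permute_labels
from .trainer import TrainConfig, TrainRun, featurize_images, predict_images, train_classifier

__all__ = ["CVResult", "render_dataset", "write_split_images", "run_image_cv"]


@dataclass
class CVResult:
    """Cross-validation outcome of the image pipeline."""

    plan: SplitPlan
    fold_reports: list[MetricsReport]
    predictions: pd.DataFrame  # columns: id, prob, label, fold
    runs: list[TrainRun] = field(default_factory=list)

    @property
    def pooled_auc(self) -> float:
        """AUC over all test-fold molecule-level predictions pooled."""
        return roc_auc(self.predictions["prob"], self.predictions["label"])

    @property
    def mean_auc(self) -> float:
        aucs = [r.auc for r in self.fold_reports if r.auc is not None]
        return float(np.mean(aucs)) if aucs else float("nan")


def render_dataset(
    mols: list[Molecule], config: RenderConfig | None = None
) -> dict[str, list[np.ndarray]]:
    """Render every molecule's full snapshot set in memory."""
    config = config or RenderConfig()
    return {
        m.id: [e["image"] for e in snap_molecule(m, config).entries] for m in mols
    }


def write_split_images(
    mols: list[Molecule],
    dataset: LabeledDataset,
    plan: SplitPlan,
    fold: int,
    config: RenderConfig | None = None,
    out_dir: str | Path = "images",
) -> Path:
    """Write the fold's image-folder layout ``<out>/<split>/<label>/<file>.png``.

    All images of a molecule land in the split its molecule was assigned to,
    never across splits.
    """
    config = config or RenderConfig()
    out_dir = Path(out_dir)
    tra_g, val_g, test_g = fold_assignment(plan, fold)
    role = {}
    for g in tra_g:
        role[g] = "tra"
    for g in val_g:
        role[g] = "val"
    role[test_g] = "test"
    label = dict(zip(dataset.ids, dataset.labels))
    for m in mols:
        split = role[plan.assignment[m.id]]
        dest = out_dir / split / label[m.id]
        dest.mkdir(parents=True, exist_ok=True)
        for entry in snap_molecule(m, config).entries:
            path = dest / snapshot_filename(m.id, entry["rotation"])
            path.write_bytes(encode_png(entry["image"]))
    return out_dir


def run_image_cv(
    dataset: LabeledDataset,
    mols: list[Molecule],
    rt: int = 1,
    rv: int = 1,
    seed: int = 0,
    n_folds: int | None = None,
    permuted: bool = False,
    render_config: RenderConfig | None = None,
    train_config: TrainConfig | None = None,
) -> CVResult:
    """Cross-validate the snapshot classifier on a labeled molecule set.

    With ``permuted=True`` the activity labels are shuffled across molecules
    before splitting and training — the no-signal control under which the
    molecule-level AUC should collapse to ~0.5.
    """
    render_config = render_config or RenderConfig()
    train_config = train_config or TrainConfig()
    labels = list(dataset.labels)
    if permuted:
        labels = permute_labels(labels, seed)
    y = {i: (1 if l == "active" else 0) for i, l in zip(dataset.ids, labels)}

    plan = make_split_plan(
        dataset.ids, rt, rv, seed=seed, labels=labels, permuted=permuted
    )
    images = render_dataset(mols, render_config)
    feats = {
        mol_id: featurize_images(imgs, train_config)
        for mol_id, imgs in images.items()
    }

    folds = plan.n_folds if n_folds is None else min(n_folds, plan.n_folds)
    reports: list[MetricsReport] = []
    runs: list[TrainRun] = []
    pred_rows: list[dict] = []
    for fold in range(folds):
        tra_g, val_g, test_g = fold_assignment(plan, fold)
        ids_of = lambda gs: [i for i, g in plan.assignment.items() if g in gs]
        tra_ids, val_ids = ids_of(set(tra_g)), ids_of(set(val_g))
        test_ids = ids_of({test_g})
        X_tr, y_tr = _stack(feats, y, tra_ids)
        X_va, y_va = _stack(feats, y, val_ids)
        run, artifact = train_classifier(
            (X_tr, y_tr), (X_va, y_va), train_config, seed=seed + fold
        )
        runs.append(run)

        val_preds = [aggregate_median(predict_images(artifact, images[i]), i) for i in val_ids]
        val_labels = [y[i] for i in val_ids]
        cutoff = (
            optimal_cutoff(val_preds, val_labels)
            if len(set(val_labels)) == 2
            else 0.5
        )
        test_preds = [aggregate_median(predict_images(artifact, images[i]), i) for i in test_ids]
        test_labels = [y[i] for i in test_ids]
        rep = metrics(confusion_at_cutoff(test_preds, test_labels, cutoff), cutoff=cutoff)
        rep.auc = roc_auc(test_preds, test_labels) if len(set(test_labels)) == 2 else None
        reports.append(rep)
        for i, p in zip(test_ids, test_preds):
            pred_rows.append({"id": i, "prob": p, "label": y[i], "fold": fold})

    return CVResult(
        plan=plan,
        fold_reports=reports,
        predictions=pd.DataFrame(pred_rows),
        runs=runs,
    )


def _stack(feats, y, ids):
    X = np.vstack([f for i in ids for f in feats[i]])
    labels = np.array([y[i] for i in ids for _ in feats[i]], dtype=int)
    return X, labels
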
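"""Descriptor-based conventional-ML comparison harness.

The image pipeline's competitors are gradient-boosted trees / random forests
/ a small neural network trained on molecular descriptors. This harness
computes a descriptor table (delegated to RDKit's descriptor engine),
filters out non-finite and constant columns with a drop log, and runs
cross-validation over exactly the same group-split plan the image pipeline
uses — same folds, same metric suite — so the two routes are directly
comparable.

The learners themselves are off-the-shelf and sit behind a registry; XGBoost,
LightGBM and CatBoost are optional dependencies that are imported lazily and
raise a clear error naming the missing package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chemio import Molecule
from .evalx import MetricsReport, confusion_at_cutoff, metrics, optimal_cutoff, roc_auc
from .splits import LabeledDataset, SplitPlan, fold_assignment

__all__ = [
    "DescriptorTable",
    "LEARNERS",
    "featurize",
    "filter_descriptor_frame",
    "run_baseline_cv",
]


@dataclass
class DescriptorTable:
    """Molecules x descriptors matrix after finiteness/variance filtering."""

    ids: list[str]
    frame: pd.DataFrame  # index = ids, columns = descriptor names
    dropped: dict[str, str] = field(default_factory=dict)  # column -> reason
    provenance: str = ""

    @property
    def n_descriptors(self) -> int:
        return self.frame.shape[1]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path)
        return path


def featurize(mols: Sequence[Molecule], provenance: str = "") -> DescriptorTable:
    """Descriptor table for a molecule list.

    Computation is delegated to the RDKit descriptor engine
    (``Chem.Descriptors.CalcMolDescriptors``); columns containing any
    non-finite value or with zero variance are dropped and recorded in the
    drop log. Row order matches the input order.
    """
    try:
        from rdkit.Chem import Descriptors
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "descriptor engine unavailable: install the optional dependency rdkit"
        ) from exc

    rows = []
    ids = []
    for m in mols:
        rd = m.to_rdkit()
        rows.append(Descriptors.CalcMolDescriptors(rd))
        ids.append(m.id)
    frame = pd.DataFrame(rows, index=ids).apply(pd.to_numeric, errors="coerce")
    frame, dropped = filter_descriptor_frame(frame)
    return DescriptorTable(ids=ids, frame=frame, dropped=dropped, provenance=provenance)


def filter_descriptor_frame(frame: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str]]:
    """Drop non-finite and constant descriptor columns; return a drop log."""
    dropped: dict[str, str] = {}
    for col in list(frame.columns):
        vals = frame[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            dropped[col] = "non-finite"
        elif np.nanmax(vals) == np.nanmin(vals):
            dropped[col] = "constant"
    return frame.drop(columns=list(dropped)), dropped


# ---------------------------------------------------------------------------
# learner registry (lazy imports for optional dependencies)
# ---------------------------------------------------------------------------

def _make_rf(seed: int, params: dict):
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(
        n_estimators=params.get("n_estimators", 200),
        max_depth=params.get("max_depth"),
        random_state=seed,
        n_jobs=1,
    )


def _make_xgb(seed: int, params: dict):
    try:
        from xgboost import XGBClassifier
    except ImportError as exc:
        raise ImportError("learner XGB requires the optional dependency xgboost") from exc
    return XGBClassifier(
        n_estimators=params.get("n_estimators", 200),
        max_depth=params.get("max_depth", 6),
        learning_rate=params.get("learning_rate", 0.1),
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        eval_metric="logloss",
    )


def _make_lgbm(seed: int, params: dict):
    try:
        from lightgbm import LGBMClassifier
    except ImportError as exc:
        raise ImportError("learner LGBM requires the optional dependency lightgbm") from exc
    return LGBMClassifier(
        n_estimators=params.get("n_estimators", 200),
        num_leaves=params.get("num_leaves", 31),
        learning_rate=params.get("learning_rate", 0.1),
        # small-sample-friendly leaf minimum; the upstream default (20)
        # forbids any split on datasets of a few dozen molecules
        min_child_samples=params.get("min_child_samples", 5),
        random_state=seed,
        n_jobs=1,
        verbose=-1,
    )


def _make_cb(seed: int, params: dict):
    try:
        from catboost import CatBoostClassifier
    except ImportError as exc:
        raise ImportError("learner CB requires the optional dependency catboost") from exc
    return CatBoostClassifier(
        iterations=params.get("n_estimators", 200), random_seed=seed, verbose=False
    )


def _make_nn(seed: int, params: dict):
    # single-hidden-layer network, the classical descriptor-NN analog
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return make_pipeline(
        StandardScaler(),
        MLPClassifier(
            hidden_layer_sizes=(params.get("hidden", 64),),
            max_iter=params.get("max_iter", 300),
            random_state=seed,
        ),
    )


LEARNERS: dict[str, Callable[[int, dict], object]] = {
    "RF": _make_rf,
    "XGB": _make_xgb,
    "LGBM": _make_lgbm,
    "CB": _make_cb,
    "NN": _make_nn,
}

_SEARCH_SPACES: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [100, 200, 400], "max_depth": [None, 6, 12]},
    "XGB": {"n_estimators": [100, 200, 400], "max_depth": [3, 6, 9],
            "learning_rate": [0.03, 0.1, 0.3]},
    "LGBM": {"n_estimators": [100, 200, 400], "num_leaves": [15, 31, 63],
             "learning_rate": [0.03, 0.1, 0.3]},
    "CB": {"n_estimators": [100, 200, 400]},
    "NN": {"hidden": [32, 64, 128]},
}


def run_baseline_cv(
    table: DescriptorTable,
    labels: Sequence[int] | LabeledDataset,
    plan: SplitPlan,
    learner: str = "RF",
    tuning: str = "off",
    seed: int = 0,
    n_tuning_draws: int = 8,
) -> list[MetricsReport]:
    """Cross-validated descriptor baseline on the shared split plan.

    For every fold the model trains on the Tra groups, the Val groups pick
    the decision cutoff (and, when tuning, the hyperparameters), and the
    test group is scored with the shared metric suite. ``tuning`` is
    ``"off"``, ``"random"`` (built-in seeded random search over a standard
    space) or ``"bayesian"`` (delegated to hyperopt when installed).
    """
    if learner not in LEARNERS:
        raise KeyError(f"unknown learner {learner!r} (choose from {sorted(LEARNERS)})")
    if tuning not in ("off", "random", "bayesian"):
        raise ValueError(f"unknown tuning mode {tuning!r}")
    if tuning == "bayesian":
        try:
            import hyperopt  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "tuning='bayesian' requires the optional dependency hyperopt; "
                "use tuning='random' for the built-in search"
            ) from exc

    y_map = _label_map(labels, table.ids)
    missing = [i for i in plan.assignment if i not in y_map or i not in set(table.ids)]
    if missing:
        raise ValueError(f"descriptor table does not cover plan ids: {missing[:5]}")
    X = table.frame
    reports: list[MetricsReport] = []
    rng = np.random.default_rng(seed)
    for fold in range(plan.n_folds):
        tra_g, val_g, test_g = fold_assignment(plan, fold)
        tra_ids = [i for i, g in plan.assignment.items() if g in tra_g]
        val_ids = [i for i, g in plan.assignment.items() if g in val_g]
        test_ids = [i for i, g in plan.assignment.items() if g == test_g]
        X_tr, y_tr = X.loc[tra_ids], np.array([y_map[i] for i in tra_ids])
        X_va, y_va = X.loc[val_ids], np.array([y_map[i] for i in val_ids])
        X_te, y_te = X.loc[test_ids], np.array([y_map[i] for i in test_ids])

        params: dict = {}
        if tuning == "random":
            params = _random_search(
                learner, X_tr, y_tr, X_va, y_va, rng, n_tuning_draws, seed
            )
        model = LEARNERS[learner](int(seed), params)
        model.fit(X_tr, y_tr)
        va_prob = model.predict_proba(X_va)[:, 1]
        cutoff = (
            optimal_cutoff(va_prob, y_va) if len(set(y_va.tolist())) == 2 else 0.5
        )
        te_prob = model.predict_proba(X_te)[:, 1]
        rep = metrics(confusion_at_cutoff(te_prob, y_te, cutoff), cutoff=cutoff)
        rep.auc = roc_auc(te_prob, y_te) if len(set(y_te.tolist())) == 2 else None
        reports.append(rep)
    return reports


def _random_search(learner, X_tr, y_tr, X_va, y_va, rng, n_draws, seed) -> dict:
    space = _SEARCH_SPACES[learner]
    best_params, best_auc = {}, -1.0
    for _ in range(n_draws):
        cand = {k: v[rng.integers(0, len(v))] for k, v in space.items()}
        model = LEARNERS[learner](int(seed), cand)
        model.fit(X_tr, y_tr)
        try:
            auc = roc_auc(model.predict_proba(X_va)[:, 1], y_va)
        except ValueError:
            auc = 0.5
        if auc > best_auc:
            best_auc, best_params = auc, cand
    return best_params


def _label_map(labels, ids) -> dict[str, int]:
    if isinstance(labels, LabeledDataset):
        return {i: (1 if l == "active" else 0) for i, l in zip(labels.ids, labels.labels)}
    return {i: int(l) for i, l in zip(ids, labels)}
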
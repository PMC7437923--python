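"""Train, cross-validate and evaluate the boosted pair classifier.

The classifier is an XGBoost ensemble with a logistic objective; the score
it emits is the raw pre-logistic margin (the "CATNIP score"), which doubles
as the edge weight of the repurposing network. Class imbalance (far more
non-sharing pairs than sharing ones) is handled by downsampling the
majority class to 1:1 inside each training fold. All randomness funnels
through one explicit seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.special import expit, logit
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .features import PairFeatureTable

__all__ = [
    "DEFAULT_PARAMS",
    "DEFAULT_GRID",
    "CatnipModel",
    "CvReport",
    "make_folds",
    "make_drug_level_folds",
    "downsample_majority",
    "grid_search",
    "train",
    "cross_validate",
    "catnip_score",
    "score_to_probability",
    "probability_to_score",
    "evaluate",
]

#: hyperparameters used when no grid search is requested
DEFAULT_PARAMS: dict = {"learning_rate": 0.1, "max_depth": 5, "n_rounds": 200}

#: default grid-search space (learning rate x depth x boosting rounds)
DEFAULT_GRID: dict[str, list] = {
    "learning_rate": [0.05, 0.1, 0.3],
    "max_depth": [3, 5, 7],
    "n_rounds": [100, 300],
}


def _xgb_params(params: Mapping, seed: int) -> dict:
    out = {
        "objective": "binary:logistic",
        "eval_metric": "logloss",
        "tree_method": "exact",
        "nthread": 1,
        "seed": int(seed),
        "base_score": 0.5,
        "learning_rate": params.get("learning_rate", 0.1),
        "max_depth": int(params.get("max_depth", 5)),
    }
    for k, v in params.items():
        if k not in out and k != "n_rounds":
            out[k] = v
    return out


def make_folds(labels: Sequence[bool] | pd.Series, k: int = 5, seed: int = 0) -> np.ndarray:
    """Pair-level stratified k-fold assignment, reproducible under *seed*."""
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(y):
        raise ValueError(f"k={k} exceeds number of pairs {len(y)}")
    folds = np.empty(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[test_idx] = fold
    return folds


def make_drug_level_folds(
    pair_index: pd.MultiIndex, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, dict[str, int]]:
    """Group-aware folds: drugs are partitioned, a pair belongs to fold f only
    when both its drugs do, and straddling pairs get fold -1 (never held out).

    Pair-level splitting leaks drug identity across folds (the same drug
    appears in training and held-out pairs); this stricter scheme removes
    that leak at the cost of discarding straddling pairs from evaluation.
    """
    drugs = sorted({d for pair in pair_index for d in pair})
    if k < 2 or k > len(drugs):
        raise ValueError("need 2 <= k <= number of drugs")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(drugs))
    drug_fold = {drugs[i]: int(f) for f, chunk in enumerate(np.array_split(perm, k)) for i in chunk}
    folds = np.array(
        [drug_fold[a] if drug_fold[a] == drug_fold[b] else -1 for a, b in pair_index]
    )
    return folds, drug_fold


def downsample_majority(labels: Sequence[bool] | pd.Series, seed: int = 0) -> np.ndarray:
    """Indices keeping the minority class whole and the majority sampled to 1:1."""
    y = np.asarray(labels, dtype=bool)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    keep = rng.choice(majority, size=len(minority), replace=False)
    return np.sort(np.concatenate([minority, keep]))


@dataclass
class CatnipModel:
    """Trained boosted ensemble plus the metadata needed to score and explain.

    ``medians`` are the per-feature medians over the full (imputed) training
    table, frozen at train time for median-ablation explanations.
    """

    booster: xgb.Booster
    registry: list[str]
    medians: pd.Series
    params: dict
    seed: int
    fold_assignment: np.ndarray | None = None

    def _dmatrix(self, X) -> xgb.DMatrix:
        arr = self._check(X)
        return xgb.DMatrix(arr, feature_names=self.registry)

    def _check(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.registry:
                raise ValueError("feature columns do not match the model registry")
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.atleast_2d(np.asarray(X, dtype=float))
            if arr.shape[1] != len(self.registry):
                raise ValueError(
                    f"expected {len(self.registry)} features, got {arr.shape[1]}"
                )
        return arr

    def score(self, X) -> np.ndarray:
        """Raw pre-logistic margin; higher = more likely to share an indication."""
        return self.booster.predict(self._dmatrix(X), output_margin=True)

    def predict_proba(self, X) -> np.ndarray:
        return self.booster.predict(self._dmatrix(X))

    def save(self, path: str | Path) -> None:
        """Portable dump: UBJSON ensemble + JSON sidecar with metadata."""
        path = Path(path)
        self.booster.save_model(path)
        meta = {
            "registry": self.registry,
            "medians": {k: float(v) for k, v in self.medians.items()},
            "params": self.params,
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )

    @classmethod
    def load(cls, path: str | Path) -> "CatnipModel":
        path = Path(path)
        booster = xgb.Booster()
        booster.load_model(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        medians = pd.Series(meta["medians"]).reindex(meta["registry"])
        return cls(booster, meta["registry"], medians, meta["params"], meta["seed"])


def train(table: PairFeatureTable, params: Mapping | None = None, seed: int = 0) -> CatnipModel:
    """Fit the booster on the downsampled table; medians stored over the full table."""
    params = dict(params or DEFAULT_PARAMS)
    X = table.features
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("feature table contains non-finite values (impute first)")
    y = table.labels.to_numpy(dtype=int)
    keep = downsample_majority(y, seed=seed)
    dtrain = xgb.DMatrix(
        X.iloc[keep].to_numpy(dtype=float), label=y[keep], feature_names=list(table.registry)
    )
    booster = xgb.train(_xgb_params(params, seed), dtrain, num_boost_round=int(params.get("n_rounds", 200)))
    medians = X.median()
    return CatnipModel(booster, list(table.registry), medians, dict(params), int(seed))


def cross_validate(
    table: PairFeatureTable,
    params: Mapping | None = None,
    k: int = 5,
    seed: int = 0,
    folds: np.ndarray | None = None,
    group_drugs: bool = False,
) -> tuple[pd.Series, np.ndarray, list[CatnipModel]]:
    """k-fold CV with per-fold downsampling; returns held-out raw scores.

    Every pair is scored by a model from whose training data it was
    excluded. With ``group_drugs=True`` folds are drug-level: a pair is
    held out only when both drugs belong to the fold, training excludes
    every pair touching a held-out drug, and pairs straddling folds keep a
    NaN score (they are never a clean held-out case).
    """
    params = dict(params or DEFAULT_PARAMS)
    X = table.features
    y = table.labels.to_numpy(dtype=int)
    drug_fold: dict[str, int] | None = None
    if folds is None:
        if group_drugs:
            folds, drug_fold = make_drug_level_folds(X.index, k=k, seed=seed)
        else:
            folds = make_folds(y, k=k, seed=seed)
    scores = np.full(len(y), np.nan)
    models: list[CatnipModel] = []
    pair_drugs = list(X.index)
    for fold in range(int(folds.max()) + 1):
        test = folds == fold
        if drug_fold is None:
            train_mask = ~test
        else:
            # exclude every pair touching a held-out drug from training
            train_mask = np.array(
                [drug_fold[a] != fold and drug_fold[b] != fold for a, b in pair_drugs]
            )
        train_idx = np.flatnonzero(train_mask)
        keep = train_idx[downsample_majority(y[train_idx], seed=seed + fold)]
        dtrain = xgb.DMatrix(
            X.iloc[keep].to_numpy(dtype=float), label=y[keep], feature_names=list(table.registry)
        )
        booster = xgb.train(
            _xgb_params(params, seed), dtrain, num_boost_round=int(params.get("n_rounds", 200))
        )
        model = CatnipModel(booster, list(table.registry), X.median(), dict(params), int(seed), folds)
        models.append(model)
        scores[test] = model.score(X.iloc[np.flatnonzero(test)])
    if drug_fold is None:
        assert not np.isnan(scores).any()
    return pd.Series(scores, index=X.index, name="catnip_score"), folds, models


def grid_search(
    table: PairFeatureTable,
    grid: Mapping[str, Sequence] | None = None,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Pick the grid point maximizing mean held-out AUC; ties break by grid order."""
    grid = dict(DEFAULT_GRID if grid is None else grid)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    names = list(grid)
    folds = make_folds(table.labels, k=k, seed=seed)
    y = table.labels.to_numpy(dtype=int)
    best, best_auc = None, -np.inf
    for values in itertools.product(*(grid[n] for n in names)):
        params = dict(zip(names, values))
        scores, _, _ = cross_validate(table, params, k=k, seed=seed, folds=folds)
        aucs = [
            roc_auc_score(y[folds == f], scores.to_numpy()[folds == f])
            for f in range(k)
            if len(np.unique(y[folds == f])) == 2
        ]
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best, best_auc = params, mean_auc
    return dict(best)


def catnip_score(model: CatnipModel, X) -> np.ndarray:
    """Raw (pre-logistic) score for one or more feature vectors in registry order."""
    return model.score(X)


def score_to_probability(s):
    """p = sigma(s) = 1/(1+e^-s), the probability that the pair shares an indication."""
    return expit(s)


def probability_to_score(p):
    """Inverse logistic transform (logit)."""
    return logit(p)


@dataclass
class CvReport:
    """Pooled evaluation of held-out scores: ROC, PRC, subset AUCs, FP rates."""

    auc: float
    auprc: float
    roc_points: pd.DataFrame
    prc_points: pd.DataFrame
    subset_aucs: dict[str, float | None] = field(default_factory=dict)
    fp_rates: dict[float, dict[str, float | None]] = field(default_factory=dict)
    prevalence: float = float("nan")


def evaluate(
    scores: Sequence[float] | pd.Series,
    labels: Sequence[bool] | pd.Series,
    subsets: Mapping[str, Sequence[bool]] | None = None,
    prob_cutoffs: Sequence[float] = (0.5, 0.75),
) -> CvReport:
    """Pooled ROC/PRC evaluation with subset AUCs and FP rates at cutoffs.

    The primary "fp_fraction" at probability cutoff c is the
    false-discovery fraction FP/(FP+TP) among pairs predicted at p >= c;
    the classical false-positive rate FP/(FP+TN) is reported alongside as
    "fpr". A subset (e.g. pairs with structure Dice < 0.5, or pairs with no
    shared target) containing a single class yields an undefined (None)
    AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(s) != len(y):
        raise ValueError("scores and labels must align")
    auc = float(roc_auc_score(y, s))
    auprc = float(average_precision_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    subset_aucs: dict[str, float | None] = {}
    for name, mask in (subsets or {}).items():
        m = np.asarray(mask, dtype=bool)
        subset_aucs[name] = (
            float(roc_auc_score(y[m], s[m])) if len(np.unique(y[m])) == 2 else None
        )
    p = score_to_probability(s)
    fp_rates: dict[float, dict[str, float | None]] = {}
    for c in prob_cutoffs:
        called = p >= c
        fp = int((called & ~y).sum())
        tp = int((called & y).sum())
        tn = int((~called & ~y).sum())
        fp_rates[float(c)] = {
            "fp_fraction": fp / (fp + tp) if (fp + tp) else None,
            "fpr": fp / (fp + tn) if (fp + tn) else None,
        }
    return CvReport(
        auc=auc,
        auprc=auprc,
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        prc_points=pd.DataFrame({"recall": rec, "precision": prec}),
        subset_aucs=subset_aucs,
        fp_rates=fp_rates,
        prevalence=float(y.mean()),
    )
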
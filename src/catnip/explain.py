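"""Per-pair median-ablation explanations and global feature importance.

The contribution of a feature to a pair's score is measured by replacing
that feature's value with the training-cohort median (the best available
stand-in for "no contribution", since the vast majority of pairs share no
indication) and rescoring; the delta is reported on the raw-score scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CatnipModel

__all__ = ["AblationProfile", "ablation_profile", "ablation_deltas", "model_feature_importance"]


@dataclass
class AblationProfile:
    """One pair's ablation result: per feature, original value, median, delta."""

    pair: tuple[str, str] | None
    table: pd.DataFrame  # index = feature; columns = original, median, delta

    def top_features(self, n: int = 5) -> pd.DataFrame:
        return self.table.reindex(
            self.table["delta"].abs().sort_values(ascending=False).index
        ).head(n)


def ablation_profile(model: CatnipModel, x, pair: tuple[str, str] | None = None) -> AblationProfile:
    """Ablate each feature independently to its stored median and rescore.

    delta = original score - ablated score, so a positive delta means the
    observed feature value pushed the score up. The input vector is never
    mutated; each feature is restored before the next is ablated.
    """
    vec = _as_vector(model, x)
    base = float(model.score(vec.reshape(1, -1))[0])
    ablated = np.tile(vec, (len(model.registry), 1))
    for i, feat in enumerate(model.registry):
        ablated[i, i] = model.medians[feat]
    scores = model.score(ablated)
    table = pd.DataFrame(
        {
            "original": vec,
            "median": model.medians.to_numpy(dtype=float),
            "delta": base - scores,
        },
        index=pd.Index(model.registry, name="feature"),
    )
    return AblationProfile(pair, table)


def ablation_deltas(model: CatnipModel, X: pd.DataFrame) -> pd.DataFrame:
    """Vectorized ablation over many pairs: rows = pairs, columns = features."""
    if list(X.columns) != model.registry:
        raise ValueError("feature columns do not match the model registry")
    arr = X.to_numpy(dtype=float)
    base = model.score(arr)
    out = np.empty_like(arr)
    for i, feat in enumerate(model.registry):
        ab = arr.copy()
        ab[:, i] = model.medians[feat]
        out[:, i] = base - model.score(ab)
    return pd.DataFrame(out, index=X.index, columns=model.registry)


def profiles_to_long(profiles: list[AblationProfile]) -> pd.DataFrame:
    """Long-format export: pair, feature, original, median, delta."""
    frames = []
    for p in profiles:
        t = p.table.reset_index()
        t.insert(0, "drug_a", p.pair[0] if p.pair else "")
        t.insert(1, "drug_b", p.pair[1] if p.pair else "")
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def model_feature_importance(model: CatnipModel, importance_type: str = "total_gain") -> pd.Series:
    """Ensemble feature importance, normalized to sum to one.

    Uses the booster's built-in importance; the default, normalized total
    gain, matches the Gain column of R xgboost's importance table.
    Features never used by any split score exactly zero.
    """
    raw = model.booster.get_score(importance_type=importance_type)
    if not raw and not model.booster.get_dump():
        raise ValueError("model appears untrained")
    imp = pd.Series({f: raw.get(f, 0.0) for f in model.registry}, dtype=float)
    total = imp.sum()
    return imp / total if total > 0 else imp


def _as_vector(model: CatnipModel, x) -> np.ndarray:
    if isinstance(x, pd.Series):
        if list(x.index) != model.registry:
            raise ValueError("feature vector does not match the model registry")
        return x.to_numpy(dtype=float)
    arr = np.asarray(x, dtype=float).ravel()
    if arr.shape[0] != len(model.registry):
        raise ValueError(f"expected {len(model.registry)} features, got {arr.shape[0]}")
    return arr
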
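"""Screen drug classes against disease areas on the score distribution.

For a (drug class, disease area) combination, the scores of pairs joining a
class member to a disease-approved drug are compared with the scores of
pairs joining a class member to a non-disease drug (Wilcoxon-Mann-Whitney,
Hodges-Lehmann location shift). A positive shift surviving BH-FDR control
suggests the class as a repurposing candidate for the disease area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DrugRecord, PairKey

__all__ = [
    "DEFAULT_CLASS_KEYWORDS",
    "DiseaseAreaDefinition",
    "select_drug_classes",
    "disease_area_drugs",
    "class_disease_shift",
    "bh_fdr",
    "screen_classes",
    "rank_predictions",
    "sensitivity_at_fraction",
]

DEFAULT_CLASS_KEYWORDS = ("inhibitor", "antagonist", "agonist")


@dataclass
class DiseaseAreaDefinition:
    """A disease area defined by semantic-type codes, keywords and/or concepts.

    A concept belongs to the area when its semantic type is listed, its
    name (or id) contains a keyword case-insensitively, or it is listed
    explicitly. At least one rule component must be non-empty.
    """

    name: str
    semantic_types: set[str] = field(default_factory=set)
    keywords: set[str] = field(default_factory=set)
    concepts: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (self.semantic_types or self.keywords or self.concepts):
            raise ValueError(f"disease area {self.name!r} has an empty definition")

    def matches(
        self,
        concept: str,
        concept_name: str | None = None,
        semantic_types: Iterable[str] = (),
    ) -> bool:
        if concept in self.concepts:
            return True
        if set(semantic_types) & self.semantic_types:
            return True
        text = f"{concept} {concept_name or ''}".lower()
        return any(kw.lower() in text for kw in self.keywords)


def select_drug_classes(
    memberships: Mapping[str, set[str]],
    keywords: Sequence[str] = DEFAULT_CLASS_KEYWORDS,
    min_size: int = 20,
) -> list[str]:
    """Classes whose name contains a mechanism keyword and with >= min_size drugs.

    *memberships* maps class name -> member drug ids.
    """
    out = []
    for name, drugs in memberships.items():
        if len(drugs) >= min_size and any(kw.lower() in name.lower() for kw in keywords):
            out.append(name)
    return sorted(out)


def disease_area_drugs(
    records: Iterable[DrugRecord],
    definition: DiseaseAreaDefinition,
    concept_semantic_types: Mapping[str, set[str]] | None = None,
    concept_names: Mapping[str, str] | None = None,
) -> set[str]:
    """Drugs with at least one standardized concept inside the area."""
    import warnings

    stypes = concept_semantic_types or {}
    names = concept_names or {}
    drugs = {
        rec.drug_id
        for rec in records
        if any(
            definition.matches(c, names.get(c), stypes.get(c, ())) for c in rec.concepts
        )
    }
    if not drugs:
        warnings.warn(f"disease area {definition.name!r} matches no drugs")
    return drugs


def _class_to_partner_scores(
    scores: pd.Series, class_drugs: set[str], partners: set[str]
) -> np.ndarray:
    """Scores of deduplicated (class drug, partner) pairs, class-internal pairs excluded."""
    vals = []
    for (a, b), s in scores.items():
        a_in, b_in = a in class_drugs, b in class_drugs
        if a_in == b_in:  # neither, or both (a pair must straddle the class)
            continue
        partner = b if a_in else a
        if partner in partners:
            vals.append(float(s))
    return np.asarray(vals)


def class_disease_shift(
    scores: pd.Series, class_drugs: set[str], disease_drugs: set[str]
) -> tuple[float, float, int, int]:
    """Rank-sum comparison of class->disease pair scores vs class->non-disease.

    Returns (Hodges-Lehmann location shift, two-sided p-value, n in-disease
    pairs, n out-of-disease pairs). The shift is the median of all
    between-group differences, positive when the in-disease group scores
    higher. Pairs internal to the class are excluded from both groups.
    scipy's rank-sum uses exact enumeration for small tie-free groups and a
    tie-corrected normal approximation otherwise.
    """
    in_class_disease = {d for d in disease_drugs if d not in class_drugs}
    all_partners = {d for pair in scores.index for d in pair}
    out_partners = {
        d for d in all_partners if d not in class_drugs and d not in disease_drugs
    }
    g1 = _class_to_partner_scores(scores, class_drugs, in_class_disease)
    g2 = _class_to_partner_scores(scores, class_drugs, out_partners)
    if len(g1) == 0:
        raise ValueError("in-disease pair group is empty")
    if len(g2) == 0:
        raise ValueError("out-of-disease pair group is empty")
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="auto")
    shift = float(np.median(np.subtract.outer(g1, g2)))
    return shift, float(res.pvalue), len(g1), len(g2)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_classes(
    scores: pd.Series,
    class_memberships: Mapping[str, set[str]],
    areas: Sequence[DiseaseAreaDefinition],
    records: Sequence[DrugRecord],
    keywords: Sequence[str] = DEFAULT_CLASS_KEYWORDS,
    min_size: int = 20,
    concept_semantic_types: Mapping[str, set[str]] | None = None,
    concept_names: Mapping[str, str] | None = None,
    fdr_level: float = 0.1,
) -> pd.DataFrame:
    """Full class x disease-area screen with BH correction and ranking.

    Returns one row per testable combination with columns: drug_class,
    disease_area, n_disease_pairs, n_other_pairs, location_shift, pvalue,
    qvalue, rank (NaN unless q < fdr_level and shift > 0).
    """
    classes = select_drug_classes(class_memberships, keywords, min_size)
    rows = []
    for area in areas:
        area_drugs = disease_area_drugs(records, area, concept_semantic_types, concept_names)
        for cls in classes:
            try:
                shift, p, n1, n2 = class_disease_shift(
                    scores, class_memberships[cls], area_drugs
                )
            except ValueError:
                continue
            rows.append(
                {
                    "drug_class": cls,
                    "disease_area": area.name,
                    "n_disease_pairs": n1,
                    "n_other_pairs": n2,
                    "location_shift": shift,
                    "pvalue": p,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "drug_class",
            "disease_area",
            "n_disease_pairs",
            "n_other_pairs",
            "location_shift",
            "pvalue",
        ],
    )
    if df.empty:
        df["qvalue"] = []
        df["rank"] = []
        return df
    df["qvalue"] = bh_fdr(df["pvalue"].to_numpy())
    return rank_predictions(df, fdr_level=fdr_level)


def rank_predictions(results: pd.DataFrame, fdr_level: float = 0.1) -> pd.DataFrame:
    """Rank significant positive shifts (q < level strictly, shift > 0) by effect size.

    Rank 1 = largest shift; non-qualifying rows get NaN rank. The input
    frame is returned sorted by (rank, then p-value).
    """
    df = results.copy()
    qualifies = (df["qvalue"] < fdr_level) & (df["location_shift"] > 0)
    df["rank"] = np.nan
    order = df.loc[qualifies, "location_shift"].sort_values(ascending=False)
    df.loc[order.index, "rank"] = np.arange(1, len(order) + 1)
    return df.sort_values(["rank", "pvalue"], na_position="last").reset_index(drop=True)


def sensitivity_at_fraction(
    results: pd.DataFrame,
    truth_fractions: Mapping[tuple[str, str], float],
    fraction_cutoff: float = 0.0,
    fdr_level: float = 0.1,
) -> float | None:
    """Fraction of true class-disease associations the screen detects.

    *truth_fractions* maps (drug_class, disease_area) to the fraction of
    class drugs approved for the disease. A combination is a true positive
    when its fraction exceeds the cutoff (> for a positive cutoff, >= 1
    drug when cutoff is 0, i.e. fraction > 0); it counts as detected when
    the screen assigns it a significant positive shift. Returns None when
    no true positive exists at the cutoff.
    """
    detected = {
        (r.drug_class, r.disease_area)
        for r in results.itertuples()
        if (r.qvalue < fdr_level) and (r.location_shift > 0)
    }
    truths = {k for k, frac in truth_fractions.items() if frac > fraction_cutoff}
    if not truths:
        return None
    return len(truths & detected) / len(truths)
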
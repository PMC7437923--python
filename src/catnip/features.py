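"""The 16 pairwise drug-similarity features, imputation and the univariate screen.

Eleven features are Jaccard indices between the annotation gene-sets
(GO BP/CC/MF, chemical/oncogenic/immunogenic signatures, microRNA, TF/motif,
KEGG, Reactome, canonical pathways) that contain each drug's targets; the
remaining five are target-set Jaccard, structural Dice over fingerprint
bits, mean Pearson correlation of target essentiality profiles, minimum
protein-interaction distance between targets, and Jaccard of active
bioassay sets. Missing cells (no annotation, no fingerprint, no connected
targets, ...) are imputed with the per-feature median over observed cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ConfigurationError, DrugRecord, PairKey, ResourceBundle

__all__ = [
    "DEFAULT_REGISTRY",
    "GENESET_FEATURES",
    "PairFeatureTable",
    "jaccard_index",
    "geneset_membership",
    "structure_dice",
    "essentiality_similarity",
    "ppi_min_target_distance",
    "bioassay_similarity",
    "build_feature_table",
    "impute_median",
    "ks_screen",
    "feature_correlation_matrix",
]

#: gene-set-membership features and the collection each one reads
GENESET_FEATURES: dict[str, str] = {
    "go_bp": "go_bp",
    "go_cc": "go_cc",
    "go_mf": "go_mf",
    "chemical_perturbation": "chemical_perturbation",
    "oncogenic_signature": "oncogenic_signature",
    "immunogenic_signature": "immunogenic_signature",
    "microrna": "microrna",
    "tf_motif": "tf_motif",
    "kegg": "kegg",
    "reactome": "reactome",
    "canonical_pathways": "canonical_pathways",
}

#: the default 16-feature registry, order-locked for model scoring
DEFAULT_REGISTRY: list[str] = [
    *GENESET_FEATURES,
    "target_jaccard",
    "structure_dice",
    "essentiality_corr",
    "ppi_min_distance",
    "bioassay_jaccard",
]

#: features where the planted/biological signal points downward
#: (closer targets -> smaller distance)
LOWER_IS_SIMILAR: frozenset[str] = frozenset({"ppi_min_distance"})


def jaccard_index(set_a: Iterable, set_b: Iterable) -> float | None:
    """|A∩B| / |A∪B|; ``None`` (missing) when both sets are empty.

    Absence of annotation on both sides is treated as no evidence, not as
    evidence of dissimilarity, so the cell falls to imputation.
    """
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return None
    return len(a & b) / len(union)


def geneset_membership(targets: Iterable[str], collection: Mapping[str, set[str]]) -> set[str]:
    """Names of the sets in *collection* containing at least one target."""
    tset = set(targets)
    return {name for name, genes in collection.items() if genes & tset}


def structure_dice(
    fp_a: Iterable[int] | None, fp_b: Iterable[int] | None, add_one: bool = False
) -> float | None:
    """Dice similarity 2|A∩B|/(|A|+|B|) of two fingerprint bit sets.

    ``add_one`` applies the add-one smoothing used by ChemmineR's
    ``fpSim`` ((2|A∩B|+1)/(|A|+|B|+1)), which some published atom-pair
    similarity values are computed with. Missing fingerprints (``None``)
    yield a missing value.
    """
    if fp_a is None or fp_b is None:
        return None
    a, b = set(fp_a), set(fp_b)
    num, den = 2 * len(a & b), len(a) + len(b)
    if add_one:
        num, den = num + 1, den + 1
    if den == 0:
        return None
    return num / den


def essentiality_similarity(
    targets_a: Iterable[str],
    targets_b: Iterable[str],
    matrix: pd.DataFrame,
    min_periods: int = 3,
) -> float | None:
    """Mean Pearson correlation between the essentiality profiles of the drugs' targets.

    Every (gene_a, gene_b) cross-pair whose rows exist in the gene x
    cell-line matrix and share at least *min_periods* non-missing cell lines
    contributes one correlation; the feature is their mean, or missing when
    no cross-pair is valid.
    """
    rows_a = [g for g in set(targets_a) if g in matrix.index]
    rows_b = [g for g in set(targets_b) if g in matrix.index]
    if not rows_a or not rows_b:
        return None
    vals = []
    for ga in rows_a:
        xa = matrix.loc[ga].to_numpy(dtype=float)
        for gb in rows_b:
            xb = matrix.loc[gb].to_numpy(dtype=float)
            ok = ~(np.isnan(xa) | np.isnan(xb))
            if ok.sum() < min_periods:
                continue
            sa, sb = xa[ok], xb[ok]
            if sa.std() == 0 or sb.std() == 0:
                continue
            vals.append(float(np.corrcoef(sa, sb)[0, 1]))
    if not vals:
        return None
    return float(np.mean(vals))


def ppi_min_target_distance(
    targets_a: Iterable[str], targets_b: Iterable[str], graph: nx.Graph
) -> float | None:
    """Minimum unweighted shortest-path length between any cross-pair of targets.

    A shared target gives 0; if no cross-pair is connected (or either side
    has no target in the graph) the value is missing.
    """
    ta = [g for g in set(targets_a) if g in graph]
    tb = [g for g in set(targets_b) if g in graph]
    if not ta or not tb:
        return None
    if set(ta) & set(tb):
        return 0.0
    # multi-source BFS from the smaller side
    if len(tb) < len(ta):
        ta, tb = tb, ta
    dist = _multi_source_distances(graph, ta)
    best = min((dist[g] for g in tb if g in dist), default=None)
    return None if best is None else float(best)


def _multi_source_distances(graph: nx.Graph, sources: Sequence[str]) -> dict[str, int]:
    # unweighted hop counts from the nearest source (edges carry no weight attr)
    return {
        n: int(d)
        for n, d in nx.multi_source_dijkstra_path_length(graph, set(sources)).items()
    }


def bioassay_similarity(
    actives_a: set[str] | None, actives_b: set[str] | None
) -> float | None:
    """Jaccard of active-assay sets; missing when either drug has no entry."""
    if actives_a is None or actives_b is None:
        return None
    return jaccard_index(actives_a, actives_b)


# ---------------------------------------------------------------------------
# pair feature table


@dataclass
class PairFeatureTable:
    """Unordered drug pairs x registry features, with labels and a missingness mask.

    ``features`` is indexed by a two-level (drug_a, drug_b) MultiIndex in
    canonical order; ``observed`` flags cells measured directly (False =
    imputed or still missing); ``labels`` is the shared-indication flag.
    """

    features: pd.DataFrame
    labels: pd.Series
    observed: pd.DataFrame
    registry: list[str] = field(default_factory=lambda: list(DEFAULT_REGISTRY))

    @property
    def pairs(self) -> list[PairKey]:
        return [PairKey(a, b) for a, b in self.features.index]

    def copy(self) -> "PairFeatureTable":
        return PairFeatureTable(
            self.features.copy(), self.labels.copy(), self.observed.copy(), list(self.registry)
        )

    def to_tsv(self, path: str | Path) -> None:
        """Export as delimited text: pair columns, features in registry order,
        label, then per-feature observed flags."""
        out = self.features.copy()
        out["label"] = self.labels.astype(int)
        for feat in self.registry:
            out[f"obs_{feat}"] = self.observed[feat].astype(int)
        out = out.reset_index(names=["drug_a", "drug_b"])
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairFeatureTable":
        df = pd.read_csv(path, sep="\t")
        registry = [
            c
            for c in df.columns
            if c not in {"drug_a", "drug_b", "label"} and not c.startswith("obs_")
        ]
        df = df.set_index(["drug_a", "drug_b"])
        feats = df[registry].astype(float)
        labels = df["label"].astype(bool)
        observed = df[[f"obs_{f}" for f in registry]].astype(bool)
        observed.columns = registry
        return cls(feats, labels, observed, registry)


def build_feature_table(
    records: Sequence[DrugRecord],
    resources: ResourceBundle,
    registry: Sequence[str] | None = None,
    labels: Mapping[PairKey, bool] | None = None,
    impute: bool = True,
) -> PairFeatureTable:
    """Compute every registry feature for every unordered drug pair.

    Labels default to shared-indication flags derived from the records'
    concept sets. With ``impute=True`` missing cells are median-filled and
    flagged in the mask.
    """
    registry = list(registry or resources.feature_registry or DEFAULT_REGISTRY)
    for feat in registry:
        coll = GENESET_FEATURES.get(feat)
        if coll is not None and coll not in resources.gene_set_collections:
            raise ConfigurationError(f"registry feature {feat!r} needs collection {coll!r}")

    recs = list(records)
    ids = [r.drug_id for r in recs]

    # per-drug precomputation
    memberships: dict[str, dict[str, set[str]]] = {}
    for feat in registry:
        coll = GENESET_FEATURES.get(feat)
        if coll is not None:
            collection = resources.gene_set_collections[coll]
            memberships[feat] = {
                r.drug_id: geneset_membership(r.targets, collection) for r in recs
            }
    ess = resources.essentiality
    gene_corr: pd.DataFrame | None = None
    if "essentiality_corr" in registry and not ess.empty:
        genes = sorted({g for r in recs for g in r.targets} & set(ess.index))
        if genes:
            # pairwise-complete Pearson between target genes, >=3 shared lines
            gene_corr = ess.loc[genes].T.corr(min_periods=3)
    ppi_dist: dict[str, dict[str, int]] = {}
    if "ppi_min_distance" in registry and resources.ppi.number_of_nodes():
        for r in recs:
            srcs = [g for g in r.targets if g in resources.ppi]
            if srcs:
                ppi_dist[r.drug_id] = _multi_source_distances(resources.ppi, srcs)

    index = []
    rows = []
    for i, a in enumerate(recs):
        for b in recs[i + 1 :]:
            pk = PairKey(a.drug_id, b.drug_id)
            ra, rb = (a, b) if pk.drug_a == a.drug_id else (b, a)
            row = {}
            for feat in registry:
                if feat in memberships:
                    row[feat] = jaccard_index(
                        memberships[feat][ra.drug_id], memberships[feat][rb.drug_id]
                    )
                elif feat == "target_jaccard":
                    row[feat] = jaccard_index(ra.targets, rb.targets)
                elif feat == "structure_dice":
                    row[feat] = structure_dice(ra.fingerprint, rb.fingerprint)
                elif feat == "essentiality_corr":
                    row[feat] = _pair_ess_corr(ra.targets, rb.targets, gene_corr)
                elif feat == "ppi_min_distance":
                    row[feat] = _pair_ppi_dist(ra, rb, ppi_dist)
                elif feat == "bioassay_jaccard":
                    row[feat] = bioassay_similarity(
                        resources.bioassay_actives.get(ra.drug_id),
                        resources.bioassay_actives.get(rb.drug_id),
                    )
                else:
                    raise ConfigurationError(f"unknown feature {feat!r}")
            index.append((pk.drug_a, pk.drug_b))
            rows.append(row)

    midx = pd.MultiIndex.from_tuples(index, names=["drug_a", "drug_b"])
    feats = pd.DataFrame(rows, index=midx, columns=registry, dtype=float)
    observed = feats.notna()
    if labels is None:
        concept = {r.drug_id: r.concepts for r in recs}
        lab = pd.Series(
            [bool(concept[a] & concept[b]) for a, b in midx], index=midx, name="label"
        )
    else:
        lab = pd.Series([bool(labels[PairKey(a, b)]) for a, b in midx], index=midx, name="label")
    table = PairFeatureTable(feats, lab, observed, registry)
    if impute:
        table = impute_median(table)
    return table


def _pair_ess_corr(ta: set[str], tb: set[str], gene_corr: pd.DataFrame | None) -> float | None:
    if gene_corr is None:
        return None
    ga = [g for g in ta if g in gene_corr.index]
    gb = [g for g in tb if g in gene_corr.index]
    if not ga or not gb:
        return None
    sub = gene_corr.loc[ga, gb].to_numpy(dtype=float)
    if np.isnan(sub).all():
        return None
    return float(np.nanmean(sub))


def _pair_ppi_dist(ra: DrugRecord, rb: DrugRecord, ppi_dist) -> float | None:
    da = ppi_dist.get(ra.drug_id)
    if da is None:
        return None
    best = None
    for g in rb.targets:
        d = da.get(g)
        if d is not None and (best is None or d < best):
            best = d
    return None if best is None else float(best)


def impute_median(table: PairFeatureTable) -> PairFeatureTable:
    """Replace missing cells with the per-feature median over observed cells.

    A feature with no observed value at all is a configuration error — there
    is nothing to impute from.
    """
    feats = table.features.copy()
    for feat in table.registry:
        col = feats[feat]
        observed = col[table.observed[feat]]
        if col.isna().any():
            if observed.empty:
                raise ConfigurationError(f"feature {feat!r} has no observed values")
            feats[feat] = col.fillna(float(observed.median()))
        elif observed.empty:
            raise ConfigurationError(f"feature {feat!r} has no observed values")
    return PairFeatureTable(feats, table.labels.copy(), table.observed.copy(), list(table.registry))


def ks_screen(table: PairFeatureTable) -> pd.DataFrame:
    """Two-sample two-sided KS test per feature: shared vs not-shared pairs.

    Returns a frame indexed by feature with columns D, pvalue and
    shift_direction (+1 when the shared group's median is larger).
    """
    pos = table.features[table.labels.to_numpy()]
    neg = table.features[~table.labels.to_numpy()]
    if pos.empty or neg.empty:
        raise ValueError("both label groups must be non-empty")
    out = []
    for feat in table.registry:
        res = stats.ks_2samp(pos[feat], neg[feat], alternative="two-sided")
        out.append(
            {
                "feature": feat,
                "D": float(res.statistic),
                "pvalue": float(res.pvalue),
                "shift_direction": int(np.sign(pos[feat].mean() - neg[feat].mean())),
            }
        )
    return pd.DataFrame(out).set_index("feature")


def feature_correlation_matrix(table: PairFeatureTable) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix between features.

    Constant columns produce NaN correlations (flagged, not an error);
    the diagonal is 1 for non-constant features.
    """
    if len(table.features) < 2:
        raise ValueError("need >=2 rows")
    return table.features.corr(method="pearson")
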
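"""End-to-end orchestration: load inputs, featurize, train, score, screen.

Each stage writes one artifact under the run's output directory and a
machine-readable run log records the config hash, seed and package
versions, so two runs with the same config hash produce byte-identical
score tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .classdisease import DiseaseAreaDefinition, screen_classes
from .explain import ablation_deltas, model_feature_importance
from .features import DEFAULT_REGISTRY, PairFeatureTable, build_feature_table, ks_screen
from .indications import IndicationVocabulary, build_groups, filter_connected_drugs
from .io import ConfigurationError, ResourceBundle
from .model import (
    DEFAULT_PARAMS,
    CatnipModel,
    cross_validate,
    evaluate,
    grid_search,
    score_to_probability,
    train,
)
from .network import atc_cross_class_summary, build_network, export_graph, prune
from .synthetic import CohortConfig, generate_cohort

ALL_STAGES = ("featurize", "train", "score", "network", "atc", "classes", "explain")

STAGE_REQUIRES = {
    "featurize": (),
    "train": ("featurize",),
    "score": ("featurize", "train"),
    "network": ("score",),
    "atc": ("network",),
    "classes": ("score",),
    "explain": ("featurize", "train"),
}

STAGE_ARTIFACTS = {
    "featurize": "features.tsv",
    "train": "model.ubj",
    "score": "scores.tsv",
    "network": "network.graphml",
    "atc": "atc_summary.tsv",
    "classes": "class_disease.tsv",
    "explain": "ablation_deltas.tsv",
}


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    drug_table: str
    gene_set_gmts: dict[str, str] = field(default_factory=dict)  # collection -> path
    ppi: str | None = None
    essentiality: str | None = None
    bioassays: str | None = None
    vocabulary: str | None = None
    atc_table: str | None = None
    class_table: str | None = None
    registry: list[str] = field(default_factory=lambda: list(DEFAULT_REGISTRY))
    seed: int = 0
    k_folds: int = 5
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    grid: dict | None = None
    threshold: float = 7.4
    fdr_level: float = 0.1
    class_keywords: list[str] = field(default_factory=lambda: ["inhibitor", "antagonist", "agonist"])
    class_min_size: int = 20
    disease_areas: list[dict] = field(default_factory=list)
    out_dir: str = "catnip_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "out_dir"},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    records = cio.read_drug_table(config.drug_table)
    resources = ResourceBundle(feature_registry=list(config.registry))
    for name, path in config.gene_set_gmts.items():
        resources.gene_set_collections[name] = cio.read_gene_sets_gmt(path)
    if config.ppi:
        resources.ppi = cio.read_ppi_edgelist(config.ppi)
    if config.essentiality:
        resources.essentiality = cio.read_essentiality_matrix(config.essentiality)
    if config.bioassays:
        resources.bioassay_actives = cio.read_bioassay_actives(config.bioassays)
    resources.validate()
    if config.vocabulary:
        vocab = IndicationVocabulary.from_table(config.vocabulary)
        build_groups(records, vocab)
    records = filter_connected_drugs(records)
    return records, resources


def _require(out: Path, stage: str, done: set[str]) -> None:
    for dep in STAGE_REQUIRES[stage]:
        if dep in done:
            continue
        if not (out / STAGE_ARTIFACTS[dep]).exists():
            raise ConfigurationError(f"stage {stage!r} requires {dep!r} to run first")


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> Path:
    """Run the requested stages, writing one artifact per stage plus a run log."""
    stages = list(stages or ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in ALL_STAGES if s in stages]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    done: set[str] = set()

    table: PairFeatureTable | None = None
    model: CatnipModel | None = None
    scores: pd.Series | None = None
    records = None

    def get_table() -> PairFeatureTable:
        nonlocal table
        if table is None:
            table = PairFeatureTable.from_tsv(out / "features.tsv")
        return table

    def get_model() -> CatnipModel:
        nonlocal model
        if model is None:
            model = CatnipModel.load(out / "model.ubj")
        return model

    def get_scores() -> pd.Series:
        nonlocal scores
        if scores is None:
            df = pd.read_csv(out / "scores.tsv", sep="\t").set_index(["drug_a", "drug_b"])
            scores = df["catnip_score"]
        return scores

    for stage in stages:
        _require(out, stage, done)
        if stage == "featurize":
            records, resources = _load_inputs(config)
            table = build_feature_table(records, resources, config.registry)
            table.to_tsv(out / "features.tsv")
            ks_screen(table).to_csv(out / "ks_screen.tsv", sep="\t")
        elif stage == "train":
            t = get_table()
            params = dict(config.params)
            if config.grid:
                params = grid_search(t, config.grid, k=config.k_folds, seed=config.seed)
            model = train(t, params, seed=config.seed)
            model.save(out / "model.ubj")
        elif stage == "score":
            t = get_table()
            cv_scores, folds, _ = cross_validate(
                t, get_model().params, k=config.k_folds, seed=config.seed
            )
            scores = cv_scores
            df = cv_scores.reset_index()
            df["probability"] = score_to_probability(df["catnip_score"])
            df["label"] = t.labels.to_numpy(dtype=int)
            df["fold"] = folds
            df.to_csv(out / "scores.tsv", sep="\t", index=False, float_format="%.10g")
            report = evaluate(cv_scores.to_numpy(), t.labels.to_numpy())
            (out / "cv_report.json").write_text(
                json.dumps(
                    {
                        "auc": report.auc,
                        "auprc": report.auprc,
                        "prevalence": report.prevalence,
                        "fp_rates": {str(k): v for k, v in report.fp_rates.items()},
                    },
                    indent=2,
                )
            )
        elif stage == "network":
            atc = cio.read_memberships(config.atc_table) if config.atc_table else {}
            net = prune(build_network(get_scores(), atc), config.threshold)
            export_graph(net, out / "network.graphml", "graphml")
            export_graph(net, out / "network_edges.tsv", "edgelist")
        elif stage == "atc":
            from .network import read_graph

            net = read_graph(out / "network.graphml")
            atc_cross_class_summary(net).to_csv(out / "atc_summary.tsv", sep="\t", index=False)
        elif stage == "classes":
            if records is None:
                records, _ = _load_inputs(config)
            classes = cio.read_memberships(config.class_table) if config.class_table else {}
            by_class: dict[str, set[str]] = {}
            for drug, names in classes.items():
                for name in names:
                    by_class.setdefault(name, set()).add(drug)
            areas = [DiseaseAreaDefinition(**a) for a in _area_dicts(config.disease_areas)]
            result = screen_classes(
                get_scores(),
                by_class,
                areas,
                records,
                keywords=config.class_keywords,
                min_size=config.class_min_size,
                fdr_level=config.fdr_level,
            )
            result.to_csv(out / "class_disease.tsv", sep="\t", index=False)
        elif stage == "explain":
            t = get_table()
            deltas = ablation_deltas(get_model(), t.features)
            deltas.reset_index().to_csv(
                out / "ablation_deltas.tsv", sep="\t", index=False, float_format="%.6g"
            )
            model_feature_importance(get_model()).rename("importance").to_csv(
                out / "feature_importance.tsv", sep="\t"
            )
        done.add(stage)

    log = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
        "version": __version__,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return out


def _area_dicts(raw: Sequence[dict]) -> list[dict]:
    out = []
    for a in raw:
        d = dict(a)
        for k in ("semantic_types", "keywords", "concepts"):
            if k in d:
                d[k] = set(d[k])
        out.append(d)
    return out


def simulate(config: CohortConfig | None, out_dir: str | Path) -> Path:
    """Generate a synthetic cohort and write its files (wraps the generator)."""
    cohort = generate_cohort(config or CohortConfig(), out_dir=out_dir)
    return Path(out_dir)


def cohort_run_config(cohort_dir: str | Path, out_dir: str | Path, seed: int = 0, **overrides) -> RunConfig:
    """RunConfig pointing at the files emitted by :func:`simulate`."""
    cohort_dir = Path(cohort_dir)
    gmts = {p.stem: str(p) for p in sorted(cohort_dir.glob("*.gmt"))}
    cfg = RunConfig(
        drug_table=str(cohort_dir / "drugs.tsv"),
        gene_set_gmts=gmts,
        ppi=str(cohort_dir / "ppi.tsv"),
        essentiality=str(cohort_dir / "essentiality.csv"),
        bioassays=str(cohort_dir / "bioassays.tsv"),
        vocabulary=str(cohort_dir / "vocabulary.tsv"),
        atc_table=str(cohort_dir / "atc.tsv"),
        class_table=str(cohort_dir / "classes.tsv"),
        seed=seed,
        out_dir=str(out_dir),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
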
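"""Synthetic drug cohorts with planted shared-indication structure.

The generator emulates the statistical regime the pair classifier faces on
real annotation data: drugs cluster into latent disease groups, and two
drugs of the same disease tend to have overlapping targets (drawn from a
disease gene module), overlapping gene-set memberships, similar synthetic
fingerprints (prototype bits plus noise), correlated target essentiality
(a shared per-disease cell-line factor), nearby targets in a
stochastic-block-model interaction network, and overlapping active
bioassays. Fingerprints are synthetic bit sets, not real chemistry — the
pipeline consumes fingerprints agnostically, so chemical realism is not
required for testing. All outputs are deterministic functions of
(config, seed).
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as cio
from .features import DEFAULT_REGISTRY, GENESET_FEATURES, LOWER_IS_SIMILAR, PairFeatureTable
from .indications import IndicationVocabulary, build_groups
from .io import DrugRecord, ResourceBundle

__all__ = ["CohortConfig", "CohortTruth", "Cohort", "generate_cohort", "planted_signal_report"]


@dataclass
class CohortConfig:
    """Tunable knobs of the planted-structure generator.

    ``p_within`` is the probability that a drug's target is drawn from its
    disease gene module rather than the background. ``fingerprint_noise``
    is scaled so that 0 reproduces the disease prototype exactly and 0.5
    yields pure-chance fingerprints (each prototype bit is replaced by a
    uniform random bit with probability ``2 * fingerprint_noise``).
    """

    n_diseases: int = 8
    drugs_per_disease: int = 15
    gene_universe: int = 2000
    module_size: int = 40
    targets_per_drug: int = 4
    p_within: float = 0.8
    fingerprint_len: int = 1024
    prototype_bits: int = 40
    fingerprint_noise: float = 0.15
    collections: tuple[str, ...] = tuple(GENESET_FEATURES.values())
    sets_per_collection: int = 30
    signal_sets_per_disease: int = 2
    set_signal_purity: float = 0.7
    ppi_p_within: float = 0.15
    ppi_p_between: float = 0.002
    n_cell_lines: int = 30
    essentiality_effect: float = 0.6
    assays_per_disease: int = 30
    background_assays: int = 200
    assays_per_drug: int = 10
    multi_indication_fraction: float = 0.1
    missing_fraction: float = 0.1
    class_size: int = 20
    class_in_fraction: float = 0.25
    planted_class_in_fraction: float = 0.6
    planted_disease: int = 0
    seed: int = 1

    def validate(self) -> None:
        probs = [
            self.p_within,
            self.fingerprint_noise,
            self.ppi_p_within,
            self.ppi_p_between,
            self.multi_indication_fraction,
            self.missing_fraction,
            self.class_in_fraction,
            self.planted_class_in_fraction,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        counts = [
            self.n_diseases,
            self.drugs_per_disease,
            self.gene_universe,
            self.module_size,
            self.targets_per_drug,
            self.fingerprint_len,
            self.prototype_bits,
            self.n_cell_lines,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("counts must be positive")
        if self.module_size * self.n_diseases > self.gene_universe:
            raise ValueError("disease modules exceed the gene universe")
        if not (0 <= self.planted_disease < self.n_diseases):
            raise ValueError("planted_disease out of range")


@dataclass
class CohortTruth:
    """Ground truth of the planted structure, consistent with emitted files."""

    assignments: dict[str, list[int]]  # drug -> latent diseases
    modules: dict[int, list[str]]  # disease -> gene module
    concepts: dict[int, str]  # disease -> concept id
    atc: dict[int, str]  # disease -> ATC level-1 letter
    class_diseases: dict[str, int]  # class name -> its disease
    planted_class: str
    planted_area: str

    def same_disease(self, drug_a: str, drug_b: str) -> bool:
        return bool(set(self.assignments[drug_a]) & set(self.assignments[drug_b]))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class Cohort:
    """In-memory synthetic cohort: records, resources and ground truth."""

    records: list[DrugRecord]
    resources: ResourceBundle
    vocabulary: IndicationVocabulary
    class_memberships: dict[str, set[str]]
    atc_codes: dict[str, set[str]]
    truth: CohortTruth
    config: CohortConfig

    def write(self, out_dir: str | Path) -> Path:
        """Emit the cohort in the pipeline's external file formats + truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_drug_table(self.records, out / "drugs.tsv")
        for name, coll in sorted(self.resources.gene_set_collections.items()):
            cio.write_gene_sets_gmt(coll, out / f"{name}.gmt")
        cio.write_ppi_edgelist(self.resources.ppi, out / "ppi.tsv")
        cio.write_essentiality_matrix(self.resources.essentiality, out / "essentiality.csv")
        cio.write_bioassay_actives(self.resources.bioassay_actives, out / "bioassays.tsv")
        cio.write_memberships(self.atc_codes, out / "atc.tsv")
        inverted = {
            drug: {c for c, members in self.class_memberships.items() if drug in members}
            for members in self.class_memberships.values()
            for drug in members
        }
        cio.write_memberships(inverted, out / "classes.tsv")
        vocab_rows = sorted(self.vocabulary.entries.items())
        with open(out / "vocabulary.tsv", "w") as fh:
            fh.write("raw_term\tconcept\n")
            for raw, concept in vocab_rows:
                fh.write(f"{raw}\t{concept}\n")
        (out / "truth.json").write_text(self.truth.to_json())
        return out


def generate_cohort(config: CohortConfig | None = None, out_dir: str | Path | None = None) -> Cohort:
    """Generate a full cohort; optionally also write it to *out_dir*.

    Same-disease pairs have, in expectation, higher target/gene-set/
    structure/essentiality/bioassay similarity and lower interaction-network
    distance than cross-disease pairs; a configurable fraction of drugs
    carries a second indication, one ATC letter is assigned per disease,
    and one mechanism-named drug class is built per disease, with the
    planted class enriched for its disease.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = np.array([f"G{i:05d}" for i in range(cfg.gene_universe)])
    modules = {
        d: sorted(genes[d * cfg.module_size : (d + 1) * cfg.module_size])
        for d in range(cfg.n_diseases)
    }
    module_arr = {d: np.array(m) for d, m in modules.items()}

    # --- drugs: ids, latent disease(s), targets, fingerprints -------------
    drug_ids = [
        f"D{d:02d}{j:02d}" for d in range(cfg.n_diseases) for j in range(cfg.drugs_per_disease)
    ]
    primary = {
        did: d
        for d, dids in zip(
            range(cfg.n_diseases),
            [
                drug_ids[d * cfg.drugs_per_disease : (d + 1) * cfg.drugs_per_disease]
                for d in range(cfg.n_diseases)
            ],
        )
        for did in dids
    }
    assignments: dict[str, list[int]] = {}
    for did in drug_ids:
        ds = [primary[did]]
        if cfg.n_diseases > 1 and rng.random() < cfg.multi_indication_fraction:
            other = int(rng.integers(cfg.n_diseases - 1))
            if other >= ds[0]:
                other += 1
            ds.append(other)
        assignments[did] = ds

    targets: dict[str, set[str]] = {}
    for did in drug_ids:
        d = primary[did]
        tset: set[str] = set()
        while len(tset) < cfg.targets_per_drug:
            if rng.random() < cfg.p_within:
                tset.add(str(rng.choice(module_arr[d])))
            else:
                tset.add(str(rng.choice(genes)))
        targets[did] = tset

    prototypes = {
        d: rng.choice(cfg.fingerprint_len, size=cfg.prototype_bits, replace=False)
        for d in range(cfg.n_diseases)
    }
    replace_p = min(1.0, 2.0 * cfg.fingerprint_noise)
    fingerprints: dict[str, frozenset[int]] = {}
    for did in drug_ids:
        bits = prototypes[primary[did]].copy()
        flip = rng.random(len(bits)) < replace_p
        bits[flip] = rng.integers(0, cfg.fingerprint_len, size=int(flip.sum()))
        fingerprints[did] = frozenset(int(b) for b in bits)

    # --- indications & vocabulary ----------------------------------------
    concepts = {d: f"DIS{d}" for d in range(cfg.n_diseases)}
    synonyms = {
        d: [f"disease {d} syndrome", f"disorder of organ {d}"] for d in range(cfg.n_diseases)
    }
    vocab = IndicationVocabulary.from_pairs(
        [(syn, concepts[d]) for d, syns in synonyms.items() for syn in syns],
        concept_names={concepts[d]: f"synthetic disease area {d}" for d in range(cfg.n_diseases)},
    )
    qualifiers = ["", "", "severe ", "mild "]
    raw_indications = {
        did: [
            qualifiers[int(rng.integers(len(qualifiers)))] + synonyms[d][int(rng.integers(2))]
            for d in assignments[did]
        ]
        for did in drug_ids
    }

    # --- ATC letters and drug classes -------------------------------------
    letters = string.ascii_uppercase
    atc_letter = {d: letters[d % 26] for d in range(cfg.n_diseases)}
    atc_codes = {did: {atc_letter[d] for d in assignments[did]} for did in drug_ids}

    class_memberships: dict[str, set[str]] = {}
    class_diseases: dict[str, int] = {}
    all_ids = np.array(drug_ids)
    for d in range(cfg.n_diseases):
        name = f"pathway {d} inhibitors"
        frac = cfg.planted_class_in_fraction if d == cfg.planted_disease else cfg.class_in_fraction
        # leave some disease drugs outside the class: the class-disease screen
        # compares class members against disease-approved partner drugs, and a
        # class that swallows its whole disease has no partners left
        size = min(cfg.class_size, len(drug_ids))
        n_in = int(round(size * frac))
        n_in = min(n_in, cfg.drugs_per_disease - max(1, cfg.drugs_per_disease // 5))
        in_pool = np.array([did for did in drug_ids if primary[did] == d])
        out_pool = np.array([did for did in drug_ids if primary[did] != d])
        n_out = min(size - n_in, len(out_pool))
        members = set(rng.choice(in_pool, size=n_in, replace=False))
        members |= set(rng.choice(out_pool, size=n_out, replace=False))
        class_memberships[name] = {str(m) for m in members}
        class_diseases[name] = d

    # --- gene-set collections ---------------------------------------------
    collections: dict[str, dict[str, set[str]]] = {}
    for cname in cfg.collections:
        coll: dict[str, set[str]] = {}
        idx = 0
        for d in range(cfg.n_diseases):
            for _ in range(cfg.signal_sets_per_disease):
                size = int(rng.integers(10, 51))
                n_sig = int(round(size * cfg.set_signal_purity))
                n_sig = min(n_sig, cfg.module_size)
                members = set(rng.choice(module_arr[d], size=n_sig, replace=False))
                members |= set(rng.choice(genes, size=size - n_sig, replace=False))
                coll[f"{cname}_set{idx:03d}"] = {str(g) for g in members}
                idx += 1
        while idx < cfg.sets_per_collection:
            size = int(rng.integers(10, 51))
            coll[f"{cname}_set{idx:03d}"] = {
                str(g) for g in rng.choice(genes, size=size, replace=False)
            }
            idx += 1
        collections[cname] = coll

    # --- PPI: stochastic block model aligned to modules --------------------
    sizes = [cfg.module_size] * cfg.n_diseases + [cfg.gene_universe - cfg.module_size * cfg.n_diseases]
    n_blocks = len(sizes)
    p = np.full((n_blocks, n_blocks), cfg.ppi_p_between)
    for d in range(cfg.n_diseases):
        p[d, d] = cfg.ppi_p_within
    sbm_seed = int(rng.integers(2**31 - 1))
    sbm = nx.stochastic_block_model(sizes, p.tolist(), seed=sbm_seed)
    order = np.concatenate([module_arr[d] for d in range(cfg.n_diseases)] + [
        genes[cfg.module_size * cfg.n_diseases :]
    ])
    ppi = nx.relabel_nodes(sbm, {i: str(order[i]) for i in range(cfg.gene_universe)})
    ppi = nx.Graph(ppi)  # plain graph, drop SBM bookkeeping
    ppi.graph.clear()

    # --- essentiality matrix ----------------------------------------------
    cell_lines = [f"CL{j:02d}" for j in range(cfg.n_cell_lines)]
    ess = rng.standard_normal((cfg.gene_universe, cfg.n_cell_lines))
    r = cfg.essentiality_effect
    for d in range(cfg.n_diseases):
        factor = rng.standard_normal(cfg.n_cell_lines)
        rows = slice(d * cfg.module_size, (d + 1) * cfg.module_size)
        ess[rows] = np.sqrt(r) * factor + np.sqrt(1 - r) * ess[rows]
    if cfg.missing_fraction > 0:
        mask = rng.random(ess.shape) < cfg.missing_fraction
        ess[mask] = np.nan
    essentiality = pd.DataFrame(ess, index=list(genes), columns=cell_lines)

    # --- bioassays ----------------------------------------------------------
    disease_assays = {
        d: [f"A{d:02d}{j:03d}" for j in range(cfg.assays_per_disease)]
        for d in range(cfg.n_diseases)
    }
    bg_assays = [f"ABG{j:03d}" for j in range(cfg.background_assays)]
    bioassays: dict[str, set[str]] = {}
    for did in drug_ids:
        pool_in = disease_assays[primary[did]]
        chosen: set[str] = set()
        while len(chosen) < cfg.assays_per_drug:
            if rng.random() < cfg.p_within:
                chosen.add(pool_in[int(rng.integers(len(pool_in)))])
            else:
                chosen.add(bg_assays[int(rng.integers(len(bg_assays)))])
        bioassays[did] = chosen

    # --- per-resource missingness ------------------------------------------
    def drop_fraction(ids: list[str]) -> set[str]:
        n_drop = int(round(cfg.missing_fraction * len(ids)))
        return set(rng.choice(np.array(ids), size=n_drop, replace=False)) if n_drop else set()

    no_fp = drop_fraction(drug_ids)
    no_assay = drop_fraction(drug_ids)
    for did in no_assay:
        bioassays.pop(did, None)

    records = [
        DrugRecord(
            drug_id=did,
            fingerprint=None if did in no_fp else fingerprints[did],
            targets=targets[did],
            raw_indications=raw_indications[did],
            atc_codes=atc_codes[did],
            drug_classes={c for c, m in class_memberships.items() if did in m},
        )
        for did in drug_ids
    ]
    build_groups(records, vocab)  # fill concepts through the standard path

    resources = ResourceBundle(
        gene_set_collections=collections,
        ppi=ppi,
        essentiality=essentiality,
        bioassay_actives=bioassays,
        feature_registry=list(DEFAULT_REGISTRY),
    )
    resources.validate()
    truth = CohortTruth(
        assignments=assignments,
        modules={d: [str(g) for g in m] for d, m in modules.items()},
        concepts=concepts,
        atc=atc_letter,
        class_diseases=class_diseases,
        planted_class=f"pathway {cfg.planted_disease} inhibitors",
        planted_area=f"area {cfg.planted_disease}",
    )
    cohort = Cohort(records, resources, vocab, class_memberships, atc_codes, truth, cfg)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def planted_signal_report(table: PairFeatureTable, truth: CohortTruth) -> pd.DataFrame:
    """KS separation per feature between same-disease and cross-disease pairs.

    Grouping uses the generator's latent disease assignments (not the noisy
    shared-indication labels). ``expected_direction`` is -1 for features
    where similarity is expressed as a smaller value (network distance),
    +1 otherwise; ``direction`` is the observed sign of the median
    difference (same-disease minus cross-disease).
    """
    from scipy import stats

    same = np.array([truth.same_disease(a, b) for a, b in table.features.index])
    rows = []
    for feat in table.registry:
        x = table.features[feat].to_numpy()
        res = stats.ks_2samp(x[same], x[~same])
        rows.append(
            {
                "feature": feat,
                "D": float(res.statistic),
                "pvalue": float(res.pvalue),
                "direction": int(np.sign(np.mean(x[same]) - np.mean(x[~same]))),
                "expected_direction": -1 if feat in LOWER_IS_SIMILAR else 1,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
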
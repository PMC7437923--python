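"""Domain types and readers/writers for every external format the pipeline touches.

The pipeline consumes five kinds of external data: a delimited drug table,
GMT gene-set collections, a protein-interaction edge list, a gene x cell-line
essentiality matrix (CSV) and a two-column table of active bioassay calls.
All gene identifiers are treated as upper-cased symbols; callers must
pre-harmonize identifiers (no mapping service is provided).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "FormatError",
    "IntegrityError",
    "ConfigurationError",
    "DrugRecord",
    "PairKey",
    "ResourceBundle",
    "ColumnMap",
    "read_drug_table",
    "write_drug_table",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_ppi_edgelist",
    "write_ppi_edgelist",
    "read_essentiality_matrix",
    "write_essentiality_matrix",
    "read_bioassay_actives",
    "write_bioassay_actives",
    "read_memberships",
    "write_memberships",
]

#: tokens interpreted as a missing numeric value
MISSING_TOKENS = {"", "NA"}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class IntegrityError(ValueError):
    """Parsed content violates a uniqueness/consistency invariant."""


class ConfigurationError(ValueError):
    """A registry, config or resource reference is inconsistent."""


@dataclass
class DrugRecord:
    """One small molecule with its structure, targets and indications.

    ``structure`` is either a SMILES string (``smiles``) or a precomputed
    binary fingerprint represented as a frozen set of on-bit indices
    (``fingerprint``); both may be absent, in which case the structural
    feature falls back to imputation downstream.
    """

    drug_id: str
    smiles: str | None = None
    fingerprint: frozenset[int] | None = None
    targets: set[str] = field(default_factory=set)
    raw_indications: list[str] = field(default_factory=list)
    concepts: set[str] = field(default_factory=set)
    atc_codes: set[str] = field(default_factory=set)
    drug_classes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.fingerprint is not None:
            fp = frozenset(int(b) for b in self.fingerprint)
            if any(b < 0 for b in fp):
                raise IntegrityError(f"{self.drug_id}: negative fingerprint bit")
            self.fingerprint = fp
        self.targets = {t.upper() for t in self.targets}


@dataclass(frozen=True, order=True)
class PairKey:
    """Canonical (lexicographically ordered) unordered drug pair."""

    drug_a: str
    drug_b: str

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise IntegrityError(f"self-pair forbidden: {self.drug_a}")
        if self.drug_a > self.drug_b:
            a, b = self.drug_b, self.drug_a
            object.__setattr__(self, "drug_a", a)
            object.__setattr__(self, "drug_b", b)

    def __iter__(self):
        return iter((self.drug_a, self.drug_b))


@dataclass
class ResourceBundle:
    """Shared annotation resources consumed by the feature builder."""

    gene_set_collections: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    ppi: nx.Graph = field(default_factory=nx.Graph)
    essentiality: pd.DataFrame = field(default_factory=pd.DataFrame)
    bioassay_actives: dict[str, set[str]] = field(default_factory=dict)
    feature_registry: list[str] = field(default_factory=list)

    def validate(self) -> None:
        from .features import GENESET_FEATURES

        for feat in self.feature_registry:
            coll = GENESET_FEATURES.get(feat)
            if coll is not None and coll not in self.gene_set_collections:
                raise ConfigurationError(
                    f"feature {feat!r} references missing collection {coll!r}"
                )
        if any(self.ppi.has_edge(n, n) for n in self.ppi):
            raise IntegrityError("PPI graph contains self-loops")
        if not self.essentiality.empty and self.essentiality.index.has_duplicates:
            raise IntegrityError("essentiality matrix has duplicate gene rows")


# ---------------------------------------------------------------------------
# drug table


@dataclass
class ColumnMap:
    """Maps logical fields to column names of a delimited drug table."""

    drug_id: str = "drug_id"
    smiles: str = "smiles"
    fingerprint: str = "fingerprint"
    targets: str = "targets"
    indications: str = "indications"
    atc_codes: str = "atc_codes"
    drug_classes: str = "drug_classes"


def _split_set(cell: str) -> list[str]:
    return [tok.strip() for tok in cell.split(";") if tok.strip()]


def _sniff_delim(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_drug_table(
    path: str | Path, dialect: ColumnMap | None = None
) -> list[DrugRecord]:
    """Read a delimited (TSV/CSV) drug table into :class:`DrugRecord` rows.

    Mandatory column: drug id. Optional columns: SMILES, fingerprint
    (semicolon-separated bit indices), targets, indications, ATC codes and
    drug classes (all semicolon-separated). Empty optional cells yield empty
    sets; duplicate drug ids are an integrity error.
    """
    cmap = dialect or ColumnMap()
    df = pd.read_csv(path, sep=_sniff_delim(path), dtype=str, keep_default_na=False)
    if cmap.drug_id not in df.columns:
        raise FormatError(f"missing mandatory column {cmap.drug_id!r}")
    records: list[DrugRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        drug_id = row[cmap.drug_id].strip()
        if not drug_id:
            raise FormatError("empty drug id")
        if drug_id in seen:
            raise IntegrityError(f"duplicate drug id {drug_id!r}")
        seen.add(drug_id)

        def cell(name: str) -> str:
            return str(row[name]).strip() if name in df.columns else ""

        fp_cell = cell(cmap.fingerprint)
        try:
            fingerprint = (
                frozenset(int(b) for b in _split_set(fp_cell)) if fp_cell else None
            )
        except ValueError as exc:
            raise FormatError(f"{drug_id}: bad fingerprint bit ({exc})") from None
        records.append(
            DrugRecord(
                drug_id=drug_id,
                smiles=cell(cmap.smiles) or None,
                fingerprint=fingerprint,
                targets=set(_split_set(cell(cmap.targets))),
                raw_indications=_split_set(cell(cmap.indications)),
                atc_codes=set(_split_set(cell(cmap.atc_codes))),
                drug_classes=set(_split_set(cell(cmap.drug_classes))),
            )
        )
    return records


def write_drug_table(
    records: Iterable[DrugRecord], path: str | Path, dialect: ColumnMap | None = None
) -> None:
    cmap = dialect or ColumnMap()
    rows = []
    for r in records:
        rows.append(
            {
                cmap.drug_id: r.drug_id,
                cmap.smiles: r.smiles or "",
                cmap.fingerprint: ";".join(str(b) for b in sorted(r.fingerprint))
                if r.fingerprint is not None
                else "",
                cmap.targets: ";".join(sorted(r.targets)),
                cmap.indications: ";".join(r.raw_indications),
                cmap.atc_codes: ";".join(sorted(r.atc_codes)),
                cmap.drug_classes: ";".join(sorted(r.drug_classes)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_sniff_delim(path), index=False)


# ---------------------------------------------------------------------------
# GMT gene-set collections


def read_gene_sets_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read one GMT collection: name, description, then tab-separated genes.

    Genes are upper-cased, empty sets are dropped and duplicate set names
    are a format error.
    """
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0]
            if name in collection:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = {g.strip().upper() for g in fields[2:] if g.strip()}
            if genes:
                collection[name] = genes
    return collection


def write_gene_sets_gmt(collection: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            genes = sorted(collection[name])
            if genes:
                fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# PPI graph


def read_ppi_edgelist(path: str | Path) -> nx.Graph:
    """Read a two-column (or SIF) edge list into an undirected simple graph.

    Duplicate edges collapse, self-loops are removed, and a blank file yields
    an empty graph rather than an error.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 3:  # SIF: source relation target
                a, b = fields[0], fields[2]
            elif len(fields) == 2:
                a, b = fields
            else:
                raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns")
            a, b = a.upper(), b.upper()
            if a != b:
                graph.add_edge(a, b)
    return graph


def write_ppi_edgelist(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# essentiality matrix


def read_essentiality_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x cell-line CSV of real-valued essentiality scores.

    First column holds gene symbols; "NA" or empty cells are missing.
    Non-numeric cells and duplicate gene rows are errors.
    """
    df = pd.read_csv(path, index_col=0, na_values=list(MISSING_TOKENS), keep_default_na=False)
    df.index = df.index.astype(str).str.upper()
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise IntegrityError(f"duplicate gene row {dup!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric essentiality value: {exc}") from None
    return df


def write_essentiality_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, na_rep="NA")


# ---------------------------------------------------------------------------
# bioassay actives


def read_bioassay_actives(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (drug_id, assay_id) table of active calls.

    One row per active call; per-drug sets are deduplicated and drugs absent
    from the file simply have no entry (their feature is imputed downstream).
    """
    actives: dict[str, set[str]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, fields in enumerate(reader, 1):
            if not fields or not any(f.strip() for f in fields):
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            drug, assay = fields[0].strip(), fields[1].strip()
            actives.setdefault(drug, set()).add(assay)
    return actives


def write_bioassay_actives(actives: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for drug in sorted(actives):
            for assay in sorted(actives[drug]):
                fh.write(f"{drug}\t{assay}\n")


# ---------------------------------------------------------------------------
# generic two-column membership tables (ATC assignments, drug classes)


def read_memberships(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (drug_id, label) file into drug -> label set."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            out.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return out


def write_memberships(memberships: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for drug in sorted(memberships):
            for label in sorted(memberships[drug]):
                fh.write(f"{drug}\t{label}\n")
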
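"""Standardize raw indication strings to disease concepts and derive pair labels.

Free-text indications ("Advanced Prostate Carcinoma", "carcinoma of the
prostate") are collapsed onto standardized disease concepts by lexical
normalization followed by lookup in a synonym vocabulary; a full NLP
concept mapper is deliberately out of scope — the mapping is data, supplied
as a table. Two drugs share an indication when their concept sets
intersect; drugs sharing no indication with any other drug are dropped
before training.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import DrugRecord, FormatError, PairKey

__all__ = [
    "UNMAPPED",
    "DEFAULT_QUALIFIER_STOPLIST",
    "IndicationVocabulary",
    "IndicationGroups",
    "normalize_text",
    "normalize_term",
    "build_groups",
    "shared_indication_labels",
    "filter_connected_drugs",
    "load_example_vocabulary",
    "load_example_records",
]

#: sentinel returned for terms absent from the vocabulary
UNMAPPED = "<UNMAPPED>"

#: leading severity/stage qualifiers stripped before lookup
DEFAULT_QUALIFIER_STOPLIST = ("advanced", "severe", "mild", "moderate")

_PUNCT_RE = re.compile(r"[^\w\s]")
_WS_RE = re.compile(r"\s+")


def normalize_text(raw: str) -> str:
    """Lowercase, strip punctuation (incl. unicode apostrophes), collapse whitespace."""
    text = unicodedata.normalize("NFKD", raw).lower()
    text = _PUNCT_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


def _strip_qualifiers(text: str, stoplist: Sequence[str]) -> str:
    words = text.split()
    while words and words[0] in stoplist:
        words = words[1:]
    return " ".join(words)


@dataclass
class IndicationVocabulary:
    """Many-to-one mapping from normalized raw terms to concept identifiers."""

    entries: dict[str, str] = field(default_factory=dict)
    concept_names: dict[str, str] = field(default_factory=dict)
    qualifier_stoplist: Sequence[str] = DEFAULT_QUALIFIER_STOPLIST

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        concept_names: dict[str, str] | None = None,
        qualifier_stoplist: Sequence[str] = DEFAULT_QUALIFIER_STOPLIST,
    ) -> "IndicationVocabulary":
        """Build a vocabulary from (raw term, concept id) pairs.

        Keys are stored under the same normalization used at lookup time, so
        synonyms differing only in case/punctuation/leading qualifiers
        collapse onto one entry.
        """
        vocab = cls(qualifier_stoplist=tuple(qualifier_stoplist))
        names = dict(concept_names or {})
        for raw, concept in pairs:
            key = _strip_qualifiers(normalize_text(raw), vocab.qualifier_stoplist)
            if not key:
                continue
            existing = vocab.entries.get(key)
            if existing is not None and existing != concept:
                raise FormatError(
                    f"term {raw!r} maps to both {existing!r} and {concept!r}"
                )
            vocab.entries[key] = concept
            names.setdefault(concept, concept)
        vocab.concept_names = names
        return vocab

    @classmethod
    def from_table(cls, path: str | Path, **kwargs) -> "IndicationVocabulary":
        """Read a two-column delimited (raw term, concept id) vocabulary file."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.shape[1] < 2:
            raise FormatError("vocabulary table needs >=2 columns")
        return cls.from_pairs(df.iloc[:, :2].itertuples(index=False, name=None), **kwargs)


@dataclass
class IndicationGroups:
    """Concept id -> set of drug ids approved/indicated for that concept."""

    groups: dict[str, set[str]] = field(default_factory=dict)

    def __getitem__(self, concept: str) -> set[str]:
        return self.groups[concept]


def normalize_term(raw: str, vocab: IndicationVocabulary) -> str:
    """Map a raw indication string to a concept id, or :data:`UNMAPPED`.

    Normalization: lowercase, strip punctuation, collapse whitespace, then
    drop leading severity qualifiers from the vocabulary's stop-list.
    Deterministic; unknown terms return the sentinel rather than being
    silently dropped.
    """
    key = _strip_qualifiers(normalize_text(raw), vocab.qualifier_stoplist)
    return vocab.entries.get(key, UNMAPPED)


def build_groups(
    records: Iterable[DrugRecord], vocab: IndicationVocabulary
) -> IndicationGroups:
    """Fill each record's concept set and return concept -> unique drug sets.

    Idempotent and permutation-invariant; unmapped raw terms contribute no
    concept (callers can audit them via :func:`normalize_term`).
    """
    groups: dict[str, set[str]] = {}
    for rec in records:
        concepts = set()
        for raw in rec.raw_indications:
            concept = normalize_term(raw, vocab)
            if concept != UNMAPPED:
                concepts.add(concept)
        rec.concepts = concepts
        for concept in concepts:
            groups.setdefault(concept, set()).add(rec.drug_id)
    return IndicationGroups(groups)


def shared_indication_labels(records: Sequence[DrugRecord]) -> dict[PairKey, bool]:
    """Label every unordered drug pair: True iff concept sets intersect."""
    labels: dict[PairKey, bool] = {}
    recs = list(records)
    for i, a in enumerate(recs):
        for b in recs[i + 1 :]:
            labels[PairKey(a.drug_id, b.drug_id)] = bool(a.concepts & b.concepts)
    return labels


def filter_connected_drugs(records: Sequence[DrugRecord]) -> list[DrugRecord]:
    """Keep exactly the drugs that share >=1 indication with another drug."""
    keep: set[str] = set()
    labels = shared_indication_labels(records)
    for pair, shared in labels.items():
        if shared:
            keep.update(pair)
    return [r for r in records if r.drug_id in keep]


# ---------------------------------------------------------------------------
# bundled example fixture: a small published-style synonym table in which
# each raw DrugBank-style indication string carries a source indication id,
# a standardized concept, and the list of drugs annotated with it.


def _example_table() -> pd.DataFrame:
    with _ilres.files("catnip.data").joinpath("indication_synonyms.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def load_example_vocabulary(level: str = "concept") -> IndicationVocabulary:
    """Load the bundled example vocabulary.

    ``level="concept"`` maps raw strings to standardized concepts (synonyms
    merge); ``level="indication_id"`` maps each raw string to its source
    indication id (no merging), which is useful for auditing per-source-id
    drug counts.
    """
    df = _example_table()
    if level == "concept":
        pairs = [(r.raw_indication, r.concept) for r in df.itertuples()]
        # the concept's own name must resolve to itself
        pairs += [(r.concept, r.concept) for r in df.itertuples()]
    elif level == "indication_id":
        # source ids are distinct even when names differ only by a severity
        # qualifier, so qualifier stripping is disabled at this granularity
        pairs = [(r.raw_indication, r.indication_id) for r in df.itertuples()]
        return IndicationVocabulary.from_pairs(pairs, qualifier_stoplist=())
    else:
        raise ValueError(f"unknown level {level!r}")
    return IndicationVocabulary.from_pairs(pairs)


def load_example_records() -> list[DrugRecord]:
    """Drug records derived from the bundled synonym table.

    Note: the source table's "Moderate Acne vulgaris" row prints a drug
    count of 3 but lists four drugs; the bundled fixture preserves the
    four-drug list as printed.
    """
    df = _example_table()
    by_drug: dict[str, list[str]] = {}
    for row in df.itertuples():
        for drug in row.drugs.split(";"):
            drug = drug.strip()
            if drug:
                by_drug.setdefault(drug, []).append(row.raw_indication)
    return [
        DrugRecord(drug_id=d, raw_indications=inds) for d, inds in sorted(by_drug.items())
    ]
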
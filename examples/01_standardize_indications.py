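"""Standardize free-text indications and count drugs per disease concept.

Raw indication strings differ in case, punctuation and severity qualifiers
("Advanced Prostate Carcinoma" vs "carcinoma of the prostate"). The
bundled synonym vocabulary maps them onto standardized concepts so that
drugs treating the same disease can be recognized as such.
"""

from catnip.indications import (
    build_groups,
    load_example_records,
    load_example_vocabulary,
    normalize_term,
)

vocab = load_example_vocabulary("concept")
records = load_example_records()

for raw in ("Advanced Prostate Carcinoma", "Paget’s Disease of Bone", "Severe Acne"):
    print(f"{raw!r:40s} -> {normalize_term(raw, vocab)!r}")

groups = build_groups(records, vocab)
print("\ndrugs per standardized concept (union over synonym spellings):")
for concept, drugs in sorted(groups.groups.items()):
    print(f"  {concept:32s} {len(drugs):2d} drugs")
# e.g. 'Paget Disease' shows 5 drugs: two raw spellings with 4 + 1 drugs merge.
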
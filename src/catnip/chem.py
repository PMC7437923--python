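"""Pluggable fingerprint providers for drugs supplied as SMILES.

A provider maps {drug_id: smiles} to {drug_id: frozenset of on-bit
indices}. The structural feature consumes bit sets agnostically, so any
fingerprint dialect plugs in; two providers are bundled — an RDKit
atom-pair provider and a ChemmineR atom-pair provider (subprocess to
Rscript) matching the dialect some published similarity values were
computed with.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path
from typing import Callable, Mapping

FingerprintProvider = Callable[[Mapping[str, str]], dict[str, frozenset[int]]]

__all__ = [
    "FingerprintProvider",
    "rdkit_atom_pair_fingerprints",
    "chemminer_atom_pair_fingerprints",
    "attach_fingerprints",
]


def rdkit_atom_pair_fingerprints(
    smiles: Mapping[str, str], n_bits: int = 1024
) -> dict[str, frozenset[int]]:
    """Folded atom-pair fingerprints via RDKit (bit sets of on-bit indices)."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=n_bits)
    out: dict[str, frozenset[int]] = {}
    for drug_id, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"{drug_id}: unparseable SMILES {smi!r}")
        out[drug_id] = frozenset(gen.GetFingerprint(mol).GetOnBits())
    return out


_R_SCRIPT = """
suppressMessages(library(ChemmineR))
args <- commandArgs(trailingOnly=TRUE)
tab <- read.delim(args[1], header=FALSE, stringsAsFactors=FALSE)
smis <- setNames(tab$V2, tab$V1)
apset <- sdf2ap(smiles2sdf(smis))
fpset <- desc2fp(apset, descnames=as.integer(args[3]), type="FPset")
m <- as.matrix(fpset)
con <- file(args[2], "w")
for (i in seq_len(nrow(m))) {
  bits <- which(m[i, ] == 1) - 1
  cat(rownames(m)[i], paste(bits, collapse=","), "\\n", sep="\\t", file=con)
}
close(con)
"""


def chemminer_atom_pair_fingerprints(
    smiles: Mapping[str, str], n_bits: int = 1024, rscript: str = "Rscript"
) -> dict[str, frozenset[int]]:
    """Atom-pair fingerprints in ChemmineR's dialect, via an Rscript subprocess.

    Requires R with the ChemmineR/ChemmineOB packages on PATH. Bit indices
    are 0-based positions in the folded ``n_bits`` fingerprint.
    """
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        infile, outfile, script = tmp / "smiles.tsv", tmp / "bits.tsv", tmp / "fp.R"
        infile.write_text("".join(f"{d}\t{s}\n" for d, s in smiles.items()))
        script.write_text(_R_SCRIPT)
        subprocess.run(
            [rscript, str(script), str(infile), str(outfile), str(n_bits)],
            check=True,
            capture_output=True,
            text=True,
        )
        out: dict[str, frozenset[int]] = {}
        for line in outfile.read_text().splitlines():
            drug_id, bits = line.split("\t")[:2]
            out[drug_id] = frozenset(int(b) for b in bits.split(",") if b.strip())
        return out


def attach_fingerprints(records, provider: FingerprintProvider = rdkit_atom_pair_fingerprints) -> None:
    """Fill missing fingerprints from SMILES in place using *provider*."""
    todo = {r.drug_id: r.smiles for r in records if r.fingerprint is None and r.smiles}
    if not todo:
        return
    fps = provider(todo)
    for r in records:
        if r.drug_id in fps:
            r.fingerprint = fps[r.drug_id]
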
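"""Structural Dice similarity from SMILES via pluggable fingerprint providers.

Fingerprints enter the pipeline as plain bit sets, so the dialect is a
provider choice: the RDKit atom-pair provider needs only Python; the
ChemmineR provider (Rscript subprocess) reproduces the dialect and add-one
similarity convention of that reference implementation, under which
tamoxifen vs anastrozole - structurally dissimilar drugs that both treat
breast cancer - scores 0.372.
"""

from catnip.chem import chemminer_atom_pair_fingerprints, rdkit_atom_pair_fingerprints
from catnip.features import structure_dice

smiles = {
    "tamoxifen": "CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1",
    "anastrozole": "CC(C)(C#N)c1cc(cc(c1)C(C)(C)C#N)Cn1cncn1",
}

fps = rdkit_atom_pair_fingerprints(smiles, n_bits=1024)
print("RDKit atom-pair Dice:",
      round(structure_dice(fps["tamoxifen"], fps["anastrozole"]), 3))

try:
    fps = chemminer_atom_pair_fingerprints(smiles, n_bits=1024)
    plain = structure_dice(fps["tamoxifen"], fps["anastrozole"])
    smoothed = structure_dice(fps["tamoxifen"], fps["anastrozole"], add_one=True)
    print(f"ChemmineR atom-pair Dice: {plain:.3f} (plain), {smoothed:.3f} (add-one smoothed)")
except Exception as exc:
    print(f"ChemmineR provider unavailable ({exc}); install R + ChemmineR to run it")
# The two dialects disagree in absolute value - which is why the provider
# is pluggable and fingerprints are treated as opaque bit sets.
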
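"""The three drug-similarity channels on a handful of real molecules.

Fingerprints come from SMILES via the optional rdkit adapter; interaction
partners and side effects are illustrative. Each channel reduces to
intersection-over-union on sets.
"""

from atcpred import DrugRecord, build_similarity_matrix, fingerprints_from_smiles

smiles = [
    ("aspirin", "CC(=O)OC1=CC=CC=C1C(=O)O"),
    ("salicylic_acid", "OC(=O)C1=CC=CC=C1O"),
    ("ibuprofen", "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O"),
    ("caffeine", "CN1C=NC2=C1C(=O)N(C)C(=O)N2C"),
]
records, failures = fingerprints_from_smiles(smiles, radius=2, n_bits=1024)
assert not failures

extras = {
    "aspirin": (("warfarin", "heparin"), ("heartburn", "hives")),
    "salicylic_acid": (("warfarin",), ("heartburn",)),
    "ibuprofen": (("warfarin", "lisinopril"), ("heartburn", "dizziness")),
    "caffeine": (("lisinopril",), ("insomnia",)),
}
drugs = [
    DrugRecord(r.drug_id, r.fingerprint,
               frozenset(extras[r.drug_id][0]), frozenset(extras[r.drug_id][1]))
    for r in records
]

for channel, meaning in [("CS", "Tanimoto on 1024-bit circular fingerprints"),
                         ("DDI", "Jaccard on interaction-partner sets"),
                         ("SE", "Jaccard on side-effect sets")]:
    m = build_similarity_matrix(drugs, channel)
    print(f"\n{channel} similarity ({meaning}):")
    print(m.to_dataframe().round(3))

print("\nAspirin and salicylic acid share substructure (high CS), while the")
print("DDI and SE channels capture overlapping clinical behaviour instead.")
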
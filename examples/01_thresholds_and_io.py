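"""Load a peptide table and apply the IEDB-convention binding thresholds.

Scores >= 0.486 mark strong binders, <= 0.362 weak binders; the open
interval in between stays unlabeled and is excluded from training.
"""

from pepgan import PeptideDataset, apply_binding_thresholds
from pepgan.io import PeptideRecord

records = [
    PeptideRecord(id="mart1", sequence="AAGIGILTV", score=0.70),
    PeptideRecord(id="test1", sequence="FLIDLAFLI", score=0.90),
    PeptideRecord(id="border", sequence="CLICMDMVV", score=0.40),
    PeptideRecord(id="weak1", sequence="GGGGGGGGG", score=0.10),
]
ds = apply_binding_thresholds(PeptideDataset(records))

for r in ds:
    print(f"{r.id:8s} {r.sequence}  score={r.score:.2f}  -> {r.label}")
print("counts:", ds.counts())
print("A score of 0.40 falls between the weak (0.362) and strong (0.486)")
print("cut-offs, so that peptide is kept in the file but never trained on.")
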
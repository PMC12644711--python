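"""Quantify a deletion rearrangement by qPCR with the 2^-ddCt method.

A small long-format Ct table: each sample has a rearrangement-specific
reaction ('del') and a control reaction ('ctrl') in the same locus. dCt =
mean(Ct_del) - mean(Ct_ctrl); samples are normalized to the Parental dCt
measured in parallel and reported as 2^-ddCt. A sample whose rearrangement
reaction comes up ~6.3 cycles earlier than parental (relative to control)
carries ~80-fold more rearrangement template.
"""

import pandas as pd

from amplijoin.qpcr import quantify_table

ct = pd.DataFrame(
    [
        ("Parental", "del", 32.1), ("Parental", "del", 32.3),
        ("Parental", "ctrl", 25.8), ("Parental", "ctrl", 25.9),
        ("CloneA", "del", 25.9), ("CloneA", "del", 26.0),
        ("CloneA", "ctrl", 25.9), ("CloneA", "ctrl", 26.0),
        ("CloneB", "del", 29.2), ("CloneB", "del", 29.1),
        ("CloneB", "ctrl", 25.7), ("CloneB", "ctrl", 25.9),
    ],
    columns=["sample", "reaction", "ct"],
)

result = quantify_table(ct, parental="Parental")
print(result.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nfold = 2^-ddCt relative to Parental; Parental is 1 by construction.")
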
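"""Deletion sizes and junction microhomology from a deletion-rich library.

Simulates deletion reads as a 60/40 mixture of microhomology-annealing events
(over planted repeat pairs of lengths 2, 3 and 4 nt) and blunt-processing
events, assigns breakpoints, and prints the deletion-size table (sizes
negative, the field's sign convention) and the microhomology-usage
distribution. MH-annealing deletions concentrate usage at the planted repeat
lengths; blunt-processing deletions mostly land at MH 0-1.
"""

import amplijoin as aj
from amplijoin.deletions import deletion_profile, records_from_calls

junction = aj.random_junction(seed=11, flank=60, repeats=aj.DEFAULT_REPEATS)
config = aj.SimConfig(
    n_reads=4000, seed=3, category_mix=(0, 0, 1, 0), w_mh=0.6, substitution_error_rate=0
)
reads, _ = aj.simulate_reads(junction, config)
calls = aj.classify_all(reads, junction)
records = records_from_calls(calls, junction)
profile = deletion_profile(records)

print("top deletion sizes (negative = nt removed):")
top = profile["size"].sort_values("reads", ascending=False).head(5)
for row in top.itertuples(index=False):
    print(f"  {row.deletion_size:>5}  {row.reads:>5} reads  ({100 * row.frequency:.1f}%)")

print("\nmicrohomology usage among deletion reads:")
for row in profile["mh_usage"].itertuples(index=False):
    print(f"  MH {row.mh:>2}: {100 * row.fraction:5.1f}%")
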
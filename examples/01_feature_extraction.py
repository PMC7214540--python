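"""Extract the three descriptor families for a single protein sequence.

Shows the reduced-alphabet recoding, a few gapped dipeptide frequencies,
the 188D physicochemical blocks, and the auto-cross covariance terms.
"""

from thermoraac import (
    ProteinRecord,
    acc_features,
    builtin_scheme,
    gapped_dipeptide_features,
    physchem188,
    reduce_sequence,
)
from thermoraac.physchem import acc_names, physchem188_names

record = ProteinRecord(
    "demo", "MKVLITGGAGFIGSHVVRELLKRGEEVIVIDNLSSGRKENIVPEAKFVEGDIRDLKVLE"
)

scheme = builtin_scheme("susko19")
reduced = reduce_sequence(record, scheme)
print(f"original ({len(record)} aa): {record.sequence[:40]}...")
print(f"reduced  (I/V merged)     : {reduced[:40]}...")

# Gapped dipeptide frequencies over the 19-symbol alphabet: 361 slots per
# gap, gaps 0..2. f(V|V) pools II, IV, VI and VV pairs of the original.
dip = gapped_dipeptide_features(reduced, scheme, max_gap=2)
by_name = dict(zip(dip.names, dip.values))
for name in ("RD|0|V|V", "RD|1|K|R", "RD|2|E|E"):
    print(f"{name:10s} = {by_name[name]:.4f}")
print(f"dipeptide family width: {dip.values.size} (= 3 x 19^2)")

# 188D vector: 20 AA frequencies + 8 properties x (3 composition,
# 15 distribution, 3 transition) values.
vec = physchem188(record)
names = physchem188_names()
print(f"188D width: {vec.size}; f(K) = {dict(zip(names, vec))['AAC|K']:.4f}")

# ACC: lagged covariances of 3 standardized property traces, lags 1-2.
acc = acc_features(record)
print(f"ACC width: {acc.size}; {acc_names()[0]} = {acc[0]:+.4f}")
print("total mixed feature width:", vec.size + dip.values.size + acc.size)
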
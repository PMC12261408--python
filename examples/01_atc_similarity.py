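"""Hierarchical ATC-code similarity: WHS versus the two simpler measures.

Parses two level-4 ATC codes, shows their nested prefix sets, and compares
the weighted-hierarchical similarity (WHS) with the uniform-weight prefix
similarity (RNPSim) and the inverse-frequency exponential measure (NPSim).
"""

from atcpred import (
    NpSimParams,
    atc_similarity_matrix,
    np_sim,
    parse_atc_code,
    rnp_sim,
    shared_levels,
    whs,
)

a, b = parse_atc_code("A03AA", 4), parse_atc_code("A03BB", 4)
print(f"prefix chain of {a.code}: {list(a.prefixes)}")
print(f"prefix chain of {b.code}: {list(b.prefixes)}")
n = shared_levels(a, b, 4)
print(f"shared levels N4 = {n}  (the codes agree through level {n})")

print(f"\nWHS_4    = {whs(a, b, 4):.4f}   # quadratic level weights, in (0, 1]")
print(f"RNPSim_4 = {rnp_sim(a, b, 4):.4f}   # every level weighted equally")
params = NpSimParams({"A03AA": 0.5, "A03BB": 0.25})
print(f"NPSim_4  = {np_sim(a, b, params, 4):.4f}   # inverse-frequency weights, unbounded")

print("\nAt level 1 the weighted and uniform measures coincide:")
print(f"  WHS_1 = {whs(a, b, 1):.4f} == RNPSim_1 = {rnp_sim(a, b, 1):.4f}")

codes = ["A03AA", "A03AB", "A03BB", "B01AC"]
print(f"\nWHS matrix at level 3 for {codes}:")
print(atc_similarity_matrix(codes, "whs", 3).round(3))
print("Entries near 1 mean the codes sit in the same branch of the hierarchy.")
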
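"""Node strength centrality and its robustness to dropping cases.

Prints the most central symptoms (largest summed absolute partial
correlations), their community loadings, and a case-dropping stability
curve with the CS coefficient.
"""

import symptomnet as sn

raw = sn.generate(sn.default_raw_study_spec(n=1463, seed=42))
m = sn.combine_items(raw, sn.STUDY_COMPOSITES)

result = sn.ega(m, compute_layout=False)
strength = sn.node_strength(result.network).sort_values(ascending=False)

print("most central symptoms (node strength):")
for code, s in strength.head(5).items():
    print(f"  {code:<16}{s:.2f}")

loadings = sn.node_loadings(result.network, result.partition)
top = strength.index[0]
print(f"\ncommunity loadings of {top}:",
      ", ".join(f"{c}: {v:.2f}" for c, v in loadings.loc[top].items()))

curve = sn.case_drop_stability(
    m, n_iter=50, drop_fractions=[0.0, 0.2, 0.4, 0.6], seed=3
)
print("\ncase-dropping stability of node strength:")
for f, mc in zip(curve.drop_fractions, curve.mean_corr):
    print(f"  drop {f:.0%}: mean correlation with full sample = {mc:.2f}")
print(f"CS coefficient = {curve.cs_coefficient:g}")
print()
print("A high CS coefficient (here the largest drop fraction at which 95%")
print("of subsamples still correlate >= 0.7 with the full sample) means the")
print("centrality ordering does not hinge on particular subjects.")
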
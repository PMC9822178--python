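"""Combine two soft sentiment classifiers with Dempster's rule.

Each classifier emits a probability vector over (negative, neutral,
positive); embedding those as singleton belief assignments and taking the
orthogonal sum yields a fused mass function plus the conflict K that the
normalisation removed.
"""

from sentifuse import bba_from_probs, combine, decide

p1 = (0.6, 0.3, 0.1)  # classifier A leans negative
p2 = (0.5, 0.3, 0.2)  # classifier B agrees, less firmly

result = combine(bba_from_probs(p1), bba_from_probs(p2))
m = result.combined
decision = decide(m)

print(f"classifier A: {p1}")
print(f"classifier B: {p2}")
print(f"fused masses  neg={m[1]:.4f}  neu={m[2]:.4f}  pos={m[4]:.4f}")
print(f"conflict K = {result.conflict:.2f}")
print(f"decision: {decision.label.value} (tie={decision.tie})")
print()
print("The fused negative mass (0.73) exceeds either input (0.6, 0.5):")
print("agreeing evidence reinforces, and the 59% of product mass that fell")
print("on contradictory class pairs was removed by normalisation.")
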
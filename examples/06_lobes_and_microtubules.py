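"""Lobe counting and microtubule cortical anchoring on cell outlines.

Builds rosette-shaped outlines with known lobe counts, recovers them from
signed-curvature analysis, then places microtubule endpoints with a 73.6%
concave-anchoring fraction (the measured 156:56 split) and recovers fraction
and per-µm cortex density.
"""

from lecmech.metrics import count_lobes, mt_anchoring
from lecmech.synth import DEFAULT_FRAC_CONCAVE, gen_lobed_outlines, gen_mt_endpoints

outlines, truth = gen_lobed_outlines(8, (0, 3, 5, 7), seed=2)
recovered = [count_lobes(o) for o in outlines]
print("lobe counts (truth -> recovered):",
      ", ".join(f"{t}->{r}" for t, r in zip(truth, recovered)))

outline = outlines[[i for i, k in enumerate(truth) if k >= 5][0]]
endpoints, classes = gen_mt_endpoints(
    outline, frac_concave=DEFAULT_FRAC_CONCAVE, n=212, seed=3
)
r = mt_anchoring(outline, endpoints)
print(f"\nmicrotubule endpoints: {r.n_assigned} assigned, {r.n_rejected} "
      f"beyond capture distance")
print(f"fraction on concave cortex: {r.fraction_concave:.3f} "
      f"(generator truth {DEFAULT_FRAC_CONCAVE:.3f})")
print(f"density: {r.density_concave:.2f} /µm concave vs "
      f"{r.density_convex:.2f} /µm convex cortex")
print("\nMicrotubules anchor preferentially in concave (neck) regions of the "
      "lobate cell cortex.")
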
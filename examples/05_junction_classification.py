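"""Five-way junction classification on a synthetic capillary-end dataset.

Draws 1,785 junction profiles from the default category mixture (20% button
junctions) with coverage noise, classifies every profile with the rule-based
classifier, and tabulates the recovered frequencies.
"""

from lecmech.metrics import classify_junction, tabulate_junction_frequencies
from lecmech.synth import JunctionMixConfig, gen_junction_dataset

config = JunctionMixConfig(rng_seed=0)  # n = 1785
profiles, truth = gen_junction_dataset(config)
calls = [classify_junction(p) for p in profiles]

accuracy = sum(c.label == t for c, t in zip(calls, truth)) / len(calls)
table = tabulate_junction_frequencies(calls)
print(f"n = {config.n} junction profiles, classifier accuracy "
      f"{100 * accuracy:.1f}% against generator truth\n")
print(table.loc["pooled"].to_string(float_format=lambda v: f"{v:.1f}"))
print("\nButton junctions (punctate deposits at lobe necks) make up ~20% of "
      "lobes; the linear curvilinear/double configurations dominate.")
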
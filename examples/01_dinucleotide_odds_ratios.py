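"""Dinucleotide odds ratios of the pooled EPB41L3 transcripts.

Feeds the bundled published observed frequencies through the uniform-
expectation odds ratio and prints the representation class per
dinucleotide: below 0.78 underrepresented, above 1.23 overrepresented.
"""

from cubkit.dinucleotides import UNIFORM, odds_ratios
from cubkit.resources import load_published_dinucleotides

observed = dict(load_published_dinucleotides()["observed"])
profile = odds_ratios(observed, expected_mode=UNIFORM)

print(profile.to_frame().round(4))
extremes = sorted(profile.odds_ratio.items(), key=lambda kv: kv[1])
print(f"\nlowest:  {extremes[0][0]} odds {extremes[0][1]:.3f} "
      f"({profile.classification[extremes[0][0]]})")
print(f"highest: {extremes[-1][0]} odds {extremes[-1][1]:.3f} "
      f"({profile.classification[extremes[-1][0]]})")
print("TA (UpA) depletion and GA (GpA) enrichment are the gene's signature.")
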
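"""Codon-anticodon adaptation for the human EPB41L3 codon preferences.

Pairs each amino acid's preferred codon (from the bundled published RSCU
column) with its Watson-Crick cognate anticodon and asks whether that
isoacceptor is the most abundant in the human tRNA gene pool.
"""

from cubkit.resources import load_published_rscu, load_trna_table
from cubkit.trna_adaptation import adaptation_report, optimal_amino_acids, report_frame

rscu_table = load_published_rscu()["homo_sapiens"]
trna = load_trna_table("homo_sapiens")

records = adaptation_report(rscu_table, trna)
print(report_frame(records)[["preferred_codon", "cognate_anticodon",
                             "cognate_count", "family_total", "is_optimal"]])
optimal = optimal_amino_acids(records)
print(f"\n{len(optimal)} amino acids where the preferred codon matches the "
      f"top isoacceptor: {', '.join(optimal)}")
print("(single-codon families Met and Trp are excluded from the statistic)")
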
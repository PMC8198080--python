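"""RSCU across five mammalian species: shared preferred codons and clustering.

Loads the bundled published per-species RSCU columns, finds codons
preferred in every species, and clusters species columns — rodents pair
with rodents, primates with primates.
"""

from cubkit.genetic_code import to_rna
from cubkit.resources import SPECIES, load_published_rscu
from cubkit.rscu import rscu_cluster, shared_preferred

tables = [load_published_rscu()[sp] for sp in SPECIES]

shared = shared_preferred(tables, inclusive=True)
print(f"{len(shared)} codons preferred (RSCU >= 1) in every species:")
print("  " + " ".join(sorted(to_rna(c) for c in shared)))

result = rscu_cluster(tables)
print("\nspecies leaf order after average-linkage clustering:")
print("  " + " -> ".join(result.col_order))
print("(adjacent species have the most similar codon-usage profiles)")
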
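"""K2P distances and a neighbor-joining tree on an ortholog-like CDS set.

Builds five species-like sequences from a shared ancestor (rodent-like
pair closer to each other, primate-like pair likewise), computes Kimura
two-parameter distances and prints the NJ tree in Newick.
"""

import numpy as np

from cubkit.phylogeny import k2p_matrix, neighbor_joining, write_newick
from cubkit.sequence_io import CodingSequence
from cubkit.synthetic_data import generate_biased_set, mutate_codons

rng = np.random.default_rng(4)
ancestor = generate_biased_set(theta=0.3, n=1, length=500, seed=4)[0]

def species(name, source, rate):
    return mutate_codons(CodingSequence(name, name, source.bases), rng,
                         rate_synonymous=0.03, rate_any=rate)

primate_anc = species("panc", ancestor, 0.04)
rodent_anc = species("ranc", ancestor, 0.06)
taxa = [
    species("human", primate_anc, 0.01),
    species("orangutan", primate_anc, 0.01),
    species("rat", rodent_anc, 0.02),
    species("mouse", rodent_anc, 0.02),
    species("cattle", ancestor, 0.05),
]

dm = k2p_matrix(taxa)
print("K2P distance matrix (substitutions/site):")
print(dm.as_tsv())
tree = neighbor_joining(dm)
print("NJ tree:", write_newick(tree))
print("Expect (human,orangutan) and (rat,mouse) to appear as cherries.")
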
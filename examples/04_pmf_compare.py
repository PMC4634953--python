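"""Compare MALDI fingerprints of three related synthetic collagens by the
top-100 shared-peak count."""

import numpy as np

from paleocollagen import pairwise_shared_matrix
from paleocollagen.phylo import Tree
from paleocollagen.simulate import SimulationConfig, simulate_alignment, simulate_pmf

config = SimulationConfig(n_taxa=3, chain_lengths=(300, 259), pmf_noise_peaks=5)
rng = np.random.default_rng(0)
# A and B are close; C is distant
tree = Tree.from_newick("(A:0.01,B:0.05,C:0.4);")
sequences = simulate_alignment(tree, config.model(), config.concatenated_length, rng)
peaklists = {
    taxon: simulate_pmf(sequences[taxon], config, np.random.default_rng(i))
    for i, taxon in enumerate("ABC")
}
matrix = pairwise_shared_matrix(peaklists, n=100, tol=0.2)
print(matrix)
print("\nOff-diagonal entries are shared peaks among each pair's most intense")
print("peaks (+-0.2 Da): closely related sequences share more peptide masses.")
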
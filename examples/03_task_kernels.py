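"""Task-taxonomy kernels and the hierarchical decomposition.

Parses a three-channel taxonomy, derives the prior task similarity
(a + shared ancestors)/(a + max depth), masks a base kernel to every tree
node's task subset, and shows the two degenerate weightings: all weight on
the root recovers the pooled (Union) kernel, uniform weight on the leaves the
per-task (Dirac) block-diagonal kernel. The latent task similarity gamma sums
the weights of shared subsets.
"""

import numpy as np

from phenomkl import (HierWeights, hierarchical_kernel,
                      latent_task_similarity, parse_newick, subset_kernels,
                      task_similarity)
from phenomkl.kernels import KernelMatrix

tree = parse_newick("((SCN1A,SCN2A),SCN5A);")
print("nodes:", tree.nodes)
print("subsets:", {n: sorted(s) for n, s in tree.node_subsets.items()})

for a in (1, 5, 100):
    K = task_similarity(tree, a)
    print(f"a={a}: sim(SCN1A,SCN2A)={K.values[0,1]:.3f}, "
          f"sim(SCN1A,SCN5A)={K.values[0,2]:.3f}")
# larger baseline a pulls every entry toward 1 (the Union limit)

rng = np.random.default_rng(0)
n = 6
A = rng.standard_normal((n, n + 1))
K = KernelMatrix(tuple(f"v{i}" for i in range(n)), A @ A.T)
tasks = ["SCN1A", "SCN2A", "SCN5A"] * 2
subs = subset_kernels(tree, K, tasks)

w_root = HierWeights({nd: float(nd == tree.root) for nd in tree.nodes}, {})
print("\nroot-only weights reproduce the base kernel:",
      np.allclose(hierarchical_kernel(subs, w_root).values, K.values))

uniform = HierWeights({nd: 1 / len(tree.nodes) for nd in tree.nodes}, {})
gamma = latent_task_similarity(tree, uniform)
print("latent task similarity (uniform weights):\n", gamma.values.round(3))
# diagonal entries dominate: a task always shares all of its own subsets
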
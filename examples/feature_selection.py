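"""Network-propagation feature selection on a synthetic panel.

Simulates a cell-line panel in which one co-expression module drives the
drug response, then ranks genes two ways: by raw |Pearson r| with the
response, and by the network-smoothed importance scores.  Prints the
top-10 genes under each ranking next to the planted causal genes.
"""

import numpy as np

from netdrug import (
    FilterConfig,
    SyntheticConfig,
    build_adjacency,
    generate,
    initial_scores,
    normalize,
    propagate,
    select_top_k,
)
from netdrug.preprocess import impute_or_drop

# weak-signal regime: marginal correlations are noisy, the network helps
cfg = SyntheticConfig(n_samples=60, noise_sd=np.sqrt(2.0), missing_rate=0.05, seed=7)
expr, resp, truth = generate(cfg)
expr = impute_or_drop(expr, FilterConfig())

net = normalize(build_adjacency(expr))
c = initial_scores(expr, resp.values[0])
imp = propagate(net, c, alpha=0.5)

top_c = select_top_k(c, expr.gene_ids, 10, method="correlation")
top_f = select_top_k(imp.f, expr.gene_ids, 10, method="network")
causal = set(truth.causal_genes["D00"])

print(f"planted causal genes: {sorted(causal)}")
print(f"correlation top-10:   {top_c.selected_gene_ids}"
      f"  ({len(set(top_c.selected_gene_ids) & causal)}/10 causal)")
print(f"network top-10:       {top_f.selected_gene_ids}"
      f"  ({len(set(top_f.selected_gene_ids) & causal)}/10 causal)")
print("\nA higher causal count in the network row means propagation over the")
print("co-expression graph denoised the per-gene correlations.")
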
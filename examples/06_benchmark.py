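"""Score edge recovery over simulation replicates.

Runs the full simulate -> infer -> score loop on a reduced design
(fewer genes and replicates than the headline benchmark, for speed)
and prints the replicate table with its mean/SD summary.
"""

import warnings

warnings.filterwarnings("ignore")

from segn import run_benchmark

table = run_benchmark(n_replicates=3, m=15, n_edges=20, delta_sq=0.01,
                      T=30, seed=1)
print(table.round(3).to_string(index=False))
# TPR = TP/(TP+FN) over true edges, FPR = FP/(FP+TN) over ordered
# non-edge pairs, AUC from sweeping a threshold over |P_ii'(t_T)| scores.
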
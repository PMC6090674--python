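"""Call ceRNA pairs on a tiny hand-built example.

Two transcripts ('spongeA', 'spongeB') share 4 of 20 expressed miRNAs and
rise together over the 14-day series; 'bystander' shares only 1 miRNA and
drifts independently. Only the first pair should satisfy both criteria.
"""

import numpy as np
import pandas as pd

from cernaforge.cerna import call_cerna_pairs, hypergeom_shared_test
from cernaforge.expression import ExpressionMatrix
from cernaforge.interactions import union_merge

rng = np.random.default_rng(0)
days = [f"Day{4 + 2 * i}" for i in range(14)]

edges = []
for m in range(4):
    edges += [(f"miR{m}", "spongeA", "mRNA"), (f"miR{m}", "spongeB", "mRNA")]
edges += [("miR0", "bystander", "mRNA"), ("miR9", "bystander", "mRNA")]
df = pd.DataFrame(edges, columns=["mirna_id", "target_id", "target_class"])
df["predictors"] = [frozenset({"toy"}) for _ in range(len(df))]
table = union_merge([df])

trend = np.linspace(3, 7, 14)
expr = ExpressionMatrix(
    pd.DataFrame(
        {
            "spongeA": trend + rng.normal(0, 0.2, 14),
            "spongeB": trend + rng.normal(0, 0.2, 14),
            "bystander": rng.normal(5, 1, 14),
        }
    ).T.set_axis(days, axis=1),
    pd.Series("mRNA", index=["spongeA", "spongeB", "bystander"]),
    "log2p1",
)

calls = call_cerna_pairs(table, expr, universe_size=20)
print(calls.candidates[["id_a", "id_b", "k_shared", "p_hyper", "r", "p_corr", "accepted"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print()
print("shared-miRNA tail for k=4 of (4,4) in a universe of 20:",
      f"{hypergeom_shared_test(4, 4, 4, 20):.2e}")
# 'accepted' requires BOTH p_hyper < 0.05 (shared regulators beyond chance)
# and r > 0.5 with p_corr < 0.05 (temporal co-expression).
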
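"""Nominate paralog families and assemble synthesis-ready guide arrays.

Builds tiny identity/expression tables, applies the strict (prototype) and
relaxed selection profiles, grows families with the difference-from-top-
paralog rule, lays out the two four-guide arrays per target and assembles
their oligos in both template dialects.
"""

import numpy as np
import pandas as pd

from quadscreen import (
    assemble_oligo,
    build_in4mer_arrays,
    expand_families,
    select_paralog_pairs,
)
from quadscreen.design import random_spacer

identity = pd.DataFrame(
    [("RAB1A", "RAB1B", 92.0, 90.0),
     ("RAB1A", "RAB35", 84.0, 82.0),
     ("VPS4A", "VPS4B", 81.0, 80.0),
     ("ARF4", "ARF5", 26.0, 24.0)],        # below the identity floor
    columns=["gene_a", "gene_b", "pct_ab", "pct_ba"],
)
expression = pd.DataFrame(
    {"mean": [5.1, 4.8, 5.5, 3.9, 4.2, 4.0, 4.4],
     "stdev": [0.8, 0.9, 1.1, 0.7, 1.0, 0.9, 0.8]},
    index=["RAB1A", "RAB1B", "RAB35", "VPS4A", "VPS4B", "ARF4", "ARF5"],
)

for profile in ("prototype", "inzolia"):
    out = select_paralog_pairs(identity, expression, profile=profile)
    kept = out[out["accepted"]]
    print(f"{profile}: accepted {len(kept)}/{len(out)} pairs "
          f"(rejections: {out.loc[~out['accepted'], 'reason'].tolist()})")

pool = ["RAB1A", "RAB1B", "RAB35", "VPS4A", "VPS4B"]
families = expand_families(pool, identity, drop_threshold=10)
print(f"\nfamilies at a 10% drop threshold: {families}")
# RAB35 joins RAB1A's family (drop 91-83 = 8 < 10), giving one triple.

rng = np.random.default_rng(1)
guides = {g: [random_spacer(rng) for _ in range(4)] for g in pool}
pads = [random_spacer(rng) for _ in range(10)]

for family in families:
    a1, a2 = build_in4mer_arrays(family, guides, pad_source=pads,
                                 profile="prototype", seed=11)
    o1 = assemble_oligo(a1, dialect="prototype")
    o2 = assemble_oligo(a1, dialect="inzolia")
    print(f"\ntarget {'+'.join(family)}: two arrays, pad={a1.pad}")
    print(f"  array1 spacers: {','.join(s[:6] + '..' for s in a1.spacers)}")
    print(f"  array2 spacers: {','.join(s[:6] + '..' for s in a2.spacers)}")
    print(f"  oligo lengths: prototype {o1.length} nt, inzolia {o2.length} nt")
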
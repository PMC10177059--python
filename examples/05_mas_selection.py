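"""Marker-assisted selection from multi-marker genotype strings.

Uses the published six-marker panel layout: each progeny's 0/1 codes are
concatenated (order chr05V42, chr05V92, chr05V158, chr09V26, chr09V212,
chr09V222), individuals fall into four chromosome-combination classes, and
the selection rule keeps progeny whose chr05V158, chr09V26 and chr09V212
codes are all '1'.
"""

import numpy as np
import pandas as pd

from frostmas import mas

rng = np.random.default_rng(1)

# Published genotype-type counts of the best combination class.
TYPE_COUNTS = {
    "001011": 11, "100111": 3, "100011": 4, "110011": 18, "101011": 15,
    "111011": 29, "011011": 9, "001111": 14, "110111": 16, "011111": 16,
    "101111": 9, "111111": 99,
}
order = mas.DEFAULT_MARKER_ORDER
rows = []
i = 0
for s, n in TYPE_COUNTS.items():
    for _ in range(n):
        rows += [
            {"marker": m, "individual_id": f"g{i:03d}", "code": float(c)}
            for m, c in zip(order, s)
        ]
        i += 1
strings, _ = mas.build_genotype_strings(pd.DataFrame(rows), order)

chrom_of = {m: m.split("V")[0] for m in order}
classes = mas.classify_population(strings, chrom_of)
print("combination classes:")
print(classes["combination_class"].value_counts().to_string())

share = (classes["code_string"] == "111111").mean()
print(f"\n'111111' share of the class: {100 * share:.2f}%")

selection = mas.select_individuals(strings, mas.DEFAULT_RULE)
kept = selection[selection["selected"]]
print(f"selected {len(kept)}/{len(selection)} progeny; genotype types kept:",
      sorted(kept["code_string"].unique()))
# The rule keeps exactly the types with chr05V158, chr09V26 and chr09V212
# all '1' -- the strongest frost-tolerant classes.
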
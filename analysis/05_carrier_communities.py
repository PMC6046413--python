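"""Individual-carrier communities and the concentration of phylogenetic diversity.

Summarises the per-biotope carrier networks: how many communities each
carrier splits into, whether ticks and voles mix, and whether a minority of
carriers accumulates most of the Faith's PD (the Pareto-style 20/80 pattern).
"""

import json
from pathlib import Path

import pandas as pd

report = json.loads(Path("results/pipeline/report.json").read_text())

for biotope in ("forest", "ecotone"):
    summary = pd.read_csv(f"results/pipeline/community_summary_{biotope}.tsv", sep="\t")
    print(f"== {biotope} ==")
    cols = ["label", "carrier", "pct_individuals", "n_genera", "pd"]
    print(summary[cols].round(2).to_string(index=False))
    for carrier in ("tick", "vole"):
        key = f"{carrier}_{biotope}"
        if key in report["pd_concentration"]:
            c = report["pd_concentration"][key]
            print(f"{key}: largest community holds {c['major_pct']:.0f}% of {carrier}s "
                  f"(PD {c['major_pd']:.2f}); the remaining {c['minor_pct']:.0f}% "
                  f"accumulate PD {c['minor_accumulated_pd']:.2f} "
                  f"(ratio {c['ratio']:.2f})")
    print()
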
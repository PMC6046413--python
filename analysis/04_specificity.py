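"""Host specificity: log read-ratio (voles/ticks) vs network weighted degree.

Prints, per biotope, the genera most strongly associated with each carrier
and saves the scatter plots that display the full ranking.
"""

import pandas as pd

from micronet.specificity import plot_specificity

for biotope in ("forest", "ecotone"):
    table = pd.read_csv(f"results/pipeline/specificity_{biotope}.tsv", sep="\t")
    print(f"== {biotope} ==")
    top_vole = table.nlargest(5, "log_score")[["genus", "log_score", "raw_ratio", "wd"]]
    top_tick = table.nsmallest(5, "log_score")[["genus", "log_score", "raw_ratio", "wd"]]
    print("most vole-associated:\n", top_vole.to_string(index=False))
    print("most tick-associated:\n", top_tick.to_string(index=False))
    plot_specificity(table, f"results/specificity_{biotope}.png", title=biotope)
    print(f"plot: results/specificity_{biotope}.png\n")
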
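"""Metric and tract rankings from the bundled reference per-tract tables.

Feeds the packaged per-bundle percent-tract-affected and effect-size
tables (bvFTD vs control, EOAD vs control) through the ranking layer:
metrics are ranked by their mean percent-tract over the 21 bundles, and
tracts by the MD/RD-averaged percent-tract.  Diffusivity metrics detect
the most widespread alterations in both comparisons, and the bvFTD
profile is dominated by frontal/anterior bundles (uncinate, frontal
callosum, anterior thalamic radiations).
"""

from tractometry import rank_from_summary
from tractometry.reference import load_reference_summaries

ref = load_reference_summaries()
for comparison in ("bvFTD_vs_control", "EOAD_vs_control"):
    ranking = rank_from_summary(ref, comparison)
    print(f"\n{comparison}")
    print("  mean % tract per metric (over 21 bundles):")
    for metric in ranking.metric_ranking:
        print(
            f"    {metric}: {ranking.mean_percent_tract[metric]:5.1f}%  "
            f"(mean r = {ranking.mean_r[metric]:.2f})"
        )
    print(f"  most affected tracts (MD/RD average): {', '.join(ranking.tract_ranking[:5])}")
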
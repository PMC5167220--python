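"""Point-wise group comparison with a planted along-tract effect.

Generates a reduced synthetic cohort (33 controls, 20 bvFTD, 23 EOAD)
with a diffusivity increase of 1.2 noise-SD planted in points 5-10 of
the left uncinate, runs the per-point disease regression with age/sex/
brain-volume covariates, pools Benjamini-Hochberg FDR across all tested
points, and prints where the detections fall.  A well-behaved analysis
concentrates its flags inside the planted segment and leaves the other
bundles quiet.
"""

from tractometry import pointwise_regression, summarize_and_rank
from tractometry.synthetic import CohortSpec, effect_from_d, generate_cohort

effect = effect_from_d("L-UNC", points=(5, 10), group="bvFTD", d=1.2)
cohort = generate_cohort(CohortSpec(seed=42), effects=(effect,), fiber_scale=0.2)
order = list(cohort.atlas)

results = {
    m: pointwise_regression(
        cohort.profiles, cohort.design, m, ("bvFTD", "control"),
        bundle_order=order, q=0.05,
    )
    for m in ("FA", "MD")
}
for metric, res in results.items():
    in_seg = res.significant & (res.bundle == "L-UNC") & (res.point >= 4) & (res.point <= 9)
    print(
        f"{metric}: {res.significant.sum():4d}/{res.n_points} points significant, "
        f"critical P = {res.critical_p:.2e}, "
        f"{100 * in_seg.sum() / max(res.significant.sum(), 1):.1f}% inside the planted segment"
    )

summary, ranking = summarize_and_rank(results, bundle_order=order)
top = summary[summary["metric"] == "MD"].nlargest(3, "percent_tract")
print("\ntop bundles by MD percent-tract affected (max possible here is 40%,")
print("since the effect spans 6 of 15 points):")
for _, row in top.iterrows():
    print(f"  {row['bundle']:8s} {row['percent_tract']:5.1f}%  mean r = {row['mean_r']:.2f}")
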
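"""Classify hair-germ volume behavior and pool contraction statistics.

Simulates a telogen cohort (31 follicles, 1,560 time points at 6-min cadence)
and an early-anagen cohort (16 follicles, 655 points), normalizes each
trajectory to its own maximum, classifies enlargement/pulsation/contraction,
and pools the fraction of observations below 90% of the per-follicle maximum.
"""

from follipulse import synth
from follipulse import volume as vol

for label, params in [
    ("telogen", synth.telogen_params(seed=1)),
    ("early anagen", synth.anagen_params(seed=2)),
]:
    layout = synth.cohort_point_counts(params.stage)
    trajs, _ = synth.gen_volume_trajectories(params, layout)
    rels = [vol.normalize_trajectory(t) for t in trajs]
    calls = [vol.classify_behavior(r) for r in rels]
    summary = vol.summarize_categories(calls)
    frac = vol.contraction_fraction(rels)
    print(f"{label}: {len(trajs)} follicles, {frac.n_timepoints} time points")
    for cat, row in summary.items():
        print(f"  {cat:25s} {row['count']:3d}  ({row['percent']}%)")
    print(f"  below 90% of max: {frac.fraction_pct:.2f}% of pooled points\n")

print(
    "A lower pooled below-90% fraction in anagen reproduces the reduced\n"
    "hair-germ contraction seen when follicles re-enter growth."
)
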
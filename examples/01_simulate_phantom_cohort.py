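"""Simulate a static phantom cohort with a known disease topography.

Builds a small ellipsoidal brain phantom, embeds a relative-decrease pattern
in the parietal/temporal/frontal lobes, and simulates 52 subjects across the
four clinical groups with group-graded expression of the pattern.
"""


import ssmpet as sp

atlas, mask = sp.make_phantom_atlas((16, 16, 16), n_regions=6, seed=0)
template = sp.make_pattern_template(
    atlas, mask, {"parietal": -1.0, "temporal": -0.6, "frontal": -0.4}
)
baseline = sp.make_baseline(mask, seed=0)

cfg = sp.SimulationConfig(seed=0)  # 15 AD / 11 MCI+ / 10 MCI- / 16 HC
cohort, truth = sp.simulate_static_cohort(template, baseline, cfg)

print(f"mask voxels: {mask.sum()}, regions: {sorted(atlas.region_names.values())}")
print(f"subjects: {len(cohort)}")
print("mean expression z per group (ground truth):")
print(truth.groupby("group")["z"].mean().round(2).to_string())
print(
    "\nz is the strength with which each subject expresses the embedded\n"
    "unit-norm template; patients (AD) express it most, controls (HC) not at\n"
    "all on average. These values are the recovery target for the pattern\n"
    "derivation in example 03."
)
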
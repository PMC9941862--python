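"""Fit one simulated session end to end and print its depth profiles.

Simulates a GE-like and an SE-like session for the same subject, runs the
full estimation chain (restricted smoothing, GLM with drift/nuisance
confounds, Holm selection, CVR regression, hyperoxia M calibration, Davis
model inversion), and prints the three metrics per cortical depth bin next
to the generating ground truth.
"""

from laminarbold.depth import BIN_NAMES
from laminarbold.pipeline import (
    PipelineConfig,
    SimulationConfig,
    fit_session,
    group_profiles,
    simulate_session,
    truth_bin_summary,
)

cfg = PipelineConfig(
    sim=SimulationConfig(n_subjects=1, grid=(12, 12, 22), tsnr=50.0), seed=7
)

tables = {}
truth = {}
for sequence in ("GE", "SE"):
    bundle = simulate_session(cfg, 0, sequence)
    table, qc = fit_session(bundle, cfg)
    tables[sequence] = table
    truth[sequence] = truth_bin_summary(bundle.truth, bundle.labels)
    print(f"{sequence}: {qc['n_selected']}/{qc['n_in_mask']} voxels pass "
          f"Holm-corrected gas-response selection")

profiles = group_profiles(tables.values())
for sequence in ("GE", "SE"):
    print(f"\n{sequence} depth profiles (estimate vs ground truth):")
    prof = profiles[sequence]
    for metric, unit in (("cvr", "%BOLD/mmHg"), ("m_pct", "%"), ("dcbv+10_pct", "%")):
        sub = prof[prof.metric == metric].sort_values("depth_bin")
        for _, row in sub.iterrows():
            t = truth[sequence].loc[
                truth[sequence].depth_bin == row.depth_bin, metric
            ].iloc[0]
            print(f"  {metric:12s} {BIN_NAMES[row.depth_bin]:12s} "
                  f"{row['mean']:7.3f} vs {t:7.3f} {unit}")
print("\nCVR rises toward the pial surface for GE (draining veins) but barely "
      "for SE (micro-vessels); the CBV increase is depth-constant for both.")
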
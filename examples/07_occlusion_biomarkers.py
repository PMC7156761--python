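"""Occlusion maps and the case-control odds-ratio biomarker table.

Uses an analytic risk function (a weighted sum over one tissue) so the
whole biomarker workflow runs in seconds: occlusion map, top-5% hotspot
mask, per-tissue flags for synthetic cases and matched controls, and the
odds-ratio table with Cornfield intervals and Fisher p values.

For the full study — cohort, trained network, stratified ensembles,
KOOS-matched controls — see tkrisk.experiments.planted_biomarker_experiment
(a few minutes on one CPU).
"""

import numpy as np

from tkrisk.occlusion import (
    OcclusionConfig,
    biomarker_table,
    hotspot_mask,
    match_controls,
    occlusion_map,
    tissue_hotspot_flags,
)
from tkrisk.synthetic import PhantomSpec, TissueSpec, generate_atlas

spec = PhantomSpec(
    grid_shape=(24, 48, 48),
    tissue_specs=[
        TissueSpec("plantaris_muscle", "ellipsoid", (15, 6, 18), (2.5, 5, 5)),
        TissueSpec("acl", "ellipsoid", (15, 18, 42), (2.5, 5, 5)),
        TissueSpec("pcl", "ellipsoid", (21, 42, 30), (2.5, 5, 5)),
    ],
    n_patients=1,
    seed=0,
)
atlas = generate_atlas(spec)
target = atlas.mask("plantaris_muscle")
config = OcclusionConfig(voxel_shape=(6, 12, 12), stride=(6, 12, 12))
rng = np.random.default_rng(0)

def flags_for_subject(carries_signal: bool):
    vol = rng.normal(5.0, 1.0, size=spec.grid_shape)
    if carries_signal:
        vol[target] += 4.0

    def risk_batch(batch):
        # classifier surrogate: saturating response to the target tissue
        # plus a weak global intensity dependence (so control maps are
        # noise-driven rather than flat)
        tissue_term = 1 / (1 + np.exp(-(batch[:, target].mean(axis=1) - 8.5) * 6))
        return tissue_term + 0.05 * batch.mean(axis=(1, 2, 3))

    omap = occlusion_map(risk_batch, vol, config, vectorized=True)
    mask = hotspot_mask(omap, config.hotspot_fraction)
    return tissue_hotspot_flags(mask, atlas)

case_flags = [flags_for_subject(True) for _ in range(15)]
control_flags = [flags_for_subject(False) for _ in range(15)]

rows = biomarker_table(case_flags, control_flags, atlas, config)
print(f"{'tissue':>18}  a  b  c  d      OR         95% CI         p      sig")
for r in rows:
    ci = f"({r.ci_low:.2f}, {'inf' if np.isinf(r.ci_high) else f'{r.ci_high:.2f}'})"
    orr = "inf" if np.isinf(r.odds_ratio) else f"{r.odds_ratio:.2f}"
    print(f"{r.tissue:>18} {r.a:2d} {r.b:2d} {r.c:2d} {r.d:2d} {orr:>7} "
          f"{ci:>16}  {r.p:.2e}  {r.significant}")
print("\nThe tissue driving the risk function is flagged in cases far more")
print("often than in controls (OR > 1, significant); bystander tissues are")
print("flagged at chance rates in both groups.")
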
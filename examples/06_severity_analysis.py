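"""Individual-level analyses: severity vs. F1, and penultimate features.

Relates each synthetic stroke subject's FMA-like severity score to their
cross-validated F1 (expected: positive correlation — milder impairment,
more ND-like movement, easier classification), and exports the
classifier's 200-unit-style penultimate features for embedding.
"""

from imuaug.evaluate import Condition, TrainConfig, run_losocv
from imuaug.models import build_conv1d
from imuaug.preprocess import preprocess_cohort
from imuaug.profiles import desk_conv1d, desk_preprocess, desk_spec, desk_train
from imuaug.report import correlate_severity_f1, export_penultimate, relative_gain
from imuaug.synthdata import generate_cohort

spec = desk_spec(seed=3)
segments, profiles = generate_cohort(spec)
windows = preprocess_cohort(segments, desk_preprocess())
layout = spec.layout()
factory = lambda s: build_conv1d(desk_conv1d(spec.n_classes), seed=s)
cfg = desk_train(seed=3)

res = run_losocv(windows, Condition("stroke-only"), cfg, factory, layout)
rep = correlate_severity_f1(profiles, res)
print(f"severity vs F1 over {rep.n} stroke subjects: "
      f"r = {rep.pearson_r:.2f} (p = {rep.p_value:.3f})")
# a single 6-subject cohort is a noisy estimate of this correlation; the
# pooled multi-seed analysis in scripts/acceptance.py is the stable one
for subj, sev, f1 in rep.pairs:
    print(f"  {subj}: FMA-like {sev:5.1f}  F1 {f1:.3f}")

# penultimate features of one trained fold model for embedding/inspection
handle = factory(0)
from imuaug.evaluate import train_model

stroke = [w for w in windows if w.group.startswith("Stroke")]
train_model(handle, stroke, None, cfg)
feats = export_penultimate(handle, stroke[:50])
print(f"feature matrix: {feats.shape[0]} windows x "
      f"{handle.penultimate_dim} penultimate features (+ label columns)")
# a 2-D view via UMAP (optional dependency):
#   from imuaug.report import embed_features; xy = embed_features(feats, seed=0)
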
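"""Simulate one subject and recover its blood flow with both estimators.

Builds a noise-free synthetic pancreas slice with known blood flow
(parenchyma 106.8, carcinoma 42.0 ml/100 ml/min), then computes a
maximum-slope map (all 34 frames) and a two-scan first-pass map (trigger
frame + AIF-peak frame) and compares ROI means against the ground truth.
"""

from ctfpa import (
    AcquisitionProtocol,
    AifParams,
    FPAConfig,
    PhantomGeometry,
    TissueSpec,
    fpa_map,
    map_stats,
    msm_map,
)
from ctfpa.synthetic import rasterize_subject
from ctfpa.timing import _pancreatic_compartment

protocol = AcquisitionProtocol()  # 34 frames / 1.5 s, injection 80 ml at 5 ml/s
specs = {
    "carcinoma": TissueSpec("carcinoma", bf_true=42.0, mtt=28.0, baseline_hu=38.0),
    "parenchyma": TissueSpec("parenchyma", bf_true=106.8, mtt=28.0, baseline_hu=45.0),
}
subject = rasterize_subject(
    protocol, PhantomGeometry(), AifParams.from_peak(), specs, noise_sigma=0.0, seed=1
)

compartment = _pancreatic_compartment(subject)
msm = msm_map(subject.series, subject.aif_true)
fpa1 = fpa_map(subject.series, subject.aif_true, FPAConfig(variant="fpa1"), compartment)

print(f"trigger frame {fpa1.timing[0]} (t = {subject.series.times[fpa1.timing[0]]:.1f} s), "
      f"second scan at the AIF peak, frame {fpa1.timing[1]} "
      f"(t = {subject.series.times[fpa1.timing[1]]:.1f} s)")
print(f"{'tissue':<12}{'true BF':>9}{'MSM':>9}{'FPA1':>9}   (ml/100 ml/min, circular-ROI mean)")
for tissue, bf_true in subject.ground_truth.items():
    roi = subject.masks[f"{tissue}_circular"]
    print(f"{tissue:<12}{bf_true:>9.1f}{map_stats(msm, roi)[0]:>9.1f}"
          f"{map_stats(fpa1, roi)[0]:>9.1f}")
# Without noise both estimators sit within a few percent of the ground truth;
# the first-pass estimate is exact because no contrast leaves the tissue
# before the second scan.
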
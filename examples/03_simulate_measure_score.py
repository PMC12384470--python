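"""Full round trip on a small synthetic study.

Generates a 2-donor x 3-condition x 2-antibody study (TIFFs on disk),
measures every image (segmentation, features, colocalization, pairing) and
scores it into mean-rank performance tables.
"""

import tempfile

from ciliaquant import PipelineConfig, measure_study, score_study
from ciliaquant.synthetic import StudyDesign, generate_study

design = StudyDesign(
    donors=("D1", "D2"),
    conditions=("-80_28d", "4/RT/-80", "RT_28d"),
    antibodies=("RSPH4A", "CCDC39"),
    images_per_slide=3,
    seed=17,
)

with tempfile.TemporaryDirectory() as tmp:
    manifest = generate_study(design, tmp)
    print(f"generated {manifest['n_slides']} slides, "
          f"{manifest['n_slides'] * design.images_per_slide} images")

    cfg = PipelineConfig()
    features, pairs, coloc, errors = measure_study(tmp, cfg)
    print(f"measured {len(coloc)} images: "
          f"{int((features.channel == 'test').sum())} red objects, "
          f"{int((features.channel == 'marker').sum())} green objects, "
          f"{len(errors)} failures")

    result = score_study(features, pairs, coloc, cfg)

print("\noverall condition performance ranks (1 = best):")
for name, value in result["overall_condition"].items():
    print(f"  {name:<12} {value}")
print("\noverall antibody performance ranks (1 = best):")
for name, value in result["overall_antibody"].items():
    print(f"  {name:<12} {value}")
print("\nsignificance screen p-values (storage-condition association):")
for name, p in sorted(result["p_values"].items()):
    flag = "*" if name in result["significant"] else " "
    print(f" {flag} {name:<30} p = {p:.2e}")

print("\nThe injected degradation rises from -80_28d to RT_28d and CCDC39")
print("was simulated as more storage-sensitive than RSPH4A; the mean-rank")
print("metric recovers both orderings from the images alone.")
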
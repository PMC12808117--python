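"""Automated training-set assembly on a pure-species slide.

Builds the easy synthetic benchmark (2 species x 12 grains), then runs the
three annotation stages on one pure-species slide: one-shot template
detection tile by tile (initial), RGB statistical outlier removal
(filtered), and tighten-plus-recover refinement (refined).  Every surviving
box inherits the slide's species label, yielding labeled training
annotations with no manual box drawing.
"""

from pollenset import detect_slide, inherit_labels, refine_annotations
from pollenset.dataset import StageCountRow, stage_report
from pollenset.synthetic import make_fixture

fixture = make_fixture("easy", seed=1, with_stacks=False)
scene = fixture.pure_slides[0]
slide = scene.as_slide_image()
exemplar = fixture.exemplars[scene.species]

initial = detect_slide(slide, exemplar)
refined, counts, fres = refine_annotations(slide, initial, exemplar)
records = inherit_labels(refined, slide)

text, _ = stage_report(
    [StageCountRow(slide.slide_id, scene.species, counts.initial,
                   counts.filtered, counts.refined)]
)
print(text)
print(f"true grains on the slide: {len(scene.gts)}")
print(f"labeled records produced: {len(records)}  (all species={scene.species!r})")
print(
    "\nThe high-confidence initial pass favors precision; the filter removes\n"
    "color outliers; the refinement re-scan at a relaxed threshold recovers\n"
    "grains the strict pass missed, so 'refined' can exceed 'initial'."
)
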
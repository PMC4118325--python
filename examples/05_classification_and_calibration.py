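"""Alive/dead classification with a threshold calibrated on known trees.

Presence detections are counted in a window around each detected tree
(55 counts for the LIDAR's boolean series, 50 for the curtain's summed
LC0-LC2 blockings).  The alive threshold is the 5th percentile of the
counts of known-alive trees, so at least 95% of calibration live trees are
kept alive — mislabelling a live tree dead is the costly nursery error.
"""

from stemsense import (
    ClassifierParams,
    CurtainParams,
    SceneConfig,
    calibrate_threshold,
    cascade_detect,
    classify_detections,
    classification_report,
    curtain_presence_series,
    generate_field,
    match_to_truth,
)

dataset = generate_field(SceneConfig(n_trees=40, dead_fraction=0.25, seed=3,
                                     tree_top_height_mm=250, height_jitter_sd_mm=10))
detections = cascade_detect(dataset.curtain, CurtainParams())
matches = match_to_truth(detections, dataset.truth)
series = curtain_presence_series(dataset.curtain, (0, 1, 2))

alive_by_pos = {t.position: t.alive for t in dataset.truth}
alive_counts = [
    series.window_sum(p.detection, 25)
    for p in matches.successes if alive_by_pos[p.truth]
]
threshold = calibrate_threshold(alive_counts, percentile=5)
print(f"calibrated alive threshold from {len(alive_counts)} known-alive trees: "
      f"{threshold:.2f} detections (5th percentile)")

params = ClassifierParams(dead_range_counts=50, threshold_count=threshold)
statuses = classify_detections(series, [p.detection for p in matches.successes], params)
confusion = classification_report(matches, statuses, dataset.truth)

print(f"alive trees well classified:   {confusion.alive_correct}/{confusion.n_alive}")
print(f"dead trees well classified:    {confusion.dead_correct}/{confusion.n_dead}")
print(f"alive classified as dead:      {confusion.alive_as_dead}")
print(f"dead classified as alive:      {confusion.dead_as_alive}")
for name, value in confusion.rates().items():
    print(f"  {name.replace('_', ' ')}: {value}%")
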
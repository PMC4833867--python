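import numpy as np
import pytest

from pbodyquant.granulequant import DetConfig, detect_granules
from pbodyquant.imgseg import SegConfig, segment_germ_cells
from pbodyquant.synthdata import SceneConfig, generate_micrograph


@pytest.fixture(scope="session")
def small_scene():
    """One 512 px field with 8 cells, moderate noise, half co-localization."""
    cfg = SceneConfig(image_size=512, n_cells=8, noise_sd=5.0,
                      coloc_fraction=0.5, seed=11)
    img, truth = generate_micrograph(cfg)
    return cfg, img, truth


@pytest.fixture(scope="session")
def segmented_scene(small_scene):
    cfg, img, truth = small_scene
    labelmap = segment_germ_cells(img.channel("cdh1"), SegConfig())
    return cfg, img, truth, labelmap


@pytest.fixture(scope="session")
def detected_scene(segmented_scene):
    cfg, img, truth, labelmap = segmented_scene
    det = DetConfig()
    ga = detect_granules(img.channel("dcp1a"), det, "dcp1a")
    gb = detect_granules(img.channel("nanos2"), det, "nanos2")
    return cfg, img, truth, labelmap, det, ga, gb


def match_detections(detections, truths, tol=2.0):
    """Greedy centroid matching; returns (n_matched, precision, recall)."""
    tp = 0
    used = set()
    for g in detections:
        cands = [
            (np.hypot(g.centroid[0] - t.centroid[0], g.centroid[1] - t.centroid[1]), i)
            for i, t in enumerate(truths)
            if i not in used
        ]
        if cands:
            d, i = min(cands)
            if d < tol:
                tp += 1
                used.add(i)
    prec = tp / len(detections) if detections else float("nan")
    rec = tp / len(truths) if truths else float("nan")
    return tp, prec, rec
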
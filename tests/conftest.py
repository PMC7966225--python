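import numpy as np
import pytest

import graftscore as g
from graftscore import phantom

#: compact grid (12 x 22 x 24 mm at 0.2 mm) that fits the default dentition
SMALL_SHAPE = (60, 110, 120)


@pytest.fixture(scope="session")
def default_phantom():
    """Default cleft-side scene: thin tapering bridge, total 3 (poor)."""
    cfg = g.PhantomConfig(volume_shape=SMALL_SHAPE)
    volume, landmarks, truth = phantom.generate_phantom(cfg)
    return cfg, volume, landmarks, truth


@pytest.fixture(scope="session")
def good_phantom():
    """Control-side-like scene: bridge wider than the incisor root everywhere."""
    cfg = phantom.good_side_config(volume_shape=SMALL_SHAPE)
    volume, landmarks, truth = phantom.generate_phantom(cfg)
    return cfg, volume, landmarks, truth


@pytest.fixture(scope="session")
def reoriented_default(default_phantom):
    from graftscore import geometry

    _, volume, landmarks, _ = default_phantom
    vol = geometry.reorient_to_tooth_axis(
        volume, landmarks["incisor"], extra_landmarks={"canine": landmarks["canine"]}
    )
    return vol, vol.meta["landmarks"]["incisor"]


def slab_section(width_mm, spacing=0.2, gap_px=40, thickness_profile=None):
    """Construct a synthetic level section: two root blobs and a bone band.

    ``thickness_profile`` optionally gives a per-station bone thickness in
    pixels (length ``gap_px - 1``); default is a uniform slab of
    ``width_mm``.
    """
    n = 96
    img = np.zeros((n, n), dtype=np.int16)
    cx = n // 2
    y_mes, y_dis = 20, 20 + gap_px
    img[cx - 10 : cx + 10, y_mes - 6 : y_mes + 1] = g.LABELS["incisor_root"]
    img[cx - 10 : cx + 10, y_dis : y_dis + 7] = g.LABELS["canine_root"]
    stations = np.arange(y_mes + 1, y_dis)
    if thickness_profile is None:
        half = int(round(width_mm / spacing)) // 2
        extra = int(round(width_mm / spacing)) % 2
        for y in stations:
            img[cx - half : cx + half + extra, y] = g.LABELS["bone"]
    else:
        for y, t in zip(stations, thickness_profile):
            t = int(t)
            if t > 0:
                img[cx - t // 2 : cx - t // 2 + t, y] = g.LABELS["bone"]
    return g.LevelSection(depth_mm=5.0, image=img, spacing_mm=spacing,
                          axis=(0.0, 0.0, 1.0))
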
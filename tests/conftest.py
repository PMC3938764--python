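import numpy as np
import pandas as pd
import pytest

from migranger.io import encode_pixels
from migranger.synthetic import MicroscopySimSpec, simulate_microscopy_panel


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated imaging dataset shared across tests."""
    spec = MicroscopySimSpec(n_cells=4, n_frames=15, seed=11)
    dataset, gt = simulate_microscopy_panel(spec)
    return dataset, gt


def _cmac_row(condition, repeat, cell_id, cmac_id, frame, x, y,
              area=0.5, major=1.2, minor=0.6, px1=None, px2=None,
              bg1=1.0, bg2=1.0):
    if px1 is None:
        px1 = [5.0] * 8
    if px2 is None:
        px2 = [4.0, 5.0, 6.0, 4.5, 5.5, 4.8, 5.2, 5.0]
    return {
        "condition": condition, "repeat": repeat, "cell_id": cell_id,
        "cmac_id": cmac_id, "frame": frame,
        "centroid_x_um": x, "centroid_y_um": y, "area_um2": area,
        "major_axis_um": major, "minor_axis_um": minor,
        "ch1_pixels": encode_pixels(px1), "ch2_pixels": encode_pixels(px2),
        "ch1_bg": bg1, "ch2_bg": bg2,
    }


@pytest.fixture()
def parsing_toy():
    """Ten CMAC tracks with known violations of each parsing rule.

    Sequence frames 0..9.  Hand enumeration of survivors:
      t1: frames 3-6, clean                      -> survives, uncensored
      t2: single frame 4                          -> removed (single frame)
      t3: frames 2-5 but minor axis 0.20 µm       -> all records removed
      t4: frames 0-3 (touches first frame)        -> survives, censored_start
      t5: frames 7-9 (touches final frame)        -> survives, censored_end
      t6: frames 2-4, one record area 0.04 µm²    -> record removed at frame 3,
          longest remaining contiguous run has 1 frame tie -> keeps frames 2
          ... actually frames 2,4 remain non-contiguous; earliest longest
          segment = frame 2 alone -> removed (single frame)
      t7: frames 1-5 with a 3 µm jump into frame 4 -> split; frames 1-3 kept
      t8: frames 5-6, clean                       -> survives
      t9: single frame 0                          -> removed (single frame)
      t10: frames 4-8, clean                      -> survives

    Survivors: t1, t4, t5, t7(frames 1-3), t8, t10 -> 6 tracks.
    Uncensored survivors: t1, t7, t8, t10 -> 4 tracks.
    """
    rows = []
    for f in range(3, 7):
        rows.append(_cmac_row("c", 1, 1, 1, f, 1.0 + 0.1 * f, 1.0))
    rows.append(_cmac_row("c", 1, 1, 2, 4, 5.0, 5.0))
    for f in range(2, 6):
        rows.append(_cmac_row("c", 1, 1, 3, f, 8.0, 1.0, minor=0.20))
    for f in range(0, 4):
        rows.append(_cmac_row("c", 1, 1, 4, f, 1.0, 8.0 + 0.1 * f))
    for f in range(7, 10):
        rows.append(_cmac_row("c", 1, 1, 5, f, 12.0, 2.0))
    for f in range(2, 5):
        rows.append(_cmac_row("c", 1, 1, 6, f, 3.0, 3.0,
                              area=0.04 if f == 3 else 0.5))
    for f in range(1, 6):
        x = 20.0 if f < 4 else 26.0  # 6 µm jump between frames 3 and 4
        rows.append(_cmac_row("c", 1, 1, 7, f, x + 0.1 * f, 4.0))
    for f in range(5, 7):
        rows.append(_cmac_row("c", 1, 1, 8, f, 30.0, 1.0))
    rows.append(_cmac_row("c", 1, 1, 9, 0, 40.0, 1.0))
    for f in range(4, 9):
        rows.append(_cmac_row("c", 1, 1, 10, f, 45.0, 1.0 + 0.05 * f))
    df = pd.DataFrame(rows)
    bounds = {("c", 1): (0, 9)}
    return df, bounds


@pytest.fixture()
def tiny_panel():
    """Deterministic 3-track feature panel for design-matrix tests."""
    rng = np.random.default_rng(7)
    rows = []
    for cell, T in ((1, 20), (2, 10), (3, 8)):
        y = rng.normal(size=T).cumsum() * 0.1 + rng.normal(size=T)
        x = rng.normal(size=T)
        for t in range(T):
            rows.append({"condition": "control", "repeat": 1, "cell_id": cell,
                         "frame": t, "X": x[t], "Y": y[t]})
    return pd.DataFrame(rows)
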
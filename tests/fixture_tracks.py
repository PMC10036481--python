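"""Constructed track fixtures with known validity labels.

Twenty tracks at 0.2 µm/px, 0.088 s/frame: five valid, five violating the
50 px span rule, five violating the 10 s duration rule, and five violating
the 20% size-consistency rule (each group violates exactly one rule, in a
way earlier rules do not catch first).
"""

import numpy as np
import pandas as pd

from cableflock.tracking import TrackSet

PIXEL_SIZE = 0.2   # µm/px -> 50 px = 10 µm
FRAME_INTERVAL = 0.088


def _track(tid, n_points, span_um, size_um, size_jump_at=None):
    frames = np.arange(n_points)
    xs = np.linspace(0.0, span_um, n_points) + 100.0
    ys = np.full(n_points, 100.0) + 0.1 * np.sin(frames)  # tiny y wiggle
    major = np.full(n_points, size_um * 1.5)
    minor = np.full(n_points, size_um * 0.5)
    if size_jump_at is not None:
        major[size_jump_at:] *= 1.3
        minor[size_jump_at:] *= 1.3
    return pd.DataFrame(
        {
            "track_id": tid,
            "frame": frames,
            "x_um": xs,
            "y_um": ys,
            "area_um2": np.pi * major * minor / 4,
            "major_um": major,
            "minor_um": minor,
        }
    )


def labeled_trackset():
    """Returns (TrackSet, labels dict: track_id -> 'valid'|'span'|'duration'|'size')."""
    long_n = 150          # 149 * 0.088 = 13.1 s
    short_n = 100         # 99 * 0.088 = 8.7 s  (< 10 s)
    wide = 30.0           # 150 px span > 50 px
    narrow = 8.0          # 40 px span  <= 50 px
    parts, labels = [], {}
    tid = 0
    for _ in range(5):
        parts.append(_track(tid, long_n, wide, 1.0)); labels[tid] = "valid"; tid += 1
    for _ in range(5):
        parts.append(_track(tid, long_n, narrow, 1.0)); labels[tid] = "span"; tid += 1
    for _ in range(5):
        parts.append(_track(tid, short_n, wide, 1.0)); labels[tid] = "duration"; tid += 1
    for _ in range(5):
        parts.append(_track(tid, long_n, wide, 1.0, size_jump_at=long_n // 2))
        labels[tid] = "size"; tid += 1
    data = pd.concat(parts, ignore_index=True)
    return TrackSet(data, frame_interval=FRAME_INTERVAL, pixel_size=PIXEL_SIZE), labels
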
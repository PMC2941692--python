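"""Shared helpers for the test modules (not a test file)."""

import numpy as np

from nucleome3d.builder import FiberPath


def small_fiber(length=2_000):
    """A minimal straight fiber covering ``length`` bp."""
    anchors = np.arange(0, length + 1, 100, dtype=np.int64)
    if anchors[-1] != length:
        anchors = np.append(anchors, length)
    pts = np.zeros((len(anchors), 3))
    pts[:, 2] = anchors * 0.01
    return FiberPath(pts, anchors, 100)
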
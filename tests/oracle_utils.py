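"""Independent brute-force oracle for per-frame quantification.

Deliberately naive and dependency-free (pure-Python loops, hand-written
flood fill) so it shares no code path with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def brute_force_quantify(frame, threshold, roi, mask=None, min_blob_px=1):
    """Exhaustive per-pixel re-statement of the detection definition.

    Candidate pixels: inside the half-open ROI, not masked, intensity
    strictly above threshold. Objects: 8-connected components of candidates
    with >= min_blob_px pixels. Returns (total_fluorescence, n_objects).
    """
    frame = np.asarray(frame)
    r0, r1, c0, c1 = roi
    h, w = frame.shape
    candidate = [[False] * w for _ in range(h)]
    for i in range(r0, r1):
        for j in range(c0, c1):
            if mask is not None and mask[i][j]:
                continue
            if frame[i][j] > threshold:
                candidate[i][j] = True

    seen = [[False] * w for _ in range(h)]
    total = 0.0
    n_objects = 0
    for i in range(h):
        for j in range(w):
            if not candidate[i][j] or seen[i][j]:
                continue
            # flood fill one 8-connected component
            stack = [(i, j)]
            seen[i][j] = True
            component = []
            while stack:
                y, x = stack.pop()
                component.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w:
                            if candidate[ny][nx] and not seen[ny][nx]:
                                seen[ny][nx] = True
                                stack.append((ny, nx))
            if len(component) >= min_blob_px:
                n_objects += 1
                for y, x in component:
                    total += float(frame[y][x])
    return total, n_objects


def random_quantification_case(rng):
    """One random (frame, threshold, roi, mask, min_blob_px) test case."""
    h = int(rng.integers(3, 33))
    w = int(rng.integers(3, 33))
    frame = rng.integers(0, 256, size=(h, w)).astype(float)
    # sprinkle a few bright blobs so components of varied size exist
    for _ in range(int(rng.integers(0, 4))):
        cy, cx = int(rng.integers(0, h)), int(rng.integers(0, w))
        r = int(rng.integers(1, 4))
        yy, xx = np.mgrid[max(0, cy - r) : min(h, cy + r + 1),
                          max(0, cx - r) : min(w, cx + r + 1)]
        frame[yy, xx] = float(rng.integers(200, 1000))
    r0 = int(rng.integers(0, h - 1))
    r1 = int(rng.integers(r0 + 1, h + 1))
    c0 = int(rng.integers(0, w - 1))
    c1 = int(rng.integers(c0 + 1, w + 1))
    mask = (rng.random((h, w)) < 0.15).astype(np.uint8) if rng.random() < 0.5 else None
    threshold = float(rng.integers(0, 300))
    min_blob_px = int(rng.integers(1, 5))
    return frame, threshold, (r0, r1, c0, c1), mask, min_blob_px
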
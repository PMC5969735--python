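"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by the most literal method
available (nested loops, exhaustive search) so they stay independent of the
library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_box_count(pixels: np.ndarray, s: int) -> int:
    """Nested-loop count of occupied s x s boxes on an origin-anchored grid."""
    h, w = pixels.shape
    n = 0
    for r0 in range(0, h, s):
        for c0 in range(0, w, s):
            if pixels[r0:r0 + s, c0:c0 + s].any():
                n += 1
    return n


def brute_force_otsu(pixels: np.ndarray) -> int:
    """Exhaustive search of the integer threshold maximizing between-class
    variance, with the dark class defined as intensity <= t."""
    flat = pixels.ravel().astype(int)
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / flat.size
        w1 = 1.0 - w0
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def zhang_suen_thin(mask: np.ndarray) -> np.ndarray:
    """Reference two-subiteration (Zhang-Suen) thinning, literal pseudocode."""
    img = np.pad(mask.astype(np.uint8), 1)

    def neighbours(r, c):
        return [img[r - 1, c], img[r - 1, c + 1], img[r, c + 1], img[r + 1, c + 1],
                img[r + 1, c], img[r + 1, c - 1], img[r, c - 1], img[r - 1, c - 1]]

    changed = True
    while changed:
        changed = False
        for step in (0, 1):
            to_delete = []
            rows, cols = np.nonzero(img)
            for r, c in zip(rows, cols):
                p = neighbours(r, c)
                b = sum(p)
                if not (2 <= b <= 6):
                    continue
                a = sum(1 for k in range(8) if p[k] == 0 and p[(k + 1) % 8] == 1)
                if a != 1:
                    continue
                if step == 0:
                    if p[0] * p[2] * p[4] != 0 or p[2] * p[4] * p[6] != 0:
                        continue
                else:
                    if p[0] * p[2] * p[6] != 0 or p[0] * p[4] * p[6] != 0:
                        continue
                to_delete.append((r, c))
            for r, c in to_delete:
                img[r, c] = 0
            changed = changed or bool(to_delete)
    return img[1:-1, 1:-1].astype(bool)


def brute_force_component_widths(pixels: np.ndarray) -> list[float]:
    """Per 8-connected component: caliper width = 2 x max over component
    pixels of the Euclidean distance to the nearest in-array background
    pixel (distances computed by exhaustive pairwise search)."""
    h, w = pixels.shape
    seen = np.zeros_like(pixels, dtype=bool)
    bg = [(r, c) for r in range(h) for c in range(w) if not pixels[r, c]]

    def dist_to_bg(r, c):
        return min(np.hypot(r - rb, c - cb) for rb, cb in bg)

    widths = []
    for r in range(h):
        for c in range(w):
            if not pixels[r, c] or seen[r, c]:
                continue
            stack, comp = [(r, c)], []
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                comp.append((rr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < h and 0 <= c2 < w and pixels[r2, c2] and not seen[r2, c2]:
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            widths.append(2.0 * max(dist_to_bg(rr, cc) for rr, cc in comp))
    return widths


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def sierpinski8() -> np.ndarray:
    """8x8 Pascal-triangle-mod-2 mask: 27 foreground pixels."""
    idx = np.arange(8)
    return np.bitwise_and.outer(idx, idx) == 0


@pytest.fixture(scope="session")
def default_simulation():
    """One default-parameter simulated plexus scene (seeded)."""
    from vasoquant import VascularTreeParams, simulate_vascular_tree

    return simulate_vascular_tree(VascularTreeParams(seed=7))
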
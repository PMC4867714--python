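"""Independent reference implementations used only to check the library.

Deliberately naive: scalar triple loops and closed-form geometry, sharing no
code with the vectorized implementations under test.
"""

from __future__ import annotations

import numpy as np

OFFSETS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
OFFSETS_4 = [(-1, 0), (0, -1), (0, 1), (1, 0)]


def growcut_bruteforce(
    values: np.ndarray,
    labels0: np.ndarray,
    strengths0: np.ndarray,
    c_max: float = 1.0,
    neighborhood: int = 8,
    max_iter: int = 1000,
):
    """Naive synchronous grow-cut: for every cell scan its labeled neighbors in
    row-major order, keep the strictly strongest attack lambda = g * theta with
    g = 1 - |dC| / c_max, and conquer if it strictly exceeds the cell's own
    strength. Returns (labels, strengths, converged)."""
    labels = labels0.copy()
    strengths = strengths0.astype(float).copy()
    h, w = values.shape
    offs = OFFSETS_8 if neighborhood == 8 else OFFSETS_4
    for _ in range(max_iter):
        new_labels = labels.copy()
        new_strengths = strengths.copy()
        changed = 0
        for r in range(h):
            for c in range(w):
                best_lam = 0.0
                best_lab = 0
                for dr, dc in offs:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w):
                        continue
                    if labels[rr, cc] == 0:
                        continue
                    g = 1.0 - abs(values[r, c] - values[rr, cc]) / c_max
                    lam = g * strengths[rr, cc]
                    if lam > best_lam:
                        best_lam = lam
                        best_lab = labels[rr, cc]
                if best_lam > strengths[r, c]:
                    new_labels[r, c] = best_lab
                    new_strengths[r, c] = best_lam
                    changed += 1
        labels, strengths = new_labels, new_strengths
        if changed == 0:
            return labels, strengths, True
    return labels, strengths, False


def chebyshev_nearest_partition(
    shape: tuple[int, int],
    fg_seeds: list[tuple[int, int]],
    bg_seeds: list[tuple[int, int]],
) -> np.ndarray:
    """Label every cell by its nearest seed set under Chebyshev distance.

    Returns int8 field with +1 / -1; exactly tied cells get 0 (caller should
    pick seed layouts without ties when asserting equality)."""
    h, w = shape
    out = np.zeros((h, w), dtype=np.int8)
    for r in range(h):
        for c in range(w):
            dfg = min(max(abs(r - sr), abs(c - sc)) for sr, sc in fg_seeds)
            dbg = min(max(abs(r - sr), abs(c - sc)) for sr, sc in bg_seeds)
            if dfg < dbg:
                out[r, c] = 1
            elif dbg < dfg:
                out[r, c] = -1
    return out


def random_seeded_grid(rng: np.random.Generator, h: int = 6, w: int = 6):
    """Random intensities plus non-overlapping random fg/bg seed cells."""
    values = rng.random((h, w))
    labels = np.zeros((h, w), dtype=np.int8)
    strengths = np.zeros((h, w), dtype=float)
    n_fg = int(rng.integers(1, 4))
    n_bg = int(rng.integers(1, 4))
    cells = rng.permutation(h * w)[: n_fg + n_bg]
    for i, flat in enumerate(cells):
        r, c = divmod(int(flat), w)
        labels[r, c] = 1 if i < n_fg else -1
        strengths[r, c] = 1.0
    return values, labels, strengths
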
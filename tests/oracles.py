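"""Independent brute-force oracles used only by the tests.

Everything here is written with explicit Python loops or first-principles
formulas, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def flood_fill_components(binary: np.ndarray, connectivity: int = 8):
    """Connected components of a 0/1 grid via breadth-first flood fill."""
    h, w = binary.shape
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros((h, w), dtype=bool)
    components = []
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                queue = deque([(r, c)])
                seen[r, c] = True
                pixels = []
                while queue:
                    rr, cc = queue.popleft()
                    pixels.append((rr, cc))
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < h and 0 <= nc < w and binary[nr, nc]
                                and not seen[nr, nc]):
                            seen[nr, nc] = True
                            queue.append((nr, nc))
                components.append(pixels)
    return components


def cross_entropy_brute(p: np.ndarray, q: np.ndarray, eps: float = 1e-7) -> float:
    """Binary-style cross-entropy summed with explicit loops."""
    pf = p.reshape(-1, 3)
    qf = q.reshape(-1, 3)
    n = pf.shape[0]
    total = 0.0
    for a in range(n):
        for i in range(3):
            qa = min(max(float(qf[a, i]), eps), 1.0 - eps)
            pa = float(pf[a, i])
            total += pa * math.log(qa) + (1.0 - pa) * math.log(1.0 - qa)
    return -total / n


def jaccard_index_brute(p: np.ndarray, q: np.ndarray, eps: float = 1e-7) -> float:
    pf = p.reshape(-1, 3)
    qf = q.reshape(-1, 3)
    n = pf.shape[0]
    inter = 0.0
    for a in range(n):
        for i in range(3):
            inter += float(pf[a, i]) * min(max(float(qf[a, i]), eps), 1.0 - eps)
    return inter / (2.0 * n - inter)


def jaccard_loss_brute(p: np.ndarray, q: np.ndarray) -> float:
    return -math.log(max(jaccard_index_brute(p, q), 1e-7))


def gap_brute(f: np.ndarray) -> np.ndarray:
    """Global average pool with explicit loops."""
    h, w, k = f.shape
    v = np.zeros(k)
    for kk in range(k):
        total = 0.0
        for i in range(h):
            for j in range(w):
                total += float(f[i, j, kk])
        v[kk] = total / (h * w)
    return v


def cam_brute(f: np.ndarray, w: np.ndarray, m: int) -> np.ndarray:
    h, wd, k = f.shape
    cam = np.zeros((h, wd))
    for i in range(h):
        for j in range(wd):
            for kk in range(k):
                cam[i, j] += float(w[m, kk]) * float(f[i, j, kk])
    return cam


def confusion_brute(pred, true, cls: int):
    """(TP, TN, FP, FN) counted one sample at a time."""
    tp = tn = fp = fn = 0
    for p, t in zip(pred, true):
        if p == cls and t == cls:
            tp += 1
        elif p == cls and t != cls:
            fp += 1
        elif p != cls and t == cls:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def binomial_99_interval(p: float, n: int) -> float:
    """Half-width of the normal-approximation 99% interval for a proportion."""
    return 2.5758 * math.sqrt(p * (1.0 - p) / n)
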
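"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — per-pixel loops, explicit pair /
run / zone enumeration, pairwise concordance counting — and shares no
code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def brute_pixel_counts(pred: np.ndarray, true: np.ndarray):
    tp = fp = fn = tn = 0
    for p, t in zip(pred.ravel(), true.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_seg_metrics(pred: np.ndarray, true: np.ndarray):
    tp, fp, fn, tn = brute_pixel_counts(pred, true)
    acc = (tp + tn) / (tp + fp + fn + tn)
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    return acc, pre, rec, f1


def brute_glcm(levels: np.ndarray, ng: int, offset: tuple[int, int]):
    """Symmetric normalised co-occurrence counts, or None if no pair."""
    h, w = levels.shape
    cnt = np.zeros((ng, ng))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + offset[0], c + offset[1]
            if 0 <= r2 < h and 0 <= c2 < w and levels[r, c] > 0 and levels[r2, c2] > 0:
                cnt[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    cnt = cnt + cnt.T
    return cnt / cnt.sum() if cnt.sum() else None


def brute_runs(levels: np.ndarray, lines) -> list[tuple[int, int]]:
    """(level, length) of all maximal equal-level runs over scan lines."""
    out = []
    for line in lines:
        cur, n = 0, 0
        for v in list(line) + [0]:
            if v == cur and v != 0:
                n += 1
            else:
                if cur != 0:
                    out.append((int(cur), n))
                cur, n = int(v), 1
    return sorted(out)


def brute_zones(levels: np.ndarray) -> list[tuple[int, int]]:
    """(level, size) of all 8-connected equal-level zones, by flood fill."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if levels[r, c] > 0 and not seen[r, c]:
                g = levels[r, c]
                stack, size = [(r, c)], 0
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (0 <= ny < h and 0 <= nx < w and not seen[ny, nx]
                                    and levels[ny, nx] == g):
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                zones.append((int(g), size))
    return sorted(zones)


def brute_euclidean_extension(mask: np.ndarray, d: float) -> np.ndarray:
    """Pixels within Euclidean distance d of any foreground pixel."""
    h, w = mask.shape
    fg = np.argwhere(mask > 0)
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            dist2 = ((fg[:, 0] - r) ** 2 + (fg[:, 1] - c) ** 2).min()
            if dist2 <= d * d:
                out[r, c] = 1
    return out


def brute_ovr_auc(y: np.ndarray, scores: np.ndarray, cls: int) -> float:
    """One-vs-rest AUC by pairwise concordance (ties count half)."""
    pos = scores[y == cls]
    neg = scores[y != cls]
    total = conc = 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                conc += 1
            elif p == n:
                conc += 0.5
    return conc / total


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar f w.r.t. array x (in place)."""
    g = np.zeros(x.shape, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        lp = f()
        x[i] = orig - eps
        lm = f()
        x[i] = orig
        g[i] = (lp - lm) / (2 * eps)
    return g
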
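"""Independent brute-force reference implementations used by the tests.

These deliberately use nested loops / exhaustive enumeration and no
code from the package under test.
"""

from __future__ import annotations

import math

import numpy as np


def median_filter_loops(frame: np.ndarray, size: int) -> np.ndarray:
    """Per-pixel median with edge replication, nested loops."""
    h, w = frame.shape
    r = size // 2
    out = np.empty_like(frame)
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    vals.append(frame[ii, jj])
            vals.sort()
            out[i, j] = vals[len(vals) // 2]
    return out


def otsu_threshold_exhaustive(frame: np.ndarray) -> int:
    """Integer threshold maximizing between-class variance over 0..254."""
    counts = np.bincount(frame.ravel(), minlength=256).astype(float)
    total = counts.sum()
    best_t, best_v = 0, -1.0
    for t in range(255):
        w0 = counts[:t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (np.arange(t + 1) * counts[:t + 1]).sum() / w0
        mu1 = (np.arange(t + 1, 256) * counts[t + 1:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def component_filter_floodfill(mask: np.ndarray, min_pixels: int) -> np.ndarray:
    """Keep 8-connected components of size >= min_pixels (BFS flood fill)."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                comp = []
                while stack:
                    a, b = stack.pop()
                    comp.append((a, b))
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            aa, bb = a + da, b + db
                            if (0 <= aa < h and 0 <= bb < w
                                    and mask[aa, bb] and not seen[aa, bb]):
                                seen[aa, bb] = True
                                stack.append((aa, bb))
                if len(comp) >= min_pixels:
                    for a, b in comp:
                        out[a, b] = True
    return out


def roi_features_loops(grid: np.ndarray) -> list[float]:
    """f1..f7 by nested loops, straight from the definitions."""
    m = len(grid)
    n = len(grid[0])
    vals = [float(grid[i][j]) for i in range(m) for j in range(n)]

    def mean(xs):
        return sum(xs) / len(xs)

    def var(xs):  # sample variance, 0 for a single observation
        if len(xs) < 2:
            return 0.0
        mu = mean(xs)
        return sum((x - mu) ** 2 for x in xs) / (len(xs) - 1)

    def med(xs):
        s = sorted(xs)
        k = len(s)
        return (s[k // 2] if k % 2 else (s[k // 2 - 1] + s[k // 2]) / 2.0)

    f1 = mean(vals)
    f2 = var(vals)
    f3 = mean([var([grid[i][j] for j in range(n)]) for i in range(m)])
    f4 = mean([var([grid[i][j] for i in range(m)]) for j in range(n)])
    f5 = med(vals)
    f6 = mean([med([grid[i][j] for j in range(n)]) for i in range(m)])
    f7 = mean([med([grid[i][j] for i in range(m)]) for j in range(n)])
    return [f1, f2, f3, f4, f5, f6, f7]


def frame_vector_loops(grids: list[np.ndarray]) -> list[float]:
    """The 154-entry vector from 11 ROI grids, per the definitions."""
    base = [roi_features_loops(g) for g in grids]
    out = []
    for k in range(len(grids)):
        diffs = ([0.0] * 7 if k == 0 else
                 [base[k][c] - base[k - 1][c] for c in range(7)])
        out.extend(base[k] + diffs)
    return out


def nca_pij_loops(X: np.ndarray, w: np.ndarray, sigma: float) -> np.ndarray:
    """p_ij by double loops from the distance and softmax definitions."""
    n, d = X.shape
    dist = [[sum(w[l] ** 2 * abs(X[i, l] - X[j, l]) for l in range(d))
             for j in range(n)] for i in range(n)]
    P = np.zeros((n, n))
    for i in range(n):
        z = sum(math.exp(-dist[i][k] / sigma) for k in range(n) if k != i)
        for j in range(n):
            if j != i:
                P[i, j] = math.exp(-dist[i][j] / sigma) / z
    return P


def metrics_loops(y_true, y_pred, labels):
    """Confusion-derived metrics from first principles."""
    n = len(y_true)
    idx = {lab: i for i, lab in enumerate(labels)}
    cm = [[0] * len(labels) for _ in labels]
    for t, p in zip(y_true, y_pred):
        cm[idx[t]][idx[p]] += 1
    acc = sum(cm[i][i] for i in range(len(labels))) / n
    per = {}
    for i, lab in enumerate(labels):
        tp = cm[i][i]
        fn = sum(cm[i]) - tp
        fp = sum(cm[r][i] for r in range(len(labels))) - tp
        tn = n - tp - fn - fp
        per[lab] = {
            "accuracy": (tp + tn) / n,
            "tpr": tp / (tp + fn) if tp + fn else float("nan"),
            "fpr": fp / (fp + tn) if fp + tn else float("nan"),
        }
    pe = sum(sum(cm[i]) * sum(cm[r][i] for r in range(len(labels)))
             for i in range(len(labels))) / n ** 2
    kappa = (acc - pe) / (1 - pe) if pe != 1 else 1.0
    return cm, acc, per, kappa


def truncnorm_rounded_mean(mu: float, sd: float, lo: float = 1.0,
                           hi: float = 9.0, n: int = 200_000,
                           seed: int = 12345) -> float:
    """Monte-Carlo expectation of a rounded [lo, hi]-truncated normal."""
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(mu, sd, size=n)
        draw = draw[(draw >= lo) & (draw <= hi)]
        out = np.concatenate([out, draw])
    return float(np.clip(np.rint(out[:n]), lo, hi).mean())
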
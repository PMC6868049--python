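"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible (explicit loops, direct
transcription of the textbook definitions) and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np

DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


# ---------------------------------------------------------------------------
# first-order histogram


def hist_oracle(image, mask) -> np.ndarray:
    x = np.asarray(image, float)[np.asarray(mask, bool)]
    n = x.size
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    if var > 0:
        skew = sum((v - mean) ** 3 for v in x) / n / sd**3
        kurt = sum((v - mean) ** 4 for v in x) / n / var**2 - 3.0
    else:
        skew = kurt = 0.0
    energy = sum(v * v for v in x)
    counts: Dict[float, int] = {}
    for v in x:
        counts[v] = counts.get(v, 0) + 1
    probs = [c / n for c in counts.values()]
    entropy = -sum(p * math.log2(p) for p in probs)
    uniformity = sum(p * p for p in probs)
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mad = sum(abs(v - mean) for v in x) / n
    return np.array([
        mean, var, sd, skew, kurt, energy, entropy,
        min(x), max(x), max(x) - min(x), med, p10, p90, p75 - p25,
        mad, uniformity,
    ])


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix_oracle(q, mask, levels, direction) -> np.ndarray:
    q = np.asarray(q)
    mask = np.asarray(mask, bool)
    h, w = q.shape
    dr, dc = direction
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[q[r, c] - 1, q[r2, c2] - 1] += 1
                counts[q[r2, c2] - 1, q[r, c] - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm_features_oracle(q, mask, levels) -> np.ndarray:
    mats = [glcm_matrix_oracle(q, mask, levels, d) for d in DIRECTIONS]
    P = sum(mats) / len(mats)
    Ng = levels
    i_idx = list(range(1, Ng + 1))
    px = [sum(P[i - 1][j - 1] for j in i_idx) for i in i_idx]
    mu = sum(i * px[i - 1] for i in i_idx)
    sigma = math.sqrt(sum((i - mu) ** 2 * px[i - 1] for i in i_idx))

    p_sum = {k: 0.0 for k in range(2, 2 * Ng + 1)}
    p_diff = {k: 0.0 for k in range(0, Ng)}
    for i in i_idx:
        for j in i_idx:
            p_sum[i + j] += P[i - 1][j - 1]
            p_diff[abs(i - j)] += P[i - 1][j - 1]

    def ent(vals):
        return -sum(p * math.log2(p) for p in vals if p > 0)

    autoc = sum(i * j * P[i - 1][j - 1] for i in i_idx for j in i_idx)
    cp = sum((i + j - 2 * mu) ** 4 * P[i - 1][j - 1] for i in i_idx for j in i_idx)
    cs = sum((i + j - 2 * mu) ** 3 * P[i - 1][j - 1] for i in i_idx for j in i_idx)
    ct = sum((i + j - 2 * mu) ** 2 * P[i - 1][j - 1] for i in i_idx for j in i_idx)
    contrast = sum((i - j) ** 2 * P[i - 1][j - 1] for i in i_idx for j in i_idx)
    correlation = (autoc - mu * mu) / (sigma * sigma) if sigma > 0 else 1.0
    da = sum(k * p for k, p in p_diff.items())
    de = ent(p_diff.values())
    dv = sum((k - da) ** 2 * p for k, p in p_diff.items())
    dissim = sum(abs(i - j) * P[i - 1][j - 1] for i in i_idx for j in i_idx)
    energy = sum(P[i - 1][j - 1] ** 2 for i in i_idx for j in i_idx)
    entropy = ent(P.ravel())
    homog = sum(P[i - 1][j - 1] / (1 + abs(i - j)) for i in i_idx for j in i_idx)
    idm = sum(P[i - 1][j - 1] / (1 + (i - j) ** 2) for i in i_idx for j in i_idx)
    hx = ent(px)
    hxy1 = -sum(
        P[i - 1][j - 1] * math.log2(px[i - 1] * px[j - 1])
        for i in i_idx for j in i_idx
        if P[i - 1][j - 1] > 0 and px[i - 1] * px[j - 1] > 0
    )
    hxy2 = ent([px[i - 1] * px[j - 1] for i in i_idx for j in i_idx])
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))
    invvar = sum(
        P[i - 1][j - 1] / (i - j) ** 2 for i in i_idx for j in i_idx if i != j
    )
    maxp = max(P[i - 1][j - 1] for i in i_idx for j in i_idx)
    sa = sum(k * p for k, p in p_sum.items())
    se = ent(p_sum.values())
    sv = sum((k - sa) ** 2 * p for k, p in p_sum.items())
    var = sum((i - mu) ** 2 * P[i - 1][j - 1] for i in i_idx for j in i_idx)
    return np.array([
        autoc, cp, cs, ct, contrast, correlation, da, de, dv, dissim,
        energy, entropy, homog, idm, imc1, imc2, invvar, mu, maxp,
        sa, se, sv, var,
    ])


# ---------------------------------------------------------------------------
# GLRLM


def runs_oracle(q, mask, direction) -> List[Tuple[int, int]]:
    """All maximal runs (level, length) along one direction."""
    q = np.asarray(q)
    mask = np.asarray(mask, bool)
    h, w = q.shape
    dr, dc = direction
    # starting points: cells with no valid same-run predecessor
    runs = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            pr, pc = r - dr, c - dc
            prev_ok = (
                0 <= pr < h and 0 <= pc < w and mask[pr, pc]
                and q[pr, pc] == q[r, c]
            )
            if prev_ok:
                continue
            length = 1
            nr, nc = r + dr, c + dc
            while (
                0 <= nr < h and 0 <= nc < w and mask[nr, nc]
                and q[nr, nc] == q[r, c]
            ):
                length += 1
                nr += dr
                nc += dc
            runs.append((int(q[r, c]), length))
    return runs


def glrlm_matrix_oracle(q, mask, levels, direction, max_len) -> np.ndarray:
    R = np.zeros((levels, max_len))
    for lvl, length in runs_oracle(q, mask, direction):
        R[lvl - 1, min(length, max_len) - 1] += 1
    return R


def rlm_features_oracle(M, n_pixels) -> np.ndarray:
    levels, max_len = M.shape
    N = M.sum()
    sre = lre = gln = rln = lgre = hgre = 0.0
    srlge = srhge = lrlge = lrhge = 0.0
    for i in range(1, levels + 1):
        row = sum(M[i - 1])
        gln += row * row
        for l in range(1, max_len + 1):
            m = M[i - 1, l - 1]
            sre += m / l**2
            lre += m * l**2
            lgre += m / i**2
            hgre += m * i**2
            srlge += m / (i**2 * l**2)
            srhge += m * i**2 / l**2
            lrlge += m * l**2 / i**2
            lrhge += m * i**2 * l**2
    for l in range(1, max_len + 1):
        col = sum(M[:, l - 1])
        rln += col * col
    p = M / N
    mu_i = sum(i * p[i - 1, l - 1] for i in range(1, levels + 1) for l in range(1, max_len + 1))
    glv = sum((i - mu_i) ** 2 * p[i - 1, l - 1] for i in range(1, levels + 1) for l in range(1, max_len + 1))
    mu_l = sum(l * p[i - 1, l - 1] for i in range(1, levels + 1) for l in range(1, max_len + 1))
    rlv = sum((l - mu_l) ** 2 * p[i - 1, l - 1] for i in range(1, levels + 1) for l in range(1, max_len + 1))
    return np.array([
        sre / N, lre / N, gln / N, rln / N, N / n_pixels, lgre / N,
        hgre / N, srlge / N, srhge / N, lrlge / N, lrhge / N, glv, rlv,
    ])


def glrlm_features_oracle(q, mask, levels) -> np.ndarray:
    h, w = np.asarray(q).shape
    max_len = max(h, w)
    mats = [glrlm_matrix_oracle(q, mask, levels, d, max_len) for d in DIRECTIONS]
    R = sum(mats) / len(mats)
    return rlm_features_oracle(R, int(np.asarray(mask, bool).sum()))


# ---------------------------------------------------------------------------
# GLSZM (flood-fill zones, 8-connected)


def zones_oracle(q, mask) -> List[Tuple[int, int]]:
    q = np.asarray(q)
    mask = np.asarray(mask, bool)
    h, w = q.shape
    seen = np.zeros((h, w), bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            lvl = q[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for ddr in (-1, 0, 1):
                    for ddc in (-1, 0, 1):
                        nr, nc = rr + ddr, cc + ddc
                        if (
                            0 <= nr < h and 0 <= nc < w and mask[nr, nc]
                            and not seen[nr, nc] and q[nr, nc] == lvl
                        ):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
            zones.append((int(lvl), size))
    return zones


def glszm_features_oracle(q, mask, levels) -> np.ndarray:
    mask = np.asarray(mask, bool)
    n_pixels = int(mask.sum())
    S = np.zeros((levels, n_pixels))
    for lvl, size in zones_oracle(q, mask):
        S[lvl - 1, size - 1] += 1
    return rlm_features_oracle(S, n_pixels)


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features_oracle(q, mask, levels, cap=1.0e6) -> np.ndarray:
    q = np.asarray(q, float)
    mask = np.asarray(mask, bool)
    h, w = q.shape
    n_i = np.zeros(levels)
    s_i = np.zeros(levels)
    N = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nb = []
            for ddr in (-1, 0, 1):
                for ddc in (-1, 0, 1):
                    if ddr == 0 and ddc == 0:
                        continue
                    nr, nc = r + ddr, c + ddc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc]:
                        nb.append(q[nr, nc])
            if not nb:
                continue
            lvl = int(q[r, c])
            n_i[lvl - 1] += 1
            s_i[lvl - 1] += abs(q[r, c] - sum(nb) / len(nb))
            N += 1
    p_i = n_i / N
    present = [i for i in range(levels) if p_i[i] > 0]
    ngp = len(present)
    denom = sum(p_i[i] * s_i[i] for i in present)
    coarseness = min(cap, 1.0 / denom) if denom > 0 else cap
    if ngp > 1:
        contrast = (
            sum(
                p_i[a] * p_i[b] * (a - b) ** 2
                for a in present for b in present
            )
            / (ngp * (ngp - 1))
            * sum(s_i) / N
        )
        busy_den = sum(
            abs((a + 1) * p_i[a] - (b + 1) * p_i[b])
            for a in present for b in present
        )
        busyness = denom / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs(a - b) * (p_i[a] * s_i[a] + p_i[b] * s_i[b]) / (p_i[a] + p_i[b])
                for a in present for b in present
            )
            / N
        )
        s_sum = sum(s_i)
        strength = (
            sum((p_i[a] + p_i[b]) * (a - b) ** 2 for a in present for b in present)
            / s_sum
            if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return np.array([coarseness, contrast, busyness, complexity, strength])


# ---------------------------------------------------------------------------
# misc oracles


def haar2x2_oracle(a, b, c, d) -> Tuple[float, float, float, float]:
    """Closed-form 2-D orthonormal Haar butterflies of one 2x2 block."""
    ll = (a + b + c + d) / 2.0
    lh = (a - b + c - d) / 2.0
    hl = (a + b - c - d) / 2.0
    hh = (a - b - c + d) / 2.0
    return ll, lh, hl, hh


def ista_lasso(X, y, lam, n_steps=200000, tol=1e-12) -> np.ndarray:
    """Proximal-gradient (ISTA) solver for the sklearn-scaled lasso:
    min_w 1/(2n)||y - Xw - b||^2 + lam*||w||_1, with intercept b.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    w = np.zeros(p)
    b = float(np.mean(y))
    L = np.linalg.norm(X, 2) ** 2 / n + 1e-12
    for _ in range(n_steps):
        r = X @ w + b - y
        grad = X.T @ r / n
        w_new = w - grad / L
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - lam / L, 0.0)
        b_new = b - np.mean(r)
        if max(np.max(np.abs(w_new - w)), abs(b_new - b)) < tol:
            w, b = w_new, b_new
            break
        w, b = w_new, b_new
    return w


def mann_whitney_auc(scores, y) -> float:
    """AUC as the normalised count of concordant positive-negative pairs."""
    scores = np.asarray(scores, float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for s_p in pos:
        for s_n in neg:
            if s_p > s_n:
                total += 1.0
            elif s_p == s_n:
                total += 0.5
    return total / (pos.size * neg.size)


def points_in_quad_bruteforce(quad, frame_shape) -> int:
    """Count integer grid points inside/on a convex quadrilateral, by angle-
    sorting the corners and testing every pixel against each edge."""
    quad = np.asarray(quad, float)
    cen = quad.mean(axis=0)
    order = np.argsort(np.arctan2(quad[:, 0] - cen[0], quad[:, 1] - cen[1]))
    quad = quad[order]
    count = 0
    for r in range(frame_shape[0]):
        for c in range(frame_shape[1]):
            on_edge = False
            signs = []
            for k in range(4):
                r0, c0 = quad[k]
                r1, c1 = quad[(k + 1) % 4]
                cross = (r1 - r0) * (c - c0) - (c1 - c0) * (r - r0)
                signs.append(cross)
                if abs(cross) < 1e-9 and (
                    min(r0, r1) - 1e-9 <= r <= max(r0, r1) + 1e-9
                    and min(c0, c1) - 1e-9 <= c <= max(c0, c1) + 1e-9
                ):
                    on_edge = True
            # inside iff all edge cross products share a sign (convex hull)
            pos_ok = all(s >= -1e-9 for s in signs)
            neg_ok = all(s <= 1e-9 for s in signs)
            if on_edge or pos_ok or neg_ok:
                count += 1
    return count
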
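"""Brute-force reference implementations, independent of the package.

Everything here is written as plain loops / exact arithmetic so it can
serve as an oracle for the vectorized implementations.
"""
from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def subtract_loop(pre, post):
    out = np.empty_like(np.asarray(pre, dtype=float))
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            out[r, c] = float(post[r, c]) - float(pre[r, c])
    return out


def quantize_loop(image, mask, n_levels):
    vals = [image[r, c] for r, c in zip(*np.nonzero(mask))]
    lo, hi = min(vals), max(vals)
    levels = np.zeros(image.shape, dtype=int)
    for r, c in zip(*np.nonzero(mask)):
        if hi == lo:
            levels[r, c] = 1
        else:
            lev = math.floor((image[r, c] - lo) / (hi - lo) * n_levels) + 1
            levels[r, c] = min(max(lev, 1), n_levels)
    return levels


def moments_loop(values):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    skew = (sum((v - mean) ** 3 for v in values) / n) / var**1.5
    kurt = (sum((v - mean) ** 4 for v in values) / n) / var**2 - 3.0
    return mean, var, skew, kurt


def glcm_loop(levels, mask, offset, n_levels):
    """Exhaustive symmetric pair counting, normalized."""
    a, b = offset
    mat = np.zeros((n_levels, n_levels))
    h, w = levels.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + a, c + b
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i, j = levels[r, c] - 1, levels[r2, c2] - 1
                mat[i, j] += 1
                mat[j, i] += 1
    total = mat.sum()
    return mat / total if total else mat


def glcm_stats_loop(p):
    """Scalar double-loop evaluation of the 19 co-occurrence statistics."""
    n = p.shape[0]
    px = [sum(p[i, j] for j in range(n)) for i in range(n)]
    py = [sum(p[i, j] for i in range(n)) for j in range(n)]
    mux = sum((i + 1) * px[i] for i in range(n))
    muy = sum((j + 1) * py[j] for j in range(n))
    sdx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(n)))
    sdy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(n)))

    def xlogx(v):
        return v * math.log(v) if v > 0 else 0.0

    acor = con = cor_num = cp = cs = dis = ene = ent = hom = sos = 0.0
    idn = idmn = hxy1 = 0.0
    mp = 0.0
    for i in range(n):
        for j in range(n):
            v = p[i, j]
            li, lj = i + 1, j + 1
            acor += li * lj * v
            con += (li - lj) ** 2 * v
            cor_num += li * lj * v
            cp += (li + lj - mux - muy) ** 4 * v
            cs += (li + lj - mux - muy) ** 3 * v
            dis += abs(li - lj) * v
            ene += v * v
            ent -= xlogx(v)
            hom += v / (1 + (li - lj) ** 2)
            mp = max(mp, v)
            sos += (li - mux) ** 2 * v
            idn += v / (1 + abs(li - lj) / n)
            idmn += v / (1 + (li - lj) ** 2 / n**2)
            if v > 0 and px[i] * py[j] > 0:
                hxy1 -= v * math.log(px[i] * py[j])
    psum = {}
    pdiff = {}
    for i in range(n):
        for j in range(n):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i, j]
    sa = sum(k * v for k, v in psum.items())
    sv = sum((k - sa) ** 2 * v for k, v in psum.items())
    se = -sum(xlogx(v) for v in psum.values())
    dmean = sum(k * v for k, v in pdiff.items())
    dv = sum((k - dmean) ** 2 * v for k, v in pdiff.items())
    de = -sum(xlogx(v) for v in pdiff.values())
    hx = -sum(xlogx(v) for v in px)
    hy = -sum(xlogx(v) for v in py)
    return {
        "ACOR": acor,
        "CON": con,
        "COR": 0.0 if sdx * sdy == 0 else (cor_num - mux * muy) / (sdx * sdy),
        "CP": cp,
        "CS": cs,
        "DIS": dis,
        "ENE": ene,
        "ENT": ent,
        "HOM": hom,
        "MP": mp,
        "SOS": sos,
        "SA": sa,
        "SV": sv,
        "SE": se,
        "DV": dv,
        "DE": de,
        "IMC": 0.0 if max(hx, hy) == 0 else (ent - hxy1) / max(hx, hy),
        "IDN": idn,
        "IDMN": idmn,
    }


_DIRECTIONS = {0: (0, 1), 90: (1, 0), 45: (-1, 1), 135: (1, 1)}


def grlm_loop(levels, mask, angle, n_levels, max_len):
    """Maximal-run enumeration by walking every run start explicitly."""
    dr, dc = _DIRECTIONS[angle]
    h, w = levels.shape
    mat = np.zeros((n_levels, max_len))

    def inside(r, c):
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            lev = levels[r, c]
            pr, pc = r - dr, c - dc
            if inside(pr, pc) and levels[pr, pc] == lev:
                continue  # not a run start
            length = 0
            rr, cc = r, c
            while inside(rr, cc) and levels[rr, cc] == lev:
                length += 1
                rr, cc = rr + dr, cc + dc
            mat[lev - 1, length - 1] += 1
    return mat


def auc_pairs(scores, labels):
    """Mann-Whitney AUC by exhaustive pair enumeration."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def fisher_2x2_enumeration(table):
    """Two-sided Fisher p by summing the full hypergeometric support
    with exact rational arithmetic."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return (
            Fraction(math.comb(r1, x)) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        p_x = prob(x)
        if p_x <= p_obs:
            total += p_x
    return float(total)


def erosion_loop(mask, struct):
    h, w = mask.shape
    sh, sw = struct.shape
    oh, ow = sh // 2, sw // 2
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            ok = True
            for i in range(sh):
                for j in range(sw):
                    if not struct[i, j]:
                        continue
                    rr, cc = r + i - oh, c + j - ow
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        ok = False
            out[r, c] = ok
    return out


def dilation_loop(mask, struct):
    h, w = mask.shape
    sh, sw = struct.shape
    oh, ow = sh // 2, sw // 2
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            hit = False
            for i in range(sh):
                for j in range(sw):
                    if not struct[i, j]:
                        continue
                    rr, cc = r - (i - oh), c - (j - ow)
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                        hit = True
            out[r, c] = hit
    return out
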
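"""Independent brute-force oracles used to validate the vectorized
implementations. Everything here is deliberately written as explicit loops /
full enumeration and shares no code with the package internals."""

from __future__ import annotations

import itertools
import math

import numpy as np


def reflect_index(i: int, n: int) -> int:
    """Half-sample symmetric reflection: (d c b a | a b c d | d c b a)."""
    while i < 0 or i >= n:
        if i < 0:
            i = -i - 1
        if i >= n:
            i = 2 * n - i - 1
    return i


def gauss_taps(sigma: float, order: int, truncate: float = 4.0):
    radius = int(truncate * sigma + 0.5)
    offsets = list(range(-radius, radius + 1))
    g = [math.exp(-(o * o) / (2.0 * sigma * sigma)) for o in offsets]
    s = sum(g)
    g = [v / s for v in g]
    if order == 1:
        g = [v * (-o / (sigma * sigma)) for v, o in zip(g, offsets)]
    return offsets, g


def sep_correlate_loop(img: np.ndarray, ky_off, ky, kx_off, kx) -> np.ndarray:
    """Separable correlation with reflect boundaries, pixel by pixel."""
    h, w = img.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for oy, wy in zip(ky_off, ky):
                yy = reflect_index(y + oy, h)
                for ox, wx in zip(kx_off, kx):
                    xx = reflect_index(x + ox, w)
                    acc += wy * wx * img[yy, xx]
            out[y, x] = acc
    return out


def structure_tensor_loop(img: np.ndarray, gradient_sigma: float, window_sigma: float):
    """Loop reimplementation of Gaussian-derivative structure tensor."""
    o0, g0 = gauss_taps(gradient_sigma, 0)
    o1, g1 = gauss_taps(gradient_sigma, 1)
    gx = sep_correlate_loop(img, o0, g0, o1, g1)
    gy = sep_correlate_loop(img, o1, g1, o0, g0)
    ow, gw = gauss_taps(window_sigma, 0)
    jxx = sep_correlate_loop(gx * gx, ow, gw, ow, gw)
    jxy = sep_correlate_loop(gx * gy, ow, gw, ow, gw)
    jyy = sep_correlate_loop(gy * gy, ow, gw, ow, gw)
    return jxx, jxy, jyy


def max_project_loop(voxels: np.ndarray) -> np.ndarray:
    nz, h, w = voxels.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            best = voxels[0, y, x]
            for z in range(1, nz):
                if voxels[z, y, x] > best:
                    best = voxels[z, y, x]
            out[y, x] = best
    return out


def threshold_count_loop(img: np.ndarray, threshold: float) -> int:
    n = 0
    for v in img.ravel():
        if v > threshold:
            n += 1
    return n


def normalized_bshg_loop(bshg: np.ndarray, ifimg: np.ndarray, mask: np.ndarray) -> float:
    sb = si = 0.0
    n = 0
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                sb += bshg[y, x]
                si += ifimg[y, x]
                n += 1
    return (sb / n) / (si / n)


def fb_mean_loop(fshg: np.ndarray, bshg: np.ndarray, mask: np.ndarray) -> float:
    acc = 0.0
    n = 0
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                acc += fshg[y, x] / bshg[y, x]
                n += 1
    return acc / n


def mean_sem_loop(values):
    n = len(values)
    m = sum(values) / n
    ss = sum((v - m) ** 2 for v in values)
    return m, math.sqrt(ss / (n - 1)) / math.sqrt(n)


def _u_statistic(x, y) -> float:
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def mann_whitney_exact_enum(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every group labeling."""
    a, b = list(a), list(b)
    n1 = len(a)
    combined = a + b
    u_obs = _u_statistic(a, b)
    n_le = n_ge = total = 0
    idx = range(len(combined))
    for chosen in itertools.combinations(idx, n1):
        chosen_set = set(chosen)
        x = [combined[i] for i in chosen]
        y = [combined[i] for i in idx if i not in chosen_set]
        u = _u_statistic(x, y)
        total += 1
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le / total, n_ge / total))


def student_t_loop(a, b):
    """Pooled-variance unpaired t statistic and two-sided p via scipy's t CDF
    is avoided; returns statistic and df only (p checked against survival
    function where needed)."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ssa = sum((v - ma) ** 2 for v in a)
    ssb = sum((v - mb) ** 2 for v in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return t, df
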
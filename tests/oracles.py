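"""Independent brute-force oracles used by the test suite.

Everything here is written as plain double loops over pixels and stencil
offsets, mirroring the defining sums directly, so it shares no code path
with the package's separable-convolution implementation.
"""
from __future__ import annotations

import numpy as np

GUARD = 1e-10


def bf_heaviside(x, eps):
    if x > eps:
        return 1.0
    if x < -eps:
        return 0.0
    return 0.5 * (1.0 + 2.0 * np.arctan(x / eps) / np.pi)


def bf_dirac(x, eps):
    return (eps / np.pi) / (eps * eps + x * x)


def bf_fitting_means(image, phi, weights2d, radius, eps):
    """f1/f2 by direct double summation, stencil clipped at borders."""
    h, w = image.shape
    f1 = np.empty((h, w))
    f2 = np.empty((h, w))
    defined = np.ones((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            n1 = d1 = n2 = d2 = pn = pd = 0.0
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    y_r, y_c = r + dr, c + dc
                    if not (0 <= y_r < h and 0 <= y_c < w):
                        continue
                    kw = weights2d[dr + radius, dc + radius]
                    hin = bf_heaviside(-phi[y_r, y_c], eps)
                    i = image[y_r, y_c]
                    n1 += kw * hin * i
                    d1 += kw * hin
                    n2 += kw * (1.0 - hin) * i
                    d2 += kw * (1.0 - hin)
                    pn += kw * i
                    pd += kw
            plain = pn / max(pd, GUARD)
            if d1 >= GUARD:
                f1[r, c] = n1 / d1
            else:
                f1[r, c] = plain
                defined[r, c] = False
            if d2 >= GUARD:
                f2[r, c] = n2 / d2
            else:
                f2[r, c] = plain
                defined[r, c] = False
    return f1, f2, defined


def bf_data_force(image, phi, f1, f2, weights2d, radius, eps, lam1, lam2):
    """delta(phi_z) * sum_x K(z,x) [l1 (I(z)-f1(x))^2 - l2 (I(z)-f2(x))^2]."""
    h, w = image.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            acc = 0.0
            iz = image[r, c]
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    x_r, x_c = r + dr, c + dc
                    if not (0 <= x_r < h and 0 <= x_c < w):
                        continue
                    kw = weights2d[dr + radius, dc + radius]
                    acc += kw * (
                        lam1 * (iz - f1[x_r, x_c]) ** 2
                        - lam2 * (iz - f2[x_r, x_c]) ** 2
                    )
            out[r, c] = bf_dirac(phi[r, c], eps) * acc
    return out


def bf_total_energy(image, phi, weights2d, radius, eps, lam1, lam2, v, mu):
    """Eq-by-eq double summation of the full energy."""
    h, w = image.shape
    f1, f2, _ = bf_fitting_means(image, phi, weights2d, radius, eps)
    e_data = 0.0
    for r in range(h):
        for c in range(w):
            inner = 0.0
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    y_r, y_c = r + dr, c + dc
                    if not (0 <= y_r < h and 0 <= y_c < w):
                        continue
                    kw = weights2d[dr + radius, dc + radius]
                    hin = bf_heaviside(-phi[y_r, y_c], eps)
                    i = image[y_r, y_c]
                    inner += kw * (
                        lam1 * hin * (i - f1[r, c]) ** 2
                        + lam2 * (1.0 - hin) * (i - f2[r, c]) ** 2
                    )
            e_data += bf_dirac(phi[r, c], eps) * inner
    gr, gc = np.gradient(phi)
    norm = np.hypot(gr, gc)
    delta = (eps / np.pi) / (eps * eps + phi * phi)
    e_len = v * float(np.sum(delta * norm))
    e_reg = mu * float(np.sum(0.5 * (norm - 1.0) ** 2))
    return e_data + e_len + e_reg


def bf_mrmse(truth, evolved, r):
    """Exhaustive nearest-within-window matching, straight from the rule."""
    truth = np.asarray(truth, float).reshape(-1, 2)
    evolved = np.asarray(evolved, float).reshape(-1, 2)
    n, m = len(truth), len(evolved)
    if n == 0:
        return 2.0 * r * r, 0, 0, m
    if m == 0:
        return 2.0 * r * r, 0, n, 0
    selected = [False] * m
    k1 = 0
    sq_sum = 0.0
    for i in range(n):
        best_j, best_d2 = -1, np.inf
        for j in range(m):
            dr = truth[i, 0] - evolved[j, 0]
            dc = truth[i, 1] - evolved[j, 1]
            if abs(dr) <= r and abs(dc) <= r:
                d2 = dr * dr + dc * dc
                if d2 < best_d2:
                    best_d2, best_j = d2, j
        if best_j >= 0:
            k1 += 1
            sq_sum += best_d2
            selected[best_j] = True
    k2 = n - k1
    k3 = 0
    for j in range(m):
        if selected[j]:
            continue
        sees_truth = any(
            abs(truth[i, 0] - evolved[j, 0]) <= r and abs(truth[i, 1] - evolved[j, 1]) <= r
            for i in range(n)
        )
        if not sees_truth:
            k3 += 1
    value = (sq_sum + 2.0 * (k2 + k3) * r * r) / (k1 + k2 + k3)
    return value, k1, k2, k3
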
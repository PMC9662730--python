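"""Literal per-pixel reference implementations of the texture operators.

These are deliberately naive double loops, written directly from the
operator definitions and independent of the vectorized implementations in
``spectrotex.texture``.  They are the primary oracle for the texture
module.
"""

import numpy as np

OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def ref_census(img):
    a = np.asarray(img, dtype=float)
    h, w = a.shape
    out = np.zeros((h - 2, w - 2), dtype=int)
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            code = 0
            for k, (di, dj) in enumerate(OFFSETS):
                bit = 1 if a[i, j] >= a[i + di, j + dj] else 0
                code |= bit << (7 - k)
            out[i - 1, j - 1] = code
    return out


def ref_riu2(code):
    bits = [(code >> b) & 1 for b in range(8)]
    u = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
    return sum(bits) if u <= 2 else 9


def ref_clbp(img, riu2=True):
    a = np.asarray(img, dtype=float)
    h, w = a.shape
    gray_mean = a.mean()
    mags = []
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            for di, dj in OFFSETS:
                mags.append(abs(a[i + di, j + dj] - a[i, j]))
    c_m = float(np.mean(mags))
    s_map = np.zeros((h - 2, w - 2), dtype=int)
    m_map = np.zeros((h - 2, w - 2), dtype=int)
    c_map = np.zeros((h - 2, w - 2), dtype=int)
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            s_code = m_code = 0
            for k, (di, dj) in enumerate(OFFSETS):
                d = a[i + di, j + dj] - a[i, j]
                if d >= 0:
                    s_code |= 1 << (7 - k)
                if abs(d) >= c_m:
                    m_code |= 1 << (7 - k)
            if riu2:
                s_code, m_code = ref_riu2(s_code), ref_riu2(m_code)
            s_map[i - 1, j - 1] = s_code
            m_map[i - 1, j - 1] = m_code
            c_map[i - 1, j - 1] = 1 if a[i, j] >= gray_mean else 0
    return s_map, m_map, c_map


def ref_ltp(img, mu=5.0):
    a = np.asarray(img, dtype=float)
    h, w = a.shape
    up = np.zeros((h - 2, w - 2), dtype=int)
    lo = np.zeros((h - 2, w - 2), dtype=int)
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            u_code = l_code = 0
            for k, (di, dj) in enumerate(OFFSETS):
                d = a[i + di, j + dj] - a[i, j]
                if d >= mu:
                    u_code |= 1 << (7 - k)
                elif d <= -mu:
                    l_code |= 1 << (7 - k)
            up[i - 1, j - 1] = u_code
            lo[i - 1, j - 1] = l_code
    return up, lo


def ref_blocks(h, w, levels=(0, 1, 2)):
    blocks = []
    for lv in sorted(levels):
        g = 2 ** lv
        bh, bw = h // g, w // g
        for i in range(g):
            for j in range(g):
                blocks.append((i * bh, (i + 1) * bh if i < g - 1 else h,
                               j * bw, (j + 1) * bw if j < g - 1 else w))
    return blocks


def ref_ccentrist(img, riu2=True, normalize=True):
    """Pixel-loop descriptor: per-block joint (S, M, C) histogram."""
    a = np.asarray(img, dtype=float)
    h, w = a.shape
    s_map, m_map, c_map = ref_clbp(a, riu2=riu2)
    n_sm = 10 if riu2 else 256
    parts = []
    for (r0, r1, c0, c1) in ref_blocks(h, w):
        hist = np.zeros((n_sm, n_sm, 2))
        for i in range(max(r0, 1), min(r1, h - 1)):
            for j in range(max(c0, 1), min(c1, w - 1)):
                hist[s_map[i - 1, j - 1], m_map[i - 1, j - 1],
                     c_map[i - 1, j - 1]] += 1
        flat = hist.ravel()
        if normalize and flat.sum() > 0:
            flat = flat / flat.sum()
        parts.append(flat)
    return np.concatenate(parts)


def ref_tcentrist(img, mu=5.0, normalize=True):
    """Pixel-loop descriptor: per-block upper + lower LTP histograms."""
    a = np.asarray(img, dtype=float)
    h, w = a.shape
    up, lo = ref_ltp(a, mu=mu)
    parts = []
    for (r0, r1, c0, c1) in ref_blocks(h, w):
        h_up = np.zeros(256)
        h_lo = np.zeros(256)
        for i in range(max(r0, 1), min(r1, h - 1)):
            for j in range(max(c0, 1), min(c1, w - 1)):
                h_up[up[i - 1, j - 1]] += 1
                h_lo[lo[i - 1, j - 1]] += 1
        if normalize:
            if h_up.sum() > 0:
                h_up = h_up / h_up.sum()
            if h_lo.sum() > 0:
                h_lo = h_lo / h_lo.sum()
        parts.append(np.concatenate([h_up, h_lo]))
    return np.concatenate(parts)
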
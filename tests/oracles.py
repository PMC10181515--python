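"""Independent brute-force reference implementations used only by tests.

Everything here is written as naively as possible (explicit loops, full
sorts, direct DFT sums) so it shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


def dft_power_direct(x: np.ndarray) -> np.ndarray:
    """|DFT|^2 / N by the defining O(N^2) sum, bins 0..N//2."""
    x = np.asarray(x, dtype=float)
    n = x.size
    out = []
    for k in range(n // 2 + 1):
        s = sum(x[m] * np.exp(-2j * np.pi * k * m / n) for m in range(n))
        out.append(abs(s) ** 2 / n)
    return np.array(out)


def real_cepstrum_direct(x: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """FFT -> log|.| -> IFFT -> real part, via explicit DFT sums."""
    x = np.asarray(x, dtype=float)
    n = x.size
    spec = np.array(
        [sum(x[m] * np.exp(-2j * np.pi * k * m / n) for m in range(n)) for k in range(n)]
    )
    logmag = np.log(np.maximum(np.abs(spec), floor))
    ceps = np.array(
        [sum(logmag[k] * np.exp(2j * np.pi * k * m / n) for k in range(n)) / n for m in range(n)]
    )
    return ceps.real


def fan_matrix_naive(points: np.ndarray, fraction: float, theiler: int) -> np.ndarray:
    """Column-wise k-nearest-neighbor matrix by full pairwise sort."""
    n = points.shape[0]
    r = np.zeros((n, n), dtype=int)
    for i in range(n):
        cand = []
        for j in range(n):
            if abs(i - j) < theiler:
                continue
            cand.append((float(np.sqrt(((points[i] - points[j]) ** 2).sum())), j))
        k = int(np.floor(fraction * len(cand)))
        cand.sort(key=lambda t: (t[0], t[1]))  # tie -> smaller row index
        for _, j in cand[:k]:
            r[j, i] = 1
    return r


def runs_in(seq, value) -> list[int]:
    out, run = [], 0
    for v in seq:
        if v == value:
            run += 1
        else:
            if run:
                out.append(run)
            run = 0
    if run:
        out.append(run)
    return out


def line_histograms_naive(r: np.ndarray):
    r = np.array(r, dtype=int)
    n = r.shape[0]
    r = r.copy()
    for i in range(n):
        r[i, i] = 0
    diag, vert, white = [], [], []
    for off in range(-(n - 1), n):
        if off == 0:
            continue
        d = [r[i - off, i] for i in range(max(0, off), min(n, n + off))] if off < 0 else None
        # simpler: walk the diagonal explicitly
        cells = []
        for i in range(n):
            j = i + off
            if 0 <= j < n:
                cells.append(r[i, j])
        diag.extend(runs_in(cells, 1))
    for col in range(n):
        cells = [r[row, col] for row in range(n)]
        vert.extend(runs_in(cells, 1))
        white.extend(runs_in(cells, 0))
    return diag, vert, white


def _entropy_naive(lengths) -> float:
    if not lengths:
        return 0.0
    vals = sorted(set(lengths))
    total = len(lengths)
    h = 0.0
    for v in vals:
        p = lengths.count(v) / total
        h -= p * np.log(p)
    return h


def rqa_measures_naive(r: np.ndarray, lmin: int = 2, vmin: int = 2) -> dict:
    """All 17 recurrence measures by explicit enumeration."""
    r = np.array(r, dtype=int).copy()
    n = r.shape[0]
    for i in range(n):
        r[i, i] = 0
    diag, vert, white = line_histograms_naive(r)
    total = int(r.sum())
    rec = total / (n * (n - 1)) if n > 1 else 0.0

    def stats(lengths, minlen):
        long = [x for x in lengths if x >= minlen]
        tot = sum(lengths)
        lmax = max(lengths) if lengths else 0
        if not long or tot == 0:
            return 0.0, 0.0, float(lmax), 0.0
        return sum(long) / tot, sum(long) / len(long), float(lmax), _entropy_naive(long)

    det, l_mean, lmax, entr = stats(diag, lmin)
    lam, tt, vmax, _ = stats(vert, vmin)

    gaps_pts, gaps_starts = [], []
    for col in range(n):
        ones = [row for row in range(n) if r[row, col]]
        for a, b in zip(ones, ones[1:]):
            gaps_pts.append(b - a)
        starts = [row for row in ones if row == 0 or not r[row - 1, col]]
        for a, b in zip(starts, starts[1:]):
            gaps_starts.append(b - a)
    t1 = float(np.mean(gaps_pts)) if gaps_pts else 0.0
    t2 = float(np.mean(gaps_starts)) if gaps_starts else 0.0

    if white:
        rt = float(np.mean(white))
        rtmax = float(max(white))
        rf = 1.0 / rtmax
        entw = _entropy_naive(white)
        rpde = entw / np.log(rtmax) if rtmax > 1 else 0.0
    else:
        rt = rtmax = rf = entw = rpde = 0.0

    # network measures: explicit triangle counting on the symmetrized graph
    a = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and (r[i, j] or r[j, i]):
                a[i, j] = 1
    local = []
    tri_total = 0
    triads_total = 0
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        links = 0
        for x in range(k):
            for y in range(k):
                if x != y and a[nbrs[x], nbrs[y]]:
                    links += 1
        tri_total += links
        triads_total += k * (k - 1)
        local.append(links / (k * (k - 1)) if k > 1 else 0.0)
    clust = float(np.mean(local)) if local else 0.0
    trans = tri_total / triads_total if triads_total else 0.0

    return dict(REC=rec, DET=det, L=l_mean, Lmax=lmax, ENTR=entr,
                LAM=lam, TT=tt, Vmax=vmax, T1=t1, T2=t2,
                RT=rt, RTmax=rtmax, RF=rf, ENTW=entw, RPDE=rpde,
                Clust=clust, Trans=trans)


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = P(score+ > score-) + 0.5 P(tie) by exhaustive pairing."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
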
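"""Recurrence quantification analysis of RR frames.

The RR interval series of a frame is embedded into an m-dimensional phase
space by time delays, thresholded into a binary recurrence matrix with the
fixed-amount-of-nearest-neighbors (FAN) rule — every column keeps its k
nearest states, giving a constant ~5% recurrence density per column — and
summarized by 17 measures of the diagonal/vertical/white-line structure of
the matrix plus two recurrence-network measures.

Periodic, deterministic dynamics (such as the cyclic variation of heart
rate during repetitive apneas) produce long diagonal lines and high
determinism; uncorrelated series produce isolated recurrence points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .preprocessing import Frame

RQA_FEATURE_NAMES: list[str] = [
    "REC", "DET", "L", "Lmax", "ENTR", "LAM", "TT", "Vmax",
    "T1", "T2", "RT", "RTmax", "RF", "ENTW", "RPDE", "Clust", "Trans",
]

#: embedding presets: (dimension m, delay tau)
EMBEDDING_PRESETS = {"physionet": (7, 4), "hugcdn": (8, 5)}


@dataclass
class EmbeddedTrajectory:
    states: np.ndarray  # (N, m)
    m: int
    tau: int


@dataclass
class RecurrenceMatrix:
    entries: np.ndarray  # (N, N) uint8; entries[j, i] = 1 if j is a neighbor of i
    method: str = "fan"
    neighbor_fraction: float = 0.05
    theiler: int = 1

    @property
    def n(self) -> int:
        return self.entries.shape[0]


def takens_embed(u: np.ndarray, m: int, tau: int) -> EmbeddedTrajectory:
    """Time-delay embedding: state i = (u[i], u[i+tau], ..., u[i+(m-1)tau])."""
    u = np.asarray(u, dtype=float)
    n = u.size
    count = n - (m - 1) * tau
    if count < 2:
        raise ValueError(
            f"series of length {n} too short for m={m}, tau={tau}; "
            f"need at least {(m - 1) * tau + 2} samples"
        )
    idx = np.arange(count)[:, None] + tau * np.arange(m)[None, :]
    return EmbeddedTrajectory(states=u[idx], m=m, tau=tau)


def fan_recurrence(
    traj: EmbeddedTrajectory, fraction: float = 0.05, theiler: int = 1
) -> RecurrenceMatrix:
    """Fixed-amount-of-nearest-neighbors recurrence matrix.

    For each column i the k = floor(fraction * N_eligible) states nearest
    to state i (Euclidean norm) are marked recurrent, where eligible rows
    are those outside the Theiler band |i - j| < theiler.  Distance ties at
    the cutoff are broken toward the smaller row index, so the matrix is
    fully deterministic; it is generally asymmetric.
    """
    pts = traj.states
    n = pts.shape[0]
    d = cdist(pts, pts)
    r = np.zeros((n, n), dtype=np.uint8)
    rows = np.arange(n)
    for i in range(n):
        eligible = np.abs(rows - i) >= theiler
        n_elig = int(eligible.sum())
        k = int(np.floor(fraction * n_elig))
        if k == 0:
            raise ValueError(
                f"neighbor count is zero (fraction={fraction}, eligible={n_elig})"
            )
        cand = rows[eligible]
        order = np.argsort(d[cand, i], kind="stable")  # stable => index tie-break
        r[cand[order[:k]], i] = 1
    return RecurrenceMatrix(entries=r, method="fan", neighbor_fraction=fraction, theiler=theiler)


# ---------------------------------------------------------------------------
# Line structures
# ---------------------------------------------------------------------------

def _run_lengths(v: np.ndarray, value: int) -> list[int]:
    """Lengths of maximal runs of ``value`` in a 1-D 0/1 array."""
    mask = np.asarray(v) == value
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size]])
    return (ends - starts).tolist()


def line_histograms(
    rm: RecurrenceMatrix | np.ndarray,
) -> tuple[list[int], list[int], list[int]]:
    """Diagonal, vertical and white-vertical line lengths of the matrix.

    The line of identity is forced to zero first; diagonal runs are taken
    along every off-main diagonal, vertical (and white-vertical) runs along
    every column.  Returns three flat length lists.
    """
    r = rm.entries if isinstance(rm, RecurrenceMatrix) else np.asarray(rm)
    r = r.astype(np.uint8).copy()
    np.fill_diagonal(r, 0)
    n = r.shape[0]
    diag: list[int] = []
    for off in range(-(n - 1), n):
        if off == 0:
            continue
        diag.extend(_run_lengths(np.diagonal(r, off), 1))
    vert: list[int] = []
    white: list[int] = []
    for i in range(n):
        col = r[:, i]
        vert.extend(_run_lengths(col, 1))
        white.extend(_run_lengths(col, 0))
    return diag, vert, white


def _entropy(lengths: list[int]) -> float:
    if not lengths:
        return 0.0
    _, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


@dataclass
class RqaMeasures:
    values: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in RQA_FEATURE_NAMES])


def rqa_measures(rm: RecurrenceMatrix | np.ndarray, lmin: int = 2, vmin: int = 2) -> RqaMeasures:
    """The 17 recurrence measures of a binary matrix (LOI excluded).

    Diagonal-line measures: DET (fraction of recurrence points on
    diagonals of length >= lmin), L (their mean length), Lmax, ENTR
    (Shannon entropy of the >= lmin diagonal length distribution).
    Vertical-line measures: LAM, TT, Vmax (with vmin).  Recurrence times:
    T1 (mean spacing of recurrence points down a column), T2 (mean spacing
    of vertical-run starts), RT/RTmax (mean/max white vertical line), RF =
    1/RTmax, ENTW (white-line entropy) and RPDE (white-line entropy
    normalized by ln RTmax).  Network measures Clust and Trans come from
    the symmetrized matrix viewed as an undirected graph.  Measures whose
    underlying structure count is zero are reported as 0 with a flag.
    """
    r = rm.entries if isinstance(rm, RecurrenceMatrix) else np.asarray(rm)
    r = r.astype(np.uint8).copy()
    np.fill_diagonal(r, 0)
    n = r.shape[0]
    flags: list[str] = []
    total_points = int(r.sum())
    rec = total_points / (n * (n - 1)) if n > 1 else 0.0

    diag, vert, white = line_histograms(r)

    def line_stats(lengths: list[int], minlen: int, what: str) -> tuple[float, float, float, float]:
        arr = np.array(lengths, dtype=float)
        long = arr[arr >= minlen]
        tot = arr.sum()
        if long.size == 0 or tot == 0:
            flags.append(f"no_{what}_lines")
            return 0.0, 0.0, float(arr.max()) if arr.size else 0.0, 0.0
        frac = float(long.sum() / tot)
        mean_len = float(long.mean())
        return frac, mean_len, float(arr.max()), _entropy(list(long.astype(int)))

    det, l_mean, lmax, entr = line_stats(diag, lmin, "diagonal")
    lam, tt, vmax, _ = line_stats(vert, vmin, "vertical")

    # recurrence times down each column
    gaps_points: list[np.ndarray] = []
    gaps_starts: list[np.ndarray] = []
    for i in range(n):
        ones = np.flatnonzero(r[:, i])
        if ones.size >= 2:
            gaps_points.append(np.diff(ones))
            starts = ones[np.diff(ones, prepend=-2) > 1]
            if starts.size >= 2:
                gaps_starts.append(np.diff(starts))
    t1 = float(np.concatenate(gaps_points).mean()) if gaps_points else 0.0
    t2 = float(np.concatenate(gaps_starts).mean()) if gaps_starts else 0.0
    if not gaps_points:
        flags.append("no_recurrence_times")

    if white:
        warr = np.array(white, dtype=float)
        rt = float(warr.mean())
        rtmax = float(warr.max())
        rf = 1.0 / rtmax
        entw = _entropy(white)
        rpde = entw / np.log(rtmax) if rtmax > 1 else 0.0
    else:
        flags.append("no_white_lines")
        rt = rtmax = rf = entw = rpde = 0.0

    clust, trans = _network_measures(r)

    values = dict(
        REC=rec, DET=det, L=l_mean, Lmax=lmax, ENTR=entr,
        LAM=lam, TT=tt, Vmax=vmax, T1=t1, T2=t2,
        RT=rt, RTmax=rtmax, RF=rf, ENTW=entw, RPDE=rpde,
        Clust=clust, Trans=trans,
    )
    return RqaMeasures(values=values, flags=flags)


def _network_measures(r: np.ndarray) -> tuple[float, float]:
    """Mean local clustering and transitivity of the symmetrized matrix."""
    a = ((r | r.T) > 0).astype(float)
    np.fill_diagonal(a, 0)
    deg = a.sum(axis=1)
    a3_diag = ((a @ a) * a).sum(axis=1)
    pairs = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        local = np.where(pairs > 0, a3_diag / pairs, 0.0)
    clust = float(local.mean()) if local.size else 0.0
    trans = float(a3_diag.sum() / pairs.sum()) if pairs.sum() > 0 else 0.0
    return clust, trans


def rqa_features(
    frame: Frame,
    m: int = 8,
    tau: int = 5,
    fraction: float = 0.05,
    theiler: int = 1,
    lmin: int = 2,
    vmin: int = 2,
) -> dict[str, float]:
    """The 17 named RQA features of a frame's RR segment."""
    u = frame.rr_segment.intervals
    needed = (m - 1) * tau + 2
    if u.size < max(needed, int(np.ceil(1 / fraction)) + (m - 1) * tau):
        raise ValueError(
            f"frame {frame.central_minute}: {u.size} beats too few for "
            f"embedding m={m}, tau={tau}"
        )
    traj = takens_embed(u, m, tau)
    rm = fan_recurrence(traj, fraction=fraction, theiler=theiler)
    meas = rqa_measures(rm, lmin=lmin, vmin=vmin)
    return {name: float(meas.values[name]) for name in RQA_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# Optional embedding-parameter estimation
# ---------------------------------------------------------------------------

def estimate_delay(u: np.ndarray, max_lag: int = 50) -> int:
    """First zero crossing of the autocorrelation (fallback: max_lag)."""
    u = np.asarray(u, dtype=float) - np.mean(u)
    denom = float(np.dot(u, u))
    if denom == 0:
        return 1
    for lag in range(1, min(max_lag, u.size - 1)):
        if np.dot(u[:-lag], u[lag:]) / denom <= 0:
            return lag
    return max_lag


def estimate_dimension(
    u: np.ndarray, tau: int, max_m: int = 12, rtol: float = 15.0, threshold: float = 0.01
) -> int:
    """Smallest embedding dimension with a false-nearest-neighbor rate below
    ``threshold`` (classic distance-ratio criterion)."""
    u = np.asarray(u, dtype=float)
    for m in range(1, max_m):
        try:
            tr_m = takens_embed(u, m, tau).states
            tr_m1 = takens_embed(u, m + 1, tau).states
        except ValueError:
            return m
        n = tr_m1.shape[0]
        pts = tr_m[:n]
        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        nn = np.argmin(d, axis=1)
        dist_m = d[np.arange(n), nn]
        dist_m1 = np.linalg.norm(tr_m1 - tr_m1[nn], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            extra = np.sqrt(np.maximum(dist_m1**2 - dist_m**2, 0.0)) / np.where(
                dist_m > 0, dist_m, np.inf
            )
        fnn_rate = float(np.mean(extra > rtol))
        if fnn_rate < threshold:
            return m
    return max_m
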
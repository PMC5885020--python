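"""Local nucleotide alignment: exact affine-gap Smith-Waterman plus a
k-mer-seeded windowed search for large targets.

The DP is the exact optimum within the searched region; for targets at or
below ``exact_max_len`` the whole target is searched, so the result is the
global Smith-Waterman optimum.  Gap convention: a gap of length L scores
``gap_open + (L - 1) * gap_extend`` (both negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import _seq

__all__ = ["Scoring", "LocalHit", "TargetIndex", "best_local_match", "smith_waterman"]


@dataclass(frozen=True)
class Scoring:
    """blastn-like scores; a length-L gap scores open + (L-1)*extend."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2


@dataclass
class LocalHit:
    """Best local alignment of a query against a target region."""

    score: int
    matches: int
    columns: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str  # '+' or '-'

    @property
    def identity(self) -> float | None:
        """% identical columns over alignment columns; None for empty hits."""
        if self.score <= 0 or self.columns == 0:
            return None
        return 100.0 * self.matches / self.columns

    def aligned_fraction(self, query_length: int) -> float:
        if self.score <= 0:
            return 0.0
        return (self.q_end - self.q_start) / query_length


_EMPTY = (0, 0, 0, 0, 0, 0, 0)


@njit(cache=False)
def _sw_score(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    """Score-only local DP with rolling rows; returns the best cell score."""
    m = q.shape[0]
    n = t.shape[0]
    NEG = -(10**9)
    Hprev = np.zeros(n + 1, dtype=np.int32)
    Hcur = np.zeros(n + 1, dtype=np.int32)
    Fprev = np.full(n + 1, NEG, dtype=np.int32)
    Fcur = np.full(n + 1, NEG, dtype=np.int32)
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        e = NEG
        Hcur[0] = 0
        for j in range(1, n + 1):
            e_open = Hcur[j - 1] + gap_open
            e_ext = e + gap_extend
            e = e_open if e_open >= e_ext else e_ext
            f_open = Hprev[j] + gap_open
            f_ext = Fprev[j] + gap_extend
            f = f_open if f_open >= f_ext else f_ext
            Fcur[j] = f
            if qi <= 3 and qi == t[j - 1]:
                s = match
            else:
                s = mismatch
            h = Hprev[j - 1] + s
            if h < 0:
                h = 0
            if e > h:
                h = e
            if f > h:
                h = f
            Hcur[j] = h
            if h > best:
                best = h
        Hprev, Hcur = Hcur, Hprev
        Fprev, Fcur = Fcur, Fprev
    return best


@njit(cache=False)
def _sw(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    m = q.shape[0]
    n = t.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -(10**9), dtype=np.int32)
    F = np.full((m + 1, n + 1), -(10**9), dtype=np.int32)
    ptrH = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    ptrE = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 from H, 0 from E
    ptrF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
            tj = t[j - 1]
            if qi <= 3 and qi == tj:
                s = match
            else:
                s = mismatch
            diag = H[i - 1, j - 1] + s
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return _EMPTY
    # traceback
    matches = 0
    columns = 0
    i = bi
    j = bj
    state = 0  # 0 in H, 2 in E, 3 in F
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if q[i - 1] <= 3 and q[i - 1] == t[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            columns += 1
            if ptrE[i, j] == 1:
                state = 0
            j -= 1
        else:
            columns += 1
            if ptrF[i, j] == 1:
                state = 0
            i -= 1
    return (best, matches, columns, i, bi, j, bj)


@njit(cache=False)
def _best_gapless(q, t, match, mismatch):  # pragma: no cover - numba
    """Best gapless local segment over all diagonals (Kadane per diagonal).

    Returns (score, matches, length, q_start, q_end, t_start, t_end).
    """
    m = q.shape[0]
    n = t.shape[0]
    best = 0
    res = (0, 0, 0, 0, 0, 0, 0)
    for d in range(-(m - 1), n):
        i0 = -d if d < 0 else 0
        j0 = i0 + d
        run = min(m - i0, n - j0)
        cur = 0
        cur_m = 0
        cur_start = 0
        for k in range(run):
            qi = q[i0 + k]
            if qi <= 3 and qi == t[j0 + k]:
                s = match
                is_m = 1
            else:
                s = mismatch
                is_m = 0
            if cur <= 0:
                cur = 0
                cur_m = 0
                cur_start = k
            cur += s
            cur_m += is_m
            if cur > best:
                best = cur
                res = (best, cur_m, k - cur_start + 1,
                       i0 + cur_start, i0 + k + 1, j0 + cur_start, j0 + k + 1)
    return res


def smith_waterman(query: np.ndarray, target: np.ndarray, scoring: Scoring) -> tuple:
    """Exact local DP on code arrays; returns the raw alignment tuple."""
    return _sw(
        np.ascontiguousarray(query),
        np.ascontiguousarray(target),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(values, positions) of all valid (ACGT-only) k-mers in `codes`."""
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    vals = np.zeros(n - k + 1, dtype=np.int64)
    bad = (codes > 3).astype(np.int32)
    for j in range(k):
        vals = vals * 4 + codes[j : n - k + 1 + j]
    cum = np.concatenate(([0], np.cumsum(bad)))
    ok = (cum[k:] - cum[:-k]) == 0
    pos = np.nonzero(ok)[0]
    return vals[pos], pos


class TargetIndex:
    """Sorted k-mer index of a target genome for seed lookup."""

    def __init__(self, codes: np.ndarray, k: int = 11):
        self.codes = np.ascontiguousarray(codes)
        self.k = k
        vals, pos = _kmer_values(self.codes, k)
        order = np.argsort(vals, kind="stable")
        self._vals = vals[order]
        self._pos = pos[order]

    def seed_positions(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (query_pos, target_pos) arrays of exact k-mer matches."""
        qvals, qpos = _kmer_values(query_codes, self.k)
        lo = np.searchsorted(self._vals, qvals, side="left")
        hi = np.searchsorted(self._vals, qvals, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qp = np.repeat(qpos, counts)
        tp = np.empty(total, dtype=np.int64)
        out = 0
        for i in range(len(qvals)):
            c = counts[i]
            if c:
                tp[out : out + c] = self._pos[lo[i] : hi[i]]
                out += c
        return qp, tp


def _diagonal_windows(
    qpos: np.ndarray,
    tpos: np.ndarray,
    qlen: int,
    tlen: int,
    band: int,
    pad: int,
    max_windows: int,
) -> list[tuple[int, int]]:
    """Cluster seed diagonals and return up to max_windows target windows."""
    if len(qpos) == 0:
        return []
    diags = np.sort(tpos - qpos)
    # split where consecutive diagonals are further apart than `band`
    breaks = np.nonzero(np.diff(diags) > band)[0] + 1
    clusters = np.split(diags, breaks)
    ranked = sorted(clusters, key=lambda c: (-len(c), int(c[0])))
    windows = []
    for c in ranked[:max_windows]:
        lo = max(0, int(c[0]) - pad)
        hi = min(tlen, int(c[-1]) + qlen + pad)
        windows.append((lo, hi))
    return windows


def best_local_match(
    fragment: str | np.ndarray,
    target: str | np.ndarray,
    scoring: Scoring | None = None,
    index: TargetIndex | None = None,
    exact_max_len: int = 5000,
    k: int = 11,
    band: int = 32,
    pad: int = 64,
    max_windows: int = 2,
) -> LocalHit:
    """Highest-scoring local alignment of fragment vs target, either strand.

    For targets up to ``exact_max_len`` the full DP matrix is computed, so
    the score is the exact Smith-Waterman optimum.  Larger targets are
    searched only in windows around clustered exact k-mer seed diagonals.
    """
    scoring = scoring or Scoring()
    q = _seq.encode(fragment) if isinstance(fragment, str) else fragment
    t = _seq.encode(target) if isinstance(target, str) else target
    qrc = _seq.revcomp_codes(q)
    best = LocalHit(0, 0, 0, 0, 0, 0, 0, "+")
    if len(t) <= exact_max_len:
        searches = [("+", q, 0, len(t)), ("-", qrc, 0, len(t))]
    else:
        if index is None:
            index = TargetIndex(t, k=k)
        searches = []
        for strand, qq in (("+", q), ("-", qrc)):
            qp, tp = index.seed_positions(qq)
            for lo, hi in _diagonal_windows(qp, tp, len(qq), len(t), band, pad, max_windows):
                searches.append((strand, qq, lo, hi))
    # score-only pass over every candidate window, full traceback once
    best_search = None
    best_score = 0
    for strand, qq, lo, hi in searches:
        score = _sw_score(np.ascontiguousarray(qq), np.ascontiguousarray(t[lo:hi]),
                          scoring.match, scoring.mismatch,
                          scoring.gap_open, scoring.gap_extend)
        if score > best_score:
            best_score = score
            best_search = (strand, qq, lo, hi)
    if best_search is not None:
        strand, qq, lo, hi = best_search
        window = np.ascontiguousarray(t[lo:hi])
        qq = np.ascontiguousarray(qq)
        # a gapless segment reaching the affine-DP optimum IS an optimal
        # local alignment; the full traceback runs only when gaps pay off
        g_score, g_m, g_len, gqs, gqe, gts, gte = _best_gapless(
            qq, window, scoring.match, scoring.mismatch)
        if g_score == best_score:
            score, matches, columns, qs, qe, ts, te = (
                g_score, g_m, g_len, gqs, gqe, gts, gte)
        else:
            score, matches, columns, qs, qe, ts, te = smith_waterman(qq, window, scoring)
        if strand == "-":
            qs, qe = len(qq) - qe, len(qq) - qs
        best = LocalHit(score, matches, columns, qs, qe, lo + ts, lo + te, strand)
    return best
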
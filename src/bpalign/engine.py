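"""Dynamic-programming engine for the partially local three-way alignment.

The alignment of a reference breakpoint region ``F`` against the two derived
fragments ``L`` and ``R`` is global at the outer ends and local toward the
breakpoint: a suffix of L and a prefix of R may remain unaligned free of
charge, and the two fragments may either overlap on F (a duplication remnant)
or leave an internal interval of F unaligned at no gap cost (a deletion).

The recursion fills a three-dimensional score tensor ``S[i, j, k]`` over
prefixes F[1..i], L[1..j], R[1..k] and a two-dimensional matrix ``M[i, k]``
holding the best score of an F-R alignment that continues after the aligned
part of L has ended.  The traceback starts at ``M[m, p]``.

Complexity is O(m*n*p) time and space; the running maximum
``mtilde[i] = max_{i'<i} max_j S[i', j, 0]`` keeps the free-interval case of
the M recursion amortized O(1) per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numba import njit

from .scoring import GAP, NucSeq, ScoringScheme, encode, gamma, pair_score_matrix, sigma

#: absolute tolerance for all score comparisons
TOL = 1e-9

_NEG = -1e30


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _fill_S(sFL, sFR, sLR, delta, g, W):  # pragma: no cover - compiled
    m, n = sFL.shape
    p = sFR.shape[1]
    td = 2.0 * delta
    S = np.empty((m + 1, n + 1, p + 1), dtype=np.float64)
    for i in range(m + 1):
        S[i, 0, 0] = i * g
    for j in range(n + 1):
        S[0, j, 0] = j * g
    for k in range(p + 1):
        S[0, 0, k] = 2.0 * g * k
    # k = 0 face: global pairwise F-L alignment (R not yet begun)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best = S[i - 1, j - 1, 0] + sFL[i - 1, j - 1]
            v = S[i - 1, j, 0] + delta
            if v > best:
                best = v
            v = S[i, j - 1, 0] + delta
            if v > best:
                best = v
            S[i, j, 0] = best
    # j = 0 face: F-R before L begins; gaps relative to L are penalized
    for i in range(1, m + 1):
        for k in range(1, p + 1):
            best = S[i - 1, 0, k - 1] + sFR[i - 1, k - 1] + td
            v = S[i - 1, 0, k] + td
            if v > best:
                best = v
            v = S[i, 0, k - 1] + td
            if v > best:
                best = v
            S[i, 0, k] = best
    # i = 0 face: L-R without F; gaps relative to F are penalized
    for j in range(1, n + 1):
        for k in range(1, p + 1):
            best = S[0, j - 1, k - 1] + sLR[j - 1, k - 1] + td
            v = S[0, j - 1, k] + td
            if v > best:
                best = v
            v = S[0, j, k - 1] + td
            if v > best:
                best = v
            S[0, j, k] = best
    # interior: the seven three-way extension cases plus the free R prefix
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sfl = sFL[i - 1, j - 1]
            for k in range(1, p + 1):
                sfr = sFR[i - 1, k - 1]
                slr = sLR[j - 1, k - 1]
                best = S[i - 1, j - 1, k - 1] + (sfl + sfr + slr) / W
                v = S[i - 1, j - 1, k] + sfl + td
                if v > best:
                    best = v
                v = S[i - 1, j, k - 1] + sfr + td
                if v > best:
                    best = v
                v = S[i - 1, j, k] + td
                if v > best:
                    best = v
                v = S[i, j - 1, k - 1] + slr + td
                if v > best:
                    best = v
                v = S[i, j - 1, k] + td
                if v > best:
                    best = v
                v = S[i, j, k - 1] + td
                if v > best:
                    best = v
                v = S[i, j, 0]  # R[1..k] stays unaligned (free prefix)
                if v > best:
                    best = v
                S[i, j, k] = best
    return S


@njit(cache=True)
def _fill_M(S, sFR, delta):  # pragma: no cover - compiled
    m = S.shape[0] - 1
    n = S.shape[1] - 1
    p = S.shape[2] - 1
    maxjS = np.empty((m + 1, p + 1), dtype=np.float64)
    for i in range(m + 1):
        for k in range(p + 1):
            mv = S[i, 0, k]
            for j in range(1, n + 1):
                if S[i, j, k] > mv:
                    mv = S[i, j, k]
            maxjS[i, k] = mv
    mtilde = np.empty(m + 1, dtype=np.float64)
    mtilde[0] = _NEG
    for i in range(1, m + 1):
        v = maxjS[i - 1, 0]
        if mtilde[i - 1] > v:
            v = mtilde[i - 1]
        mtilde[i] = v
    M = np.empty((m + 1, p + 1), dtype=np.float64)
    M[0, 0] = maxjS[0, 0]
    for k in range(1, p + 1):
        best = M[0, k - 1] + delta
        if maxjS[0, k] > best:
            best = maxjS[0, k]
        M[0, k] = best
    for i in range(1, m + 1):
        best = M[i - 1, 0] + delta
        if maxjS[i, 0] > best:
            best = maxjS[i, 0]
        if mtilde[i] > best:
            best = mtilde[i]
        M[i, 0] = best
        for k in range(1, p + 1):
            best = M[i - 1, k - 1] + sFR[i - 1, k - 1]
            v = M[i - 1, k] + delta
            if v > best:
                best = v
            v = M[i, k - 1] + delta
            if v > best:
                best = v
            if maxjS[i, k] > best:
                best = maxjS[i, k]
            if mtilde[i] > best:
                best = mtilde[i]
            M[i, k] = best
    return maxjS, mtilde, M


# ---------------------------------------------------------------------------
# state and result containers


@dataclass
class DPState:
    """Filled DP arrays for one (F, L, R, scheme) instance."""

    S: np.ndarray
    sFL: np.ndarray
    sFR: np.ndarray
    sLR: np.ndarray
    maxjS: np.ndarray | None = None
    mtilde: np.ndarray | None = None
    M: np.ndarray | None = None

    @property
    def complete(self) -> bool:
        return self.M is not None


#: per-column scoring regimes
#: G  - gamma-scored column (S interior or i=0 / j=0 face)
#: P  - pairwise sigma column on the k=0 face (F-L before R begins)
#: M  - pairwise sigma column of the F-R continuation after L's end
#: EF/EL/ER - initialization-edge columns scored g, g and 2g respectively
#: fF/fL/fR - free (unscored) columns of F, L and R
REGIME_TAG = {
    "G": "FLR",
    "ER": "FLR",
    "P": "FL",
    "EF": "FL",
    "EL": "FL",
    "M": "FR",
    "fF": "F_FREE",
    "fL": "L_FREE",
    "fR": "R_FREE",
}

TAG_CHAR = {"FL": "L", "FLR": "O", "FR": "R", "F_FREE": "f", "L_FREE": "l", "R_FREE": "r"}


class Column(NamedTuple):
    f: str
    l: str
    r: str
    regime: str
    f_pos: int  # 1-based position in F, 0 if gap
    l_pos: int
    r_pos: int

    @property
    def tag(self) -> str:
        return REGIME_TAG[self.regime]


@dataclass
class TriAlignment:
    """A column-wise three-row alignment of (F, L, R) with its score."""

    F: NucSeq
    L: NucSeq
    R: NucSeq
    scheme: ScoringScheme
    columns: list[Column]
    score: float

    @property
    def l_end_in_F(self) -> int:
        """1-based F position of the last column pairing F and L letters (0 if none)."""
        pos = 0
        for c in self.columns:
            if c.f != GAP and c.l != GAP:
                pos = c.f_pos
        return pos

    @property
    def r_start_in_F(self) -> int:
        """1-based F position of the first column pairing F and R letters (0 if none)."""
        for c in self.columns:
            if c.f != GAP and c.r != GAP:
                return c.f_pos
        return 0

    def gapped_rows(self) -> tuple[str, str, str]:
        return (
            "".join(c.f for c in self.columns),
            "".join(c.l for c in self.columns),
            "".join(c.r for c in self.columns),
        )

    def region_tags(self) -> list[str]:
        return [c.tag for c in self.columns]

    def region_string(self) -> str:
        return "".join(TAG_CHAR[c.tag] for c in self.columns)

    def rescore(self) -> float:
        """Recompute the score from the columns and their scoring regimes."""
        sch = self.scheme
        total = 0.0
        for c in self.columns:
            if c.regime == "G":
                total += gamma(c.f, c.l, c.r, sch)
            elif c.regime == "P":
                total += sigma(c.f, c.l, sch)
            elif c.regime == "M":
                total += sigma(c.f, c.r, sch)
            elif c.regime in ("EF", "EL"):
                total += sch.g
            elif c.regime == "ER":
                total += 2.0 * sch.g
            # free columns contribute 0
        return total

    def check(self) -> None:
        """Assert the structural invariants of a valid alignment."""
        f, l, r = self.gapped_rows()
        assert f.replace(GAP, "") == self.F.seq
        assert l.replace(GAP, "") == self.L.seq
        assert r.replace(GAP, "") == self.R.seq
        for c in self.columns:
            assert not (c.f == GAP and c.l == GAP and c.r == GAP)
        assert abs(self.rescore() - self.score) < TOL


# ---------------------------------------------------------------------------
# filling


def _validate_inputs(F: NucSeq, L: NucSeq, R: NucSeq) -> None:
    if len(F) == 0:
        raise ValueError("the reference F must be non-empty")
    if len(L) == 0:
        raise ValueError("the left fragment L must be non-empty")
    # an empty R degenerates gracefully (pairwise F-L problem); allowed


def fill_S(F: NucSeq, L: NucSeq, R: NucSeq, scheme: ScoringScheme) -> DPState:
    """Fill the three-dimensional score tensor S."""
    _validate_inputs(F, L, R)
    mat = pair_score_matrix(scheme)
    cf, cl, cr = encode(F), encode(L), encode(R)
    sFL = mat[cf[:, None], cl[None, :]] if len(L) else np.zeros((len(F), 0))
    sFR = mat[cf[:, None], cr[None, :]] if len(R) else np.zeros((len(F), 0))
    sLR = mat[cl[:, None], cr[None, :]] if len(R) else np.zeros((len(L), 0))
    S = _fill_S(
        np.ascontiguousarray(sFL, dtype=np.float64),
        np.ascontiguousarray(sFR, dtype=np.float64),
        np.ascontiguousarray(sLR, dtype=np.float64),
        float(scheme.gap),
        float(scheme.g),
        float(scheme.sop_weight),
    )
    return DPState(S=S, sFL=np.asarray(sFL), sFR=np.asarray(sFR), sLR=np.asarray(sLR))


def fill_M(state: DPState, F: NucSeq, L: NucSeq, R: NucSeq, scheme: ScoringScheme) -> DPState:
    """Complete the DP state with maxjS, mtilde and the matrix M."""
    maxjS, mtilde, M = _fill_M(
        state.S, np.ascontiguousarray(state.sFR, dtype=np.float64), float(scheme.gap)
    )
    state.maxjS = maxjS
    state.mtilde = mtilde
    state.M = M
    return state


# ---------------------------------------------------------------------------
# traceback


def _close(a: float, b: float) -> bool:
    return abs(a - b) < TOL


def traceback(state: DPState, F: NucSeq, L: NucSeq, R: NucSeq, scheme: ScoringScheme) -> TriAlignment:
    """Recover one optimal alignment from the filled DP state.

    Ties are broken deterministically: in M, pairwise extensions are
    preferred over the transition into S (largest j first) over the free
    F-interval case (largest i', then largest j); in S, the Eq-order of the
    extension cases is used with the free R prefix considered last.
    """
    if not state.complete:
        raise ValueError("DP state is incomplete; call fill_M first")
    S, M = state.S, state.M
    mtilde = state.mtilde
    sFL, sFR, sLR = state.sFL, state.sFR, state.sLR
    f, l, r = F.seq, L.seq, R.seq
    m, n, p = len(f), len(l), len(r)
    delta = scheme.gap
    g = scheme.g
    W = scheme.sop_weight
    td = 2.0 * delta
    cols: list[Column] = []  # built right-to-left

    def fail(where: str, idx: tuple) -> None:
        raise AssertionError(
            f"traceback: no predecessor reproduces {where}{idx}; engine bug"
        )

    # --- phase 1: matrix M, from (m, p) until the transition into S
    i, k = m, p
    in_S = False
    j = 0
    while not in_S:
        val = M[i, k]
        if i > 0 and k > 0 and _close(val, M[i - 1, k - 1] + sFR[i - 1, k - 1]):
            cols.append(Column(f[i - 1], GAP, r[k - 1], "M", i, 0, k))
            i, k = i - 1, k - 1
            continue
        if i > 0 and _close(val, M[i - 1, k] + delta):
            cols.append(Column(f[i - 1], GAP, GAP, "M", i, 0, 0))
            i -= 1
            continue
        if k > 0 and _close(val, M[i, k - 1] + delta):
            cols.append(Column(GAP, GAP, r[k - 1], "M", 0, 0, k))
            k -= 1
            continue
        # transition: L ends with position j (largest j)
        jstar = -1
        for jj in range(n, -1, -1):
            if _close(S[i, jj, k], val):
                jstar = jj
                break
        if jstar >= 0:
            for jj in range(n, jstar, -1):
                cols.append(Column(GAP, l[jj - 1], GAP, "fL", 0, jj, 0))
            j = jstar
            in_S = True
            continue
        # free F interval: largest i' < i, then largest j
        if _close(mtilde[i], val):
            found = False
            for ip in range(i - 1, -1, -1):
                for jj in range(n, -1, -1):
                    if _close(S[ip, jj, 0], val):
                        for kk in range(k, 0, -1):
                            cols.append(Column(GAP, GAP, r[kk - 1], "fR", 0, 0, kk))
                        for ii in range(i, ip, -1):
                            cols.append(Column(f[ii - 1], GAP, GAP, "fF", ii, 0, 0))
                        for lj in range(n, jj, -1):
                            cols.append(Column(GAP, l[lj - 1], GAP, "fL", 0, lj, 0))
                        i, j, k = ip, jj, 0
                        found = True
                        break
                if found:
                    break
            if not found:
                fail("mtilde", (i,))
            in_S = True
            continue
        fail("M", (i, k))

    # --- phase 2: tensor S, down to (0, 0, 0)
    while i > 0 or j > 0 or k > 0:
        val = S[i, j, k]
        if k > 0 and i > 0 and j > 0:
            sfl = sFL[i - 1, j - 1]
            sfr = sFR[i - 1, k - 1]
            slr = sLR[j - 1, k - 1]
            if _close(val, S[i - 1, j - 1, k - 1] + (sfl + sfr + slr) / W):
                cols.append(Column(f[i - 1], l[j - 1], r[k - 1], "G", i, j, k))
                i, j, k = i - 1, j - 1, k - 1
            elif _close(val, S[i - 1, j - 1, k] + sfl + td):
                cols.append(Column(f[i - 1], l[j - 1], GAP, "G", i, j, 0))
                i, j = i - 1, j - 1
            elif _close(val, S[i - 1, j, k - 1] + sfr + td):
                cols.append(Column(f[i - 1], GAP, r[k - 1], "G", i, 0, k))
                i, k = i - 1, k - 1
            elif _close(val, S[i - 1, j, k] + td):
                cols.append(Column(f[i - 1], GAP, GAP, "G", i, 0, 0))
                i -= 1
            elif _close(val, S[i, j - 1, k - 1] + slr + td):
                cols.append(Column(GAP, l[j - 1], r[k - 1], "G", 0, j, k))
                j, k = j - 1, k - 1
            elif _close(val, S[i, j - 1, k] + td):
                cols.append(Column(GAP, l[j - 1], GAP, "G", 0, j, 0))
                j -= 1
            elif _close(val, S[i, j, k - 1] + td):
                cols.append(Column(GAP, GAP, r[k - 1], "G", 0, 0, k))
                k -= 1
            elif _close(val, S[i, j, 0]):
                for kk in range(k, 0, -1):
                    cols.append(Column(GAP, GAP, r[kk - 1], "fR", 0, 0, kk))
                k = 0
            else:
                fail("S", (i, j, k))
        elif k > 0 and i > 0:  # j == 0 face
            sfr = sFR[i - 1, k - 1]
            if _close(val, S[i - 1, 0, k - 1] + sfr + td):
                cols.append(Column(f[i - 1], GAP, r[k - 1], "G", i, 0, k))
                i, k = i - 1, k - 1
            elif _close(val, S[i - 1, 0, k] + td):
                cols.append(Column(f[i - 1], GAP, GAP, "G", i, 0, 0))
                i -= 1
            elif _close(val, S[i, 0, k - 1] + td):
                cols.append(Column(GAP, GAP, r[k - 1], "G", 0, 0, k))
                k -= 1
            else:
                fail("S", (i, 0, k))
        elif k > 0 and j > 0:  # i == 0 face
            slr = sLR[j - 1, k - 1]
            if _close(val, S[0, j - 1, k - 1] + slr + td):
                cols.append(Column(GAP, l[j - 1], r[k - 1], "G", 0, j, k))
                j, k = j - 1, k - 1
            elif _close(val, S[0, j - 1, k] + td):
                cols.append(Column(GAP, l[j - 1], GAP, "G", 0, j, 0))
                j -= 1
            elif _close(val, S[0, j, k - 1] + td):
                cols.append(Column(GAP, GAP, r[k - 1], "G", 0, 0, k))
                k -= 1
            else:
                fail("S", (0, j, k))
        elif k > 0:  # i == j == 0 edge, scored 2g per R letter
            cols.append(Column(GAP, GAP, r[k - 1], "ER", 0, 0, k))
            k -= 1
        elif i > 0 and j > 0:  # k == 0 face: pairwise F-L
            if _close(val, S[i - 1, j - 1, 0] + sFL[i - 1, j - 1]):
                cols.append(Column(f[i - 1], l[j - 1], GAP, "P", i, j, 0))
                i, j = i - 1, j - 1
            elif _close(val, S[i - 1, j, 0] + delta):
                cols.append(Column(f[i - 1], GAP, GAP, "P", i, 0, 0))
                i -= 1
            elif _close(val, S[i, j - 1, 0] + delta):
                cols.append(Column(GAP, l[j - 1], GAP, "P", 0, j, 0))
                j -= 1
            else:
                fail("S", (i, j, 0))
        elif i > 0:  # edge, scored g per F letter
            cols.append(Column(f[i - 1], GAP, GAP, "EF", i, 0, 0))
            i -= 1
        else:  # edge, scored g per L letter
            cols.append(Column(GAP, l[j - 1], GAP, "EL", 0, j, 0))
            j -= 1

    cols.reverse()
    aln = TriAlignment(F=F, L=L, R=R, scheme=scheme, columns=cols, score=float(M[m, p]))
    return aln


def align(F: NucSeq | str, L: NucSeq | str, R: NucSeq | str, scheme: ScoringScheme | None = None) -> TriAlignment:
    """Compute one optimal partially local three-way alignment.

    Convenience wrapper over :func:`fill_S`, :func:`fill_M` and
    :func:`traceback`.  Strings are wrapped into :class:`NucSeq`.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if isinstance(F, str):
        F = NucSeq("F", F)
    if isinstance(L, str):
        L = NucSeq("L", L)
    if isinstance(R, str):
        R = NucSeq("R", R)
    state = fill_S(F, L, R, scheme)
    state = fill_M(state, F, L, R, scheme)
    return traceback(state, F, L, R, scheme)


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_score(F: NucSeq | str, L: NucSeq | str, R: NucSeq | str,
                      scheme: ScoringScheme, max_len: int = 6) -> float:
    """Exhaustive reference score for tiny instances (test oracle).

    Enumerates every legal partially local structure directly: a global
    pairwise F-L prefix alignment, then either an unpenalized internal F
    interval (with the remaining prefix of R unaligned) or a three-way
    gamma-scored segment, then a global pairwise F-R suffix alignment; the
    unaligned suffix of L and prefix of R are unscored.  Each structure is
    scored from the sigma/gamma definitions with plain (memoized) global
    alignments of the subsequences, independently of the DP tensor
    recursions.
    """
    f, l, r = str(F), str(L), str(R)
    m, n, p = len(f), len(l), len(r)
    if max(m, n, p) > max_len:
        raise ValueError(f"brute force refuses sequences longer than {max_len}")
    if not _close(scheme.g, scheme.gap):
        raise ValueError("brute force oracle requires edge gap g == delta")
    delta = scheme.gap

    memo2: dict[tuple[str, str], float] = {}
    memo3: dict[tuple[str, str, str], float] = {}

    def nw2(x: str, y: str) -> float:
        if not x:
            return len(y) * delta
        if not y:
            return len(x) * delta
        key = (x, y)
        v = memo2.get(key)
        if v is None:
            v = nw2(x[:-1], y[:-1]) + sigma(x[-1], y[-1], scheme)
            v = max(v, nw2(x[:-1], y) + delta, nw2(x, y[:-1]) + delta)
            memo2[key] = v
        return v

    def nw3(x: str, y: str, z: str) -> float:
        if not x and not y and not z:
            return 0.0
        key = (x, y, z)
        v = memo3.get(key)
        if v is None:
            v = _NEG
            if x and y and z:
                v = max(v, nw3(x[:-1], y[:-1], z[:-1]) + gamma(x[-1], y[-1], z[-1], scheme))
            if x and y:
                v = max(v, nw3(x[:-1], y[:-1], z) + gamma(x[-1], y[-1], GAP, scheme))
            if x and z:
                v = max(v, nw3(x[:-1], y, z[:-1]) + gamma(x[-1], GAP, z[-1], scheme))
            if x:
                v = max(v, nw3(x[:-1], y, z) + gamma(x[-1], GAP, GAP, scheme))
            if y and z:
                v = max(v, nw3(x, y[:-1], z[:-1]) + gamma(GAP, y[-1], z[-1], scheme))
            if y:
                v = max(v, nw3(x, y[:-1], z) + gamma(GAP, y[-1], GAP, scheme))
            if z:
                v = max(v, nw3(x, y, z[:-1]) + gamma(GAP, GAP, z[-1], scheme))
            memo3[key] = v
        return v

    best = _NEG
    # structures without a three-way segment: flush junction or free F interval
    for i1 in range(m + 1):
        for i2 in range(i1, m + 1):
            for j1 in range(n + 1):
                left = nw2(f[:i1], l[:j1])
                for k0 in range(p + 1):
                    # a free R prefix at a flush junction is only reachable
                    # through an interior cell, which needs i1, j1 >= 1
                    if i1 == i2 and k0 > 0 and (i1 == 0 or j1 == 0):
                        continue
                    best = max(best, left + nw2(f[i2:], r[k0:]))
    # structures with a gamma-scored middle segment
    for ia in range(m + 1):
        for ja in range(n + 1):
            for k0 in range(p + 1):
                if k0 > 0 and (ia == 0 or ja == 0):
                    continue  # free R prefix needs an interior jump point
                left = nw2(f[:ia], l[:ja])
                for ib in range(ia, m + 1):
                    for j1 in range(ja, n + 1):
                        for kb in range(k0, p + 1):
                            if ib == ia and j1 == ja and kb == k0:
                                continue  # empty segment: covered above
                            cand = (left
                                    + nw3(f[ia:ib], l[ja:j1], r[k0:kb])
                                    + nw2(f[ib:], r[kb:]))
                            if cand > best:
                                best = cand
    return best
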
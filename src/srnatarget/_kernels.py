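"""Numba kernels for the intermolecular duplex DP and McCaskill folding.

Hot loops only; all orchestration, tracebacks and caching live in
:mod:`srnatarget.thermo` and :mod:`srnatarget.accessibility`.  Energy
parameters arrive as precomputed lookup tables (loop energies, Boltzmann
factors) so the inner loops are pure table arithmetic — no exp/log calls.

Partition-function matrices are rescaled by ``sigma`` per nucleotide so
that long or very stable sequences stay inside double-precision range;
every probability reported upstream is a ratio in which the scale cancels
exactly.
"""

import math

import numpy as np
from numba import njit

INF = 1e30


_PACK_CACHE: dict = {}


def pack_model(model):
    """Precompute kernel lookup tables for an EnergyModel.

    Returns (stack, ptab, le) where ``le[g1, g2]`` is the bulge/interior
    loop energy for g1 x g2 unpaired nt (INF at [0, 0]: that is a stack).
    """
    from .params import PAIR_TABLE

    if id(model) in _PACK_CACHE:
        return _PACK_CACHE[id(model)]

    stack = np.ascontiguousarray(model.stack, dtype=np.float64)
    m = model.max_internal_loop
    le = np.full((m + 1, m + 1), INF)
    for g1 in range(m + 1):
        for g2 in range(m + 1):
            if g1 == 0 and g2 == 0:
                continue
            le[g1, g2] = model.loop_energy(g1, g2)
    _PACK_CACHE[id(model)] = (stack, PAIR_TABLE.copy(), le)
    return _PACK_CACHE[id(model)]


def fold_tables(model, n, sigma):
    """Boltzmann-factor tables for one fold of length ``n`` at scale sigma.

    All factors absorb the sigma power matching the number of nucleotides
    they account for, so every recursion term scales as sigma**length.
    """
    stack, _, le = pack_model(model)
    rt = model.RT
    maxl = model.max_internal_loop
    sb = np.exp(-stack / rt) * sigma * sigma
    lb = np.zeros_like(le)
    for g1 in range(maxl + 1):
        for g2 in range(maxl + 1):
            if g1 == 0 and g2 == 0:
                continue
            if g1 + g2 <= maxl:  # total-size cap in intramolecular folds
                lb[g1, g2] = math.exp(-le[g1, g2] / rt) * sigma ** (g1 + g2 + 2)
    hb = np.zeros(n + 1)
    for l in range(model.min_hairpin, n + 1):
        hb[l] = math.exp(-model.hairpin_energy(l) / rt) * sigma ** (l + 2)
    mlw = math.exp(-(model.ml_init + model.ml_branch) / rt) * sigma * sigma
    mlw2 = math.exp(-(model.ml_init + 2.0 * model.ml_branch) / rt) * sigma * sigma
    b1f = np.empty(n + 1)
    uf = np.empty(n + 1)
    eb = math.exp(-model.ml_branch / rt)
    for k in range(n + 1):
        cu = math.exp(-model.ml_unpaired * k / rt) * sigma ** k
        b1f[k] = eb * cu
        uf[k] = cu
    return sb, lb, hb, mlw, mlw2, b1f, uf


# ---------------------------------------------------------------------------
# intermolecular duplex DP


@njit(cache=True)
def duplex_tables(s, w, ptab, stack, le, duplex_init, au_end, maxl):
    """Forward/backward duplex DP over sRNA ``s`` and *reversed* window ``w``.

    A[i,j]: best energy of a duplex whose last pair is (i,j), including
    initiation and the left helix-end penalty.  B[i,j]: best energy of a
    duplex suffix whose first pair is (i,j), including the right end
    penalty.  Parent/child pointers enable traceback.
    """
    n = s.shape[0]
    m = w.shape[0]
    pt = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        for j in range(m):
            pt[i, j] = ptab[s[i], w[j]]
    endp = np.array([au_end, au_end, 0.0, 0.0, au_end, au_end])
    A = np.full((n, m), INF)
    Ap = np.full((n, m, 2), -1, dtype=np.int32)
    B = np.full((n, m), INF)
    Bc = np.full((n, m, 2), -1, dtype=np.int32)
    for i in range(n):
        for j in range(m):
            p = pt[i, j]
            if p < 0:
                continue
            best = duplex_init + endp[p]
            bi = -1
            bj = -1
            k0 = i - 1 - maxl
            if k0 < 0:
                k0 = 0
            l0 = j - 1 - maxl
            if l0 < 0:
                l0 = 0
            for k in range(k0, i):
                for l in range(l0, j):
                    a = A[k, l]
                    if a >= INF:
                        continue
                    g1 = i - k - 1
                    g2 = j - l - 1
                    if g1 == 0 and g2 == 0:
                        e = a + stack[pt[k, l], p]
                    else:
                        e = a + le[g1, g2]
                    if e < best:
                        best = e
                        bi = k
                        bj = l
            A[i, j] = best
            Ap[i, j, 0] = bi
            Ap[i, j, 1] = bj
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            p = pt[i, j]
            if p < 0:
                continue
            best = endp[p]
            bi = -1
            bj = -1
            k1 = i + 2 + maxl
            if k1 > n:
                k1 = n
            l1 = j + 2 + maxl
            if l1 > m:
                l1 = m
            for k in range(i + 1, k1):
                for l in range(j + 1, l1):
                    b = B[k, l]
                    if b >= INF:
                        continue
                    g1 = k - i - 1
                    g2 = l - j - 1
                    if g1 == 0 and g2 == 0:
                        e = b + stack[p, pt[k, l]]
                    else:
                        e = b + le[g1, g2]
                    if e < best:
                        best = e
                        bi = k
                        bj = l
            B[i, j] = best
            Bc[i, j, 0] = bi
            Bc[i, j, 1] = bj
    return A, Ap, B, Bc, pt


@njit(cache=True)
def seed_totals(A, B, pt, stack, le, au_end, maxl, min_seed):
    """Best total duplex energy whose seed helix starts at each (i, j).

    The seed is an exact run of ``min_seed`` consecutive stacked pairs
    starting at (i, j); the duplex may extend on either side through
    bulge/interior loops.  T holds total energies (INF where no seed
    fits); Tc the chosen continuation pair after the helix (-1 = none).
    """
    n, m = A.shape
    endp = np.array([au_end, au_end, 0.0, 0.0, au_end, au_end])
    T = np.full((n, m), INF)
    Tc = np.full((n, m, 2), -1, dtype=np.int32)
    for i in range(n - min_seed + 1):
        for j in range(m - min_seed + 1):
            if pt[i, j] < 0 or A[i, j] >= INF:
                continue
            hel = 0.0
            ok = True
            for t in range(min_seed - 1):
                p1 = pt[i + t, j + t]
                p2 = pt[i + t + 1, j + t + 1]
                if p1 < 0 or p2 < 0:
                    ok = False
                    break
                hel += stack[p1, p2]
            if not ok:
                continue
            ie = i + min_seed - 1
            je = j + min_seed - 1
            pe = pt[ie, je]
            cbest = endp[pe]
            ci = -1
            cj = -1
            k1 = ie + 2 + maxl
            if k1 > n:
                k1 = n
            l1 = je + 2 + maxl
            if l1 > m:
                l1 = m
            for k in range(ie + 1, k1):
                for l in range(je + 1, l1):
                    if B[k, l] >= INF:
                        continue
                    g1 = k - ie - 1
                    g2 = l - je - 1
                    if g1 == 0 and g2 == 0:
                        e = B[k, l] + stack[pe, pt[k, l]]
                    else:
                        e = B[k, l] + le[g1, g2]
                    if e < cbest:
                        cbest = e
                        ci = k
                        cj = l
            T[i, j] = A[i, j] + hel + cbest
            Tc[i, j, 0] = ci
            Tc[i, j, 1] = cj
    return T, Tc


# ---------------------------------------------------------------------------
# McCaskill partition function


@njit(cache=True)
def fold_inside(s, ptab, sb, lb, hb, mlw, b1f, uf, sigma, maxl, minh, mask):
    """Inside recursions (Qb/QM/QM1 + exterior), sigma-rescaled.

    ``mask[i] != 0`` forbids position i from pairing (constrained
    partition functions).  Returns (Qb, QM, Qx, Qs); Z = Qx[n].
    """
    n = s.shape[0]
    Qb = np.zeros((n, n))
    QM = np.zeros((n, n))
    QM1 = np.zeros((n, n))
    for d in range(minh + 1, n):
        for i in range(0, n - d):
            j = i + d
            p = ptab[s[i], s[j]]
            if p >= 0 and mask[i] == 0 and mask[j] == 0:
                q = hb[d - 1]
                kmax = i + maxl + 1
                if kmax > j - 1:
                    kmax = j - 1
                for k in range(i + 1, kmax + 1):
                    g1 = k - i - 1
                    lmin = j - 1 - (maxl - g1)
                    if lmin < k + minh + 1:
                        lmin = k + minh + 1
                    for l in range(lmin, j):
                        qkl = Qb[k, l]
                        if qkl <= 0.0:
                            continue
                        g2 = j - l - 1
                        if g1 == 0 and g2 == 0:
                            q += qkl * sb[p, ptab[s[k], s[l]]]
                        else:
                            q += qkl * lb[g1, g2]
                for k in range(i + 2, j):
                    qm_l = QM[i + 1, k - 1]
                    if qm_l <= 0.0:
                        continue
                    qm_r = QM1[k, j - 1]
                    if qm_r > 0.0:
                        q += qm_l * qm_r * mlw
                Qb[i, j] = q
            # QM1: single branch, pair (i, l), l+1..j unpaired
            q1 = 0.0
            for l in range(i + minh + 1, j + 1):
                qb = Qb[i, l]
                if qb > 0.0:
                    q1 += qb * b1f[j - l]
            QM1[i, j] = q1
            # QM: one or more branches over i..j
            qm = 0.0
            for k in range(i, j + 1):
                q1k = QM1[k, j]
                if q1k <= 0.0:
                    continue
                qm += uf[k - i] * q1k
                if k > i:
                    qmik = QM[i, k - 1]
                    if qmik > 0.0:
                        qm += qmik * q1k
            QM[i, j] = qm
    Qx = np.zeros(n + 1)
    Qx[0] = 1.0
    for j in range(n):
        v = Qx[j] * sigma
        for k in range(j):
            if Qb[k, j] > 0.0:
                v += Qx[k] * Qb[k, j]
        Qx[j + 1] = v
    Qs = np.zeros(n + 1)
    Qs[n] = 1.0
    for i in range(n - 1, -1, -1):
        v = Qs[i + 1] * sigma
        for l in range(i + 1, n):
            if Qb[i, l] > 0.0:
                v += Qb[i, l] * Qs[l + 1]
        Qs[i] = v
    return Qb, QM, Qx, Qs


@njit(cache=True)
def fold_outside(s, ptab, sb, lb, mlw2, uf, maxl, minh, Qb, QM, Qx, Qs):
    """Outside recursions: base-pair probability matrix P[i, j].

    The multiloop term enumerates enclosing pairs directly (O(n^4) worst
    case); acceptable because the outside pass runs once per sRNA and in
    small-sequence tests, never per candidate gene.
    """
    n = s.shape[0]
    Z = Qx[n]
    Oh = np.zeros((n, n))
    P = np.zeros((n, n))
    for d in range(n - 1, minh, -1):
        for i in range(0, n - d):
            j = i + d
            if Qb[i, j] <= 0.0:
                continue
            o = Qx[i] * Qs[j + 1] / Z
            pmin = i - maxl - 1
            if pmin < 0:
                pmin = 0
            for pp in range(pmin, i):
                g1 = i - pp - 1
                qmax = j + 1 + (maxl - g1)
                if qmax > n - 1:
                    qmax = n - 1
                for qq in range(j + 1, qmax + 1):
                    oh = Oh[pp, qq]
                    if oh <= 0.0:
                        continue
                    g2 = qq - j - 1
                    if g1 == 0 and g2 == 0:
                        o += oh * sb[ptab[s[pp], s[qq]], ptab[s[i], s[j]]]
                    else:
                        o += oh * lb[g1, g2]
            for pp in range(0, i):
                for qq in range(j + 1, n):
                    oh = Oh[pp, qq]
                    if oh <= 0.0:
                        continue
                    left = i - pp - 1
                    right = qq - j - 1
                    qml = QM[pp + 1, i - 1] if left > 0 else 0.0
                    qmr = QM[j + 1, qq - 1] if right > 0 else 0.0
                    combo = qml * uf[right] + uf[left] * qmr + qml * qmr
                    if combo > 0.0:
                        o += oh * mlw2 * combo
            Oh[i, j] = o
            P[i, j] = Qb[i, j] * o
    return P
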
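"""Independent brute-force oracles for the thermodynamic code.

These enumerate *every* legal configuration explicitly — antiparallel
intermolecular pairings for duplexes, nested secondary structures for
folding — and score each one with the energy model's public primitives.
They share no recursion with the production dynamic programs and are only
feasible for tiny sequences, which is the point.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

from srnatarget.params import DEFAULT_MODEL, PAIR_TABLE, encode


def duplex_best_energy(srna: str, window: str, model=DEFAULT_MODEL,
                       min_seed: int = 2) -> float | None:
    """Minimum hybrid energy over all legal antiparallel pairing sets.

    A pairing set is a chain: sRNA positions strictly increasing, window
    positions strictly decreasing, every pair Watson-Crick or G.U, gaps
    between consecutive pairs at most ``max_internal_loop`` per side.  The
    chain must contain a run of >= min_seed consecutive pairs and close
    with energy < 0, matching the duplex_mfe contract.
    """
    s = encode(srna)
    w = encode(window)
    n, m = len(s), len(w)
    maxl = model.max_internal_loop
    cells = [(i, j) for i in range(n) for j in range(m) if PAIR_TABLE[s[i], w[j]] >= 0]
    best = [None]

    def close(energy, i, j, run, maxrun):
        e = energy + model.end_penalty(model.pair_type(s[i], w[j]))
        if max(run, maxrun) >= min_seed and e < 0:
            if best[0] is None or e < best[0]:
                best[0] = e

    def extend(i, j, energy, run, maxrun):
        close(energy, i, j, run, maxrun)
        for k, l in cells:
            if k <= i or l >= j:
                continue
            g1 = k - i - 1
            g2 = j - l - 1
            if g1 > maxl or g2 > maxl:
                continue
            if g1 == 0 and g2 == 0:
                de = model.stack_energy(model.pair_type(s[i], w[j]),
                                        model.pair_type(s[k], w[l]))
                extend(k, l, energy + de, run + 1, maxrun)
            else:
                extend(k, l, energy + model.loop_energy(g1, g2),
                       1, max(maxrun, run))

    for i, j in cells:
        e0 = model.duplex_init + model.end_penalty(model.pair_type(s[i], w[j]))
        extend(i, j, e0, 1, 1)
    return best[0]


def enumerate_structures(seq: str, model=DEFAULT_MODEL, mask=None):
    """All nested secondary structures (tuples of (i, j) pairs, 0-based).

    Minimum hairpin loop from the model; no pseudoknots; ``mask`` lists
    0-based positions forbidden to pair.
    """
    s = encode(seq)
    n = len(s)
    minh = model.min_hairpin
    forbidden = set(mask or ())

    @lru_cache(maxsize=None)
    def structs(i, j):
        if j - i + 1 <= minh:
            return (tuple(),)
        out = list(structs(i + 1, j))  # i unpaired
        if i not in forbidden:
            for k in range(i + minh + 1, j + 1):
                if k in forbidden or PAIR_TABLE[s[i], s[k]] < 0:
                    continue
                inner = structs(i + 1, k - 1)
                outer = structs(k + 1, j) if k + 1 <= j else (tuple(),)
                for a, b in itertools.product(inner, outer):
                    out.append(((i, k),) + a + b)
        return tuple(out)

    if n == 0:
        return (tuple(),)
    return structs(0, n - 1)


def structure_energy(pairs, seq: str, model=DEFAULT_MODEL) -> float:
    """Free energy of one structure by explicit loop decomposition."""
    s = encode(seq)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    total = 0.0
    for i, j in pairs:
        children = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in partner:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            total += model.hairpin_energy(j - i - 1)
        elif len(children) == 1:
            (k, l) = children[0]
            g1 = k - i - 1
            g2 = j - l - 1
            if g1 == 0 and g2 == 0:
                total += model.stack_energy(model.pair_type(s[i], s[j]),
                                            model.pair_type(s[k], s[l]))
            else:
                total += model.loop_energy(g1, g2)
        else:
            total += (model.ml_init + model.ml_branch * (len(children) + 1)
                      + model.ml_unpaired * unpaired)
    return total


def ensemble_properties(seq: str, model=DEFAULT_MODEL):
    """(Z, per-position unpaired probabilities) by exhaustive enumeration."""
    n = len(seq)
    rt = model.RT
    z = 0.0
    unpaired_w = [0.0] * n
    for st in enumerate_structures(seq, model):
        w = math.exp(-structure_energy(st, seq, model) / rt)
        z += w
        paired = {p for ij in st for p in ij}
        for k in range(n):
            if k not in paired:
                unpaired_w[k] += w
    return z, [u / z for u in unpaired_w]


def interval_unpaired_probability(seq: str, i: int, j: int, model=DEFAULT_MODEL) -> float:
    """P(positions i..j all unpaired), 1-based, by enumeration."""
    rt = model.RT
    z = 0.0
    zc = 0.0
    span = set(range(i - 1, j))
    for st in enumerate_structures(seq, model):
        w = math.exp(-structure_energy(st, seq, model) / rt)
        z += w
        paired = {p for ij in st for p in ij}
        if not (span & paired):
            zc += w
    return zc / z
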
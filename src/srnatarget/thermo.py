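"""Minimum-free-energy sRNA-mRNA duplex search.

The hybrid model is intermolecular-only (RNAduplex-like): Watson-Crick and
G.U pairs, helix stacks from the nearest-neighbor table, bulge and interior
loops up to ``max_internal_loop`` nt per side, duplex initiation and AU/GU
helix-end penalties, no dangling ends and no intramolecular pairs (those
are handled separately as accessibility opening energies).  Every reported
hybrid must contain a seed: at least ``min_seed`` consecutive base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import DEFAULT_MODEL, EnergyModel, encode
from .sequence_io import NucleotideSequence

_PACKED_CACHE: dict[int, tuple] = {}


def _packed(model: EnergyModel):
    key = id(model)
    if key not in _PACKED_CACHE:
        _PACKED_CACHE[key] = _kernels.pack_model(model)
    return _PACKED_CACHE[key]


@dataclass(frozen=True)
class DuplexHit:
    """One intermolecular hybrid between an sRNA and a target window.

    Intervals are 1-based inclusive; ``pairing`` lists (sRNA position,
    window position) base pairs with sRNA positions increasing and window
    positions decreasing (the hybrid is antiparallel when both sequences
    are read 5'->3').
    """

    srna_interval: tuple
    mrna_interval: tuple
    pairing: tuple
    e_hyb: float
    seed_len: int


def _longest_run(pairing) -> int:
    best = run = 1
    for (s0, m0), (s1, m1) in zip(pairing, pairing[1:]):
        if s1 == s0 + 1 and m1 == m0 - 1:
            run += 1
            best = max(best, run)
        else:
            run = 1
    return best


def seed_region(hit: DuplexHit) -> tuple:
    """sRNA interval (1-based inclusive) of the 5'-most longest pair run."""
    runs = []
    start = 0
    pairing = hit.pairing
    for idx in range(1, len(pairing) + 1):
        if idx == len(pairing) or not (
            pairing[idx][0] == pairing[idx - 1][0] + 1
            and pairing[idx][1] == pairing[idx - 1][1] - 1
        ):
            runs.append((pairing[start][0], pairing[idx - 1][0]))
            start = idx
    return max(runs, key=lambda r: (r[1] - r[0], -r[0]))


class _DuplexTables:
    """DP tables for one (sRNA, window, model, min_seed) instance."""

    def __init__(self, srna: NucleotideSequence, window: NucleotideSequence,
                 model: EnergyModel, min_seed: int):
        if min_seed < 2:
            raise ValueError("min_seed must be >= 2")
        self.m = len(window)
        s = encode(srna.residues)
        w = encode(window.residues[::-1])  # reversed: both indices increase
        stack, ptab, le = _packed(model)
        self.A, self.Ap, self.B, self.Bc, self.pt = _kernels.duplex_tables(
            s, w, ptab, stack, le, model.duplex_init, model.au_end_penalty,
            model.max_internal_loop)
        self.T, self.Tc = _kernels.seed_totals(
            self.A, self.B, self.pt, stack, le, model.au_end_penalty,
            model.max_internal_loop, min_seed)
        self.min_seed = min_seed

    def trace(self, i: int, j: int) -> DuplexHit:
        """Reconstruct the optimal duplex whose seed helix starts at (i, j)."""
        pairs = []
        k, l = i, j
        while k >= 0:
            pairs.append((k, l))
            k, l = int(self.Ap[k, l, 0]), int(self.Ap[k, l, 1])
        pairs.reverse()
        for t in range(1, self.min_seed):
            pairs.append((i + t, j + t))
        k, l = int(self.Tc[i, j, 0]), int(self.Tc[i, j, 1])
        while k >= 0:
            pairs.append((k, l))
            k, l = int(self.Bc[k, l, 0]), int(self.Bc[k, l, 1])
        # back to 1-based sRNA coords and original window orientation
        pairing = tuple((s0 + 1, self.m - j0) for s0, j0 in pairs)
        srna_iv = (pairing[0][0], pairing[-1][0])
        mrna_iv = (pairing[-1][1], pairing[0][1])
        return DuplexHit(
            srna_interval=srna_iv,
            mrna_interval=mrna_iv,
            pairing=pairing,
            e_hyb=float(self.T[i, j]),
            seed_len=_longest_run(pairing),
        )


def duplex_mfe(srna: NucleotideSequence, window: NucleotideSequence,
               model: EnergyModel = DEFAULT_MODEL, min_seed: int = 7) -> DuplexHit | None:
    """The minimum-free-energy seeded hybrid, or None if none has e_hyb < 0."""
    tab = _DuplexTables(srna, window, model, min_seed)
    flat = int(np.argmin(tab.T))
    i, j = divmod(flat, tab.T.shape[1])
    if tab.T[i, j] >= 0.0 or tab.T[i, j] >= _kernels.INF:
        return None
    return tab.trace(i, j)


def duplex_suboptimals(srna: NucleotideSequence, window: NucleotideSequence,
                       model: EnergyModel = DEFAULT_MODEL, min_seed: int = 7,
                       delta: float = 0.0) -> list[DuplexHit]:
    """Non-overlapping hybrids within ``delta`` kcal/mol of the MFE.

    Greedy by energy: candidate seed anchors are visited best-first and a
    hit is kept only if its window interval does not overlap an already
    accepted hit.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    tab = _DuplexTables(srna, window, model, min_seed)
    mfe = float(tab.T.min())
    if mfe >= 0.0 or mfe >= _kernels.INF:
        return []
    cand = np.argwhere(tab.T <= mfe + delta + 1e-9)
    order = sorted(cand.tolist(), key=lambda ij: (tab.T[ij[0], ij[1]], ij[0], ij[1]))
    hits: list[DuplexHit] = []
    for i, j in order:
        if tab.T[i, j] >= 0.0:
            continue
        hit = tab.trace(i, j)
        lo, hi = hit.mrna_interval
        if any(not (hi < h.mrna_interval[0] or lo > h.mrna_interval[1]) for h in hits):
            continue
        hits.append(hit)
    return hits
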
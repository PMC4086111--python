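"""Ensemble accessibility: unpaired probabilities and opening energies.

A McCaskill partition function over intramolecular secondary structures
(minimum hairpin loop 3, no pseudoknots) gives, for any sRNA or mRNA
window, the Boltzmann probability that a position or an interval is
unpaired.  Interval probabilities are exact constrained-ensemble ratios
Z(i..j unpaired)/Z, and convert to opening energies ED = -RT ln p: the
free-energy cost of exposing the interval so it can hybridize.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels
from .params import DEFAULT_MODEL, EnergyModel, encode
from .sequence_io import AnnotatedReplicon, NucleotideSequence, TargetWindow

DEFAULT_MAX_LEN = 2000
DEFAULT_P_FLOOR = 1e-30


class SequenceTooLongError(ValueError):
    pass


class AccessibilityProfile:
    """Unpaired probabilities for one folded sequence.

    Per-position probabilities come from the base-pair probability matrix
    (outside algorithm, computed lazily); interval probabilities come from
    constrained refolds and are cached per interval.  All coordinates are
    1-based inclusive.
    """

    def __init__(self, seq: NucleotideSequence, model: EnergyModel = DEFAULT_MODEL,
                 max_len: int = DEFAULT_MAX_LEN, p_floor: float = DEFAULT_P_FLOOR,
                 sigma: float | None = None):
        n = len(seq)
        if n > max_len:
            raise SequenceTooLongError(
                f"sequence of {n} nt exceeds the configured maximum {max_len}; "
                "fold a window plus local context instead"
            )
        self.seq = seq
        self.seq_len = n
        self.model = model
        self.rt = model.RT
        self.p_floor = p_floor
        self._enc = encode(seq.residues)
        _, self._ptab, _ = _kernels.pack_model(model)
        self._tables_cache: dict[float, tuple] = {}
        self._sigma, self._inside = self._fold(np.zeros(n, dtype=np.int8), sigma=sigma)
        self._p_pos: np.ndarray | None = None
        self._interval_cache: dict[tuple, float] = {}

    def _fold(self, mask, sigma=None):
        """Inside pass with automatic rescaling until Z is representable.

        When ``sigma`` is given (constrained refolds must reuse the scale of
        the unconstrained fold so the ratio is exact) a single pass is run;
        an underflowing constrained Z then simply reads as probability 0.
        """
        n = self.seq_len
        if sigma is not None:
            return sigma, self._inside_pass(sigma, mask)
        gc = (np.sum(self._enc == 1) + np.sum(self._enc == 2)) / max(n, 1)
        s_per_nt = 0.05 + 1.6 * gc * gc if n > 60 else 0.0
        sigma = math.exp(-s_per_nt / self.rt)
        for _ in range(12):
            Qb, QM, Qx, Qs = self._inside_pass(sigma, mask)
            z = Qx[n]
            if math.isinf(z) or math.isnan(z):
                sigma *= math.exp(-0.8 / self.rt)
                continue
            if z <= 1e-250:
                sigma *= math.exp(0.8 / self.rt)
                continue
            return sigma, (Qb, QM, Qx, Qs)
        raise FloatingPointError("partition function could not be rescaled")

    def _inside_pass(self, sigma, mask):
        if sigma not in self._tables_cache:
            self._tables_cache[sigma] = _kernels.fold_tables(
                self.model, self.seq_len, sigma)
        sb, lb, hb, mlw, mlw2, b1f, uf = self._tables_cache[sigma]
        return _kernels.fold_inside(
            self._enc, self._ptab, sb, lb, hb, mlw, b1f, uf, sigma,
            self.model.max_internal_loop, self.model.min_hairpin, mask)

    @property
    def Z(self) -> float:
        """Partition function, rescaled by sigma**n (ratios are exact)."""
        return float(self._inside[2][self.seq_len])

    @property
    def sigma(self) -> float:
        return self._sigma

    @property
    def pair_probabilities(self) -> np.ndarray:
        """Base-pair probability matrix P[i, j] (0-based upper triangle)."""
        if self._p_pos is None:
            self._run_outside()
        return self._P

    def _run_outside(self):
        Qb, QM, Qx, Qs = self._inside
        sb, lb, hb, mlw, mlw2, b1f, uf = self._tables_cache[self._sigma]
        self._P = _kernels.fold_outside(
            self._enc, self._ptab, sb, lb, mlw2, uf,
            self.model.max_internal_loop, self.model.min_hairpin,
            Qb, QM, Qx, Qs)
        p_paired = self._P.sum(axis=0) + self._P.sum(axis=1)
        self._p_pos = np.clip(1.0 - p_paired, 0.0, 1.0)

    @property
    def p_unpaired_pos(self) -> np.ndarray:
        """Per-position unpaired probability, index 0 = sequence position 1."""
        if self._p_pos is None:
            self._run_outside()
        return self._p_pos

    def p_unpaired_interval(self, i: int, j: int) -> float:
        """Probability that all of positions i..j (1-based) are unpaired."""
        if not (1 <= i <= j <= self.seq_len):
            raise IndexError(f"interval {i}..{j} out of range 1..{self.seq_len}")
        key = (i, j)
        if key not in self._interval_cache:
            mask = np.zeros(self.seq_len, dtype=np.int8)
            mask[i - 1:j] = 1
            _, (_, _, Qx, _) = self._fold(mask, sigma=self._sigma)
            p = float(Qx[self.seq_len]) / self.Z
            self._interval_cache[key] = min(p, 1.0)
        return self._interval_cache[key]

    def opening_energy(self, i: int, j: int) -> float:
        """ED(i, j) = -RT ln P(i..j unpaired), in kcal/mol (>= 0)."""
        p = self.p_unpaired_interval(i, j)
        if p < self.p_floor:
            return math.inf
        return max(0.0, -self.rt * math.log(p))


def fold_partition(seq: NucleotideSequence, model: EnergyModel = DEFAULT_MODEL,
                   max_len: int = DEFAULT_MAX_LEN) -> AccessibilityProfile:
    """Fold a whole sequence and return its accessibility profile."""
    return AccessibilityProfile(seq, model=model, max_len=max_len)


class ProjectedProfile:
    """A window's view into the profile of a longer folded sequence.

    Exposes the AccessibilityProfile interface in window coordinates while
    the fold itself included flanking genomic context.
    """

    def __init__(self, parent: AccessibilityProfile, offset: int, length: int):
        self.parent = parent
        self.offset = offset  # 0-based start of the window inside the parent
        self.seq_len = length
        self.rt = parent.rt

    @property
    def p_unpaired_pos(self) -> np.ndarray:
        return self.parent.p_unpaired_pos[self.offset:self.offset + self.seq_len]

    def p_unpaired_interval(self, i: int, j: int) -> float:
        if not (1 <= i <= j <= self.seq_len):
            raise IndexError(f"interval {i}..{j} out of window range 1..{self.seq_len}")
        return self.parent.p_unpaired_interval(i + self.offset, j + self.offset)

    def opening_energy(self, i: int, j: int) -> float:
        if not (1 <= i <= j <= self.seq_len):
            raise IndexError(f"interval {i}..{j} out of window range 1..{self.seq_len}")
        return self.parent.opening_energy(i + self.offset, j + self.offset)


def windowed_accessibility(window: TargetWindow, replicon: AnnotatedReplicon,
                           model: EnergyModel = DEFAULT_MODEL,
                           context: int = 50) -> AccessibilityProfile | ProjectedProfile:
    """Accessibility of a target window folded with flanking genomic context.

    The window is extended by up to ``context`` nt of replicon sequence on
    each side (respecting strand, truncating at replicon ends), folded, and
    the resulting probabilities are reported in window coordinates.
    """
    if context < 0:
        raise ValueError("context must be >= 0")
    if context == 0:
        return fold_partition(window.window_seq, model=model)
    g_start, g_end, strand = window.genomic_interval
    n = len(replicon.sequence)
    e_start = max(1, g_start - context)
    e_end = min(n, g_end + context)
    raw = replicon.sequence.residues[e_start - 1:e_end]
    ext = NucleotideSequence(raw, name=window.gene_id + "|context")
    if strand == "-":
        ext = ext.reverse_complement()
        offset = e_end - g_end
    else:
        offset = g_start - e_start
    parent = fold_partition(ext, model=model)
    return ProjectedProfile(parent, offset, len(window.window_seq))
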
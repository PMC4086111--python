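"""Nearest-neighbor RNA energy model shared by duplex and folding code.

The model is a simplified Turner-2004-style parameterization at 37 degC:
helix stacks (Watson-Crick and G.U wobble) come from a versioned TSV data
file; loop contributions use small initiation tables with the standard
``1.75*RT*ln`` Jacobson-Stockmayer length extrapolation; multiloops use the
affine ``a + b*branches + c*unpaired`` approximation.  Terminal mismatches,
dangling ends and special hairpin sequences are deliberately excluded so
that an exhaustive enumerator can score any structure from the same small
set of primitives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

GAS_CONSTANT = 1.987e-3  # kcal/(mol*K)

#: integer encoding of the RNA alphabet used by all kernels
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
BASES = "ACGU"

#: canonical pair types, in the order used by the stack matrix
PAIR_NAMES = ("AU", "UA", "CG", "GC", "GU", "UG")
PAIR_INDEX = {
    (0, 3): 0,  # A.U
    (3, 0): 1,  # U.A
    (1, 2): 2,  # C.G
    (2, 1): 3,  # G.C
    (2, 3): 4,  # G.U
    (3, 2): 5,  # U.G
}

# 4x4 lookup: pair type of (base_i, base_j), -1 if not pairable
PAIR_TABLE = np.full((4, 4), -1, dtype=np.int8)
for (_a, _b), _t in PAIR_INDEX.items():
    PAIR_TABLE[_a, _b] = _t

# reversal of a pair type: pair (x, y) read from the other strand is (y, x)
PAIR_REVERSE = np.array([1, 0, 3, 2, 5, 4], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string as int8 indices into :data:`BASES`."""
    try:
        return np.array([BASE_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"non-RNA character {exc} in sequence") from exc


class ParameterError(KeyError):
    """Lookup of an energy parameter that is not defined by the model."""


def _load_stack_table(name: str = "stack_turner2004.tsv") -> np.ndarray:
    stack = np.full((6, 6), np.nan)
    text = resources.files("srnatarget.data").joinpath(name).read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("pair5"):
            continue
        p5, p3, dg = line.split("\t")
        i = PAIR_NAMES.index(p5)
        j = PAIR_NAMES.index(p3)
        stack[i, j] = float(dg)
    if np.isnan(stack).any():
        raise ParameterError("incomplete stack table " + name)
    # a stack read from the opposite strand is the same physical motif
    for i in range(6):
        for j in range(6):
            ri, rj = PAIR_REVERSE[j], PAIR_REVERSE[i]
            if abs(stack[i, j] - stack[ri, rj]) > 1e-9:
                raise ParameterError(
                    f"stack table violates strand symmetry at {PAIR_NAMES[i]}/{PAIR_NAMES[j]}"
                )
    return stack


@dataclass(frozen=True)
class EnergyModel:
    """Free-energy parameters (kcal/mol) for duplexes and secondary structures."""

    stack: np.ndarray = field(default_factory=_load_stack_table)
    temperature: float = 310.15  # K
    duplex_init: float = 4.09
    au_end_penalty: float = 0.45  # per AU or GU duplex end
    max_internal_loop: int = 30  # nt per side in duplexes, total in folds
    bulge_init: float = 3.8
    interior_init: tuple = (1.5, 2.0, 2.5)  # total size 2, 3, 4
    loop_asym: float = 0.6  # per nt of asymmetry
    loop_asym_max: float = 3.0
    hairpin_init: tuple = (5.4, 5.6, 5.7, 5.4, 6.0, 5.5, 6.4)  # loop size 3..9
    min_hairpin: int = 3
    ml_init: float = 3.4  # multiloop closing penalty (a)
    ml_branch: float = 0.4  # per branch incl. closing pair (b)
    ml_unpaired: float = 0.0  # per unpaired multiloop nt (c)

    @property
    def RT(self) -> float:
        return GAS_CONSTANT * self.temperature

    # -- primitives shared by the DP kernels and the enumeration oracles --

    def pair_type(self, a: int, b: int) -> int:
        return int(PAIR_TABLE[a, b])

    def pairable(self, a: int, b: int) -> bool:
        return PAIR_TABLE[a, b] >= 0

    def stack_energy(self, outer: int, inner: int) -> float:
        """Stack of inner pair on outer pair; fails loudly for non-pairs."""
        if outer < 0 or inner < 0:
            raise ParameterError("stack energy requested for a non-pair")
        return float(self.stack[outer, inner])

    def loop_energy(self, g1: int, g2: int) -> float:
        """Bulge/interior loop with g1 and g2 unpaired nt on the two sides."""
        if g1 == 0 and g2 == 0:
            raise ParameterError("0x0 loop is a stack, not a loop")
        if g1 < 0 or g2 < 0:
            raise ParameterError("negative loop size")
        if min(g1, g2) == 0:
            n = max(g1, g2)
            if n == 1:
                return self.bulge_init
            return self.bulge_init + 1.75 * self.RT * math.log(n)
        t = g1 + g2
        if t <= 4:
            init = self.interior_init[t - 2]
        else:
            init = self.interior_init[-1] + 1.75 * self.RT * math.log(t / 4.0)
        asym = min(self.loop_asym * abs(g1 - g2), self.loop_asym_max)
        return init + asym

    def hairpin_energy(self, loop_len: int) -> float:
        if loop_len < self.min_hairpin:
            raise ParameterError(f"hairpin loop of {loop_len} nt below minimum")
        if loop_len <= 9:
            return self.hairpin_init[loop_len - 3]
        return self.hairpin_init[-1] + 1.75 * self.RT * math.log(loop_len / 9.0)

    def end_penalty(self, pair: int) -> float:
        """Helix-end penalty for AU/UA/GU/UG terminal duplex pairs."""
        if pair < 0:
            raise ParameterError("end penalty requested for a non-pair")
        return self.au_end_penalty if pair in (0, 1, 4, 5) else 0.0


DEFAULT_MODEL = EnergyModel()
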
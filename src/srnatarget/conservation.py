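"""Per-position sRNA conservation from a homolog multiple alignment.

Interaction sites of trans-acting sRNAs tend to be better conserved than
the rest of the molecule, so columns of a homolog alignment are summarized
as Shannon entropies over the five states {A, C, G, U, gap} and mapped back
to sRNA coordinates by skipping reference gaps.  A gap counts as a state:
indels in homologs are evidence of non-conservation.  The conservation
weight is ``1 - H/log2(5)``, i.e. 1 for a perfectly conserved column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import AlignIO

from .sequence_io import NucleotideSequence, normalize_residues

_STATES = "ACGU-"
N_STATES = 5
MAX_ENTROPY = math.log2(N_STATES)


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class HomologAlignment:
    """Aligned sRNA homologs; the reference row is the query sRNA itself."""

    rows: tuple  # of (id, aligned string over ACGU-)
    reference_row: str

    def __post_init__(self):
        if not self.rows:
            raise AlignmentError("empty alignment")
        width = len(self.rows[0][1])
        for rid, aligned in self.rows:
            if len(aligned) != width:
                raise AlignmentError(
                    f"ragged alignment: row {rid!r} has length {len(aligned)}, "
                    f"expected {width}"
                )
            bad = set(aligned) - set(_STATES)
            if bad:
                raise AlignmentError(f"row {rid!r} contains invalid states {sorted(bad)}")
        if self.reference_row not in {rid for rid, _ in self.rows}:
            raise AlignmentError(f"reference row {self.reference_row!r} not in alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def reference_aligned(self) -> str:
        return next(a for rid, a in self.rows if rid == self.reference_row)


def read_alignment(path, format: str = "aligned_fasta", reference_id: str | None = None,
                   srna: NucleotideSequence | None = None) -> HomologAlignment:
    """Read a Clustal or aligned-FASTA homolog alignment.

    If ``srna`` is given, the degapped reference row must reproduce it
    exactly (first mismatch position reported otherwise).
    """
    fmt = {"clustal": "clustal", "aligned_fasta": "fasta", "fasta": "fasta"}.get(format)
    if fmt is None:
        raise AlignmentError(f"unknown alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentError(f"{path}: {exc}") from exc
    rows = []
    for rec in msa:
        aligned = "".join(
            "-" if c in "-." else normalize_residues(c, name=rec.id, strict=True)
            for c in str(rec.seq).upper()
        )
        rows.append((rec.id, aligned))
    if reference_id is None:
        reference_id = rows[0][0]
    aln = HomologAlignment(rows=tuple(rows), reference_row=reference_id)
    if srna is not None:
        degapped = aln.reference_aligned().replace("-", "")
        if degapped != srna.residues:
            pos = next(
                (k + 1 for k, (a, b) in enumerate(zip(degapped, srna.residues)) if a != b),
                min(len(degapped), len(srna)) + 1,
            )
            raise AlignmentError(
                f"reference row {reference_id!r} does not match the sRNA "
                f"(first mismatch at sRNA position {pos})"
            )
    return aln


@dataclass(frozen=True)
class ConservationProfile:
    entropy: np.ndarray  # bits, one per sRNA position
    weight: np.ndarray  # 1 - H/log2(5), in [0, 1]
    n_rows: int
    low_confidence: bool = False

    def mean_weight(self, i: int, j: int) -> float:
        """Mean conservation weight over sRNA positions i..j (1-based)."""
        return float(self.weight[i - 1:j].mean())


def positional_entropy(aln: HomologAlignment, pseudocount: float = 0.5) -> ConservationProfile:
    """Column entropies (bits) at each ungapped reference position.

    Frequencies are taken over all rows with ``pseudocount`` added per
    state (beta = 0.5 by default; 0 gives pure counts for closed-form
    checks).  A single-row alignment yields zero entropy everywhere and is
    flagged low-confidence.
    """
    ref = aln.reference_aligned()
    entropies = []
    low_conf = aln.n_rows < 2
    for col in range(aln.width):
        if ref[col] == "-":
            continue
        if low_conf:
            entropies.append(0.0)
            continue
        counts = np.full(N_STATES, pseudocount, dtype=float)
        for _, aligned in aln.rows:
            counts[_STATES.index(aligned[col])] += 1.0
        freqs = counts / counts.sum()
        nz = freqs[freqs > 0]
        entropies.append(float(-(nz * np.log2(nz)).sum()))
    entropy = np.array(entropies)
    weight = np.clip(1.0 - entropy / MAX_ENTROPY, 0.0, 1.0)
    return ConservationProfile(entropy=entropy, weight=weight, n_rows=aln.n_rows,
                               low_confidence=low_conf)
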
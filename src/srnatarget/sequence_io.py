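"""Sequence and annotation input, and extraction of start-codon windows.

Trans-acting sRNAs overwhelmingly bind their targets in a neighborhood of
the ribosome binding site, so the scan never looks at whole genes: each
gene contributes a single window around its translation start, read on the
mRNA sense strand.  Coordinates are 1-based inclusive in all user-facing
structures (the GFF convention) and converted to 0-based half-open only
inside extraction arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

_RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}
_AMBIGUITY = {
    "R": "A", "Y": "C", "S": "C", "W": "A", "K": "G", "M": "A",
    "B": "C", "D": "A", "H": "A", "V": "A", "N": "A",
}


class FastaParseError(ValueError):
    pass


class AlphabetError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class NucleotideSequence:
    """An RNA sequence, 5'->3'.  DNA input is transcribed T->U on read."""

    residues: str
    name: str = ""

    def __post_init__(self):
        if len(self.residues) < 1:
            raise AlphabetError(f"empty sequence {self.name!r}")
        bad = set(self.residues) - set("ACGU")
        if bad:
            raise AlphabetError(
                f"sequence {self.name!r} contains non-ACGU characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def reverse_complement(self) -> "NucleotideSequence":
        rc = "".join(_RNA_COMPLEMENT[c] for c in reversed(self.residues))
        return NucleotideSequence(rc, name=self.name)


def normalize_residues(raw: str, name: str = "", strict: bool = True) -> str:
    """Case-fold, transcribe T->U, and resolve or reject ambiguity codes."""
    s = raw.upper().replace("T", "U")
    out = []
    for i, c in enumerate(s):
        if c in "ACGU":
            out.append(c)
        elif c in _AMBIGUITY:
            if strict:
                raise AlphabetError(
                    f"ambiguity code {c!r} at position {i + 1} of {name!r} "
                    "(strict alphabet mode)"
                )
            out.append(_AMBIGUITY[c])
        else:
            raise AlphabetError(f"invalid character {c!r} at position {i + 1} of {name!r}")
    return "".join(out)


def read_fasta(path, strict_alphabet: bool = True) -> list[NucleotideSequence]:
    """Read a FASTA file into normalized RNA sequences, order preserved."""
    path = Path(path)
    # light pre-scan so syntax errors can name the offending line
    n_headers = 0
    last_header_line = None
    has_seq = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(">"):
            if last_header_line is not None and not has_seq:
                raise FastaParseError(
                    f"{path}: record starting at line {last_header_line} has no sequence"
                )
            n_headers += 1
            last_header_line = lineno
            has_seq = False
        elif line.strip():
            if last_header_line is None:
                raise FastaParseError(f"{path}: sequence data before any header at line {lineno}")
            has_seq = True
    if n_headers == 0:
        raise FastaParseError(f"{path}: no FASTA records found")
    if not has_seq:
        raise FastaParseError(f"{path}: record starting at line {last_header_line} has no sequence")

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = normalize_residues(str(rec.seq), name=rec.id, strict=strict_alphabet)
        records.append(NucleotideSequence(residues, name=rec.id))
    return records


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    name: str
    strand: str  # '+' or '-'
    cds_start: int  # 1-based inclusive, cds_start <= cds_end on the genome
    cds_end: int
    product: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (1 <= self.cds_start <= self.cds_end):
            raise AnnotationError(
                f"{self.gene_id}: invalid coordinates {self.cds_start}..{self.cds_end}"
            )


@dataclass
class AnnotatedReplicon:
    sequence: NucleotideSequence
    genes: list[GeneRecord]
    replicon_id: str = "replicon"

    def __post_init__(self):
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.cds_end > len(self.sequence):
                raise AnnotationError(
                    f"{g.gene_id}: cds_end {g.cds_end} beyond replicon length "
                    f"{len(self.sequence)}"
                )


_GFF_ID_KEYS = ("ID", "locus_tag", "gene", "Name")


def _parse_gff_attributes(text: str) -> dict:
    attrs = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_annotation(path, dialect: str = "gff3",
                    feature_types: tuple = ("CDS", "gene")) -> list[GeneRecord]:
    """Read gene records from GFF3 or a minimal 6-column table.

    Table dialect: whitespace-separated ``gene_id name strand start stop
    product`` (product may contain spaces).  For GFF3 only the configured
    feature types are retained; where both a gene and its CDS appear, the
    CDS coordinates win.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    if dialect == "table":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = re.split(r"\s+", line.strip(), maxsplit=5)
            if len(parts) < 5:
                raise AnnotationError(f"{path}:{lineno}: expected >= 5 columns")
            gene_id, name, strand, start, stop = parts[:5]
            product = parts[5] if len(parts) == 6 else ""
            try:
                genes.append(GeneRecord(gene_id, name, strand, int(start), int(stop), product))
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
        return genes
    if dialect != "gff3":
        raise AnnotationError(f"unknown annotation dialect {dialect!r}")

    by_id: dict[str, GeneRecord] = {}
    order: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 9:
            raise AnnotationError(f"{path}:{lineno}: expected 9 tab-separated columns")
        _, _, ftype, start_s, end_s, _, strand, _, attr_s = cols
        if ftype not in feature_types:
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from exc
        attrs = _parse_gff_attributes(attr_s)
        gene_id = next((attrs[k] for k in _GFF_ID_KEYS if k in attrs), None)
        if gene_id is None:
            raise AnnotationError(f"{path}:{lineno}: no ID/locus_tag/gene attribute")
        gene_id = gene_id.removeprefix("cds-").removeprefix("gene-")
        name = attrs.get("gene", attrs.get("Name", gene_id))
        product = attrs.get("product", "")
        try:
            rec = GeneRecord(gene_id, name, strand, start, end, product)
        except AnnotationError as exc:
            raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
        if gene_id in by_id:
            if ftype == "CDS":  # CDS refines a prior gene feature
                by_id[gene_id] = rec
        else:
            by_id[gene_id] = rec
            order.append(gene_id)
    return [by_id[g] for g in order]


@dataclass(frozen=True)
class TargetWindow:
    """The subsequence around one gene's start codon, on the mRNA strand.

    Window position ``offset_up + 1`` (1-based) is the first base of the
    start codon when the window is not truncated at a replicon boundary.
    """

    gene_id: str
    window_seq: NucleotideSequence
    offset_up: int
    offset_down: int
    genomic_interval: tuple  # (start, end, strand), 1-based inclusive
    truncated: bool = False
    gene: GeneRecord | None = field(default=None, compare=False)

    def relative_position(self, window_pos: int) -> int:
        """Map a 1-based window position to start-codon-relative coordinates.

        Position +1 is the first base of the start codon; upstream positions
        are negative (there is no position 0).
        """
        rel = window_pos - self.offset_up
        return rel if rel >= 1 else rel - 1


def extract_window(replicon: AnnotatedReplicon, gene: GeneRecord,
                   offset_up: int = 80, offset_down: int = 20,
                   circular: bool = False) -> TargetWindow:
    """Extract the start-codon neighborhood of a gene, 5'->3' on its mRNA."""
    if offset_up < 0 or offset_down < 1:
        raise ValueError("offset_up must be >= 0 and offset_down >= 1")
    n = len(replicon.sequence)
    seq = replicon.sequence.residues
    if gene.strand == "+":
        g_start = gene.cds_start - offset_up  # 1-based, may underflow
        g_end = gene.cds_start + offset_down - 1
    else:
        g_start = gene.cds_end - offset_down + 1
        g_end = gene.cds_end + offset_up

    truncated = False
    if circular:
        idx = [(p - 1) % n for p in range(g_start, g_end + 1)]
        raw = "".join(seq[i] for i in idx)
        up = offset_up
        down = offset_down
    else:
        c_start = max(g_start, 1)
        c_end = min(g_end, n)
        if c_start > c_end:
            raise AnnotationError(f"{gene.gene_id}: window entirely outside the replicon")
        truncated = (c_start != g_start) or (c_end != g_end)
        raw = seq[c_start - 1:c_end]
        if gene.strand == "+":
            up = gene.cds_start - c_start
            down = c_end - gene.cds_start + 1
        else:
            up = c_end - gene.cds_end
            down = gene.cds_end - c_start + 1
        g_start, g_end = c_start, c_end

    window = NucleotideSequence(raw, name=gene.gene_id)
    if gene.strand == "-":
        window = window.reverse_complement()
    return TargetWindow(
        gene_id=gene.gene_id,
        window_seq=window,
        offset_up=up,
        offset_down=down,
        genomic_interval=(g_start, g_end, gene.strand),
        truncated=truncated,
        gene=gene,
    )
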
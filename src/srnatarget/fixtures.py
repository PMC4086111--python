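"""Deterministic synthetic fixtures: replicons with planted sRNA targets.

The generator emulates the statistical structure the scan assumes — exact
or near-exact reverse complements of a designated sRNA "interacting
region" planted near gene starts, homolog alignments whose substitution
rate is lower inside that region than outside it, and a DE table in which
true targets (and optionally some decoys) are co-differentially expressed
with the sRNA.  It makes no attempt at realistic genome composition
(operons, codon bias); decoy genes are i.i.d. nucleotides at a specified
GC fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .conservation import HomologAlignment
from .sequence_io import (AnnotatedReplicon, GeneRecord, NucleotideSequence)

_RNA = np.array(list("ACGU"))
_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def _rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


@dataclass(frozen=True)
class PlantedTarget:
    gene_index: int
    length: int = 20  # nt of complementarity to the sRNA interacting region
    mismatches: int = 0
    site_offset: int = -20  # start of the site relative to the start codon
    structured: bool = False  # embed the site in a hairpin stem


@dataclass(frozen=True)
class FixtureSpec:
    n_genes: int = 200
    gene_length: tuple = (150, 300)
    intergenic_length: tuple = (120, 250)
    gc: float = 0.5
    srna_length: int = 60
    interacting_region: tuple = (5, 24)  # 1-based inclusive on the sRNA
    planted: tuple = ()  # of PlantedTarget
    homologs: int = 0  # rows in the synthetic alignment (0 = none)
    sub_rate_in: float = 0.03  # substitutions/position inside the region
    sub_rate_out: float = 0.15  # elevated rate outside it
    indel_rate: float = 0.01
    condition_pairs: tuple = ("c1_vs_c2", "c2_vs_c3")
    co_de_gene_indices: tuple = ()  # genes DE in the sRNA's condition pair
    rng_seed: int = 0


@dataclass
class Fixture:
    spec: FixtureSpec
    srna: NucleotideSequence
    replicon: AnnotatedReplicon
    alignment: HomologAlignment | None
    de_table: "object"  # pandas.DataFrame or None
    truth: list  # of (gene_id, PlantedTarget)


def _random_seq(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_RNA, size=n, p=p))


def _plant(site: str, genome: list, gene: GeneRecord, rel_start: int):
    """Write ``site`` (mRNA-sense RNA) into the genome at a start-codon
    relative offset (negative = upstream; no position 0)."""
    L = len(site)
    for k in range(L):
        rel = rel_start + k
        if rel >= 0:
            rel += 1  # skip the nonexistent position 0
        if gene.strand == "+":
            g = gene.cds_start + (rel - 1 if rel > 0 else rel)
            genome[g - 1] = site[k]
        else:
            g = gene.cds_end - (rel - 1 if rel > 0 else rel)
            genome[g - 1] = _COMP[site[k]]


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the in-memory fixture for a spec (byte-deterministic)."""
    rng = np.random.default_rng(spec.rng_seed)
    srna = NucleotideSequence(_random_seq(rng, spec.srna_length, spec.gc), name="srna")

    genes = []
    genome_parts = []
    pos = 1
    for gi in range(spec.n_genes):
        ig = int(rng.integers(spec.intergenic_length[0], spec.intergenic_length[1] + 1))
        gl = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
        genome_parts.append(_random_seq(rng, ig, spec.gc))
        pos += ig
        strand = "+" if rng.random() < 0.5 else "-"
        genome_parts.append(_random_seq(rng, gl, spec.gc))
        genes.append(GeneRecord(
            gene_id=f"g{gi:04d}", name=f"gene{gi:04d}", strand=strand,
            cds_start=pos, cds_end=pos + gl - 1,
            product=f"hypothetical protein {gi}"))
        pos += gl
    genome_parts.append(_random_seq(rng, 200, spec.gc))
    genome = list("".join(genome_parts))

    ia, ib = spec.interacting_region
    region = srna.residues[ia - 1:ib]
    truth = []
    for pt in spec.planted:
        # the site must fall inside the default -80..+20 search window
        if pt.length > ib - ia + 1:
            raise ValueError("planted site longer than the sRNA interacting region")
        if pt.site_offset < -80 or pt.site_offset + pt.length > 21:
            raise ValueError(
                f"planted site at offset {pt.site_offset} (length {pt.length}) "
                "does not fit in the default search window")
        gene = genes[pt.gene_index]
        site = _rc(region)[:pt.length]
        if pt.mismatches:
            site_l = list(site)
            for k in rng.choice(len(site), size=pt.mismatches, replace=False):
                site_l[k] = str(rng.choice([b for b in "ACGU" if b != site_l[k]]))
            site = "".join(site_l)
        _plant(site, genome, gene, pt.site_offset)
        if pt.structured:
            # a complementary copy downstream turns the site into a stem
            _plant(_rc(site), genome, gene, pt.site_offset + pt.length + 4)
        truth.append((gene.gene_id, pt))

    replicon = AnnotatedReplicon(
        sequence=NucleotideSequence("".join(genome), name="fixture_replicon"),
        genes=genes, replicon_id="fixture_replicon")

    alignment = None
    if spec.homologs > 0:
        rows = [("srna", srna.residues)]
        in_region = np.zeros(spec.srna_length, dtype=bool)
        in_region[ia - 1:ib] = True
        for h in range(spec.homologs):
            hom = []
            for k, c in enumerate(srna.residues):
                rate = spec.sub_rate_in if in_region[k] else spec.sub_rate_out
                if rng.random() < spec.indel_rate and not in_region[k]:
                    hom.append("-")  # deletion in the homolog
                elif rng.random() < rate:
                    hom.append(str(rng.choice([b for b in "ACGU" if b != c])))
                else:
                    hom.append(c)
            rows.append((f"hom{h}", "".join(hom)))
        alignment = HomologAlignment(rows=tuple(rows), reference_row="srna")

    de_table = None
    if spec.co_de_gene_indices or spec.condition_pairs:
        import pandas as pd
        srna_pair = spec.condition_pairs[0]
        records = []
        for cp in spec.condition_pairs:
            records.append({
                "gene_id": "srna", "condition_pair": cp,
                "log2fc": round(float(rng.normal(2.0, 0.3)), 3),
                "pvalue": 1e-4 if cp == srna_pair else 0.5,
            })
        co = set(spec.co_de_gene_indices)
        for gi, gene in enumerate(genes):
            for cp in spec.condition_pairs:
                if gi in co and cp == srna_pair:
                    p = float(rng.uniform(1e-5, 5e-3))
                else:
                    p = float(rng.uniform(0.02, 0.95))
                records.append({
                    "gene_id": gene.gene_id, "condition_pair": cp,
                    "log2fc": round(float(rng.normal(0.0, 1.5)), 3),
                    "pvalue": round(p, 6),
                })
        de_table = pd.DataFrame.from_records(records)

    return Fixture(spec=spec, srna=srna, replicon=replicon,
                   alignment=alignment, de_table=de_table, truth=truth)


def null_spec(seed: int, n_genes: int = 300, **kw) -> FixtureSpec:
    """A replicon with no planted sites, for P-value calibration checks."""
    return FixtureSpec(n_genes=n_genes, planted=(), rng_seed=seed, **kw)


def planted_spec(seed: int, n_genes: int = 200, n_planted: int = 1,
                 length: int = 20, mismatches: int = 0,
                 with_de: bool = False, n_co_de_decoys: int = 30, **kw) -> FixtureSpec:
    """A replicon with perfect-complement sites planted in random genes.

    With ``with_de`` the DE table marks the planted genes plus
    ``n_co_de_decoys`` decoys as co-differentially expressed with the sRNA
    (the situation the co-expression filter is designed for).
    """
    rng = np.random.default_rng(seed + 10_000)
    idx = sorted(int(i) for i in rng.choice(n_genes, size=n_planted, replace=False))
    planted = tuple(PlantedTarget(gene_index=i, length=length, mismatches=mismatches)
                    for i in idx)
    if with_de:
        others = [i for i in range(n_genes) if i not in set(idx)]
        decoys = rng.choice(len(others), size=min(n_co_de_decoys, len(others)),
                            replace=False)
        co = tuple(sorted(idx + [others[int(d)] for d in decoys]))
        kw.setdefault("co_de_gene_indices", co)
    return FixtureSpec(n_genes=n_genes, planted=planted, rng_seed=seed, **kw)


# ---------------------------------------------------------------------------
# file output

def write_fixture(fix: Fixture, outdir) -> dict:
    """Write the fixture as FASTA/GFF3/TSV files; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _fasta(path, name, seq):
        lines = [f">{name}"]
        for k in range(0, len(seq), 70):
            lines.append(seq[k:k + 70])
        path.write_text("\n".join(lines) + "\n")

    paths["srna"] = outdir / "srna.fa"
    _fasta(paths["srna"], fix.srna.name, fix.srna.residues)
    paths["replicon"] = outdir / "replicon.fa"
    _fasta(paths["replicon"], fix.replicon.replicon_id, fix.replicon.sequence.residues)

    paths["annotation"] = outdir / "genes.gff3"
    gff = ["##gff-version 3"]
    for g in fix.replicon.genes:
        attrs = f"ID={g.gene_id};gene={g.name};product={g.product}"
        gff.append("\t".join([fix.replicon.replicon_id, "fixture", "CDS",
                              str(g.cds_start), str(g.cds_end), ".", g.strand,
                              "0", attrs]))
    paths["annotation"].write_text("\n".join(gff) + "\n")

    if fix.alignment is not None:
        paths["alignment"] = outdir / "homologs.afa"
        lines = []
        for rid, aligned in fix.alignment.rows:
            lines.append(f">{rid}")
            lines.append(aligned)
        paths["alignment"].write_text("\n".join(lines) + "\n")

    if fix.de_table is not None:
        paths["de_table"] = outdir / "de.tsv"
        fix.de_table.to_csv(paths["de_table"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.tsv"
    rows = ["gene_id\tsite_offset\tlength\tmismatches\tstructured"]
    for gene_id, pt in fix.truth:
        rows.append(f"{gene_id}\t{pt.site_offset}\t{pt.length}\t{pt.mismatches}\t"
                    f"{int(pt.structured)}")
    paths["truth"].write_text("\n".join(rows) + "\n")
    return paths
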
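# srnatarget

Genome-wide prediction of the mRNA targets of *trans*-acting bacterial
small regulatory RNAs (sRNAs).

Most characterized trans-acting sRNAs regulate translation by base-pairing
with limited complementarity near the ribosome binding site of their target
mRNAs. `srnatarget` takes an sRNA sequence and an annotated replicon,
extracts a window around every gene's start codon (default −80..+20), and
scores each candidate interaction by combining four signals:

1. **Hybridization energy** `E_hyb`: the minimum free energy of the
   intermolecular sRNA–mRNA duplex (nearest-neighbor stacks, bulge and
   interior loops, G·U wobble pairs), subject to a seed of at least
   `min_seed` consecutive base pairs.
2. **sRNA accessibility**: Boltzmann-ensemble unpaired probabilities from a
   McCaskill partition function over the sRNA's secondary structures.
3. **mRNA accessibility**: the same computation for each target window,
   folded with 50 nt of flanking genomic context.
4. **sRNA conservation**: positional entropies of a homolog multiple
   alignment (5-state alphabet including gaps), mapped to conservation
   weights `w = 1 − H/log2 5`.

Accessibility enters the score as additive opening energies,

    E_total = E_hyb + ED_sRNA(site) + ED_mRNA(site),
    ED(i..j) = −RT · ln P(i..j unpaired),

so every term is a free energy; conservation and sRNA accessibility
additionally gate which sRNA positions may anchor the seed. Genome-wide
`E_total` scores are calibrated to P-values with a Gumbel (extreme-value)
fit — each gene's score is the best of many candidate sites, so "an
interaction at least this favorable by chance" is an extreme-value null —
and targets are reported ranked by P-value. If RNA-seq differential
expression tables are available, the search can be restricted to genes
co-differentially expressed with the sRNA in the same pair of conditions,
which sharply reduces false positives.

Both dynamic programs are validated exactly against exhaustive enumeration
oracles in the test suite (all antiparallel pairings for the duplex; all
nested secondary structures for the partition function).

## Worked example

Generate a synthetic replicon with one planted target (a perfect 20-nt
reverse complement of the sRNA's interacting region placed at offset −20
from the start codon of gene 17), then scan it:

```sh
cat > spec.yaml <<EOF
n_genes: 120
homologs: 8
planted:
  - {gene_index: 17, length: 20, site_offset: -20}
EOF
srna-target-fixtures --spec spec.yaml --seed 11 -o fixture/
srna-target-scan --srna fixture/srna.fa --replicon fixture/replicon.fa \
    --annotation fixture/genes.gff3 --alignment fixture/homologs.afa -o out/
```

The scan prints `1 significant target(s)` and `out/predictions.tsv` begins

```
rank  gene_id  name      product                  e_hyb   ed_srna  ed_mrna  e_total  p_value
1     g0017    gene0017  hypothetical protein 17  -38.39  7.93     7.73     -22.73   3.948e-03
```

The planted gene is ranked first: its duplex gains −38.39 kcal/mol, of
which 15.66 kcal/mol is paid to open the interacting intervals of both
molecules, leaving `E_total = −22.73` — far in the tail of the genome-wide
score distribution (`p = 0.004`). `out/report.txt` renders each
significant interaction ('|' Watson–Crick, ':' G·U, dashes for bulges;
mRNA coordinates relative to the start codon):

```
[1] g0017 (gene0017)  e_total = -22.73 kcal/mol  p = 3.948e-03
    hypothetical protein 17
mRNA    -43 5' GCGCAUG-AUCACCACCUAGUGUUGCUACACCAUGCCGCAUUAUU 3' 1
              ||:     |||      ||:|   |||||||||||||||||||||
sRNA     47 3' CGUCCAAAUAGACUACCAUUAGC-CGAUGUGGUACGGCGUAAUAA 5' 4
```

To use an RNA-seq co-expression filter, add
`--de-table de.tsv --srna-gene-id <id>`; the P-value calibration is then
re-run on the filtered gene set only.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a planted fixture from the seed, runs the complete file-based
pipeline (sequence and annotation I/O, conservation, accessibility, duplex
search, calibration, co-expression filtering, report writing), and writes
the results JSON.
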
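# Methods

## Model overview

A candidate interaction between a trans-acting sRNA and an mRNA is scored
as the free-energy balance of forming an intermolecular duplex at a site
near the ribosome binding site:

    E_total = E_hyb + ED_sRNA(i1..j1) + ED_mRNA(i2..j2)

`E_hyb` is the minimum free energy of the intermolecular hybrid;
`ED(i..j) = −RT ln P(i..j unpaired)` is the ensemble cost of freeing the
interacting interval of each molecule from intramolecular structure. This
additive decomposition treats hybrid formation as a two-step process (open
both sites, then hybridize) and makes every feature dimensionally an
energy. Conservation and sRNA accessibility act as a gate rather than an
energy term: the seed must overlap at least one sRNA position with
unpaired probability ≥ `p_min` (default 0.25) and, when a homolog
alignment is supplied, conservation weight ≥ `w_min` (default 0.5). A gene
is scored only if an accepted hybrid exists and `E_total < 0`.

## Energy model

A single nearest-neighbor parameter set at 37 °C serves both the duplex
and folding computations (`src/srnatarget/data/stack_turner2004.tsv`):

- Helix stacks for all Watson–Crick and G·U pair combinations. The
  Watson–Crick block uses the published Turner/Xia values; G·U entries are
  plausible Turner-2004-like values. The loader enforces the physical
  symmetry `E(p,q) = E(rev q, rev p)`.
- Bulges: 3.8 kcal/mol for 1 nt, plus `1.75·RT·ln n` beyond. Interior
  loops: initiation 1.5/2.0/2.5 kcal/mol for total size 2/3/4 with the
  same logarithmic extrapolation, plus 0.6 kcal/mol per nt of asymmetry
  (capped at 3.0).
- Hairpins: tabulated initiations for loops of 3–9 nt, logarithmic beyond;
  minimum loop 3.
- Multiloops: affine `a + b·branches + c·unpaired` with a = 3.4,
  b = 0.4, c = 0 kcal/mol.
- Duplexes only: initiation 4.09 kcal/mol and a 0.45 kcal/mol penalty per
  AU or GU helix end.

Terminal mismatches, dangling ends, coaxial stacking and special hairpin
sequences are deliberately omitted. This sacrifices some thermodynamic
realism (predicted energies are systematically a little less negative than
RNAduplex/RNAfold would give) but keeps the model small enough that an
exhaustive enumerator can score any structure from the same primitives,
which is what makes the exact oracle tests possible.

## Duplex search

The hybrid model is intermolecular-only: no multiloops, bulge/interior
loops up to 30 nt per side (`max_internal_loop`), and a required seed of
`min_seed` consecutive base pairs (default 7; set 2 to disable — whether
the original web service enforces a seed is not documented, so it is fully
configurable). The seed constraint is implemented by decomposition rather
than run-length DP state: every valid hybrid contains an exact helix of
`min_seed` stacked pairs, so

    MFE = min over seed anchors (i,j) of
          A(i,j) + helix(i,j; min_seed) + C(i+s−1, j+s−1)

where A is the best duplex prefix ending at pair (i,j) and C the best
continuation after the helix, both computed by unconstrained O(n·m·L²)
DPs. Tracebacks reconstruct the pairing list; suboptimal, non-overlapping
sites are enumerated greedily by anchor energy. Equivalence with exhaustive
enumeration of all legal antiparallel pairings is asserted for 500 seeded
random pairs.

## Accessibility

Unpaired probabilities come from McCaskill inside/outside recursions over
the same parameter set (no pseudoknots, minimum hairpin loop 3, interior
loops capped at 30 nt total). Interval probabilities are computed exactly
as constrained-ensemble ratios Z(i..j unpaired)/Z via a masked refold, and
cached per interval; per-position probabilities come from the base-pair
probability matrix (outside algorithm, computed lazily — the genome scan
itself only needs interval probabilities on the mRNA side, which keeps the
per-gene cost to two inside passes). mRNA windows are folded with 50 nt of
flanking genomic context on each side (a single local fold approximating
RNAplfold-style locality; the window plus context is ~200 nt, comparable
to a plfold span) and probabilities are projected back to window
coordinates.

All matrices are rescaled by a per-nucleotide factor σ chosen from the GC
content and adjusted automatically until Z is representable, so folds up
to the configured 2000-nt maximum stay finite; probabilities are ratios in
which σ cancels exactly. Constrained refolds reuse the unconstrained σ; a
constrained Z that underflows to zero reads as probability 0 and an
opening energy of +∞ (sentinel, with a configurable probability floor of
1e−30).

## Conservation

Alignment columns are summarized as Shannon entropy over the five states
{A, C, G, U, −}; a gap is a state because indels in homologs are evidence
of non-conservation. Frequencies take a pseudocount β = 0.5 per state
(β = 0 available for closed-form tests). Columns map to sRNA positions by
skipping reference gaps; the weight is `1 − H/log2 5`. Homolog discovery
and alignment construction are upstream of the package: it consumes an
aligned FASTA or Clustal file. Without an alignment the weight is 1
everywhere and the feature is effectively off (logged).

## P-values

Genome-wide scores x = −E_total are modeled as extreme values: each gene's
score is the best over many candidate sites, so the chance null is
Gumbel-shaped. With ≥ 20 finite scores, location and scale are fitted by
the method of moments (β̂ = s·√6/π, μ̂ = x̄ − γβ̂) and
p = 1 − exp(−exp(−(x−μ̂)/β̂)). Genes with no accepted hybrid keep p = 1.
With fewer finite scores, or a degenerate (zero-variance) fit, empirical
rank p-values r/(N+1) are used with N the number of genes *scanned*: a
gene with no accepted hit is still a competitor, censored at
E_total ≥ 0, so the strongest of 200 candidates earns p = 1/201, not
1/(n_finite+1). Calibration always runs on exactly the scanned gene set,
so a co-expression subset changes the null along with the candidates.
An optional empirical mode re-scores dinucleotide-shuffled windows
(Altschul–Erikson shuffle, N = 200 by default) for cross-validation of the
parametric fit. Raw p-values are reported, as a scanning web service
would; no multiple-testing correction is applied for filtering.

## Co-expression filter

The filter consumes a per-gene differential-expression table (gene,
condition pair, log2FC, p-value) from any DE caller. A gene is retained if
there is at least one condition pair (configurable `--min-pairs`) in which
both the sRNA and the gene are differentially expressed at α = 0.01;
`--de-direction same/opposite` optionally constrains the sign of the
gene's change relative to the sRNA's (default `either`, since sRNAs both
repress and activate).

## Synthetic fixtures: what they do and do not establish

The generator emulates exactly the statistical structure the method
assumes: i.i.d. replicon sequence at a given GC fraction (default 0.5)
carrying 150–300 nt genes on random strands with 120–250 nt intergenic
spacing; an sRNA (default 60 nt) with a designated 20-nt interacting
region near its 5′ end; planted sites that are exact or k-mismatch reverse
complements of that region at a start-codon-relative offset (default −20,
inside the −80..+20 search window); homolog alignments mutated at 0.03
substitutions/position inside the interacting region versus 0.15 outside
(plus 0.01 single-nt indels) so entropy is genuinely lower where the sRNA
binds; and DE tables in which true targets and a configurable number of
decoys are co-DE with the sRNA. Fixtures are byte-deterministic in the
seed.

Green tests on these fixtures establish internal correctness and
calibration — the DPs equal their enumeration oracles, planted signals are
recovered, null p-values behave like a null — not biological accuracy:
real genomes have operons, codon bias and shared regulatory motifs, real
sRNA sites tolerate mismatches and G·U-rich imperfect pairing, and real DE
data carry correlated noise, none of which the generator models.

## Numerical and procedural choices

- Coordinates are 1-based inclusive at every user-facing surface (GFF
  convention) and 0-based half-open internally; start-codon-relative
  coordinates skip 0 (−1 abuts +1).
- Ranking ties break by (p-value, E_total, gene_id), making reports
  byte-deterministic; reruns with the same config are byte-identical.
- Replicons are linear by default; `--circular` enables wraparound
  windows. Windows truncated at replicon ends are flagged.
- The duplex returns `none` rather than a positive-energy hybrid; reported
  hits always have E_hyb < 0 and E_total < 0.
- On typical hardware the scan costs ~30 ms per gene (one duplex DP plus
  two ~200-nt inside folds), ~6 s for a 200-gene fixture.

## Known limitations

- The score combination and P-value model are this package's
  interpretation: the original publication names the four features and a
  P-value ranking but not the combination formula or null model. The
  empirical p-value mode exists so users can check the parametric fit.
- Post-hoc accessibility correction (MFE hybrid first, opening energies
  after) can reject a gene whose best *accessible* site was not the MFE
  site; joint optimization in the style of IntaRNA is out of scope. A
  practical consequence is that on random-sequence nulls only a minority
  of genes receive finite scores — the calibration covers exactly the
  population it is fitted on.
- Dangling ends and terminal mismatches are not modeled; absolute energies
  are not directly comparable to ViennaRNA outputs.
- One replicon per scan; multi-replicon genomes are run per replicon.
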
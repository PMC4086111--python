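"""Interaction scoring, genome-wide P-value calibration and ranking.

Each candidate gene's best seeded hybrid is scored as a total free energy

    e_total = e_hyb + ED_sRNA(site) + ED_mRNA(site)

so that structural accessibility enters as the additive opening-energy cost
of exposing both interacting intervals (IntaRNA-style), while conservation
and sRNA accessibility additionally gate which sRNA positions may anchor a
seed.  P-values come from a Gumbel (extreme-value) fit to the genome-wide
score distribution: each gene's score is the best of many possible sites,
so the null of "as strong an interaction by chance" is an extreme-value
null.  An empirical mode (dinucleotide-shuffled windows) cross-validates
the parametric fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from .accessibility import fold_partition, windowed_accessibility
from .conservation import ConservationProfile
from .params import DEFAULT_MODEL, EnergyModel
from .sequence_io import (AnnotatedReplicon, NucleotideSequence, TargetWindow,
                          extract_window)
from .thermo import DuplexHit, duplex_mfe, seed_region

logger = logging.getLogger(__name__)

EULER_GAMMA = 0.5772156649015329
MIN_SCORES_FOR_FIT = 20


@dataclass(frozen=True)
class ScanConfig:
    """All tunables of a target scan (energies in kcal/mol)."""

    window_up: int = 80  # nt upstream of the start codon
    window_down: int = 20  # nt of coding sequence
    circular: bool = False
    context: int = 50  # flanking nt folded with each mRNA window
    min_seed: int = 7  # consecutive base pairs required to nucleate
    p_min: float = 0.25  # sRNA anchor: minimum unpaired probability
    w_min: float = 0.5  # sRNA anchor: minimum conservation weight
    threshold: float = 0.05  # report targets with p below this
    pvalue_mode: str = "gumbel"  # or "empirical"
    empirical_n: int = 200  # shuffles per gene in empirical mode
    max_fold_len: int = 2000
    seed: int = 0  # rng seed (empirical mode only; the scan is deterministic)


@dataclass(frozen=True)
class InteractionScore:
    e_hyb: float
    ed_srna: float
    ed_mrna: float
    e_total: float
    cons_mean: float


@dataclass(frozen=True)
class TargetPrediction:
    gene_id: str
    gene_name: str
    product: str
    hit: DuplexHit
    score: InteractionScore
    p_value: float
    rank: int = 0
    window: TargetWindow | None = field(default=None, compare=False)


def _anchor_positions(srna_access, srna_cons: ConservationProfile | None,
                      p_min: float, w_min: float) -> np.ndarray:
    """0-based sRNA positions that may anchor a seed."""
    ok = srna_access.p_unpaired_pos >= p_min
    if srna_cons is not None:
        ok &= srna_cons.weight >= w_min
    return np.flatnonzero(ok)


def _finish_score(hit: DuplexHit, srna_access, srna_cons, window_access) -> InteractionScore | None:
    i1, j1 = hit.srna_interval
    m1, m2 = hit.mrna_interval
    ed_s = srna_access.opening_energy(i1, j1)
    ed_m = window_access.opening_energy(m1, m2)
    e_total = hit.e_hyb + ed_s + ed_m
    if not (e_total < 0.0):  # also rejects inf opening energies
        return None
    cons = srna_cons.mean_weight(i1, j1) if srna_cons is not None else 1.0
    return InteractionScore(e_hyb=hit.e_hyb, ed_srna=ed_s, ed_mrna=ed_m,
                            e_total=e_total, cons_mean=cons)


def _seed_overlaps_anchor(hit: DuplexHit, anchors: np.ndarray) -> bool:
    lo, hi = seed_region(hit)  # 1-based sRNA interval
    return bool(np.any((anchors >= lo - 1) & (anchors <= hi - 1)))


def score_candidate(srna: NucleotideSequence, srna_access,
                    srna_cons: ConservationProfile | None,
                    window: NucleotideSequence, window_access,
                    model: EnergyModel = DEFAULT_MODEL,
                    config: ScanConfig = ScanConfig()) -> tuple[DuplexHit, InteractionScore] | None:
    """Score one sRNA-window candidate, or None if no acceptable interaction.

    The MFE hybrid is rejected unless its seed overlaps at least one
    anchor: an sRNA position that is accessible (p_unpaired >= p_min) and,
    when a homolog alignment was provided, conserved (weight >= w_min).
    """
    hit = duplex_mfe(srna, window, model=model, min_seed=config.min_seed)
    if hit is None:
        return None
    anchors = _anchor_positions(srna_access, srna_cons, config.p_min, config.w_min)
    if not _seed_overlaps_anchor(hit, anchors):
        return None
    score = _finish_score(hit, srna_access, srna_cons, window_access)
    if score is None:
        return None
    return hit, score


def gumbel_fit_moments(x: np.ndarray) -> tuple[float, float]:
    """Gumbel location/scale by method of moments from sample mean and SD."""
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance: degenerate Gumbel fit")
    beta = sd * math.sqrt(6.0) / math.pi
    mu = float(np.mean(x)) - EULER_GAMMA * beta
    return mu, beta


def calibrate_pvalues(e_totals: dict) -> dict:
    """Per-gene P-values from the genome-wide e_total distribution.

    x = -e_total is treated as an extreme-value score; with >= 20 finite
    scores a Gumbel is fitted by moments and p = P(X >= x) is its upper
    tail.  With fewer scores, or a degenerate fit, empirical rank p-values
    r/(n+1) are used (warned).  Genes without a scored hit get p = 1.
    """
    finite = {g: e for g, e in e_totals.items() if e is not None and math.isfinite(e)}
    pvals = {g: 1.0 for g in e_totals}
    if not finite:
        return pvals
    genes = sorted(finite)
    x = -np.array([finite[g] for g in genes])
    use_fit = len(genes) >= MIN_SCORES_FOR_FIT
    if use_fit:
        try:
            mu, beta = gumbel_fit_moments(x)
        except ValueError:
            use_fit = False
    if use_fit:
        # upper tail 1 - exp(-exp(-(x-mu)/beta)), kept in (0, 1]
        t = np.exp(-(x - mu) / beta)
        p = -np.expm1(-t)
        p = np.clip(p, 1e-300, 1.0)
    else:
        # empirical rank p over the whole candidate set: genes without an
        # accepted hit are competitors too (censored at e_total >= 0, i.e.
        # worse than any finite score), so n is the number of genes scanned
        logger.warning(
            "only %d finite scores: falling back to empirical rank p-values",
            len(genes))
        r = rankdata([finite[g] for g in genes], method="min")  # best e_total -> rank 1
        p = r / (len(e_totals) + 1.0)
    for g, pv in zip(genes, p):
        pvals[g] = float(pv)
    return pvals


def rank_targets(predictions: list[TargetPrediction],
                 threshold: float = 0.05) -> list[TargetPrediction]:
    """Sort by (p_value, e_total, gene_id), rank, and filter at threshold."""
    ordered = sorted(predictions,
                     key=lambda t: (t.p_value, t.score.e_total, t.gene_id))
    ranked = [replace(t, rank=i + 1) for i, t in enumerate(ordered)]
    return [t for t in ranked if t.p_value < threshold]


# ---------------------------------------------------------------------------
# genome-wide scan

def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle preserving dinucleotide composition."""
    if len(seq) <= 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    for _ in range(200):
        trial = {a: list(bs) for a, bs in edges.items()}
        for bs in trial.values():
            rng.shuffle(bs)
        # walk the Eulerian path greedily; success iff all edges consumed
        out = [seq[0]]
        cur = seq[0]
        idx = {a: 0 for a in trial}
        n_edges = len(seq) - 1
        for _step in range(n_edges):
            lst = trial.get(cur)
            if lst is None or idx[cur] >= len(lst):
                break
            nxt = lst[idx[cur]]
            idx[cur] += 1
            out.append(nxt)
            cur = nxt
        if len(out) == len(seq) and cur == last:
            return "".join(out)
    return seq  # highly constrained composition; give up and keep the original


@dataclass
class ScanResult:
    predictions: list  # ranked, significant TargetPrediction
    all_pvalues: dict  # gene_id -> p_value for every scanned gene
    e_totals: dict  # gene_id -> e_total or None
    n_scanned: int
    conservation_used: bool = False


def scan_replicon(srna: NucleotideSequence, replicon: AnnotatedReplicon,
                  config: ScanConfig = ScanConfig(),
                  srna_cons: ConservationProfile | None = None,
                  subset: set | None = None,
                  model: EnergyModel = DEFAULT_MODEL) -> ScanResult:
    """Scan every annotated gene (or a subset) for sRNA interactions.

    Returns ranked significant predictions plus the full per-gene P-value
    map.  P-value calibration always runs on exactly the scanned gene set,
    so a co-expression subset changes the null as well as the candidates.
    """
    if srna_cons is None:
        logger.info("no homolog alignment: conservation weights fixed at 1")
    srna_access = fold_partition(srna, model=model, max_len=config.max_fold_len)
    anchors = _anchor_positions(srna_access, srna_cons, config.p_min, config.w_min)

    windows = [extract_window(replicon, g, config.window_up, config.window_down,
                              circular=config.circular)
               for g in replicon.genes]
    if subset is not None:
        from .expression_filter import apply_gene_subset
        windows = apply_gene_subset(windows, subset)

    e_totals: dict = {}
    candidates: dict = {}
    for win in windows:
        hit = duplex_mfe(srna, win.window_seq, model=model, min_seed=config.min_seed)
        if hit is None or not _seed_overlaps_anchor(hit, anchors):
            e_totals[win.gene_id] = None
            continue
        window_access = windowed_accessibility(win, replicon, model=model,
                                               context=config.context)
        score = _finish_score(hit, srna_access, srna_cons, window_access)
        if score is None:
            e_totals[win.gene_id] = None
            continue
        e_totals[win.gene_id] = score.e_total
        candidates[win.gene_id] = (win, hit, score)

    if config.pvalue_mode == "empirical":
        pvals = _empirical_pvalues(srna, replicon, windows, e_totals, config,
                                   srna_access, srna_cons, model)
    else:
        pvals = calibrate_pvalues(e_totals)

    preds = []
    for gene_id, (win, hit, score) in candidates.items():
        gene = win.gene
        preds.append(TargetPrediction(
            gene_id=gene_id,
            gene_name=gene.name if gene else gene_id,
            product=gene.product if gene else "",
            hit=hit, score=score, p_value=pvals[gene_id], window=win,
        ))
    ranked = rank_targets(preds, threshold=config.threshold)
    return ScanResult(predictions=ranked, all_pvalues=pvals, e_totals=e_totals,
                      n_scanned=len(windows),
                      conservation_used=srna_cons is not None)


def _empirical_pvalues(srna, replicon, windows, e_totals, config,
                       srna_access, srna_cons, model) -> dict:
    """p by scoring dinucleotide-shuffled windows (N = config.empirical_n)."""
    rng = np.random.default_rng(config.seed)
    anchors = _anchor_positions(srna_access, srna_cons, config.p_min, config.w_min)
    pvals = {}
    win_by_gene = {w.gene_id: w for w in windows}
    for gene_id, e_obs in e_totals.items():
        if e_obs is None:
            pvals[gene_id] = 1.0
            continue
        win = win_by_gene[gene_id]
        worse = 0
        for _ in range(config.empirical_n):
            shuf = _dinucleotide_shuffle(win.window_seq.residues, rng)
            wseq = NucleotideSequence(shuf, name=win.gene_id + "|shuffle")
            hit = duplex_mfe(srna, wseq, model=model, min_seed=config.min_seed)
            if hit is None or not _seed_overlaps_anchor(hit, anchors):
                continue
            acc = fold_partition(wseq, model=model, max_len=config.max_fold_len)
            score = _finish_score(hit, srna_access, srna_cons, acc)
            if score is not None and score.e_total <= e_obs:
                worse += 1
        pvals[gene_id] = (1.0 + worse) / (config.empirical_n + 1.0)
    return pvals
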
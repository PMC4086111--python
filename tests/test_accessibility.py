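import math

import numpy as np
import pytest

from srnatarget.accessibility import (AccessibilityProfile, SequenceTooLongError,
                                      fold_partition, windowed_accessibility)
from srnatarget.params import DEFAULT_MODEL
from srnatarget.sequence_io import (AnnotatedReplicon, GeneRecord,
                                    NucleotideSequence as NS, extract_window)

from conftest import random_rna
from oracles import ensemble_properties, interval_unpaired_probability


class TestFoldPartition:
    def test_unpairable_sequence_is_fully_accessible(self):
        prof = fold_partition(NS("AAAAAAA"))
        assert prof.Z == pytest.approx(prof.sigma ** 7)
        assert np.all(prof.p_unpaired_pos == 1.0)

    def test_partition_function_matches_enumeration(self):
        z, _ = ensemble_properties("GGGAAAACCC")
        prof = fold_partition(NS("GGGAAAACCC"))
        assert prof.Z / prof.sigma ** 10 == pytest.approx(z, rel=1e-9)

    def test_unpaired_probabilities_match_enumeration(self):
        _, pu = ensemble_properties("GGGAAAACCC")
        prof = fold_partition(NS("GGGAAAACCC"))
        assert prof.p_unpaired_pos == pytest.approx(pu, rel=1e-9, abs=1e-12)
        # middle As can never pair (min hairpin loop 3 leaves no partner)
        assert prof.p_unpaired_pos[4] == pytest.approx(1.0)

    def test_random_battery_with_rescaling(self):
        # sigma deliberately != 1 so the per-nucleotide rescaling
        # bookkeeping is exercised at enumerable lengths
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(8, 19))
            s = random_rna(rng, n)
            prof = AccessibilityProfile(NS(s), sigma=0.8)
            z, pu = ensemble_properties(s)
            assert prof.Z / 0.8 ** n == pytest.approx(z, rel=1e-9)
            assert prof.p_unpaired_pos == pytest.approx(pu, rel=1e-9, abs=1e-12)

    def test_interval_probability_is_constrained_ratio(self):
        rng = np.random.default_rng(12)
        for _ in range(8):
            s = random_rna(rng, int(rng.integers(10, 17)))
            prof = fold_partition(NS(s))
            n = len(s)
            i = int(rng.integers(1, n))
            j = int(rng.integers(i, min(i + 4, n) + 1))
            assert prof.p_unpaired_interval(i, j) == pytest.approx(
                interval_unpaired_probability(s, i, j), rel=1e-9, abs=1e-12)

    def test_interval_invariants(self):
        rng = np.random.default_rng(13)
        s = random_rna(rng, 40)
        prof = fold_partition(NS(s))
        pos = prof.p_unpaired_pos
        assert np.all((pos >= 0) & (pos <= 1))
        for i in (1, 5, 17):
            # single-position interval equals the positional probability
            assert prof.p_unpaired_interval(i, i) == pytest.approx(pos[i - 1], rel=1e-9)
            # widening the interval can only lower the probability
            prev = prof.p_unpaired_interval(i, i)
            for j in range(i + 1, i + 6):
                cur = prof.p_unpaired_interval(i, j)
                assert cur <= prev + 1e-12
                assert cur <= pos[j - 1] + 1e-12
                prev = cur

    def test_length_limit_names_windowed_variant(self):
        with pytest.raises(SequenceTooLongError, match="window"):
            fold_partition(NS("A" * 50), max_len=49)

    def test_scaling_robust_at_max_length(self):
        # a GC-rich 2000-mer overflows double precision without rescaling
        rng = np.random.default_rng(14)
        s = "".join(rng.choice(list("GCGA"), size=2000))
        prof = fold_partition(NS(s))
        assert math.isfinite(prof.Z) and prof.Z > 0


class TestOpeningEnergy:
    def test_identities(self):
        prof = fold_partition(NS("AAAAAAA"))
        assert prof.opening_energy(1, 7) == 0.0  # p = 1 -> ED = 0
        # p = e^-1 -> ED = RT, by direct construction of the cache
        prof._interval_cache[(2, 3)] = math.exp(-1.0)
        assert prof.opening_energy(2, 3) == pytest.approx(DEFAULT_MODEL.RT)

    def test_monotone_in_interval_width(self):
        rng = np.random.default_rng(15)
        s = random_rna(rng, 50)
        prof = fold_partition(NS(s))
        eds = [prof.opening_energy(10, j) for j in range(10, 22)]
        assert all(b >= a - 1e-9 for a, b in zip(eds, eds[1:]))

    def test_underflow_returns_sentinel(self):
        prof = fold_partition(NS("A" * 10))
        prof._interval_cache[(1, 2)] = 0.0
        assert prof.opening_energy(1, 2) == math.inf

    def test_out_of_range_interval(self):
        prof = fold_partition(NS("ACGUACGU"))
        with pytest.raises(IndexError):
            prof.opening_energy(0, 3)
        with pytest.raises(IndexError):
            prof.p_unpaired_interval(3, 9)


class TestWindowedAccessibility:
    def _fixture(self, core: str, rng):
        # plant `core` so the window covers it exactly, with real flanks
        up = random_rna(rng, 120)
        down = random_rna(rng, 120)
        seq = up + core + down
        start = len(up) + len(core) + 1  # start codon right after the core
        rep = AnnotatedReplicon(NS(seq), [GeneRecord("g", "g", "+", start,
                                                     start + 59)])
        win = extract_window(rep, rep.genes[0], offset_up=len(core), offset_down=10)
        return rep, win

    def test_context_zero_equals_plain_fold(self):
        rng = np.random.default_rng(16)
        rep, win = self._fixture(random_rna(rng, 20), rng)
        prof0 = windowed_accessibility(win, rep, context=0)
        plain = fold_partition(win.window_seq)
        assert prof0.p_unpaired_pos == pytest.approx(plain.p_unpaired_pos, rel=1e-12)

    def test_planted_hairpin_is_less_accessible_than_open_stretch(self):
        rng = np.random.default_rng(17)
        # stem positions (GGGGGG...CCCCCC) vs an unstructured A stretch
        core = "GGGGGGAAAAACCCCCCAAAAAA"
        rep, win = self._fixture(core, rng)
        prof = windowed_accessibility(win, rep, context=50)
        stem = prof.p_unpaired_pos[0:6]
        open_a = prof.p_unpaired_pos[17:23]
        assert stem.mean() < open_a.mean()

    def test_projection_respects_minus_strand(self):
        rng = np.random.default_rng(18)
        seq = random_rna(rng, 400)
        rep = AnnotatedReplicon(NS(seq), [GeneRecord("g", "g", "-", 120, 300)])
        win = extract_window(rep, rep.genes[0], offset_up=30, offset_down=15)
        prof = windowed_accessibility(win, rep, context=40)
        assert prof.seq_len == len(win.window_seq)
        p = prof.p_unpaired_pos
        assert len(p) == prof.seq_len and np.all((p >= 0) & (p <= 1))
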
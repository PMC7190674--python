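"""Intron features, site windows, the max-entropy model and group tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spliceomix.intron_code import (compare_intron_groups,
                                    extract_site_windows, fit_chain_maxent,
                                    fit_maxent, intron_features,
                                    reverse_complement, score_site,
                                    score_sites, select_constitutive_introns)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=80)


def events_frame(dpsi):
    return pd.DataFrame({"delta_psi": dpsi},
                        index=[f"E{i}" for i in range(len(dpsi))])


class TestConstitutiveSelection:
    def test_takes_the_zeros_when_exactly_enough(self):
        ev = events_frame([-0.3, -0.1, 0.0, 0.0, 0.0, 0.2])
        chosen = select_constitutive_introns(ev, n=3)
        assert (chosen["delta_psi"] == 0).all() and len(chosen) == 3

    def test_central_selection_matches_index_arithmetic(self):
        # 100 negatives, 400 zeros, 100 positives: the sorted list has the
        # zeros at positions 100..499; the 300 nearest position 299.5 are
        # positions 150..449
        dpsi = [-0.5] * 100 + [0.0] * 400 + [0.5] * 100
        ev = events_frame(dpsi)
        chosen = select_constitutive_introns(ev, n=300)
        positions = sorted(int(i[1:]) for i in chosen.index)
        assert positions == list(range(150, 450))

    def test_short_supply_returns_all_with_warning(self):
        ev = events_frame([0.0] * 50 + [0.3] * 10)
        with pytest.warns(UserWarning, match="only 50"):
            chosen = select_constitutive_introns(ev, n=300)
        assert len(chosen) == 50


class TestSiteWindows:
    # pad | exon1 (ends CAG) | intron GTAAGT...TTTCAG | exon2 (starts G)
    EXON1 = "A" * 17 + "CAG"
    INTRON = "GTAAGT" + "C" * 22 + "TTTCAG"
    EXON2 = "G" + "T" * 19
    CHROM = "N" * 0 + "ACGTACGTAC" + EXON1 + INTRON + EXON2 + "ACGTACGTAC"
    START = 10 + len(EXON1)
    END = START + len(INTRON)

    def test_plus_strand_windows_by_string_slicing(self):
        donor, acceptor = extract_site_windows(self.CHROM, self.START,
                                               self.END, "+")
        assert donor == "CAGGTAAGT"
        assert acceptor == self.INTRON[-20:] + "G"
        assert len(donor) == 9 and len(acceptor) == 21

    def test_minus_strand_copy_gives_identical_windows(self):
        rc = reverse_complement(self.CHROM)
        L = len(self.CHROM)
        start, end = L - self.END, L - self.START
        donor, acceptor = extract_site_windows(rc, start, end, "-")
        assert (donor, acceptor) == extract_site_windows(
            self.CHROM, self.START, self.END, "+")

    def test_wider_acceptor_geometry_available(self):
        donor, acceptor = extract_site_windows(self.CHROM, self.START,
                                               self.END, "+",
                                               acceptor_exonic=3)
        assert len(acceptor) == 23
        assert acceptor.endswith(self.EXON2[:3])

    def test_window_at_sequence_edge_errors_with_intron_name(self):
        with pytest.raises(ValueError, match="intron i0"):
            extract_site_windows("GTAAGTCCCCTTTCAG" + "A" * 30, 0, 16, "+",
                                 intron_id="i0")


class TestIntronFeatures:
    @pytest.mark.parametrize("seq,length,gc", [
        ("GCGC", 4, 1.0),
        ("ATAT", 4, 0.0),
        ("GATC", 4, 0.5),
        ("GANC", 3 + 1, 2 / 3),  # N excluded from GC, counted in length
    ])
    def test_length_and_gc(self, seq, length, gc):
        l, g = intron_features(seq)
        assert l == length and g == pytest.approx(gc)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            intron_features("")

    @settings(max_examples=50, derandomize=True)
    @given(seq=DNA)
    def test_gc_invariant_under_reverse_complement(self, seq):
        _, gc = intron_features(seq)
        l_rc, gc_rc = intron_features(reverse_complement(seq))
        assert gc_rc == pytest.approx(gc)
        assert l_rc == len(seq)


def random_windows(n, w, seed, consensus=None, n_mut=2):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    if consensus is None:
        return ["".join(bases[rng.integers(0, 4, w)]) for _ in range(n)]
    out = []
    for _ in range(n):
        chars = list(consensus)
        for i in rng.choice(len(chars), n_mut, replace=False):
            chars[i] = bases[rng.integers(0, 4)]
        out.append("".join(chars))
    return out


class TestMaxEnt:
    def test_order0_distribution_is_product_of_positional_frequencies(self):
        wins = random_windows(80, 5, seed=0)
        model = fit_chain_maxent(wins, order=0)
        w = wins[0]
        expected = 1.0
        for i in range(5):
            expected *= np.mean([x[i] == w[i] for x in wins])
        assert 2.0 ** model.log2_prob(w) == pytest.approx(expected)

    @pytest.mark.parametrize("order", [0, 1])
    def test_fitted_marginals_match_empirical_constraints(self, order):
        wins = random_windows(200, 9, seed=1, consensus="CAGGTAAGT", n_mut=4)
        model = fit_chain_maxent(wins, order=order)
        x = np.array([[("ACGT".index(b)) for b in w] for w in wins])
        pos_emp = np.stack([np.bincount(x[:, i], minlength=4) / len(x)
                            for i in range(9)])
        assert np.abs(model.fitted_positional_marginals() - pos_emp).max() < 1e-6
        if order == 1:
            pairs = np.zeros((8, 4, 4))
            for k in range(8):
                np.add.at(pairs[k], (x[:, k], x[:, k + 1]), 1.0 / len(x))
            assert np.abs(model.pair_marginals() - pairs).max() < 1e-6

    def test_order1_distribution_sums_to_one(self):
        wins = random_windows(150, 5, seed=2)
        model = fit_chain_maxent(wins, order=1)
        total = sum(2.0 ** model.log2_prob("".join(k))
                    for k in itertools.product("ACGT", repeat=5))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_order0_score_is_sum_of_positional_log_odds(self):
        sig = random_windows(100, 7, seed=3, consensus="GTAAGTA", n_mut=3)
        bkg = random_windows(100, 7, seed=4)
        model = fit_maxent(sig, bkg, order=0, pseudocount=0.5)
        for w in sig[:10]:
            expected = 0.0
            for i in range(7):
                fs = (sum(x[i] == w[i] for x in sig) + 0.5) / (100 + 2.0)
                fb = (sum(x[i] == w[i] for x in bkg) + 0.5) / (100 + 2.0)
                expected += math.log2(fs / fb)
            assert score_site(model, w) == pytest.approx(expected)

    def test_identical_training_sets_score_zero_everywhere(self):
        wins = random_windows(100, 9, seed=5)
        model = fit_maxent(wins, wins, order=1)
        assert all(score_site(model, w) == 0.0 for w in wins)

    def test_consensus_vs_shuffled_background_gap_exceeds_two_bits(self):
        rng = np.random.default_rng(6)
        sig = random_windows(300, 9, seed=6, consensus="CAGGTAAGT", n_mut=2)
        bkg = ["".join(rng.permutation(list(w))) for w in sig]
        model = fit_maxent(sig, bkg, order=0, pseudocount=0.5)
        gap = np.mean([score_site(model, w) for w in sig]) \
            - np.mean([score_site(model, w) for w in bkg])
        assert gap > 2.0

    def test_too_few_signal_windows_rejected(self):
        with pytest.raises(ValueError, match="at least 50"):
            fit_maxent(random_windows(10, 9, 7), random_windows(60, 9, 8))

    def test_inconsistent_window_lengths_rejected(self):
        wins = random_windows(60, 9, 9) + ["ACGT"]
        with pytest.raises(ValueError):
            fit_chain_maxent(wins)

    def test_ambiguous_windows_flagged_not_scored(self):
        wins = random_windows(60, 9, 10)
        model = fit_maxent(wins, wins)
        out = score_sites(model, ["NNNNNNNNN", wins[0], "ACGT"])
        assert out["flag"].tolist() == ["ambiguous_base", "", "wrong_length"]
        assert np.isnan(out["score"].iloc[0])


class TestGroupComparison:
    def frame(self, values, col="GC"):
        return pd.DataFrame({col: values})

    def test_identical_small_groups_give_exact_p_of_one(self):
        a = self.frame([0.1, 0.2, 0.3, 0.4])
        out = compare_intron_groups(a, a.copy(), features=("GC",))
        assert out.loc["GC", "p_value"] == pytest.approx(1.0)

    def test_small_sample_p_matches_rank_enumeration(self):
        # exact two-sided rank-sum p by enumerating every assignment of the
        # pooled observations to the two groups
        a = [1.2, 3.4, 0.5, 7.7, 2.2]
        b = [5.1, 6.3, 8.8, 4.4]
        out = compare_intron_groups(self.frame(a), self.frame(b),
                                    features=("GC",))
        pooled = np.array(a + b)
        ranks = pooled.argsort().argsort() + 1
        n_a = len(a)
        obs_u = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
        us = np.array([ranks[list(combo)].sum() - n_a * (n_a + 1) / 2
                       for combo in itertools.combinations(range(len(pooled)),
                                                           n_a)])
        mean_u = n_a * len(b) / 2
        p_exact = np.mean(np.abs(us - mean_u) >= abs(obs_u - mean_u) - 1e-12)
        assert out.loc["GC", "p_value"] == pytest.approx(p_exact, abs=1e-12)

    def test_planted_gc_shift_is_detected(self):
        rng = np.random.default_rng(11)
        a = self.frame(rng.normal(0.45, 0.05, 300))
        b = self.frame(rng.normal(0.60, 0.05, 300))
        out = compare_intron_groups(a, b, features=("GC",))
        assert out.loc["GC", "p_value"] < 1e-6

    def test_same_distribution_rarely_significant(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(40):
            a = self.frame(rng.normal(0.5, 0.1, 100))
            b = self.frame(rng.normal(0.5, 0.1, 100))
            out = compare_intron_groups(a, b, features=("GC",))
            hits += out.loc["GC", "p_value"] < 0.01
        assert hits <= 2

    def test_tiny_group_refused(self):
        with pytest.raises(ValueError, match="group size"):
            compare_intron_groups(self.frame([1, 2]), self.frame([1, 2, 3]),
                                  features=("GC",))
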
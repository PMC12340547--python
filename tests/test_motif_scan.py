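import itertools
import math

import numpy as np
import pytest

from leaderless_scan._seq import encode, revcomp
from leaderless_scan.genome_io import UpstreamWindow
from leaderless_scan.motif_discovery import MotifModel
from leaderless_scan.motif_scan import (
    best_site_per_gene,
    exact_pvalues,
    make_scoring_matrix,
    min_passing_int_score,
    null_band_hit_probability,
    scan_gene_windows,
    scan_sequence,
    sites_to_table,
)


def random_model(rng, w=6, bg_conc=5.0):
    theta = rng.dirichlet(np.ones(4), size=w).T
    bg = rng.dirichlet(np.ones(4) * bg_conc)
    return MotifModel(w, theta, bg, 0.5)


def one_hot_model(word="TACACT", bg=None):
    w = len(word)
    theta = np.full((4, w), 1e-12)
    for j, b in enumerate(word):
        theta[:, j] = 0.0
        theta["ACGT".index(b), j] = 1.0
    if bg is None:
        bg = np.full(4, 0.25)
    return MotifModel(w, theta, np.asarray(bg), 0.5)


def brute_force_pvalues(matrix, background):
    """Independent oracle: enumerate all 4^w words on the same lattice."""
    w = matrix.w
    words = np.array(list(itertools.product(range(4), repeat=w)))
    scores = matrix.int_scores[words, np.arange(w)].sum(axis=1)
    probs = np.prod(np.asarray(background)[words], axis=1)
    return words, scores, probs


class TestScoringMatrix:
    def test_background_columns_score_zero(self):
        bg = np.array([0.2, 0.3, 0.3, 0.2])
        model = MotifModel(4, np.tile(bg[:, None], 4), bg, 0.5)
        mat = make_scoring_matrix(model)
        assert np.allclose(mat.log_odds, 0.0, atol=1e-2)

    def test_consensus_word_scores_maximum(self):
        mat = make_scoring_matrix(one_hot_model("TACACT"))
        best = mat.score_word("TACACT")
        rng = np.random.default_rng(0)
        for _ in range(50):
            word = "".join("ACGT"[b] for b in rng.integers(0, 4, 6))
            assert mat.score_word(word) <= best + 1e-12

    def test_all_words_match_per_word_evaluation(self):
        rng = np.random.default_rng(1)
        model = random_model(rng)
        mat = make_scoring_matrix(model)
        for codes in itertools.product(range(4), repeat=3):
            word = "".join("ACGT"[c] for c in codes) + "ACG"
            direct = mat.int_scores[encode(word), np.arange(6)].sum() * mat.granularity
            assert math.isclose(mat.score_word(word), direct, rel_tol=0, abs_tol=1e-12)


class TestExactPvalues:
    def test_minimum_score_has_pvalue_one(self):
        rng = np.random.default_rng(2)
        model = random_model(rng)
        mat = make_scoring_matrix(model)
        dist = exact_pvalues(mat)
        assert dist.pvalue_int(dist.min_int) == 1.0
        assert dist.pvalue_int(dist.min_int - 100) == 1.0

    def test_one_hot_consensus_closed_form(self):
        mat = make_scoring_matrix(one_hot_model("TACACT"))
        dist = exact_pvalues(mat)
        top = mat.int_scores.max(axis=0).sum()
        assert math.isclose(dist.pvalue_int(int(top)), 0.25**6, rel_tol=1e-9)

    @pytest.mark.parametrize("trial", range(3))
    def test_matches_brute_force_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        model = random_model(rng)
        mat = make_scoring_matrix(model)
        dist = exact_pvalues(mat)
        _, scores, probs = brute_force_pvalues(mat, model.background)
        for s in np.unique(scores):
            brute = math.fsum(probs[scores >= s])
            assert abs(brute - dist.pvalue_int(int(s))) <= 1e-12

    def test_lattice_overflow_guarded(self):
        model = one_hot_model("TACACT")
        mat = make_scoring_matrix(model, granularity=1e-9)
        with pytest.raises(ValueError, match="granularity"):
            exact_pvalues(mat)


class TestScanSequence:
    def setup_method(self):
        self.model = one_hot_model("TACACT", bg=[0.175, 0.325, 0.325, 0.175])
        self.mat = make_scoring_matrix(self.model)
        self.dist = exact_pvalues(self.mat)

    def test_short_sequence_empty(self):
        assert scan_sequence("ACG", self.mat, self.dist) == []

    def test_planted_site_reported_at_offset(self):
        rng = np.random.default_rng(4)
        seq = "".join("ACGT"[b] for b in rng.choice(4, 450, p=[.175,.325,.325,.175]))
        seq = seq[:294] + "TACACT" + seq[300:]
        hits = scan_sequence(seq, self.mat, self.dist, 0.015)
        assert any(h[0] == 294 and h[1] == "TACACT" for h in hits)

    def test_reverse_strand_site_invisible_by_default(self):
        seq = "G" * 20 + revcomp("TACACT") + "G" * 20
        assert scan_sequence(seq, self.mat, self.dist, 0.015) == []
        with_rc = scan_sequence(seq, self.mat, self.dist, 0.015, scan_revcomp=True)
        assert len(with_rc) == 1 and with_rc[0][0] == 20

    def test_n_containing_words_skipped(self):
        seq = "G" * 10 + "TACNCT" + "G" * 10
        assert scan_sequence(seq, self.mat, self.dist, 0.5) == [] or all(
            "N" not in h[1] for h in scan_sequence(seq, self.mat, self.dist, 0.5)
        )

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 300))
        prev = set()
        for thr in (0.001, 0.005, 0.015, 0.05, 0.2):
            hits = {h[0] for h in scan_sequence(seq, self.mat, self.dist, thr)}
            assert prev <= hits
            prev = hits

    def test_score_pvalue_consistency(self):
        rng = np.random.default_rng(6)
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 400))
        hits = scan_sequence(seq, self.mat, self.dist, 1.0)
        hits.sort(key=lambda h: h[2])
        for a, b in zip(hits, hits[1:]):
            assert a[3] >= b[3]  # higher score -> p no larger

    def test_uniform_null_passing_rate_binomial(self):
        """Expected passing count ~ (L-w+1)*alpha on background text."""
        rng = np.random.default_rng(7)
        bg = [0.175, 0.325, 0.325, 0.175]
        L, alpha, reps = 450, 0.015, 300
        total = 0
        for _ in range(reps):
            seq = "".join("ACGT"[b] for b in rng.choice(4, L, p=bg))
            total += len(scan_sequence(seq, self.mat, self.dist, alpha))
        n_trials = reps * (L - 5)
        # realized per-offset rate is the discrete tail mass <= alpha
        u = self.dist.sf[self.dist.sf <= alpha].max()
        sd = math.sqrt(n_trials * u * (1 - u))
        assert abs(total - n_trials * u) < 4 * sd


class TestGeneWindows:
    def setup_method(self):
        self.model = one_hot_model("TACACT", bg=[0.175, 0.325, 0.325, 0.175])
        self.mat = make_scoring_matrix(self.model)
        self.dist = exact_pvalues(self.mat)

    def test_offsets_become_start_codon_relative(self):
        win = UpstreamWindow("g1", "G" * 7 + "TACACT" + "G" * 7, offset_of_last_base=-1)
        sites = scan_gene_windows([win], self.mat, self.dist, 0.015)
        assert len(sites) == 1
        assert sites[0].offset == -13
        assert sites[0].spacer == 7

    def test_equal_p_tie_keeps_most_three_prime(self):
        win = UpstreamWindow(
            "g1", "TACACT" + "G" * 4 + "TACACT" + "G" * 4, offset_of_last_base=-1
        )
        best = best_site_per_gene(scan_gene_windows([win], self.mat, self.dist, 0.015))
        assert best["g1"].offset == -10

    def test_gene_without_sites_absent(self):
        win = UpstreamWindow("g1", "G" * 30, offset_of_last_base=-1)
        sites = scan_gene_windows([win], self.mat, self.dist, 0.015)
        assert sites == []
        assert best_site_per_gene(sites) == {}

    def test_table_uses_one_based_coordinates_without_zero(self):
        win = UpstreamWindow("g1", "G" * 7 + "TACACT" + "G" * 7, offset_of_last_base=-1)
        table = sites_to_table(scan_gene_windows([win], self.mat, self.dist, 0.015))
        assert table.iloc[0]["start"] == -13
        assert table.iloc[0]["stop"] == -8


class TestNullBandProbability:
    def test_matches_simulation_and_beats_independence_bound(self):
        rng = np.random.default_rng(11)
        model = one_hot_model("TACACT", bg=[0.175, 0.325, 0.325, 0.175])
        # soften so some non-consensus words pass too
        theta = (model.theta + 0.08) / (model.theta + 0.08).sum(axis=0)
        model = MotifModel(6, theta, model.background, 0.5)
        mat = make_scoring_matrix(model)
        dist = exact_pvalues(mat)
        alpha, B = 0.015, 21
        f0 = null_band_hit_probability(mat, dist, B, alpha)
        u = dist.sf[dist.sf <= alpha].max()
        indep = 1 - (1 - u) ** B
        assert f0 <= indep + 1e-12
        cut = min_passing_int_score(dist, alpha)
        hits = 0
        reps = 4000
        for _ in range(reps):
            text = rng.choice(4, size=B + 5, p=model.background)
            sc = np.array(
                [mat.int_scores[text[i : i + 6], np.arange(6)].sum() for i in range(B)]
            )
            hits += bool((sc >= cut).any())
        se = math.sqrt(f0 * (1 - f0) / reps)
        assert abs(hits / reps - f0) < 4 * se
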
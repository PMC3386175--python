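import numpy as np
import pytest

from dhsevo.ioformats import GeneModel, GenomicInterval
from dhsevo.selection import (
    AlignmentBlock,
    SelectionConfig,
    SubstitutionModel,
    alignment_loglik,
    bootstrap_p,
    branch_lrt,
    collect_background,
    compare_branches,
    fit_neutral,
    hky_rate_matrix,
    pruning_loglik,
    simulate_alignment,
    transition_matrices,
)
from dhsevo.selection import _pattern_compress

MODEL = SubstitutionModel(
    4.0,
    np.array([0.3, 0.2, 0.2, 0.3]),
    {"human": 0.01, "chimp": 0.012, "hc": 0.02, "macaque": 0.06, "orangutan": 0.04},
)


class TestHKY:
    def test_rate_matrix_properties(self):
        Q = hky_rate_matrix(4.0, MODEL.pi)
        assert np.allclose(Q.sum(axis=1), 0)
        assert np.allclose(MODEL.pi @ Q, 0, atol=1e-12)  # stationarity
        assert -np.dot(MODEL.pi, np.diag(Q)) == pytest.approx(1.0)  # unit rate

    def test_transition_matrices_are_stochastic(self):
        P = transition_matrices(4.0, MODEL.pi, MODEL.branch_lengths)
        for m in P.values():
            assert np.allclose(m.sum(axis=1), 1.0)
            assert (m >= 0).all()

    def test_detailed_balance(self):
        P = transition_matrices(4.0, MODEL.pi, {"b": 0.1})["b"]
        lhs = MODEL.pi[:, None] * P
        assert np.allclose(lhs, lhs.T)


class TestPruning:
    def test_matches_bruteforce_ancestral_sum(self):
        """Pruning equals explicit summation over both internal nodes."""
        rng = np.random.default_rng(3)
        aln = simulate_alignment(MODEL, 30, rng)
        pats, w = _pattern_compress(aln.complete_columns())
        fast = pruning_loglik(pats, w, MODEL.kappa, MODEL.pi, MODEL.branch_lengths)
        P = transition_matrices(MODEL.kappa, MODEL.pi, MODEL.branch_lengths)
        total = 0.0
        for col in aln.complete_columns().T:
            site = 0.0
            for root in range(4):
                for x in range(4):
                    site += (
                        MODEL.pi[root]
                        * P["hc"][root, x]
                        * P["human"][x, col[0]]
                        * P["chimp"][x, col[1]]
                        * P["macaque"][root, col[2]]
                        * P["orangutan"][root, col[3]]
                    )
            total += np.log(site)
        assert abs(fast - total) < 1e-8

    def test_missing_data_partial_likelihood(self):
        aln = AlignmentBlock(
            {"human": "ANCG", "chimp": "AACG", "macaque": "AACG", "orangutan": "AACG"}
        )
        lnl = alignment_loglik(aln, MODEL)
        assert np.isfinite(lnl)


class TestFitNeutral:
    def test_identical_sequences_zero_branches(self):
        seq = "ACGT" * 100
        aln = AlignmentBlock({t: seq for t in ("human", "chimp", "macaque", "orangutan")})
        fit = fit_neutral(aln)
        assert all(v == 0 for v in fit.branch_lengths.values())
        assert fit.flagged

    def test_too_short_background_rejected(self):
        seq = "ACGT" * 10
        aln = AlignmentBlock({t: seq for t in ("human", "chimp", "macaque", "orangutan")})
        with pytest.raises(ValueError):
            fit_neutral(aln)

    def test_jc_branch_length_recovery(self):
        """Under kappa=1/uniform frequencies, divergence follows the
        Jukes-Cantor mismatch curve; lengths recover at 10 kb."""
        jc = SubstitutionModel(
            1.0, np.full(4, 0.25),
            {"human": 0.05, "chimp": 0.05, "hc": 0.02, "macaque": 0.06, "orangutan": 0.04},
        )
        rng = np.random.default_rng(1)
        aln = simulate_alignment(jc, 10_000, rng)
        # sanity: observed human-chimp mismatch matches JC expectation at t=0.12
        mism = np.mean(
            [a != b for a, b in zip(aln.sequences["human"], aln.sequences["chimp"])]
        )
        t_tot = 0.05 + 0.05
        expected = 0.75 * (1 - np.exp(-4 * t_tot / 3))
        assert mism == pytest.approx(expected, abs=0.01)
        fit = fit_neutral(aln)
        assert 0.08 < fit.branch_lengths["human"] + fit.branch_lengths["chimp"] < 0.12

    def test_kappa_recovery(self):
        rng = np.random.default_rng(2)
        aln = simulate_alignment(MODEL, 10_000, rng)
        fit = fit_neutral(aln)
        assert 3.0 < fit.kappa < 5.0
        for k, v in MODEL.branch_lengths.items():
            assert fit.branch_lengths[k] == pytest.approx(v, abs=0.02)


class TestBranchLRT:
    def test_identical_region_boundary_p_half(self):
        seq = "ACGT" * 100
        region = AlignmentBlock({t: seq for t in ("human", "chimp", "macaque", "orangutan")})
        rng = np.random.default_rng(0)
        neutral = fit_neutral(simulate_alignment(MODEL, 4000, rng))
        lnl0, lnl1, lam, p, _ = branch_lrt(region, neutral, "human")
        assert lam == pytest.approx(0.0, abs=1e-6)
        assert p == 0.5

    def test_nesting_invariant(self):
        rng = np.random.default_rng(7)
        neutral = fit_neutral(simulate_alignment(MODEL, 4000, rng))
        for _ in range(10):
            region = simulate_alignment(MODEL, 200, rng)
            lnl0, lnl1, lam, p, _ = branch_lrt(region, neutral, "human")
            assert lnl1 >= lnl0 - 1e-6
            assert 0 < p <= 1

    def test_accelerated_branch_detected(self):
        rng = np.random.default_rng(8)
        neutral = fit_neutral(simulate_alignment(MODEL, 8000, rng))
        fast = SubstitutionModel(
            MODEL.kappa, MODEL.pi,
            {**MODEL.branch_lengths, "human": MODEL.branch_lengths["human"] * 8},
        )
        rejections = 0
        for _ in range(20):
            region = simulate_alignment(fast, 300, rng)
            *_, p, info = branch_lrt(region, neutral, "human")
            rejections += p < 0.05
        assert rejections >= 10

    def test_invalid_branch_rejected(self):
        with pytest.raises(ValueError):
            branch_lrt(
                AlignmentBlock({t: "ACGT" * 20 for t in
                                ("human", "chimp", "macaque", "orangutan")}),
                MODEL, "macaque",
            )


class TestBootstrap:
    def test_single_bootstrap_equals_plain_lrt(self):
        rng = np.random.default_rng(5)
        bg = simulate_alignment(MODEL, 1000, rng)
        region = simulate_alignment(MODEL, 200, np.random.default_rng(6))
        cfg = SelectionConfig(n_bootstrap=1, seed=0)
        res = bootstrap_p(region, bg, "human", cfg)
        neutral = fit_neutral(bg)
        *_, p, _ = branch_lrt(region, neutral, "human")
        assert res.p == pytest.approx(p, abs=1e-9)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(5)
        bg = simulate_alignment(MODEL, 600, rng)
        region = simulate_alignment(MODEL, 150, np.random.default_rng(6))
        cfg = SelectionConfig(n_bootstrap=5, seed=42)
        p1 = bootstrap_p(region, bg, "human", cfg).p
        p2 = bootstrap_p(region, bg, "human", cfg).p
        assert p1 == p2

    def test_invariant_background_p_equals_single_test(self):
        """A variation-free background pins every bootstrap's branch
        lengths at zero, so the averaged p equals the single-test p."""
        seq = "ACGT" * 150
        bg = AlignmentBlock({t: seq for t in ("human", "chimp", "macaque", "orangutan")})
        region_rng = np.random.default_rng(4)
        region = simulate_alignment(MODEL, 100, region_rng)
        cfg = SelectionConfig(n_bootstrap=4, seed=1)
        res = bootstrap_p(region, bg, "human", cfg)
        neutral = fit_neutral(bg)
        *_, p_single, _ = branch_lrt(region, neutral, "human")
        assert res.p == pytest.approx(p_single)


class TestCollectBackground:
    def fetch(self, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        genome = simulate_alignment(MODEL, 50_000, rng)

        def fetch_alignment(iv: GenomicInterval) -> AlignmentBlock:
            return AlignmentBlock(
                {t: genome.sequences[t][iv.start : iv.end] for t in genome.sequences}
            )

        return fetch_alignment

    def gene(self, gid, start, exon_len=200, intron_len=1000, n_exons=4):
        exons = tuple(
            (start + i * (exon_len + intron_len), start + i * (exon_len + intron_len) + exon_len)
            for i in range(n_exons)
        )
        span = GenomicInterval("hg", "chr1", exons[0][0], exons[-1][1], "+")
        return GeneModel(gid, span, exons)

    def test_eligible_intron_gives_exact_target(self):
        genes = [self.gene("g", 1000)]
        region = GenomicInterval("hg", "chr1", 6000, 6300)
        cfg = SelectionConfig(background_target=1500, max_window=50_000)
        bg = collect_background(region, genes, [], self.fetch(), cfg)
        assert bg is not None
        assert bg.complete_columns().shape[1] == 1500

    def test_only_first_introns_discarded(self):
        genes = [self.gene("g", 1000, n_exons=2)]  # single intron = first intron
        region = GenomicInterval("hg", "chr1", 4000, 4300)
        assert collect_background(region, genes, [], self.fetch()) is None

    def test_short_eligible_total_discarded(self):
        genes = [self.gene("g", 1000, intron_len=500, n_exons=3)]
        # non-first introns: one of 500 - 40 trim = 460 < 2000 target
        region = GenomicInterval("hg", "chr1", 3000, 3300)
        assert collect_background(region, genes, [], self.fetch()) is None

    def test_dhs_bases_excluded(self):
        genes = [self.gene("g", 1000)]
        region = GenomicInterval("hg", "chr1", 6000, 6300)
        cfg = SelectionConfig(background_target=900, max_window=50_000)
        bg_free = collect_background(region, genes, [], self.fetch(), cfg)
        # mask the intron nearest the region; collection must fall back
        # to the remaining eligible intron and change the background
        dhs = [GenomicInterval("hg", "chr1", 3600, 4600)]
        bg_masked = collect_background(region, genes, dhs, self.fetch(), cfg)
        assert bg_free is not None and bg_masked is not None
        assert bg_masked.sequences["human"] != bg_free.sequences["human"]


class TestCompareBranches:
    def test_identical_lists_p_one(self):
        assert compare_branches([0.2, 0.5, 0.7], [0.2, 0.5, 0.7]) == pytest.approx(1.0)

    def test_exact_small_sample(self):
        # complete separation with n=m=3: exact two-sided p = 2/20
        p = compare_branches([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert p == pytest.approx(0.1)

    def test_too_few_regions_error(self):
        with pytest.raises(ValueError):
            compare_branches([0.1, 0.2], [0.3, 0.4, 0.5])
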
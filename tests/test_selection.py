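"""GY94 model construction, likelihood machinery, and omega recovery."""

import dendropy
import numpy as np
import pytest

from mitocomp.codon_usage import CODON_TO_AA, SENSE_CODONS
from mitocomp.selection import (
    CodonAlignment,
    GY94Params,
    f3x4,
    gy94_q,
    one_ratio_omega,
    pairwise_omega,
    simulate_codon_alignment,
    transition_matrix,
)

IDX = {c: i for i, c in enumerate(SENSE_CODONS)}


def random_pi(rng):
    return rng.dirichlet(np.full(62, 2.0))


class TestF3x4:
    def test_uniform_base_usage(self):
        seqs = ["".join(SENSE_CODONS)] * 2  # near-uniform positional usage
        aln = CodonAlignment.from_sequences(["a", "b"], seqs)
        pi = f3x4(aln)
        assert pi.shape == (62,)
        assert pi.sum() == pytest.approx(1.0)

    def test_single_codon_alignment(self):
        aln = CodonAlignment.from_sequences(["a"], ["AAAAAAAAA"])
        pi = f3x4(aln)
        assert pi[IDX["AAA"]] == pytest.approx(1.0)

    def test_matches_analytic_product(self, rng):
        # planted positional frequencies -> closed-form product
        f = rng.dirichlet(np.full(4, 5.0), size=3)  # T C A G per position
        bases = "TCAG"
        n = 4000
        cols = ["".join(rng.choice(list(bases), p=f[p]) for p in range(3))
                for _ in range(n)]
        seq = "".join(c for c in cols if c not in ("TAA", "TAG"))
        aln = CodonAlignment.from_sequences(["a"], [seq])
        pi = f3x4(aln)
        # recompute expectation from the realized positional counts
        counts = np.zeros((3, 4))
        for k in range(0, len(seq), 3):
            for p in range(3):
                counts[p, bases.index(seq[k + p])] += 1
        freq = counts / counts.sum(axis=1, keepdims=True)
        expect = np.array([
            freq[0, bases.index(c[0])] * freq[1, bases.index(c[1])]
            * freq[2, bases.index(c[2])] for c in SENSE_CODONS])
        expect /= expect.sum()
        assert np.allclose(pi, expect, atol=1e-12)


class TestGeneratorMatrix:
    def test_zero_for_multi_nucleotide_changes(self, rng):
        q = gy94_q(2.0, 0.5, random_pi(rng))
        for a, b in [("AAA", "ACC"), ("AAA", "CCC"), ("TTT", "AAG")]:
            assert q[IDX[a], IDX[b]] == 0.0

    def test_transition_and_synonymy_factors(self, rng):
        pi = np.full(62, 1 / 62)
        kappa, omega = 3.0, 0.2
        q = gy94_q(kappa, omega, pi)
        # AAA->AAG: A->G transition; Lys->Lys synonymous under table 5
        assert CODON_TO_AA["AAA"] == CODON_TO_AA["AAG"]
        # AAA->AAC: transversion, Lys->Asn nonsynonymous
        r_syn_ts = q[IDX["AAA"], IDX["AAG"]]
        r_nonsyn_tv = q[IDX["AAA"], IDX["AAC"]]
        assert r_syn_ts / r_nonsyn_tv == pytest.approx(kappa / omega)

    def test_rows_sum_to_zero_and_detailed_balance(self, rng):
        pi = random_pi(rng)
        q = gy94_q(1.7, 0.4, pi)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        flux = pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-14)

    def test_expected_rate_scaled_to_one(self, rng):
        pi = random_pi(rng)
        q = gy94_q(2.0, 0.1, pi)
        assert -pi @ np.diag(q) == pytest.approx(1.0)


class TestTransitionProbabilities:
    def test_stochastic_rows_and_identity_at_zero(self, rng):
        pi = random_pi(rng)
        p0 = transition_matrix(2.0, 0.3, pi, 0.0)
        assert np.allclose(p0, np.eye(62), atol=1e-9)
        p = transition_matrix(2.0, 0.3, pi, 0.7)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)

    def test_chapman_kolmogorov(self, rng):
        pi = random_pi(rng)
        kappa, omega = float(rng.uniform(1, 5)), float(rng.uniform(0.05, 2))
        ps = transition_matrix(kappa, omega, pi, 0.3)
        pt = transition_matrix(kappa, omega, pi, 0.5)
        pst = transition_matrix(kappa, omega, pi, 0.8)
        assert np.allclose(ps @ pt, pst, atol=1e-10)


class TestSimulation:
    def test_zero_branch_lengths_identical_rows(self, rng):
        tree = dendropy.Tree.get(data="(a:0.0,b:0.0,c:0.0);", schema="newick")
        aln = simulate_codon_alignment(
            tree, GY94Params(2.0, 0.5, np.full(62, 1 / 62)), 50, seed=3)
        assert np.all(aln.codons == aln.codons[0])

    def test_long_branch_converges_to_pi(self, rng):
        pi = random_pi(rng)
        tree = dendropy.Tree.get(data="(a:40.0,b:40.0);", schema="newick")
        aln = simulate_codon_alignment(tree, GY94Params(2.0, 0.5, pi),
                                       100_000, seed=4)
        freqs = np.bincount(aln.codons[0], minlength=62) / aln.n_sites
        assert 0.5 * np.abs(freqs - pi).sum() < 0.01  # total variation

    def test_seed_reproducibility(self):
        tree = dendropy.Tree.get(data="(a:0.3,b:0.3);", schema="newick")
        params = GY94Params(2.0, 0.5, np.full(62, 1 / 62))
        a1 = simulate_codon_alignment(tree, params, 200, seed=9)
        a2 = simulate_codon_alignment(tree, params, 200, seed=9)
        assert np.array_equal(a1.codons, a2.codons)


class TestPairwise:
    def test_identical_sequences_flagged(self):
        fit = pairwise_omega("ATGAAACCC" * 20, "ATGAAACCC" * 20)
        assert fit.indeterminate_omega
        assert fit.params.t <= 1e-6

    def test_recovery_at_moderate_omega(self, rng):
        pi = random_pi(np.random.default_rng(0))
        tree = dendropy.Tree.get(data="(a:0.25,b:0.25);", schema="newick")
        aln = simulate_codon_alignment(tree, GY94Params(2.0, 0.1, pi),
                                       5000, seed=21)
        fit = pairwise_omega(aln.row("a"), aln.row("b"), seed=2)
        assert fit.params.omega == pytest.approx(0.1, abs=0.03)
        assert fit.params.t == pytest.approx(0.5, rel=0.2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_omega("ATGAAA", "ATG")


class TestOneRatio:
    def test_star_tree_identical_sequences(self):
        tree = dendropy.Tree.get(data="(a:0.1,b:0.1,c:0.1);", schema="newick")
        seq = "ATGAAACCCTTTGGG" * 8
        aln = CodonAlignment.from_sequences(["a", "b", "c"], [seq] * 3)
        fit = one_ratio_omega(aln, tree)
        assert all(t <= 1e-5 for t in fit.branch_lengths.values())

    def test_recovery_on_small_tree(self):
        from mitocomp.synthetic import make_chronogram

        tree = make_chronogram(6, 1.0, seed=3)
        for e in tree.preorder_edge_iter():
            if e.length:
                e.length *= 0.3
        pi = np.full(62, 1 / 62)
        aln = simulate_codon_alignment(tree, GY94Params(2.0, 0.05, pi),
                                       600, seed=7)
        fit = one_ratio_omega(aln, tree, seed=1)
        assert fit.params.omega == pytest.approx(0.05, rel=0.35)
        assert fit.lnL < 0 and np.isfinite(fit.lnL)

    def test_likelihood_at_truth_beats_perturbed(self):
        # consistency smoke test on a fixed simulation
        from mitocomp.selection import _pruning_lnl, _TreeIndex

        tree = dendropy.Tree.get(data="(a:0.2,b:0.2,c:0.2);", schema="newick")
        pi = np.full(62, 1 / 62)
        aln = simulate_codon_alignment(tree, GY94Params(2.0, 0.1, pi),
                                       3000, seed=13)
        ti = _TreeIndex(tree, aln.taxa)
        pats, w = np.unique(aln.codons, axis=1, return_counts=True)
        ts = np.full(len(ti.branch_nodes), 0.2)
        at_truth = _pruning_lnl(ts, 2.0, 0.1, pi, ti, pats, w.astype(float))
        perturbed = _pruning_lnl(ts, 2.0, 0.5, pi, ti, pats, w.astype(float))
        assert at_truth < perturbed  # negative log-likelihoods
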
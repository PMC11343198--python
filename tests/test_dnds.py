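"""Nei–Gojobori counting, Fitch ancestors, and the selection/drift statistics."""

import itertools

import numpy as np
import pytest
import scipy.stats as st

from codiverge.dnds import (
    BASES,
    CODONS,
    GeneDnDsSummary,
    GeneFamily,
    STOP_CODONS,
    bh_adjust,
    binomial_asymmetry,
    branch_dnds,
    clade_drift_tests,
    gene_summary,
    ng86_pairwise,
    ng86_sites,
    paired_drift_test,
    phyl_anova,
    quadrant_classify,
    translate,
)
from codiverge.phylo import parse_newick
from codiverge.simulate import SimConfig, simulate_codon_alignment


def neighbor_enumeration_sites(codon):
    """Independent oracle: enumerate the 9 single-base neighbors directly."""
    n = s = 0.0
    for pos, base in itertools.product(range(3), BASES):
        if base == codon[pos]:
            continue
        mut = codon[:pos] + base + codon[pos + 1 :]
        if mut in STOP_CODONS:
            continue
        if translate(mut) == translate(codon):
            s += 1 / 3
        else:
            n += 1 / 3
    return n, s


class TestSites:
    def test_phenylalanine(self):
        n, s = ng86_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_methionine_has_no_synonymous_sites(self):
        assert ng86_sites("ATG")[1] == 0.0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")

    def test_matches_neighbor_enumeration_for_all_codons(self):
        for codon in CODONS:
            if codon in STOP_CODONS:
                continue
            n, s = ng86_sites(codon)
            n_ref, s_ref = neighbor_enumeration_sites(codon)
            assert (n, s) == pytest.approx((n_ref, s_ref))
            # sites conservation: total is 3 minus the stop-neighbor share
            stop_neighbors = sum(
                codon[:p] + b + codon[p + 1 :] in STOP_CODONS
                for p, b in itertools.product(range(3), BASES)
                if b != codon[p]
            )
            assert n + s == pytest.approx(3 - stop_neighbors / 3)


class TestPairwise:
    def test_identical_sequences(self):
        seq = "ATGGCTAAA" * 10
        r = ng86_pairwise(seq, seq)
        assert (r.nd, r.sd, r.dn, r.ds) == (0.0, 0.0, 0.0, 0.0)
        assert np.isnan(r.dnds)

    def test_single_synonymous_difference(self):
        a = "GCT" * 100  # Ala
        b = "GCC" + "GCT" * 99  # third-position synonymous change
        r = ng86_pairwise(a, b)
        assert r.sd == pytest.approx(1.0)
        assert r.nd == pytest.approx(0.0)
        assert r.dn == 0.0
        assert r.ds > 0

    def test_gapped_codons_skipped(self):
        a = "ATG" + "GCT" * 5
        b = "AT-" + "GCT" * 5
        r = ng86_pairwise(a, b)
        assert r.n_sites + r.s_sites == pytest.approx(5 * 3, abs=1.0)

    def test_neutral_simulation_recovery(self):
        tree = parse_newick("(x:0.04,y:0.04);")
        cfg = SimConfig(gene_length_codons=10000, omega_lab=1.0, omega_wild=1.0,
                        kappa=1.0)
        fam, _ = simulate_codon_alignment(
            tree, {"x": "lab", "y": "wild"}, cfg, rng_seed=8, omega_other=1.0
        )
        r = ng86_pairwise(fam.alignment["x"], fam.alignment["y"])
        assert 0.9 <= r.dnds <= 1.1


class TestBranchDnds:
    def test_parsimony_assigns_mutation_to_one_branch(self):
        # c differs from a and b at one third-position (synonymous) site
        aln = {"a": "GCTGCT", "b": "GCTGCT", "c": "GCTGCC"}
        tree = parse_newick("((a:1,b:1):1,c:1);")
        out = {b.branch_id: b for b in branch_dnds(
            GeneFamily("g", aln, tree, {"a": "lab", "b": "wild", "c": "other"})
        )}
        assert out["c"].sd == pytest.approx(1.0)
        assert out["a"].sd == out["a"].nd == 0.0
        assert out["b"].sd == out["b"].nd == 0.0

    def test_tip_order_invariance(self):
        cfg = SimConfig(gene_length_codons=150)
        tree = parse_newick("((lab1:0.05,wild1:0.05):0.02,(lab2:0.05,wild2:0.05):0.02);")
        groups = {"lab1": "lab", "lab2": "lab", "wild1": "wild", "wild2": "wild"}
        fam, _ = simulate_codon_alignment(tree, groups, cfg, rng_seed=4)
        res1 = {b.branch_id: b for b in branch_dnds(fam)}
        shuffled = GeneFamily(
            "g2", dict(reversed(list(fam.alignment.items()))), fam.gene_tree,
            fam.tip_group,
        )
        res2 = {b.branch_id: b for b in branch_dnds(shuffled)}
        for k in res1:
            assert res1[k].nd == res2[k].nd
            assert res1[k].sd == res2[k].sd

    def test_two_tip_fallback(self):
        aln = {"L": "GCTGCT", "W": "GCAGCT"}
        tree = parse_newick("(L:1,W:1);")
        out = branch_dnds(GeneFamily("g", aln, tree, {"L": "lab", "W": "wild"}))
        assert len(out) == 2
        assert out[0].sd == out[1].sd == pytest.approx(1.0)

    def test_group_recovery_lab_exceeds_wild(self):
        cfg = SimConfig(gene_length_codons=800, omega_lab=0.8, omega_wild=0.2)
        tree = parse_newick(
            "((lab1:0.06,lab2:0.06):0.03,(wild1:0.06,wild2:0.06):0.03);"
        )
        groups = {"lab1": "lab", "lab2": "lab", "wild1": "wild", "wild2": "wild"}
        wins = 0
        for k in range(12):
            fam, _ = simulate_codon_alignment(tree, groups, cfg, rng_seed=100 + k)
            s = gene_summary(fam)
            if s.mean_lab_dnds > s.mean_wild_dnds:
                wins += 1
        assert wins >= 10


class TestGeneLevelStats:
    def test_quadrants(self):
        mk = lambda i, lab, wild: GeneDnDsSummary(f"g{i}", lab, wild, 2, 2)
        summaries = [
            mk(1, 1.5, 0.3), mk(2, 0.3, 1.5), mk(3, 1.2, 1.2), mk(4, 0.5, 0.5),
            mk(5, 2.0, 0.9), mk(6, 0.4, 0.6), mk(7, 1.0, 0.5), mk(8, float("nan"), 0.5),
        ]
        counts = quadrant_classify(summaries)
        assert counts == {"lab_pos_wild_pur": 2, "wild_pos_lab_pur": 1,
                          "both_pos": 1, "both_pur": 2}

    def test_binomial_center_and_oracle(self):
        assert binomial_asymmetry(63, 126) == pytest.approx(1.0)
        # direct pmf-sum oracle for (5, 10)
        pmf = np.array([st.binom.pmf(i, 10, 0.5) for i in range(11)])
        expect = pmf[pmf <= pmf[5] + 1e-12].sum()
        assert binomial_asymmetry(5, 10) == pytest.approx(expect)
        with pytest.raises(ValueError):
            binomial_asymmetry(1, 0)

    def test_paired_identical_means(self):
        summaries = [GeneDnDsSummary(f"g{i}", 0.4, 0.4, 2, 2) for i in range(5)]
        assert paired_drift_test(summaries) == (0.0, 1.0)

    def test_paired_constant_shift_closed_form(self, rng):
        # log-differences ~ N(0.1, 0.05^2), n=20: p from the t distribution
        diffs = rng.normal(0.1, 0.05, size=20)
        summaries = [
            GeneDnDsSummary(f"g{i}", float(0.5 * np.exp(d)), 0.5, 2, 2)
            for i, d in enumerate(diffs)
        ]
        t, p = paired_drift_test(summaries)
        t_expect = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(20))
        assert t == pytest.approx(t_expect, rel=1e-9)
        assert p == pytest.approx(2 * st.t.sf(abs(t_expect), 19), rel=1e-9)
        assert p < 1e-4

    def test_purifying_only_subset(self):
        summaries = [
            GeneDnDsSummary("g1", 0.5, 0.4, 2, 2),
            GeneDnDsSummary("g2", 0.6, 0.5, 2, 2),
            GeneDnDsSummary("g3", 1.5, 0.4, 2, 2),  # excluded: lab mean > 1
            GeneDnDsSummary("g4", 0.7, 0.55, 2, 2),
        ]
        t_all, _ = paired_drift_test(summaries, "all")
        t_pur, _ = paired_drift_test(summaries, "purifying_only")
        assert t_all != t_pur

    def test_bh_stepup(self):
        np.testing.assert_allclose(
            bh_adjust([0.001, 0.02, 0.04, 0.9]),
            [0.004, 0.04, 0.0533333333, 0.9],
            atol=1e-8,
        )

    def test_clade_drift_table(self):
        rng = np.random.default_rng(2)
        by_clade = {}
        for c in range(3):
            shifts = rng.normal(0.2, 0.1, size=10)
            by_clade[f"clade{c}"] = [
                GeneDnDsSummary(f"g{i}", float(0.4 * np.exp(d)), 0.4, 2, 2)
                for i, d in enumerate(shifts)
            ]
        df = clade_drift_tests(by_clade)
        assert set(df["clade_id"]) == {"clade0", "clade1", "clade2"}
        assert (df["p_adj"] >= df["p"] - 1e-15).all()


class TestPhylAnova:
    def test_constant_trait(self):
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        f, p = phyl_anova(tree, dict.fromkeys("abcd", 2.0),
                          {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}, n_sim=99)
        assert (f, p) == (0.0, 1.0)

    def test_degenerate_grouping_rejected(self):
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ValueError):
            phyl_anova(tree, {t: 1.0 for t in "abcd"},
                       {"a": "g1", "b": "g2", "c": "g2", "d": "g2"}, n_sim=9)

    def test_star_tree_matches_classical_anova(self, rng):
        # on a star tree Brownian motion is iid, so the simulation p should
        # track the classical F-test p
        n = 12
        labels = [f"t{i}" for i in range(n)]
        newick = "(" + ",".join(f"{l}:1" for l in labels) + ");"
        tree = parse_newick(newick)
        trait = {l: float(v) for l, v in zip(labels, rng.normal(size=n))}
        groups = {l: ("g1" if i < n // 2 else "g2") for i, l in enumerate(labels)}
        f, p = phyl_anova(tree, trait, groups, n_sim=2000, rng_seed=1)
        x = [trait[l] for l in labels[: n // 2]]
        y = [trait[l] for l in labels[n // 2 :]]
        f_classical, p_classical = st.f_oneway(x, y)
        assert f == pytest.approx(f_classical, rel=1e-9)
        assert p == pytest.approx(p_classical, abs=0.02)

    def test_phylogenetic_p_more_conservative_with_clustered_groups(self):
        # groups confounded with one long-branch subtree: a signal-free BM
        # trait produces larger phylogenetic than classical p most of the time
        tree = parse_newick(
            "(((a:0.1,b:0.1):5,(c:0.1,d:0.1):5):1,((e:0.1,f:0.1):5,(g:0.1,h:0.1):5):1);"
        )
        groups = {t: ("g1" if t in "abcd" else "g2") for t in "abcdefgh"}
        from codiverge.dnds import _vcv_matrix

        order = [l.taxon.label for l in tree.leaf_node_iter()]
        C = _vcv_matrix(tree, order)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(len(order)))
        rng = np.random.default_rng(3)
        wins = 0
        n_rep = 25
        for _ in range(n_rep):
            x = L @ rng.standard_normal(len(order))
            trait = dict(zip(order, map(float, x)))
            f, p_phy = phyl_anova(tree, trait, groups, n_sim=300, rng_seed=11)
            g1 = [trait[t] for t in order if groups[t] == "g1"]
            g2 = [trait[t] for t in order if groups[t] == "g2"]
            _, p_cls = st.f_oneway(g1, g2)
            wins += p_phy > p_cls
        assert wins >= 0.8 * n_rep


class TestOmegaZero:
    def test_no_amino_acid_changes_when_omega_zero(self):
        tree = parse_newick("((a:0.3,b:0.3):0.1,c:0.4);")
        cfg = SimConfig(gene_length_codons=200, omega_lab=1e-9, omega_wild=1e-9)
        fam, truth = simulate_codon_alignment(
            tree, {"a": "lab", "b": "wild", "c": "other"}, cfg, rng_seed=0,
            omega_other=1e-9,
        )
        assert all(v["nd"] == 0 for v in truth["branch_counts"].values())
        prots = {
            t: "".join(translate(s[i:i + 3]) for i in range(0, len(s), 3))
            for t, s in fam.alignment.items()
        }
        assert len(set(prots.values())) == 1
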
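import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from stromarch.io_core import ValidationError
from stromarch.metaprograms import (
    FactorSignature,
    consensus_cluster,
    fit_nmf_sample,
    jaccard_distance,
    refine_program,
    score_cells,
)
from stromarch.synthetic import generate_expression_cohort


def block_matrix(n_per_block=30, n_marker=20, noise=0.05, seed=0):
    """3 orthogonal planted blocks: block k's cells express block k's genes."""
    rng = np.random.default_rng(seed)
    genes = [f"g{j:03d}" for j in range(3 * n_marker)]
    X = rng.uniform(0, noise, (3 * n_per_block, 3 * n_marker))
    for k in range(3):
        X[k * n_per_block:(k + 1) * n_per_block, k * n_marker:(k + 1) * n_marker] += rng.uniform(
            2, 4, (n_per_block, n_marker)
        )
    return pd.DataFrame(X, columns=genes), [
        set(genes[k * n_marker:(k + 1) * n_marker]) for k in range(3)
    ]


class TestFitNMF:
    def test_planted_blocks_recovered(self):
        expr, blocks = block_matrix()
        sigs = fit_nmf_sample(expr, rank=3, top=20, seed=0)
        tops = [set(s.genes[:10]) for s in sigs]
        for blk in blocks:
            overlaps = [len(t & blk) for t in tops]
            assert max(overlaps) >= 9

    def test_negative_values_are_clipped(self):
        expr, _ = block_matrix(seed=1)
        noisy = expr.copy()
        noisy.iloc[0, 0] = -5.0
        clipped = noisy.clip(lower=0)
        s1 = fit_nmf_sample(noisy, rank=3, seed=0)
        s2 = fit_nmf_sample(clipped, rank=3, seed=0)
        assert [s.genes for s in s1] == [s.genes for s in s2]

    def test_deterministic(self):
        expr, _ = block_matrix(seed=2)
        s1 = fit_nmf_sample(expr, rank=3, seed=4)
        s2 = fit_nmf_sample(expr, rank=3, seed=4)
        assert [s.genes for s in s1] == [s.genes for s in s2]

    def test_all_zero_matrix_is_error(self):
        with pytest.raises(ValidationError):
            fit_nmf_sample(pd.DataFrame(np.zeros((20, 20))), rank=3)


class TestJaccard:
    def test_identity(self):
        assert jaccard_distance({"a", "b"}, {"a", "b"}) == 0.0

    def test_disjoint(self):
        assert jaccard_distance({"a"}, {"b"}) == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.sets(st.integers(0, 30), max_size=15),
        st.sets(st.integers(0, 30), max_size=15),
    )
    def test_metric_properties(self, a, b):
        d = jaccard_distance(a, b)
        assert 0.0 <= d <= 1.0
        assert d == jaccard_distance(b, a)
        assert (d == 0.0) == (a == b)


def jittered_signatures(n_programs=9, n_sigs=230, sig_size=100, n_replace=20, seed=0):
    rng = np.random.default_rng(seed)
    universe = [f"g{j:04d}" for j in range(5000)]
    programs = [
        list(rng.choice(universe, sig_size, replace=False)) for _ in range(n_programs)
    ]
    sigs, truth = [], []
    for i in range(n_sigs):
        k = int(rng.integers(n_programs))
        genes = list(programs[k])
        drop = rng.choice(sig_size, n_replace, replace=False)
        decoys = rng.choice(universe, n_replace, replace=False)
        for d_idx, g in zip(drop, decoys):
            genes[d_idx] = g
        # decoys may collide with kept genes; deduplicate preserving order
        seen, uniq = set(), []
        for g in genes:
            if g not in seen:
                seen.add(g)
                uniq.append(g)
        sigs.append(FactorSignature(sample_id=f"P{i % 23}", factor_id=i, genes=uniq))
        truth.append(k)
    return sigs, np.array(truth)


class TestConsensusCluster:
    def test_planted_partition_recovered(self):
        sigs, truth = jittered_signatures()
        programs = consensus_cluster(sigs, n_programs=9)
        labels = np.empty(len(sigs), dtype=int)
        for prog in programs:
            for m in prog.members:
                labels[m.factor_id] = prog.program_id
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_recurrence_requires_two_samples(self):
        a = FactorSignature("S1", 0, ["g1", "g2"])
        b = FactorSignature("S1", 1, ["g1", "g2"])
        c = FactorSignature("S2", 2, ["x1", "x2"])
        d = FactorSignature("S3", 3, ["x1", "x2"])
        programs = consensus_cluster([a, b, c, d], n_programs=2)
        by_genes = {tuple(p.consensus_genes): p for p in programs}
        assert not by_genes[("g1", "g2")].recurrent
        assert by_genes[("x1", "x2")].recurrent

    def test_consensus_set_majority_rule(self):
        a = FactorSignature("S1", 0, ["g1", "g2", "g3"])
        b = FactorSignature("S2", 1, ["g1", "g2", "g4"])
        programs = consensus_cluster([a, b], n_programs=1)
        assert programs[0].consensus_genes[:2] == ["g1", "g2"]
        assert set(programs[0].consensus_genes) == {"g1", "g2", "g3", "g4"}

    def test_too_many_programs_is_error(self):
        a = FactorSignature("S1", 0, ["g1"])
        b = FactorSignature("S2", 1, ["g2"])
        with pytest.raises(ValidationError):
            consensus_cluster([a, b], n_programs=3)


class TestScoreCells:
    def test_uniform_expression_scores_one(self):
        expr = pd.DataFrame(np.ones((4, 3)), columns=["a", "b", "c"])
        assert (score_cells(expr, ["a", "b", "c"]) == 1.0).all()

    def test_arithmetic_mean(self):
        expr = pd.DataFrame([[2.0, 4.0]], columns=["a", "b"])
        assert score_cells(expr, ["a", "b"]).iloc[0] == pytest.approx(3.0)

    def test_missing_gene_dropped_with_warning(self):
        expr = pd.DataFrame([[2.0, 4.0]], columns=["a", "b"])
        with pytest.warns(UserWarning, match="missing"):
            s = score_cells(expr, ["a", "zzz"])
        assert s.iloc[0] == pytest.approx(2.0)

    def test_zero_overlap_is_error(self):
        expr = pd.DataFrame([[1.0]], columns=["a"])
        with pytest.raises(ValidationError, match="zz"):
            score_cells(expr, ["zz"])


class TestRefineProgram:
    def make_program(self, expr, genes):
        sig = FactorSignature("S1", 0, list(genes))
        return consensus_cluster([sig, FactorSignature("S2", 1, list(genes))],
                                 n_programs=1)[0]

    def test_dominant_driver_ranks_first(self):
        # the driver carries nearly all score variance; the others are flat
        rng = np.random.default_rng(0)
        driver = rng.uniform(0, 10, 200)
        expr = pd.DataFrame(
            {
                "driver": driver,
                "weak": rng.normal(5, 0.5, 200),
                "noise": rng.normal(3, 0.5, 200),
            }
        ).clip(lower=0)
        mp = self.make_program(expr, ["driver", "weak", "noise"])
        mp = refine_program(mp, expr, top=2)
        assert mp.refined_genes[0] == "driver"

    def test_fewer_candidates_than_top_keeps_all(self):
        expr = pd.DataFrame(
            np.random.default_rng(1).uniform(0, 2, (30, 3)), columns=["a", "b", "c"]
        )
        mp = self.make_program(expr, ["a", "b"])
        mp = refine_program(mp, expr, top=30)
        assert set(mp.refined_genes) == {"a", "b"}

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.uniform(0, 3, (50, 5)), columns=list("abcde"))
        mp1 = refine_program(self.make_program(expr, list("abc")), expr, top=3)
        perm = expr.sample(frac=1.0, random_state=0)
        mp2 = refine_program(self.make_program(perm, list("abc")), perm, top=3)
        assert mp1.refined_genes == mp2.refined_genes

    def test_constant_score_is_error(self):
        expr = pd.DataFrame(np.ones((10, 2)), columns=["a", "b"])
        mp = self.make_program(expr, ["a"])
        with pytest.raises(ValidationError):
            refine_program(mp, expr)


class TestEndToEndRecovery:
    def test_shared_programs_recovered_across_samples(self):
        samples, planted = generate_expression_cohort(seed=42)
        sigs = []
        for i, expr in enumerate(samples):
            sigs.extend(fit_nmf_sample(expr, sample_id=f"S{i}", rank=10, seed=0))
        programs = consensus_cluster(sigs, n_programs=10)
        recovered = 0
        for planted_set in planted:
            best = max(
                1.0 - jaccard_distance(p.consensus_genes, planted_set)
                for p in programs
                if p.recurrent
            )
            recovered += best >= 0.6
        assert recovered >= 3
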
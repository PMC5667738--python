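"""SVM-CV fitness, repeatability thresholding, branch runs and merging."""

import numpy as np
import pytest

from swarmselect import (
    FitnessConfig,
    GeneList,
    SwarmConfig,
    SyntheticSpec,
    gbpso_branch,
    generate,
    merge_subsets,
    svm_cv_fitness,
)
from swarmselect.filters import RankedGeneList, filter_stage
from swarmselect.wrapper import select_repeatable, stage_seed

from conftest import two_class_matrix


def _separable_matrix(n=20, noise_genes=4, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.0, 1.0, (n, noise_genes + 1))
    x1 = rng.normal(0.0, 1.0, (n, noise_genes + 1))
    x0[:, 0] = rng.normal(0.0, 0.5, n)
    x1[:, 0] = rng.normal(20.0, 0.5, n)  # gene 0 separates perfectly
    return two_class_matrix(x0, x1)


class TestSvmCvFitness:
    def test_empty_mask_scores_zero(self):
        m = _separable_matrix()
        assert svm_cv_fitness(m, np.zeros(m.n_genes, bool), FitnessConfig(cv_folds=4)) == 0.0

    def test_perfectly_separating_gene_scores_one(self):
        m = _separable_matrix()
        mask = np.zeros(m.n_genes, bool)
        mask[0] = True
        assert svm_cv_fitness(m, mask, FitnessConfig(cv_folds=4)) == 1.0

    def test_noise_genes_score_near_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for seed in range(12):
            x = rng.normal(size=(40, 6))
            m = two_class_matrix(x[:20], x[20:])
            accs.append(svm_cv_fitness(m, np.ones(6, bool), FitnessConfig(cv_folds=4, seed=seed)))
        # mean CV accuracy of pure noise: within 3 SE of 0.5
        assert abs(np.mean(accs) - 0.5) < 3 * np.std(accs, ddof=1) / np.sqrt(len(accs)) + 0.05

    def test_wrong_mask_length_rejected(self):
        m = _separable_matrix()
        with pytest.raises(ValueError, match="mask length"):
            svm_cv_fitness(m, np.ones(3, bool), FitnessConfig())

    def test_too_many_folds_for_class_size_rejected(self):
        m = _separable_matrix(n=4)
        with pytest.raises(ValueError, match="stratified folds"):
            svm_cv_fitness(m, np.ones(m.n_genes, bool), FitnessConfig(cv_folds=10))


class TestSelectRepeatable:
    def test_seven_of_ten_rule(self):
        final = select_repeatable({"A": 10, "B": 7, "C": 6}, threshold=7)
        assert final.ids == ["A", "B"]

    def test_raising_threshold_never_enlarges(self):
        rng = np.random.default_rng(2)
        counts = {f"g{i}": int(rng.integers(0, 11)) for i in range(50)}
        sizes = [len(select_repeatable(counts, t)) for t in range(1, 11)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_ordering_by_count_then_id(self):
        final = select_repeatable({"b": 9, "a": 9, "c": 10}, threshold=7)
        assert final.ids == ["c", "a", "b"]


class TestMergeSubsets:
    def test_identical_subsets_merge_to_themselves(self):
        s = GeneList(["a", "b"])
        assert merge_subsets([s, s, s]).as_set() == {"a", "b"}

    def test_disjoint_union_arithmetic(self):
        subsets = [
            GeneList([f"x{i}" for i in range(48)]),
            GeneList([f"y{i}" for i in range(46)]),
            GeneList([f"z{i}" for i in range(37)]),
        ]
        assert len(merge_subsets(subsets)) == 131

    def test_merged_is_exact_union(self):
        a, b = GeneList(["a", "b", "c"]), GeneList(["b", "c", "d"])
        assert merge_subsets([a, b]).as_set() == {"a", "b", "c", "d"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_subsets([])


@pytest.fixture(scope="module")
def branch_setup():
    m, planted = generate(SyntheticSpec(n_class0=15, n_class1=15, n_genes=60,
                                        n_discriminative=3, effect_size=4.0,
                                        outlier_rate=0.0, seed=31))
    panel = filter_stage(m, "tt", R=12, K=5, seed=0)
    fitness = FitnessConfig(cv_folds=3, seed=5)
    swarm = SwarmConfig(swarm_size=6, max_iterations=6, patience=3, seed=5)
    return m, planted, panel, fitness, swarm


class TestGbpsoBranch:
    def test_subsets_stay_within_panel_and_counts_bounded(self, branch_setup):
        m, _, panel, fitness, swarm = branch_setup
        br = gbpso_branch(m, panel, fitness, swarm, K=4, threshold=3)
        panel_set = panel.as_set()
        for sub in br.per_run_subsets:
            assert sub.as_set() <= panel_set
        assert br.final.as_set() <= panel_set
        assert all(0 <= c <= 4 for c in br.frequencies.values())
        assert br.final.as_set() == {g for g, c in br.frequencies.items() if c >= 3}

    def test_branch_fitness_at_least_full_panel_fitness(self, branch_setup):
        """The injected full-panel particle guarantees the returned best
        subset never scores below the whole panel."""
        m, _, panel, fitness, swarm = branch_setup
        br = gbpso_branch(m, panel, fitness, swarm, K=2, threshold=2)
        from swarmselect.wrapper import _cv_folds, _masked_cv_accuracy

        sub = m.subset_genes(panel.ids)
        y = np.asarray(sub.labels)
        for k, best_fit in enumerate(br.per_run_fitness):
            folds = _cv_folds(y, fitness.cv_folds, stage_seed(fitness.seed, f"cv{k}"))
            full = _masked_cv_accuracy(sub.values, y, np.ones(len(panel), bool), folds, fitness)
            assert best_fit >= full

    def test_deterministic_given_seeds(self, branch_setup):
        m, _, panel, fitness, swarm = branch_setup
        b1 = gbpso_branch(m, panel, fitness, swarm, K=2, threshold=2)
        b2 = gbpso_branch(m, panel, fitness, swarm, K=2, threshold=2)
        assert b1.final.ids == b2.final.ids
        assert b1.per_run_fitness == b2.per_run_fitness

    def test_threshold_above_runs_warns(self, branch_setup):
        m, _, panel, fitness, swarm = branch_setup
        with pytest.warns(UserWarning, match="exceeds"):
            gbpso_branch(m, panel, fitness, swarm, K=2, threshold=3)
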
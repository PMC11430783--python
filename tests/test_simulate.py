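"""Synthetic-data generator: label sampling, motif planting, fixtures."""

import numpy as np
import pytest

from rnaloc import reference
from rnaloc.dataset import CompartmentUniverse, summarize
from rnaloc.prior import fit_cooccurrence
from rnaloc.simulate import (
    JointLabelTable,
    MotifSpec,
    SyntheticConfig,
    benchmark_fixture,
    chain_joint,
    default_motifs,
    generate_sequences,
    sample_label_sets,
    simulate_dataset,
)

U2 = CompartmentUniverse(("A", "B"))


class TestJointLabelTable:
    def test_normalization_enforced(self):
        with pytest.raises(ValueError, match="not normalized"):
            JointLabelTable.from_dict({("A",): 0.5, ("B",): 0.4}, U2)

    def test_all_zero_configuration_forbidden(self):
        with pytest.raises(ValueError, match="all-zero"):
            JointLabelTable(U2, np.array([[0, 0], [1, 0]]), np.array([0.5, 0.5]))

    def test_analytic_marginals_and_conditionals(self):
        joint = JointLabelTable.from_dict({("A",): 0.5, ("A", "B"): 0.5}, U2)
        np.testing.assert_allclose(joint.marginals(), [1.0, 0.5])
        np.testing.assert_allclose(joint.conditional()[0], [1.0, 0.5])
        np.testing.assert_allclose(joint.conditional()[1], [1.0, 1.0])

    def test_chain_joint_is_valid_and_cooccurring(self):
        joint = chain_joint()
        assert joint.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (joint.configs.sum(axis=1) >= 1).all()
        cond = joint.conditional()
        marg = joint.marginals()
        # chain dependence: P(X_{i+1} | X_i) > P(X_{i+1}) for every link
        assert all(cond[i, i + 1] > marg[i + 1] for i in range(8))


class TestSampleLabelSets:
    def test_degenerate_joint(self):
        joint = JointLabelTable.from_dict({("A",): 1.0}, U2)
        cfg = SyntheticConfig(joint=joint, motifs=default_motifs(U2), n=5,
                              length_range=(50, 60), seed=0)
        rows = sample_label_sets(cfg)
        np.testing.assert_array_equal(rows, np.tile([1, 0], (5, 1)))

    def test_conditional_recovered_within_mc_error(self):
        joint = JointLabelTable.from_dict({("A",): 0.5, ("A", "B"): 0.5}, U2)
        cfg = SyntheticConfig(joint=joint, motifs=default_motifs(U2), n=10_000,
                              length_range=(50, 60), seed=7)
        rows = sample_label_sets(cfg)
        p_b_given_a = rows[rows[:, 0] == 1, 1].mean()
        se = np.sqrt(0.25 / 10_000)
        assert abs(p_b_given_a - 0.5) < 3 * se

    def test_marginals_recovered_within_mc_error(self):
        joint = chain_joint()
        cfg = SyntheticConfig(joint=joint, motifs=default_motifs(), n=10_000,
                              length_range=(50, 60), seed=3)
        rows = sample_label_sets(cfg)
        truth = joint.marginals()
        emp = rows.mean(axis=0)
        se = np.sqrt(truth * (1 - truth) / 10_000)
        assert (np.abs(emp - truth) < 3 * se + 1e-12).all()


class TestGenerateSequences:
    def test_motif_present_with_poisson_rate(self):
        motifs = {"A": MotifSpec("A", "ACGTAC", copies=2.0),
                  "B": MotifSpec("B", "GGGGGG", copies=2.0)}
        joint = JointLabelTable.from_dict({("A",): 1.0}, U2)
        cfg = SyntheticConfig(joint=joint, motifs=motifs, n=1000,
                              length_range=(100, 150), seed=5)
        ds = simulate_dataset(cfg)
        hits = np.mean(["ACGTAC" in r.sequence for r in ds.records])
        # >=1 insertion with prob 1 - e^-2 (~0.865); background hits only add
        expect = 1 - np.exp(-2.0)
        assert hits > expect - 3 * np.sqrt(expect * (1 - expect) / 1000)

    def test_background_gc_fraction(self):
        joint = JointLabelTable.from_dict({("A",): 1.0}, U2)
        motifs = {"A": MotifSpec("A", "ACGTA", copies=0.0001)}
        cfg = SyntheticConfig(joint=joint, motifs=motifs, n=400,
                              length_range=(250, 250), background_gc=0.5, seed=9)
        ds = simulate_dataset(cfg)
        seq = "".join(ds.sequences)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_same_seed_identical_output(self, tmp_path):
        from rnaloc.dataset import write_dataset

        cfg = SyntheticConfig(joint=chain_joint(), motifs=default_motifs(), n=30,
                              length_range=(60, 100), seed=21)
        for name in ("a", "b"):
            write_dataset(simulate_dataset(cfg), tmp_path / f"{name}.fasta",
                          tmp_path / f"{name}.tsv")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_length_range_too_small_rejected(self):
        with pytest.raises(ValueError, match="minimum length"):
            SyntheticConfig(joint=chain_joint(), motifs=default_motifs(), n=5,
                            length_range=(7, 10))

    def test_missing_motif_for_active_label_rejected(self):
        joint = JointLabelTable.from_dict({("A", "B"): 1.0}, U2)
        cfg = SyntheticConfig(joint=joint, motifs={"A": MotifSpec("A", "ACGTA")},
                              n=2, length_range=(50, 60))
        with pytest.raises(ValueError, match="no motif"):
            generate_sequences(sample_label_sets(cfg), cfg)


def test_motif_detector_recall_above_080():
    """Exact substring search recovers planted labels: the task is learnable."""
    cfg_joint = chain_joint()
    motifs = default_motifs(copies=2.0)
    cfg = SyntheticConfig(joint=cfg_joint, motifs=motifs, n=500,
                          length_range=(200, 400), seed=13)
    ds = simulate_dataset(cfg)
    for j, label in enumerate(ds.universe.labels):
        carriers = ds.label_matrix[:, j] == 1
        if carriers.sum() == 0:
            continue
        motif = motifs[label].motif
        found = np.array([motif in r.sequence for r in ds.records])
        recall = found[carriers].mean()
        assert recall > 0.8, f"{label}: recall {recall:.2f}"


def test_estimator_recovers_generator_joint():
    """fit_cooccurrence on 10k samples matches the analytic tables to 3 SE."""
    joint = chain_joint()
    cfg = SyntheticConfig(joint=joint, motifs=default_motifs(), n=10_000,
                          length_range=(50, 60), seed=17)
    rows = sample_label_sets(cfg)
    fit = fit_cooccurrence(rows)
    n = len(rows)
    m_true = joint.marginals()
    se_m = np.sqrt(m_true * (1 - m_true) / n)
    assert (np.abs(fit.marginal - m_true) < 3 * se_m + 1e-12).all()
    c_true = joint.conditional()
    n_cond = np.maximum(rows.sum(axis=0), 1)[:, None]
    se_c = np.sqrt(np.clip(c_true * (1 - c_true), 1e-12, None) / n_cond)
    assert (np.abs(fit.conditional - c_true) < 3 * se_c + 1e-9).all()


@pytest.fixture(scope="module")
def fixture_summary():
    return summarize(benchmark_fixture())


class TestBenchmarkFixture:
    def test_total_and_histogram(self, fixture_summary):
        s = fixture_summary
        assert s.total == reference.TOTAL_SEQUENCES == 36_971
        assert tuple(s.cardinality_histogram) == reference.CARDINALITY_HISTOGRAM
        assert s.cardinality_histogram[0] == 12_884
        assert s.cardinality_histogram[8] == 122

    def test_per_label_totals(self, fixture_summary):
        assert tuple(int(x) for x in fixture_summary.per_label_counts) == reference.PER_LABEL_TOTALS
        assert fixture_summary.per_label_counts[0] == 31_448  # exosome
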
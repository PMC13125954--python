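import numpy as np
import pytest

from hybridotype.ancestry import (
    estimate_q_supervised,
    estimate_q_unsupervised,
    run_pca,
)
from hybridotype.panel import ascertain_panel
from hybridotype.simhyb import SimConfig, simulate_cohort
from hybridotype.vcf_io import GroupLabels, filter_chain

from .util import diagnostic_table


def build(x_gts, n_loci=100, n_parentals=1):
    samples = (
        [f"l{i}" for i in range(n_parentals)]
        + [f"r{i}" for i in range(n_parentals)]
        + ["x"]
    )
    rows = [
        [(0, 0)] * n_parentals + [(1, 1)] * n_parentals + [gt]
        for gt in x_gts * (n_loci // len(x_gts))
    ]
    table = diagnostic_table(samples, rows)
    labels = GroupLabels(
        {s: ("L" if s.startswith("l") else "R" if s.startswith("r") else "E")
         for s in samples}
    )
    panel = ascertain_panel(table, labels)
    return table, labels, panel


def test_supervised_closed_form_at_fixed_loci():
    # all heterozygous -> q exactly 0.5
    table, labels, panel = build([(0, 1)])
    assert estimate_q_supervised(table, labels, "x", panel=panel).q_l == 0.5
    # all homozygous for the L allele -> q exactly 1
    table, labels, panel = build([(0, 0)])
    assert estimate_q_supervised(table, labels, "x", panel=panel).q_l == 1.0
    # 100 loci carrying 75 L alleles of 200 -> q = 0.375
    table, labels, panel = build([(0, 0)] * 25 + [(0, 1)] * 25 + [(1, 1)] * 50,
                                 n_loci=100)
    est = estimate_q_supervised(table, labels, "x", panel=panel)
    assert est.q_l == 0.375
    assert est.n_loci == 100


def test_supervised_numeric_mode_agrees_with_closed_form():
    table, labels, panel = build([(0, 1)] * 3 + [(0, 0)], n_loci=100,
                                 n_parentals=5)
    exact = estimate_q_supervised(table, labels, "x", panel=panel).q_l
    numeric = estimate_q_supervised(table, labels, "x").q_l
    # pseudocount frequencies pull the numeric optimum slightly inward
    assert numeric == pytest.approx(exact, abs=0.02)


def test_supervised_no_informative_loci_error():
    table, labels, panel = build([None])
    with pytest.raises(ValueError, match="no informative"):
        estimate_q_supervised(table, labels, "x", panel=panel)


@pytest.fixture(scope="module")
def trio_cohort():
    cfg = SimConfig(seed=21, n_markers=500, prop_diagnostic=0.3,
                    n_l=5, n_r=5, n_e2=5, n_e3_llr=0, n_e3_lrr=0)
    table, labels, truth = simulate_cohort(cfg)
    return filter_chain(table), labels, truth


def test_unsupervised_recovers_parentals_and_f1(trio_cohort):
    filt, labels, truth = trio_cohort
    estimates = {e.sample_id: e for e in
                 estimate_q_unsupervised(filt, seed=3, n_replicates=5,
                                         labels=labels)}
    truth_q = dict(zip(truth.samples["sample_id"], truth.samples["true_q_l"]))
    for s, e in estimates.items():
        assert e.q_l == pytest.approx(truth_q[s], abs=0.02), s


def test_unsupervised_agrees_with_supervised(trio_cohort):
    filt, labels, _ = trio_cohort
    unsup = {e.sample_id: e.q_l for e in
             estimate_q_unsupervised(filt, seed=3, n_replicates=5,
                                     labels=labels)}
    for s in filt.sample_ids:
        sup = estimate_q_supervised(filt, labels, s).q_l
        assert unsup[s] == pytest.approx(sup, abs=0.03), s


def test_unsupervised_preconditions(trio_cohort):
    filt, _, _ = trio_cohort
    with pytest.raises(ValueError, match="K=2"):
        estimate_q_unsupervised(filt, k=3)
    two = type(filt)(sample_ids=filt.sample_ids[:2],
                     records=[])
    with pytest.raises(ValueError, match=">= 3 samples"):
        estimate_q_unsupervised(two)


def test_triploid_llr_bias_grows_as_depth_falls():
    """Diploid-called triploids lean toward the double-dose parent, worse
    at low coverage."""
    excess = {}
    for depth in (40, 20, 10):
        cfg = SimConfig(seed=11, n_markers=300, prop_diagnostic=1.0,
                        n_l=4, n_r=4, n_e2=0, n_e3_llr=20, n_e3_lrr=0,
                        mean_depth=float(depth))
        table, labels, truth = simulate_cohort(cfg)
        panel = truth.diagnostic_panel()
        qs = [estimate_q_supervised(table, labels, s, panel=panel).q_l
              for s in table.sample_ids if s.startswith("E3_LLR")]
        excess[depth] = float(np.mean(qs)) - 0.5
    assert excess[10] > 0
    assert excess[10] > excess[20] > excess[40]


def test_pca_separates_the_three_taxa(trio_cohort):
    filt, labels, _ = trio_cohort
    res = run_pca(filt)
    pc1 = res.coordinates[:, 0]
    groups = np.array([labels[s] for s in res.sample_ids])
    # silhouette on PC1: hybrids sit between the two parental clusters
    from sklearn.metrics import silhouette_score

    sil = silhouette_score(pc1.reshape(-1, 1), groups)
    assert sil > 0.8
    mid = pc1[groups == "E"].mean()
    lo, hi = sorted([pc1[groups == "L"].mean(), pc1[groups == "R"].mean()])
    assert lo < mid < hi
    assert np.all(np.diff(res.variance_fractions) <= 1e-12)


def test_pca_identical_samples_and_single_locus():
    table = diagnostic_table(["a", "b", "c"],
                             [[(0, 1), (0, 1), (0, 0)]])
    res = run_pca(table)
    assert res.variance_fractions[0] == pytest.approx(1.0)
    np.testing.assert_allclose(res.coordinates[0], res.coordinates[1],
                               atol=1e-12)


def test_pca_constant_matrix_is_an_error():
    table = diagnostic_table(["a", "b"], [[(0, 0), (0, 0)]] * 5)
    with pytest.raises(ValueError, match="monomorphic"):
        run_pca(table)
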
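import filecmp

import numpy as np
import pytest

from hybridotype.covwin import best_window_min
from hybridotype.simhyb import (
    GROUP_DOSAGE,
    SimConfig,
    _call_diploid,
    simulate_cohort,
    simulate_depth_tracks,
    write_fixture,
)
from hybridotype.vcf_io import read_labels, read_vcf


def test_config_validation():
    with pytest.raises(ValueError, match="prop_diagnostic"):
        SimConfig(prop_diagnostic=1.5)
    with pytest.raises(ValueError, match="epsilon"):
        SimConfig(epsilon=0.7)
    with pytest.raises(ValueError, match="depth_model"):
        SimConfig(depth_model="uniform")
    with pytest.raises(ValueError, match="n_markers"):
        SimConfig(n_markers=-1)


def test_cohort_composition_mirrors_config():
    cfg = SimConfig(seed=1, n_markers=20)
    table, labels, truth = simulate_cohort(cfg)
    counts = truth.samples["group"].value_counts().to_dict()
    assert counts == {"E2": 13, "R": 12, "L": 11, "E3_LLR": 8, "E3_LRR": 1}
    assert len(table.sample_ids) == 45
    assert labels.samples_in_group("E") == [
        s for s in table.sample_ids if s.startswith("E")
    ]
    # dosage bookkeeping matches the group definitions
    for row in truth.samples.itertuples():
        c_l, c_r = GROUP_DOSAGE[row.group]
        assert row.ploidy == c_l + c_r
        assert row.true_q_l == pytest.approx(c_l / (c_l + c_r))


def test_same_seed_gives_identical_tables():
    cfg = SimConfig(seed=99, n_markers=30)
    t1, _, _ = simulate_cohort(cfg)
    t2, _, _ = simulate_cohort(cfg)
    for r1, r2 in zip(t1.records, t2.records):
        assert r1.genotypes == r2.genotypes
        np.testing.assert_array_equal(r1.allele_depths, r2.allele_depths)


def test_mean_allele_ratios_converge_to_dosage_fractions():
    cfg = SimConfig(seed=55, n_markers=400, prop_diagnostic=1.0,
                    n_l=1, n_r=1, n_e2=3, n_e3_llr=3, n_e3_lrr=3,
                    epsilon=0.0, mean_depth=60.0)
    table, _, truth = simulate_cohort(cfg)
    panel_loci = {(r.marker_id, int(r.pos)): (r.l_allele, r.r_allele)
                  for r in truth.loci.itertuples()}
    for group, frac in (("E2", 0.5), ("E3_LLR", 2 / 3), ("E3_LRR", 1 / 3)):
        idx = [table.sample_index(s) for s in table.sample_ids
               if s.startswith(group + "_")]
        ratios = []
        for rec in table.records:
            la, _ = panel_loci[(rec.marker_id, rec.pos)]
            li = rec.alleles.index(la)
            for i in idx:
                ad = rec.allele_depths[i]
                if ad.sum() > 0:
                    ratios.append(ad[li] / ad.sum())
        se = np.sqrt(frac * (1 - frac) / 60 / len(ratios))
        assert np.mean(ratios) == pytest.approx(frac, abs=5 * se)


def test_diploid_caller_recovers_f1_genotypes_at_high_depth():
    cfg = SimConfig(seed=66, n_markers=300, prop_diagnostic=1.0,
                    n_l=1, n_r=1, n_e2=2, n_e3_llr=0, n_e3_lrr=0,
                    epsilon=0.0, mean_depth=200.0)
    table, _, _ = simulate_cohort(cfg)
    for rec in table.records:
        for s in ("E2_01", "E2_02"):
            assert rec.genotypes[table.sample_index(s)] == (0, 1)


def test_triploid_het_miscall_rate_decreases_with_depth():
    rates = {}
    for depth in (10, 20, 40):
        cfg = SimConfig(seed=44, n_markers=500, prop_diagnostic=1.0,
                        n_l=1, n_r=1, n_e2=0, n_e3_llr=4, n_e3_lrr=0,
                        mean_depth=float(depth))
        table, _, _ = simulate_cohort(cfg)
        idx = [table.sample_index(s) for s in table.sample_ids
               if s.startswith("E3_LLR")]
        calls = [rec.genotypes[i] for rec in table.records for i in idx
                 if rec.genotypes[i] is not None]
        rates[depth] = np.mean([gt[0] == gt[1] for gt in calls])
    assert rates[10] > rates[20] > rates[40]
    assert rates[10] > 0.02  # the artifact is material at low coverage


def test_extreme_allele_depth_forces_homozygous_miscall():
    # 12 reads all supporting one allele: the het hypothesis is rejected
    gt, gq = _call_diploid(n_a=12, depth=12, a_idx=0, epsilon=0.005)
    assert gt == (0, 0)
    assert gq > 0


def test_true_ploidy_genotypes_roundtrip(tmp_path):
    cfg = SimConfig(seed=5, n_markers=20, n_l=1, n_r=1, n_e2=1,
                    n_e3_llr=2, n_e3_lrr=1, emit_true_ploidy_gt=True)
    table, _, truth = simulate_cohort(cfg)
    tri = [table.sample_index(s) for s in table.sample_ids
           if s.startswith("E3")]
    assert all(
        len(rec.genotypes[i]) == 3
        for rec in table.records for i in tri if rec.genotypes[i] is not None
    )
    from hybridotype.vcf_io import write_vcf

    path = tmp_path / "tri.vcf"
    write_vcf(table, path)
    back = read_vcf(path)
    assert [r.genotypes for r in back.records] == [r.genotypes for r in table.records]


def test_depth_tracks_deterministic_and_constant_mode():
    cfg = SimConfig(seed=8, n_markers=10, n_l=1, n_r=0, n_e2=0,
                    n_e3_llr=0, n_e3_lrr=0)
    t1, truth1 = simulate_depth_tracks(cfg)
    t2, _ = simulate_depth_tracks(cfg)
    for a, b in zip(t1["L_01"], t2["L_01"]):
        np.testing.assert_array_equal(a.depths, b.depths)
    # noiseless constant-rate tracks hit their rate exactly
    cfg_const = SimConfig(seed=8, n_markers=5, n_l=1, n_r=0, n_e2=0,
                          n_e3_llr=0, n_e3_lrr=0, track_noise=False,
                          prop_poor_markers=0.0, mean_depth=30.0)
    tracks, truth = simulate_depth_tracks(cfg_const)
    for t, eff in zip(tracks["L_01"], truth["efficiency"]):
        assert best_window_min(t) == int(round(30.0 * eff))


def test_write_fixture_is_complete_and_byte_stable(tmp_path):
    cfg = SimConfig(seed=17, n_markers=25, n_l=2, n_r=2, n_e2=1,
                    n_e3_llr=1, n_e3_lrr=0)
    d1 = tmp_path / "f1"
    d2 = tmp_path / "f2"
    write_fixture(cfg, d1)
    write_fixture(cfg, d2)
    table = read_vcf(d1 / "cohort.vcf")
    labels = read_labels(d1 / "labels.tsv")
    assert table.n_samples == 6
    labels.validate_against(table)
    truth_lines = (d1 / "truth_samples.tsv").read_text().splitlines()
    assert len(truth_lines) == 7  # header + 6 samples
    for name in ("cohort.vcf", "labels.tsv", "truth_loci.tsv",
                 "truth_samples.tsv", "README.txt"):
        assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name
    for p in sorted((d1 / "depth").glob("*.tsv")):
        assert filecmp.cmp(p, d2 / "depth" / p.name, shallow=False), p.name
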
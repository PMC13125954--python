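import numpy as np
import pytest

from hybridotype.simhyb import SimConfig, simulate_cohort
from hybridotype.vcf_io import (
    GroupLabels,
    VcfFormatError,
    filter_chain,
    read_labels,
    read_vcf,
    thin_one_per_marker,
    write_labels,
    write_vcf,
)

from .util import make_record, make_table


def tables_equal(t1, t2) -> bool:
    if t1.sample_ids != t2.sample_ids or len(t1) != len(t2):
        return False
    for r1, r2 in zip(t1.records, t2.records):
        if (
            r1.marker_id != r2.marker_id
            or r1.pos != r2.pos
            or r1.ref != r2.ref
            or r1.alts != r2.alts
            or r1.genotypes != r2.genotypes
            or not np.array_equal(r1.allele_depths, r2.allele_depths)
            or not np.array_equal(r1.depths, r2.depths)
            or not np.array_equal(r1.gqs, r2.gqs)
        ):
            return False
    return True


def test_roundtrip_preserves_all_consumed_fields(tmp_path, sim_cohort):
    table, _, _ = sim_cohort
    path = tmp_path / "cohort.vcf"
    write_vcf(table, path)
    assert tables_equal(read_vcf(path), table)


def test_roundtrip_triploid_and_missing_genotypes(tmp_path):
    # a triploid GT written as 0/0/1 must come back with 3 allele indices,
    # and a missing genotype must stay explicitly missing
    rec = make_record(
        "m1", 10, "A", ("G",),
        genotypes=[(0, 0, 1), None, (0, 1)],
        ads=[(10, 5), (-1, -1), (12, 13)],
        dps=[15, -1, 25],
        gqs=[50, -1, 99],
    )
    table = make_table(["s1", "s2", "s3"], [rec])
    path = tmp_path / "tri.vcf"
    write_vcf(table, path)
    back = read_vcf(path)
    assert back.records[0].genotypes == [(0, 0, 1), None, (0, 1)]
    assert tables_equal(back, table)


def test_empty_table_roundtrip(tmp_path):
    table = make_table(["s1"], [])
    path = tmp_path / "empty.vcf"
    write_vcf(table, path)
    back = read_vcf(path)
    assert back.sample_ids == ["s1"] and len(back) == 0


def test_missing_ad_field_is_an_error(tmp_path):
    path = tmp_path / "noad.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        "m1\t10\t.\tA\tG\t.\t.\t.\tGT\t0/1\n"
    )
    with pytest.raises(VcfFormatError, match="AD"):
        read_vcf(path)


@pytest.fixture()
def toy_six_record_table():
    """Six records, each violating exactly one filter rule except the last."""
    samples = list("abcdefghij")
    het = [(0, 1)] * 10
    records = [
        make_record("m1", 5, "AT", ("A",), het),  # indel
        # MAF = 1/20 = 0.05 < 0.1: one het among 10 diploids
        make_record("m2", 5, "A", ("G",), [(0, 1)] + [(0, 0)] * 9),
        make_record("m3", 5, "A", ("G",), [None] + het[1:]),  # missing GT
        make_record("m4", 5, "A", ("G",), het,
                    ads=[(4, 4)] + [(20, 20)] * 9,
                    dps=[8] + [40] * 9),  # one sample DP=8
        make_record("m5", 5, "A", ("G",), het,
                    gqs=[15] + [99] * 9),  # one sample GQ=15
        make_record("m6", 5, "A", ("G",), het),  # clean
    ]
    return make_table(samples, records)


def test_filter_chain_applies_every_rule(toy_six_record_table):
    log = []
    out = filter_chain(toy_six_record_table, log=log)
    assert [r.marker_id for r in out.records] == ["m6"]
    assert dict(((m, r) for m, _, r in log)) == {
        "m1": "indel",
        "m2": "maf<0.1",
        "m3": "missing_genotype",
        "m4": "depth<10",
        "m5": "gq<20",
    }


def test_filter_chain_idempotent_and_identity_on_clean(toy_six_record_table):
    once = filter_chain(toy_six_record_table)
    twice = filter_chain(once)
    assert tables_equal(once, twice)
    assert tables_equal(filter_chain(once), once)


def test_filter_chain_maf_zero_disables_maf_rule(toy_six_record_table):
    out = filter_chain(toy_six_record_table, maf_min=0.0)
    assert [r.marker_id for r in out.records] == ["m2", "m6"]


def test_filter_chain_rejects_multiallelic():
    rec = make_record("m1", 5, "A", ("G", "T"), [(0, 1), (1, 2)],
                      ads=[(10, 10, 0), (0, 15, 15)])
    out = filter_chain(make_table(["a", "b"], [rec]))
    assert len(out) == 0


def test_thin_keeps_first_snp_per_marker():
    samples = ["a", "b"]
    het = [(0, 1)] * 2
    records = [
        make_record("mA", 50, "A", ("G",), het),
        make_record("mA", 10, "C", ("T",), het),
        make_record("mA", 200, "G", ("A",), het),
        make_record("mB", 30, "T", ("C",), het),
    ]
    out = thin_one_per_marker(make_table(samples, records))
    assert [(r.marker_id, r.pos) for r in out.records] == [("mA", 10), ("mB", 30)]


def test_thin_output_count_equals_distinct_markers(sim_cohort):
    table, _, _ = sim_cohort
    cfg = SimConfig(seed=3, n_markers=50, snps_per_marker=(1, 5))
    multi, _, _ = simulate_cohort(cfg)
    thinned = thin_one_per_marker(multi)
    assert len(thinned) == len(set(r.marker_id for r in multi.records))
    # already-thin table is unchanged
    assert tables_equal(thin_one_per_marker(table), table)


def test_group_labels_roundtrip_and_validation(tmp_path):
    labels = GroupLabels({"s1": "L", "s2": "R", "s3": "E"})
    path = tmp_path / "labels.tsv"
    write_labels(labels, path)
    assert read_labels(path).labels == labels.labels
    with pytest.raises(ValueError, match="invalid group"):
        GroupLabels({"s1": "X"})
    with pytest.raises(ValueError, match="without a group"):
        labels.validate_against(make_table(["s1", "s9"], []))
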
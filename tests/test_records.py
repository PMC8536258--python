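"""Clone-record categorization, day-2 reclassification and aggregation."""

import random

import pytest

from ovoclone import (
    AggregatedFrequencies,
    BasalStalk,
    CategoryStats,
    CloneCategory,
    CloneCategoryTable,
    EmptyInputError,
    FCLocation,
    MalformedRecordError,
    OvarioleRecord,
    ScoringAge,
    UsageError,
    aggregate_frequencies,
    ingest_records,
    read_aggregated_csv,
    read_records_csv,
    reclassify_day2_adult,
    write_records_csv,
)

I, G, E1, E2, E3, E4 = FCLocation


def rec(oid="o", fsc=0, r1=None, r2a=None, ec=None, fcs=(), **kw):
    return OvarioleRecord(
        ovariole_id=oid, n_fsc=fsc, n_r1_ec=r1, n_r2a_ec=r2a, n_ec=ec,
        fc_locations=frozenset(fcs), **kw,
    )


class TestCategorization:
    @pytest.mark.parametrize(
        "record, expected",
        [
            # an EC-only clone: marked r1 and r2a escort cells, nothing else
            (rec(r1=2, r2a=1), CloneCategory.EC_ONLY),
            # a lineage spanning an r2a EC, FSCs and FCs is FSC-containing with ECs
            (rec(r1=0, r2a=1, fsc=2, fcs=[I]), CloneCategory.EC_FSC),
            (rec(fsc=3), CloneCategory.FSC_ONLY),
            (rec(fsc=1, fcs=[E4]), CloneCategory.FSC_ONLY),
            (rec(fcs=[E3, E4]), CloneCategory.FC_ONLY),
            # discontinuous ECs + FCs with no FSC: the two-lineage signature
            (rec(ec=2, fcs=[E4]), CloneCategory.EC_PLUS_FC),
            (rec(), None),
            # basal-stalk marking alone never defines a clone category
            (rec(basal_stalk=BasalStalk.MARKED), None),
        ],
    )
    def test_category_assignment(self, record, expected):
        assert record.category is expected

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = random.Random(17)
        records = [
            rec(
                oid=f"r{i}",
                fsc=rng.randrange(3),
                ec=rng.randrange(4),
                fcs=rng.sample(list(FCLocation), rng.randrange(3)),
            )
            for i in range(300)
        ]
        table = ingest_records(records)
        marked = [r for r in records if r.category is not None]
        assert table.marked == len(marked)
        assert table.n_unlabeled == len(records) - len(marked)
        assert sum(table.count(c) for c in CloneCategory) == len(marked)

    def test_split_must_be_consistent(self):
        with pytest.raises(MalformedRecordError):
            rec(r1=2, r2a=1, ec=5)
        with pytest.raises(MalformedRecordError):
            OvarioleRecord(ovariole_id="x", n_r1_ec=1)  # split for one region only
        with pytest.raises(MalformedRecordError):
            rec(fsc=-1)

    def test_ingest_reproduces_published_raw_row(self, marcm_0hr):
        """98 marked of 207 with category counts 46/24/3/9/16 and the
        resulting totals, rebuilt from individual synthetic records."""
        records = []
        k = 0
        def add(n, **kw):
            nonlocal k
            for _ in range(n):
                records.append(rec(oid=f"r{k}", **kw)); k += 1
        add(46, ec=2)
        add(24, ec=4, fsc=4)
        add(3, fsc=5)
        add(9, fcs=[E4])
        add(16, ec=3, fcs=[E3])
        add(109)
        table = ingest_records(records)
        assert table.n_scored == 207 and table.marked == 98
        for cat, n in zip(CloneCategory, (46, 24, 3, 9, 16)):
            assert table.count(cat) == n
        f = aggregate_frequencies(table)
        ref = aggregate_frequencies(marcm_0hr.table)
        assert f.f_ec_obs == ref.f_ec_obs
        assert f.f_fc_obs == ref.f_fc_obs
        assert table.total_ec_marked == 46 * 2 + 24 * 4 + 16 * 3
        assert table.total_fsc_marked == 24 * 4 + 3 * 5


class TestReclassification:
    def test_recent_fcs_rescue_a_lost_fsc_lineage(self):
        r = rec(ec=1, fcs=[E1], scoring_age=ScoringAge.ADULT_DAY2)
        out = reclassify_day2_adult(r)
        assert out.category is CloneCategory.EC_FSC
        assert out.n_fsc == 0  # FSC count scored as zero, lineage retained

    def test_old_fcs_do_not_fire_the_rule(self):
        r = rec(fcs=[E4], scoring_age=ScoringAge.ADULT_DAY2)
        assert reclassify_day2_adult(r).category is CloneCategory.FC_ONLY

    def test_identity_when_fscs_present(self):
        r = rec(fsc=3, ec=2, scoring_age=ScoringAge.ADULT_DAY2)
        out = reclassify_day2_adult(r)
        assert out == r and out.n_fsc == 3

    def test_idempotent(self):
        r = rec(fcs=[G], scoring_age=ScoringAge.ADULT_DAY2)
        once = reclassify_day2_adult(r)
        assert reclassify_day2_adult(once) == once
        assert once.category is CloneCategory.FSC_ONLY

    def test_rejects_day0_records(self):
        with pytest.raises(UsageError):
            reclassify_day2_adult(rec(fcs=[E1]))


class TestAggregation:
    def test_published_observed_fractions(self, marcm_0hr, marcm_36hr):
        f = aggregate_frequencies(marcm_0hr.table)
        # EC_plus_FC counted inside both EC- and FC-without-FSC fractions
        assert f.f_ec_obs == pytest.approx(0.63, abs=0.005)
        assert f.f_fc_obs == pytest.approx(0.25, abs=0.006)
        assert f.f_fsc_obs == pytest.approx(0.03, abs=0.001)
        f36 = aggregate_frequencies(marcm_36hr.table)
        assert f36.f_ec_obs == pytest.approx(0.645, abs=0.002)
        assert f36.f_fc_obs == pytest.approx(0.529, abs=0.001)

    def test_pure_ec_table(self):
        table = CloneCategoryTable(categories={CloneCategory.EC_ONLY: CategoryStats(n=5)})
        f = aggregate_frequencies(table)
        assert (f.f_ec_obs, f.f_fc_obs, f.f_fsc_obs, f.f_ecfc_obs) == (1.0, 0.0, 0.0, 0.0)

    def test_empty_table_rejected(self):
        table = CloneCategoryTable(categories={})
        with pytest.raises(EmptyInputError):
            aggregate_frequencies(table)

    def test_order_invariance(self):
        rng = random.Random(5)
        records = [
            rec(oid=f"r{i}", fsc=rng.randrange(2), ec=rng.randrange(3),
                fcs=rng.sample([E1, E4], rng.randrange(2)))
            for i in range(100)
        ]
        f1 = aggregate_frequencies(ingest_records(records))
        rng.shuffle(records)
        f2 = aggregate_frequencies(ingest_records(records))
        assert f1 == f2

    def test_ecfc_bound_invariant(self):
        with pytest.raises(MalformedRecordError):
            AggregatedFrequencies(f_ec_obs=0.1, f_fc_obs=0.5, f_fsc_obs=0.0, f_ecfc_obs=0.3)

    def test_count_reconciliation_enforced(self):
        with pytest.raises(MalformedRecordError):
            CloneCategoryTable(
                categories={CloneCategory.EC_ONLY: CategoryStats(n=5)},
                n_scored=10,
                n_unlabeled=2,
            )


class TestIO:
    def test_records_csv_round_trip(self, tmp_path):
        records = [
            rec(oid="a", r1=2, r2a=1, fsc=1, fcs=[I, E1]),
            rec(oid="b", fcs=[E4], basal_stalk=BasalStalk.MARKED),
            rec(oid="c", scoring_age=ScoringAge.ADULT_DAY2),
        ]
        path = tmp_path / "records.csv"
        write_records_csv(records, path)
        back = read_records_csv(path)
        assert back == records

    def test_aggregated_csv(self, tmp_path):
        path = tmp_path / "agg.csv"
        path.write_text(
            "category,n,mean_ec,mean_fsc\n"
            "EC_only,46,2.4,\nEC_FSC,24,4.0,4.0\nFSC_only,3,,4.667\n"
            "FC_only,9,,\nEC_plus_FC,16,2.9,\nunlabeled,109,,\n"
            "total_EC_marked,253,,\ntotal_FSC_marked,111,,\n"
        )
        table = read_aggregated_csv(path)
        assert table.marked == 98
        assert table.n_scored == 207
        assert table.total_ec_marked == 253.0
        assert table.stats(CloneCategory.EC_FSC).mean_fsc == 4.0
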
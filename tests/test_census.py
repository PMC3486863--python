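import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnacensus import census
from rnacensus.census import (
    BroadDistributionCall,
    PresenceMatrix,
    broad_distribution,
    broad_distribution_rate,
    build_presence,
    interdomain_units,
    normalized_abundance,
    percent_half_up,
    venn_partition,
)
from rnacensus.taxonomy import DOMAIN_LABELS


def assignments_frame(rows):
    return pd.DataFrame(rows, columns=["taxon_id", "domain", "division"])


def records_frame(rows):
    return pd.DataFrame(rows, columns=["seq_accession", "family_accession", "taxon_id"])


ASSIGN = assignments_frame(
    [
        (1, "Bacteria", "Proteobacteria"),
        (2, "Bacteria", "Firmicutes"),
        (3, "Archaea", "Euryarchaeota"),
        (4, "Eukaryota", "Opisthokonta"),
        (5, "Viruses", "Viruses"),
    ]
)


class TestBuildPresence:
    def test_family_level_hand_count(self):
        records = records_frame([("s1", "F1", 1), ("s2", "F1", 2), ("s3", "F1", 1)])
        m = build_presence(records, ASSIGN)
        assert m.presence_set("F1") == frozenset({"Bacteria"})
        assert m.support.loc["F1", "Bacteria"] == 3

    def test_empty_records_give_zero_rows(self):
        m = build_presence(records_frame([]), ASSIGN)
        assert m.present.shape[0] == 0

    def test_clan_level_ors_member_families(self):
        records = records_frame([("s1", "F1", 1), ("s2", "F2", 3)])
        m = build_presence(records, ASSIGN, level="CLAN", clan_map={"F1": "C1", "F2": "C1"})
        assert m.unit_ids == ["C1"]
        assert m.presence_set("C1") == frozenset({"Bacteria", "Archaea"})

    def test_clan_level_without_map_errors(self):
        with pytest.raises(ValueError):
            build_presence(records_frame([("s1", "F1", 1)]), ASSIGN, level="CLAN")

    def test_division_scope_filters_other_domains(self):
        records = records_frame([("s1", "F1", 1), ("s2", "F1", 3), ("s3", "F2", 2)])
        m = build_presence(
            records, ASSIGN, domain="Bacteria",
            columns=["Proteobacteria", "Firmicutes", "Cyanobacteria"],
        )
        assert m.presence_set("F1") == frozenset({"Proteobacteria"})
        assert m.column_ids == ["Proteobacteria", "Firmicutes", "Cyanobacteria"]

    def test_unassigned_taxa_are_excluded(self):
        records = records_frame([("s1", "F1", 99)])
        m = build_presence(records, ASSIGN)
        assert m.present.shape[0] == 0 or not m.presence_set("F1")

    def test_subsampling_never_creates_presence(self):
        rng = np.random.default_rng(5)
        rows = [
            (f"s{i}", f"F{rng.integers(4)}", int(rng.choice(ASSIGN.taxon_id)))
            for i in range(60)
        ]
        records = records_frame(rows)
        full = build_presence(records, ASSIGN)
        sub = build_presence(records.sample(30, random_state=0), ASSIGN)
        for unit in sub.unit_ids:
            assert sub.presence_set(unit) <= full.presence_set(unit)


def domain_matrix(support_rows, units):
    support = pd.DataFrame(support_rows, index=units, columns=list(DOMAIN_LABELS))
    return PresenceMatrix.from_support(support)


class TestVenn:
    def test_direct_enumeration(self):
        rows = [[1, 0, 0, 0]] * 4 + [[0, 2, 0, 0]] * 3 + [[0, 0, 1, 0]] * 2
        rows += [[1, 1, 1, 1]]
        m = domain_matrix(rows, [f"U{i}" for i in range(10)])
        v = venn_partition(m)
        singles = sum(
            n for s, n in v.region_counts.items() if len(s) == 1
        )
        assert singles == 9
        assert v.count("Archaea", "Bacteria", "Eukaryota", "Viruses") == 1
        assert v.domain_specific_fraction() == pytest.approx(0.9)

    def test_all_units_one_domain(self):
        m = domain_matrix([[0, 3, 0, 0]] * 5, [f"U{i}" for i in range(5)])
        v = venn_partition(m)
        assert v.region_counts == {frozenset({"Bacteria"}): 5}

    def test_empty_presence_is_not_a_region(self):
        m = domain_matrix([[0, 0, 0, 0], [1, 0, 0, 0]], ["U0", "U1"])
        v = venn_partition(m)
        assert v.no_presence == 1
        assert v.total_present() == 1

    def test_wrong_columns_is_usage_error(self):
        support = pd.DataFrame([[1]], index=["U0"], columns=["Bacteria"])
        with pytest.raises(ValueError):
            venn_partition(PresenceMatrix.from_support(support))

    @settings(derandomize=True, max_examples=100)
    @given(
        data=st.lists(
            st.tuples(*(st.integers(0, 3) for _ in range(4))), min_size=1, max_size=30
        )
    )
    def test_region_counts_conserve_units(self, data):
        m = domain_matrix([list(r) for r in data], [f"U{i}" for i in range(len(data))])
        v = venn_partition(m)
        n_nonempty = sum(1 for r in data if any(r))
        assert v.total_present() == n_nonempty
        assert v.no_presence == len(data) - n_nonempty


class TestInterdomain:
    def test_definition(self):
        m = domain_matrix([[1, 1, 0, 0], [0, 1, 0, 0]], ["AB", "Bonly"])
        res = interdomain_units(m)
        assert res.interdomain == ["AB"]

    def test_virus_sharing_is_separate(self):
        m = domain_matrix([[0, 1, 0, 1]], ["BV"])
        res = interdomain_units(m)
        assert res.interdomain == []
        assert res.virus_shared == ["BV"]

    def test_empty_matrix(self):
        m = domain_matrix([], [])
        res = interdomain_units(m)
        assert res.interdomain == [] and res.virus_shared == []


def division_matrix(rows, units, ncols=5, domain="Bacteria"):
    cols = [f"D{i}" for i in range(ncols)]
    support = pd.DataFrame(rows, index=units, columns=cols)
    return PresenceMatrix.from_support(support, domain=domain)


class TestBroadDistribution:
    def test_three_of_five_is_broad(self):
        m = division_matrix([[1, 1, 1, 0, 0]], ["U"])
        (call,) = broad_distribution(m)
        assert call.broad and call.divisions_present == 3 and call.divisions_total == 5

    def test_exactly_half_is_broad(self):
        m = division_matrix([[1, 1, 0, 0]], ["U"], ncols=4)
        (call,) = broad_distribution(m)
        assert call.broad

    def test_zero_presence_is_not_broad(self):
        m = division_matrix([[0, 0, 0, 0, 0]], ["U"])
        (call,) = broad_distribution(m)
        assert not call.broad

    def test_denominator_counts_all_columns(self):
        """Unoccupied divisions stay in the denominator."""
        m = division_matrix([[1, 1, 0, 0, 0], [0, 0, 0, 0, 0]], ["U1", "U2"])
        (c1, _) = broad_distribution(m)
        assert c1.divisions_total == 5 and not c1.broad

    def test_threshold_validation(self):
        m = division_matrix([[1, 0, 0, 0, 0]], ["U"])
        with pytest.raises(ValueError):
            broad_distribution(m, threshold=0.0)
        with pytest.raises(ValueError):
            broad_distribution(m, threshold=1.5)

    def test_adding_presence_never_unbroads(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 2, size=(10, 6))
        m1 = division_matrix(base, [f"U{i}" for i in range(10)], ncols=6)
        grown = base.copy()
        grown[rng.integers(10), rng.integers(6)] = 1
        m2 = division_matrix(grown, [f"U{i}" for i in range(10)], ncols=6)
        for c1, c2 in zip(broad_distribution(m1), broad_distribution(m2)):
            assert c2.broad or not c1.broad


class TestBroadRate:
    @pytest.mark.parametrize(
        "broad,total,pct",
        [(13, 69, 18.8), (15, 223, 6.7), (20, 826, 2.4), (0, 10, 0.0)],
    )
    def test_rates_from_counts(self, broad, total, pct):
        calls = [
            BroadDistributionCall(f"U{i}", "Archaea", 3 if i < broad else 1, 6, i < broad)
            for i in range(total)
        ]
        frac, percent = broad_distribution_rate(calls)
        assert percent == pct
        assert frac == pytest.approx(broad / total)

    def test_empty_calls_error(self):
        with pytest.raises(ValueError):
            broad_distribution_rate([])

    def test_mixed_domain_calls_error(self):
        calls = [
            BroadDistributionCall("U1", "Archaea", 1, 2, False),
            BroadDistributionCall("U2", "Bacteria", 1, 2, False),
        ]
        with pytest.raises(ValueError):
            broad_distribution_rate(calls)

    def test_rounding_is_half_up(self):
        assert percent_half_up(1, 8) == 12.5
        assert percent_half_up(69, 400) == 17.3  # 17.25 rounds up, not to even


class TestNormalizedAbundance:
    ROSTER = {"Proteobacteria": {1, 2, 3, 4}, "Firmicutes": {5, 6}}
    ASSIGN = assignments_frame(
        [(i, "Bacteria", "Proteobacteria") for i in (1, 2, 3, 4)]
        + [(i, "Bacteria", "Firmicutes") for i in (5, 6)]
    )

    def test_half_coverage(self):
        records = records_frame([("s1", "F1", 1), ("s2", "F1", 2), ("s3", "F1", 2)])
        out = normalized_abundance(records, self.ASSIGN, self.ROSTER)
        assert out.loc["F1", "Proteobacteria"] == pytest.approx(0.5)

    def test_absent_unit_is_zero_and_full_coverage_is_one(self):
        records = records_frame([("s1", "F1", 5), ("s2", "F1", 6)])
        out = normalized_abundance(records, self.ASSIGN, self.ROSTER)
        assert out.loc["F1", "Firmicutes"] == 1.0
        assert out.loc["F1", "Proteobacteria"] == 0.0

    def test_values_bounded(self, sim_default):
        ann = sim_default.annotations
        assign = assignments_frame(
            [
                (tid, name.split("_")[0], name.rsplit("_", 1)[0])
                for name, tid in sim_default.tip_taxa.items()
            ]
        )
        roster = {}
        for name, tid in sim_default.tip_taxa.items():
            roster.setdefault(name.rsplit("_", 1)[0], set()).add(tid)
        out = normalized_abundance(ann, assign, roster)
        assert ((out.values >= 0) & (out.values <= 1)).all()


def test_presence_matrix_tsv_roundtrip(tmp_path):
    m = domain_matrix([[1, 0, 2, 0], [0, 1, 0, 0]], ["U1", "U2"])
    path = tmp_path / "m.tsv"
    m.to_tsv(path)
    back = PresenceMatrix.from_tsv(path)
    assert back.support.equals(m.support)
    assert back.present.equals(m.present)
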
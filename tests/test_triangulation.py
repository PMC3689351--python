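import math

import pandas as pd
import pytest

from mtprov.differentiation import fst_matrix
from mtprov.geo_specificity import sharing_matrix
from mtprov.haplotypes import collapse_haplotypes
from mtprov.triangulation import (
    AssignmentRecord,
    TriangulationError,
    batch_frequency_support,
    read_assignment_records,
    triangulate,
    write_assignment_records,
)

from conftest import make_dataset


def _rec(sid, true, assigned, group="savanna"):
    return AssignmentRecord(
        sample_id=sid,
        true_locality=true,
        nuclear_assigned_locality=assigned,
        species_group=group,
    )


@pytest.fixture
def toy_matrices():
    """Three localities: AA/BB share a haplotype and differ strongly in
    frequency; CC is disjoint from both."""
    seqs = ["AAA"] * 9 + ["TTT"] + ["TTT"] * 9 + ["AAA"] + ["GGG"] * 4
    locs = ["AA"] * 10 + ["BB"] * 10 + ["CC"] * 4
    table = collapse_haplotypes(make_dataset(seqs, locs, ["C" + l for l in locs]))
    return table, sharing_matrix(table), fst_matrix(table, n_permutations=999, seed=2)


class TestTriangulate:
    def test_categories_follow_priority_rules(self, toy_matrices):
        table, sharing, fst = toy_matrices
        records = [
            _rec("s1", "AA", "AA"),  # correct
            _rec("s2", "AA", "CC"),  # disjoint -> precluded
            _rec("s3", "AA", "BB"),  # shared but significant -> distinguishes
        ]
        report = triangulate(records, sharing, fst, alpha=0.05)
        cats = [o.category for o in report.outcomes]
        assert cats == ["nuclear_correct", "mtdna_precludes", "mtdna_distinguishes"]
        assert report.improvement_count == 2 and report.n_misassigned == 2

    def test_non_significant_shared_pair_unresolved(self, toy_matrices):
        table, sharing, fst = toy_matrices
        report = triangulate([_rec("s1", "AA", "BB")], sharing, fst, alpha=1e-4)
        assert report.outcomes[0].category == "unresolved"

    def test_distinguishes_set_non_increasing_in_stricter_alpha(self, toy_matrices):
        table, sharing, fst = toy_matrices
        records = [_rec(f"s{i}", "AA", "BB") for i in range(4)]

        def n_dist(alpha):
            rep = triangulate(records, sharing, fst, alpha=alpha)
            return rep.counts["mtdna_distinguishes"]

        counts = [n_dist(a) for a in (0.2, 0.05, 0.005, 0.0005)]
        assert counts == sorted(counts, reverse=True)

    def test_counts_sum_and_species_contingency(self, toy_matrices):
        table, sharing, fst = toy_matrices
        records = [
            _rec("s1", "AA", "AA", "forest"),
            _rec("s2", "AA", "CC", "forest"),
            _rec("s3", "BB", "CC", "savanna"),
        ]
        report = triangulate(records, sharing, fst)
        assert sum(report.counts.values()) == 3
        assert int(report.counts_by_species.loc["forest", "mtdna_precludes"]) == 1

    def test_missing_pair_names_the_pair(self, toy_matrices):
        table, sharing, fst = toy_matrices
        with pytest.raises(TriangulationError, match="AA.*ZZ"):
            triangulate([_rec("s1", "AA", "ZZ")], sharing, fst)

    def test_alpha_bounds_validated(self, toy_matrices):
        table, sharing, fst = toy_matrices
        with pytest.raises(TriangulationError):
            triangulate([], sharing, fst, alpha=1.5)


class TestBatchSupport:
    def test_private_haplotype_flags_and_maximizes_source(self):
        seqs = ["AAA"] * 3 + ["TTT"] * 3
        locs = ["AA"] * 3 + ["BB"] * 3
        table = collapse_haplotypes(make_dataset(seqs, locs, ["C"] * 6))
        batch = [s for s in table.sample_to_hap if s.startswith("AA")]
        scores = batch_frequency_support(batch, table, ["AA", "BB"])
        assert bool(scores.loc["AA", "has_private_haplotype"])
        assert not bool(scores.loc["BB", "has_private_haplotype"])
        assert scores.loc["AA", "log_score"] > scores.loc["BB", "log_score"]

    def test_score_difference_matches_smoothed_frequencies(self):
        # one batch sample; its haplotype seen 5x in AA (n=10) vs 1x in BB
        # (n=10): score gap = log((5+1)/(1+1)) under add-one smoothing
        seqs = ["AAA"] * 5 + ["TTT"] * 5 + ["AAA"] + ["GGG"] * 9
        locs = ["AA"] * 10 + ["BB"] * 10
        table = collapse_haplotypes(make_dataset(seqs, locs, ["C"] * 20))
        scores = batch_frequency_support(["AA0001"], table, ["AA", "BB"])
        gap = scores.loc["AA", "log_score"] - scores.loc["BB", "log_score"]
        assert gap == pytest.approx(math.log(6 / 2))

    def test_unknown_sample_rejected(self):
        table = collapse_haplotypes(make_dataset(["AAA"], ["AA"], ["C"]))
        with pytest.raises(TriangulationError, match="ghost"):
            batch_frequency_support(["ghost"], table, ["AA"])


class TestRecordsIO:
    def test_round_trip(self, tmp_path):
        records = [_rec("s1", "AA", "BB", "forest"), _rec("s2", "CC", "CC")]
        path = tmp_path / "records.tsv"
        write_assignment_records(records, path)
        assert read_assignment_records(path) == records

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"sample_id": ["s1"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(TriangulationError):
            read_assignment_records(path)
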
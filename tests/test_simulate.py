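import numpy as np
import pytest
from scipy import stats

from mtprov.geo_specificity import sharing_matrix, specificity
from mtprov.haplotypes import collapse_haplotypes
from mtprov.simulate import (
    SimConfig,
    SimulationError,
    simulate_mtdna,
    simulate_nuclear_assignments,
    truth_hap_labels,
)

SMALL = dict(
    L=1200,
    n_localities=16,
    samples_per_locality=20,
    haplotypes_per_locality=4,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"private_fraction": 1.2},
            {"missing_rate": -0.1},
            {"frequency_skew": 0.0},
            {"n_fixed_sites_per_split": 0},
            {"L": 30},  # mutation budget exceeds alignment length
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            SimConfig(seed=1, **kwargs).validate()


class TestSimulateMtdna:
    def test_byte_identical_given_seed(self):
        cfg = SimConfig(seed=7, **SMALL)
        ds1, t1 = simulate_mtdna(cfg)
        ds2, t2 = simulate_mtdna(cfg)
        assert [s.sequence for s in ds1] == [s.sequence for s in ds2]
        assert t1.subclade_of_sample == t2.subclade_of_sample
        ds3, _ = simulate_mtdna(SimConfig(seed=8, **SMALL))
        assert [s.sequence for s in ds1] != [s.sequence for s in ds3]

    def test_fully_private_pools_give_spread_one(self):
        cfg = SimConfig(seed=3, private_fraction=1.0, **SMALL)
        ds, truth = simulate_mtdna(cfg)
        assert all(len(h.localities) == 1 for h in truth.haplotypes)
        table = collapse_haplotypes(ds)
        rep = specificity(table, "locality")
        assert rep.hap_fraction_by_spread == {1: 1.0}

    def test_shared_pools_populate_sharing_matrix(self):
        cfg = SimConfig(seed=3, private_fraction=0.0, **SMALL)
        ds, truth = simulate_mtdna(cfg)
        # every pool haplotype was placed in >= 2 localities
        assert all(len(h.localities) >= 2 for h in truth.haplotypes)
        m = sharing_matrix(collapse_haplotypes(ds))
        off_diag = m.shared_count.to_numpy()[
            ~np.eye(len(m.units), dtype=bool)
        ]
        assert off_diag.sum() > 0

    def test_generating_key_recovered_from_truth_labels(self):
        cfg = SimConfig(seed=1, **SMALL)
        ds, truth = simulate_mtdna(cfg)
        from mtprov.diagnostic_key import derive_key

        table = collapse_haplotypes(ds)
        key = derive_key(table, truth_hap_labels(truth, table), truth.hierarchy)
        planted = {(s.level, s.parent_label, s.column) for s in truth.key.sites}
        derived_fixed = {
            (s.level, s.parent_label, s.column) for s in key.sites if s.fixed
        }
        # every planted diagnostic site is recovered as fixed
        assert planted <= derived_fixed

    def test_missing_rate_masks_bases(self):
        cfg = SimConfig(seed=5, missing_rate=0.02, **SMALL)
        ds, _ = simulate_mtdna(cfg)
        n_total = len(ds) * ds.length
        n_masked = sum(s.sequence.count("N") for s in ds)
        assert 0.01 < n_masked / n_total < 0.03


class TestNuclearAssignments:
    def test_zero_rate_all_correct(self):
        cfg = SimConfig(seed=2, nuclear_misassignment_rate=0.0, **SMALL)
        ds, truth = simulate_mtdna(cfg)
        records = simulate_nuclear_assignments(cfg, truth)
        assert all(r.true_locality == r.nuclear_assigned_locality for r in records)

    def test_rate_one_with_two_localities_all_swapped(self):
        cfg = SimConfig(
            seed=2,
            nuclear_misassignment_rate=1.0,
            L=600,
            n_localities=2,
            samples_per_locality=10,
            haplotypes_per_locality=2,
        )
        ds, truth = simulate_mtdna(cfg)
        records = simulate_nuclear_assignments(cfg, truth)
        assert all(r.true_locality != r.nuclear_assigned_locality for r in records)

    def test_misassignment_count_within_binomial_99_interval(self):
        # 270 samples at rate 0.45: the realized count should fall in the
        # central 99% of Binomial(270, 0.45)
        cfg = SimConfig(
            seed=11,
            nuclear_misassignment_rate=0.45,
            L=1200,
            n_localities=6,
            samples_per_locality=45,
            haplotypes_per_locality=4,
        )
        ds, truth = simulate_mtdna(cfg)
        records = simulate_nuclear_assignments(cfg, truth)
        n_mis = sum(r.true_locality != r.nuclear_assigned_locality for r in records)
        lo, hi = stats.binom.interval(0.99, 270, 0.45)
        assert lo <= n_mis <= hi

    def test_errors_independent_of_subclade(self):
        cfg = SimConfig(seed=4, **SMALL)
        ds, truth = simulate_mtdna(cfg)
        records = simulate_nuclear_assignments(cfg, truth)
        # mis-assignment rate per clade should not differ significantly
        import pandas as pd

        df = pd.DataFrame(
            {
                "clade": [
                    truth.clade_of(truth.subclade_of_sample[r.sample_id])
                    for r in records
                ],
                "mis": [
                    r.true_locality != r.nuclear_assigned_locality for r in records
                ],
            }
        )
        ct = pd.crosstab(df["clade"], df["mis"])
        _, p, _, _ = stats.chi2_contingency(ct)
        assert p > 0.001
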
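import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from emvprofiler.io_formats import IonFeature, ProteinEntry
from emvprofiler.quant import (
    fold_enrichment,
    group_by_family,
    group_signal,
    mann_whitney_exact,
    signal_fraction,
    total_signal,
)


def ion(intensity, peptide=None):
    return IonFeature(mz=500.0, charge=2, rt=10.0, intensity=intensity,
                      peptide=peptide)


MAPPING = {"pepA": {"P1"}, "pepB": {"P1", "P2"}, "pepC": {"P3"}}


class TestGroupSignal:
    def test_shared_peptide_counts_fully_for_each_group(self):
        ions = [ion(100.0, "pepA"), ion(50.0, "pepB")]
        assert group_signal(ions, MAPPING, {"P1"}) == 150.0
        assert group_signal(ions, MAPPING, {"P2"}) == 50.0

    def test_ion_counted_once_per_group(self):
        # pepB maps to both members of the group; its ion counts once
        ions = [ion(50.0, "pepB")]
        assert group_signal(ions, MAPPING, {"P1", "P2"}) == 50.0

    def test_empty_group_is_zero(self):
        assert group_signal([ion(10.0, "pepA")], MAPPING, set()) == 0.0

    def test_unmapped_peptide_is_an_error(self):
        with pytest.raises(KeyError, match="pepZ"):
            group_signal([ion(1.0, "pepZ")], MAPPING, {"P1"})

    def test_monotone_in_group_inclusion(self):
        rng = np.random.default_rng(2)
        ions = [ion(float(rng.uniform(1, 100)),
                    f"pep{rng.integers(0, 10)}" if rng.random() < 0.8 else None)
                for _ in range(100)]
        mapping = {f"pep{i}": {f"P{i % 4}"} for i in range(10)}
        smaller = group_signal(ions, mapping, {"P0"})
        larger = group_signal(ions, mapping, {"P0", "P1", "P2"})
        assert smaller <= larger


class TestSignalFraction:
    def test_unassigned_ions_count_toward_total(self):
        ions = [ion(100.0, "pepA"), ion(50.0, "pepC"), ion(50.0, None)]
        report = signal_fraction(ions, MAPPING, {"P1"})
        assert report.fraction == pytest.approx(0.50)

    def test_all_assigned_all_grouped_is_one(self):
        ions = [ion(100.0, "pepA"), ion(50.0, "pepC")]
        report = signal_fraction(ions, MAPPING, {"P1", "P2", "P3"})
        assert report.fraction == pytest.approx(1.0)

    def test_partition_plus_unassigned_closes_to_one(self):
        # without shared peptides, disjoint group fractions + unassigned = 1
        mapping = {"a": {"P1"}, "b": {"P2"}}
        ions = [ion(60.0, "a"), ion(30.0, "b"), ion(10.0, None)]
        f1 = signal_fraction(ions, mapping, {"P1"}).fraction
        f2 = signal_fraction(ions, mapping, {"P2"}).fraction
        unassigned = 10.0 / total_signal(ions)
        assert f1 + f2 + unassigned == pytest.approx(1.0)

    def test_shared_peptides_can_push_fraction_sum_above_one(self):
        ions = [ion(90.0, "pepB"), ion(10.0, "pepA")]
        f1 = signal_fraction(ions, MAPPING, {"P1"}).fraction
        f2 = signal_fraction(ions, MAPPING, {"P2"}).fraction
        assert f1 + f2 > 1.0

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            signal_fraction([ion(0.0, "pepA")], MAPPING, {"P1"})

    def test_identified_only_flag_shrinks_total(self):
        ions = [ion(100.0, "pepA"), ion(100.0, None)]
        assert signal_fraction(ions, MAPPING, {"P1"},
                               include_unassigned=False).fraction == 1.0


def test_fold_enrichment_inverts_uniform_group_scaling():
    """Scaling every group ion by k moves the odds-ratio fold by exactly k."""
    mapping = {"a": {"P1"}, "b": {"P2"}}
    base = [ion(200.0, "a"), ion(300.0, "b"), ion(100.0, None)]
    k = 3.3
    scaled = [ion(200.0 * k, "a"), ion(300.0, "b"), ion(100.0, None)]
    rep_a = signal_fraction(scaled, mapping, {"P1"}, "a")
    rep_b = signal_fraction(base, mapping, {"P1"}, "b")
    assert fold_enrichment(rep_a, rep_b) == pytest.approx(k)
    assert rep_a.fraction / rep_b.fraction != pytest.approx(k)


def test_group_by_family_partitions_accessions():
    def protein(acc, gene, fam):
        return ProteinEntry(accession=acc, gene_symbol=gene,
                            family_symbol=fam, theoretical_mw_kda=42.0)

    proteins = [protein("P1", "ACTB", "ACT"), protein("P2", "ACTG1", "ACT"),
                protein("P3", "TUBB", "TUB")]
    families = group_by_family(proteins)
    assert families == {"ACT": {"P1", "P2"}, "TUB": {"P3"}}
    assert group_by_family([]) == {}


class TestMannWhitneyExact:
    def test_complete_separation_of_triplicates(self):
        u, p = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 of 20 labelings are as extreme

    def test_complete_ties_give_p_one(self):
        _, p = mann_whitney_exact([1, 1, 1], [1, 1, 1])
        assert p == 1.0

    def test_single_observations(self):
        _, p = mann_whitney_exact([1], [2])
        assert p == 1.0  # both labelings equally extreme, two-sided

    def test_large_samples_are_rejected(self):
        with pytest.raises(ValueError, match="normal-approximation"):
            mann_whitney_exact(list(range(7)), list(range(6)))
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1])

    def test_agrees_with_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            pooled = rng.permutation(rng.uniform(0, 1, 6))
            a, b = list(pooled[:3]), list(pooled[3:])
            u, p = mann_whitney_exact(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_matches_null_distribution_for_all_3v3_arrangements(self):
        """Every assignment of {1..6} to two triples yields the p-value
        implied by the exact null distribution of U."""
        values = [1, 2, 3, 4, 5, 6]
        u_null = []
        for idx in itertools.combinations(range(6), 3):
            ranks = [values[i] for i in idx]  # values are their own ranks
            u_null.append(sum(ranks) - 6)
        for idx in itertools.combinations(range(6), 3):
            a = [values[i] for i in idx]
            b = [values[i] for i in range(6) if i not in idx]
            u, p = mann_whitney_exact(a, b)
            expected = sum(abs(x - 4.5) >= abs(u - 4.5) for x in u_null) / 20
            assert p == pytest.approx(expected)
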
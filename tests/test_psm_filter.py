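import numpy as np
import pytest

from emvprofiler.io_formats import PSMRecord
from emvprofiler.psm_filter import (
    FilterThresholds,
    apply_filters,
    compute_fpr,
    optimize_thresholds,
)


def make_psm(score=50.0, parent=0.01, fragment=0.05, missed=0, prob=0.95,
             decoy=False, peptide="PEPTIDEK", charge=2, sid="S"):
    acc = "REV_P1" if decoy else "P1"
    return PSMRecord(spectrum_id=sid, peptide=peptide, proteins=[acc],
                     ion_score=score, parent_error_da=parent,
                     fragment_error_da=fragment, missed_cleavages=missed,
                     charge=charge, probability=prob, is_decoy=decoy)


def random_psms(rng, n):
    return [make_psm(score=float(rng.uniform(0, 80)),
                     parent=float(rng.normal(0, 0.08)),
                     fragment=float(abs(rng.normal(0, 0.12))),
                     missed=int(rng.integers(0, 3)),
                     prob=float(rng.uniform(0.5, 1.0)),
                     decoy=bool(rng.random() < 0.4),
                     peptide=f"PEP{rng.integers(0, n // 2)}K",
                     charge=int(rng.choice([2, 3, 4])),
                     sid=f"S{i}")
            for i in range(n)]


class TestComputeFPR:
    @pytest.mark.parametrize("n_rev,n_fwd,expected", [
        (1, 399, 0.005),
        (0, 100, 0.0),
        (5, 5, 1.0),     # 2*5/10 hits the cap exactly
        (9, 1, 1.0),     # capped
    ])
    def test_known_values(self, n_rev, n_fwd, expected):
        assert compute_fpr(n_rev, n_fwd) == pytest.approx(expected)

    def test_no_retained_peptides_is_an_error(self):
        with pytest.raises(ValueError, match="no retained peptides"):
            compute_fpr(0, 0)


class TestApplyFilters:
    def test_score_bound_is_strict(self):
        """An ion score of exactly 40 fails the >40 gate."""
        at = make_psm(score=40.0)
        above = make_psm(score=40.0001)
        result = apply_filters([at, above])
        assert result.retained == [above]

    def test_probability_bound_is_inclusive(self):
        assert apply_filters([make_psm(prob=0.90)]).retained

    def test_parent_error_uses_absolute_value(self):
        assert apply_filters([make_psm(parent=-0.05)]).retained
        assert not apply_filters([make_psm(parent=-0.15)]).retained

    def test_two_forward_two_decoy_give_fpr_one(self):
        psms = [make_psm(sid=f"S{i}", decoy=i % 2 == 0) for i in range(4)]
        result = apply_filters(psms)
        assert (result.n_fwd, result.n_rev, result.fpr) == (2, 2, 1.0)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            apply_filters([])

    def test_result_invariants(self):
        rng = np.random.default_rng(5)
        result = apply_filters(random_psms(rng, 300))
        assert result.n_fwd + result.n_rev == len(result.retained)
        assert result.fpr == compute_fpr(result.n_rev, result.n_fwd)

    @pytest.mark.parametrize("tighten", [
        dict(min_ion_score=55.0),
        dict(max_parent_error_da=0.05),
        dict(max_fragment_error_da=0.1),
        dict(max_missed_cleavages=0),
        dict(min_probability=0.95),
    ])
    def test_tightening_any_gate_never_adds_a_psm(self, tighten):
        rng = np.random.default_rng(17)
        psms = random_psms(rng, 400)
        loose = {p.spectrum_id for p in apply_filters(psms).retained}
        tight_t = FilterThresholds(**tighten)
        tight = {p.spectrum_id for p in apply_filters(psms, tight_t).retained}
        assert tight <= loose


def brute_force_optimum(psms, fpr_max, grid):
    """Independent exhaustive enumeration of the score grid."""
    def evaluate(g):
        kept = [p for p in psms
                if p.ion_score > g and abs(p.parent_error_da) < 0.1
                and p.fragment_error_da < 0.2 and p.missed_cleavages <= 1
                and p.probability >= 0.90]
        n_rev = sum(p.is_decoy for p in kept)
        n_fwd = len(kept) - n_rev
        fpr = min(1.0, 2 * n_rev / (n_rev + n_fwd)) if kept else 0.0
        peps = len({(p.peptide, p.charge) for p in kept if not p.is_decoy})
        return fpr, peps

    best = None
    for g in grid:
        fpr, peps = evaluate(g)
        if fpr > fpr_max:
            continue
        key = (peps, -fpr, g)
        if best is None or key > best[0]:
            best = (key, g, fpr, peps)
    return best  # None if infeasible everywhere


class TestOptimizeThresholds:
    def test_all_forward_high_scores_retained_with_zero_fpr(self):
        psms = [make_psm(score=50.0, sid=f"S{i}", peptide=f"P{i}K")
                for i in range(10)]
        result = optimize_thresholds(psms, grid=[40.0])
        assert result.fpr == 0.0
        assert len(result.retained) == 10
        assert result.constraint_met

    def test_matches_brute_force_on_toy_grid(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            psms = random_psms(rng, 100)
            grid = [10.0, 20.0, 30.0, 40.0]
            result = optimize_thresholds(psms, fpr_max=0.3, grid=grid)
            oracle = brute_force_optimum(psms, 0.3, grid)
            if oracle is None:
                assert not result.constraint_met
            else:
                assert result.constraint_met
                assert result.thresholds_used.min_ion_score == oracle[1]
                assert result.fpr == pytest.approx(oracle[2])
                assert result.n_fwd_peptides == oracle[3]

    def test_infeasible_grid_flags_constraint_failure(self):
        # every grid point retains 1 fwd + 1 rev -> fpr 1 everywhere
        psms = [make_psm(score=70, sid="a", decoy=False),
                make_psm(score=70, sid="b", decoy=True)]
        result = optimize_thresholds(psms, fpr_max=0.005, grid=[10.0, 20.0])
        assert not result.constraint_met
        assert result.fpr == 1.0

    def test_empty_grid_is_an_error(self):
        with pytest.raises(ValueError, match="grid"):
            optimize_thresholds([make_psm()], grid=[])


def test_subsample_fpr_deviation_shrinks_with_size():
    """FPR on a random half-sample approaches the full-table FPR as the
    table grows (stability of the Eq.-1 estimator)."""
    from emvprofiler.synthetic_data import SimConfig, generate_psm_table

    def mean_abs_dev(n_psms):
        devs = []
        for seed in range(10):
            psms = generate_psm_table(SimConfig(
                seed=seed, n_forward_psms=n_psms, decoy_fraction=0.5))
            full = apply_filters(psms, FilterThresholds(min_ion_score=20.0))
            rng = np.random.default_rng(seed + 100)
            idx = rng.choice(len(psms), size=len(psms) // 2, replace=False)
            half = apply_filters([psms[i] for i in idx],
                                 FilterThresholds(min_ion_score=20.0))
            devs.append(abs(half.fpr - full.fpr))
        return float(np.mean(devs))

    assert mean_abs_dev(2000) < mean_abs_dev(200)
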
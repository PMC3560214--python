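import numpy as np
import pytest

from emvprofiler.psm_filter import FilterThresholds, apply_filters
from emvprofiler.quant import fold_enrichment, signal_fraction
from emvprofiler.synthetic_data import (
    SimConfig,
    generate_emv_experiment,
    generate_psm_table,
    write_bundle,
)


class TestSimConfig:
    def test_invalid_fields_are_named(self):
        with pytest.raises(ValueError, match="decoy_fraction"):
            SimConfig(decoy_fraction=1.5)
        with pytest.raises(ValueError, match="marker_enrichment"):
            SimConfig(marker_enrichment=-1)
        with pytest.raises(ValueError, match="n_forward_psms"):
            SimConfig(n_forward_psms=0)
        with pytest.raises(ValueError, match="uniform_probability_range"):
            SimConfig(uniform_probability_range=(0.9, 0.2))


class TestGeneratePSMTable:
    def test_forward_and_decoy_counts(self):
        psms = generate_psm_table(SimConfig(seed=1, n_forward_psms=100,
                                            decoy_fraction=0.5))
        n_dec = sum(p.is_decoy for p in psms)
        assert (len(psms) - n_dec, n_dec) == (100, 100)

    def test_decoy_count_follows_odds_formula(self):
        psms = generate_psm_table(SimConfig(seed=1, n_forward_psms=300,
                                            decoy_fraction=0.25))
        assert sum(p.is_decoy for p in psms) == round(300 * 0.25 / 0.75)

    def test_identical_config_gives_byte_identical_tables(self, tmp_path):
        from emvprofiler.io_formats import write_psm_table

        config = SimConfig(seed=42, n_forward_psms=200)
        for name in ("a.tsv", "b.tsv"):
            write_psm_table(generate_psm_table(config), tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == \
            (tmp_path / "b.tsv").read_bytes()

    def test_filtering_depletes_decoys(self):
        """Lower-mean decoy scores mean the filter removes decoys
        preferentially."""
        psms = generate_psm_table(SimConfig(seed=3, n_forward_psms=1000))
        pre = sum(p.is_decoy for p in psms) / len(psms)
        result = apply_filters(psms, FilterThresholds())
        post = (result.n_rev / len(result.retained)) if result.retained else 0
        assert post < pre

    def test_each_gate_has_planted_violations(self):
        psms = generate_psm_table(SimConfig(seed=4, n_forward_psms=2000))
        fwd = [p for p in psms if not p.is_decoy]
        assert any(abs(p.parent_error_da) >= 0.1 for p in fwd)
        assert any(p.fragment_error_da >= 0.2 for p in fwd)
        assert any(p.missed_cleavages > 1 for p in fwd)
        assert any(p.probability < 0.90 for p in fwd)

    def test_uniform_probability_override(self):
        config = SimConfig(seed=5, n_forward_psms=500,
                           uniform_probability_range=(0.5, 1.0))
        probs = [p.probability for p in generate_psm_table(config)]
        assert min(probs) >= 0.5
        assert max(probs) <= 1.0
        assert np.std(probs) > 0.05  # genuinely spread, not clumped


class TestExperimentBundle:
    def test_zero_degraded_fraction_plants_zero(self):
        from emvprofiler.gel_bands import assemble_bands, band_summary

        bundle = generate_emv_experiment(SimConfig(
            seed=2, n_proteins=150, degraded_fraction=0.0))
        mw = {p.accession: p.theoretical_mw_kda for p in bundle.proteins}
        bands = assemble_bands(bundle.band_assignments, mw,
                               bundle.band_bounds)
        for band in bands:
            report = band_summary(band)
            if report.stats_defined:
                assert report.pct_signal_degraded == 0.0

    def test_zero_edge_density_gives_zero_summary(self):
        from emvprofiler.interactome import count_interactions

        bundle = generate_emv_experiment(SimConfig(
            seed=2, n_proteins=100, edge_density=0.0))
        emv_edges = {e for e in bundle.edges
                     if e & bundle.emv_surface and e & bundle.target_surface}
        summary = count_interactions(bundle.emv_surface,
                                     bundle.target_surface, bundle.edges)
        assert summary.n_interactions == len(emv_edges) == 0 or \
            summary.n_interactions == 0

    def test_reproducible_bundles_serialize_identically(self, tmp_path):
        config = SimConfig(seed=9, n_proteins=80)
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        write_bundle(generate_emv_experiment(config), dir_a)
        write_bundle(generate_emv_experiment(config), dir_b)
        for name in ("psms.tsv", "proteins.tsv", "emv_ions.tsv",
                     "band_assignments.tsv", "edges.tsv", "markers.tsv",
                     "config.yaml"):
            assert (dir_a / name).read_bytes() == (dir_b / name).read_bytes()

    def test_marker_ions_carry_planted_enrichment(self, small_bundle):
        markers = set(small_bundle.marker_families)
        rep_emv = signal_fraction(small_bundle.emv_ions,
                                  small_bundle.peptide_map, markers, "emv")
        rep_wce = signal_fraction(small_bundle.wce_ions,
                                  small_bundle.peptide_map, markers, "wce")
        fold = fold_enrichment(rep_emv, rep_wce)
        planted = small_bundle.config.marker_enrichment
        assert fold == pytest.approx(planted, rel=0.35)  # small-n tolerance

    def test_estimation_error_shrinks_with_problem_size(self):
        """Parameter-recovery error contracts as the roster grows."""
        def mean_abs_err(n_proteins, seeds):
            errs = []
            for seed in seeds:
                b = generate_emv_experiment(SimConfig(
                    seed=seed, n_proteins=n_proteins))
                markers = set(b.marker_families)
                fold = fold_enrichment(
                    signal_fraction(b.emv_ions, b.peptide_map, markers, "e"),
                    signal_fraction(b.wce_ions, b.peptide_map, markers, "w"))
                errs.append(abs(fold - b.config.marker_enrichment))
            return float(np.mean(errs))

        seeds = range(20, 30)
        assert mean_abs_err(1200, seeds) < mean_abs_err(120, seeds)

    def test_surface_fraction_is_respected(self, small_bundle):
        frac = (len(small_bundle.emv_surface)
                / len(small_bundle.proteins))
        assert frac == pytest.approx(small_bundle.config.surface_fraction,
                                     abs=0.1)

    def test_fc5_peptide_pinned_in_transitions(self, small_bundle):
        assert small_bundle.transitions.peptide == "ITWGGDNTFYSNSVK"
        assert small_bundle.transitions.precursor_mz == 844.92
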
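"""End-to-end orchestration: validate a YAML config, run the enabled
stages in dependency order, and emit a consolidated, reproducible report.

Stage outputs are exactly what the standalone stage functions return; the
report adds a provenance block (config hash, package version, seed) so
every number is traceable to one stage run under one configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .enrichment import marker_overlap, overrep_test, venn
from .gel_bands import assemble_bands, band_summary, overall_degraded_pct
from .interactome import count_interactions
from .io_formats import (
    TransitionSet,
    read_band_assignments,
    read_band_bounds,
    read_catalog,
    read_edge_list,
    read_fasta,
    read_ion_table,
    read_peptide_map,
    read_protein_table,
    read_psm_table,
    read_trace_table,
    mw_table_from_fasta,
)
from .mrm import detect_peptide, extract_transition_signal, relative_level
from .psm_filter import FilterThresholds, apply_filters, optimize_thresholds
from .quant import fold_enrichment, signal_fraction

logger = logging.getLogger(__name__)

STAGES = ("filter", "quant", "gel_bands", "enrichment", "interactome", "mrm")


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid pipeline config:\n  " + "\n  ".join(errors))


@dataclass
class PipelineConfig:
    seed: int
    base_dir: Path
    output_dir: Path
    stages: dict[str, bool]
    raw: dict[str, Any]
    config_hash: str

    def stage(self, name: str) -> dict[str, Any]:
        return self.raw.get(name, {}) or {}

    def path(self, relative: str) -> Path:
        p = Path(relative)
        return p if p.is_absolute() else self.base_dir / p


_REQUIRED_INPUTS = {
    "filter": ["psm_table"],
    "quant": ["emv_ions", "wce_ions", "peptide_map", "markers"],
    "gel_bands": ["band_assignments", "band_bounds"],
    "enrichment": ["identified", "markers", "proteins", "category"],
    "interactome": ["emv_surface", "target_surface", "edges"],
    "mrm": ["traces", "control_ids", "transitions"],
}


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and fully validate a pipeline YAML; reports every problem at
    once rather than failing on the first."""
    path = Path(path)
    errors: list[str] = []
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    text = path.read_text()
    raw = yaml.safe_load(text) or {}
    base = path.parent

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("'seed' must be an integer")
        seed = 0
    stages = {s: bool(raw.get("stages", {}).get(s, False)) for s in STAGES}

    def check_path(stage: str, key: str, value: Any) -> None:
        if value is None:
            errors.append(f"{stage}: missing required field '{key}'")
        elif isinstance(value, str) and not (base / value).exists() \
                and not Path(value).is_absolute():
            errors.append(f"{stage}: path '{value}' does not exist")

    for stage_name, keys in _REQUIRED_INPUTS.items():
        if not stages[stage_name]:
            continue
        section = raw.get(stage_name, {}) or {}
        for key in keys:
            value = section.get(key)
            if key in ("category", "control_ids"):
                if not value:
                    errors.append(
                        f"{stage_name}: missing required field '{key}'")
            elif key == "traces":
                if not isinstance(value, dict) or not value:
                    errors.append("mrm: 'traces' must map sample ids to paths")
                else:
                    for sid, p in value.items():
                        check_path("mrm", f"traces[{sid}]", p)
            else:
                check_path(stage_name, key, value)

    fpr_max = (raw.get("filter", {}) or {}).get("fpr_max", 0.005)
    if stages["filter"] and not (0 < fpr_max <= 1):
        errors.append("filter: 'fpr_max' must be in (0, 1]")
    B = (raw.get("enrichment", {}) or {}).get("B", 100)
    if stages["enrichment"] and (not isinstance(B, int) or B < 1):
        errors.append("enrichment: 'B' must be a positive integer")

    if errors:
        raise ConfigError(errors)
    return PipelineConfig(
        seed=seed, base_dir=base,
        output_dir=base / str(raw.get("output_dir", "pipeline_out")),
        stages=stages, raw=raw,
        config_hash=hashlib.sha256(text.encode()).hexdigest()[:16])


@dataclass
class PipelineReport:
    provenance: dict[str, Any]
    stages: dict[str, Any] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, Any]:
        return {"provenance": self.provenance, "stages": self.stages,
                "errors": self.errors}

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True)


def _run_filter(cfg: PipelineConfig, outdir: Path) -> dict[str, Any]:
    section = cfg.stage("filter")
    psms = read_psm_table(cfg.path(section["psm_table"]))
    logger.info("filter: %d PSMs in", len(psms))
    if section.get("optimize", True):
        result = optimize_thresholds(
            psms, fpr_max=section.get("fpr_max", 0.005),
            grid=section.get("score_grid", list(range(10, 85, 5))))
    else:
        result = apply_filters(psms, FilterThresholds(
            fpr_max=section.get("fpr_max", 0.005)))
    logger.info("filter: %d retained (%d fwd / %d rev), FPR %.5f",
                len(result.retained), result.n_fwd, result.n_rev, result.fpr)
    from .io_formats import write_psm_table
    write_psm_table(result.retained, outdir / "retained_psms.tsv")
    return result.summary()


def _run_quant(cfg: PipelineConfig, outdir: Path) -> dict[str, Any]:
    section = cfg.stage("quant")
    emv = read_ion_table(cfg.path(section["emv_ions"]))
    wce = read_ion_table(cfg.path(section["wce_ions"]))
    mapping = read_peptide_map(cfg.path(section["peptide_map"]))
    markers = set(read_catalog(cfg.path(section["markers"])))
    include = bool(section.get("include_unassigned", True))
    rep_emv = signal_fraction(emv, mapping, markers, "markers_emv", include)
    rep_wce = signal_fraction(wce, mapping, markers, "markers_wce", include)
    rows = [{"group_id": r.group_id, "group_signal": r.group_signal,
             "total_signal": r.total_signal, "fraction": r.fraction}
            for r in (rep_emv, rep_wce)]
    pd.DataFrame(rows).to_csv(outdir / "signal_fractions.tsv",
                              sep="\t", index=False)
    return {
        "marker_fraction_emv": rep_emv.fraction,
        "marker_fraction_wce": rep_wce.fraction,
        "fold_fraction_ratio": rep_emv.fraction / rep_wce.fraction,
        "fold_enrichment_odds": fold_enrichment(rep_emv, rep_wce),
        "shared_peptide_double_counting": "fractions of overlapping groups "
                                          "may sum above 1",
    }


def _run_gel_bands(cfg: PipelineConfig, outdir: Path) -> dict[str, Any]:
    section = cfg.stage("gel_bands")
    assignments = read_band_assignments(cfg.path(section["band_assignments"]))
    bounds = read_band_bounds(cfg.path(section["band_bounds"]))
    if "proteins" in section:
        table = read_protein_table(cfg.path(section["proteins"]))
        mw_table = {p.accession: p.theoretical_mw_kda for p in table}
    elif "fasta" in section:
        mw_table = mw_table_from_fasta(read_fasta(cfg.path(section["fasta"])))
    else:
        from .io_formats import read_mw_table
        mw_table = read_mw_table(cfg.path(section["mw_table"]))
    bands = assemble_bands(assignments, mw_table, bounds)
    reports = [band_summary(b) for b in bands]
    pd.DataFrame([vars(r) for r in reports]).to_csv(
        outdir / "band_reports.tsv", sep="\t", index=False)
    return {
        "per_band_pct_degraded": {r.index: r.pct_signal_degraded
                                  for r in reports},
        "overall_pct_degraded": overall_degraded_pct(bands),
    }


def _run_enrichment(cfg: PipelineConfig, outdir: Path) -> dict[str, Any]:
    section = cfg.stage("enrichment")
    identified = set(read_catalog(cfg.path(section["identified"])))
    markers = read_catalog(cfg.path(section["markers"]))
    marker_fams = {k: v or k for k, v in markers.items()}
    n_found, n_total, fams = marker_overlap(identified, marker_fams)
    out: dict[str, Any] = {
        "markers_found": n_found, "markers_total": n_total,
        "marker_families_found": sorted(fams),
    }
    if section.get("method_lists"):
        sets = {name: set(read_catalog(cfg.path(p)))
                for name, p in section["method_lists"].items()}
        counts = venn(sets)
        out["venn"] = counts.regions
        out["venn_union"] = counts.union_size
    reference = read_protein_table(cfg.path(section["proteins"]))
    result = overrep_test(identified, reference, section["category"],
                          B=section.get("B", 100), seed=cfg.seed)
    out["overrep"] = {"category": result.category,
                      "observed": result.observed,
                      "p_empirical": result.p_empirical,
                      "B": result.B,
                      "p_floor": 1.0 / (result.B + 1)}
    with open(outdir / "enrichment.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    return out


def _run_interactome(cfg: PipelineConfig, outdir: Path) -> dict[str, Any]:
    section = cfg.stage("interactome")
    emv = set(read_catalog(cfg.path(section["emv_surface"])))
    target = set(read_catalog(cfg.path(section["target_surface"])))
    edges = read_edge_list(cfg.path(section["edges"]))
    summary = count_interactions(emv, target, edges)
    pd.DataFrame(summary.edges, columns=["emv_accession", "target_accession"]
                 ).to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    out = summary.as_dict()
    out["ppi_source"] = str(section["edges"])
    return out


def _load_transitions(path: Path) -> TransitionSet:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return TransitionSet(**data)


def _run_mrm(cfg: PipelineConfig, outdir: Path) -> dict[str, Any]:
    section = cfg.stage("mrm")
    transitions = _load_transitions(cfg.path(section["transitions"]))
    min_frag = int(section.get("min_fragments_matched", 3))
    raw: dict[str, float] = {}
    detected: dict[str, bool] = {}
    for sid, p in sorted(section["traces"].items()):
        trace = read_trace_table(cfg.path(p))
        signals, total = extract_transition_signal(trace, transitions)
        raw[sid] = total
        detected[sid] = detect_peptide(signals, min_frag)
    extra_detect: dict[str, bool] = {}
    for sid, p in sorted(section.get("detection_traces", {}).items()):
        trace = read_trace_table(cfg.path(p))
        signals, _ = extract_transition_signal(trace, transitions)
        extra_detect[sid] = detect_peptide(signals, min_frag)
    levels = relative_level(raw, section["control_ids"])
    pd.DataFrame([vars(l) for l in levels]).to_csv(
        outdir / "relative_levels.tsv", sep="\t", index=False)
    return {
        "relative_levels": {l.sample_id: l.relative_to_median_control
                            for l in levels},
        "detected": detected,
        "detection_traces": extra_detect,
        "peptide": transitions.peptide,
        "precursor_mz": transitions.precursor_mz,
    }


_STAGE_RUNNERS = {
    "filter": _run_filter,
    "quant": _run_quant,
    "gel_bands": _run_gel_bands,
    "enrichment": _run_enrichment,
    "interactome": _run_interactome,
    "mrm": _run_mrm,
}

def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every enabled stage; a stage failure halts nothing independent.

    The quant stage consumes the peptide map given in the config (in a
    real analysis, derived from the retained PSMs), so all six stages are
    mutually independent once their inputs exist; failures are collected
    in the report and reflected in the CLI exit code.
    """
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(provenance={
        "config_hash": config.config_hash,
        "seed": config.seed,
        "emvprofiler_version": __version__,
    })
    for stage_name in STAGES:
        if not config.stages.get(stage_name):
            continue
        try:
            report.stages[stage_name] = _STAGE_RUNNERS[stage_name](
                config, outdir)
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            logger.error("stage %s failed: %s", stage_name, exc)
            report.errors[stage_name] = str(exc)
    (outdir / "report.json").write_text(report.to_json())
    return report
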
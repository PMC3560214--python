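"""Synthetic fixtures with planted ground truth for every pipeline stage.

No raw data or protein lists are deposited with the study this pipeline
emulates, so each stage is exercised on generated inputs whose true
parameters are known: forward/decoy score distributions for the filter,
marker-family intensity enrichment for quantification, a degraded signal
fraction for gel-band analysis, an over-represented category for the
permutation test, a bipartite surface-edge density for interactomics, and
spiked/blank transition traces for MRM.

Score model: forward and decoy ion scores are drawn from two Gumbel
distributions (heavy right tail, as search-engine score maxima behave),
the decoy distribution with a lower mean. Ion intensities are log-normal
(MS1 intensities are multiplicative). Peptides are random tryptic-like
strings ending in K/R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io_formats import (
    IonFeature,
    PSMRecord,
    ProteinEntry,
    TransitionSet,
    compute_theoretical_mw,
    write_band_assignments,
    write_band_bounds,
    write_catalog,
    write_edge_list,
    write_fasta,
    write_ion_table,
    write_peptide_map,
    write_protein_table,
    write_psm_table,
    write_trace_table,
)
from .mrm import fc5_transitions

_AA = "ACDEFGHIKLMNPQRSTVWY"
_EULER_GAMMA = 0.5772156649015329

#: the eight functional classes used for category annotation
CATEGORIES = (
    "membrane_traffic", "rna_dna_binding", "cytoskeletal", "enzyme",
    "receptor", "signal_transduction", "cell_adhesion", "cell_motility",
)
#: the category planted as over-represented in the identified list
PLANTED_CATEGORY = "membrane_traffic"

#: fixed share of band signal planted below the lower MW bound
MODIFIED_SHARE = 0.05


def _require(condition: bool, name: str, message: str) -> None:
    if not condition:
        raise ValueError(f"invalid config field '{name}': {message}")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for fixture generation; identical configs yield
    byte-identical outputs."""

    seed: int = 0
    n_forward_psms: int = 2000
    decoy_fraction: float = 0.5
    forward_score_mean: float = 52.0
    forward_score_sd: float = 13.0
    decoy_score_mean: float = 18.0
    decoy_score_sd: float = 6.0
    n_proteins: int = 2000
    marker_fraction: float = 0.1
    marker_enrichment: float = 3.3
    degraded_fraction: float = 0.20
    surface_fraction: float = 0.35
    edge_density: float = 0.05
    n_bands: int = 10
    #: draw probabilities uniformly from this range instead of coupling
    #: them to the ion score
    uniform_probability_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        _require(self.n_forward_psms > 0, "n_forward_psms", "must be > 0")
        _require(0 < self.decoy_fraction < 1, "decoy_fraction",
                 "must be in (0, 1)")
        _require(self.n_proteins > 0, "n_proteins", "must be > 0")
        _require(0 < self.marker_fraction < 1, "marker_fraction",
                 "must be in (0, 1)")
        _require(self.marker_enrichment > 0, "marker_enrichment",
                 "must be > 0")
        _require(0 <= self.degraded_fraction <= 1, "degraded_fraction",
                 "must be in [0, 1]")
        _require(0 < self.surface_fraction < 1, "surface_fraction",
                 "must be in (0, 1)")
        _require(0 <= self.edge_density <= 1, "edge_density",
                 "must be in [0, 1]")
        _require(self.n_bands >= 1, "n_bands", "must be >= 1")
        _require(self.forward_score_sd > 0, "forward_score_sd", "must be > 0")
        _require(self.decoy_score_sd > 0, "decoy_score_sd", "must be > 0")
        if self.uniform_probability_range is not None:
            lo, hi = self.uniform_probability_range
            _require(0 <= lo < hi <= 1, "uniform_probability_range",
                     "must satisfy 0 <= lo < hi <= 1")


def _gumbel(rng: np.random.Generator, mean: float, sd: float,
            size: int) -> np.ndarray:
    scale = sd * math.sqrt(6) / math.pi
    loc = mean - _EULER_GAMMA * scale
    return rng.gumbel(loc, scale, size)


def _tryptic_peptide(rng: np.random.Generator,
                     min_len: int = 8, max_len: int = 16) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    body = "".join(_AA[i] for i in rng.integers(0, len(_AA), length - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def generate_psm_table(config: SimConfig) -> list[PSMRecord]:
    """Forward + decoy PSMs with planted score separation.

    Exactly ``n_forward_psms`` forward records and
    ``round(n_forward_psms * decoy_fraction / (1 - decoy_fraction))``
    decoy records. Probabilities are coupled to the ion score through a
    logistic curve (unless ``uniform_probability_range`` overrides);
    parent/fragment errors and missed cleavages each contain a planted
    subset violating the corresponding default gate.
    """
    rng = np.random.default_rng(config.seed)
    n_fwd = config.n_forward_psms
    n_dec = round(n_fwd * config.decoy_fraction / (1 - config.decoy_fraction))

    records: list[PSMRecord] = []
    for block, n, decoy in (("F", n_fwd, False), ("D", n_dec, True)):
        if decoy:
            scores = _gumbel(rng, config.decoy_score_mean,
                             config.decoy_score_sd, n)
        else:
            scores = _gumbel(rng, config.forward_score_mean,
                             config.forward_score_sd, n)
        scores = np.clip(scores, 0.0, None)
        # ~5% of rows deliberately violate each tolerance gate
        parent = rng.normal(0.0, 0.04, n)
        bad_parent = rng.random(n) < 0.05
        parent[bad_parent] = (rng.choice([-1.0, 1.0], bad_parent.sum())
                              * rng.uniform(0.1, 0.3, bad_parent.sum()))
        fragment = np.abs(rng.normal(0.0, 0.07, n))
        bad_frag = rng.random(n) < 0.05
        fragment[bad_frag] = rng.uniform(0.2, 0.5, bad_frag.sum())
        missed = rng.choice([0, 1, 2], size=n, p=[0.80, 0.15, 0.05])
        charge = rng.choice([2, 3, 4], size=n, p=[0.6, 0.3, 0.1])
        if config.uniform_probability_range is not None:
            lo, hi = config.uniform_probability_range
            prob = rng.uniform(lo, hi, n)
        else:
            prob = 1.0 / (1.0 + np.exp(-(scores - 30.0) / 6.0))
            prob = np.clip(prob + rng.normal(0.0, 0.05, n), 0.0, 1.0)
        for i in range(n):
            acc = f"P{int(rng.integers(0, config.n_proteins)):05d}"
            if decoy:
                acc = "REV_" + acc
            records.append(PSMRecord(
                spectrum_id=f"S_{block}{i:06d}",
                peptide=_tryptic_peptide(rng),
                proteins=[acc],
                ion_score=float(scores[i]),
                parent_error_da=float(parent[i]),
                fragment_error_da=float(fragment[i]),
                missed_cleavages=int(missed[i]),
                charge=int(charge[i]),
                probability=float(prob[i]),
                is_decoy=decoy,
            ))
    return records


@dataclass
class ExperimentBundle:
    """Everything one synthetic experiment comprises, in memory."""

    config: SimConfig
    proteins: list[ProteinEntry]
    sequences: dict[str, str]
    emv_ions: list[IonFeature]
    wce_ions: list[IonFeature]
    peptide_map: dict[str, set[str]]
    band_bounds: dict[int, tuple[float, float]]
    band_assignments: list[tuple[str, int, float]]
    marker_families: dict[str, str]          # marker accession -> family
    identified: set[str]
    method_lists: dict[str, set[str]]
    emv_surface: set[str]
    target_surface: set[str]
    edges: set[frozenset[str]]
    transitions: TransitionSet
    traces: dict[str, list[tuple[float, float]]]   # incl. "spiked"/"blank"
    mrm_samples: dict[str, list[tuple[float, float]]]
    mrm_control_ids: list[str]
    psms: list[PSMRecord] = field(default_factory=list)


def _make_sequence(rng: np.random.Generator, target_mw_kda: float) -> str:
    # ~111.17 Da mean residue mass for a uniform composition
    length = max(5, int(round(target_mw_kda * 1000.0 / 111.17)))
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), length))


def generate_emv_experiment(config: SimConfig) -> ExperimentBundle:
    """One complete synthetic vesicle-proteome experiment.

    Planted structure: marker-family proteins carry ``marker_enrichment``-
    fold mean ion intensity in the vesicle run (not in the whole-cell run);
    ``degraded_fraction`` of each gel band's signal comes from proteins
    above the band's upper MW bound (plus a fixed 5% "modified" share
    below the lower bound); the identified list over-samples one category;
    bipartite surface edges are drawn at ``edge_density``; one MRM trace
    is spiked with the FC5 fragments and one is blank.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins

    # --- protein roster: bulk 8-250 kDa, plus heavy/light tails so that
    # every band has candidate degraded (above-range) and modified
    # (below-range) donors
    mw_targets = np.exp(rng.normal(math.log(40.0), 0.6, n))
    mw_targets = np.clip(mw_targets, 11.0, 240.0)
    n_heavy = max(3, n // 50)
    n_light = max(2, n // 50)
    mw_targets[:n_heavy] = rng.uniform(270.0, 420.0, n_heavy)
    mw_targets[n_heavy:n_heavy + n_light] = rng.uniform(4.0, 9.0, n_light)

    n_families = max(1, n // 3)
    family_of = rng.integers(0, n_families, n)
    fam_sizes: dict[int, int] = {}
    proteins: list[ProteinEntry] = []
    sequences: dict[str, str] = {}
    surface_flags = rng.random(n) < config.surface_fraction
    for i in range(n):
        acc = f"P{i:05d}"
        seq = _make_sequence(rng, float(mw_targets[i]))
        fam = f"FAM{int(family_of[i]):04d}"
        fam_sizes[family_of[i]] = fam_sizes.get(family_of[i], 0) + 1
        n_cats = 1 + int(rng.random() < 0.3)
        cats = set(rng.choice(CATEGORIES, size=n_cats, replace=False))
        proteins.append(ProteinEntry(
            accession=acc, gene_symbol=f"{fam}_{fam_sizes[family_of[i]]}",
            family_symbol=fam,
            theoretical_mw_kda=compute_theoretical_mw(seq),
            is_surface=bool(surface_flags[i]), categories=cats))
        sequences[acc] = seq
    mw = {p.accession: p.theoretical_mw_kda for p in proteins}

    # --- marker families: whole families until marker_fraction of the
    # roster is covered
    target_markers = config.marker_fraction * n
    marker_families: dict[str, str] = {}
    for fam_id in rng.permutation(n_families):
        if len(marker_families) >= target_markers:
            break
        fam = f"FAM{int(fam_id):04d}"
        for p in proteins:
            if p.family_symbol == fam:
                marker_families[p.accession] = fam
    marker_accs = set(marker_families)

    # --- MS1 ion features for the vesicle (EMV) and whole-cell (WCE) runs
    peptide_map: dict[str, set[str]] = {}
    emv_ions: list[IonFeature] = []
    wce_ions: list[IonFeature] = []
    base_mu = math.log(1e6)
    sigma = 0.7
    n_peps = 1 + rng.poisson(3.0, n)
    for p, k in zip(proteins, n_peps):
        boost = config.marker_enrichment if p.accession in marker_accs else 1.0
        for _ in range(int(k)):
            pep = _tryptic_peptide(rng, 9, 15)
            while pep in peptide_map:
                pep = _tryptic_peptide(rng, 9, 15)
            peptide_map[pep] = {p.accession}
            mz = float(rng.uniform(400.0, 2000.0))
            rt = float(rng.uniform(5.0, 65.0))
            charge = int(rng.choice([2, 3, 4]))
            emv_ions.append(IonFeature(
                mz=mz, charge=charge, rt=rt,
                intensity=float(boost * rng.lognormal(base_mu, sigma)),
                peptide=pep))
            wce_ions.append(IonFeature(
                mz=mz, charge=charge, rt=rt,
                intensity=float(rng.lognormal(base_mu, sigma)),
                peptide=pep))
    n_unassigned = len(emv_ions) // 10
    for ions in (emv_ions, wce_ions):
        for _ in range(n_unassigned):
            ions.append(IonFeature(
                mz=float(rng.uniform(400.0, 2000.0)),
                charge=int(rng.choice([1, 2, 3])),
                rt=float(rng.uniform(5.0, 65.0)),
                intensity=float(rng.lognormal(base_mu, sigma)),
                peptide=None))

    # --- per-protein EMV signal, reused for the gel lane
    protein_signal: dict[str, float] = {p.accession: 0.0 for p in proteins}
    for ion in emv_ions:
        if ion.peptide is not None:
            for acc in peptide_map[ion.peptide]:
                protein_signal[acc] += ion.intensity

    # --- gel bands: log-spaced observed MW windows from 250 down to 10 kDa
    edges = np.logspace(math.log10(250.0), math.log10(10.0),
                        config.n_bands + 1)
    band_bounds = {i + 1: (float(edges[i + 1]), float(edges[i]))
                   for i in range(config.n_bands)}

    def band_of(mw_kda: float) -> int | None:
        for idx, (lo, hi) in band_bounds.items():
            if lo <= mw_kda <= hi:
                return idx
        return None

    assignments: list[tuple[str, int, float]] = []
    band_concordant: dict[int, float] = {i: 0.0 for i in band_bounds}
    for p in proteins:
        idx = band_of(p.theoretical_mw_kda)
        if idx is None:
            continue
        sig = protein_signal[p.accession]
        if sig > 0:
            assignments.append((p.accession, idx, sig))
            band_concordant[idx] += sig

    f, m = config.degraded_fraction, MODIFIED_SHARE
    heavy_pool = [p.accession for p in proteins]
    for idx, (lo, hi) in band_bounds.items():
        s_band = band_concordant[idx]
        if s_band <= 0:
            continue
        total = s_band / max(1e-12, (1.0 - f - m))
        donors_deg = [a for a in heavy_pool if mw[a] > hi]
        donors_mod = [a for a in heavy_pool if mw[a] < lo]
        if f > 0 and donors_deg:
            d_total = f * total * float(rng.lognormal(0.0, 0.1))
            picks = rng.choice(len(donors_deg), size=min(3, len(donors_deg)),
                               replace=False)
            shares = rng.dirichlet(np.ones(len(picks)))
            for j, w in zip(picks, shares):
                assignments.append((donors_deg[int(j)], idx,
                                    float(d_total * w)))
        if m > 0 and donors_mod:
            m_total = m * total * float(rng.lognormal(0.0, 0.1))
            picks = rng.choice(len(donors_mod), size=min(2, len(donors_mod)),
                               replace=False)
            shares = rng.dirichlet(np.ones(len(picks)))
            for j, w in zip(picks, shares):
                assignments.append((donors_mod[int(j)], idx,
                                    float(m_total * w)))

    # --- identified list with the planted over-represented category
    identified: set[str] = set()
    for p in proteins:
        p_in = 0.85 if PLANTED_CATEGORY in p.categories else 0.50
        if rng.random() < p_in:
            identified.add(p.accession)
    method_lists = {
        name: {a for a in identified if rng.random() < 0.7}
        for name in ("gel_lc", "fasp", "dr")
    }

    # --- surfaces and bipartite PPI edges
    emv_surface = {p.accession for p in proteins if p.is_surface}
    n_target = 300
    target_surface = {f"T{i:04d}" for i in range(n_target)}
    emv_list = sorted(emv_surface)
    target_list = sorted(target_surface)
    mask = rng.random((len(emv_list), n_target)) < config.edge_density
    edges_set: set[frozenset[str]] = set()
    ii, jj = np.nonzero(mask)
    for a, b in zip(ii, jj):
        edges_set.add(frozenset((emv_list[int(a)], target_list[int(b)])))
    # noise edges touching intracellular proteins: never counted
    non_surface = sorted(set(p.accession for p in proteins) - emv_surface)
    if non_surface:
        for _ in range(50):
            a = non_surface[int(rng.integers(len(non_surface)))]
            b = target_list[int(rng.integers(n_target))]
            edges_set.add(frozenset((a, b)))

    # --- MRM traces
    transitions = fc5_transitions()

    def make_trace(spike_scale: float) -> list[tuple[float, float]]:
        points: list[tuple[float, float]] = []
        while len(points) < 60:
            mz_bg = float(rng.uniform(300.0, 1400.0))
            if min(abs(mz_bg - fmz) for fmz in transitions.fragment_mzs) < 0.2:
                continue
            points.append((mz_bg, float(rng.lognormal(math.log(500.0), 0.5))))
        if spike_scale > 0:
            for fmz in transitions.fragment_mzs:
                for _ in range(3):
                    points.append((
                        fmz + float(rng.uniform(-0.02, 0.02)),
                        float(spike_scale
                              * rng.lognormal(math.log(2e4), 0.3))))
        points.sort()
        return points

    traces = {"spiked": make_trace(1.0), "blank": make_trace(0.0)}
    mrm_samples: dict[str, list[tuple[float, float]]] = {}
    control_ids = [f"untreated_{i}" for i in (1, 2, 3)]
    for sid in control_ids:
        mrm_samples[sid] = make_trace(float(rng.uniform(0.8, 1.2)))
    for i in (1, 2, 3):
        mrm_samples[f"fc5_treated_{i}"] = make_trace(float(rng.uniform(3.0, 6.0)))

    psms = generate_psm_table(config)

    return ExperimentBundle(
        config=config, proteins=proteins, sequences=sequences,
        emv_ions=emv_ions, wce_ions=wce_ions, peptide_map=peptide_map,
        band_bounds=band_bounds, band_assignments=assignments,
        marker_families=marker_families, identified=identified,
        method_lists=method_lists, emv_surface=emv_surface,
        target_surface=target_surface, edges=edges_set,
        transitions=transitions, traces=traces, mrm_samples=mrm_samples,
        mrm_control_ids=control_ids, psms=psms)


def write_bundle(bundle: ExperimentBundle, outdir: str | Path) -> Path:
    """Serialize a bundle into the documented dialects plus a ready-to-run
    pipeline config; returns the config path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_psm_table(bundle.psms, out / "psms.tsv")
    write_fasta(sorted(bundle.sequences.items()), out / "proteins.fasta")
    write_protein_table(bundle.proteins, out / "proteins.tsv")
    write_ion_table(bundle.emv_ions, out / "emv_ions.tsv")
    write_ion_table(bundle.wce_ions, out / "wce_ions.tsv")
    write_peptide_map(bundle.peptide_map, out / "peptide_map.tsv")
    write_band_bounds(bundle.band_bounds, out / "band_bounds.tsv")
    write_band_assignments(bundle.band_assignments,
                           out / "band_assignments.tsv")
    write_catalog(bundle.marker_families, out / "markers.tsv")
    write_catalog(sorted(bundle.identified), out / "identified.tsv")
    for name, members in bundle.method_lists.items():
        write_catalog(sorted(members), out / f"method_{name}.tsv")
    write_catalog(sorted(bundle.emv_surface), out / "emv_surface.tsv")
    write_catalog(sorted(bundle.target_surface), out / "target_surface.tsv")
    write_edge_list(bundle.edges, out / "edges.tsv")
    traces_dir = out / "traces"
    traces_dir.mkdir(exist_ok=True)
    for sid, trace in {**bundle.traces, **bundle.mrm_samples}.items():
        write_trace_table(trace, traces_dir / f"{sid}.tsv")
    t = bundle.transitions
    with open(out / "transitions.yaml", "w") as fh:
        yaml.safe_dump({
            "precursor_mz": t.precursor_mz, "peptide": t.peptide,
            "fragment_mzs": t.fragment_mzs, "tolerance_da": t.tolerance_da,
        }, fh, sort_keys=True)
    config = {
        "seed": bundle.config.seed,
        "output_dir": "pipeline_out",
        "stages": {s: True for s in ("filter", "quant", "gel_bands",
                                     "enrichment", "interactome", "mrm")},
        "filter": {"psm_table": "psms.tsv", "fpr_max": 0.005,
                   "score_grid": list(range(10, 85, 5)), "optimize": True},
        "quant": {"emv_ions": "emv_ions.tsv", "wce_ions": "wce_ions.tsv",
                  "peptide_map": "peptide_map.tsv", "markers": "markers.tsv",
                  "include_unassigned": True},
        "gel_bands": {"band_assignments": "band_assignments.tsv",
                      "band_bounds": "band_bounds.tsv",
                      "proteins": "proteins.tsv"},
        "enrichment": {
            "method_lists": {name: f"method_{name}.tsv"
                             for name in bundle.method_lists},
            "identified": "identified.tsv", "markers": "markers.tsv",
            "proteins": "proteins.tsv", "category": PLANTED_CATEGORY,
            "B": 100},
        "interactome": {"emv_surface": "emv_surface.tsv",
                        "target_surface": "target_surface.tsv",
                        "edges": "edges.tsv"},
        "mrm": {"traces": {sid: f"traces/{sid}.tsv"
                           for sid in sorted(bundle.mrm_samples)},
                "detection_traces": {sid: f"traces/{sid}.tsv"
                                     for sid in sorted(bundle.traces)},
                "control_ids": bundle.mrm_control_ids,
                "transitions": "transitions.yaml",
                "min_fragments_matched": 3},
    }
    config_path = out / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
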
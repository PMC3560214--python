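# emvprofiler

Downstream computational characterization of extracellular microvesicle
(EMV) proteomes, built for the analyses that follow a shotgun-proteomics
study of vesicles shed by brain endothelial cells: deciding which
peptide-spectrum matches (PSMs) to trust, asking how much of the MS signal
known exosome markers carry, whether the cargo is intact or degraded,
whether functional categories are over-represented, which surface proteins
could couple vesicles to target cells, and how much of a targeted analyte a
sample contains.

It is aimed at proteomics bioinformaticians who have search-engine exports,
ion-feature tables and marker catalogs in hand and want the downstream
statistics to be explicit, testable and reproducible — including on
synthetic data with planted ground truth.

## What it computes

**Target-decoy filtering.** For a composite forward+reverse database
search, the false-positive rate of a retained PSM set is estimated as

```
FPR = 2·N_rev / (N_rev + N_fwd)
```

The filter cascade gates on ion score (strict, default > 40), absolute
parent mass error (< 0.1 Da), fragment mass error (< 0.2 Da), missed
cleavages (≤ 1) and peptide probability (≥ 0.90). The ion-score threshold
is then chosen to maximize the number of retained forward peptides subject
to FPR ≤ 0.5%.

**Signal-fraction quantification.** The MS signal of a protein group is
the summed intensity of ions whose peptides map into the group; the total
is the summed intensity of every ion in the run. Marker enrichment between
two runs is reported both as the plain fraction ratio and as the odds
ratio `(f₁/(1−f₁))/(f₂/(1−f₂))`, which exactly inverts a uniform per-protein
fold change. Small-sample group comparisons use an exact (fully enumerated)
two-sided Mann–Whitney U test with midranks.

**Gel-band MW concordance.** Proteins identified in an SDS-PAGE band are
classified against the band's observed MW window (log-linear marker-lane
interpolation): above it → degraded/truncated, below → potentially
modified, inside → concordant; per band and overall, the percentage of MS
signal in each class is reported.

**Overlap and over-representation.** Exact 2-/3-set Venn region counts,
marker-family overlap, and a permutation over-representation test: B
random same-size lists drawn from a reference proteome, with the add-one
empirical p-value `(1 + #{null ≥ obs})/(B + 1)` (floor 1/(B+1) ≈ 0.0099 at
the default B = 100).

**Surface interactomics.** Given two surface proteomes and a PPI edge
list, counts distinct unordered cross-surface pairs and the number of
partnered proteins on each side.

**MRM quantification.** Extracts signature-fragment signal from transition
traces within ±0.05 Da (default), calls presence from the number of
matched fragments, and normalizes to the median untreated-control signal.
The pinned default target is the FC5 signature peptide ITWGGDNTFYSNSVK
(precursor m/z 844.92; fragments 534.48, 729.47, 737.89, 1288.44).

## Worked example

Every stage runs on synthetic fixtures with planted ground truth:

```python
from emvprofiler import SimConfig, generate_emv_experiment, \
    generate_psm_table, optimize_thresholds
from emvprofiler.quant import signal_fraction, fold_enrichment
from emvprofiler.gel_bands import assemble_bands, overall_degraded_pct

psms = generate_psm_table(SimConfig(seed=42, n_forward_psms=5000,
                                    decoy_fraction=0.5))
res = optimize_thresholds(psms, fpr_max=0.005, grid=range(10, 85, 5))
print(f"ion score > {res.thresholds_used.min_ion_score:.0f}: "
      f"{res.n_fwd_peptides} forward peptides retained, "
      f"FPR = {100*res.fpr:.2f}%")

bundle = generate_emv_experiment(SimConfig(seed=7))   # enrichment 3.3 planted
markers = set(bundle.marker_families)
emv = signal_fraction(bundle.emv_ions, bundle.peptide_map, markers, "emv")
wce = signal_fraction(bundle.wce_ions, bundle.peptide_map, markers, "wce")
print(f"marker signal fraction: EMV {100*emv.fraction:.1f}%, "
      f"whole-cell {100*wce.fraction:.1f}%, "
      f"fold enrichment {fold_enrichment(emv, wce):.2f}")

mw = {p.accession: p.theoretical_mw_kda for p in bundle.proteins}
bands = assemble_bands(bundle.band_assignments, mw, bundle.band_bounds)
print(f"degraded/truncated MS signal across the gel lane: "
      f"{overall_degraded_pct(bands):.1f}%")
```

prints

```
ion score > 45: 2597 forward peptides retained, FPR = 0.38%
marker signal fraction: EMV 26.2%, whole-cell 9.4%, fold enrichment 3.44
degraded/truncated MS signal across the gel lane: 19.8%
```

The optimizer lands on a threshold that keeps the decoy-estimated FPR under
the 0.5% ceiling; the odds-ratio fold recovers the planted 3.3-fold marker
enrichment; the gel-lane analysis recovers the planted 20% degraded share.

The same works from the shell:

```sh
emvprofiler simulate --seed 7 --outdir exp/
emvprofiler run --config exp/config.yaml      # writes exp/pipeline_out/report.json
```

Each stage also has its own subcommand (`filter`, `quantify`, `gel-bands`,
`venn`, `overrep`, `interactome`, `mrm`); see `emvprofiler --help`.

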
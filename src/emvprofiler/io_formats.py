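"""Readers and writers for every file the pipeline touches.

All tabular dialects are tab-separated UTF-8 with a required header row and
"." as the decimal mark. Molecular weights are kept in kDa everywhere inside
the package; any Da input is converted at the boundary.

Dialects
--------
PSM table      : spectrum_id, peptide, proteins (";"-joined), ion_score,
                 parent_error_da, fragment_error_da, missed_cleavages,
                 charge, probability.  Unknown extra columns are preserved
                 on a round trip.
Ion table      : mz, charge, rt_min, intensity, peptide (empty allowed).
Edge list      : protein_a, protein_b.
Catalog        : identifier [, category].
Trace table    : mz, intensity [, rt_min].
Peptide map    : peptide, proteins (";"-joined).
Band assignment: accession, band_index, ms_signal.
Band bounds    : band_index, mw_lower_kda, mw_upper_kda.
MW table       : accession, theoretical_mw_kda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._constants import (
    AVERAGE_RESIDUE_MASS_DA,
    CANONICAL_AA,
    FASTA_AA,
    MS1_MZ_MAX,
    MS1_MZ_MIN,
    WATER_MASS_DA,
)

logger = logging.getLogger(__name__)

#: accession prefix marking reverse-database (decoy) entries
DECOY_PREFIX = "REV_"


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


class RowError(FormatError):
    """A single data row violates a field invariant."""

    def __init__(self, message: str, line: int, column: str | None = None):
        self.line = line
        self.column = column
        super().__init__(f"line {line}: {message}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PSMRecord:
    """One peptide-spectrum match as exported by a database search engine."""

    spectrum_id: str
    peptide: str
    proteins: list[str]
    ion_score: float
    parent_error_da: float
    fragment_error_da: float
    missed_cleavages: int
    charge: int
    probability: float
    is_decoy: bool = False
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("peptide must be non-empty")
        if not self.proteins:
            raise ValueError("proteins must be non-empty")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")


@dataclass
class IonFeature:
    """One MS1 ion feature (m/z, charge, retention time, intensity)."""

    mz: float
    charge: int
    rt: float
    intensity: float
    peptide: str | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("mz must be positive")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if not (self.intensity >= 0):  # also rejects NaN
            raise ValueError("intensity must be finite and non-negative")


@dataclass
class ProteinEntry:
    """A protein with the annotations the downstream stages consume."""

    accession: str
    gene_symbol: str
    family_symbol: str
    theoretical_mw_kda: float
    is_surface: bool = False
    categories: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.theoretical_mw_kda <= 0:
            raise ValueError("theoretical_mw_kda must be positive")
        if not self.family_symbol:
            raise ValueError("family_symbol must be non-empty")


@dataclass
class TransitionSet:
    """Precursor and signature fragment m/z values for one target peptide."""

    precursor_mz: float
    peptide: str
    fragment_mzs: list[float]
    tolerance_da: float

    def __post_init__(self) -> None:
        if not self.fragment_mzs:
            raise ValueError("fragment_mzs must be non-empty")
        if self.tolerance_da <= 0:
            raise ValueError("tolerance_da must be positive")
        # canonical order: sorted, duplicates removed
        self.fragment_mzs = sorted(set(float(m) for m in self.fragment_mzs))
        if any(m <= 0 for m in self.fragment_mzs):
            raise ValueError("fragment m/z values must be positive")


# ---------------------------------------------------------------------------
# generic TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing column '{col}' in {path.name}")
    return df


def _num(value: str, column: str, line: int, kind=float):
    try:
        return kind(value)
    except (TypeError, ValueError):
        raise RowError(f"non-numeric value {value!r} in column '{column}'",
                       line=line, column=column) from None


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

PSM_COLUMNS = [
    "spectrum_id", "peptide", "proteins", "ion_score", "parent_error_da",
    "fragment_error_da", "missed_cleavages", "charge", "probability",
]


def is_decoy_accessions(accessions: Iterable[str]) -> bool:
    """A PSM is decoy iff *all* of its accessions are reverse-database hits.

    Mirrors composite forward+reverse searching: a peptide shared with any
    forward protein is a forward identification.
    """
    accs = list(accessions)
    return bool(accs) and all(a.startswith(DECOY_PREFIX) for a in accs)


def read_psm_table(path: str | Path) -> list[PSMRecord]:
    df = _read_tsv(path, PSM_COLUMNS)
    extra_cols = [c for c in df.columns if c not in PSM_COLUMNS]
    records: list[PSMRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        proteins = [p for p in str(r["proteins"]).split(";") if p]
        if not proteins:
            raise RowError("empty 'proteins' field", line, "proteins")
        charge = _num(r["charge"], "charge", line, int)
        if charge not in (2, 3, 4):
            raise RowError(f"invalid value {charge} in column 'charge' "
                           "(allowed: 2, 3, 4)", line, "charge")
        mc = _num(r["missed_cleavages"], "missed_cleavages", line, int)
        if mc < 0:
            raise RowError("negative missed_cleavages", line, "missed_cleavages")
        prob = _num(r["probability"], "probability", line)
        if not 0.0 <= prob <= 1.0:
            raise RowError(f"probability {prob} outside [0, 1]", line, "probability")
        score = _num(r["ion_score"], "ion_score", line)
        if score < 0:
            raise RowError("negative ion_score", line, "ion_score")
        frag = _num(r["fragment_error_da"], "fragment_error_da", line)
        if frag < 0:
            raise RowError("negative fragment_error_da", line, "fragment_error_da")
        records.append(PSMRecord(
            spectrum_id=str(r["spectrum_id"]),
            peptide=str(r["peptide"]),
            proteins=proteins,
            ion_score=score,
            parent_error_da=_num(r["parent_error_da"], "parent_error_da", line),
            fragment_error_da=frag,
            missed_cleavages=mc,
            charge=charge,
            probability=prob,
            is_decoy=is_decoy_accessions(proteins),
            extras={c: str(r[c]) for c in extra_cols},
        ))
    return records


def write_psm_table(records: Sequence[PSMRecord], path: str | Path) -> None:
    extra_cols: list[str] = []
    for rec in records:
        for c in rec.extras:
            if c not in extra_cols:
                extra_cols.append(c)
    rows = []
    for rec in records:
        row = {
            "spectrum_id": rec.spectrum_id,
            "peptide": rec.peptide,
            "proteins": ";".join(rec.proteins),
            "ion_score": repr(rec.ion_score),
            "parent_error_da": repr(rec.parent_error_da),
            "fragment_error_da": repr(rec.fragment_error_da),
            "missed_cleavages": rec.missed_cleavages,
            "charge": rec.charge,
            "probability": repr(rec.probability),
        }
        for c in extra_cols:
            row[c] = rec.extras.get(c, "")
        rows.append(row)
    pd.DataFrame(rows, columns=PSM_COLUMNS + extra_cols).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a protein FASTA; accession = first token of the header line."""
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        seq = str(rec.seq).upper().replace(" ", "")
        bad = set(seq) - FASTA_AA
        if bad:
            raise FormatError(
                f"record '{accession}': non-amino-acid letter(s) "
                f"{sorted(bad)} in sequence")
        if accession in seen:
            raise FormatError(f"duplicate accession '{accession}'")
        seen.add(accession)
        out.append((accession, seq))
    return out


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for acc, seq in records:
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def compute_theoretical_mw(sequence: str) -> float:
    """Theoretical molecular weight of a protein sequence in kDa.

    Sum of average residue masses plus one water, using the pinned mass
    table. Raises on an empty sequence or any letter outside the 20
    canonical amino acids (including X, whose mass is undefined).
    """
    if not sequence:
        raise ValueError("empty sequence has no molecular weight")
    total = WATER_MASS_DA
    for letter in sequence:
        try:
            total += AVERAGE_RESIDUE_MASS_DA[letter]
        except KeyError:
            raise ValueError(f"unknown amino-acid letter '{letter}'") from None
    return total / 1000.0


def mw_table_from_fasta(records: Iterable[tuple[str, str]]) -> dict[str, float]:
    """Accession -> theoretical MW (kDa); X-containing sequences are skipped
    with a warning since their mass is undefined."""
    out: dict[str, float] = {}
    for acc, seq in records:
        if "X" in seq:
            logger.warning("excluding %s from MW table: sequence contains X", acc)
            continue
        out[acc] = compute_theoretical_mw(seq)
    return out


# ---------------------------------------------------------------------------
# ion features
# ---------------------------------------------------------------------------

def read_ion_table(path: str | Path) -> list[IonFeature]:
    df = _read_tsv(path, ["mz", "charge", "rt_min", "intensity", "peptide"])
    ions: list[IonFeature] = []
    for i, r in enumerate(df.to_dict("records")):
        line = i + 2
        intensity = _num(r["intensity"], "intensity", line)
        if intensity < 0:
            raise RowError("negative intensity", line, "intensity")
        mz = _num(r["mz"], "mz", line)
        if mz <= 0:
            raise RowError("non-positive mz", line, "mz")
        pep = str(r["peptide"]) or None
        ions.append(IonFeature(
            mz=mz,
            charge=_num(r["charge"], "charge", line, int),
            rt=_num(r["rt_min"], "rt_min", line),
            intensity=intensity,
            peptide=pep,
        ))
    return ions


def write_ion_table(ions: Sequence[IonFeature], path: str | Path) -> None:
    pd.DataFrame(
        [{"mz": repr(i.mz), "charge": i.charge, "rt_min": repr(i.rt),
          "intensity": repr(i.intensity), "peptide": i.peptide or ""}
         for i in ions],
        columns=["mz", "charge", "rt_min", "intensity", "peptide"],
    ).to_csv(path, sep="\t", index=False)


def read_mzml_ions(path: str | Path,
                   mz_min: float = MS1_MZ_MIN,
                   mz_max: float = MS1_MZ_MAX) -> list[IonFeature]:
    """Map MS1 centroid peaks of an mzML file to :class:`IonFeature`.

    Only peaks inside the acquisition window [mz_min, mz_max] are kept,
    matching a survey scan acquired on m/z 400-2000. Charge is unknown at
    the centroid level and is reported as 1. Supports 32/64-bit float
    arrays, raw or zlib-compressed.
    """
    import base64
    import struct
    import zlib

    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"

    def decode(array_el) -> tuple[str | None, list[float]]:
        fmt, compressed, kind = "d", False, None
        b64 = ""
        for cv in array_el.iter(ns + "cvParam"):
            acc = cv.get("accession")
            if acc == "MS:1000521":
                fmt = "f"
            elif acc == "MS:1000523":
                fmt = "d"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        binary = array_el.find(ns + "binary")
        if binary is not None and binary.text:
            b64 = binary.text.strip()
        raw = base64.b64decode(b64) if b64 else b""
        if compressed and raw:
            raw = zlib.decompress(raw)
        size = struct.calcsize(fmt)
        values = list(struct.unpack(f"<{len(raw) // size}{fmt}", raw))
        return kind, values

    ions: list[IonFeature] = []
    for _, spectrum in etree.iterparse(str(path), tag=ns + "spectrum"):
        ms_level = None
        rt = 0.0
        for cv in spectrum.iter(ns + "cvParam"):
            if cv.get("accession") == "MS:1000511":
                ms_level = int(cv.get("value"))
            elif cv.get("accession") == "MS:1000016":
                rt = float(cv.get("value"))
        if ms_level == 1:
            arrays: dict[str, list[float]] = {}
            for array_el in spectrum.iter(ns + "binaryDataArray"):
                kind, values = decode(array_el)
                if kind:
                    arrays[kind] = values
            for mz, inten in zip(arrays.get("mz", []),
                                 arrays.get("intensity", [])):
                if mz_min <= mz <= mz_max and inten > 0:
                    ions.append(IonFeature(mz=float(mz), charge=1, rt=rt,
                                           intensity=float(inten)))
        spectrum.clear()
    return ions


# ---------------------------------------------------------------------------
# edge lists, catalogs, traces, small mapping tables
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> set[frozenset[str]]:
    df = _read_tsv(path, ["protein_a", "protein_b"])
    edges: set[frozenset[str]] = set()
    for i, r in enumerate(df.to_dict("records")):
        a, b = str(r["protein_a"]), str(r["protein_b"])
        if not a or not b:
            raise RowError("empty accession in edge", i + 2)
        edges.add(frozenset((a, b)))
    return edges


def write_edge_list(edges: Iterable[tuple[str, str] | frozenset],
                    path: str | Path) -> None:
    rows = []
    for e in edges:
        pair = sorted(e)
        if len(pair) == 1:  # self-edge
            pair = pair * 2
        rows.append({"protein_a": pair[0], "protein_b": pair[1]})
    rows.sort(key=lambda r: (r["protein_a"], r["protein_b"]))
    pd.DataFrame(rows, columns=["protein_a", "protein_b"]).to_csv(
        path, sep="\t", index=False)


def read_catalog(path: str | Path) -> dict[str, str | None]:
    """Identifier catalog, optionally with a category column.

    Returns identifier -> category (None when absent). Duplicate
    identifiers are deduplicated; the count is logged.
    """
    df = _read_tsv(path, ["identifier"])
    has_cat = "category" in df.columns
    out: dict[str, str | None] = {}
    dupes = 0
    for r in df.to_dict("records"):
        ident = str(r["identifier"])
        if ident in out:
            dupes += 1
            continue
        out[ident] = (str(r["category"]) or None) if has_cat else None
    if dupes:
        logger.info("catalog %s: deduplicated %d duplicate entries",
                    Path(path).name, dupes)
    return out


def write_catalog(entries: Mapping[str, str | None] | Iterable[str],
                  path: str | Path) -> None:
    if isinstance(entries, Mapping):
        items = sorted(entries.items())
        has_cat = any(v is not None for _, v in items)
        if has_cat:
            df = pd.DataFrame(
                [{"identifier": k, "category": v or ""} for k, v in items])
        else:
            df = pd.DataFrame([{"identifier": k} for k, _ in items])
    else:
        df = pd.DataFrame([{"identifier": k} for k in sorted(entries)])
    df.to_csv(path, sep="\t", index=False)


def read_trace_table(path: str | Path) -> list[tuple[float, float]]:
    """MRM trace: list of (m/z, intensity) points; optional rt_min ignored
    here (see :func:`read_trace_table_rt`)."""
    df = _read_tsv(path, ["mz", "intensity"])
    points = []
    for i, r in enumerate(df.to_dict("records")):
        line = i + 2
        inten = _num(r["intensity"], "intensity", line)
        if inten < 0:
            raise RowError("negative intensity", line, "intensity")
        points.append((_num(r["mz"], "mz", line), inten))
    return points


def read_trace_table_rt(path: str | Path) -> list[tuple[float, float, float]]:
    """MRM trace with a retention-time column: (m/z, intensity, rt_min)."""
    df = _read_tsv(path, ["mz", "intensity", "rt_min"])
    return [(_num(r["mz"], "mz", i + 2), _num(r["intensity"], "intensity", i + 2),
             _num(r["rt_min"], "rt_min", i + 2))
            for i, r in enumerate(df.to_dict("records"))]


def write_trace_table(points: Sequence[tuple[float, float]],
                      path: str | Path) -> None:
    pd.DataFrame([{"mz": repr(p[0]), "intensity": repr(p[1])} for p in points],
                 columns=["mz", "intensity"]).to_csv(path, sep="\t", index=False)


def read_peptide_map(path: str | Path) -> dict[str, set[str]]:
    df = _read_tsv(path, ["peptide", "proteins"])
    out: dict[str, set[str]] = {}
    for r in df.to_dict("records"):
        accs = {p for p in str(r["proteins"]).split(";") if p}
        out.setdefault(str(r["peptide"]), set()).update(accs)
    return out


def write_peptide_map(mapping: Mapping[str, Iterable[str]],
                      path: str | Path) -> None:
    pd.DataFrame(
        [{"peptide": pep, "proteins": ";".join(sorted(accs))}
         for pep, accs in sorted(mapping.items())],
        columns=["peptide", "proteins"],
    ).to_csv(path, sep="\t", index=False)


def read_band_assignments(path: str | Path) -> list[tuple[str, int, float]]:
    df = _read_tsv(path, ["accession", "band_index", "ms_signal"])
    rows = []
    for i, r in enumerate(df.to_dict("records")):
        line = i + 2
        sig = _num(r["ms_signal"], "ms_signal", line)
        if sig < 0:
            raise RowError("negative ms_signal", line, "ms_signal")
        rows.append((str(r["accession"]),
                     _num(r["band_index"], "band_index", line, int), sig))
    return rows


def write_band_assignments(rows: Sequence[tuple[str, int, float]],
                           path: str | Path) -> None:
    pd.DataFrame(
        [{"accession": a, "band_index": b, "ms_signal": repr(s)}
         for a, b, s in rows],
        columns=["accession", "band_index", "ms_signal"],
    ).to_csv(path, sep="\t", index=False)


def read_band_bounds(path: str | Path) -> dict[int, tuple[float, float]]:
    df = _read_tsv(path, ["band_index", "mw_lower_kda", "mw_upper_kda"])
    out: dict[int, tuple[float, float]] = {}
    for i, r in enumerate(df.to_dict("records")):
        line = i + 2
        lo = _num(r["mw_lower_kda"], "mw_lower_kda", line)
        hi = _num(r["mw_upper_kda"], "mw_upper_kda", line)
        if not 0 < lo < hi:
            raise RowError(f"invalid MW bounds ({lo}, {hi})", line)
        out[_num(r["band_index"], "band_index", line, int)] = (lo, hi)
    return out


def write_band_bounds(bounds: Mapping[int, tuple[float, float]],
                      path: str | Path) -> None:
    pd.DataFrame(
        [{"band_index": k, "mw_lower_kda": repr(v[0]), "mw_upper_kda": repr(v[1])}
         for k, v in sorted(bounds.items())],
        columns=["band_index", "mw_lower_kda", "mw_upper_kda"],
    ).to_csv(path, sep="\t", index=False)


def read_protein_table(path: str | Path) -> list[ProteinEntry]:
    """Protein annotation table: accession, gene_symbol, family_symbol,
    theoretical_mw_kda, is_surface (0/1), categories (";"-joined)."""
    df = _read_tsv(path, ["accession", "gene_symbol", "family_symbol",
                          "theoretical_mw_kda", "is_surface", "categories"])
    out: list[ProteinEntry] = []
    seen: set[str] = set()
    for i, r in enumerate(df.to_dict("records")):
        line = i + 2
        acc = str(r["accession"])
        if acc in seen:
            raise RowError(f"duplicate accession '{acc}'", line, "accession")
        seen.add(acc)
        mw = _num(r["theoretical_mw_kda"], "theoretical_mw_kda", line)
        surf = _num(r["is_surface"], "is_surface", line, int)
        cats = {c for c in str(r["categories"]).split(";") if c}
        out.append(ProteinEntry(
            accession=acc, gene_symbol=str(r["gene_symbol"]),
            family_symbol=str(r["family_symbol"]), theoretical_mw_kda=mw,
            is_surface=bool(surf), categories=cats))
    return out


def write_protein_table(proteins: Sequence[ProteinEntry],
                        path: str | Path) -> None:
    pd.DataFrame(
        [{"accession": p.accession, "gene_symbol": p.gene_symbol,
          "family_symbol": p.family_symbol,
          "theoretical_mw_kda": repr(p.theoretical_mw_kda),
          "is_surface": int(p.is_surface),
          "categories": ";".join(sorted(p.categories))}
         for p in proteins],
        columns=["accession", "gene_symbol", "family_symbol",
                 "theoretical_mw_kda", "is_surface", "categories"],
    ).to_csv(path, sep="\t", index=False)


def read_mw_table(path: str | Path) -> dict[str, float]:
    df = _read_tsv(path, ["accession", "theoretical_mw_kda"])
    out = {}
    for i, r in enumerate(df.to_dict("records")):
        mw = _num(r["theoretical_mw_kda"], "theoretical_mw_kda", i + 2)
        if mw <= 0:
            raise RowError("non-positive theoretical_mw_kda", i + 2)
        out[str(r["accession"])] = mw
    return out


def write_mw_table(mws: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        [{"accession": a, "theoretical_mw_kda": repr(m)}
         for a, m in sorted(mws.items())],
        columns=["accession", "theoretical_mw_kda"],
    ).to_csv(path, sep="\t", index=False)
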
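"""Pinned physical constants.

Average (not monoisotopic) residue masses are used throughout because the
downstream use case is concordance with SDS-PAGE migration, which reflects
the average isotopic composition of a bulk protein population.

Masses are average masses of amino-acid *residues* (monomer minus water) in
daltons, from the standard IUPAC atomic-weight-based table used by common
proteomics mass calculators.
"""

#: average residue masses, Da
AVERAGE_RESIDUE_MASS_DA: dict[str, float] = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

#: average mass of one water molecule, Da (added once per peptide chain)
WATER_MASS_DA: float = 18.0153

#: canonical amino-acid alphabet
CANONICAL_AA = frozenset(AVERAGE_RESIDUE_MASS_DA)

#: FASTA letters tolerated on input; X has no defined mass
FASTA_AA = CANONICAL_AA | {"X"}

# Signature-peptide transition set for the blood-brain-barrier-crossing
# single-domain antibody FC5, monitored by SRM/MRM.
FC5_PEPTIDE = "ITWGGDNTFYSNSVK"
FC5_PRECURSOR_MZ = 844.92
FC5_FRAGMENT_MZS = (534.48, 729.47, 737.89, 1288.44)

#: default fragment-matching tolerance for MRM trace extraction, Da
DEFAULT_MRM_TOLERANCE_DA = 0.05

#: MS1 acquisition m/z window used when ingesting mzML centroids
MS1_MZ_MIN = 400.0
MS1_MZ_MAX = 2000.0
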
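"""Biochemical protein properties: length, molecular weight, theoretical pI, GRAVY.

Molecular weight uses average (not monoisotopic) residue masses plus one
water, the peptide-bond convention behind the kDa values protein-analysis
servers report.  The isoelectric point solves the Henderson–Hasselbalch net
charge for zero by bisection using the Bjellqvist pKa set (bundled as a TSV
so an alternative table, e.g. EMBOSS, can be substituted).  GRAVY is the
mean Kyte–Doolittle hydropathy index.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

WATER_MASS = 18.0153

# average residue masses, Da (monomer mass minus water)
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class PkaTable:
    nterm: dict[str, float]
    cterm: dict[str, float]
    positive: dict[str, float]
    negative: dict[str, float]


def load_pka_table(path: str | Path | None = None) -> PkaTable:
    """Load a pKa TSV (columns: group, residue, pka); default is Bjellqvist."""
    if path is None:
        source = resources.files("gfam.data").joinpath("bjellqvist_pka.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    groups: dict[str, dict[str, float]] = {"nterm": {}, "cterm": {}, "positive": {}, "negative": {}}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        groups[row["group"]][row["residue"]] = float(row["pka"])
    return PkaTable(**groups)


_DEFAULT_PKA = load_pka_table()


@dataclass(frozen=True)
class ProteinProperties:
    protein_id: str
    length: int
    mol_weight: float
    pI: float
    gravy: float


def _check_canonical(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    for i, aa in enumerate(sequence):
        if aa not in AVERAGE_RESIDUE_MASS:
            raise ValueError(f"non-canonical residue {aa!r} at position {i}")


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water."""
    _check_canonical(sequence)
    return sum(AVERAGE_RESIDUE_MASS[aa] for aa in sequence) + WATER_MASS


def net_charge(sequence: str, ph: float, pka: PkaTable = _DEFAULT_PKA) -> float:
    """Henderson–Hasselbalch net charge at a given pH.

    Ionizable groups: the termini plus D, E, C, Y (acidic) and H, K, R
    (basic).  Monotone decreasing in pH, so the pI root is unique.
    """
    _check_canonical(sequence)
    nterm_pka = pka.nterm.get(sequence[0], pka.nterm["default"])
    cterm_pka = pka.cterm.get(sequence[-1], pka.cterm["default"])
    charge = 1.0 / (1.0 + 10.0 ** (ph - nterm_pka))
    charge -= 1.0 / (1.0 + 10.0 ** (cterm_pka - ph))
    for aa, aa_pka in pka.positive.items():
        charge += sequence.count(aa) / (1.0 + 10.0 ** (ph - aa_pka))
    for aa, aa_pka in pka.negative.items():
        charge -= sequence.count(aa) / (1.0 + 10.0 ** (aa_pka - ph))
    return charge


def isoelectric_point(sequence: str, pka: PkaTable = _DEFAULT_PKA) -> float:
    """pH at which the net charge crosses zero, found by bisection in [0, 14]."""
    _check_canonical(sequence)
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-3:
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pka)
        if abs(q) < 1e-4:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle index over residues."""
    _check_canonical(sequence)
    return sum(KYTE_DOOLITTLE[aa] for aa in sequence) / len(sequence)


def protein_properties(protein_id: str, sequence: str) -> ProteinProperties:
    return ProteinProperties(
        protein_id=protein_id,
        length=len(sequence),
        mol_weight=molecular_weight(sequence),
        pI=isoelectric_point(sequence),
        gravy=gravy(sequence),
    )
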
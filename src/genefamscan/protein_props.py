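"""Per-protein physicochemical descriptors.

For each family member: residue count, average-isotopic molecular mass,
isoelectric point (pI), CDS length and GRAVY (grand average of
hydropathicity: the mean Kyte-Doolittle hydropathy over all residues;
negative values mean a hydrophilic protein).

pI is solved by bisection on the Henderson-Hasselbalch net-charge
function over the ionizable groups (D, E, C, Y, H, K, R and the two
termini).  The net charge is strictly decreasing in pH so the root in
(0, 14) is unique.  Two pKa sets are shipped: "bjellqvist" (default,
the set behind the common web protein-parameter calculators) and
"emboss".  Different published pKa sets move pI by up to ~0.2 pH units,
so second-decimal agreement with other tools is not guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from genefamscan.io_formats import get_logger

logger = get_logger(__name__)

#: Average (not monoisotopic) residue masses in Da, matching the
#: protein-parameter convention; free-peptide mass adds one water.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: pKa sets: (positive groups incl. N-terminus, negative groups incl. C-terminus)
PKA_SETS: dict[str, dict[str, float]] = {
    "bjellqvist": {
        "Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98,
        "Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    },
    "emboss": {
        "Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5,
        "Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
}

_STOP_CODONS = set(standard_dna_table.stop_codons)


@dataclass
class ProteinProperties:
    gene_id: str
    n_residues: int
    mol_mass: float
    pI: float
    cds_length: int
    gravy: float

    @property
    def hydropathy_class(self) -> str:
        return "hydrophilic" if self.gravy < 0 else "hydrophobic"


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    The terminal stop codon is stripped; an internal stop is an error;
    codons containing N translate to X.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if len(cds) == 0:
        raise ValueError("empty CDS")
    residues = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in _STOP_CODONS:
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon {codon} at codon {i + 1}")
        if "N" in codon:
            residues.append("X")
        else:
            try:
                residues.append(standard_dna_table.forward_table[codon])
            except KeyError:
                raise ValueError(f"invalid codon {codon!r} at codon {i + 1}")
    return "".join(residues)


def gravy(protein: str) -> float:
    """Mean Kyte-Doolittle hydropathy.  X residues are excluded from
    both the sum and the count (GRAVY is a mean, robust to exclusion)."""
    if not protein:
        raise ValueError("empty protein")
    total, n = 0.0, 0
    n_skipped = 0
    for residue in protein.upper():
        if residue == "X":
            n_skipped += 1
            continue
        if residue not in KYTE_DOOLITTLE:
            raise ValueError(f"residue {residue!r} not in hydropathy table")
        total += KYTE_DOOLITTLE[residue]
        n += 1
    if n_skipped:
        logger.info("gravy: excluded %d X residues", n_skipped)
    if n == 0:
        raise ValueError("no scorable residues")
    return total / n


def molecular_weight(protein: str) -> float:
    """Sum of average residue masses plus one water.  Unknown residues
    (including X) are an error: a sum is not robust to exclusion."""
    if not protein:
        raise ValueError("empty protein")
    mass = WATER_MASS
    for residue in protein.upper():
        try:
            mass += AVERAGE_RESIDUE_MASS[residue]
        except KeyError:
            raise ValueError(f"unknown residue {residue!r} for mass computation")
    return mass


def net_charge(protein: str, pH: float, pka_set: str = "bjellqvist") -> float:
    """Henderson-Hasselbalch net charge at a given pH."""
    pka = PKA_SETS[pka_set]
    seq = protein.upper()
    charge = 1.0 / (1.0 + 10 ** (pH - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - pH))
    for residue, group in (("K", "K"), ("R", "R"), ("H", "H")):
        n = seq.count(residue)
        charge += n / (1.0 + 10 ** (pH - pka[group]))
    for residue, group in (("D", "D"), ("E", "E"), ("C", "C"), ("Y", "Y")):
        n = seq.count(residue)
        charge -= n / (1.0 + 10 ** (pka[group] - pH))
    return charge


def isoelectric_point(
    protein: str, pka_set: str = "bjellqvist", tol: float = 1e-4
) -> float:
    """pH at which the net charge is zero, by bisection on (0, 14)."""
    if not protein:
        raise ValueError("empty protein")
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-9:
        mid = (lo + hi) / 2.0
        q = net_charge(protein, mid, pka_set)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def protein_properties(
    gene_id: str, cds: str, pka_set: str = "bjellqvist"
) -> ProteinProperties:
    """All Table-style descriptors for one gene from its CDS."""
    protein = translate_cds(cds)
    return ProteinProperties(
        gene_id=gene_id,
        n_residues=len(protein),
        mol_mass=molecular_weight(protein),
        pI=isoelectric_point(protein, pka_set),
        cds_length=len(cds),
        gravy=gravy(protein),
    )
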
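"""Protein physicochemistry: translation, MW, pI, GRAVY and MW-rank naming.

Conventions follow the ProtParam web tool: average (not monoisotopic) residue
masses, the Bjellqvist pK set for the isoelectric point, and the
Kyte–Doolittle hydropathy index for GRAVY.  Family members are named
``<prefix>-1 .. <prefix>-n`` in ascending molecular-weight order, the naming
rule used for plant gene families sized by their protein mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "ProteinRecord",
    "translate_cds",
    "molecular_weight",
    "isoelectric_point",
    "net_charge",
    "gravy",
    "assign_family_names",
    "build_protein_records",
]

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"

# Average residue masses (Da), as used by ProtParam.
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER = 18.0153

# Bjellqvist pK values (the set behind ProtParam's "theoretical pI").
PK_SIDE_CHAIN = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0, "H": 5.98, "K": 10.0, "R": 12.0}
PK_C_TERM = 3.55
PK_N_TERM_DEFAULT = 7.5
PK_N_TERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}

# Kyte-Doolittle hydropathy index.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class ProteinRecord:
    """Translated gene product with its Table-style physicochemistry."""

    gene_id: str
    sequence: str
    mw_da: float
    pi: float
    gravy: float
    chromosome: str = ""
    start: int = 0
    family_name: str = ""

    @property
    def aa_count(self) -> int:
        return len(self.sequence)

    @property
    def mw_kda(self) -> float:
        return self.mw_da / 1000.0


def _check_protein(protein: str) -> str:
    if not protein:
        raise ValueError("empty protein sequence")
    protein = protein.upper()
    bad = set(protein) - set(_RESIDUE_MASS)
    if bad:
        raise ValueError(f"unknown or ambiguous residue symbols {sorted(bad)}")
    return protein


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    A terminal stop codon is dropped; an internal stop raises with its codon
    index, as does a length not divisible by 3.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    n_codons = len(cds) // 3
    aas = []
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        aa = _CODON_TO_AA.get(codon)
        if aa is None:
            raise ValueError(f"untranslatable codon {codon!r} at codon index {i}")
        if aa == "*":
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon {codon!r} at codon index {i}")
        aas.append(aa)
    return "".join(aas)


def molecular_weight(protein: str) -> float:
    """Average-mass molecular weight in Da (residue masses + one water)."""
    protein = _check_protein(protein)
    return sum(_RESIDUE_MASS[a] for a in protein) + _WATER


def net_charge(protein: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge at the given pH.

    Positive groups: N-terminus, H, K, R; negative: C-terminus, D, E, C, Y.
    """
    protein = _check_protein(protein)
    pos = 1.0 / (1.0 + 10 ** (ph - PK_N_TERM.get(protein[0], PK_N_TERM_DEFAULT)))
    neg = 1.0 / (1.0 + 10 ** (PK_C_TERM - ph))
    for aa in protein:
        pk = PK_SIDE_CHAIN.get(aa)
        if pk is None:
            continue
        if aa in "HKR":
            pos += 1.0 / (1.0 + 10 ** (ph - pk))
        else:
            neg += 1.0 / (1.0 + 10 ** (pk - ph))
    return pos - neg


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so bisection always converges.
    """
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(200):
        ph = (lo + hi) / 2.0
        q = net_charge(protein, ph)
        if abs(q) < tol:
            return ph
        if q > 0:
            lo = ph
        else:
            hi = ph
    return ph


def gravy(protein: str) -> float:
    """Grand average of hydropathicity: mean Kyte–Doolittle index."""
    protein = _check_protein(protein)
    return sum(_KD[a] for a in protein) / len(protein)


def build_protein_records(
    cds: Mapping[str, str],
    gene_models: Mapping[str, "object"] | None = None,
) -> list[ProteinRecord]:
    """Translate every CDS and compute MW/pI/GRAVY.

    ``gene_models`` (gene_id → GeneModel) supplies chromosome/start for the
    positional tie-break used in naming.
    """
    records = []
    for gid, seq in cds.items():
        prot = translate_cds(seq)
        gm = gene_models.get(gid) if gene_models else None
        records.append(
            ProteinRecord(
                gene_id=gid,
                sequence=prot,
                mw_da=molecular_weight(prot),
                pi=isoelectric_point(prot),
                gravy=gravy(prot),
                chromosome=getattr(gm, "chromosome", ""),
                start=getattr(gm, "start", 0),
            )
        )
    return records


def assign_family_names(records: Sequence[ProteinRecord], prefix: str) -> list[ProteinRecord]:
    """Name records ``<prefix>-1..n`` by ascending molecular weight.

    Ties are broken deterministically by (chromosome, start, gene_id).
    """
    ordered = sorted(records, key=lambda r: (r.mw_da, r.chromosome, r.start, r.gene_id))
    for i, rec in enumerate(ordered, start=1):
        rec.family_name = f"{prefix}-{i}"
    return ordered


def properties_table(records: Sequence[ProteinRecord]) -> "pandas.DataFrame":
    """Report mirroring the family characterization table (MW in kDa, 2 dp)."""
    import pandas as pd

    rows = [
        dict(
            family_name=r.family_name,
            gene_id=r.gene_id,
            chromosome=r.chromosome,
            start=r.start,
            aa=r.aa_count,
            mw_kda=round(r.mw_kda, 2),
            pi=round(r.pi, 2),
            gravy=round(r.gravy, 3),
        )
        for r in records
    ]
    return pd.DataFrame(rows)
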
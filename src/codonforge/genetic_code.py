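"""Genetic-code tables, degeneracy classes, and amino-acid property scales.

Every downstream index (RSCU, ENC, CAI, GRAVY, AROMO, synonymous-position
compositions) is defined relative to a translation table: which codons are
synonymous, how large each synonymous family is, and which families are
informative (degenerate). This module holds that structure plus the
Kyte-Doolittle hydropathy scale and the aromatic indicator used for the
protein-level indices.

Codons are 3-letter uppercase DNA strings (T, not U); RNA input is
normalized on read elsewhere. Stop codons are represented by ``"*"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from Bio.Data import CodonTable

STOP = "*"

#: Kyte-Doolittle hydropathy scale (unitless; positive = hydrophobic).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Aromatic residues (Phe, Tyr, Trp). His is excluded, following the
#: convention of the CodonW aromaticity index.
AROMATIC = frozenset({"F", "Y", "W"})

BASES = "TCAG"
ALL_CODONS = tuple(b1 + b2 + b3 for b1 in BASES for b2 in BASES for b3 in BASES)


class UnsupportedCodeError(ValueError):
    """Raised for an NCBI translation-table id this package cannot load."""


@dataclass(frozen=True)
class AminoAcidScales:
    """Per-residue property scales used by GRAVY and AROMO.

    hydropathy maps each of the 20 amino acids to its Kyte-Doolittle
    index; aromatic maps each amino acid to 1 (Phe/Tyr/Trp) or 0.
    Both maps are swappable for sensitivity analyses.
    """

    hydropathy: dict[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    aromatic: dict[str, int] = field(
        default_factory=lambda: {aa: int(aa in AROMATIC) for aa in KYTE_DOOLITTLE}
    )


@dataclass(frozen=True)
class GeneticCode:
    """A translation table with its synonymous-family structure.

    Attributes
    ----------
    table_id :
        NCBI translation-table id.
    codon_to_aa :
        All 64 codons mapped to a one-letter amino acid or ``"*"`` (stop).
    synonymous_families :
        Amino acid -> sorted list of its codons. The families partition
        the sense codons.
    degeneracy :
        Amino acid -> family size (1, 2, 3, 4 or 6 under the standard code).
    """

    table_id: int
    codon_to_aa: dict[str, str]
    synonymous_families: dict[str, list[str]]
    degeneracy: dict[str, int]

    @property
    def stop_codons(self) -> list[str]:
        return sorted(c for c, aa in self.codon_to_aa.items() if aa == STOP)

    @property
    def sense_codons(self) -> list[str]:
        return sorted(c for c, aa in self.codon_to_aa.items() if aa != STOP)

    @property
    def start_codons(self) -> list[str]:
        return list(self._start_codons)

    def translate(self, seq: str) -> str:
        """Translate an in-frame DNA string; stops render as ``*``."""
        if len(seq) % 3:
            raise ValueError(f"sequence length {len(seq)} not divisible by 3")
        return "".join(self.codon_to_aa[seq[i:i + 3]] for i in range(0, len(seq), 3))


def load_code(table_id: int = 1) -> GeneticCode:
    """Load an NCBI translation table as a :class:`GeneticCode`.

    Parameters
    ----------
    table_id :
        NCBI translation-table id (1 = standard code, the default used
        throughout the pipeline).

    Raises
    ------
    UnsupportedCodeError
        If ``table_id`` is not an NCBI nuclear/organellar table known to
        Biopython.
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[int(table_id)]
    except (KeyError, ValueError) as exc:
        raise UnsupportedCodeError(
            f"translation table {table_id!r} is not a supported NCBI table"
        ) from exc
    codon_to_aa = {c: STOP for c in table.stop_codons}
    codon_to_aa.update(table.forward_table)
    if len(codon_to_aa) != 64:
        # Some mitochondrial tables have ambiguous entries; refuse rather
        # than guess.
        raise UnsupportedCodeError(
            f"translation table {table_id} does not map all 64 codons unambiguously"
        )
    families: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = codon_to_aa[codon]
        if aa != STOP:
            families.setdefault(aa, []).append(codon)
    families = {aa: sorted(cods) for aa, cods in sorted(families.items())}
    degeneracy = {aa: len(cods) for aa, cods in families.items()}
    code = GeneticCode(
        table_id=int(table_id),
        codon_to_aa=codon_to_aa,
        synonymous_families=families,
        degeneracy=degeneracy,
    )
    object.__setattr__(code, "_start_codons", list(table.start_codons))
    return code


def informative_codons(code: GeneticCode) -> list[str]:
    """Sense codons of degenerate families, in a stable documented order.

    Single-codon families (Met and Trp under the standard code) carry no
    synonymous-choice information and are excluded; this yields the 59
    columns of the codon-usage matrix under the standard code. Ordering is
    by amino acid (alphabetical one-letter code), then codon (TCAG-free
    plain alphabetical), so matrix columns are reproducible across runs.
    """
    out: list[str] = []
    for aa, codons in code.synonymous_families.items():
        if len(codons) > 1:
            out.extend(codons)
    return out


def degeneracy_class_sizes(code: GeneticCode) -> dict[int, int]:
    """Number of amino-acid families per degeneracy class (e.g. {2: 9, ...})."""
    sizes: dict[int, int] = {}
    for aa, k in code.degeneracy.items():
        if k > 1:
            sizes[k] = sizes.get(k, 0) + 1
    return sizes


def write_scales_table(path) -> None:
    """Write the bundled machine-readable codon table to ``path``.

    One row per codon: codon, amino acid (or ``*``), family degeneracy,
    Kyte-Doolittle hydropathy of the encoded residue, aromatic indicator.
    Provided so the scales the package uses are auditable as plain text.
    """
    code = load_code(1)
    scales = AminoAcidScales()
    with open(path, "w") as fh:
        fh.write("codon\tamino_acid\tdegeneracy\thydropathy\taromatic\n")
        for codon in ALL_CODONS:
            aa = code.codon_to_aa[codon]
            if aa == STOP:
                fh.write(f"{codon}\t*\t0\t\t\n")
            else:
                fh.write(
                    f"{codon}\t{aa}\t{code.degeneracy[aa]}\t"
                    f"{scales.hydropathy[aa]}\t{scales.aromatic[aa]}\n"
                )


def bundled_scales_path():
    """Path of the bundled plain-text codon/scale table."""
    return resources.files("codonforge.data") / "standard_code_scales.tsv"
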
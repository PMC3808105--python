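"""Per-gene codon-usage indices.

For each curated ORF this module computes the classical codon-bias
statistics:

* RSCU — relative synonymous codon usage, the observed count of a codon
  scaled by its family degeneracy so that even within-family usage gives 1.
* ENC — Wright's effective number of codons, from the per-family homozygosity
  F averaged within each degeneracy class; 20 = one codon per amino acid,
  61 = perfectly even usage.
* expected ENC — Wright's null curve ``2 + s + 29/(s^2 + (1-s)^2)`` giving
  the ENC of a gene whose codon usage is shaped only by the G+C content at
  synonymous third positions, s = GC3s.
* CAI — codon adaptation index, the geometric mean of relative-adaptiveness
  weights toward a highly-expressed-gene reference set.
* GRAVY / AROMO — mean Kyte-Doolittle hydropathy and aromatic-residue
  fraction of the conceptual translation.
* Compositions — GC, GC12 (mean of first- and second-position G+C) and the
  synonymous third-position nucleotide fractions A3s/T3s/C3s/G3s with
  GC3s = C3s + G3s.

Undefined quantities (e.g. ENC when a degeneracy class cannot be estimated)
are returned as ``None``, never silently as 0 or NaN; table writers render
them as empty cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genetic_code import STOP, AminoAcidScales, GeneticCode, informative_codons
from .orf_io import ORFRecord

#: Column order of the per-gene index table consumed by ordination/varpart.
INDEX_COLUMNS = (
    "T3s", "C3s", "A3s", "G3s", "GC3s", "GC", "GC12",
    "CAI", "ENC", "GRAVY", "AROMO", "length_nt",
)


@dataclass(frozen=True)
class CodonCountTable:
    """Sense-codon counts for one ORF (stop codons excluded)."""

    orf_id: str
    counts: dict[str, int]
    total_codons: int

    def __post_init__(self):
        if self.total_codons != sum(self.counts.values()):
            raise ValueError("total_codons inconsistent with counts")


@dataclass(frozen=True)
class CAIReference:
    """Relative-adaptiveness weights w for CAI.

    Within every synonymous family the most adapted codon has w == 1.
    ATG, TGG and stop codons are excluded from the CAI computation
    (single-codon families carry no adaptation signal).
    """

    name: str
    w: dict[str, float]


@dataclass
class GeneIndices:
    """All per-gene indices for one ORF; ``None`` marks undefined values."""

    orf_id: str
    rscu: dict[str, float | None]
    enc: float | None
    cai: float | None
    gravy: float | None
    aromo: float | None
    gc: float
    gc12: float
    gc3s: float | None
    a3s: float | None
    t3s: float | None
    c3s: float | None
    g3s: float | None
    length_nt: int

    def as_row(self) -> dict[str, float | None]:
        return {
            "orf_id": self.orf_id,
            "T3s": self.t3s, "C3s": self.c3s, "A3s": self.a3s, "G3s": self.g3s,
            "GC3s": self.gc3s, "GC": self.gc, "GC12": self.gc12,
            "CAI": self.cai, "ENC": self.enc,
            "GRAVY": self.gravy, "AROMO": self.aromo,
            "length_nt": self.length_nt,
        }


class FrameError(ValueError):
    """Sequence length not divisible by 3."""


def _trim_stop(seq: str, code: GeneticCode) -> str:
    if len(seq) % 3:
        raise FrameError(f"ORF length {len(seq)} is not divisible by 3")
    if len(seq) >= 3 and seq[-3:] in code.stop_codons:
        return seq[:-3]
    return seq


def count_codons(orf: ORFRecord | str, code: GeneticCode) -> CodonCountTable:
    """Count sense codons of an in-frame ORF; one terminal stop is trimmed."""
    seq = orf.seq if isinstance(orf, ORFRecord) else orf
    orf_id = orf.id if isinstance(orf, ORFRecord) else "seq"
    seq = _trim_stop(seq, code)
    counts: dict[str, int] = {}
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        aa = code.codon_to_aa.get(codon)
        if aa is None or aa == STOP:
            # internal stops / ambiguous codons are a curation failure
            raise ValueError(f"{orf_id}: non-sense codon {codon!r} at nt {i}")
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(orf_id=orf_id, counts=counts, total_codons=len(seq) // 3)


def rscu(counts: CodonCountTable, code: GeneticCode) -> dict[str, float | None]:
    """RSCU for every degenerate-family codon.

    RSCU(codon) = observed count x family degeneracy / family total. Codons
    of families with no observed member are undefined (``None``), not zero:
    an unobserved family says nothing about within-family preference.
    """
    out: dict[str, float | None] = {}
    for aa, codons in code.synonymous_families.items():
        if len(codons) == 1:
            continue
        family_total = sum(counts.counts.get(c, 0) for c in codons)
        for c in codons:
            if family_total == 0:
                out[c] = None
            else:
                out[c] = counts.counts.get(c, 0) * len(codons) / family_total
    return out


def _family_F(n_i: list[int]) -> tuple[int, float | None]:
    """Wright's codon homozygosity F for one family; None when n < 2."""
    n = sum(n_i)
    if n < 2:
        return n, None
    S = sum((x / n) ** 2 for x in n_i)
    return n, (n * S - 1) / (n - 1)

#: ENC numerators per degeneracy class: 9 two-fold, 1 three-fold (Ile),
#: 5 four-fold and 3 six-fold families under the standard code.
_ENC_WEIGHTS = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}


def enc(counts: CodonCountTable, code: GeneticCode) -> float | None:
    """Wright's effective number of codons.

    F is computed per family from within-family codon frequencies and
    averaged over the families of each degeneracy class; families observed
    fewer than twice are excluded from their class mean. A missing 3-fold
    class (Ile unobserved) is imputed as the mean of the 2- and 4-fold
    class means; any other missing class, or a non-positive class mean,
    makes ENC undefined. Sampling noise can push the estimator above the
    theoretical maximum, so values are clamped at 61.
    """
    class_F: dict[int, list[float]] = {k: [] for k in _ENC_WEIGHTS}
    for aa, codons in code.synonymous_families.items():
        k = len(codons)
        if k == 1:
            continue
        n, F = _family_F([counts.counts.get(c, 0) for c in codons])
        if F is not None:
            class_F[k].append(F)
    means: dict[int, float | None] = {
        k: (float(np.mean(v)) if v else None) for k, v in class_F.items()
    }
    if means[3] is None and means[2] is not None and means[4] is not None:
        means[3] = (means[2] + means[4]) / 2.0
    if any(m is None or m <= 0 for m in means.values()):
        return None
    value = 2.0 + sum(w / means[k] for k, w in _ENC_WEIGHTS.items())
    return min(value, 61.0)


def expected_enc(gc3s: float) -> float:
    """Wright's null ENC at synonymous third-position G+C fraction s."""
    s = float(gc3s)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s must lie in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def load_cai_reference(path=None) -> CAIReference:
    """Load a two-column codon→w table (default: bundled E. coli-style set).

    The bundled table is a synthetic stand-in constructed from the commonly
    cited E. coli optimal-codon set (optimal codon w = 1, other family
    members w = 0.3); see the file header. Any two-column whitespace- or
    tab-separated file can be substituted.
    """
    if path is None:
        path = resources.files("codonforge.data") / "cai_reference_ecoli_synthetic.tsv"
        name = "ecoli-synthetic"
    else:
        name = str(path)
    w: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("codon"):
                continue
            codon, val = line.split()[:2]
            w[codon.upper().replace("U", "T")] = float(val)
    return CAIReference(name=name, w=w)


#: Codons excluded from CAI: non-degenerate families and stops.
CAI_EXCLUDED = frozenset({"ATG", "TGG", "TAA", "TAG", "TGA"})


def cai(counts: CodonCountTable, ref: CAIReference, code: GeneticCode) -> float | None:
    """Codon adaptation index: geometric mean of w over included codons."""
    log_sum = 0.0
    n = 0
    for codon, cnt in counts.counts.items():
        if codon in CAI_EXCLUDED:
            continue
        w = ref.w.get(codon)
        if w is None or w <= 0:
            raise ValueError(f"CAI reference {ref.name!r} lacks a weight for {codon}")
        log_sum += cnt * math.log(w)
        n += cnt
    if n == 0:
        return None
    return math.exp(log_sum / n)


def _residue_counts(counts: CodonCountTable, code: GeneticCode) -> dict[str, int]:
    aa_counts: dict[str, int] = {}
    for codon, cnt in counts.counts.items():
        aa = code.codon_to_aa[codon]
        aa_counts[aa] = aa_counts.get(aa, 0) + cnt
    return aa_counts


def gravy(counts: CodonCountTable, code: GeneticCode,
          scales: AminoAcidScales | None = None) -> float | None:
    """Grand average of hydropathy of the conceptual translation."""
    scales = scales or AminoAcidScales()
    aa_counts = _residue_counts(counts, code)
    n = sum(aa_counts.values())
    if n == 0:
        return None
    return sum(scales.hydropathy[aa] * c for aa, c in aa_counts.items()) / n


def aromo(counts: CodonCountTable, code: GeneticCode,
          scales: AminoAcidScales | None = None) -> float | None:
    """Fraction of aromatic residues (Phe/Tyr/Trp) in the translation."""
    scales = scales or AminoAcidScales()
    aa_counts = _residue_counts(counts, code)
    n = sum(aa_counts.values())
    if n == 0:
        return None
    return sum(scales.aromatic[aa] * c for aa, c in aa_counts.items()) / n


def composition(orf: ORFRecord | str, code: GeneticCode) -> dict[str, float | None]:
    """Nucleotide compositions of an in-frame ORF.

    GC is the G+C fraction over all positions of the (stop-trimmed)
    sequence; GC12 = (GC1 + GC2)/2 over all codons, the neutrality-plot
    convention. A3s/T3s/C3s/G3s are nucleotide fractions at third positions
    of codons belonging to degenerate families only (synonymous third
    positions), so they sum to 1, and GC3s = C3s + G3s.
    """
    seq = orf.seq if isinstance(orf, ORFRecord) else orf
    seq = _trim_stop(seq, code)
    n = len(seq)
    if n == 0:
        raise ValueError("empty ORF after stop trimming")
    gc_all = sum(1 for b in seq if b in "GC") / n
    pos1 = seq[0::3]
    pos2 = seq[1::3]
    gc1 = sum(1 for b in pos1 if b in "GC") / len(pos1)
    gc2 = sum(1 for b in pos2 if b in "GC") / len(pos2)
    syn_third: list[str] = []
    for i in range(0, n, 3):
        codon = seq[i:i + 3]
        aa = code.codon_to_aa.get(codon)
        if aa and aa != STOP and len(code.synonymous_families[aa]) > 1:
            syn_third.append(codon[2])
    if not syn_third:
        frac = {b: None for b in "ATCG"}
        gc3s = None
    else:
        m = len(syn_third)
        frac = {b: syn_third.count(b) / m for b in "ATCG"}
        gc3s = frac["G"] + frac["C"]
    return {
        "gc": gc_all,
        "gc12": (gc1 + gc2) / 2.0,
        "gc3s": gc3s,
        "a3s": frac["A"], "t3s": frac["T"], "c3s": frac["C"], "g3s": frac["G"],
    }


def gene_indices(orf: ORFRecord, code: GeneticCode,
                 ref: CAIReference | None = None,
                 scales: AminoAcidScales | None = None) -> GeneIndices:
    """Assemble the full per-gene index row for one curated ORF."""
    ref = ref or load_cai_reference()
    scales = scales or AminoAcidScales()
    counts = count_codons(orf, code)
    comp = composition(orf, code)
    return GeneIndices(
        orf_id=orf.id,
        rscu=rscu(counts, code),
        enc=enc(counts, code),
        cai=cai(counts, ref, code),
        gravy=gravy(counts, code, scales),
        aromo=aromo(counts, code, scales),
        gc=comp["gc"], gc12=comp["gc12"], gc3s=comp["gc3s"],
        a3s=comp["a3s"], t3s=comp["t3s"], c3s=comp["c3s"], g3s=comp["g3s"],
        length_nt=len(orf.seq),
    )


def indices_table(orfs: Iterable[ORFRecord], code: GeneticCode,
                  ref: CAIReference | None = None,
                  scales: AminoAcidScales | None = None) -> pd.DataFrame:
    """Genes x indices table (the explanatory matrix of the ordination)."""
    ref = ref or load_cai_reference()
    scales = scales or AminoAcidScales()
    rows = [gene_indices(o, code, ref, scales).as_row() for o in orfs]
    df = pd.DataFrame(rows, columns=["orf_id", *INDEX_COLUMNS])
    return df.set_index("orf_id")


def rscu_matrix(orfs: Iterable[ORFRecord], code: GeneticCode,
                values: str = "rscu") -> pd.DataFrame:
    """Genes x informative-codons matrix of RSCU values or raw counts.

    Undefined RSCU (unobserved family) is stored as 0 here: for the
    chi-square/variance machinery of the ordination a missing family
    contributes no usage mass. Set ``values="counts"`` for raw counts.
    """
    cols = informative_codons(code)
    rows = []
    ids = []
    for orf in orfs:
        counts = count_codons(orf, code)
        if values == "counts":
            row = [counts.counts.get(c, 0) for c in cols]
        elif values == "rscu":
            r = rscu(counts, code)
            row = [r[c] if r[c] is not None else 0.0 for c in cols]
        else:
            raise ValueError(f"values must be 'rscu' or 'counts', got {values!r}")
        rows.append(row)
        ids.append(orf.id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="orf_id"), columns=cols)
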
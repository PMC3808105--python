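"""Synthetic virus-like ORF corpora with known causal structure.

Each generated gene is built from two independent causal axes so that
every downstream stage of the pipeline can be tested against ground truth:

* a mutational axis — a per-gene target G+C content at synonymous third
  positions (GC3s), drawn uniformly from a corpus-wide gradient. Within
  every synonymous family, G/C-ending codons are up-weighted so that the
  expected realized GC3s equals the target exactly, and usage is uniform
  within the G/C-ending and A/T-ending groups (Wright's null model, so a
  mutation-only corpus falls on the expected-ENC curve);
* a selectional axis — a per-gene expression weight in [0, 1] that
  exponentially up-weights the reference-optimal codon of each family,
  scaled by ``selection_strength``. This raises CAI in proportion to
  expression, mimicking translational selection.

Amino-acid composition is sampled from an exponentially tilted
distribution solved to hit a per-gene hydrophobicity target, with the
aromatic residues (F/Y/W) renormalized to a per-gene aromatic fraction.
Optionally a neutrality slope is planted: the per-gene first/second
position G+C target is set to ``gc12_slope * target_gc3s +
gc12_intercept`` plus noise, and the amino-acid distribution is tilted to
meet it (mutation pressure acting, attenuated, on non-synonymous
positions).

Gene i draws from its own counter-derived substream ``(seed, i)``, so
corpora are reproducible and order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .codon_metrics import load_cai_reference
from .genetic_code import AminoAcidScales, GeneticCode, informative_codons, load_code
from .orf_io import ORFRecord, write_fasta


class ConfigError(ValueError):
    """Infeasible or ill-formed generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Defaults emulate a mixed virus ORF set: gene lengths spanning the
    350-bp curation floor up to typical virus gene sizes, a broad GC3s
    gradient across genomes, modest translational selection, and a
    typical protein composition (slightly hydrophilic, ~8% aromatic).
    """

    n_genes: int = 300
    length_range_nt: tuple[int, int] = (350, 1800)
    gc3_gradient: tuple[float, float] = (0.25, 0.75)
    selection_strength: float = 1.0
    hydrophobicity_target: float = -0.2
    aromatic_fraction: float = 0.08
    noise_sd: float = 0.02
    seed: int = 0
    gc12_slope: float | None = None
    gc12_intercept: float = 0.2

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        lo, hi = self.length_range_nt
        if not (350 <= lo <= hi):
            raise ConfigError("length_range_nt must be well-ordered with min >= 350")
        g0, g1 = self.gc3_gradient
        if not (0.0 < g0 <= g1 < 1.0):
            raise ConfigError("gc3_gradient must be well-ordered within (0, 1)")
        if self.selection_strength < 0:
            raise ConfigError("selection_strength must be >= 0")
        if not 0.0 <= self.aromatic_fraction <= 1.0:
            raise ConfigError("aromatic_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def dna_virus_preset(**overrides) -> GeneratorConfig:
    """DNA-virus-like corpus: wide GC3s gradient, longer genes."""
    kw = dict(gc3_gradient=(0.15, 0.85), length_range_nt=(350, 2400))
    kw.update(overrides)
    return GeneratorConfig(**kw)


def rna_virus_preset(**overrides) -> GeneratorConfig:
    """RNA-virus-like corpus: narrower, AT-shifted GC3s gradient."""
    kw = dict(gc3_gradient=(0.25, 0.6), length_range_nt=(350, 1500))
    kw.update(overrides)
    return GeneratorConfig(**kw)


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside a generated corpus."""

    per_gene: pd.DataFrame
    neutrality_slope: float
    neutrality_intercept: float
    mut_sel_variance_ratio: float | None
    config: GeneratorConfig

    def write_json(self, path) -> None:
        payload = {
            "neutrality_slope": self.neutrality_slope,
            "neutrality_intercept": self.neutrality_intercept,
            "mut_sel_variance_ratio": self.mut_sel_variance_ratio,
            "config": asdict(self.config),
            "per_gene": self.per_gene.reset_index().to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")


_AAS = tuple("ACDEFGHIKLMNPQRSTVWY")


def _family_gc12(code: GeneticCode) -> dict[str, float]:
    """Mean G+C fraction at codon positions 1-2 across each family."""
    out = {}
    for aa, codons in code.synonymous_families.items():
        gc = [sum(b in "GC" for b in c[:2]) / 2.0 for c in codons]
        out[aa] = float(np.mean(gc))
    return out


def _tilt(base: np.ndarray, scores: np.ndarray, target: float) -> np.ndarray:
    """Exponentially tilt ``base`` along ``scores`` to hit an expected value."""
    lo_v = scores.min() + 1e-9
    hi_v = scores.max() - 1e-9
    target = min(max(target, lo_v), hi_v)

    def expectation(beta):
        w = base * np.exp(beta * scores)
        p = w / w.sum()
        return float(p @ scores) - target

    try:
        beta = brentq(expectation, -60.0, 60.0, xtol=1e-10)
    except ValueError:
        beta = 60.0 if expectation(60.0) < 0 else -60.0
    w = base * np.exp(beta * scores)
    return w / w.sum()


def _aa_distribution(rng, cfg: GeneratorConfig, code: GeneticCode,
                     scales: AminoAcidScales, gc12_by_aa: np.ndarray,
                     target_gravy: float, target_aromo: float,
                     target_gc12: float | None) -> np.ndarray:
    kd = np.array([scales.hydropathy[a] for a in _AAS])
    arom = np.array([float(a in "FYW") for a in _AAS])
    p = _tilt(np.full(len(_AAS), 1.0 / len(_AAS)), kd, target_gravy)
    if target_gc12 is not None:
        p = _tilt(p, gc12_by_aa, target_gc12)
    mass = float(p @ arom)
    if 0 < mass < 1:
        p = np.where(arom == 1, p * target_aromo / mass,
                     p * (1 - target_aromo) / (1 - mass))
    return p / p.sum()


def _codon_weights(code: GeneticCode, optimal: set[str],
                   gc3_odds: float, sel: float) -> dict[str, np.ndarray]:
    """Within-family sampling weights for one gene.

    G/C-ending codons get weight ``odds * (n_AT / n_GC)`` so the family's
    expected G/C-ending probability equals the target GC3s exactly; the
    reference-optimal codon is additionally up-weighted by ``exp(sel)``.
    """
    weights = {}
    for aa, codons in code.synonymous_families.items():
        gc_end = np.array([c[2] in "GC" for c in codons])
        n_gc, n_at = int(gc_end.sum()), int((~gc_end).sum())
        if n_gc and n_at:
            w = np.where(gc_end, gc3_odds * n_at / n_gc, 1.0)
        else:
            w = np.ones(len(codons))
        opt = np.array([c in optimal for c in codons])
        weights[aa] = w * np.exp(sel * opt)
    return weights


def _expected_rscu_matrix(code: GeneticCode, optimal: set[str],
                          gc3_odds: np.ndarray, sel: np.ndarray) -> np.ndarray:
    """Expected per-gene RSCU over the informative codons (genes x 59)."""
    cols = informative_codons(code)
    col_pos = {c: j for j, c in enumerate(cols)}
    out = np.empty((len(gc3_odds), len(cols)))
    for aa, fam in code.synonymous_families.items():
        if len(fam) == 1:
            continue
        gc = np.array([c[2] in "GC" for c in fam])
        n_gc, n_at = int(gc.sum()), int((~gc).sum())
        base = np.where(gc, n_at / n_gc, 1.0) if (n_gc and n_at) else np.ones(len(fam))
        opt = np.array([c in optimal for c in fam], dtype=float)
        # genes x family-codons weight matrix
        w = base[None, :] * np.where(gc, gc3_odds[:, None], 1.0) \
            * np.exp(sel[:, None] * opt[None, :])
        p = w / w.sum(axis=1, keepdims=True)
        for j, c in enumerate(fam):
            out[:, col_pos[c]] = p[:, j] * len(fam)
    return out


def planted_variance_ratio(code: GeneticCode, optimal: set[str],
                           gc3_odds: np.ndarray, sel: np.ndarray) -> float | None:
    """Planted mutation:selection variance ratio on the RSCU response scale.

    The mutational component is the expected RSCU driven by each gene's
    GC3s odds with selection off; the selectional component is the
    expected RSCU driven by each gene's selection term at the corpus
    median GC3s odds. The ratio of their trace variances across genes is
    the planted ratio of the variance that variation partitioning
    decomposes; ``None`` when the selectional variance is zero
    (mutation-only corpus).
    """
    mut = _expected_rscu_matrix(code, optimal, gc3_odds, np.zeros_like(sel))
    med = np.full_like(gc3_odds, np.median(gc3_odds))
    selm = _expected_rscu_matrix(code, optimal, med, sel)
    v_mut = float(mut.var(axis=0, ddof=1).sum())
    v_sel = float(selm.var(axis=0, ddof=1).sum())
    if v_sel <= 1e-12 * max(v_mut, 1.0):  # mutation-only corpus
        return None
    return v_mut / v_sel


def calibrate_selection_strength(config: GeneratorConfig,
                                 target_ratio: float) -> GeneratorConfig:
    """Return a config whose planted mutation:selection ratio is ``target_ratio``.

    Solves for the selection_strength whose planted RSCU-scale variance
    ratio (see :func:`planted_variance_ratio`) equals ``target_ratio``,
    given the per-gene draws implied by the config's seed.
    """
    code = load_code(1)
    optimal = {c for c, w in load_cai_reference().w.items() if w >= 1.0}
    draws = [_gene_params(config, i) for i in range(config.n_genes)]
    odds = np.array([d["gc3_odds"] for d in draws])
    expr = np.array([d["expression_weight"] for d in draws])
    if np.ptp(expr) == 0:
        raise ConfigError("cannot calibrate: expression weights have no variance")

    def gap(log_s):
        return np.log(planted_variance_ratio(
            code, optimal, odds, np.exp(log_s) * expr)) - np.log(target_ratio)

    strength = float(np.exp(brentq(gap, -6.0, 4.0, xtol=1e-6)))
    return GeneratorConfig(**{**asdict(config), "selection_strength": strength})


def _gene_params(cfg: GeneratorConfig, i: int) -> dict:
    rng = np.random.default_rng([cfg.seed, i])
    lo, hi = cfg.length_range_nt
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    target_gc3s = float(rng.uniform(*cfg.gc3_gradient))
    eff = float(np.clip(target_gc3s + rng.normal(0, cfg.noise_sd), 0.02, 0.98))
    expression = float(rng.uniform(0.0, 1.0))
    target_gravy = float(cfg.hydrophobicity_target + rng.normal(0, 0.3))
    target_aromo = float(np.clip(cfg.aromatic_fraction + rng.normal(0, 0.02),
                                 0.0, 0.5))
    if cfg.gc12_slope is None:
        target_gc12 = None
    else:
        target_gc12 = float(np.clip(
            cfg.gc12_slope * target_gc3s + cfg.gc12_intercept
            + rng.normal(0, cfg.noise_sd), 0.05, 0.95))
    return {
        "index": i, "n_codons": n_codons, "target_gc3s": target_gc3s,
        "gc3_odds": eff / (1 - eff), "effective_gc3s": eff,
        "expression_weight": expression, "target_gravy": target_gravy,
        "target_aromo": target_aromo, "target_gc12": target_gc12,
        "rng_key": (cfg.seed, i),
    }


def generate_corpus(config: GeneratorConfig,
                    code: GeneticCode | None = None,
                    ) -> tuple[list[ORFRecord], SyntheticTruth]:
    """Generate a corpus of in-frame ORFs plus its ground truth."""
    code = code or load_code(1)
    scales = AminoAcidScales()
    optimal = {c for c, w in load_cai_reference().w.items() if w >= 1.0}
    gc12_by_aa_map = _family_gc12(code)
    gc12_by_aa = np.array([gc12_by_aa_map[a] for a in _AAS])
    orfs: list[ORFRecord] = []
    rows = []
    odds_all = np.empty(config.n_genes)
    expr_all = np.empty(config.n_genes)
    for i in range(config.n_genes):
        par = _gene_params(config, i)
        rng = np.random.default_rng([config.seed, i, 1])
        p_aa = _aa_distribution(rng, config, code, scales, gc12_by_aa,
                                par["target_gravy"], par["target_aromo"],
                                par["target_gc12"])
        # body codons exclude the fixed ATG start and the stop
        n_body = par["n_codons"] - 2
        aa_counts = rng.multinomial(n_body, p_aa)
        weights = _codon_weights(code, optimal, par["gc3_odds"],
                                 config.selection_strength
                                 * par["expression_weight"])
        codon_list: list[str] = []
        for aa, cnt in zip(_AAS, aa_counts):
            if cnt == 0:
                continue
            fam = code.synonymous_families[aa]
            w = weights[aa]
            draws = rng.multinomial(cnt, w / w.sum())
            for codon, k in zip(fam, draws):
                codon_list.extend([codon] * int(k))
        order = rng.permutation(len(codon_list))
        body = "".join(codon_list[j] for j in order)
        seq = "ATG" + body + "TAA"
        gid = f"synth_genome_{i:04d}"
        orfs.append(ORFRecord(id=f"synth_g{i:04d}", genome_id=gid,
                              start=0, end=len(seq), strand="+", seq=seq))
        odds_all[i] = par["gc3_odds"]
        expr_all[i] = par["expression_weight"]
        rows.append({k: par[k] for k in (
            "target_gc3s", "effective_gc3s", "expression_weight",
            "target_gravy", "target_aromo", "target_gc12", "n_codons")})
    per_gene = pd.DataFrame(rows, index=[o.id for o in orfs])
    per_gene.index.name = "orf_id"
    ratio = planted_variance_ratio(
        code, optimal, odds_all, config.selection_strength * expr_all)
    truth = SyntheticTruth(
        per_gene=per_gene,
        neutrality_slope=config.gc12_slope if config.gc12_slope is not None else 0.0,
        neutrality_intercept=config.gc12_intercept,
        mut_sel_variance_ratio=ratio,
        config=config,
    )
    return orfs, truth


_SAFE_CODONS = ("GCT", "GCC", "AAA", "AAG", "CTG", "CTT", "GAT", "TTC")


def _filler(n_codons: int, offset: int = 0) -> str:
    return "".join(_SAFE_CODONS[(i + offset) % len(_SAFE_CODONS)]
                   for i in range(n_codons))


def generate_degenerate_cases() -> list[ORFRecord]:
    """Fixture ORFs exercising each curation-filter branch exactly once.

    Returns seven ORFs: two clean ones, one shorter than 350 nt, one
    overlapping pair member (the shorter of two same-genome ORFs), one
    with an untranslatable N-containing codon, and one whose sense codons
    are all Met/Trp (no synonymous codons). Passed through
    ``filter_orfs`` this yields exactly one removal per report category
    and three retained ORFs.
    """
    def orf(name, genome, seq, start=0):
        return ORFRecord(id=name, genome_id=genome, start=start,
                         end=start + len(seq), strand="+", seq=seq)

    valid1 = "ATG" + _filler(118) + "TAA"            # 360 nt
    valid2 = "ATG" + _filler(130, 3) + "TAA"         # 396 nt
    short = "ATG" + _filler(114) + "TAA"             # 348 nt < 350
    over_long = "ATG" + _filler(140, 1) + "TAA"      # 426 nt
    over_short = "ATG" + _filler(120, 2) + "TAA"     # 366 nt, overlaps above
    nontrans = "ATG" + _filler(58) + "ANN" + _filler(58, 5) + "TAA"
    no_syn = "ATG" + "ATGTGG" * 58 + "TAA"           # Met/Trp only, 351 nt

    return [
        orf("degen_valid1", "g_valid1", valid1),
        orf("degen_valid2", "g_valid2", valid2),
        orf("degen_short", "g_short", short),
        orf("degen_overlap_long", "g_overlap", over_long, start=0),
        orf("degen_overlap_short", "g_overlap", over_short, start=200),
        orf("degen_nontranslatable", "g_nontrans", nontrans),
        orf("degen_no_synonymous", "g_nosyn", no_syn),
    ]


def write_corpus(orfs: list[ORFRecord], truth: SyntheticTruth, outdir) -> None:
    """Write FASTA + truth JSON + config YAML echo for one corpus."""
    import pathlib

    import yaml

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(orfs, outdir / "corpus.fasta")
    truth.write_json(outdir / "truth.json")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(truth.config), fh, sort_keys=False)
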
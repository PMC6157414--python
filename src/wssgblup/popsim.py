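"""Synthetic aquaculture breeding population: pedigree, genotypes, trait.

The generator emulates the statistical structure of a two-year-class
full-sib breeding population measured for fillet (muscle) yield: a founder
pool, discrete generations of full-sib families, SNP genotypes dropped
through the pedigree with Haldane-model recombination, a handful of
large-effect QTL on a polygenic background, a shared-rearing family
deviation, and fixed harvest-group / hatch-year effects.  Defaults target a
trait with mean 48.91 and SD 2.42 (fillet yield in percent of body weight),
heritability 0.4, family common-environment share 0.1, and a founder minor
allele frequency spectrum with mean about 0.25.

Founder linkage disequilibrium comes from a first-order Markov chain along
each chromosome: site frequencies follow a slowly drifting logit-normal
profile and each haplotype copies its previous allele state with
probability equal to the configured adjacent-marker correlation.  That is
enough for 50-SNP windows to localize planted QTL without coalescent
machinery, and every draw flows from named sub-streams of one global seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geno_io import (
    GenotypeMatrix,
    Pedigree,
    SnpMap,
    write_genotypes,
    write_map,
    write_pedigree,
    write_phenotypes,
    write_plink,
)

__all__ = [
    "SimConfig",
    "TruthSet",
    "SimulatedDataset",
    "simulate_pedigree",
    "simulate_genotypes",
    "assign_qtl_and_phenotypes",
    "simulate_dataset",
    "write_dataset",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-condition defaults: a scaled-down two-generation population of
    ~98 four-offspring full-sib families per year class genotyped at 5000
    SNPs on 10 chromosomes, fillet yield mean 48.91 / SD 2.42, h2 0.4,
    family share 0.1, two QTL each carrying 10% of the additive variance on
    a polygenic background."""

    n_founders: int = 200
    n_generations: int = 2
    n_families_per_gen: int = 98
    n_offspring_per_family: int = 4
    n_chromosomes: int = 10
    snps_per_chromosome: int = 500
    chromosome_length_morgans: float = 1.0
    founder_hap_correlation: float = 0.7
    founder_freq_logit_sd: float = 1.7  # gives mean founder MAF ~ 0.25
    n_qtl: int = 2
    qtl_variance_shares: tuple[float, ...] = (0.10, 0.10)
    qtl_maf_min: float = 0.10  # QTL drawn from common variants (survive MAF QC)
    h2: float = 0.4
    c2_family: float = 0.1
    trait_mean: float = 48.91
    trait_sd: float = 2.42
    missing_rate: float = 0.01
    n_harvest_groups: int = 5
    harvest_group_spread: float = 0.2  # total fixed-effect spread in units of SD
    hatch_year_spread: float = 0.2
    first_hatch_year: int = 2010
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_founders": self.n_founders,
            "n_chromosomes": self.n_chromosomes,
            "snps_per_chromosome": self.snps_per_chromosome,
            "n_families_per_gen": self.n_families_per_gen,
            "n_offspring_per_family": self.n_offspring_per_family,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1 (got {v})")
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be >= 0")
        if not (0.0 <= self.founder_hap_correlation < 1.0):
            raise ConfigurationError("founder_hap_correlation must be in [0, 1)")
        if self.chromosome_length_morgans < 0:
            raise ConfigurationError("chromosome_length_morgans must be >= 0")
        if not (0.0 < self.h2 < 1.0):
            raise ConfigurationError("h2 must be in (0, 1)")
        if not (0.0 <= self.c2_family < 1.0):
            raise ConfigurationError("c2_family must be in [0, 1)")
        if self.h2 + self.c2_family >= 1.0:
            raise ConfigurationError("h2 + c2_family must be < 1")
        if self.n_qtl != len(self.qtl_variance_shares):
            raise ConfigurationError(
                f"n_qtl={self.n_qtl} but {len(self.qtl_variance_shares)} shares given"
            )
        if self.n_qtl and (min(self.qtl_variance_shares) <= 0):
            raise ConfigurationError("qtl_variance_shares must be positive")
        if sum(self.qtl_variance_shares) > 1.0 + 1e-12:
            raise ConfigurationError("qtl_variance_shares must sum to <= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.trait_sd <= 0:
            raise ConfigurationError("trait_sd must be > 0")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named, independent random sub-streams from the single seed."""
        names = ("pedigree", "founders", "genedrop", "qtl", "phenotype", "missing")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class TruthSet:
    """Ground truth for recovery tests.

    ``true_breeding_values`` is the dot product of centered causal genotypes
    (major QTL plus any polygenic-background SNPs) with their effects; when
    the QTL shares sum to 1 there is no background and the TBV is exactly
    the centered-QTL dot product.
    """

    qtl_snp_indices: np.ndarray
    qtl_effects: np.ndarray
    background_snp_indices: np.ndarray
    background_effects: np.ndarray
    true_breeding_values: pd.Series  # indexed by animal id, pedigree order
    realized_h2: float
    per_qtl_variance_share: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.true_breeding_values.index,
             "tbv": self.true_breeding_values.to_numpy()}
        )


@dataclass
class SimulatedDataset:
    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix  # with missingness applied
    truth_codes: np.ndarray  # complete codes recorded before missingness
    founder_haplotypes: np.ndarray  # (2*n_founders, n_snps)
    phenotypes: pd.DataFrame
    truth: TruthSet


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Discrete-generation full-sib pedigree.

    Founders (generation 0) have unknown parents.  For each later
    generation the previous generation's animals are shuffled and split
    into disjoint sire/dam pairs, one pair per full-sib family, so there is
    no selfing and parents always precede offspring.
    """
    rng = cfg.streams()["pedigree"]
    rows: list[tuple[str, str, str]] = []
    founders = [f"F{i + 1}" for i in range(cfg.n_founders)]
    rows += [(a, "0", "0") for a in founders]
    prev = founders
    for g in range(1, cfg.n_generations + 1):
        need = 2 * cfg.n_families_per_gen
        if len(prev) < need:
            raise ConfigurationError(
                f"generation {g} needs {need} distinct parents but only "
                f"{len(prev)} animals are available in generation {g - 1}"
            )
        perm = rng.permutation(len(prev))
        cur: list[str] = []
        for f in range(cfg.n_families_per_gen):
            sire = prev[perm[2 * f]]
            dam = prev[perm[2 * f + 1]]
            for o in range(cfg.n_offspring_per_family):
                a = f"G{g}F{f + 1}O{o + 1}"
                rows.append((a, sire, dam))
                cur.append(a)
        prev = cur
    return Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _founder_frequencies(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Slowly drifting logit-normal site frequency profile per chromosome.

    High adjacent-allele correlation forces nearby marginals to be similar,
    so frequencies follow a logit-scale AR(1) with autocorrelation 0.98 and
    stationary SD founder_freq_logit_sd; the wide stationary spread gives a
    realistic minor-allele-frequency spectrum across the genome.
    """
    m = cfg.snps_per_chromosome
    phi = 0.98
    tau = cfg.founder_freq_logit_sd
    out = np.empty(cfg.n_chromosomes * m)
    for c in range(cfg.n_chromosomes):
        z = np.empty(m)
        z[0] = rng.normal(0.0, tau)
        eps = rng.normal(0.0, tau * np.sqrt(1 - phi**2), size=m - 1)
        for j in range(1, m):
            z[j] = phi * z[j - 1] + eps[j - 1]
        out[c * m:(c + 1) * m] = 1.0 / (1.0 + np.exp(-z))
    return np.clip(out, 0.01, 0.99)


def _founder_haplotypes(cfg: SimConfig, p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """First-order Markov haplotypes with adjacent-state copy probability r.

    Site j copies site j-1's allele state with probability r and otherwise
    draws Bernoulli(p_j); chains restart at chromosome boundaries.
    """
    n_hap = 2 * cfg.n_founders
    m_chr = cfg.snps_per_chromosome
    r = cfg.founder_hap_correlation
    H = np.empty((n_hap, len(p)), dtype=np.int8)
    for c in range(cfg.n_chromosomes):
        off = c * m_chr
        H[:, off] = rng.random(n_hap) < p[off]
        if m_chr > 1:
            copy = rng.random((n_hap, m_chr - 1)) < r
            fresh = rng.random((n_hap, m_chr - 1)) < p[off + 1:off + m_chr]
            for j in range(1, m_chr):
                H[:, off + j] = np.where(
                    copy[:, j - 1], H[:, off + j - 1], fresh[:, j - 1]
                )
    return H


def _make_map(cfg: SimConfig) -> SnpMap:
    # evenly spaced physical positions, 10 kb apart, 1-based
    rows = []
    for c in range(cfg.n_chromosomes):
        for j in range(cfg.snps_per_chromosome):
            rows.append(
                (f"snp_c{c + 1}_{j + 1}", str(c + 1), 10_000 * j + 1)
            )
    return SnpMap(pd.DataFrame(rows, columns=["snp_id", "chromosome", "position"]))


def _gamete(hap_pair: np.ndarray, cfg: SimConfig, gpos: np.ndarray, rng) -> np.ndarray:
    """One recombinant gamete via Haldane (Poisson crossover) model."""
    m_chr = cfg.snps_per_chromosome
    L = cfg.chromosome_length_morgans
    out = np.empty(hap_pair.shape[1], dtype=np.int8)
    for c in range(cfg.n_chromosomes):
        off = c * m_chr
        nx = rng.poisson(L)
        start = rng.integers(2)
        if nx == 0:
            strand = np.full(m_chr, start)
        else:
            points = np.sort(rng.random(nx) * L)
            strand = (start + np.searchsorted(points, gpos)) % 2
        seg = hap_pair[:, off:off + m_chr]
        out[off:off + m_chr] = seg[strand, np.arange(m_chr)]
    return out


def simulate_genotypes(
    ped: Pedigree, cfg: SimConfig
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Gene-drop genotypes for every pedigree animal.

    Returns (GenotypeMatrix with missingness applied, complete truth codes,
    founder haplotypes).  Founder haplotypes are Markov-correlated; each
    meiosis recombines with Poisson(chromosome length in Morgans)
    crossovers at genetic positions given by physical order scaled to the
    chromosome length; missing calls are masked uniformly at random after
    the complete codes are recorded.
    """
    streams = cfg.streams()
    rng_f = streams["founders"]
    rng_g = streams["genedrop"]
    rng_m = streams["missing"]

    smap = _make_map(cfg)
    m = len(smap)
    p0 = _founder_frequencies(cfg, rng_f)
    founder_haps = _founder_haplotypes(cfg, p0, rng_f)

    m_chr = cfg.snps_per_chromosome
    gpos = (np.arange(m_chr) + 0.5) / m_chr * cfg.chromosome_length_morgans

    n = len(ped)
    hap = np.empty((n, 2, m), dtype=np.int8)
    founder_counter = 0
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s < 0 and d < 0:
            hap[i, 0] = founder_haps[2 * founder_counter]
            hap[i, 1] = founder_haps[2 * founder_counter + 1]
            founder_counter += 1
        else:
            # both parents known by construction of the simulator
            hap[i, 0] = _gamete(hap[s], cfg, gpos, rng_g)
            hap[i, 1] = _gamete(hap[d], cfg, gpos, rng_g)

    truth_codes = hap.sum(axis=1).astype(np.float64)
    codes = truth_codes.copy()
    if cfg.missing_rate > 0:
        mask = rng_m.random(codes.shape) < cfg.missing_rate
        codes[mask] = np.nan
    geno = GenotypeMatrix(ped.ids, smap, codes)
    return geno, truth_codes, founder_haps


# ---------------------------------------------------------------------------
# QTL and phenotypes
# ---------------------------------------------------------------------------

def _spread_effects(n_levels: int, spread_sd_units: float, sd: float) -> np.ndarray:
    """Evenly spaced, zero-mean fixed-effect level values."""
    if n_levels == 1:
        return np.zeros(1)
    half = spread_sd_units * sd / 2.0
    return np.linspace(-half, half, n_levels)


def assign_qtl_and_phenotypes(
    geno: GenotypeMatrix,
    ped: Pedigree,
    cfg: SimConfig,
    truth_codes: np.ndarray | None = None,
) -> tuple[pd.DataFrame, TruthSet]:
    """Plant QTL, build true breeding values, and emit the phenotype table.

    The additive target is sigma2_a = h2 * trait_sd^2.  Each of the n_qtl
    major loci is scaled (on the phenotyped animals' realized genotype
    variance) to its configured share of sigma2_a; the remaining share is
    spread as a polygenic background of random-sign effects over all other
    polymorphic SNPs.  With n_qtl = 0 there is no genetic signal at all and
    every true breeding value is exactly zero.

    Phenotype = trait_mean + harvest-group effect + hatch-year effect + TBV
    + family deviate (variance c2_family * trait_sd^2) + residual; the
    harvest group cycles within family, mirroring one fish per family per
    weekly slaughter group; only non-founder animals are phenotyped.
    """
    rng_q = cfg.streams()["qtl"]
    rng_p = cfg.streams()["phenotype"]
    M = truth_codes if truth_codes is not None else np.nan_to_num(geno.codes)
    n, m = M.shape
    sigma_p2 = cfg.trait_sd**2
    sigma_a2 = cfg.h2 * sigma_p2

    is_pheno = ~ped.is_founder if cfg.n_generations > 0 else np.ones(n, bool)
    pheno_rows = np.flatnonzero(is_pheno)

    pbar = M.mean(axis=0) / 2.0
    Zc = M - 2.0 * pbar
    col_var = Zc[pheno_rows].var(axis=0)
    polymorphic = np.flatnonzero(col_var > 1e-12)
    maf = np.minimum(pbar, 1.0 - pbar)
    qtl_candidates = np.flatnonzero((col_var > 1e-12) & (maf >= cfg.qtl_maf_min))
    if len(qtl_candidates) < cfg.n_qtl:
        qtl_candidates = polymorphic

    tbv = np.zeros(n)
    qtl_idx = np.array([], dtype=np.int64)
    qtl_eff = np.array([])
    bg_idx = np.array([], dtype=np.int64)
    bg_eff = np.array([])
    shares = np.asarray(cfg.qtl_variance_shares, dtype=np.float64)

    if cfg.n_qtl > 0:
        if cfg.n_qtl > len(polymorphic):
            raise ConfigurationError(
                f"requested {cfg.n_qtl} QTL but only {len(polymorphic)} "
                "polymorphic SNPs are available"
            )
        qtl_idx = np.sort(
            _spaced_choice(rng_q, qtl_candidates, cfg.n_qtl, min_gap=2 * 50)
        )
        qtl_eff = np.sqrt(shares * sigma_a2 / col_var[qtl_idx])
        tbv += Zc[:, qtl_idx] @ qtl_eff

        bg_share = 1.0 - shares.sum()
        if bg_share > 1e-12:
            bg_idx = np.setdiff1d(polymorphic, qtl_idx)
            signs = rng_q.choice([-1.0, 1.0], size=len(bg_idx))
            bg_eff = signs * np.sqrt(
                bg_share * sigma_a2 / (len(bg_idx) * col_var[bg_idx])
            )
            tbv += Zc[:, bg_idx] @ bg_eff

    # realized per-QTL shares of the additive target, on phenotyped animals
    if cfg.n_qtl > 0:
        per_qtl = qtl_eff**2 * col_var[qtl_idx] / sigma_a2
    else:
        per_qtl = np.array([])

    realized_h2 = float(tbv[pheno_rows].var() / sigma_p2)

    hg_eff = _spread_effects(cfg.n_harvest_groups, cfg.harvest_group_spread, cfg.trait_sd)
    years = sorted({int(g) for g in ped.generation[pheno_rows]})
    hy_eff = {
        g: v
        for g, v in zip(years, _spread_effects(len(years), cfg.hatch_year_spread, cfg.trait_sd))
    }

    sigma_w2 = cfg.c2_family * sigma_p2
    sigma_e2 = max(sigma_p2 * (1.0 - cfg.h2 - cfg.c2_family), 1e-12)
    if cfg.n_qtl == 0:
        # no genetic signal: residual absorbs the additive share
        sigma_e2 = max(sigma_p2 * (1.0 - cfg.c2_family), 1e-12)

    fams = ped.family[pheno_rows]
    fam_levels = pd.unique(fams)
    fam_dev = dict(
        zip(fam_levels, rng_p.normal(0.0, np.sqrt(sigma_w2), size=len(fam_levels)))
    )

    rows = []
    fam_counter: dict[str, int] = {}
    resid = rng_p.normal(0.0, np.sqrt(sigma_e2), size=len(pheno_rows))
    for j, i in enumerate(pheno_rows):
        fam = ped.family[i]
        kth = fam_counter.get(fam, 0)
        fam_counter[fam] = kth + 1
        hg = kth % cfg.n_harvest_groups
        g = int(ped.generation[i])
        year = cfg.first_hatch_year + 2 * (g - min(years)) if years else cfg.first_hatch_year
        yv = (
            cfg.trait_mean
            + hg_eff[hg]
            + hy_eff[g]
            + tbv[i]
            + fam_dev[fam]
            + resid[j]
        )
        rows.append(
            {
                "animal": ped.ids[i],
                "family": fam,
                "hatch_year": f"YC{year}",
                "harvest_group": f"wk{hg + 1}",
                "trait": yv,
            }
        )
    pheno = pd.DataFrame(rows)

    truth = TruthSet(
        qtl_snp_indices=qtl_idx,
        qtl_effects=qtl_eff,
        background_snp_indices=bg_idx,
        background_effects=bg_eff,
        true_breeding_values=pd.Series(tbv, index=ped.ids, name="tbv"),
        realized_h2=realized_h2,
        per_qtl_variance_share=per_qtl,
    )
    return pheno, truth


def _spaced_choice(rng, candidates: np.ndarray, k: int, min_gap: int) -> np.ndarray:
    """Draw k candidates pairwise at least min_gap map indices apart; falls
    back to an unconstrained draw if the spacing cannot be met."""
    for _ in range(200):
        pick = rng.choice(candidates, size=k, replace=False)
        if k == 1 or np.min(np.diff(np.sort(pick))) >= min_gap:
            return pick
    return rng.choice(candidates, size=k, replace=False)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Pedigree + genotypes + phenotypes + truth in one seeded call."""
    ped = simulate_pedigree(cfg)
    geno, truth_codes, fh = simulate_genotypes(ped, cfg)
    pheno, truth = assign_qtl_and_phenotypes(geno, ped, cfg, truth_codes)
    return SimulatedDataset(
        config=cfg, pedigree=ped, genotypes=geno, truth_codes=truth_codes,
        founder_haplotypes=fh, phenotypes=pheno, truth=truth,
    )


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write the native-TSV bundle (plus PLINK PED/MAP and truth table)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": out / "pedigree.tsv",
        "map": out / "snp_map.tsv",
        "genotypes": out / "genotypes.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.tsv",
        "plink_ped": out / "genotypes.ped",
        "plink_map": out / "genotypes.map",
    }
    write_pedigree(ds.pedigree, paths["pedigree"])
    write_map(ds.genotypes.snp_map, paths["map"])
    write_genotypes(ds.genotypes, paths["genotypes"])
    write_phenotypes(ds.phenotypes, paths["phenotypes"])
    ds.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    write_plink(ds.genotypes, paths["plink_ped"], paths["plink_map"])
    return paths
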
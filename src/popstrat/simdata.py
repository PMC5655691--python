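"""Synthetic two-population datasets with the structure the pipeline assumes.

The generator emulates a pair of closely related cattle populations drifted
from a common base:

* ancestral allele frequencies drawn uniform on [0.05, 0.95], mimicking the
  flat frequency spectrum of an ascertained genotyping array;
* per-population frequencies drawn from the Balding-Nichols model around the
  ancestral frequency with drift parameter ``fst`` (0.01 by default, which
  gives a cross-population base-frequency correlation near 0.97);
* distance-dependent LD induced by a first-order latent copying process
  along each chromosome whose allelic correlation decays as
  ``exp(-rate * distance_bp)`` with a population-specific rate;
* a shallow pedigree: ``pedigree_depth`` non-genotyped generations above a
  final genotyped generation, haplotypes transmitted by gene dropping with
  Haldane recombination (1 cM/Mbp);
* true SNP effects drawn bivariate normal across populations with
  correlation ``effect_corr`` and per-population totals ``sigma2_a``;
* deregressed proofs y = mu + Z g + e with per-animal residual variance
  ``sigma2_e / EDC`` and log-normal effective daughter contributions.

All randomness flows through one seeded generator, so one seed yields one
byte-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .basefreq import Pedigree, UNKNOWN_PARENT
from .panels import MISSING, GenotypePanel, HaplotypePanel
from .snpblup import DeregressedProofs, design_matrix

MORGAN_PER_BP = 1e-8  # 1 cM per Mbp


@dataclass
class SimConfig:
    """Study conditions for one synthetic two-population dataset."""

    n_animals: int = 400          # genotyped animals per population
    n_snp: int = 2000
    n_chrom: int = 5
    chrom_length_bp: int = 25_000_000
    ld_decay_rate: dict = field(default_factory=lambda: {"PL": 2.5e-7, "DE": 5.0e-7})
    fst: float = 0.01
    effect_corr: float = 0.3
    sigma2_a: dict = field(default_factory=lambda: {"PL": 1.0, "DE": 2.0})
    sigma2_e: float = 10.0
    edc_meanlog: float = 4.0
    edc_sdlog: float = 0.7
    missing_rate: float = 0.002
    pedigree_depth: int = 2       # non-genotyped generations above the genotyped one
    trait: str = "MY"
    trait_mean: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if not -1 <= self.effect_corr <= 1:
            raise ValueError("effect_corr must lie in [-1, 1]")
        if any(r <= 0 for r in self.ld_decay_rate.values()):
            raise ValueError("ld decay rates must be positive")

    @property
    def populations(self) -> list[str]:
        return list(self.ld_decay_rate)

    def true_G(self) -> np.ndarray:
        """True per-SNP effect (co)variance matrix across populations."""
        va, vb = (self.sigma2_a[p] / self.n_snp for p in self.populations)
        c = self.effect_corr * np.sqrt(va * vb)
        return np.array([[va, c], [c, vb]])


@dataclass
class SimTruth:
    """Generating values stored with every dataset for recovery tests."""

    base_freqs: np.ndarray
    pop_freqs: dict
    true_effects: dict
    true_G: np.ndarray
    decay_rates: dict


@dataclass
class PopulationData:
    haplotypes: HaplotypePanel
    genotypes: GenotypePanel
    pedigree: Pedigree
    proofs: DeregressedProofs


@dataclass
class SimDataset:
    config: SimConfig
    truth: SimTruth
    populations: dict  # label -> PopulationData


def simulate_base_freqs(n_snp: int, seed) -> np.ndarray:
    """Ancestral allele frequencies, uniform on [0.05, 0.95]."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(0.05, 0.95, size=n_snp)


def make_snp_map(cfg: SimConfig, rng: np.random.Generator):
    """One shared marker map: (chrom labels, positions, snp ids)."""
    per = np.full(cfg.n_chrom, cfg.n_snp // cfg.n_chrom)
    per[: cfg.n_snp % cfg.n_chrom] += 1
    chrom, pos = [], []
    for c in range(cfg.n_chrom):
        p = np.sort(rng.integers(1, cfg.chrom_length_bp - cfg.n_snp, size=per[c]))
        p = p + np.arange(per[c])  # enforce strictly increasing positions
        chrom.append(np.full(per[c], str(c + 1)))
        pos.append(p)
    chrom = np.concatenate(chrom)
    pos = np.concatenate(pos)
    snp_ids = [f"snp{c}_{p}" for c, p in zip(chrom, pos)]
    return chrom, pos.astype(np.int64), snp_ids


def balding_nichols(base: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Population frequencies drifted from the base with dispersion F p(1-p)."""
    a = base * (1.0 - fst) / fst
    b = (1.0 - base) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)


def _copying_haplotypes(
    freqs: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    n_hap: int,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder haplotypes with exp(-rate*d) latent correlation along chromosomes."""
    n_snp = freqs.size
    c = np.zeros(n_snp)
    c[1:] = np.where(
        chrom[1:] == chrom[:-1], np.exp(-rate * np.diff(pos).astype(float)), 0.0
    )
    thresh = norm.ppf(freqs)
    H = np.empty((n_hap, n_snp), dtype=np.int8)
    z = rng.standard_normal(n_hap)
    H[:, 0] = z < thresh[0]
    for k in range(1, n_snp):
        z = c[k] * z + np.sqrt(1.0 - c[k] ** 2) * rng.standard_normal(n_hap)
        H[:, k] = z < thresh[k]
    return H


def _meiosis(
    hap0: np.ndarray,
    hap1: np.ndarray,
    switch_p: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a parent's haplotype pair with Haldane recombination."""
    switches = rng.random(switch_p.size) < switch_p
    choice = np.cumsum(switches) % 2
    return np.where(choice == 1, hap1, hap0)


def simulate_population(
    base_freqs: np.ndarray,
    snp_map,
    cfg: SimConfig,
    pop: str,
    rng: np.random.Generator,
):
    """Haplotypes, genotypes and pedigree for one drifted population.

    Returns ``(HaplotypePanel, GenotypePanel, Pedigree, pop_freqs)``.  The
    founder generation carries the drifted population frequencies; later
    generations arise by random mating and gene dropping, the last one being
    the genotyped sample.
    """
    chrom, pos, snp_ids = snp_map
    pop_freqs = balding_nichols(base_freqs, cfg.fst, rng)
    n = cfg.n_animals
    n_gen = cfg.pedigree_depth + 1

    # per-interval recombination probabilities; chromosome starts re-draw at 1/2
    switch_p = np.empty(pos.size)
    switch_p[0] = 0.5
    d = np.diff(pos).astype(float)
    switch_p[1:] = np.where(
        chrom[1:] == chrom[:-1], 0.5 * (1.0 - np.exp(-2.0 * d * MORGAN_PER_BP)), 0.5
    )

    rate = cfg.ld_decay_rate[pop]
    haps = _copying_haplotypes(pop_freqs, chrom, pos, 2 * n, rate, rng)

    animal_ids: list[str] = []
    sire_ids: list[str] = []
    dam_ids: list[str] = []
    gen_ids = [f"{pop}_G0_{i}" for i in range(n)]
    animal_ids += gen_ids
    sire_ids += [UNKNOWN_PARENT] * n
    dam_ids += [UNKNOWN_PARENT] * n

    for g in range(1, n_gen):
        prev_ids = gen_ids
        gen_ids = [f"{pop}_G{g}_{i}" for i in range(n)]
        new_haps = np.empty_like(haps)
        for i in range(n):
            si, di = rng.choice(n, size=2, replace=False)
            new_haps[2 * i] = _meiosis(haps[2 * si], haps[2 * si + 1], switch_p, rng)
            new_haps[2 * i + 1] = _meiosis(haps[2 * di], haps[2 * di + 1], switch_p, rng)
            animal_ids.append(gen_ids[i])
            sire_ids.append(prev_ids[si])
            dam_ids.append(prev_ids[di])
        haps = new_haps

    genotyped = np.zeros(len(animal_ids), dtype=bool)
    genotyped[-n:] = True
    ped = Pedigree(animal_ids, sire_ids, dam_ids, genotyped)

    hap_panel = HaplotypePanel(
        population_id=pop, animal_ids=gen_ids, snp_ids=list(snp_ids),
        chrom=chrom, pos_bp=pos, haplotypes=haps,
    )
    geno = hap_panel.to_genotypes()
    if cfg.missing_rate > 0:
        mask = rng.random(geno.genotypes.shape) < cfg.missing_rate
        g = geno.genotypes.copy()
        g[mask] = MISSING
        geno.genotypes = g
    return hap_panel, geno, ped, pop_freqs


def simulate_effects(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """True per-SNP effects, correlated across the two populations."""
    G = cfg.true_G()
    L = np.linalg.cholesky(G)
    eff = rng.standard_normal((cfg.n_snp, 2)) @ L.T
    return {p: eff[:, i] for i, p in enumerate(cfg.populations)}


def simulate_proofs(
    panel: GenotypePanel,
    true_effects: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> DeregressedProofs:
    """Deregressed proofs with EDC-weighted residuals for one population."""
    Z = design_matrix(panel)
    edc = rng.lognormal(cfg.edc_meanlog, cfg.edc_sdlog, size=panel.n_animals)
    e = rng.standard_normal(panel.n_animals) * np.sqrt(cfg.sigma2_e / edc)
    y = cfg.trait_mean + Z @ true_effects + e
    return DeregressedProofs(list(panel.animal_ids), cfg.trait, y, edc)


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Full two-population dataset: panels, pedigrees, proofs and the truth."""
    rng = np.random.default_rng(cfg.seed)
    base = simulate_base_freqs(cfg.n_snp, rng)
    snp_map = make_snp_map(cfg, rng)
    effects = simulate_effects(cfg, rng)

    pops: dict[str, PopulationData] = {}
    pop_freqs: dict[str, np.ndarray] = {}
    for p in cfg.populations:
        hap, geno, ped, freqs = simulate_population(base, snp_map, cfg, p, rng)
        proofs = simulate_proofs(geno, effects[p], cfg, rng)
        pops[p] = PopulationData(hap, geno, ped, proofs)
        pop_freqs[p] = freqs

    truth = SimTruth(
        base_freqs=base,
        pop_freqs=pop_freqs,
        true_effects=effects,
        true_G=cfg.true_G(),
        decay_rates=dict(cfg.ld_decay_rate),
    )
    return SimDataset(config=cfg, truth=truth, populations=pops)
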
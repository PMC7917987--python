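"""Synthetic multi-generation herd: pedigree, gene-dropped genotypes,
and traits with configurable genetic architecture.

The generator mirrors the structure a single-step evaluation consumes:
a discrete-generation pedigree, biallelic SNP genotypes transmitted from
founder haplotypes by Mendelian segregation with recombination (1
crossover per Morgan, bp mapped linearly at 100 Mb/Morgan), and a trait
built from a handful of large QTL (oligogenic, carcass-weight-like) or
many tiny ones (polygenic, marbling-like), a pedigree-transmitted
polygenic remainder, fixed batch effects, and i.i.d. residuals.
Genotyping is restricted to a subset of animals, always including the
youngest (validation) generation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genomic import MarkerPanel
from .pedigree import UNKNOWN_PARENT, PedigreeTable, inbreeding

MORGAN_BP = 100_000_000  # 1 cM per Mb


class SimulationError(ValueError):
    pass


@dataclass
class SimulationScenario:
    """Knobs of one synthetic herd; defaults follow the oligogenic preset."""

    name: str = "oligogenic"
    n_founders: int = 400
    n_generations: int = 5          # founders + 4 offspring generations
    n_offspring_per_gen: int = 400
    n_sires_per_gen: int = 25
    n_snps: int = 2000
    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    n_qtl: int = 5
    qtl_var_total: float = 0.80     # fraction of additive variance on the QTL
    h2: float = 0.35
    sigma_p2: float = 100.0         # phenotypic variance, trait units^2
    mu: float = 350.0
    trait: str = "trait"
    n_batches_per_gen: int = 4
    batch_sd: float = 5.0
    phenotyped_fraction: float = 1.0   # validation generation always recorded
    genotyped_fraction: float = 0.40
    base_year: int = 2000
    seed: int = 1

    def __post_init__(self):
        if not 0 < self.h2 < 1:
            raise SimulationError("h2 must lie in (0,1)")
        if self.n_qtl > self.n_snps:
            raise SimulationError("n_qtl exceeds n_snps")
        if not 0 <= self.qtl_var_total <= 1:
            raise SimulationError("qtl_var_total must lie in [0,1]")
        for f in ("n_founders", "n_generations", "n_offspring_per_gen",
                  "n_sires_per_gen", "n_snps", "n_chromosomes"):
            if getattr(self, f) < 1:
                raise SimulationError(f"{f} must be positive")

    @property
    def sigma_a2(self) -> float:
        return self.h2 * self.sigma_p2

    @property
    def sigma_e2(self) -> float:
        return (1.0 - self.h2) * self.sigma_p2

    @property
    def last_year(self) -> int:
        return self.base_year + self.n_generations - 1

    @property
    def cutoff_year(self) -> int:
        """Training includes everything before the last generation."""
        return self.last_year - 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationScenario":
        return cls(**d)


def scenario_presets(name: str) -> SimulationScenario:
    """Study presets: few large QTL vs many small ones.

    oligogenic: 5 QTL carrying 80% of the additive variance (remainder
    polygenic); polygenic: 500 equal-effect QTL carrying all of it.
    """
    if name == "oligogenic":
        return SimulationScenario(name="oligogenic", n_qtl=5, qtl_var_total=0.80,
                                  phenotyped_fraction=0.5, seed=1)
    if name == "polygenic":
        return SimulationScenario(name="polygenic", n_qtl=500, qtl_var_total=1.0,
                                  phenotyped_fraction=0.5, seed=1)
    raise SimulationError(f"unknown scenario {name!r}; choose oligogenic or polygenic")


@dataclass
class TruthRecord:
    """Ground truth of a simulated trait for parameter-recovery checks."""

    tbv: pd.Series                 # true breeding value per animal
    snp_effects: np.ndarray        # per-SNP allele substitution effect
    qtl_indices: np.ndarray        # column positions of the QTL
    batch_effects: pd.Series       # per batch level


@dataclass
class SimulatedHerd:
    scenario: SimulationScenario
    pedigree: PedigreeTable
    panel_all: MarkerPanel         # genotypes of every animal
    panel: MarkerPanel             # genotyped subset only
    phenotypes: pd.DataFrame       # animal, trait, batch, birth_year
    truth: TruthRecord
    haplotypes: np.ndarray = field(repr=False, default=None)


def _generation_slices(scn: SimulationScenario):
    sizes = [scn.n_founders] + [scn.n_offspring_per_gen] * (scn.n_generations - 1)
    offsets = np.cumsum([0] + sizes)
    return [(int(offsets[g]), int(offsets[g + 1])) for g in range(scn.n_generations)]


def simulate_pedigree(scn: SimulationScenario, rng: np.random.Generator) -> PedigreeTable:
    """Discrete generations; sires drawn from a small male pool per generation."""
    slices = _generation_slices(scn)
    n_total = slices[-1][1]
    width = len(str(n_total))
    ids = np.array([f"A{i + 1:0{width}d}" for i in range(n_total)], dtype=object)
    sire = np.full(n_total, UNKNOWN_PARENT, dtype=object)
    dam = np.full(n_total, UNKNOWN_PARENT, dtype=object)
    year = np.empty(n_total, dtype=np.int64)
    sex = np.empty(n_total, dtype=np.int8)  # 0 male, 1 female
    for g, (lo, hi) in enumerate(slices):
        year[lo:hi] = scn.base_year + g
        sex[lo:hi] = rng.integers(0, 2, size=hi - lo)
        if g == 0:
            continue
        plo, phi = slices[g - 1]
        prev = np.arange(plo, phi)
        males = prev[sex[plo:phi] == 0]
        females = prev[sex[plo:phi] == 1]
        if len(males) == 0 or len(females) == 0:
            raise SimulationError("a generation lacks one sex; infeasible matings")
        k = min(scn.n_sires_per_gen, len(males))
        sires = rng.choice(males, size=k, replace=False)
        for i in range(lo, hi):
            sire[i] = ids[rng.choice(sires)]
            dam[i] = ids[rng.choice(females)]
    return PedigreeTable(ids, sire, dam, year)


def simulate_genotypes(
    ped: PedigreeTable, scn: SimulationScenario, rng: np.random.Generator
) -> tuple[MarkerPanel, np.ndarray]:
    """Gene dropping with recombination; returns the panel and haplotypes."""
    if not ped.is_sorted():
        raise SimulationError("pedigree must be sorted before gene dropping")
    m = scn.n_snps
    per_chrom = np.full(scn.n_chromosomes, m // scn.n_chromosomes)
    per_chrom[: m % scn.n_chromosomes] += 1
    chroms, poss = [], []
    for c, k in enumerate(per_chrom, start=1):
        pos = np.unique(rng.integers(1, scn.chrom_length_bp, size=2 * k + 16))
        while len(pos) < k:  # pragma: no cover - astronomically unlikely top-up
            pos = np.unique(np.concatenate([pos, rng.integers(1, scn.chrom_length_bp, size=k)]))
        pos = np.sort(rng.choice(pos, size=k, replace=False))
        chroms.append(np.full(k, c))
        poss.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    snp_map = pd.DataFrame(
        {"snp": [f"snp{j + 1:05d}" for j in range(m)], "chrom": chrom, "pos_bp": pos}
    )
    # adjacent recombination fractions (Haldane), 0.5 across chromosome breaks
    d_morgan = np.diff(pos) / MORGAN_BP
    rfrac = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    rfrac[np.diff(chrom) != 0] = 0.5
    founder_p = rng.uniform(0.05, 0.95, size=m)

    s_idx, d_idx = ped.parent_codes()
    haps = np.zeros((ped.n, 2, m), dtype=np.int8)

    def gamete(parent: int) -> np.ndarray:
        switch = rng.random(m - 1) < rfrac
        src = np.empty(m, dtype=np.int8)
        src[0] = rng.integers(0, 2)
        src[1:] = switch
        src = np.cumsum(src) % 2
        return haps[parent, src, np.arange(m)]

    for i in range(ped.n):
        for h, par in enumerate((s_idx[i], d_idx[i])):
            if par < 0:
                haps[i, h] = (rng.random(m) < founder_p).astype(np.int8)
            else:
                haps[i, h] = gamete(par)
    genotypes = haps.sum(axis=1).astype(np.int8)
    return MarkerPanel(ids=ped.animal.copy(), genotypes=genotypes, snp_map=snp_map), haps


def simulate_trait(
    panel: MarkerPanel,
    ped: PedigreeTable,
    scn: SimulationScenario,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Trait = mu + batch + TBV + e, with TBV split QTL / polygenic."""
    if panel.n != ped.n:
        raise SimulationError("trait simulation needs genotypes for every animal")
    m = panel.m
    # QTL are common, observable panel variants: a near-fixed SNP cannot
    # carry its variance share without a degenerate allele effect
    freq = panel.genotypes.mean(axis=0) / 2.0
    common = np.flatnonzero(np.minimum(freq, 1 - freq) >= 0.1)
    pool = common if len(common) >= scn.n_qtl else np.arange(m)
    qtl = np.sort(rng.choice(pool, size=scn.n_qtl, replace=False))
    frac = np.full(scn.n_qtl, scn.qtl_var_total / scn.n_qtl)
    geno = panel.genotypes.astype(float)
    beta = np.zeros(m)
    for j, f in zip(qtl, frac):
        vg = np.var(geno[:, j])
        if vg <= 0:
            vg = 1e-6
        beta[j] = rng.choice([-1.0, 1.0]) * np.sqrt(f * scn.sigma_a2 / vg)
    qtl_bv = (geno[:, qtl] - geno[:, qtl].mean(axis=0)) @ beta[qtl]
    # pedigree-transmitted polygenic remainder via Mendelian-sampling recursion
    poly_var = (1.0 - scn.qtl_var_total) * scn.sigma_a2
    u_poly = np.zeros(ped.n)
    if poly_var > 0:
        s_idx, d_idx = ped.parent_codes()
        F = inbreeding(ped)
        for i in range(ped.n):
            si, di = s_idx[i], d_idx[i]
            if si < 0 and di < 0:
                u_poly[i] = rng.normal(0.0, np.sqrt(poly_var))
            else:
                pa = 0.0
                ms_var = poly_var
                if si >= 0 and di >= 0:
                    pa = 0.5 * (u_poly[si] + u_poly[di])
                    ms_var = 0.5 * poly_var * (1.0 - 0.5 * (F[si] + F[di]))
                else:
                    p = si if si >= 0 else di
                    pa = 0.5 * u_poly[p]
                    ms_var = 0.75 * poly_var * (1.0 - F[p] / 3.0)
                u_poly[i] = pa + rng.normal(0.0, np.sqrt(ms_var))
    tbv = qtl_bv + u_poly
    gen = ped.birth_year - scn.base_year
    batch_idx = rng.integers(0, scn.n_batches_per_gen, size=ped.n)
    batch_label = np.array(
        [f"g{g}_b{b}" for g, b in zip(gen, batch_idx)], dtype=object
    )
    levels = pd.unique(batch_label)
    batch_eff = pd.Series(rng.normal(0.0, scn.batch_sd, size=len(levels)), index=levels)
    e = rng.normal(0.0, np.sqrt(scn.sigma_e2), size=ped.n)
    y = scn.mu + batch_eff.loc[batch_label].to_numpy() + tbv + e
    phen = pd.DataFrame(
        {
            "animal": ped.animal,
            scn.trait: y,
            "batch": batch_label,
            "birth_year": ped.birth_year,
        }
    )
    if scn.phenotyped_fraction < 1.0:
        # partial recording, as in field data; the validation generation is
        # always measured so masked adjusted phenotypes exist for it
        keep = rng.random(ped.n) < scn.phenotyped_fraction
        keep |= ped.birth_year == scn.last_year
        phen = phen.loc[keep].reset_index(drop=True)
    truth = TruthRecord(
        tbv=pd.Series(tbv, index=ped.animal),
        snp_effects=beta,
        qtl_indices=qtl,
        batch_effects=batch_eff,
    )
    return phen, truth


def genotyping_mask(
    ped: PedigreeTable, scn: SimulationScenario, rng: np.random.Generator
) -> np.ndarray:
    """Genotyped ids: the whole last generation plus a random older fill."""
    target = int(round(scn.genotyped_fraction * ped.n))
    last = ped.birth_year == scn.last_year
    chosen = set(np.flatnonzero(last))
    # fill from the two generations preceding validation (phenotyped
    # candidates and parents of the validation animals, as in progeny tests)
    older = np.flatnonzero(~last & (ped.birth_year >= scn.last_year - 2))
    need = max(0, target - len(chosen))
    if need and len(older):
        extra = rng.choice(older, size=min(need, len(older)), replace=False)
        chosen.update(extra.tolist())
    idx = np.sort(np.fromiter(chosen, dtype=np.int64))
    return ped.animal[idx]


def simulate_herd(scn: SimulationScenario, seed: int | None = None) -> SimulatedHerd:
    """End-to-end: pedigree, genotypes, trait and genotyping mask."""
    rng = np.random.default_rng(scn.seed if seed is None else seed)
    ped = simulate_pedigree(scn, rng)
    panel_all, haps = simulate_genotypes(ped, scn, rng)
    phen, truth = simulate_trait(panel_all, ped, scn, rng)
    gids = genotyping_mask(ped, scn, rng)
    panel = panel_all.subset_animals(gids)
    return SimulatedHerd(
        scenario=scn, pedigree=ped, panel_all=panel_all, panel=panel,
        phenotypes=phen, truth=truth, haplotypes=haps,
    )
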
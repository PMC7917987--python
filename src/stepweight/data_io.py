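"""Readers/writers for pedigree, genotype, phenotype and config files,
plus the end-to-end pipeline: adjust -> split -> solve (PBLUP, ssGBLUP,
WssGBLUP iterations) -> evaluate.

File formats
------------
* pedigree: CSV/TSV ``animal,sire,dam,birth_year``; unknown parents "0".
* genotypes: whitespace-delimited matrix, header = SNP names, first
  column = animal id, entries 0/1/2; sidecar map CSV ``snp,chrom,pos_bp``.
  A PLINK .raw-style additive export (6 leading columns, ``SNP_A``
  headers) is accepted for interoperability.
* phenotypes: CSV with a header naming the trait and fixed-effect
  columns; empty cells are missing, flagged but never imputed.
* config: YAML key-value file, see :class:`PipelineConfig`.
"""

from __future__ import annotations

import io
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import evaluate, split_by_birth_year
from .genomic import GenomicError, MarkerPanel, filter_snps
from .mixed_model import (
    VarianceComponents,
    adjust_phenotypes,
    incidence,
    make_design,
    pblup,
    solve_blup,
)
from .pedigree import (
    UNKNOWN_PARENT,
    PedigreeTable,
    build_A_inverse,
    sort_pedigree,
)
from .simulate import SimulationScenario, scenario_presets, simulate_herd
from .weighting import WeightStrategy, run_weighting_iterations


class DataError(ValueError):
    pass


def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if "\t" in head else ","


def read_pedigree(path) -> PedigreeTable:
    """Read and topologically sort a pedigree file."""
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    required = {"animal", "sire", "dam", "birth_year"}
    if not required.issubset(df.columns):
        raise DataError(f"pedigree needs columns {sorted(required)}, got {list(df.columns)}")
    for col in ("sire", "dam"):
        df[col] = df[col].fillna(UNKNOWN_PARENT)
    ped = PedigreeTable(
        df["animal"].to_numpy(dtype=object),
        df["sire"].to_numpy(dtype=object),
        df["dam"].to_numpy(dtype=object),
        df["birth_year"].astype(int).to_numpy(),
    )
    return sort_pedigree(ped)


def write_pedigree(path, ped: PedigreeTable) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_genotypes(path, map_path, dialect: str = "matrix-text") -> MarkerPanel:
    """Read a 0/1/2 genotype matrix plus its marker map.

    ``dialect='matrix-text'``: header of SNP names, rows ``id g1 g2 ...``.
    ``dialect='plink-raw-like'``: PLINK .raw additive export; the IID
    column identifies animals and ``SNP_A`` headers are stripped to SNP
    names.
    """
    snp_map = pd.read_csv(map_path)
    if not {"snp", "chrom", "pos_bp"}.issubset(snp_map.columns):
        raise DataError("map needs columns snp,chrom,pos_bp")
    df = pd.read_csv(path, sep=r"\s+")
    if dialect == "plink-raw-like":
        lead = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
        if "IID" not in lead:
            raise DataError("plink-raw-like file lacks an IID column")
        ids = df["IID"].astype(str).to_numpy(dtype=object)
        geno_df = df.drop(columns=lead)
        geno_df.columns = [re.sub(r"_[ACGT0-9]+$", "", c) for c in geno_df.columns]
    elif dialect == "matrix-text":
        ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
        geno_df = df.iloc[:, 1:]
    else:
        raise DataError(f"unknown genotype dialect {dialect!r}")
    if geno_df.shape[1] != len(snp_map):
        raise DataError(
            f"matrix has {geno_df.shape[1]} SNP columns but map lists {len(snp_map)}"
        )
    vals = geno_df.to_numpy()
    bad = ~np.isin(vals, [0, 1, 2]) & ~pd.isna(vals)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise DataError(
            f"invalid genotype code {vals[r, c]} at row {ids[r]!r}, "
            f"column {geno_df.columns[c]!r} (must be 0/1/2 or missing)"
        )
    if pd.isna(vals).any():
        raise DataError("missing genotypes present; complete the matrix first "
                        "(see mean_impute)")
    # align matrix columns with (chrom, pos) map order
    snp_map = snp_map.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
    order = [list(geno_df.columns).index(s) for s in snp_map["snp"]]
    genotypes = vals[:, order].astype(np.int8)
    return MarkerPanel(ids=ids, genotypes=genotypes, snp_map=snp_map)


def write_genotypes(path, map_path, panel: MarkerPanel) -> None:
    with open(path, "w") as fh:
        fh.write("id " + " ".join(panel.snp_map["snp"]) + "\n")
        for i, a in enumerate(panel.ids):
            fh.write(str(a) + " " + " ".join(map(str, panel.genotypes[i])) + "\n")
    panel.snp_map.to_csv(map_path, index=False)


def mean_impute(genotypes: np.ndarray) -> np.ndarray:
    """Replace missing entries by the column mean (preprocessing utility)."""
    g = np.asarray(genotypes, dtype=float)
    means = np.nanmean(g, axis=0)
    nan = np.isnan(g)
    g[nan] = np.take(means, np.where(nan)[1])
    return g


def read_phenotypes(path, ped: PedigreeTable | None = None) -> pd.DataFrame:
    """Typed phenotype table; missing values flagged, never imputed."""
    try:
        df = pd.read_csv(path, sep=_sniff_sep(path))
    except pd.errors.EmptyDataError:
        raise DataError(f"phenotype file {path} is empty") from None
    if df.empty:
        raise DataError(f"phenotype file {path} has no records")
    if "animal" not in df.columns:
        raise DataError("phenotype file needs an 'animal' column")
    df["animal"] = df["animal"].astype(str)
    if ped is not None:
        missing = sorted(set(df["animal"]) - set(ped.animal))
        if missing:
            raise DataError(f"animals absent from pedigree: {missing[:10]}")
    return df


@dataclass
class PipelineConfig:
    """Everything one evaluation run needs, YAML-serializable."""

    trait: str = "trait"
    sigma_a2: float = 35.0
    sigma_e2: float = 65.0
    strategy: str = "default"
    ct: float = 1.25
    cap: float = 5.0
    window_size: int = 75
    n_iterations: int = 10
    cutoff_year: int | None = None
    maf_min: float = 0.01
    hwe_dev_max: float = 0.15
    g_coef: float = 0.95
    a_coef: float = 0.05
    seed: int = 1
    fixed_factors: list = field(default_factory=lambda: ["batch"])
    covariates: list = field(default_factory=list)
    scenario: str | None = None        # simulate instead of reading files
    pedigree_path: str | None = None
    genotypes_path: str | None = None
    map_path: str | None = None
    phenotypes_path: str | None = None
    outdir: str | None = None

    def __post_init__(self):
        if self.g_coef <= 0 or self.a_coef <= 0:
            raise DataError("blend coefficients must be positive")
        if self.n_iterations < 1:
            raise DataError("n_iterations must be >= 1")
        for t in (self.maf_min, self.hwe_dev_max):
            if not 0 <= t <= 0.5:
                raise DataError("filter thresholds must lie in [0, 0.5]")

    def weight_strategy(self) -> WeightStrategy:
        return WeightStrategy(
            name=self.strategy, ct=self.ct, cap=self.cap, window_size=self.window_size
        )

    def variance_components(self) -> VarianceComponents:
        return VarianceComponents(self.sigma_a2, self.sigma_e2)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    report: pd.DataFrame
    traces: dict
    y_adj: pd.Series
    train_ids: np.ndarray
    val_ids: np.ndarray
    pedigree: PedigreeTable
    panel: MarkerPanel
    filter_log: pd.DataFrame


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, DataError):
                raise DataError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute adjust -> split -> solve -> evaluate, reproducibly by seed."""
    rng_seed = int(config.seed)
    if config.scenario is None and config.cutoff_year is None:
        raise DataError("cutoff_year is required when reading files")
    with _stage("load"):
        if config.scenario is not None:
            scn = scenario_presets(config.scenario)
            herd = simulate_herd(scn, seed=rng_seed)
            ped, panel, phen = herd.pedigree, herd.panel, herd.phenotypes
            trait = scn.trait
            cutoff = config.cutoff_year if config.cutoff_year is not None else scn.cutoff_year
        else:
            ped = read_pedigree(config.pedigree_path)
            panel = read_genotypes(config.genotypes_path, config.map_path)
            phen = read_phenotypes(config.phenotypes_path, ped)
            trait = config.trait
            cutoff = config.cutoff_year
    with _stage("filter"):
        panel, flog = filter_snps(panel, config.maf_min, config.hwe_dev_max)
    vc = config.variance_components()
    with _stage("adjust"):
        recorded = phen.dropna(subset=[trait])
        X, names = make_design(recorded, factors=config.fixed_factors,
                               covariates=config.covariates)
        A_inv = build_A_inverse(ped)
        Z = incidence(recorded["animal"].to_numpy(dtype=object), ped)
        fit = solve_blup(
            recorded[trait].to_numpy(dtype=float), X, Z, A_inv, vc,
            fixed_names=names, animal_ids=ped.animal,
            record_animals=recorded["animal"].to_numpy(dtype=object),
        )
        y_adj = adjust_phenotypes(fit)
    with _stage("split"):
        train_ids, val_ids = split_by_birth_year(y_adj.index, ped, cutoff)
        y_train = y_adj.loc[train_ids]
        y_val = y_adj.loc[val_ids]

    def evaluator(gebv: pd.Series) -> dict:
        return evaluate(y_val, gebv, vc.h2)

    rows = []
    with _stage("pblup"):
        fit_p = pblup(ped, y_train, vc, A_inv=A_inv)
        rows.append({"method": "PBLUP", "strategy": "-", "iteration": 1,
                     **evaluator(fit_p.a)})
    with _stage("wssgblup"):
        trace = run_weighting_iterations(
            ped, panel, y_train, vc,
            strategy=config.weight_strategy(), n_iter=config.n_iterations,
            g_coef=config.g_coef, a_coef=config.a_coef, evaluator=evaluator,
        )
        for rec in trace.records:
            method = "ssGBLUP" if rec.iteration == 1 else "WssGBLUP"
            rows.append({"method": method, "strategy": config.strategy,
                         "iteration": rec.iteration, **rec.metrics})
    report = pd.DataFrame(rows)
    wmask = report["method"].isin(["ssGBLUP", "WssGBLUP"])
    best_it = report.loc[wmask, "accuracy"].idxmax()
    report["is_best_iteration"] = False
    report.loc[best_it, "is_best_iteration"] = True

    result = PipelineResult(
        report=report, traces={config.strategy: trace}, y_adj=y_adj,
        train_ids=train_ids, val_ids=val_ids, pedigree=ped, panel=panel,
        filter_log=flog,
    )
    if config.outdir:
        write_outputs(Path(config.outdir), result)
    return result


def write_outputs(outdir: Path, result: PipelineResult) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    result.report.to_csv(outdir / "report.csv", index=False, float_format=fmt)
    result.filter_log.to_csv(outdir / "filter_log.csv", index=False, float_format=fmt)
    result.pedigree.id_map().to_csv(outdir / "id_map.csv", index=False)
    snps = result.panel.snp_map["snp"]
    for trace in result.traces.values():
        for rec in trace.records:
            t = rec.iteration
            pd.DataFrame({"snp": snps, "d": rec.weights.d}).to_csv(
                outdir / f"weights_iter{t}.csv", index=False, float_format=fmt)
            pd.DataFrame({"snp": snps, "u_hat": rec.effects.u_hat,
                          "var_u": rec.effects.var_u}).to_csv(
                outdir / f"snp_effects_iter{t}.csv", index=False, float_format=fmt)
            rec.gebv.rename("gebv").rename_axis("animal").to_csv(
                outdir / f"gebv_iter{t}.csv", float_format=fmt)


def write_simulated_herd(outdir, herd) -> PipelineConfig:
    """Emit the exact file formats the readers consume, plus truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(outdir / "pedigree.csv", herd.pedigree)
    write_genotypes(outdir / "genotypes.txt", outdir / "map.csv", herd.panel)
    herd.phenotypes.to_csv(outdir / "phenotypes.csv", index=False, float_format="%.10g")
    herd.truth.tbv.rename("tbv").rename_axis("animal").to_csv(
        outdir / "truth.csv", float_format="%.10g")
    snps = herd.panel_all.snp_map["snp"]
    is_qtl = np.zeros(len(snps), dtype=bool)
    is_qtl[herd.truth.qtl_indices] = True
    pd.DataFrame({"snp": snps, "effect": herd.truth.snp_effects,
                  "is_qtl": is_qtl}).to_csv(outdir / "truth_snps.csv",
                                            index=False, float_format="%.10g")
    scn = herd.scenario
    cfg = PipelineConfig(
        trait=scn.trait, sigma_a2=scn.sigma_a2, sigma_e2=scn.sigma_e2,
        cutoff_year=scn.cutoff_year, seed=scn.seed,
        pedigree_path=str(outdir / "pedigree.csv"),
        genotypes_path=str(outdir / "genotypes.txt"),
        map_path=str(outdir / "map.csv"),
        phenotypes_path=str(outdir / "phenotypes.csv"),
        outdir=str(outdir / "results"),
    )
    cfg.to_yaml(outdir / "config.yaml")
    return cfg
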
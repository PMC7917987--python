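"""Iterative SNP weighting for weighted single-step GBLUP.

From a single-step solve, SNP effects are back-solved from the direct
genomic values of the genotyped animals,

    u_hat = lambda * D * M' * G^-1 * a_hat,   lambda = 1 / (2 Σ p_i(1-p_i)),

their per-SNP variances sigma2_u,i = 2 p_i (1-p_i) u_hat_i^2 feed one of
six weighting strategies (single-SNP: default / constant / nonlinear-A;
window: largest / mean / summed over consecutive SNP groups), the
weights are normalized to mean one, the genomic matrix is rebuilt, and
the evaluation is re-solved. Iteration 1 always uses unit weights and is
exactly the unweighted single-step evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomic import (
    MarkerPanel,
    allele_frequencies,
    blend_G,
    build_G,
    build_H_inverse,
    center_genotypes,
    vanraden_denominator,
)
from .mixed_model import BlupSolution, VarianceComponents, incidence, solve_blup
from .pedigree import PedigreeTable, build_A_inverse, extract_A22

SINGLE_STRATEGIES = ("default", "constant", "nonlinearA")
WINDOW_STRATEGIES = ("window_largest", "window_mean", "window_summed")
STRATEGIES = SINGLE_STRATEGIES + WINDOW_STRATEGIES


class WeightingError(ValueError):
    pass


@dataclass(frozen=True)
class WeightStrategy:
    """Tag + parameters of one weighting rule.

    ct/cap apply to nonlinear-A (departure from normality and the upper
    limit on a SNP's variance change); window_size to the window rules.
    """

    name: str = "default"
    ct: float = 1.25
    cap: float = 5.0
    window_size: int = 75
    span_chromosomes: bool = False

    def __post_init__(self):
        if self.name not in STRATEGIES:
            raise WeightingError(f"unknown strategy {self.name!r}; choose from {STRATEGIES}")
        if self.window_size < 1:
            raise WeightingError("window_size must be >= 1")


@dataclass
class WeightState:
    """Diagonal SNP-weight vector with provenance."""

    d: np.ndarray
    iteration: int
    strategy: WeightStrategy

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.iteration >= 1 and np.any(self.d <= 0):
            raise WeightingError("normalized weights must be strictly positive")


@dataclass
class SnpEffects:
    """Back-solved SNP effects and their per-SNP genetic variances."""

    u_hat: np.ndarray
    var_u: np.ndarray  # 2 p (1-p) u^2
    iteration: int


@dataclass
class IterationRecord:
    iteration: int
    weights: WeightState
    effects: SnpEffects
    gebv: pd.Series
    dgv: np.ndarray
    metrics: dict | None = None


@dataclass
class IterationTrace:
    strategy: WeightStrategy
    records: list[IterationRecord] = field(default_factory=list)
    constant_c: float | None = None

    def __len__(self):
        return len(self.records)

    def __getitem__(self, t):
        return self.records[t]

    def report(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"iteration": r.iteration, "strategy": self.strategy.name}
            if r.metrics:
                row.update(r.metrics)
            rows.append(row)
        return pd.DataFrame(rows)


def backsolve_snp_effects(
    d: np.ndarray, M: np.ndarray, G_inv: np.ndarray, a_hat: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """u_hat = lambda * D * M' * G^-1 * a_hat over the genotyped animals."""
    d = np.asarray(d, dtype=float)
    a_hat = np.asarray(a_hat, dtype=float)
    if M.shape[1] != len(d) or M.shape[0] != len(a_hat) or G_inv.shape[0] != len(a_hat):
        raise WeightingError("dimension mismatch between weights, M, G^-1 and a_hat")
    lam = 1.0 / vanraden_denominator(p)
    return lam * d * (M.T @ (G_inv @ a_hat))


def compute_dgv(G_inv: np.ndarray, gebv: np.ndarray) -> np.ndarray:
    """Direct genomic values: DGV_i = -(sum_{j!=i} g^ij GEBV_j) / g^ii."""
    gebv = np.asarray(gebv, dtype=float)
    diag = np.diag(G_inv)
    if np.any(diag == 0):
        raise WeightingError("zero diagonal in G^-1")
    return gebv - (G_inv @ gebv) / diag


def snp_variances(u_hat: np.ndarray, p: np.ndarray) -> np.ndarray:
    return 2.0 * p * (1.0 - p) * np.asarray(u_hat) ** 2


def weight_default(effects: SnpEffects) -> np.ndarray:
    """Single-SNP weighting by the individual SNP genetic variance."""
    return effects.var_u.copy()


def weight_constant(effects: SnpEffects, c: float) -> np.ndarray:
    """Variance plus a constant c (the max SNP variance at iteration 1)."""
    if c <= 0:
        raise WeightingError("constant c must be positive")
    return effects.var_u + c


def weight_nonlinear_a(effects: SnpEffects, ct: float = 1.25, cap: float = 5.0) -> np.ndarray:
    """d_i = min(CT^(|u_i|/sd(u) - 2), cap); unit weights if sd(u) = 0."""
    u = effects.u_hat
    sd = float(np.std(u, ddof=1)) if len(u) > 1 else 0.0
    if sd == 0.0:
        warnings.warn("sd(u_hat) is zero; nonlinear-A weights fall back to 1", stacklevel=2)
        return np.ones_like(u, dtype=float)
    expo = np.abs(u) / sd - 2.0
    return np.minimum(np.power(ct, expo), cap)


def _window_groups(snp_map: pd.DataFrame, size: int, span_chromosomes: bool) -> np.ndarray:
    """Group label per SNP: consecutive non-overlapping blocks of ``size``."""
    m = len(snp_map)
    if span_chromosomes:
        return np.arange(m) // size
    labels = np.empty(m, dtype=np.int64)
    nxt = 0
    for _, idx in snp_map.groupby("chrom", sort=False).indices.items():
        idx = np.sort(idx)
        local = np.arange(len(idx)) // size
        labels[idx] = local + nxt
        nxt += local[-1] + 1
    return labels


def window_weights(
    effects: SnpEffects,
    snp_map: pd.DataFrame,
    size: int,
    mode: str,
    span_chromosomes: bool = False,
) -> np.ndarray:
    """Every SNP in a window gets the window's max/mean/sum of variances."""
    if size < 1:
        raise WeightingError("window size must be >= 1")
    if mode not in ("largest", "mean", "summed"):
        raise WeightingError(f"unknown window mode {mode!r}")
    groups = _window_groups(snp_map, size, span_chromosomes)
    s = pd.Series(effects.var_u)
    agg = {"largest": "max", "mean": "mean", "summed": "sum"}[mode]
    return s.groupby(groups).transform(agg).to_numpy()


def normalize_weights(d_raw: np.ndarray, floor_rel: float = 1e-8) -> np.ndarray:
    """Floor at floor_rel * mean, then rescale so the weights average one."""
    d_raw = np.asarray(d_raw, dtype=float)
    if np.any(d_raw < 0):
        raise WeightingError("raw weights must be non-negative")
    mean = d_raw.mean()
    if mean <= 0:
        raise WeightingError("all raw weights are zero")
    d = np.maximum(d_raw / mean, floor_rel)  # scale out first: overflow-safe
    return d * (len(d) / d.sum())


def strategy_weights(
    strategy: WeightStrategy,
    effects: SnpEffects,
    snp_map: pd.DataFrame,
    constant_c: float | None = None,
) -> np.ndarray:
    """Raw (pre-normalization) weights for the next iteration."""
    if strategy.name == "default":
        return weight_default(effects)
    if strategy.name == "constant":
        if constant_c is None:
            raise WeightingError("constant strategy requires c from iteration 1")
        return weight_constant(effects, constant_c)
    if strategy.name == "nonlinearA":
        return weight_nonlinear_a(effects, strategy.ct, strategy.cap)
    mode = strategy.name.removeprefix("window_")
    return window_weights(effects, snp_map, strategy.window_size, mode, strategy.span_chromosomes)


def run_weighting_iterations(
    ped: PedigreeTable,
    panel: MarkerPanel,
    y: pd.Series,
    vc: VarianceComponents,
    strategy: WeightStrategy | None = None,
    n_iter: int = 10,
    g_coef: float = 0.95,
    a_coef: float = 0.05,
    evaluator=None,
) -> IterationTrace:
    """Drive the weighted single-step loop for ``n_iter`` iterations.

    ``evaluator``, if given, is called with the GEBV series of each
    iteration and must return a metrics dict recorded in the trace.
    Iteration 1 uses unit weights (the unweighted single-step solve);
    iteration t back-solves SNP effects from iteration t-1's DGVs. The
    full trace is kept even when accuracy degrades: the best iteration
    is a post-hoc choice, never an early stop.
    """
    strategy = strategy or WeightStrategy()
    if n_iter < 1:
        raise WeightingError("n_iter must be >= 1")
    if not ped.is_sorted():
        raise WeightingError("pedigree must be sorted")
    A_inv = build_A_inverse(ped)
    A22 = extract_A22(ped, panel.ids)
    p = allele_frequencies(panel, warn_monomorphic=False)
    M = center_genotypes(panel.genotypes, p)
    gidx = np.array([ped.position(a) for a in panel.ids], dtype=np.int64)
    rec_animals = np.asarray(y.index, dtype=object)
    Z = incidence(rec_animals, ped)
    X = np.ones((len(y), 1))
    yv = y.to_numpy(dtype=float)

    trace = IterationTrace(strategy=strategy)
    d = np.ones(panel.m)
    for t in range(1, n_iter + 1):
        G = build_G(M, p, d)
        Gb = blend_G(G, A22, g_coef, a_coef)
        Gb_inv = np.linalg.inv(Gb)
        try:
            H_inv = build_H_inverse(A_inv, Gb, A22, gidx)
            sol = solve_blup(
                yv, X, Z, H_inv, vc,
                fixed_names=["mu"], animal_ids=ped.animal, record_animals=rec_animals,
            )
        except Exception as err:
            raise WeightingError(f"iteration {t} failed: {err}") from err
        gebv = sol.a
        dgv = compute_dgv(Gb_inv, gebv.to_numpy()[gidx])
        u_hat = backsolve_snp_effects(d, M, Gb_inv, dgv, p)
        effects = SnpEffects(u_hat=u_hat, var_u=snp_variances(u_hat, p), iteration=t)
        if t == 1:
            trace.constant_c = float(effects.var_u.max())
        metrics = evaluator(gebv) if evaluator is not None else None
        trace.records.append(
            IterationRecord(
                iteration=t,
                weights=WeightState(d=d.copy(), iteration=t, strategy=strategy),
                effects=effects,
                gebv=gebv,
                dgv=dgv,
                metrics=metrics,
            )
        )
        if t < n_iter:
            raw = strategy_weights(strategy, effects, panel.snp_map, trace.constant_c)
            d = normalize_weights(raw)
    return trace
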
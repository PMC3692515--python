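"""Replicated experiment harness: bias and precision of heritability
estimators across mating regimes, heritabilities and marker-panel sizes.

Each cell of the experiment grid fixes (N, S, target h2, L_M) and runs
``n_replicates`` independent simulations. For every replicate the harness
builds the generation-10 pedigree kinship matrix and the Loiselle marker
matrix, fits the animal model by REML once per method, and records the
heritability estimate. The three methods mirror the estimation strategies
compared in the study:

* ``pedigree``          G* = 2 Phi_A / (1 + F_ped), F from the pedigree;
* ``marker``            G* = 2 K / (1 + F_eq), F_eq = S / (2 - S)
                        (pedigree assumed unknown);
* ``marker_truncated``  as ``marker`` after element-wise truncation of
                        negative Loiselle values to zero.

Performance is summarized by the bias E(h2_hat - h2) and the sampling error
E(h2_hat - E(h2_hat))^2 over converged replicates.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import animal_model, relatedness, simulator
from .config import ExperimentGrid, SimulationConfig, cell_seed

__all__ = [
    "METHODS",
    "ReplicateResult",
    "run_cell",
    "run_grid",
    "to_table",
    "bias",
    "sampling_error",
    "paired_compare",
    "kinship_regression",
    "relatedness_variance",
    "panel_sweep",
    "relatedness_replicates",
    "summarize_bias",
]

logger = logging.getLogger(__name__)

METHODS = ("pedigree", "marker", "marker_truncated")


@dataclass
class ReplicateResult:
    """One REML fit of one simulated population with one method."""

    N: int
    S: float
    target_h2: float
    L_M: int
    replicate: int
    seed: int
    method: str
    h2_hat: float
    se: float
    converged: bool
    boundary: bool


def _fit_method(pop, method, phi, F_ped, K):
    cfg = pop.config
    if method == "pedigree":
        G = relatedness.covariance_structure(phi, F_ped)
    elif method == "marker":
        F_eq = relatedness.equilibrium_inbreeding(cfg.S)
        G = relatedness.covariance_structure(K, F_eq)
    elif method == "marker_truncated":
        F_eq = relatedness.equilibrium_inbreeding(cfg.S)
        G = relatedness.covariance_structure(relatedness.truncate_nonnegative(K), F_eq)
    else:
        raise ValueError(f"unknown method {method!r}")
    return animal_model.fit_reml(pop.phenotypes, G)


def run_cell(config: SimulationConfig, methods=METHODS) -> list:
    """Simulate config.n_replicates populations and fit every method.

    Non-convergence is recorded in the result rows, never fatal.
    Deterministic given config.seed.
    """
    results = []
    for r in range(config.n_replicates):
        pop = simulator.simulate(config, replicate=r)
        g = config.n_generations
        phi = relatedness.pedigree_kinship(pop.pedigree, g)
        F_ped = relatedness.pedigree_inbreeding(pop.pedigree, g).mean_F
        K = relatedness.loiselle_kinship(pop.marker_genotypes, ids=pop.ids)
        for method in methods:
            try:
                fit = _fit_method(pop, method, phi, F_ped, K)
                row = ReplicateResult(
                    N=config.N,
                    S=config.S,
                    target_h2=config.target_h2,
                    L_M=config.L_M,
                    replicate=r,
                    seed=config.seed + r,
                    method=method,
                    h2_hat=fit.h2,
                    se=fit.se_h2,
                    converged=bool(fit.converged and fit.identifiable),
                    boundary=bool(fit.boundary),
                )
            except (animal_model.RemlError, np.linalg.LinAlgError) as exc:
                logger.warning("replicate %d method %s failed: %s", r, method, exc)
                row = ReplicateResult(
                    N=config.N,
                    S=config.S,
                    target_h2=config.target_h2,
                    L_M=config.L_M,
                    replicate=r,
                    seed=config.seed + r,
                    method=method,
                    h2_hat=np.nan,
                    se=np.nan,
                    converged=False,
                    boundary=False,
                )
            results.append(row)
    return results


def to_table(results) -> pd.DataFrame:
    """List of ReplicateResult -> tidy DataFrame (the ExperimentTable)."""
    return pd.DataFrame([asdict(r) for r in results])


def run_grid(grid: ExperimentGrid, methods=METHODS, experiment_seed: int = 0) -> pd.DataFrame:
    """Run every cell of the grid; one deterministic seed per cell."""
    rows = []
    for cfg in grid.cells():
        seed = cell_seed(experiment_seed, N=cfg.N, S=cfg.S, h2=cfg.target_h2, L_M=cfg.L_M)
        cfg = cfg.replace(seed=seed)
        logger.info(
            "cell N=%d S=%.2f h2=%.2f L_M=%d (seed %d)",
            cfg.N, cfg.S, cfg.target_h2, cfg.L_M, seed,
        )
        rows.extend(run_cell(cfg, methods=methods))
    return to_table(rows)


def bias(results, true_h2: float) -> float:
    """Mean of (h2_hat - true_h2) over converged replicates.

    ``results`` is a DataFrame or list of ReplicateResult. Non-converged
    replicates are excluded (their count is logged).
    """
    df = results if isinstance(results, pd.DataFrame) else to_table(results)
    ok = df[df["converged"] & df["h2_hat"].notna()]
    n_excluded = len(df) - len(ok)
    if n_excluded:
        logger.info("bias: excluded %d non-converged replicates", n_excluded)
    if ok.empty:
        raise ValueError("no converged replicates; bias undefined")
    return float((ok["h2_hat"] - true_h2).mean())


def sampling_error(results) -> float:
    """Mean squared deviation of h2_hat around its replicate mean."""
    df = results if isinstance(results, pd.DataFrame) else to_table(results)
    ok = df[df["converged"] & df["h2_hat"].notna()]
    if len(ok) < 2:
        raise ValueError("need at least 2 converged replicates")
    h = ok["h2_hat"].to_numpy()
    return float(np.mean((h - h.mean()) ** 2))


def summarize_bias(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell and per-method bias / sampling error / convergence summary."""
    out = []
    for (N, S, h2, L_M, method), grp in table.groupby(["N", "S", "target_h2", "L_M", "method"]):
        ok = grp[grp["converged"] & grp["h2_hat"].notna()]
        out.append(
            {
                "N": N,
                "S": S,
                "target_h2": h2,
                "L_M": L_M,
                "method": method,
                "n": len(grp),
                "n_converged": len(ok),
                "mean_h2_hat": ok["h2_hat"].mean() if len(ok) else np.nan,
                "bias": bias(grp, h2) if len(ok) else np.nan,
                "sampling_error": sampling_error(grp) if len(ok) > 1 else np.nan,
            }
        )
    return pd.DataFrame(out)


def paired_compare(results_A, results_B) -> dict:
    """Wilcoxon signed-rank test on replicate-paired estimates.

    Inputs are equal-length vectors of per-replicate values (e.g. biases of
    two methods on the same simulated populations).
    """
    a = np.asarray(results_A, dtype=float)
    b = np.asarray(results_B, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired comparison needs equal-length vectors")
    diffs = a - b
    if np.allclose(diffs, 0.0):
        return {"statistic": np.nan, "pvalue": 1.0, "n": len(a), "degenerate": True}
    res = stats.wilcoxon(a, b)
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue), "n": len(a), "degenerate": False}


def kinship_regression(K_x: relatedness.KinshipMatrix, K_y: relatedness.KinshipMatrix) -> dict:
    """OLS of K_y off-diagonals on K_x off-diagonals: slope, intercept, r.

    A slope near 1 means relatedness measured on the x-loci predicts
    relatedness on the y-loci without attenuation.
    """
    if list(K_x.ids) != list(K_y.ids):
        raise ValueError("kinship matrices must share individual ids")
    x = K_x.off_diagonal()
    y = K_y.off_diagonal()
    if np.allclose(x, x[0]):
        raise ValueError("constant predictor matrix: slope undefined")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept), "r": float(res.rvalue)}


def relatedness_variance(K: relatedness.KinshipMatrix, doubled: bool = False) -> float:
    """Variance of the off-diagonal pairwise coefficients.

    ``doubled=True`` reports the relatedness (2 x kinship) scale.
    """
    off = K.off_diagonal()
    if doubled:
        off = 2.0 * off
    return float(np.var(off))


def panel_sweep(
    base: SimulationConfig,
    panel_sizes=(384, 1500, 3000, 5000),
    methods=("marker", "marker_truncated"),
    experiment_seed: int = 0,
) -> pd.DataFrame:
    """Bias as a function of the number of marker loci (one mating regime)."""
    grid = ExperimentGrid(
        selfing_rates=(base.S,),
        heritabilities=(base.target_h2,),
        panel_sizes=tuple(panel_sizes),
        population_sizes=(base.N,),
        n_replicates=base.n_replicates,
        base=base,
    )
    return run_grid(grid, methods=methods, experiment_seed=experiment_seed)


def relatedness_replicates(config: SimulationConfig, n_replicates: int = 10, with_qtl: bool = True) -> pd.DataFrame:
    """Per-replicate relatedness structure summaries at the final generation.

    For each replicate: variance (and mean) of pedigree and marker pairwise
    coefficients on both the kinship and doubled scales, and the regressions
    of (a) pedigree kinship on marker kinship and (b) QTL-based Loiselle
    kinship on marker-based Loiselle kinship.
    """
    import dataclasses

    rows = []
    for r in range(n_replicates):
        pop = simulator.simulate(config, replicate=r)
        g = config.n_generations
        phi = relatedness.pedigree_kinship(pop.pedigree, g)
        # pedigree kinship labels rows by global integer id; relabel with the
        # population's string ids so the regressions can pair individuals
        phi = dataclasses.replace(phi, ids=list(pop.ids))
        K = relatedness.loiselle_kinship(pop.marker_genotypes, ids=pop.ids)
        F_eq = relatedness.equilibrium_inbreeding(config.S)
        F_ped = relatedness.pedigree_inbreeding(pop.pedigree, g).mean_F
        row = {
            "replicate": r,
            "S": config.S,
            "N": config.N,
            "L_M": config.L_M,
            # variance of the inbreeding-adjusted relatedness 2K/(1+F): the
            # coefficients that actually parameterize the animal-model
            # covariance among individuals
            "var_marker_adjusted": float(np.var(2.0 * K.off_diagonal() / (1.0 + F_eq))),
            "var_pedigree_adjusted": float(np.var(2.0 * phi.off_diagonal() / (1.0 + F_ped))),
            "var_marker_kinship": relatedness_variance(K),
            "var_marker_relatedness": relatedness_variance(K, doubled=True),
            "var_pedigree_kinship": relatedness_variance(phi),
            "var_pedigree_relatedness": relatedness_variance(phi, doubled=True),
            "mean_marker_kinship": float(K.off_diagonal().mean()),
            "mean_pedigree_kinship": float(phi.off_diagonal().mean()),
        }
        reg = kinship_regression(K, phi)
        row["slope_pedigree_on_marker"] = reg["slope"]
        row["r_pedigree_on_marker"] = reg["r"]
        if with_qtl:
            Kq = relatedness.loiselle_kinship(pop.qtl_genotypes, ids=pop.ids, source="qtl")
            regq = kinship_regression(K, Kq)
            row["slope_qtl_on_marker"] = regq["slope"]
            row["r_qtl_on_marker"] = regq["r"]
            row["var_qtl_kinship"] = relatedness_variance(Kq)
        rows.append(row)
    return pd.DataFrame(rows)
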
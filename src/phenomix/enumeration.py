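"""Class-enumeration diagnostics for choosing the number of latent classes.

For each candidate K the module reports penalized-likelihood criteria
(AIC, BIC, CAIC, SABIC), a 3-fold cross-validated log-likelihood, a naive
chi-square likelihood-ratio test between consecutive K, the relative entropy
of the posterior responsibilities, the average posterior probability of
assigned individuals per class (AvePP), and the size of the smallest class.
Final model choice is a user decision informed by this table (elbow /
first-minimum reading plus interpretability); no criterion auto-selects K.

The likelihood-ratio test here is the plain chi-square on 2*(LL_K - LL_{K-1})
with df equal to the parameter-count difference.  This is NOT the
Lo-Mendell-Rubin adjusted test: the naive chi-square reference distribution
is anti-conservative for mixture-order testing, and outputs are flagged
accordingly (``lrt_kind = "naive"``).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import FeatureSchema, PhenotypeCohort
from .gfmm import FitConfig, MixtureFit, fit as gfmm_fit, e_step, n_parameters

__all__ = [
    "information_criteria",
    "cv_log_likelihood",
    "pairwise_lrt",
    "entropy",
    "avepp",
    "enumerate_models",
    "summarize_enumeration",
]


def information_criteria(LL: float, p: int, n: int) -> dict[str, float]:
    """AIC/BIC/CAIC/SABIC from a log-likelihood, parameter count and n.

    SABIC replaces ln(n) in the BIC penalty with ln((n + 2) / 24).
    """
    if not np.isfinite(LL):
        raise ValueError("log-likelihood must be finite")
    if n < 1 or p < 1:
        raise ValueError("need n >= 1 and p >= 1")
    return {
        "AIC": -2.0 * LL + 2.0 * p,
        "BIC": -2.0 * LL + p * np.log(n),
        "CAIC": -2.0 * LL + p * (np.log(n) + 1.0),
        "SABIC": -2.0 * LL + p * np.log((n + 2.0) / 24.0),
    }


def cv_log_likelihood(
    cohort: PhenotypeCohort,
    schema: FeatureSchema | None = None,
    K: int = 4,
    config: FitConfig | None = None,
    n_folds: int = 3,
    n_reps: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Held-out log-likelihood, one value per repetition.

    Each repetition shuffles the cohort, splits it into ``n_folds`` folds,
    fits on the remaining folds and evaluates the frozen-parameter
    log-likelihood on the held-out fold; the value reported is the total
    summed over all held-out individuals (every individual is held out
    exactly once per repetition).
    """
    schema = schema or cohort.schema
    config = config or FitConfig()
    n = len(cohort)
    if n < n_folds * K:
        raise ValueError(f"cohort of n={n} too small for {n_folds}-fold CV at K={K}")
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for rep in range(n_reps):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % n_folds
        total = 0.0
        for f in range(n_folds):
            test_mask = fold_of == f
            if test_mask.sum() < K:
                raise ValueError("fold smaller than K")
            train = cohort.subset_rows(~test_mask)
            test = cohort.subset_rows(test_mask)
            sub_cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
            fit_res = gfmm_fit(train, schema, K, sub_cfg)
            _, ll = e_step(fit_res.params, test, schema)
            total += ll
        out[rep] = total
    return out


def pairwise_lrt(fit_km1: MixtureFit, fit_k: MixtureFit, n: int) -> tuple[float, int, float]:
    """Naive chi-square LRT between consecutive-K fits on the same cohort.

    Returns (statistic, df, p).  The statistic 2*(LL_K - LL_{K-1}) is clipped
    at zero; df is the free-parameter difference.  The chi-square reference is
    a naive (non-LMR-adjusted) approximation.
    """
    if fit_k.K != fit_km1.K + 1:
        raise ValueError("fits must have consecutive K (K-1 then K)")
    if fit_k.params.schema.names != fit_km1.params.schema.names or len(
        fit_k.responsibilities
    ) != len(fit_km1.responsibilities):
        raise ValueError("fits are not nested (different cohorts or schemas)")
    stat = max(0.0, 2.0 * (fit_k.log_likelihood - fit_km1.log_likelihood))
    df = fit_k.n_parameters - fit_km1.n_parameters
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p


def entropy(responsibilities: np.ndarray) -> float:
    """Relative entropy of the responsibility matrix, in [0, 1].

    1 - sum_i sum_k(-g_ik ln g_ik) / (n ln K); 1 means perfectly crisp
    assignment, 0 means uniform posteriors.  Undefined (NaN) for K = 1.
    """
    gamma = np.asarray(responsibilities, dtype=float)
    n, K = gamma.shape
    if K < 2:
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(gamma > 0, gamma * np.log(gamma), 0.0).sum()
    return float(1.0 - h / (n * np.log(K)))


def avepp(responsibilities: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Average maximum posterior probability among individuals of each class.

    Empty classes get NaN.
    """
    gamma = np.asarray(responsibilities, dtype=float)
    labels = np.asarray(labels)
    K = gamma.shape[1]
    row_max = gamma.max(axis=1)
    out = np.full(K, np.nan)
    for k in range(K):
        members = labels == k
        if members.any():
            out[k] = row_max[members].mean()
    return out


def enumerate_models(
    cohort: PhenotypeCohort,
    schema: FeatureSchema | None = None,
    K_range=(1, 2, 3, 4, 5, 6),
    config: FitConfig | None = None,
    n_reps: int = 1,
    seed: int = 0,
    cv: bool = False,
    cv_folds: int = 3,
) -> pd.DataFrame:
    """Fit every K in ``K_range`` ``n_reps`` times and tabulate diagnostics.

    Returns a long table with one row per (K, rep).  Fit failures are
    recorded as NaN rows rather than aborting the scan.  The LRT column for a
    given K compares against the same rep's K-1 fit (NaN for the smallest K
    or when either fit failed).
    """
    schema = schema or cohort.schema
    config = config or FitConfig()
    K_range = sorted(set(int(k) for k in K_range))
    if not K_range:
        raise ValueError("K_range must be non-empty")
    n = len(cohort)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        prev_fit: MixtureFit | None = None
        prev_K = None
        for K in K_range:
            row: dict = {"K": K, "rep": rep, "lrt_kind": "naive"}
            sub_cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
            try:
                fit_res = gfmm_fit(cohort, schema, K, sub_cfg)
            except Exception as exc:  # fit failure recorded per cell, not fatal
                row.update({"error": str(exc)})
                rows.append(row)
                prev_fit, prev_K = None, K
                continue
            ll = fit_res.log_likelihood
            crit = information_criteria(ll, fit_res.n_parameters, n)
            sizes = np.bincount(fit_res.labels, minlength=K)
            row.update(
                {
                    "LL": ll,
                    "n_parameters": fit_res.n_parameters,
                    **crit,
                    "entropy": entropy(fit_res.responsibilities),
                    "avepp_min": np.nanmin(avepp(fit_res.responsibilities, fit_res.labels)),
                    "smallest_class_n": int(sizes.min()),
                    "smallest_class_prop": float(sizes.min() / n),
                    "converged": fit_res.converged,
                }
            )
            if cv:
                row["CV_LL"] = float(
                    cv_log_likelihood(
                        cohort, schema, K, config, n_folds=cv_folds, n_reps=1,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )[0]
                )
            if prev_fit is not None and prev_K == K - 1:
                stat, df, p = pairwise_lrt(prev_fit, fit_res, n)
                row.update({"lrt_stat": stat, "lrt_df": df, "lrt_p": p})
            rows.append(row)
            prev_fit, prev_K = fit_res, K
    return pd.DataFrame(rows)


def summarize_enumeration(table: pd.DataFrame) -> pd.DataFrame:
    """Per-K means over repetitions of the enumeration table."""
    numeric = table.select_dtypes(include=[np.number]).columns.drop(["K", "rep"], errors="ignore")
    return table.groupby("K")[list(numeric)].mean().reset_index()
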
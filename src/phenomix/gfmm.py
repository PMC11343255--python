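"""Mixed-data-type finite mixture model with covariate-dependent class priors.

The model (a general finite mixture model, GFMM) assumes that each individual
belongs to one of K latent classes and that, conditional on the class, the
phenotype features are independent with a family chosen by feature type:
Gaussian for continuous features, Bernoulli for binary items, multinomial for
categorical items.  The class prior is not a fixed mixing vector but a
multinomial-logit function of the covariates (intercept, sex, age in years),
i.e. the "1-step with covariates" configuration:

    pi_k(c_i) = softmax_k(beta_k . [1, sex_i, age_i]),   beta_0 = 0

Fitting is by expectation-maximization with multi-start: ``n_init``
independent chains from random soft assignments, keeping the chain with the
highest final log-likelihood.  Individuals are assigned to the class with the
maximum posterior probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .data import Feature, FeatureSchema, PhenotypeCohort, SchemaError

__all__ = [
    "FitConfig",
    "MixtureParams",
    "MixtureFit",
    "DegenerateClassError",
    "FitFailureError",
    "component_log_density",
    "e_step",
    "m_step",
    "fit",
    "predict",
    "n_parameters",
]

LOG_2PI = float(np.log(2.0 * np.pi))
CAT_SMOOTH = 1e-10  # pseudo-mass added to categorical level probabilities
PROB_EPS = 1e-12  # clip for Bernoulli success probabilities


class DegenerateClassError(RuntimeError):
    """A class collapsed (total responsibility below threshold) during the M-step."""


class FitFailureError(RuntimeError):
    """Every EM chain failed (all degenerate)."""


@dataclass
class FitConfig:
    """EM hyperparameters.

    ``n_init`` independent restarts (the study-scale default is 200; the demo
    default here is 20), convergence when the log-likelihood improves by less
    than ``tol``, Gaussian variances floored at ``variance_floor`` to prevent
    singular components.
    """

    n_init: int = 20
    max_iter: int = 500
    tol: float = 1e-6
    variance_floor: float = 1e-4
    seed: int = 0


@dataclass
class MixtureParams:
    """All parameters of a K-class GFMM, aligned with a feature schema."""

    K: int
    schema: FeatureSchema
    prior_coef: np.ndarray  # (K, 3) multinomial-logit coefficients; row 0 is zero
    cont_mean: np.ndarray  # (K, Fc)
    cont_var: np.ndarray  # (K, Fc)
    bin_p: np.ndarray  # (K, Fb)
    cat_p: list[np.ndarray]  # per categorical feature: (K, n_levels)

    def validate(self) -> None:
        if not np.allclose(self.prior_coef[0], 0.0):
            raise ValueError("reference class (index 0) must have zero prior coefficients")
        if (self.cont_var <= 0).any():
            raise ValueError("non-positive Gaussian variance")
        if ((self.bin_p < 0) | (self.bin_p > 1)).any():
            raise ValueError("Bernoulli probability outside [0, 1]")
        for p in self.cat_p:
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-10):
                raise ValueError("categorical probabilities must sum to 1")

    def to_dict(self) -> dict:
        return {
            "format": "phenomix-gfmm-1",
            "K": int(self.K),
            "schema": self.schema.to_frame().to_dict(orient="list"),
            "prior_coef": self.prior_coef.tolist(),
            "cont_mean": self.cont_mean.tolist(),
            "cont_var": self.cont_var.tolist(),
            "bin_p": self.bin_p.tolist(),
            "cat_p": [p.tolist() for p in self.cat_p],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureParams":
        import pandas as pd

        schema = FeatureSchema.from_frame(pd.DataFrame(d["schema"]))
        return cls(
            K=int(d["K"]),
            schema=schema,
            prior_coef=np.asarray(d["prior_coef"], dtype=float),
            cont_mean=np.asarray(d["cont_mean"], dtype=float),
            cont_var=np.asarray(d["cont_var"], dtype=float),
            bin_p=np.asarray(d["bin_p"], dtype=float),
            cat_p=[np.asarray(p, dtype=float) for p in d["cat_p"]],
        )


@dataclass
class MixtureFit:
    """Result of a multi-start EM fit."""

    params: MixtureParams
    responsibilities: np.ndarray  # (n, K)
    log_likelihood: float
    ll_trace: np.ndarray  # per-iteration LL of the winning chain
    n_parameters: int
    labels: np.ndarray  # argmax posterior, ties -> lowest class index
    converged: bool
    restart_seed: int  # chain index of the winning restart
    config: FitConfig = field(default_factory=FitConfig)

    @property
    def K(self) -> int:
        return self.params.K

    def save(self, path: str | Path) -> None:
        payload = {
            "params": self.params.to_dict(),
            "log_likelihood": float(self.log_likelihood),
            "n_parameters": int(self.n_parameters),
            "converged": bool(self.converged),
            "restart_seed": int(self.restart_seed),
            "config": vars(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load_params(cls, path: str | Path) -> MixtureParams:
        with open(path) as fh:
            payload = json.load(fh)
        return MixtureParams.from_dict(payload["params"])


# ---------------------------------------------------------------------------
# Feature blocks: split the cohort matrix by feature family once per fit
# ---------------------------------------------------------------------------


@dataclass
class FeatureBlocks:
    cont: np.ndarray  # (n, Fc)
    binary: np.ndarray  # (n, Fb)
    cat: np.ndarray  # (n, Fcat), int levels
    cont_names: list[str]
    bin_names: list[str]
    cat_names: list[str]
    cat_levels: list[int]

    @classmethod
    def from_cohort(cls, cohort: PhenotypeCohort, schema: FeatureSchema | None = None) -> "FeatureBlocks":
        schema = schema or cohort.schema
        if [f.name for f in schema] != [f.name for f in cohort.schema] or any(
            fa.ftype != fb.ftype or fa.n_levels != fb.n_levels
            for fa, fb in zip(schema, cohort.schema)
        ):
            raise SchemaError("cohort schema does not match the model schema")
        if cohort.features.isna().any().any():
            raise ValueError("cohort contains missing values; apply completeness_filter first")
        cont_names = [f.name for f in schema if f.ftype == "continuous"]
        bin_names = [f.name for f in schema if f.ftype == "binary"]
        cat_feats = [f for f in schema if f.ftype == "categorical"]
        X = cohort.features
        return cls(
            cont=X[cont_names].to_numpy(dtype=float),
            binary=X[bin_names].to_numpy(dtype=float),
            cat=X[[f.name for f in cat_feats]].to_numpy(dtype=float).astype(int)
            if cat_feats
            else np.empty((len(X), 0), dtype=int),
            cont_names=cont_names,
            bin_names=bin_names,
            cat_names=[f.name for f in cat_feats],
            cat_levels=[int(f.n_levels) for f in cat_feats],
        )


def _covariate_design(cohort: PhenotypeCohort) -> np.ndarray:
    """(n, 3) design: intercept, sex (0/1), age in years (unstandardized)."""
    n = len(cohort)
    C = np.empty((n, 3))
    C[:, 0] = 1.0
    C[:, 1] = cohort.covariates["sex"].to_numpy(dtype=float)
    C[:, 2] = cohort.covariates["age_years"].to_numpy(dtype=float)
    return C


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------


def _log_density_matrix(params: MixtureParams, blocks: FeatureBlocks) -> np.ndarray:
    """(n, K) class-conditional log densities, summed over features."""
    n = blocks.cont.shape[0]
    ld = np.zeros((n, params.K))
    if blocks.cont.shape[1]:
        mu = params.cont_mean  # (K, Fc)
        var = params.cont_var
        # sum_f -0.5*(log 2pi var + (x-mu)^2/var), vectorized over classes
        x = blocks.cont  # (n, Fc)
        const = -0.5 * (LOG_2PI + np.log(var)).sum(axis=1)  # (K,)
        x2 = x**2
        quad = (
            x2 @ (0.5 / var).T
            - x @ (mu / var).T
            + (0.5 * mu**2 / var).sum(axis=1)[None, :]
        )
        ld += const[None, :] - quad
    if blocks.binary.shape[1]:
        p = np.clip(params.bin_p, PROB_EPS, 1.0 - PROB_EPS)
        ld += blocks.binary @ np.log(p).T + (1.0 - blocks.binary) @ np.log1p(-p).T
    for j, levels in enumerate(blocks.cat_levels):
        xj = blocks.cat[:, j]
        if (xj < 0).any() or (xj >= levels).any():
            raise ValueError(f"categorical level out of range for feature {blocks.cat_names[j]!r}")
        logp = np.log(params.cat_p[j])  # (K, L)
        ld += logp[:, xj].T
    return ld


def component_log_density(
    params: MixtureParams, k: int, x, schema: FeatureSchema
) -> float:
    """Log density of one feature row under class ``k`` (features independent
    given the class)."""
    if not 0 <= k < params.K:
        raise IndexError(f"class index {k} out of range for K={params.K}")
    import pandas as pd

    row = pd.DataFrame([list(x)], columns=schema.names, dtype=float)
    cohort = PhenotypeCohort(
        features=row,
        covariates=pd.DataFrame({"sex": [0.0], "age_years": [0.0]}),
        role=np.array(["proband"], dtype=object),
        schema=schema,
    )
    blocks = FeatureBlocks.from_cohort(cohort, schema)
    return float(_log_density_matrix(params, blocks)[0, k])


def _log_prior(params: MixtureParams, C: np.ndarray) -> np.ndarray:
    logits = C @ params.prior_coef.T  # (n, K)
    return logits - logsumexp(logits, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# E-step / M-step
# ---------------------------------------------------------------------------


def e_step(
    params: MixtureParams, cohort: PhenotypeCohort, schema: FeatureSchema | None = None
) -> tuple[np.ndarray, float]:
    """Posterior responsibilities and total log-likelihood.

    Computed in log space (log-sum-exp), so class densities as small as
    exp(-700) per row do not underflow.
    """
    blocks = FeatureBlocks.from_cohort(cohort, schema)
    C = _covariate_design(cohort)
    return _e_step_arrays(params, blocks, C)


def _e_step_arrays(
    params: MixtureParams, blocks: FeatureBlocks, C: np.ndarray
) -> tuple[np.ndarray, float]:
    ld = _log_density_matrix(params, blocks)
    if not np.isfinite(ld).all():
        bad = np.argwhere(~np.isfinite(ld))
        i, k = bad[0]
        raise FloatingPointError(
            f"non-finite class-conditional density (row {i}, class {k}); "
            "check feature scaling and variance floor"
        )
    log_joint = _log_prior(params, C) + ld
    norm = logsumexp(log_joint, axis=1, keepdims=True)
    gamma = np.exp(log_joint - norm)
    # -inf log-prior (pi = 0) is legitimate: those classes get gamma = 0
    return gamma, float(norm.sum())


def _fit_prior_coef(
    C: np.ndarray, gamma: np.ndarray, coef0: np.ndarray, gtol: float = 1e-8
) -> np.ndarray:
    """Weighted multinomial-logit fit of responsibilities on covariates.

    Maximizes sum_i sum_k gamma_ik log softmax(C beta^T)_ik over the free
    coefficients (classes 1..K-1; class 0 is the reference) by damped Newton
    iteration with the analytic gradient and Hessian, warm-started from the
    current coefficients.  The warm start is kept whenever the solver fails
    to improve on it, so each M-step can only raise the EM objective.
    """
    n, K = gamma.shape
    if K == 1:
        return np.zeros((1, C.shape[1]))
    d = C.shape[1]
    m = (K - 1) * d

    def negll_grad(coef: np.ndarray):
        logits = C @ coef.T
        mx = logits.max(axis=1, keepdims=True)
        lse = mx + np.log(np.exp(logits - mx).sum(axis=1, keepdims=True))
        logpi = logits - lse
        f = -float((gamma * logpi).sum())
        pi = np.exp(logpi)
        G = (pi - gamma).T @ C  # (K, d)
        return f, G[1:].ravel(), pi

    coef = coef0.copy()
    f, g, pi = negll_grad(coef)
    f0 = f
    for _ in range(60):
        if np.linalg.norm(g, ord=np.inf) < gtol:
            break
        # Hessian of the negative log-likelihood over the free classes:
        # H[(k,a),(l,b)] = sum_i C_ia C_ib pi_ik (delta_kl - pi_il)
        H = np.empty((m, m))
        for k in range(1, K):
            for l in range(1, K):
                w = pi[:, k] * ((k == l) - pi[:, l])
                H[(k - 1) * d : k * d, (l - 1) * d : l * d] = (C * w[:, None]).T @ C
        try:
            step = np.linalg.solve(H + 1e-10 * n * np.eye(m), g)
        except np.linalg.LinAlgError:
            step = g / max(np.abs(g).max(), 1.0)
        stepsize = 1.0
        improved = False
        for _ in range(30):
            cand = coef.copy()
            cand[1:] -= stepsize * step.reshape(K - 1, d)
            f_c, g_c, pi_c = negll_grad(cand)
            if f_c <= f:
                coef, f, g, pi = cand, f_c, g_c, pi_c
                improved = True
                break
            stepsize *= 0.5
        if not improved:
            break
    return coef if f <= f0 else coef0.copy()


def m_step(
    cohort: PhenotypeCohort,
    schema: FeatureSchema,
    responsibilities: np.ndarray,
    config: FitConfig | None = None,
    prev_params: MixtureParams | None = None,
) -> MixtureParams:
    blocks = FeatureBlocks.from_cohort(cohort, schema)
    C = _covariate_design(cohort)
    return _m_step_arrays(blocks, C, schema, responsibilities, config or FitConfig(), prev_params)


def _m_step_arrays(
    blocks: FeatureBlocks,
    C: np.ndarray,
    schema: FeatureSchema,
    gamma: np.ndarray,
    config: FitConfig,
    prev_params: MixtureParams | None,
) -> MixtureParams:
    n, K = gamma.shape
    Nk = gamma.sum(axis=0)
    tiny = Nk < 1e-6 * n
    if tiny.any():
        raise DegenerateClassError(
            f"class(es) {np.flatnonzero(tiny).tolist()} collapsed "
            f"(responsibility mass {Nk[tiny].tolist()})"
        )
    inv = 1.0 / Nk[:, None]
    if blocks.cont.shape[1]:
        mean = (gamma.T @ blocks.cont) * inv
        ex2 = (gamma.T @ (blocks.cont**2)) * inv
        var = np.maximum(ex2 - mean**2, config.variance_floor)
    else:
        mean = np.empty((K, 0))
        var = np.empty((K, 0))
    if blocks.binary.shape[1]:
        bin_p = np.clip((gamma.T @ blocks.binary) * inv, 0.0, 1.0)
    else:
        bin_p = np.empty((K, 0))
    cat_p = []
    for j, levels in enumerate(blocks.cat_levels):
        onehot = np.zeros((n, levels))
        onehot[np.arange(n), blocks.cat[:, j]] = 1.0
        counts = gamma.T @ onehot + CAT_SMOOTH
        cat_p.append(counts / counts.sum(axis=1, keepdims=True))
    coef0 = prev_params.prior_coef if prev_params is not None else np.zeros((K, C.shape[1]))
    prior_coef = _fit_prior_coef(C, gamma, coef0)
    return MixtureParams(
        K=K, schema=schema, prior_coef=prior_coef,
        cont_mean=mean, cont_var=var, bin_p=bin_p, cat_p=cat_p,
    )


# ---------------------------------------------------------------------------
# Parameter counting (for information criteria)
# ---------------------------------------------------------------------------


def n_parameters(schema: FeatureSchema, K: int) -> int:
    """Free-parameter count: (K-1) prior-coefficient vectors of length 3 plus
    per class 2 per continuous, 1 per binary, n_levels-1 per categorical."""
    per_class = 0
    for f in schema:
        if f.ftype == "continuous":
            per_class += 2
        elif f.ftype == "binary":
            per_class += 1
        else:
            per_class += f.n_levels - 1
    return (K - 1) * 3 + K * per_class


# ---------------------------------------------------------------------------
# Fit / predict
# ---------------------------------------------------------------------------


def _run_chain(
    blocks: FeatureBlocks,
    C: np.ndarray,
    schema: FeatureSchema,
    K: int,
    config: FitConfig,
    rng: np.random.Generator,
) -> tuple[MixtureParams, np.ndarray, list[float], bool]:
    n = blocks.cont.shape[0]
    gamma = rng.dirichlet(np.ones(K), size=n)
    params = _m_step_arrays(blocks, C, schema, gamma, config, None)
    trace: list[float] = []
    converged = False
    for _ in range(config.max_iter):
        gamma, ll = _e_step_arrays(params, blocks, C)
        trace.append(ll)
        if len(trace) >= 2 and trace[-1] - trace[-2] < config.tol:
            converged = True
            break
        params = _m_step_arrays(blocks, C, schema, gamma, config, params)
    return params, gamma, trace, converged


def fit(
    cohort: PhenotypeCohort,
    schema: FeatureSchema | None = None,
    K: int = 4,
    config: FitConfig | None = None,
) -> MixtureFit:
    """Multi-start EM fit; returns the restart with the highest final LL."""
    schema = schema or cohort.schema
    config = config or FitConfig()
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(cohort):
        raise ValueError(f"K={K} exceeds cohort size n={len(cohort)}")
    blocks = FeatureBlocks.from_cohort(cohort, schema)
    C = _covariate_design(cohort)
    rng = np.random.default_rng(config.seed)
    best: tuple[float, int, MixtureParams, np.ndarray, list[float], bool] | None = None
    failures = 0
    for chain in range(max(config.n_init, 1)):
        chain_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        try:
            params, gamma, trace, converged = _run_chain(blocks, C, schema, K, config, chain_rng)
        except DegenerateClassError:
            failures += 1
            continue
        ll = trace[-1]
        if best is None or ll > best[0]:
            best = (ll, chain, params, gamma, trace, converged)
    if best is None:
        raise FitFailureError(f"all {failures} EM chains degenerated (K={K}, n={len(cohort)})")
    ll, chain, params, gamma, trace, converged = best
    labels = np.argmax(gamma, axis=1)
    return MixtureFit(
        params=params,
        responsibilities=gamma,
        log_likelihood=ll,
        ll_trace=np.asarray(trace),
        n_parameters=n_parameters(schema, K),
        labels=labels,
        converged=converged,
        restart_seed=chain,
        config=config,
    )


def predict(
    fit_result: MixtureFit | MixtureParams,
    cohort: PhenotypeCohort,
    schema: FeatureSchema | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Frozen-parameter E-step followed by max-posterior assignment.

    Posterior ties are broken toward the lowest class index (the behaviour of
    argmax on exact ties), making prediction deterministic.
    """
    params = fit_result.params if isinstance(fit_result, MixtureFit) else fit_result
    schema = schema or params.schema
    gamma, _ = e_step(params, cohort, schema)
    labels = np.argmax(gamma, axis=1)
    return labels, gamma
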
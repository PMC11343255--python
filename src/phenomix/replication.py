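"""Cross-cohort replication of latent classes.

A model trained on the discovery cohort, restricted to the features shared
with an independent cohort, is applied to the second cohort to transfer class
labels.  Both cohorts are then profiled with the same affinity machinery and
compared: Pearson correlations per phenotype category (the K class values of
that category across cohorts) and one overall correlation on the flattened
classes x categories matrix.  Significance of the overall similarity comes
from a label-permutation null: the test cohort's labels are shuffled (class
sizes preserved), the affinity matrix recomputed with the contributory
feature set frozen from the unpermuted analysis, and the observed correlation
compared against the resulting null distribution with the add-one convention
p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .data import FeatureSchema, PhenotypeCohort, PHENOTYPE_CATEGORIES, SchemaError
from .gfmm import FitConfig, MixtureFit, fit as gfmm_fit, predict
from .profiles import (
    AffinityMatrix,
    Q_THRESHOLD,
    _enrichment_arrays,
    _feature_arrays,
    affinity_scores,
    feature_enrichment,
    feature_exclusion,
)

__all__ = ["transfer_model", "model_similarity", "permutation_test", "ReplicationResult"]


@dataclass
class ReplicationResult:
    fit: MixtureFit
    labels_test: np.ndarray
    affinity_train: AffinityMatrix
    affinity_test: AffinityMatrix
    overall_r: float
    per_category_r: pd.Series
    permutation_p: float | None = None
    null_distribution: np.ndarray | None = None


def transfer_model(
    cohort_train: PhenotypeCohort,
    cohort_test: PhenotypeCohort,
    common_features: list[str],
    K: int,
    config: FitConfig | None = None,
) -> tuple[MixtureFit, np.ndarray, list[str]]:
    """Refit on the training cohort restricted to shared features and predict
    labels for the test cohort.

    Also recomputes the contributory-feature exclusion on the training data
    only, returning (fit, test labels, contributory features).
    """
    for name in common_features:
        if name not in cohort_test.schema.names:
            raise SchemaError(f"common feature {name!r} missing from the test cohort")
        ftr = cohort_train.schema[name]
        fte = cohort_test.schema[name]
        if ftr.ftype != fte.ftype or ftr.n_levels != fte.n_levels:
            raise SchemaError(f"feature {name!r} has mismatched type across cohorts")
    train = cohort_train.subset_features(common_features)
    test = cohort_test.subset_features(common_features)
    fit_res = gfmm_fit(train, train.schema, K, config)
    labels_test, _ = predict(fit_res, test, train.schema)
    enr = feature_enrichment(train, fit_res.labels, train.schema)
    contributory = feature_exclusion(enr)
    return fit_res, labels_test, contributory


def model_similarity(
    affinity_A: AffinityMatrix | pd.DataFrame, affinity_B: AffinityMatrix | pd.DataFrame
) -> tuple[float, pd.Series]:
    """Pearson correlation between two class-by-category affinity matrices.

    Per-category r correlates the K class values of that category; the
    overall r correlates the flattened matrices.  NaN cells (categories with
    no contributory features) are excluded pairwise; zero-variance vectors
    yield NaN with a warning.
    """
    A = affinity_A.scores if isinstance(affinity_A, AffinityMatrix) else affinity_A
    B = affinity_B.scores if isinstance(affinity_B, AffinityMatrix) else affinity_B
    if A.shape != B.shape or list(A.columns) != list(B.columns):
        raise ValueError("affinity matrices must share shape and category ordering")
    per_cat = {}
    for g in A.columns:
        per_cat[g] = _pearson(A[g].to_numpy(), B[g].to_numpy())
    overall = _pearson(A.to_numpy().ravel(), B.to_numpy().ravel())
    return overall, pd.Series(per_cat)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        import warnings

        warnings.warn("zero-variance or too-short vector in correlation; returning NaN")
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def _fast_affinity(
    X: np.ndarray,
    is_binary: np.ndarray,
    labels: np.ndarray,
    K: int,
    cat_onehot: np.ndarray,
    n_per_cat: np.ndarray,
    q_threshold: float,
) -> np.ndarray:
    """Array-only affinity recomputation used inside the permutation loop.

    ``cat_onehot`` is (F, G) mapping contributory features to categories;
    ``n_per_cat`` the per-category contributory counts (0 -> NaN cell).
    """
    res = _enrichment_arrays(X, is_binary, labels, K)
    hits_up = bh_adjust(res["p_upper"], axis=1) < q_threshold
    hits_lo = bh_adjust(res["p_lower"], axis=1) < q_threshold
    signed = hits_up.astype(float) - hits_lo.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = (signed @ cat_onehot) / np.where(n_per_cat > 0, n_per_cat, np.nan)
    return scores


def _flat_r(scores: np.ndarray, ref: np.ndarray) -> float:
    """Flattened-matrix correlation used by the permutation null.

    An affinity matrix with no variation (typically all-zero: no significant
    cells anywhere, common for shuffled labels) carries no class signal; its
    similarity to the reference is defined as 0 so every permutation yields a
    comparable statistic and the exceedance count stays valid.
    """
    a, b = scores.ravel(), ref.ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def permutation_test(
    affinity_A: AffinityMatrix | pd.DataFrame,
    cohort_B: PhenotypeCohort,
    labels_B: np.ndarray,
    contributory: list[str],
    category_map: dict[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
    q_threshold: float = Q_THRESHOLD,
    categories: tuple[str, ...] = PHENOTYPE_CATEGORIES,
) -> tuple[float, float, np.ndarray]:
    """Label-permutation null for overall cross-cohort affinity similarity.

    Shuffles the test-cohort label vector (class sizes preserved), recomputes
    the affinity matrix with the frozen contributory-feature set, and
    correlates against the reference affinity matrix.  Returns
    (p, r_observed, null distribution).  With zero exceedances the add-one
    convention reports p = 1 / (1 + n_perm) < 1/n_perm.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels_B = np.asarray(labels_B, dtype=int)
    if len(labels_B) != len(cohort_B):
        raise ValueError("labels_B length must match cohort_B size")
    ref = (affinity_A.scores if isinstance(affinity_A, AffinityMatrix) else affinity_A).to_numpy()
    K = ref.shape[0]
    sub = cohort_B.subset_features(contributory)
    X, is_binary = _feature_arrays(sub, sub.schema)
    G = len(categories)
    cat_onehot = np.zeros((len(contributory), G))
    cat_index = {g: j for j, g in enumerate(categories)}
    for i, f in enumerate(contributory):
        g = category_map.get(f)
        if g in cat_index:
            cat_onehot[i, cat_index[g]] = 1.0
    n_per_cat = cat_onehot.sum(axis=0)
    r_obs = _flat_r(_fast_affinity(X, is_binary, labels_B, K, cat_onehot, n_per_cat, q_threshold), ref)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    labels = labels_B.copy()
    for i in range(n_perm):
        rng.shuffle(labels)
        null[i] = _flat_r(
            _fast_affinity(X, is_binary, labels, K, cat_onehot, n_per_cat, q_threshold), ref
        )
    exceed = int(np.sum(null >= r_obs))
    p = (1.0 + exceed) / (1.0 + n_perm)
    return p, r_obs, null


def replicate(
    cohort_train: PhenotypeCohort,
    cohort_test: PhenotypeCohort,
    common_features: list[str],
    K: int,
    category_map: dict[str, str],
    config: FitConfig | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ReplicationResult:
    """End-to-end replication: transfer, profile both cohorts, permute."""
    fit_res, labels_test, contributory = transfer_model(
        cohort_train, cohort_test, common_features, K, config
    )
    train = cohort_train.subset_features(common_features)
    test = cohort_test.subset_features(common_features)
    enr_train = feature_enrichment(train, fit_res.labels, train.schema)
    aff_train = affinity_scores(enr_train, contributory, category_map)
    enr_test = feature_enrichment(test, labels_test, test.schema, n_classes=K)
    aff_test = affinity_scores(enr_test, contributory, category_map)
    overall_r, per_cat = model_similarity(aff_train, aff_test)
    p, r_obs, null = permutation_test(
        aff_train, test, labels_test, contributory, category_map, n_perm=n_perm, seed=seed
    )
    return ReplicationResult(
        fit=fit_res,
        labels_test=labels_test,
        affinity_train=aff_train,
        affinity_test=aff_test,
        overall_r=overall_r,
        per_category_r=per_cat,
        permutation_p=p,
        null_distribution=null,
    )
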
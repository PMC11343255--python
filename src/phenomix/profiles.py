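"""Class "affinity" profiles over phenotype categories.

Once individuals are assigned to latent classes, each feature is tested for
enrichment (upper tail) and depletion (lower tail) in each class against the
pooled remaining classes: an exact one-sided binomial test for binary items,
a one-sided independent t-test for continuous and categorical items
(categorical items scored by level index).  Benjamini-Hochberg correction is
applied separately within each (class, direction) family.  Features are then
excluded if (1) they are never significantly enriched or depleted in any
class, (2) they are continuous/categorical with |Cohen's d| < 0.2 in every
class, or (3) they are binary with fold enrichment < 1.5 in every class.  The
surviving "contributory" features are mapped to seven phenotype categories
and each (class, category) cell receives a signed affinity score in [-1, 1]:
the proportion of contributory features significantly enriched minus the
proportion significantly depleted.

The same machinery supports external validation: fold enrichment of binary
diagnoses against a sibling background, and per-class means/CIs with
class-versus-sibling t-tests for features measured in siblings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import (
    bh_adjust,
    binom_tails,
    group_mean_var,
    normal_ci,
    t_tail_p,
    t_test_from_stats,
)
from .data import FeatureSchema, PhenotypeCohort, PHENOTYPE_CATEGORIES

__all__ = [
    "completeness_filter",
    "feature_enrichment",
    "feature_exclusion",
    "affinity_scores",
    "diagnosis_enrichment",
    "group_vs_sibling_tests",
    "AffinityMatrix",
    "EmptyCohortError",
]

Q_THRESHOLD = 0.05
D_THRESHOLD = 0.2
FE_THRESHOLD = 1.5


class EmptyCohortError(ValueError):
    """Completeness filtering removed every individual or every feature."""


def completeness_filter(
    cohort: PhenotypeCohort, feature_threshold: float = 0.90
) -> tuple[PhenotypeCohort, dict]:
    """Drop sparse features, then incomplete individuals.

    Features observed in fewer than ``feature_threshold`` of individuals are
    removed first; individuals with any missing value in the surviving
    features are then removed.  Returns the filtered cohort and a report with
    the dropped counts.
    """
    completeness = 1.0 - cohort.features.isna().mean(axis=0)
    keep_features = completeness[completeness >= feature_threshold].index.tolist()
    if not keep_features:
        raise EmptyCohortError("no feature meets the completeness threshold")
    filtered = cohort.subset_features(keep_features)
    complete_rows = ~filtered.features.isna().any(axis=1).to_numpy()
    if not complete_rows.any():
        raise EmptyCohortError("no individual is complete on the surviving features")
    report = {
        "n_features_dropped": len(cohort.schema) - len(keep_features),
        "features_dropped": [n for n in cohort.schema.names if n not in keep_features],
        "n_individuals_dropped": int((~complete_rows).sum()),
    }
    return filtered.subset_rows(complete_rows), report


# ---------------------------------------------------------------------------
# Feature-level enrichment
# ---------------------------------------------------------------------------


def _feature_arrays(cohort: PhenotypeCohort, schema: FeatureSchema):
    """Numeric score matrix plus per-feature type flags.

    Binary features keep their 0/1 coding; categorical features are scored by
    level index (so t statistics and Cohen's d apply to them as to continuous
    features).
    """
    X = cohort.features[schema.names].to_numpy(dtype=float)
    is_binary = np.array([f.ftype == "binary" for f in schema])
    return X, is_binary


def _enrichment_arrays(
    X: np.ndarray, is_binary: np.ndarray, labels: np.ndarray, K: int, equal_var: bool = True
):
    """Vectorized per-(class, feature) test battery.

    Returns dict of (K, F) arrays: p_upper, p_lower, cohens_d, fold_enrichment.
    Binary features get exact binomial tails and fold enrichment; numeric
    features get one-sided t tails and pooled-SD Cohen's d.  Each statistic is
    NaN for the feature family it does not apply to.
    """
    n, F = X.shape
    onehot = np.zeros((n, K))
    onehot[np.arange(n), labels] = 1.0
    means, variances, counts = group_mean_var(X, onehot)
    tot_sum = X.sum(axis=0)
    tot_sq = (X * X).sum(axis=0)

    # complementary ("pooled others") group stats per class
    n_oth = (n - counts)[:, None]
    sum_oth = tot_sum[None, :] - counts[:, None] * means
    mean_oth = sum_oth / n_oth
    sq_oth = tot_sq[None, :] - (variances * (counts[:, None] - 1) + counts[:, None] * means**2)
    with np.errstate(invalid="ignore"):
        var_oth = np.maximum((sq_oth - n_oth * mean_oth**2) / (n_oth - 1), 0.0)

    p_upper = np.full((K, F), np.nan)
    p_lower = np.full((K, F), np.nan)
    cohens_d = np.full((K, F), np.nan)
    fold = np.full((K, F), np.nan)

    num = ~is_binary
    if num.any():
        t, df = t_test_from_stats(
            means[:, num], variances[:, num], counts[:, None],
            mean_oth[:, num], var_oth[:, num], n_oth,
            equal_var=equal_var,
        )
        p_upper[:, num] = t_tail_p(t, df, "greater")
        p_lower[:, num] = t_tail_p(t, df, "less")
        with np.errstate(divide="ignore", invalid="ignore"):
            sp = np.sqrt(
                ((counts[:, None] - 1) * variances[:, num] + (n_oth - 1) * var_oth[:, num])
                / (counts[:, None] + n_oth - 2)
            )
            d = (means[:, num] - mean_oth[:, num]) / sp
        cohens_d[:, num] = np.where(np.isfinite(d), d, np.nan)

    if is_binary.any():
        kk = counts[:, None] * means[:, is_binary]  # class successes
        p0 = mean_oth[:, is_binary]  # pooled-other rate as the null proportion
        up, lo = binom_tails(np.round(kk), counts[:, None], np.clip(p0, 0.0, 1.0))
        p_upper[:, is_binary] = up
        p_lower[:, is_binary] = lo
        with np.errstate(divide="ignore", invalid="ignore"):
            fe = means[:, is_binary] / p0
        fold[:, is_binary] = fe

    return {
        "p_upper": p_upper,
        "p_lower": p_lower,
        "cohens_d": cohens_d,
        "fold_enrichment": fold,
        "class_mean": means,
        "class_n": counts,
    }


def feature_enrichment(
    cohort: PhenotypeCohort,
    labels: np.ndarray,
    schema: FeatureSchema | None = None,
    equal_var: bool = True,
    n_classes: int | None = None,
) -> pd.DataFrame:
    """Per-(feature, class) enrichment/depletion tests with BH correction.

    Long-format table with upper/lower one-sided p, BH q per (class,
    direction) family, Cohen's d (numeric features) and fold enrichment
    (binary features).
    """
    schema = schema or cohort.schema
    labels = np.asarray(labels, dtype=int)
    K = n_classes if n_classes is not None else int(labels.max()) + 1
    if K < 2:
        raise ValueError("need at least 2 classes for enrichment tests")
    sizes = np.bincount(labels, minlength=K)
    if (sizes == 0).any() and n_classes is None:
        raise ValueError(f"empty class(es): {np.flatnonzero(sizes == 0).tolist()}")
    X, is_binary = _feature_arrays(cohort, schema)
    res = _enrichment_arrays(X, is_binary, labels, K, equal_var=equal_var)
    # BH within each (class, direction) family, across features
    q_upper = bh_adjust(res["p_upper"], axis=1)
    q_lower = bh_adjust(res["p_lower"], axis=1)
    F = len(schema.names)
    out = pd.DataFrame(
        {
            "feature": np.tile(schema.names, K),
            "type": np.tile([f.ftype for f in schema], K),
            "class": np.repeat(np.arange(K), F),
            "p_upper": res["p_upper"].ravel(),
            "p_lower": res["p_lower"].ravel(),
            "q_upper": q_upper.ravel(),
            "q_lower": q_lower.ravel(),
            "cohens_d": res["cohens_d"].ravel(),
            "fold_enrichment": res["fold_enrichment"].ravel(),
            "class_mean": res["class_mean"].ravel(),
        }
    )
    return out


def feature_exclusion(
    enrichment: pd.DataFrame,
    q_threshold: float = Q_THRESHOLD,
    d_threshold: float = D_THRESHOLD,
    fe_threshold: float = FE_THRESHOLD,
) -> list[str]:
    """Contributory features surviving the three exclusion criteria.

    A feature is kept only if it (1) is significantly enriched or depleted
    (q < ``q_threshold``) in at least one class and direction, and (2) for
    numeric features reaches |Cohen's d| >= ``d_threshold`` in some class, or
    (3) for binary features reaches fold enrichment >= ``fe_threshold`` in
    some class.
    """
    g = enrichment.groupby("feature", sort=False)
    sig = g.apply(
        lambda df: bool(((df["q_upper"] < q_threshold) | (df["q_lower"] < q_threshold)).any()),
        include_groups=False,
    )
    keep = []
    for feature, df in g:
        if not sig[feature]:
            continue
        ftype = df["type"].iloc[0]
        if ftype == "binary":
            fe = df["fold_enrichment"].abs()
            if not (fe >= fe_threshold).any():
                continue
        else:
            if not (df["cohens_d"].abs() >= d_threshold).any():
                continue
        keep.append(feature)
    return keep


@dataclass
class AffinityMatrix:
    """Signed class-by-category affinity scores plus per-cell counts."""

    scores: pd.DataFrame  # classes x categories, values in [-1, 1] or NaN
    n_enriched: pd.DataFrame
    n_depleted: pd.DataFrame
    n_contributory: pd.Series  # per category

    def flattened(self) -> np.ndarray:
        return self.scores.to_numpy().ravel()


def affinity_scores(
    enrichment: pd.DataFrame,
    contributory: list[str],
    category_map: dict[str, str],
    q_threshold: float = Q_THRESHOLD,
    categories: tuple[str, ...] = PHENOTYPE_CATEGORIES,
) -> AffinityMatrix:
    """Signed affinity of each class toward each phenotype category.

    cell(c, g) = (#contributory features of category g enriched in class c
    - #depleted) / #contributory features of category g, using q <
    ``q_threshold`` in the respective direction.  Categories with no
    contributory feature get NaN cells.
    """
    unknown = [f for f in contributory if f not in category_map]
    if unknown:
        raise ValueError(f"contributory features missing from category map: {unknown[:5]}")
    sub = enrichment[enrichment["feature"].isin(contributory)].copy()
    sub["category"] = sub["feature"].map(category_map)
    K = int(sub["class"].max()) + 1
    classes = np.arange(K)
    n_contrib = pd.Series(
        {g: len({f for f in contributory if category_map[f] == g}) for g in categories}
    )
    enr = pd.DataFrame(0, index=classes, columns=list(categories))
    dep = pd.DataFrame(0, index=classes, columns=list(categories))
    hit_up = sub[sub["q_upper"] < q_threshold].groupby(["class", "category"]).size()
    hit_lo = sub[sub["q_lower"] < q_threshold].groupby(["class", "category"]).size()
    for (c, g), v in hit_up.items():
        if g in enr.columns:
            enr.loc[c, g] = v
    for (c, g), v in hit_lo.items():
        if g in dep.columns:
            dep.loc[c, g] = v
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = (enr - dep) / n_contrib.replace(0, np.nan)
    return AffinityMatrix(
        scores=scores.astype(float),
        n_enriched=enr,
        n_depleted=dep,
        n_contributory=n_contrib,
    )


# ---------------------------------------------------------------------------
# External validation
# ---------------------------------------------------------------------------


def diagnosis_enrichment(
    diagnoses: pd.DataFrame,
    labels: np.ndarray,
    sibling_mask: np.ndarray,
    pseudo_rate: float = 0.5,
) -> pd.DataFrame:
    """Fold enrichment of binary diagnoses per class against siblings.

    ``diagnoses`` has one 0/1 column per diagnosis (NaN allowed) covering the
    same individuals as ``labels``/``sibling_mask``; proband rows carry class
    labels, sibling rows are the background.  FE = class prevalence / sibling
    prevalence; p is the exact upper-tail binomial test of the class count
    against the sibling rate; BH across all emitted (class, diagnosis) cells.
    A sibling prevalence of zero yields infinite FE and an exact test against
    ``pseudo_rate / n_siblings``.
    """
    sibling_mask = np.asarray(sibling_mask, dtype=bool)
    labels = np.asarray(labels)
    rows = []
    for diag in diagnoses.columns:
        col = diagnoses[diag].to_numpy(dtype=float)
        sib = col[sibling_mask]
        sib = sib[~np.isnan(sib)]
        if len(sib) == 0:
            continue
        sib_rate = sib.mean()
        for c in sorted(set(labels[~sibling_mask])):
            cls = col[(~sibling_mask) & (labels == c)]
            cls = cls[~np.isnan(cls)]
            if len(cls) == 0:
                continue
            k = int(cls.sum())
            rate0 = sib_rate if sib_rate > 0 else pseudo_rate / len(sib)
            up, _ = binom_tails(k, len(cls), rate0)
            fe = (cls.mean() / sib_rate) if sib_rate > 0 else np.inf
            rows.append(
                {
                    "class": c,
                    "diagnosis": diag,
                    "class_prevalence": cls.mean(),
                    "sibling_prevalence": sib_rate,
                    "fold_enrichment": fe,
                    "p": float(up),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def group_vs_sibling_tests(
    cohort: PhenotypeCohort,
    labels: np.ndarray,
    features: list[str],
    alternative: str = "greater",
    equal_var: bool = True,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-class means, normal-approximation CIs and t-tests versus siblings.

    ``labels`` apply to proband rows of ``cohort`` (any value on sibling rows
    is ignored).  BH correction is applied per feature across classes.
    Features with no sibling data are skipped.
    """
    sib_mask = ~cohort.is_proband
    rows = []
    for feat in features:
        col = cohort.features[feat].to_numpy(dtype=float)
        sib = col[sib_mask]
        sib = sib[~np.isnan(sib)]
        if len(sib) == 0:
            continue
        ms, vs = sib.mean(), sib.var(ddof=1) if len(sib) > 1 else 0.0
        feat_rows = []
        for c in sorted(set(np.asarray(labels)[cohort.is_proband])):
            cls = col[cohort.is_proband & (np.asarray(labels) == c)]
            cls = cls[~np.isnan(cls)]
            if len(cls) == 0:
                continue
            m, v = cls.mean(), cls.var(ddof=1) if len(cls) > 1 else 0.0
            t, df = t_test_from_stats(m, v, len(cls), ms, vs, len(sib), equal_var=equal_var)
            p = float(t_tail_p(t, df, alternative))
            lo, hi = normal_ci(m, np.sqrt(v), len(cls), ci_level)
            feat_rows.append(
                {
                    "feature": feat,
                    "class": c,
                    "n": len(cls),
                    "mean": m,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "sibling_mean": ms,
                    "sibling_n": len(sib),
                    "p": p,
                }
            )
        if feat_rows:
            q = bh_adjust(np.array([r["p"] for r in feat_rows]))
            for r, qv in zip(feat_rows, q):
                r["q"] = float(qv)
            rows.extend(feat_rows)
    return pd.DataFrame(rows)
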
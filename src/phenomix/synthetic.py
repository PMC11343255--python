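"""Synthetic cohorts with known ground truth.

Real cohorts of this kind sit behind controlled-access repositories, so every
stage of the pipeline is exercised on generated data that emulates their
structure: a proband phenotype matrix with latent classes (binary
questionnaire items, 0-3 categorical items, t-score-like and
milestone-age-like continuous features), a sibling cohort measured only on a
questionnaire/milestone subset, a smaller replication cohort sharing a
feature subset, class-dependent de novo and inherited variant tables, gene
annotations (pLI, named gene sets, developmental-expression sets) and
polygenic-score tables.

Feature families are generated from the same distributions the mixture model
assumes (Gaussian / Bernoulli / multinomial per class), which makes exact
parameter recovery well-defined.  ``separation`` scales all class effects;
at separation 0 every class shares one distribution, so label-free null
behaviour of every downstream statistic can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    Feature,
    FeatureSchema,
    GeneAnnotationTable,
    PhenotypeCohort,
    PHENOTYPE_CATEGORIES,
    SchemaError,
    empty_variant_table,
    validate_variant_table,
)
from .genetics import LOF_CONSEQUENCES, MISSENSE_CONSEQUENCES

__all__ = [
    "CohortSpec",
    "GeneticSpec",
    "ConfigurationError",
    "default_schema",
    "default_class_effects",
    "spark_like_spec",
    "default_genetic_spec",
    "generate_cohort",
    "generate_replication_cohort",
    "generate_variant_table",
    "generate_gene_annotations",
    "generate_pgs_table",
]

DEVDEG_TRENDS = ("Up", "TransUp", "Down", "TransDown")
DEVDEG_CELLTYPES = ("excitatory", "MGE_IN", "CGE_IN", "glia")


class ConfigurationError(ValueError):
    """A generator spec is internally inconsistent."""


# ---------------------------------------------------------------------------
# Phenotype cohort spec
# ---------------------------------------------------------------------------


def default_schema(
    n_milestone: int = 8, n_scq: int = 20, n_rbsr: int = 16, n_cbcl: int = 16
) -> FeatureSchema:
    """Demo-scale feature schema (default 60 features) emulating the study's
    instrument mix.

    * ``milestone_*`` - continuous ages (months) of developmental milestones;
    * ``scq_*`` - binary social-communication questionnaire items;
    * ``rbsr_*`` - 0-3 categorical repetitive-behaviour items;
    * ``cbcl_*`` - continuous behaviour-checklist t-scores.
    """
    feats: list[Feature] = []
    for i in range(n_milestone):
        feats.append(Feature(f"milestone_{i:02d}", "continuous", None, "developmental delay"))
    for i in range(n_scq):
        cat = "limited social/communication" if i < int(round(n_scq * 0.7)) else "restricted/repetitive behavior"
        feats.append(Feature(f"scq_{i:02d}", "binary", None, cat))
    for i in range(n_rbsr):
        cat = "restricted/repetitive behavior" if i < int(round(n_rbsr * 0.625)) else "self-injury"
        feats.append(Feature(f"rbsr_{i:02d}", "categorical", 4, cat))
    third = max(n_cbcl // 3, 1)
    for i in range(n_cbcl):
        cat = ("attention", "disruptive behavior", "anxiety/mood")[min(i // third, 2)]
        feats.append(Feature(f"cbcl_{i:02d}", "continuous", None, cat))
    return FeatureSchema(tuple(feats))


#: Per-class, per-category effect pattern (rows: the four emulated classes).
#: Class 0 scores uniformly below other probands, class 1 uniformly above;
#: class 2 is elevated on social/behavioural categories without developmental
#: delay; class 3 combines developmental delay and repetitive behaviour with
#: lower behavioural scores.
DEFAULT_CLASS_PATTERN = pd.DataFrame(
    [
        [-0.8, -0.8, -0.8, -0.8, -0.8, -0.8, -0.8],
        [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
        [1.0, 0.6, 1.0, 1.0, 1.0, -1.0, 0.3],
        [-0.3, 0.8, -0.6, -0.5, -0.6, 1.2, 0.5],
    ],
    columns=list(PHENOTYPE_CATEGORIES),
)


def default_class_effects(schema: FeatureSchema, pattern: pd.DataFrame | None = None) -> np.ndarray:
    """(K, F) effect matrix: each feature inherits its category's pattern."""
    pattern = DEFAULT_CLASS_PATTERN if pattern is None else pattern
    cols = []
    for f in schema:
        if f.category in pattern.columns:
            cols.append(pattern[f.category].to_numpy())
        else:
            cols.append(np.zeros(len(pattern)))
    return np.column_stack(cols)


@dataclass
class CohortSpec:
    """Generator settings for one phenotype cohort.

    ``class_effects`` is a (K, F) matrix in standard-deviation units (logit
    units for binary items, level-tilt units for categorical items), scaled
    globally by ``separation``.  ``mixing`` is a length-K probability vector;
    alternatively ``mixing_logit`` (K, 3) makes class membership depend on the
    covariates (intercept, sex, age) through a multinomial logit.
    """

    n_individuals: int = 2000
    n_siblings: int = 1000
    n_classes: int = 4
    mixing: np.ndarray | None = None
    mixing_logit: np.ndarray | None = None
    feature_schema: FeatureSchema = field(default_factory=default_schema)
    class_effects: np.ndarray | None = None
    separation: float = 1.0
    age_mean: float = 8.56
    age_sd: float = 3.15
    sex_p: float = 0.774
    missingness: float | Mapping[str, float] = 0.0
    sibling_effect: float = -1.5
    sibling_feature_prefixes: tuple[str, ...] = ("scq_", "milestone_")
    truncate_milestones: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_siblings < 0 or self.n_classes < 1:
            raise ValueError("invalid cohort sizes")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.mixing is None and self.mixing_logit is None:
            self.mixing = np.full(self.n_classes, 1.0 / self.n_classes)
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=float)
            if len(self.mixing) != self.n_classes:
                raise ConfigurationError("mixing length must equal n_classes")
            if abs(self.mixing.sum() - 1.0) > 1e-12:
                raise ConfigurationError("mixing probabilities must sum to 1")
        if self.class_effects is None:
            eff = default_class_effects(self.feature_schema)
            if len(eff) < self.n_classes:
                raise ConfigurationError(
                    "default class pattern covers 4 classes; provide class_effects for larger K"
                )
            self.class_effects = eff[: self.n_classes]
        self.class_effects = np.asarray(self.class_effects, dtype=float)
        if self.class_effects.shape != (self.n_classes, len(self.feature_schema)):
            raise ConfigurationError(
                f"class_effects must be (K={self.n_classes}, F={len(self.feature_schema)})"
            )


def spark_like_spec(
    n_individuals: int = 2000, n_siblings: int = 1000, separation: float = 1.0, seed: int = 0,
    **overrides,
) -> CohortSpec:
    """Demo-scale spec emulating the discovery cohort's structure: four
    latent classes with mixing proportions matching the reported class sizes
    (1976/554/1860/1002 of 5392), covariates age ~ N(8.56, 3.15) years and
    77.4% male."""
    mixing = np.array([1976.0, 554.0, 1860.0, 1002.0])
    mixing /= mixing.sum()
    return CohortSpec(
        n_individuals=n_individuals,
        n_siblings=n_siblings,
        n_classes=4,
        mixing=mixing,
        separation=separation,
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Phenotype generation
# ---------------------------------------------------------------------------


def _base_params(feature: Feature) -> tuple[float, float]:
    """(location, scale) of the class-free baseline for a feature."""
    if feature.name.startswith("milestone_"):
        return 14.0, 5.0  # months
    if feature.name.startswith("cbcl_"):
        return 55.0, 10.0  # t-score scale
    if feature.ftype == "continuous":
        return 0.0, 1.0
    if feature.ftype == "binary":
        return 0.45, 1.0  # baseline success probability
    return 0.0, 1.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _sample_features(
    schema: FeatureSchema,
    effects_per_row: np.ndarray,  # (n, F) effect (already separation-scaled)
    rng: np.random.Generator,
    truncate_milestones: bool,
) -> pd.DataFrame:
    n = effects_per_row.shape[0]
    out = {}
    for j, f in enumerate(schema):
        eff = effects_per_row[:, j]
        loc, scale = _base_params(f)
        if f.ftype == "continuous":
            x = loc + scale * (eff + rng.standard_normal(n))
            if truncate_milestones and f.name.startswith("milestone_"):
                x = np.maximum(x, 0.0)
            out[f.name] = x
        elif f.ftype == "binary":
            p = _sigmoid(np.log(loc / (1.0 - loc)) + eff)
            out[f.name] = (rng.random(n) < p).astype(float)
        else:
            L = f.n_levels
            lin = (np.arange(L) - (L - 1) / 2.0) / ((L - 1) / 2.0)
            logits = eff[:, None] * lin[None, :]
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(n)
            out[f.name] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(float)
    return pd.DataFrame(out)


def generate_cohort(spec: CohortSpec) -> PhenotypeCohort:
    """Draw a proband + sibling cohort with known class labels.

    Probands carry ``true_class``; siblings are drawn from a reference
    distribution shifted by ``sibling_effect`` on the questionnaire/milestone
    subset and have NaN for all other features (emulating the limited sibling
    battery).  Identical spec + seed reproduces bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    K, F = spec.n_classes, len(spec.feature_schema)
    n_p, n_s = spec.n_individuals, spec.n_siblings
    n = n_p + n_s
    sex = (rng.random(n) < spec.sex_p).astype(float)
    age = spec.age_mean + spec.age_sd * rng.standard_normal(n)
    if spec.mixing_logit is not None:
        C = np.column_stack([np.ones(n_p), sex[:n_p], age[:n_p]])
        logits = C @ np.asarray(spec.mixing_logit, dtype=float).T
        logits -= logits.max(axis=1, keepdims=True)
        pk = np.exp(logits)
        pk /= pk.sum(axis=1, keepdims=True)
        labels = (pk.cumsum(axis=1) < rng.random(n_p)[:, None]).sum(axis=1)
    else:
        labels = rng.choice(K, size=n_p, p=spec.mixing)
    eff_p = spec.class_effects[labels] * spec.separation  # (n_p, F)
    feats_p = _sample_features(spec.feature_schema, eff_p, rng, spec.truncate_milestones)

    sib_cols = [
        f.name
        for f in spec.feature_schema
        if any(f.name.startswith(p) for p in spec.sibling_feature_prefixes)
    ]
    eff_s = np.zeros((n_s, F))
    for j, f in enumerate(spec.feature_schema):
        if f.name in sib_cols:
            eff_s[:, j] = spec.sibling_effect
    feats_s = _sample_features(spec.feature_schema, eff_s, rng, spec.truncate_milestones)
    for f in spec.feature_schema:
        if f.name not in sib_cols:
            feats_s[f.name] = np.nan

    features = pd.concat([feats_p, feats_s], ignore_index=True)
    # missingness (completely at random)
    if isinstance(spec.missingness, Mapping):
        miss = {name: float(spec.missingness.get(name, 0.0)) for name in spec.feature_schema.names}
    else:
        miss = {name: float(spec.missingness) for name in spec.feature_schema.names}
    for name, rate in miss.items():
        if rate > 0:
            mask = rng.random(n) < rate
            features.loc[mask, name] = np.nan

    ids = [f"P{i:06d}" for i in range(n_p)] + [f"S{i:06d}" for i in range(n_s)]
    features.index = pd.Index(ids, name="individual_id")
    covariates = pd.DataFrame({"sex": sex, "age_years": age}, index=features.index)
    role = np.array(["proband"] * n_p + ["sibling"] * n_s, dtype=object)
    true_class = np.concatenate([labels.astype(float), np.full(n_s, np.nan)])
    return PhenotypeCohort(
        features=features[spec.feature_schema.names],
        covariates=covariates,
        role=role,
        schema=spec.feature_schema,
        true_class=true_class,
    )


def generate_replication_cohort(spec: CohortSpec, common_features: Sequence[str]) -> PhenotypeCohort:
    """A cohort from the same class-conditional distributions restricted to a
    shared feature subset (emulating an independent replication cohort)."""
    unknown = set(common_features) - set(spec.feature_schema.names)
    if unknown:
        raise SchemaError(f"unknown feature name(s): {sorted(unknown)}")
    full = generate_cohort(spec)
    return full.subset_features(list(common_features))


# ---------------------------------------------------------------------------
# Genetics spec and generation
# ---------------------------------------------------------------------------


@dataclass
class GeneticSpec:
    """Generator settings for variant tables and gene annotations.

    ``rates`` maps a variant type (dnLoF, dnMis, dnSyn, inhLoF, inhMis) to a
    {gene-set name: per-group Poisson rate vector} map; rate vectors have
    length K+1 with the last entry applying to siblings.  Gene-set name
    ``"genome"`` denotes the whole gene universe.  ``fraction_zero_dnv``
    individuals are forced to have zero de novo calls (they still appear in
    count rosters).
    """

    n_genes: int = 1000
    n_classes: int = 4
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    pli: np.ndarray | None = None
    devdeg: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    rates: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    af_range: tuple[float, float] = (1e-5, 0.5)  # log-uniform for inherited AF
    fraction_zero_dnv: float = 0.045
    lof_hc_prob: float = 0.9
    mis_pathogenic_prob: float = 0.8
    n_shared_variants: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pli is not None:
            self.pli = np.asarray(self.pli, dtype=float)
            if ((self.pli < 0) | (self.pli > 1)).any():
                raise ConfigurationError("pLI values must lie in [0, 1]")
        for vtype, per_set in self.rates.items():
            for name, r in per_set.items():
                r = np.asarray(r, dtype=float)
                if (r < 0).any():
                    raise ConfigurationError(f"negative rate for {vtype}/{name}")
                if len(r) != self.n_classes + 1:
                    raise ConfigurationError(
                        f"rate vector {vtype}/{name} must have length K+1={self.n_classes + 1} "
                        "(last entry = siblings)"
                    )
                per_set[name] = r

    @property
    def genes(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]


def default_genetic_spec(n_classes: int = 4, seed: int = 0) -> GeneticSpec:
    """Default genetic generator emulating reported cohort-level magnitudes.

    Total de novo rates approximate 2.71 calls/proband and 2.47/sibling;
    4.5% of individuals have zero de novo calls.  Class-specific elevations
    place extra de novo LoF in an autism-risk gene set for every class and a
    devDEG (Down x excitatory) elevation in the developmental-delay-like
    class, plus extra rare inherited LoF in that class.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(1000)]
    # bimodal pLI: ~25% of genes drawn near 1
    high = rng.random(1000) < 0.25
    pli = np.where(high, rng.beta(12, 0.5, 1000), rng.beta(0.5, 8, 1000))
    order = rng.permutation(1000)
    asd_risk = [genes[i] for i in order[:100]]
    fmrp = [genes[i] for i in order[80:230]]
    gene_sets = {
        "all_genes": list(genes),
        "asd_risk": asd_risk,
        "fmrp": fmrp,
        "high_pli": [g for g, p in zip(genes, pli) if p > 0.9],
    }
    devdeg: dict[tuple[str, str], list[str]] = {}
    for trend in DEVDEG_TRENDS:
        for ct in DEVDEG_CELLTYPES:
            devdeg[(trend, ct)] = [genes[i] for i in rng.permutation(1000)[:60]]
    K = n_classes
    rates = {
        "dnSyn": {"genome": np.full(K + 1, 1.0)},
        "dnMis": {"genome": np.concatenate([np.full(K, 1.3), [1.17]])},
        "dnLoF": {
            "genome": np.concatenate([np.full(K, 0.3), [0.3]]),
            "asd_risk": np.concatenate([np.array([0.03, 0.15, 0.05, 0.08])[:K], [0.0]]),
        },
        "inhLoF": {"genome": np.concatenate([np.full(K, 2.0), [2.0]])},
        "inhMis": {"genome": np.concatenate([np.full(K, 4.0), [4.0]])},
    }
    # extra inherited LoF in the developmental-delay-like class (index 3)
    if K >= 4:
        extra = np.zeros(K + 1)
        extra[3] = 0.6
        rates["inhLoF"]["asd_risk"] = extra
    return GeneticSpec(
        n_genes=1000,
        n_classes=K,
        gene_sets=gene_sets,
        pli=pli,
        devdeg=devdeg,
        rates=rates,
        seed=seed,
    )


def generate_gene_annotations(gspec: GeneticSpec) -> GeneAnnotationTable:
    """Materialize the per-gene annotation table from a genetic spec."""
    genes = gspec.genes
    if gspec.pli is None:
        rng = np.random.default_rng(gspec.seed)
        high = rng.random(gspec.n_genes) < 0.25
        pli = np.where(high, rng.beta(12, 0.5, gspec.n_genes), rng.beta(0.5, 8, gspec.n_genes))
    else:
        pli = gspec.pli
    return GeneAnnotationTable(
        pli=pd.Series(pli, index=pd.Index(genes, name="gene")),
        gene_sets={k: list(v) for k, v in gspec.gene_sets.items()},
        devdeg={k: list(v) for k, v in gspec.devdeg.items()},
    )


_BASES = np.array(list("ACGT"))


def _records_for(
    individuals: np.ndarray,
    families: np.ndarray,
    counts: np.ndarray,
    genes: list[str],
    vtype: str,
    gspec: GeneticSpec,
    rng: np.random.Generator,
) -> list[dict]:
    total = int(counts.sum())
    if total == 0:
        return []
    owner = np.repeat(np.arange(len(individuals)), counts)
    gene_idx = rng.integers(0, len(genes), total)
    chrom = rng.integers(1, 23, total)
    pos = rng.integers(10_000, 100_000_000, total)
    ref_i = rng.integers(0, 4, total)
    alt_i = (ref_i + rng.integers(1, 4, total)) % 4
    origin = "denovo" if vtype.startswith("dn") else "inherited"
    if vtype.endswith("LoF"):
        csq = rng.choice(sorted(LOF_CONSEQUENCES), total)
        lof = np.where(rng.random(total) < gspec.lof_hc_prob, "HC", "LC")
        mis = np.full(total, np.nan, dtype=object)
    elif vtype.endswith("Mis"):
        csq = rng.choice(sorted(MISSENSE_CONSEQUENCES), total)
        lof = np.full(total, np.nan, dtype=object)
        mis = np.where(
            rng.random(total) < gspec.mis_pathogenic_prob, "likely_pathogenic", "likely_benign"
        )
    else:
        csq = np.full(total, "synonymous_variant", dtype=object)
        lof = np.full(total, np.nan, dtype=object)
        mis = np.full(total, np.nan, dtype=object)
    if origin == "inherited":
        lo, hi = gspec.af_range
        af = np.exp(rng.uniform(np.log(lo), np.log(hi), total))
    else:
        af = np.full(total, np.nan)
    return [
        {
            "individual_id": individuals[o],
            "family_id": families[o],
            "gene": genes[g],
            "origin": origin,
            "consequence": c,
            "lof_confidence": lc,
            "missense_class": mc,
            "allele_frequency": a,
            "chrom": f"chr{ch}",
            "pos": int(p),
            "ref": _BASES[r],
            "alt": _BASES[al],
        }
        for o, g, c, lc, mc, a, ch, p, r, al in zip(
            owner, gene_idx, csq, lof, mis, af, chrom, pos, ref_i, alt_i
        )
    ]


def generate_variant_table(cohort: PhenotypeCohort, gspec: GeneticSpec) -> pd.DataFrame:
    """Class-dependent de novo and inherited variant records.

    Counts per individual per (variant type, gene set) are Poisson with the
    spec's group rate; genes are drawn uniformly within the set.  Probands
    use their true class, siblings the last rate entry.  A
    ``fraction_zero_dnv`` subset of individuals receives no de novo records
    at all (their zero counts are restored downstream by the de novo
    filter).  Optionally ``n_shared_variants`` de novo records are duplicated
    into a second family to exercise the non-singleton filter.
    """
    if cohort.true_class is None:
        raise ValueError("cohort must carry true class labels for probands")
    rng = np.random.default_rng(gspec.seed)
    is_proband = cohort.is_proband
    labels = np.asarray(cohort.true_class, dtype=float)
    if np.isnan(labels[is_proband]).any():
        raise ValueError("probands must have non-missing true_class")
    K = gspec.n_classes
    if is_proband.any() and labels[is_proband].max() >= K:
        raise ConfigurationError("rate table missing a class present in the cohort")
    ids = cohort.ids.to_numpy().astype(str)
    # family: proband i owns family F{i}; sibling j is paired with proband j
    fam = np.array([f"F{int(x[1:]):06d}" for x in ids])
    group = np.where(is_proband, labels, K).astype(int)  # sibling group = K

    zero_dnv = np.zeros(len(ids), dtype=bool)
    n_zero = int(np.floor(gspec.fraction_zero_dnv * len(ids)))
    if n_zero:
        zero_dnv[rng.choice(len(ids), n_zero, replace=False)] = True

    rows: list[dict] = []
    for vtype, per_set in sorted(gspec.rates.items()):
        is_dn = vtype.startswith("dn")
        eligible = ~zero_dnv if is_dn else np.ones(len(ids), dtype=bool)
        for set_name, rate_vec in sorted(per_set.items()):
            genes = gspec.genes if set_name == "genome" else list(gspec.gene_sets[set_name])
            lam = rate_vec[group] * eligible
            counts = rng.poisson(lam)
            rows.extend(_records_for(ids, fam, counts, genes, vtype, gspec, rng))
    if not rows:
        table = empty_variant_table()
    else:
        table = pd.DataFrame(rows)
    if gspec.n_shared_variants and len(table):
        dn_idx = table.index[table["origin"] == "denovo"]
        take = rng.choice(dn_idx, min(gspec.n_shared_variants, len(dn_idx)), replace=False)
        dup = table.loc[take].copy()
        other = rng.integers(0, len(ids), len(dup))
        dup["individual_id"] = ids[other]
        dup["family_id"] = fam[other]
        table = pd.concat([table, dup], ignore_index=True)
    return validate_variant_table(table.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Polygenic scores
# ---------------------------------------------------------------------------


def generate_pgs_table(
    cohort: PhenotypeCohort,
    traits: Sequence[str],
    class_shifts: Mapping[str, Sequence[float]],
    n_pcs: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-individual trait scores with class shifts, sex/PC structure and
    unit noise; siblings draw from the zero-shift reference distribution.

    Returns a table with one column per trait plus ``PC1..PCn`` ancestry
    components, indexed by individual.
    """
    traits = list(traits)
    if not traits:
        raise ValueError("trait list must be non-empty")
    if n_pcs < 0:
        raise ValueError("n_pcs must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    pcs = rng.standard_normal((n, n_pcs))
    sex = cohort.covariates["sex"].to_numpy(dtype=float)
    labels = (
        np.asarray(cohort.true_class, dtype=float)
        if cohort.true_class is not None
        else np.full(n, np.nan)
    )
    out = pd.DataFrame(index=cohort.ids)
    pc_beta = 0.15 * np.ones(n_pcs)
    for trait in traits:
        shifts = np.asarray(class_shifts.get(trait, np.zeros(1)), dtype=float)
        shift = np.zeros(n)
        probands = cohort.is_proband
        lab = labels.copy()
        lab[~probands] = -1
        for k, s in enumerate(shifts):
            shift[lab == k] = s
        out[trait] = shift + 0.2 * sex + pcs @ pc_beta + rng.standard_normal(n)
    for j in range(n_pcs):
        out[f"PC{j + 1}"] = pcs[:, j]
    return out
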
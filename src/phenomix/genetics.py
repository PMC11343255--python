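"""Class-stratified rare-variant, gene-set and polygenic-score analyses.

Variants arrive pre-annotated (consequence string, LOFTEE-style confidence
flag, AlphaMissense-style pathogenicity class, population allele frequency)
and are classified into four working classes: high-confidence loss of
function (LoF_HC), damaging missense, synonymous, other.  De novo calls are
quality-filtered (per-individual outlier exclusion at mean + 3 SD of the
total call count, removal of variants seen in more than one family, explicit
zero counts for individuals with no calls); inherited calls are restricted to
rare variants (allele frequency < 1%, with missing frequencies treated as
rare-by-absence).  Downstream, per-individual variant counts within gene sets
are compared between each proband class and the sibling background with
one-sided t-tests (count burden), carrier-based odds ratios with one-sided
Fisher tests, developmental-expression (trend x cell type) burden scans,
Mood's median test on the pLI of impacted genes, hypergeometric term
enrichment, and sibling-normalized polygenic-score contrasts.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, t_tail_p, t_test_from_stats
from .data import validate_variant_table

logger = logging.getLogger(__name__)

__all__ = [
    "LOF_CONSEQUENCES",
    "MISSENSE_CONSEQUENCES",
    "classify_variant",
    "classify_variants",
    "filter_de_novo",
    "filter_rare_inherited",
    "variant_counts",
    "burden_test",
    "odds_ratio_test",
    "constraint_bin",
    "devdeg_enrichment",
    "pli_median_test",
    "hypergeom_enrichment",
    "pgs_compare",
]

#: VEP-style consequence terms counted as loss of function (when LOFTEE-HC).
LOF_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "start_lost",
        "stop_lost",
        "transcript_ablation",
    }
)

#: Consequence terms counted as missense-like (when AlphaMissense-pathogenic).
MISSENSE_CONSEQUENCES = frozenset(
    {
        "missense_variant",
        "inframe_deletion",
        "inframe_insertion",
        "protein_altering_variant",
    }
)

KNOWN_CONSEQUENCES = LOF_CONSEQUENCES | MISSENSE_CONSEQUENCES | {"synonymous_variant"}

_warned_consequences: set[str] = set()


def classify_variant(consequence: str, lof_confidence=None, missense_class=None) -> str:
    """Classify one annotated variant into {LoF_HC, missense_damaging,
    synonymous, other}."""
    csq = str(consequence)
    if csq in LOF_CONSEQUENCES:
        return "LoF_HC" if lof_confidence == "HC" else "other"
    if csq in MISSENSE_CONSEQUENCES:
        return "missense_damaging" if missense_class == "likely_pathogenic" else "other"
    if csq == "synonymous_variant":
        return "synonymous"
    if csq not in _warned_consequences:
        _warned_consequences.add(csq)
        logger.warning("unknown consequence %r classified as 'other'", csq)
    return "other"


def classify_variants(table: pd.DataFrame) -> pd.Series:
    """Vectorized variant classification; adds nothing to the table."""
    csq = table["consequence"].astype(str)
    lof = table.get("lof_confidence")
    mis = table.get("missense_class")
    out = pd.Series("other", index=table.index, dtype=object)
    is_lof = csq.isin(LOF_CONSEQUENCES)
    if lof is not None:
        out[is_lof & (lof == "HC")] = "LoF_HC"
    is_mis = csq.isin(MISSENSE_CONSEQUENCES)
    if mis is not None:
        out[is_mis & (mis == "likely_pathogenic")] = "missense_damaging"
    out[csq == "synonymous_variant"] = "synonymous"
    for unknown in set(csq[~csq.isin(KNOWN_CONSEQUENCES)]) - _warned_consequences:
        _warned_consequences.add(unknown)
        logger.warning("unknown consequence %r classified as 'other'", unknown)
    return out


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def _variant_key(table: pd.DataFrame) -> pd.Series:
    """Identity key for non-singleton detection: positional fields when
    present, otherwise (gene, consequence, variant_id-like hash columns)."""
    positional = all(c in table.columns for c in ("chrom", "pos", "ref", "alt"))
    if positional and table["pos"].notna().all():
        return (
            table["gene"].astype(str)
            + ":" + table["chrom"].astype(str)
            + ":" + table["pos"].astype(str)
            + ":" + table["ref"].astype(str)
            + ":" + table["alt"].astype(str)
        )
    if "variant_id" in table.columns:
        return table["gene"].astype(str) + ":" + table["variant_id"].astype(str)
    return table["gene"].astype(str) + ":" + table["consequence"].astype(str)


def filter_de_novo(
    table: pd.DataFrame, roster: Sequence[str]
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Quality-control filter for de novo calls.

    1. individuals whose total de novo count exceeds mean + 3 SD (computed
       once over the full roster, zero-callers included) are excluded;
    2. variants whose identity key occurs in more than one family are removed
       from every family;
    3. the returned per-individual counts carry explicit zeros for roster
       members with no surviving records.
    """
    roster = pd.Index([str(r) for r in roster]).unique()
    if len(roster) == 0:
        raise ValueError("empty roster")
    table = validate_variant_table(table)
    dnv = table[table["origin"] == "denovo"].copy()
    counts = (
        dnv.groupby("individual_id").size().reindex(roster, fill_value=0).astype(float)
    )
    mean, sd = counts.mean(), counts.std(ddof=1)
    cutoff = mean + 3.0 * sd
    outliers = counts.index[counts > cutoff]
    dnv = dnv[~dnv["individual_id"].astype(str).isin(outliers)]
    key = _variant_key(dnv)
    fam_per_key = dnv.assign(_key=key).groupby("_key")["family_id"].nunique()
    multi = set(fam_per_key.index[fam_per_key > 1])
    nonsingleton = key.isin(multi)
    dnv = dnv[~nonsingleton.to_numpy()]
    kept_roster = roster.difference(outliers)
    final_counts = (
        dnv.groupby("individual_id").size().reindex(kept_roster, fill_value=0).astype(int)
    )
    report = {
        "n_outlier_individuals": int(len(outliers)),
        "outlier_cutoff": float(cutoff),
        "n_nonsingleton_removed": int(nonsingleton.sum()),
        "n_zero_call_individuals": int((final_counts == 0).sum()),
    }
    return dnv.reset_index(drop=True), final_counts, report


def filter_rare_inherited(table: pd.DataFrame, af_threshold: float = 0.01) -> pd.DataFrame:
    """Restrict inherited records to rare variants (AF < ``af_threshold``).

    Records with missing AF are kept and flagged ``rare_by_absence`` (absence
    from the population reference implies rarity).  De novo records pass
    through untouched.  AF outside [0, 1] raises.
    """
    table = validate_variant_table(table)
    af = pd.to_numeric(table.get("allele_frequency"), errors="coerce")
    bad = af.notna() & ((af < 0) | (af > 1))
    if bad.any():
        raise ValueError(f"{int(bad.sum())} record(s) with allele_frequency outside [0, 1]")
    inherited = table["origin"] == "inherited"
    keep = ~inherited | (af < af_threshold) | af.isna()
    out = table[keep].copy()
    out["rare_by_absence"] = (out["origin"] == "inherited") & pd.to_numeric(
        out.get("allele_frequency"), errors="coerce"
    ).isna()
    n_flagged = int(out["rare_by_absence"].sum())
    if n_flagged:
        logger.info("%d inherited record(s) kept with missing AF (rare_by_absence)", n_flagged)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Counting and burden
# ---------------------------------------------------------------------------


def variant_counts(
    table: pd.DataFrame,
    roster: Sequence[str],
    variant_class: str | None = None,
    gene_set: Sequence[str] | None = None,
    origin: str | None = None,
) -> pd.Series:
    """Per-individual variant counts with explicit zeros over ``roster``.

    Optionally restricted to one classified variant class (``LoF_HC`` etc.,
    or the union ``high_impact`` = LoF_HC + missense_damaging), a gene set,
    and an origin.
    """
    roster = pd.Index([str(r) for r in roster]).unique()
    sub = table
    if origin is not None:
        sub = sub[sub["origin"] == origin]
    if variant_class is not None:
        cls = classify_variants(sub)
        if variant_class == "high_impact":
            sub = sub[cls.isin(["LoF_HC", "missense_damaging"])]
        else:
            sub = sub[cls == variant_class]
    if gene_set is not None:
        sub = sub[sub["gene"].isin(set(gene_set))]
    return sub.groupby("individual_id").size().reindex(roster, fill_value=0).astype(int)


def burden_test(
    counts: pd.Series,
    groups: pd.Series,
    sibling_label: str = "sibling",
    alternative: str = "greater",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Count-burden comparison of each proband group against siblings.

    ``counts`` and ``groups`` are aligned per individual (zeros included).
    Reports per group: n, mean count per offspring, SE = sd/sqrt(n), fold
    enrichment of means versus siblings, the one-sided t-test p, and BH q
    across groups (one correction family per call).
    """
    groups = groups.reindex(counts.index)
    sib = counts[groups == sibling_label].to_numpy(dtype=float)
    if len(sib) == 0:
        raise ValueError("sibling group is empty")
    ms = sib.mean()
    vs = sib.var(ddof=1) if len(sib) > 1 else 0.0
    rows = []
    for grp in [g for g in pd.unique(groups.dropna()) if g != sibling_label]:
        x = counts[groups == grp].to_numpy(dtype=float)
        if len(x) == 0:
            continue
        m = x.mean()
        v = x.var(ddof=1) if len(x) > 1 else 0.0
        t, df = t_test_from_stats(m, v, len(x), ms, vs, len(sib), equal_var=equal_var)
        p = float(t_tail_p(t, df, alternative))
        fe = m / ms if ms > 0 else (np.inf if m > 0 else np.nan)
        rows.append(
            {
                "group": grp,
                "n": len(x),
                "mean": m,
                "se": float(np.sqrt(v / len(x))),
                "sibling_mean": ms,
                "sibling_se": float(np.sqrt(vs / len(sib))),
                "fold_enrichment": fe,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def odds_ratio_test(
    table: pd.DataFrame,
    groups: pd.Series,
    gene_set: Sequence[str],
    variant_class: str,
    sibling_label: str = "sibling",
    origin: str | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Carrier odds ratios of each proband group against siblings.

    A carrier has >= 1 variant of ``variant_class`` in ``gene_set``.  The
    odds ratio uses the Haldane-Anscombe +0.5 correction when any cell of the
    2x2 table is zero; the p-value is the one-sided Fisher exact test on the
    uncorrected table.  BH across groups (one family per call).
    """
    roster = groups.dropna().index
    counts = variant_counts(table, roster, variant_class, gene_set, origin=origin)
    carrier = counts > 0
    sib_mask = groups == sibling_label
    c = int(carrier[groups.index[sib_mask]].sum())
    d = int((~carrier[groups.index[sib_mask]]).sum())
    if c + d == 0:
        raise ValueError("sibling group is empty")
    rows = []
    for grp in [g for g in pd.unique(groups.dropna()) if g != sibling_label]:
        idx = groups.index[groups == grp]
        if len(idx) == 0:
            raise ValueError(f"group {grp!r} has zero members")
        a = int(carrier[idx].sum())
        b = int((~carrier[idx]).sum())
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) / (b + 0.5)) / ((c + 0.5) / (d + 0.5))
        else:
            orr = (a / b) / (c / d)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        rows.append(
            {
                "group": grp,
                "carriers": a,
                "non_carriers": b,
                "sibling_carriers": c,
                "sibling_non_carriers": d,
                "odds_ratio": float(orr),
                "p": float(p),
            }
        )
    if not rows:
        raise ValueError("no proband group present")
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def constraint_bin(pli: float) -> str:
    """Constraint bin from pLI: high (>= 0.995), intermediate ([0.5, 0.995)),
    none otherwise."""
    if not 0.0 <= pli <= 1.0:
        raise ValueError(f"pLI {pli} outside [0, 1]")
    if pli >= 0.995:
        return "high"
    if pli >= 0.5:
        return "intermediate"
    return "none"


# ---------------------------------------------------------------------------
# Developmental expression, pLI, term enrichment
# ---------------------------------------------------------------------------


def devdeg_enrichment(
    table: pd.DataFrame,
    groups: pd.Series,
    devdeg_sets: Mapping[tuple[str, str], Sequence[str]],
    sibling_label: str = "sibling",
    variant_class: str = "LoF_HC",
    origin: str | None = "denovo",
    pooled_label: str = "all_probands",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Burden scan over developmental-expression gene sets.

    For each (trend, cell type) gene set, runs the count-burden test for each
    proband group and for the pooled proband group against siblings; BH
    correction per gene set.  Empty gene sets give NaN rows.
    """
    roster = groups.dropna().index
    pooled = groups.copy()
    pooled[(groups.notna()) & (groups != sibling_label)] = pooled_label
    rows = []
    for (trend, celltype), genes in sorted(devdeg_sets.items()):
        if len(genes) == 0:
            rows.append(
                {"trend": trend, "celltype": celltype, "group": None, "mean": np.nan,
                 "fold_enrichment": np.nan, "p": np.nan, "q": np.nan}
            )
            continue
        counts = variant_counts(table, roster, variant_class, genes, origin=origin)
        res = burden_test(counts, groups, sibling_label, equal_var=equal_var)
        res_pool = burden_test(counts, pooled, sibling_label, equal_var=equal_var)
        res = pd.concat([res, res_pool], ignore_index=True)
        res["q"] = bh_adjust(res["p"].to_numpy())  # BH per gene set incl. pooled row
        res.insert(0, "celltype", celltype)
        res.insert(0, "trend", trend)
        rows.append(res)
    frames = [r for r in rows if isinstance(r, pd.DataFrame)]
    nans = [r for r in rows if isinstance(r, dict)]
    out = pd.concat(frames + [pd.DataFrame(nans)] if nans else frames, ignore_index=True)
    return out


def pli_median_test(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    pli: Mapping[str, float] | pd.Series,
    alternative: str = "less",
) -> dict:
    """One-tailed Mood's median test on the pLI of two impacted-gene lists.

    Pools both lists, takes the grand median, builds the 2x2 table of
    (> grand median / <= grand median) x group with ties assigned to the
    "<=" cell, and computes a one-sided Fisher exact p for the pre-declared
    direction (``less``: group A sits below group B; ``greater``: above).
    Returns the chi-square statistic of the table, the p-value, the grand
    median and the two group medians.  If every pooled value is identical the
    test is degenerate and p = 1 is returned flagged.
    """
    pli = pd.Series(pli)
    a = pli.reindex([str(g) for g in genes_a]).dropna().to_numpy(dtype=float)
    b = pli.reindex([str(g) for g in genes_b]).dropna().to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both gene lists must be non-empty with pLI available")
    pooled = np.concatenate([a, b])
    grand = float(np.median(pooled))
    above_a, below_a = int((a > grand).sum()), int((a <= grand).sum())
    above_b, below_b = int((b > grand).sum()), int((b <= grand).sum())
    tbl = np.array([[above_a, below_a], [above_b, below_b]])
    degenerate = np.all(pooled == pooled[0])
    if degenerate:
        stat, p = 0.0, 1.0
    else:
        with np.errstate(invalid="ignore"):
            try:
                stat = float(stats.chi2_contingency(tbl, correction=False)[0])
            except ValueError:  # a zero margin
                stat = 0.0
        # 'less': A shifted below B  <=>  A has fewer above-median genes
        fisher_alt = "less" if alternative == "less" else "greater"
        _, p = stats.fisher_exact(tbl, alternative=fisher_alt)
    return {
        "statistic": float(stat),
        "p": float(p),
        "grand_median": grand,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "table": tbl,
        "degenerate": bool(degenerate),
    }


def hypergeom_enrichment(
    impacted: Sequence[str],
    term_sets: Mapping[str, Sequence[str]],
    background: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric term enrichment over a fixed gene background.

    For a term with K_t background genes, k overlapping impacted genes, n
    impacted genes and N background genes: FE = (k/n)/(K_t/N) and
    p = P(X >= k) for X ~ Hypergeometric(N, K_t, n).  BH across terms;
    sortable by q then fold enrichment.
    """
    background = set(map(str, background))
    impacted = set(map(str, impacted)) & background
    n = len(impacted)
    if n == 0:
        raise ValueError("no impacted genes within the background")
    N = len(background)
    rows = []
    for term, genes in term_sets.items():
        genes = set(map(str, genes)) & background
        Kt = len(genes)
        k = len(impacted & genes)
        fe = (k / n) / (Kt / N) if Kt > 0 else np.nan
        p = float(stats.hypergeom.sf(k - 1, N, Kt, n)) if Kt > 0 else np.nan
        rows.append({"term": term, "K_term": Kt, "k_overlap": k, "fold_enrichment": fe, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["q", "fold_enrichment"], ascending=[True, False]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Polygenic scores
# ---------------------------------------------------------------------------


def pgs_compare(
    pgs: pd.DataFrame,
    groups: pd.Series,
    covariates: pd.DataFrame,
    traits: Sequence[str] | None = None,
    sibling_label: str = "sibling",
    scale: bool = True,
    alternative: str = "two-sided",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Sibling-normalized polygenic-score contrasts per class and trait.

    Scores are residualized by least squares on (intercept, sex, ancestry
    PCs) over all individuals, then centered on the sibling mean and (by
    default) scaled by the sibling SD, per trait.  Each proband group is
    compared to siblings with a t-test (two-sided by default, since both
    enrichments and depletions are expected); BH across all (group, trait)
    cells.
    """
    traits = list(traits) if traits is not None else [c for c in pgs.columns]
    X = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "singular covariate design; check for collinear columns among "
            f"{['intercept', *covariates.columns]}"
        )
    groups = groups.reindex(pgs.index)
    sib_mask = (groups == sibling_label).to_numpy()
    if not sib_mask.any():
        raise ValueError("sibling group is empty")
    rows = []
    for trait in traits:
        y = pgs[trait].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        mu, sd = resid[sib_mask].mean(), resid[sib_mask].std(ddof=1)
        z = (resid - mu) / (sd if scale and sd > 0 else 1.0)
        sib = z[sib_mask]
        for grp in [g for g in pd.unique(groups.dropna()) if g != sibling_label]:
            x = z[(groups == grp).to_numpy()]
            t, df = t_test_from_stats(
                x.mean(), x.var(ddof=1), len(x), sib.mean(), sib.var(ddof=1), len(sib),
                equal_var=equal_var,
            )
            p = float(t_tail_p(t, df, alternative))
            se = float(np.sqrt(x.var(ddof=1) / len(x)))
            rows.append(
                {
                    "group": grp,
                    "trait": trait,
                    "n": len(x),
                    "mean": float(x.mean()),
                    "se": se,
                    "ci_low": float(x.mean() - 1.959963984540054 * se),
                    "ci_high": float(x.mean() + 1.959963984540054 * se),
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
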
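"""Run orchestration: configuration, staging, manifests.

A run is driven by a :class:`RunConfig` (YAML or JSON on disk).  The
phenotype stage applies the completeness filter, fits the mixture model (or
scans a K range), computes feature enrichment, the contributory-feature
exclusion and the affinity matrix, and serializes every artifact as tidy
TSV/JSON under the run directory.  The genetics stage consumes the labels
plus variant/annotation/PGS tables and emits burden, odds-ratio, devDEG,
enrichment and PGS results.  A manifest records the config snapshot, seeds,
input checksums and per-stage row counts so a run can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    GeneAnnotationTable,
    PhenotypeCohort,
    FeatureSchema,
    read_category_map_tsv,
    read_variant_tsv,
    write_category_map_tsv,
    write_json,
)
from .enumeration import enumerate_models, summarize_enumeration
from .genetics import (
    burden_test,
    devdeg_enrichment,
    filter_de_novo,
    filter_rare_inherited,
    hypergeom_enrichment,
    odds_ratio_test,
    pgs_compare,
    variant_counts,
)
from .gfmm import FitConfig, fit as gfmm_fit
from .profiles import (
    affinity_scores,
    completeness_filter,
    feature_enrichment,
    feature_exclusion,
)
from .synthetic import (
    default_genetic_spec,
    generate_cohort,
    generate_gene_annotations,
    generate_pgs_table,
    generate_variant_table,
    spark_like_spec,
)

__all__ = ["RunConfig", "run_phenotype_stage", "run_genetics_stage", "run_all", "simulate_inputs"]


@dataclass
class RunConfig:
    """All knobs of an end-to-end run, with the study's fixed constants as
    defaults (completeness 0.90, q 0.05, |d| 0.2, FE 1.5, AF 0.01, pLI
    0.995/0.5 bins, 10,000 permutations)."""

    outdir: str = "phenomix_run"
    seed: int = 0
    # inputs (paths); None => simulate demo inputs
    cohort_tsv: str | None = None
    schema_tsv: str | None = None
    category_map_tsv: str | None = None
    variant_tsv: str | None = None
    pli_tsv: str | None = None
    gene_sets_gmt: str | None = None
    devdeg_tsv: str | None = None
    pgs_tsv: str | None = None
    # model
    K: int = 4
    K_range: list[int] | None = None
    n_init: int = 20
    max_iter: int = 500
    tol: float = 1e-6
    variance_floor: float = 1e-4
    # thresholds
    completeness: float = 0.90
    q_threshold: float = 0.05
    d_threshold: float = 0.2
    fe_threshold: float = 1.5
    af_threshold: float = 0.01
    n_perm: int = 10_000
    burden_equal_var: bool = True
    # demo simulation scale
    simulate: bool = True
    n_individuals: int = 2000
    n_siblings: int = 1000
    separation: float = 1.0
    pgs_traits: list[str] = field(default_factory=lambda: ["asd", "adhd", "iq"])

    def fit_config(self, seed: int | None = None) -> FitConfig:
        return FitConfig(
            n_init=self.n_init,
            max_iter=self.max_iter,
            tol=self.tol,
            variance_floor=self.variance_floor,
            seed=self.seed if seed is None else seed,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Run provenance: written at start, finalized at the end."""

    def __init__(self, outdir: Path, config: RunConfig):
        self.path = outdir / "manifest.json"
        self.data = {
            "software": {"name": "phenomix", "version": __version__},
            "config": dataclasses.asdict(config),
            "seeds": {"root": config.seed},
            "inputs": {},
            "stages": {},
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "finished": None,
        }
        write_json(self.data, self.path)

    def record_input(self, name: str, path: str | Path) -> None:
        self.data["inputs"][name] = {"path": str(path), "sha256": _checksum(path)}

    def record_stage(self, name: str, **counts) -> None:
        self.data["stages"][name] = counts

    def finalize(self) -> None:
        self.data["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        write_json(self.data, self.path)


def _substream(seed: int, stage: str) -> int:
    """Stage-derived deterministic sub-seed (< 2**31)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# Simulation of demo inputs
# ---------------------------------------------------------------------------


def simulate_inputs(config: RunConfig, outdir: Path) -> dict[str, Path]:
    """Generate the demo cohort, variant, annotation and PGS files."""
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spark_like_spec(
        n_individuals=config.n_individuals,
        n_siblings=config.n_siblings,
        separation=config.separation,
        seed=_substream(config.seed, "cohort"),
    )
    cohort = generate_cohort(spec)
    gspec = default_genetic_spec(n_classes=spec.n_classes, seed=_substream(config.seed, "genetics"))
    variants = generate_variant_table(cohort, gspec)
    annotations = generate_gene_annotations(gspec)
    shifts = {t: 0.3 * np.array([-1.0, 1.0, 0.5, -0.5]) for t in config.pgs_traits}
    pgs = generate_pgs_table(
        cohort, config.pgs_traits, shifts, n_pcs=6, seed=_substream(config.seed, "pgs")
    )
    paths = {
        "cohort_tsv": outdir / "cohort.tsv",
        "schema_tsv": outdir / "cohort.schema.tsv",
        "category_map_tsv": outdir / "category_map.tsv",
        "variant_tsv": outdir / "variants.tsv",
        "pli_tsv": outdir / "pli.tsv",
        "gene_sets_gmt": outdir / "gene_sets.gmt",
        "devdeg_tsv": outdir / "devdeg.tsv",
        "pgs_tsv": outdir / "pgs.tsv",
    }
    cohort.write_tsv(paths["cohort_tsv"], paths["schema_tsv"])
    write_category_map_tsv(cohort.schema.category_map(), paths["category_map_tsv"])
    variants.to_csv(paths["variant_tsv"], sep="\t", index=False, float_format="%.10g")
    annotations.write(paths["pli_tsv"], paths["gene_sets_gmt"], paths["devdeg_tsv"])
    pgs.reset_index().rename(columns={"index": "individual_id"}).to_csv(
        paths["pgs_tsv"], sep="\t", index=False, float_format="%.10g"
    )
    return paths


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def run_phenotype_stage(
    config: RunConfig,
    cohort: PhenotypeCohort,
    category_map: dict[str, str],
    outdir: Path,
    manifest: Manifest | None = None,
) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    probands = cohort.probands()
    filtered, filter_report = completeness_filter(probands, config.completeness)
    artifacts: dict = {"filter_report": filter_report, "cohort": filtered}

    if config.K_range:
        table = enumerate_models(
            filtered,
            filtered.schema,
            K_range=config.K_range,
            config=config.fit_config(_substream(config.seed, "enumerate")),
        )
        table.to_csv(outdir / "enumeration.tsv", sep="\t", index=False, float_format="%.10g")
        summarize_enumeration(table).to_csv(
            outdir / "enumeration_summary.tsv", sep="\t", index=False, float_format="%.10g"
        )
        artifacts["enumeration"] = table

    fit_res = gfmm_fit(
        filtered, filtered.schema, config.K, config.fit_config(_substream(config.seed, "fit"))
    )
    fit_res.save(outdir / "model.json")
    labels = pd.DataFrame({"individual_id": filtered.ids, "label": fit_res.labels})
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)

    enr = feature_enrichment(filtered, fit_res.labels, filtered.schema)
    enr.to_csv(outdir / "feature_enrichment.tsv", sep="\t", index=False, float_format="%.10g")
    contributory = feature_exclusion(
        enr, config.q_threshold, config.d_threshold, config.fe_threshold
    )
    mapped = [f for f in contributory if f in category_map]
    aff = affinity_scores(enr, mapped, category_map, config.q_threshold)
    aff.scores.to_csv(outdir / "affinity.tsv", sep="\t", float_format="%.10g")
    write_json(
        {
            "contributory_features": contributory,
            "scores": {c: aff.scores[c].tolist() for c in aff.scores.columns},
        },
        outdir / "affinity.json",
    )
    artifacts.update({"fit": fit_res, "enrichment": enr, "contributory": contributory, "affinity": aff})
    if manifest is not None:
        manifest.record_stage(
            "phenotype",
            n_probands=len(filtered),
            n_features=len(filtered.schema),
            n_contributory=len(contributory),
            K=config.K,
            log_likelihood=float(fit_res.log_likelihood),
        )
    return artifacts


def run_genetics_stage(
    config: RunConfig,
    cohort: PhenotypeCohort,
    labels: pd.Series,
    variants: pd.DataFrame,
    annotations: GeneAnnotationTable,
    pgs: pd.DataFrame | None,
    outdir: Path,
    manifest: Manifest | None = None,
) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    ids = cohort.ids.astype(str)
    is_proband = cohort.is_proband
    if not is_proband.any():
        raise ValueError("no proband groups: cohort contains only siblings")
    groups = pd.Series(
        np.where(is_proband, labels.reindex(ids).to_numpy(), "sibling"), index=ids
    )

    dnv, dnv_counts, dnv_report = filter_de_novo(variants, list(ids))
    rare = filter_rare_inherited(variants, config.af_threshold)
    rare_inh = rare[rare["origin"] == "inherited"]
    roster = dnv_counts.index  # outlier-filtered roster

    results: dict = {"dnv_filter_report": dnv_report}
    burden_rows = []
    for set_name, genes in annotations.gene_sets.items():
        for vclass, table, origin in (
            ("LoF_HC", dnv, "denovo"),
            ("missense_damaging", dnv, "denovo"),
            ("synonymous", dnv, "denovo"),
            ("LoF_HC", rare_inh, "inherited"),
            ("missense_damaging", rare_inh, "inherited"),
        ):
            counts = variant_counts(table, roster, vclass, genes, origin=origin)
            res = burden_test(counts, groups, equal_var=config.burden_equal_var)
            res.insert(0, "variant_class", f"{'dn' if origin == 'denovo' else 'inh'}_{vclass}")
            res.insert(0, "gene_set", set_name)
            burden_rows.append(res)
    burden = pd.concat(burden_rows, ignore_index=True)
    burden.to_csv(outdir / "burden.tsv", sep="\t", index=False, float_format="%.10g")
    results["burden"] = burden

    or_rows = []
    for set_name, genes in annotations.gene_sets.items():
        for vclass, table, origin in (("LoF_HC", dnv, "denovo"), ("synonymous", dnv, "denovo")):
            res = odds_ratio_test(
                table, groups.loc[groups.index.isin(roster)], genes, vclass, origin=origin
            )
            res.insert(0, "variant_class", vclass)
            res.insert(0, "gene_set", set_name)
            or_rows.append(res)
    ors = pd.concat(or_rows, ignore_index=True)
    ors.to_csv(outdir / "odds_ratios.tsv", sep="\t", index=False, float_format="%.10g")
    results["odds_ratios"] = ors

    if annotations.devdeg:
        dd = devdeg_enrichment(dnv, groups.loc[groups.index.isin(roster)], annotations.devdeg)
        dd.to_csv(outdir / "devdeg.tsv", sep="\t", index=False, float_format="%.10g")
        results["devdeg"] = dd

    # term enrichment on genes impacted by high-impact de novo variants, pooled probands
    from .genetics import classify_variants

    cls = classify_variants(dnv)
    impacted = sorted(
        set(
            dnv.loc[
                cls.isin(["LoF_HC", "missense_damaging"])
                & dnv["individual_id"].astype(str).isin(set(groups.index[groups != "sibling"])),
                "gene",
            ]
        )
    )
    if impacted and annotations.gene_sets:
        terms = {k: v for k, v in annotations.gene_sets.items() if k != "all_genes"}
        if terms:
            enrich = hypergeom_enrichment(impacted, terms, annotations.genes)
            enrich.to_csv(outdir / "term_enrichment.tsv", sep="\t", index=False, float_format="%.10g")
            results["term_enrichment"] = enrich

    if pgs is not None:
        trait_cols = [c for c in pgs.columns if not c.startswith("PC")]
        pc_cols = [c for c in pgs.columns if c.startswith("PC")]
        covs = pd.DataFrame(
            {"sex": cohort.covariates["sex"].to_numpy()}, index=ids
        ).join(pgs[pc_cols])
        pgs_res = pgs_compare(pgs[trait_cols], groups, covs, trait_cols)
        pgs_res.to_csv(outdir / "pgs.tsv", sep="\t", index=False, float_format="%.10g")
        results["pgs"] = pgs_res

    if manifest is not None:
        manifest.record_stage(
            "genetics",
            n_variants_in=len(variants),
            n_denovo_kept=len(dnv),
            n_rare_inherited=len(rare_inh),
            **{f"dnv_{k}": v for k, v in dnv_report.items()},
        )
    return results


def run_all(config: RunConfig) -> dict:
    """Simulate (or load) inputs, then run the phenotype and genetics stages."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir, config)
    if config.simulate and config.cohort_tsv is None:
        paths = simulate_inputs(config, outdir / "inputs")
    else:
        required = ["cohort_tsv", "schema_tsv", "category_map_tsv"]
        missing = [k for k in required if getattr(config, k) is None]
        if missing:
            raise ValueError(f"missing input path(s) in config: {missing}")
        paths = {
            k: Path(getattr(config, k))
            for k in (
                "cohort_tsv", "schema_tsv", "category_map_tsv", "variant_tsv",
                "pli_tsv", "gene_sets_gmt", "devdeg_tsv", "pgs_tsv",
            )
            if getattr(config, k) is not None
        }
    for name, p in paths.items():
        manifest.record_input(name, p)

    cohort = PhenotypeCohort.read_tsv(paths["cohort_tsv"], FeatureSchema.read_tsv(paths["schema_tsv"]))
    category_map = read_category_map_tsv(paths["category_map_tsv"])
    pheno = run_phenotype_stage(config, cohort, category_map, outdir / "phenotype", manifest)

    results = {"phenotype": pheno}
    if "variant_tsv" in paths:
        variants = read_variant_tsv(paths["variant_tsv"])
        annotations = GeneAnnotationTable.read(
            paths["pli_tsv"], paths.get("gene_sets_gmt"), paths.get("devdeg_tsv")
        )
        pgs = None
        if "pgs_tsv" in paths:
            pgs = pd.read_csv(paths["pgs_tsv"], sep="\t").set_index("individual_id")
            pgs.index = pgs.index.astype(str)
        labels = pd.Series(
            pheno["fit"].labels.astype(object), index=pheno["cohort"].ids.astype(str)
        )
        results["genetics"] = run_genetics_stage(
            config, cohort, labels, variants, annotations, pgs, outdir / "genetics", manifest
        )
    manifest.finalize()
    return results
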
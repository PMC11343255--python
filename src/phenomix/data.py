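"""Shared data containers and file formats.

The package works on four kinds of tabular inputs: a typed phenotype matrix
(individuals x features, with covariates and a proband/sibling role flag), a
per-individual variant table, gene annotation tables (pLI, named gene sets,
developmental-expression gene sets) and a polygenic-score table.  Everything
round-trips through plain-text formats: TSV with a sidecar schema file for the
cohort, TSV for variants/pLI/PGS, and GMT for gene sets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FEATURE_TYPES = ("continuous", "binary", "categorical")

#: The seven phenotype categories used for class "affinity" profiling.
PHENOTYPE_CATEGORIES = (
    "limited social/communication",
    "restricted/repetitive behavior",
    "attention",
    "disruptive behavior",
    "anxiety/mood",
    "developmental delay",
    "self-injury",
)


class SchemaError(ValueError):
    """A feature matrix does not conform to its declared schema."""


class IntegrityError(ValueError):
    """An annotation table violates a uniqueness/consistency constraint."""


@dataclass(frozen=True)
class Feature:
    """One typed phenotype feature.

    ``n_levels`` is only meaningful for categorical features (>= 2 levels,
    coded 0..n_levels-1).  ``category`` assigns the feature to one of the seven
    phenotype categories; it may be empty for features outside the affinity
    analysis.
    """

    name: str
    ftype: str
    n_levels: int | None = None
    category: str = ""

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise SchemaError(f"unknown feature type {self.ftype!r} for {self.name!r}")
        if self.ftype == "categorical":
            if self.n_levels is None or self.n_levels < 2:
                raise SchemaError(f"categorical feature {self.name!r} needs n_levels >= 2")
        elif self.n_levels is not None:
            raise SchemaError(f"n_levels only applies to categorical features ({self.name!r})")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered list of typed features; the contract between cohort and model."""

    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __getitem__(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "FeatureSchema":
        """Schema restricted to ``names``, keeping this schema's order."""
        missing = set(names) - set(self.names)
        if missing:
            raise SchemaError(f"unknown feature name(s): {sorted(missing)}")
        keep = set(names)
        return FeatureSchema(tuple(f for f in self.features if f.name in keep))

    def category_map(self) -> dict[str, str]:
        return {f.name: f.category for f in self.features if f.category}

    # --- sidecar TSV ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [f.name for f in self.features],
                "type": [f.ftype for f in self.features],
                "n_levels": [f.n_levels if f.n_levels is not None else "" for f in self.features],
                "category": [f.category for f in self.features],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureSchema":
        feats = []
        for _, row in df.iterrows():
            n_levels = row.get("n_levels", "")
            n_levels = None if (pd.isna(n_levels) or n_levels == "") else int(n_levels)
            cat = row.get("category", "")
            cat = "" if pd.isna(cat) else str(cat)
            feats.append(Feature(str(row["name"]), str(row["type"]), n_levels, cat))
        return cls(tuple(feats))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureSchema":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class PhenotypeCohort:
    """A typed feature matrix with covariates and proband/sibling roles.

    ``features`` holds one column per schema feature (floats; NaN = missing).
    ``covariates`` carries ``sex`` (0/1) and ``age_years``.  ``true_class`` is
    only populated for synthetic cohorts where the generating class is known
    (NaN otherwise, and always NaN for siblings).
    """

    features: pd.DataFrame
    covariates: pd.DataFrame
    role: np.ndarray
    schema: FeatureSchema
    true_class: np.ndarray | None = None

    def __post_init__(self) -> None:
        if list(self.features.columns) != self.schema.names:
            raise SchemaError("feature columns do not match schema order")
        for col in ("sex", "age_years"):
            if col not in self.covariates.columns:
                raise SchemaError(f"covariates missing required column {col!r}")
        if len(self.features) != len(self.covariates) or len(self.features) != len(self.role):
            raise SchemaError("features, covariates and role must have equal length")
        self._validate_values()

    def _validate_values(self) -> None:
        for f in self.schema:
            col = self.features[f.name]
            vals = col.dropna()
            if f.ftype == "binary" and not vals.isin([0, 1]).all():
                raise SchemaError(f"binary feature {f.name!r} has values outside {{0,1}}")
            if f.ftype == "categorical":
                ok = (vals >= 0) & (vals < f.n_levels) & (vals == vals.astype(int))
                if not ok.all():
                    raise SchemaError(
                        f"categorical feature {f.name!r} has levels outside 0..{f.n_levels - 1}"
                    )

    def __len__(self) -> int:
        return len(self.features)

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def ids(self) -> pd.Index:
        return self.features.index

    @property
    def is_proband(self) -> np.ndarray:
        return np.asarray(self.role) == "proband"

    @property
    def is_complete(self) -> bool:
        return not self.features.isna().any().any()

    def subset_rows(self, mask: np.ndarray) -> "PhenotypeCohort":
        mask = np.asarray(mask)
        return PhenotypeCohort(
            features=self.features.loc[mask].copy(),
            covariates=self.covariates.loc[mask].copy(),
            role=np.asarray(self.role)[mask],
            schema=self.schema,
            true_class=None if self.true_class is None else np.asarray(self.true_class)[mask],
        )

    def subset_features(self, names: Sequence[str]) -> "PhenotypeCohort":
        sub = self.schema.subset(names)
        return PhenotypeCohort(
            features=self.features[sub.names].copy(),
            covariates=self.covariates.copy(),
            role=np.asarray(self.role).copy(),
            schema=sub,
            true_class=None if self.true_class is None else np.asarray(self.true_class).copy(),
        )

    def probands(self) -> "PhenotypeCohort":
        return self.subset_rows(self.is_proband)

    # --- TSV round trip -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        out = self.features.copy()
        out.insert(0, "individual_id", self.features.index.astype(str))
        out["sex"] = self.covariates["sex"].to_numpy()
        out["age_years"] = self.covariates["age_years"].to_numpy()
        out["role"] = self.role
        if self.true_class is not None:
            out["true_class"] = self.true_class
        return out.reset_index(drop=True)

    def write_tsv(self, path: str | Path, schema_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        if schema_path is not None:
            self.schema.write_tsv(schema_path)

    @classmethod
    def read_tsv(cls, path: str | Path, schema: FeatureSchema | str | Path) -> "PhenotypeCohort":
        if not isinstance(schema, FeatureSchema):
            schema = FeatureSchema.read_tsv(schema)
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("individual_id")
        df.index = df.index.astype(str)
        true_class = df["true_class"].to_numpy(dtype=float) if "true_class" in df else None
        return cls(
            features=df[schema.names].astype(float),
            covariates=df[["sex", "age_years"]].astype(float),
            role=df["role"].to_numpy(dtype=object),
            schema=schema,
            true_class=true_class,
        )


# ---------------------------------------------------------------------------
# Variant table
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "individual_id",
    "family_id",
    "gene",
    "origin",
    "consequence",
    "lof_confidence",
    "missense_class",
    "allele_frequency",
    "chrom",
    "pos",
    "ref",
    "alt",
]


def empty_variant_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in VARIANT_COLUMNS}).astype(
        {"allele_frequency": float, "pos": float}
    )


def validate_variant_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("individual_id", "family_id", "gene", "origin", "consequence"):
        if col not in table.columns:
            raise SchemaError(f"variant table missing column {col!r}")
    bad = ~table["origin"].isin(["denovo", "inherited"])
    if bad.any():
        raise SchemaError(f"unknown origin values: {sorted(table.loc[bad, 'origin'].unique())}")
    return table


def write_variant_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_variant_tsv(path: str | Path) -> pd.DataFrame:
    return validate_variant_table(pd.read_csv(path, sep="\t", dtype={"individual_id": str, "family_id": str}))


def read_variant_vcf(path: str | Path) -> pd.DataFrame:
    """Read a minimal VCF into the variant-table layout.

    Expects an uncompressed, 1-based VCF whose INFO field carries ``GENE``,
    ``CSQ`` (consequence string), and optionally ``LOF`` (HC/LC), ``AMCLASS``
    (likely_pathogenic/likely_benign/ambiguous), ``AF`` and ``ORIGIN``
    (denovo/inherited); ``FAMILY`` maps samples to families as
    ``sample:family`` pairs are not encoded, so family defaults to the sample
    id.  One output row is emitted per carrier sample (GT with any ALT allele).
    """
    import pysam

    def _get(info, key, default=None):
        try:
            val = info.get(key, default)
        except (KeyError, ValueError):  # key absent from the header
            return default
        return val

    rows: list[dict] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            info = rec.info
            gene = _get(info, "GENE")
            csq = _get(info, "CSQ", "other")
            lof = _get(info, "LOF")
            amc = _get(info, "AMCLASS")
            af = _get(info, "AF")
            if isinstance(af, (tuple, list)):
                af = af[0]
            origin = _get(info, "ORIGIN", "inherited")
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None or not any(a not in (None, 0) for a in gt):
                    continue
                rows.append(
                    {
                        "individual_id": sample,
                        "family_id": sample,
                        "gene": gene,
                        "origin": origin,
                        "consequence": csq,
                        "lof_confidence": lof if lof is not None else np.nan,
                        "missense_class": amc if amc is not None else np.nan,
                        "allele_frequency": float(af) if af is not None else np.nan,
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": rec.alts[0] if rec.alts else np.nan,
                    }
                )
    if not rows:
        return empty_variant_table()
    return validate_variant_table(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnotationTable:
    """Per-gene pLI plus named gene-set and devDEG memberships."""

    pli: pd.Series  # index: gene, values in [0, 1]
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    devdeg: dict[tuple[str, str], list[str]] = field(default_factory=dict)  # (trend, celltype)

    def __post_init__(self) -> None:
        if self.pli.index.duplicated().any():
            raise IntegrityError("duplicate gene IDs in pLI table")
        if ((self.pli < 0) | (self.pli > 1)).any():
            raise IntegrityError("pLI values must lie in [0, 1]")
        universe = set(self.pli.index)
        for name, genes in self.gene_sets.items():
            extra = set(genes) - universe
            if extra:
                raise IntegrityError(f"gene set {name!r} contains unknown genes: {sorted(extra)[:5]}")
        for key, genes in self.devdeg.items():
            extra = set(genes) - universe
            if extra:
                raise IntegrityError(f"devDEG set {key!r} contains unknown genes: {sorted(extra)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.pli.index)

    def write(self, pli_path: str | Path, gmt_path: str | Path, devdeg_path: str | Path) -> None:
        pd.DataFrame({"gene": self.pli.index, "pli": self.pli.to_numpy()}).to_csv(
            pli_path, sep="\t", index=False, float_format="%.10g"
        )
        write_gmt(self.gene_sets, gmt_path)
        rows = [
            {"trend": trend, "celltype": celltype, "gene": g}
            for (trend, celltype), genes in sorted(self.devdeg.items())
            for g in genes
        ]
        pd.DataFrame(rows, columns=["trend", "celltype", "gene"]).to_csv(
            devdeg_path, sep="\t", index=False
        )

    @classmethod
    def read(
        cls, pli_path: str | Path, gmt_path: str | Path | None = None, devdeg_path: str | Path | None = None
    ) -> "GeneAnnotationTable":
        pli_df = pd.read_csv(pli_path, sep="\t")
        pli = pd.Series(pli_df["pli"].to_numpy(), index=pli_df["gene"].astype(str))
        gene_sets = read_gmt(gmt_path) if gmt_path is not None else {}
        devdeg: dict[tuple[str, str], list[str]] = {}
        if devdeg_path is not None:
            dd = pd.read_csv(devdeg_path, sep="\t")
            for (trend, celltype), grp in dd.groupby(["trend", "celltype"]):
                devdeg[(str(trend), str(celltype))] = list(grp["gene"].astype(str))
        return cls(pli=pli, gene_sets=gene_sets, devdeg=devdeg)


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# Misc serialization helpers
# ---------------------------------------------------------------------------


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_category_map_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_category_map_tsv(category_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"feature": list(category_map.keys()), "category": list(category_map.values())}
    ).to_csv(path, sep="\t", index=False)
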
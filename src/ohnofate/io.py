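"""Readers, writers, configuration and the end-to-end pipeline driver.

Canonical exchange formats: CSV for tabular data (Ct tables, expression,
family maps), YAML for configuration, JSON for structured results,
Newick for dendrograms. ``run_pipeline`` composes the stages in analysis
order — quantification, per-gene time-course statistics, pattern
discovery, cross-species correlation, retention classification — and is
fully reproducible from its configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import patterns, qpcr, retention, timecourse
from .qpcr import CT_COLUMNS
from .retention import FamilyRecord

log = logging.getLogger("ohnofate")


class ValidationError(ValueError):
    """Input file violates a structural invariant."""


@dataclass
class AnalysisConfig:
    alpha: float = 0.05
    calibrator_timepoint: float = -96
    reference_genes: tuple = ("rpl13", "rpl19", "ppiaa")
    efficiency: float = 2.0
    k_clusters: int = 3
    pairing: str = "replicate_level"
    posthoc_adjust: str = "bonferroni"
    seed: int = 0
    fasted_ref_timepoint: float = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.k_clusters < 1:
            raise ValidationError("k_clusters must be >= 1")
        if self.pairing not in ("replicate_level", "timepoint_means"):
            raise ValidationError(f"unknown pairing rule {self.pairing!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "reference_genes" in doc:
            doc["reference_genes"] = tuple(doc["reference_genes"])
        cfg = cls(**doc)
        cfg.validate()
        return cfg


def read_ct_table(path, reference_genes: list[str] | None = None) -> pd.DataFrame:
    """Read and validate a long-format Ct table.

    Enforces: required columns, numeric Ct in (0, 45], unique
    (sample_id, gene) pairs, and (optionally) every reference gene
    present in every sample.
    """
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    df = df[list(CT_COLUMNS)]
    ct = pd.to_numeric(df["ct"], errors="coerce")
    bad = df.index[ct.isna() & df["ct"].notna()]
    if len(bad):
        raise ValidationError(f"{path}: non-numeric ct at rows {list(bad[:5])}")
    df["ct"] = ct
    out_of_range = df.index[(df["ct"] <= 0) | (df["ct"] > 45)]
    if len(out_of_range):
        rows = df.loc[out_of_range[:5], ["sample_id", "gene", "ct"]]
        raise ValidationError(
            f"{path}: ct outside (0, 45] for rows:\n{rows.to_string()}"
        )
    dup = df.duplicated(subset=["sample_id", "gene"])
    if dup.any():
        pairs = df.loc[dup, ["sample_id", "gene"]].head().to_records(index=False)
        raise ValidationError(f"{path}: duplicate (sample_id, gene) pairs: {list(pairs)}")
    if reference_genes:
        per_sample = df.groupby("sample_id")["gene"].apply(set)
        lacking = [
            s for s, genes in per_sample.items()
            if not set(reference_genes) <= genes
        ]
        if lacking:
            raise ValidationError(
                f"{path}: samples missing reference genes: {lacking[:5]}"
            )
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    df[list(CT_COLUMNS)].to_csv(path, index=False)


def read_family_map(path) -> list[FamilyRecord]:
    """Read a family map CSV and validate gene-id uniqueness."""
    df = pd.read_csv(path)
    required = {"family", "duplicated_lineage", "lso_a", "lso_b", "singleton"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: family map is empty")
    records = []
    seen: dict[str, str] = {}
    for row in df.itertuples(index=False):
        rec = FamilyRecord(
            name=row.family,
            duplicated_lineage=row.duplicated_lineage,
            lso_a=row.lso_a,
            lso_b=row.lso_b,
            singleton=row.singleton,
            pathway=getattr(row, "pathway", "igf_akt_mtor"),
        )
        for gene in (rec.lso_a, rec.lso_b, rec.singleton):
            if gene in seen:
                raise ValidationError(
                    f"{path}: gene id {gene!r} used in families "
                    f"{seen[gene]!r} and {rec.name!r}"
                )
            seen[gene] = rec.name
        records.append(rec)
    return records


@dataclass
class PipelineResult:
    config: AnalysisConfig
    stability: dict = field(default_factory=dict)  # species -> StabilityRanking
    relexpr_ddct: pd.DataFrame | None = None
    relexpr_dct: pd.DataFrame | None = None
    timecourse: dict = field(default_factory=dict)  # (species, gene) -> result
    responsiveness: dict = field(default_factory=dict)  # family -> triple
    clusters: dict = field(default_factory=dict)  # species -> {...}
    pca: dict = field(default_factory=dict)  # species -> PcaResult
    correlations: dict = field(default_factory=dict)  # family -> record
    calls: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def _species_of(families: list[FamilyRecord]) -> dict[str, str]:
    """Map each gene to the species letter that carries it (A = first lineage)."""
    lineages = sorted({f.duplicated_lineage for f in families})
    letter = {lin: sp for lin, sp in zip(lineages, ("A", "B"))}
    gene_species = {}
    for f in families:
        dup = letter.get(f.duplicated_lineage, f.duplicated_lineage)
        other = "B" if dup == "A" else "A"
        gene_species[f.lso_a] = dup
        gene_species[f.lso_b] = dup
        gene_species[f.singleton] = other
    return gene_species


def run_pipeline(
    config: AnalysisConfig,
    ct_a: pd.DataFrame,
    ct_b: pd.DataFrame,
    families: list[FamilyRecord],
    compute_patterns: bool = True,
) -> PipelineResult:
    """Execute quantify -> stats -> patterns -> correlate -> classify.

    ``ct_a``/``ct_b`` are the two species' Ct tables; genes named in each
    family are looked up in whichever table contains them (the duplicated
    pair and the singleton must live in different tables).
    """
    config.validate()
    refs = list(config.reference_genes)
    result = PipelineResult(config=config)
    tables = {"A": ct_a, "B": ct_b}

    log.info("stage=quantify refs=%s calibrator=%s", refs, config.calibrator_timepoint)
    relexpr = {}
    rel_dct = {}
    for sp, ct in tables.items():
        quantities = qpcr.reference_quantities(ct, refs, config.efficiency)
        result.stability[sp] = qpcr.genorm_m(quantities)
        relexpr[sp] = qpcr.relative_expression(
            ct, refs, config.calibrator_timepoint, "ddct", config.efficiency
        )
        rel_dct[sp] = qpcr.relative_expression(
            ct, refs, None, "dct", config.efficiency
        )
    result.relexpr_ddct = pd.concat(relexpr.values(), ignore_index=True)
    result.relexpr_dct = pd.concat(rel_dct.values(), ignore_index=True)

    log.info("stage=stats alpha=%s adjust=%s", config.alpha, config.posthoc_adjust)
    for sp, rel in relexpr.items():
        for gene, sub in rel.groupby("gene", sort=True):
            by_tp = {
                tp: grp["rel_expr"].dropna().to_numpy()
                for tp, grp in sub.groupby("timepoint_h")
            }
            res = timecourse.omnibus_and_posthoc(
                by_tp, config.alpha, config.posthoc_adjust, gene=gene
            )
            res.responsive = timecourse.responsiveness(
                res, config.fasted_ref_timepoint, alpha=config.alpha
            )
            result.timecourse[(sp, gene)] = res

    if compute_patterns:
        log.info("stage=patterns k=%d", config.k_clusters)
        for sp, rel in rel_dct.items():
            profiles = patterns.profile_matrix(rel, per_timepoint_means=True)
            dist = patterns.pearson_distance(profiles)
            tree = patterns.hclust_average(dist)
            flat = patterns.cut_tree(tree, config.k_clusters)
            km = patterns.kmeans_profiles(
                profiles, config.k_clusters, seed=config.seed
            )
            result.clusters[sp] = {
                "hierarchical": tree,
                "hierarchical_cut": flat,
                "kmeans": km.assignments,
            }
            scaled = patterns.unit_variance_scale(profiles)
            result.pca[sp] = patterns.pca_svd_impute(scaled)

    log.info("stage=correlate pairing=%s", config.pairing)
    gene_species = _species_of(families)
    for fam in families:
        dup_sp = gene_species[fam.lso_a]
        single_sp = gene_species[fam.singleton]
        rec = retention.family_correlations(
            relexpr[dup_sp],
            relexpr[single_sp],
            fam,
            pairing=config.pairing,
            alpha=config.alpha,
        )
        result.correlations[fam.name] = rec
        resp = (
            result.timecourse[(dup_sp, fam.lso_a)].responsive,
            result.timecourse[(dup_sp, fam.lso_b)].responsive,
            result.timecourse[(single_sp, fam.singleton)].responsive,
        )
        result.responsiveness[fam.name] = resp
        comember = {}
        if compute_patterns:
            cut = result.clusters[dup_sp]["hierarchical_cut"]
            cut_other = result.clusters[single_sp]["hierarchical_cut"]
            if fam.lso_a in cut and fam.lso_b in cut:
                comember["lso_pair_same_cluster"] = cut[fam.lso_a] == cut[fam.lso_b]
            if fam.singleton in cut_other:
                comember["singleton_cluster"] = cut_other[fam.singleton]
        result.calls.append(retention.classify_retention(rec, resp, comember))

    result.summary = retention.summarize(result.calls)
    log.info("stage=classify counts=%s", result.summary["counts"])
    return result


def correlations_table(correlations: dict) -> pd.DataFrame:
    rows = []
    for name, rec in correlations.items():
        rows.append(
            {
                "family": name,
                "r_ab": rec.r_ab,
                "p_ab": rec.p_ab,
                "r_as": rec.r_as,
                "p_as": rec.p_as,
                "r_bs": rec.r_bs,
                "p_bs": rec.p_bs,
                "n_pairs": rec.n_pairs,
                "sig_ab": rec.sig_ab,
                "sig_as": rec.sig_as,
                "sig_bs": rec.sig_bs,
            }
        )
    return pd.DataFrame(rows)


def write_results(bundle: PipelineResult, outdir) -> dict:
    """Write all artifacts plus a manifest with config echo and checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, sep=","):
        p = outdir / name
        df.to_csv(p, index=False, sep=sep)
        written.append(p)

    def save_json(obj, name: str):
        p = outdir / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True, default=str)
        written.append(p)

    if bundle.relexpr_ddct is not None:
        save_df(bundle.relexpr_ddct, "relative_expression_ddct.csv")
    if bundle.relexpr_dct is not None:
        save_df(bundle.relexpr_dct, "relative_expression_dct.csv")
    if bundle.stability:
        save_json(
            {sp: s.to_json_dict() for sp, s in bundle.stability.items()},
            "reference_stability.json",
        )
    if bundle.timecourse:
        rows = []
        for (sp, _), res in sorted(bundle.timecourse.items()):
            row = timecourse.timecourse_table([res]).iloc[0].to_dict()
            row["species"] = sp
            rows.append(row)
        save_df(pd.DataFrame(rows), "timecourse_stats.tsv", sep="\t")
    for sp, cl in bundle.clusters.items():
        save_df(
            pd.DataFrame(
                {
                    "gene": list(cl["hierarchical_cut"]),
                    "hierarchical_cluster": list(cl["hierarchical_cut"].values()),
                    "kmeans_cluster": [
                        cl["kmeans"][g] for g in cl["hierarchical_cut"]
                    ],
                }
            ),
            f"clusters_{sp}.tsv",
            sep="\t",
        )
        p = outdir / f"dendrogram_{sp}.nwk"
        p.write_text(patterns.to_newick(cl["hierarchical"]) + "\n")
        written.append(p)
    if bundle.correlations:
        save_df(correlations_table(bundle.correlations), "family_correlations.tsv", sep="\t")
    if bundle.calls:
        save_df(retention.calls_table(bundle.calls), "retention_calls.tsv", sep="\t")
        save_json(bundle.summary, "summary.json")

    manifest = {
        "config": dataclasses.asdict(bundle.config),
        "artifacts": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
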
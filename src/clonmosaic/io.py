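"""Readers/writers for the pipeline's formats and end-to-end orchestration.

Formats: multi-sample VCF v4.2 (FORMAT ``AD``/``DP`` for allele depths,
``FT`` for per-sample filter flags), tab-separated sample/variant tables
(UTF-8, '.' for missing), BED exclusion intervals (0-based half-open,
converted to 1-based inclusive on read), JSON manifests and ground-truth
files, and YAML run configuration.

``run_pipeline`` executes filter -> clonality -> signatures -> lineage ->
spatial on a variant table and writes every stage artifact plus a
machine-readable manifest; reruns with the same inputs and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from intervaltree import IntervalTree

from . import filters as flt
from . import __version__
from .clonality import classify_cohort, estimate_clone_sizes
from .lineage import analyze_case_lineage
from .signatures import refit_samples
from .spatial import (
    age_burden_regression,
    asymmetry_analysis,
    driver_summary,
    proximity_analysis,
    sample_burdens,
    zonal_comparison,
)
from .synthetic import CohortConfig, simulate_cohort

VARIANT_COLUMNS = [
    "case_id", "sample_id", "variant_id", "chrom", "pos", "ref", "alt",
    "context", "alt_count", "total_depth", "vaf", "variant_type",
    "population_af", "gene", "effect", "filter_flags",
]


# ---------------------------------------------------------------------------
# TSV tables

def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False, na_rep=".")


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])


def write_variants_tsv(variants: pd.DataFrame, path) -> None:
    cols = [c for c in VARIANT_COLUMNS if c in variants.columns]
    variants[cols].to_csv(path, sep="\t", index=False, na_rep=".")


def read_variants_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", na_values=["."],
        dtype={"chrom": str, "gene": str, "effect": str, "filter_flags": str,
               "context": str},
    )
    missing = {"sample_id", "chrom", "pos", "alt_count", "total_depth"} - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV lacks required columns: {sorted(missing)}")
    for col, default in (("gene", ""), ("effect", ""), ("filter_flags", ""), ("context", "")):
        if col in df.columns:
            df[col] = df[col].fillna(default)
    if "vaf" not in df.columns:
        df["vaf"] = df["alt_count"] / df["total_depth"]
    return df


# ---------------------------------------------------------------------------
# VCF

def write_vcf(variants: pd.DataFrame, path, case_id: str | None = None) -> None:
    """Multi-sample VCF v4.2 with AD/DP/FT FORMAT fields.

    One file per cohort (or per case with ``case_id``); samples become VCF
    columns, variant annotations travel in INFO (POPAF, CTX, GENE, EFF,
    VTYPE) and per-sample filter flags in the FT genotype field.
    """
    df = variants if case_id is None else variants[variants["case_id"] == case_id]
    sample_ids = sorted(df["sample_id"].unique())
    by_site: dict[str, dict] = {}
    meta = {}
    for row in df.itertuples(index=False):
        by_site.setdefault(row.variant_id, {})[row.sample_id] = row
        meta[row.variant_id] = row

    def sort_key(vid):
        m = meta[vid]
        chrom = str(m.chrom)
        return (len(chrom), chrom, int(m.pos))

    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=pop_af,Description="Population allele frequency above threshold">',
        '##FILTER=<ID=germline_binomial,Description="Pooled exact binomial germline">',
        '##FILTER=<ID=trio_germline,Description="Shared in all trio samples at het VAF">',
        '##FILTER=<ID=artifact_betabinom,Description="Recurrent low-VAF beta-binomial artifact">',
        '##FILTER=<ID=indel_support,Description="Insufficient indel read support">',
        '##FILTER=<ID=paralog,Description="Paralogous region">',
        '##INFO=<ID=POPAF,Number=1,Type=Float,Description="Population allele frequency">',
        '##INFO=<ID=CTX,Number=1,Type=String,Description="Reference trinucleotide context">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene annotation">',
        '##INFO=<ID=EFF,Number=1,Type=String,Description="Effect annotation">',
        '##INFO=<ID=VTYPE,Number=1,Type=String,Description="SBS or indel">',
        '##INFO=<ID=CASE,Number=1,Type=String,Description="Case identifier">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (placeholder)">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref and alt read depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##FORMAT=<ID=FT,Number=1,Type=String,Description="Per-sample filter flags">',
    ]
    for chrom in sorted({str(m.chrom) for m in meta.values()}, key=lambda c: (len(c), c)):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    for vid in sorted(by_site, key=sort_key):
        m = meta[vid]
        site_flags = sorted(
            {
                f
                for r in by_site[vid].values()
                for f in str(r.filter_flags).split(";")
                if f
            }
        )
        filt = ";".join(site_flags) if site_flags else "PASS"
        info = (
            f"POPAF={float(m.population_af):g};CTX={m.context or '.'};"
            f"GENE={m.gene or '.'};EFF={m.effect or '.'};VTYPE={m.variant_type};"
            f"CASE={m.case_id}"
        )
        cells = []
        for sid in sample_ids:
            r = by_site[vid].get(sid)
            if r is None:
                cells.append("./.:.:.:.")
            else:
                ft = ";".join(sorted(filter(None, str(r.filter_flags).split(";")))) or "PASS"
                ad = f"{int(r.total_depth) - int(r.alt_count)},{int(r.alt_count)}"
                cells.append(f"0/1:{ad}:{int(r.total_depth)}:{ft}")
        lines.append(
            f"{m.chrom}\t{int(m.pos)}\t{vid}\t{m.ref}\t{m.alt}\t.\t{filt}\t{info}"
            f"\tGT:AD:DP:FT\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Long-form variant table from a multi-sample VCF with AD/DP fields."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        if "AD" not in vcf.header.formats:
            raise ValueError("VCF lacks the required FORMAT field AD (allele depths)")
        if "DP" not in vcf.header.formats:
            raise ValueError("VCF lacks the required FORMAT field DP (total depth)")
        for rec in vcf:
            info = rec.info
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
            for sid, call in rec.samples.items():
                ad = call.get("AD")
                dp = call.get("DP")
                if ad is None or ad[0] is None:
                    continue  # sample not covered at this site
                alt_count = int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
                depth = int(dp) if dp is not None else int(sum(a or 0 for a in ad))
                ft = call.get("FT")
                flags = "" if ft in (None, ".", "PASS") else str(ft)
                rows.append(
                    dict(
                        case_id=str(info.get("CASE", "")),
                        sample_id=sid,
                        variant_id=vid,
                        chrom=str(rec.chrom),
                        pos=int(rec.pos),
                        ref=rec.ref,
                        alt=rec.alts[0],
                        context="" if str(info.get("CTX", ".")) == "." else str(info.get("CTX")),
                        alt_count=alt_count,
                        total_depth=depth,
                        vaf=alt_count / depth if depth else 0.0,
                        variant_type=str(info.get("VTYPE", "SBS")),
                        population_af=float(info.get("POPAF", 0.0)),
                        gene="" if str(info.get("GENE", ".")) == "." else str(info.get("GENE")),
                        effect="" if str(info.get("EFF", ".")) == "." else str(info.get("EFF")),
                        filter_flags=flags,
                    )
                )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def read_variants(path, fmt: str | None = None) -> pd.DataFrame:
    path = Path(path)
    fmt = fmt or ("vcf" if path.suffix == ".vcf" else "tsv")
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        return read_variants_tsv(path)
    raise ValueError(f"unknown variant format: {fmt!r}")


# ---------------------------------------------------------------------------
# BED / segments / truth

def read_bed_intervals(path) -> dict[str, IntervalTree]:
    """BED (0-based half-open) -> per-chrom IntervalTree over 1-based positions."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            trees.setdefault(chrom, IntervalTree()).addi(int(start) + 1, int(end) + 1)
    return trees


def read_segments(path) -> pd.DataFrame:
    """Copy-number segment table: chrom, start0, end, total_cn (BED-like)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"chrom", "start0", "end", "total_cn"}
    if not need <= set(df.columns):
        raise ValueError(f"segment table needs columns {sorted(need)}")
    return df


def cn_lookup_from_segments(segments: pd.DataFrame):
    trees: dict[str, IntervalTree] = {}
    for row in segments.itertuples(index=False):
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start0) + 1, int(row.end) + 1, float(row.total_cn)
        )

    def lookup(chrom, pos, sample_id=None):
        hits = trees.get(str(chrom), IntervalTree()).at(int(pos))
        return next(iter(hits)).data if hits else 2.0

    return lookup


def write_truth(truth, path) -> None:
    payload = {
        "variant_labels": truth.variant_labels.reset_index().to_dict(orient="list"),
        "clone_fraction": truth.clone_fraction.to_dict(),
        "lineage_parent": truth.lineage_parent,
        "lineage_label": truth.lineage_label.to_dict(),
        "eem_sets": {k: sorted(v) for k, v in truth.eem_sets.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Run configuration and pipeline

@dataclass
class RunConfig:
    """End-to-end run settings; every module threshold in one place."""

    vcf: str = ""
    samples: str = ""
    segments: str = ""
    paralog_bed: str = ""
    out: str = "out"
    design: str = "trio"
    pop_af_threshold: float = 0.01
    germline_alpha: float = 0.01
    vaf_window: tuple = (0.3, 0.7)
    trio_min_mean_vaf: float = 0.3
    rho_cutoff: float = 0.1
    min_carriers: int = 3
    clonality_method: str = "median_ccf"
    presence_min_weight: float = 0.05
    eem_min_carriers: int = 3
    eem_min_median_vaf: float = 0.2
    tau: float = 0.5
    kappa: float = 0.8
    seed: int = 0
    drop_filtered: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.vaf_window, list):
            cfg.vaf_window = tuple(cfg.vaf_window)
        return cfg


def cohort_config_from_yaml(path) -> CohortConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {k: v for k, v in raw.items() if k in CohortConfig.__dataclass_fields__}
    cfg = CohortConfig(**known)
    for name in ("grid_dims", "ages", "artifact_vaf_range", "subclonal_ccf_range"):
        val = getattr(cfg, name)
        if isinstance(val, list):
            setattr(cfg, name, tuple(val))
    return cfg


def simulate_to_dir(config: CohortConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, variants, truth = simulate_cohort(config)
    write_samples(samples, out / "samples.tsv")
    write_variants_tsv(variants, out / "variants.tsv")
    write_vcf(variants, out / "variants.vcf")
    write_truth(truth, out / "truth.json")


def run_pipeline(config: RunConfig) -> dict:
    """Filter -> clonality -> signatures -> lineage -> spatial, with manifest."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "version": __version__, "stages": {}}
    try:
        samples = read_samples(config.samples)
        variants = read_variants(config.vcf)
        paralog = read_bed_intervals(config.paralog_bed) if config.paralog_bed else None
        cn_lookup = (
            cn_lookup_from_segments(read_segments(config.segments))
            if config.segments
            else None
        )

        flagged, counts = flt.run_cascade(
            variants,
            design=config.design,
            pop_af_threshold=config.pop_af_threshold,
            germline_alpha=config.germline_alpha,
            vaf_window=tuple(config.vaf_window),
            trio_min_mean_vaf=config.trio_min_mean_vaf,
            rho_cutoff=config.rho_cutoff,
            min_carriers=config.min_carriers,
            paralog_intervals=paralog,
        )
        write_vcf(flagged, out / "filtered.vcf")
        if config.drop_filtered:
            write_variants_tsv(flt.passed(flagged), out / "passed.tsv")
        manifest["stages"]["filter"] = counts

        kept = flt.passed(flagged)
        clones = estimate_clone_sizes(kept, method=config.clonality_method)
        write_samples(clones, out / "clones.tsv")
        classes = classify_cohort(kept, clones, cn_lookup=cn_lookup)
        classes.to_csv(out / "mutation_classes.tsv", sep="\t", index=False)
        manifest["stages"]["clonality"] = {
            "samples_estimated": int(len(clones)),
            "class_counts": {
                k: int(v) for k, v in sorted(
                    classes["sharing_class"].value_counts().to_dict().items()
                )
            },
        }

        spectra, exposures, presence = refit_samples(
            kept, min_weight=config.presence_min_weight
        )
        spectra.to_csv(out / "spectra.tsv", sep="\t")
        exposures.round(6).to_csv(out / "exposures.tsv", sep="\t")
        presence.to_csv(out / "presence.tsv", sep="\t")
        manifest["stages"]["signatures"] = {
            "samples_fitted": int(len(exposures)),
            "presence_fraction": {
                g: round(float(presence[g].mean()), 4) for g in sorted(presence.columns)
            } if len(presence) else {},
        }

        lineage_out = {}
        if config.design == "grid3d":
            for case, grp in kept.groupby("case_id", sort=True):
                model = analyze_case_lineage(
                    grp, samples,
                    tau=config.tau, kappa=config.kappa, seed=config.seed,
                    min_carriers=config.eem_min_carriers,
                    min_median_vaf=config.eem_min_median_vaf,
                )
                model.labels.rename("lineage").to_frame().to_csv(
                    out / f"lineages_{case}.tsv", sep="\t"
                )
                if model.tree is not None:
                    (out / f"tree_{case}.nwk").write_text(model.tree.newick() + "\n")
                lineage_out[case] = {
                    "pattern": model.pattern,
                    "axis_scores": {
                        k: round(v, 4) for k, v in sorted(model.axis_scores.items())
                    },
                    "n_lineages": int(
                        (model.labels != "absent").sum() and model.labels[
                            model.labels != "absent"
                        ].nunique()
                    ),
                }
            (out / "pattern.json").write_text(
                json.dumps(lineage_out, indent=1, sort_keys=True)
            )
        manifest["stages"]["lineage"] = lineage_out

        stats_report: dict = {}
        burdened = sample_burdens(kept, samples)
        write_samples(burdened, out / "sample_burdens.tsv")
        for tissue in ("normal", "BPH"):
            sub = burdened[burdened["tissue"] == tissue]
            if len(sub) >= 3 and sub["age"].nunique() > 1:
                reg = age_burden_regression(sub)
                stats_report[f"age_burden_{tissue}"] = {
                    "slope": round(reg.slope, 3),
                    "r_squared": round(reg.r_squared, 4),
                    "ci": [round(reg.slope_ci[0], 3), round(reg.slope_ci[1], 3)],
                    "n": reg.n,
                }
        if config.design == "trio":
            try:
                prox = proximity_analysis(burdened, "burden", seed=config.seed)
                stats_report["proximity_burden"] = {
                    "mean_difference": round(prox.statistic, 3),
                    "p_value": round(prox.p_value, 5),
                }
            except ValueError:
                pass
        else:
            for case, grp in burdened.groupby("case_id"):
                entry = {}
                try:
                    z = zonal_comparison(grp, "burden")
                    entry["zonal_p"] = round(z.p_value, 5)
                except ValueError:
                    pass
                try:
                    asym = asymmetry_analysis(grp, "lateral", ps_counts=None)
                    entry["lateral_burden_p"] = round(asym["burden"].p_value, 5)
                except ValueError:
                    pass
                stats_report[f"case_{case}"] = entry
        stats_report["drivers"] = driver_summary(kept, samples)
        (out / "report.json").write_text(json.dumps(stats_report, indent=1, sort_keys=True))
        manifest["stages"]["spatial"] = {"tests": sorted(stats_report)}
    except Exception as err:
        manifest["error"] = f"{type(err).__name__}: {err}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
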
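"""Somatic-variant filtering cascade for multi-region sampling data.

Filters flag records, never delete them. The cascade order is
population-AF -> germline (trio rule for trio designs, pooled exact
binomial for grid designs) -> beta-binomial cross-sample artifact ->
indel read support. Germline removal precedes artifact fitting so that
true germline sharing does not masquerade as cross-sample artifact
structure.

* population-AF: flag when the population allele frequency exceeds 0.01
  (strict inequality).
* trio germline: a variant detected (>=1 alt read) in every sample of a
  case with mean VAF > 0.3 is germline-shared.
* binomial germline (grid): exact two-sided (minimum-likelihood) binomial
  test of pooled alt/depth against p0 = 0.5; germline when the test does
  not reject (p >= alpha) and the pooled VAF lies in a heterozygous window.
* beta-binomial artifact: per site across all cohort samples, the
  maximum-likelihood overdispersion rho of a beta-binomial with common
  mean is fitted by bounded 1-D search; recurrent low-VAF sites with many
  carriers and tight dispersion (low rho) are artifacts.
* indel support: indels with fewer than seven total reads or fewer than
  two variant reads, or falling in user-supplied paralog intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import betabinom, binom

FLAG_POP_AF = "pop_af"
FLAG_GERMLINE_BINOM = "germline_binomial"
FLAG_ARTIFACT = "artifact_betabinom"
FLAG_TRIO_GERMLINE = "trio_germline"
FLAG_INDEL = "indel_support"
FLAG_PARALOG = "paralog"

GERMLINE_FLAGS = (FLAG_GERMLINE_BINOM, FLAG_TRIO_GERMLINE)
ALL_FLAGS = (
    FLAG_POP_AF, FLAG_GERMLINE_BINOM, FLAG_ARTIFACT,
    FLAG_TRIO_GERMLINE, FLAG_INDEL, FLAG_PARALOG,
)


def add_flag(variants: pd.DataFrame, mask, flag: str) -> pd.DataFrame:
    """Union ``flag`` into ``filter_flags`` for rows where mask is true (idempotent)."""
    if "filter_flags" not in variants.columns:
        variants = variants.assign(filter_flags="")
    flags = variants["filter_flags"].to_numpy(dtype=object).copy()
    mask = np.asarray(mask, dtype=bool)
    for i in np.nonzero(mask)[0]:
        cur = set(filter(None, str(flags[i]).split(";")))
        cur.add(flag)
        flags[i] = ";".join(sorted(cur))
    out = variants.copy()
    out["filter_flags"] = flags
    return out


def has_flag(variants: pd.DataFrame, flag: str) -> pd.Series:
    return variants["filter_flags"].fillna("").str.split(";").apply(lambda fs: flag in fs)


def filter_population_af(variants: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Flag records whose population allele frequency exceeds ``threshold`` (strict)."""
    af = variants["population_af"].fillna(0.0)
    if (af < 0).any():
        raise ValueError("population_af must be non-negative")
    return add_flag(variants, (af > threshold).to_numpy(), FLAG_POP_AF)


def binomial_germline_test(alt_count, total_depth, p0: float = 0.5):
    """Exact two-sided binomial p-value(s), minimum-likelihood method.

    The p-value is the total probability of all outcomes whose likelihood
    under Binomial(n, p0) does not exceed that of the observed count.
    Accepts scalars or arrays; vectorized over records sharing a depth.
    """
    alt = np.atleast_1d(np.asarray(alt_count, dtype=int))
    depth = np.atleast_1d(np.asarray(total_depth, dtype=int))
    alt, depth = np.broadcast_arrays(alt, depth)
    if np.any(depth < 1):
        raise ValueError("total_depth must be >= 1")
    if np.any((alt < 0) | (alt > depth)):
        raise ValueError("alt_count must lie in [0, total_depth]")
    pvals = np.empty(alt.shape, dtype=float)
    for n in np.unique(depth):
        sel = depth == n
        pmf = binom.pmf(np.arange(n + 1), n, p0)
        order = np.argsort(pmf, kind="stable")
        sorted_pmf = pmf[order]
        csum = np.cumsum(sorted_pmf)
        # rank of each outcome's pmf in the sorted list (last index with
        # pmf <= observed pmf * (1 + eps), tolerating float ties)
        thresh = pmf[alt[sel]] * (1 + 1e-7)
        idx = np.searchsorted(sorted_pmf, thresh, side="right") - 1
        pvals[sel] = np.minimum(csum[np.clip(idx, 0, n)], 1.0)
    if np.isscalar(alt_count) and np.isscalar(total_depth):
        return float(pvals[0])
    return pvals.reshape(np.shape(alt_count) or np.shape(total_depth))


def germline_binomial_filter(
    variants: pd.DataFrame,
    alpha: float = 0.01,
    vaf_window: tuple[float, float] = (0.3, 0.7),
) -> pd.DataFrame:
    """Pooled exact-binomial germline filter for multi-region (grid) cases.

    Counts are pooled across all samples of a case per variant; the variant
    is germline when the exact test does not reject p0 = 0.5 (p >= alpha)
    and the pooled VAF lies inside the heterozygous window.
    """
    g = variants.groupby(["case_id", "variant_id"], sort=False).agg(
        alt=("alt_count", "sum"), depth=("total_depth", "sum")
    )
    p = binomial_germline_test(g["alt"].to_numpy(), g["depth"].to_numpy())
    vaf = g["alt"] / g["depth"]
    flagged = set(
        g.index[(p >= alpha) & (vaf >= vaf_window[0]) & (vaf <= vaf_window[1])]
    )
    mask = [
        (c, v) in flagged
        for c, v in zip(variants["case_id"], variants["variant_id"])
    ]
    return add_flag(variants, np.asarray(mask), FLAG_GERMLINE_BINOM)


def trio_germline_filter(
    variants: pd.DataFrame, min_mean_vaf: float = 0.3
) -> pd.DataFrame:
    """Flag variants detected in ALL samples of their case with mean VAF > 0.3."""
    n_samples = variants.groupby("case_id")["sample_id"].nunique()
    tmp = variants.assign(det=(variants["alt_count"] >= 1).astype(int))
    per_var = tmp.groupby(["case_id", "variant_id"], sort=False).agg(
        n_det=("det", "sum"), mean_vaf=("vaf", "mean")
    )
    need = per_var.index.get_level_values("case_id").map(n_samples)
    flagged = set(
        per_var.index[
            (per_var["n_det"].to_numpy() == need.to_numpy())
            & (per_var["mean_vaf"].to_numpy() > min_mean_vaf)
        ]
    )
    mask = [
        (c, v) in flagged
        for c, v in zip(variants["case_id"], variants["variant_id"])
    ]
    return add_flag(variants, np.asarray(mask), FLAG_TRIO_GERMLINE)


def fit_betabinomial_rho(
    alt_counts, total_depths, bounds: tuple[float, float] = (1e-6, 0.89)
) -> float:
    """Maximum-likelihood beta-binomial overdispersion across samples.

    The mean is fixed at the pooled alt/depth fraction and the
    overdispersion rho is found by bounded 1-D search of the likelihood.
    Low rho = counts tightly binomial around a common mean (artifact-like);
    high rho = bursty, sample-restricted support (genuine variant-like).
    Deterministic for fixed input. Requires >= 3 samples with depth >= 1.
    """
    alt = np.asarray(alt_counts, dtype=int)
    depth = np.asarray(total_depths, dtype=int)
    usable = depth >= 1
    if usable.sum() < 3:
        raise ValueError("need >= 3 samples with depth >= 1 to fit overdispersion")
    alt, depth = alt[usable], depth[usable]
    if depth.sum() == 0:
        raise ValueError("all depths are zero")
    mu = float(np.clip(alt.sum() / depth.sum(), 1e-6, 1 - 1e-6))

    def negll(rho):
        a = mu * (1 - rho) / rho
        b = (1 - mu) * (1 - rho) / rho
        return -betabinom.logpmf(alt, depth, a, b).sum()

    res = minimize_scalar(negll, bounds=bounds, method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def artifact_filter(
    variants: pd.DataFrame,
    rho_cutoff: float = 0.1,
    min_carriers: int = 3,
    max_mean_vaf: float = 0.25,
    exclude_flags: tuple[str, ...] = (FLAG_POP_AF,) + GERMLINE_FLAGS,
) -> tuple[pd.DataFrame, pd.Series]:
    """Beta-binomial cross-sample artifact filter over the whole cohort.

    A site is an artifact when it has >= ``min_carriers`` carrier samples,
    its fitted overdispersion rho is below ``rho_cutoff`` and its pooled
    mean VAF is below ``max_mean_vaf`` (the last guard keeps germline-like
    half-VAF sharing for the germline filters). Sites already flagged by
    upstream filters are not refitted. Returns the flagged table and the
    per-site fitted rho values.
    """
    flags = variants["filter_flags"].fillna("")
    excluded_vids = set(
        variants.loc[
            flags.str.split(";").apply(lambda fs: any(f in fs for f in exclude_flags)),
            "variant_id",
        ]
    )
    stats = variants.groupby("variant_id", sort=False).agg(
        n_carriers=("alt_count", lambda a: int((np.asarray(a) >= 1).sum())),
        n_rows=("alt_count", "size"),
    )
    candidates = stats.index[
        (stats["n_carriers"] >= min_carriers)
        & (stats["n_rows"] >= 3)
        & ~stats.index.isin(excluded_vids)
    ]
    rhos = {}
    flagged_vids = set()
    cand = variants[variants["variant_id"].isin(candidates)]
    for vid, grp in cand.groupby("variant_id", sort=False):
        rho = fit_betabinomial_rho(grp["alt_count"], grp["total_depth"])
        rhos[vid] = rho
        mean_vaf = grp["alt_count"].sum() / grp["total_depth"].sum()
        if rho < rho_cutoff and mean_vaf < max_mean_vaf:
            flagged_vids.add(vid)
    mask = variants["variant_id"].isin(flagged_vids).to_numpy()
    out = add_flag(variants, mask, FLAG_ARTIFACT)
    return out, pd.Series(rhos, name="rho_bb")


def indel_support_filter(
    variants: pd.DataFrame,
    min_total_reads: int = 7,
    min_alt_reads: int = 2,
    paralog_intervals=None,
) -> pd.DataFrame:
    """Flag indels with < 7 total reads or < 2 variant reads; optional paralog BED.

    ``paralog_intervals`` maps chrom -> IntervalTree of excluded regions
    (1-based inclusive positions after BED conversion on read).
    """
    is_indel = (variants["variant_type"] == "indel").to_numpy()
    weak = (
        (variants["total_depth"] < min_total_reads)
        | (variants["alt_count"] < min_alt_reads)
    ).to_numpy()
    out = add_flag(variants, is_indel & weak, FLAG_INDEL)
    if paralog_intervals:
        in_paralog = np.array(
            [
                bool(paralog_intervals.get(str(c), ()))
                and bool(paralog_intervals[str(c)].overlap(p, p + 1))
                for c, p in zip(out["chrom"], out["pos"])
            ]
        )
        out = add_flag(out, is_indel & in_paralog, FLAG_PARALOG)
    return out


def run_cascade(
    variants: pd.DataFrame,
    design: str,
    pop_af_threshold: float = 0.01,
    germline_alpha: float = 0.01,
    vaf_window: tuple[float, float] = (0.3, 0.7),
    trio_min_mean_vaf: float = 0.3,
    rho_cutoff: float = 0.1,
    min_carriers: int = 3,
    paralog_intervals=None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full filter cascade; returns (flagged table, per-stage counts)."""
    if design not in ("trio", "grid3d"):
        raise ValueError(f"unknown design: {design!r}")
    counts = {"input": int(variants["variant_id"].nunique())}
    out = filter_population_af(variants, threshold=pop_af_threshold)
    counts[FLAG_POP_AF] = int(out.loc[has_flag(out, FLAG_POP_AF), "variant_id"].nunique())
    if design == "trio":
        out = trio_germline_filter(out, min_mean_vaf=trio_min_mean_vaf)
        counts[FLAG_TRIO_GERMLINE] = int(
            out.loc[has_flag(out, FLAG_TRIO_GERMLINE), "variant_id"].nunique()
        )
    else:
        out = germline_binomial_filter(out, alpha=germline_alpha, vaf_window=vaf_window)
        counts[FLAG_GERMLINE_BINOM] = int(
            out.loc[has_flag(out, FLAG_GERMLINE_BINOM), "variant_id"].nunique()
        )
    out, rhos = artifact_filter(out, rho_cutoff=rho_cutoff, min_carriers=min_carriers)
    counts[FLAG_ARTIFACT] = int(
        out.loc[has_flag(out, FLAG_ARTIFACT), "variant_id"].nunique()
    )
    out = indel_support_filter(out, paralog_intervals=paralog_intervals)
    counts[FLAG_INDEL] = int(out.loc[has_flag(out, FLAG_INDEL), "variant_id"].nunique())
    # a site is "passed" only when no record of it carries any flag
    any_flagged = set(out.loc[out["filter_flags"] != "", "variant_id"])
    counts["passed"] = int(counts["input"] - len(any_flagged))
    return out, counts


def passed(variants: pd.DataFrame) -> pd.DataFrame:
    """Records with no filter flag set."""
    return variants[variants["filter_flags"].fillna("") == ""]
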
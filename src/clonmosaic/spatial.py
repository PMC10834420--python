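"""Cohort- and case-level statistics for multi-region somatic profiles.

Wraps the study's statistical toolkit — ordinary least squares for the
age-burden relation, Mann-Whitney U (exact for small groups), Kruskal-
Wallis, and Pearson chi-square — and the derived analyses: zonal
(PZ/CZ/TZ) comparisons, spatial asymmetry along the lateral / antero-
posterior / vertical axes, paired ipsilateral-vs-contralateral proximity
tests, and driver / RTK-RAS pathway convergence summaries.

Raw p-values are reported (no multiple-testing correction by default,
with an optional Benjamini-Hochberg helper for batch reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import DRIVER_GENES, RTK_RAS_GENES


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    group_summary: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple
    p_value: float
    n: int


def age_burden_regression(
    samples: pd.DataFrame,
    tissue: str | None = None,
    burden_col: str = "burden",
    conf: float = 0.95,
) -> RegressionResult:
    """OLS of per-clone mutation burden on age (optionally one tissue)."""
    df = samples if tissue is None else samples[samples["tissue"] == tissue]
    df = df.dropna(subset=["age", burden_col])
    if len(df) < 3:
        raise ValueError("need >= 3 samples with age and burden")
    age = df["age"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("age is constant; slope undefined")
    y = df[burden_col].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0,
            slope_ci=(0.0, 0.0), p_value=1.0, n=len(df),
        )
    res = stats.linregress(age, y)
    tcrit = stats.t.ppf(1 - (1 - conf) / 2, len(df) - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_ci=(float(ci[0]), float(ci[1])),
        p_value=float(res.pvalue),
        n=len(df),
    )


def age_corrected_values(samples: pd.DataFrame, value_col: str) -> pd.Series:
    """Residuals of value ~ age, for age-corrected group comparisons."""
    df = samples.dropna(subset=["age", value_col])
    res = stats.linregress(df["age"], df[value_col])
    return df[value_col] - (res.intercept + res.slope * df["age"])


def _mannwhitney(x, y) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    r = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        name="mannwhitney",
        statistic=float(r.statistic),
        p_value=float(r.pvalue),
        group_summary={"median_x": float(np.median(x)), "median_y": float(np.median(y))},
        n={"x": len(x), "y": len(y)},
    )


def group_test(values, labels=None, kind: str = "mannwhitney") -> TestResult:
    """Two-group Mann-Whitney, k-group Kruskal-Wallis, or table chi-square.

    ``mannwhitney``/``kruskal``: ``values`` with parallel ``labels`` (or a
    list of per-group arrays with labels None). ``chisq``: ``values`` is a
    contingency table.
    """
    if kind == "chisq":
        table = np.asarray(values, dtype=float)
        if table.min() < 0:
            raise ValueError("contingency table entries must be non-negative")
        stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
        return TestResult(
            name="chisq", statistic=float(stat), p_value=float(p),
            n={"total": int(table.sum())},
        )
    if labels is None:
        groups = [np.asarray(g, dtype=float) for g in values]
    else:
        values = np.asarray(values, dtype=float)
        labels = np.asarray(labels)
        groups = [values[labels == g] for g in pd.unique(labels)]
    if any(len(g) == 0 for g in groups) or len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if kind == "mannwhitney":
        if len(groups) != 2:
            raise ValueError("mannwhitney takes exactly 2 groups")
        return _mannwhitney(*groups)
    if kind == "kruskal":
        if all((g == groups[0][0]).all() for g in groups):
            return TestResult(
                name="kruskal", statistic=0.0, p_value=1.0,
                n={f"g{i}": len(g) for i, g in enumerate(groups)},
            )
        stat, p = stats.kruskal(*groups)
        return TestResult(
            name="kruskal", statistic=float(stat), p_value=float(p),
            group_summary={f"median_g{i}": float(np.median(g)) for i, g in enumerate(groups)},
            n={f"g{i}": len(g) for i, g in enumerate(groups)},
        )
    raise ValueError(f"unknown test kind: {kind!r}")


def zonal_comparison(
    case_samples: pd.DataFrame, value_col: str = "burden"
) -> TestResult:
    """Kruskal-Wallis of a per-sample value across PZ / CZ / TZ zones."""
    df = case_samples[case_samples["zone"].isin(["PZ", "CZ", "TZ"])].dropna(
        subset=[value_col]
    )
    zones = [z for z in ("PZ", "CZ", "TZ") if (df["zone"] == z).any()]
    if len(zones) < 2:
        raise ValueError("need >= 2 zones represented")
    groups = [df.loc[df["zone"] == z, value_col].to_numpy() for z in zones]
    res = group_test(groups, kind="kruskal")
    medians = {z: float(np.median(g)) for z, g in zip(zones, groups)}
    res.name = "zonal_kruskal"
    res.group_summary = dict(sorted(medians.items(), key=lambda kv: -kv[1]))
    res.n = {z: len(g) for z, g in zip(zones, groups)}
    return res


AXIS_COLUMNS = {"lateral": "x", "anteroposterior": "y", "vertical": "z"}


def _axis_halves(df: pd.DataFrame, axis: str):
    col = AXIS_COLUMNS[axis]
    if axis == "vertical":
        mid = df[col].median()
        lo, hi = df[df[col] <= mid], df[df[col] > mid]
        names = ("lower", "upper")
    else:
        lo, hi = df[df[col] < 0], df[df[col] > 0]  # x/y == 0 excluded (midline)
        names = ("left", "right") if axis == "lateral" else ("anterior", "posterior")
    return lo, hi, names


def asymmetry_analysis(
    case_samples: pd.DataFrame,
    axis: str = "lateral",
    fields: tuple = ("burden", "telomere_length"),
    ps_counts: tuple[str, str] | None = ("ps_count", "total_count"),
) -> dict[str, TestResult]:
    """Per-axis asymmetry tests: Mann-Whitney on per-sample values and a
    pooled chi-square on private-subclonal proportions when counts exist."""
    if axis not in AXIS_COLUMNS:
        raise ValueError(f"unknown axis: {axis!r}")
    lo, hi, names = _axis_halves(case_samples, axis)
    if len(lo) == 0 or len(hi) == 0:
        raise ValueError(f"both sides of the {axis} axis must be represented")
    out = {}
    for fieldname in fields:
        if fieldname not in case_samples.columns:
            continue
        r = _mannwhitney(lo[fieldname].dropna(), hi[fieldname].dropna())
        r.name = f"{fieldname}_{axis}"
        r.group_summary = {
            names[0]: float(lo[fieldname].median()),
            names[1]: float(hi[fieldname].median()),
        }
        out[fieldname] = r
    if ps_counts and all(c in case_samples.columns for c in ps_counts):
        ps, tot = ps_counts
        table = [
            [lo[ps].sum(), lo[tot].sum() - lo[ps].sum()],
            [hi[ps].sum(), hi[tot].sum() - hi[ps].sum()],
        ]
        r = group_test(table, kind="chisq")
        r.name = f"ps_proportion_{axis}"
        r.group_summary = {
            names[0]: float(lo[ps].sum() / max(lo[tot].sum(), 1)),
            names[1]: float(hi[ps].sum() / max(hi[tot].sum(), 1)),
        }
        out["ps_proportion"] = r
    return out


def proximity_analysis(
    trio_samples: pd.DataFrame,
    value_col: str = "burden",
    n_permutations: int = 10000,
    seed: int = 0,
) -> TestResult:
    """Paired ipsilateral (N1) vs contralateral (N2) comparison.

    Sign-flip permutation test on the mean within-case difference
    (exact enumeration up to 12 pairs, seeded Monte-Carlo above).
    """
    piv = trio_samples.pivot_table(
        index="case_id", columns="role", values=value_col, aggfunc="first"
    )
    if "N1" not in piv.columns or "N2" not in piv.columns:
        raise ValueError("trio cases need N1 and N2 samples")
    piv = piv.dropna(subset=["N1", "N2"])
    d = (piv["N1"] - piv["N2"]).to_numpy(dtype=float)
    n = len(d)
    if n == 0:
        raise ValueError("no complete N1/N2 pairs")
    obs = abs(d.mean())
    if n <= 12:
        signs = np.array(
            [[1 if (mask >> i) & 1 else -1 for i in range(n)] for mask in range(2**n)]
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1, 1], size=(n_permutations, n))
    perm = np.abs((signs * d).mean(axis=1))
    p = float((perm >= obs - 1e-12).mean())
    return TestResult(
        name=f"proximity_{value_col}",
        statistic=float(d.mean()),
        p_value=p,
        group_summary={"mean_N1": float(piv["N1"].mean()), "mean_N2": float(piv["N2"].mean())},
        n={"pairs": n},
    )


def driver_summary(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    driver_genes=DRIVER_GENES,
    pathway_genes=RTK_RAS_GENES,
    min_pathway_vaf: float = 0.1,
) -> dict:
    """Nonsilent driver counts per tissue and RTK/RAS pathway convergence.

    Counts mutation-sample carrier records (alt >= 1) with a nonsilent
    effect in the configured driver list; convergence is flagged when
    singleton high-VAF pathway mutations hit >= 2 distinct pathway genes
    in disjoint samples of a case (same pathway, different genes,
    different clones).
    """
    if "gene" not in variants.columns or "effect" not in variants.columns:
        raise ValueError("variant table must carry gene and effect annotation columns")
    tissue_of = samples.set_index("sample_id")["tissue"]
    carriers = variants[(variants["alt_count"] >= 1) & (variants["effect"] != "")]
    drv = carriers[carriers["gene"].isin(set(driver_genes) | set(pathway_genes))].copy()
    drv["tissue"] = drv["sample_id"].map(tissue_of)
    per_tissue = {}
    for tissue in ("normal", "BPH", "PCA"):
        sids = samples.loc[samples["tissue"] == tissue, "sample_id"]
        sub = drv[drv["tissue"] == tissue]
        n_samples = max(len(sids), 1)
        pathway_samples = sub.loc[sub["gene"].isin(pathway_genes), "sample_id"].nunique()
        per_tissue[tissue] = {
            "n_driver_mutations": int(len(sub)),
            "mean_per_sample": float(len(sub) / n_samples),
            "pathway_sample_fraction": float(pathway_samples / n_samples),
        }
    convergence = {}
    pw = drv[drv["gene"].isin(pathway_genes)]
    pw = pw[pw["alt_count"] / pw["total_depth"] >= min_pathway_vaf]
    for case, grp in pw.groupby("case_id"):
        by_var = grp.groupby("variant_id").agg(
            gene=("gene", "first"), carriers=("sample_id", lambda s: frozenset(s))
        )
        singletons = by_var[by_var["carriers"].apply(len) == 1]
        genes = singletons["gene"].unique()
        carrier_sets = list(singletons["carriers"])
        disjoint = all(
            len(a & b) == 0
            for i, a in enumerate(carrier_sets)
            for b in carrier_sets[i + 1:]
        )
        convergence[case] = {
            "n_pathway_singletons": int(len(singletons)),
            "n_genes": int(len(genes)),
            "convergent": bool(len(genes) >= 2 and disjoint and len(singletons) >= 2),
        }
    return {"per_tissue": per_tissue, "convergence": convergence}


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values for an optional batch report."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.minimum(q, 1.0)
    return out


def sample_burdens(variants: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Attach per-sample passed somatic burden (carrier records, alt >= 1)."""
    burden = (
        variants[variants["alt_count"] >= 1]
        .groupby("sample_id")["variant_id"]
        .nunique()
        .rename("burden")
    )
    out = samples.copy()
    out["burden"] = out["sample_id"].map(burden).fillna(0).astype(int)
    return out
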
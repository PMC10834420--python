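"""Clone-size estimation, mutant copy number, clonal status and sharing classes.

For a mutation observed at variant allele frequency ``v`` in a sample with
clone/purity fraction ``rho``, local total copy number ``c_t`` and normal
copy number ``c_n``, the expected mutant copies per carrying cell are

    n_mut = v * (rho * c_t + (1 - rho) * c_n) / rho

and the cancer-cell-fraction point estimate is ``n_mut`` itself while
``n_mut <= 1``, else ``n_mut`` divided by its nearest integer, capped at 1.
A mutation is *clonal* when the exact binomial confidence interval of the
VAF, propagated through this formula, is compatible with one mutant copy
per cell (CCF upper bound >= 0.9 by default).

Clone size per microdissected area is estimated either from the peak of a
Gaussian kernel density over VAF (diploid assumption: clone = 2 x peak) or
as the median cell fraction of the mutations called clonal (default for
reported values).

Within a case, mutations are classified SC / PC / SS / PS: shared vs
private by carrier count, clonal vs subclonal by the per-carrier call
(shared-clonal requires clonal in every carrier).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

SHARING_CLASSES = ("SC", "PC", "SS", "PS")


def mutant_copy_number(vaf, rho, cn_tumor=2.0, cn_normal=2.0):
    """Expected mutant allele copies per carrying cell (vectorized)."""
    vaf = np.asarray(vaf, dtype=float)
    rho_a = np.asarray(rho, dtype=float)
    if np.any(rho_a <= 0) or np.any(rho_a > 1):
        raise ValueError("rho must lie in (0, 1]")
    if np.any((vaf < 0) | (vaf > 1)):
        raise ValueError("vaf must lie in [0, 1]")
    n_mut = vaf * (rho_a * cn_tumor + (1 - rho_a) * cn_normal) / rho_a
    return n_mut if n_mut.ndim else float(n_mut)


def ccf_from_nmut(n_mut):
    """CCF point estimate: n_mut itself below one copy, else n_mut / round(n_mut), capped at 1."""
    n_mut = np.asarray(n_mut, dtype=float)
    nearest = np.maximum(np.round(n_mut), 1.0)
    ccf = np.where(n_mut <= 1.0, n_mut, n_mut / nearest)
    ccf = np.minimum(ccf, 1.0)
    return ccf if ccf.ndim else float(ccf)


def binomial_ci(alt, depth, conf: float = 0.95):
    """Exact (Clopper-Pearson) binomial interval for the VAF (vectorized)."""
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    a = (1 - conf) / 2
    lo = np.where(alt == 0, 0.0, beta_dist.ppf(a, alt, depth - alt + 1))
    hi = np.where(alt == depth, 1.0, beta_dist.ppf(1 - a, alt + 1, depth - alt))
    return lo, hi


def call_clonal_status(
    alt_count,
    total_depth,
    rho=1.0,
    cn_tumor=2.0,
    cn_normal=2.0,
    ccf_threshold: float = 0.9,
    conf: float = 0.95,
    point_threshold: float | None = None,
):
    """Clonal call: exact binomial VAF interval propagated to CCF; clonal
    iff the CCF upper bound reaches ``ccf_threshold`` (vectorized).

    With ``point_threshold`` set (the pipeline uses 0.5), the CCF point
    estimate must additionally reach it — the usual majority-of-clone
    convention, which keeps shallow-coverage intervals (whose upper bound
    is almost always compatible with one mutant copy) from absorbing
    clearly subclonal mutations.
    """
    alt = np.asarray(alt_count)
    depth = np.asarray(total_depth)
    _, hi = binomial_ci(alt, depth, conf=conf)
    nmut_hi = mutant_copy_number(hi, rho, cn_tumor, cn_normal)
    # an interval reaching one mutant copy (or more) is compatible with clonal
    ccf_hi = np.minimum(np.asarray(nmut_hi, dtype=float), 1.0)
    clonal = ccf_hi >= ccf_threshold
    if point_threshold is not None:
        vaf = alt / depth
        point = ccf_from_nmut(mutant_copy_number(vaf, rho, cn_tumor, cn_normal))
        clonal = clonal & (np.asarray(point) >= point_threshold)
    return clonal if clonal.ndim else bool(clonal)


@dataclass
class CloneEstimate:
    """Estimated dominant-clone cell fraction for one sample."""

    sample_id: str
    clone_size: float
    method: str
    n_mutations_used: int
    low_confidence: bool = False


def _kde_peak(vafs: np.ndarray, bandwidth: float, grid_step: float = 0.002) -> float:
    grid = np.arange(0.0, 1.0 + grid_step, grid_step)
    z = (grid[:, None] - vafs[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def estimate_clone_size(
    sample_variants: pd.DataFrame,
    method: str = "median_ccf",
    bandwidth: float = 0.03,
    min_mutations: int = 10,
    ccf_threshold: float = 0.9,
    sample_id: str = "",
    carrier_min_alt: int = 1,
) -> CloneEstimate:
    """Dominant-clone cell fraction from a sample's passed somatic SBS calls.

    ``vaf_peak``: 2 x argmax of a fixed-bandwidth Gaussian KDE over VAF.
    ``median_ccf``: an initial peak estimate anchors per-mutation clonal
    calls (exact binomial CI through the mutant-copy-number formula); the
    clone size is the median diploid cell fraction (2 x VAF) of the
    mutations called clonal. Estimates below 0.15 are flagged low
    confidence (no resolvable clone).
    """
    if method not in ("vaf_peak", "median_ccf"):
        raise ValueError(f"unknown method: {method!r}")
    df = sample_variants[sample_variants["alt_count"] >= carrier_min_alt]
    if len(df) < min_mutations:
        raise ValueError(
            f"need >= {min_mutations} somatic mutations, got {len(df)}"
        )
    vafs = (df["alt_count"] / df["total_depth"]).to_numpy(dtype=float)
    peak = _kde_peak(vafs, bandwidth)
    peak_size = float(np.clip(2.0 * peak, 0.0, 1.0))
    if method == "vaf_peak":
        size, n_used = peak_size, len(vafs)
    else:
        # anchor on the VAF peak, then refine once: clonal assignment with
        # the majority-of-clone condition, re-anchored on its own median
        rho0 = max(peak_size, 0.05)
        size, n_used = peak_size, len(vafs)
        for _ in range(2):
            clonal = call_clonal_status(
                df["alt_count"].to_numpy(),
                df["total_depth"].to_numpy(),
                rho=rho0,
                ccf_threshold=ccf_threshold,
                point_threshold=0.5,
            )
            if not np.any(clonal):
                break
            size = float(np.clip(np.median(2.0 * vafs[clonal]), 0.0, 1.0))
            n_used = int(clonal.sum())
            rho0 = max(size, 0.05)
    return CloneEstimate(
        sample_id=sample_id,
        clone_size=size,
        method=method,
        n_mutations_used=n_used,
        low_confidence=size < 0.15,
    )


def estimate_clone_sizes(
    variants: pd.DataFrame,
    method: str = "median_ccf",
    min_mutations: int = 10,
    **kwargs,
) -> pd.DataFrame:
    """Per-sample clone sizes over a cohort table of passed somatic SBS calls."""
    rows = []
    for sid, grp in variants.groupby("sample_id", sort=True):
        sbs = grp[grp["variant_type"] == "SBS"]
        if (sbs["alt_count"] >= 1).sum() < min_mutations:
            continue
        est = estimate_clone_size(
            sbs, method=method, min_mutations=min_mutations, sample_id=sid, **kwargs
        )
        rows.append(
            dict(
                sample_id=sid,
                clone_size=est.clone_size,
                method=est.method,
                n_mutations_used=est.n_mutations_used,
                low_confidence=est.low_confidence,
            )
        )
    return pd.DataFrame(rows)


def classify_sharing(
    case_variants: pd.DataFrame,
    clone_sizes: dict | pd.Series,
    carrier_min_alt: int = 2,
    carrier_min_vaf: float = 0.02,
    ccf_threshold: float = 0.9,
    cn_lookup=None,
) -> pd.DataFrame:
    """SC/PC/SS/PS classification of one case's somatic mutations.

    A sample carries a mutation when alt >= ``carrier_min_alt`` and
    VAF >= ``carrier_min_vaf``. Shared = >= 2 carriers. Clonal per carrier
    via the binomial-CI rule with that sample's clone size as rho;
    shared-clonal (SC) requires clonal in all carriers. Mutations with no
    carrier are omitted. ``cn_lookup(chrom, pos, sample_id)`` may supply
    local total copy number (default diploid).
    """
    df = case_variants
    carrier = (df["alt_count"] >= carrier_min_alt) & (
        df["alt_count"] / df["total_depth"] >= carrier_min_vaf
    )
    carriers_df = df[carrier].copy()
    if len(carriers_df) == 0:
        return pd.DataFrame(
            columns=["variant_id", "case_id", "n_carriers", "sharing_class"]
        )
    rho = carriers_df["sample_id"].map(clone_sizes).fillna(0.5).clip(0.05, 1.0)
    if cn_lookup is None:
        cn_t = 2.0
    else:
        cn_t = np.array(
            [
                cn_lookup(c, p, s)
                for c, p, s in zip(
                    carriers_df["chrom"], carriers_df["pos"], carriers_df["sample_id"]
                )
            ]
        )
    clonal = call_clonal_status(
        carriers_df["alt_count"].to_numpy(),
        carriers_df["total_depth"].to_numpy(),
        rho=rho.to_numpy(),
        cn_tumor=cn_t,
        ccf_threshold=ccf_threshold,
        point_threshold=0.5,
    )
    carriers_df["clonal"] = clonal
    agg = carriers_df.groupby("variant_id").agg(
        case_id=("case_id", "first"),
        n_carriers=("sample_id", "nunique"),
        all_clonal=("clonal", "all"),
    )
    shared = agg["n_carriers"] >= 2
    agg["sharing_class"] = np.where(
        shared,
        np.where(agg["all_clonal"], "SC", "SS"),
        np.where(agg["all_clonal"], "PC", "PS"),
    )
    return agg.reset_index()[["variant_id", "case_id", "n_carriers", "sharing_class"]]


def classify_cohort(
    variants: pd.DataFrame, clone_sizes: pd.DataFrame, **kwargs
) -> pd.DataFrame:
    """Sharing classification for every case of a cohort table."""
    size_map = clone_sizes.set_index("sample_id")["clone_size"]
    parts = [
        classify_sharing(grp, size_map, **kwargs)
        for _, grp in variants.groupby("case_id", sort=True)
    ]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(
            columns=["variant_id", "case_id", "n_carriers", "sharing_class"]
        )
    return pd.concat(parts, ignore_index=True)
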
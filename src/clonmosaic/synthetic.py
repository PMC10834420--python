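"""Synthetic multi-region prostate cohorts with full ground truth.

The generator emulates the two sampling designs the analysis assumes:

* ``trio`` — per case one tumor area (T, prostate cancer) plus an
  ipsilateral (N1) and a contralateral (N2) nontumor area (normal or BPH);
* ``grid3d`` — one case sampled on an integer 3D grid of microdissected
  areas, with early embryonic mutations (EEMs) propagated on an embryonic
  lineage tree and placed in a layered or mixed spatial pattern.

Per-sample somatic burden grows linearly with age (defaults: 16 mutations
per year per clone in normal tissue, 43.4 in BPH), clone cell fractions
differ by tissue (0.36 normal, 0.41 BPH, 0.77 tumor), read counts are
binomial at Poisson-distributed depth (WGS ~16x, deep panel ~997x),
trinucleotide contexts are drawn from per-sample mixtures over the bundled
seven-signature profiles (the ROS signature SBS18 enters a sample's mixture
with a tissue-dependent probability: 0.22 normal / 0.23 BPH / 0.90 tumor),
and germline and recurrent low-VAF artifact sites are injected as labeled
confounders. Every emitted variant carries exactly one ground-truth label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sbs96 import channel_to_context_alt
from .signatures import SIGNATURE_NAMES, load_reference_signatures

TISSUES = ("normal", "BPH", "PCA")
LABELS = ("somatic_clonal", "somatic_subclonal", "germline", "artifact", "eem")

#: A small driver-gene panel used only to annotate injected nonsilent mutations.
DRIVER_GENES = ("FOXA1", "KMT2C", "BCOR", "KMT2A", "SPOP", "TP53", "PTEN", "CHD1")
RTK_RAS_GENES = (
    "KRAS", "HRAS", "NRAS", "BRAF", "EGFR", "ERBB2", "ERBB3",
    "FGFR1", "FGFR2", "FGFR3", "NF1", "PTPN11", "SOS1", "MAP2K1",
)


def _default_signature_mix() -> dict[str, tuple[float, ...]]:
    # order: SBS1, SBS2, SBS3, SBS5, SBS13, SBS18, SBS92 — aging-dominant,
    # SBS18 kept at 0 here and switched on per sample by ros presence.
    base = (0.30, 0.03, 0.05, 0.50, 0.03, 0.0, 0.09)
    pca = (0.25, 0.08, 0.05, 0.42, 0.08, 0.0, 0.12)
    return {"normal": base, "BPH": base, "PCA": pca}


@dataclass
class CohortConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults are the study conditions: burden slopes 16 (normal) and 43.4
    (BPH) mutations/year/clone, clone fractions 0.36/0.41/0.77, mean depths
    16 (WGS) and 997 (panel), ROS-signature presence probability
    0.22/0.23/0.90 and ~4.9 (normal) / 6.3 (BPH) nonsilent driver mutations
    per sample.
    """

    n_cases: int = 20
    design: str = "trio"
    grid_dims: tuple[int, int, int] = (4, 4, 4)
    ages: tuple[float, float] = (50.0, 80.0)
    burden_slope_by_tissue: dict = field(
        default_factory=lambda: {"normal": 16.0, "BPH": 43.4, "PCA": 43.4}
    )
    burden_intercept_by_tissue: dict = field(
        default_factory=lambda: {"normal": 0.0, "BPH": 0.0, "PCA": 2000.0}
    )
    clone_fraction_by_tissue: dict = field(
        default_factory=lambda: {"normal": 0.36, "BPH": 0.41, "PCA": 0.77}
    )
    clone_fraction_sd: float = 0.04
    wgs_depth: float = 16.0
    panel_depth: float = 997.0
    depth_mode: str = "wgs"
    signature_mix_by_tissue: dict = field(default_factory=_default_signature_mix)
    ros_presence_prob_by_tissue: dict = field(
        default_factory=lambda: {"normal": 0.22, "BPH": 0.23, "PCA": 0.90}
    )
    ros_weight: float = 0.18
    n_germline: int = 30
    n_artifact_sites: int = 10
    artifact_vaf_range: tuple[float, float] = (0.01, 0.05)
    artifact_carrier_frac: float = 0.9
    eem_generations: int = 3
    eem_pattern: str = "layered"
    eems_per_node: int = 3
    eem_mosaic_vaf: float = 0.4
    eem_vaf_sd: float = 0.04
    subclonal_fraction: float = 0.25
    subclonal_ccf_range: tuple[float, float] = (0.1, 0.5)
    shared_fraction: float = 0.05
    indel_fraction: float = 0.05
    driver_rate_by_tissue: dict = field(
        default_factory=lambda: {"normal": 4.9, "BPH": 6.3, "PCA": 10.0}
    )
    bph_prob_nontumor: float = 0.325
    telomere_mean_by_tissue: dict = field(
        default_factory=lambda: {"normal": 6.0, "BPH": 5.2, "PCA": 4.5}
    )
    telomere_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.design not in ("trio", "grid3d"):
            raise ValueError(f"unknown design: {self.design!r}")
        if self.eem_pattern not in ("layered", "mixed"):
            raise ValueError(f"unknown eem_pattern: {self.eem_pattern!r}")
        if self.depth_mode not in ("wgs", "panel"):
            raise ValueError(f"unknown depth_mode: {self.depth_mode!r}")
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if any(d < 1 for d in self.grid_dims):
            raise ValueError("grid dimensions must be positive")
        if self.wgs_depth <= 0 or self.panel_depth <= 0:
            raise ValueError("depths must be positive")
        for t, f in self.clone_fraction_by_tissue.items():
            if not 0 < f <= 1:
                raise ValueError(f"clone fraction for {t} must be in (0, 1]")
        for t, p in self.ros_presence_prob_by_tissue.items():
            if not 0 <= p <= 1:
                raise ValueError(f"ros presence probability for {t} must be in [0, 1]")
        for t, mix in self.signature_mix_by_tissue.items():
            if len(mix) != len(SIGNATURE_NAMES):
                raise ValueError("signature mixes must have 7 entries")
            if abs(sum(mix) - 1.0) > 1e-6:
                raise ValueError(f"signature mix for {t} must sum to 1")

    @property
    def depth_mean(self) -> float:
        return self.wgs_depth if self.depth_mode == "wgs" else self.panel_depth


@dataclass
class GroundTruth:
    """Per-variant, per-sample and per-case truth for a simulated cohort."""

    variant_labels: pd.DataFrame  # variant_id -> label, case_id
    true_vaf: pd.DataFrame  # (variant_id, sample_id) -> true_vaf, true_ccf
    clone_fraction: pd.Series  # sample_id -> cell fraction
    signature_weights: pd.DataFrame  # sample_id x 7
    sharing_class: pd.DataFrame  # (case_id, variant_id) -> SC/PC/SS/PS for somatic
    lineage_parent: dict  # lineage node -> parent (grid3d only)
    lineage_label: pd.Series  # sample_id -> first-generation lineage (grid3d only)
    eem_sets: dict  # lineage node -> set of EEM variant_ids (grid3d only)


def simulate_reads(true_vaf, depth_mean: float, rng, size=None):
    """Binomial read sampling: depth ~ max(Poisson(depth_mean), 1), alt ~ Bin(depth, vaf)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    vaf = np.asarray(true_vaf, dtype=float)
    if np.any((vaf < 0) | (vaf > 1)):
        raise ValueError("true_vaf must lie in [0, 1]")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    shape = vaf.shape if size is None else size
    depth = np.maximum(rng.poisson(depth_mean, size=shape), 1)
    alt = rng.binomial(depth, np.broadcast_to(vaf, shape))
    return alt, depth


def grid_positions(grid_dims: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    """Integer sampling coordinates: x lateral (no zero; negative = left),
    y antero(-)/posterior(+), z = vertical layer 1..nz."""
    nx, ny, nz = grid_dims

    def axis_vals(n):
        half = n // 2
        vals = list(range(-half, 0)) + list(range(1, n - half + 1))
        return vals

    xs, ys = axis_vals(nx), axis_vals(ny)
    return [(x, y, z) for z in range(1, nz + 1) for y in ys for x in xs]


def zone_of(x: int, y: int) -> str:
    """Deterministic zone rings on (x, y): TZ innermost, CZ middle, PZ outer."""
    r = max(abs(x), abs(y))
    if r <= 1:
        return "TZ"
    if r == 2:
        return "CZ"
    return "PZ"


def simulate_embryonic_lineage(
    grid_dims: tuple[int, int, int],
    generations: int,
    pattern: str,
    seed,
    eems_per_node: int = 3,
):
    """Embryonic lineage tree, per-position lineage labels, and nested EEM sets.

    The first cleavage yields lineages L1 and L2; each subsequent generation
    splits every lineage in two (node names ``L1.1``, ``L1.2`` ...). Every
    node carries ``eems_per_node`` EEM identifiers and a child inherits all
    of its parent's EEMs (nesting). Spatial placement:

    * ``layered`` — each vertical layer is pure for one first-generation
      lineage, alternating between adjacent layers;
    * ``mixed`` — every layer contains both first-generation lineages,
      partitioned laterally (left vs right).

    Deeper generations subdivide a lineage's territory by coordinate medians,
    so descendant territories stay spatially contiguous.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if pattern not in ("layered", "mixed"):
        raise ValueError(f"unknown pattern: {pattern!r}")
    nx, ny, nz = grid_dims
    if pattern == "layered" and nz < 2:
        raise ValueError("layered pattern requires at least 2 vertical layers")

    positions = grid_positions(grid_dims)

    # tree: root -> L1, L2 -> L1.1 ... depth = generations
    parent: dict[str, str | None] = {"root": None, "L1": "root", "L2": "root"}
    frontier = ["L1", "L2"]
    for _ in range(generations - 1):
        nxt = []
        for node in frontier:
            for i in (1, 2):
                child = f"{node}.{i}"
                parent[child] = node
                nxt.append(child)
        frontier = nxt

    # first-generation territories
    territory: dict[str, list[tuple[int, int, int]]] = {}
    if pattern == "layered":
        territory["L1"] = [p for p in positions if p[2] % 2 == 1]
        territory["L2"] = [p for p in positions if p[2] % 2 == 0]
    else:
        territory["L1"] = [p for p in positions if p[0] > 0]
        territory["L2"] = [p for p in positions if p[0] < 0]

    def split(posns, axis_order=(0, 1, 2)):
        # median split along the first axis with >1 distinct value
        for ax in axis_order:
            vals = sorted({p[ax] for p in posns})
            if len(vals) > 1:
                mid = vals[len(vals) // 2]
                a = [p for p in posns if p[ax] < mid]
                b = [p for p in posns if p[ax] >= mid]
                if a and b:
                    return a, b
        half = max(1, len(posns) // 2)
        return posns[:half], posns[half:]

    nodes_at = {1: ["L1", "L2"]}
    for g in range(2, generations + 1):
        nodes_at[g] = [f"{n}.{i}" for n in nodes_at[g - 1] for i in (1, 2)]
    for g in range(2, generations + 1):
        for node in nodes_at[g - 1]:
            if node not in territory:
                continue
            a, b = split(territory[node])
            territory[f"{node}.1"] = a
            territory[f"{node}.2"] = b

    leaf_nodes = nodes_at[generations]
    label = {}
    for node in leaf_nodes:
        first = node.split(".")[0]
        for p in territory.get(node, []):
            label[p] = first

    eem_sets: dict[str, set[str]] = {}
    all_nodes = [n for g in nodes_at.values() for n in g]
    for node in all_nodes:
        own = {f"eem_{node}_{i}" for i in range(eems_per_node)}
        par = parent[node]
        inherited = eem_sets.get(par, set()) if par != "root" else set()
        eem_sets[node] = inherited | own

    return parent, label, eem_sets


def _case_signature_weights(cfg: CohortConfig, tissue: str, rng) -> np.ndarray:
    base = np.asarray(cfg.signature_mix_by_tissue[tissue], dtype=float)
    if rng.random() < cfg.ros_presence_prob_by_tissue[tissue]:
        w = base * (1.0 - cfg.ros_weight)
        w[SIGNATURE_NAMES.index("SBS18")] += cfg.ros_weight
    else:
        w = base.copy()
        w[SIGNATURE_NAMES.index("SBS18")] = 0.0
        w = w / w.sum()
    return w


class _VariantFactory:
    """Allocates unique sites (chrom, pos, ref, alt, context)."""

    def __init__(self, rng, profile_matrix: np.ndarray):
        self.rng = rng
        self.profiles = profile_matrix  # 96 x 7
        self.used = set()

    def new_site(self, channel: int | None = None, indel: bool = False):
        while True:
            chrom = str(self.rng.integers(1, 23))
            pos = int(self.rng.integers(1, 100_000_000))
            if (chrom, pos) not in self.used:
                self.used.add((chrom, pos))
                break
        if indel:
            ref, alt, context = "AT", "A", ""
        elif channel is None:
            context, ref, alt = channel_to_context_alt(int(self.rng.integers(0, 96)))
        else:
            context, ref, alt = channel_to_context_alt(channel)
        vid = f"{chrom}:{pos}:{ref}:{alt}"
        return vid, chrom, pos, ref, alt, context

    def channels_for_mix(self, weights: np.ndarray, n: int) -> np.ndarray:
        p = self.profiles @ weights
        p = p / p.sum()
        return self.rng.choice(96, size=n, p=p)


def _truth_sharing(carrier_ccfs: dict[str, float]) -> str:
    clonal_all = all(c >= 1.0 for c in carrier_ccfs.values())
    if len(carrier_ccfs) >= 2:
        return "SC" if clonal_all else "SS"
    return "PC" if clonal_all else "PS"


def simulate_cohort(config: CohortConfig):
    """Generate (samples, variants, GroundTruth) for one cohort.

    Deterministic for a fixed config seed. The variant table is long-form,
    one row per (variant, sample-of-its-case) — non-carrier rows keep
    alt_count drawn at true VAF 0 so cross-sample genotyping sees depth.
    Artifact sites additionally span every case of the cohort.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    profiles = load_reference_signatures()[list(SIGNATURE_NAMES)].to_numpy()
    factory = _VariantFactory(rng, profiles)

    samples_rows = []
    var_meta = {}  # vid -> (chrom,pos,ref,alt,context,variant_type,gene,effect,case)
    truth_label = {}
    true_vaf_rows = []
    sharing_rows = []
    sig_weight_rows = {}
    clone_frac = {}
    lineage_parent: dict = {}
    lineage_label_rows = {}
    eem_sets: dict = {}

    # per-case carrier maps: case -> {vid: {sample: (vaf, ccf)}}
    case_carriers: dict[str, dict] = {}
    case_samples: dict[str, list[str]] = {}

    for ci in range(cfg.n_cases):
        case = f"CASE{ci+1:02d}"
        age = float(rng.uniform(*cfg.ages))
        carriers: dict[str, dict] = {}
        case_carriers[case] = carriers

        if cfg.design == "trio":
            roles = ["N1", "N2", "T"]
            tissues = [
                "BPH" if rng.random() < cfg.bph_prob_nontumor else "normal",
                "BPH" if rng.random() < cfg.bph_prob_nontumor else "normal",
                "PCA",
            ]
            ty = int(rng.integers(-2, 3))
            coords = [(2, ty, 2), (-2, -ty, 2), (2, ty, 3)]
        else:
            positions = grid_positions(cfg.grid_dims)
            roles = [f"A{i+1:02d}" for i in range(len(positions))]
            tissues = [
                "BPH" if rng.random() < cfg.bph_prob_nontumor else "normal"
                for _ in positions
            ]
            coords = positions

        sample_ids = [f"{case}_{r}" for r in roles]
        case_samples[case] = sample_ids

        for sid, role, tissue, (x, y, z) in zip(sample_ids, roles, tissues, coords):
            f = float(
                np.clip(
                    rng.normal(cfg.clone_fraction_by_tissue[tissue], cfg.clone_fraction_sd),
                    0.05,
                    0.95,
                )
            )
            clone_frac[sid] = f
            samples_rows.append(
                dict(
                    case_id=case,
                    sample_id=sid,
                    role=role,
                    tissue=tissue,
                    zone=zone_of(x, y),
                    x=x, y=y, z=z,
                    side="left" if x < 0 else ("right" if x > 0 else "mid"),
                    age=round(age, 1),
                    clonality=round(f, 4),
                    ploidy=2.0,
                    telomere_length=round(
                        float(rng.normal(cfg.telomere_mean_by_tissue[tissue], cfg.telomere_sd)), 3
                    ),
                    depth_mean=cfg.depth_mean,
                )
            )

            # private somatic mutations
            lam = (
                cfg.burden_intercept_by_tissue[tissue]
                + cfg.burden_slope_by_tissue[tissue] * age
            )
            n_mut = int(rng.poisson(lam))
            weights = _case_signature_weights(cfg, tissue, rng)
            sig_weight_rows[sid] = weights
            n_indel = int(rng.binomial(n_mut, cfg.indel_fraction))
            n_sbs = n_mut - n_indel
            channels = factory.channels_for_mix(weights, n_sbs)
            subclonal = rng.random(n_mut) < cfg.subclonal_fraction
            ccfs = np.where(
                subclonal, rng.uniform(*cfg.subclonal_ccf_range, size=n_mut), 1.0
            )
            n_driver = int(rng.poisson(cfg.driver_rate_by_tissue[tissue]))
            driver_idx = set(
                rng.choice(n_mut, size=min(n_driver, n_mut), replace=False).tolist()
            ) if n_mut else set()
            for i in range(n_mut):
                indel = i >= n_sbs
                vid, chrom, pos, ref, alt, ctx = factory.new_site(
                    channel=None if indel else int(channels[i]), indel=indel
                )
                gene, effect = "", ""
                if i in driver_idx:
                    pool = RTK_RAS_GENES if rng.random() < 0.4 else DRIVER_GENES
                    gene = pool[int(rng.integers(len(pool)))]
                    effect = "missense"
                var_meta[vid] = (
                    chrom, pos, ref, alt, ctx,
                    "indel" if indel else "SBS", gene, effect, case,
                )
                ccf = float(ccfs[i])
                truth_label[vid] = "somatic_subclonal" if ccf < 1.0 else "somatic_clonal"
                carriers[vid] = {sid: (ccf * f / 2.0, ccf)}

        # shared somatic mutations within the case
        mean_burden = np.mean(
            [
                cfg.burden_intercept_by_tissue[t] + cfg.burden_slope_by_tissue[t] * age
                for t in tissues
            ]
        )
        n_shared = int(rng.poisson(cfg.shared_fraction * mean_burden))
        for _ in range(n_shared):
            k = int(rng.integers(2, len(sample_ids) + 1)) if len(sample_ids) > 2 else 2
            k = min(k, 3) if cfg.design == "trio" else min(k, 4)
            members = rng.choice(len(sample_ids), size=k, replace=False)
            weights = sig_weight_rows[sample_ids[int(members[0])]]
            ch = int(factory.channels_for_mix(weights, 1)[0])
            vid, chrom, pos, ref, alt, ctx = factory.new_site(channel=ch)
            var_meta[vid] = (chrom, pos, ref, alt, ctx, "SBS", "", "", case)
            sub = rng.random() < cfg.subclonal_fraction
            entry = {}
            for m in members:
                sid = sample_ids[int(m)]
                ccf = float(rng.uniform(*cfg.subclonal_ccf_range)) if sub else 1.0
                entry[sid] = (ccf * clone_frac[sid] / 2.0, ccf)
            truth_label[vid] = "somatic_subclonal" if sub else "somatic_clonal"
            carriers[vid] = entry

        # EEMs on the embryonic lineage tree (grid design only)
        if cfg.design == "grid3d":
            parent, pos_label, node_eems = simulate_embryonic_lineage(
                cfg.grid_dims, cfg.eem_generations, cfg.eem_pattern, rng,
                eems_per_node=cfg.eems_per_node,
            )
            pos_to_sid = {p: sid for p, sid in zip(coords, sample_ids)}
            sid_label = {pos_to_sid[p]: lab for p, lab in pos_label.items()}
            # per-node carrier samples = union of positions under the node
            node_positions = _node_positions(node_eems, parent, pos_label, cfg)
            eem_vid_sets: dict[str, set] = {n: set() for n in node_eems}
            own_eems = {
                n: {e for e in node_eems[n]
                    if parent[n] == "root" or e not in node_eems[parent[n]]}
                for n in node_eems
            }
            for node, eids in sorted(own_eems.items()):
                for _ in sorted(eids):
                    ch = int(rng.integers(0, 96))
                    vid, chrom, pos, ref, alt, ctx = factory.new_site(channel=ch)
                    var_meta[vid] = (chrom, pos, ref, alt, ctx, "SBS", "", "", case)
                    truth_label[vid] = "eem"
                    tv = float(
                        np.clip(rng.normal(cfg.eem_mosaic_vaf, cfg.eem_vaf_sd), 0.25, 0.5)
                    )
                    entry = {}
                    for p in node_positions.get(node, set()):
                        sid = pos_to_sid[p]
                        entry[sid] = (tv, np.nan)
                    if entry:
                        carriers[vid] = entry
                    eem_vid_sets[node].add(vid)
            # nested variant-id sets along the tree
            closed: dict[str, set] = {}

            def close(n):
                if n in closed:
                    return closed[n]
                par = parent[n]
                base = set() if par in (None, "root") else close(par)
                closed[n] = base | eem_vid_sets.get(n, set())
                return closed[n]

            for n in node_eems:
                close(n)
            lineage_parent = {n: parent[n] for n in node_eems}
            eem_sets = closed
            for sid in sample_ids:
                lineage_label_rows[sid] = sid_label.get(sid, "absent")

        # truth sharing classes for somatic variants of this case
        for vid, entry in carriers.items():
            if truth_label[vid] in ("somatic_clonal", "somatic_subclonal"):
                sharing_rows.append(
                    dict(
                        case_id=case,
                        variant_id=vid,
                        truth_class=_truth_sharing({s: c for s, (v, c) in entry.items()}),
                        n_true_carriers=len(entry),
                    )
                )

    samples = pd.DataFrame(samples_rows)

    # inject confounders (germline per case, recurrent artifacts cohort-wide)
    germ_sites, art_sites = _confounder_sites(
        cfg, rng, factory, case_samples, var_meta, truth_label
    )
    for case, vids in germ_sites.items():
        for vid in vids:
            case_carriers[case][vid] = {
                sid: (0.5, np.nan) for sid in case_samples[case]
            }
    for vid, (tv, carrier_sids) in art_sites.items():
        for case, sids in case_samples.items():
            entry = {
                sid: (tv, np.nan) for sid in sids if sid in carrier_sids
            }
            case_carriers[case].setdefault(vid, {}).update(entry)

    # emit reads: one row per (variant, sample of its case)
    var_rows = []
    for case, sids in case_samples.items():
        vids = sorted(case_carriers[case])
        if not vids:
            continue
        nv, ns = len(vids), len(sids)
        vmat = np.zeros((nv, ns))
        for i, vid in enumerate(vids):
            entry = case_carriers[case][vid]
            for j, sid in enumerate(sids):
                if sid in entry:
                    vmat[i, j] = entry[sid][0]
        alt, depth = simulate_reads(vmat, cfg.depth_mean, rng)
        for i, vid in enumerate(vids):
            chrom, pos, ref, altb, ctx, vtype, gene, effect, vcase = var_meta[vid]
            entry = case_carriers[case][vid]
            for j, sid in enumerate(sids):
                var_rows.append(
                    (
                        case, sid, vid, chrom, pos, ref, altb, ctx,
                        int(alt[i, j]), int(depth[i, j]), vtype, 0.0, gene, effect,
                    )
                )
                if sid in entry:
                    true_vaf_rows.append(
                        dict(
                            variant_id=vid, sample_id=sid,
                            true_vaf=entry[sid][0], true_ccf=entry[sid][1],
                        )
                    )

    variants = pd.DataFrame(
        var_rows,
        columns=[
            "case_id", "sample_id", "variant_id", "chrom", "pos", "ref", "alt",
            "context", "alt_count", "total_depth", "variant_type",
            "population_af", "gene", "effect",
        ],
    )
    variants["vaf"] = variants["alt_count"] / variants["total_depth"]
    variants["filter_flags"] = ""

    truth = GroundTruth(
        variant_labels=pd.DataFrame(
            {
                "variant_id": list(truth_label),
                "label": [truth_label[v] for v in truth_label],
                "case_id": [var_meta[v][8] if v in var_meta else "" for v in truth_label],
            }
        ).set_index("variant_id"),
        true_vaf=pd.DataFrame(true_vaf_rows),
        clone_fraction=pd.Series(clone_frac, name="clone_fraction"),
        signature_weights=pd.DataFrame.from_dict(
            sig_weight_rows, orient="index", columns=list(SIGNATURE_NAMES)
        ),
        sharing_class=pd.DataFrame(sharing_rows),
        lineage_parent=lineage_parent,
        lineage_label=pd.Series(lineage_label_rows, name="lineage", dtype=object),
        eem_sets=eem_sets,
    )
    return samples, variants, truth


def _node_positions(node_eems, parent, pos_label, cfg):
    """Positions under each lineage node, derived from leaf territories."""
    # leaf territory = positions whose deepest-node path includes the node.
    # pos_label maps position -> first-generation label; recompute full paths
    # by re-running the deterministic territory construction.
    # Simpler: a node's positions are those whose first-gen label is the
    # node's first-generation ancestor AND which fall in the node's split —
    # we reconstruct by splitting again with the same deterministic rule.
    return _territories(cfg, pos_label)


def _territories(cfg, pos_label):
    positions = sorted(pos_label)
    terr = {
        "L1": [p for p in positions if pos_label[p] == "L1"],
        "L2": [p for p in positions if pos_label[p] == "L2"],
    }

    def split(posns):
        for ax in (0, 1, 2):
            vals = sorted({p[ax] for p in posns})
            if len(vals) > 1:
                mid = vals[len(vals) // 2]
                a = [p for p in posns if p[ax] < mid]
                b = [p for p in posns if p[ax] >= mid]
                if a and b:
                    return a, b
        half = max(1, len(posns) // 2)
        return posns[:half], posns[half:]

    frontier = ["L1", "L2"]
    for _ in range(cfg.eem_generations - 1):
        nxt = []
        for node in frontier:
            a, b = split(terr[node])
            terr[f"{node}.1"] = a
            terr[f"{node}.2"] = b
            nxt += [f"{node}.1", f"{node}.2"]
        frontier = nxt
    return {n: set(ps) for n, ps in terr.items()}


def _confounder_sites(cfg, rng, factory, case_samples, var_meta, truth_label):
    """Allocate germline (per case) and recurrent artifact (cohort) sites."""
    germ: dict[str, list[str]] = {}
    for case in case_samples:
        vids = []
        for _ in range(cfg.n_germline):
            ch = int(rng.integers(0, 96))
            vid, chrom, pos, ref, alt, ctx = factory.new_site(channel=ch)
            var_meta[vid] = (chrom, pos, ref, alt, ctx, "SBS", "", "", case)
            truth_label[vid] = "germline"
            vids.append(vid)
        germ[case] = vids

    all_sids = [s for sids in case_samples.values() for s in sids]
    art: dict[str, tuple[float, set]] = {}
    for _ in range(cfg.n_artifact_sites):
        ch = int(rng.integers(0, 96))
        vid, chrom, pos, ref, alt, ctx = factory.new_site(channel=ch)
        var_meta[vid] = (chrom, pos, ref, alt, ctx, "SBS", "", "", "cohort")
        truth_label[vid] = "artifact"
        tv = float(rng.uniform(*cfg.artifact_vaf_range))
        k = max(1, int(round(cfg.artifact_carrier_frac * len(all_sids))))
        carrier_sids = set(
            np.asarray(all_sids)[rng.choice(len(all_sids), size=k, replace=False)]
        )
        art[vid] = (tv, carrier_sids)
    return germ, art


def inject_confounders(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    n_germline: int,
    n_artifact_sites: int,
    seed,
    artifact_vaf_range=(0.01, 0.05),
    artifact_carrier_frac=0.9,
):
    """Append germline and recurrent-artifact rows to an existing table.

    Germline variants appear in every sample of each case at true VAF 0.5;
    artifact sites recur across ``artifact_carrier_frac`` of all cohort
    samples at a site-specific low VAF. Returns (variants, labels) where
    labels maps the new variant_ids to their ground-truth class.
    """
    if n_germline < 0 or n_artifact_sites < 0:
        raise ValueError("confounder counts must be non-negative")
    if n_germline == 0 and n_artifact_sites == 0:
        return variants, pd.DataFrame(columns=["variant_id", "label"])
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    profiles = load_reference_signatures()[list(SIGNATURE_NAMES)].to_numpy()
    factory = _VariantFactory(rng, profiles)
    for vid in variants["variant_id"].unique():
        chrom, pos = vid.split(":")[:2]
        factory.used.add((chrom, int(pos)))

    depth_mean = (
        samples["depth_mean"].iloc[0] if "depth_mean" in samples.columns else 16.0
    )
    rows, labels = [], []

    def emit(vid, chrom, pos, ref, alt, ctx, case, sid, tv):
        a, d = simulate_reads(np.array([tv]), depth_mean, rng)
        rows.append(
            dict(
                case_id=case, sample_id=sid, variant_id=vid, chrom=chrom, pos=pos,
                ref=ref, alt=alt, context=ctx, alt_count=int(a[0]),
                total_depth=int(d[0]), variant_type="SBS", population_af=0.0,
                gene="", effect="", vaf=float(a[0] / d[0]), filter_flags="",
            )
        )

    for case, grp in samples.groupby("case_id", sort=True):
        for _ in range(n_germline):
            vid, chrom, pos, ref, alt, ctx = factory.new_site(
                channel=int(rng.integers(0, 96))
            )
            labels.append(dict(variant_id=vid, label="germline"))
            for sid in grp["sample_id"]:
                emit(vid, chrom, pos, ref, alt, ctx, case, sid, 0.5)

    all_samples = samples[["case_id", "sample_id"]].to_numpy()
    for _ in range(n_artifact_sites):
        vid, chrom, pos, ref, alt, ctx = factory.new_site(
            channel=int(rng.integers(0, 96))
        )
        labels.append(dict(variant_id=vid, label="artifact"))
        tv = float(rng.uniform(*artifact_vaf_range))
        k = max(1, int(round(artifact_carrier_frac * len(all_samples))))
        idx = rng.choice(len(all_samples), size=k, replace=False)
        carrier = set(all_samples[idx, 1])
        for case, sid in all_samples:
            emit(vid, chrom, pos, ref, alt, ctx, case, sid, tv if sid in carrier else 0.0)

    out = pd.concat([variants, pd.DataFrame(rows)], ignore_index=True)
    return out, pd.DataFrame(labels)
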
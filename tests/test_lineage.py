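"""EEM detection rules, two-state ML tree vs brute-force oracle, lineage
assignment and layered/mixed spatial pattern calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clonmosaic.lineage import (
    PhyloTree,
    analyze_case_lineage,
    assign_lineages,
    build_tree,
    classify_spatial_pattern,
    detect_eems,
    _enumerate_topologies,
)
from clonmosaic.synthetic import simulate_cohort

from conftest import small_grid_config


def case_table(rows):
    df = pd.DataFrame(rows)
    df["case_id"] = "C1"
    df["vaf"] = df["alt_count"] / df["total_depth"]
    return df


class TestDetectEems:
    @staticmethod
    def table(carrier_map, n_samples=10, depth=30):
        rows = []
        sids = [f"s{i}" for i in range(n_samples)]
        for vid, (carriers, vaf) in carrier_map.items():
            for sid in sids:
                alt = int(round(vaf * depth)) if sid in carriers else 0
                rows.append(
                    dict(sample_id=sid, variant_id=vid, alt_count=alt,
                         total_depth=depth)
                )
        return case_table(rows)

    def test_high_vaf_multisample_mosaic_is_eem(self):
        df = self.table({"v1": ({"s0", "s1", "s2", "s3"}, 0.4)})
        out = detect_eems(df)
        assert list(out["variant_id"]) == ["v1"]
        assert out.iloc[0]["n_carriers"] == 4

    def test_two_carriers_is_not_an_eem(self):
        df = self.table({"v1": ({"s0", "s1"}, 0.4)})
        assert len(detect_eems(df)) == 0

    def test_low_median_vaf_is_not_an_eem(self):
        df = self.table({"v1": ({"s0", "s1", "s2", "s3", "s4"}, 0.05)})
        assert len(detect_eems(df)) == 0

    def test_near_universal_het_sharing_treated_as_germline(self):
        df = self.table({"v1": (set(f"s{i}" for i in range(10)), 0.5)})
        assert len(detect_eems(df)) == 0

    def test_requires_four_samples(self):
        df = self.table({"v1": ({"s0"}, 0.4)}, n_samples=3)
        with pytest.raises(ValueError):
            detect_eems(df)


def brute_force_loglik(adj, presence, t):
    """Oracle: sum over all internal-state assignments, explicit transition
    products — independent of the pruning implementation."""
    p = 0.5 * (1 - np.exp(-2 * t))
    P = np.array([[1 - p, p], [p, 1 - p]])
    internals = [n for n in adj if isinstance(n, int)]
    edges = {
        tuple(sorted((u, v), key=str))
        for u, nbrs in adj.items() for v in nbrs
    }
    data = presence.to_numpy(dtype=int)
    idx = {s: i for i, s in enumerate(presence.index)}
    total = 0.0
    for char in range(data.shape[1]):
        lik = 0.0
        for states in itertools.product([0, 1], repeat=len(internals)):
            smap = dict(zip(internals, states))
            for leaf in presence.index:
                smap[leaf] = data[idx[leaf], char]
            prob = 0.5  # stationary at an arbitrary root; model is reversible
            root = internals[0]
            # orient edges away from root by BFS
            seen = {root}
            stack = [root]
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if v in seen:
                        continue
                    seen.add(v)
                    prob *= P[smap[u], smap[v]]
                    if isinstance(v, int):
                        stack.append(v)
            lik += prob
        total += np.log(lik)
    return total


class TestBuildTree:
    def test_four_leaf_topology_matches_exhaustive_oracle(self):
        pres = pd.DataFrame(
            {"m1": [1, 1, 0, 0], "m2": [0, 0, 1, 1], "m3": [1, 0, 0, 0]},
            index=list("ABCD"),
        )
        tree = build_tree(pres)
        # the only nontrivial split of ((A,B),(C,D)) not containing A
        assert tree.splits() == {frozenset({"C", "D"})}

    def test_pruning_likelihood_matches_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 6))
            leaves = [f"t{i}" for i in range(n)]
            pres = pd.DataFrame(
                rng.integers(0, 2, size=(n, 8)), index=leaves
            )
            if (pres.to_numpy() == pres.to_numpy()[0]).all():
                continue
            from clonmosaic.lineage import _pruning_loglik

            for adj in _enumerate_topologies(leaves)[:5]:
                t = float(rng.uniform(0.05, 1.0))
                assert _pruning_loglik(adj, pres, t) == pytest.approx(
                    brute_force_loglik(adj, pres, t), rel=1e-9
                )

    def test_identical_rows_become_sisters(self):
        pres = pd.DataFrame(
            {"m1": [1, 1, 0, 0, 0], "m2": [0, 0, 1, 1, 1], "m3": [0, 0, 1, 1, 0]},
            index=list("ABCDE"),
        )
        tree = build_tree(pres)
        assert frozenset({"C", "D"}) in tree.splits() or frozenset({"A", "B"}) in tree.splits()

    def test_all_identical_rows_give_star_tree_with_warning(self):
        pres = pd.DataFrame({"m1": [1, 1, 1], "m2": [0, 0, 0]}, index=list("ABC"))
        with pytest.warns(UserWarning):
            tree = build_tree(pres)
        assert tree.star

    def test_noise_free_eight_leaf_recovery(self, rng):
        # characters generated down a known fully resolved topology
        leaves = list("ABCDEFGH")
        true_splits = [
            {"A", "B"}, {"A", "B", "C"}, {"A", "B", "C", "D"},
            {"E", "F"}, {"G", "H"},
        ]
        cols = {}
        for i in range(120):
            grp = true_splits[i % len(true_splits)] if i % 3 else {
                leaves[int(rng.integers(8))]
            }
            cols[f"m{i}"] = [1 if l in grp else 0 for l in leaves]
        pres = pd.DataFrame(cols, index=leaves)
        tree = build_tree(pres)
        ref = tree.leaves[0]
        want = {
            frozenset(set(leaves) - s) if ref in s else frozenset(s)
            for s in true_splits
        }
        assert tree.splits() == want  # Robinson-Foulds distance 0

    def test_newick_roundtrips_through_skbio(self):
        import io as _io

        from skbio import TreeNode

        pres = pd.DataFrame(
            {"m1": [1, 1, 0, 0], "m2": [0, 0, 1, 1]}, index=list("ABCD")
        )
        tree = build_tree(pres)
        parsed = TreeNode.read(_io.StringIO(tree.newick()))
        assert {t.name for t in parsed.tips()} == set("ABCD")


class TestAssignLineages:
    @staticmethod
    def eem_df(sets):
        return pd.DataFrame(
            [
                dict(variant_id=vid, n_carriers=len(c), median_vaf=0.4,
                     carriers=frozenset(c))
                for vid, c in sets.items()
            ]
        )

    def test_two_disjoint_clades_partition_samples(self):
        sids = [f"s{i}" for i in range(10)]
        eems = self.eem_df(
            {"e1": sids[:4], "e2": sids[4:8], "e1b": sids[:2]}
        )
        model = assign_lineages(eems, sids)
        labs = model.labels
        assert set(labs[sids[:4]]) == {"L1"}
        assert set(labs[sids[4:8]]) == {"L2"}
        assert set(labs[sids[8:]]) == {"absent"}
        assert not model.inconsistent

    def test_three_exclusive_clades_get_three_labels(self):
        sids = [f"s{i}" for i in range(9)]
        eems = self.eem_df({"a": sids[:3], "b": sids[3:6], "c": sids[6:]})
        model = assign_lineages(eems, sids)
        assert model.labels.nunique() == 3

    def test_no_eems_all_absent(self):
        model = assign_lineages(self.eem_df({}), ["s0", "s1"])
        assert (model.labels == "absent").all()

    def test_heavily_overlapping_founders_flagged_inconsistent(self):
        sids = [f"s{i}" for i in range(8)]
        eems = self.eem_df({"a": sids[:5], "b": sids[2:8]})
        model = assign_lineages(eems, sids, containment_join=0.95)
        assert model.inconsistent


class TestSpatialPattern:
    @staticmethod
    def grid_coords(nz=4, per_layer=8):
        rows = []
        for z in range(1, nz + 1):
            for i in range(per_layer):
                x = (-1) ** i * (i // 2 + 1)
                rows.append(dict(x=x, y=(i % 3) - 1, z=z))
        return pd.DataFrame(rows, index=[f"s{i}" for i in range(nz * per_layer)])

    def test_alternating_pure_layers_called_layered(self):
        coords = self.grid_coords()
        labels = pd.Series(
            ["L1" if z % 2 else "L2" for z in coords["z"]], index=coords.index
        )
        pattern, scores = classify_spatial_pattern(labels, coords)
        assert pattern == "layered"
        assert scores["vertical"] == pytest.approx(1.0)

    def test_lateral_split_within_layers_called_mixed(self):
        coords = self.grid_coords()
        labels = pd.Series(
            ["L1" if x > 0 else "L2" for x in coords["x"]], index=coords.index
        )
        pattern, scores = classify_spatial_pattern(labels, coords)
        assert pattern == "mixed"
        assert scores["lateral"] == pytest.approx(1.0)

    def test_single_lineage_indeterminate_without_error(self):
        coords = self.grid_coords()
        labels = pd.Series("L1", index=coords.index)
        pattern, _ = classify_spatial_pattern(labels, coords)
        assert pattern == "indeterminate"

    def test_random_labels_mostly_indeterminate(self, rng):
        coords = pd.DataFrame(
            {
                "x": rng.integers(-2, 3, 100),
                "y": rng.integers(-2, 3, 100),
                "z": rng.integers(1, 5, 100),
            },
            index=[f"s{i}" for i in range(100)],
        )
        calls = []
        for _ in range(100):
            labels = pd.Series(rng.choice(["L1", "L2"], 100), index=coords.index)
            calls.append(classify_spatial_pattern(labels, coords)[0])
        assert calls.count("indeterminate") >= 90


class TestEndToEndLineage:
    @pytest.mark.parametrize("pattern", ["layered", "mixed"])
    def test_generated_pattern_recovered(self, pattern):
        cfg = small_grid_config(seed=4, pattern=pattern)
        samples, variants, truth = simulate_cohort(cfg)
        model = analyze_case_lineage(variants, samples, build_phylogeny=False)
        assert model.pattern == pattern
        # labels match truth up to naming: same partition
        pred = model.labels[model.labels != "absent"]
        want = truth.lineage_label.reindex(pred.index)
        table = pd.crosstab(pred, want)
        assert (table.max(axis=1) == table.sum(axis=1)).all()

    def test_detected_eem_sets_nest_along_truth_tree(self, grid_cohort):
        samples, variants, truth = grid_cohort
        eems = detect_eems(variants)
        carriers = dict(zip(eems["variant_id"], eems["carriers"]))
        label_of = truth.variant_labels["label"]
        true_eems = [v for v in carriers if label_of.get(v) == "eem"]
        # eem_sets are closed under inheritance: the owning node is the
        # shallowest (earliest-generation) node carrying the variant
        node_of = {}
        for node in sorted(truth.eem_sets, key=len):
            for vid in truth.eem_sets[node]:
                node_of.setdefault(vid, node)
        for a in true_eems:
            for b in true_eems:
                ca, cb = carriers[a], carriers[b]
                if ca < cb:  # strict subset -> a's node below b's node
                    assert node_of[a].startswith(node_of[b])
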
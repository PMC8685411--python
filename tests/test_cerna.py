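import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet import build_network, call_de, coexpression_pairs, expression_filter, \
    find_triplets
from cernet.cerna import FilterConfig, TargetMap, whitelist_filter

from conftest import make_matrix


class TestExpressionFilter:
    def test_mean_and_fraction_rules(self):
        m = make_matrix([
            [0.6, 0.6, 0.6, 0.1, 0.1, 0.1],   # A mean 0.6 > 0.5, expressed 6/6 -> kept
            [0.4, 0.4, 0.4, 0.45, 0.45, 0.45],  # both means <= 0.5 -> removed
            [3.0, 0.0, 0.0, 0.0, 0.0, 0.0],   # A mean 1.0 but expressed 1/6 -> removed
        ])
        assert expression_filter(m) == {"f1"}

    def test_toy_matrix_exactly_four_pass(self):
        rows = {
            "keep1": [1, 1, 1, 0, 1, 1],
            "keep2": [0.0, 0.0, 0.1, 2, 2, 2],
            "keep3": [5, 5, 5, 5, 5, 5],
            "keep4": [0.6, 0.7, 0.8, 0.2, 0.1, 0.0],
            "lowmean": [0.3, 0.3, 0.3, 0.3, 0.3, 0.3],
            "sparse": [9, 0, 0, 9, 0, 0],
            "zero": [0, 0, 0, 0, 0, 0],
            "edge_mean": [0.5, 0.5, 0.5, 0.5, 0.5, 0.5],   # mean not strictly > 0.5
            "edge_frac": [1, 1, 1, 0, 0, 0],               # expressed 3/6 < 2/3
            "lowA_highH": [0.1, 0.1, 0.1, 0.9, 0.9, 0.9],  # H group rescues: kept? yes
        }
        m = make_matrix(list(rows.values()), features=list(rows))
        # manual evaluation: keep1..keep4 plus lowA_highH satisfy both rules
        assert expression_filter(m) == {"keep1", "keep2", "keep3", "keep4", "lowA_highH"}

    def test_empty_matrix_gives_empty_set(self):
        m = make_matrix(np.empty((0, 6)))
        assert expression_filter(m) == set()

    def test_monotone_in_min_group_mean(self, default_sim):
        _, matrices, _ = default_sim
        m = matrices["mRNA"]
        previous = expression_filter(m, FilterConfig(min_group_mean=0.1))
        for thr in (0.5, 2.0, 10.0, 100.0):
            current = expression_filter(m, FilterConfig(min_group_mean=thr))
            assert current <= previous
            previous = current


def _toy_inputs():
    """m1 targets L1 and G1; L1 and G1 strongly DE and coexpressed."""
    lnc = make_matrix([[8, 9, 10, 1, 1.5, 2]], rna_class="lncRNA", features=["L1"])
    mrna = make_matrix([[16, 18, 20, 2, 3, 4]], rna_class="mRNA", features=["G1"])
    de = {"mRNA": call_de(mrna), "lncRNA": call_de(lnc)}
    pairs = coexpression_pairs(de["mRNA"], de["lncRNA"], mrna, lnc)
    matrices = {"mRNA": mrna, "lncRNA": lnc}
    return de, pairs, matrices


class TestFindTriplets:
    def test_empty_target_map_yields_nothing(self):
        de, pairs, matrices = _toy_inputs()
        targets = TargetMap(edges=pd.DataFrame(columns=["mirna", "target", "target_class"]))
        assert len(find_triplets(de, pairs, targets, matrices=matrices)) == 0

    def test_single_shared_mirna_gives_one_triplet(self):
        de, pairs, matrices = _toy_inputs()
        targets = TargetMap(edges=pd.DataFrame(
            [("m1", "L1", "lncRNA"), ("m1", "G1", "mRNA")],
            columns=["mirna", "target", "target_class"],
        ))
        out = find_triplets(de, pairs, targets, matrices=matrices)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["sponge"], row["mirna"], row["mrna"]) == ("L1", "m1", "G1")
        assert row["mirna_direction"] == "unknown"  # no miRNA DE table supplied
        assert row["r"] > 0

    def test_planted_triplets_recovered_exactly(self, default_sim):
        from cernet import simulate_target_map

        config, matrices, truth = default_sim
        de = {cls: call_de(m) for cls, m in matrices.items()}
        frames = [
            coexpression_pairs(de["mRNA"], de[cls], matrices["mRNA"], matrices[cls])
            for cls in ("lncRNA", "circRNA")
        ]
        pairs = pd.concat(frames, ignore_index=True)
        targets = simulate_target_map(config, truth)
        out = find_triplets(de, pairs, targets, matrices=matrices)
        got = set(zip(out["sponge"], out["mirna"], out["mrna"]))
        want = {(t.sponge, t.mirna, t.mrna) for t in truth.triplets}
        assert want <= got
        # planted miRNAs are DE down, so their direction is annotated
        planted = out[out["mirna"].isin({t.mirna for t in truth.triplets})]
        assert (planted["mirna_direction"] == "down").all()

    def test_matches_brute_force_enumerator_on_small_instance(self):
        """Audit on a <=50-feature instance: every emitted triplet, and only
        those, passes DE + filters + shared-miRNA checks re-derived from raw
        inputs with scipy's pearsonr."""
        rng = np.random.default_rng(42)
        n_l, n_g, n_mi = 12, 18, 8
        lnc = make_matrix(2.0 ** rng.normal(3, 2, (n_l, 6)), rna_class="lncRNA",
                          features=[f"L{i}" for i in range(n_l)])
        mrna = make_matrix(2.0 ** rng.normal(3, 2, (n_g, 6)), rna_class="mRNA",
                           features=[f"G{i}" for i in range(n_g)])
        edges = pd.DataFrame(
            [(f"m{k}", f"L{rng.integers(n_l)}", "lncRNA") for k in range(n_mi) for _ in range(3)]
            + [(f"m{k}", f"G{rng.integers(n_g)}", "mRNA") for k in range(n_mi) for _ in range(4)],
            columns=["mirna", "target", "target_class"],
        ).drop_duplicates().reset_index(drop=True)
        targets = TargetMap(edges=edges)
        de = {"mRNA": call_de(mrna), "lncRNA": call_de(lnc)}
        pairs = coexpression_pairs(de["mRNA"], de["lncRNA"], mrna, lnc)
        matrices = {"mRNA": mrna, "lncRNA": lnc}
        out = find_triplets(de, pairs, targets, matrices=matrices)
        got = set(zip(out["sponge"], out["mirna"], out["mrna"]))

        # independent enumeration over all (miRNA, lncRNA, mRNA) combinations
        cfg = FilterConfig()
        expected = set()
        passing = {cls: set(t.loc[t["passes"], "feature"]) for cls, t in de.items()}
        for mi in edges["mirna"].unique():
            tgt = set(edges.loc[edges["mirna"] == mi, "target"])
            for sponge in [f"L{i}" for i in range(n_l)]:
                for gene in [f"G{i}" for i in range(n_g)]:
                    if sponge not in tgt or gene not in tgt:
                        continue
                    if sponge not in passing["lncRNA"] or gene not in passing["mRNA"]:
                        continue
                    sv = lnc.values.loc[sponge].to_numpy()
                    gv = mrna.values.loc[gene].to_numpy()
                    for vec, mat in ((sv, lnc), (gv, mrna)):
                        means = [vec[:3].mean(), vec[3:].mean()]
                        if max(means) <= cfg.min_group_mean:
                            break
                        if (vec > 0).sum() / 6 < cfg.min_expressed_fraction:
                            break
                    else:
                        r, p = stats.pearsonr(np.log2(sv + 0.01), np.log2(gv + 0.01))
                        if r > 0 and abs(r) >= 0.8 and p < 0.05:
                            expected.add((sponge, mi, gene))
        assert got == expected

    def test_all_triplet_members_pass_expression_filter(self, default_sim):
        from cernet import simulate_target_map

        config, matrices, truth = default_sim
        de = {cls: call_de(m) for cls, m in matrices.items()}
        pairs = pd.concat(
            [coexpression_pairs(de["mRNA"], de[cls], matrices["mRNA"], matrices[cls])
             for cls in ("lncRNA", "circRNA")], ignore_index=True)
        targets = simulate_target_map(config, truth)
        out = find_triplets(de, pairs, targets, matrices=matrices)
        kept = {cls: expression_filter(m) for cls, m in matrices.items()}
        for row in out.itertuples(index=False):
            assert row.sponge in kept[row.sponge_class]
            assert row.mrna in kept["mRNA"]


class TestNetwork:
    def test_empty_triplets_empty_network(self):
        net = build_network(pd.DataFrame(columns=[
            "sponge", "sponge_class", "mirna", "mrna", "r", "p",
            "sponge_direction", "mrna_direction", "mirna_direction"]))
        assert net.summary["n_triplets"] == 0
        assert net.summary["n_edges"] == 0

    def test_shared_mirna_node_counts(self):
        trips = pd.DataFrame(
            [("L1", "lncRNA", "m1", "G1", 0.9, 0.01, "up", "up", "unknown"),
             ("L2", "lncRNA", "m1", "G2", 0.9, 0.01, "up", "up", "unknown")],
            columns=["sponge", "sponge_class", "mirna", "mrna", "r", "p",
                     "sponge_direction", "mrna_direction", "mirna_direction"])
        s = build_network(trips).summary
        assert (s["n_sponges"], s["n_miRNAs"], s["n_mRNAs"]) == (2, 1, 2)

    def test_counts_equal_brute_force_set_cardinalities(self, default_sim):
        rng = np.random.default_rng(3)
        trips = pd.DataFrame(
            [(f"S{rng.integers(6)}", "circRNA", f"m{rng.integers(4)}",
              f"G{rng.integers(5)}", 0.9, 0.01, "up", "down", "unknown")
             for _ in range(15)],
            columns=["sponge", "sponge_class", "mirna", "mrna", "r", "p",
                     "sponge_direction", "mrna_direction", "mirna_direction"])
        s = build_network(trips).summary
        assert s["n_sponges"] == trips["sponge"].nunique()
        assert s["n_miRNAs"] == trips["mirna"].nunique()
        assert s["n_mRNAs"] == trips["mrna"].nunique()
        assert s["n_triplets"] == len(trips)

    def test_tripartite_roles(self):
        trips = pd.DataFrame(
            [("L1", "lncRNA", "m1", "G1", 0.9, 0.01, "up", "up", "down")],
            columns=["sponge", "sponge_class", "mirna", "mrna", "r", "p",
                     "sponge_direction", "mrna_direction", "mirna_direction"])
        g = build_network(trips).graph
        for u, v, d in g.edges(data=True):
            kinds = {g.nodes[u]["kind"], g.nodes[v]["kind"]}
            if d["interaction"].startswith("mirna"):
                assert "miRNA" in kinds
            else:
                assert "miRNA" not in kinds

    def test_whitelist_filter(self):
        trips = pd.DataFrame(
            [("L1", "lncRNA", "m1", "G1", 0.9, 0.01, "up", "up", "unknown"),
             ("L2", "lncRNA", "m2", "G2", 0.9, 0.01, "up", "up", "unknown")],
            columns=["sponge", "sponge_class", "mirna", "mrna", "r", "p",
                     "sponge_direction", "mrna_direction", "mirna_direction"])
        assert list(whitelist_filter(trips, {"G2"})["sponge"]) == ["L2"]
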
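"""Orthology, correlation, enrichment, Venn and network assembly."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import graftmobile as gm
from graftmobile import delta
from graftmobile.integrate import (
    EDGE_DEG_DIM,
    EDGE_MOBILE_DEG,
    best_hit_orthology,
    build_network,
    correlate_deg_dim,
    pathway_enrichment,
    to_networkx,
    venn_overlap,
    write_sif,
)


class TestBestHitOrthology:
    def test_identical_pair_among_unrelated(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        a = {"a1": "ACGTACGTACGTACGTACGT", "a2": "".join(rng.choice(bases, 20))}
        b = {"b1": "ACGTACGTACGTACGTACGT", "b2": "".join(rng.choice(bases, 20))}
        out = best_hit_orthology(a, b)
        assert ("a1", "b1") in set(zip(out["id_a"], out["id_b"]))

    def test_recovers_generator_pair_map(self, small_dataset):
        out = best_hit_orthology(
            small_dataset.references["Csa"], small_dataset.references["Cmo"]
        )
        got = list(zip(out["id_a"], out["id_b"]))
        expected = list(
            small_dataset.pair_map.sort_values("id_a").itertuples(index=False, name=None)
        )
        assert got == expected

    def test_duplicate_best_hits_keep_higher_score(self):
        # a1 is an exact match to b1; a2 is a one-substitution match to the same b1
        seq = "ACGTACGTACGTACGTACGT"
        a = {"a1": seq, "a2": seq[:-1] + "C"}
        b = {"b1": seq}
        out = best_hit_orthology(a, b)
        assert list(zip(out["id_a"], out["id_b"])) == [("a1", "b1")]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            best_hit_orthology({}, {"b": "ACGT"})


class TestCorrelateDegDim:
    def test_planted_pairs_recovered(self, small_dataset, gene_contrasts, metabolite_contrasts):
        edges = correlate_deg_dim(gene_contrasts, metabolite_contrasts)
        got = {(r.gene, r.metabolite, r.sign) for r in edges.itertuples(index=False)}
        assert small_dataset.truth.correlation_truth <= got
        planted = {
            (g, m) for (g, m, _) in small_dataset.truth.correlation_truth
        }
        for r in edges.itertuples(index=False):
            if (r.gene, r.metabolite) in planted:
                assert abs(r.cor) == pytest.approx(1.0, abs=1e-12)

    def test_threshold_excludes_moderate_correlation(self):
        genes = pd.DataFrame({"k1": [1.0], "k2": [2.0], "k3": [3.0], "k4": [4.0]}, index=["g"])
        mets = pd.DataFrame({"k1": [1.0], "k2": [3.0], "k3": [2.0], "k4": [4.0]}, index=["m"])
        r = np.corrcoef(genes.loc["g"], mets.loc["m"])[0, 1]
        assert abs(r) < 0.95
        assert correlate_deg_dim(genes, mets).empty

    def test_min_points_enforced(self):
        genes = pd.DataFrame({"k1": [1.0], "k2": [2.0]}, index=["g"])
        mets = pd.DataFrame({"k1": [1.0], "k2": [2.0]}, index=["m"])
        assert correlate_deg_dim(genes, mets, min_points=4).empty
        assert len(correlate_deg_dim(genes, mets, min_points=2)) == 1

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(13)
        keys = [f"k{i}" for i in range(8)]
        genes = pd.DataFrame(rng.normal(size=(50, 8)), columns=keys,
                             index=[f"g{i}" for i in range(50)])
        mets = pd.DataFrame(rng.normal(size=(30, 8)), columns=keys,
                            index=[f"m{i}" for i in range(30)])
        threshold = 0.5
        edges = correlate_deg_dim(genes, mets, threshold=threshold)
        got = {(r.gene, r.metabolite): r.cor for r in edges.itertuples(index=False)}
        expected = {}
        for g in genes.index:
            for m in mets.index:
                r = np.corrcoef(genes.loc[g], mets.loc[m])[0, 1]
                if abs(r) >= threshold:
                    expected[(g, m)] = r
        assert set(got) == set(expected)
        for pair, r in expected.items():
            assert got[pair] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_pairs_skipped(self):
        genes = pd.DataFrame({"k1": [1.0], "k2": [1.0], "k3": [1.0], "k4": [1.0]}, index=["g"])
        mets = pd.DataFrame({"k1": [1.0], "k2": [2.0], "k3": [3.0], "k4": [4.0]}, index=["m"])
        assert correlate_deg_dim(genes, mets).empty


def hypergeom_tail(hits, bg_size, bg_hits, set_size):
    """Closed-form upper tail by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(hits, min(bg_hits, set_size) + 1):
        total += (
            math.comb(bg_hits, x)
            * math.comb(bg_size - bg_hits, set_size - x)
            / math.comb(bg_size, set_size)
        )
    return total


class TestPathwayEnrichment:
    def test_enriched_pathway_ranks_first_with_closed_form_p(self):
        background = {f"g{i}" for i in range(500)}
        pathway_members = [f"g{i}" for i in range(10)]
        feature_set = set(pathway_members) | {"g100", "g101"}  # 10 of 12 hits
        rows = [("g%d" % i, "mapP") for i in range(10)]
        rows += [(f"g{i}", "mapQ") for i in range(50, 90)]
        annotation = pd.DataFrame(rows, columns=["feature", "pathway"])
        out = pathway_enrichment(feature_set, annotation, background)
        assert out.iloc[0]["pathway"] == "mapP"
        expected = hypergeom_tail(10, 500, 10, 12)
        assert out.iloc[0]["p"] == pytest.approx(expected, abs=1e-12)

    def test_set_equals_background_gives_p_one(self):
        background = {f"g{i}" for i in range(20)}
        annotation = pd.DataFrame(
            [(f"g{i}", "mapA") for i in range(5)], columns=["feature", "pathway"]
        )
        out = pathway_enrichment(set(background), annotation, background)
        assert np.allclose(out["p"], 1.0)

    def test_zero_hit_pathway_has_p_one(self):
        background = {f"g{i}" for i in range(20)}
        annotation = pd.DataFrame(
            [(f"g{i}", "mapA") for i in range(10, 15)], columns=["feature", "pathway"]
        )
        out = pathway_enrichment({"g0", "g1"}, annotation, background)
        row = out[out["pathway"] == "mapA"].iloc[0]
        assert row["hits"] == 0
        assert row["p"] == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pathway_enrichment(set(), pd.DataFrame(columns=["feature", "pathway"]), {"g"})

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(2)
        background = {f"g{i}" for i in range(200)}
        rows = [
            (f"g{int(i)}", f"map{j}")
            for j in range(6)
            for i in rng.choice(200, size=25, replace=False)
        ]
        annotation = pd.DataFrame(rows, columns=["feature", "pathway"])
        feature_set = {f"g{i}" for i in range(30)}
        out = pathway_enrichment(feature_set, annotation, background)
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert out["p"].is_monotonic_increasing


class TestVenn:
    def test_two_set_intersection(self):
        out = venn_overlap([{"a", "b", "c"}, {"b", "c", "d"}])
        counts = {r.region: r.count for r in out.itertuples(index=False)}
        assert counts[(1, 1)] == 2
        assert counts[(1, 0)] == 1
        assert counts[(0, 1)] == 1

    def test_disjoint_sets(self):
        out = venn_overlap([{"a"}, {"b"}])
        counts = {r.region: r.count for r in out.itertuples(index=False)}
        assert counts[(1, 1)] == 0

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(7)
        sets = [set(rng.choice(40, size=rng.integers(5, 25), replace=False).tolist())
                for _ in range(4)]
        out = venn_overlap(sets)
        counts = {r.region: r.count for r in out.itertuples(index=False)}
        universe = set().union(*sets)
        for pattern in itertools.product((1, 0), repeat=4):
            if not any(pattern):
                continue
            expected = sum(
                1 for e in universe
                if all((e in s) == bool(f) for s, f in zip(sets, pattern))
            )
            assert counts[pattern] == expected

    def test_more_than_four_sets_rejected(self):
        with pytest.raises(ValueError, match="4"):
            venn_overlap([set()] * 5)


class TestBuildNetwork:
    @pytest.fixture()
    def chain_parts(self, chain_dataset):
        ds = chain_dataset
        pairs = gm.pairs_from_map(ds.references, ds.pair_map)
        mobile = gm.call_mobile_transcripts(ds.reads, pairs)
        degs = gm.call_degs(ds.expression["Csa"], "Csa", "leaf")
        orthology = best_hit_orthology(ds.references["Csa"], ds.references["Cmo"])
        gene_fc = delta.contrast_log2fc(ds.expression["Csa"])
        met_fc = delta.contrast_log2fc(ds.intensity)
        correlations = correlate_deg_dim(gene_fc, met_fc)
        return ds, mobile, degs, orthology, correlations

    def test_planted_chain_recovered_as_two_edges(self, chain_parts):
        ds, mobile, degs, orthology, correlations = chain_parts
        edges = build_network(mobile, degs, orthology, correlations, ds.annotation)
        assert len(edges) == 2
        by_type = {r.edge_type: r for r in edges.itertuples(index=False)}
        assert by_type[EDGE_MOBILE_DEG].source == "Cmo_0005"
        assert by_type[EDGE_MOBILE_DEG].target == "Csa_0005"
        assert by_type[EDGE_DEG_DIM].source == "Csa_0005"
        assert by_type[EDGE_DEG_DIM].target == "met_0010"
        assert by_type[EDGE_DEG_DIM].sign == 1

    def test_no_shared_pathway_no_mobile_deg_edge(self, chain_parts):
        ds, mobile, degs, orthology, correlations = chain_parts
        annotation = ds.annotation[
            ~((ds.annotation["feature"] == "Cmo_0005") & (ds.annotation["pathway"] == "map00042"))
        ]
        shared = set(
            annotation.loc[annotation["feature"] == "Cmo_0005", "pathway"]
        ) & set(annotation.loc[annotation["feature"] == "Csa_0005", "pathway"])
        annotation = annotation[~annotation["pathway"].isin(shared)]
        edges = build_network(mobile, degs, orthology, correlations, annotation)
        assert (edges["edge_type"] != EDGE_MOBILE_DEG).all()

    def test_empty_correlations_leave_only_mobile_deg(self, chain_parts):
        ds, mobile, degs, orthology, _ = chain_parts
        empty = pd.DataFrame(columns=["gene", "metabolite", "cor", "sign"])
        edges = build_network(mobile, degs, orthology, empty, ds.annotation)
        assert set(edges["edge_type"]) == {EDGE_MOBILE_DEG}

    def test_exports(self, tmp_path, chain_parts):
        ds, mobile, degs, orthology, correlations = chain_parts
        edges = build_network(mobile, degs, orthology, correlations, ds.annotation)
        write_sif(edges, tmp_path / "net.sif")
        lines = (tmp_path / "net.sif").read_text().strip().split("\n")
        assert len(lines) == len(edges)
        assert all(len(line.split("\t")) == 3 for line in lines)
        graph = to_networkx(edges)
        assert graph.number_of_edges() == len(edges)
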
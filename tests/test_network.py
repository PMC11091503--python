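"""Correlation network construction, candidate selection, export."""

import warnings

import numpy as np
import pandas as pd
import pytest

from hetcirc.network import (
    _exact_spearman_null,
    build_graph,
    correlate_pairs,
    export_network,
    read_sif,
    select_candidates,
    spearman_with_p,
)


def _expr(arr, prefix):
    arr = np.atleast_2d(arr)
    return pd.DataFrame(arr,
                        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=[f"s{i}" for i in range(arr.shape[1])])


def _assignment(features, module="turquoise"):
    return pd.DataFrame({"feature_id": features, "module": module,
                         "kme": 1.0})


def _trait_corr(module="turquoise", trait="RFI", p=0.001):
    return pd.DataFrame({"module": [module], "trait": [trait],
                         "r": [-0.6], "p": [p], "n": [32],
                         "significant": [p < 0.01]})


class TestSpearmanExact:
    def test_identical_ranks_small_p(self):
        import math
        x = np.arange(8.0)
        r, p = spearman_with_p(x, x + 3)
        assert r == pytest.approx(1.0)
        # exact two-sided permutation p for perfect rank agreement:
        # only the identity and the full reversal reach |rho| = 1
        assert p == pytest.approx(2 / math.factorial(8), rel=1e-9)

    def test_anticorrelated(self):
        x = np.arange(8.0)
        r, _ = spearman_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_null_distribution_is_symmetric_and_complete(self):
        null = _exact_spearman_null(5)
        assert null.size == 120
        assert null.min() >= 0 and null.max() == pytest.approx(1.0)

    def test_exact_p_uniformity(self, rng):
        # p-values from the exact null are valid: P(p <= a) <= a (+ atom)
        ps = []
        for _ in range(400):
            r, p = spearman_with_p(rng.normal(size=7), rng.normal(size=7))
            ps.append(p)
        ps = np.array(ps)
        assert (ps < 0.05).mean() < 0.09
        assert (ps < 0.5).mean() < 0.6

    def test_ties_fall_back_to_t_approximation(self):
        from scipy import stats
        x = np.array([1.0, 1.0, 2, 3, 4, 5, 6, 7])
        y = np.arange(8.0)
        r, p = spearman_with_p(x, y)
        r2, p2 = stats.spearmanr(x, y)
        assert (r, p) == (pytest.approx(r2), pytest.approx(p2))


class TestCorrelatePairs:
    def test_perfect_pair_stored_anticorrelated_excluded(self):
        x = np.arange(8.0)
        circ = _expr(np.vstack([x, -x]), "circ_")
        gene = _expr(x, "gene_")
        asn = _assignment(["circ_0", "circ_1", "gene_0"])
        edges = correlate_pairs(circ, gene, asn, _trait_corr())
        assert list(edges["circ_id"]) == ["circ_0"]
        assert edges["spearman_r"].iloc[0] == pytest.approx(1.0)

    def test_no_qualifying_module_warns_empty(self):
        circ = _expr(np.arange(8.0), "circ_")
        gene = _expr(np.arange(8.0), "gene_")
        asn = _assignment(["circ_0", "gene_0"])
        with pytest.warns(UserWarning, match="no module"):
            edges = correlate_pairs(circ, gene, asn,
                                    _trait_corr(p=0.5))
        assert edges.empty

    def test_null_edge_fraction_matches_exact_probability(self, rng):
        n_pairs = 1000
        circ = _expr(rng.normal(size=(n_pairs, 8)), "circ_")
        gene = _expr(rng.normal(size=(n_pairs, 8)), "gene_")
        stored = 0
        for i in range(n_pairs):
            r, p = spearman_with_p(circ.iloc[i].to_numpy(),
                                   gene.iloc[i].to_numpy())
            stored += (r > 0.6) and (p < 0.05)
        # exact joint null probability of (r > 0.6 and two-sided p < 0.05):
        # the null holds |rho| for every permutation; halve for the sign
        null = _exact_spearman_null(8)
        qualifies = np.array([
            rho > 0.6 and np.mean(null >= rho - 1e-12) < 0.05
            for rho in null])
        q = qualifies.mean() / 2.0
        frac = stored / n_pairs
        se = np.sqrt(q * (1 - q) / n_pairs)
        assert abs(frac - q) < 4 * se + 1e-3

    def test_stored_edges_respect_thresholds(self, rng):
        circ = _expr(rng.normal(size=(10, 8)), "circ_")
        gene = _expr(rng.normal(size=(15, 8)), "gene_")
        asn = _assignment(list(circ.index) + list(gene.index))
        edges = correlate_pairs(circ, gene, asn, _trait_corr())
        assert (edges["spearman_r"] > 0.6).all()
        assert (edges["p"] < 0.05).all()


def _calls(rows):
    return pd.DataFrame(rows, columns=["feature_id", "cross", "pattern",
                                       "pattern_class"])


class TestCandidates:
    def _edges(self):
        return pd.DataFrame([{
            "circ_id": "circ_0", "gene_id": "gene_0", "spearman_r": 0.9,
            "p": 0.01, "module": "turquoise", "tissue": "liver",
            "cross": "WY",
        }])

    def test_same_pattern_flag(self):
        calls = _calls([("circ_0", "WY", "V", "dominant"),
                        ("circ_0", "YW", "V", "dominant"),
                        ("gene_0", "WY", "V", "dominant")])
        out = select_candidates(self._edges(), calls)
        assert len(out) == 1
        assert out["same_pattern"].iloc[0]
        assert not out["cross_divergent"].iloc[0]

    def test_cross_divergent_circ(self):
        # pattern III in one cross direction, V in the other
        calls = _calls([("circ_0", "WY", "III", "dominant"),
                        ("circ_0", "YW", "V", "dominant"),
                        ("gene_0", "WY", "XI", "dominant")])
        out = select_candidates(self._edges(), calls)
        assert out["cross_divergent"].iloc[0]
        assert not out["same_pattern"].iloc[0]

    def test_additive_endpoint_excluded(self):
        calls = _calls([("circ_0", "WY", "V", "dominant"),
                        ("gene_0", "WY", "IV", "additive")])
        assert select_candidates(self._edges(), calls).empty

    def test_missing_call_skips_edge_with_warning(self):
        calls = _calls([("circ_0", "WY", "V", "dominant")])
        with pytest.warns(UserWarning, match="gene_0"):
            out = select_candidates(self._edges(), calls)
        assert out.empty

    def test_candidates_subset_of_edges(self, rng):
        circ = _expr(rng.normal(size=(5, 8)), "circ_")
        gene = _expr(rng.normal(size=(8, 8)), "gene_")
        asn = _assignment(list(circ.index) + list(gene.index))
        edges = correlate_pairs(circ, gene, asn, _trait_corr())
        calls = _calls([(f, c, "V", "dominant")
                        for f in list(circ.index) + list(gene.index)
                        for c in ("WY", "YW")])
        edges["cross"] = "WY"
        cands = select_candidates(edges, calls)
        got = set(zip(cands["circ_id"], cands["gene_id"]))
        all_edges = set(zip(edges["circ_id"], edges["gene_id"]))
        assert got <= all_edges


class TestExport:
    def test_empty_network(self, tmp_path):
        edges = pd.DataFrame(columns=["circ_id", "gene_id", "spearman_r",
                                      "p", "module", "tissue", "cross"])
        export_network(edges, None, str(tmp_path / "g.graphml"),
                       str(tmp_path / "g.sif"))
        assert read_sif(str(tmp_path / "g.sif")).empty
        import networkx as nx
        g = nx.read_graphml(str(tmp_path / "g.graphml"))
        assert g.number_of_nodes() == 0

    def test_toy_network_counts_and_idempotence(self, tmp_path):
        edges = pd.DataFrame([
            ("c1", "g1", 0.9, 0.01, "turquoise", "liver", "WY"),
            ("c1", "g2", 0.8, 0.02, "turquoise", "liver", "WY"),
            ("c2", "g1", 0.7, 0.04, "turquoise", "liver", "WY"),
        ], columns=["circ_id", "gene_id", "spearman_r", "p", "module",
                    "tissue", "cross"])
        g = build_graph(edges)
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 3
        p1, p2 = tmp_path / "a.sif", tmp_path / "b.sif"
        export_network(edges, None, str(tmp_path / "a.graphml"), str(p1))
        back = read_sif(str(p1))
        edges2 = edges.copy()
        edges2[["circ_id", "gene_id"]] = back[["circ_id", "gene_id"]]
        export_network(edges2, None, str(tmp_path / "b.graphml"), str(p2))
        assert p1.read_text() == p2.read_text()


class TestPlantedRecovery:
    def test_nonadditive_module_circ_recovers_partner_genes(self):
        """A planted nonadditive circRNA in a trait-linked module keeps
        most of its planted gene partners in the candidate set."""
        import warnings as w
        from hetcirc import (SimConfig, generate_counts,
                             generate_phenotypes, compute_cpm)
        from hetcirc.config import ModuleSpec
        from hetcirc.phenotypes import compute_derived_traits, fit_rfi
        from hetcirc.modules import (mad_filter, pick_soft_threshold,
                                     signed_adjacency, compute_tom,
                                     detect_modules, eigengene_matrix,
                                     module_trait_correlation)
        cfg = SimConfig(seed=5, pattern_proportions={"dominant": 0.25},
                        module_spec=ModuleSpec(effect_log2=2.5))
        phen, truth = generate_phenotypes(cfg)
        phen = compute_derived_traits(phen)
        phen, _ = fit_rfi(phen)
        with w.catch_warnings():
            w.simplefilter("ignore")
            circ, gene, meta, truth = generate_counts(cfg, phen, truth)
        m = meta.set_index("sample_id")
        samples = m.index[m["tissue"] == "hypothalamus"].tolist()
        lc = np.log2(compute_cpm(circ[samples], meta) + 1)
        lg = np.log2(compute_cpm(gene[samples], meta) + 1)
        expr = mad_filter(lc, lg)
        power, _ = pick_soft_threshold(expr)
        asn = detect_modules(compute_tom(signed_adjacency(expr, power)),
                             expr)
        eig = eigengene_matrix(expr, asn)
        traits = phen.set_index("bird_id").loc[
            m.loc[samples, "bird_id"], ["MBW", "BWG", "DEM", "DFC", "RFI"]]
        traits.index = samples
        mt = module_trait_correlation(eig, traits)
        edges = correlate_pairs(lc, lg, asn, mt, meta=m,
                                tissue="hypothalamus", cross="WY")
        tt = truth.features.set_index("feature_id")
        calls = _calls([(fid, cr, row["pattern"], row["pattern_class"])
                        for cr in ("WY", "YW")
                        for fid, row in tt.iterrows()])
        cands = select_candidates(edges, calls)
        mem = tt[tt["module_member"]]
        planted_circ = mem.index[(mem["kind"] == "circ")
                                 & (mem["pattern_class"] == "dominant")]
        planted_gene = set(mem.index[(mem["kind"] == "gene")
                                     & (mem["pattern_class"]
                                        == "dominant")])
        assert len(planted_circ) > 0 and len(planted_gene) > 5
        rates = []
        for c in planted_circ:
            k = cands[(cands["circ_id"] == c)
                      & cands["gene_id"].isin(planted_gene)][
                          "gene_id"].nunique()
            rates.append(k / len(planted_gene))
        assert np.mean(rates) >= 0.8
        assert min(rates) >= 0.7
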
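"""Module detection, Zi-Pi cartography and keystone abundance summaries."""

import itertools
import logging

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import asvnet as av
from asvnet.keystone import ModuleAssignment


def two_cliques(k=6):
    g = nx.Graph()
    left = [f"L{i}" for i in range(k)]
    right = [f"R{i}" for i in range(k)]
    g.add_edges_from(itertools.combinations(left, 2))
    g.add_edges_from(itertools.combinations(right, 2))
    g.add_edge(left[0], right[0])
    return g, left, right


class TestDetectModules:
    @pytest.mark.parametrize("method", ["greedy", "louvain"])
    def test_two_cliques_recovered(self, method):
        g, left, right = two_cliques()
        assign = av.detect_modules(g, method=method, seed=0)
        mods = {m: {n for n, mm in assign.membership.items() if mm == m}
                for m in set(assign.membership.values())}
        assert set(map(frozenset, mods.values())) == {
            frozenset(left),
            frozenset(right),
        }
        assert assign.modularity > 0.3

    @pytest.mark.parametrize("method", ["greedy", "louvain"])
    def test_deterministic(self, method):
        g = nx.gnp_random_graph(30, 0.2, seed=9)
        a = av.detect_modules(g, method=method, seed=4)
        b = av.detect_modules(g, method=method, seed=4)
        assert a.membership == b.membership

    def test_planted_partition_recovery(self, default_run):
        """Simulated modules are recovered with adjusted Rand index >= 0.8."""
        from sklearn.metrics import adjusted_rand_score

        d = default_run["design"]
        net = default_run["net"]
        assign = av.detect_modules(net)
        planted = {t: k for k, m in enumerate(d.modules) for t in m.member_taxa}
        nodes = list(net.nodes)
        ari = adjusted_rand_score(
            [planted[n] for n in nodes], [assign.membership[n] for n in nodes]
        )
        assert ari >= 0.8

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            av.detect_modules(nx.empty_graph(4))


def brute_force_zi_pi(g, membership):
    """Literal per-node summation of within-module degree z-scores and
    participation coefficients."""
    out = {}
    for v in g.nodes:
        k_m = {}
        for u in g.neighbors(v):
            k_m[membership[u]] = k_m.get(membership[u], 0) + 1
        k = sum(k_m.values())
        pi = 1 - sum((x / k) ** 2 for x in k_m.values()) if k else 0.0
        own = membership[v]
        within = [
            sum(1 for u in g.neighbors(w) if membership[u] == own)
            for w in g.nodes
            if membership[w] == own
        ]
        mu, sd = np.mean(within), np.std(within)
        w_v = sum(1 for u in g.neighbors(v) if membership[u] == own)
        zi = (w_v - mu) / sd if sd > 0 and len(within) > 1 else 0.0
        out[v] = (zi, pi)
    return out


class TestZiPi:
    def test_all_links_inside_module_pi_zero(self):
        g, left, right = two_cliques()
        assign = av.detect_modules(g)
        roles = av.zi_pi(g, assign)
        assert roles.loc["L3", "pi"] == pytest.approx(0.0)

    def test_even_split_pi_half(self):
        g = nx.Graph()
        g.add_edges_from([("x", "a1"), ("x", "a2"), ("x", "b1"), ("x", "b2")])
        membership = {"x": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        roles = av.zi_pi(g, ModuleAssignment(membership, 0.0))
        assert roles.loc["x", "pi"] == pytest.approx(1 - 2 * 0.5**2)

    def test_zi_sums_to_zero_within_modules(self, default_run):
        assign = av.detect_modules(default_run["net"])
        roles = av.zi_pi(default_run["net"], assign)
        for _, sub in roles.groupby("module"):
            if sub["zi"].abs().sum() > 0:
                assert sub["zi"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(30, 0.25, seed=8)
        membership = {n: int(rng.integers(3)) for n in g.nodes}
        roles = av.zi_pi(g, ModuleAssignment(membership, 0.0))
        expected = brute_force_zi_pi(g, membership)
        for node, (zi, pi) in expected.items():
            assert roles.loc[node, "zi"] == pytest.approx(zi, abs=1e-12)
            assert roles.loc[node, "pi"] == pytest.approx(pi, abs=1e-12)

    def test_module_relabeling_invariance(self):
        g = nx.gnp_random_graph(20, 0.3, seed=1)
        membership = {n: n % 3 for n in g.nodes}
        relabeled = {n: {0: 7, 1: 2, 2: 5}[m] for n, m in membership.items()}
        a = av.zi_pi(g, ModuleAssignment(membership, 0.0))
        b = av.zi_pi(g, ModuleAssignment(relabeled, 0.0))
        assert np.allclose(a["zi"], b["zi"]) and np.allclose(a["pi"], b["pi"])

    def test_pi_bounded_by_module_count(self):
        g = nx.gnp_random_graph(24, 0.4, seed=2)
        m_count = 4
        membership = {n: n % m_count for n in g.nodes}
        roles = av.zi_pi(g, ModuleAssignment(membership, 0.0))
        assert (roles["pi"] <= 1 - 1 / m_count + 1e-12).all()

    def test_isolated_node_pi_zero_with_warning(self, caplog):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("lone")
        membership = {"a": 0, "b": 0, "lone": 1}
        with caplog.at_level(logging.WARNING, logger="asvnet"):
            roles = av.zi_pi(g, ModuleAssignment(membership, 0.0))
        assert roles.loc["lone", "pi"] == 0.0
        assert "degree 0" in caplog.text

    def test_uncovered_node_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        with pytest.raises(ValueError, match="cover"):
            av.zi_pi(g, ModuleAssignment({"a": 0}, 0.0))


class TestClassifyNodes:
    @pytest.mark.parametrize(
        "zi, pi, role",
        [
            (3.0, 0.1, "module_hub"),
            (0.0, 0.9, "connector"),
            (3.0, 0.9, "network_hub"),
            (0.0, 0.1, "peripheral"),
            (2.5, 0.62, "peripheral"),  # boundaries are strict
        ],
    )
    def test_role_assignment(self, zi, pi, role):
        roles = pd.DataFrame({"zi": [zi], "pi": [pi]}, index=["n"])
        assert av.classify_nodes(roles).loc["n", "role"] == role

    def test_roles_partition_all_nodes(self, default_run):
        assign = av.detect_modules(default_run["net"])
        roles = av.classify_nodes(av.zi_pi(default_run["net"], assign))
        counts = roles["role"].value_counts()
        assert counts.sum() == default_run["net"].number_of_nodes()
        assert set(counts.index) <= {
            "peripheral",
            "connector",
            "module_hub",
            "network_hub",
        }


class TestKeystoneAbundance:
    def _setup(self):
        table = pd.DataFrame(
            {
                "P0r1": [100, 50, 850],
                "P1r1": [200, 100, 700],
            },
            index=pd.Index(["k1", "k2", "other"], name="taxon_id"),
        )
        taxonomy = pd.DataFrame(
            {
                "domain": ["fungi", "fungi", "bacteria"],
                "phylum": ["Ascomycota", "Ascomycota", "Proteobacteria"],
            },
            index=table.index,
        )
        metadata = pd.DataFrame(
            {"treatment": ["P0", "P1"]}, index=pd.Index(["P0r1", "P1r1"])
        )
        return table, taxonomy, metadata

    def _roles(self, mapping):
        return pd.DataFrame(
            {"zi": 0.0, "pi": 0.0, "role": list(mapping.values())},
            index=pd.Index(list(mapping.keys()), name="node"),
        )

    def test_no_keystones_empty_summary(self):
        table, taxonomy, metadata = self._setup()
        roles = self._roles({"k1": "peripheral", "k2": "peripheral"})
        out = av.keystone_abundance(roles, table, taxonomy, metadata)
        assert out.empty or (out.to_numpy() == 0).all()

    def test_single_phylum_pooled_share(self):
        table, taxonomy, metadata = self._setup()
        roles = self._roles({"k1": "module_hub", "k2": "connector"})
        out = av.keystone_abundance(roles, table, taxonomy, metadata)
        assert list(out.index) == ["Ascomycota"]
        assert out.loc["Ascomycota", "P0"] == pytest.approx(150 / 1000)
        assert out.loc["Ascomycota", "P1"] == pytest.approx(300 / 1000)

    def test_hubs_only_selection(self):
        table, taxonomy, metadata = self._setup()
        roles = self._roles({"k1": "module_hub", "k2": "connector"})
        out = av.keystone_abundance(
            roles, table, taxonomy, metadata,
            keystone_roles=("module_hub", "network_hub"),
        )
        assert out.loc["Ascomycota", "P0"] == pytest.approx(100 / 1000)

    def test_planted_hub_phyla_dominate(self, default_run):
        """Relative abundance summed over keystone rows equals the keystone
        read share per treatment, with planted hubs' phyla on top."""
        net = default_run["net"]
        assign = av.detect_modules(net)
        roles = av.classify_nodes(av.zi_pi(net, assign))
        # treat planted hubs as the keystone set via a forced role column
        hubs = [h for m in default_run["design"].modules for h in m.hub_taxa
                if h in roles.index]
        roles.loc[hubs, "role"] = "module_hub"
        out = av.keystone_abundance(
            roles.loc[hubs],
            default_run["counts"],
            default_run["taxonomy"],
            default_run["metadata"],
        )
        counts = default_run["counts"]
        meta = default_run["metadata"]
        p0_cols = meta.index[meta["treatment"] == "P0"]
        expected = counts.loc[hubs, p0_cols].sum().sum() / counts[p0_cols].sum().sum()
        assert out["P0"].sum() == pytest.approx(expected)


def test_annotate_network_round_trip(default_run):
    net = default_run["net"]
    assign = av.detect_modules(net)
    roles = av.classify_nodes(av.zi_pi(net, assign))
    annotated = av.annotate_network(net, roles)
    some = next(iter(annotated.nodes))
    assert annotated.nodes[some]["role"] in {
        "peripheral", "connector", "module_hub", "network_hub"
    }
    assert annotated.nodes[some]["module"] == roles.loc[some, "module"]
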
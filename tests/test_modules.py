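import numpy as np
import pytest

from diffint.differential import ACTIVATED, REPRESSED, DifferentialPPI, SupportingState
from diffint.io import canonical_edge
from diffint.modules import (
    DIPModule,
    ModuleCatalog,
    build_modules,
    intersect_catalogs,
    module_summary,
)


def dppi(a, b, direction=ACTIVATED):
    state = (1, 1) if direction == ACTIVATED else (-1, -1)
    q = 0.95 if direction == ACTIVATED else 0.05
    return DifferentialPPI(
        canonical_edge(a, b), direction, (SupportingState(state, q, 0.01, 0.4),)
    )


def star(hub, n, direction=ACTIVATED, offset=0):
    return [dppi(hub, f"P{offset + i}", direction) for i in range(n)]


class TestBuildModules:
    def test_five_edge_star_kept(self):
        catalog = build_modules(star("H", 5))
        assert set(catalog.modules) == {"mH"}
        assert len(catalog.modules["mH"]) == 5
        assert catalog.modules["mH"].members == frozenset(f"P{i}" for i in range(5))

    def test_four_edge_star_dropped(self):
        assert len(build_modules(star("H", 4))) == 0

    def test_overlapping_stars_share_the_common_edge(self):
        calls = star("H1", 5) + star("H2", 4, offset=10) + [dppi("H1", "H2")]
        catalog = build_modules(calls)
        assert set(catalog.modules) == {"mH1", "mH2"}
        shared = canonical_edge("H1", "H2")
        assert shared in catalog.modules["mH1"].edges
        assert shared in catalog.modules["mH2"].edges
        assert len(catalog.modules["mH1"]) == 6
        assert len(catalog.modules["mH2"]) == 5

    def test_both_directions_count_one_edge(self):
        calls = star("H", 4) + [dppi("H", "P0", REPRESSED)]
        catalog = build_modules(calls)  # still only 4 distinct edges
        assert len(catalog) == 0
        calls += [dppi("H", "P99")]
        catalog = build_modules(calls)
        module = catalog.modules["mH"]
        assert module.directions[canonical_edge("H", "P0")] == frozenset(
            {ACTIVATED, REPRESSED}
        )

    def test_empty_input(self):
        assert len(build_modules([])) == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_hub_detection_matches_naive_incidence_count(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(12)]
        calls = []
        seen = set()
        for _ in range(int(rng.integers(5, 50))):
            a, b = rng.choice(12, size=2, replace=False)
            e = canonical_edge(genes[a], genes[b])
            d = ACTIVATED if rng.random() < 0.5 else REPRESSED
            if (e, d) in seen:
                continue
            seen.add((e, d))
            calls.append(dppi(*e, d))
        catalog = build_modules(calls, min_edges=3)

        incidence: dict[str, set] = {}
        for e, _ in seen:
            for g in e:
                incidence.setdefault(g, set()).add(e)
        expected_hubs = {g for g, es in incidence.items() if len(es) >= 3}
        assert catalog.hubs() == expected_hubs
        for name, module in catalog.modules.items():
            assert module.edges == frozenset(incidence[module.hub])


def _catalog(spec, provenance=""):
    """spec: {hub: [(partner, {dirs}), ...]}"""
    modules = {}
    for hub, partners in spec.items():
        edges = {canonical_edge(hub, p): frozenset(d) for p, d in partners}
        modules[f"m{hub}"] = DIPModule(
            hub=hub,
            members=frozenset(p for p, _ in partners),
            edges=frozenset(edges),
            directions=edges,
        )
    return ModuleCatalog(modules, provenance=provenance)


def random_catalog(rng, n_hubs=4, n_partners=6):
    spec = {}
    for h in rng.choice(8, size=n_hubs, replace=False):
        hub = f"H{h}"
        partners = []
        for p in rng.choice(n_partners, size=int(rng.integers(1, n_partners)),
                            replace=False):
            dirs = {ACTIVATED} if rng.random() < 0.6 else {REPRESSED}
            if rng.random() < 0.2:
                dirs = {ACTIVATED, REPRESSED}
            partners.append((f"P{p}", dirs))
        spec[hub] = partners
    return _catalog(spec)


class TestIntersectCatalogs:
    def test_identical_catalogs_unchanged(self):
        a = _catalog({"H": [("P1", {ACTIVATED}), ("P2", {ACTIVATED})]})
        out = intersect_catalogs(a, a)
        assert set(out.modules) == {"mH"}
        assert out.modules["mH"].edges == a.modules["mH"].edges

    def test_disjoint_hubs_give_empty(self):
        a = _catalog({"H1": [("P1", {ACTIVATED})]})
        b = _catalog({"H2": [("P1", {ACTIVATED})]})
        assert len(intersect_catalogs(a, b)) == 0

    def test_edge_sets_intersect(self):
        a = _catalog({"H": [("P1", {ACTIVATED}), ("P2", {ACTIVATED}),
                            ("P3", {ACTIVATED})]})
        b = _catalog({"H": [("P2", {ACTIVATED}), ("P3", {ACTIVATED}),
                            ("P4", {ACTIVATED})]})
        out = intersect_catalogs(a, b)
        assert out.modules["mH"].members == frozenset({"P2", "P3"})

    def test_direction_disagreement_drops_edge_by_default(self):
        a = _catalog({"H": [("P1", {ACTIVATED})]})
        b = _catalog({"H": [("P1", {REPRESSED})]})
        assert len(intersect_catalogs(a, b)) == 0
        relaxed = intersect_catalogs(a, b, require_direction_agreement=False)
        assert set(relaxed.modules) == {"mH"}

    def test_empty_intersection_module_dropped(self):
        a = _catalog({"H": [("P1", {ACTIVATED})]})
        b = _catalog({"H": [("P2", {ACTIVATED})]})
        assert len(intersect_catalogs(a, b)) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_algebra_on_random_catalogs(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_catalog(rng), random_catalog(rng)
        ab = intersect_catalogs(a, b)
        ba = intersect_catalogs(b, a)
        # commutativity
        assert set(ab.modules) == set(ba.modules)
        for name in ab.modules:
            assert ab.modules[name].edges == ba.modules[name].edges
            assert ab.modules[name].directions == ba.modules[name].directions
        # subset closure
        for name, m in ab.modules.items():
            assert m.edges <= a.modules[name].edges
            assert m.edges <= b.modules[name].edges
        # idempotence
        aa = intersect_catalogs(a, a)
        for name in aa.modules:
            assert aa.modules[name].edges == a.modules[name].edges
        assert set(aa.modules) == set(a.modules)
        # absorption: (a & b) & b == a & b
        abb = intersect_catalogs(ab, b)
        assert set(abb.modules) == set(ab.modules)
        for name in abb.modules:
            assert abb.modules[name].edges == ab.modules[name].edges


class TestModuleSummary:
    def test_isolated_hub_shares_nothing(self):
        c = _catalog({"H": [("P1", {ACTIVATED})]})
        df = module_summary(c)
        assert df.loc[0, "hub_sharing_degree"] == 0
        assert df.loc[0, "n_edges"] == 1

    def test_hub_counted_as_member_elsewhere(self):
        c = _catalog(
            {
                "A": [("B", {ACTIVATED}), ("C", {ACTIVATED})],
                "B": [("A", {ACTIVATED})],
                "C": [("A", {ACTIVATED}), ("X", {ACTIVATED})],
            }
        )
        df = module_summary(c).set_index("module")
        assert df.loc["mA", "hub_sharing_degree"] == 2  # A appears in mB and mC
        assert df.loc["mB", "hub_sharing_degree"] == 1

    def test_empty_catalog(self):
        assert len(module_summary(ModuleCatalog({}))) == 0


class TestDIPModuleInvariants:
    def test_star_shape_enforced(self):
        with pytest.raises(ValueError, match="incident"):
            DIPModule(
                hub="H",
                members=frozenset({"A", "B"}),
                edges=frozenset({("A", "B"), ("B", "H")}),
                directions={},
            )

    def test_catalog_names_match_hubs(self):
        m = DIPModule("H", frozenset({"A"}), frozenset({("A", "H")}),
                      {("A", "H"): frozenset({ACTIVATED})})
        with pytest.raises(ValueError, match="catalog key"):
            ModuleCatalog({"mX": m})
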
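"""Metapath enumeration, HeteSim and degree-weighted path counts."""

import itertools

import numpy as np
import pytest

from lbdhub.kgraph import IN, OUT
from lbdhub.pathscore import (
    MetapathSchema,
    MetapathStep,
    PathInstance,
    along_path_degrees,
    dwpc,
    enumerate_metapaths,
    enumerate_to_target,
    hetesim,
)

from conftest import HetesimOracle, all_schemas, build_graph, random_typed_graph


class TestSchema:
    def test_string_round_trip(self):
        schema = MetapathSchema(
            (MetapathStep("CAUSES", OUT), MetapathStep("TREATS", IN))
        )
        assert str(schema) == "OUT:CAUSES|IN:TREATS"
        assert MetapathSchema.parse(str(schema)) == schema

    def test_reversed_flips_order_and_direction(self):
        schema = MetapathSchema.parse("OUT:CAUSES|IN:TREATS")
        assert str(schema.reversed()) == "OUT:TREATS|IN:CAUSES"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            MetapathSchema(())


class TestEnumerate:
    def test_direct_edge(self):
        g = build_graph([("S", "CAUSES", "T")])
        groups = enumerate_metapaths(g, "S", "T", max_len=2)
        assert list(map(str, groups)) == ["OUT:CAUSES"]
        [inst] = groups[MetapathSchema.parse("OUT:CAUSES")]
        assert inst.nodes == ("S", "T")

    def test_disconnected_pair_empty(self):
        g = build_graph([("S", "CAUSES", "A"), ("B", "CAUSES", "T")])
        assert enumerate_metapaths(g, "S", "T", max_len=2) == {}

    def test_unknown_node_raises(self):
        g = build_graph([("S", "CAUSES", "T")])
        with pytest.raises(KeyError):
            enumerate_metapaths(g, "S", "C9999999", 2)

    def test_matches_bruteforce_pair_and_triple_scan(self, rng):
        """Depth-2 enumeration equals an exhaustive scan over node tuples."""
        for _ in range(5):
            g, cuis = random_typed_graph(rng, n_nodes=10)
            edge_set = {(e.subject, e.predicate, e.object) for e in g.edges()}

            def steps_between(a, b):
                out = []
                for s, p, o in edge_set:
                    if (s, o) == (a, b):
                        out.append(MetapathStep(p, OUT))
                    if (s, o) == (b, a):
                        out.append(MetapathStep(p, IN))
                return out

            src, dst = cuis[0], cuis[1]
            expected = set()
            for st in steps_between(src, dst):
                expected.add((("%s" % src, dst), MetapathSchema((st,))))
            for mid in cuis:
                if mid in (src, dst):
                    continue
                for st1 in steps_between(src, mid):
                    for st2 in steps_between(mid, dst):
                        expected.add(((src, mid, dst), MetapathSchema((st1, st2))))

            got = {
                (inst.nodes, schema)
                for schema, insts in enumerate_metapaths(g, src, dst, 2).items()
                for inst in insts
            }
            assert got == {(tuple(n), s) for n, s in expected}

    def test_enumerate_to_target_agrees_with_per_pair_enumeration(self, rng):
        g, cuis = random_typed_graph(rng, n_nodes=9)
        target = cuis[0]
        collected = enumerate_to_target(g, target, max_len=2)
        for src in cuis[1:]:
            per_pair = enumerate_metapaths(g, src, target, 2)
            mine = {
                schema: insts
                for (s, schema), insts in collected.items()
                if s == src
            }
            assert mine == per_pair

    def test_insertion_order_invariance(self):
        edges = [("S", "A", "M"), ("M", "B", "T"), ("S", "C", "T"), ("X", "A", "T")]
        g1 = build_graph(edges)
        g2 = build_graph(list(reversed(edges)))
        assert enumerate_metapaths(g1, "S", "T", 2) == enumerate_metapaths(g2, "S", "T", 2)


class TestHetesim:
    def test_unbranched_chain_is_one(self):
        g = build_graph([("S", "CAUSES", "M"), ("M", "CAUSES", "T")])
        schema = MetapathSchema.parse("OUT:CAUSES|OUT:CAUSES")
        assert hetesim(g, "S", "T", schema) == pytest.approx(1.0, abs=1e-12)

    def test_two_branch_example(self):
        # S meets T on M; S also reaches M2: u=(1/2,1/2) vs v=(1,0).
        g = build_graph([("S", "REL", "M"), ("S", "REL", "M2"), ("T", "REL", "M")])
        schema = MetapathSchema.parse("OUT:REL|IN:REL")
        assert hetesim(g, "S", "T", schema) == pytest.approx(
            1 / np.sqrt(2), abs=1e-9
        )

    def test_unreachable_is_zero(self):
        g = build_graph([("S", "REL", "M"), ("X", "REL", "T")])
        schema = MetapathSchema.parse("OUT:REL|OUT:REL")
        assert hetesim(g, "S", "T", schema) == 0.0

    def test_direct_edge_odd_schema(self):
        g = build_graph([("S", "CAUSES", "T")])
        assert hetesim(g, "S", "T", MetapathSchema.parse("OUT:CAUSES")) == 1.0

    def test_self_similarity_along_palindromic_schema(self, rng):
        """s vs s along P + reverse(P) scores 1 whenever P is realized at s."""
        g, cuis = random_typed_graph(rng, n_nodes=8)
        checked = 0
        for s in cuis:
            for schema in all_schemas(("REL", "ACT"), 1):
                full = MetapathSchema(schema.steps + schema.reversed().steps)
                score = hetesim(g, s, s, full)
                if g.neighbors(s, schema.steps[0].predicate, schema.steps[0].direction):
                    assert score == pytest.approx(1.0, abs=1e-12)
                    checked += 1
                else:
                    assert score == 0.0
        assert checked > 0

    def test_symmetry_under_reversal(self, rng):
        g, cuis = random_typed_graph(rng, n_nodes=8)
        for schema in all_schemas(("REL", "ACT"), 2):
            for s, t in itertools.islice(itertools.permutations(cuis, 2), 20):
                assert hetesim(g, s, t, schema) == pytest.approx(
                    hetesim(g, t, s, schema.reversed()), abs=1e-12
                )

    def test_matches_matrix_oracle_on_random_graphs(self, rng):
        """Walk-based scores equal the explicit transition-matrix oracle."""
        schemas = all_schemas(("REL", "ACT"), 2)
        for _ in range(10):
            g, cuis = random_typed_graph(rng)
            oracle = HetesimOracle(g)
            for schema in schemas:
                expected = oracle.all_pairs(schema)
                for s, t in itertools.permutations(cuis, 2):
                    got = hetesim(g, s, t, schema)
                    assert got == pytest.approx(
                        expected[oracle.idx[s], oracle.idx[t]], abs=1e-9
                    ), (s, t, str(schema))


class TestDwpc:
    def _single_instance(self):
        # Along-path degrees (2, 3, 2): S leaves along 2 matching out-edges,
        # M is reached among 3 matching in-edges, T among 2.
        g = build_graph(
            [
                ("S", "REL", "M"),
                ("S", "REL", "X"),
                ("A", "REL", "M"),
                ("A2", "REL", "M"),
                ("M", "REL", "T"),
                ("B", "REL", "T"),
            ]
        )
        schema = MetapathSchema.parse("OUT:REL|OUT:REL")
        inst = PathInstance(("S", "M", "T"), schema)
        return g, inst

    def test_along_path_degrees(self):
        g, inst = self._single_instance()
        assert along_path_degrees(g, inst) == (2, 3, 2)

    def test_damped_single_instance(self):
        g, inst = self._single_instance()
        assert dwpc([inst], g, w=0.4) == pytest.approx(12 ** (-0.4), abs=1e-9)

    def test_zero_damping_is_raw_count(self, rng):
        for _ in range(10):
            g, cuis = random_typed_graph(rng, n_nodes=8)
            groups = enumerate_metapaths(g, cuis[0], cuis[1], 2)
            for schema, insts in groups.items():
                assert dwpc(insts, g, w=0.0) == pytest.approx(len(insts))

    def test_unit_degrees_give_count_for_any_w(self):
        g = build_graph([("S", "REL", "M"), ("M", "ACT", "T")])
        schema = MetapathSchema.parse("OUT:REL|OUT:ACT")
        inst = PathInstance(("S", "M", "T"), schema)
        for w in (0.0, 0.4, 2.5):
            assert dwpc([inst], g, w) == pytest.approx(1.0)

    def test_non_increasing_in_w(self, rng):
        grid = [0.0, 0.2, 0.4, 0.8]
        for _ in range(10):
            g, cuis = random_typed_graph(rng, n_nodes=8)
            groups = enumerate_metapaths(g, cuis[0], cuis[1], 2)
            for schema, insts in groups.items():
                values = [dwpc(insts, g, w) for w in grid]
                assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))
                if any(
                    d > 1 for inst in insts for d in along_path_degrees(g, inst)
                ):
                    assert values[0] > values[-1]

    def test_negative_w_rejected(self):
        g, inst = self._single_instance()
        with pytest.raises(ValueError):
            dwpc([inst], g, w=-0.1)
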
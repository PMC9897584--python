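"""Interface extraction, network screens, BBH maps and the perturbation test."""

import numpy as np
import pytest

from homolot import ppi_evidence as ppi
from homolot import synthetic_data as sd
from homolot.io_formats import AtomRecord, BlastRow, ProteinRecord


def atom(chain, resnum, x, y=0.0, z=0.0):
    return AtomRecord(chain, resnum, "ALA", "CA", x, y, z)


class TestInterfaceResidues:
    def test_threshold_cases(self):
        near = ppi.interface_residues([atom("A", 1, 4.0)], [atom("B", 1, 0.0)])
        far = ppi.interface_residues([atom("A", 1, 6.0)], [atom("B", 1, 0.0)])
        assert near == {("A", 1)} and far == set()

    def test_any_atom_rule(self):
        atoms_a = [atom("A", 1, 4.9), atom("A", 1, 50.0), atom("A", 2, 80.0)]
        assert ppi.interface_residues(atoms_a, [atom("B", 1, 0.0)]) == {("A", 1)}

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            ppi.interface_residues([atom("A", 1, 1.0)], [atom("B", 1, 0.0)], cutoff=0)

    def test_matches_bruteforce_distance_scan(self, rng):
        for _ in range(10):
            atoms_a = [
                atom("A", int(r), *rng.uniform(-10, 10, size=3))
                for r in rng.integers(1, 20, size=50)
            ]
            atoms_b = [
                atom("B", int(r), *rng.uniform(-10, 10, size=3))
                for r in rng.integers(1, 10, size=50)
            ]
            expected = set()
            for a in atoms_a:
                for b in atoms_b:
                    d = np.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2)
                    if d <= 5.0:
                        expected.add((a.chain, a.residue_number))
            assert ppi.interface_residues(atoms_a, atoms_b) == expected

    def test_rigid_transform_invariance(self, rng):
        atoms_a = [atom("A", i, *rng.uniform(-5, 5, size=3)) for i in range(1, 30)]
        atoms_b = [atom("B", i, *rng.uniform(-5, 5, size=3)) for i in range(1, 20)]
        base = ppi.interface_residues(atoms_a, atoms_b)
        # random rotation (QR-orthogonalized) + translation applied to both
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.uniform(-100, 100, size=3)

        def transform(atoms):
            out = []
            for a in atoms:
                x, y, z = q @ np.array([a.x, a.y, a.z]) + t
                out.append(AtomRecord(a.chain, a.residue_number, a.residue_name, a.atom_name, x, y, z))
            return out

        assert ppi.interface_residues(transform(atoms_a), transform(atoms_b)) == base

    def test_planted_complex_recovered(self, small_config):
        ic = sd.make_interface_complex(small_config)
        residues = ppi.interface_residues(ic.atoms_a, ic.atoms_b)
        assert {r for _, r in residues} == ic.interface_positions


class PlantedScorer:
    """Interacting pairs are exactly those listed; everything else 0.1."""

    def __init__(self, pairs):
        self.pairs = set(pairs)

    def score(self, seq_a, seq_b):
        return 0.9 if (seq_a[:6], seq_b[:6]) in self.pairs else 0.1


def records(prefix, n):
    return [
        ProteinRecord(f"{prefix}{i}", f"{prefix}{i}", f"{prefix}{i}".ljust(6, "X") + "M" * 10)
        for i in range(1, n + 1)
    ]


class TestScreen:
    def test_planted_edges_only(self):
        alphas, betas, gammas = records("a", 2), records("b", 2), records("g", 1)
        key = lambda r: r.sequence[:6]
        scorer = PlantedScorer(
            {(key(alphas[0]), key(betas[0])), (key(betas[0]), key(gammas[0]))}
        )
        net, table = ppi.screen(alphas, betas, gammas, scorer)
        assert set(net.edges) == {
            frozenset(("a1", "b1")),
            frozenset(("b1", "g1")),
        }
        assert len(table) == 2 * 2 + 2 * 1 + 2 * 1

    def test_empty_gamma_list(self):
        alphas, betas = records("a", 3), records("b", 2)
        net, table = ppi.screen(alphas, betas, [], PlantedScorer(set()))
        assert len(table) == 6
        assert set(table.role_b) == {"beta"}

    def test_pair_count_formula(self):
        na, nb, ng = 12, 20, 5
        net, table = ppi.screen(
            records("a", na), records("b", nb), records("g", ng), PlantedScorer(set())
        )
        assert len(table) == na * nb + nb * ng + na * ng

    def test_same_role_edges_rejected(self):
        net = ppi.PPINetwork({"a1": "alpha", "a2": "alpha"})
        with pytest.raises(ValueError, match="alpha"):
            net.add_edge("a1", "a2", 0.9)


class TestBBHMap:
    def test_mutual_best_pair(self):
        fwd = [BlastRow("P1", "M1", 90, 1e-50, 200)]
        rev = [BlastRow("M1", "P1", 90, 1e-50, 200)]
        assert ppi.bbh_map(fwd, rev).pairs == {("P1", "M1")}

    def test_non_mutual_rejected(self):
        fwd = [BlastRow("P1", "M1", 90, 1e-50, 200)]
        rev = [BlastRow("M1", "P2", 90, 1e-50, 200)]
        assert ppi.bbh_map(fwd, rev).pairs == set()

    def test_tie_breaking_bitscore_evalue_lexicographic(self):
        fwd = [
            BlastRow("P1", "M2", 90, 1e-50, 200),
            BlastRow("P1", "M1", 90, 1e-50, 200),
            BlastRow("P1", "M3", 90, 1e-60, 180),
        ]
        rev = [BlastRow("M1", "P1", 90, 1e-50, 200)]
        assert ppi.bbh_map(fwd, rev).pairs == {("P1", "M1")}

    def test_matches_bruteforce_mutual_best(self, rng):
        for _ in range(30):
            fwd = [
                BlastRow(f"P{q}", f"M{t}", 50.0, float(e), float(b))
                for q in range(6)
                for t, e, b in zip(
                    rng.integers(0, 6, size=4),
                    10.0 ** rng.uniform(-60, -5, size=4),
                    rng.integers(50, 300, size=4),
                )
            ]
            rev = [
                BlastRow(f"M{q}", f"P{t}", 50.0, float(e), float(b))
                for q in range(6)
                for t, e, b in zip(
                    rng.integers(0, 6, size=4),
                    10.0 ** rng.uniform(-60, -5, size=4),
                    rng.integers(50, 300, size=4),
                )
            ]

            def best(rows):
                out = {}
                for r in rows:
                    cur = out.get(r.query_id)
                    if cur is None or (-r.bitscore, r.evalue, r.target_id) < (
                        -cur.bitscore,
                        cur.evalue,
                        cur.target_id,
                    ):
                        out[r.query_id] = r
                return {q: r.target_id for q, r in out.items()}

            fbest, rbest = best(fwd), best(rev)
            expected = {(p, m) for p, m in fbest.items() if rbest.get(m) == p}
            assert ppi.bbh_map(fwd, rev).pairs == expected


class TestOverlay:
    def roles(self, n):
        r = {}
        for i in range(n):
            r[f"a{i}"] = "alpha"
            r[f"b{i}"] = "beta"
        return r

    def test_identity_map_conserves_everything(self):
        net = ppi.PPINetwork(self.roles(3))
        net.add_edge("a0", "b0", 0.9)
        net.add_edge("a1", "b2", 0.8)
        cross = ppi.CrossSpeciesMap({(n, n) for n in net.roles})
        assert ppi.overlay(net, net, cross) == set(net.edges)

    def test_conserved_triangle_pattern(self):
        roles1 = {"pA": "alpha", "pB": "beta", "pG": "gamma"}
        roles2 = {"mA": "alpha", "mB": "beta", "mG": "gamma"}
        net1, net2 = ppi.PPINetwork(roles1), ppi.PPINetwork(roles2)
        for x, y in (("pA", "pB"), ("pB", "pG"), ("pA", "pG")):
            net1.add_edge(x, y, 0.9)
        for x, y in (("mA", "mB"), ("mB", "mG"), ("mA", "mG")):
            net2.add_edge(x, y, 0.9)
        cross = ppi.CrossSpeciesMap({("pA", "mA"), ("pB", "mB"), ("pG", "mG")})
        assert ppi.overlay(net1, net2, cross) == set(net1.edges)

    def test_matches_bruteforce_translated_lookup(self, rng):
        for _ in range(20):
            net1 = ppi.PPINetwork(self.roles(5))
            net2 = ppi.PPINetwork(self.roles(5))
            for net in (net1, net2):
                for _ in range(8):
                    a, b = f"a{rng.integers(5)}", f"b{rng.integers(5)}"
                    net.add_edge(a, b, 0.9)
            cross = ppi.CrossSpeciesMap({(n, n) for n in ("a0", "a1", "b0", "b1", "b2")})
            mapping = cross.forward()
            expected = set()
            for edge in net1.edges:
                x, y = tuple(edge)
                if x in mapping and y in mapping and frozenset((mapping[x], mapping[y])) in net2.edges:
                    expected.add(edge)
            assert ppi.overlay(net1, net2, cross) == expected


class TestTriangles:
    def build(self, edges):
        roles = {}
        for prefix, role in (("a", "alpha"), ("b", "beta"), ("g", "gamma")):
            for i in range(4):
                roles[f"{prefix}{i}"] = role
        net = ppi.PPINetwork(roles)
        for x, y in edges:
            net.add_edge(x, y, 0.9)
        return net

    def test_complete_triangle(self):
        net = self.build([("a0", "b0"), ("b0", "g0"), ("a0", "g0")])
        assert ppi.triangle_evidence(net) == [("a0", "b0", "g0")]

    def test_missing_edge_breaks_triangle(self):
        net = self.build([("a0", "b0"), ("b0", "g0")])
        assert ppi.triangle_evidence(net) == []

    def test_matches_cubic_enumeration(self, rng):
        for _ in range(20):
            edges = set()
            for _ in range(14):
                kind = rng.integers(3)
                if kind == 0:
                    edges.add((f"a{rng.integers(4)}", f"b{rng.integers(4)}"))
                elif kind == 1:
                    edges.add((f"b{rng.integers(4)}", f"g{rng.integers(4)}"))
                else:
                    edges.add((f"a{rng.integers(4)}", f"g{rng.integers(4)}"))
            net = self.build(edges)
            expected = [
                (f"a{i}", f"b{j}", f"g{k}")
                for i in range(4)
                for j in range(4)
                for k in range(4)
                if net.has_edge(f"a{i}", f"b{j}")
                and net.has_edge(f"b{j}", f"g{k}")
                and net.has_edge(f"a{i}", f"g{k}")
            ]
            assert ppi.triangle_evidence(net) == sorted(expected)


@pytest.fixture(scope="module")
def complex_():
    return sd.make_interface_complex(
        sd.SyntheticConfig(seed=99), length_a=300, n_interface=30
    )


class TestPerturbation:

    def test_k_zero_is_noop(self, complex_):
        r = ppi.perturbation_test(
            complex_.seq_a, complex_.seq_b, complex_.scorer,
            complex_.interface_positions, k=0, n_trials=5, seed=1,
        )
        assert r.permuted_mean == r.random_mean == r.original
        assert r.permuted_sd == r.random_sd == 0.0

    def test_constant_scorer_exactly_flat(self, complex_):
        r = ppi.perturbation_test(
            complex_.seq_a, complex_.seq_b, sd.ConstantScorer(0.7),
            complex_.interface_positions, k=25, n_trials=10, seed=2,
        )
        assert r.original == r.permuted_mean == r.random_mean == 0.7
        assert r.permuted_sd == r.random_sd == 0.0

    def test_deterministic_from_seed(self, complex_):
        kwargs = dict(k=25, n_trials=20, seed=42)
        r1 = ppi.perturbation_test(
            complex_.seq_a, complex_.seq_b, complex_.scorer,
            complex_.interface_positions, **kwargs,
        )
        r2 = ppi.perturbation_test(
            complex_.seq_a, complex_.seq_b, complex_.scorer,
            complex_.interface_positions, **kwargs,
        )
        assert r1 == r2

    def test_site_arm_drops_random_arm_stable(self, complex_):
        r = ppi.perturbation_test(
            complex_.seq_a, complex_.seq_b, complex_.scorer,
            complex_.interface_positions, k=25, n_trials=50, seed=3,
        )
        assert r.permuted_mean < r.original
        se = r.random_sd / np.sqrt(r.n_trials)
        assert abs(r.random_mean - r.original) <= max(3 * se, 0.05)

    def test_k_larger_than_site_set_rejected(self, complex_):
        with pytest.raises(ValueError, match="exceeds"):
            ppi.perturbation_test(
                complex_.seq_a, complex_.seq_b, complex_.scorer,
                {1, 2, 3}, k=25, n_trials=2, seed=0,
            )

    def test_small_site_set_clips_k_with_warning(self, complex_):
        with pytest.warns(UserWarning, match="k=3"):
            r = ppi.perturbation_test(
                complex_.seq_a, complex_.seq_b, complex_.scorer,
                {5, 10, 15}, k=None, n_trials=2, seed=0,
            )
        assert r.k == 3


class TestSiteMapping:
    def test_identity_alignment(self):
        assert ppi.site_positions_from_alignment("MKVL", "MKVL", {2, 4}) == {2, 4}

    def test_gap_drops_site_with_warning(self):
        with pytest.warns(UserWarning, match="gaps"):
            mapped = ppi.site_positions_from_alignment("M-VL", "MKVL", {2, 4})
        assert mapped == {3}

    def test_shifted_alignment_offsets_positions(self):
        # candidate has 3 extra N-terminal residues: reference gap columns
        cand = "ABCMKVL"
        ref = "---MKVL"
        assert ppi.site_positions_from_alignment(cand, ref, {1, 3}) == {4, 6}
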
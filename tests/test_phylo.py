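"""Assembly, Jukes-Cantor distances, neighbor joining, bootstrap and locus
placement."""

import itertools

import networkx as nx
import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from slatyper.library import extract_amplicon
from slatyper.phylo import (AssembledSequence, AssemblyError, assemble_exon2_3,
                            assign_locus, bipartitions, bootstrap_support,
                            jc_distance, jc_distance_info, jc_matrix, nj_tree,
                            two_taxon_tree)
from slatyper.simulate import make_fixture_library

from conftest import random_insert


class TestAssembly:
    def test_engineered_overlaps_length_arithmetic(self, rng):
        core = random_insert(rng, 320)
        e2 = random_insert(rng, 120) + core[:100]     # 100-nt exact overlap
        e3 = core[-140:] + random_insert(rng, 160)    # 140-nt exact overlap
        asm = assemble_exon2_3(core, e2, e3, ns_id="NS#9")
        assert asm.length == len(e2) + 320 + len(e3) - 100 - 140
        assert core in asm.sequence
        assert asm.sequence.startswith(e2) and asm.sequence.endswith(e3)

    def test_containment_collapses(self, rng):
        core = random_insert(rng, 320)
        asm = assemble_exon2_3(core, core[:80], core[-90:])
        assert asm.sequence == core

    def test_overlap_mismatch_raises_with_position(self, rng):
        core = random_insert(rng, 320)
        bad = core[:100]
        bad = bad[:50] + ("A" if bad[50] != "A" else "C") + bad[51:]
        with pytest.raises(AssemblyError, match="exon2/core"):
            assemble_exon2_3(core, random_insert(rng, 60) + bad,
                             core[-100:] + random_insert(rng, 50))

    def test_short_overlap_rejected(self, rng):
        core = random_insert(rng, 320)
        with pytest.raises(AssemblyError):
            assemble_exon2_3(core, random_insert(rng, 100) + core[:20],
                             core[-100:])

    def test_completeness_flags(self, rng):
        full = AssembledSequence("NS#2", random_insert(rng, 605))
        assert full.exon2_complete and full.exon3_complete
        partial = AssembledSequence("NS#5", random_insert(rng, 282))
        assert not partial.exon2_complete and not partial.exon3_complete


class TestJukesCantor:
    def test_identical_zero(self):
        assert jc_distance("ACGT" * 30, "ACGT" * 30) == 0.0

    def test_p_ten_percent_closed_form(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        assert jc_distance(a, b) == pytest.approx(0.107326, abs=5e-7)

    def test_saturation_cap(self):
        info = jc_distance_info("A" * 100, "C" * 75 + "A" * 25)
        assert info.saturated and info.distance == 5.0

    def test_ambiguous_positions_excluded(self):
        d = jc_distance("ACGTN" + "A" * 20, "ACGTA" + "A" * 20)
        assert d == 0.0  # the N column is ignored entirely

    def test_no_comparable_positions(self):
        with pytest.raises(ValueError):
            jc_distance("NNNN", "ACGT")

    def test_symmetric_and_monotone_in_p(self, rng):
        a = "A" * 200
        last = -1.0
        for k in range(0, 150, 10):
            b = "C" * k + "A" * (200 - k)
            d = jc_distance(a, b)
            assert d == jc_distance(b, a)
            assert d > last
            last = d


def random_binary_tree(names, rng):
    """Random unrooted binary topology with random positive edge lengths,
    as a networkx graph."""
    g = nx.Graph()
    g.add_node("I0")
    for name in names[:3]:
        g.add_edge("I0", name, length=float(rng.uniform(0.1, 1.0)))
    ni = 1
    for name in names[3:]:
        u, v = list(g.edges())[int(rng.integers(g.number_of_edges()))]
        w = g[u][v]["length"]
        inode = f"I{ni}"
        g.remove_edge(u, v)
        g.add_edge(u, inode, length=w / 2)
        g.add_edge(inode, v, length=w / 2)
        g.add_edge(inode, name, length=float(rng.uniform(0.1, 1.0)))
        ni += 1
    return g


def tree_distances(g, names):
    n = len(names)
    D = np.zeros((n, n))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            D[i, j] = paths[a][b]
    return (D + D.T) / 2.0  # exact symmetry for float path sums


def graph_bipartitions(g, names):
    out = set()
    ref = min(names)
    for u, v in list(g.edges()):
        if str(u).startswith("I") and str(v).startswith("I"):
            h = g.copy()
            h.remove_edge(u, v)
            side = {n for n in names
                    if nx.has_path(h, n, u)}
            if ref in side:
                side = set(names) - side
            if 2 <= len(side) <= len(names) - 2:
                out.add(frozenset(side))
    return out


def enumerate_topologies(names):
    """All unrooted binary leaf-labeled topologies (as networkx graphs)."""
    base = nx.Graph()
    for n in names[:3]:
        base.add_edge("I0", n)
    trees = [(base, 1)]
    for name in names[3:]:
        nxt = []
        for g, ni in trees:
            for u, v in list(g.edges()):
                h = g.copy()
                h.remove_edge(u, v)
                inode = f"I{ni}"
                h.add_edge(u, inode)
                h.add_edge(inode, v)
                h.add_edge(inode, name)
                nxt.append((h, ni + 1))
        trees = nxt
    return [g for g, _ in trees]


def best_fit_topology(D, names):
    """Exhaustive search: the topology whose least-squares branch lengths
    reproduce the distance matrix exactly."""
    pairs = list(itertools.combinations(range(len(names)), 2))
    for g in enumerate_topologies(names):
        edges = list(g.edges())
        A = np.zeros((len(pairs), len(edges)))
        d = np.zeros(len(pairs))
        for r, (i, j) in enumerate(pairs):
            path = nx.shortest_path(g, names[i], names[j])
            for u, v in zip(path, path[1:]):
                e = edges.index((u, v)) if (u, v) in edges \
                    else edges.index((v, u))
                A[r, e] = 1.0
            d[r] = D[i, j]
        x, res, *_ = np.linalg.lstsq(A, d, rcond=None)
        if np.max(np.abs(A @ x - d)) < 1e-8:
            return g
    raise AssertionError("no exactly fitting topology (matrix not additive?)")


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):3,C:4,D:5): pairwise path lengths below
        dm = DistanceMatrix([[0, 3, 8, 9], [3, 0, 9, 10],
                             [8, 9, 0, 9], [9, 10, 9, 0]], ids=list("ABCD"))
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 4.0, "D": 5.0}
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        # path metric round-trip
        for a, b in itertools.combinations("ABCD", 2):
            ta = tree.find(a)
            tb = tree.find(b)
            assert ta.distance(tb) == pytest.approx(dm[a, b])

    def test_three_equidistant_taxa(self):
        dm = DistanceMatrix([[0, 2, 2], [2, 0, 2], [2, 2, 0]], ids=list("ABC"))
        tree = nj_tree(dm)
        assert sorted(t.length for t in tree.tips()) == [1.0, 1.0, 1.0]

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ids=list("AB"))
        with pytest.raises(ValueError):
            nj_tree(dm)
        t2 = two_taxon_tree(dm)
        assert {t.name for t in t2.tips()} == {"A", "B"}

    @pytest.mark.parametrize("n_taxa", [5, 6])
    def test_recovers_additive_matrices_vs_exhaustive_search(self, n_taxa):
        rng = np.random.default_rng(n_taxa * 17)
        names = [f"t{i}" for i in range(n_taxa)]
        for _ in range(3):
            g = random_binary_tree(names, rng)
            D = tree_distances(g, names)
            nj = nj_tree(DistanceMatrix(D, ids=names))
            best = best_fit_topology(D, names)
            assert bipartitions(nj) == graph_bipartitions(best, names)
            # and the metric itself is reproduced
            for i, j in itertools.combinations(range(n_taxa), 2):
                ta, tb = nj.find(names[i]), nj.find(names[j])
                assert ta.distance(tb) == pytest.approx(D[i, j], abs=1e-9)

    def test_topology_agrees_with_reference_nj(self, rng):
        """Independent cross-check against scikit-bio's NJ on random
        (noisy, non-additive) matrices: same unrooted topology."""
        for _ in range(5):
            n = int(rng.integers(4, 9))
            names = [f"s{i}" for i in range(n)]
            g = random_binary_tree(names, rng)
            D = tree_distances(g, names)
            noise = rng.uniform(0, 0.01, D.shape)
            D = D + (noise + noise.T)  # keep exact float symmetry
            np.fill_diagonal(D, 0.0)
            dm = DistanceMatrix(D, ids=names)
            ours = bipartitions(nj_tree(dm))
            ref = bipartitions(skbio_nj(dm))
            assert ours == ref

    def test_negative_branches_clamped(self):
        dm = DistanceMatrix([[0, 1, 5, 5], [1, 0, 5, 5],
                             [5, 5, 0, 1], [5, 5, 1, 0]], ids=list("ABCD"))
        tree = nj_tree(dm)
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0.0


class TestBootstrap:
    def _seqs(self, rng):
        # two identical sequences vs a distant (also identical) pair: every
        # column resample preserves the separating split
        a = random_insert(rng, 200)
        z = list(a)
        for p in rng.choice(200, size=50, replace=False):
            z[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[z[p]]
        z = "".join(z)
        return {"a1": a, "a2": a, "z1": z, "z2": z}

    def test_clear_split_supported_everywhere(self, rng):
        seqs = self._seqs(rng)
        tree, supports = bootstrap_support(seqs, n_reps=30, seed=5)
        assert supports == {frozenset({"z1", "z2"}): 100.0}

    def test_single_replicate_binary_support(self, rng):
        _, supports = bootstrap_support(self._seqs(rng), n_reps=1, seed=5)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_seed_determinism(self, rng):
        seqs = self._seqs(rng)
        _, s1 = bootstrap_support(seqs, n_reps=20, seed=9)
        _, s2 = bootstrap_support(seqs, n_reps=20, seed=9)
        assert s1 == s2


class TestAssignLocus:
    def test_near_neighbor_dominance(self, fixture_pool):
        rec = fixture_pool.library["SLA-3*02:01"]
        ins = extract_amplicon(rec, fixture_pool.primers).insert
        mutated = ("A" if ins[0] != "A" else "C") + ins[1:]
        asg = assign_locus(AssembledSequence("NS#1", mutated),
                           fixture_pool.library, fixture_pool.primers,
                           n_reps=25, seed=3)
        assert asg.locus == "SLA-3"
        assert not asg.low_confidence

    def test_recovers_generating_locus_for_simulated_novels(self):
        pool = make_fixture_library(3, divergence=5, seed=91)
        inserts = {rec.name: extract_amplicon(rec, pool.primers).insert
                   for rec in pool.library}
        rng = np.random.default_rng(8)
        hits = total = 0
        for name, ins in inserts.items():
            locus = pool.library[name].locus
            pos = rng.choice(len(ins), size=3, replace=False)
            novel = list(ins)
            for p in pos:
                novel[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[novel[p]]
            asg = assign_locus(AssembledSequence("NS#x", "".join(novel)),
                               pool.library, pool.primers, n_reps=10,
                               seed=int(rng.integers(2**31)))
            total += 1
            hits += asg.locus == locus
        assert hits / total >= 0.95

    def test_short_span_refused(self, fixture_pool):
        with pytest.raises(ValueError, match="unreliable"):
            assign_locus(AssembledSequence("NS#s", "ACGT" * 20),
                         fixture_pool.library, fixture_pool.primers)

    def test_equidistant_two_locus_toy_falls_back(self, rng):
        from slatyper.library import AlleleLibrary
        from conftest import make_allele
        base = random_insert(rng, 120)
        a = list(base)
        b = list(base)
        novel = list(base)
        # novel differs from each library allele at disjoint positions
        a[10] = "A" if base[10] != "A" else "C"
        b[50] = "A" if base[50] != "A" else "C"
        lib = AlleleLibrary([make_allele("SLA-1*01:01", "".join(a), rng),
                             make_allele("SLA-2*01:01", "".join(b), rng)])
        asg = assign_locus(AssembledSequence("NS#t", base), lib,
                           n_reps=5, seed=1)
        assert asg.low_confidence


def test_newick_round_trip(tmp_path, rng):
    seqs = {f"x{i}": random_insert(rng, 150) for i in range(5)}
    tree, _ = bootstrap_support(seqs, n_reps=10, seed=2)
    path = tmp_path / "tree.nwk"
    tree.write(str(path))
    from skbio import TreeNode
    back = TreeNode.read(str(path))
    assert {t.name for t in back.tips()} == set(seqs)
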
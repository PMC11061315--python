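"""Two-step clustering, MCL, taxonomy consensus and co-occurrence."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ragath import families, synthetic
from ragath.families import Cluster, SimilarityGraph
from ragath.islands import NeighborhoodWindow
from ragath.seqs import random_protein


# ---------------------------------------------------------------------------
# align_pair

def test_self_alignment_is_perfect():
    seq = "MKVLATTWEIRAAGHQPLMN"
    pa = families.align_pair(seq, seq)
    assert pa.identity == 1.0 and pa.coverage == 1.0


def _gotoh_local(a, b, matrix, gap_open=-11.0, gap_extend=-1.0):
    """Independent affine-gap Smith-Waterman (plain dynamic programming)."""
    n, m = len(a), len(b)
    NEG = -1e18
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def test_local_score_matches_independent_dp():
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    rng = np.random.default_rng(1)
    for _ in range(5):
        a = random_protein(rng, 12)
        b = random_protein(rng, 10)
        pa = families.align_pair(a, b)
        assert pa.score == pytest.approx(_gotoh_local(a, b, blosum))


def test_unrelated_sequences_have_low_coverage():
    rng = np.random.default_rng(2)
    for _ in range(5):
        a, b = random_protein(rng, 200), random_protein(rng, 200)
        assert families.align_pair(a, b).coverage < 0.6


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        families.align_pair("", "MKV")


# ---------------------------------------------------------------------------
# greedy_cluster

def _labels(clusters, names):
    member_of = {m: cl.cluster_id for cl in clusters for m in cl.members}
    return [member_of[n] for n in names]


def test_zero_divergence_families_recovered_exactly():
    prot, truth = synthetic.generate_families(
        synthetic.FamilySpec(3, 4, consensus_length=90, divergence=0.0, seed=3)
    )
    clusters = families.greedy_cluster(prot)
    names = sorted(prot)
    ari = adjusted_rand_score(
        [t for t in truth.set_index("member").loc[names, "family"]],
        _labels(clusters, names),
    )
    assert ari == 1.0


def test_greedy_recovery_at_divergence_point_two():
    prot, truth = synthetic.generate_families(
        synthetic.FamilySpec(4, 6, consensus_length=120, divergence=0.2, seed=4)
    )
    clusters = families.greedy_cluster(prot)
    names = sorted(prot)
    ari = adjusted_rand_score(
        [t for t in truth.set_index("member").loc[names, "family"]],
        _labels(clusters, names),
    )
    assert ari >= 0.9


def test_singleton_outlier_stays_singleton():
    prot, _ = synthetic.generate_families(
        synthetic.FamilySpec(2, 3, consensus_length=100, divergence=0.05, seed=5)
    )
    prot["outlier"] = random_protein(np.random.default_rng(99), 100)
    clusters = families.greedy_cluster(prot)
    home = next(cl for cl in clusters if "outlier" in cl.members)
    assert home.members == ["outlier"]


# ---------------------------------------------------------------------------
# build_profile

def test_single_member_profile_consensus_is_the_member():
    seq = "MKVLATTWEIRAAGHQ"
    prof = families.build_profile(Cluster("c0", "p0", ["p0"]), {"p0": seq})
    assert prof.consensus == seq


def test_identical_members_dominate_every_column():
    seqs = {f"p{i}": "MKVLATTWEI" for i in range(5)}
    prof = families.build_profile(Cluster("c0", "p0", list(seqs)), seqs)
    # Laplace pseudocount 1: dominant frequency (5+1)/(5+20)
    assert np.allclose(prof.freqs.max(axis=1), 6.0 / 25.0)
    assert prof.consensus == "MKVLATTWEI"


def test_profile_frequencies_equal_manual_counts():
    seqs = {
        "p0": "MKVLA",
        "p1": "MKVLA",
        "p2": "MRVLA",
        "p3": "MKVIA",
        "p4": "MKVLA",
    }
    prof = families.build_profile(Cluster("c0", "p0", sorted(seqs)), seqs)
    from ragath.seqs import AA

    # column 1: K x4, R x1 -> (4+1)/25 and (1+1)/25
    assert prof.freqs[1, AA.index("K")] == pytest.approx(5 / 25)
    assert prof.freqs[1, AA.index("R")] == pytest.approx(2 / 25)
    # column 3: L x4, I x1
    assert prof.freqs[3, AA.index("L")] == pytest.approx(5 / 25)
    assert prof.freqs[3, AA.index("I")] == pytest.approx(2 / 25)


# ---------------------------------------------------------------------------
# similarity_graph

@pytest.fixture(scope="module")
def small_graph():
    prot, truth = synthetic.generate_families(
        synthetic.FamilySpec(3, 4, consensus_length=100, divergence=0.15, seed=6)
    )
    initial = families.greedy_cluster(prot)
    profs = {cl.cluster_id: families.build_profile(cl, prot) for cl in initial}
    graph = families.similarity_graph(prot, initial, profs, seed=0)
    return prot, truth, initial, graph


def test_graph_is_symmetric_with_unit_self_loops(small_graph):
    _, _, _, graph = small_graph
    W = graph.weights
    assert np.abs(W - W.T).max() == 0.0
    assert np.allclose(np.diag(W), 1.0)


def test_own_cluster_weight_near_one(small_graph):
    prot, truth, initial, graph = small_graph
    idx = {n: i for i, n in enumerate(graph.node_ids)}
    for cl in initial:
        for a in cl.members:
            for b in cl.members:
                assert graph.weights[idx[a], idx[b]] >= 0.9


def test_unrelated_protein_gets_no_cross_edges(small_graph):
    prot, truth, initial, _ = small_graph
    prot2 = dict(prot)
    prot2["stranger"] = random_protein(np.random.default_rng(123), 100)
    initial2 = families.greedy_cluster(prot2)
    profs = {cl.cluster_id: families.build_profile(cl, prot2) for cl in initial2}
    graph = families.similarity_graph(prot2, initial2, profs, seed=0)
    idx = {n: i for i, n in enumerate(graph.node_ids)}
    i = idx["stranger"]
    off_diag = np.delete(graph.weights[i], i)
    assert (off_diag == 0).all()


# ---------------------------------------------------------------------------
# MCL (with an independently coded reference implementation as the oracle)

def _reference_mcl(W, inflation=2.0, prune=1e-5, tol=1e-6, max_iter=100):
    """Plain-loop MCL used as an oracle; returns a frozenset partition."""
    n = len(W)
    M = [[float(W[i][j]) for j in range(n)] for i in range(n)]
    for i in range(n):
        if M[i][i] == 0.0:
            incident = max((M[k][i] for k in range(n)), default=0.0)
            M[i][i] = incident if incident > 0 else 1.0
    for j in range(n):
        s = sum(M[i][j] for i in range(n))
        for i in range(n):
            M[i][j] /= s
    for _ in range(max_iter):
        M2 = [[sum(M[i][k] * M[k][j] for k in range(n)) for j in range(n)]
              for i in range(n)]
        M2 = [[v**inflation for v in row] for row in M2]
        M2 = [[0.0 if v < prune else v for v in row] for row in M2]
        for j in range(n):
            s = sum(M2[i][j] for i in range(n)) or 1.0
            for i in range(n):
                M2[i][j] /= s
        diff = max(abs(M2[i][j] - M[i][j]) for i in range(n) for j in range(n))
        M = M2
        if diff < tol:
            break
    # components of the symmetrized support
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(n):
            if M[i][j] > 0 or M[j][i] > 0:
                adj[i].add(j)
                adj[j].add(i)
    seen, parts = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        parts.append(frozenset(comp))
    return frozenset(parts)


def _partition(clusters, node_ids):
    idx = {n: i for i, n in enumerate(node_ids)}
    return frozenset(frozenset(idx[m] for m in cl.members) for cl in clusters)


def test_two_disjoint_cliques_stay_separate():
    W = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    W[i, j] = 1.0
    graph = SimilarityGraph([f"n{i}" for i in range(8)], W)
    clusters, converged = families.mcl(graph, inflation=1.5)
    assert converged
    assert _partition(clusters, graph.node_ids) == frozenset(
        {frozenset(range(4)), frozenset(range(4, 8))}
    )


def test_single_edge_forms_one_cluster():
    W = np.array([[0.0, 0.7], [0.7, 0.0]])
    clusters, _ = families.mcl(SimilarityGraph(["a", "b"], W))
    assert len(clusters) == 1 and sorted(clusters[0].members) == ["a", "b"]


def test_mcl_matches_reference_on_random_graphs():
    rng = np.random.default_rng(17)
    for _ in range(30):
        n = int(rng.integers(2, 9))
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    W[i, j] = W[j, i] = round(float(rng.random()), 3)
        graph = SimilarityGraph([f"n{i}" for i in range(n)], W)
        ours, _ = families.mcl(graph)
        assert _partition(ours, graph.node_ids) == _reference_mcl(W)


def test_every_protein_lands_in_exactly_one_cluster():
    rng = np.random.default_rng(23)
    n = 12
    W = (rng.random((n, n)) < 0.3).astype(float) * 0.5
    W = np.triu(W, 1)
    W = W + W.T
    graph = SimilarityGraph([f"n{i}" for i in range(n)], W)
    clusters, _ = families.mcl(graph)
    all_members = [m for cl in clusters for m in cl.members]
    assert sorted(all_members) == sorted(graph.node_ids)


# ---------------------------------------------------------------------------
# two-step recovery

def test_two_step_recovery_divergence_point_three():
    prot, truth = synthetic.generate_families(
        synthetic.FamilySpec(4, 6, consensus_length=120, divergence=0.3, seed=8)
    )
    final, _, _ = families.two_step_cluster(prot, seed=0)
    names = sorted(prot)
    ari = adjusted_rand_score(
        [t for t in truth.set_index("member").loc[names, "family"]],
        _labels(final, names),
    )
    assert ari >= 0.9


def test_no_cross_edges_means_no_merges():
    """Pipeline monotonicity: clusters merge only via above-cutoff edges."""
    prot, _ = synthetic.generate_families(
        synthetic.FamilySpec(3, 4, consensus_length=100, divergence=0.1, seed=9)
    )
    final, initial, graph = families.two_step_cluster(prot, seed=0)
    idx = {n: i for i, n in enumerate(graph.node_ids)}
    initial_of = {m: cl.cluster_id for cl in initial for m in cl.members}
    for cl in final:
        merged_initials = {initial_of[m] for m in cl.members}
        if len(merged_initials) > 1:
            cross = [
                graph.weights[idx[a], idx[b]]
                for a in cl.members
                for b in cl.members
                if initial_of[a] != initial_of[b]
            ]
            assert max(cross) > 0


# ---------------------------------------------------------------------------
# dedupe

def test_exact_duplicates_collapse():
    prot = {"a": "MKVLATTWEI" * 5, "b": "MKVLATTWEI" * 5}
    assert families.dedupe(prot) == ["a"]


def test_ninety_five_percent_pair_collapses():
    rng = np.random.default_rng(10)
    base = random_protein(rng, 100)
    from ragath.seqs import mutate_protein

    variant = mutate_protein(rng, base, 0.05)
    assert families.align_pair(base, variant).identity >= 0.9
    assert len(families.dedupe({"a": base, "b": variant})) == 1


def test_distinct_set_all_kept():
    rng = np.random.default_rng(11)
    prot = {f"p{i}": random_protein(rng, 100) for i in range(4)}
    assert sorted(families.dedupe(prot)) == sorted(prot)


# ---------------------------------------------------------------------------
# taxonomy

LIN = "Bacteria;Firmicutes;Clostridia;Eubacteriales;Lachnospiraceae;GenusX;SpeciesX"


def _hits(lineages):
    return [(lin, 0.8, 0.9) for lin in lineages]


def test_unanimous_species_assigned():
    ta = families.assign_taxonomy("c1", _hits([LIN] * 10), LIN)
    assert ta.assigned_rank == "species"
    assert ta.labels["species"] == "SpeciesX"
    assert ta.agreement == 1.0


def test_species_below_70_percent_falls_back_to_genus():
    other = LIN.replace("SpeciesX", "SpeciesY")
    ta = families.assign_taxonomy("c1", _hits([LIN] * 6 + [other] * 4), LIN)
    assert ta.assigned_rank == "genus"
    assert ta.labels["genus"] == "GenusX"
    assert ta.agreement == 1.0  # all 10 agree at genus


def test_nucleotide_disagreement_undetermined():
    nuc = LIN.replace("GenusX", "GenusZ")
    ta = families.assign_taxonomy("c1", _hits([LIN] * 10), nuc)
    assert not ta.determined


def test_low_identity_hits_excluded_from_denominator():
    hits = [(LIN, 0.8, 0.9)] * 3 + [(LIN.replace("GenusX", "GenusQ"), 0.2, 0.9)] * 7
    ta = families.assign_taxonomy("c1", hits, LIN)
    assert ta.assigned_rank == "species"


def test_no_annotated_proteins_undetermined():
    ta = families.assign_taxonomy("c1", [], LIN)
    assert not ta.determined


# ---------------------------------------------------------------------------
# co-occurrence

def _window(hid, genes):
    return NeighborhoodWindow(hid, genes, [])


def test_cooccurrence_all_adjacent_is_one():
    hits = [(f"h{i}", "ragath18") for i in range(5)]
    windows = {f"h{i}": _window(f"h{i}", [f"g{i}"]) for i in range(5)}
    fam = Cluster("tnpb", "g0", [f"g{i}" for i in range(5)])
    table = families.cooccurrence(hits, windows, [fam])
    assert table.iloc[0].fraction == 1.0


def test_cooccurrence_zero_without_members():
    hits = [(f"h{i}", "ragath18") for i in range(5)]
    windows = {f"h{i}": _window(f"h{i}", [f"g{i}"]) for i in range(5)}
    fam = Cluster("absent", "x0", ["x0", "x1"])
    table = families.cooccurrence(hits, windows, [fam])
    assert table.iloc[0].fraction == 0.0


def test_cooccurrence_sixty_four_percent():
    """100 hits, 64 with a family member in the window -> fraction 0.64."""
    hits = [(f"h{i}", "ragath18") for i in range(100)]
    windows = {
        f"h{i}": _window(f"h{i}", [f"g{i}" if i < 64 else f"z{i}"])
        for i in range(100)
    }
    fam = Cluster("tnpb", "g0", [f"g{i}" for i in range(64)])
    table = families.cooccurrence(hits, windows, [fam])
    row = table.iloc[0]
    assert (row["count"], row.total, row.fraction) == (64, 100, 0.64)


# ---------------------------------------------------------------------------
# representative selection

def test_at_most_six_per_species():
    members = [f"p{i}" for i in range(10)]
    cl = Cluster("c0", "p0", members)
    kept = families.select_representatives(
        [cl], {m: "sp1" for m in members}, {m: 100 + i for i, m in enumerate(members)}
    )
    assert len(kept) == 6
    assert kept[0] == "p9"  # longest first


def test_small_clusters_kept_whole():
    cl = Cluster("c0", "p0", ["p0", "p1", "p2"])
    kept = families.select_representatives(
        [cl], {m: "sp1" for m in cl.members}, {m: 100 for m in cl.members}
    )
    assert sorted(kept) == ["p0", "p1", "p2"]


def test_two_species_capped_independently():
    members = [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)]
    cl = Cluster("c0", members[0], members)
    species = {m: ("spA" if m.startswith("a") else "spB") for m in members}
    kept = families.select_representatives(
        [cl], species, {m: 100 for m in members}
    )
    assert len([m for m in kept if m.startswith("a")]) == 6
    assert len([m for m in kept if m.startswith("b")]) == 6
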
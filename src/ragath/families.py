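"""Two-step protein family clustering and co-occurrence statistics.

Step one is greedy identity clustering (longest sequence founds a
cluster; later sequences join the first representative passing both the
identity and coverage thresholds).  Step two integrates remote homology:
a frequency profile is built per initial cluster by star alignment, a
protein-vs-profile similarity graph is assembled with calibrated
significance filtering, and Markov clustering (MCL, inflation 2.0)
yields the final families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .islands import NeighborhoodWindow
from .profiles import Profile, score_profile
from .seqs import AA, random_protein

RANKS = ["superkingdom", "phylum", "class", "order", "family", "genus", "species"]


# ---------------------------------------------------------------------------
# Pairwise alignment

def _protein_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass
class PairAlignment:
    query: str
    subject: str
    identity: float     # identical / aligned (non-gap both) columns
    coverage: float     # aligned columns / min(len_q, len_s)
    score: float


def align_pair(
    a: str,
    b: str,
    query_id: str = "query",
    subject_id: str = "subject",
    mode: str = "local",
) -> PairAlignment:
    """Smith-Waterman local alignment (BLOSUM62, affine gaps) of two proteins."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _protein_aligner(mode)
    aln = aligner.align(a, b)[0]
    a_blocks, b_blocks = aln.aligned
    aligned_cols = sum(int(e - s) for s, e in a_blocks)
    matches = 0
    for (as_, ae), (bs, _) in zip(a_blocks, b_blocks):
        for k in range(ae - as_):
            if a[as_ + k] == b[bs + k]:
                matches += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    coverage = aligned_cols / min(len(a), len(b))
    return PairAlignment(query_id, subject_id, identity, coverage, float(aln.score))


# ---------------------------------------------------------------------------
# Greedy identity clustering (step one)

@dataclass
class Cluster:
    cluster_id: str
    representative: str
    members: list[str]


def greedy_cluster(
    proteins: dict[str, str],
    min_identity: float = 0.3,
    min_coverage: float = 0.6,
) -> list[Cluster]:
    """Longest-first greedy clustering on identity x coverage thresholds.

    Each protein joins the first existing representative (in founding
    order) for which both identity >= ``min_identity`` and coverage >=
    ``min_coverage`` hold, else it founds a new cluster.
    """
    order = sorted(proteins, key=lambda k: (-len(proteins[k]), k))
    clusters: list[Cluster] = []
    for name in order:
        seq = proteins[name]
        placed = False
        for cl in clusters:
            pa = align_pair(seq, proteins[cl.representative])
            if pa.identity >= min_identity and pa.coverage >= min_coverage:
                cl.members.append(name)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(f"c{len(clusters):04d}", name, [name]))
    return clusters


# ---------------------------------------------------------------------------
# Cluster profiles (star alignment, Laplace pseudocount)

def build_profile(cluster: Cluster, proteins: dict[str, str]) -> Profile:
    """Frequency profile over the cluster from a star alignment.

    The longest member anchors the alignment; every other member is
    globally aligned to it and its residues are projected onto anchor
    columns (insertions relative to the anchor are dropped).  Column
    frequencies use a Laplace pseudocount of 1.
    """
    members = sorted(cluster.members, key=lambda m: (-len(proteins[m]), m))
    anchor = proteins[members[0]]
    L = len(anchor)
    counts = np.zeros((L, 20))
    aa_index = {a: i for i, a in enumerate(AA)}
    for i, ch in enumerate(anchor):
        if ch in aa_index:
            counts[i, aa_index[ch]] += 1
    aligner = _protein_aligner("global")
    for m in members[1:]:
        seq = proteins[m]
        aln = aligner.align(anchor, seq)[0]
        a_blocks, b_blocks = aln.aligned
        for (as_, ae), (bs, _) in zip(a_blocks, b_blocks):
            for k in range(ae - as_):
                ch = seq[bs + k]
                if ch in aa_index:
                    counts[as_ + k, aa_index[ch]] += 1
    freqs = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + 20.0)
    return Profile(cluster.cluster_id, freqs)


# ---------------------------------------------------------------------------
# Similarity graph (step two input)

@dataclass
class SimilarityGraph:
    node_ids: list[str]
    weights: np.ndarray   # symmetric, in [0, 1], with self-loops

    def __post_init__(self):
        if self.weights.size and np.abs(self.weights - self.weights.T).max() > 1e-12:
            raise ValueError("similarity graph weights must be symmetric")


def _profile_null_threshold(
    profile: Profile,
    length: int,
    tail: float,
    n_null: int,
    seed: int,
    cache: dict,
) -> float:
    from scipy import stats

    key = (profile.profile_id, max(50, int(round(length / 50)) * 50))
    if key not in cache:
        rng = np.random.default_rng(seed + hash(key) % (2**16))
        scores = np.array(
            [score_profile(random_protein(rng, key[1]), profile) for _ in range(n_null)]
        )
        loc, scale = stats.gumbel_r.fit(scores)
        cache[key] = float(stats.gumbel_r.isf(tail, loc=loc, scale=scale))
    return cache[key]


def similarity_graph(
    proteins: dict[str, str],
    clusters: list[Cluster],
    profiles: dict[str, Profile],
    significance_tail: float = 1e-5,
    n_null: int = 200,
    seed: int = 0,
) -> SimilarityGraph:
    """Protein graph weighted by normalized cross-profile scores.

    The directed affinity of protein i toward cluster c(j) is
    score(i, P_c(j)) / score(i, P_c(i)); affinities whose raw score
    falls below the calibrated significance threshold (1e-5 tail
    analogue, shuffled-background Gumbel fit per length bin) are
    dropped.  Weights are symmetrized by averaging and clipped to [0, 1].
    """
    node_ids = sorted(proteins)
    idx = {n: i for i, n in enumerate(node_ids)}
    cluster_of = {m: cl.cluster_id for cl in clusters for m in cl.members}
    n = len(node_ids)

    self_score = np.empty(n)
    raw = np.zeros((n, len(clusters)))
    thresholds = np.zeros((n, len(clusters)))
    cache: dict = {}
    cluster_ids = [cl.cluster_id for cl in clusters]
    for i, name in enumerate(node_ids):
        seq = proteins[name]
        for j, cid in enumerate(cluster_ids):
            raw[i, j] = score_profile(seq, profiles[cid])
            thresholds[i, j] = _profile_null_threshold(
                profiles[cid], len(seq), significance_tail, n_null, seed, cache
            )
        self_score[i] = raw[i, cluster_ids.index(cluster_of[name])]

    col_of = {cid: j for j, cid in enumerate(cluster_ids)}
    W = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            ca, cb = cluster_of[node_ids[a]], cluster_of[node_ids[b]]
            terms = []
            s_ab = raw[a, col_of[cb]]
            if s_ab >= thresholds[a, col_of[cb]] and self_score[a] > 0:
                terms.append(s_ab / self_score[a])
            s_ba = raw[b, col_of[ca]]
            if s_ba >= thresholds[b, col_of[ca]] and self_score[b] > 0:
                terms.append(s_ba / self_score[b])
            if terms:
                w = float(np.clip(np.mean(terms), 0.0, 1.0))
                W[a, b] = W[b, a] = w
    return SimilarityGraph(node_ids, W)


# ---------------------------------------------------------------------------
# Markov clustering

def mcl(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    prune: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[list[Cluster], bool]:
    """Markov clustering: alternate expansion and inflation to convergence.

    Missing self-loops are added as the maximum incident edge weight.
    Returns (clusters, converged); clusters are the weakly connected
    components of the attractor support, ordered by smallest member
    index so overlapping attractors resolve to the lowest-indexed
    cluster.
    """
    W = graph.weights.astype(float).copy()
    n = W.shape[0]
    if n == 0:
        return [], True
    diag = np.diag(W).copy()
    incident_max = np.where(W.sum(axis=0) > 0, W.max(axis=0), 1.0)
    np.fill_diagonal(W, np.where(diag > 0, diag, incident_max))

    colsum = W.sum(axis=0)
    colsum[colsum == 0] = 1.0
    M = W / colsum
    converged = False
    for _ in range(max_iter):
        M2 = M @ M
        M2 = np.power(M2, inflation)
        M2[M2 < prune] = 0.0
        colsum = M2.sum(axis=0)
        colsum[colsum == 0] = 1.0
        M2 /= colsum
        if np.abs(M2 - M).max() < tol:
            M = M2
            converged = True
            break
        M = M2

    adj = csr_matrix(((M + M.T) > 0).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=False)
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    clusters = []
    for k, members_idx in enumerate(sorted(groups.values(), key=min)):
        members = sorted(graph.node_ids[i] for i in members_idx)
        clusters.append(Cluster(f"mcl{k:04d}", members[0], members))
    return clusters, converged


def two_step_cluster(
    proteins: dict[str, str],
    min_identity: float = 0.3,
    min_coverage: float = 0.6,
    inflation: float = 2.0,
    significance_tail: float = 1e-5,
    n_null: int = 200,
    seed: int = 0,
) -> tuple[list[Cluster], list[Cluster], SimilarityGraph]:
    """Full two-step procedure: greedy clusters -> profiles -> graph -> MCL.

    Returns (final_clusters, initial_clusters, graph).
    """
    initial = greedy_cluster(proteins, min_identity, min_coverage)
    profs = {cl.cluster_id: build_profile(cl, proteins) for cl in initial}
    graph = similarity_graph(
        proteins, initial, profs, significance_tail, n_null, seed
    )
    final, _ = mcl(graph, inflation=inflation)
    return final, initial, graph


# ---------------------------------------------------------------------------
# Redundancy filtering

def dedupe(proteins: dict[str, str], min_identity: float = 0.9) -> list[str]:
    """Greedy longest-first redundancy filter.

    Every removed protein has identity >= ``min_identity`` to some kept
    representative.
    """
    order = sorted(proteins, key=lambda k: (-len(proteins[k]), k))
    reps: list[str] = []
    for name in order:
        redundant = any(
            align_pair(proteins[name], proteins[r]).identity >= min_identity
            for r in reps
        )
        if not redundant:
            reps.append(name)
    return reps


# ---------------------------------------------------------------------------
# Taxonomy

@dataclass
class TaxonomyAssignment:
    contig: str
    assigned_rank: str | None   # rank name, or None when undetermined
    labels: dict[str, str]      # nested labels up to the assigned rank
    agreement: float

    @property
    def determined(self) -> bool:
        return self.assigned_rank is not None


def assign_taxonomy(
    contig: str,
    protein_hits: list[tuple[str, float, float]],
    nucleotide_lineage: str | None,
    min_identity: float = 0.4,
    min_coverage: float = 0.7,
    min_agreement: float = 0.70,
) -> TaxonomyAssignment:
    """Consensus taxonomy from protein best hits, confirmed by the
    nucleotide-level best hit.

    ``protein_hits`` are (7-rank lineage, identity, coverage) triples;
    hits below the identity/coverage filter are excluded from the
    denominator.  The protein consensus is the most specific rank with
    > ``min_agreement`` agreement; the assignment stands only if the
    nucleotide lineage carries the same label at that rank.
    """
    kept = [
        lin.split(";")
        for lin, ident, cov in protein_hits
        if ident > min_identity and cov > min_coverage
    ]
    kept = [l for l in kept if len(l) == 7]
    if not kept:
        return TaxonomyAssignment(contig, None, {}, 0.0)

    consensus_rank = None
    consensus_prefix: tuple[str, ...] = ()
    agreement = 0.0
    for depth in range(7, 0, -1):  # most specific rank first
        prefixes = [tuple(l[:depth]) for l in kept]
        top, count = max(
            ((p, prefixes.count(p)) for p in set(prefixes)), key=lambda t: (t[1], t[0])
        )
        frac = count / len(kept)
        if frac > min_agreement:
            consensus_rank = RANKS[depth - 1]
            consensus_prefix = top
            agreement = frac
            break
    if consensus_rank is None:
        return TaxonomyAssignment(contig, None, {}, 0.0)

    if nucleotide_lineage is None:
        return TaxonomyAssignment(contig, None, {}, agreement)
    nuc = tuple(nucleotide_lineage.split(";")[: len(consensus_prefix)])
    if nuc != consensus_prefix:
        return TaxonomyAssignment(contig, None, {}, agreement)
    labels = dict(zip(RANKS, consensus_prefix))
    return TaxonomyAssignment(contig, consensus_rank, labels, agreement)


# ---------------------------------------------------------------------------
# Co-occurrence and representative selection

def cooccurrence(
    hits: list[tuple[str, str]],
    windows: dict[str, NeighborhoodWindow],
    families: list[Cluster],
    gene_to_protein: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per (motif, family): fraction of motif hits whose neighborhood
    window contains >= 1 family member.

    ``hits`` are (hit_id, motif_name) pairs; ``gene_to_protein`` maps
    window gene ids to protein ids (identity mapping by default).
    """
    rows = []
    motifs = sorted({m for _, m in hits})
    for motif in motifs:
        motif_hits = [h for h, m in hits if m == motif]
        total = len(motif_hits)
        for fam in families:
            member_set = set(fam.members)
            count = 0
            for h in motif_hits:
                win = windows.get(h)
                if win is None:
                    continue
                prots = {
                    gene_to_protein.get(g, g) if gene_to_protein else g
                    for g in win.gene_ids
                }
                if prots & member_set:
                    count += 1
            rows.append(
                dict(
                    motif=motif,
                    family=fam.cluster_id,
                    count=count,
                    total=total,
                    fraction=count / total if total else 0.0,
                )
            )
    df = pd.DataFrame(rows, columns=["motif", "family", "count", "total", "fraction"])
    return df.sort_values(
        ["fraction", "motif", "family"], ascending=[False, True, True]
    ).reset_index(drop=True)


def select_representatives(
    clusters: list[Cluster],
    species_of: dict[str, str],
    lengths: dict[str, int],
    max_per_species: int = 6,
) -> list[str]:
    """Keep at most ``max_per_species`` proteins per species per cluster,
    longest first (ties by id); deterministic ordering."""
    kept: list[str] = []
    for cl in clusters:
        by_species: dict[str, list[str]] = {}
        for m in cl.members:
            by_species.setdefault(species_of.get(m, "unknown"), []).append(m)
        for sp in sorted(by_species):
            members = sorted(by_species[sp], key=lambda m: (-lengths[m], m))
            kept.extend(members[:max_per_species])
    return kept
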
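"""Defense-island mining: role annotation, island calling, IGR extraction
and gene neighborhoods around RNA hits.

A defense island is a maximal contiguous run of non-housekeeping genes,
bounded on each side by a housekeeping gene (or the contig edge, flagged
as such), that contains at least one defense gene.  Island contiguity is
strand-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .profiles import ProfileDB, best_hit, calibrate_db_null, significance

DEFENSE_EVALUE = 1e-4
HOUSEKEEPING_EVALUE = 1e-2


@dataclass
class GeneRecord:
    contig: str
    gene_id: str
    start: int
    end: int
    strand: str
    protein: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


def genes_from_frame(df: pd.DataFrame) -> list[GeneRecord]:
    return [
        GeneRecord(
            r["contig"], r["gene_id"], int(r["start"]), int(r["end"]),
            r["strand"], r.get("protein", ""),
        )
        for r in df.to_dict("records")
    ]


@dataclass
class RoleAnnotation:
    gene_id: str
    role: str
    best_profile: str | None
    score: float
    evalue: float


@dataclass
class DefenseIsland:
    contig: str
    members: list[str]
    left_flank: str | None      # housekeeping gene id, or None at a contig edge
    right_flank: str | None
    n_defense: int
    start: int
    end: int

    @property
    def edge(self) -> bool:
        return self.left_flank is None or self.right_flank is None


@dataclass
class IntergenicRegion:
    contig: str
    igr_id: str
    start: int
    end: int
    left_gene: str | None
    right_gene: str | None
    inside_island: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class NeighborhoodWindow:
    anchor: str
    upstream: list[str]     # genomic order, nearest last
    downstream: list[str]   # genomic order, nearest first

    @property
    def gene_ids(self) -> list[str]:
        return self.upstream + self.downstream


# ---------------------------------------------------------------------------

def annotate_roles(
    genes: list[GeneRecord],
    defense_db: ProfileDB,
    housekeeping_db: ProfileDB,
    defense_evalue: float = DEFENSE_EVALUE,
    housekeeping_evalue: float = HOUSEKEEPING_EVALUE,
    n_null: int = 1000,
    seed: int = 0,
) -> list[RoleAnnotation]:
    """Assign exactly one role per gene from profile-DB hits.

    Significance of the best hit is the Gumbel tail probability fitted
    to best-over-DB scores of random sequences in the gene's length bin;
    the defense threshold (1e-4 analogue) is stricter than the
    housekeeping one (1e-2 analogue), and defense wins when both pass.
    """
    out = []
    for g in genes:
        if not g.protein:
            warnings.warn(f"gene {g.gene_id}: empty protein, assigning role=other")
            out.append(RoleAnnotation(g.gene_id, "other", None, float("-inf"), 1.0))
            continue
        d_id, d_score = best_hit(g.protein, defense_db)
        h_id, h_score = best_hit(g.protein, housekeeping_db)
        d_null = calibrate_db_null(defense_db, len(g.protein), n_null, seed)
        h_null = calibrate_db_null(housekeeping_db, len(g.protein), n_null, seed)
        d_sig = significance(d_score, d_null)
        h_sig = significance(h_score, h_null)
        if d_sig <= defense_evalue:
            out.append(RoleAnnotation(g.gene_id, "defense", d_id, d_score, d_sig))
        elif h_sig <= housekeeping_evalue:
            out.append(RoleAnnotation(g.gene_id, "housekeeping", h_id, h_score, h_sig))
        else:
            best = max((d_score, d_id, d_sig), (h_score, h_id, h_sig))
            out.append(RoleAnnotation(g.gene_id, "other", best[1], best[0], best[2]))
    return out


def call_islands(
    genes: list[GeneRecord],
    roles: dict[str, str],
) -> list[DefenseIsland]:
    """Call defense islands on each contig from per-gene roles.

    ``genes`` must be sorted by start within each contig; islands are
    maximal non-housekeeping runs with >= 1 defense member, reported
    with their bounding housekeeping genes (None at contig edges).
    """
    islands: list[DefenseIsland] = []
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for contig, glist in by_contig.items():
        glist = sorted(glist, key=lambda g: g.start)
        n = len(glist)
        i = 0
        while i < n:
            if roles[glist[i].gene_id] == "housekeeping":
                i += 1
                continue
            j = i
            while j + 1 < n and roles[glist[j + 1].gene_id] != "housekeeping":
                j += 1
            run = glist[i : j + 1]
            n_def = sum(roles[g.gene_id] == "defense" for g in run)
            if n_def >= 1:
                islands.append(
                    DefenseIsland(
                        contig=contig,
                        members=[g.gene_id for g in run],
                        left_flank=glist[i - 1].gene_id if i > 0 else None,
                        right_flank=glist[j + 1].gene_id if j + 1 < n else None,
                        n_defense=n_def,
                        start=run[0].start,
                        end=run[-1].end,
                    )
                )
            i = j + 1
    return islands


def extract_igrs(
    contig_lengths: dict[str, int],
    genes: list[GeneRecord],
    min_len: int = 15,
    islands: list[DefenseIsland] | None = None,
) -> list[IntergenicRegion]:
    """Regions strictly between gene spans (and contig termini).

    Overlapping genes are merged before gap extraction; IGRs shorter
    than ``min_len`` are discarded.  ``inside_island`` marks IGRs that
    fall within an island's gene span.
    """
    island_spans: dict[str, list[tuple[int, int]]] = {}
    for isl in islands or []:
        island_spans.setdefault(isl.contig, []).append((isl.start, isl.end))

    out: list[IntergenicRegion] = []
    by_contig: dict[str, list[GeneRecord]] = {c: [] for c in contig_lengths}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)

    for contig, length in contig_lengths.items():
        glist = sorted(by_contig.get(contig, []), key=lambda g: g.start)
        # merge overlapping gene intervals, remembering flanking gene ids
        merged: list[tuple[int, int, str]] = []
        for g in glist:
            if merged and g.start < merged[-1][1]:
                s, e, gid = merged[-1]
                merged[-1] = (s, max(e, g.end), gid)
            else:
                merged.append((g.start, g.end, g.gene_id))
        bounds = [(0, None)] + [(e, gid) for _, e, gid in merged]
        next_starts = [(s, gid) for s, _, gid in merged] + [(length, None)]
        k = 0
        for (gap_start, left_id), (gap_end, right_id) in zip(bounds, next_starts):
            if gap_end - gap_start < min_len:
                continue
            inside = any(
                gap_start >= s and gap_end <= e
                for s, e in island_spans.get(contig, [])
            )
            out.append(
                IntergenicRegion(
                    contig, f"{contig}_igr{k}", gap_start, gap_end,
                    left_id, right_id, inside,
                )
            )
            k += 1
    return out


def neighborhood(
    hit_contig: str,
    hit_start: int,
    hit_end: int,
    genes: list[GeneRecord],
    k: int = 5,
    anchor: str = "hit",
) -> NeighborhoodWindow:
    """Nearest k genes on each side of an RNA hit, in genomic order.

    Genes ending at or before the hit start count as upstream; genes
    starting at or after the hit end count as downstream.  Windows are
    truncated at contig edges.
    """
    contig_genes = sorted(
        (g for g in genes if g.contig == hit_contig), key=lambda g: g.start
    )
    upstream = [g.gene_id for g in contig_genes if g.end <= hit_start][-k:]
    downstream = [g.gene_id for g in contig_genes if g.start >= hit_end][:k]
    return NeighborhoodWindow(anchor, upstream, downstream)
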
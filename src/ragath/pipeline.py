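"""End-to-end discovery workflow and run manifests.

The discovery pipeline chains: role annotation -> island calling -> IGR
extraction -> structured RNA motif scan -> gene neighborhoods ->
two-step protein clustering -> RNA-protein co-occurrence.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .families import Cluster, SimilarityGraph, cooccurrence, two_step_cluster
from .islands import (
    DefenseIsland,
    GeneRecord,
    IntergenicRegion,
    NeighborhoodWindow,
    RoleAnnotation,
    annotate_roles,
    call_islands,
    extract_igrs,
    neighborhood,
)
from .motif import MotifHit, StructuredMotifModel, calibrate_null, scan
from .profiles import ProfileDB

DEFAULT_CONFIG = {
    "igr_min_len": 15,
    "cluster_identity": 0.3,
    "cluster_coverage": 0.6,
    "mcl_inflation": 2.0,
    "tax_agreement": 0.70,
    "tax_identity": 0.40,
    "tax_coverage": 0.70,
    "dedupe_identity": 0.90,
    "max_per_species": 6,
    "neighborhood_k": 5,
    "tam_len": 7,
    "guide_len": 20,
    "scan_fpr": 1e-3,
    "null_n": 10000,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    subcommand: str
    parameters: dict
    seeds: list[int]
    version: str = __version__
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0

    def add_input(self, path: str | Path) -> None:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_checksums[str(path)] = h

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "subcommand": self.subcommand,
                "parameters": self.parameters,
                "seeds": self.seeds,
                "input_checksums": self.input_checksums,
                "outputs": self.outputs,
                "started": self.started,
                "finished": self.finished,
                "rng": "numpy PCG64 via default_rng",
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


@dataclass
class DiscoveryResult:
    roles: list[RoleAnnotation]
    islands: list[DefenseIsland]
    igrs: list[IntergenicRegion]
    hits: list[MotifHit]
    windows: dict[str, NeighborhoodWindow]
    final_clusters: list[Cluster]
    graph: SimilarityGraph
    cooccurrence: pd.DataFrame
    threshold: float
    manifest: RunManifest


def run_discovery(
    genomes: dict[str, str],
    genes: list[GeneRecord],
    defense_db: ProfileDB,
    housekeeping_db: ProfileDB,
    model: StructuredMotifModel,
    seed: int = 0,
    config: dict | None = None,
) -> DiscoveryResult:
    """Execute the full discovery workflow on annotated genomes.

    Raises :class:`StageError` naming the first failing stage; an empty
    genome set is rejected up front.
    """
    if not genomes:
        raise StageError("input", ValueError("empty genome set"))
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    manifest = RunManifest("discover", cfg, [seed], started=time.time())

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, exc) from exc

    roles = stage("annotate_roles", annotate_roles, genes, defense_db,
                  housekeeping_db, seed=seed)
    role_map = {r.gene_id: r.role for r in roles}
    islands = stage("call_islands", call_islands, genes, role_map)
    contig_lengths = {c: len(s) for c, s in genomes.items()}
    igrs = stage("extract_igrs", extract_igrs, contig_lengths, genes,
                 cfg["igr_min_len"], islands)

    _, threshold = stage("calibrate_null", calibrate_null, model,
                         cfg["null_n"], seed, cfg["scan_fpr"])
    hits: list[MotifHit] = []
    for igr in igrs:
        seq = genomes[igr.contig][igr.start : igr.end]
        for h in stage("scan", scan, seq, model, threshold, igr.igr_id):
            # lift hit coordinates from the IGR onto the contig
            h.start += igr.start
            h.end += igr.start
            h.igr_id = igr.igr_id
            hits.append(h)

    igr_contig = {igr.igr_id: igr.contig for igr in igrs}
    windows: dict[str, NeighborhoodWindow] = {}
    neighborhood_proteins: dict[str, str] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for i, h in enumerate(hits):
        hid = f"hit{i:04d}"
        win = stage("neighborhood", neighborhood, igr_contig[h.igr_id],
                    h.start, h.end, genes, cfg["neighborhood_k"], hid)
        windows[hid] = win
        for gid in win.gene_ids:
            if gene_by_id[gid].protein:
                neighborhood_proteins[gid] = gene_by_id[gid].protein

    if neighborhood_proteins:
        final, _initial, graph = stage(
            "cluster", two_step_cluster, neighborhood_proteins,
            cfg["cluster_identity"], cfg["cluster_coverage"],
            cfg["mcl_inflation"], seed=seed,
        )
    else:
        final, graph = [], SimilarityGraph([], np.zeros((0, 0)))

    hit_pairs = [(f"hit{i:04d}", model.name) for i in range(len(hits))]
    cooc = stage("cooccurrence", cooccurrence, hit_pairs, windows, final)

    manifest.finished = time.time()
    return DiscoveryResult(
        roles, islands, igrs, hits, windows, final, graph, cooc,
        threshold, manifest,
    )
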
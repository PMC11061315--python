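"""Synthetic-data generators with exported ground truth.

Every input the pipeline consumes can be generated here, with truth
tables sufficient to score any downstream stage: annotated genomes with
planted defense islands and intergenic RNA motifs, protein families at
controlled divergence, and the four read types used to characterize the
nuclease (TAM library, run-off products, small RNA, amplicons).

All generators are pure functions of (spec, seed): identical inputs
produce byte-identical outputs.  Sequencing noise is substitution-only,
so indel truth in amplicon reads is unambiguous.  FASTQ qualities are a
constant high symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleavage import CleavageEngineParams, ConfigurationError, DnaSubstrate, draw_cut
from .io import FastqRead
from .profiles import ProfileDB
from .seqs import mutate_dna, mutate_protein, random_dna, random_protein, revcomp

ROLES = ("defense", "housekeeping", "other")
_QUAL = "I"


@dataclass
class ReadSimParams:
    depth: int
    error_rate: float = 0.001
    read_length: int = 100
    adapter: str = "ACACGACGCTCTTC"
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ConfigurationError("depth must be positive")
        if not 0 <= self.error_rate <= 0.1:
            raise ConfigurationError("error_rate must be in [0, 0.1]")


# ---------------------------------------------------------------------------
# Genomes

@dataclass
class PlantedIsland:
    contig: int
    start_gene: int     # index of the first island member on the contig
    n_genes: int
    n_defense: int = 1


@dataclass
class MotifPlant:
    contig: int
    igr_index: int      # IGR i precedes gene i; there are n_genes + 1 IGRs
    strand: str
    sequence: str


@dataclass
class GenomeSpec:
    n_contigs: int
    genes_per_contig: int
    role_mix: tuple[float, float, float] = (0.1, 0.4, 0.5)  # defense, hk, other
    island_spec: list[PlantedIsland] = field(default_factory=list)
    motif_plants: list[MotifPlant] = field(default_factory=list)
    gene_length_range: tuple[int, int] = (300, 900)
    igr_length_range: tuple[int, int] = (30, 150)
    seed: int = 0
    defense_profiles: ProfileDB | None = None
    housekeeping_profiles: ProfileDB | None = None

    def __post_init__(self):
        if abs(sum(self.role_mix) - 1.0) > 1e-9:
            raise ConfigurationError("role_mix must sum to 1")
        for lo, hi in (self.gene_length_range, self.igr_length_range):
            if lo <= 0 or hi < lo:
                raise ConfigurationError("length ranges must be positive and ordered")
        for isl in self.island_spec:
            if isl.n_defense < 1 or isl.n_defense > isl.n_genes:
                raise ConfigurationError("island needs 1 <= n_defense <= n_genes")
            if isl.start_gene < 1 or isl.start_gene + isl.n_genes > self.genes_per_contig - 1:
                raise ConfigurationError(
                    "island (with housekeeping flanks) does not fit on the contig"
                )
            if not 0 <= isl.contig < self.n_contigs:
                raise ConfigurationError("island contig index out of range")
        for mp in self.motif_plants:
            if not 0 <= mp.contig < self.n_contigs:
                raise ConfigurationError("motif contig index out of range")
            if not 0 <= mp.igr_index <= self.genes_per_contig:
                raise ConfigurationError("motif IGR index out of range")
            if len(mp.sequence) + 2 > self.igr_length_range[1]:
                raise ConfigurationError(
                    "igr_length_range too short for planted motif"
                )
            if mp.strand not in "+-":
                raise ConfigurationError("motif strand must be + or -")


@dataclass
class GenomeData:
    sequences: dict[str, str]
    genes: pd.DataFrame       # contig, gene_id, start, end, strand, role, protein
    islands: pd.DataFrame     # contig, island_id, first/last gene index, coords
    igrs: pd.DataFrame        # contig, igr_index, start, end
    motifs: pd.DataFrame      # contig, igr_index, strand, start, end, sequence


def _enumerate_role_islands(roles: list[str]) -> list[tuple[int, int, bool, bool]]:
    """Maximal runs of non-housekeeping genes containing >= 1 defense gene.

    Returns (first_idx, last_idx inclusive, left_edge, right_edge) where
    the edge flags mark contig-edge (rather than housekeeping) bounds.
    """
    out = []
    i, n = 0, len(roles)
    while i < n:
        if roles[i] == "housekeeping":
            i += 1
            continue
        j = i
        while j + 1 < n and roles[j + 1] != "housekeeping":
            j += 1
        if any(roles[k] == "defense" for k in range(i, j + 1)):
            out.append((i, j, i == 0, j == n - 1))
        i = j + 1
    return out


def generate_genome(spec: GenomeSpec) -> GenomeData:
    """Generate contigs with planted islands and IGR motifs, plus truth tables.

    Genes are non-overlapping, ordered, and alternate with IGRs so that
    genes + IGRs tile each contig exactly.  Coordinates are 0-based
    half-open everywhere.
    """
    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    gene_rows, island_rows, igr_rows, motif_rows = [], [], [], []

    plants_by_contig: dict[int, list[MotifPlant]] = {}
    for mp in spec.motif_plants:
        plants_by_contig.setdefault(mp.contig, []).append(mp)

    for c in range(spec.n_contigs):
        contig = f"contig{c:03d}"
        n = spec.genes_per_contig
        roles = list(rng.choice(ROLES, size=n, p=spec.role_mix))
        for isl in spec.island_spec:
            if isl.contig != c:
                continue
            s = isl.start_gene
            for k in range(isl.n_genes):
                roles[s + k] = "defense" if k < isl.n_defense else "other"
            roles[s - 1] = "housekeeping"
            roles[s + isl.n_genes] = "housekeeping"

        glo, ghi = spec.gene_length_range
        ilo, ihi = spec.igr_length_range
        gene_lens = rng.integers(glo, ghi + 1, size=n)
        igr_lens = rng.integers(ilo, ihi + 1, size=n + 1)
        contig_plants = plants_by_contig.get(c, [])
        for mp in contig_plants:
            need = len(mp.sequence) + 2
            if igr_lens[mp.igr_index] < need:
                igr_lens[mp.igr_index] = need

        pieces: list[str] = []
        pos = 0
        igr_coords = []
        gene_coords = []
        for i in range(n + 1):
            igr_seq = random_dna(rng, int(igr_lens[i]))
            igr_coords.append((pos, pos + len(igr_seq)))
            pieces.append(igr_seq)
            pos += len(igr_seq)
            if i < n:
                gene_seq = random_dna(rng, int(gene_lens[i]))
                gene_coords.append((pos, pos + len(gene_seq)))
                pieces.append(gene_seq)
                pos += len(gene_seq)

        # embed planted motifs inside their IGRs
        for mp in contig_plants:
            idx = 2 * mp.igr_index  # pieces alternate igr, gene, igr, ...
            igr_seq = pieces[idx]
            mlen = len(mp.sequence)
            off = int(rng.integers(0, len(igr_seq) - mlen + 1))
            embedded = mp.sequence if mp.strand == "+" else revcomp(mp.sequence)
            pieces[idx] = igr_seq[:off] + embedded + igr_seq[off + mlen :]
            m0 = igr_coords[mp.igr_index][0] + off
            motif_rows.append(
                dict(
                    contig=contig,
                    igr_index=mp.igr_index,
                    strand=mp.strand,
                    start=m0,
                    end=m0 + mlen,
                    sequence=mp.sequence,
                )
            )

        sequences[contig] = "".join(pieces)

        for i in range(n):
            role = roles[i]
            length = int(gene_lens[i])
            if role == "defense" and spec.defense_profiles is not None:
                prof = list(spec.defense_profiles)[
                    int(rng.integers(len(spec.defense_profiles)))
                ]
                protein = prof.sample(rng)
            elif role == "housekeeping" and spec.housekeeping_profiles is not None:
                prof = list(spec.housekeeping_profiles)[
                    int(rng.integers(len(spec.housekeeping_profiles)))
                ]
                protein = prof.sample(rng)
            else:
                protein = random_protein(rng, max(30, length // 3))
            s, e = gene_coords[i]
            gene_rows.append(
                dict(
                    contig=contig,
                    gene_id=f"{contig}_g{i:03d}",
                    start=s,
                    end=e,
                    strand="+" if rng.random() < 0.5 else "-",
                    role=role,
                    protein=protein,
                )
            )

        for i, (s, e) in enumerate(igr_coords):
            igr_rows.append(dict(contig=contig, igr_index=i, start=s, end=e))

        for k, (i, j, le, re_) in enumerate(_enumerate_role_islands(roles)):
            island_rows.append(
                dict(
                    contig=contig,
                    island_id=f"{contig}_isl{k}",
                    first_gene=i,
                    last_gene=j,
                    gene_ids=",".join(f"{contig}_g{g:03d}" for g in range(i, j + 1)),
                    n_defense=sum(roles[g] == "defense" for g in range(i, j + 1)),
                    start=gene_coords[i][0],
                    end=gene_coords[j][1],
                    left_edge=le,
                    right_edge=re_,
                )
            )

    return GenomeData(
        sequences=sequences,
        genes=pd.DataFrame(gene_rows),
        islands=pd.DataFrame(
            island_rows,
            columns=[
                "contig", "island_id", "first_gene", "last_gene", "gene_ids",
                "n_defense", "start", "end", "left_edge", "right_edge",
            ],
        ),
        igrs=pd.DataFrame(igr_rows),
        motifs=pd.DataFrame(
            motif_rows,
            columns=["contig", "igr_index", "strand", "start", "end", "sequence"],
        ),
    )


# ---------------------------------------------------------------------------
# Protein families

@dataclass
class FamilySpec:
    n_families: int
    members_per_family: int
    consensus_length: int = 150
    divergence: float = 0.2
    species_labels: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.divergence < 1:
            raise ConfigurationError("divergence must be in [0, 1)")
        if min(self.n_families, self.members_per_family, self.consensus_length) < 1:
            raise ConfigurationError("family spec counts must be positive")


def _default_lineage(i: int) -> str:
    return (
        "Bacteria;Firmicutes;Clostridia;Eubacteriales;"
        f"Lachnospiraceae;Genus{i:02d};Species{i:02d}"
    )


def generate_families(spec: FamilySpec) -> tuple[dict[str, str], pd.DataFrame]:
    """Point-substituted families from random consensus sequences.

    Returns (proteins, truth) where truth columns are member, family,
    lineage (7-rank, semicolon-separated).
    """
    rng = np.random.default_rng(spec.seed)
    proteins: dict[str, str] = {}
    rows = []
    for f in range(spec.n_families):
        consensus = random_protein(rng, spec.consensus_length)
        for m in range(spec.members_per_family):
            name = f"fam{f:02d}_m{m:02d}"
            proteins[name] = mutate_protein(rng, consensus, spec.divergence)
            lineage = (
                spec.species_labels.get(name, _default_lineage(f))
                if spec.species_labels
                else _default_lineage(f)
            )
            if lineage.count(";") != 6:
                raise ConfigurationError(f"lineage for {name} must have 7 ranks")
            rows.append(dict(member=name, family=f"fam{f:02d}", lineage=lineage))
    return proteins, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TAM library

@dataclass
class TamLibrarySubstrate:
    """Plasmid backbone with a 7-nt randomized window immediately 5' of the
    20-nt target sequence."""

    backbone: str
    window_start: int

    def __post_init__(self):
        self.backbone = self.backbone.upper()
        if self.window_start < 12:
            raise ConfigurationError("need >= 12 nt of backbone 5' of the window")
        if self.window_start + 7 + 20 > len(self.backbone):
            raise ConfigurationError("window + target exceed the backbone")

    @property
    def window(self) -> tuple[int, int]:
        return (self.window_start, self.window_start + 7)

    @property
    def target(self) -> str:
        return self.backbone[self.window_start + 7 : self.window_start + 27]


def make_tam_library_substrate(
    engine: CleavageEngineParams, seed: int = 0, flank: int = 40
) -> TamLibrarySubstrate:
    """Convenience constructor: random backbone with the engine's guide
    sequence as the (fully matched) target."""
    rng = np.random.default_rng(seed)
    backbone = random_dna(rng, flank) + "N" * 7 + engine.guide + random_dna(rng, flank)
    # the randomized window is filled per molecule; placeholder N's here
    return TamLibrarySubstrate(backbone, flank)


def simulate_tam_library_reads(
    engine: CleavageEngineParams,
    substrate: TamLibrarySubstrate,
    params: ReadSimParams,
    n_reads: int | None = None,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Simulate the randomized-TAM cleavage library.

    Each of ``params.depth`` library molecules carries a uniform random
    7-mer in the randomized window.  A molecule is cleaved iff its 5
    TAM-proximal bases (the window's 3' end, adjacent to the target)
    equal the engine consensus and the guide matches the target under
    the engine; cleaved molecules emit adapter-prefixed reads spanning
    the TAM window, uncleaved molecules emit none.

    By default each cleaved molecule emits exactly one read.  When
    ``n_reads`` is given, the cleaved pool is amplified and sequenced to
    that depth (reads drawn uniformly with replacement from cleaved
    molecules), emulating the PCR step of the assay.
    """
    rng = np.random.default_rng(params.seed)
    w0, w1 = substrate.window
    target = substrate.target
    anchor = substrate.backbone[w0 - 12 : w0]

    codes = rng.integers(0, 4, size=(params.depth, 7))
    cons = np.array(["ACGT".find(c) for c in engine.tam_consensus])
    tam_match = (codes[:, 2:] == cons).all(axis=1)
    eff_matched = engine.efficiency(engine.tam_consensus, target)
    cleaved = tam_match & (rng.random(params.depth) < eff_matched)
    bases = np.array(list("ACGT"))
    mers = ["".join(row) for row in bases[codes]]
    truth = pd.DataFrame(
        dict(
            molecule=[f"mol{i:06d}" for i in range(params.depth)],
            sevenmer=mers,
            cleaved=cleaved,
        )
    )

    cleaved_idx = np.flatnonzero(cleaved)
    if n_reads is None:
        emit = cleaved_idx
    elif len(cleaved_idx) == 0:
        emit = cleaved_idx
    else:
        emit = rng.choice(cleaved_idx, size=n_reads, replace=True)
    reads: list[FastqRead] = []
    for k, i in enumerate(emit):
        cut = draw_cut(rng, engine.nts_site_dist)
        insert = anchor + mers[i] + substrate.backbone[w1 : w1 + cut]
        insert = mutate_dna(rng, insert, params.error_rate)
        seq = (params.adapter + insert)[: max(params.read_length, len(params.adapter) + 19)]
        reads.append(FastqRead(f"read{k:06d}_mol{i:06d}", seq, _QUAL * len(seq)))
    return reads, truth


# ---------------------------------------------------------------------------
# Run-off reads

def simulate_runoff_reads(
    engine: CleavageEngineParams,
    substrate: DnaSubstrate,
    n: int,
    seed: int = 0,
) -> tuple[list[FastqRead], list[FastqRead], pd.DataFrame]:
    """Per-strand run-off reads whose terminal base marks the cut.

    Cut positions are drawn i.i.d. from the engine's per-strand site
    distributions; the substrate must carry an exact TAM and fully
    matched target.  Returns (ts_reads, nts_reads, truth).
    """
    if engine.efficiency(substrate.tam, substrate.target) != 1.0:
        raise ConfigurationError(
            "run-off simulation needs an exact TAM and fully matched target"
        )
    rng = np.random.default_rng(seed)
    seq = substrate.sequence
    t0 = substrate.target_start
    ts_reads, nts_reads, rows = [], [], []
    for i in range(n):
        pos = draw_cut(rng, engine.nts_site_dist)
        read = seq[: t0 + pos]
        nts_reads.append(FastqRead(f"nts{i:06d}", read, _QUAL * len(read)))
        rows.append(dict(read=f"nts{i:06d}", strand="NTS", position=pos))
    for i in range(n):
        pos = draw_cut(rng, engine.ts_site_dist)
        read = revcomp(seq[t0 + pos :])
        ts_reads.append(FastqRead(f"ts{i:06d}", read, _QUAL * len(read)))
        rows.append(dict(read=f"ts{i:06d}", strand="TS", position=pos))
    return ts_reads, nts_reads, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Small RNA

def simulate_small_rna_reads(
    locus: str,
    transcript_bounds: tuple[int, int],
    params: ReadSimParams,
    mode: str = "random",
    step: int = 1,
) -> list[FastqRead]:
    """Reads sampled strictly from within the transcript bounds.

    ``mode='tiling'`` emits every ``step``-spaced window exactly once
    (deterministic); ``mode='random'`` samples ``depth`` uniform start
    positions with substitution errors at ``error_rate``.
    """
    t0, t1 = transcript_bounds
    if not 0 <= t0 < t1 <= len(locus):
        raise ConfigurationError("transcript bounds outside the locus")
    rl = params.read_length
    if t1 - t0 < rl:
        raise ConfigurationError("transcript shorter than read_length")
    rng = np.random.default_rng(params.seed)
    reads = []
    if mode == "tiling":
        starts = range(t0, t1 - rl + 1, step)
    elif mode == "random":
        starts = rng.integers(t0, t1 - rl + 1, size=params.depth)
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    for i, s in enumerate(starts):
        seq = mutate_dna(rng, locus[int(s) : int(s) + rl], params.error_rate)
        reads.append(FastqRead(f"sr{i:06d}", seq, _QUAL * rl))
    return reads


# ---------------------------------------------------------------------------
# Amplicons

def simulate_amplicon_reads(
    reference: str,
    indel_rate: float,
    indel_window: tuple[int, int],
    params: ReadSimParams,
    max_indel: int = 10,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Amplicon reads with exactly round(indel_rate * depth) edited molecules.

    Each edited read carries one indel of 1..``max_indel`` nt at a
    uniform position inside the window; all reads additionally receive
    substitution errors at ``error_rate``.  Truth flags every read.
    """
    w0, w1 = indel_window
    if not 0 <= w0 < w1 <= len(reference):
        raise ConfigurationError("indel window outside the reference")
    if w1 - w0 < max_indel:
        raise ConfigurationError("indel window too small for the maximum indel")
    rng = np.random.default_rng(params.seed)
    n_edit = round(indel_rate * params.depth)
    flags = np.zeros(params.depth, dtype=bool)
    flags[:n_edit] = True
    rng.shuffle(flags)
    reads, rows = [], []
    bases = "ACGT"
    for i in range(params.depth):
        name = f"amp{i:06d}"
        if flags[i]:
            size = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5 and w1 - w0 >= size:  # deletion
                pos = int(rng.integers(w0, w1 - size + 1))
                seq = reference[:pos] + reference[pos + size :]
            else:  # insertion
                pos = int(rng.integers(w0, w1 + 1))
                ins = "".join(bases[rng.integers(4)] for _ in range(size))
                seq = reference[:pos] + ins + reference[pos:]
        else:
            seq = reference
        seq = mutate_dna(rng, seq, params.error_rate)
        reads.append(FastqRead(name, seq, _QUAL * len(seq)))
        rows.append(dict(read=name, edited=bool(flags[i])))
    return reads, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Guide panels (single-substitution mismatch screens)

def guide_panel_rates(
    engine: CleavageEngineParams, base_rate: float
) -> dict[tuple[int, str], float]:
    """Expected indel rate for every single-substitution guide variant.

    The target is held fixed (matching the original guide); each variant
    guide's cleavage efficiency scales the base editing rate.  Keys are
    (position 1-20, substituted base).
    """
    rates = {}
    target = engine.guide
    for pos in range(1, len(engine.guide) + 1):
        for base in "ACGT":
            if base == engine.guide[pos - 1]:
                continue
            variant = engine.guide[: pos - 1] + base + engine.guide[pos:]
            veng = CleavageEngineParams(
                guide=variant,
                tam_consensus=engine.tam_consensus,
                seed_region=engine.seed_region,
                distal_mismatch_factor=engine.distal_mismatch_factor,
                ts_site_dist=engine.ts_site_dist,
                nts_site_dist=engine.nts_site_dist,
            )
            rates[(pos, base)] = base_rate * veng.efficiency(
                engine.tam_consensus, target
            )
    return rates
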
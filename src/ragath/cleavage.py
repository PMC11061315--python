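"""In-silico cleavage engine and nuclease characterization from reads.

The engine models an RNA-guided, TAM-dependent dsDNA endonuclease of the
IS607 TnpB type: cleavage requires an exact match to the 5-nt TAM
(default 5'-AGGAG) immediately 5' of a 20-nt target, and perfect
guide-target complementarity over the seed region (target positions
1-13, counted from the TAM-proximal edge).  Mismatches in the distal
region (14-20) each multiply the cleavage efficiency by a constant
factor.  Cut positions on the target strand (TS) and non-target strand
(NTS) are drawn from configurable per-strand distributions whose default
modes (TS 22, NTS 16) produce the characteristic 6-nt 5' overhang at the
TAM-distal end.

Position conventions
--------------------
Target positions are 1-20 counted from the TAM-proximal edge; TAM
positions are -5..-1.  The NTS is the TAM-bearing strand read 5'->3'
through TAM then target; the TS is its complement.  Overhang sign:
positive = 5' overhang.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .seqs import hamming, revcomp

try:
    import edlib
except ImportError:  # pragma: no cover
    edlib = None


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Engine

def _validate_dist(dist: dict[int, float], name: str) -> None:
    if not dist:
        raise ConfigurationError(f"{name} is empty")
    if any(p < 0 for p in dist.values()) or sum(dist.values()) <= 0:
        raise ConfigurationError(f"{name} has non-positive mass")
    if abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must sum to 1")
    if any(pos < 1 for pos in dist):
        raise ConfigurationError(f"{name} positions must be >= 1")


@dataclass
class CleavageEngineParams:
    """Parameters of the in-silico cleavage model."""

    guide: str
    tam_consensus: str = "AGGAG"
    seed_region: tuple[int, int] = (1, 13)   # inclusive, 1-based
    distal_mismatch_factor: float = 0.5
    ts_site_dist: dict[int, float] = field(
        default_factory=lambda: {22: 0.65, 21: 0.20, 23: 0.15}
    )
    nts_site_dist: dict[int, float] = field(
        default_factory=lambda: {16: 0.85, 15: 0.075, 17: 0.075}
    )

    def __post_init__(self):
        self.guide = self.guide.upper()
        self.tam_consensus = self.tam_consensus.upper()
        if len(self.guide) != 20:
            raise ConfigurationError("guide must be 20 nt")
        if not 0 < self.distal_mismatch_factor <= 1:
            raise ConfigurationError("distal_mismatch_factor must be in (0, 1]")
        _validate_dist(self.ts_site_dist, "ts_site_dist")
        _validate_dist(self.nts_site_dist, "nts_site_dist")

    def efficiency(self, tam: str, target: str) -> float:
        """Cleavage efficiency for a TAM + target pair in [0, 1]."""
        if tam.upper() != self.tam_consensus:
            return 0.0
        target = target.upper()
        if len(target) != len(self.guide):
            raise ConfigurationError("target length must match guide length")
        lo, hi = self.seed_region
        eff = 1.0
        for i, (g, t) in enumerate(zip(self.guide, target), start=1):
            if g == t:
                continue
            if lo <= i <= hi:
                return 0.0
            eff *= self.distal_mismatch_factor
        return eff


def default_engine(guide: str = "ATGCATGCATGCATGCATGC") -> CleavageEngineParams:
    return CleavageEngineParams(guide=guide)


@dataclass
class DnaSubstrate:
    """A linear dsDNA substrate with annotated TAM and target coordinates.

    The sequence given is the NTS (TAM-bearing) strand; the 20-nt target
    starts immediately 3' of the TAM.
    """

    sequence: str
    tam_start: int

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if self.tam_start is None or not 0 <= self.tam_start:
            raise ConfigurationError("substrate missing TAM annotation")
        if self.tam_start + 25 > len(self.sequence):
            raise ConfigurationError("TAM + 20-nt target exceeds substrate length")

    @property
    def target_start(self) -> int:
        return self.tam_start + 5

    @property
    def tam(self) -> str:
        return self.sequence[self.tam_start : self.tam_start + 5]

    @property
    def target(self) -> str:
        return self.sequence[self.target_start : self.target_start + 20]


@dataclass
class Fragment:
    top_length: int
    bottom_length: int


@dataclass
class CleavageOutcome:
    cleaved: bool
    efficiency: float
    ts_cut: int | None          # target-relative position, 1-based
    nts_cut: int | None
    fragments: list[Fragment]

    @property
    def fragment_lengths(self) -> list[int]:
        """Top-strand fragment lengths; always sum to the substrate length."""
        return [f.top_length for f in self.fragments]


def draw_cut(rng: np.random.Generator, dist: dict[int, float]) -> int:
    positions = sorted(dist)
    probs = np.array([dist[p] for p in positions])
    return int(rng.choice(positions, p=probs / probs.sum()))


def cleave_in_silico(
    substrate: DnaSubstrate,
    engine: CleavageEngineParams,
    seed: int | np.random.Generator = 0,
) -> CleavageOutcome:
    """Apply the engine to one substrate molecule.

    Cleavage happens with probability equal to the engine efficiency;
    cut positions are then drawn from the per-strand site distributions
    and the duplex is split into two fragments.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eff = engine.efficiency(substrate.tam, substrate.target)
    n = len(substrate.sequence)
    if eff <= 0 or rng.random() >= eff:
        return CleavageOutcome(False, eff, None, None, [Fragment(n, n)])
    ts_cut = draw_cut(rng, engine.ts_site_dist)
    nts_cut = draw_cut(rng, engine.nts_site_dist)
    c_nts = substrate.target_start + nts_cut   # top-strand break coordinate
    c_ts = substrate.target_start + ts_cut     # bottom-strand break coordinate
    fragments = [Fragment(c_nts, c_ts), Fragment(n - c_nts, n - c_ts)]
    return CleavageOutcome(True, eff, ts_cut, nts_cut, fragments)


# ---------------------------------------------------------------------------
# TAM discovery

@dataclass
class TamObservationSet:
    sevenmers: list[str]
    background: Counter | None
    rejected: Counter
    n_input: int


def _seq_of(read) -> str:
    return read if isinstance(read, str) else read.sequence


def extract_tam_observations(
    reads,
    backbone: str,
    window: tuple[int, int],
    adapter: str,
    max_adapter_mismatch: int = 1,
    max_anchor_mismatch: int = 1,
    anchor_len: int = 12,
    background_reads=None,
) -> TamObservationSet:
    """Excise randomized 7-mers from adapter-marked cleaved-product reads.

    A read is kept when its 5' end matches the adapter within
    ``max_adapter_mismatch`` and the ``anchor_len`` backbone bases
    immediately 5' of the randomized window match at their expected
    offset within ``max_anchor_mismatch``.  The 7-mer is then excised by
    coordinates.  Rejected reads are counted by reason.
    """
    w0, w1 = window
    if w1 - w0 != 7:
        raise ConfigurationError("randomized window must be exactly 7 nt")
    if w0 < anchor_len:
        raise ConfigurationError("backbone window leaves no room for the anchor")
    anchor = backbone[w0 - anchor_len : w0]
    if backbone.count(anchor) != 1:
        raise ConfigurationError("backbone anchor flanking the window is not unique")

    la = len(adapter)
    sevenmers: list[str] = []
    rejected: Counter = Counter()
    n_input = 0
    for read in reads:
        n_input += 1
        seq = _seq_of(read).upper()
        if len(seq) < la + anchor_len + 7:
            rejected["too_short"] += 1
            continue
        if hamming(seq[:la], adapter) > max_adapter_mismatch:
            rejected["no_adapter"] += 1
            continue
        if hamming(seq[la : la + anchor_len], anchor) > max_anchor_mismatch:
            rejected["no_anchor"] += 1
            continue
        mer = seq[la + anchor_len : la + anchor_len + 7]
        if any(c not in "ACGT" for c in mer):
            rejected["ambiguous_base"] += 1
            continue
        sevenmers.append(mer)

    background = None
    if background_reads is not None:
        background = Counter()
        for read in background_reads:
            seq = _seq_of(read).upper()
            mer = seq[w0:w1] if len(seq) >= w1 else None
            if mer and all(c in "ACGT" for c in mer):
                background[mer] += 1
    return TamObservationSet(sevenmers, background, rejected, n_input)


@dataclass
class TamEnrichment:
    frequencies: np.ndarray        # (7, 4) over A,C,G,T; rows sum to 1
    information: np.ndarray        # bits per position, in [0, 2]
    enrichment: np.ndarray         # log2 ratio vs background
    consensus: str                 # majority base where IC >= 1 bit, else N
    confidence: np.ndarray         # majority-base frequency per position


def tam_enrichment(
    obs: TamObservationSet,
    pseudo: float = 1e-3,
    ic_call_threshold: float = 1.0,
) -> TamEnrichment:
    """Per-position nucleotide frequencies, information content and
    enrichment over the input-library background for the 7-nt window."""
    if not obs.sevenmers:
        raise ValueError("no TAM observations to analyse")
    counts = np.zeros((7, 4))
    for mer in obs.sevenmers:
        for i, c in enumerate(mer):
            counts[i, "ACGT".find(c)] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)

    if obs.background:
        bg_counts = np.zeros((7, 4))
        for mer, k in obs.background.items():
            for i, c in enumerate(mer):
                bg_counts[i, "ACGT".find(c)] += k
        bg = bg_counts / bg_counts.sum(axis=1, keepdims=True)
    else:
        bg = np.full((7, 4), 0.25)

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    information = 2.0 + plogp.sum(axis=1)
    enrichment = np.log2((freqs + pseudo) / (bg + pseudo))
    majority = freqs.argmax(axis=1)
    consensus = "".join(
        "ACGT"[majority[i]] if information[i] >= ic_call_threshold else "N"
        for i in range(7)
    )
    confidence = freqs[np.arange(7), majority]
    return TamEnrichment(freqs, information, enrichment, consensus, confidence)


# ---------------------------------------------------------------------------
# Cut-site mapping

def _identity(a: str, b: str) -> float:
    if len(a) != len(b) or not a:
        return 0.0
    return 1.0 - hamming(a, b) / len(a)


@dataclass
class CutSiteProfile:
    ts: dict[int, float]
    nts: dict[int, float]
    ts_mode: int
    nts_mode: int
    discarded: Counter

    @property
    def overhang(self) -> int:
        """TS mode - NTS mode; positive = 5' overhang (TAM-distal)."""
        return self.ts_mode - self.nts_mode


def map_cut_sites(
    ts_reads,
    nts_reads,
    reference: str,
    tam_start: int,
    tam_len: int = 5,
    min_identity: float = 0.9,
) -> CutSiteProfile:
    """Map run-off read ends to TAM-relative cut positions per strand.

    NTS reads are prefixes of the TAM-bearing strand; TS reads are
    prefixes of the complementary strand (i.e. reverse-complemented
    suffixes of the reference).  The terminal base of each read marks
    the cut; position 1 is the target base adjacent to the TAM.
    """
    reference = reference.upper()
    n = len(reference)
    target_start = tam_start + tam_len
    discarded: Counter = Counter()
    nts_counts: Counter = Counter()
    ts_counts: Counter = Counter()

    for read in nts_reads:
        seq = _seq_of(read).upper()
        pos = len(seq) - target_start
        if pos < 1 or len(seq) > n:
            discarded["nts_unmappable"] += 1
            continue
        if _identity(seq, reference[: len(seq)]) < min_identity:
            discarded["nts_low_identity"] += 1
            continue
        nts_counts[pos] += 1

    for read in ts_reads:
        seq = _seq_of(read).upper()
        c = n - len(seq)
        pos = c - target_start
        if pos < 1 or len(seq) > n:
            discarded["ts_unmappable"] += 1
            continue
        if _identity(seq, revcomp(reference[c:])) < min_identity:
            discarded["ts_low_identity"] += 1
            continue
        ts_counts[pos] += 1

    if not ts_counts or not nts_counts:
        raise ValueError("no mappable run-off reads on one or both strands")
    ts = {p: c / sum(ts_counts.values()) for p, c in sorted(ts_counts.items())}
    nts = {p: c / sum(nts_counts.values()) for p, c in sorted(nts_counts.items())}
    ts_mode = max(ts, key=lambda p: (ts[p], -p))
    nts_mode = max(nts, key=lambda p: (nts[p], -p))
    return CutSiteProfile(ts, nts, ts_mode, nts_mode, discarded)


# ---------------------------------------------------------------------------
# Small-RNA anatomy

@dataclass
class Segment:
    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReRnaAnatomy:
    transcript_start: int
    transcript_end: int
    segments: list[Segment]
    truncated: bool
    orf_offset: int | None       # distance from upstream ORF end to 5' boundary
    unmapped_reads: int

    @property
    def total_length(self) -> int:
        return self.transcript_end - self.transcript_start


def small_rna_anatomy(
    reads,
    locus: str,
    motif_span: tuple[int, int],
    upstream_orf_end: int | None = None,
    flank3_end: int | None = None,
    min_cov_frac: float = 0.10,
    max_edit_frac: float = 0.10,
) -> ReRnaAnatomy:
    """Call transcript boundaries from small-RNA coverage and segment them.

    The transcript is the maximal contiguous region, containing the
    coverage peak, where coverage is at least ``min_cov_frac`` of the
    maximum.  Segments: 5' flanking up to the motif, the motif itself,
    3' flanking up to ``flank3_end`` (when given), then the
    non-conserved tail.
    """
    locus = locus.upper()
    cov = np.zeros(len(locus), dtype=np.int64)
    unmapped = 0
    for read in reads:
        seq = _seq_of(read).upper()
        i = locus.find(seq)
        if i >= 0:
            cov[i : i + len(seq)] += 1
            continue
        placed = False
        if edlib is not None:
            k = max(1, int(max_edit_frac * len(seq)))
            res = edlib.align(seq, locus, mode="HW", task="locations", k=k)
            if res["editDistance"] >= 0 and res["locations"]:
                s, e = res["locations"][0]
                cov[s : e + 1] += 1
                placed = True
        if not placed:
            unmapped += 1
    if cov.max() == 0:
        raise ValueError("zero coverage: no reads mapped to the locus")

    thresh = min_cov_frac * cov.max()
    peak = int(cov.argmax())
    t0 = peak
    while t0 > 0 and cov[t0 - 1] >= thresh:
        t0 -= 1
    t1 = peak + 1
    while t1 < len(locus) and cov[t1] >= thresh:
        t1 += 1
    # walk down the monotone coverage ramp left by read ends so that the
    # called bounds reach the true transcript edges, not the 10% contour
    while t0 > 0 and 0 < cov[t0 - 1] <= cov[t0]:
        t0 -= 1
    while t1 < len(locus) and 0 < cov[t1] <= cov[t1 - 1]:
        t1 += 1
    truncated = t0 == 0 or t1 == len(locus)

    m0 = max(motif_span[0], t0)
    m1 = min(motif_span[1], t1)
    if m1 <= m0:
        raise ValueError("motif hit does not overlap the called transcript")
    segments = [Segment("5p_flanking", t0, m0), Segment("ragath18", m0, m1)]
    if flank3_end is not None and m1 < flank3_end < t1:
        segments.append(Segment("3p_flanking", m1, flank3_end))
        segments.append(Segment("tail", flank3_end, t1))
    else:
        segments.append(Segment("3p_flanking", m1, t1))
    segments = [s for s in segments if s.length > 0]
    orf_offset = None if upstream_orf_end is None else t0 - upstream_orf_end
    return ReRnaAnatomy(t0, t1, segments, truncated, orf_offset, unmapped)


def assemble_rerna(scaffold: str, guide: str) -> str:
    """Assemble a guide-programmed reRNA: scaffold with the guide at its 3' end."""
    return scaffold + guide


# ---------------------------------------------------------------------------
# Amplicon indel quantification

def _amplicon_aligner(match=2.0, mismatch=-3.0, gap_open=-8.0, gap_extend=-1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@dataclass
class IndelReport:
    amplicon_id: str
    total: int
    edited: int
    histogram: np.ndarray
    discarded: int

    @property
    def fraction(self) -> float:
        return self.edited / self.total if self.total else 0.0


def quantify_indels(
    reads,
    reference: str,
    window: tuple[int, int],
    amplicon_id: str = "amplicon",
    min_identity: float = 0.8,
) -> IndelReport:
    """Count reads with >= 1 indel overlapping the target window.

    Each read is globally aligned to the reference with affine gap
    penalties; a read is edited when a gap column overlaps the window
    (substitutions never count).  Reads below ``min_identity`` over the
    aligned columns are discarded.
    """
    reference = reference.upper()
    if any(len(_seq_of(r)) > len(reference) + 20 for r in reads):
        raise ValueError("reads much longer than the reference amplicon")
    w0, w1 = window
    aligner = _amplicon_aligner()
    total = edited = discarded = 0
    hist = np.zeros(len(reference), dtype=np.int64)
    for read in reads:
        seq = _seq_of(read).upper()
        aln = aligner.align(reference, seq)[0]
        ref_blocks, read_blocks = aln.aligned
        aligned_cols = sum(e - s for s, e in ref_blocks)
        matches = 0
        for (rs, re_), (qs, _) in zip(ref_blocks, read_blocks):
            for k in range(re_ - rs):
                if reference[rs + k] == seq[qs + k]:
                    matches += 1
        if aligned_cols == 0 or matches / aligned_cols < min_identity:
            discarded += 1
            continue
        total += 1
        is_edited = False
        for i in range(len(ref_blocks) - 1):
            r1, r2 = ref_blocks[i][1], ref_blocks[i + 1][0]
            q1, q2 = read_blocks[i][1], read_blocks[i + 1][0]
            if r2 > r1:   # deletion relative to the reference
                hist[r1:r2] += 1
                if r1 < w1 and r2 > w0:
                    is_edited = True
            if q2 > q1:   # insertion at reference position r1
                if r1 < len(hist):
                    hist[r1] += 1
                if w0 <= r1 <= w1:
                    is_edited = True
        if is_edited:
            edited += 1
    return IndelReport(amplicon_id, total, edited, hist, discarded)


# ---------------------------------------------------------------------------
# Mismatch heatmap

@dataclass
class MismatchHeatmap:
    matrix: pd.DataFrame       # raw indel fractions, rows A/C/G/T, cols 1..20
    normalized: pd.DataFrame   # divided by the WT fraction; WT cells = 1
    wt_fraction: float
    guide: str


def mismatch_heatmap(
    variant_reports: dict[tuple[int, str], IndelReport],
    wt_report: IndelReport,
    guide: str,
) -> MismatchHeatmap:
    """Assemble the single-mismatch guide panel into a 4 x 20 heatmap.

    ``variant_reports`` maps (position 1-20, substituted base) to the
    indel report of that single-substitution guide; normalization is to
    the original-guide fraction.
    """
    if wt_report.fraction <= 0:
        raise ValueError("WT indel fraction is zero: normalization undefined")
    positions = list(range(1, len(guide) + 1))
    raw = pd.DataFrame(np.nan, index=list("ACGT"), columns=positions)
    norm = pd.DataFrame(np.nan, index=list("ACGT"), columns=positions)
    for pos in positions:
        raw.loc[guide[pos - 1], pos] = wt_report.fraction
        norm.loc[guide[pos - 1], pos] = 1.0
    for (pos, base), report in variant_reports.items():
        if not 1 <= pos <= len(guide) or base not in "ACGT":
            raise ValueError(f"invalid variant key ({pos}, {base})")
        raw.loc[base, pos] = report.fraction
        norm.loc[base, pos] = report.fraction / wt_report.fraction
    return MismatchHeatmap(raw, norm, wt_report.fraction, guide)


# ---------------------------------------------------------------------------
# Off-target candidate enumeration

def find_offtarget_candidates(
    genome: dict[str, str],
    tam_consensus: str,
    guide: str,
    max_mismatches: int = 3,
) -> pd.DataFrame:
    """Enumerate genomic sites with an exact TAM followed by a near-match target.

    Both strands are scanned; a candidate needs an exact TAM and at most
    ``max_mismatches`` substitutions (no bulges) over the guide-length
    window.  Coordinates are 0-based half-open on the forward strand of
    each contig; sorted by mismatch count then coordinate.
    """
    tam = tam_consensus.upper()
    guide = guide.upper()
    lt, lg = len(tam), len(guide)
    rows = []
    for contig, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            start = s.find(tam)
            while start != -1:
                t0 = start + lt
                if t0 + lg <= n:
                    mm = hamming(s[t0 : t0 + lg], guide)
                    if mm <= max_mismatches:
                        if strand == "+":
                            tam_start, target_start = start, t0
                        else:
                            target_start = n - (t0 + lg)
                            tam_start = n - (start + lt)
                        rows.append(
                            dict(
                                contig=contig,
                                strand=strand,
                                tam_start=tam_start,
                                target_start=target_start,
                                mismatches=mm,
                            )
                        )
                start = s.find(tam, start + 1)
    df = pd.DataFrame(
        rows, columns=["contig", "strand", "tam_start", "target_start", "mismatches"]
    )
    return df.sort_values(
        ["mismatches", "contig", "target_start", "strand"]
    ).reset_index(drop=True)
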
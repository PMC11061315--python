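"""Structure-constrained RNA motif model and scanner.

A deliberately lightweight stand-in for a full covariance model: a
position weight matrix (log-odds against a uniform background) augmented
with base-pair constraints taken from a consensus secondary structure.
Windows are fixed-length and ungapped; insert/delete states are not
modelled.

Scores are in bits.  For a window ``w`` of length L::

    score(w) = sum_j log2(f_j(w_j) / 0.25)
             + sum_(j,k in pairs) [ +b  if (w_j, w_k) can pair
                                    -p  otherwise ]

where pairing admits Watson-Crick and G·U wobble pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SeedAlignment
from .seqs import encode_dna, revcomp

GAP_CHARS = set("-.~")
_OPEN = {"(": ")", "<": ">", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}

# compatible pairs over the A,C,G,U index alphabet (T encoded as U)
_PAIR_OK = np.zeros((4, 4), dtype=bool)
for _a, _b in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:  # AU UA CG GC GU UG
    _PAIR_OK[_a, _b] = True


def parse_structure_pairs(structure: str) -> list[tuple[int, int]]:
    """Extract column index pairs from a dot-bracket string.

    Supports (), <>, [] and {} bracket families (each balanced
    independently, so simple pseudoknot annotations work).
    """
    stacks: dict[str, list[int]] = {b: [] for b in _OPEN}
    pairs = []
    for i, ch in enumerate(structure):
        if ch in _OPEN:
            stacks[ch].append(i)
        elif ch in _CLOSE:
            opener = _CLOSE[ch]
            if not stacks[opener]:
                raise ValueError(f"unbalanced structure string at column {i}")
            pairs.append((stacks[opener].pop(), i))
    leftovers = [b for b, s in stacks.items() if s]
    if leftovers:
        raise ValueError(f"unbalanced structure string: unclosed {leftovers}")
    return sorted(pairs)


@dataclass
class StructuredMotifModel:
    """Per-column log-odds plus base-pair constraints."""

    name: str
    log_odds: np.ndarray            # (L, 4) bits, columns A,C,G,U
    pairs: list[tuple[int, int]]    # indices into match columns
    pair_bonus: float = 1.0
    pair_penalty: float = 1.0
    consensus: str = ""

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        _, score = self.best_window()
        return score

    def best_window(self) -> tuple[str, float]:
        """Highest-scoring sequence under the model and its score.

        Unpaired columns take their argmax base; each (disjoint) pair is
        optimized jointly over the 16 base combinations including the
        pair bonus/penalty, so the result respects the structure.
        """
        lo = self.log_odds
        paired = {c for p in self.pairs for c in p}
        best = [""] * self.length
        score = 0.0
        for j in range(self.length):
            if j not in paired:
                k = int(lo[j].argmax())
                best[j] = "ACGU"[k]
                score += lo[j, k]
        for a, b in self.pairs:
            cand = [
                (
                    lo[a, x] + lo[b, y]
                    + (self.pair_bonus if _PAIR_OK[x, y] else -self.pair_penalty),
                    x, y,
                )
                for x in range(4)
                for y in range(4)
            ]
            s, x, y = max(cand)
            best[a], best[b] = "ACGU"[x], "ACGU"[y]
            score += s
        return "".join(best), score


@dataclass
class MotifHit:
    igr_id: str
    strand: str
    start: int      # 0-based half-open, on the scanned (forward) sequence
    end: int
    score: float
    significance: float | None = None  # empirical FPR, if a null is attached


def build_model(
    alignment: SeedAlignment,
    gap_fraction_max: float = 0.5,
    pseudocount: float = 0.5,
    pair_bonus: float = 1.0,
    pair_penalty: float = 1.0,
) -> StructuredMotifModel:
    """Build a motif model from a seed alignment and its consensus structure.

    Match columns are those with gap fraction < ``gap_fraction_max``;
    base pairs are kept only when both partners are match columns.
    """
    rows = [r.upper().replace("T", "U") for r in alignment.rows]
    n = len(rows)
    if n == 0:
        raise ValueError("empty alignment")
    ncol = len(rows[0])
    all_pairs = parse_structure_pairs(alignment.structure)

    gap_frac = np.array(
        [sum(r[j] in GAP_CHARS for r in rows) / n for j in range(ncol)]
    )
    match_cols = [j for j in range(ncol) if gap_frac[j] < gap_fraction_max]
    col_of = {j: i for i, j in enumerate(match_cols)}

    L = len(match_cols)
    if L < 10:
        raise ValueError(f"model needs >= 10 match columns, got {L}")

    counts = np.zeros((L, 4))
    for r in rows:
        for i, j in enumerate(match_cols):
            ch = r[j]
            if ch in GAP_CHARS:
                continue
            k = "ACGU".find(ch)
            if k >= 0:
                counts[i, k] += 1
    nongap = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount) / (nongap + 4 * pseudocount)
    log_odds = np.log2(freqs / 0.25)

    pairs = [
        (col_of[a], col_of[b])
        for a, b in all_pairs
        if a in col_of and b in col_of
    ]
    model = StructuredMotifModel(
        name=alignment.name,
        log_odds=log_odds,
        pairs=pairs,
        pair_bonus=pair_bonus,
        pair_penalty=pair_penalty,
    )
    model.consensus, _ = model.best_window()
    return model


def _window_scores(codes: np.ndarray, model: StructuredMotifModel) -> np.ndarray:
    """Score every length-L window of an encoded sequence (vectorized)."""
    L = model.length
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    # treat non-ACGU characters as worst-case at each column
    safe = np.where(codes < 0, 0, codes)
    lo = model.log_odds
    worst = lo.min(axis=1)
    scores = np.zeros(n)
    for j in range(L):
        col = codes[j : j + n]
        vals = lo[j, safe[j : j + n]]
        scores += np.where(col < 0, worst[j], vals)
    for a, b in model.pairs:
        ca = safe[a : a + n]
        cb = safe[b : b + n]
        ok = _PAIR_OK[ca, cb] & (codes[a : a + n] >= 0) & (codes[b : b + n] >= 0)
        scores += np.where(ok, model.pair_bonus, -model.pair_penalty)
    return scores


def scan(
    sequence: str,
    model: StructuredMotifModel,
    threshold: float,
    igr_id: str = "seq",
    null_scores: np.ndarray | None = None,
) -> list[MotifHit]:
    """Scan both strands of a sequence, reporting non-overlapping hits.

    Hits at or above ``threshold`` are accepted greedily by descending
    score (ties broken by leftmost start, + strand first); a hit is kept
    only if it does not overlap an already-kept hit on either strand.
    """
    L = model.length
    N = len(sequence)
    if N < L:
        return []
    candidates: list[tuple[float, int, int, str]] = []
    fwd = _window_scores(encode_dna(sequence), model)
    for i, s in enumerate(fwd):
        if s >= threshold:
            candidates.append((s, i, i + L, "+"))
    rev = _window_scores(encode_dna(revcomp(sequence)), model)
    for i, s in enumerate(rev):
        if s >= threshold:
            start = N - i - L
            candidates.append((s, start, start + L, "-"))

    candidates.sort(key=lambda c: (-c[0], c[1], c[3]))
    kept: list[MotifHit] = []
    occupied: list[tuple[int, int]] = []
    for score, start, end, strand in candidates:
        if any(start < e and s < end for s, e in occupied):
            continue
        sig = None
        if null_scores is not None:
            sig = float(np.mean(null_scores >= score))
        kept.append(MotifHit(igr_id, strand, start, end, float(score), sig))
        occupied.append((start, end))
    kept.sort(key=lambda h: h.start)
    return kept


def calibrate_null(
    model: StructuredMotifModel,
    n: int = 10000,
    seed: int = 0,
    fpr: float = 1e-3,
) -> tuple[np.ndarray, float]:
    """Score i.i.d. uniform-background windows and return (scores, threshold).

    The threshold is the empirical (1 - fpr) quantile of the null score
    distribution.
    """
    if n < 1000:
        raise ValueError("null calibration needs n >= 1000")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n, model.length))
    lo = model.log_odds
    scores = lo[np.arange(model.length), codes].sum(axis=1)
    for a, b in model.pairs:
        ok = _PAIR_OK[codes[:, a], codes[:, b]]
        scores += np.where(ok, model.pair_bonus, -model.pair_penalty)
    threshold = float(np.quantile(scores, 1.0 - fpr))
    return scores, threshold
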
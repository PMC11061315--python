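"""Position-frequency protein profiles and calibrated significance.

Profiles are per-column amino-acid frequency models.  A sequence is
scored against a profile by the best ungapped full-overlap placement,
summing log2(f/background) per column (background uniform over the 20
standard residues).  An e-value-like significance is obtained by
fitting a Gumbel (EVD) right tail to scores of random background
sequences, binned by query length, mirroring how profile search tools
calibrate their e-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqs import AA, encode_aa, random_protein

_BG = 1.0 / len(AA)


@dataclass
class Profile:
    profile_id: str
    freqs: np.ndarray      # (L, 20) columns over AA order; rows sum to 1

    def __post_init__(self):
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"profile {self.profile_id}: columns must sum to 1")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA[k] for k in self.freqs.argmax(axis=1))

    def sample(self, rng: np.random.Generator) -> str:
        """Emit a sequence column-by-column from the frequency model."""
        u = rng.random(self.length)
        cum = self.freqs.cumsum(axis=1)
        picks = (u[:, None] > cum).sum(axis=1)
        return "".join(AA[k] for k in picks)

    @property
    def log_odds(self) -> np.ndarray:
        if not hasattr(self, "_log_odds"):
            self._log_odds = np.log2(np.maximum(self.freqs, 1e-12) / _BG)
        return self._log_odds


class ProfileDB:
    """A named collection of profiles with cached null calibrations."""

    def __init__(self, profiles: list[Profile], name: str = "db"):
        if not profiles:
            raise ValueError("profile DB must be non-empty")
        self.name = name
        self.profiles = {p.profile_id: p for p in profiles}
        self._null_cache: dict[int, tuple[float, float]] = {}

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles.values())


def score_profile(seq: str, profile: Profile) -> float:
    """Best ungapped full-overlap log-odds score of a sequence vs a profile."""
    enc = encode_aa(seq)
    enc = enc[enc >= 0]
    m, L = len(enc), profile.length
    if m == 0:
        return -np.inf
    # B[k, j] = log-odds of residue j of the query at profile column k;
    # a full-overlap placement score is a diagonal sum of B
    B = profile.log_odds[:, enc]
    if m >= L:
        offsets = range(0, m - L + 1)
    else:
        offsets = range(0, -(L - m + 1), -1)
    return float(max(B.diagonal(off).sum() for off in offsets))


def best_hit(seq: str, db: ProfileDB) -> tuple[str, float]:
    scores = {pid: score_profile(seq, p) for pid, p in db.profiles.items()}
    pid = max(scores, key=scores.get)
    return pid, scores[pid]


def _length_bin(length: int, width: int = 50) -> int:
    return max(width, int(round(length / width)) * width)


def calibrate_db_null(
    db: ProfileDB,
    length: int,
    n_null: int = 1000,
    seed: int = 0,
    bin_width: int = 50,
) -> tuple[float, float]:
    """Fit a Gumbel to best-over-DB scores of random sequences in a length bin.

    Returns the (location, scale) of the fitted right-tail model; cached
    per length bin on the DB instance.
    """
    key = _length_bin(length, bin_width)
    if key in db._null_cache:
        return db._null_cache[key]
    rng = np.random.default_rng(seed + key)
    scores = np.empty(n_null)
    for i in range(n_null):
        seq = random_protein(rng, key)
        scores[i] = max(score_profile(seq, p) for p in db)
    loc, scale = stats.gumbel_r.fit(scores)
    db._null_cache[key] = (loc, scale)
    return loc, scale


def significance(score: float, null_params: tuple[float, float]) -> float:
    """Tail probability of the best-hit score under the fitted null."""
    loc, scale = null_params
    return float(stats.gumbel_r.sf(score, loc=loc, scale=scale))


def make_profile_db(
    n_profiles: int,
    length: int,
    seed: int,
    name: str = "db",
    dominance: float = 0.7,
) -> ProfileDB:
    """Generate a synthetic profile DB: random consensus sequences with a
    dominant-residue frequency of ``dominance`` per column."""
    rng = np.random.default_rng(seed)
    profiles = []
    off = (1.0 - dominance) / 19.0
    for i in range(n_profiles):
        cons = rng.integers(0, 20, size=length)
        freqs = np.full((length, 20), off)
        freqs[np.arange(length), cons] = dominance
        profiles.append(Profile(f"{name}_{i:03d}", freqs))
    return ProfileDB(profiles, name=name)


def write_profile_db(db: ProfileDB, path) -> None:
    """Serialize a profile DB as a long-format TSV frequency matrix."""
    rows = []
    for p in db:
        for i in range(p.length):
            rows.append([p.profile_id, i, *p.freqs[i]])
    df = pd.DataFrame(rows, columns=["profile_id", "pos", *AA])
    df.to_csv(path, sep="\t", index=False)


def read_profile_db(path, name: str = "db") -> ProfileDB:
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for pid, grp in df.groupby("profile_id", sort=True):
        grp = grp.sort_values("pos")
        profiles.append(Profile(str(pid), grp[list(AA)].to_numpy(float)))
    return ProfileDB(profiles, name=name)
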
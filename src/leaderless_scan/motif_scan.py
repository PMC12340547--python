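"""PWM scanning with log-odds scores and exact p-values.

Scores are log2(theta/background) sums; p-values come from the exact null
distribution of the score of a random background w-mer, computed by dynamic
programming over a discretized score lattice (the standard staged-convolution
construction). Scanning is single-strand by default, matching promoter
elements' strand specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import N_CODE, encode, revcomp
from .genome_io import UpstreamWindow
from .motif_discovery import MotifModel

_THETA_PSEUDO = 1e-3
_MAX_LATTICE = 100_000_000


@dataclass
class ScoringMatrix:
    """Discretized log-odds matrix ready for scanning and exact-p-value DP."""

    w: int
    log_odds: np.ndarray  # (4, w), log2(theta'/background)
    granularity: float
    background: np.ndarray
    int_scores: np.ndarray = field(init=False)  # (4, w) lattice scores

    def __post_init__(self):
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("log-odds entries must be finite")
        if self.granularity <= 0:
            raise ValueError("granularity must be positive")
        self.int_scores = np.rint(self.log_odds / self.granularity).astype(np.int64)

    def score_word(self, word: str) -> float:
        """Lattice-consistent log2-odds score of one N-free w-mer."""
        enc = encode(word)
        if len(enc) != self.w or (enc == N_CODE).any():
            raise ValueError("word must be an N-free sequence of motif width")
        return float(self.int_scores[enc, np.arange(self.w)].sum() * self.granularity)


@dataclass
class ScoreDistribution:
    """Survival function of the discretized null score: P(score >= s)."""

    granularity: float
    min_int: int  # lattice score of the worst possible word
    sf: np.ndarray  # sf[k] = P(int score >= min_int + k)

    def pvalue_int(self, int_score: int) -> float:
        k = int_score - self.min_int
        if k <= 0:
            return 1.0
        if k >= len(self.sf):
            return 0.0
        return float(self.sf[k])

    def pvalue(self, score: float) -> float:
        return self.pvalue_int(int(np.rint(score / self.granularity)))


@dataclass(frozen=True)
class MotifSite:
    """One reported motif occurrence in start-codon-relative coordinates.

    ``offset`` is the site's first base relative to the first base of the
    start codon (negative = upstream). ``spacer`` is the number of bases
    strictly between the site's last base and the start codon; it is
    negative when the site overlaps or lies inside the ORF.
    """

    gene_id: str
    offset: int
    word: str
    score: float
    p_value: float
    spacer: int

    @property
    def width(self) -> int:
        return len(self.word)


def make_scoring_matrix(model: MotifModel, granularity: float = 1e-3) -> ScoringMatrix:
    """Log2-odds matrix from a fitted motif, with a small floor on theta."""
    theta = model.theta + _THETA_PSEUDO
    theta = theta / theta.sum(axis=0, keepdims=True)
    log_odds = np.log2(theta / model.background[:, None])
    return ScoringMatrix(model.width, log_odds, granularity, model.background.copy())


def exact_pvalues(matrix: ScoringMatrix, background: np.ndarray | None = None) -> ScoreDistribution:
    """Exact null score distribution by column-wise convolution on the lattice."""
    if background is None:
        background = matrix.background
    background = np.asarray(background, dtype=float)
    s = matrix.int_scores
    col_min = s.min(axis=0)
    col_max = s.max(axis=0)
    span = int((col_max - col_min).sum())
    if span + 1 > _MAX_LATTICE:
        raise ValueError(
            f"score lattice of size {span + 1} too large; use a coarser granularity"
        )
    pmf = np.zeros(span + 1)
    pmf[0] = 1.0
    width_so_far = 0
    for j in range(matrix.w):
        new = np.zeros_like(pmf)
        for b in range(4):
            off = int(s[b, j] - col_min[j])
            new[off : off + width_so_far + 1] += background[b] * pmf[: width_so_far + 1]
        pmf = new
        width_so_far += int(col_max[j] - col_min[j])
    sf = np.cumsum(pmf[::-1])[::-1].copy()
    sf[0] = 1.0  # guard rounding: P(score >= minimum) is exactly 1
    return ScoreDistribution(matrix.granularity, int(col_min.sum()), sf)


def _int_scores_along(enc: np.ndarray, matrix: ScoringMatrix):
    """Lattice scores for every offset of an encoded sequence; N windows invalid."""
    w = matrix.w
    m = len(enc) - w + 1
    if m <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    ext = np.vstack([matrix.int_scores, np.zeros((1, w), dtype=np.int64)])
    scores = np.zeros(m, dtype=np.int64)
    has_n = np.zeros(m, dtype=bool)
    for k in range(w):
        col = enc[k : k + m]
        scores += ext[col, k]
        has_n |= col == N_CODE
    return scores, ~has_n


def scan_sequence(
    seq: str,
    matrix: ScoringMatrix,
    dist: ScoreDistribution,
    p_threshold: float = 0.015,
    scan_revcomp: bool = False,
) -> list[tuple[int, str, float, float]]:
    """All offsets whose w-mer passes the p-value threshold, given strand only.

    Returns (offset_in_seq, word, score, p_value) tuples. With
    ``scan_revcomp`` the reverse strand is also scanned and hits are
    reported at their forward offset with the reverse-complement word.
    """
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must lie in (0, 1]")
    out: list[tuple[int, str, float, float]] = []
    enc = encode(seq)
    scores, valid = _int_scores_along(enc, matrix)
    for i in np.flatnonzero(valid):
        p = dist.pvalue_int(int(scores[i]))
        if p <= p_threshold:
            out.append(
                (int(i), seq[i : i + matrix.w], float(scores[i] * matrix.granularity), p)
            )
    if scan_revcomp:
        rc_hits = scan_sequence(revcomp(seq), matrix, dist, p_threshold, False)
        L = len(seq)
        for j, word, score, p in rc_hits:
            out.append((L - matrix.w - j, word, score, p))
        out.sort(key=lambda t: t[0])
    return out


def scan_gene_windows(
    windows: list[UpstreamWindow],
    matrix: ScoringMatrix,
    dist: ScoreDistribution,
    p_threshold: float = 0.015,
) -> list[MotifSite]:
    """Scan each gene's window and report sites in start-codon-relative coordinates."""
    sites: list[MotifSite] = []
    w = matrix.w
    for win in windows:
        first = win.offset_of_first_base
        for i, word, score, p in scan_sequence(win.seq, matrix, dist, p_threshold):
            offset = first + i
            sites.append(
                MotifSite(
                    gene_id=win.gene_id,
                    offset=offset,
                    word=word,
                    score=score,
                    p_value=p,
                    spacer=-(offset + w),
                )
            )
    return sites


def min_passing_int_score(dist: ScoreDistribution, p_threshold: float) -> int | None:
    """Smallest lattice score whose survival probability clears the threshold."""
    passing = np.flatnonzero(dist.sf <= p_threshold)
    if len(passing) == 0:
        return None
    return dist.min_int + int(passing[0])


def null_band_hit_probability(
    matrix: ScoringMatrix,
    dist: ScoreDistribution,
    n_offsets: int,
    p_threshold: float = 0.015,
    background: np.ndarray | None = None,
) -> float:
    """Exact P(>=1 passing w-mer among ``n_offsets`` consecutive offsets of null text).

    Overlapping w-mers are correlated, so the naive 1-(1-u)^n bound
    overstates this probability; here it is computed exactly by a
    transfer-matrix dynamic program whose state is the last w-1 bases of
    the background text.
    """
    if background is None:
        background = matrix.background
    background = np.asarray(background, dtype=float)
    w = matrix.w
    if n_offsets < 1:
        return 0.0
    cutoff = min_passing_int_score(dist, p_threshold)
    if cutoff is None:
        return 0.0
    if w > 10:
        raise ValueError("transfer-matrix null is limited to motif widths <= 10")

    n_states = 4 ** (w - 1)
    # survive[s]: probability mass of length-(w-1) suffix s with no hit so far
    survive = np.zeros(n_states)
    for s in range(n_states):
        p = 1.0
        x = s
        for _ in range(w - 1):
            p *= background[x % 4]
            x //= 4
        survive[s] = p
    # state encoding: most recent base is the low digit
    # state digits: oldest suffix base in the highest digit, newest in the
    # lowest; the low digit is therefore scored with column w-2
    scores_last = matrix.int_scores[:, w - 1]
    prefix_scores = np.zeros(n_states, dtype=np.int64)
    for s in range(n_states):
        x = s
        for j in range(w - 2, -1, -1):
            base = x % 4
            prefix_scores[s] += matrix.int_scores[base, j]
            x //= 4

    for _ in range(n_offsets):
        new = np.zeros(n_states)
        for s in range(n_states):
            if survive[s] == 0.0:
                continue
            for b in range(4):
                if prefix_scores[s] + scores_last[b] >= cutoff:
                    continue  # hit: mass absorbed
                ns = (s * 4 + b) % n_states
                new[ns] += survive[s] * background[b]
        survive = new
    return float(1.0 - survive.sum())


def best_site_per_gene(sites: list[MotifSite]) -> dict[str, MotifSite]:
    """Minimum-p site per gene; p ties resolved to the most 3' (largest offset)."""
    best: dict[str, MotifSite] = {}
    for site in sites:
        cur = best.get(site.gene_id)
        if (
            cur is None
            or site.p_value < cur.p_value
            or (site.p_value == cur.p_value and site.offset > cur.offset)
        ):
            best[site.gene_id] = site
    return best


def sites_to_table(sites: list[MotifSite]) -> pd.DataFrame:
    """FIMO-like table; start/stop 1-based inclusive, start-codon-relative.

    Position +1 is the first base of the start codon and -1 the base
    immediately upstream (there is no position 0 in the reports).
    """

    def one_based(rel: int) -> int:
        return rel + 1 if rel >= 0 else rel

    rows = [
        {
            "gene_id": s.gene_id,
            "start": one_based(s.offset),
            "stop": one_based(s.offset + s.width - 1),
            "score": s.score,
            "p-value": s.p_value,
            "matched_sequence": s.word,
            "spacer": s.spacer,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "start", "stop", "score", "p-value", "matched_sequence", "spacer"],
    )
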
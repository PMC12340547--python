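"""De novo ZOOPS motif discovery by expectation-maximization.

The model: each window independently contains either exactly one motif site
(with prior probability gamma, at a uniformly chosen offset) or none, with
all non-site bases drawn from a 0-order background. This is the classic
"zero or one occurrence per sequence" finite mixture; EM alternates between
posterior site assignment (E-step) and re-estimation of the position
probability matrix theta and gamma (M-step).

Multiple motifs are found sequentially: after each motif, its
maximum-a-posteriori site in every confidently-assigned window is erased
(masked to N) before the next round of discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._seq import ALPHABET, N_CODE, encode
from .genome_io import UpstreamWindow

log = logging.getLogger(__name__)

_BG_FLOOR = 1e-6
_M_STEP_PSEUDO = 0.01  # total pseudo-mass per theta column, spread as background
_SEED_EPS = 0.05  # per-mismatch-base probability when converting a w-mer seed to theta


@dataclass
class MotifModel:
    """A fitted PWM: column-stochastic theta over rows A,C,G,T plus the ZOOPS prior."""

    width: int
    theta: np.ndarray  # (4, w)
    background: np.ndarray  # (4,)
    gamma: float
    log_likelihood: float = float("nan")
    n_training_sequences: int = 0
    ll_trace: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.theta.shape != (4, self.width):
            raise ValueError("theta must be 4 x width")
        if not np.allclose(self.theta.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("theta columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.theta.argmax(axis=0))


@dataclass
class SitePosterior:
    """Per-window posterior over site start offsets plus the no-site alternative."""

    gene_id: str
    offsets: np.ndarray  # posterior of a site starting at each valid offset
    p_no_site: float

    @property
    def p_site(self) -> float:
        return float(self.offsets.sum())

    @property
    def map_offset(self) -> int:
        return int(self.offsets.argmax())


def _encode_windows(windows) -> list[np.ndarray]:
    out = []
    for w in windows:
        seq = w.seq if isinstance(w, UpstreamWindow) else str(w)
        out.append(encode(seq))
    return out


def estimate_background(windows) -> np.ndarray:
    """0-order background: mononucleotide frequencies over all windows, N excluded."""
    if len(windows) == 0:
        raise ValueError("need at least one window")
    counts = np.zeros(5)
    for enc in _encode_windows(windows):
        counts += np.bincount(enc, minlength=5)
    freq = counts[:4]
    if freq.sum() == 0:
        raise ValueError("windows contain no ACGT bases")
    freq = freq / freq.sum()
    freq = np.maximum(freq, _BG_FLOOR)
    return freq / freq.sum()


def seed_candidates(windows, w: int, n_seeds: int, background=None) -> list[np.ndarray]:
    """Initial theta matrices from the most over-represented w-mers.

    Every N-free w-mer in the windows is counted in one pass and ranked by
    count relative to its 0-order background probability; ties break
    lexicographically. Each selected w-mer becomes a theta with probability
    1 - 3*eps on the matching base and eps elsewhere (eps = 0.05).
    """
    if background is None:
        background = estimate_background(windows)
    encs = _encode_windows(windows)
    if min(len(e) for e in encs) < w:
        raise ValueError("w exceeds the shortest window")
    counts: dict[str, int] = {}
    for enc, win in zip(encs, windows):
        seq = win.seq if isinstance(win, UpstreamWindow) else str(win)
        for i in range(len(seq) - w + 1):
            word = seq[i : i + w]
            if "N" in word:
                continue
            counts[word] = counts.get(word, 0) + 1

    logbg = np.log(background)

    def over_representation(item):
        word, count = item
        expected = np.exp(sum(logbg["ACGT".index(b)] for b in word))
        return count / expected

    ranked = sorted(counts.items(), key=lambda it: (-over_representation(it), it[0]))
    seeds = []
    for word, _count in ranked[:n_seeds]:
        theta = np.full((4, w), _SEED_EPS)
        for j, b in enumerate(word):
            theta["ACGT".index(b), j] = 1.0 - 3.0 * _SEED_EPS
        seeds.append(theta)
    return seeds


def _prepare(encs: list[np.ndarray], w: int):
    """Group equal-length windows into matrices for vectorized EM."""
    groups: dict[int, list[int]] = {}
    for i, e in enumerate(encs):
        if len(e) < w:
            raise ValueError(f"window shorter than motif width {w}")
        groups.setdefault(len(e), []).append(i)
    packed = []
    for L, idx in sorted(groups.items()):
        X = np.stack([encs[i] for i in idx]).astype(np.int64)
        packed.append((np.array(idx), X, L - w + 1))
    return packed


def zoops_em(
    windows,
    theta0: np.ndarray,
    background: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
    gamma0: float = 0.5,
) -> tuple[MotifModel, list[SitePosterior]]:
    """Fit the ZOOPS mixture by EM from an initial theta.

    Iterates until the observed-data log likelihood changes by less than
    ``tol`` or ``max_iter`` is reached. N bases are treated as uninformative
    (they contribute neither to site odds nor to theta counts).

    The M-step smooths theta with a small background-proportional
    pseudocount, which makes each update ascend the penalized (posterior)
    objective rather than the raw likelihood; near a boundary fixed point
    the raw likelihood can then drift down by a sliver per iteration. A
    monotone safeguard rejects any update that lowers the observed-data log
    likelihood and terminates at the previous iterate, so the reported
    likelihood trace is non-decreasing by construction.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    w = theta.shape[1]
    background = np.asarray(background, dtype=float)
    encs = _encode_windows(windows)
    packed = _prepare(encs, w)
    n = len(encs)
    gamma = float(gamma0)

    # constant background log-probability of each window (N bases contribute 0)
    logbg5 = np.concatenate([np.log(background), [0.0]])
    const_ll = sum(float(logbg5[e].sum()) for e in encs)

    ll_trace: list[float] = []
    prev_ll = None
    Z_groups = None
    prev_state = None  # (theta, gamma, Z_groups) of the last accepted iterate
    for it in range(max_iter):
        # E-step: log-odds of a site at each offset
        lor = np.vstack([np.log(theta) - np.log(background)[:, None], np.zeros((1, w))])
        Z_groups = []
        ll = const_ll
        counts = np.zeros((4, w))
        site_mass = 0.0
        for idx, X, m in packed:
            R = np.zeros((X.shape[0], m))
            for k in range(w):
                R += lor[X[:, k : k + m], k]
            r = np.exp(R)
            denom = (1.0 - gamma) + (gamma / m) * r.sum(axis=1)
            Z = (gamma / m) * r / denom[:, None]
            ll += float(np.log(denom).sum())
            Z_groups.append((idx, X, m, Z, (1.0 - gamma) / denom))
            site_mass += float(Z.sum())
            for k in range(w):
                ck = np.bincount(
                    X[:, k : k + m].ravel(), weights=Z.ravel(), minlength=5
                )
                counts[:, k] += ck[:4]
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite ZOOPS likelihood at iteration {it}")
        if prev_ll is not None and ll < prev_ll:
            # monotone safeguard: keep the previous, better iterate
            theta, gamma, Z_groups = prev_state
            break
        ll_trace.append(ll)
        if prev_ll is not None and abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
        prev_state = (theta.copy(), gamma, Z_groups)

        # M-step
        counts += _M_STEP_PSEUDO * background[:, None]
        theta = counts / counts.sum(axis=0, keepdims=True)
        gamma = min(max(site_mass / n, 1e-9), 1.0 - 1e-9)

    posteriors: list[SitePosterior] = [None] * n  # type: ignore[list-item]
    for idx, X, m, Z, no_site in Z_groups:
        for row, i in enumerate(idx):
            win = windows[i]
            gid = win.gene_id if isinstance(win, UpstreamWindow) else f"seq_{i}"
            posteriors[i] = SitePosterior(gid, Z[row].copy(), float(no_site[row]))

    model = MotifModel(
        width=w,
        theta=theta,
        background=background,
        gamma=gamma,
        log_likelihood=ll_trace[-1],
        n_training_sequences=n,
        ll_trace=ll_trace,
    )
    return model, posteriors


def site_posteriors(model: MotifModel, windows) -> list[SitePosterior]:
    """E-step only: posterior site locations under a fixed fitted model."""
    _, post = zoops_em(
        windows, model.theta, model.background, max_iter=1, tol=np.inf, gamma0=model.gamma
    )
    return post


def discover_motifs(
    windows,
    w: int,
    nmotifs: int = 2,
    n_seeds: int = 50,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> list[MotifModel]:
    """Sequential ZOOPS discovery of ``nmotifs`` motifs of width ``w``.

    For each motif the EM is restarted from the ``n_seeds`` most
    over-represented w-mer seeds and the highest-likelihood fit is kept;
    confidently assigned sites (MAP posterior > 0.5) are then masked to N
    before the next motif is sought. The procedure is deterministic; ``seed``
    is kept for interface stability of seeded restart schedules.
    """
    if nmotifs < 1:
        raise ValueError("nmotifs must be >= 1")
    del seed  # restarts are a deterministic seed ranking
    background = estimate_background(windows)
    work = [
        UpstreamWindow(
            win.gene_id if isinstance(win, UpstreamWindow) else f"seq_{i}",
            win.seq if isinstance(win, UpstreamWindow) else str(win),
            win.offset_of_last_base if isinstance(win, UpstreamWindow) else -1,
        )
        for i, win in enumerate(windows)
    ]
    models: list[MotifModel] = []
    for _ in range(nmotifs):
        best: tuple[MotifModel, list[SitePosterior]] | None = None
        for theta0 in seed_candidates(work, w, n_seeds, background):
            model, post = zoops_em(work, theta0, background, max_iter=max_iter, tol=tol)
            if best is None or model.log_likelihood > best[0].log_likelihood:
                best = (model, post)
        if best is None:
            raise ValueError("no valid seeds found")
        model, post = best
        models.append(model)
        if len(models) == nmotifs:
            break
        # erase MAP sites before the next discovery round
        erased = []
        for win, p in zip(work, post):
            seq = win.seq
            if p.p_site > 0.5:
                j = p.map_offset
                seq = seq[:j] + "N" * w + seq[j + w :]
            erased.append(UpstreamWindow(win.gene_id, seq, win.offset_of_last_base))
        work = erased
    return models


def consensus_and_variants(model: MotifModel, windows, posteriors=None):
    """Consensus string plus a count table of exact w-mers at MAP sites.

    Only windows whose total site posterior exceeds 0.5 contribute a variant.
    Returns (consensus, DataFrame with columns variant, count) sorted by
    descending count then alphabetically.
    """
    import pandas as pd

    if posteriors is None:
        posteriors = site_posteriors(model, windows)
    w = model.width
    counts: dict[str, int] = {}
    for win, post in zip(windows, posteriors):
        if post.p_site <= 0.5:
            continue
        seq = win.seq if isinstance(win, UpstreamWindow) else str(win)
        word = seq[post.map_offset : post.map_offset + w]
        if "N" in word:
            continue
        counts[word] = counts.get(word, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["variant", "count"],
    )
    return model.consensus, table


def information_content(model: MotifModel) -> np.ndarray:
    """Per-column relative-entropy (bits) of theta against the background."""
    theta = np.maximum(model.theta, 1e-12)
    return (theta * np.log2(theta / model.background[:, None])).sum(axis=0)
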
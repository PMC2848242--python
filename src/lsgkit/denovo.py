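"""Discriminative de novo motif discovery and PWM-to-PWM matching.

Discovery uses a plain discriminative Gibbs sampler: one candidate site
per foreground promoter (ZOOPS — zero or one occurrence per sequence, via
an explicit no-site option), a PWM re-estimated from the current sites
with pseudocounts, and window scores that are log-odds against a 0-order
background model estimated from the background promoter set.  The
objective that ranks motifs is

    mean over foreground sequences of the best-site log-odds
    - mean over background sequences of the best-site log-odds   (nats),

which is ~0 when foreground and background are indistinguishable and grows
with discriminative signal.  The best of ``restarts`` independent seeded
restarts is reported, so results are deterministic given the RNG seed.

Discovered matrices are matched against a known-PWM library by the best
mean aligned-column Pearson correlation over all offsets (minimum overlap
4 columns) and both orientations, with an empirical p-value from shuffling
the target's columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .motifscan import PWM, encode

_RC_PERM = np.array([3, 2, 1, 0])


@dataclass
class DenovoConfig:
    width_min: int = 6
    width_max: int = 16
    restarts: int = 100  # independent sampler restarts per width
    seed: int = 0
    pseudocount: float = 0.5
    sweeps: int = 40  # Gibbs sweeps per restart
    background_order: int = 0

    def __post_init__(self) -> None:
        if self.width_min < 4:
            raise ValueError("motif widths must be >= 4")
        if self.restarts < 1:
            raise ValueError("need at least one restart")
        if self.background_order != 0:
            raise ValueError("only a 0-order background model is supported")


@dataclass
class DiscoveredMotif:
    frequencies: np.ndarray  # (width, 4), rows sum to 1
    width: int
    objective: float  # discriminative log-odds gap, nats
    sites: dict[str, int | None] = field(default_factory=dict)  # 0-based starts

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.frequencies, axis=1))

    def to_pwm(self, matrix_id: str, depth: int = 100) -> PWM:
        return PWM(matrix_id, np.round(self.frequencies * depth, 6) + 1e-9)


def estimate_background(sequences) -> np.ndarray:
    """0-order base frequencies over {A,C,G,T}; N and other codes excluded."""
    counts = np.zeros(4)
    seqs = sequences.values() if isinstance(sequences, dict) else sequences
    for seq in seqs:
        codes = encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no informative (ACGT) bases in background")
    return counts / counts.sum()


def _prepare(seqs: dict[str, str], width: int):
    """Coded sequences with >= 1 valid window; shorter ones are excluded."""
    ids, coded = [], []
    for sid, seq in seqs.items():
        c = encode(seq.upper())
        if len(c) >= width:
            ids.append(sid)
            coded.append(c)
        else:
            warnings.warn(f"sequence {sid} shorter than width {width}; excluded")
    return ids, coded


def _window_logodds(codes: np.ndarray, logodds: np.ndarray, width: int) -> np.ndarray:
    """Log-odds of every window; windows touching non-ACGT codes get -inf."""
    n_win = len(codes) - width + 1
    padded = np.hstack([logodds, np.full((width, 1), -np.inf)])
    s = np.zeros(n_win)
    for j in range(width):
        s += padded[j, codes[j : j + n_win]]
    return s


def _counts_from_sites(coded, sites, width: int) -> np.ndarray:
    counts = np.zeros((width, 4))
    for c, pos in zip(coded, sites):
        if pos is None:
            continue
        win = c[pos : pos + width]
        counts[np.arange(width), win] += 1.0
    return counts


def _pwm_logodds(counts, bg, pseudocount) -> np.ndarray:
    f = counts + pseudocount * 4 * bg  # pseudocounts proportional to background
    f = f / f.sum(axis=1, keepdims=True)
    return np.log(f) - np.log(bg)


def discover(
    foreground: dict[str, str],
    background: dict[str, str],
    width: int,
    cfg: DenovoConfig | None = None,
) -> DiscoveredMotif:
    """Best discriminative motif of a fixed width over seeded restarts."""
    cfg = cfg or DenovoConfig()
    fg_ids, fg = _prepare(foreground, width)
    if len(fg) < 5:
        raise ValueError("need at least 5 usable foreground sequences")
    bg_ids, bg_seqs = _prepare(background, width)
    bg_freq = estimate_background(background)

    # valid (N-free) window indicators, reused across restarts
    def valid_windows(codes):
        n_win = len(codes) - width + 1
        bad = codes >= 4
        if not bad.any():
            return np.ones(n_win, dtype=bool)
        csum = np.concatenate([[0], np.cumsum(bad)])
        return (csum[width:] - csum[:-width]) == 0

    fg_valid = [valid_windows(c) for c in fg]

    best: DiscoveredMotif | None = None
    for restart in range(cfg.restarts):
        rng = np.random.default_rng([cfg.seed, width, restart])
        # seed-driven start: pick one random foreground window and place
        # every sequence's initial site at its best match to that word,
        # which finds sparse planted sites in long promoters far more
        # reliably than uniformly random initial sites
        si0 = int(rng.integers(len(fg)))
        v0 = np.nonzero(fg_valid[si0])[0]
        sites: list[int | None]
        if len(v0):
            p0 = int(rng.choice(v0))
            seed_counts = _counts_from_sites([fg[si0]], [p0], width)
            lo0 = _pwm_logodds(seed_counts, bg_freq, cfg.pseudocount)
            sites = []
            for c, v in zip(fg, fg_valid):
                if not v.any():
                    sites.append(None)
                    continue
                s = _window_logodds(c, lo0, width)
                sites.append(int(np.argmax(np.where(v, s, -np.inf))))
        else:
            sites = [
                int(rng.choice(np.nonzero(v)[0])) if v.any() else None
                for v in fg_valid
            ]
        counts = _counts_from_sites(fg, sites, width)

        for _sweep in range(cfg.sweeps):
            for si in range(len(fg)):
                pos = sites[si]
                if pos is not None:
                    win = fg[si][pos : pos + width]
                    counts[np.arange(width), win] -= 1.0
                if not fg_valid[si].any():
                    sites[si] = None
                    continue
                lo = _pwm_logodds(counts, bg_freq, cfg.pseudocount)
                scores = _window_logodds(fg[si], lo, width)
                scores[~fg_valid[si]] = -np.inf
                # ZOOPS: the no-site option competes with score 0 (log-odds 1:1)
                w = np.exp(np.concatenate([scores - scores.max(), [0.0 - scores.max()]]))
                w /= w.sum()
                pick = rng.choice(len(w), p=w)
                new_pos = None if pick == len(w) - 1 else int(pick)
                sites[si] = new_pos
                if new_pos is not None:
                    win = fg[si][new_pos : new_pos + width]
                    counts[np.arange(width), win] += 1.0

        # foreground scored leave-one-out (each sequence's own site removed
        # before scoring it) so the objective is ~0 when foreground and
        # background are indistinguishable instead of optimistically biased
        fg_best = []
        for si, (c, v) in enumerate(zip(fg, fg_valid)):
            if not v.any():
                continue
            cts = counts.copy()
            if sites[si] is not None:
                win = c[sites[si] : sites[si] + width]
                cts[np.arange(width), win] -= 1.0
            lo_i = _pwm_logodds(cts, bg_freq, cfg.pseudocount)
            s = _window_logodds(c, lo_i, width)
            fg_best.append(float(np.max(np.where(v, s, -np.inf))))
        lo = _pwm_logodds(counts, bg_freq, cfg.pseudocount)
        bg_best = []
        for c in bg_seqs:
            s = _window_logodds(c, lo, width)
            if len(s) and np.isfinite(s.max()):
                bg_best.append(float(s.max()))
        objective = float(
            (np.mean(fg_best) if fg_best else 0.0)
            - (np.mean(bg_best) if bg_best else 0.0)
        )
        if best is None or objective > best.objective:
            f = counts + cfg.pseudocount * 4 * bg_freq
            f = f / f.sum(axis=1, keepdims=True)
            best = DiscoveredMotif(
                frequencies=f,
                width=width,
                objective=objective,
                sites=dict(zip(fg_ids, sites)),
            )
    assert best is not None
    return best


def discover_all(
    foreground: dict[str, str],
    background: dict[str, str],
    cfg: DenovoConfig | None = None,
) -> list[DiscoveredMotif]:
    """One motif per width in [width_min, width_max], ranked by objective."""
    cfg = cfg or DenovoConfig()
    if not foreground:
        raise ValueError("empty foreground")
    motifs = [
        discover(foreground, background, w, cfg)
        for w in range(cfg.width_min, cfg.width_max + 1)
    ]
    motifs.sort(key=lambda m: -m.objective)
    return motifs


# ---------------------------------------------------------------------------
# PWM-to-PWM matching
# ---------------------------------------------------------------------------

@dataclass
class MotifMatch:
    query_id: str
    target_id: str
    offset: int
    orientation: str  # "+" or "-"
    score: float  # best mean aligned-column Pearson correlation
    p: float
    significant: bool


def _col_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two frequency columns (4-vectors)."""
    ad = a - a.mean()
    bd = b - b.mean()
    denom = np.sqrt((ad ** 2).sum() * (bd ** 2).sum())
    if denom == 0:
        return 0.0
    return float((ad * bd).sum() / denom)


def _align_score(q: np.ndarray, t: np.ndarray, min_overlap: int = 4):
    """(score, offset): best aligned-column correlation over all alignments.

    The correlation sum is averaged over the full query width, so query
    columns left unaligned contribute zero — a short high-correlation
    overlap cannot outscore a full-length match.
    """
    wq, wt = len(q), len(t)
    best, best_off = -np.inf, 0
    for off in range(-(wt - min_overlap), wq - min_overlap + 1):
        cols = [
            _col_corr(q[i], t[i - off])
            for i in range(max(0, off), min(wq, wt + off))
        ]
        if len(cols) < min_overlap:
            continue
        s = float(np.sum(cols) / wq)
        if s > best:
            best, best_off = s, off
    return best, best_off


def _revcomp_freqs(f: np.ndarray) -> np.ndarray:
    return f[::-1][:, _RC_PERM]


def pwm_compare(
    query: np.ndarray | PWM,
    target: np.ndarray | PWM,
    n_shuffles: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
    query_id: str = "query",
    target_id: str = "target",
) -> MotifMatch:
    """Match two PWMs by aligned-column correlation with a shuffle null.

    The empirical p-value is (1 + #{column-shuffled targets scoring >= the
    observed score}) / (n_shuffles + 1); a match is significant when
    p < alpha (default 0.01).
    """
    if isinstance(query, PWM):
        query_id, query = query.matrix_id, query.frequencies
    if isinstance(target, PWM):
        target_id, target = target.matrix_id, target.frequencies
    q = np.asarray(query, dtype=float)
    t = np.asarray(target, dtype=float)
    if len(q) < 4 or len(t) < 4:
        raise ValueError("both PWMs need >= 4 columns")

    s_fwd, off_fwd = _align_score(q, t)
    s_rev, off_rev = _align_score(q, _revcomp_freqs(t))
    if s_fwd >= s_rev:
        observed, offset, orient = s_fwd, off_fwd, "+"
    else:
        observed, offset, orient = s_rev, off_rev, "-"

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(len(t))
        ts = t[perm]
        s1, _ = _align_score(q, ts)
        s2, _ = _align_score(q, _revcomp_freqs(ts))
        if max(s1, s2) >= observed - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_shuffles + 1)
    return MotifMatch(
        query_id=query_id,
        target_id=target_id,
        offset=offset,
        orientation=orient,
        score=observed,
        p=p,
        significant=p < alpha,
    )


def match_library(
    motif: DiscoveredMotif,
    library: list[PWM],
    n_shuffles: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
    query_id: str = "denovo",
) -> list[MotifMatch]:
    """Match a discovered motif against every library PWM, best first."""
    matches = [
        pwm_compare(
            motif.frequencies,
            pwm.frequencies,
            n_shuffles=n_shuffles,
            seed=seed + i,
            alpha=alpha,
            query_id=query_id,
            target_id=pwm.matrix_id,
        )
        for i, pwm in enumerate(library)
    ]
    matches.sort(key=lambda m: (m.p, -m.score))
    return matches


def write_meme(motifs: list[DiscoveredMotif], path, background=None) -> None:
    """MEME minimal motif format."""
    bg = background if background is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            f"A {bg[0]:.4f} C {bg[1]:.4f} G {bg[2]:.4f} T {bg[3]:.4f}\n\n"
        )
        for i, m in enumerate(motifs, start=1):
            n_sites = sum(1 for p in m.sites.values() if p is not None) or 1
            fh.write(f"MOTIF DN{i}_{m.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {n_sites} E= 0\n"
            )
            for row in m.frequencies:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def write_matches_tsv(matches: list[MotifMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("query\ttarget\toffset\torientation\tscore\tp\tsignificant\n")
        for m in matches:
            fh.write(
                f"{m.query_id}\t{m.target_id}\t{m.offset}\t{m.orientation}\t"
                f"{m.score:.4f}\t{m.p:.6g}\t{int(m.significant)}\n"
            )
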
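"""Position-weight-matrix parsing and Match-style promoter scanning.

A PWM is stored as per-position nucleotide counts (TRANSFAC flat-file
convention, columns A C G T).  Scanning follows the Match scoring scheme:
each position carries an information weight

    I(i) = sum_b f(i,b) * ln(4 * f(i,b))        (0 * ln 0 := 0)

and a candidate word w is scored by the matrix similarity

    MSS = (Current - Min) / (Max - Min)

with Current = sum_i I(i) * f(i, w_i) and Min/Max the analogous sums over
the least/most frequent base per position.  The core similarity applies the
same formula restricted to the five consecutive most informative positions.
Both scores lie in [0, 1] and equal 1 for a consensus word.  The log base
cancels in the ratio; natural log is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_PERM = np.array([3, 2, 1, 0])  # A<->T, C<->G
CORE_LENGTH = 5


class DegenerateMatrixError(ValueError):
    """Raised when a PWM carries no information (Max == Min)."""


@dataclass
class PWM:
    """A position count matrix with Match-style derived quantities."""

    matrix_id: str
    counts: np.ndarray  # shape (width, 4), columns A C G T
    name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"{self.matrix_id}: counts must be (width, 4)")
        sums = self.counts.sum(axis=1)
        if np.any(sums <= 0):
            row = int(np.argmin(sums)) + 1
            raise ValueError(f"{self.matrix_id}: position {row} has zero total count")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    @property
    def information(self) -> np.ndarray:
        """Per-position information vector I(i), in nats, range [0, ln 4]."""
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(f > 0, f * np.log(4.0 * f), 0.0)
        return term.sum(axis=1)

    @property
    def consensus(self) -> str:
        """Most frequent base per position; ties resolved in A<C<G<T order."""
        return "".join(BASES[i] for i in np.argmax(self.frequencies, axis=1))

    def core_positions(self, core_length: int = CORE_LENGTH) -> tuple[int, int]:
        """0-based [start, end) of the most informative consecutive window.

        Ties go to the leftmost window.  A matrix narrower than the core
        length uses its full width (with a warning).
        """
        info = self.information
        if self.width < core_length:
            warnings.warn(
                f"{self.matrix_id}: width {self.width} < core length "
                f"{core_length}; using full width as core"
            )
            return 0, self.width
        sums = np.convolve(info, np.ones(core_length), mode="valid")
        start = int(np.argmax(np.round(sums, 12)))
        return start, start + core_length

    def reverse_complement(self) -> "PWM":
        rc = self.counts[::-1, _COMPLEMENT_PERM]
        return PWM(self.matrix_id, rc.copy(), name=self.name)


@dataclass(frozen=True)
class HitRecord:
    """A PWM match on a promoter, coordinates 1-based on the forward strand."""

    promoter_id: str
    matrix_id: str
    start: int
    end: int
    strand: str
    core_sim: float
    matrix_sim: float


@dataclass
class MatchConfig:
    core_threshold: float = 0.9
    matrix_threshold: float = 0.85
    core_length: int = CORE_LENGTH
    both_strands: bool = True

    def __post_init__(self) -> None:
        for t in (self.core_threshold, self.matrix_threshold):
            if not 0 < t <= 1:
                raise ValueError(f"thresholds must be in (0, 1], got {t}")


def _similarity_weights(pwm: PWM, positions: slice | None = None):
    """(weights, min_sum, max_sum) for the MSS formula over given positions."""
    f = pwm.frequencies
    info = pwm.information
    if positions is not None:
        f = f[positions]
        info = info[positions]
    w = info[:, None] * f  # contribution of base b at position i
    lo = w.min(axis=1).sum()
    hi = w.max(axis=1).sum()
    return w, lo, hi


def encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0 C=1 G=2 T=3, anything else 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _word_score(weights: np.ndarray, lo: float, hi: float, codes: np.ndarray) -> float:
    if hi - lo <= 0:
        raise DegenerateMatrixError("degenerate matrix")
    cur = weights[np.arange(len(codes)), codes].sum()
    return (cur - lo) / (hi - lo)


def mss(pwm: PWM, word: str) -> float:
    """Matrix similarity of ``word`` (must be PWM-width, over ACGT)."""
    if len(word) != pwm.width:
        raise ValueError(f"word length {len(word)} != width {pwm.width}")
    codes = encode(word)
    if np.any(codes > 3):
        raise ValueError(f"word {word!r} contains non-ACGT characters")
    return _word_score(*_similarity_weights(pwm), codes)


def core_similarity(pwm: PWM, word: str, core_length: int = CORE_LENGTH) -> float:
    """Matrix-similarity formula restricted to the core positions."""
    if len(word) != pwm.width:
        raise ValueError(f"word length {len(word)} != width {pwm.width}")
    a, b = pwm.core_positions(core_length)
    codes = encode(word)[a:b]
    return _word_score(*_similarity_weights(pwm, slice(a, b)), codes)


def _window_scores(
    pwm: PWM, codes: np.ndarray, core_length: int, core_window: tuple[int, int] | None = None
):
    """Vectorised (mss, css) arrays for every window of a coded sequence.

    Windows containing a non-ACGT code score -inf.  ``core_window``
    overrides the matrix's own core positions (used when scanning the
    reverse strand: the core is a property of the matrix, so the mirrored
    forward core is imposed on the reverse-complemented matrix).
    """
    w = pwm.width
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0)
    weights, lo, hi = _similarity_weights(pwm)
    if hi - lo <= 0:
        raise DegenerateMatrixError(f"{pwm.matrix_id}: degenerate matrix")
    a, b = core_window if core_window is not None else pwm.core_positions(core_length)
    cweights, clo, chi = _similarity_weights(pwm, slice(a, b))
    padded = np.hstack([weights, np.full((w, 1), -np.inf)])
    cpadded = np.hstack([cweights, np.full((b - a, 1), -np.inf)])
    cur = np.zeros(n_win)
    ccur = np.zeros(n_win)
    for j in range(w):
        cur += padded[j, codes[j : j + n_win]]
        if a <= j < b:
            ccur += cpadded[j - a, codes[j : j + n_win]]
    ms = (cur - lo) / (hi - lo)
    if chi - clo > 0:
        cs = (ccur - clo) / (chi - clo)
    else:
        # core carries no information: any ACGT word matches the core fully
        cs = np.where(np.isfinite(ccur), 1.0, -np.inf)
    return ms, cs


def scan(
    pwm: PWM,
    promoter_id: str,
    sequence: str,
    cfg: MatchConfig | None = None,
) -> list[HitRecord]:
    """All windows passing both thresholds, on both strands by default.

    Coordinates are 1-based on the promoter's own (TSS-oriented) forward
    coordinate system regardless of which strand matched.  Windows touching
    an N (or any non-ACGT base) are skipped.
    """
    cfg = cfg or MatchConfig()
    codes = encode(sequence)
    hits: list[HitRecord] = []
    a, b = pwm.core_positions(cfg.core_length)
    strands = [("+", pwm, (a, b))]
    if cfg.both_strands:
        # mirror the forward core onto the reverse-complemented matrix
        strands.append(("-", pwm.reverse_complement(), (pwm.width - b, pwm.width - a)))
    for strand, mat, core in strands:
        ms, cs = _window_scores(mat, codes, cfg.core_length, core_window=core)
        keep = np.nonzero(
            (ms >= cfg.matrix_threshold) & (cs >= cfg.core_threshold)
        )[0]
        for i in keep:
            hits.append(
                HitRecord(
                    promoter_id=promoter_id,
                    matrix_id=pwm.matrix_id,
                    start=int(i) + 1,
                    end=int(i) + pwm.width,
                    strand=strand,
                    core_sim=float(cs[i]),
                    matrix_sim=float(ms[i]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def scan_promoters(
    pwms: Sequence[PWM],
    promoters: dict[str, str],
    cfg: MatchConfig | None = None,
) -> dict[str, list[HitRecord]]:
    """Scan every promoter with every PWM; hits per promoter, sorted by start."""
    cfg = cfg or MatchConfig()
    out: dict[str, list[HitRecord]] = {}
    for pid, seq in promoters.items():
        hits: list[HitRecord] = []
        for pwm in pwms:
            hits.extend(scan(pwm, pid, seq, cfg))
        hits.sort(key=lambda h: (h.start, h.end, h.matrix_id, h.strand))
        out[pid] = hits
    return out


def presence_map(
    pwms: Sequence[PWM],
    promoters: dict[str, str],
    cfg: MatchConfig | None = None,
    hits: dict[str, list[HitRecord]] | None = None,
) -> dict[str, set[str]]:
    """Binary per-promoter presence of each matrix (one occurrence counts).

    Full hit lists (needed for composite analysis) can be passed in to avoid
    rescanning, or are computed on the fly.
    """
    if hits is None:
        hits = scan_promoters(pwms, promoters, cfg)
    return {pid: {h.matrix_id for h in hs} for pid, hs in hits.items()}


# ---------------------------------------------------------------------------
# TRANSFAC flat-file format
# ---------------------------------------------------------------------------

def parse_transfac(path_or_lines) -> list[PWM]:
    """Parse a TRANSFAC flat matrix file (AC/ID/NA/P0 records, // separator).

    Counts are preserved exactly as written.  A position row whose counts
    sum to zero is an error naming the matrix and row.
    """
    if isinstance(path_or_lines, (str, bytes)) or hasattr(path_or_lines, "__fspath__"):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)

    pwms: list[PWM] = []
    ac = name = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal ac, name, rows
        if ac is not None and rows:
            counts = np.array(rows, dtype=float)
            zero = np.nonzero(counts.sum(axis=1) == 0)[0]
            if zero.size:
                raise ValueError(
                    f"matrix {ac}: row {zero[0] + 1} has zero total count"
                )
            pwms.append(PWM(ac, counts, name=name or ""))
        ac = name = None
        rows = []

    for line in lines:
        line = line.rstrip("\n")
        tag = line[:2]
        rest = line[2:].strip()
        if tag == "//":
            flush()
        elif tag == "AC":
            ac = rest
        elif tag == "ID":
            if ac is None:
                ac = rest
        elif tag == "NA":
            name = rest
        elif tag in ("P0", "PO"):
            continue  # header row listing the base columns
        elif tag.isdigit():
            parts = rest.split()
            if len(parts) < 4:
                raise ValueError(f"matrix {ac}: malformed count row {line!r}")
            rows.append([float(x) for x in parts[:4]])
    flush()
    return pwms


def write_transfac(pwms: Iterable[PWM], path) -> None:
    """Write matrices in TRANSFAC flat format (valid even when empty)."""
    with open(path, "w") as fh:
        fh.write("VV  lsgkit synthetic matrix library\nXX\n//\n")
        for pwm in pwms:
            fh.write(f"AC  {pwm.matrix_id}\nXX\n")
            fh.write(f"ID  {pwm.matrix_id}\nXX\n")
            if pwm.name:
                fh.write(f"NA  {pwm.name}\nXX\n")
            fh.write("P0      A      C      G      T\n")
            cons = pwm.consensus
            for i, row in enumerate(pwm.counts, start=1):
                cells = "  ".join(f"{v:g}".rjust(5) for v in row)
                fh.write(f"{i:02d}  {cells}  {cons[i - 1]}\n")
            fh.write("XX\n//\n")


def write_hits_tsv(hits: dict[str, list[HitRecord]], path) -> None:
    with open(path, "w") as fh:
        fh.write("promoter\tmatrix\tstart\tend\tstrand\tcore_sim\tmatrix_sim\n")
        for pid in sorted(hits):
            for h in hits[pid]:
                fh.write(
                    f"{h.promoter_id}\t{h.matrix_id}\t{h.start}\t{h.end}\t"
                    f"{h.strand}\t{h.core_sim:.6f}\t{h.matrix_sim:.6f}\n"
                )


def write_hits_gff3(hits: dict[str, list[HitRecord]], path) -> None:
    """Hits as GFF3 with promoter-relative coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for pid in sorted(hits):
            for h in hits[pid]:
                attrs = f"ID={h.matrix_id};matrix_sim={h.matrix_sim:.4f};core_sim={h.core_sim:.4f}"
                fh.write(
                    f"{pid}\tlsgkit\tTF_binding_site\t{h.start}\t{h.end}\t"
                    f"{h.matrix_sim:.4f}\t{h.strand}\t.\t{attrs}\n"
                )
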
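"""Position-weight-matrix construction, scanning and exact p-values.

A position frequency matrix (PFM, base counts per motif column) is converted
into a log2-odds position weight matrix (PWM) against a background base
composition, with a pseudocount distributed proportionally to the background:

    w[j][b] = log2( ((c[j][b] + q*bg[b]) / (N_j + q)) / bg[b] )

where ``c`` are counts, ``N_j`` the column total and ``q`` the pseudocount.
Window scores are sums of per-column weights; the JASPAR-style *relative
score* rescales a score linearly onto [0, 1] between the minimal and maximal
attainable sums.  Exact p-values under the background model are obtained by
dynamic-programming convolution of the discretized per-column score
distributions, the same construction FIMO uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("bgregulome.pwm")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default background: uniform base composition
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
#: default pseudocount (TFBS/Biopython convention)
DEFAULT_PSEUDOCOUNT = 0.8
#: default relative-score scan threshold (JASPAR web default)
DEFAULT_REL_THRESHOLD = 0.8
#: default p-value discretization, as a fraction of the score range
DEFAULT_GRANULARITY_FRACTION = 1e-3


class InvalidWindowError(ValueError):
    """A window cannot be scored (wrong length, or bases outside {A,C,G,T})."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PositionFrequencyMatrix:
    """Base counts per motif column, rows ordered A, C, G, T transposed to
    an (L, 4) array."""

    identifier: str
    counts: np.ndarray  # shape (L, 4), non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an (L, 4) array")
        if self.counts.shape[0] < 4:
            raise ValueError("motif length must be at least 4")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError("every column needs at least one positive count")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))

    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmin(axis=1))


def read_jaspar_pfm(path) -> PositionFrequencyMatrix:
    """Read a single motif in JASPAR PFM text format (Bio.motifs backend)."""
    from Bio import motifs

    with open(path) as handle:
        motif = motifs.read(handle, "jaspar")
    counts = np.array([motif.counts[b] for b in BASES], dtype=float).T
    return PositionFrequencyMatrix(identifier=motif.matrix_id or motif.name, counts=counts)


def write_jaspar_pfm(pfm: PositionFrequencyMatrix, path) -> None:
    with open(path, "w") as out:
        out.write(f">{pfm.identifier} {pfm.identifier}\n")
        for i, base in enumerate(BASES):
            row = " ".join(f"{v:g}" for v in pfm.counts[:, i])
            out.write(f"{base} [ {row} ]\n")


@dataclass
class PositionWeightMatrix:
    """Log2-odds weights with score bounds and per-column information content.

    ``info_content[j]`` is 2 + sum_b p log2 p of the pseudocounted column
    probabilities, in bits; it defines the motif's core columns.
    """

    identifier: str
    weights: np.ndarray       # (L, 4) log2-odds
    background: np.ndarray    # (4,) probabilities
    pseudocount: float
    s_min: float
    s_max: float
    info_content: np.ndarray  # (L,) bits
    _pvalue_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    def core_columns(self, n: int = 4) -> np.ndarray:
        """Indices of the n highest-information columns, ascending."""
        order = np.argsort(-self.info_content, kind="stable")[:n]
        return np.sort(order)


def build_pwm(
    pfm: PositionFrequencyMatrix,
    background=UNIFORM_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PositionWeightMatrix:
    """Convert a count matrix into a log2-odds PWM.

    The pseudocount is shared across bases proportionally to the background.
    With ``pseudocount=0`` any zero count produces a -inf weight, which is
    permitted (the consensus score stays finite) but leaves relative scores
    and p-values undefined; a zero *column total* with zero pseudocount is an
    error.
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be 4 strictly positive probabilities")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background probabilities must sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    totals = pfm.counts.sum(axis=1)
    if pseudocount == 0 and np.any(totals == 0):
        raise ValueError("zero column total with zero pseudocount (log of zero)")
    probs = (pfm.counts + pseudocount * bg) / (totals + pseudocount)[:, None]
    with np.errstate(divide="ignore"):
        weights = np.log2(probs / bg)
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return PositionWeightMatrix(
        identifier=pfm.identifier,
        weights=weights,
        background=bg,
        pseudocount=float(pseudocount),
        s_min=float(weights.min(axis=1).sum()),
        s_max=float(weights.max(axis=1).sum()),
        info_content=info,
    )


def score_window(pwm: PositionWeightMatrix, window: str) -> float:
    """Log2-odds score of one window; columns are summed left to right."""
    if len(window) != pwm.length:
        raise InvalidWindowError(
            f"window length {len(window)} != motif length {pwm.length}"
        )
    try:
        idx = [_BASE_INDEX[b] for b in window]
    except KeyError as exc:
        raise InvalidWindowError(f"unscorable base {exc.args[0]!r} in window") from None
    return float(pwm.weights[np.arange(pwm.length), idx].sum())


def relative_score(pwm: PositionWeightMatrix, s: float) -> float:
    """Rescale a score onto [0, 1]: (s - s_min) / (s_max - s_min)."""
    span = pwm.s_max - pwm.s_min
    if not np.isfinite(span) or span <= 0:
        raise ValueError("degenerate matrix: s_max equals s_min")
    r = (s - pwm.s_min) / span
    # clamp float round-off at the consensus/anti-consensus boundaries
    if -1e-9 <= r <= 1 + 1e-9:
        r = min(max(r, 0.0), 1.0)
    return r


@dataclass
class MotifHit:
    """A scored motif occurrence.

    ``start`` is the 0-based forward-strand start of the occupied interval
    [start, start + L).  ``window`` is the sequence actually scored, i.e. the
    reverse complement of the genomic forward-strand slice for "-" hits.
    """

    contig: str
    start: int
    strand: str
    window: str
    score: float
    relative_score: float
    p_value: float | None = None

    @property
    def end(self) -> int:
        return self.start + len(self.window)


def _strand_scores(weights: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Window scores for one weight matrix; NaN where a window contains N."""
    L = weights.shape[0]
    n_win = codes.size - L + 1
    # 5th column catches N / unknown codes
    ext = np.hstack([weights, np.full((L, 1), np.nan)])
    scores = np.zeros(n_win)
    for j in range(L):
        scores += ext[j, codes[j : j + n_win]]
    return scores


def scan_sequence(
    pwm: PositionWeightMatrix,
    sequence,
    threshold: float = DEFAULT_REL_THRESHOLD,
    strands: str = "both",
    granularity: float | None = None,
    with_pvalues: bool = True,
) -> list[MotifHit]:
    """Report every window on the requested strands with relative score >=
    threshold, sorted by start.  Reverse-strand hits are placed at their
    forward-strand interval with strand "-".  Windows containing N are
    skipped (counted in the log)."""
    name = getattr(sequence, "name", "seq")
    seq = getattr(sequence, "sequence", sequence)
    L = pwm.length
    if len(seq) < L:
        return []
    lut = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]

    span = pwm.s_max - pwm.s_min
    if span <= 0 or not np.isfinite(span):
        raise ValueError("degenerate matrix: s_max equals s_min")
    matrices = []
    if strands in ("both", "+"):
        matrices.append(("+", pwm.weights))
    if strands in ("both", "-"):
        matrices.append(("-", pwm.weights[::-1, ::-1]))
    if not matrices:
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")

    dist = _score_distribution(pwm, granularity) if with_pvalues else None
    hits: list[MotifHit] = []
    n_skipped = 0
    for strand, weights in matrices:
        scores = _strand_scores(weights, codes)
        if strand == "+":  # count N-containing windows once
            n_skipped = int(np.isnan(scores).sum())
        rel = (scores - pwm.s_min) / span
        for i in np.flatnonzero(rel >= threshold - 1e-12):
            window = seq[i : i + L]
            if strand == "-":
                window = reverse_complement(window)
            s = float(scores[i])
            hits.append(
                MotifHit(
                    contig=name,
                    start=int(i),
                    strand=strand,
                    window=window,
                    score=s,
                    relative_score=float(min(max(rel[i], 0.0), 1.0)),
                    p_value=dist.pvalue(s) if dist is not None else None,
                )
            )
    if n_skipped:
        logger.info("scan %s: skipped %d windows containing N", name, n_skipped)
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


class _ScoreDistribution:
    """Discretized null distribution of window scores under the background."""

    def __init__(self, pwm: PositionWeightMatrix, granularity: float):
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        if not np.isfinite(pwm.weights).all():
            raise ValueError("p-values require finite weights (pseudocount > 0)")
        self.granularity = granularity
        self.s_min = pwm.s_min
        # subdividing the bin by L keeps the accumulated per-column rounding
        # within half a granularity step over the whole window
        self._bin = granularity / pwm.length
        col_min = pwm.weights.min(axis=1)
        offsets = np.rint((pwm.weights - col_min[:, None]) / self._bin).astype(int)
        pmf = np.ones(1)
        for j in range(pwm.length):
            nxt = np.zeros(pmf.size + offsets[j].max())
            for b in range(4):
                o = offsets[j, b]
                nxt[o : o + pmf.size] += pwm.background[b] * pmf
            pmf = nxt
        # tail[k] = P(K >= k) on the discretized grid
        self.tail = np.cumsum(pmf[::-1])[::-1]

    def pvalue(self, s: float) -> float:
        k = int(round((s - self.s_min) / self._bin))
        k = min(max(k, 0), self.tail.size - 1)
        return float(self.tail[k])


def _score_distribution(pwm: PositionWeightMatrix, granularity: float | None) -> _ScoreDistribution:
    if granularity is None:
        granularity = DEFAULT_GRANULARITY_FRACTION * (pwm.s_max - pwm.s_min)
    key = round(granularity, 15)
    if key not in pwm._pvalue_cache:
        pwm._pvalue_cache[key] = _ScoreDistribution(pwm, granularity)
    return pwm._pvalue_cache[key]


def score_pvalue(pwm: PositionWeightMatrix, s: float, granularity: float | None = None) -> float:
    """P(window score >= s) under the background model, by DP convolution of
    the per-column score distributions discretized to ``granularity``
    (default: 1e-3 of the score range).  Monotone non-increasing in s and
    exact up to the discretization."""
    return _score_distribution(pwm, granularity).pvalue(s)
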
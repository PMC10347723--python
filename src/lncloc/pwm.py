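"""Position weight matrices: parsing, score thresholds, scanning.

Motif hits are called on log-odds scores against an i.i.d. background.  The
score threshold for a target p-value is computed by exact dynamic programming
over a discretized score distribution (bin width <= 0.01 log-odds units), the
standard approach for PWM p-values.  Hits from all of a protein's PWMs are
pooled and merged (interval union with a 1-bp gap tolerance), and the merged
interval count is the protein's feature value on a tile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmers import encode_sequence

__all__ = [
    "PWM",
    "parse_jaspar",
    "parse_meme",
    "pwm_threshold",
    "scan_hits",
    "merge_intervals",
    "scan_and_merge",
]

_UNIFORM = np.full(4, 0.25)

#: log-odds discretization used by both the threshold DP and the scanner,
#: so "score >= threshold" means exactly the same event in both
SCORE_BIN = 0.005


@dataclass
class PWM:
    """A position-probability matrix with background and pseudocount.

    ``matrix`` is positions x 4 (A, C, G, T) base probabilities; rows are
    renormalized to sum to 1 after adding the pseudocount.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: _UNIFORM.copy())
    pseudocount: float = 0.001

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4")
        m = m + self.pseudocount
        self.matrix = m / m.sum(axis=1, keepdims=True)
        bg = np.asarray(self.background, dtype=float)
        self.background = bg / bg.sum()

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    @property
    def log_odds_quantized(self) -> np.ndarray:
        """Log-odds snapped to the shared SCORE_BIN grid."""
        return np.round(self.log_odds / SCORE_BIN) * SCORE_BIN

    def score(self, seq: str) -> float:
        """Log-odds score (on the shared grid) of a motif-length sequence."""
        codes = encode_sequence(seq)
        if len(codes) != len(self) or (codes < 0).any():
            raise ValueError("sequence must be ACGT of motif length")
        return float(self.log_odds_quantized[np.arange(len(self)), codes].sum())


def parse_jaspar(text: str) -> list[PWM]:
    """Parse JASPAR-style PFM text (counts or probabilities).

    Format: a ``>name`` header, then four lines ``A [ ... ]`` etc. (brackets
    optional).
    """
    pwms: list[PWM] = []
    name = None
    rows: dict[str, list[float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None and rows:
                pwms.append(_pwm_from_rows(name, rows))
            name = line[1:].split()[0]
            rows = {}
        else:
            parts = line.replace("[", " ").replace("]", " ").split()
            if parts and parts[0].upper() in "ACGT":
                rows[parts[0].upper()] = [float(x) for x in parts[1:]]
    if name is not None and rows:
        pwms.append(_pwm_from_rows(name, rows))
    return pwms


def _pwm_from_rows(name: str, rows: dict[str, list[float]]) -> PWM:
    mat = np.array([rows[b] for b in "ACGT"], dtype=float).T
    sums = mat.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return PWM(name, mat / sums)


def parse_meme(text: str) -> list[PWM]:
    """Parse MEME minimal motif format."""
    pwms: list[PWM] = []
    lines = text.splitlines()
    bg = _UNIFORM.copy()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            freq = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            bg = np.array([freq.get(b, 0.25) for b in "ACGT"])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            rows = []
            i += 1
            while i < len(lines):
                s = lines[i].strip()
                if s.startswith("letter-probability"):
                    i += 1
                    continue
                parts = s.split()
                if len(parts) == 4 and all(_is_float(p) for p in parts):
                    rows.append([float(p) for p in parts])
                    i += 1
                else:
                    break
            pwms.append(PWM(name, np.array(rows), background=bg.copy()))
            continue
        i += 1
    return pwms


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def pwm_threshold(pwm: PWM, pval: float = 1e-4, bin_width: float = SCORE_BIN) -> float:
    """Smallest log-odds score s* with P(score >= s* | background) <= pval.

    Exact DP: scores are discretized on a grid of width ``bin_width``
    (<= 0.01 log-odds units) and the distribution of the total score under
    the i.i.d. background is accumulated position by position.
    """
    if not 0 < pval < 1:
        raise ValueError("pval must be in (0, 1)")
    lo = pwm.log_odds
    L = len(pwm)
    q = np.round(lo / bin_width).astype(np.int64)  # same grid as the scanner
    offset = q.min(axis=1)
    qpos = q - offset[:, None]  # nonneg per-position integer scores
    max_total = int(qpos.max(axis=1).sum())
    dist = np.zeros(max_total + 1)
    dist[0] = 1.0
    for i in range(L):
        new = np.zeros_like(dist)
        for b in range(4):
            p = pwm.background[b]
            s = qpos[i, b]
            new[s:] += p * dist[: len(dist) - s]
        dist = new
    # survival function over the integer grid
    sf = np.cumsum(dist[::-1])[::-1]
    base = int(offset.sum())
    ok = np.nonzero(sf <= pval)[0]
    if len(ok) == 0:
        # no achievable score is rare enough: threshold just above the max
        return (max_total + base + 1) * bin_width
    return (ok[0] + base) * bin_width


def scan_hits(seq: str, pwm: PWM, threshold: float,
              both_strands: bool = True) -> list[tuple[int, int]]:
    """All motif-length windows scoring >= threshold, as [start, end) intervals.

    Windows containing non-ACGT characters are skipped.  With
    ``both_strands`` the reverse-complement scan is reported on forward
    coordinates.
    """
    codes = encode_sequence(seq)
    L = len(pwm)
    n = len(codes)
    if n < L:
        return []
    lo = pwm.log_odds_quantized
    hits = _strand_hits(codes, lo, threshold)
    if both_strands:
        # scanning the reverse strand == scanning forward with the
        # reverse-complemented matrix
        lo_rc = lo[::-1, ::-1]
        hits |= _strand_hits(codes, lo_rc, threshold)
    return [(int(s), int(s) + L) for s in sorted(hits)]


def _strand_hits(codes: np.ndarray, log_odds: np.ndarray, threshold: float) -> set:
    L = log_odds.shape[0]
    n = len(codes)
    valid = codes >= 0
    c = np.where(valid, codes, 0)
    score = np.zeros(n - L + 1)
    win_valid = np.ones(n - L + 1, dtype=bool)
    for j in range(L):
        score += log_odds[j, c[j : n - L + 1 + j]]
        win_valid &= valid[j : n - L + 1 + j]
    return set(np.nonzero(win_valid & (score >= threshold - 1e-9))[0].tolist())


def merge_intervals(intervals: list[tuple[int, int]], gap: int = 1) -> list[tuple[int, int]]:
    """Union of intervals, merging pairs overlapping or separated by <= gap."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def scan_and_merge(seq: str, pwms: list[PWM], thresholds: dict[str, float] | None = None,
                   pval: float = 1e-4, merge_gap: int = 1,
                   both_strands: bool = True) -> int:
    """Merged motif-hit count for one protein on one sequence.

    Hits passing each PWM's threshold are pooled across the protein's PWMs,
    merged with ``merge_gap`` tolerance, and counted.  The result does not
    depend on the order PWMs are pooled.
    """
    if not pwms:
        return 0
    all_hits: list[tuple[int, int]] = []
    for pwm in pwms:
        thr = thresholds[pwm.name] if thresholds else pwm_threshold(pwm, pval)
        all_hits.extend(scan_hits(seq, pwm, thr, both_strands=both_strands))
    return len(merge_intervals(all_hits, gap=merge_gap))
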
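"""Triplex formation potential between a lncRNA and a DNA tile.

A purine-motif search in the spirit of dedicated triplex scanners: RNA
triplex-forming oligos (TFOs) are purine-rich windows, DNA triplex target
sites (TTSs) are purine tracts on either strand, and a TFO binds a TTS via
Hoogsteen pairing (A.AT, G.GC), i.e. the TFO purine sequence must match the
TTS purine-strand sequence.  The built-in scorer is a deliberate
simplification with explicit parameters (window >= 15 nt, >= 90 % A/G,
<= 1 mismatch per 15 nt); an external provider can supply precomputed
per-(lncRNA, tile) quartets instead.

The per-pair summary quartet is (number of TFO-TTS pairs, total matched
length, max per-pair score, fraction of the tile covered by matched TTSs).
"""

from __future__ import annotations

import warnings

import numpy as np

from .kmers import encode_sequence
from .pwm import merge_intervals

__all__ = ["TriplexQuartet", "purine_windows", "triplex_quartet",
           "BuiltinTriplexScorer", "ExternalTriplexProvider"]

TriplexQuartet = tuple[float, float, float, float]

MIN_LEN = 15
MIN_PURITY = 0.9


def purine_windows(seq: str, min_len: int = MIN_LEN,
                   min_purity: float = MIN_PURITY,
                   strand: str = "+") -> list[tuple[int, int]]:
    """Maximal purine-rich regions as [start, end) intervals on `seq`.

    A region is the union of length-``min_len`` windows whose purine (A/G)
    fraction is >= ``min_purity``.  ``strand='-'`` searches pyrimidine tracts
    (purine tracts on the complementary strand), still reported in forward
    coordinates.
    """
    codes = encode_sequence(seq)
    if strand == "+":
        is_pur = (codes == 0) | (codes == 2)  # A or G
    else:
        is_pur = (codes == 1) | (codes == 3)  # C or T (purine on other strand)
    n = len(codes)
    if n < min_len:
        return []
    need = int(np.ceil(min_purity * min_len))
    counts = np.convolve(is_pur.astype(np.int64), np.ones(min_len, dtype=np.int64), "valid")
    starts = np.nonzero(counts >= need)[0]
    return merge_intervals([(int(s), int(s) + min_len) for s in starts], gap=0)


def _purine_string(seq: str, start: int, end: int, strand: str) -> str:
    """Purine-strand sequence of a TTS region (A/G alphabet up to mismatches)."""
    sub = seq[start:end]
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        sub = sub.translate(comp)[::-1]
    return sub


def _best_match(tfo: str, tts: str, min_len: int = MIN_LEN) -> int:
    """Length of the best Hoogsteen match between a TFO and a TTS.

    Slides the TFO along the TTS (both as purine-strand strings); at each
    offset finds the longest stretch with at most 1 mismatch per 15 nt.
    Returns 0 if no stretch of length >= min_len qualifies.
    """
    best = 0
    la, lb = len(tfo), len(tts)
    for off in range(-(la - min_len), lb - min_len + 1):
        a0 = max(0, -off)
        b0 = max(0, off)
        ln = min(la - a0, lb - b0)
        if ln < min_len:
            continue
        eq = np.frombuffer(tfo[a0:a0 + ln].encode(), dtype=np.uint8) == \
            np.frombuffer(tts[b0:b0 + ln].encode(), dtype=np.uint8)
        best = max(best, _longest_tolerant_run(eq, min_len))
    return best


def _longest_tolerant_run(eq: np.ndarray, min_len: int) -> int:
    """Longest window of `eq` with mismatches <= floor(len/15)."""
    n = len(eq)
    mis = np.concatenate([[0], np.cumsum(~eq)])
    best = 0
    lo = 0
    for hi in range(min_len, n + 1):
        while mis[hi] - mis[lo] > (hi - lo) // MIN_LEN:
            lo += 1
        if hi - lo >= min_len:
            best = max(best, hi - lo)
    return best


def triplex_quartet(lncrna_seq: str, tile_seq: str,
                    min_len: int = MIN_LEN, min_purity: float = MIN_PURITY) -> TriplexQuartet:
    """Built-in triplex potential summary for one (lncRNA, tile) pair."""
    return BuiltinTriplexScorer(lncrna_seq, min_len, min_purity)(tile_seq)


class BuiltinTriplexScorer:
    """Quartet scorer with the lncRNA's TFO windows precomputed once."""

    def __init__(self, lncrna_seq: str, min_len: int = MIN_LEN,
                 min_purity: float = MIN_PURITY):
        self.min_len = min_len
        self.min_purity = min_purity
        self._tfos = [lncrna_seq[s:e]
                      for s, e in purine_windows(lncrna_seq, min_len, min_purity, "+")]

    def __call__(self, tile_seq: str) -> TriplexQuartet:
        if not self._tfos:
            return (0.0, 0.0, 0.0, 0.0)
        tts_all = [(iv, "+") for iv in purine_windows(tile_seq, self.min_len, self.min_purity, "+")] + \
                  [(iv, "-") for iv in purine_windows(tile_seq, self.min_len, self.min_purity, "-")]
        n_pairs = 0
        total_len = 0
        max_score = 0
        covered: list[tuple[int, int]] = []
        for (ts, te), strand in tts_all:
            tts_str = _purine_string(tile_seq, ts, te, strand)
            hit = False
            for tfo in self._tfos:
                score = _best_match(tfo, tts_str, self.min_len)
                if score >= self.min_len:
                    n_pairs += 1
                    total_len += score
                    max_score = max(max_score, score)
                    hit = True
            if hit:
                covered.append((ts, te))
        cov = sum(e - s for s, e in merge_intervals(covered, gap=0)) / max(len(tile_seq), 1)
        return (float(n_pairs), float(total_len), float(max_score), float(cov))


class ExternalTriplexProvider:
    """Precomputed per-(lncRNA, tile) quartets, e.g. from a dedicated scanner.

    ``table`` maps (lncrna_name, tile_id) -> 4 values.  Missing pairs yield
    zeros with a warning, so partial tables degrade gracefully.
    """

    def __init__(self, table: dict[tuple[str, int], TriplexQuartet]):
        self.table = {k: tuple(float(x) for x in v) for k, v in table.items()}

    def __call__(self, lncrna_name: str, tile_id: int) -> TriplexQuartet:
        key = (lncrna_name, tile_id)
        if key not in self.table:
            warnings.warn(f"no triplex entry for {key}; zeros")
            return (0.0, 0.0, 0.0, 0.0)
        return self.table[key]
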
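"""Heptad-repeat coiled-coil prediction and multi-source consensus tiers.

A COILS-style sliding-window predictor: each 28-residue window is scored
for all seven heptad registers as the geometric mean of bundled
position-specific residue propensities (hydrophobics favored at the a/d
core positions, charged residues at e/g); a residue's score is the best
over windows covering it, and scores convert to probabilities through a
two-Gaussian (coil vs background) likelihood ratio with bundled
parameters.  Segments from multiple predictors (the built-in one plus
imported external tables) combine into strong/moderate/weak confidence
tiers, echoing multi-tool consensus annotation practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, pi, sqrt

import numpy as np

from coconut_census.templates import AMINO_ACIDS

WINDOW = 28
P_MIN = 0.5
MIN_LEN = 21  # three heptads

# Bundled heptad propensity table, positions a-g.  Values are relative
# frequencies (coiled-coil vs globular background) in the lineage of the
# classic sliding-window predictors: branched/aliphatic hydrophobics are
# strongly favored at a and d, charged and amide residues at e and g,
# proline is near-prohibitive everywhere, glycine unfavorable.
_PROPENSITIES: dict[str, tuple[float, ...]] = {
    #        a     b     c     d     e     f     g
    "A": (1.60, 1.30, 1.30, 1.40, 1.00, 1.00, 1.00),
    "C": (0.70, 0.60, 0.60, 0.70, 0.50, 0.50, 0.50),
    "D": (0.40, 1.00, 1.10, 0.40, 1.20, 1.00, 0.90),
    "E": (0.60, 1.30, 1.40, 0.60, 2.50, 1.10, 1.90),
    "F": (1.20, 0.60, 0.60, 1.00, 0.50, 0.60, 0.50),
    "G": (0.30, 0.60, 0.60, 0.30, 0.50, 0.70, 0.50),
    "H": (0.60, 0.80, 0.80, 0.60, 0.80, 0.80, 0.80),
    "I": (2.50, 0.80, 0.80, 1.50, 0.60, 0.70, 0.60),
    "K": (0.70, 1.20, 1.30, 0.70, 2.20, 1.10, 2.20),
    "L": (3.20, 0.90, 0.90, 3.00, 0.70, 0.80, 0.70),
    "M": (2.00, 0.90, 0.90, 1.50, 0.70, 0.80, 0.70),
    "N": (0.60, 1.00, 1.00, 0.60, 1.00, 1.00, 1.00),
    "P": (0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05),
    "Q": (0.80, 1.20, 1.30, 0.80, 1.80, 1.10, 1.60),
    "R": (0.70, 1.10, 1.20, 0.70, 1.60, 1.00, 1.60),
    "S": (0.70, 0.90, 0.90, 0.70, 0.90, 1.00, 0.90),
    "T": (0.80, 0.90, 0.90, 0.80, 0.90, 0.90, 0.90),
    "V": (1.80, 0.80, 0.80, 1.00, 0.60, 0.70, 0.60),
    "W": (0.90, 0.60, 0.60, 0.80, 0.50, 0.60, 0.50),
    "Y": (0.90, 0.70, 0.70, 0.80, 0.60, 0.60, 0.60),
}

_LOG_PROP = np.full((20, 7), log(0.5))
for _aa, _row in _PROPENSITIES.items():
    _LOG_PROP[AMINO_ACIDS.index(_aa)] = np.log(_row)

# Two-Gaussian conversion of window scores to probabilities: parameters of
# the coiled-coil and background score distributions, with a 30% prior on
# coil.  Bundled calibration constants of the predictor (see docs); scores
# below the background mean clamp to probability 0 so the left tail cannot
# flip to the wider coil Gaussian.
GAUSS_CC = (1.75, 0.15)
GAUSS_BG = (1.05, 0.06)
PRIOR_CC = 0.30


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * sqrt(2 * pi))


@dataclass
class CoilSegment:
    gene_id: str
    start_aa: int  # 1-based inclusive
    end_aa: int
    max_probability: float
    register: int  # heptad phase 0-6 at the maximum
    tier: str | None = None


def _scan(seq: str, window: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(seq)
    if n < window:
        return np.zeros(0), np.zeros(0, dtype=np.int64)
    codes = np.fromiter(
        (AMINO_ACIDS.index(ch) if ch in AMINO_ACIDS else 0 for ch in seq),
        dtype=np.int64, count=n,
    )
    positions = np.arange(n)
    best_score = np.full(n, -np.inf)
    best_phase = np.zeros(n, dtype=np.int64)
    kernel = np.ones(window) / window
    for phase in range(7):
        logp = _LOG_PROP[codes, (positions + phase) % 7]
        window_means = np.convolve(logp, kernel, mode="valid")  # n - window + 1
        # residue score = max over covering windows
        scores = np.full(n, -np.inf)
        sliding = np.lib.stride_tricks.sliding_window_view(
            np.pad(window_means, (window - 1, window - 1), constant_values=-np.inf),
            window,
        )
        scores = sliding.max(axis=1)[: n]
        update = scores > best_score
        best_score[update] = scores[update]
        best_phase[update] = phase
    geometric = np.exp(best_score)
    num = PRIOR_CC * _gauss(geometric, *GAUSS_CC)
    den = num + (1 - PRIOR_CC) * _gauss(geometric, *GAUSS_BG)
    prob = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    prob = np.where(geometric < GAUSS_BG[0], 0.0, prob)
    return np.clip(prob, 0.0, 1.0), best_phase


def coils_scan(seq: str, window: int = WINDOW) -> np.ndarray:
    """Per-residue coiled-coil probabilities (length == len(seq)).

    Sequences shorter than the window yield an empty array (no error).
    """
    return _scan(seq, window)[0]


def call_segments(
    probabilities: np.ndarray,
    phases: np.ndarray | None = None,
    gene_id: str = "",
    p_min: float = P_MIN,
    min_len: int = MIN_LEN,
) -> list[CoilSegment]:
    """Maximal runs with probability >= p_min and length >= min_len."""
    segments: list[CoilSegment] = []
    n = len(probabilities)
    i = 0
    while i < n:
        if probabilities[i] < p_min:
            i += 1
            continue
        j = i
        while j < n and probabilities[j] >= p_min:
            j += 1
        if j - i >= min_len:
            peak = int(np.argmax(probabilities[i:j])) + i
            segments.append(
                CoilSegment(
                    gene_id=gene_id, start_aa=i + 1, end_aa=j,
                    max_probability=float(probabilities[peak]),
                    register=int(phases[peak]) if phases is not None else 0,
                    tier=_single_source_tier(float(probabilities[peak])),
                )
            )
        i = j
    return segments


def predict_segments(seq: str, gene_id: str = "", window: int = WINDOW,
                     p_min: float = P_MIN, min_len: int = MIN_LEN) -> list[CoilSegment]:
    """Scan + segment in one call."""
    if len(seq) < window:
        return []
    prob, phases = _scan(seq, window)
    return call_segments(prob, phases, gene_id=gene_id, p_min=p_min, min_len=min_len)


def _single_source_tier(p: float) -> str:
    return "moderate" if p >= 0.9 else "weak"


def _overlap_fraction(a: CoilSegment, b: tuple[int, int]) -> float:
    lo = max(a.start_aa, b[0])
    hi = min(a.end_aa, b[1])
    if hi < lo:
        return 0.0
    shorter = min(a.end_aa - a.start_aa + 1, b[1] - b[0] + 1)
    return (hi - lo + 1) / shorter


def consensus_tier(
    builtin_segments: list[CoilSegment],
    external_calls: list[dict[str, object]] | None = None,
) -> list[CoilSegment]:
    """Assign confidence tiers by multi-source support.

    External rows need keys (gene_id, tool, start, end, probability).  Two
    calls support the same segment when they overlap at least half of the
    shorter one.  Tiers: strong = >=2 sources with max probability >= 0.9;
    moderate = one source >= 0.9 or >=2 sources >= 0.5; weak = a single
    sub-0.9 source (near the limit of detection).
    """
    external_calls = external_calls or []
    out: list[CoilSegment] = []
    for seg in builtin_segments:
        probs = [seg.max_probability]
        tools: set[str] = {"builtin"}
        for row in external_calls:
            if row["gene_id"] != seg.gene_id:
                continue
            span = (int(row["start"]), int(row["end"]))
            if _overlap_fraction(seg, span) >= 0.5:
                tools.add(str(row["tool"]))
                probs.append(float(row["probability"]))
        n_sources = len(tools)
        max_p = max(probs)
        if n_sources >= 2 and max_p >= 0.9:
            tier = "strong"
        elif max_p >= 0.9 or (n_sources >= 2 and max_p >= 0.5):
            tier = "moderate"
        else:
            tier = "weak"
        out.append(
            CoilSegment(
                gene_id=seg.gene_id, start_aa=seg.start_aa, end_aa=seg.end_aa,
                max_probability=max_p, register=seg.register, tier=tier,
            )
        )
    return out
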
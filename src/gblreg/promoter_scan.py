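"""Bipartite −35/spacer/−10 promoter scanning.

Bacterial promoters recognised by the housekeeping sigma factor consist of
two hexamer boxes (−35 and −10) separated by a variable spacer.  Following
the classic matrix-comparison approach for *Streptomyces* promoters, each box
is scored with a 13-column position weight matrix (the consensus hexamer plus
flanks) and a combined matrix for a spacer of n nucleotides is formed by
inserting n all-zero ("null") columns between the two 13-column blocks, so
the combined score is exactly the sum of the two window scores.

The 13-column matrices themselves are inputs.  Because the original class A /
class C alignment matrices are not shipped with this package, two synthetic
stand-ins are provided: consensus-derived log-odds matrices, and matrices
learned from a small set of experimentally mapped promoter hexamers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster_io import AnchoredInterval, anchored_ordinal, ordinal_to_anchored

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MATRIX_WIDTH = 13

__all__ = [
    "PromoterMatrix",
    "BipartiteModel",
    "PromoterHit",
    "score_window",
    "build_combined",
    "scan_bipartite",
    "annotate_vs_tsp",
    "consensus_matrix",
    "matrix_from_hexamers",
    "default_model",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "AmbiguousBaseError",
]


class AmbiguousBaseError(ValueError):
    """A scoring window contains a base outside A/C/G/T (score undefined)."""


@dataclass(frozen=True)
class PromoterMatrix:
    """A 13-column additive weight matrix for one promoter box.

    ``hexamer_offset`` is the 0-based column where the consensus hexamer
    begins within the 13-nt stretch (default 3: hexamer occupies columns
    3–8, roughly centred).
    """

    label: str
    weights: np.ndarray  # 4 x 13, rows A,C,G,T
    hexamer_offset: int = 3

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4, MATRIX_WIDTH):
            raise ValueError(f"matrix must be 4x{MATRIX_WIDTH}, got {w.shape}")
        if not (0 <= self.hexamer_offset <= 7):
            raise ValueError("hexamer_offset must be in [0, 7]")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class BipartiteModel:
    minus35: PromoterMatrix
    minus10: PromoterMatrix
    spacer_range: tuple[int, int] = (14, 22)  # hexamer-to-hexamer gap, inclusive
    null_value: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.spacer_range
        if hi < lo:
            raise ValueError("empty spacer range")

    def null_columns(self, hexamer_spacer: int) -> int:
        """Null columns between the 13-nt blocks for a given hexamer gap."""
        tail35 = MATRIX_WIDTH - (self.minus35.hexamer_offset + 6)
        return hexamer_spacer - tail35 - self.minus10.hexamer_offset


@dataclass
class PromoterHit:
    gene: str
    minus35_window: AnchoredInterval
    minus10_window: AnchoredInterval
    hexamer_spacer: int
    score35: float
    score10: float
    score_total: float
    tsp_offset: float | None = None

    def hexamers(self, seq: str, seq_end_anchor: int = -1) -> tuple[str, str]:
        """Extract the two hexamer strings from the scanned sequence."""
        first = anchored_ordinal(seq_end_anchor) - len(seq) + 1

        def cut(w: AnchoredInterval, off: int) -> str:
            lo, _ = w.ordinals
            i = lo - first + off
            return seq[i : i + 6]

        return cut(self.minus35_window, self._off35), cut(self.minus10_window, self._off10)

    _off35: int = 3
    _off10: int = 3


def score_window(matrix: PromoterMatrix, seq13: str) -> float:
    """Additive matrix score of one 13-nt window (deterministic)."""
    if len(seq13) != MATRIX_WIDTH:
        raise ValueError(f"window must be {MATRIX_WIDTH} nt")
    try:
        idx = [BASE_INDEX[b] for b in seq13]
    except KeyError as exc:
        raise AmbiguousBaseError(f"base {exc} in scoring window") from None
    return float(matrix.weights[idx, range(MATRIX_WIDTH)].sum())


def build_combined(model: BipartiteModel, n: int) -> np.ndarray:
    """Combined 4×(26+n) matrix: class C block, n null columns, class A block."""
    if n < 0:
        raise ValueError("null-column count must be >= 0")
    null = np.full((4, n), model.null_value)
    return np.hstack([model.minus35.weights, null, model.minus10.weights])


def _window_scores(matrix: PromoterMatrix, codes: np.ndarray) -> np.ndarray:
    """Score every 13-nt window; NaN where the window contains non-ACGT."""
    L = codes.size
    n_win = L - MATRIX_WIDTH + 1
    if n_win <= 0:
        return np.empty(0)
    idx = np.arange(n_win)[:, None] + np.arange(MATRIX_WIDTH)[None, :]
    win = codes[idx]
    valid = (win >= 0).all(axis=1)
    safe = np.where(win >= 0, win, 0)
    scores = matrix.weights[safe, np.arange(MATRIX_WIDTH)[None, :]].sum(axis=1)
    return np.where(valid, scores, np.nan)


def scan_bipartite(
    seq: str,
    model: BipartiteModel,
    gene: str = "region",
    seq_end_anchor: int = -1,
    tsp_anchored: int | None = None,
) -> list[PromoterHit]:
    """Exhaustive bipartite scan over every (position, spacer) combination.

    ``seq`` is read in the gene's orientation with its last base at anchored
    position ``seq_end_anchor`` (default −1, i.e. an upstream region ending
    just before the start codon).  Hits are ranked by total score; ties are
    broken by |tsp_offset − 10| when a TSP is supplied, else by the 3′-most
    −10 box.  Windows containing N are skipped.
    """
    seq = seq.upper()
    min_gap = max(model.spacer_range[0], -_min_gap_bound(model))
    if len(seq) < 2 * MATRIX_WIDTH + model.null_columns(min_gap):
        return []
    codes = np.array([BASE_INDEX.get(b, -1) for b in seq])
    s35 = _window_scores(model.minus35, codes)
    s10 = _window_scores(model.minus10, codes)
    first_ord = anchored_ordinal(seq_end_anchor) - len(seq) + 1
    off35, off10 = model.minus35.hexamer_offset, model.minus10.hexamer_offset
    hits: list[PromoterHit] = []
    for gap in range(model.spacer_range[0], model.spacer_range[1] + 1):
        n = model.null_columns(gap)
        if n < 0:
            continue
        shift = MATRIX_WIDTH + n  # start of −10 window relative to −35 window
        for i in range(0, len(seq) - (2 * MATRIX_WIDTH + n) + 1):
            j = i + shift
            if np.isnan(s35[i]) or np.isnan(s10[j]):
                continue
            w35 = AnchoredInterval(
                gene,
                ordinal_to_anchored(first_ord + i),
                ordinal_to_anchored(first_ord + i + MATRIX_WIDTH - 1),
            )
            w10 = AnchoredInterval(
                gene,
                ordinal_to_anchored(first_ord + j),
                ordinal_to_anchored(first_ord + j + MATRIX_WIDTH - 1),
            )
            hit = PromoterHit(
                gene=gene,
                minus35_window=w35,
                minus10_window=w10,
                hexamer_spacer=gap,
                score35=float(s35[i]),
                score10=float(s10[j]),
                score_total=float(s35[i] + s10[j]),
            )
            hit._off35, hit._off10 = off35, off10
            if tsp_anchored is not None:
                annotate_vs_tsp(hit, tsp_anchored)
            hits.append(hit)

    def sort_key(h: PromoterHit):
        if tsp_anchored is not None:
            tie = abs(h.tsp_offset - 10)
        else:
            tie = -h.minus10_window.ordinals[0]  # prefer 3'-most −10
        return (-h.score_total, tie)

    hits.sort(key=sort_key)
    return hits


def _min_gap_bound(model: BipartiteModel) -> int:
    # smallest hexamer gap with a non-negative null-column count
    return (MATRIX_WIDTH - model.minus35.hexamer_offset - 6) + model.minus10.hexamer_offset


def _minus10_center_ordinal(hit: PromoterHit) -> float:
    lo, _ = hit.minus10_window.ordinals
    return lo + hit._off10 + 2.5  # mean of the hexamer's endpoint ordinals


def annotate_vs_tsp(hit: PromoterHit, tsp_anchored: int) -> PromoterHit:
    """Set ``tsp_offset``: distance from the −10 hexamer centre to the TSP.

    Positive when the hexamer lies upstream of the TSP; the centre is the
    mean of the hexamer's two endpoint positions (half-integer for hexamers).
    """
    hit.tsp_offset = float(anchored_ordinal(tsp_anchored) - _minus10_center_ordinal(hit))
    return hit


# ---------------------------------------------------------------------------
# Stand-in matrices (the original class A / class C alignment matrices are
# not redistributable; these synthetic substitutes keep the geometry honest).

_CLASS_A_MINUS10 = "TATAAT"  # sigma-70-like −10 consensus hexamer
_CLASS_C_MINUS35 = "TTGACA"  # sigma-70-like −35 consensus hexamer

# Hexamers of the five experimentally mapped promoters of the sfb cluster
# (two TSPs for sfbR2), usable to learn a cluster-specific stand-in matrix.
SFB_PROMOTER_HEXAMERS: dict[str, list[str]] = {
    "minus10": ["TATCAT", "TAGCAT", "TTTAAT", "CAGGGT", "TTTGTT", "TATATT"],
    "minus35": ["AGTAGT", "CCGCCC", "TCCACT", "CTGTCC", "CGGAGC", "TCGCCC"],
}


def consensus_matrix(label: str, hexamer: str, hexamer_offset: int = 3, weight: float = 2.0) -> PromoterMatrix:
    """Synthetic stand-in: +weight on each consensus hexamer base, 0 elsewhere."""
    w = np.zeros((4, MATRIX_WIDTH))
    for k, b in enumerate(hexamer):
        w[BASE_INDEX[b], hexamer_offset + k] = weight
    return PromoterMatrix(label, w, hexamer_offset)


def matrix_from_hexamers(
    label: str,
    hexamers: list[str],
    hexamer_offset: int = 3,
    pseudoweight: float = 0.1,
    background: float = 0.25,
) -> PromoterMatrix:
    """Synthetic stand-in learned from aligned hexamers: log-odds vs uniform."""
    n = len(hexamers)
    w = np.zeros((4, MATRIX_WIDTH))
    counts = np.zeros((4, 6))
    for h in hexamers:
        for k, b in enumerate(h):
            counts[BASE_INDEX[b], k] += 1
    freqs = (counts + pseudoweight) / (n + 4 * pseudoweight)
    w[:, hexamer_offset : hexamer_offset + 6] = np.log2(freqs / background)
    return PromoterMatrix(label, w, hexamer_offset)


def default_model(kind: str = "consensus", spacer_range: tuple[int, int] = (14, 22)) -> BipartiteModel:
    """Bundled bipartite model: ``consensus`` or ``sfb_learned`` stand-ins."""
    if kind == "consensus":
        m35 = consensus_matrix("classC_minus35", _CLASS_C_MINUS35)
        m10 = consensus_matrix("classA_minus10", _CLASS_A_MINUS10)
    elif kind == "sfb_learned":
        m35 = matrix_from_hexamers("classC_minus35", SFB_PROMOTER_HEXAMERS["minus35"])
        m10 = matrix_from_hexamers("classA_minus10", SFB_PROMOTER_HEXAMERS["minus10"])
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return BipartiteModel(m35, m10, spacer_range)


def read_matrix_tsv(path: str | Path, label: str = "", hexamer_offset: int = 3) -> PromoterMatrix:
    """Matrix TSV: header = column index 1..13; four rows labeled A,C,G,T."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.loc[list(BASES)]
    return PromoterMatrix(label or Path(path).stem, df.to_numpy(float), hexamer_offset)


def write_matrix_tsv(matrix: PromoterMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.weights, index=list(BASES), columns=range(1, MATRIX_WIDTH + 1))
    df.to_csv(path, sep="\t")
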
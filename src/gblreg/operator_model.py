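"""DNase-I footprint interval algebra and operator information models.

GBL receptors and pseudo-receptors protect short, roughly palindromic
operators (ARE boxes) on both strands of their target promoters.  This
module provides (i) the coordinate algebra used to summarise footprinting
results — protection lengths, the displacement between the two strands'
protected regions, and their overlap — and (ii) an information-theoretic
model of the operator built from the protected sequences: per-position
entropy and information, the total information content R_sequence, an IUPAC
consensus, a dyad-symmetry score, and an individual-information (Ri) scanner
for locating candidate operator sites elsewhere.

Information follows Schneider's convention: with background entropy 2 bits
per position (uniform DNA), info_l = 2 − H_l − e(n), where e(n) is the
small-sample correction (the expected entropy shortfall when estimating
frequencies from n sites).  Ri of a window is Σ_l [2 + log2 f(b_l, l)] with
pseudo-frequencies so no base has probability zero; windows scoring above
0 bits are candidate sites.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster_io import AnchoredInterval, ClusterRecord, revcomp

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# IUPAC nucleotide codes as base sets
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_CODE = {frozenset(v): k for k, v in IUPAC.items()}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

__all__ = [
    "FootprintPair",
    "InfoModel",
    "AreHit",
    "interval_length",
    "strand_displacement",
    "strand_overlap",
    "extract_core_sites",
    "build_info_model",
    "small_sample_correction",
    "call_consensus",
    "dyad_symmetry",
    "ri_score",
    "scan_ri",
    "read_footprint_tsv",
    "sfb_footprints",
]


@dataclass(frozen=True)
class FootprintPair:
    """Protected regions on the two strands of one promoter."""

    promoter: str
    top: AnchoredInterval
    bottom: AnchoredInterval

    def __post_init__(self) -> None:
        if self.top.anchor_gene != self.bottom.anchor_gene:
            raise ValueError("both intervals must be anchored to the same gene")


def interval_length(interval: AnchoredInterval) -> int:
    """Inclusive length of an anchored interval."""
    lo, hi = interval.ordinals
    return hi - lo + 1


def strand_displacement(pair: FootprintPair) -> tuple[int, int, set[int]]:
    """Edge displacement between the two strands' protected regions.

    Returns (upstream_edge_offset, downstream_edge_offset, summary), where
    the edge offsets are absolute differences of corresponding interval edges
    in genomic order and the summary is the set of distinct nonzero offsets
    ({0} when the regions coincide exactly).
    """
    t_lo, t_hi = pair.top.ordinals
    b_lo, b_hi = pair.bottom.ordinals
    up, down = abs(t_lo - b_lo), abs(t_hi - b_hi)
    summary = {d for d in (up, down) if d != 0} or {0}
    return up, down, summary


def strand_overlap(pair: FootprintPair) -> int:
    """Inclusive length of the intersection of the two protected regions."""
    t_lo, t_hi = pair.top.ordinals
    b_lo, b_hi = pair.bottom.ordinals
    return max(0, min(t_hi, b_hi) - max(t_lo, b_lo) + 1)


# ---------------------------------------------------------------------------
# Information model


@dataclass
class InfoModel:
    n_sites: int
    width: int
    counts: np.ndarray          # 4 x width
    freqs: np.ndarray           # 4 x width, columns sum to 1
    H: np.ndarray               # per-position entropy, bits
    e_n: float                  # small-sample correction per position, bits
    info: np.ndarray            # 2 − H − e_n
    R_sequence: float
    consensus: str
    dyad_score: float
    sites: list[str] = field(default_factory=list)

    def ri_frequencies(self) -> np.ndarray:
        """Pseudo-frequency-smoothed f for Ri scoring: (count + ½)/(n + 2)."""
        return (self.counts + 0.5) / (self.n_sites + 2.0)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "n_sites": self.n_sites,
            "width": self.width,
            "counts": self.counts.astype(int).tolist(),
            "freqs": self.freqs.tolist(),
            "info": self.info.tolist(),
            "R_sequence": self.R_sequence,
            "consensus": self.consensus,
            "dyad_score": self.dyad_score,
            "sites": self.sites,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    def logo_matrix(self) -> pd.DataFrame:
        """Per-base information (freq × column info), the usual logo input."""
        return pd.DataFrame(
            (self.freqs * np.maximum(self.info, 0.0)).T, columns=list(BASES)
        )


def small_sample_correction(n: int, alphabet_size: int = 4) -> float:
    """Expected entropy shortfall e(n) when estimating from n uniform draws.

    Computed exactly by enumerating base-count compositions of n under the
    uniform multinomial; approaches (alphabet_size−1)/(2·ln2·n) for large n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    log_n_fact = math.lgamma(n + 1)
    e_h = 0.0
    for comp in itertools.combinations_with_replacement(range(alphabet_size), n):
        counts = np.bincount(comp, minlength=alphabet_size)
        # multinomial probability of this count vector under uniform p
        log_p = log_n_fact - sum(math.lgamma(c + 1) for c in counts) - n * math.log(alphabet_size)
        f = counts / n
        h = -sum(fi * math.log2(fi) for fi in f if fi > 0)
        e_h += math.exp(log_p) * h
    return math.log2(alphabet_size) - e_h


def _count_sites(sites: list[str]) -> np.ndarray:
    width = len(sites[0])
    counts = np.zeros((4, width))
    for s in sites:
        if len(s) != width:
            raise ValueError("sites must all have equal width")
        for k, b in enumerate(s.upper()):
            if b not in BASE_INDEX:
                raise ValueError(f"non-ACGT base {b!r} in site")
            counts[BASE_INDEX[b], k] += 1
    return counts


def build_info_model(
    sites: list[str],
    correction: bool = False,
    consensus_min_freq: float = 0.10,
) -> InfoModel:
    """Aligned operator sites → counts, entropies, information, consensus.

    With ``correction`` the Schneider small-sample term e(n) is subtracted
    from every column's information (off by default).
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    counts = _count_sites(sites)
    n = len(sites)
    width = counts.shape[1]
    freqs = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    H = -terms.sum(axis=0)
    e_n = small_sample_correction(n) if correction else 0.0
    info = 2.0 - H - e_n
    consensus = _consensus_from_freqs(freqs, consensus_min_freq)
    return InfoModel(
        n_sites=n,
        width=width,
        counts=counts,
        freqs=freqs,
        H=H,
        e_n=e_n,
        info=info,
        R_sequence=float(info.sum()),
        consensus=consensus,
        dyad_score=dyad_symmetry(consensus),
        sites=[s.upper() for s in sites],
    )


def _consensus_from_freqs(freqs: np.ndarray, min_freq: float) -> str:
    out = []
    for col in freqs.T:
        included = frozenset(b for b, f in zip(BASES, col) if f >= min_freq)
        if not included:  # degenerate guard: take the single most frequent base
            included = frozenset(BASES[int(np.argmax(col))])
        out.append(_SET_TO_CODE[included])
    return "".join(out)


def call_consensus(model: InfoModel, min_freq: float = 0.10) -> str:
    """Minimal IUPAC code per column covering all bases with freq ≥ min_freq."""
    if not (0 < min_freq < 1):
        raise ValueError("min_freq must be in (0, 1)")
    return _consensus_from_freqs(model.freqs, min_freq)


def dyad_symmetry(consensus: str) -> float:
    """Fraction of positions matching the reverse complement of the consensus.

    Position l agrees when its IUPAC base set equals the complemented base
    set at the mirrored position; perfect palindromes score 1.0.
    """
    w = len(consensus)
    sets = []
    for c in consensus.upper():
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {c!r}")
        sets.append(frozenset(IUPAC[c]))
    matches = 0
    for l in range(w):
        mirrored = frozenset(_COMPLEMENT[b] for b in sets[w - 1 - l])
        if sets[l] == mirrored:
            matches += 1
    return matches / w


# ---------------------------------------------------------------------------
# Individual information (Ri) scanning


@dataclass(frozen=True)
class AreHit:
    """A candidate operator site: position of the window and its Ri in bits."""

    start: int  # 1-based within the scanned sequence, top-strand coordinates
    end: int
    strand: str  # "top" or "bottom"
    ri: float
    site: str


def ri_score(window: str, model: InfoModel) -> float:
    """Individual information of one window: Σ_l [2 + log2 f'(b_l, l)] bits."""
    if len(window) != model.width:
        raise ValueError("window width must equal model width")
    f = model.ri_frequencies()
    total = 0.0
    for l, b in enumerate(window.upper()):
        if b not in BASE_INDEX:
            return float("-inf")  # N and friends can never form a site
        total += 2.0 + math.log2(f[BASE_INDEX[b], l])
    return total


def scan_ri(seq: str, model: InfoModel, threshold: float = 0.0) -> list[AreHit]:
    """Scan both strands for windows with Ri ≥ threshold, sorted descending.

    Positive Ri marks candidate binding sites (Schneider convention).  The
    scan is an exhaustive window enumeration; N-containing windows never hit.
    """
    seq = seq.upper()
    w = model.width
    f = model.ri_frequencies()
    logf = np.log2(f) + 2.0
    hits: list[AreHit] = []
    for strand, s in (("top", seq), ("bottom", revcomp(seq))):
        codes = np.array([BASE_INDEX.get(b, -1) for b in s])
        L = codes.size
        if L < w:
            continue
        idx = np.arange(L - w + 1)[:, None] + np.arange(w)[None, :]
        win = codes[idx]
        valid = (win >= 0).all(axis=1)
        safe = np.where(win >= 0, win, 0)
        scores = logf[safe, np.arange(w)[None, :]].sum(axis=1)
        for i in np.nonzero(valid & (scores >= threshold))[0]:
            if strand == "top":
                start, end = int(i) + 1, int(i) + w
            else:  # report in top-strand coordinates
                start, end = L - w - int(i) + 1, L - int(i)
            hits.append(AreHit(start, end, strand, float(scores[i]), s[i : i + w]))
    hits.sort(key=lambda h: (-h.ri, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Core-site extraction from footprints


def extract_core_sites(
    record: ClusterRecord,
    footprints: list[FootprintPair],
    width: int = 18,
    max_rounds: int = 50,
) -> list[str]:
    """Extract one aligned width-nt core site per strand of each footprint.

    Protected regions are longer than the operator core, so the core window
    within each protection is chosen by an align-and-refine loop: start at
    the protection centre, build a frequency model from the current windows,
    re-place each window to maximise its Ri, and iterate to a fixpoint.
    Returns 2 × len(footprints) site strings of equal width.
    """
    region_seqs: list[str] = []
    names: list[str] = []
    for pair in footprints:
        for strand, iv in (("top", pair.top), ("bottom", pair.bottom)):
            if interval_length(iv) < width:
                raise ValueError(
                    f"{pair.promoter}: width {width} exceeds protection length "
                    f"{interval_length(iv)} on {strand} strand"
                )
            region_seqs.append(iv.sequence(record))
            names.append(f"{pair.promoter}/{strand}")
    # initialise at the centre of each protection
    offsets = [(len(s) - width) // 2 for s in region_seqs]
    for _ in range(max_rounds):
        sites = [s[o : o + width] for s, o in zip(region_seqs, offsets)]
        model = build_info_model(sites)
        new_offsets = []
        for s in region_seqs:
            cands = [(ri_score(s[o : o + width], model), -o) for o in range(len(s) - width + 1)]
            best = max(cands)
            new_offsets.append(-best[1])
        if new_offsets == offsets:
            break
        offsets = new_offsets
    return [s[o : o + width] for s, o in zip(region_seqs, offsets)]


# ---------------------------------------------------------------------------
# Footprint tables


def read_footprint_tsv(path: str | Path) -> list[FootprintPair]:
    """Footprint TSV: promoter, strand (top/bottom), from, to — anchored."""
    df = pd.read_csv(path, sep="\t", comment="#")
    pairs = []
    for promoter, grp in df.groupby("promoter", sort=False):
        ivs = {}
        for _, row in grp.iterrows():
            ivs[row["strand"]] = AnchoredInterval(
                anchor_gene=row.get("gene", promoter.rstrip("p")),
                from_pos=int(row["from"]),
                to_pos=int(row["to"]),
                strand_of_read=row["strand"],
            )
        if set(ivs) != {"top", "bottom"}:
            raise ValueError(f"{promoter}: need exactly one top and one bottom interval")
        pairs.append(FootprintPair(promoter, ivs["top"], ivs["bottom"]))
    return pairs


def sfb_footprints() -> list[FootprintPair]:
    """The ten experimentally mapped protected regions of the sfb cluster."""
    return read_footprint_tsv(Path(__file__).parent / "data" / "footprints_sfb.tsv")
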
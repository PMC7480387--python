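"""Receptor vs pseudo-receptor classification of TetR-family regulators.

Genuine GBL receptors tend to have slightly acidic-to-neutral isoelectric
points, while pseudo-receptors (which recognise the same operators but bind
other ligands) tend to be basic.  Classification here combines a computed pI
with the protein's clade in a bootstrapped neighbor-joining tree built from
a supplied multiple alignment; proteins whose pI label disagrees with their
clade are flagged as discordant (the "atypical" cases).

The pI solver finds the pH where the Henderson–Hasselbalch net charge
crosses zero by bisection.  Two pKa sets ship: a Bjellqvist-style set
(ExPASy-compatible) and the EMBOSS set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# pKa sets: side chains D,E,C,Y,H,K,R plus termini.
PKA_SETS: dict[str, dict[str, float]] = {
    # Bjellqvist et al. values as used by ExPASy Compute pI
    "bjellqvist": {
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
        "H": 5.98, "K": 10.0, "R": 12.0,
        "Nterm": 7.5, "Cterm": 3.55,
    },
    "emboss": {
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
        "H": 6.5, "K": 10.8, "R": 12.5,
        "Nterm": 8.6, "Cterm": 3.6,
    },
}

NEGATIVE = ("D", "E", "C", "Y", "Cterm")
POSITIVE = ("H", "K", "R", "Nterm")

# distance corrections: observed proportion p -> evolutionary distance
DISTANCE_MODELS = ("p_distance", "poisson", "kimura_protein")
SATURATION_CAP = 10.0

__all__ = [
    "ProteinRecord",
    "DistanceMatrix",
    "net_charge",
    "isoelectric_point",
    "classify_by_pi",
    "protein_distance",
    "neighbor_joining",
    "bootstrap",
    "classify_proteins",
    "PKA_SETS",
]


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    pi: float | None = None
    clade: str = "unassigned"  # receptor / pseudo_receptor / unassigned
    concordant: bool | None = None


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("matrix must be symmetric, non-negative, zero-diagonal")
        object.__setattr__(self, "d", d)


def _composition(sequence: str) -> dict[str, int]:
    seq = sequence.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    counts = {aa: seq.count(aa) for aa in "DECYHKR"}
    counts["Nterm"] = counts["Cterm"] = 1
    return counts


def net_charge(sequence: str, ph: float, pka_set: str | dict = "bjellqvist") -> float:
    """Henderson–Hasselbalch net charge of a peptide at a given pH."""
    pka = PKA_SETS[pka_set] if isinstance(pka_set, str) else pka_set
    counts = _composition(sequence)
    pos = sum(counts[g] / (1.0 + 10.0 ** (ph - pka[g])) for g in POSITIVE)
    neg = sum(counts[g] / (1.0 + 10.0 ** (pka[g] - ph)) for g in NEGATIVE)
    return pos - neg


def isoelectric_point(sequence: str, pka_set: str | dict = "bjellqvist") -> float:
    """pH where the net charge crosses zero, by bisection on [0, 14].

    Converges to |charge| < 1e−4; deterministic for a given pKa set.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pka_set)
        if abs(q) < 1e-4 and hi - lo < 1e-6:
            return mid
        if q > 0:
            lo = mid  # still net positive: pI is higher
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_by_pi(pi: float, threshold: float = 7.0) -> str:
    """receptor_like below the threshold, pseudo_like at or above it."""
    return "receptor_like" if pi < threshold else "pseudo_like"


# ---------------------------------------------------------------------------
# Distances


def _pairwise_p(a: str, b: str) -> float:
    """Proportion of differing sites, gap columns pairwise-deleted."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    diffs = compared = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-." or y in "-.":
            continue
        compared += 1
        diffs += x != y
    if compared == 0:
        raise ValueError("no comparable (ungapped) columns")
    return diffs / compared


def _correct(p: float, model: str) -> float:
    if model == "p_distance":
        return p
    if model == "poisson":
        arg = 1.0 - p
    elif model == "kimura_protein":
        arg = 1.0 - p - p * p / 5.0
    else:
        raise ValueError(f"unknown distance model {model!r}")
    if arg <= 0:
        warnings.warn(f"saturated distance (p={p:.3f}); capped at {SATURATION_CAP}")
        return SATURATION_CAP
    return -np.log(arg)


def protein_distance(alignment: dict[str, str], model: str = "kimura_protein") -> DistanceMatrix:
    """Pairwise corrected distances from an aligned sequence dict."""
    ids = tuple(alignment)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _pairwise_p(alignment[ids[i]], alignment[ids[j]])
            d[i, j] = d[j, i] = _correct(p, model)
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; returns an unrooted tree (trifurcating root).

    Ties in the Q criterion are broken by the lowest (i, j) pair in current
    matrix order, making the agglomeration fully deterministic.  On additive
    matrices the generating topology and branch lengths are recovered.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=i) for i in dm.ids]
    d = dm.d.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, None)
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best[0] - 1e-12:
                    best = (q[a, b], (a, b))
        a, b = best[1]
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = max(li, 0.0), max(lj, 0.0)
        parent.extend([ni, nj])
        # distances from the new node to all others
        new_row = np.zeros(d.shape[0] + 1)
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]
    # join the last three nodes at a trifurcating root (closed-form lengths)
    i, j, k = active
    root = TreeNode()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = max(ln, 0.0)
        root.append(node)
    return root


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, as the smaller-name side."""
    leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            other = leaves - side
            parts.add(min(side, other, key=sorted))
    return parts


def bootstrap(
    alignment: dict[str, str],
    reps: int = 1000,
    seed: int = 0,
    model: str = "kimura_protein",
) -> TreeNode:
    """NJ tree with bootstrap supports (percent of replicates per bipartition).

    Alignment columns are resampled i.i.d. with replacement; each replicate
    tree's bipartitions are tallied against those of the original tree.
    Supports are written as internal node names; reproducible per seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ids = list(alignment)
    cols = np.array([list(alignment[i]) for i in ids])  # taxa x sites
    length = cols.shape[1]
    tree = neighbor_joining(protein_distance(alignment, model))
    target = {}
    leaves = frozenset(ids)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            target[node] = min(side, leaves - side, key=sorted)
    counts = {node: 0 for node in target}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        idx = rng.integers(0, length, size=length)
        boot_aln = {i: "".join(row) for i, row in zip(ids, cols[:, idx])}
        rep_parts = _bipartitions(neighbor_joining(protein_distance(boot_aln, model)))
        for node, part in target.items():
            if part in rep_parts:
                counts[node] += 1
    for node, c in counts.items():
        node.name = f"{100.0 * c / reps:g}"
    return tree


# ---------------------------------------------------------------------------
# Combined classification


def classify_proteins(
    proteins: dict[str, str],
    clades: dict[str, str] | None = None,
    pka_set: str = "bjellqvist",
    pi_threshold: float = 7.0,
) -> list[ProteinRecord]:
    """Compute pI per protein and flag concordance with a clade assignment.

    ``clades`` maps protein id → "receptor"/"pseudo_receptor" (e.g. read off
    a bootstrapped tree).  A record is concordant when its pI label agrees
    with its clade; discordant records are the tree's "atypical" cases.
    """
    out = []
    for pid, seq in proteins.items():
        pi = isoelectric_point(seq, pka_set)
        clade = (clades or {}).get(pid, "unassigned")
        conc = None
        if clade in {"receptor", "pseudo_receptor"}:
            pi_label = classify_by_pi(pi, pi_threshold)
            conc = (clade == "receptor") == (pi_label == "receptor_like")
        out.append(ProteinRecord(pid, seq, pi=pi, clade=clade, concordant=conc))
    return out
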
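"""RT-qPCR relative quantification and operon calling.

Amplification efficiency E (fold amplification per cycle) is estimated from
a dilution standard curve as E = 10^(−1/slope).  Relative expression uses
the efficiency-corrected (Pfaffl) ratio

    ratio = E_target^ΔCt_target / E_ref^ΔCt_ref,   ΔCt = Ct(control) − Ct(sample)

so a ratio above 1 means higher expression in the sample than in the
control.  Significance is assessed with a randomization test that permutes
condition labels and compares |log2 ratio| of each permutation with the
observed value.  Operons are called from intergenic RT-PCR presence/absence
between adjacent same-strand genes by transitive closure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "QpcrSample",
    "CotxCall",
    "InvalidCurveError",
    "fit_standard_curve",
    "pfaffl_ratio",
    "randomization_test",
    "call_operons",
]


class InvalidCurveError(ValueError):
    """The dilution series does not describe a valid amplification curve."""


@dataclass
class StandardCurve:
    log10_quantity: list[float]
    ct: list[float]
    slope: float
    intercept: float
    r2: float
    efficiency: float
    r2_ok: bool


@dataclass(frozen=True)
class QpcrSample:
    gene: str
    condition: str  # control / treated
    ct_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct_replicates:
            raise ValueError("need at least one Ct replicate")
        if any(c <= 0 for c in self.ct_replicates):
            raise ValueError("Ct values must be positive")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_replicates))


@dataclass(frozen=True)
class CotxCall:
    gene_pair: tuple[str, str]
    amplified: bool


def fit_standard_curve(
    log10_quantity: list[float], ct: list[float], r2_min: float = 0.99
) -> StandardCurve:
    """OLS fit of Ct vs log10 template quantity; E = 10^(−1/slope).

    A perfectly doubling reaction has slope −1/log10(2) ≈ −3.32 and E = 2.
    A non-negative slope cannot arise from amplification and is an error;
    r² below ``r2_min`` only sets ``r2_ok = False`` (soft warning).
    """
    x = np.asarray(log10_quantity, float)
    y = np.asarray(ct, float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired points")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise InvalidCurveError(f"slope {fit.slope:.3f} >= 0: Ct must fall with template amount")
    r2 = float(fit.rvalue**2)
    return StandardCurve(
        log10_quantity=list(x),
        ct=list(y),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        efficiency=float(10.0 ** (-1.0 / fit.slope)),
        r2_ok=r2 >= r2_min,
    )


def pfaffl_ratio(e_target: float, dct_target: float, e_ref: float, dct_ref: float) -> float:
    """Efficiency-corrected expression ratio E_t^ΔCt_t / E_r^ΔCt_r."""
    for e in (e_target, e_ref):
        if not (1.0 <= e <= 10.0):
            raise ValueError(f"efficiency {e} outside [1, 10]")
    return float(e_target**dct_target / e_ref**dct_ref)


def _log2_ratio(tc: np.ndarray, tt: np.ndarray, rc: np.ndarray, rt: np.ndarray,
                e_t: float, e_r: float) -> float:
    dct_t = tc.mean() - tt.mean()
    dct_r = rc.mean() - rt.mean()
    return dct_t * np.log2(e_t) - dct_r * np.log2(e_r)


def randomization_test(
    target_ctrl: list[float],
    target_trt: list[float],
    ref_ctrl: list[float],
    ref_trt: list[float],
    e_target: float = 2.0,
    e_ref: float = 2.0,
    reps: int = 2000,
    seed: int = 0,
) -> float:
    """REST-style label-permutation p-value for the Pfaffl ratio.

    Condition labels are permuted independently within the target and the
    reference gene; the two-sided p-value is the fraction of permutations
    whose |log2 ratio| reaches the observed one, with the +1/(reps+1)
    correction so p is never exactly zero.  Reproducible per seed.
    """
    groups = [np.asarray(g, float) for g in (target_ctrl, target_trt, ref_ctrl, ref_trt)]
    if any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 replicates per group")
    tc, tt, rc, rt = groups
    observed = abs(_log2_ratio(tc, tt, rc, rt, e_target, e_ref))
    rng = np.random.default_rng(seed)
    t_all, r_all = np.concatenate([tc, tt]), np.concatenate([rc, rt])
    n_tc, n_rc = tc.size, rc.size

    def perm_dcts(pool: np.ndarray, n_ctrl: int) -> np.ndarray:
        mats = rng.permuted(np.tile(pool, (reps, 1)), axis=1)
        return mats[:, :n_ctrl].mean(axis=1) - mats[:, n_ctrl:].mean(axis=1)

    stats_ = np.abs(perm_dcts(t_all, n_tc) * np.log2(e_target)
                    - perm_dcts(r_all, n_rc) * np.log2(e_ref))
    hits = int(np.sum(stats_ >= observed - 1e-12))
    return (hits + 1.0) / (reps + 1.0)


def call_operons(
    gene_order: list[str],
    strands: dict[str, str],
    cotx_calls: list[CotxCall],
) -> list[list[str]]:
    """Partition a gene list into transcriptional units.

    Positive co-transcription calls between adjacent same-strand genes are
    merged transitively; opposite-strand (convergent/divergent) neighbours
    are never merged, whatever the call says; everything else is a
    singleton.  Idempotent and independent of call order.
    """
    index = {g: i for i, g in enumerate(gene_order)}
    parent = list(range(len(gene_order)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for call in sorted(cotx_calls, key=lambda c: c.gene_pair):
        a, b = call.gene_pair
        if a not in index or b not in index:
            raise ValueError(f"unknown gene in pair {call.gene_pair}")
        ia, ib = sorted((index[a], index[b]))
        if ib - ia != 1:
            raise ValueError(f"co-transcription call for non-adjacent pair {call.gene_pair}")
        if strands[a] != strands[b]:
            continue  # convergent/divergent neighbours can never share a transcript
        if call.amplified:
            parent[find(ia)] = find(ib)
    units: dict[int, list[str]] = {}
    for g in gene_order:
        units.setdefault(find(index[g]), []).append(g)
    return [units[k] for k in sorted(units, key=lambda k: index[units[k][0]])]
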
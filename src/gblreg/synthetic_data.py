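"""Synthetic data generators with machine-readable truth.

Every analysis stage in this package can be exercised without any external
download: these generators produce (i) gene clusters with implanted
−35/spacer/−10 promoters, PFM-sampled operator (ARE) sites and TTA codons,
(ii) qPCR dilution series and Ct tables following the exponential
amplification model Ct = intercept − log_E(quantity) with configurable true
efficiencies and fold changes, and (iii) protein families evolved by i.i.d.
substitutions along a given tree.  Each generator is a pure function of its
configuration (the seed included) and returns a truth table recording what
was implanted where.

Background DNA is i.i.d. with a default GC content of 0.72, emulating the
strongly GC-skewed composition of *Streptomyces* genomes so that log-odds
scanners are exercised off the uniform background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skbio import TreeNode

from .cluster_io import ClusterRecord, CdsFeature

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
STOPS = {"TAA", "TAG", "TGA"}

SCHEMA = "gblreg-truth-1"

__all__ = [
    "SimConfig",
    "TruthTable",
    "Implant",
    "generate_cluster",
    "generate_qpcr",
    "generate_protein_family",
    "random_sequence",
    "sample_pfm_site",
    "pfm_from_consensus",
]


@dataclass(frozen=True)
class Implant:
    kind: str  # promoter / are_site / tta_codon
    gene: str
    anchored_pos: int  # 5'-most anchored position of the implant (upstream < 0)
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class SimConfig:
    seed: int
    cluster_length: int = 12000
    n_genes: int = 9
    gc_content: float = 0.72
    gene_length: int = 600  # nt per synthetic CDS (multiple of 3)
    gene_spacing: int = 600  # intergenic room ahead of each gene
    implants: list[Implant] = field(default_factory=list)
    # qPCR block
    true_efficiency: dict[str, float] = field(default_factory=dict)
    true_fold_change: dict[str, float] = field(default_factory=dict)
    ct_noise_sd: float = 0.0
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    # protein-family block
    tree_newick: str = ""
    substitution_rate: float = 1.0
    protein_length: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.gc_content < 1):
            raise ValueError("gc must be in (0, 1)")
        if self.gene_length % 3:
            raise ValueError("gene_length must be a multiple of 3")


@dataclass
class TruthTable:
    schema: str = SCHEMA
    implants: list[dict] = field(default_factory=list)
    qpcr: dict[str, dict] = field(default_factory=dict)
    tree_newick: str = ""

    def of_kind(self, kind: str) -> list[dict]:
        return [r for r in self.implants if r["kind"] == kind]


def pfm_from_consensus(iupac: str, strength: float = 0.9) -> np.ndarray:
    """4×w probability matrix from an IUPAC string.

    ``strength`` is shared among the code's allowed bases; the remainder is
    spread over the other bases (an N column is uniform).
    """
    from .operator_model import IUPAC

    w = len(iupac)
    pfm = np.zeros((4, w))
    for k, c in enumerate(iupac.upper()):
        allowed = IUPAC[c]
        if len(allowed) == 4:
            pfm[:, k] = 0.25
            continue
        for b in BASES:
            pfm[BASE_INDEX[b], k] = (
                strength / len(allowed) if b in allowed else (1 - strength) / (4 - len(allowed))
            )
    return pfm


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.72) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def sample_pfm_site(rng: np.random.Generator, pfm: np.ndarray) -> str:
    """One site drawn column-wise from a 4×w probability matrix (rows ACGT)."""
    pfm = np.asarray(pfm, float)
    cols = pfm / pfm.sum(axis=0, keepdims=True)
    return "".join(BASES[rng.choice(4, p=cols[:, k])] for k in range(pfm.shape[1]))


def _random_cds(rng: np.random.Generator, length: int, gc: float, with_tta: list[int]) -> str:
    """A valid CDS: start codon, stop-free body, terminal stop; TTA at the
    requested 1-based codon indices."""
    n_codons = length // 3
    body = []
    for _ in range(n_codons - 2):
        while True:
            codon = random_sequence(rng, 3, gc)
            if codon not in STOPS:
                break
        body.append(codon)
    codons = ["ATG"] + body + ["TGA"]
    for idx in with_tta:
        if not (1 < idx < n_codons):
            raise ValueError(f"TTA codon index {idx} outside CDS body")
        codons[idx - 1] = "TTA"
    return "".join(codons)


def generate_cluster(config: SimConfig) -> tuple[ClusterRecord, TruthTable]:
    """Cluster with implanted promoters, ARE sites and TTA codons.

    Genes are laid out left to right on the + strand with ``gene_spacing``
    of intergenic background ahead of each CDS; implants are placed in the
    upstream region of their gene at the stated anchored position.
    Deterministic for a given config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    needed = config.n_genes * (config.gene_length + config.gene_spacing)
    if config.cluster_length < needed:
        raise ValueError(f"cluster_length {config.cluster_length} < required {needed}")
    seq = list(random_sequence(rng, config.cluster_length, config.gc_content))
    features = []
    pos = 0
    for g in range(config.n_genes):
        gene = f"gene{g + 1}"
        start = pos + config.gene_spacing + 1  # 1-based
        tta = [
            imp.params["codon_index"]
            for imp in config.implants
            if imp.kind == "tta_codon" and imp.gene == gene
        ]
        cds = _random_cds(rng, config.gene_length, config.gc_content, tta)
        seq[start - 1 : start - 1 + config.gene_length] = list(cds)
        features.append(CdsFeature(gene, start, start + config.gene_length - 1, "+", "ATG"))
        pos = start + config.gene_length - 1

    truth = TruthTable()
    occupied: list[tuple[int, int]] = []
    for imp in config.implants:
        feat = next(f for f in features if f.gene == imp.gene)
        if imp.kind == "tta_codon":
            truth.implants.append({"kind": "tta_codon", "gene": imp.gene,
                                   "codon_index": imp.params["codon_index"]})
            continue
        if imp.kind == "promoter":
            m35, m10 = imp.params["minus35"], imp.params["minus10"]
            spacer = imp.params["spacer"]
            site = m35 + random_sequence(rng, spacer, config.gc_content) + m10
        elif imp.kind == "are_site":
            site = imp.params.get("site") or sample_pfm_site(rng, imp.params["pfm"])
        else:
            raise ValueError(f"unknown implant kind {imp.kind!r}")
        # anchored_pos is the 5'-most base of the implant, upstream of the gene
        g_start = feat.start + imp.anchored_pos  # anchored −k -> genomic start−k
        g_end = g_start + len(site) - 1
        if g_start < max(1, feat.start - config.gene_spacing) or g_end >= feat.start:
            raise ValueError(f"implant for {imp.gene} does not fit in the upstream region")
        for a, b in occupied:
            if g_start <= b and a <= g_end:
                raise ValueError(f"implants overlap near {imp.gene}")
        occupied.append((g_start, g_end))
        seq[g_start - 1 : g_end] = list(site)
        rec = {"kind": imp.kind, "gene": imp.gene, "anchored_pos": imp.anchored_pos,
               "genomic_start": g_start, "genomic_end": g_end, "site": site}
        rec.update({k: v for k, v in imp.params.items() if k != "pfm"})
        truth.implants.append(rec)

    record = ClusterRecord(f"synthetic_cluster_seed{config.seed}", "".join(seq), features)
    return record, truth


def generate_qpcr(
    config: SimConfig,
) -> tuple[dict[str, dict], dict[str, dict[str, list[float]]], TruthTable]:
    """Dilution series and Ct tables under the exponential amplification model.

    Returns (curves, ct_tables, truth).  ``curves[gene]`` holds the 5-fold
    dilution series (log10_quantity, ct); ``ct_tables[gene]`` holds control
    and treated Ct replicates encoding the configured fold change under the
    Pfaffl model: Ct_treated = Ct_control − log_E(fold).
    """
    if config.ct_noise_sd < 0:
        raise ValueError("ct noise sd must be >= 0")
    rng = np.random.default_rng(config.seed)
    curves: dict[str, dict] = {}
    cts: dict[str, dict[str, list[float]]] = {}
    truth = TruthTable()
    n_rep = config.n_bio_reps * config.n_tech_reps
    quantities = 40.0 / 5.0 ** np.arange(6)  # ng, 5-fold series 40 → 0.0128
    for gene, e in config.true_efficiency.items():
        fold = config.true_fold_change.get(gene, 1.0)
        if fold <= 0:
            raise ValueError(f"fold change for {gene} must be > 0")
        intercept = 22.0
        logq = np.log10(quantities)
        ct_curve = intercept - logq / np.log10(e)
        ct_curve = ct_curve + rng.normal(0.0, config.ct_noise_sd, ct_curve.size)
        curves[gene] = {"log10_quantity": logq.tolist(), "ct": ct_curve.tolist()}
        base_ct = 24.0
        ctrl = base_ct + rng.normal(0.0, config.ct_noise_sd, n_rep)
        trt = base_ct - np.log(fold) / np.log(e) + rng.normal(0.0, config.ct_noise_sd, n_rep)
        cts[gene] = {"control": ctrl.tolist(), "treated": trt.tolist()}
        truth.qpcr[gene] = {"efficiency": e, "fold_change": fold}
    return curves, cts, truth


def generate_protein_family(config: SimConfig) -> tuple[dict[str, str], TruthTable]:
    """Protein family evolved on a tree by i.i.d. substitutions.

    The root sequence is uniform over the 20 amino acids; along each branch
    of length t every site mutates with probability 1 − exp(−rate·t) to a
    uniformly chosen different residue (a Jukes–Cantor-style process on 20
    letters).  The returned alignment is gap-free, so it doubles as its own
    multiple alignment.
    """
    if not config.tree_newick:
        raise ValueError("config.tree_newick is required")
    if config.substitution_rate < 0:
        raise ValueError("substitution rate must be >= 0")
    rng = np.random.default_rng(config.seed)
    tree = TreeNode.read([config.tree_newick])
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    root_seq = rng.integers(0, 20, size=config.protein_length)
    sequences: dict[str, str] = {}

    def evolve(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            t = child.length or 0.0
            p = 1.0 - np.exp(-config.substitution_rate * t)
            s = seq.copy()
            mut = rng.random(s.size) < p
            if mut.any():
                shifts = rng.integers(1, 20, size=int(mut.sum()))
                s[mut] = (s[mut] + shifts) % 20
            if child.is_tip():
                sequences[child.name] = "".join(aa[s])
            else:
                evolve(child, s)

    evolve(tree, root_seq)
    truth = TruthTable(tree_newick=config.tree_newick)
    return sequences, truth
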
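"""End-to-end orchestration of the cluster analysis stages.

Stages run in dependency order: sequence I/O → promoter scan → footprint
algebra + operator information model → ARE (Ri) scan → receptor
classification → qPCR quantification → operon calling.  Every stage writes
its tables (TSV/JSON) into the output directory, every table carries both
anchored and genomic coordinates, and the resolved configuration — seeds
included — is serialized alongside so a rerun is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import cluster_io, expression_quant, operator_model, promoter_scan, receptor_classify

log = logging.getLogger("gblreg")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    outdir: str
    cluster_path: str | None = None
    cluster_format: str = "genbank"
    feature_tsv: str | None = None
    footprint_tsv: str | None = None
    promoter_tsv: str | None = None
    protein_fasta: str | None = None
    protein_alignment: str | None = None
    ct_tsv: str | None = None
    curve_tsv: str | None = None
    cotx_tsv: str | None = None
    stages: list[str] = field(default_factory=lambda: [
        "io", "promoters", "operator", "are_scan", "classify", "qpcr", "operons",
    ])
    # stage parameters
    upstream_length: int = 300
    spacer_range: tuple[int, int] = (14, 22)
    matrix_kind: str = "consensus"
    core_width: int = 18
    consensus_min_freq: float = 0.10
    small_sample_correction: bool = False
    ri_threshold: float = 0.0
    pka_set: str = "bjellqvist"
    pi_threshold: float = 7.0
    distance_model: str = "kimura_protein"
    bootstrap_reps: int = 1000
    seed: int = 1
    r2_min: float = 0.99
    reference_gene: str = "rrnA1"
    randomization_reps: int = 2000


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "spacer_range" in raw:
        raw["spacer_range"] = tuple(raw["spacer_range"])
    return RunConfig(**raw)


class StageError(RuntimeError):
    pass


def _require(cfg: RunConfig, attr: str, stage: str) -> str:
    val = getattr(cfg, attr)
    if not val:
        raise StageError(f"stage '{stage}' needs input '{attr}' but it is not configured")
    return val


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns a report dict (also written as JSON)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    report: dict = {"stages": {}}
    record = None
    footprints = None
    info_model = None

    # fail fast on missing inputs before any stage runs
    needs = {
        "io": ["cluster_path"],
        "promoters": ["cluster_path"],
        "operator": ["cluster_path", "footprint_tsv"],
        "are_scan": ["cluster_path", "footprint_tsv"],
        "classify": ["protein_alignment"],
        "qpcr": ["ct_tsv"],
        "operons": ["cotx_tsv"],
    }
    for stage in cfg.stages:
        for attr in needs.get(stage, []):
            _require(cfg, attr, stage)
    deps = {"promoters": "io", "operator": "io", "are_scan": "operator",
            "classify": None, "qpcr": None, "operons": None}
    for stage in cfg.stages:
        d = deps.get(stage)
        if d and d not in cfg.stages:
            raise StageError(f"stage '{stage}' requires stage '{d}' to be enabled")

    if "io" in cfg.stages:
        record = cluster_io.read_cluster(cfg.cluster_path, cfg.cluster_format, cfg.feature_tsv)
        log.info("read %s: %d bp, %d features", record.id, len(record), len(record.features))
        tta = {
            f.gene: cluster_io.find_tta_codons(f, record) for f in record.features
        }
        pd.DataFrame(
            [
                {"gene": f.gene, "start": f.start, "end": f.end, "strand": f.strand,
                 "length_nt": f.length, "tta_codons": ",".join(map(str, tta[f.gene]))}
                for f in record.features
            ]
        ).to_csv(out / "genes.tsv", sep="\t", index=False)
        report["stages"]["io"] = {"record": record.id, "length": len(record),
                                  "n_features": len(record.features)}

    if "promoters" in cfg.stages:
        model = promoter_scan.default_model(cfg.matrix_kind, cfg.spacer_range)
        rows = []
        for feat in record.features:
            up, truncated = cluster_io.extract_upstream(feat, record, cfg.upstream_length)
            if truncated:
                log.warning("upstream region of %s truncated at record edge", feat.gene)
            hits = promoter_scan.scan_bipartite(up, model, gene=feat.gene)
            for h in hits[:3]:
                rows.append({
                    "gene": h.gene,
                    "m35_from": h.minus35_window.from_pos, "m35_to": h.minus35_window.to_pos,
                    "m10_from": h.minus10_window.from_pos, "m10_to": h.minus10_window.to_pos,
                    "m35_genomic": h.minus35_window.genomic(feat)[0],
                    "m10_genomic": h.minus10_window.genomic(feat)[0],
                    "hexamer_spacer": h.hexamer_spacer,
                    "score35": h.score35, "score10": h.score10, "score_total": h.score_total,
                })
        pd.DataFrame(rows).to_csv(out / "promoter_hits.tsv", sep="\t", index=False)
        report["stages"]["promoters"] = {"n_hits_reported": len(rows)}

    if "operator" in cfg.stages:
        footprints = operator_model.read_footprint_tsv(cfg.footprint_tsv)
        rows = []
        for pair in footprints:
            up, down, summary = operator_model.strand_displacement(pair)
            rows.append({
                "promoter": pair.promoter,
                "top_from": pair.top.from_pos, "top_to": pair.top.to_pos,
                "bottom_from": pair.bottom.from_pos, "bottom_to": pair.bottom.to_pos,
                "top_length": operator_model.interval_length(pair.top),
                "bottom_length": operator_model.interval_length(pair.bottom),
                "displacement": ",".join(map(str, sorted(summary))),
                "overlap": operator_model.strand_overlap(pair),
            })
        pd.DataFrame(rows).to_csv(out / "footprints.tsv", sep="\t", index=False)
        sites = operator_model.extract_core_sites(record, footprints, cfg.core_width)
        info_model = operator_model.build_info_model(
            sites, correction=cfg.small_sample_correction,
            consensus_min_freq=cfg.consensus_min_freq,
        )
        info_model.to_json(out / "operator_model.json")
        info_model.logo_matrix().to_csv(out / "operator_logo.tsv", sep="\t", index=False)
        report["stages"]["operator"] = {
            "n_sites": info_model.n_sites,
            "R_sequence_bits": info_model.R_sequence,
            "consensus": info_model.consensus,
            "dyad_score": info_model.dyad_score,
        }

    if "are_scan" in cfg.stages:
        rows = []
        for feat in record.features:
            up, _ = cluster_io.extract_upstream(feat, record, cfg.upstream_length)
            for h in operator_model.scan_ri(up, info_model, cfg.ri_threshold):
                anchored_start = h.start - len(up) - 1  # last base of up is −1
                rows.append({
                    "gene": feat.gene, "anchored_start": anchored_start,
                    "anchored_end": anchored_start + info_model.width - 1,
                    "strand": h.strand, "ri_bits": h.ri, "site": h.site,
                })
        pd.DataFrame(rows).to_csv(out / "are_hits.tsv", sep="\t", index=False)
        report["stages"]["are_scan"] = {"n_hits": len(rows)}

    if "classify" in cfg.stages:
        from Bio import SeqIO
        aln = {r.id: str(r.seq) for r in SeqIO.parse(cfg.protein_alignment, "fasta")}
        tree = receptor_classify.bootstrap(
            aln, reps=cfg.bootstrap_reps, seed=cfg.seed, model=cfg.distance_model
        )
        tree.write(str(out / "receptors.nwk"))
        records = receptor_classify.classify_proteins(
            {k: v.replace("-", "") for k, v in aln.items()},
            pka_set=cfg.pka_set, pi_threshold=cfg.pi_threshold,
        )
        pd.DataFrame(
            [{"id": r.id, "pi": r.pi, "clade": r.clade, "concordant": r.concordant}
             for r in records]
        ).to_csv(out / "classification.tsv", sep="\t", index=False)
        report["stages"]["classify"] = {"n_proteins": len(records)}

    if "qpcr" in cfg.stages:
        ct = pd.read_csv(cfg.ct_tsv, sep="\t")
        effs: dict[str, float] = {}
        if cfg.curve_tsv:
            curves = pd.read_csv(cfg.curve_tsv, sep="\t")
            for gene, grp in curves.groupby("gene"):
                sc = expression_quant.fit_standard_curve(
                    grp["log10_quantity"].tolist(), grp["ct"].tolist(), cfg.r2_min
                )
                if not sc.r2_ok:
                    log.warning("standard curve for %s has r2 %.4f < %.2f", gene, sc.r2, cfg.r2_min)
                effs[gene] = sc.efficiency
        ref = cfg.reference_gene
        ref_rows = ct[ct["gene"] == ref]
        if ref_rows.empty:
            raise StageError(f"reference gene {ref!r} absent from Ct table")
        rows = []
        for gene, grp in ct.groupby("gene"):
            if gene == ref:
                continue
            e_t, e_r = effs.get(gene, 2.0), effs.get(ref, 2.0)
            tc = grp.loc[grp["condition"] == "control", "ct"].tolist()
            tt = grp.loc[grp["condition"] == "treated", "ct"].tolist()
            rc = ref_rows.loc[ref_rows["condition"] == "control", "ct"].tolist()
            rt = ref_rows.loc[ref_rows["condition"] == "treated", "ct"].tolist()
            ratio = expression_quant.pfaffl_ratio(
                e_t, float(pd.Series(tc).mean() - pd.Series(tt).mean()),
                e_r, float(pd.Series(rc).mean() - pd.Series(rt).mean()),
            )
            p = expression_quant.randomization_test(
                tc, tt, rc, rt, e_t, e_r, reps=cfg.randomization_reps, seed=cfg.seed
            )
            rows.append({"gene": gene, "ratio": ratio, "p_value": p,
                         "E_target": e_t, "E_ref": e_r})
        pd.DataFrame(rows).to_csv(out / "expression.tsv", sep="\t", index=False)
        report["stages"]["qpcr"] = {"n_genes": len(rows)}

    if "operons" in cfg.stages:
        cot = pd.read_csv(cfg.cotx_tsv, sep="\t", comment="#")
        genes_df = pd.read_csv(
            Path(__file__).parent / "data" / "genes_sfb.tsv", sep="\t", comment="#"
        ) if record is None else None
        if record is not None:
            order = [f.gene for f in record.features]
            strands = {f.gene: f.strand for f in record.features}
        else:
            order = genes_df["gene"].tolist()
            strands = dict(zip(genes_df["gene"], genes_df["strand"]))
        calls = [
            expression_quant.CotxCall((r["gene_a"], r["gene_b"]),
                                      str(r["amplified"]).lower() == "true")
            for _, r in cot.iterrows()
        ]
        units = expression_quant.call_operons(order, strands, calls)
        pd.DataFrame({"unit": range(1, len(units) + 1),
                      "genes": [",".join(u) for u in units]}).to_csv(
            out / "operons.tsv", sep="\t", index=False)
        report["stages"]["operons"] = {"units": [",".join(u) for u in units]}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
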
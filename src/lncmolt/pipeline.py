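"""End-to-end orchestration: discover -> quantify -> DE -> profiles ->
targets -> network -> enrichment -> qPCR -> report.

The pipeline consumes a reference annotation (GTF), assembled novel
transcripts (GTF), transcript sequences (FASTA), a count matrix with a
stage design, a flat term annotation, and optionally a qPCR Ct table, and
produces per-stage result tables plus a JSON run report whose summary counts
are all re-derivable from the stage outputs. Structural (non-protein-coding,
non-lncRNA) reference transcripts such as rRNA are excluded from the
differential-expression input, as is standard practice.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from lncmolt import expression_de, lncrna_discovery, target_network
from lncmolt.enrichment import enrich
from lncmolt.expression_de import ExpressionMatrix, de_summary, run_de
from lncmolt.genome_model import (
    GenomeAnnotation,
    annotation_from_transcripts,
    read_fasta,
    read_gtf,
    write_bed6,
    write_gtf,
)
from lncmolt.lncrna_discovery import (
    call_lncrnas,
    classify_all,
    train_hexamer_table,
)
from lncmolt.qpcr_validation import anova_tukey, relative_expression
from lncmolt.target_network import (
    build_network,
    cis_targets,
    combine_targets,
    edges_table,
    hub_nodes,
    mode_summary,
    trans_targets,
)
from lncmolt.temporal_profiles import (
    assign_all,
    assignments_table,
    enumerate_profiles,
    profile_significance,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    The thresholds default to the analysis' printed rules: lncRNA length
    > 200 nt, ORF cutoff 300 nt, DE call at FDR < 0.05 and |log2FC| >= 2,
    cis window 10 kb (inclusive), trans |r| > 0.95 (strict), network
    |r| > 0.98 (strict), profile unit change c = 1 with minimum template
    correlation 0.7.
    """

    reference_gtf: str = ""
    novel_gtf: str = ""
    transcripts_fasta: str = ""
    counts_tsv: str = ""
    design_tsv: str = ""
    terms_tsv: str = ""
    qpcr_tsv: str = ""
    outdir: str = "lncmolt_out"
    seed: int = 0
    min_lnc_length: int = 200
    orf_cutoff: int = 300
    bidirectional_window: int = 1000
    cis_window: int = 10_000
    trans_r: float = 0.95
    network_r: float = 0.98
    fdr_cutoff: float = 0.05
    lfc_cutoff: float = 2.0
    profile_c: int = 1
    min_profile_correlation: float = 0.7
    min_profile_fold: float = 2.0
    top_hubs: int = 20
    qpcr_calibrator: str = "PE"

    def validate(self) -> None:
        for name in ("trans_r", "network_r"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not 0.0 < self.fdr_cutoff < 1.0:
            raise ValueError("fdr_cutoff must lie in (0, 1)")
        for name in (
            "min_lnc_length", "orf_cutoff", "cis_window", "bidirectional_window",
            "lfc_cutoff", "profile_c", "min_profile_fold", "top_hubs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _shuffled(seq: str, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return arr.tobytes().decode()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in dependency order and write the run report.

    Any stage failure aborts with the failing stage named; outputs written
    before the failure are retained. Returns the report dict (also written
    as report.json, plus a human-readable report.txt).
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    config.to_yaml(os.path.join(config.outdir, "config_used.yaml"))
    report: dict = {"config": dataclasses.asdict(config)}
    stage = "load_inputs"
    try:
        t0 = time.time()
        reference_ts = read_gtf(config.reference_gtf)
        reference = annotation_from_transcripts(reference_ts)
        novel = read_gtf(config.novel_gtf)
        sequences = read_fasta(config.transcripts_fasta)
        counts = pd.read_csv(config.counts_tsv, sep="\t", index_col=0)
        design = pd.read_csv(config.design_tsv, sep="\t", index_col=0)["stage"].to_dict()
        terms = pd.read_csv(config.terms_tsv, sep="\t") if config.terms_tsv else None
        logger.info("loaded %d reference genes, %d novel transcripts, %d x %d counts (%.1fs)",
                    len(reference), len(novel), *counts.shape, time.time() - t0)

        stage = "discover"
        t0 = time.time()
        rng = np.random.default_rng(config.seed)
        coding_seqs = [
            sequences[t.transcript_id]
            for g in reference.coding_genes()
            for t in g.transcripts
            if t.transcript_id in sequences
        ]
        table = train_hexamer_table(coding_seqs, [_shuffled(s, rng) for s in coding_seqs])
        lncrnas, cp_calls, class_codes = call_lncrnas(
            novel, reference, sequences, table,
            min_length=config.min_lnc_length, orf_cutoff=config.orf_cutoff,
        )
        positions = classify_all(lncrnas, reference, config.bidirectional_window)
        _write_discovery(config.outdir, lncrnas, positions, cp_calls, class_codes)
        class_counts = _count_values(p.cls for p in positions.values())
        report["discovery"] = {
            "n_novel": len(novel),
            "n_lncrna": len(lncrnas),
            "classes": class_counts,
        }
        logger.info("called %d lncRNAs (%.1fs)", len(lncrnas), time.time() - t0)

        stage = "expression_de"
        t0 = time.time()
        lnc_ids = [t.transcript_id for t in lncrnas]
        coding_tx = {
            t.transcript_id: g.gene_id
            for g in reference.coding_genes()
            for t in g.transcripts
        }
        keep = [t for t in counts.index if t in coding_tx or t in set(lnc_ids)]
        lengths = pd.Series(
            {
                t.transcript_id: sum(e - s for s, e in t.exons)
                for t in list(reference.transcripts()) + list(lncrnas)
            }
        )
        # FPKM uses full library depth (all quantified transcripts)
        full_lengths = lengths.reindex(counts.index)
        novel_len = {t.transcript_id: sum(e - s for s, e in t.exons) for t in novel}
        full_lengths = full_lengths.fillna(pd.Series(novel_len)).fillna(1000.0)
        fpkm_all = expression_de.compute_fpkm(counts, full_lengths)
        matrix = ExpressionMatrix(
            counts.loc[keep], design, full_lengths.loc[keep], fpkm=fpkm_all.loc[keep]
        )
        de_table = run_de(matrix, config.fdr_cutoff, config.lfc_cutoff)
        de_table["biotype"] = [
            "lncRNA" if t in set(lnc_ids) else "coding" for t in de_table["transcript_id"]
        ]
        de_table.to_csv(os.path.join(config.outdir, "de_results.tsv"), sep="\t", index=False)
        matrix.fpkm.to_csv(os.path.join(config.outdir, "fpkm.tsv"), sep="\t",
                           index_label="transcript_id")
        report["de"] = {
            "summary": de_summary(de_table),
            "by_biotype": {
                bt: de_summary(de_table[de_table["biotype"] == bt])
                for bt in ("lncRNA", "coding")
            },
        }
        logger.info("DE done (%.1fs)", time.time() - t0)

        stage = "profiles"
        t0 = time.time()
        de_ids = sorted(set(de_table.loc[de_table["is_de"], "transcript_id"]))
        stage_means = matrix.stage_mean_fpkm().loc[de_ids]
        profiles = enumerate_profiles(3, config.profile_c)
        assignments = assign_all(
            stage_means, profiles, config.min_profile_correlation, config.min_profile_fold
        )
        assignments_table(assignments).to_csv(
            os.path.join(config.outdir, "profiles.tsv"), sep="\t", index=False
        )
        sig = profile_significance(
            stage_means, profiles, config.min_profile_correlation, config.min_profile_fold
        )
        sig.to_csv(os.path.join(config.outdir, "profile_summary.tsv"), sep="\t", index=False)
        report["profiles"] = {
            "n_assigned": int(sum(a.kept for a in assignments)),
            "sizes": {
                str(p.profile_id): int(sum(a.kept and a.profile_id == p.profile_id
                                           for a in assignments))
                for p in profiles
            },
        }
        logger.info("profiles done (%.1fs)", time.time() - t0)

        stage = "targets_network"
        t0 = time.time()
        de_lnc = [t for t in lncrnas if t.transcript_id in set(de_ids)]
        log_fpkm = np.log2(fpkm_all + 1.0)
        gene_expr = log_fpkm.loc[[t for t in coding_tx if t in log_fpkm.index]].copy()
        gene_expr.index = [coding_tx[t] for t in gene_expr.index]
        lnc_expr = log_fpkm.loc[[t.transcript_id for t in de_lnc]]
        cis_edges = [e for t in de_lnc for e in cis_targets(t, reference, config.cis_window)]
        trans_edges = trans_targets(lnc_expr, gene_expr, config.trans_r)
        targets = combine_targets(cis_edges, trans_edges)
        edges_table(targets).to_csv(
            os.path.join(config.outdir, "targets.tsv"), sep="\t", index=False
        )
        de_cod_genes = sorted(
            {
                coding_tx[t]
                for t in de_ids
                if t in coding_tx
            }
        )
        net = build_network(
            lnc_expr, gene_expr.loc[gene_expr.index.isin(de_cod_genes)],
            config.network_r,
        )
        import networkx as nx

        nx.write_graphml(net, os.path.join(config.outdir, "network.graphml"))
        pd.DataFrame(
            [(u, v, d["r"]) for u, v, d in net.edges(data=True)],
            columns=["node_a", "node_b", "r"],
        ).to_csv(os.path.join(config.outdir, "edges.tsv"), sep="\t", index=False)
        hubs = hub_nodes(net, config.top_hubs)
        pd.DataFrame(hubs, columns=["node", "degree"]).to_csv(
            os.path.join(config.outdir, "hubs.tsv"), sep="\t", index=False
        )
        report["targets"] = {
            "modes": mode_summary(targets),
            "network": {"nodes": net.number_of_nodes(), "edges": net.number_of_edges()},
            "top_hubs": hubs[:5],
        }
        logger.info("targets/network done (%.1fs)", time.time() - t0)

        stage = "enrichment"
        t0 = time.time()
        if terms is not None and len(terms):
            expressed = {
                coding_tx[t] for t in coding_tx
                if t in counts.index and counts.loc[t].sum() > 0
            }
            target_genes = sorted(
                {e.mrna_gene_id for e in targets} & expressed
            )
            queries = {
                "de_mrna": sorted(set(de_cod_genes) & expressed),
                "lnc_targets": target_genes,
            }
            report["enrichment"] = {}
            for qname, query in queries.items():
                result = (
                    enrich(query, terms, expressed) if query else None
                )
                if result is not None and len(result):
                    result.to_csv(
                        os.path.join(config.outdir, f"enrichment_{qname}.tsv"),
                        sep="\t", index=False,
                    )
                    report["enrichment"][qname] = {
                        "n_tested": int(len(result)),
                        "n_significant": int((result["fdr"] < config.fdr_cutoff).sum()),
                        "top_terms": list(result["term_id"].head(5)),
                    }
                else:
                    report["enrichment"][qname] = {"n_tested": 0, "n_significant": 0,
                                                   "top_terms": []}
        logger.info("enrichment done (%.1fs)", time.time() - t0)

        stage = "qpcr"
        if config.qpcr_tsv and os.path.exists(config.qpcr_tsv):
            qpcr = pd.read_csv(config.qpcr_tsv, sep="\t")
            rq = relative_expression(qpcr, config.qpcr_calibrator)
            rq_out = rq.drop(columns=["rq_replicates"]).copy()
            letters_rows = []
            for gene, grp in rq.groupby("gene_id"):
                groups = {r["group"]: r["rq_replicates"] for _, r in grp.iterrows()}
                if all(len(v) >= 2 for v in groups.values()) and len(groups) >= 2:
                    res = anova_tukey(groups)
                    for gname in groups:
                        letters_rows.append(
                            {"gene_id": gene, "group": gname,
                             "letter": res.letters[gname],
                             "anova_p": res.p_value}
                        )
            rq_out.to_csv(os.path.join(config.outdir, "rq.tsv"), sep="\t", index=False)
            if letters_rows:
                pd.DataFrame(letters_rows).to_csv(
                    os.path.join(config.outdir, "anova.tsv"), sep="\t", index=False
                )
            report["qpcr"] = {"n_genes": int(rq["gene_id"].nunique())}
    except Exception as exc:  # noqa: BLE001 - abort names the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report_path = os.path.join(config.outdir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(os.path.join(config.outdir, "report.txt"), "w") as fh:
        fh.write(_human_report(report))
    return report


def _count_values(values) -> dict[str, int]:
    out: dict[str, int] = {}
    for v in values:
        out[v] = out.get(v, 0) + 1
    return dict(sorted(out.items()))


def _write_discovery(outdir, lncrnas, positions, cp_calls, class_codes) -> None:
    write_gtf(lncrnas, os.path.join(outdir, "lncrna.gtf"))
    rows = [
        {
            "transcript_id": t.transcript_id,
            "class_code": class_codes[t.transcript_id],
            "lnc_class": positions[t.transcript_id].cls,
            "anchor_gene": positions[t.transcript_id].anchor_gene_id,
        }
        for t in lncrnas
    ]
    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "lncrna_classes.tsv"), sep="\t", index=False
    )
    cp_rows = [
        {
            "transcript_id": tid,
            "class_code": class_codes.get(tid, ""),
            "orf_noncoding": c.predictor_a_noncoding,
            "hexamer_noncoding": c.predictor_b_noncoding,
            "consensus_noncoding": c.consensus_noncoding,
        }
        for tid, c in cp_calls.items()
    ]
    pd.DataFrame(cp_rows).to_csv(
        os.path.join(outdir, "coding_potential.tsv"), sep="\t", index=False
    )
    write_bed6(
        (
            (t.chrom, t.span[0], t.span[1], t.transcript_id, 0.0, t.strand)
            for t in lncrnas
        ),
        os.path.join(outdir, "lncrna.bed"),
    )


def _human_report(report: dict) -> str:
    lines = ["lncmolt run summary", "===================", ""]
    d = report.get("discovery", {})
    lines.append(f"lncRNAs called: {d.get('n_lncrna', 0)} of {d.get('n_novel', 0)} novel transcripts")
    for cls, n in d.get("classes", {}).items():
        lines.append(f"  {cls}: {n}")
    for comp, s in report.get("de", {}).get("summary", {}).items():
        lines.append(f"DE {comp}: {s['up']} up, {s['down']} down")
    p = report.get("profiles", {})
    lines.append(f"profile-assigned transcripts: {p.get('n_assigned', 0)}")
    t = report.get("targets", {})
    for mode, s in t.get("modes", {}).items():
        lines.append(f"targets {mode}: {s['pairs']} pairs, {s['unique_genes']} genes")
    net = t.get("network", {})
    lines.append(f"network: {net.get('nodes', 0)} nodes, {net.get('edges', 0)} edges")
    for qname, e in report.get("enrichment", {}).items():
        lines.append(
            f"enrichment [{qname}]: {e['n_significant']} significant of {e['n_tested']} terms"
        )
    return "\n".join(lines) + "\n"


def demo(outdir: str, seed: int = 0) -> tuple[dict, "object"]:
    """Generate the bundled synthetic study and run the full pipeline on it.

    Returns (report, GroundTruth). Deterministic: the same seed yields a
    byte-identical report.
    """
    from lncmolt.synthetic_data import GroundTruth, SimulationConfig, write_study

    data_dir = os.path.join(outdir, "data")
    cfg = SimulationConfig(seed=seed)
    paths = write_study(cfg, data_dir)
    pcfg = PipelineConfig(
        reference_gtf=paths["reference"],
        novel_gtf=paths["novel"],
        transcripts_fasta=paths["transcripts"],
        counts_tsv=paths["counts"],
        design_tsv=paths["design"],
        terms_tsv=paths["terms"],
        qpcr_tsv=paths["qpcr"],
        outdir=os.path.join(outdir, "results"),
        seed=seed,
    )
    report = run_all(pcfg)
    return report, GroundTruth.from_json(paths["truth"])
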
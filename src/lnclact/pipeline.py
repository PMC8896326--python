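"""End-to-end orchestration: identify -> DE -> targets -> network -> ORA -> qPCR.

A PipelineConfig names every input/output and stage parameter; ``run_all``
executes the enabled stages in dependency order and writes a manifest with
input hashes and parameters.  Identical config + inputs reproduce identical
result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .coding_potential import (
    LogisticModel,
    build_hexamer_table,
    consensus_noncoding,
    read_call_table,
    score_transcripts,
    train_model,
)
from .core import ExpressionMatrix, ValidationError
from .enrichment import enrichment_frame, ora
from .expression import common_de_table, run_comparisons
from .identify import (
    accept_lncrnas,
    classify_all,
    plot_summary,
    summarize_features,
    triage,
)
from .qpcr import concordance, ddct, qpcr_log2fc
from .targets import (
    cis_targets,
    cis_targets_frame,
    edges_frame,
    export_graphml,
    panel_network,
    trans_targets,
)

logger = logging.getLogger("lnclact")


@dataclass
class PipelineConfig:
    # inputs
    reference_gtf: str = "reference.gtf"
    assembled_gtf: str = "assembled.gtf"
    transcripts_fasta: str = "transcripts.fa"
    training_coding_fasta: str = "training_coding.fa"
    training_noncoding_fasta: str = "training_noncoding.fa"
    expression_tsv: str = "expression.tsv"
    design_tsv: str = "design.tsv"
    ct_tsv: str = ""
    panel_txt: str = ""
    gene_sets_gmt: str = ""
    external_calls_tsv: str = ""
    outdir: str = "results"
    # stage toggles
    run_identify: bool = True
    run_de: bool = True
    run_targets: bool = True
    run_network: bool = True
    run_enrich: bool = True
    run_qpcr: bool = True
    # parameters
    min_length: int = 200
    min_exons: int = 2
    cpat_threshold: float = 0.02
    epsilon: float = 0.01
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    window: int = 100_000
    r_min: float = 0.9
    qpcr_epsilon: float = 1e-9
    seed: int = 7
    expression_unit: str = "fpkm"
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def run_all(config: PipelineConfig) -> dict:
    """Execute the enabled stages; return the manifest (also written to disk).

    On a stage failure the run aborts with the stage name and cause, and any
    outputs already written are renamed with a ``.partial`` suffix.  A run
    log mirrors the stderr logging into ``<outdir>/run.log``.
    """
    if config.run_targets and not config.run_de:
        raise ValidationError("targets stage requires the de stage")
    if config.run_network and not config.run_de:
        raise ValidationError("network stage requires the de stage")
    if (config.run_targets or config.run_network) and not config.run_identify:
        raise ValidationError("targets/network stages require the identify stage")
    if config.run_enrich and not config.run_targets:
        raise ValidationError("enrich stage requires the targets stage")
    if config.run_qpcr and not config.run_de:
        raise ValidationError("qpcr stage requires the de stage")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    state: dict = {"stage": "setup", "outputs": {}}
    try:
        return _run_all(config, out, state)
    except Exception as exc:
        for p in state["outputs"].values():
            p = Path(p)
            if p.exists():
                p.rename(p.with_name(p.name + ".partial"))
        raise StageError(f"stage {state['stage']!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _run_all(config: PipelineConfig, out: Path, state: dict) -> dict:
    outputs: dict[str, Path] = state["outputs"]
    stage_results: dict[str, object] = {}

    state["stage"] = "annotation input"
    reference = lio.read_gtf(config.reference_gtf)
    assembled = lio.read_gtf(config.assembled_gtf)
    coding_ref = [t for t in reference if t.biotype == "protein_coding"]
    assembled_by_id = {t.transcript_id: t for t in assembled}

    accepted_ids: list[str] = []
    if config.run_identify:
        state["stage"] = "identify"
        logger.info("identify: triage + coding potential on %d transcripts", len(assembled))
        sequences = lio.read_fasta(config.transcripts_fasta)
        decisions = triage(
            assembled, reference, min_length=config.min_length, min_exons=config.min_exons
        )
        train_cod = list(lio.read_fasta(config.training_coding_fasta).values())
        train_non = list(lio.read_fasta(config.training_noncoding_fasta).values())
        model, table = train_model(train_cod, train_non)
        candidates = [
            d.transcript_id for d in decisions if d.fate == "candidate_for_coding_potential"
        ]
        results = score_transcripts(
            model, table, sequences, candidates, threshold=config.cpat_threshold
        )
        external = (
            read_call_table(config.external_calls_tsv) if config.external_calls_tsv else {}
        )
        consensus = {}
        for tid, res in results.items():
            calls = dict(res.predictor_calls)
            calls.update(external.get(tid, {}))
            enabled = sorted(calls)
            flag = consensus_noncoding(calls, enabled)
            res.consensus_noncoding = flag
            consensus[tid] = flag
        accepted_ids, decisions = accept_lncrnas(decisions, consensus)
        accepted = [assembled_by_id[t] for t in accepted_ids]
        classes = classify_all(accepted, coding_ref)

        triage_df = pd.DataFrame(
            [(d.transcript_id, d.fate, d.reason) for d in decisions],
            columns=["transcript_id", "fate", "reason"],
        )
        cp_df = pd.DataFrame(
            [
                (
                    r.transcript_id,
                    r.orf_size,
                    r.orf_coverage,
                    r.fickett,
                    r.hexamer,
                    r.probability,
                    r.consensus_noncoding,
                )
                for r in results.values()
            ],
            columns=[
                "transcript_id", "orf_size", "orf_coverage", "fickett",
                "hexamer", "probability", "consensus_noncoding",
            ],
        ).sort_values("transcript_id")
        outputs["triage_tsv"] = out / "triage.tsv"
        triage_df.to_csv(outputs["triage_tsv"], sep="\t", index=False)
        outputs["coding_potential_tsv"] = out / "coding_potential.tsv"
        cp_df.to_csv(outputs["coding_potential_tsv"], sep="\t", index=False)
        outputs["lncrna_gtf"] = out / "lncrnas.gtf"
        lio.write_gtf(accepted, outputs["lncrna_gtf"])
        outputs["lncrna_bed"] = out / "lncrnas.bed"
        lio.write_bed6(accepted, outputs["lncrna_bed"])
        outputs["classes_tsv"] = out / "lncrna_classes.tsv"
        classes.to_csv(outputs["classes_tsv"], sep="\t", index=False)
        outputs["model_txt"] = out / "coding_model.txt"
        model.save(outputs["model_txt"])
        stage_results["accepted_ids"] = accepted_ids
        stage_results["classes"] = classes

    matrix: ExpressionMatrix | None = None
    de_results: pd.DataFrame | None = None
    if config.run_de:
        state["stage"] = "de"
        matrix = lio.read_expression(
            config.expression_tsv, config.design_tsv, unit=config.expression_unit
        )
        logger.info("de: %d transcripts x %d samples", *matrix.values.shape)
        de_results = run_comparisons(
            matrix,
            epsilon=config.epsilon,
            alpha=config.alpha,
            lfc_threshold=config.lfc_threshold,
        )
        outputs["de_tsv"] = out / "de_results.tsv"
        de_results.to_csv(outputs["de_tsv"], sep="\t", index=False)
        for breed in sorted({s.breed for s in matrix.samples}):
            common = common_de_table(de_results, matrix, breed)
            p = out / f"common_de_{breed}.tsv"
            outputs[f"common_de_{breed}"] = p
            common.to_csv(p, sep="\t", index=False)
        stage_results["de_results"] = de_results

        if config.run_identify and config.make_plots:
            lnc_models = [assembled_by_id[t] for t in accepted_ids]
            mrna_models = [t for t in assembled if t.biotype == "protein_coding"] or coding_ref
            summary = summarize_features(lnc_models, mrna_models, matrix)
            for name, df in summary.items():
                p = out / f"summary_{name}.tsv"
                outputs[f"summary_{name}"] = p
                df.to_csv(p, sep="\t", index=False)
            plot_summary(summary, str(out / "summary.png"))

    gene_of = {t.transcript_id: t.gene_id for t in assembled}
    breeds = sorted({s.breed for s in matrix.samples}) if matrix is not None else []

    def de_ids(breed: str, ids: Sequence[str]) -> list[str]:
        sub = de_results[
            (de_results["breed"] == breed)
            & de_results["is_de"]
            & de_results["transcript_id"].isin(set(ids))
        ]
        return sorted(set(sub["transcript_id"]))

    cis_genes: dict[str, set[str]] = {b: set() for b in breeds}
    trans_genes: dict[str, set[str]] = {b: set() for b in breeds}
    if config.run_targets:
        state["stage"] = "targets"
        assert matrix is not None and de_results is not None
        lnc_models = [assembled_by_id[t] for t in accepted_ids]
        coding_ids = [
            t.transcript_id for t in coding_ref if t.transcript_id in matrix.values.index
        ]
        de_lnc_by_breed = {b: de_ids(b, accepted_ids) for b in breeds}
        cis = cis_targets(
            [assembled_by_id[t] for t in sorted(set().union(*de_lnc_by_breed.values()))]
            if breeds else lnc_models,
            coding_ref,
            window=config.window,
        )
        cis_df = cis_targets_frame(cis)
        outputs["cis_tsv"] = out / "cis_targets.tsv"
        cis_df.to_csv(outputs["cis_tsv"], sep="\t", index=False)
        for b in breeds:
            lnc_set = set(de_lnc_by_breed[b])
            cis_genes[b] = set(cis_df.loc[cis_df["lncrna_id"].isin(lnc_set), "gene_id"])

        all_trans = []
        for b in breeds:
            cols = matrix.samples_for(breed=b)
            lncs_de = de_lnc_by_breed[b]
            mrna_de = de_ids(b, coding_ids)
            if not lncs_de or not mrna_de:
                continue
            edges = trans_targets(
                matrix.values.loc[lncs_de, cols],
                matrix.values.loc[mrna_de, cols],
                r_min=config.r_min,
                p_max=config.alpha,
            )
            for e in edges:
                trans_genes[b].add(gene_of[e.gene_id])
            df = edges_frame(edges)
            df.insert(0, "breed", b)
            # trans edges are transcript-level; report the gene too
            df["target_gene"] = df["gene_id"].map(gene_of)
            all_trans.append(df)
        trans_df = (
            pd.concat(all_trans, ignore_index=True)
            if all_trans
            else pd.DataFrame(
                columns=["breed", "lncrna_id", "gene_id", "method", "r",
                         "p_value", "fdr", "sign", "relation", "target_gene"]
            )
        )
        outputs["trans_tsv"] = out / "trans_targets.tsv"
        trans_df.to_csv(outputs["trans_tsv"], sep="\t", index=False)
        stage_results["cis"] = cis_df
        stage_results["trans"] = trans_df

    if config.run_network:
        state["stage"] = "network"
        assert matrix is not None and de_results is not None
        panel = lio.read_gene_list(config.panel_txt) if config.panel_txt else []
        tid_by_gene: dict[str, str] = {}
        for t in coding_ref:
            tid_by_gene.setdefault(t.gene_id, t.transcript_id)
        present = [g for g in panel if tid_by_gene.get(g) in matrix.values.index]
        missing = [g for g in panel if g not in present]
        if missing:
            logger.warning("network: panel genes missing from matrix: %s", missing)
        if not present:
            raise ValidationError("no panel gene is present in the expression matrix")
        net_frames, summaries = [], []
        all_edges = []
        # Pearson co-expression is computed on log2(FPKM + eps): the linear
        # scale is dominated by lognormal skew and masks inverse relations
        log_vals = np.log2(matrix.values + config.epsilon)
        for b in breeds:
            cols = matrix.samples_for(breed=b)
            lncs_de = de_ids(b, accepted_ids)
            if not lncs_de:
                continue
            panel_rows = log_vals.loc[[tid_by_gene[g] for g in present], cols]
            panel_rows.index = pd.Index(present)
            edges, summary = panel_network(
                log_vals.loc[lncs_de, cols], panel_rows, alpha=config.alpha
            )
            df = edges_frame(edges)
            df.insert(0, "breed", b)
            net_frames.append(df)
            summary.insert(0, "breed", b)
            summaries.append(summary)
            all_edges.extend(edges)
        net_df = (
            pd.concat(net_frames, ignore_index=True)
            if net_frames
            else pd.DataFrame(
                columns=["breed", "lncrna_id", "gene_id", "method", "r",
                         "p_value", "fdr", "sign", "relation"]
            )
        )
        outputs["network_tsv"] = out / "panel_network.tsv"
        net_df.to_csv(outputs["network_tsv"], sep="\t", index=False)
        summary_df = (
            pd.concat(summaries, ignore_index=True)
            if summaries
            else pd.DataFrame(columns=["breed", "edges", "positive", "negative"])
        )
        outputs["network_summary_tsv"] = out / "panel_network_summary.tsv"
        summary_df.to_csv(outputs["network_summary_tsv"], sep="\t", index=False)
        if all_edges:
            outputs["network_graphml"] = out / "panel_network.graphml"
            export_graphml(all_edges, str(outputs["network_graphml"]))
        stage_results["network_summary"] = summary_df

    if config.run_enrich and config.gene_sets_gmt:
        state["stage"] = "enrich"
        collection = lio.read_gmt(config.gene_sets_gmt)
        background = sorted({t.gene_id for t in coding_ref})
        frames = []
        for b in breeds:
            target = sorted((cis_genes[b] | trans_genes[b]) & set(background))
            if not target:
                continue
            records = ora(target, collection, background, alpha=config.alpha)
            df = enrichment_frame(records)
            df.insert(0, "breed", b)
            frames.append(df)
        enr_df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(
                columns=["breed", "set_name", "category", "k", "K", "n", "N",
                         "p_value", "fdr", "significant"]
            )
        )
        outputs["enrichment_tsv"] = out / "enrichment.tsv"
        enr_df.to_csv(outputs["enrichment_tsv"], sep="\t", index=False)
        stage_results["enrichment"] = enr_df

    if config.run_qpcr and config.ct_tsv:
        state["stage"] = "qpcr"
        assert matrix is not None
        ct = lio.read_ct_table(config.ct_tsv)
        refs = [g for g in ("GAPDH_REF", "UXT_REF") if g in set(ct["gene_id"])]
        if len(refs) < 2:
            refs = sorted(set(ct["gene_id"]))[:2]  # caller-supplied references
        target_genes = [
            g for g in sorted(set(ct["gene_id"])) if g not in refs
        ]
        stages = list(dict.fromkeys(s.stage for s in matrix.samples))
        rq_frames = []
        qpcr_lfc, rna_lfc, labels = [], [], []
        for gene in target_genes:
            rq = ddct(ct, gene, reference_genes=refs)
            rq_frames.append(rq)
            if gene not in matrix.values.index:
                continue
            for b in breeds:
                sa = matrix.samples_for(breed=b, stage=stages[0])
                sb = matrix.samples_for(breed=b, stage=stages[-1])
                sa = [s for s in sa if s in set(rq["sample_id"])]
                sb = [s for s in sb if s in set(rq["sample_id"])]
                if len(sa) < 1 or len(sb) < 1:
                    continue
                q = qpcr_log2fc(rq, sa, sb)
                ma = float(matrix.values.loc[gene, sa].mean())
                mb = float(matrix.values.loc[gene, sb].mean())
                r = float(
                    np.log2((mb + config.qpcr_epsilon) / (ma + config.qpcr_epsilon))
                )
                qpcr_lfc.append(q)
                rna_lfc.append(r)
                labels.append((gene, b))
        rq_df = (
            pd.concat(rq_frames, ignore_index=True) if rq_frames else pd.DataFrame()
        )
        outputs["qpcr_rq_tsv"] = out / "qpcr_rq.tsv"
        rq_df.to_csv(outputs["qpcr_rq_tsv"], sep="\t", index=False)
        if len(qpcr_lfc) >= 3:
            r_val, paired = concordance(qpcr_lfc, rna_lfc)
            paired.insert(0, "gene_id", [l[0] for l in labels])
            paired.insert(1, "breed", [l[1] for l in labels])
            outputs["concordance_tsv"] = out / "qpcr_concordance.tsv"
            paired.to_csv(outputs["concordance_tsv"], sep="\t", index=False)
            stage_results["qpcr_r"] = r_val
            (out / "qpcr_concordance_r.txt").write_text(f"{r_val:.6f}\n")
            outputs["concordance_r"] = out / "qpcr_concordance_r.txt"

    state["stage"] = "manifest"
    manifest = {
        "parameters": asdict(config),
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in sorted(outputs.items())
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["_results"] = stage_results
    return manifest
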
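"""End-to-end orchestration: simulate/load -> QC -> normalize -> model ->
signature -> DMR -> enrichment, with a reproducibility manifest."""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .bmiq import probe_type_correct
from .config import PipelineConfig
from .enrich import (enhancer_enrichment, gc_comparison, meth_expr_by_context,
                     tabulate_context)
from .io import load_tables, qc_filter, write_table
from .models import (BlockedAnovaModel, DesignSpec, ModeratedLinearModel,
                     estimate_surrogates, group_delta_beta)
from .normalize import beta_to_m, quantile_normalize
from .signature import (build_cd133_signature, build_tgfb_signature, call_dmrs,
                        dmrs_to_bed, dmrs_to_table, signature_overlap_test)
from .simulate import generate_dataset, generate_expression, generate_manifest

log = logging.getLogger("stablemeth")


def _setup_logging(level: int = logging.INFO) -> None:
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
        log.addHandler(handler)
    log.setLevel(level)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns a result bundle of key tables.

    Every output directory gets a ``run_manifest.json`` recording the
    config hash, seed, package version and per-stage probe counts.
    """
    _setup_logging()
    config.validate()
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    results: dict = {}

    # ------------------------------------------------------------ inputs
    if config.simulate:
        log.info("simulating dataset (%d probes, seed %d)",
                 config.sim.n_probes, config.sim.seed)
        manifest = generate_manifest(config.sim)
        beta, sheet, truth, companions = generate_dataset(config.sim, manifest)
        write_table(manifest, outdir / "manifest.tsv")
        write_table(beta, outdir / "beta.tsv")
        write_table(companions["detection_p"], outdir / "detection_p.tsv")
        write_table(companions["bead_count"], outdir / "bead_count.tsv")
        write_table(sheet, outdir / "sample_sheet.tsv", index_label="sample_id")
        write_table(truth, outdir / "truth.tsv")
        results["truth"] = truth
    else:
        manifest, beta, sheet, companions = load_tables(
            config.manifest, config.beta, config.sample_sheet,
            detp_path=config.detection_p, beads_path=config.bead_count)
    counts["input_probes"] = len(beta)
    results.update(manifest=manifest, sheet=sheet)

    # ---------------------------------------------------------------- QC
    if config.run_qc:
        cross = None
        if config.cross_reactive:
            cross = set(Path(config.cross_reactive).read_text().split())
        beta, qc_report = qc_filter(
            beta, manifest,
            detection_p=companions.get("detection_p"),
            bead_count=companions.get("bead_count"),
            detp_threshold=config.detp_threshold, min_beads=config.min_beads,
            cross_reactive_ids=cross)
        log.info("QC: %d probes retained (%s)", qc_report.n_retained,
                 qc_report.to_dict())
        counts.update({f"qc_{k}": v for k, v in qc_report.to_dict().items()})
        results["qc_report"] = qc_report

    # -------------------------------------------------------- normalize
    if config.run_quantile_norm:
        beta = quantile_normalize(beta)
        log.info("quantile normalization done")
    if config.run_bmiq:
        beta, bmiq_diag = probe_type_correct(beta, manifest)
        write_table(bmiq_diag, outdir / "bmiq_diagnostics.tsv",
                    index_label="sample_id")
        log.info("probe-type correction done (%d samples)", len(bmiq_diag))
    write_table(beta, outdir / "beta_normalized.tsv")
    results["beta"] = beta
    m = beta_to_m(beta, eps=config.m_eps)
    counts["analysis_probes"] = len(beta)

    # --------------------------------------------- treatment contrasts
    # one joint model over both timepoints: residual variance is pooled
    # across all bulk samples while each timepoint keeps its own contrast
    spec = DesignSpec(factor="treatment", contrast=("TGFB", "control"),
                      covariates=("cell_line",), per_timepoint_effects=True)
    sub_sheet = spec.select_samples(sheet)
    sv = None
    if config.run_sva:
        base = spec.build(sub_sheet)
        sv = estimate_surrogates(m, base, max_k=config.max_surrogates,
                                 seed=config.seed)
        log.info("SVA: %d surrogate(s)", sv.shape[1])
    dmp = {}
    for tp in ("T4", "T8"):
        model = ModeratedLinearModel.from_sample_sheet(m, sheet, spec,
                                                       surrogates=sv,
                                                       timepoint=tp)
        res = model.fit(trend=True)
        dmp[tp] = res
        write_table(res.to_frame(), outdir / f"dmp_{tp}.tsv")
        log.info("contrast %s: %d probes with q < %.2g", tp,
                 len(res.significant(config.q_max)), config.q_max)
        counts[f"dmp_{tp}_q_lt_{config.q_max}"] = len(res.significant(config.q_max))
    results["dmp"] = dmp

    deltas = group_delta_beta(beta, sheet)
    write_table(deltas, outdir / "delta_beta.tsv")
    results["deltas"] = deltas

    # ----------------------------------------------------- signature(s)
    sig = build_tgfb_signature(dmp["T4"].to_frame(), dmp["T8"].to_frame(),
                               deltas, q_max=config.q_max,
                               delta_min=config.delta_min_tgfb)
    write_table(sig.to_frame(), outdir / "signature_tgfb.tsv")
    log.info("persistent signature: %d probes", len(sig))
    counts["signature_tgfb"] = len(sig)
    results["signature"] = sig

    cd_sig = None
    if config.run_cd133:
        frac_sheet = sheet[sheet["fraction"].isin(["neg", "pos"])]
        if frac_sheet.empty:
            raise ValueError("run_cd133 requested but no fraction samples present")
        m_frac = m[frac_sheet.index]
        blocked = BlockedAnovaModel(m_frac, frac_sheet["fraction"],
                                    frac_sheet["cell_line"]).fit()
        cd_deltas = group_delta_beta(beta[frac_sheet.index], frac_sheet,
                                     factor="fraction", contrast=("pos", "neg"),
                                     stratify_by=("cell_line",))
        cd_sig = build_cd133_signature(pd.Series(blocked.p, index=blocked.probe_ids),
                                       cd_deltas, p_max=config.p_max_cd133,
                                       delta_min=config.delta_min_cd133)
        write_table(cd_sig.to_frame(), outdir / "signature_cd133.tsv")
        counts["signature_cd133"] = len(cd_sig)
        log.info("CD133 signature: %d probes", len(cd_sig))
        universe_genes = set(manifest.loc[beta.index, "gene_symbol"]
                             .replace("", pd.NA).dropna().unique())
        ov, p_ov = signature_overlap_test(sig.genes(manifest) & universe_genes,
                                          cd_sig.genes(manifest) & universe_genes,
                                          universe_genes)
        results["signature_overlap"] = {"overlap": ov, "p": p_ov}
        counts["signature_overlap_genes"] = ov
        log.info("signature gene overlap: %d genes (p = %.3g)", ov, p_ov)
        results["cd133_signature"] = cd_sig

    # ---------------------------------------------------------------- DMR
    if config.run_dmr and len(sig):
        dmrs = call_dmrs(sig, manifest, max_gap=config.max_gap,
                         min_probes=config.min_probes)
        dmrs_to_table(dmrs).to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
        dmrs_to_bed(dmrs).to_csv(outdir / "dmrs.bed", sep="\t", index=False,
                                 header=False)
        counts["dmrs"] = len(dmrs)
        log.info("%d DMRs called", len(dmrs))
        results["dmrs"] = dmrs

    # --------------------------------------------------------- enrichment
    if config.run_enrichment and len(sig):
        context = tabulate_context(sig, manifest)
        context.to_csv(outdir / "context_distribution.tsv", sep="\t", index=False)
        enh = enhancer_enrichment(sig, manifest, n_draws=config.n_draws,
                                  seed=config.seed, universe=beta.index)
        gc = gc_comparison(sig, manifest, n_draws=min(config.n_draws, 200),
                           seed=config.seed, universe=beta.index)
        pd.DataFrame([enh.to_dict()]).to_csv(outdir / "enhancer_enrichment.tsv",
                                             sep="\t", index=False)
        pd.DataFrame([gc]).to_csv(outdir / "gc_comparison.tsv", sep="\t", index=False)
        results.update(context=context, enhancer=enh, gc=gc)
        log.info("enhancer fold %.2f (p = %.3g); GC p = %.3g",
                 enh.fold, enh.p_upper, gc["p"])

    if config.run_expression:
        if config.simulate:
            expr = generate_expression(results["truth"], manifest,
                                       coupling=0.5, seed=config.seed)
        else:
            expr = pd.read_csv(config.expression, sep="\t", index_col=0)
        corr = meth_expr_by_context(deltas[[c for c in deltas.columns
                                            if c != "overall"]].mean(axis=1),
                                    expr, manifest)
        corr.to_csv(outdir / "meth_expr_correlation.tsv", sep="\t", index=False)
        results["meth_expr"] = corr

    # ------------------------------------------------------ run manifest
    run_manifest = {
        "package": "stablemeth", "version": __version__,
        "config_hash": config.digest(), "seed": config.seed,
        "counts": counts, "elapsed_s": round(time.time() - t0, 2),
        "config": config.to_dict(),
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, sort_keys=True, default=str))
    results["run_manifest"] = run_manifest
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return results
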
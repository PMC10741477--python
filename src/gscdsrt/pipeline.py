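"""End-to-end driver: synthetic generation (optional) → dose–response
scoring → drug-level heterogeneity statistics → expression classification,
with every table written as TSV stamped with the config hash and seed."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dose_response as dr
from . import dss_analysis as da
from . import expression as ex
from . import synthetic as syn
from .config import RunConfig

log = logging.getLogger("gscdsrt")


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig,
                 index: bool = True) -> None:
    header = f"# gscdsrt config_hash={config.config_hash()} seed={config.seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def _load_groups(config: RunConfig, cultures) -> pd.Series:
    if config.groups_path:
        g = pd.read_csv(config.groups_path, sep="\t", comment="#",
                        names=["culture", "group"], header=0)
        return g.set_index("culture")["group"]
    # synthetic ids encode their group
    return pd.Series(
        {c: ("multiregional" if str(c).startswith("MR") else "reference")
         for c in cultures})


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the machine-readable summary.

    Any stage failure aborts with the stage name in the exception; tables
    written so far are left in place for inspection.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash()}
    stage = "setup"
    try:
        # ------------------------------------------------------------- screen
        stage = "screen_input"
        if config.plates_path:
            plates = syn.read_plates(config.plates_path)
            truth = None
        else:
            design = syn.ScreenDesign(
                n_multiregional=config.n_multiregional,
                n_reference=config.n_reference,
                n_drugs=config.n_drugs,
                doses_per_drug=config.doses_per_drug,
                dose_range=(config.dose_min, config.dose_max),
            )
            truth_cfg = syn.ScreenTruthConfig(
                intra_sd=config.intra_sd, inter_sd=config.inter_sd,
                noise_cv=config.noise_cv, dss_variant=config.dss_variant,
                dss_threshold=config.dss_threshold,
            )
            plates, truth = syn.make_screen(design, truth_cfg, seed=config.seed)
            syn.write_plates(plates, outdir / "plates.tsv")
            _write_table(truth.params, outdir / "screen_truth.tsv", config,
                         index=False)
        log.info("stage %s: %d plates", stage, len(plates))

        stage = "fit_screen"
        screen = dr.screen_to_dss(
            plates, mode=config.scaling_mode,
            threshold=config.dss_threshold, variant=config.dss_variant,
        )
        _write_table(screen.dss, outdir / "dss_matrix.tsv", config)
        _write_table(screen.auc, outdir / "auc_matrix.tsv", config)
        _write_table(screen.ic50, outdir / "ic50_matrix.tsv", config)

        stage = "groups"
        groups = _load_groups(config, screen.dss.index)
        mr_ids = sorted(groups.index[groups == "multiregional"])
        ref_ids = sorted(groups.index[groups == "reference"])

        stage = "sdss"
        sdss_mat = da.sdss(screen.dss, ref_ids)
        _write_table(sdss_mat, outdir / "sdss_matrix.tsv", config)

        stage = "responders"
        # responder drugs are defined on the multiregional cultures: DSS ≥
        # threshold in at least one of them
        responders = da.filter_responders(screen.dss.loc[mr_ids],
                                          config.responder_threshold)
        per_culture = da.filter_responders(
            screen.dss, config.responder_threshold, scope="per_culture")
        _write_table(per_culture.to_frame("n_responder_drugs"),
                     outdir / "responders_per_culture.tsv", config)
        summary["n_responder_drugs"] = len(responders)
        summary["responders_per_culture"] = {str(k): int(v)
                                             for k, v in per_culture.items()}

        stage = "correlation"
        corr, corr_summary = da.correlation_matrix(screen.dss.loc[mr_ids])
        _write_table(corr, outdir / "spearman_multiregional.tsv", config)
        summary["spearman_mean"] = round(corr_summary["mean"], 6)
        summary["spearman_sd"] = round(corr_summary["sd"], 6)

        stage = "variance_f_tests"
        ftests = da.variance_f_tests(screen.dss, ref_ids, mr_ids,
                                     alpha=config.alpha,
                                     fdr_method=config.fdr_method)
        _write_table(ftests, outdir / "variance_f_tests.tsv", config,
                     index=False)
        summary["n_variance_significant"] = int(ftests["significant"].sum())
        summary["n_variance_tested"] = int(len(ftests))

        stage = "delta"
        delta = da.delta_analysis(screen.dss, mr_ids, ref_ids)
        _write_table(delta, outdir / "delta_dss_sd.tsv", config)
        summary["delta_quadrant_counts"] = (
            delta["quadrant"].value_counts().sort_index().to_dict())

        stage = "clustering"
        if responders:
            clust = da.cluster_heatmap(
                screen.dss, drug_filter=responders,
                metric=config.cluster_metric, method=config.cluster_method)
            _write_table(clust.ordered, outdir / "cluster_ordered_dss.tsv", config)
            (outdir / "cluster_cultures.nwk").write_text(clust.row_newick + "\n")
            (outdir / "cluster_drugs.nwk").write_text(clust.col_newick + "\n")

        stage = "pca"
        scores, evr = da.pca_view(screen.dss, log_transform=True,
                                  pseudo=config.pca_pseudo)
        _write_table(scores.round(9), outdir / "pca_scores.tsv", config)
        summary["pca_explained_variance"] = [round(float(v), 6) for v in evr[:3]]
        summary["pca_n_drugs_used"] = int(scores.attrs["n_drugs_used"])

        # --------------------------------------------------------- expression
        if config.expression_path or config.run_expression:
            stage = "expression_input"
            if config.expression_path:
                expr = syn.read_expression(config.expression_path)
            else:
                expr, expr_truth = syn.make_expression(
                    n_genes=config.n_genes, n_samples=config.n_samples,
                    seed=config.seed)
                syn.write_expression(expr, outdir / "expression_tpm.tsv")

            stage = "expression_filter"
            kept, reasons = ex.filter_genes(expr)
            stage = "expression_mixture"
            log_sd = ex.dispersion(kept)
            fit = ex.fit_mixture(log_sd, seed=config.seed)
            stage = "expression_classify"
            classes = ex.classify(fit, threshold=config.mixture_threshold,
                                  filter_reason=reasons)
            _write_table(classes, outdir / "gene_classification.tsv", config)
            (outdir / "mixture_fit.json").write_text(json.dumps({
                "means": fit.means.tolist(), "sds": fit.sds.tolist(),
                "weights": fit.weights.tolist(),
                "log_likelihood": fit.log_likelihood,
                "n_iter": fit.n_iter, "converged": fit.converged,
            }, indent=2))
            counts = classes["label"].value_counts().to_dict()
            summary["gene_counts"] = {k: int(counts.get(k, 0)) for k in ex.LABELS}
        else:
            log.info("no expression input configured; expression stages skipped")
            summary["gene_counts"] = None
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
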
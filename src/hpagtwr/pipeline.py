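"""End-to-end pipeline: simulate/ingest -> lexicon -> score -> fit -> report.

Stage order mirrors the analysis workflow: obtain documents and covariates,
build the health lexicon (embedding expansion from seeds), score the policy
attention index per (city, year), test for spatial autocorrelation, fit the
OLS baseline and the CV-calibrated GTWR, and emit summary tables. Every
artifact lands in the run directory together with a manifest recording the
config hash, the global seed, per-stage seeds and timings, and content
hashes of all inputs and outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as diag
from . import gtwr, io, lexicon as lex, scoring, synth
from .config import PipelineConfig, stage_seed
from .errors import ConfigurationError, HpagtwrError

__all__ = ["run_pipeline", "PipelineResult"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    run_dir: Path
    panel: gtwr.CityPanel
    lexicon: lex.Lexicon | None
    scored: pd.DataFrame | None
    ols: gtwr.OLSFit
    fit: gtwr.GTWRFit
    report: diag.DiagnosticsReport
    manifest: dict = field(default_factory=dict)


def _auto_bandwidth_range(panel: gtwr.CityPanel, lambda_s: float, mu_t: float
                          ) -> tuple[float, float, float]:
    d2 = gtwr._st_distance_matrix(panel, lambda_s, mu_t)
    dmax = float(np.sqrt(d2.max()))
    return dmax / 100.0, 2.0 * dmax, dmax / 200.0


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute the full pipeline into ``out_dir``.

    Deterministic stages are bit-identical across reruns with the same
    config; a failing stage aborts with its name, keeping partial outputs.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.content_hash(),
                      "seed": config.seed, "stages": [], "inputs": {},
                      "outputs": []}
    timings = manifest["stages"]

    current_stage = "init"

    def _stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("stage %s", name)
        return time.perf_counter()

    def _done(name, t0):
        timings.append({"stage": name,
                        "seed": stage_seed(config.seed, name),
                        "seconds": round(time.perf_counter() - t0, 3)})

    def _out(path: Path):
        manifest["outputs"].append({"path": path.name,
                                    "sha256": io.file_sha256(path)})

    gen = config.generator
    seeds_words: list[str] = []
    synonyms: list[str] = []
    cooc: list[list[str]] | None = None
    scored = None
    lexicon_obj: lex.Lexicon | None = None

    try:
        # ---------------- simulate / ingest ----------------
        t0 = _stage("simulate" if config.mode == "simulate" else "ingest")
        if config.mode == "simulate":
            grid = synth.generate_city_grid(
                gen["n_cities"], gen["extent_km"],
                stage_seed(config.seed, "grid"))
            surfaces = synth.study_hpa_surfaces(
                grid, gen["extent_km"], gen["noise_sd"])
            panel_df, truth = synth.generate_panel(
                grid, gen["years"], surfaces, synth.STUDY_COVARIATES,
                stage_seed(config.seed, "panel"))
            covars = [c.name for c in synth.STUDY_COVARIATES]
            health_vocab = [f"health{i}" for i in range(gen["n_health_words"])]
            filler_vocab = [f"filler{i}" for i in range(gen["n_filler_words"])]
            seeds_words = health_vocab[: gen["n_seed_words"]]
            synonyms = health_vocab[gen["n_seed_words"]:]
            targets = np.clip(panel_df["y"].to_numpy(), 0.0, 100.0)
            docs = synth.generate_corpus(
                panel_df, targets, gen["doc_length"], health_vocab,
                filler_vocab, stage_seed(config.seed, "corpus"))
            cooc = synth.generate_cooccurrence_corpus(
                seeds_words, synonyms, filler_vocab[:20],
                gen["cooccurrence_sentences"],
                stage_seed(config.seed, "cooccurrence"))
            panel = gtwr.CityPanel(panel_df, covars)
            io.write_panel(panel, run_dir / "panel.csv"); _out(run_dir / "panel.csv")
            truth.to_csv(run_dir / "truth.csv", index=False); _out(run_dir / "truth.csv")
            io.write_corpus(docs, run_dir / "corpus.jsonl"); _out(run_dir / "corpus.jsonl")
        else:
            for key, p in config.paths.items():
                manifest["inputs"][key] = io.file_sha256(p)
            panel = io.read_panel(config.paths["panel"])
            docs = None
            if "corpus" in config.paths:
                docs, _ = io.read_corpus(config.paths["corpus"])
            if "seed_lexicon" in config.paths:
                seeds_words = lex.Lexicon.load_words(config.paths["seed_lexicon"])
        _done("simulate" if config.mode == "simulate" else "ingest", t0)

        # ---------------- lexicon ----------------
        if config.mode == "simulate" and cooc is not None:
            t0 = _stage("lexicon")
            emb = lex.train_embeddings(
                cooc, seed=stage_seed(config.seed, "cbow"), **config.cbow)
            candidates = lex.expand_seed_set(
                emb, seeds_words, top_k=config.expansion["top_k"],
                min_similarity=config.expansion["min_similarity"])
            # curation: the accept list stands in for expert review; in
            # simulate mode the generator's health vocabulary plays the
            # expert, rejecting candidates that are not truly health words
            accept = [w for w, _, _ in candidates if w in set(health_vocab)]
            lexicon_obj = lex.curate_lexicon(seeds_words, candidates, accept)
            logger.info("lexicon: %d/%d planted synonyms recovered",
                        len(accept), len(synonyms))
            emb.save_word2vec_text(run_dir / "embeddings.w2v.txt")
            _out(run_dir / "embeddings.w2v.txt")
            lexicon_obj.save(run_dir / "lexicon.txt"); _out(run_dir / "lexicon.txt")
            pd.DataFrame(candidates,
                         columns=["word", "score", "nearest_seed"]).to_csv(
                run_dir / "candidates.csv", index=False)
            _out(run_dir / "candidates.csv")
            _done("lexicon", t0)
        elif config.mode == "ingest" and seeds_words:
            lexicon_obj = lex.curate_lexicon(seeds_words, [], [])

        # ---------------- score + merge ----------------
        if docs is not None and lexicon_obj is not None:
            t0 = _stage("score")
            keys = [(int(c), int(t)) for c, t in
                    panel.data[["city_id", "t"]].itertuples(index=False)]
            scored, missing = scoring.score_corpus(
                docs, lexicon_obj, expected_keys=keys)
            if missing:
                logger.warning("%d panel keys lack documents: %s...",
                               len(missing), missing[:5])
            scored.to_csv(run_dir / "hpa_scores.csv", index=False)
            _out(run_dir / "hpa_scores.csv")
            merged = panel.data.merge(
                scored.rename(columns={"year": "t"}), on=["city_id", "t"],
                how="inner")
            merged["y"] = merged.pop("hpa")
            panel = gtwr.CityPanel(merged, panel.covariates)
            _done("score", t0)

        # ---------------- diagnostics (pre-fit) ----------------
        t0 = _stage("diagnostics")
        dcfg = config.diagnostics
        city_means = (panel.data.groupby("city_id")
                      .agg(u=("u", "first"), v=("v", "first"), y=("y", "mean")))
        Wmat = diag.build_spatial_weights(
            city_means[["u", "v"]].to_numpy(), "knn", k=dcfg["knn_k"])
        mi, mi_p = diag.morans_i_pvalue(
            city_means["y"].to_numpy(), Wmat, n_perm=dcfg["n_perm"],
            seed=stage_seed(config.seed, "moran"))
        _done("diagnostics", t0)

        # ---------------- fit ----------------
        t0 = _stage("fit")
        kcfg = config.kernel
        lambda_s = kcfg["lambda_s"]
        mu_t = kcfg["mu_t"]
        if mu_t is None:
            mu_t = gtwr.default_temporal_scale(panel)
        ols = gtwr.fit_ols(panel)
        if kcfg["bandwidth"] == "auto":
            lo, hi, tol = _auto_bandwidth_range(panel, lambda_s, mu_t)
            lo = kcfg["lo"] or lo
            hi = kcfg["hi"] or hi
            tol = kcfg["tol"] or tol
            h_star, cv_curve = gtwr.select_bandwidth(
                panel, lambda_s, mu_t, lo=lo, hi=hi, tol=tol,
                kernel=kcfg["kernel"])
        else:
            h_star, cv_curve = float(kcfg["bandwidth"]), []
        fit = gtwr.fit_gtwr(panel, gtwr.STKernelParams(
            h=h_star, lambda_s=lambda_s, mu_t=mu_t, kernel=kcfg["kernel"]))
        fit.local_table().to_csv(run_dir / "local_coefficients.csv", index=False)
        _out(run_dir / "local_coefficients.csv")
        io.write_coefficients_geojson(fit, run_dir / "local_coefficients.geojson")
        _out(run_dir / "local_coefficients.geojson")
        summary = {"gtwr": fit.summary_dict(),
                   "ols": {"aicc": ols.aicc, "adj_r2": ols.adj_r2,
                           "coefficients": dict(zip(ols.var_names,
                                                    ols.coefficients))},
                   "cv_curve": cv_curve}
        io.write_report(summary, run_dir / "fit_summary.json")
        _out(run_dir / "fit_summary.json")
        _done("fit", t0)

        # ---------------- report ----------------
        t0 = _stage("report")
        report = diag.DiagnosticsReport(
            morans_i=mi, morans_p=mi_p, n_perm=dcfg["n_perm"],
            seed=stage_seed(config.seed, "moran"),
            nonstationarity=diag.nonstationarity_test(fit, ols),
            coefficient_summary=diag.summarize_coefficients(fit),
            period_averages=diag.period_average_coefficients(
                fit, dcfg["split_year"]))
        io.write_report(report.to_dict(), run_dir / "diagnostics.json")
        _out(run_dir / "diagnostics.json")
        report.coefficient_summary.to_csv(run_dir / "coefficient_summary.csv")
        _out(run_dir / "coefficient_summary.csv")
        report.period_averages.to_csv(run_dir / "period_averages.csv")
        _out(run_dir / "period_averages.csv")
        _done("report", t0)
    except HpagtwrError as exc:
        raise ConfigurationError(
            f"pipeline failed in stage {current_stage!r}: {exc}") from exc

    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return PipelineResult(run_dir=run_dir, panel=panel, lexicon=lexicon_obj,
                          scored=scored, ols=ols, fit=fit, report=report,
                          manifest=manifest)
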
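"""End-to-end orchestration, run manifests, and evaluation against truth.

``run_all`` executes the full chain — optional simulation, usage
computation, expression filtering, DTU and DTE testing, switch
identification, quantification, and prioritization — writing each stage's
table before the next begins. For the built-in statistical paths every
stage is a pure function of (inputs, config, seed), so a rerun with the
same configuration reproduces every TSV byte for byte; only the JSON run
manifest carries timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression, io, prioritize, quantify, simulate, switches as sw_mod, usage
from .config import AnalysisConfig

logger = logging.getLogger(__name__)


def _tool_version() -> str:
    try:
        return pkg_version("switchquant")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_run_config(path: str | Path) -> dict:
    """Load and validate the YAML run configuration.

    Top-level keys: ``config`` (AnalysisConfig fields), and either
    ``inputs`` (tpm, counts, tx2gene, samples paths) or ``simulate``
    (ScenarioSpec fields, with ``planted`` as a list of PlantedSwitch
    fields and optional ``cohorts`` as a list of cohort names).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "inputs" not in raw and "simulate" not in raw:
        raise ValueError("run config needs an 'inputs' or a 'simulate' block")
    if "inputs" in raw:
        required = {"tpm", "counts", "tx2gene", "samples"}
        missing = required - set(raw["inputs"])
        if missing:
            raise ValueError(f"inputs block missing paths: {sorted(missing)}")
        for key, p in raw["inputs"].items():
            if not Path(p).exists():
                raise ValueError(f"input file for {key!r} does not exist: {p}")
    return raw


def scenario_from_config(block: dict, seed: int | None = None) -> tuple[
    simulate.ScenarioSpec, list[str] | None
]:
    block = dict(block)
    cohorts = block.pop("cohorts", None)
    planted_raw = block.pop("planted", [])
    plant_all = block.pop("plant", None)
    if seed is not None:
        block["seed"] = seed
    if "isoforms_per_gene" in block:
        block["isoforms_per_gene"] = tuple(block["isoforms_per_gene"])
    spec = simulate.ScenarioSpec(
        planted=[simulate.PlantedSwitch(**p) for p in planted_raw], **block
    )
    if plant_all:
        planted = []
        start = 0
        for entry in plant_all:
            entry = dict(entry)
            n = entry.pop("n")
            planted += simulate.plant_switches(spec, n, start_gene=start, **entry)
            start += n
        spec = dataclasses.replace(spec, planted=planted)
    return spec, cohorts


def run_all(
    config_path: str | Path,
    outdir: str | Path,
    seed: int | None = None,
) -> dict:
    """Execute the full pipeline; returns the run manifest as a dict."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw = load_run_config(config_path)
    config = AnalysisConfig.from_dict(raw.get("config", {}))
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)

    manifest: dict = {
        "tool_version": _tool_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "stages": {},
        "input_digests": {},
    }

    if "simulate" in raw:
        spec, cohorts = scenario_from_config(raw["simulate"], seed=config.seed)
        logger.info("simulating cohort(s): %s genes, seed %d", spec.n_genes,
                    spec.seed)
        if cohorts:
            counts, tpm, annotation, samples, truth = simulate.generate_cohorts(
                spec, cohorts
            )
        else:
            counts, tpm, annotation, samples, truth = simulate.generate_cohort(spec)
        io.write_expression_matrix(counts, outdir / "counts.tsv")
        io.write_expression_matrix(tpm, outdir / "tpm.tsv")
        io.write_tx2gene(annotation, outdir / "tx2gene.tsv")
        io.write_sample_sheet(samples, outdir / "samples.tsv")
        io.write_table(truth, outdir / "truth.tsv")
        manifest["stages"]["simulate"] = {
            "n_transcripts": counts.shape[0],
            "n_samples": counts.shape[1],
            "n_planted": int(len(truth)),
        }
    else:
        paths = {k: Path(v) for k, v in raw["inputs"].items()}
        tpm = io.read_expression_matrix(paths["tpm"], kind="tpm")
        counts = io.read_expression_matrix(paths["counts"], kind="counts")
        annotation = io.read_tx2gene(paths["tx2gene"])
        samples = io.read_sample_sheet(paths["samples"])
        tpm, counts, annotation, samples = io.align_inputs(
            tpm, counts, annotation, samples
        )
        truth = None
        manifest["input_digests"] = {k: _digest(p) for k, p in paths.items()}

    usage_matrix = usage.compute_usage(tpm, annotation)
    io.write_table(usage_matrix.rename_axis("transcript_id"),
                   outdir / "usage.tsv", index=True)
    manifest["stages"]["usage"] = {"n_transcripts": int(len(usage_matrix))}
    logger.info("usage computed for %d transcripts", len(usage_matrix))

    cohorts_present = sorted(samples["cohort"].unique())
    if config.filter_per_cohort:
        kept_per_cohort = {
            c: usage.filter_transcripts(counts, samples, c)
            for c in cohorts_present
        }
    else:
        pooled = samples.copy()
        pooled["cohort"] = "__all__"
        kept_all = usage.filter_transcripts(counts, pooled, "__all__")
        kept_per_cohort = {c: kept_all for c in cohorts_present}
    manifest["stages"]["filter"] = {
        c: len(kept_per_cohort[c]) for c in cohorts_present
    }
    logger.info("expression filter kept %s transcripts per cohort",
                manifest["stages"]["filter"])

    dtu = usage.run_dtu(usage_matrix, annotation, samples, kept_per_cohort, config)
    io.write_table(dtu, outdir / "dtu_results.tsv")
    manifest["stages"]["dtu"] = {"n_tests": int(len(dtu))}

    dte = expression.run_dte(tpm, annotation, samples, kept_per_cohort, config)
    io.write_table(dte, outdir / "dte_results.tsv")
    manifest["stages"]["dte"] = {"n_tests": int(len(dte))}

    switch_tbl = sw_mod.identify_switches(dtu, config)
    io.write_table(switch_tbl, outdir / "switches.tsv")
    summary = sw_mod.summarize_switches(switch_tbl)
    manifest["stages"]["switches"] = summary
    logger.info("identified %d switches (%d genes, %d unique pairs)",
                summary["n_switches"], summary["n_unique_genes"],
                summary["n_unique_pairs"])

    quantified = quantify.classify_switches(switch_tbl, dte)
    quantified = quantify.switch_frequencies(quantified, tpm, samples)
    io.write_table(quantified, outdir / "switches_quantified.tsv")
    io.write_table(quantify.class_summary(quantified),
                   outdir / "class_summary.tsv")
    io.write_table(quantify.frequency_curve(quantified),
                   outdir / "frequency_curve.tsv")
    transcript_results = quantify._switch_transcript_table(quantified, dtu, dte)
    battery_parts = []
    strat = quantify.stratify_by_expression(
        transcript_results, tpm, samples, config.low_expression_tpm
    )
    if len(strat):
        strat.insert(0, "analysis", "expression_stratification")
        battery_parts.append(strat)
    corr = quantify.expression_effect_correlation(transcript_results, tpm, samples)
    if len(corr):
        corr.insert(0, "analysis", "expression_effect_correlation")
        battery_parts.append(corr)
    comps = quantify.cohort_comparisons(quantified, transcript_results)
    if len(comps):
        comps.insert(0, "analysis", "cohort_comparisons")
        battery_parts.append(comps)
    battery = (
        pd.concat(battery_parts, ignore_index=True)
        if battery_parts else pd.DataFrame()
    )
    io.write_table(battery, outdir / "stats_battery.tsv")
    manifest["stages"]["quantify"] = {
        "n_switches": int(len(quantified)),
        "class_counts": quantified["concordance_class"].value_counts().to_dict()
        if len(quantified) else {},
    }

    report = prioritize.filter_chain(quantified, config)
    io.write_table(report.ranked, outdir / "prioritized.tsv")
    report.to_json(outdir / "filter_report.json")
    manifest["stages"]["prioritize"] = {
        "stages": report.stages,
        "n_final": int(len(report.ranked)),
    }
    logger.info("prioritization: %s", [s["n_out"] for s in report.stages])

    if truth is not None:
        metrics = evaluate_against_truth(quantified, truth, seed=config.seed)
        io.write_table(metrics, outdir / "evaluation.tsv")
        manifest["stages"]["evaluate"] = {
            row["metric"]: row["value"] for _, row in metrics.iterrows()
        }

    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S%z")
    manifest["elapsed_seconds"] = round(time.time() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _expected_frequencies(
    truth_row: pd.Series, dispersion: float, n_draws: int = 4000,
    seed: int = 0,
) -> tuple[float, float]:
    """Simulation-based expectation of the characteristic frequencies.

    Draws independent negative-binomial counts around the planted expected
    expressions (proportional to expected TPM; the normalization constant
    cancels from the order comparison) and estimates the probability that
    the cancer transcript out-expresses the normal transcript in a cancer
    sample, and the reverse in a normal sample. Ties count as not-higher,
    matching the frequency definition.
    """
    rng = np.random.default_rng([seed, 3])

    def draw(mean_tpm: float) -> np.ndarray:
        mean = mean_tpm / 1e6 * 2_000_000
        if not np.isfinite(dispersion):
            return np.full(n_draws, mean)
        p = dispersion / (dispersion + mean)
        return rng.negative_binomial(dispersion, p, size=n_draws).astype(float)

    c_in_cancer = draw(truth_row["exp_tpm_cancer_tx_cancer"])
    n_in_cancer = draw(truth_row["exp_tpm_normal_tx_cancer"])
    c_in_normal = draw(truth_row["exp_tpm_cancer_tx_normal"])
    n_in_normal = draw(truth_row["exp_tpm_normal_tx_normal"])
    f_cancer = float((c_in_cancer > n_in_cancer).mean())
    f_normal = float((n_in_normal > c_in_normal).mean())
    return f_cancer, f_normal


def evaluate_against_truth(
    detected: pd.DataFrame,
    truth: pd.DataFrame,
    dispersion: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Score detected switches against the generator's planted ledger.

    A detected switch matches a planted one when (cohort, gene, ordered
    transcript pair) agree. Sensitivity is matched/planted; the observed
    switch-level FDR is unmatched/detected. Classification accuracy is the
    share of matched switches whose concordance class equals the planted
    pair's expectation-implied class. When the detected table carries
    frequencies, the RMSE of the combined frequency against a
    simulation-based expectation under the generator's count model is also
    reported.
    """
    key = ["cohort", "gene_id", "cancer_tx", "normal_tx"]
    rows = []
    n_planted = len(truth)
    n_detected = len(detected)
    if n_detected:
        merged = detected.merge(truth, on=key, how="left", suffixes=("", "_truth"))
        matched = merged["expected_class"].notna()
    else:
        merged = detected.copy()
        matched = pd.Series(dtype=bool)
    n_matched = int(matched.sum()) if n_detected else 0
    rows.append({"metric": "n_planted", "value": float(n_planted)})
    rows.append({"metric": "n_detected", "value": float(n_detected)})
    rows.append({"metric": "n_matched", "value": float(n_matched)})
    if n_planted:
        rows.append(
            {"metric": "sensitivity", "value": n_matched / n_planted}
        )
    if n_detected:
        rows.append(
            {"metric": "fdr", "value": (n_detected - n_matched) / n_detected}
        )
    if n_matched and "concordance_class" in detected.columns:
        sub = merged[matched]
        acc = float(
            (sub["concordance_class"] == sub["expected_class"]).mean()
        )
        rows.append({"metric": "classification_accuracy", "value": acc})
    if n_matched and "combined_freq" in detected.columns:
        sub = merged[matched]
        expected = np.array(
            [
                np.prod(_expected_frequencies(row, dispersion, seed=seed))
                for _, row in sub.iterrows()
            ]
        )
        rmse = float(np.sqrt(np.mean((sub["combined_freq"].to_numpy() - expected) ** 2)))
        rows.append({"metric": "combined_freq_rmse", "value": rmse})
    return pd.DataFrame(rows)
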
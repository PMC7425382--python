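"""End-to-end orchestration: simulate, analyse, sweep, report.

``run_simulate`` writes a synthetic cohort to disk; ``run_analyze``
takes a cohort (on disk or in memory) through preprocessing, threshold
selection, burst detection, spectral fitting, the group/session and
symptom models, the ROC suite and optionally the threshold sweep,
emitting tidy TSV tables plus a human-readable report. All randomness
derives from the master seed through named sub-seeds so stages are
individually reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .bursts import BurstDetector, default_k_grid, summarize_subject
from .classify import roc_suite, roc_table, threshold_sweep
from .config import groups_from_config, save_config, symptom_specs_from_config
from .datatypes import CohortDataset
from .preprocess import BetaEnvelopeTransformer
from .spectral import spectral_features
from .stats import (
    events_long_table,
    fit_feature_model,
    fit_rate_model,
    fit_symptom_models,
    summaries_to_frame,
)

logger = logging.getLogger("betabursts")

STAGE_SEEDS = {"simulate": 11, "stats": 23, "roc": 37}


def _stage_seed(master_seed: int, stage: str) -> int:
    # stable, documented scheme: one sub-stream per named stage
    return int(
        np.random.SeedSequence(
            entropy=int(master_seed), spawn_key=(STAGE_SEEDS[stage],)
        ).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunManifest:
    """Per-stage bookkeeping of a pipeline run."""

    stages: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, status: str, **info) -> None:
        self.stages[stage] = {"status": status, **info}

    def add_output(self, path: Path) -> None:
        self.outputs.append(str(path))

    def save(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {"stages": self.stages, "outputs": self.outputs, "warnings": self.warnings},
                indent=2,
            )
        )

    @property
    def failed(self) -> bool:
        return any(s.get("status") == "failed" for s in self.stages.values())


def run_simulate(config: dict, out_dir: str | Path) -> CohortDataset:
    """Generate the configured cohort and materialise it under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = _stage_seed(int(config["seed"]), "simulate")
    cohort = gen_cohort_from_config(config, seed)
    bio.write_cohort(cohort, out_dir, fmt=config["synth"].get("signal_format", "binary"))
    save_config(config, out_dir / "config.yaml")
    logger.info("simulated %d records into %s", len(cohort), out_dir)
    return cohort


def gen_cohort_from_config(config: dict, seed: int | None = None) -> CohortDataset:
    from .simulate import gen_cohort

    if seed is None:
        seed = _stage_seed(int(config["seed"]), "simulate")
    return gen_cohort(
        groups=groups_from_config(config),
        sessions=int(config["synth"]["sessions"]),
        seed=seed,
        symptom_specs=symptom_specs_from_config(config),
    )


def compute_envelopes(cohort: CohortDataset, config: dict):
    """Beta envelope for every record; returns (envelopes, errors)."""
    band = config["band"]
    transformer = BetaEnvelopeTransformer(
        low=band["low"],
        high=band["high"],
        trans_low=band["trans_low"],
        trans_high=band["trans_high"],
        edge_trim_s=config["envelope"]["edge_trim_s"],
    )
    envelopes = {}
    errors = []
    for row, ts in cohort.iter_records():
        key = (row["subject"], int(row["session"]))
        try:
            if ts is None:
                raise FileNotFoundError(f"no signal for {key}")
            envelopes[key] = transformer.fit(None).transform([ts])[0]
        except Exception as exc:  # noqa: BLE001
            errors.append(f"{key}: {exc}")
    return envelopes, errors


def run_analyze(
    config: dict,
    cohort: CohortDataset | str | Path,
    out_dir: str | Path,
    k_override: float | None = None,
) -> RunManifest:
    """Full analysis of a cohort; writes every result table under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    if not isinstance(cohort, CohortDataset):
        cohort = bio.read_cohort(cohort)
    save_config(config, out_dir / "config.yaml")

    # --- preprocessing -------------------------------------------------
    envelopes, errors = compute_envelopes(cohort, config)
    manifest.warnings.extend(errors)
    manifest.record(
        "preprocess",
        "failed" if not envelopes else "ok",
        n_records=len(envelopes),
        n_errors=len(errors),
    )
    if not envelopes:
        manifest.save(out_dir / "run_manifest.json")
        return manifest
    keys = list(envelopes)

    # --- threshold + burst detection ------------------------------------
    thr = config["threshold"]
    detector = BurstDetector(
        k=thr["k"] if k_override is None else k_override,
        k_min=thr["k_min"],
        k_max=thr["k_max"],
        k_step=thr["k_step"],
        segment_len_s=thr["segment_len_s"],
        center=thr["center"],
        threshold_mode=thr["mode"],
    )
    detector.fit([envelopes[k] for k in keys])
    events_per_key = dict(zip(keys, detector.transform([envelopes[k] for k in keys])))
    if detector.grid_ is not None:
        grid_df = pd.DataFrame(
            {
                "k": detector.grid_.k_values,
                "mean_r": detector.grid_.mean_r,
                "n_valid": detector.grid_.n_valid,
            }
        )
        _write(grid_df, out_dir / "threshold_grid.tsv", manifest)
    manifest.record("threshold", "ok", k_star=detector.k_)

    meta = {
        (row["subject"], int(row["session"])): row
        for _, row in cohort.manifest.iterrows()
    }
    summaries = [
        summarize_subject(
            events_per_key[key],
            envelopes[key],
            subject=key[0],
            group=meta[key]["group"],
            session=key[1],
        )
        for key in keys
    ]
    sdf = summaries_to_frame(summaries)
    _write(sdf, out_dir / "burst_summaries.tsv", manifest)
    events_rows = [
        {
            "subject": key[0],
            "session": key[1],
            "group": meta[key]["group"],
            "onset_s": ev.onset_s,
            "offset_s": ev.offset_s,
            "peak_time_s": ev.peak_time_s,
            "peak_amp": ev.peak_amp,
            "duration_ms": ev.duration_s * 1000.0,
        }
        for key in keys
        for ev in events_per_key[key]
    ]
    _write(pd.DataFrame(events_rows), out_dir / "burst_events.tsv", manifest)
    manifest.record("detect", "ok", n_events=len(events_rows))

    # --- spectral -------------------------------------------------------
    psd_cfg = config["psd"]
    spec_rows = []
    for row, ts in cohort.iter_records():
        key = (row["subject"], int(row["session"]))
        if ts is None:
            continue
        try:
            feats = spectral_features(
                ts,
                seg_len_s=psd_cfg["seg_len_s"],
                overlap=psd_cfg["overlap"],
                fmin=psd_cfg["fmin"],
                fmax=psd_cfg["fmax"],
            )
        except Exception as exc:  # noqa: BLE001
            manifest.warnings.append(f"spectral {key}: {exc}")
            continue
        spec_rows.append(
            {"subject": key[0], "session": key[1], "group": row["group"], **feats}
        )
    spec_df = pd.DataFrame(spec_rows)
    _write(spec_df, out_dir / "spectral_fits.tsv", manifest)
    manifest.record("spectral", "ok", n_records=len(spec_rows))

    # --- group/session models ------------------------------------------
    stats_seed = _stage_seed(int(config["seed"]), "stats")
    bootstrap_n = int(config["stats"]["bootstrap_n"])
    report_lines = []
    rate_result = fit_rate_model(sdf, bootstrap_n=bootstrap_n, seed=stats_seed)
    report_lines.append(_describe_model("Burst rate (Poisson)", rate_result))

    long = events_long_table(summaries)
    feature_results = {"rate": rate_result}
    for column, family, label in [
        ("duration_ms", "shifted_lognormal", "Burst duration (shifted lognormal)"),
        ("ibi_ms", "lognormal", "Inter-burst interval (lognormal)"),
        ("peak_amp", "shifted_lognormal", "Peak amplitude (shifted lognormal)"),
    ]:
        values = long[column].to_numpy(float)
        try:
            result = fit_feature_model(values, long, family=family)
            feature_results[column] = result
            report_lines.append(_describe_model(label, result))
        except Exception as exc:  # noqa: BLE001
            manifest.warnings.append(f"feature model {column}: {exc}")
    manifest.record("group_stats", "ok", n_models=len(feature_results))

    # --- symptom models -------------------------------------------------
    symptom_rows = []
    if cohort.clinical_scores is not None:
        try:
            effects = fit_symptom_models(
                sdf, cohort.clinical_scores, bootstrap_n=bootstrap_n, seed=stats_seed
            )
            for eff in effects:
                symptom_rows.append(
                    {
                        "factor": eff.factor,
                        "pct_change_per_10": eff.pct_change_per_10,
                        "ci_lo": eff.ci_lo,
                        "ci_hi": eff.ci_hi,
                        "p_prob": eff.p_prob,
                    }
                )
            report_lines.append(_describe_symptoms(effects))
        except Exception as exc:  # noqa: BLE001
            manifest.warnings.append(f"symptom models: {exc}")
    _write(
        pd.DataFrame(
            symptom_rows,
            columns=["factor", "pct_change_per_10", "ci_lo", "ci_hi", "p_prob"],
        ),
        out_dir / "symptom_effects.tsv",
        manifest,
    )
    manifest.record("symptoms", "ok", n_factors=len(symptom_rows))

    # --- ROC suite ------------------------------------------------------
    feature_table = sdf.merge(
        spec_df.drop(columns=["group"]), on=["subject", "session"], how="left"
    ) if not spec_df.empty else sdf
    roc_results = roc_suite(feature_table, criterion=config["roc"]["criterion"])
    _write(roc_table(roc_results), out_dir / "roc_table.tsv", manifest)
    manifest.record("roc", "ok", n_curves=len(roc_results))

    # --- threshold sweep ------------------------------------------------
    if config["sweep"]["enabled"]:
        k_grid = default_k_grid(thr["k_min"], thr["k_max"], config["sweep"]["k_step"])
        sweep_df = threshold_sweep(
            envelopes,
            cohort.manifest,
            k_grid=k_grid,
            center=thr["center"],
            threshold_mode=thr["mode"],
        )
        _write(sweep_df, out_dir / "threshold_sweep.tsv", manifest)
        manifest.record("sweep", "ok", n_thresholds=len(sweep_df))

    (out_dir / "report.txt").write_text("\n\n".join(report_lines) + "\n")
    manifest.add_output(out_dir / "report.txt")
    manifest.save(out_dir / "run_manifest.json")
    return manifest


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, sep="\t", index=False)
    manifest.add_output(path)


def _describe_model(label: str, result) -> str:
    lines = [label, "-" * len(label)]
    for name, c in result.contrasts.items():
        lines.append(
            f"{name}: {c['pct']:+.1f}% (95% CI {c['pct_ci_lo']:+.1f} to "
            f"{c['pct_ci_hi']:+.1f}), P = {c['p_prob']:.4g}"
        )
    for bf_name in ("bf_group", "bf_session", "bf_interaction"):
        bf = getattr(result, bf_name)
        if bf is not None:
            lines.append(f"{bf_name} = {bf:.3g}")
    return "\n".join(lines)


def _describe_symptoms(effects) -> str:
    lines = ["Symptom-score models (Poisson, % change per +10 bursts/min)", "-" * 40]
    for eff in effects:
        lines.append(
            f"{eff.factor}: {eff.pct_change_per_10:+.1f}% "
            f"(95% CI {eff.ci_lo:+.1f} to {eff.ci_hi:+.1f}), P = {eff.p_prob:.4g}"
        )
    return "\n".join(lines)
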
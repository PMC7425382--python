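"""Reading and writing signals, manifests and score tables.

Signals are stored either as single-column delimited text (one sample per
line) or as raw little-endian float64 binary with a JSON sidecar header
(`<name>.json` next to `<name>.f64`) recording ``fs`` and ``n_samples``.
Cohort manifests and clinical-score tables are TSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CohortDataset, TimeSeries

MANIFEST_COLUMNS = ["subject", "group", "session", "path", "truth_rate"]

SYMPTOM_FACTORS = [
    "midline_function",
    "rest_tremor",
    "rigidity",
    "bradykinesia",
    "postural_kinetic_tremor",
    "lower_limb_bradykinesia",
]


def write_signal(ts: TimeSeries, path: str | Path, fmt: str = "binary") -> Path:
    """Write a TimeSeries to disk.

    ``fmt='binary'`` writes raw little-endian float64 samples to
    ``<path>.f64`` plus a JSON sidecar; ``fmt='text'`` writes one sample
    per line to ``<path>`` as-is.
    """
    path = Path(path)
    if fmt == "text":
        np.savetxt(path, ts.samples, fmt="%.10g")
        return path
    if fmt == "binary":
        if path.suffix != ".f64":
            path = path.with_suffix(".f64")
        ts.samples.astype("<f8").tofile(path)
        sidecar = {"fs": ts.fs, "n_samples": int(ts.n_samples), "t0": ts.t0}
        path.with_suffix(".json").write_text(json.dumps(sidecar))
        return path
    raise ValueError(f"unknown signal format {fmt!r}")


def read_signal(path: str | Path, fs: float | None = None) -> TimeSeries:
    """Read a signal written by :func:`write_signal`.

    Text files need ``fs`` supplied; binary files carry it in the sidecar.
    """
    path = Path(path)
    if path.suffix == ".f64":
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing sidecar header {sidecar_path}")
        meta = json.loads(sidecar_path.read_text())
        samples = np.fromfile(path, dtype="<f8")
        if samples.size != int(meta["n_samples"]):
            raise ValueError(
                f"{path}: expected {meta['n_samples']} samples, found {samples.size}"
            )
        return TimeSeries(samples, fs=float(meta["fs"]), t0=float(meta.get("t0", 0.0)))
    if fs is None:
        raise ValueError("fs is required when reading single-column text signals")
    samples = np.loadtxt(path, ndmin=1)
    return TimeSeries(samples, fs=fs)


def write_manifest(cohort: CohortDataset, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in MANIFEST_COLUMNS if c in cohort.manifest.columns]
    cohort.manifest[cols].to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype={"subject": str})
    manifest["session"] = manifest["session"].astype(int)
    return manifest


def write_cohort(cohort: CohortDataset, out_dir: str | Path, fmt: str = "binary") -> Path:
    """Materialise a cohort on disk: signals, manifest, truth and scores."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig_dir = out_dir / "signals"
    sig_dir.mkdir(exist_ok=True)

    paths = []
    for row, ts in cohort.iter_records():
        key = (row["subject"], int(row["session"]))
        stem = sig_dir / f"{row['subject']}_ses{row['session']}"
        if ts is None:
            raise ValueError(f"no signal in memory for record {key}")
        written = write_signal(ts, stem, fmt=fmt)
        paths.append(str(written.relative_to(out_dir)))
    cohort.manifest = cohort.manifest.assign(path=paths)
    write_manifest(cohort, out_dir / "manifest.tsv")

    if cohort.truth_events:
        rows = []
        for (subject, session), events in cohort.truth_events.items():
            for onset_s, duration_s, amplitude, freq_hz in np.atleast_2d(
                events.reshape(-1, 4) if events.size else np.empty((0, 4))
            ):
                rows.append(
                    {
                        "subject": subject,
                        "session": session,
                        "onset_s": onset_s,
                        "duration_s": duration_s,
                        "amplitude": amplitude,
                        "freq_hz": freq_hz,
                    }
                )
        pd.DataFrame(
            rows,
            columns=["subject", "session", "onset_s", "duration_s", "amplitude", "freq_hz"],
        ).to_csv(out_dir / "truth_events.tsv", sep="\t", index=False)

    if cohort.clinical_scores is not None:
        cohort.clinical_scores.to_csv(out_dir / "clinical_scores.tsv", sep="\t", index=False)
    return out_dir


def read_cohort(out_dir: str | Path, load_signals: bool = True) -> CohortDataset:
    """Load a cohort directory written by :func:`write_cohort`."""
    out_dir = Path(out_dir)
    manifest = read_manifest(out_dir / "manifest.tsv")
    signals: dict[tuple[str, int], TimeSeries] = {}
    if load_signals:
        for _, row in manifest.iterrows():
            signals[(row["subject"], int(row["session"]))] = read_signal(
                out_dir / row["path"]
            )
    truth: dict[tuple[str, int], np.ndarray] = {}
    truth_path = out_dir / "truth_events.tsv"
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, sep="\t", dtype={"subject": str})
        for (subject, session), grp in tdf.groupby(["subject", "session"]):
            truth[(subject, int(session))] = grp[
                ["onset_s", "duration_s", "amplitude", "freq_hz"]
            ].to_numpy()
    scores = None
    scores_path = out_dir / "clinical_scores.tsv"
    if scores_path.exists():
        scores = read_clinical_scores(scores_path)
    return CohortDataset(
        manifest=manifest, signals=signals, truth_events=truth, clinical_scores=scores
    )


def read_clinical_scores(path: str | Path) -> pd.DataFrame:
    """Read a clinical-score TSV (subject, session, one column per factor)."""
    scores = pd.read_csv(path, sep="\t", dtype={"subject": str})
    scores["session"] = scores["session"].astype(int)
    return scores
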
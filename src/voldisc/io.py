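"""CSV bundle + JSON manifest serialization for simulated cohorts.

A dataset directory holds long-format tables with a ``subject`` column
(indifference.csv, choices.csv, predictions.csv, intervals.csv,
true_parameters.csv) and a manifest.json recording the design, seed
and generator settings.  Prices are rounded to £0.01 on write only.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from voldisc.inference import SubjectData

__all__ = ["save_cohort", "load_dataset", "load_manifest"]

_MONEY_COLS = {
    "x_report", "X", "x_immediate", "lower", "upper", "best_guess",
    "observed_price", "predicted_price", "guaranteed", "mean",
}


def _round_money(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for c in df.columns:
        if c in _MONEY_COLS:
            df[c] = df[c].round(2)
    return df


def save_cohort(records: Sequence, out_dir, manifest: dict | None = None) -> Path:
    """Write a list of SubjectRecords as a CSV bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {"indifference": [], "choices": [], "predictions": [], "intervals": []}
    truth = []
    for rec in records:
        truth.append({"subject": rec.subject_id, "seed": rec.seed, **rec.true_params})
        for name, df in (
            ("indifference", rec.data.indifference),
            ("choices", rec.data.choices),
            ("predictions", rec.predictions),
            ("intervals", rec.intervals),
        ):
            if df is not None and len(df):
                tables[name].append(df.assign(subject=rec.subject_id))
    for name, parts in tables.items():
        if parts:
            _round_money(pd.concat(parts, ignore_index=True)).to_csv(
                out / f"{name}.csv", index=False
            )
    pd.DataFrame(truth).to_csv(out / "true_parameters.csv", index=False)
    meta = {"n_subjects": len(records)}
    meta.update(manifest or {})
    with open(out / "manifest.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return out


def load_manifest(data_dir) -> dict:
    with open(Path(data_dir) / "manifest.json") as fh:
        return json.load(fh)


def load_dataset(data_dir) -> list[SubjectData]:
    """Read a CSV bundle back into per-subject data containers."""
    d = Path(data_dir)
    frames = {}
    for name in ("indifference", "choices"):
        p = d / f"{name}.csv"
        frames[name] = pd.read_csv(p) if p.exists() else None
    subjects: list[str] = []
    for df in frames.values():
        if df is not None:
            subjects.extend(df["subject"].unique())
    out = []
    for sid in sorted(dict.fromkeys(subjects)):
        kwargs = {}
        for name, df in frames.items():
            if df is not None:
                sub = df[df["subject"] == sid].drop(columns="subject")
                kwargs[name] = sub.reset_index(drop=True) if len(sub) else None
        out.append(SubjectData(subject_id=str(sid), **kwargs))
    return out
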
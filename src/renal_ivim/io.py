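"""Tabular file schemas and (de)serialization.

Interchange is plain CSV/JSON:

* ``signals.csv``  -- one row per (subject, ROI, measurement channel), with
  the relative signal under columns ``b0, b10, ..., b1000`` in ascending
  b order, plus ``subject_id``, ``roi_id`` and an optional ``model`` column
  naming the channel (``mono`` / ``biexp`` / ``stretched``).
* ``subjects.csv``, ``params_true.csv``, ``pathology.csv``, ``readers.csv``
  -- tidy cohort tables written by the generator.
* ``fitted.csv`` -- one row per fitted curve with the six parameters
  (diffusivities in 10^-3 mm^2/s on disk, per the reporting convention),
  residual sum of squares and convergence flags.

All floats are written with a fixed ``%.10g`` format so re-running a
pipeline with the same seed yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortConfig
from .fitting import FitConfig, SignalCurve, fit_all_models, _FITTERS
from .models import BValueScheme, DEFAULT_B_VALUES, DEFAULT_NEX

__all__ = [
    "SchemaError",
    "FLOAT_FMT",
    "write_csv",
    "write_cohort",
    "read_cohort_tables",
    "read_signals",
    "parse_signal_columns",
    "fit_signals_table",
    "write_config",
]

FLOAT_FMT = "%.10g"
ID_COLS = ("subject_id", "roi_id")

#: Columns of fitted.csv that hold diffusivities (scaled 1e3 on disk).
_DISPLAY_1E3 = ("adc", "d_slow", "d_fast", "ddc")


class SchemaError(ValueError):
    """A table does not match its documented schema."""


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def write_config(cfg, path) -> None:
    d = dataclasses.asdict(cfg)
    if "scheme" in d:
        d["scheme"] = {"b_values": list(d["scheme"]["b_values"]),
                       "nex": list(d["scheme"]["nex"])}
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def read_config(path) -> CohortConfig:
    d = json.loads(Path(path).read_text())
    scheme = d.pop("scheme", None)
    kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
    if scheme is not None:
        kwargs["scheme"] = BValueScheme(tuple(scheme["b_values"]),
                                        tuple(scheme["nex"]))
    return CohortConfig(**kwargs)


def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    """Write the generated cohort tables + config echo to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("subjects", cohort.subjects_df),
                     ("params_true", cohort.params_df),
                     ("signals", cohort.signals_df),
                     ("pathology", cohort.pathology_df),
                     ("readers", cohort.readers_df)):
        p = outdir / f"{name}.csv"
        write_csv(df, p)
        paths[name] = p
    write_config(cohort.config, outdir / "config.json")
    paths["config"] = outdir / "config.json"
    return paths


def read_cohort_tables(cohort_dir) -> dict[str, pd.DataFrame]:
    cohort_dir = Path(cohort_dir)
    out = {}
    for name in ("subjects", "params_true", "signals", "pathology", "readers"):
        p = cohort_dir / f"{name}.csv"
        if not p.exists():
            raise SchemaError(f"missing cohort table: {p.name}")
        out[name] = pd.read_csv(p)
    return out


def parse_signal_columns(columns) -> tuple[list[str], np.ndarray]:
    """Split a signals header into id columns and ascending b-value columns."""
    cols = list(columns)
    id_cols = [c for c in cols if c in (*ID_COLS, "model")]
    b_cols = [c for c in cols if c not in id_cols]
    for c in ID_COLS:
        if c not in id_cols:
            raise SchemaError(f"missing required column {c!r}")
    if not b_cols:
        raise SchemaError("no b-value columns found (expected b0, b10, ...)")
    b_vals = []
    for c in b_cols:
        if not c.startswith("b"):
            raise SchemaError(f"unrecognized column {c!r}: b-value columns "
                              "must be named like 'b200'")
        try:
            b_vals.append(float(c[1:]))
        except ValueError:
            raise SchemaError(f"column {c!r} is not a valid b-value column") from None
    b = np.asarray(b_vals)
    if np.any(np.diff(b) <= 0):
        raise SchemaError("b-value columns must be in strictly ascending order")
    if b[0] != 0:
        raise SchemaError("first b-value column must be b0")
    return b_cols, b


def read_signals(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"signals file {path} is empty")
    parse_signal_columns(df.columns)
    return df


def _scheme_for(b: np.ndarray) -> BValueScheme:
    if tuple(b) == tuple(float(x) for x in DEFAULT_B_VALUES):
        return BValueScheme.default()
    return BValueScheme(tuple(b), tuple([1] * len(b)))


def fit_signals_table(signals: pd.DataFrame,
                      cfg: FitConfig | None = None) -> pd.DataFrame:
    """Fit every row of a signals table; returns the fitted-parameters table.

    Rows carrying a ``model`` column are fitted with the matching model
    only; rows without one are fitted with all three.  Diffusivities in
    the returned table are in 10^-3 mm^2/s (display convention).
    """
    b_cols, b = parse_signal_columns(signals.columns)
    scheme = _scheme_for(b)
    rows = []
    has_model = "model" in signals.columns
    for _, rec in signals.iterrows():
        curve = SignalCurve(scheme, tuple(float(rec[c]) for c in b_cols))
        models = [rec["model"]] if has_model else list(_FITTERS)
        if has_model and rec["model"] not in _FITTERS:
            raise SchemaError(f"unknown model {rec['model']!r} in signals table")
        results = fit_all_models(curve, cfg) if not has_model else {
            rec["model"]: _FITTERS[rec["model"]](curve, cfg)
        }
        for model, res in results.items():
            row = {"subject_id": rec["subject_id"], "roi_id": rec["roi_id"],
                   "model": model,
                   "adc": np.nan, "d_slow": np.nan, "d_fast": np.nan,
                   "f": np.nan, "ddc": np.nan, "alpha": np.nan}
            p = res.params
            if p is not None:
                if model == "mono":
                    row["adc"] = p.adc * 1e3
                elif model == "biexp":
                    row["d_slow"] = p.d_slow * 1e3
                    row["d_fast"] = p.d_fast * 1e3
                    row["f"] = p.f
                else:
                    row["ddc"] = p.ddc * 1e3
                    row["alpha"] = p.alpha
            row["rss"] = res.rss
            row["converged"] = bool(res.converged)
            row["flags"] = ";".join(res.flags)
            rows.append(row)
    return pd.DataFrame(rows)


def fitted_to_subject_params(fitted: pd.DataFrame,
                             readers: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-ROI fitted values into per-subject, per-reader summaries.

    The fitted table (display units) is mapped back to internal units and,
    per parameter, each model's own channel supplies the value: ``mono``
    rows give ADC, ``biexp`` rows give d_slow/d_fast/f, ``stretched`` rows
    give DDC/alpha.  Reader ROI-placement factors from ``readers.csv`` are
    applied before averaging over ROIs.
    """
    chan = {"adc": ("mono", "adc", 1e-3),
            "adc_slow": ("biexp", "d_slow", 1e-3),
            "adc_fast": ("biexp", "d_fast", 1e-3),
            "f": ("biexp", "f", 1.0),
            "ddc": ("stretched", "ddc", 1e-3),
            "alpha": ("stretched", "alpha", 1.0)}
    out: pd.DataFrame | None = None
    for param, (model, col, scale) in chan.items():
        sub = fitted.loc[fitted["model"] == model,
                         ["subject_id", "roi_id", col]].copy()
        sub = sub.rename(columns={col: "value"})
        sub["value"] = sub["value"] * scale
        for reader in ("a", "b"):
            fac = readers.loc[readers["reader"] == reader,
                              ["subject_id", "roi_id", param]]
            fac = fac.rename(columns={param: "factor"})
            merged = sub.merge(fac, on=["subject_id", "roi_id"], how="left",
                               validate="1:1")
            if merged["factor"].isna().any():
                missing = merged.loc[merged["factor"].isna(), "subject_id"].unique()
                raise SchemaError(
                    "reader factors missing for subjects: "
                    + ", ".join(map(str, missing[:5]))
                )
            vals = (merged["value"] * merged["factor"]).groupby(
                merged["subject_id"]).mean()
            colname = f"{param}_reader_{reader}"
            piece = vals.rename(colname).reset_index()
            out = piece if out is None else out.merge(piece, on="subject_id")
    return out
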
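"""Readers, writers and run configuration.

File formats are deliberately plain: long-format fish records
(``date,tl_mm[,sl_mm,sex]``), otolith CSV
(``fish_id,date,tl_mm,annuli,reader1_age,reader2_age``), histogram CSV
(``month,bin_lower,bin_upper,count``) and a YAML run configuration that
reproduces a fit bit-for-bit together with its seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fit import FitResult, ModelSpec
from .growth import CalendarDate, GrowthParams
from .lfreq import BinGrid, LengthHistogram, SampleMonth
from .otolith import OtolithRecord
from .simulate import SyntheticScenario

__all__ = [
    "RunConfig",
    "read_records",
    "write_records",
    "read_otoliths",
    "write_histograms",
    "read_histograms",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "fit_to_json",
]


class RecordsError(ValueError):
    """Malformed records file, with row-level diagnostics."""


def read_records(path) -> pd.DataFrame:
    """Read fish length records, validating every row.

    Requires columns ``date`` (ISO) and ``tl_mm`` (> 0).  Bad rows are
    reported by 1-based data row number rather than silently dropped.
    """
    df = pd.read_csv(path)
    missing = {"date", "tl_mm"} - set(df.columns)
    if missing:
        raise RecordsError(f"{path}: missing columns {sorted(missing)}")
    problems = []
    dates = pd.to_datetime(df["date"], errors="coerce")
    tl = pd.to_numeric(df["tl_mm"], errors="coerce")
    for i in df.index[dates.isna()]:
        problems.append(f"row {i + 1}: unparseable date {df.loc[i, 'date']!r}")
    for i in df.index[tl.isna() | (tl <= 0)]:
        problems.append(f"row {i + 1}: invalid length {df.loc[i, 'tl_mm']!r}")
    if problems:
        raise RecordsError(f"{path}: " + "; ".join(problems[:20]))
    out = df.copy()
    out["date"] = dates
    out["tl_mm"] = tl
    out["month"] = dates.dt.strftime("%Y-%m")
    return out


def write_records(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("date", "tl_mm", "sl_mm", "sex", "age_class", "month") if c in df.columns]
    out = df[cols].copy()
    if np.issubdtype(out["date"].dtype, np.datetime64):
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_otoliths(path) -> list[OtolithRecord]:
    """Read otolith CSV; reader agreement is equality of the two reads."""
    df = pd.read_csv(path)
    required = {"fish_id", "date", "tl_mm", "annuli", "reader1_age", "reader2_age"}
    missing = required - set(df.columns)
    if missing:
        raise RecordsError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        dt = pd.to_datetime(row["date"])
        doy = min(int(dt.dayofyear), 365)
        records.append(
            OtolithRecord(
                fish_id=str(row["fish_id"]),
                capture_date=CalendarDate((doy - 1) / 365.0),
                total_length=float(row["tl_mm"]),
                annuli=int(row["annuli"]),
                reader_agreement=int(row["reader1_age"]) == int(row["reader2_age"]),
            )
        )
    return records


def write_histograms(hists: list[LengthHistogram], path) -> None:
    rows = []
    for h in hists:
        for lo, hi, c in zip(h.grid.lower_edges, h.grid.upper_edges, h.counts):
            rows.append({"month": h.month.label, "sample_time": h.month.sample_time,
                         "N_t": h.month.N_t, "bin_lower": lo, "bin_upper": hi,
                         "count": c})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_histograms(path) -> list[LengthHistogram]:
    df = pd.read_csv(path)
    hists = []
    for label, sub in df.groupby("month", sort=False):
        sub = sub.sort_values("bin_lower")
        width = float(sub["bin_upper"].iloc[0] - sub["bin_lower"].iloc[0])
        grid = BinGrid(width=width, n_bins=len(sub), start=float(sub["bin_lower"].iloc[0]))
        month = SampleMonth(str(label), float(sub["sample_time"].iloc[0]),
                            int(sub["N_t"].iloc[0]))
        hists.append(LengthHistogram(grid=grid, counts=sub["count"].to_numpy(float),
                                     month=month))
    return hists


# ---------------------------------------------------------------------------
# scenario / config serialization


def scenario_to_yaml(scenario: SyntheticScenario, path) -> None:
    doc = {
        "growth": {k: getattr(scenario.growth, k)
                   for k in ("L_inf", "K", "t0", "C", "t_s", "t_b")},
        "sigmas": list(scenario.sigmas),
        "months": [
            {"label": m.label, "sample_time": m.sample_time, "N_t": m.N_t,
             "year_index": m.year_index}
            for m in scenario.months
        ],
        "proportions": [list(p) for p in scenario.proportions],
        "seed": scenario.seed,
        "seasonal": scenario.seasonal,
        "birth_jitter_sd": scenario.birth_jitter_sd,
        "selectivity": list(scenario.selectivity) if scenario.selectivity else None,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def scenario_from_yaml(path) -> SyntheticScenario:
    doc = yaml.safe_load(Path(path).read_text())
    return SyntheticScenario(
        growth=GrowthParams(**doc["growth"]),
        sigmas=tuple(doc["sigmas"]),
        months=tuple(SampleMonth(**m) for m in doc["months"]),
        proportions=tuple(tuple(p) for p in doc["proportions"]),
        seed=int(doc.get("seed", 0)),
        seasonal=bool(doc.get("seasonal", True)),
        birth_jitter_sd=float(doc.get("birth_jitter_sd", 0.0)),
        selectivity=tuple(doc["selectivity"]) if doc.get("selectivity") else None,
    )


@dataclass
class RunConfig:
    """Everything needed to reproduce a fitting run."""

    records_csv: str | None = None
    otolith_csv: str | None = None
    output_dir: str = "lenage_out"
    grid_width: float = 10.0
    grid_n_bins: int = 46
    L_inf_fixed: float | None = 448.0
    objective: str = "multinomial"
    n_starts: int = 25
    seed: int = 0
    n_eff: int = 276

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]

    def grid(self) -> BinGrid:
        return BinGrid(width=self.grid_width, n_bins=self.grid_n_bins)

    def model_specs(self, n_months: int) -> dict[str, ModelSpec]:
        """The 2x2 candidate set (seasonal x variance structure)."""
        fixed = {"t0": 0.0}
        if self.L_inf_fixed is not None:
            fixed["L_inf"] = self.L_inf_fixed
        specs = {}
        for i, (seas, var) in enumerate(
            [(True, "variable"), (True, "fixed"), (False, "variable"), (False, "fixed")],
            start=1,
        ):
            specs[f"model_{i}"] = ModelSpec(
                seasonal=seas, variance_at_age=var, fixed_params=dict(fixed),
                grid=self.grid(), n_months=n_months, objective=self.objective,
            )
        return specs


def fit_to_json(fit: FitResult, path) -> None:
    doc = {
        "params": {k: getattr(fit.params, k)
                   for k in ("L_inf", "K", "t0", "C", "t_s", "t_b")},
        "sigmas": list(fit.sigmas),
        "proportions": [list(p.normalized()) for p in fit.proportions],
        "neg_log_lik": fit.neg_log_lik,
        "K_params": fit.K_params,
        "converged": fit.converged,
        "n_evals": fit.n_evals,
        "seasonal": fit.spec.seasonal,
        "variance_at_age": fit.spec.variance_at_age,
        "objective": fit.spec.objective,
    }
    Path(path).write_text(json.dumps(doc, indent=2))
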
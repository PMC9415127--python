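"""Data model, validation and CSV I/O for long-term-experiment (LTE) plot data.

An LTE maintains fixed fertiliser treatments on the same plots for decades.
The analysis needs, per site and year, the long-term fertilised plot (LT_N),
its never-fertilised control (LT_0N), and optionally two short-term
superimposed subplots: a first-season zero-N subplot (ST_0N_subplot) and a
:sup:`15`\\ N-labelled subplot (ST_15N_subplot). Observations are exchanged as
long-format CSV, one row per plot observation, with site-level co-variables
in a second file keyed by ``site_id``.
"""

from __future__ import annotations

import math
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .exceptions import DatasetValidationError, PairingError

__all__ = [
    "Crop",
    "Treatment",
    "Method",
    "PlotObservation",
    "CovariateSet",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "OBSERVATION_COLUMNS",
    "COVARIATE_COLUMNS",
]


class Crop(str, Enum):
    winter_wheat = "winter_wheat"
    spring_barley = "spring_barley"
    winter_barley = "winter_barley"
    maize = "maize"
    rotation = "rotation"


class Treatment(str, Enum):
    LT_N = "LT_N"  # long-term fertilised main plot
    LT_0N = "LT_0N"  # long-term zero-N control plot
    ST_0N_subplot = "ST_0N_subplot"  # one-season zero-N subplot in the LT_N plot
    ST_15N_subplot = "ST_15N_subplot"  # one-season 15N-labelled subplot


class Method(str, Enum):
    """How first-season recovery was estimated for a record."""

    isotope15N = "isotope15N"
    subplot = "subplot"
    direct_delta = "direct_delta"  # externally computed ΔRE, no RE parts


class PlotObservation(BaseModel):
    """One treatment x site x year record of N applied and N taken up.

    ``n_rate`` always carries the annual rate of the paired long-term
    fertilised plot, also on control rows (bookkeeping: the control itself
    received 0 N in the observation year). ``n15_rate``/``n15_uptake`` are
    present only on 15N subplots. ``n15_uptake`` may exceed ``n15_rate``
    (measurement noise) but may not be negative.
    """

    model_config = ConfigDict(frozen=True)

    site_id: str
    year: int
    crop: Crop
    treatment: Treatment
    n_rate: float = Field(ge=0)
    n15_rate: Optional[float] = Field(default=None, gt=0)
    n_uptake: float = Field(ge=0)
    n15_uptake: Optional[float] = Field(default=None, ge=0)
    n_field_reps: int = Field(default=1, ge=1)
    n_years_pooled: int = Field(default=1, ge=1)

    @property
    def key(self) -> tuple[str, int, Treatment]:
        return (self.site_id, self.year, self.treatment)


class CovariateSet(BaseModel):
    """Site-level co-variables entering the meta-model.

    Climate follows the Global Yield Gap Atlas triplet: growing degree days
    (°C·day), temperature seasonality (°C, SD of monthly means) and aridity
    index (annual precipitation / annual potential evapotranspiration).
    """

    model_config = ConfigDict(frozen=True)

    gdd: float
    temp_seasonality: float = Field(ge=0)
    aridity: float = Field(gt=0)
    crop: Crop
    duration_years: int = Field(ge=1)
    avg_n_rate: float = Field(ge=0)
    clay_pct: float = Field(ge=0, le=100)
    method: Method
    residue_retained: bool


class Dataset(BaseModel):
    """Validated collection of plot observations plus per-site co-variables."""

    observations: list[PlotObservation]
    covariates: dict[str, CovariateSet] = Field(default_factory=dict)

    def __eq__(self, other) -> bool:  # order-sensitive, exact
        return (
            isinstance(other, Dataset)
            and self.observations == other.observations
            and self.covariates == other.covariates
        )

    def check(self) -> None:
        """Raise :class:`PairingError` listing *all* pairing/uniqueness problems."""
        problems: list[str] = []
        seen: set[tuple[str, int, Treatment]] = set()
        for obs in self.observations:
            if obs.key in seen:
                problems.append(
                    f"duplicate (site_id, year, treatment) = "
                    f"({obs.site_id}, {obs.year}, {obs.treatment.value})"
                )
            seen.add(obs.key)
        by_group: dict[tuple[str, int], set[Treatment]] = {}
        for obs in self.observations:
            by_group.setdefault((obs.site_id, obs.year), set()).add(obs.treatment)
        for (site, year), treatments in sorted(by_group.items()):
            if Treatment.LT_N in treatments and Treatment.LT_0N not in treatments:
                problems.append(
                    f"site {site} year {year}: fertilised plot LT_N has no LT_0N control partner"
                )
            has_st = treatments & {Treatment.ST_0N_subplot, Treatment.ST_15N_subplot}
            if has_st and not {Treatment.LT_N, Treatment.LT_0N} <= treatments:
                names = ", ".join(sorted(t.value for t in has_st))
                problems.append(
                    f"site {site} year {year}: short-term subplot(s) {names} lack the "
                    f"long-term LT_N/LT_0N partner plots"
                )
        if problems:
            raise PairingError(problems)


OBSERVATION_COLUMNS = [
    "site_id",
    "year",
    "crop",
    "treatment",
    "n_rate",
    "n15_rate",
    "n_uptake",
    "n15_uptake",
    "n_field_reps",
    "n_years_pooled",
]

COVARIATE_COLUMNS = [
    "site_id",
    "gdd",
    "temp_seasonality",
    "aridity",
    "crop",
    "duration_years",
    "avg_n_rate",
    "clay_pct",
    "method",
    "residue_retained",
]

_OPTIONAL_FLOAT = {"n15_rate", "n15_uptake"}
_INT_FIELDS = {"year", "n_field_reps", "n_years_pooled", "duration_years"}


def _parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in {"true", "1", "yes"}:
        return True
    if v in {"false", "0", "no"}:
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def _fmt(value) -> str:
    """Format a cell: 6 significant digits for floats, '' for missing."""
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return f"{value:.6g}"
    if isinstance(value, Enum):
        return value.value
    return str(value)


def read_dataset(
    obs_path: str | Path,
    cov_path: str | Path | None = None,
    schema: Mapping[str, str] | None = None,
) -> Dataset:
    """Read and validate observations (and optionally co-variables) from CSV.

    Parameters
    ----------
    obs_path
        Long-format observations CSV (one row per plot observation).
    cov_path
        Optional site-level co-variable CSV keyed by ``site_id``.
    schema
        Optional map from canonical column names to the names used in the
        file, for ingesting differently labelled exports.

    Raises
    ------
    DatasetValidationError
        With *every* violation found, each tagged with its row number.
    PairingError
        When a plot lacks its required partner plots.
    """
    schema = dict(schema or {})

    def rename(df: pd.DataFrame) -> pd.DataFrame:
        return df.rename(columns={v: k for k, v in schema.items()})

    obs_df = rename(pd.read_csv(obs_path, dtype=str, keep_default_na=False))
    missing_cols = [c for c in OBSERVATION_COLUMNS if c not in obs_df.columns]
    if missing_cols:
        raise DatasetValidationError(
            [f"observations file lacks column(s): {', '.join(missing_cols)}"]
        )

    problems: list[str] = []
    observations: list[PlotObservation] = []
    for i, row in enumerate(obs_df.itertuples(index=False), start=2):  # header is row 1
        raw = {c: getattr(row, c) for c in OBSERVATION_COLUMNS}
        fields: dict = {}
        try:
            for name, cell in raw.items():
                cell = cell.strip() if isinstance(cell, str) else cell
                if cell == "" or cell is None:
                    if name in _OPTIONAL_FLOAT:
                        fields[name] = None
                        continue
                    raise ValueError(f"field '{name}' is empty")
                if name in _INT_FIELDS:
                    fields[name] = int(cell)
                elif name in {"n_rate", "n_uptake"} | _OPTIONAL_FLOAT:
                    fields[name] = float(cell)
                else:
                    fields[name] = cell
            observations.append(PlotObservation(**fields))
        except (ValueError, ValidationError) as exc:
            problems.append(f"observations row {i}: {_summarise(exc)}")

    covariates: dict[str, CovariateSet] = {}
    if cov_path is not None:
        cov_df = rename(pd.read_csv(cov_path, dtype=str, keep_default_na=False))
        for i, row in enumerate(cov_df.itertuples(index=False), start=2):
            try:
                site = str(row.site_id)
                covariates[site] = CovariateSet(
                    gdd=float(row.gdd),
                    temp_seasonality=float(row.temp_seasonality),
                    aridity=float(row.aridity),
                    crop=row.crop,
                    duration_years=int(row.duration_years),
                    avg_n_rate=float(row.avg_n_rate),
                    clay_pct=float(row.clay_pct),
                    method=row.method,
                    residue_retained=_parse_bool(row.residue_retained),
                )
            except (ValueError, ValidationError, AttributeError) as exc:
                problems.append(f"covariates row {i}: {_summarise(exc)}")

    if problems:
        raise DatasetValidationError(problems)

    ds = Dataset(observations=observations, covariates=covariates)
    ds.check()
    return ds


def _summarise(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        return "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
    return str(exc)


def write_dataset(
    ds: Dataset,
    obs_path: str | Path,
    cov_path: str | Path | None = None,
) -> None:
    """Write a dataset to CSV, byte-stable under a fixed column order.

    Numbers are formatted with 6 significant digits and '.' decimal
    separator; missing optional fields are empty cells; encoding is UTF-8
    with LF line endings. Writing the same dataset twice yields identical
    bytes.
    """
    rows = []
    for obs in ds.observations:
        rows.append([_fmt(getattr(obs, c)) for c in OBSERVATION_COLUMNS])
    text = ",".join(OBSERVATION_COLUMNS) + "\n"
    text += "".join(",".join(r) + "\n" for r in rows)
    Path(obs_path).write_text(text, encoding="utf-8", newline="\n")

    if cov_path is not None:
        crows = []
        for site in sorted(ds.covariates):
            cov = ds.covariates[site]
            crows.append(
                [site] + [_fmt(getattr(cov, c)) for c in COVARIATE_COLUMNS[1:]]
            )
        ctext = ",".join(COVARIATE_COLUMNS) + "\n"
        ctext += "".join(",".join(r) + "\n" for r in crows)
        Path(cov_path).write_text(ctext, encoding="utf-8", newline="\n")
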
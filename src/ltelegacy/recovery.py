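"""Fertiliser-N recovery statistics and assembly of the analysis table.

Definitions (all fractions of the annual N rate, stored unbounded):

* long-term apparent recovery
  ``RE_LT = (U_N_LT - U_0N_LT) / Nrate`` — increment of annual crop N uptake
  on the long-term fertilised plot over the never-fertilised control; it
  includes uptake of fertiliser N applied in earlier seasons.
* first-season recovery, subplot method
  ``RE_1st = (U_N_LT - U_0N_ST) / Nrate`` — N uptake lost when fertiliser is
  withheld for one season on a subplot inside the fertilised plot.
* first-season recovery, 15N method
  ``RE_1st = U_15N / Nrate_15N`` — labelled-fertiliser uptake over labelled
  rate in the year of application.
* delta recovery ``ΔRE = RE_LT - RE_1st`` — the legacy effect of sustained
  fertilisation, i.e. crop uptake of fertiliser N retained in soil from
  earlier applications.

Values of RE_LT above 1 and negative ΔRE are legal observations and are
retained (with a warning flag), matching how such points are treated in
long-term-experiment syntheses.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .exceptions import DomainError, PairingError
from .ltedata import CovariateSet, Crop, Dataset, Method, Treatment

__all__ = [
    "RecoveryRecord",
    "re_lt",
    "re_1st_subplot",
    "re_1st_15n",
    "delta_re",
    "delta_re_withheld",
    "delta_re_scaled",
    "relative_soil_n_uptake_increase",
    "build_recovery_table",
    "direct_delta_record",
    "records_to_frame",
    "frame_to_records",
    "write_recovery",
    "read_recovery",
]

Number = Union[float, np.ndarray]


class RecoveryRecord(BaseModel):
    """One analysis unit: a (site, year, method) with its recovery statistics.

    ``method == direct_delta`` records carry an externally computed ΔRE and
    no RE parts (used for trials whose design allows ΔRE but not RE_1st /
    RE_LT separately).
    """

    model_config = ConfigDict(frozen=True)

    site_id: str
    year: int
    crop: Crop
    method: Method
    n_rate: float = Field(gt=0)
    re_1st: Optional[float] = None
    re_lt: Optional[float] = None
    delta_re: float
    delta_re_scaled: Optional[float] = None
    weight: float = Field(gt=0)
    covariates: CovariateSet
    flags: tuple[str, ...] = ()


def _require_positive(name: str, value: Number) -> None:
    if np.any(np.asarray(value) <= 0):
        raise DomainError(f"{name} must be > 0")


def re_lt(u_n_lt: Number, u_0n_lt: Number, n_rate: Number) -> Number:
    """Long-term apparent recovery; may be negative or exceed 1."""
    _require_positive("n_rate", n_rate)
    return (u_n_lt - u_0n_lt) / n_rate


def re_1st_subplot(u_n_lt: Number, u_0n_st: Number, n_rate: Number) -> Number:
    """First-season recovery from a superimposed zero-N subplot."""
    _require_positive("n_rate", n_rate)
    return (u_n_lt - u_0n_st) / n_rate


def re_1st_15n(u15_uptake: Number, n15_rate: Number) -> Number:
    """First-season recovery of 15N-labelled fertiliser."""
    _require_positive("n15_rate", n15_rate)
    return u15_uptake / n15_rate


def delta_re(re_lt_val: Number, re_1st_val: Number) -> Number:
    """Legacy effect: long-term minus first-season recovery."""
    return re_lt_val - re_1st_val


def delta_re_withheld(u_0n_st: Number, u_0n_lt: Number, n_rate: Number) -> Number:
    """ΔRE computed directly from the two zero-N uptakes.

    Substituting the definitions, RE_LT - RE_1st(subplot) collapses to
    ``(U_0N_ST - U_0N_LT) / Nrate``: the extra uptake on a one-season
    withheld-N subplot over the long-term control, per unit of the historic
    N rate. Identical to the two-step route for any consistent inputs.
    """
    _require_positive("n_rate", n_rate)
    return (u_0n_st - u_0n_lt) / n_rate


def delta_re_scaled(delta: Number, re_1st_val: Number) -> Number:
    """ΔRE expressed as a fraction of the N not recovered in season one."""
    if np.any(np.asarray(re_1st_val) >= 1):
        raise DomainError("delta_re_scaled is undefined for re_1st >= 1")
    return delta / (1 - re_1st_val)


def relative_soil_n_uptake_increase(delta: Number, n_rate: Number, u_0n: Number) -> Number:
    """Relative increase (%) of soil-derived N uptake on fertilised plots.

    ``ΔRE * Nrate / U_0N * 100`` — the extra soil-N uptake attributable to
    the fertiliser legacy, relative to uptake on the unfertilised control.
    """
    _require_positive("u_0n", u_0n)
    return delta * n_rate / u_0n * 100.0


def direct_delta_record(
    site_id: str,
    year: int,
    crop: Crop | str,
    delta: float,
    weight: float,
    covariates: CovariateSet,
    n_rate: float,
) -> RecoveryRecord:
    """Build a pass-through record for designs where only ΔRE is available."""
    cov = covariates.model_copy(update={"method": Method.direct_delta})
    return RecoveryRecord(
        site_id=site_id,
        year=year,
        crop=Crop(crop),
        method=Method.direct_delta,
        n_rate=n_rate,
        delta_re=delta,
        weight=weight,
        covariates=cov,
        flags=("direct_delta",) + (("negative_delta",) if delta < 0 else ()),
    )


def build_recovery_table(
    ds: Dataset,
    direct_delta_records: Iterable[RecoveryRecord] = (),
) -> list[RecoveryRecord]:
    """Assemble one RecoveryRecord per (site, year, method) from paired plots.

    A site-year offering both a zero-N subplot and a 15N subplot yields two
    records (one per method) that share RE_LT but differ in RE_1st. The
    record weight is ``n_years_pooled * n_field_reps`` of the underlying
    short-term observation. No pairing is ever silently dropped: the number
    of short-term subplot observations equals the number of emitted records
    (plus any supplied direct-ΔRE pass-through records).
    """
    ds.check()
    by_group: dict[tuple[str, int], dict[Treatment, object]] = {}
    for obs in ds.observations:
        by_group.setdefault((obs.site_id, obs.year), {})[obs.treatment] = obs

    records: list[RecoveryRecord] = []
    problems: list[str] = []
    for (site, year), group in sorted(by_group.items()):
        st_obs = [
            group[t]
            for t in (Treatment.ST_0N_subplot, Treatment.ST_15N_subplot)
            if t in group
        ]
        if not st_obs:
            continue
        lt_n = group.get(Treatment.LT_N)
        lt_0n = group.get(Treatment.LT_0N)
        if lt_n is None or lt_0n is None:
            problems.append(f"site {site} year {year}: missing long-term partner plots")
            continue
        if site not in ds.covariates:
            problems.append(f"site {site}: no covariate row")
            continue
        relt = re_lt(lt_n.n_uptake, lt_0n.n_uptake, lt_n.n_rate)
        for st in st_obs:
            if st.treatment is Treatment.ST_0N_subplot:
                method = Method.subplot
                re1 = re_1st_subplot(lt_n.n_uptake, st.n_uptake, lt_n.n_rate)
            else:
                method = Method.isotope15N
                if st.n15_rate is None or st.n15_uptake is None:
                    problems.append(
                        f"site {site} year {year}: 15N subplot lacks n15_rate/n15_uptake"
                    )
                    continue
                re1 = re_1st_15n(st.n15_uptake, st.n15_rate)
            d = delta_re(relt, re1)
            flags = []
            if relt > 1:
                flags.append("re_lt_gt_1")
            if d < 0:
                flags.append("negative_delta")
            cov = ds.covariates[site].model_copy(update={"method": method})
            records.append(
                RecoveryRecord(
                    site_id=site,
                    year=year,
                    crop=lt_n.crop,
                    method=method,
                    n_rate=lt_n.n_rate,
                    re_1st=re1,
                    re_lt=relt,
                    delta_re=d,
                    delta_re_scaled=(d / (1 - re1) if re1 < 1 else None),
                    weight=st.n_years_pooled * st.n_field_reps,
                    covariates=cov,
                    flags=tuple(flags),
                )
            )
    if problems:
        raise PairingError(problems)
    records.extend(direct_delta_records)
    return records


_RECOVERY_COLUMNS = [
    "site_id",
    "year",
    "crop",
    "method",
    "n_rate",
    "re_1st",
    "re_lt",
    "delta_re",
    "delta_re_scaled",
    "weight",
    "gdd",
    "temp_seasonality",
    "aridity",
    "duration_years",
    "avg_n_rate",
    "clay_pct",
    "residue_retained",
    "flags",
]


def records_to_frame(records: Sequence[RecoveryRecord]) -> pd.DataFrame:
    """Flatten records (with their co-variables) into a DataFrame."""
    rows = []
    for r in records:
        c = r.covariates
        rows.append(
            {
                "site_id": r.site_id,
                "year": r.year,
                "crop": r.crop.value,
                "method": r.method.value,
                "n_rate": r.n_rate,
                "re_1st": r.re_1st,
                "re_lt": r.re_lt,
                "delta_re": r.delta_re,
                "delta_re_scaled": r.delta_re_scaled,
                "weight": r.weight,
                "gdd": c.gdd,
                "temp_seasonality": c.temp_seasonality,
                "aridity": c.aridity,
                "duration_years": c.duration_years,
                "avg_n_rate": c.avg_n_rate,
                "clay_pct": c.clay_pct,
                "residue_retained": c.residue_retained,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows, columns=_RECOVERY_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[RecoveryRecord]:
    records = []
    for row in df.itertuples(index=False):
        cov = CovariateSet(
            gdd=row.gdd,
            temp_seasonality=row.temp_seasonality,
            aridity=row.aridity,
            crop=row.crop,
            duration_years=int(row.duration_years),
            avg_n_rate=row.avg_n_rate,
            clay_pct=row.clay_pct,
            method=row.method,
            residue_retained=bool(row.residue_retained),
        )
        records.append(
            RecoveryRecord(
                site_id=str(row.site_id),
                year=int(row.year),
                crop=row.crop,
                method=row.method,
                n_rate=row.n_rate,
                re_1st=None if pd.isna(row.re_1st) else float(row.re_1st),
                re_lt=None if pd.isna(row.re_lt) else float(row.re_lt),
                delta_re=float(row.delta_re),
                delta_re_scaled=(
                    None if pd.isna(row.delta_re_scaled) else float(row.delta_re_scaled)
                ),
                weight=float(row.weight),
                covariates=cov,
                flags=tuple(f for f in str(getattr(row, "flags", "") or "").split(";") if f),
            )
        )
    return records


def write_recovery(records: Sequence[RecoveryRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.10g")


def read_recovery(path) -> list[RecoveryRecord]:
    return frame_to_records(pd.read_csv(path))
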
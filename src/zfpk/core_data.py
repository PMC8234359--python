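"""Domain types and delimited-table I/O for the zebrafish-embryo PK pipeline.

The pipeline's observational unit is an RFU time course: integrated
fluorescence intensity inside a delineated region (whole body, yolk sac,
or rest-of-body) of a single embryo cohort, sampled at fixed hours after
exposure start.  Tables are tidy (long-format) CSV/TSV with an explicit
``censored`` flag column, so that excluded observations travel with the
data instead of being silently dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Imaging timepoints, hours post exposure start.
STANDARD_GRID = (0.25, 1.0, 3.0, 6.0, 24.0, 48.0, 72.0, 96.0, 120.0)

#: Yolk contours are only drawn while the yolk sac is discernible.
YOLK_MAX_TIME = 72.0


class Route(str, Enum):
    """Administration route: bath immersion or intrayolk microinjection."""

    IMM = "IMM"
    IY = "IY"


class Compartment(str, Enum):
    """Quantified region: whole body, yolk sac, or rest-of-body."""

    WB = "WB"
    YOLK = "Yolk"
    ROB = "RoB"


class SchemaError(ValueError):
    """A table is missing required columns."""


class TableParseError(ValueError):
    """One or more rows of a table failed validation."""


@dataclass(frozen=True)
class CompoundDescriptor:
    """Physicochemical descriptors of one fluorescent compound.

    Parameters
    ----------
    name : str
        Short compound label, unique within a table.
    mw : float
        Molecular weight, g/mol.
    rotor : int
        Rotatable-bond count.
    hba, hbd : int
        Hydrogen-bond acceptor / donor counts.
    mr : float
        Molar refractivity (unitless convention of the descriptor table).
    tpsa : float
        Topological polar surface area, A^2.
    logd : float
        Experimental distribution coefficient, log10 scale.
    """

    name: str
    mw: float
    rotor: int
    hba: int
    hbd: int
    mr: float
    tpsa: float
    logd: float

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.name}: mw must be > 0, got {self.mw}")
        if self.mr <= 0:
            raise ValueError(f"{self.name}: mr must be > 0, got {self.mr}")
        if self.tpsa < 0:
            raise ValueError(f"{self.name}: tpsa must be >= 0, got {self.tpsa}")
        for attr in ("rotor", "hba", "hbd"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0")


@dataclass(frozen=True)
class RFUPoint:
    """One observation: time (h), integrated intensity, censor flag."""

    time: float
    rfu: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.rfu < 0:
            raise ValueError(f"rfu must be >= 0, got {self.rfu} at t={self.time}")


@dataclass(frozen=True)
class RFUSeries:
    """An RFU time course for one (compound, route, compartment).

    Times are hours post exposure start and must be strictly increasing.
    """

    compound: str
    route: Route
    compartment: Compartment
    points: tuple[RFUPoint, ...]

    def __post_init__(self) -> None:
        times = [p.time for p in self.points]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                f"{self.key()}: times must be strictly increasing, got {times}"
            )

    def key(self) -> tuple[str, str, str]:
        return (self.compound, self.route.value, self.compartment.value)

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(p.time for p in self.points)

    @property
    def rfus(self) -> tuple[float, ...]:
        return tuple(p.rfu for p in self.points)

    def uncensored(self) -> tuple[RFUPoint, ...]:
        return tuple(p for p in self.points if not p.censored)

    def with_points(self, points: Iterable[RFUPoint]) -> "RFUSeries":
        return replace(self, points=tuple(points))


@dataclass(frozen=True)
class AUCResult:
    """Trapezoidal AUC for one series over a stated window, RFU*h.

    ``n_used`` is the count of uncensored observations the integral used;
    it is ``None`` for AUC values transcribed from an external report,
    where the underlying observation count is unknown.
    """

    compound: str
    route: Route
    compartment: Compartment
    window: tuple[float, float]
    auc: float
    n_used: int | None = None

    def __post_init__(self) -> None:
        if self.auc < 0:
            raise ValueError(f"{self.compound}: auc must be >= 0, got {self.auc}")
        if self.n_used is not None:
            if self.n_used < 1:
                raise ValueError(f"{self.compound}: n_used must be >= 1")
            if self.n_used == 1 and self.auc != 0:
                raise ValueError(
                    f"{self.compound}: a single observation spans no interval; "
                    "auc must be 0"
                )


@dataclass(frozen=True)
class ExposureSummary:
    """Per-compound relative-exposure statistics (the route comparison).

    ``re_*`` is AUC(immersion)/AUC(injection) for each compartment;
    ``rd`` is AUC_RoB/AUC_WB after injection.  Fields are ``None`` when
    the required compartment AUCs were absent from the input.
    """

    compound: str
    re_wb: float | None = None
    re_rob: float | None = None
    re_yolk: float | None = None
    rd: float | None = None
    fold_iy_over_imm: float | None = None

    def __post_init__(self) -> None:
        for attr in ("re_wb", "re_rob", "re_yolk"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise ValueError(f"{self.compound}: {attr} must be >= 0, got {v}")
        if self.rd is not None and not (0.0 <= self.rd <= 1.0):
            raise ValueError(f"{self.compound}: rd must lie in [0, 1], got {self.rd}")


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_DESCRIPTOR_COLUMNS = ("compound", "mw", "rotor", "hba", "hbd", "mr", "tpsa", "logd")
_RFU_COLUMNS = ("compound", "route", "compartment", "time_h", "rfu", "censored")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- (default) or tab-delimited UTF-8 table with header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=None, engine="python", encoding="utf-8")


def read_descriptor_table(path: str | Path) -> list[CompoundDescriptor]:
    """Read a compound-descriptor table into validated records.

    Validation failures are aggregated and reported together with their
    1-based data row numbers, so a malformed table is diagnosed in one pass.
    """
    df = _read_delimited(path)
    missing = [c for c in _DESCRIPTOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing descriptor column(s) {missing}")
    records: list[CompoundDescriptor] = []
    errors: list[str] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rownum = int(i) + 1
        bad = [
            c
            for c in _DESCRIPTOR_COLUMNS[1:]
            if pd.isna(row[c]) or not np.isfinite(float(row[c]))
        ]
        if bad:
            errors.append(f"row {rownum}: non-numeric value in column(s) {bad}")
            continue
        try:
            rec = CompoundDescriptor(
                name=str(row["compound"]),
                mw=float(row["mw"]),
                rotor=int(row["rotor"]),
                hba=int(row["hba"]),
                hbd=int(row["hbd"]),
                mr=float(row["mr"]),
                tpsa=float(row["tpsa"]),
                logd=float(row["logd"]),
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"row {rownum}: {exc}")
            continue
        if rec.name in seen:
            errors.append(f"row {rownum}: duplicate compound name {rec.name!r}")
            continue
        seen.add(rec.name)
        records.append(rec)
    if errors:
        raise TableParseError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    return records


def read_rfu_table(path: str | Path) -> list[RFUSeries]:
    """Read a long-format RFU table and group it into time series.

    Rows may arrive out of time order (they are sorted ascending per
    group); duplicate (compound, route, compartment, time) keys and
    negative RFU values are errors.
    """
    df = _read_delimited(path)
    missing = [c for c in _RFU_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing RFU column(s) {missing}")
    return rfu_table_to_series(df, source=str(path))


def rfu_table_to_series(df: pd.DataFrame, source: str = "<table>") -> list[RFUSeries]:
    """Group a tidy RFU DataFrame into :class:`RFUSeries` objects."""
    errors: list[str] = []
    out: list[RFUSeries] = []
    dup = df.duplicated(subset=["compound", "route", "compartment", "time_h"])
    if dup.any():
        keys = df.loc[dup, ["compound", "route", "compartment", "time_h"]]
        errors.append(f"duplicate observations:\n{keys.to_string(index=False)}")
    if (df["rfu"] < 0).any():
        bad = df.loc[df["rfu"] < 0]
        errors.append(f"negative rfu values:\n{bad.to_string(index=False)}")
    if errors:
        raise TableParseError(f"{source}: " + "; ".join(errors))
    for (compound, route, compartment), grp in df.groupby(
        ["compound", "route", "compartment"], sort=True
    ):
        grp = grp.sort_values("time_h")
        points = tuple(
            RFUPoint(
                time=float(r.time_h), rfu=float(r.rfu), censored=bool(r.censored)
            )
            for r in grp.itertuples()
        )
        out.append(
            RFUSeries(
                compound=str(compound),
                route=Route(route),
                compartment=Compartment(compartment),
                points=points,
            )
        )
    return out


def series_to_rfu_table(series: Sequence[RFUSeries]) -> pd.DataFrame:
    """Flatten series into the tidy long-format layout."""
    rows = [
        {
            "compound": s.compound,
            "route": s.route.value,
            "compartment": s.compartment.value,
            "time_h": p.time,
            "rfu": p.rfu,
            "censored": p.censored,
        }
        for s in series
        for p in s.points
    ]
    return pd.DataFrame(rows, columns=list(_RFU_COLUMNS))


def write_rfu_table(series: Sequence[RFUSeries], path: str | Path) -> None:
    """Write series as delimited text; inverse of :func:`read_rfu_table`."""
    series_to_rfu_table(series).to_csv(path, index=False)


def derive_rob(wb: RFUSeries, yolk: RFUSeries) -> RFUSeries:
    """Rest-of-body signal by subtraction: RoB(t) = WB(t) - Yolk(t).

    The whole-body contour contains the yolk contour, so the non-yolk
    signal is the pointwise difference of the two integrated intensities.
    Noise can drive the difference negative; integrated fluorescence is a
    non-negative quantity, so negatives are clamped to zero and each clamp
    is logged.  A point censored in either input is censored in the output.
    """
    if (wb.compound, wb.route) != (yolk.compound, yolk.route):
        raise ValueError(
            f"series mismatch: {wb.key()} vs {yolk.key()} "
            "(compound and route must agree)"
        )
    if wb.times != yolk.times:
        missing_in_yolk = sorted(set(wb.times) - set(yolk.times))
        missing_in_wb = sorted(set(yolk.times) - set(wb.times))
        raise ValueError(
            f"{wb.compound}/{wb.route.value}: time grids differ; "
            f"missing in yolk: {missing_in_yolk}; missing in wb: {missing_in_wb}"
        )
    points = []
    for pw, py in zip(wb.points, yolk.points):
        diff = pw.rfu - py.rfu
        if diff < 0:
            logger.warning(
                "%s/%s t=%g h: WB (%g) < Yolk (%g); RoB clamped to 0",
                wb.compound,
                wb.route.value,
                pw.time,
                pw.rfu,
                py.rfu,
            )
            diff = 0.0
        points.append(
            RFUPoint(time=pw.time, rfu=diff, censored=pw.censored or py.censored)
        )
    return RFUSeries(
        compound=wb.compound,
        route=wb.route,
        compartment=Compartment.ROB,
        points=tuple(points),
    )


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    from importlib.resources import files

    return Path(str(files("zfpk.data").joinpath(name)))


def load_reference_descriptors() -> list[CompoundDescriptor]:
    """The seven fluorescent dyes of the reference study with their
    SwissADME descriptors and experimental Log D values."""
    return read_descriptor_table(_data_path("table4_descriptors.csv"))


def load_reference_aucs(window: tuple[float, float] = (0.25, 72.0)) -> list[AUCResult]:
    """Published AUC values (RFU x 1e7, 0.25-72 h window) for the seven
    dyes under both routes and all three compartments."""
    df = pd.read_csv(_data_path("table1_auc.csv"))
    return [
        AUCResult(
            compound=str(r.compound),
            route=Route(r.route),
            compartment=Compartment(r.compartment),
            window=window,
            auc=float(r.auc),
            n_used=None,
        )
        for r in df.itertuples()
    ]


def load_reference_exposure() -> pd.DataFrame:
    """Published relative-exposure / relative-distribution table."""
    return pd.read_csv(_data_path("table2_re.csv"), index_col="compound")
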
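"""End-to-end orchestration: quantify -> NCA -> exposure -> QSPkR.

Every stage materializes its result as a file (an auditable chain of
AUC table -> exposure table -> model fits), and a run log records the
tool version, a hash of the configuration, the seed, and every censoring
and clamping decision taken along the way.  Two runs with the same
configuration and seed produce byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .core_data import (
    AUCResult,
    Compartment,
    CompoundDescriptor,
    ExposureSummary,
    RFUSeries,
    Route,
    read_descriptor_table,
    read_rfu_table,
)
from .exposure_metrics import exposure_to_frame, summarize_exposure
from .nca import AUCConfig, CensorPolicy, apply_censor_policy, trapezoid_auc
from .qspkr import Centering, QSPkRFit, evaluate_model, fit_reference_suite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, analysis settings, and reporting precision for one run.

    Exactly one of ``rfu`` (raw time courses, NCA will run) or ``auc``
    (pre-computed AUC table, NCA skipped) must be provided.  ``decimals``
    controls only report rounding; file outputs keep full precision.
    """

    out_dir: Path
    rfu: Path | None = None
    auc: Path | None = None
    descriptors: Path | None = None
    t_start: float = 0.25
    t_end: float = 72.0
    censor_policy: CensorPolicy = CensorPolicy.EXPLICIT
    quench_theta: float = 0.8
    centering: Centering = Centering.SAMPLE_MEAN
    seed: int = 0
    ratio_decimals: int = 2
    stat_decimals: int = 3

    def __post_init__(self) -> None:
        if (self.rfu is None) == (self.auc is None):
            raise ValueError("provide exactly one of 'rfu' or 'auc' inputs")
        if self.ratio_decimals < 0 or self.stat_decimals < 0:
            raise ValueError("report decimals must be >= 0")
        for name in ("rfu", "auc", "descriptors"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input does not exist: {p}")

    def auc_config(self) -> AUCConfig:
        return AUCConfig(
            t_start=self.t_start,
            t_end=self.t_end,
            censor_policy=self.censor_policy,
            quench_theta=self.quench_theta,
        )

    def digest(self) -> str:
        payload = {
            k: (str(v) if isinstance(v, (Path, CensorPolicy, Centering)) else v)
            for k, v in asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Build a config from a YAML key-value file plus overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    for key in ("out_dir", "rfu", "auc", "descriptors"):
        if raw.get(key) is not None:
            raw[key] = Path(raw[key])
    if "censor_policy" in raw:
        raw["censor_policy"] = CensorPolicy(raw["censor_policy"])
    if "centering" in raw:
        raw["centering"] = Centering(raw["centering"])
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def run_nca(
    series_list: Sequence[RFUSeries], config: AUCConfig
) -> tuple[list[AUCResult], list[dict]]:
    """AUC per series plus a log of the points the censor policy flagged."""
    results: list[AUCResult] = []
    censor_log: list[dict] = []
    explicit = AUCConfig(
        t_start=config.t_start,
        t_end=config.t_end,
        censor_policy=CensorPolicy.EXPLICIT,
    )
    for series in series_list:
        working = apply_censor_policy(series, config.censor_policy, config.quench_theta)
        for before, after in zip(series.points, working.points):
            if after.censored and not before.censored:
                censor_log.append(
                    {
                        "compound": series.compound,
                        "route": series.route.value,
                        "compartment": series.compartment.value,
                        "time_h": before.time,
                        "rfu": before.rfu,
                    }
                )
        results.append(trapezoid_auc(working, explicit))
    return results, censor_log


def auc_to_frame(results: Sequence[AUCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound": r.compound,
                "route": r.route.value,
                "compartment": r.compartment.value,
                "t_start": r.window[0],
                "t_end": r.window[1],
                "auc": r.auc,
                "n_used": r.n_used,
            }
            for r in results
        ]
    )


def read_auc_table(path: str | Path) -> list[AUCResult]:
    """Read an AUC table written by :func:`auc_to_frame` (or transcribed)."""
    df = pd.read_csv(path)
    required = {"compound", "route", "compartment", "auc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing AUC column(s) {sorted(missing)}")
    out = []
    for r in df.itertuples():
        window = (
            float(getattr(r, "t_start", 0.25)),
            float(getattr(r, "t_end", 72.0)),
        )
        n_used = getattr(r, "n_used", None)
        n_used = None if n_used is None or pd.isna(n_used) else int(n_used)
        out.append(
            AUCResult(
                compound=str(r.compound),
                route=Route(r.route),
                compartment=Compartment(r.compartment),
                window=window,
                auc=float(r.auc),
                n_used=n_used,
            )
        )
    return out


def qspkr_payload(
    fits: dict[str, QSPkRFit],
    descriptors: Sequence[CompoundDescriptor],
) -> dict:
    payload: dict = {}
    for name, fit in fits.items():
        payload[name] = {
            "equation": fit.equation(),
            "coefficients": dict(fit.coefficients),
            "centers": dict(fit.centers),
            "n": fit.n,
            "p": fit.p,
            "r2": fit.r2,
            "r2_adj": fit.r2_adj,
            "rmse": fit.rmse,
            "f_pvalue": fit.f_pvalue,
            "predictions": {
                d.name: evaluate_model(fit, fit.spec, d) for d in descriptors
            },
        }
    return payload


@dataclass
class RunResult:
    auc: list[AUCResult]
    exposure: list[ExposureSummary]
    fits: dict[str, QSPkRFit] | None
    censor_log: list[dict]
    clamp_log: list[str]
    files: dict[str, Path]


class _ClampCapture(logging.Handler):
    """Collects the subtraction-clamping warnings emitted by derive_rob."""

    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        if "clamped" in record.getMessage():
            self.messages.append(record.getMessage())


def run_full(config: PipelineConfig) -> RunResult:
    """Execute the configured stages and write the output bundle.

    Writes auc.csv, exposure.csv, qspkr.json (when descriptors are
    given), report.md, and run_log.json into ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    clamp_capture = _ClampCapture()
    logging.getLogger("zfpk.core_data").addHandler(clamp_capture)
    try:
        censor_log: list[dict] = []
        if config.rfu is not None:
            series_list = read_rfu_table(config.rfu)
            aucs, censor_log = run_nca(series_list, config.auc_config())
        else:
            aucs = read_auc_table(config.auc)
        files["auc"] = out_dir / "auc.csv"
        auc_to_frame(aucs).to_csv(files["auc"], index=False)

        exposure = summarize_exposure(aucs)
        files["exposure"] = out_dir / "exposure.csv"
        exposure_to_frame(exposure).to_csv(files["exposure"], index=False)

        fits = None
        if config.descriptors is not None:
            descriptors = read_descriptor_table(config.descriptors)
            complete = {
                s.compound
                for s in exposure
                if None not in (s.re_wb, s.re_rob, s.re_yolk)
            }
            usable = [d for d in descriptors if d.name in complete]
            if len(usable) == len(descriptors):
                fits = fit_reference_suite(
                    descriptors,
                    exposure,
                    centering=config.centering,
                )
                files["qspkr"] = out_dir / "qspkr.json"
                files["qspkr"].write_text(
                    json.dumps(
                        qspkr_payload(fits, descriptors), indent=2, sort_keys=True
                    )
                )
            else:
                logger.warning(
                    "QSPkR stage skipped: incomplete exposure summaries for %s",
                    sorted(set(d.name for d in descriptors) - complete),
                )
    finally:
        logging.getLogger("zfpk.core_data").removeHandler(clamp_capture)

    result = RunResult(
        auc=aucs,
        exposure=exposure,
        fits=fits,
        censor_log=censor_log,
        clamp_log=clamp_capture.messages,
        files=files,
    )
    files["report"] = out_dir / "report.md"
    files["report"].write_text(make_report(result, config))
    files["run_log"] = out_dir / "run_log.json"
    files["run_log"].write_text(
        json.dumps(
            {
                "version": __version__,
                "config_hash": config.digest(),
                "seed": config.seed,
                "censored_points": censor_log,
                "clamp_events": clamp_capture.messages,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return result


def make_report(result: RunResult, config: PipelineConfig) -> str:
    """Human-readable markdown summary of one pipeline run."""
    rd, sd = config.ratio_decimals, config.stat_decimals
    lines = ["# Exposure analysis report", ""]

    lines += ["## Relative exposure and distribution", ""]
    df = exposure_to_frame(result.exposure, decimals=rd)
    lines += ["```", df.to_string(index=False), "```", ""]
    with_re = [s for s in result.exposure if s.re_wb is not None]
    if with_re:
        top = max(with_re, key=lambda s: s.re_wb)
        lines += [
            f"Highest whole-body relative exposure: **{top.compound}** "
            f"(RE-WB = {round(top.re_wb, rd)}).",
            "",
        ]
        folds = [
            f"{s.compound}: {round(s.fold_iy_over_imm, 1)}x"
            for s in with_re
            if s.fold_iy_over_imm is not None
        ]
        if folds:
            lines += [
                "Injection-over-immersion whole-body fold exposure (1/RE): "
                + ", ".join(folds),
                "",
            ]

    lines += ["## QSPkR models", ""]
    if result.fits:
        for name, fit in result.fits.items():
            lines += [
                f"### {name}",
                "",
                f"`{fit.equation(sd)}`",
                "",
                f"n = {fit.n}, p = {fit.p}, R^2 = {round(fit.r2, sd)}, "
                f"adj R^2 = {round(fit.r2_adj, sd)}, RMSE = {round(fit.rmse, sd)}, "
                f"F-test p = {round(fit.f_pvalue, sd)}",
                "",
            ]
    else:
        lines += ["_No models fitted (descriptor table absent or exposure",
                  "summaries incomplete)._", ""]

    lines += ["## Censored observations", ""]
    if result.censor_log:
        for e in result.censor_log:
            lines.append(
                f"- {e['compound']} {e['route']}/{e['compartment']} "
                f"t = {e['time_h']:g} h (rfu = {e['rfu']:.4g})"
            )
    else:
        lines.append("_None._")
    lines.append("")

    lines += ["## Subtraction clamping events", ""]
    if result.clamp_log:
        lines += [f"- {m}" for m in result.clamp_log]
    else:
        lines.append("_None._")
    lines.append("")
    return "\n".join(lines)
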
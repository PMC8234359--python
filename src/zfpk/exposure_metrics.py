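"""Route-comparison statistics: Relative Exposure and Relative Distribution.

Absolute integrated-fluorescence AUCs cannot be compared across compounds
(they depend on quantum yield and camera settings), but their ratio within
a compound cancels the fluorescence scale.  Two such ratios are computed:

* Relative Exposure, RE = AUC(immersion) / AUC(injection), per
  compartment — how well bath exposure matches the injected reference.
* Relative Distribution, RD = AUC_RoB / AUC_WB after injection — the
  fraction of injected-compound exposure reaching non-yolk tissue.

Both are unitless and invariant under rescaling of the fluorescence axis.
"""

from __future__ import annotations

import logging
import warnings

import pandas as pd

from .core_data import AUCResult, Compartment, ExposureSummary, Route

logger = logging.getLogger(__name__)


class UndefinedRatioError(ZeroDivisionError):
    """The denominator AUC is zero, so the ratio is undefined.

    Distinct from a ratio of exactly 0, which arises from a zero
    numerator over a positive denominator.
    """


def relative_exposure(auc_imm: float, auc_iy: float) -> float:
    """RE = AUC after immersion / AUC after intrayolk injection.

    A zero immersion AUC yields RE = 0 exactly (no detectable uptake from
    the bath); a zero injection AUC leaves the ratio undefined.
    """
    if auc_imm < 0 or auc_iy < 0:
        raise ValueError(f"AUCs must be >= 0, got ({auc_imm}, {auc_iy})")
    if auc_iy == 0:
        raise UndefinedRatioError(
            "injection AUC is 0; relative exposure is undefined"
        )
    return auc_imm / auc_iy


def relative_distribution(auc_rob_iy: float, auc_wb_iy: float) -> float:
    """RD = AUC_RoB / AUC_WB after injection, the redistributed fraction.

    Whole-body signal decomposes as yolk + rest-of-body, so RD lies in
    [0, 1] for exact inputs.  Published tables carry rounded AUCs that can
    violate the decomposition slightly; a numerator exceeding the
    denominator is therefore a warning, not an error, and the ratio is
    returned as computed.
    """
    if auc_rob_iy < 0:
        raise ValueError(f"AUC_RoB must be >= 0, got {auc_rob_iy}")
    if auc_wb_iy == 0:
        raise UndefinedRatioError(
            "whole-body injection AUC is 0; relative distribution is undefined"
        )
    if auc_wb_iy < 0:
        raise ValueError(f"AUC_WB must be >= 0, got {auc_wb_iy}")
    if auc_rob_iy > auc_wb_iy:
        warnings.warn(
            f"AUC_RoB ({auc_rob_iy}) exceeds AUC_WB ({auc_wb_iy}); "
            "inputs violate the yolk + RoB = WB decomposition "
            "(rounded inputs?)",
            UserWarning,
            stacklevel=2,
        )
    return auc_rob_iy / auc_wb_iy


def summarize_exposure(auc_table: list[AUCResult]) -> list[ExposureSummary]:
    """Per-compound RE (all compartments) and RD from an AUC table.

    For each compound the whole-body AUC must be present for both routes;
    compounds lacking an injection whole-body AUC are skipped with a
    warning.  Missing yolk or rest-of-body AUCs leave the corresponding
    fields absent (``None``), not zero.  ``fold_iy_over_imm`` (1/RE for
    the whole body) is carried along for report narrative.
    """
    by_compound: dict[str, dict[tuple[Route, Compartment], float]] = {}
    order: list[str] = []
    for r in auc_table:
        if r.compound not in by_compound:
            by_compound[r.compound] = {}
            order.append(r.compound)
        by_compound[r.compound][(r.route, r.compartment)] = r.auc

    out: list[ExposureSummary] = []
    for compound in order:
        aucs = by_compound[compound]
        wb_iy = aucs.get((Route.IY, Compartment.WB))
        wb_imm = aucs.get((Route.IMM, Compartment.WB))
        if wb_iy is None or wb_iy == 0 or wb_imm is None:
            warnings.warn(
                f"{compound}: whole-body AUCs incomplete for both routes; "
                "skipped",
                UserWarning,
                stacklevel=2,
            )
            continue

        def _re(comp: Compartment) -> float | None:
            imm = aucs.get((Route.IMM, comp))
            iy = aucs.get((Route.IY, comp))
            if imm is None or iy is None or iy == 0:
                return None
            return relative_exposure(imm, iy)

        re_wb = relative_exposure(wb_imm, wb_iy)
        rob_iy = aucs.get((Route.IY, Compartment.ROB))
        rd = None
        if rob_iy is not None:
            rd = min(relative_distribution(rob_iy, wb_iy), 1.0)
        out.append(
            ExposureSummary(
                compound=compound,
                re_wb=re_wb,
                re_rob=_re(Compartment.ROB),
                re_yolk=_re(Compartment.YOLK),
                rd=rd,
                fold_iy_over_imm=(1.0 / re_wb) if re_wb > 0 else None,
            )
        )
    return out


def exposure_to_frame(
    summaries: list[ExposureSummary], decimals: int | None = None
) -> pd.DataFrame:
    """Tabulate summaries; optional rounding at this reporting boundary."""
    df = pd.DataFrame(
        [
            {
                "compound": s.compound,
                "re_wb": s.re_wb,
                "re_rob": s.re_rob,
                "re_yolk": s.re_yolk,
                "rd": s.rd,
                "fold_iy_over_imm": s.fold_iy_over_imm,
            }
            for s in summaries
        ]
    )
    if decimals is not None:
        num = df.columns.drop("compound")
        df[num] = df[num].round(decimals)
    return df
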
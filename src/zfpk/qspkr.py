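"""QSPkR: regression of relative exposure on molecular descriptors.

The relative-exposure statistics of the seven-dye panel are modelled by
ordinary least squares on small polynomial design matrices.  Higher-order
terms follow the centered-polynomial convention of standard statistical
packages: a quadratic in x enters as (x - x_bar)^2 and an interaction as
(a - a_bar)(b - b_bar), which decorrelates them from the linear terms
without changing the fitted surface.  Three model forms are supported as
the reference suite:

* RE_WB  ~ 1 + LogD + (LogD - mean)^2
* RE_RoB ~ 1 + LogD + (LogD - mean)^2
* RE_Yolk ~ 1 + LogD + TPSA + MR + (LogD - mean)(MR - mean)

Centering constants default to the sample means of the input descriptors;
a fixed-constants mode reproduces externally printed equations bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .core_data import CompoundDescriptor, ExposureSummary


class Centering(str, Enum):
    SAMPLE_MEAN = "sample_mean"
    FIXED = "fixed"


@dataclass(frozen=True)
class Term:
    """One design-matrix column: intercept, linear, centered quadratic,
    or centered interaction."""

    kind: str  # "intercept" | "linear" | "centered_quadratic" | "centered_interaction"
    descriptors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arity = {"intercept": 0, "linear": 1, "centered_quadratic": 1,
                 "centered_interaction": 2}
        if self.kind not in arity:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if len(self.descriptors) != arity[self.kind]:
            raise ValueError(
                f"{self.kind} takes {arity[self.kind]} descriptor(s), "
                f"got {self.descriptors}"
            )

    @property
    def label(self) -> str:
        if self.kind == "intercept":
            return "intercept"
        if self.kind == "linear":
            return self.descriptors[0]
        if self.kind == "centered_quadratic":
            return f"({self.descriptors[0]} - center)^2"
        return f"({self.descriptors[0]} - center)({self.descriptors[1]} - center)"


def intercept() -> Term:
    return Term("intercept")


def linear(descriptor: str) -> Term:
    return Term("linear", (descriptor,))


def centered_quadratic(descriptor: str) -> Term:
    return Term("centered_quadratic", (descriptor,))


def centered_interaction(a: str, b: str) -> Term:
    return Term("centered_interaction", (a, b))


@dataclass(frozen=True)
class ModelSpec:
    """Response name, ordered term list, and centering mode.

    ``fixed_centers`` maps descriptor name -> centering constant and is
    required (for every descriptor appearing in a centered term) when
    ``centering`` is FIXED.
    """

    response: str
    terms: tuple[Term, ...]
    centering: Centering = Centering.SAMPLE_MEAN
    fixed_centers: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        n_icpt = sum(1 for t in self.terms if t.kind == "intercept")
        if n_icpt != 1:
            raise ValueError(f"exactly one intercept term required, got {n_icpt}")


@dataclass(frozen=True)
class QSPkRFit:
    """An OLS fit: coefficients plus the usual goodness-of-fit summary.

    ``rmse`` is the residual standard error sqrt(SSE / (n - p)), the
    convention of regression ANOVA tables.  ``centers`` records the
    centering constants actually used so that predictions for new
    compounds evaluate the same polynomial.
    """

    spec: ModelSpec
    coefficients: tuple[tuple[str, float], ...]
    centers: tuple[tuple[str, float], ...]
    n: int
    p: int
    sse: float
    sst: float
    r2: float
    r2_adj: float
    rmse: float
    f_pvalue: float

    def coef_dict(self) -> dict[str, float]:
        return dict(self.coefficients)

    def equation(self, decimals: int = 3) -> str:
        """Render the fitted model in conventional printed notation."""
        parts = []
        centers = dict(self.centers)

        def _c(name: str) -> str:
            c = centers[name]
            return f"{name} - {round(c, decimals)}" if c >= 0 else \
                f"{name} + {round(-c, decimals)}"

        for term, (_, beta) in zip(self.spec.terms, self.coefficients):
            b = round(beta, decimals)
            if term.kind == "intercept":
                parts.append(f"{b}")
            elif term.kind == "linear":
                parts.append(f"{b}({term.descriptors[0]})")
            elif term.kind == "centered_quadratic":
                parts.append(f"({_c(term.descriptors[0])})^2 x {b}")
            else:
                a_, b_ = term.descriptors
                parts.append(f"({_c(a_)})({_c(b_)}) x {b}")
        return f"{self.spec.response} = " + " + ".join(parts)


class RankDeficiencyError(ValueError):
    """The design matrix has collinear (or constant) columns."""


def _descriptor_matrix(
    descriptors: Sequence[CompoundDescriptor],
) -> dict[str, np.ndarray]:
    cols = {}
    for name in ("mw", "rotor", "hba", "hbd", "mr", "tpsa", "logd"):
        cols[name] = np.array([float(getattr(d, name)) for d in descriptors])
    return cols


def resolve_centers(
    descriptors: Sequence[CompoundDescriptor], spec: ModelSpec
) -> dict[str, float]:
    """Centering constant per descriptor used in a centered term."""
    cols = _descriptor_matrix(descriptors)
    needed = sorted(
        {d for t in spec.terms if t.kind.startswith("centered") for d in t.descriptors}
    )
    if spec.centering is Centering.SAMPLE_MEAN:
        return {name: float(cols[name].mean()) for name in needed}
    fixed = dict(spec.fixed_centers)
    missing = [n for n in needed if n not in fixed]
    if missing:
        raise ValueError(f"fixed centering requires constants for {missing}")
    return {n: float(fixed[n]) for n in needed}


def build_design(
    descriptors: Sequence[CompoundDescriptor], spec: ModelSpec
) -> tuple[np.ndarray, list[str], dict[str, float]]:
    """Design matrix, column labels, and the centering constants used.

    Raises
    ------
    RankDeficiencyError
        If any non-intercept column is constant across compounds, which
        makes the least-squares problem singular before it is even posed.
    """
    unknown = sorted(
        {d for t in spec.terms for d in t.descriptors}
        - {"mw", "rotor", "hba", "hbd", "mr", "tpsa", "logd"}
    )
    if unknown:
        raise ValueError(f"unknown descriptor(s) in model terms: {unknown}")
    cols = _descriptor_matrix(descriptors)
    centers = resolve_centers(descriptors, spec)
    n = len(descriptors)
    columns: list[np.ndarray] = []
    labels: list[str] = []
    for t in spec.terms:
        if t.kind == "intercept":
            columns.append(np.ones(n))
        elif t.kind == "linear":
            columns.append(cols[t.descriptors[0]])
        elif t.kind == "centered_quadratic":
            x = t.descriptors[0]
            columns.append((cols[x] - centers[x]) ** 2)
        else:
            a, b = t.descriptors
            columns.append((cols[a] - centers[a]) * (cols[b] - centers[b]))
        labels.append(t.label)
    X = np.column_stack(columns)
    for j, t in enumerate(spec.terms):
        if t.kind != "intercept" and np.ptp(X[:, j]) == 0:
            raise RankDeficiencyError(
                f"design column {labels[j]!r} is constant across compounds"
            )
    return X, labels, centers


def ols_fit(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    labels: Sequence[str] | None = None,
    centers: dict[str, float] | None = None,
) -> QSPkRFit:
    """Ordinary least squares with the standard ANOVA summary.

    R^2 = 1 - SSE/SST (SST about the mean), adjusted R^2 penalizes by the
    residual degrees of freedom, and the p-value is that of the overall
    F-test of the regression against the intercept-only model.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p observations, got n={n}, p={p}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        lbl = list(labels) if labels else [f"col{j}" for j in range(p)]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {p} columns; "
            f"collinearity among {lbl}"
        )
    res = sm.OLS(y, X).fit()
    sse = float(res.ssr)
    sst = float(res.centered_tss)
    labels = list(labels) if labels is not None else [f"col{j}" for j in range(p)]
    return QSPkRFit(
        spec=spec,
        coefficients=tuple(zip(labels, (float(b) for b in res.params))),
        centers=tuple(sorted((centers or {}).items())),
        n=n,
        p=p,
        sse=sse,
        sst=sst,
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        rmse=float(np.sqrt(sse / (n - p))),
        f_pvalue=float(res.f_pvalue),
    )


def fit_model(
    descriptors: Sequence[CompoundDescriptor],
    y: np.ndarray,
    spec: ModelSpec,
) -> QSPkRFit:
    """Build the design for ``spec`` and fit it to the response ``y``."""
    X, labels, centers = build_design(descriptors, spec)
    return ols_fit(X, y, spec, labels=labels, centers=centers)


def evaluate_model(
    fit_or_coeffs: QSPkRFit | Sequence[float],
    spec: ModelSpec,
    compound: CompoundDescriptor,
    centers: dict[str, float] | None = None,
) -> float:
    """Predicted response for one compound under a fitted (or printed) model.

    Predictions are the raw polynomial value — no clipping to [0, inf);
    the quadratic models genuinely dip below zero near their vertex.
    """
    if isinstance(fit_or_coeffs, QSPkRFit):
        betas = [b for _, b in fit_or_coeffs.coefficients]
        centers = dict(fit_or_coeffs.centers)
    else:
        betas = list(fit_or_coeffs)
        centers = dict(centers or {})
    if len(betas) != len(spec.terms):
        raise ValueError(
            f"{len(betas)} coefficients for {len(spec.terms)} model terms"
        )
    value = 0.0
    for beta, t in zip(betas, spec.terms):
        if t.kind == "intercept":
            value += beta
        elif t.kind == "linear":
            value += beta * float(getattr(compound, t.descriptors[0]))
        elif t.kind == "centered_quadratic":
            x = t.descriptors[0]
            value += beta * (float(getattr(compound, x)) - centers[x]) ** 2
        else:
            a, b = t.descriptors
            value += beta * (
                (float(getattr(compound, a)) - centers[a])
                * (float(getattr(compound, b)) - centers[b])
            )
    return value


# ---------------------------------------------------------------------------
# Reference model suite
# ---------------------------------------------------------------------------

PARABOLIC_TERMS = (intercept(), linear("logd"), centered_quadratic("logd"))
YOLK_TERMS = (
    intercept(),
    linear("logd"),
    linear("tpsa"),
    linear("mr"),
    centered_interaction("logd", "mr"),
)


def reference_specs(
    centering: Centering = Centering.SAMPLE_MEAN,
    fixed_centers: dict[str, float] | None = None,
) -> dict[str, ModelSpec]:
    """The three model forms of the reference analysis, keyed by response."""
    fixed = tuple(sorted((fixed_centers or {}).items()))
    return {
        "RE_WB": ModelSpec("RE_WB", PARABOLIC_TERMS, centering, fixed),
        "RE_RoB": ModelSpec("RE_RoB", PARABOLIC_TERMS, centering, fixed),
        "RE_Yolk": ModelSpec("RE_Yolk", YOLK_TERMS, centering, fixed),
    }


def fit_reference_suite(
    descriptors: Sequence[CompoundDescriptor],
    exposure: Sequence[ExposureSummary],
    centering: Centering = Centering.SAMPLE_MEAN,
    fixed_centers: dict[str, float] | None = None,
) -> dict[str, QSPkRFit]:
    """Fit the three reference models to an exposure summary.

    Requires a complete RE triple per compound.  The yolk model spends
    five parameters on seven observations; its near-saturated fit (two
    residual degrees of freedom) is flagged with a warning.
    """
    by_name = {s.compound: s for s in exposure}
    ordered = [by_name[d.name] for d in descriptors if d.name in by_name]
    if len(ordered) != len(descriptors):
        missing = [d.name for d in descriptors if d.name not in by_name]
        raise ValueError(f"exposure summaries missing for {missing}")
    responses = {
        "RE_WB": np.array([s.re_wb for s in ordered], dtype=float),
        "RE_RoB": np.array([s.re_rob for s in ordered], dtype=float),
        "RE_Yolk": np.array([s.re_yolk for s in ordered], dtype=float),
    }
    for name, y in responses.items():
        if np.isnan(y).any():
            raise ValueError(f"incomplete {name} responses (missing values)")
    specs = reference_specs(centering, fixed_centers)
    fits = {}
    for name, spec in specs.items():
        fit = fit_model(descriptors, responses[name], spec)
        if fit.n - fit.p <= 2:
            warnings.warn(
                f"{name}: only {fit.n - fit.p} residual degrees of freedom; "
                "fit statistics are fragile",
                UserWarning,
                stacklevel=2,
            )
        fits[name] = fit
    return fits
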
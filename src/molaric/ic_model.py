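"""The inhibitory-cascade (IC) model of molar proportions.

The IC model holds that sequentially forming molars inherit a balance
between a mesenchymal activator (a) and an inhibitor (i) produced by
earlier molars.  Relative molar area at position X in {1, 2, 3} is
linear in position:

    Y = 1 + [(a - i)/i] * (X - 1)

so with rho = a/i the predicted areas are M1 = 1, M2 = rho,
M3 = 2*rho - 1 — an arithmetic progression.  Two testable consequences
follow: (1) across groups, M3/M1 regressed on M2/M1 gives a line with
slope 2 and intercept -1; (2) M2 is exactly one third of the molar row
(M1 + M2 + M3) for every admissible rho.  Groups whose molar areas are
not monotone along the row (e.g. M1 < M2 > M3) lie outside the
morphospace the cascade can generate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_tables import PhyloTree, ValidationError
from .molar_metrics import MolarTriple, classify_pattern
from .phylo import BMCovariance, RegressionResult, ols_fit, pgls_fit
from .spatial import SpatialWeights, lag_sar_fit

IC_SLOPE = 2.0
IC_INTERCEPT = -1.0


@dataclass(frozen=True)
class ICParameters:
    """Activator/inhibitor balance a/i.

    ratio = 1 predicts equal molars; ratio > 1 a distally increasing
    row; predicted M3 is positive only for ratio > 0.5.
    """

    ratio: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ratio) and self.ratio > 0):
            raise ValidationError(f"activator/inhibitor ratio must be > 0, got {self.ratio}")


@dataclass(frozen=True)
class MorphospaceCall:
    """Position of one group relative to the IC morphospace."""

    group_id: str
    jaw: str
    r2: float
    r3: float
    pattern: str
    inside: bool


@dataclass(frozen=True)
class ICFitResult:
    """Regression of M3/M1 on M2/M1 with IC-consistency flags."""

    result: RegressionResult
    slope_consistent: bool
    intercept_consistent: bool


def ic_relative_area(position: int, params: ICParameters) -> float:
    """Relative molar area at a tooth position under the cascade:
    1 + (a/i - 1) * (position - 1)."""
    if position not in (1, 2, 3):
        raise ValidationError(f"position must be 1, 2 or 3, got {position}")
    return 1.0 + (params.ratio - 1.0) * (position - 1)


def ic_triple(params: ICParameters) -> tuple[float, float, float]:
    """Predicted (M1, M2, M3) = (1, a/i, 2a/i - 1); requires a/i > 0.5."""
    if params.ratio <= 0.5:
        raise ValidationError(
            f"activator/inhibitor ratio {params.ratio} predicts non-positive M3"
        )
    return tuple(ic_relative_area(p, params) for p in (1, 2, 3))


def ic_predicted_r3(r2: float) -> float:
    """The model line M3/M1 = 2 (M2/M1) - 1."""
    if r2 <= 0:
        raise ValidationError(f"M2/M1 ratio must be positive, got {r2}")
    return IC_SLOPE * r2 + IC_INTERCEPT


def estimate_activation_ratio(triple: MolarTriple) -> ICParameters:
    """Back out a/i from an observed triple: after normalizing M1 = 1,
    M2 = a/i, so the estimate is simply M2/M1."""
    return ICParameters(ratio=triple.r2)


def distance_to_line(r2: float, r3: float) -> float:
    """Perpendicular distance from (M2/M1, M3/M1) to the IC line
    r3 = 2 r2 - 1 (diagnostic only; not used for the inside/outside call)."""
    return abs(IC_SLOPE * r2 - r3 + IC_INTERCEPT) / math.sqrt(IC_SLOPE**2 + 1.0)


def classify_morphospace(triple: MolarTriple, tol: float = 0.0) -> MorphospaceCall:
    """Inside/outside call against the IC morphospace.

    The cascade can only generate monotone molar rows, so a group is
    inside iff its pattern is M1 > M2 > M3, M1 < M2 < M3, or all equal
    (boundary).  Non-monotone patterns (M1 < M2 > M3, M1 > M2 < M3)
    fall outside regardless of distance to the predicted line.
    """
    pattern = classify_pattern(triple.a1, triple.a2, triple.a3, tol=tol)
    comparisons = {pattern[2], pattern[5]}
    inside = not ({"<", ">"} <= comparisons)
    return MorphospaceCall(
        group_id=triple.group_id,
        jaw=triple.jaw,
        r2=triple.r2,
        r3=triple.r3,
        pattern=pattern,
        inside=inside,
    )


def fit_ic_line(
    points,
    method: str = "OLS",
    cov: BMCovariance | None = None,
    weights: SpatialWeights | None = None,
) -> ICFitResult:
    """Regress M3/M1 on M2/M1 and test consistency with the IC line.

    Parameters
    ----------
    points : sequence of (r2, r3) pairs, or an object with ``r2``/``r3``
        columns (a triples DataFrame).
    method : {"OLS", "PGLS", "lagSAR"}
        Regression engine; PGLS needs ``cov`` (Brownian covariance over
        the same groups, in order), lagSAR needs ``weights``.

    The fit is flagged consistent with the cascade when the 95%
    confidence interval of the slope contains 2 and that of the
    intercept contains -1.
    """
    if hasattr(points, "r2") and hasattr(points, "r3"):
        r2 = np.asarray(points.r2, dtype=float)
        r3 = np.asarray(points.r3, dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError("points must be (r2, r3) pairs")
        r2, r3 = arr[:, 0], arr[:, 1]
    if r2.size < 3:
        raise ValidationError(f"need >= 3 points to fit the IC line, got {r2.size}")
    if np.ptp(r2) == 0:
        raise ValidationError("singular design: all M2/M1 ratios identical")

    if method == "OLS":
        result = ols_fit(r2, r3)
    elif method == "PGLS":
        if cov is None:
            raise ValidationError("PGLS fit requires a Brownian covariance (cov=)")
        result = pgls_fit(r2, r3, cov)
    elif method == "lagSAR":
        if weights is None:
            raise ValidationError("lagSAR fit requires spatial weights (weights=)")
        result = lag_sar_fit(r2, r3, weights).as_regression_result()
    else:
        raise ValueError(f"unknown method: {method!r}")

    lo_s, hi_s = result.ci95_slope
    lo_i, hi_i = result.ci95_intercept
    return ICFitResult(
        result=result,
        slope_consistent=bool(lo_s <= IC_SLOPE <= hi_s),
        intercept_consistent=bool(lo_i <= IC_INTERCEPT <= hi_i),
    )
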
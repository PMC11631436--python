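"""Log-log allometry of individual molar size against molar-row size.

For each tooth, log(area) is regressed on log(M1+M2+M3) across groups;
the scaling exponent classifies the tooth as negatively allometric
(CI upper bound < 1), isometric (CI contains 1), or positively
allometric (CI lower bound > 1).  The engine can be OLS, PGLS (with a
phylogeny) or lagSAR (with spatial weights).  Natural logarithms are
used; slope and CI are invariant to the log base since both axes are
transformed identically.

Note: each tooth is regressed on the full row *including itself*; the
part-whole correlation this induces is a property of the quantity
being described, not corrected away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import ValidationError
from .phylo import BMCovariance, RegressionResult, ols_fit, pgls_fit
from .spatial import SpatialWeights, lag_sar_fit

logger = logging.getLogger(__name__)

TEETH = ("M1", "M2", "M3")
AREA_COLUMN = {"M1": "a1", "M2": "a2", "M3": "a3"}


def classify_allometry(ci95: tuple[float, float]) -> str:
    """Classify a scaling exponent by its 95% CI against isometry (1).

    negative iff upper < 1; positive iff lower > 1; isometric otherwise.
    """
    lo, hi = ci95
    if lo > hi:
        raise ValidationError("CI endpoints out of order")
    if hi < 1.0:
        return "negative"
    if lo > 1.0:
        return "positive"
    return "isometric"


@dataclass(frozen=True)
class AllometryRow:
    """One row of a Table-2/3-style allometry summary."""

    jaw: str
    tooth: str
    method: str
    r2: float
    slope: float
    ci95: tuple[float, float]
    allometry_class: str
    result: RegressionResult

    def as_dict(self) -> dict:
        return {
            "jaw": self.jaw,
            "tooth": self.tooth,
            "method": self.method,
            "r2": self.r2,
            "slope": self.slope,
            "ci_lo": self.ci95[0],
            "ci_hi": self.ci95[1],
            "class": self.allometry_class,
        }


def _fit(x, y, method, cov, weights) -> RegressionResult:
    if method == "OLS":
        return ols_fit(x, y)
    if method == "PGLS":
        if cov is None:
            raise ValidationError("PGLS allometry requires a Brownian covariance (cov=)")
        return pgls_fit(x, y, cov)
    if method == "lagSAR":
        if weights is None:
            raise ValidationError("lagSAR allometry requires spatial weights (weights=)")
        return lag_sar_fit(x, y, weights).as_regression_result()
    raise ValueError(f"unknown method: {method!r}")


def loglog_allometry(
    triples: pd.DataFrame,
    tooth: str,
    method: str = "OLS",
    cov: BMCovariance | None = None,
    weights: SpatialWeights | None = None,
) -> AllometryRow:
    """Fit log(area of ``tooth``) ~ log(row) across the groups of one jaw.

    ``triples`` is a triples table (one jaw) as produced by
    :func:`molaric.molar_metrics.aggregate_group`; it must carry
    ``a1..a3``, ``row`` and a single ``jaw`` value.  The covariance /
    weights context must be ordered like the rows of ``triples``.
    """
    if tooth not in TEETH:
        raise ValidationError(f"tooth must be one of {TEETH}, got {tooth!r}")
    jaws = triples["jaw"].unique()
    if len(jaws) != 1:
        raise ValidationError(f"expected a single jaw, got {list(jaws)}")
    if len(triples) < 3:
        raise ValidationError(f"need >= 3 groups, got {len(triples)}")
    x = np.log(triples["row"].to_numpy(dtype=float))
    y = np.log(triples[AREA_COLUMN[tooth]].to_numpy(dtype=float))
    result = _fit(x, y, method, cov, weights)
    return AllometryRow(
        jaw=str(jaws[0]),
        tooth=tooth,
        method=method,
        r2=result.r2,
        slope=result.slope,
        ci95=result.ci95_slope,
        allometry_class=classify_allometry(result.ci95_slope),
        result=result,
    )


def allometry_table(
    triples: pd.DataFrame,
    methods: tuple[str, ...] = ("OLS",),
    cov_by_jaw: dict[str, BMCovariance] | None = None,
    weights_by_jaw: dict[str, SpatialWeights] | None = None,
) -> pd.DataFrame:
    """Full jaw x tooth x method allometry summary.

    Contexts are supplied per jaw because the set of groups with a
    complete triple can differ between jaws.  Returns a tidy DataFrame
    ``jaw, tooth, method, r2, slope, ci_lo, ci_hi, class``.
    """
    rows = []
    for jaw, sub in triples.groupby("jaw", sort=True):
        for method in methods:
            cov = (cov_by_jaw or {}).get(jaw)
            weights = (weights_by_jaw or {}).get(jaw)
            for tooth in TEETH:
                row = loglog_allometry(sub, tooth, method, cov=cov, weights=weights)
                rows.append(row.as_dict())
    return pd.DataFrame(rows)
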
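"""Crown areas, molar-row size, molar ratios, and size-pattern census.

Molar size is estimated as crown area = buccolingual x mesiodistal
diameter (mm^2).  Per group and jaw the three molar areas give the row
size (M1+M2+M3), the ratios M2/M1 and M3/M1, the M2 share of the row,
and a categorical size pattern such as ``"M1>M2>M3"``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import ValidationError

logger = logging.getLogger(__name__)

TRIPLE_COLUMNS = [
    "group_id", "jaw", "a1", "a2", "a3", "row", "r2", "r3", "m2_share", "pattern",
]


def crown_area(md: float, bl: float) -> float:
    """Crown area (mm^2) as the product of mesiodistal and buccolingual
    diameters."""
    if not (md > 0 and bl > 0):
        raise ValidationError(f"diameters must be positive: md={md}, bl={bl}")
    return md * bl


@dataclass(frozen=True)
class MolarTriple:
    """M1, M2, M3 crown areas (mm^2) for one group x jaw, with derived
    row size, ratios, and M2 share.

    ``r2 = a2/a1`` and ``r3 = a3/a1`` are the molar proportions used to
    place the group in the inhibitory-cascade morphospace; ``m2_share``
    is the fraction (not percent) of the row occupied by M2.
    """

    group_id: str
    jaw: str
    a1: float
    a2: float
    a3: float
    row: float = field(init=False)
    r2: float = field(init=False)
    r3: float = field(init=False)
    m2_share: float = field(init=False)

    def __post_init__(self) -> None:
        for name, a in (("a1", self.a1), ("a2", self.a2), ("a3", self.a3)):
            if not (np.isfinite(a) and a > 0):
                raise ValidationError(f"{name} must be a positive area, got {a}")
        object.__setattr__(self, "row", self.a1 + self.a2 + self.a3)
        object.__setattr__(self, "r2", self.a2 / self.a1)
        object.__setattr__(self, "r3", self.a3 / self.a1)
        object.__setattr__(self, "m2_share", self.a2 / self.row)

    @property
    def areas(self) -> tuple[float, float, float]:
        return (self.a1, self.a2, self.a3)

    def pattern(self, tol: float = 0.0) -> str:
        return classify_pattern(self.a1, self.a2, self.a3, tol=tol)


def _compare(x: float, y: float, tol: float) -> str:
    """Adjacent-size comparison with relative tolerance ``tol``."""
    if abs(x - y) <= tol * max(abs(x), abs(y)):
        return "="
    return ">" if x > y else "<"


def classify_pattern(a1: float, a2: float, a3: float, tol: float = 0.0) -> str:
    """Categorical molar-size pattern, e.g. ``"M1>M2>M3"``.

    Adjacent areas whose relative difference is <= ``tol`` compare as
    equal (``=``).  The default ``tol=0`` reports strict inequalities,
    matching how patterns are reported for real-valued group means.
    """
    return f"M1{_compare(a1, a2, tol)}M2{_compare(a2, a3, tol)}M3"


def m2_share(triple: MolarTriple) -> float:
    """M2 area as a percentage of the molar row (M1+M2+M3).

    Any exact inhibitory-cascade triple (areas in arithmetic
    progression) gives exactly 100/3 = 33.333...%.
    """
    return 100.0 * triple.m2_share


def aggregate_group(
    measurements: pd.DataFrame, mode: str = "mean_diameters"
) -> pd.DataFrame:
    """Aggregate per-record diameters into one MolarTriple per (group, jaw).

    Parameters
    ----------
    measurements : DataFrame
        Validated table from :func:`molaric.io_tables.read_measurements`.
    mode : {"mean_diameters", "mean_areas"}
        ``mean_diameters``: area = mean(md) x mean(bl) — appropriate for
        literature-compiled sample-mean diameters (the default).
        ``mean_areas``: area = mean(md x bl) over records — appropriate
        for per-specimen data.  The two differ by the within-group
        covariance of md and bl; they coincide when each tooth has a
        single record.

    Groups lacking any of M1, M2, M3 for a jaw are dropped and logged.

    Returns
    -------
    DataFrame with columns ``group_id, jaw, a1, a2, a3, row, r2, r3,
    m2_share, pattern`` (one row per retained group x jaw).
    """
    if mode not in ("mean_diameters", "mean_areas"):
        raise ValueError(f"unknown aggregation mode: {mode!r}")
    rows = []
    dropped = []
    for (gid, jaw), sub in measurements.groupby(["group_id", "jaw"], sort=True):
        areas = {}
        for tooth, tsub in sub.groupby("tooth"):
            if mode == "mean_diameters":
                areas[tooth] = float(tsub["md"].mean() * tsub["bl"].mean())
            else:
                areas[tooth] = float((tsub["md"] * tsub["bl"]).mean())
        if not {"M1", "M2", "M3"} <= set(areas):
            dropped.append((gid, jaw, sorted(set(areas))))
            continue
        t = MolarTriple(group_id=gid, jaw=jaw, a1=areas["M1"], a2=areas["M2"], a3=areas["M3"])
        rows.append(
            {
                "group_id": gid, "jaw": jaw,
                "a1": t.a1, "a2": t.a2, "a3": t.a3,
                "row": t.row, "r2": t.r2, "r3": t.r3,
                "m2_share": t.m2_share, "pattern": t.pattern(),
            }
        )
    for gid, jaw, present in dropped:
        logger.warning(
            "group %r jaw %r dropped: incomplete molar triple (has %s)",
            gid, jaw, present,
        )
    return pd.DataFrame(rows, columns=TRIPLE_COLUMNS)


def triples_from_frame(df: pd.DataFrame) -> list[MolarTriple]:
    """Materialize :class:`MolarTriple` objects from a triples table."""
    return [
        MolarTriple(group_id=r.group_id, jaw=r.jaw, a1=r.a1, a2=r.a2, a3=r.a3)
        for r in df.itertuples()
    ]


def pattern_census(
    triples: pd.DataFrame | list[MolarTriple], tol: float = 0.0
) -> pd.DataFrame:
    """Count categorical size patterns over a set of molar triples.

    Returns a DataFrame ``pattern, count, percent`` sorted by descending
    count; percentages are over the triples supplied (exclusions for
    missing teeth happen upstream and are logged there).
    """
    if isinstance(triples, pd.DataFrame):
        triples = triples_from_frame(triples)
    if len(triples) == 0:
        raise ValidationError("pattern census of an empty triple set")
    counts = Counter(t.pattern(tol=tol) for t in triples)
    total = sum(counts.values())
    out = pd.DataFrame(
        [
            {"pattern": p, "count": c, "percent": 100.0 * c / total}
            for p, c in counts.most_common()
        ]
    )
    return out
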
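"""Cross-sectional area change and cohort statistics.

The conventional integrated stiffness surrogate is the relative
cross-sectional area change (A_max - A_min)/A_min from a cine series; the
quadrant-resolved stretch is compared across subject groups with a two-way
ANOVA (factors: group and quadrant, with interaction) followed by Tukey
honest-significant-difference comparisons, and against the area change with
Pearson's correlation.  These are standard methods delegated to
statsmodels/scipy behind a thin validated surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import LinearRing
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import GeometryError, ParameterError, StatisticsError, ValidationError
from .geometry import QUADRANT_LABELS


def polygon_area(contour) -> float:
    """Absolute (orientation-independent) shoelace area of a simple polygon, mm^2."""
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ParameterError("polygon needs at least 3 (x, y) vertices")
    if not LinearRing(pts).is_simple:
        raise GeometryError("polygon is self-intersecting")
    x, y = pts[:, 0], pts[:, 1]
    return float(0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


@dataclass
class AreaSeries:
    """Per-frame lumen contours with derived areas (mm^2)."""

    contours: list  # list of (n_i, 2) arrays, mm
    frame_times: np.ndarray | None = None

    def __post_init__(self):
        if len(self.contours) < 2:
            raise ParameterError("an area series needs at least 2 frames")
        self.contours = [np.asarray(c, dtype=float) for c in self.contours]
        self.areas = np.array([polygon_area(c) for c in self.contours])
        if np.any(self.areas <= 0):
            raise ValidationError("all frame areas must be positive")


def relative_area_change(series: AreaSeries) -> float:
    """(A_max - A_min)/A_min over the series, dimensionless."""
    a_min, a_max = float(series.areas.min()), float(series.areas.max())
    if a_min <= 0:
        raise ValidationError("minimum area must be positive")
    return (a_max - a_min) / a_min


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ParameterError("need two equal-length 1-D samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatisticsError("zero variance in one of the samples")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# cohort table and two-way ANOVA


def cohort_table(records) -> pd.DataFrame:
    """Validated long-format cohort table.

    ``records`` is an iterable of (subject, group, quadrant, stretch) rows or
    an equivalent DataFrame; every subject must contribute exactly one row
    per quadrant (4 rows).
    """
    if isinstance(records, pd.DataFrame):
        table = records.copy()
    else:
        table = pd.DataFrame(
            records, columns=["subject", "group", "quadrant", "stretch"]
        )
    required = {"subject", "group", "quadrant", "stretch"}
    if not required.issubset(table.columns):
        raise ValidationError(f"cohort table needs columns {sorted(required)}")
    bad_q = set(table["quadrant"]) - set(QUADRANT_LABELS)
    if bad_q:
        raise ValidationError(f"unknown quadrant labels: {sorted(bad_q)}")
    counts = table.groupby("subject")["quadrant"].agg(["count", "nunique"])
    wrong = counts[(counts["count"] != 4) | (counts["nunique"] != 4)]
    if len(wrong):
        raise ValidationError(
            "each subject must contribute exactly 4 quadrant rows; offending "
            f"subjects: {list(wrong.index)}"
        )
    return table


@dataclass
class AnovaResult:
    """Two-way ANOVA effects plus Tukey pairwise comparisons per factor."""

    effects: pd.DataFrame  # index: group, quadrant, interaction; cols F, p, df
    tukey_group: object
    tukey_quadrant: object

    def p_value(self, effect: str) -> float:
        return float(self.effects.loc[effect, "p"])


def stretch_anova(table) -> AnovaResult:
    """Two-way ANOVA with interaction on per-subject quadrant stretch.

    The unit of observation is the per-subject, per-quadrant mean stretch
    (4 rows per subject); factors are subject group and quadrant.  Tukey HSD
    ranges are computed within each factor.
    """
    table = cohort_table(table)
    groups = table["group"].unique()
    if len(groups) < 2:
        raise StatisticsError("need at least 2 groups")
    n_per_group = table.groupby("group")["subject"].nunique()
    if (n_per_group < 2).any():
        raise StatisticsError(
            f"need >= 2 subjects per group; got {n_per_group.to_dict()}"
        )
    cells = table.groupby(["group", "quadrant"]).size()
    missing = [
        (g, q)
        for g in groups
        for q in QUADRANT_LABELS
        if (g, q) not in cells.index
    ]
    if missing:
        raise StatisticsError(f"empty design cells: {missing}")

    model = ols("stretch ~ C(group) * C(quadrant)", data=table).fit()
    raw = anova_lm(model, typ=2)
    # a perfectly flat table has zero effect and residual sums of squares;
    # report F = 0, p = 1 instead of the 0/0 NaN
    scale = max(float(np.var(table["stretch"])), 0.0)
    if scale < 1e-24 * max(1.0, float(np.mean(table["stretch"]) ** 2)):
        raw["F"] = 0.0
        raw["PR(>F)"] = 1.0
    effects = pd.DataFrame(
        {
            "F": [
                raw.loc["C(group)", "F"],
                raw.loc["C(quadrant)", "F"],
                raw.loc["C(group):C(quadrant)", "F"],
            ],
            "p": [
                raw.loc["C(group)", "PR(>F)"],
                raw.loc["C(quadrant)", "PR(>F)"],
                raw.loc["C(group):C(quadrant)", "PR(>F)"],
            ],
            "df": [
                raw.loc["C(group)", "df"],
                raw.loc["C(quadrant)", "df"],
                raw.loc["C(group):C(quadrant)", "df"],
            ],
        },
        index=["group", "quadrant", "interaction"],
    )
    tukey_group = pairwise_tukeyhsd(table["stretch"], table["group"])
    tukey_quadrant = pairwise_tukeyhsd(table["stretch"], table["quadrant"])
    return AnovaResult(
        effects=effects, tukey_group=tukey_group, tukey_quadrant=tukey_quadrant
    )
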
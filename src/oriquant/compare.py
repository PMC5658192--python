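"""Cross-genotype comparison of per-origin peak areas.

Pairs two peak tables computed against the same origin annotation, scores
their concordance as the squared Pearson correlation of raw areas, and
classifies each origin as shared-active, specific to either genotype, or
inactive, relative to an activity threshold. Origins flagged in either
table (overlapping peak territories, masked, truncated walks) are excluded
from the statistic and reported as "excluded".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import MIN_TRAVERSAL_POINTS, PeakTable

__all__ = [
    "ComparisonResult",
    "join_peak_tables",
    "r_squared",
    "classify_origins",
    "default_activity_threshold",
    "compare_peak_tables",
]

CLASSES = ("shared-active", "genotype1-specific", "genotype2-specific", "inactive", "excluded")


def join_peak_tables(table_a: PeakTable, table_b: PeakTable) -> pd.DataFrame:
    """Inner-join two peak tables on origin id.

    Returns a frame with columns origin_id, area_1, area_2, excluded; an
    origin is excluded when flagged in either table. Ids present in only
    one table indicate an annotation mismatch and raise a warning with
    counts.
    """
    a, b = table_a.by_id(), table_b.by_id()
    only_a, only_b = set(a) - set(b), set(b) - set(a)
    if only_a or only_b:
        warnings.warn(
            f"annotation mismatch: {len(only_a)} ids only in {table_a.genotype}, "
            f"{len(only_b)} only in {table_b.genotype}",
            stacklevel=2,
        )
    shared = [i for i in a if i in b]  # keeps table A's origin order
    return pd.DataFrame(
        {
            "origin_id": shared,
            "area_1": [a[i].area for i in shared],
            "area_2": [b[i].area for i in shared],
            "excluded": [a[i].flagged or b[i].flagged for i in shared],
        }
    )


def r_squared(pairs: pd.DataFrame) -> float:
    """Squared Pearson correlation of raw areas over comparable pairs."""
    ok = pairs.loc[~pairs["excluded"]]
    if len(ok) < 3:
        raise ValueError(f"need >= 3 comparable pairs, have {len(ok)}")
    x = ok["area_1"].to_numpy(float)
    y = ok["area_2"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on an axis: correlation undefined")
    return float(stats.pearsonr(x, y).statistic ** 2)


def default_activity_threshold(theta: float) -> float:
    """Activity cutoff in area units: θ times the minimal traversal length.

    A flat track sitting exactly at the genome mean yields this area over
    the shortest possible walk (origin point plus three points per side),
    so areas below it are indistinguishable from background.
    """
    return theta * MIN_TRAVERSAL_POINTS


def classify_origins(pairs: pd.DataFrame, theta_act: float) -> pd.DataFrame:
    """Assign each paired origin an activity class at threshold ``theta_act``."""
    if theta_act <= 0:
        raise ValueError("theta_act must be positive")
    out = pairs.copy()
    a1 = out["area_1"] >= theta_act
    a2 = out["area_2"] >= theta_act
    cls = np.where(
        a1 & a2,
        "shared-active",
        np.where(a1, "genotype1-specific", np.where(a2, "genotype2-specific", "inactive")),
    )
    out["class"] = np.where(out["excluded"], "excluded", cls)
    return out


@dataclass
class ComparisonResult:
    """Joined, classified origin table with the concordance statistic."""

    genotype1: str
    genotype2: str
    table: pd.DataFrame
    r_squared: float
    theta_act: float

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.table["class"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in CLASSES}

    def write(self, path) -> None:
        cols = ["origin_id", "area_1", "area_2", "class"]
        self.table[cols].to_csv(path, sep="\t", index=False)


def compare_peak_tables(
    table_a: PeakTable, table_b: PeakTable, theta_act: float | None = None
) -> ComparisonResult:
    """Full comparison: join, R², classification.

    ``theta_act`` defaults to the mean of the two samples' genome-mean
    thresholds times the minimal traversal length.
    """
    if theta_act is None:
        theta_act = default_activity_threshold(
            0.5 * (table_a.threshold + table_b.threshold)
        )
    pairs = join_peak_tables(table_a, table_b)
    classified = classify_origins(pairs, theta_act)
    return ComparisonResult(
        table_a.genotype, table_b.genotype, classified, r_squared(pairs), theta_act
    )
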
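"""QA/QC statistics, false-positive arithmetic and group comparison.

Covers the method-performance numbers of the screening workflow: replicate
relative standard deviation, identification efficiency of spiked labelled
standards, false-positive rates of the diagnostic-ion rule, fold-change
differential analysis between sample groups, and the per-mode comparison
report (precursor ions / candidate ions / confidence-level counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FeatureMatrix",
    "ComparisonReport",
    "rsd",
    "false_positive_rate",
    "identification_efficiency",
    "differential_analysis",
    "build_comparison_report",
]


@dataclass
class FeatureMatrix:
    """Replicate intensity matrix: rows are features, columns replicates.

    ``groups`` maps a group label (e.g. ``fertile``, ``infertile``,
    ``blank``) to its replicate column names in ``data``. Missing values
    are NaN.
    """

    data: pd.DataFrame  # indexed by feature, with (mz, rt_min) columns present
    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        for g, cols in self.groups.items():
            missing = [c for c in cols if c not in self.data.columns]
            if missing:
                raise ValueError(f"group {g!r}: missing columns {missing}")

    def replicate_counts(self) -> dict[str, int]:
        return {g: len(cols) for g, cols in self.groups.items()}


def rsd(intensities) -> float:
    """Relative standard deviation of replicate intensities, in percent.

    100 x sample standard deviation / mean, reported to one decimal.
    Requires at least two replicates and a positive mean.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        raise ValueError("RSD requires at least two replicate values")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("RSD undefined for non-positive mean intensity")
    return float(round(100.0 * x.std(ddof=1) / mean, 1))


def false_positive_rate(n_false: int, n_total: int, decimals: int = 1) -> float:
    """Percentage of false positives, rounded half-up.

    ``decimals=1`` matches the labelled-standard reporting style (21.4%);
    ``decimals=0`` the feature-level style (86%).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_false <= n_total):
        raise ValueError("n_false must lie in [0, n_total]")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(n_false) / Decimal(n_total)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


def identification_efficiency(
    spiked_names: list[str],
    identified_names: list[str],
) -> dict:
    """Identification efficiency of spiked standards, plus extras.

    Returns the identified/spiked fraction together with the per-standard
    hit table; identified names that were never spiked are counted
    separately as false positives (their rate uses the spiked count as
    denominator, the convention for labelled-standard QC).
    """
    if not spiked_names:
        raise ValueError("spiked standard list is empty")
    spiked = list(dict.fromkeys(spiked_names))
    identified = set(identified_names)
    hits = [name for name in spiked if name in identified]
    extras = sorted(identified - set(spiked))
    table = pd.DataFrame(
        {"name": spiked, "identified": [n in identified for n in spiked]}
    )
    return {
        "n_spiked": len(spiked),
        "n_identified": len(hits),
        "efficiency": len(hits) / len(spiked),
        "n_false_positive": len(extras),
        "false_positive_rate": false_positive_rate(len(extras), len(spiked)),
        "table": table,
        "extras": extras,
    }


def differential_analysis(
    matrix: FeatureMatrix,
    group_a: str,
    group_b: str,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    detection_floor: float = 0.0,
) -> pd.DataFrame:
    """Fold-change + significance labelling between two groups.

    Fold change is mean(b)/mean(a) on raw intensities; the p-value is a
    two-sided Welch t-test on log10 intensities. Labels: ``up`` if fold >
    ``fold_threshold`` and p < ``alpha``; ``down`` if fold <
    1/``fold_threshold`` and p < ``alpha``; else ``unchanged``. A feature
    entirely missing from one group gets an infinite (or zero) fold and is
    labelled up/down only if every present replicate exceeds
    ``detection_floor``; no p-value is computed for it. Identical groups
    with zero variance get p = 1 by convention.
    """
    cols_a = matrix.groups[group_a]
    cols_b = matrix.groups[group_b]
    rows = []
    for idx, row in matrix.data.iterrows():
        a = row[cols_a].to_numpy(dtype=float)
        b = row[cols_b].to_numpy(dtype=float)
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        fold = np.nan
        p = np.nan
        label = "unchanged"
        if a.size == 0 and b.size == 0:
            pass
        elif a.size == 0 or b.size == 0:
            present = b if a.size == 0 else a
            fold = np.inf if a.size == 0 else 0.0
            if present.min() > detection_floor:
                label = "up" if a.size == 0 else "down"
        else:
            fold = float(b.mean() / a.mean()) if a.mean() > 0 else np.inf
            if a.size >= 2 and b.size >= 2:
                la, lb = np.log10(a), np.log10(b)
                if la.std(ddof=1) == 0 and lb.std(ddof=1) == 0:
                    p = 1.0 if la.mean() == lb.mean() else 0.0
                else:
                    p = float(sps.ttest_ind(lb, la, equal_var=False).pvalue)
                if p < alpha:
                    if fold > fold_threshold:
                        label = "up"
                    elif fold < 1.0 / fold_threshold:
                        label = "down"
        rows.append(
            {
                "feature": idx,
                "mz": row.get("mz", np.nan),
                "rt_min": row.get("rt_min", np.nan),
                "fold_change": fold,
                "p_value": p,
                "label": label,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


@dataclass
class ComparisonReport:
    """Per-mode/sample counts: precursor ions through confidence levels."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_text(self) -> str:
        if self.rows.empty:
            return "no annotated sets\n"
        return self.rows.to_string(index=False) + "\n"


def build_comparison_report(per_mode_counts: list[dict]) -> ComparisonReport:
    """Assemble the mode/sample comparison table and check count sanity.

    Each input dict carries ``mode``, ``sample``, ``n_precursor_ions``,
    ``n_candidate_ions`` and level counts. The invariant chain
    precursor >= candidate >= sum(level counts) is asserted — a violation
    indicates a pipeline bookkeeping bug, not a data property.
    """
    if not per_mode_counts:
        raise ValueError("at least one analyzed mode is required")
    cols = [
        "mode", "sample", "n_precursor_ions", "n_candidate_ions",
        "n_level1", "n_level2", "n_level3",
    ]
    rows = []
    for rec in per_mode_counts:
        row = {c: rec.get(c, 0) for c in cols}
        n_levels = row["n_level1"] + row["n_level2"] + row["n_level3"]
        if row["n_candidate_ions"] > row["n_precursor_ions"]:
            raise ValueError(
                f"{row['mode']}/{row['sample']}: candidate count exceeds "
                "precursor count"
            )
        if n_levels > row["n_candidate_ions"]:
            raise ValueError(
                f"{row['mode']}/{row['sample']}: level counts exceed "
                "candidate count"
            )
        rows.append(row)
    return ComparisonReport(rows=pd.DataFrame(rows, columns=cols))
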
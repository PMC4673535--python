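"""Expression-level primitives for single-array-per-group microarray profiles.

The experimental design this package models is a pooled design: RNA from
8-10 animals per group is pooled and hybridized onto one array per group,
for four groups (normal small-IEC, normal large-IEC, inflamed small-IEC,
inflamed large-IEC).  With no within-group replication, differential calls
are made by dual thresholds on fold change and absolute fluorescence
intensity rather than by per-probe hypothesis tests:

* main filter   -- fold change > 2 and the higher-expressed side's
                   background-subtracted intensity > 100 arbitrary units;
* high tier     -- same fold criterion with intensity > 10,000 units.

Presence ("expressed") calls use a single pooled median computed over the
valid spots of all four arrays of a channel; a probe is expressed in a
group when its intensity strictly exceeds that pooled median.

All threshold comparisons are strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Default dual-threshold parameters (arbitrary fluorescence units).
FOLD_THRESHOLD = 2.0
INTENSITY_THRESHOLD = 100.0
HIGH_TIER_INTENSITY = 10_000.0

RECORD_COLUMNS = [
    "probe_id",
    "group_a",
    "group_b",
    "intensity_a",
    "intensity_b",
    "log2_fc",
    "direction",
    "passes_main_filter",
    "passes_high_tier",
]


@dataclass
class ExpressionMatrix:
    """Probe x group table of background-subtracted intensities.

    Parameters
    ----------
    intensity:
        DataFrame indexed by unique probe ids with one column per group.
    channel:
        ``"miRNA"`` or ``"mRNA"``.
    valid:
        Boolean DataFrame of the same shape flagging valid spots; defaults
        to all-valid.
    """

    intensity: pd.DataFrame
    channel: str
    valid: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.channel not in ("miRNA", "mRNA"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.intensity.index.duplicated().any():
            raise ValueError("duplicate probe ids")
        if self.intensity.columns.duplicated().any():
            raise ValueError("duplicate group labels")
        if self.valid is None:
            self.valid = pd.DataFrame(
                True, index=self.intensity.index, columns=self.intensity.columns
            )
        if not self.valid.index.equals(self.intensity.index) or not (
            self.valid.columns.equals(self.intensity.columns)
        ):
            raise ValueError("valid mask must align with the intensity table")
        vals = self.intensity.to_numpy(dtype=float)
        mask = self.valid.to_numpy(dtype=bool)
        if not np.isfinite(vals[mask]).all():
            raise ValueError("non-finite intensity on a valid spot")
        if (vals[mask] < 0).any():
            raise ValueError("negative intensity on a valid spot")

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensity.index

    @property
    def groups(self) -> list[str]:
        return list(self.intensity.columns)

    def to_tsv(self, path) -> None:
        self.intensity.rename_axis("probe_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, channel: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        return cls(intensity=df, channel=channel)


def log2_fold_change(intensity_a: float, intensity_b: float, floor: float = 1.0) -> float:
    """log2 of ``b`` over ``a`` with both sides clamped at ``floor``.

    The floor keeps background-level spots from producing infinite ratios.
    Antisymmetric: swapping the arguments negates the result.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    a, b = float(intensity_a), float(intensity_b)
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError("non-finite intensity")
    return math.log2(max(b, floor) / max(a, floor))


def differential_table(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    *,
    floor: float = 1.0,
    fold_threshold: float = FOLD_THRESHOLD,
    intensity_threshold: float = INTENSITY_THRESHOLD,
    high_tier_intensity: float = HIGH_TIER_INTENSITY,
) -> pd.DataFrame:
    """Per-probe differential records for ``group_b`` versus ``group_a``.

    ``group_a`` is the reference: positive ``log2_fc`` means higher in
    ``group_b``.  Only spots valid in both groups are compared.  The
    intensity gate applies to the higher-expressed side of each probe.
    """
    for g in (group_a, group_b):
        if g not in matrix.intensity.columns:
            raise KeyError(f"unknown group {g!r}")
    ok = matrix.valid[group_a] & matrix.valid[group_b]
    a = matrix.intensity.loc[ok, group_a].to_numpy(dtype=float)
    b = matrix.intensity.loc[ok, group_b].to_numpy(dtype=float)
    if floor <= 0:
        raise ValueError("floor must be positive")
    fc = np.log2(np.maximum(b, floor) / np.maximum(a, floor))
    peak = np.maximum(a, b)
    log2_thresh = math.log2(fold_threshold)
    main = (np.abs(fc) > log2_thresh) & (peak > intensity_threshold)
    high = (np.abs(fc) > log2_thresh) & (peak > high_tier_intensity)
    direction = np.where(~main, "unchanged", np.where(fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "probe_id": matrix.intensity.index[ok],
            "group_a": group_a,
            "group_b": group_b,
            "intensity_a": a,
            "intensity_b": b,
            "log2_fc": fc,
            "direction": direction,
            "passes_main_filter": main,
            "passes_high_tier": high,
        }
    )


def _refilter(
    records: pd.DataFrame, fold_threshold: float, intensity_threshold: float
) -> pd.DataFrame:
    missing = {"log2_fc", "intensity_a", "intensity_b"} - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    fc = records["log2_fc"].to_numpy(dtype=float)
    peak = np.maximum(
        records["intensity_a"].to_numpy(dtype=float),
        records["intensity_b"].to_numpy(dtype=float),
    )
    keep = (np.abs(fc) > math.log2(fold_threshold)) & (peak > intensity_threshold)
    out = records.loc[keep].copy()
    out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    return out


def apply_main_filter(
    records: pd.DataFrame,
    *,
    fold_threshold: float = FOLD_THRESHOLD,
    intensity_threshold: float = INTENSITY_THRESHOLD,
) -> pd.DataFrame:
    """Keep records with fold change and peak intensity above the main gates."""
    return _refilter(records, fold_threshold, intensity_threshold)


def apply_high_tier(
    records: pd.DataFrame,
    *,
    fold_threshold: float = FOLD_THRESHOLD,
    intensity_threshold: float = HIGH_TIER_INTENSITY,
) -> pd.DataFrame:
    """Keep records passing the stricter >10,000-unit intensity gate."""
    return _refilter(records, fold_threshold, intensity_threshold)


def presence_calls(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Expressed/not-expressed calls against the pooled-median threshold.

    One median is computed over the valid intensities of *all* arrays of
    the channel; a probe is expressed in a group when its spot is valid and
    its intensity strictly exceeds that pooled median.
    """
    vals = matrix.intensity.to_numpy(dtype=float)
    mask = matrix.valid.to_numpy(dtype=bool)
    pooled = vals[mask]
    if pooled.size == 0:
        raise ValueError("no valid spots")
    threshold = float(np.median(pooled))
    frames = []
    for g in matrix.groups:
        expressed = (matrix.intensity[g] > threshold) & matrix.valid[g]
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": matrix.probe_ids,
                    "group": g,
                    "expressed": expressed.to_numpy(),
                    "threshold_used": threshold,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def expressed_sets(matrix: ExpressionMatrix) -> dict[str, set[str]]:
    """Per-group sets of expressed probe ids (pooled-median rule)."""
    calls = presence_calls(matrix)
    return {
        g: set(sub.loc[sub["expressed"], "probe_id"])
        for g, sub in calls.groupby("group", sort=False)
    }


def relative_quantification_ddct(
    ct_target: float,
    ct_reference: float,
    ct_target_cal: float,
    ct_reference_cal: float,
) -> float:
    """Fold change by the comparative-Ct (delta-delta-Ct) method.

    ``ct_reference`` is the endogenous control (U6 for miRNA, beta-actin
    for mRNA); the calibrator is the untreated sample.  Returns
    ``2 ** -((Ct_t - Ct_r) - (Ct_t,cal - Ct_r,cal))``.
    """
    cts = (ct_target, ct_reference, ct_target_cal, ct_reference_cal)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("non-finite Ct value")
    ddct = (ct_target - ct_reference) - (ct_target_cal - ct_reference_cal)
    return 2.0 ** (-ddct)


def two_sample_t(group1, group2) -> tuple[float, float]:
    """Classical pooled-variance two-sample t test (two-sided).

    Degenerate case: if the pooled variance is zero and the means are equal
    the test is uninformative and ``(0.0, 1.0)`` is returned by convention.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)
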
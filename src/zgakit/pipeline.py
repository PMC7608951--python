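"""Gene-classification procedures for ZGA under cell-cycle arrest.

Conditions are addressed by '<condition>:<cycle_label>' keys, e.g.
``control:C12``, ``control:C14L``, ``arrested:30``. All comparisons are
made on condition means of Log2(CPM+1), replicate embryos averaged first.

The arrest-response grouping mirrors the three observed phenotypes:
group 1 — mRNA rises during the cycle-12 arrest with no initial dip;
group 2 — an initial decrease (maternal degradation dominating) at 30 and
50 minutes of arrest followed by re-accumulation at 70 minutes; group 3 —
no increase during the arrest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from zgakit.expression import ExpressionMatrix


@dataclass(frozen=True)
class ClassifierConfig:
    fold_change_threshold: float = 1.5
    alpha: float = 0.05
    increase_margin: float = 0.0  # Log2 units
    baseline_label: str = "control:C12"
    #: require the dip at both 30' and 50' ("both") or at either ("either")
    decrease_mode: str = "both"

    def __post_init__(self) -> None:
        if not self.fold_change_threshold > 1:
            raise ValueError("fold_change_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.increase_margin < 0:
            raise ValueError("increase_margin must be >= 0")
        if self.decrease_mode not in ("both", "either"):
            raise ValueError("decrease_mode must be 'both' or 'either'")


@dataclass(frozen=True)
class ClassificationResult:
    """Per-gene labels plus the statistics that produced them."""

    table: pd.DataFrame
    counts: dict = field(default_factory=dict)


def _replicate_columns(matrix: ExpressionMatrix, label: str) -> list[str]:
    keys = matrix.condition_key()
    cols = list(keys.index[keys == label])
    if not cols:
        raise KeyError(f"condition {label!r} not present in matrix")
    return cols


def identify_zygotic(
    matrix: ExpressionMatrix,
    late_label: str,
    early_label: str,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Flag genes up-regulated late vs early in control embryos.

    A gene is called zygotic iff its linear fold change (from the
    difference of mean Log2 CPM+1) is strictly greater than the threshold
    AND a Welch two-sample t test on the replicate Log2 CPM+1 values gives
    p strictly below alpha. Returns a per-gene table with the supporting
    statistics (mean_early, mean_late, log2_fc, fold_change, p_value,
    zygotic).
    """
    matrix._require_stage("log2cpm", "identify_zygotic")
    late_cols = _replicate_columns(matrix, late_label)
    early_cols = _replicate_columns(matrix, early_label)
    for label, cols in ((late_label, late_cols), (early_label, early_cols)):
        if len(cols) < 2:
            raise ValueError(f"condition {label!r} has < 2 replicates")
    late = matrix.values[late_cols].to_numpy(dtype=float)
    early = matrix.values[early_cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(late, early, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance ties
    log2_fc = late.mean(axis=1) - early.mean(axis=1)
    fc = 2.0**log2_fc
    out = pd.DataFrame(
        {
            "mean_early": early.mean(axis=1),
            "mean_late": late.mean(axis=1),
            "log2_fc": log2_fc,
            "fold_change": fc,
            "p_value": pvals,
            "zygotic": (fc > cfg.fold_change_threshold) & (pvals < cfg.alpha),
        },
        index=matrix.values.index,
    )
    out.index.name = "gene_id"
    return out


def intersect_with_prior(own: list[str], prior: list[str]) -> list[str]:
    """Genes present in both lists, in the order they appear in ``own``."""
    prior_set = set(prior)
    return [g for g in own if g in prior_set]


def categorize_groups(
    matrix: ExpressionMatrix,
    analyzed: list[str],
    arrest_labels_ordered: list[str] = (
        "arrested:15",
        "arrested:30",
        "arrested:50",
        "arrested:70",
    ),
    cfg: ClassifierConfig = ClassifierConfig(),
) -> ClassificationResult:
    """Partition the analyzed zygotic genes into arrest-response groups.

    Using condition means relative to the baseline (control C12 by
    default), with the last three arrest time points (30', 50', 70'):

    * initial decrease: value below baseline - margin at both 30' and 50'
      (or either, per config);
    * group 1: no initial decrease AND value(70') > baseline + margin;
    * group 2: initial decrease AND value(70') > min(value(30'),
      value(50')) + margin (re-accumulation);
    * group 3: the remainder (no increase upon arrest).

    The 15' point is carried in the output for profiles but plays no role
    in the rule.
    """
    matrix._require_stage("log2cpm", "categorize_groups")
    if not analyzed:
        raise ValueError("analyzed gene set must be non-empty")
    if len(arrest_labels_ordered) < 3:
        raise ValueError("need at least the 30/50/70-minute arrest labels")
    means = matrix.condition_means()
    needed = [cfg.baseline_label, *arrest_labels_ordered]
    missing = [lbl for lbl in needed if lbl not in means.columns]
    if missing:
        raise KeyError(f"condition(s) not present: {missing}")
    absent = set(analyzed) - set(means.index)
    if absent:
        raise KeyError(f"genes not in matrix: {sorted(absent)[:5]}")

    sub = means.loc[list(analyzed)]
    base = sub[cfg.baseline_label]
    l30, l50, l70 = arrest_labels_ordered[-3:]
    v30, v50, v70 = sub[l30], sub[l50], sub[l70]
    m = cfg.increase_margin

    dec30 = v30 < base - m
    dec50 = v50 < base - m
    decrease = (dec30 & dec50) if cfg.decrease_mode == "both" else (dec30 | dec50)
    group1 = ~decrease & (v70 > base + m)
    group2 = decrease & (v70 > np.minimum(v30, v50) + m)
    label = pd.Series("3", index=sub.index)
    label[group2] = "2"
    label[group1] = "1"

    table = pd.DataFrame(
        {
            "group": label,
            "baseline": base,
            l30.split(":")[-1] + "_min": v30,
            l50.split(":")[-1] + "_min": v50,
            l70.split(":")[-1] + "_min": v70,
            "initial_decrease": decrease,
        }
    )
    if len(arrest_labels_ordered) == 4:
        table.insert(2, "15_min", sub[arrest_labels_ordered[0]])
    table.index.name = "gene_id"
    counts = {
        "analyzed": len(table),
        "group1": int((label == "1").sum()),
        "group2": int((label == "2").sum()),
        "group3": int((label == "3").sum()),
        "initial_decrease": int(decrease.sum()),
    }
    return ClassificationResult(table=table, counts=counts)


def select_maternal(
    prior_maternal: list[str],
    matrix: ExpressionMatrix,
    early_label: str = "control:C12",
    late_label: str = "control:C14L",
    margin: float = 0.0,
) -> list[str]:
    """Previously reported purely-maternal genes whose abundance also
    decreases across the control time course (late mean below early mean
    by more than ``margin`` Log2 units)."""
    matrix._require_stage("log2cpm", "select_maternal")
    means = matrix.condition_means()
    for lbl in (early_label, late_label):
        if lbl not in means.columns:
            raise KeyError(f"condition {lbl!r} not present")
    present = [g for g in prior_maternal if g in means.index]
    sub = means.loc[present]
    keep = sub[late_label] < sub[early_label] - margin
    return list(sub.index[keep])


def feature_enrichment(
    set_a: list[str], set_b: list[str], feature_members: list[str]
):
    """Fisher's exact test for a priming feature between two gene sets.

    Builds the 2x2 table (rows: set a / set b; columns: feature-positive /
    feature-negative) and returns ``(table, odds_ratio, p_two_sided)``.
    The sets must be disjoint for the contingency design to be valid.
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("both gene sets must be non-empty")
    overlap = a & b
    if overlap:
        raise ValueError(f"gene sets overlap ({len(overlap)} genes); must be disjoint")
    feat = set(feature_members)
    table = np.array(
        [
            [len(a & feat), len(a - feat)],
            [len(b & feat), len(b - feat)],
        ]
    )
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return table, odds_ratio, p
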
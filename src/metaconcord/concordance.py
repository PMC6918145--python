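"""Cross-method concordance cascade for two-sample relative quantification.

Given the integrated dataset (several analytical methods, each reporting
triplicate intensities for two cell-extract samples), this module answers,
per metabolite: do the methods agree on the HT-29/AsPc-1 ratio?

The cascade:

1. **Replicate ratios.**  For each method, HT-29 and AsPc-1 replicate
   intensities are paired by replicate index (run order) and divided,
   yielding up to three dimensionless ratios per method.  Pairs with a zero
   denominator are dropped with a warning; a method contributing fewer than
   two surviving pairs is excluded for that metabolite.
2. **Per-method significance.**  A two-sided Student's t-test (pooled
   variance, alpha = 0.05) on raw HT-29 vs AsPc-1 intensities decides
   whether the method sees a difference at all; the direction (up/down) is
   read off the mean ratio against 1.
3. **Direction discordance.**  A metabolite is flagged when at least one
   method is significantly up and another significantly down — the clearest
   form of cross-method contradiction.
4. **Homogeneity.**  A one-way ANOVA across methods, on the replicate
   ratios, tests whether all methods report the same relative level
   (concordant iff p > alpha).
5. **Leave-one-method-out rescue.**  When the full ANOVA rejects, it is
   re-run omitting each method in turn; if some omission restores p > alpha
   the metabolite is "rescued" and the omitted method maximizing p is
   reported as the outlier (ties broken by method id).  At least three
   methods are required — with two discordant methods no outlier is
   identifiable.

No multiple-testing correction is applied anywhere in the cascade; every
test runs at its nominal alpha.  Counts are aggregated into a six-row
summary (identified / multi-method / t-significant / direction-discordant /
ANOVA-concordant / concordant-with-rescue) per category and in total, with
percentages rounded half-away-from-zero to one decimal.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SAMPLES, CATEGORIES, IntegratedDataset, replicate_arrays

__all__ = [
    "Direction",
    "Classification",
    "RatioSet",
    "TTestResult",
    "AnovaResult",
    "RescueResult",
    "ConcordanceRecord",
    "SummaryTable",
    "ratio_replicates",
    "student_t_test",
    "one_way_anova",
    "direction_discordant",
    "leave_one_out_rescue",
    "classify",
    "records_to_frame",
    "round_half_away",
]

logger = logging.getLogger(__name__)


class Direction(enum.Enum):
    UP = "up"
    DOWN = "down"
    NONE = "none"


class Classification(enum.Enum):
    SINGLE_METHOD = "single_method"
    CONCORDANT = "concordant"
    RESCUED_ONE_OUTLIER = "rescued_one_outlier"
    DISCORDANT = "discordant"


# ---------------------------------------------------------------------------
# Ratios
# ---------------------------------------------------------------------------


@dataclass
class RatioSet:
    """Per-replicate HT-29/AsPc-1 ratios for one (method, metabolite)."""

    method_id: str
    metabolite: str
    ratios: tuple[float, ...]
    mean: float
    sd: float

    @property
    def n(self) -> int:
        return len(self.ratios)


def ratio_replicates(
    ht29: Sequence[float],
    aspc1: Sequence[float],
    method_id: str = "",
    metabolite: str = "",
    mode: str = "paired_replicates",
) -> Optional[RatioSet]:
    """Form HT-29/AsPc-1 ratios for one method x metabolite cell.

    ``ht29`` and ``aspc1`` are replicate vectors aligned by replicate index
    (NaN = missing).  In the default ``paired_replicates`` mode, ratio_i =
    HT29_i / ASPC1_i for every index present in both samples; pairs with a
    zero denominator are dropped with a warning, and fewer than two
    surviving pairs excludes the method (returns None).  In
    ``ratio_of_means`` mode a single ratio of the sample means is returned
    (such methods cannot enter the cross-method ANOVA, which needs at least
    two observations per group).
    """
    h = np.asarray(ht29, dtype=float)
    a = np.asarray(aspc1, dtype=float)
    if h.shape != a.shape:
        raise ValueError("replicate vectors must be aligned")

    if mode == "ratio_of_means":
        hv, av = h[~np.isnan(h)], a[~np.isnan(a)]
        if len(hv) == 0 or len(av) == 0 or float(np.mean(av)) == 0.0:
            return None
        r = float(np.mean(hv)) / float(np.mean(av))
        return RatioSet(method_id, metabolite, (r,), r, 0.0)
    if mode != "paired_replicates":
        raise ValueError(f"unknown ratio mode {mode!r}")

    paired = ~np.isnan(h) & ~np.isnan(a)
    zero_den = paired & (a == 0)
    if zero_den.any():
        logger.warning(
            "method %s, metabolite %s: dropping %d replicate pair(s) with "
            "zero AsPc-1 intensity",
            method_id,
            metabolite,
            int(zero_den.sum()),
        )
    keep = paired & ~zero_den
    if int(keep.sum()) < 2:
        logger.warning(
            "method %s, metabolite %s: <2 usable replicate pairs; method "
            "excluded for this metabolite",
            method_id,
            metabolite,
        )
        return None
    ratios = tuple(float(x) for x in h[keep] / a[keep])
    return RatioSet(
        method_id,
        metabolite,
        ratios,
        float(np.mean(ratios)),
        float(np.std(ratios, ddof=1)),
    )


# ---------------------------------------------------------------------------
# Student's t-test
# ---------------------------------------------------------------------------


@dataclass
class TTestResult:
    t_statistic: float
    dof: int
    p_value: float
    significant: bool
    direction: Direction
    alpha: float = 0.05


def student_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = 0.05,
    ratio_mean: Optional[float] = None,
) -> TTestResult:
    """Two-sided pooled-variance (Student's) two-sample t-test.

    ``ratio_mean`` — the mean HT-29/AsPc-1 ratio for the same cell — fixes
    the reported direction (up iff > 1) when the test is significant; if it
    is not supplied, direction falls back to the comparison of group means.
    Zero pooled variance is handled by convention: equal means -> p = 1,
    unequal means -> p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values for a t-test")
    dof = len(a) + len(b) - 2

    ss = float(np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
    if ss == 0.0:
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat = math.inf if a.mean() > b.mean() else -math.inf
            p = 0.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p = float(t_stat), float(p)

    significant = p < alpha
    direction = Direction.NONE
    if significant:
        key = ratio_mean if ratio_mean is not None else (
            math.inf if a.mean() > b.mean() else -math.inf
        )
        pivot = 1.0 if ratio_mean is not None else 0.0
        if key > pivot:
            direction = Direction.UP
        elif key < pivot:
            direction = Direction.DOWN
    return TTestResult(t_stat, dof, p, significant, direction, alpha)


# ---------------------------------------------------------------------------
# One-way ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    f_statistic: float
    dof_between: int
    dof_within: int
    p_value: float


def one_way_anova(groups: Sequence[Sequence[float]]) -> Optional[AnovaResult]:
    """Classical one-way ANOVA (between/within decomposition).

    Groups with fewer than two values are excluded with a warning; if fewer
    than two groups remain the result is absent (None).  Degenerate inputs
    (zero within-group variance) resolve to F = 0, p = 1 when the group
    means also coincide, else F = inf, p = 0.
    """
    usable = [np.asarray(g, dtype=float) for g in groups]
    usable = [g[~np.isnan(g)] for g in usable]
    dropped = sum(1 for g in usable if len(g) < 2)
    if dropped:
        logger.warning("one_way_anova: excluding %d group(s) with <2 values", dropped)
    usable = [g for g in usable if len(g) >= 2]
    if len(usable) < 2:
        return None

    k = len(usable)
    n_total = sum(len(g) for g in usable)
    dof_between, dof_within = k - 1, n_total - k

    ssw = float(sum(np.sum((g - g.mean()) ** 2) for g in usable))
    if ssw == 0.0:
        grand = float(np.concatenate(usable).mean())
        ssb = float(sum(len(g) * (g.mean() - grand) ** 2 for g in usable))
        if ssb == 0.0:
            return AnovaResult(0.0, dof_between, dof_within, 1.0)
        return AnovaResult(math.inf, dof_between, dof_within, 0.0)

    f_stat, p = stats.f_oneway(*usable)
    return AnovaResult(float(f_stat), dof_between, dof_within, float(p))


# ---------------------------------------------------------------------------
# Discordance and rescue
# ---------------------------------------------------------------------------


def direction_discordant(results: Sequence[TTestResult]) -> bool:
    """True iff one method is significantly up while another is
    significantly down (relative level vs 1)."""
    dirs = {r.direction for r in results if r.significant}
    return Direction.UP in dirs and Direction.DOWN in dirs


@dataclass
class RescueResult:
    rescued: bool
    outlier_method: Optional[str] = None
    p_after: Optional[float] = None
    candidates: tuple[tuple[str, float], ...] = ()
    reason: Optional[str] = None


def leave_one_out_rescue(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> RescueResult:
    """Re-run the cross-method ANOVA omitting each method in turn.

    Intended for metabolites whose full-set ANOVA rejected homogeneity
    (p < alpha).  Rescued iff some omission yields p > alpha; the reported
    outlier is the omission maximizing p (ties broken by method id order),
    and all rescuing candidates are retained.  Requires >= 3 methods:
    removing one must leave a two-group ANOVA.
    """
    method_ids = sorted(groups)
    if len(method_ids) < 3:
        return RescueResult(False, reason="insufficient methods")

    candidates: list[tuple[str, float]] = []
    best: Optional[tuple[str, float]] = None
    for omit in method_ids:
        res = one_way_anova([groups[m] for m in method_ids if m != omit])
        if res is None:
            continue
        if res.p_value > alpha:
            candidates.append((omit, res.p_value))
        if best is None or res.p_value > best[1]:
            best = (omit, res.p_value)  # strict > keeps first max on ties
    if not candidates:
        return RescueResult(False, reason="no omission restores homogeneity")
    assert best is not None
    return RescueResult(
        True,
        outlier_method=best[0],
        p_after=best[1],
        candidates=tuple(candidates),
    )


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

ROW_KEYS = (
    "identified_any",
    "multi_method_both",
    "t_significant_multi",
    "direction_discordant",
    "anova_concordant",
    "concordant_with_rescue",
)

ROW_LABELS = {
    "identified_any": "Identified from either sample by >=1 method",
    "multi_method_both": "Identified from both samples by >=2 methods",
    "t_significant_multi": "t-test significant (HT-29 vs AsPc-1) in >=2 methods",
    "direction_discordant": "Significant in opposite directions across methods",
    "anova_concordant": "Homogeneous ratios across methods (ANOVA p > alpha)",
    "concordant_with_rescue": "Homogeneous after ignoring at most one outlier method",
}

# percentage name -> (numerator row, denominator row)
PCT_DEFS = {
    "multi_method_pct": ("multi_method_both", "identified_any"),
    "direction_discordant_pct": ("direction_discordant", "t_significant_multi"),
    "anova_concordant_pct": ("anova_concordant", "multi_method_both"),
    "concordant_with_rescue_pct": ("concordant_with_rescue", "multi_method_both"),
}

COLUMNS = ("hydrophilic", "hydrophobic", "total")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (Decimal ROUND_HALF_UP)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SummaryTable:
    """Six-row x three-column concordance summary plus derived percentages."""

    counts: dict[str, dict[str, int]]
    percentages: dict[str, dict[str, float]]
    alpha: float = 0.05

    @classmethod
    def from_category_counts(
        cls,
        hydrophilic: Sequence[int],
        hydrophobic: Sequence[int],
        alpha: float = 0.05,
    ) -> "SummaryTable":
        """Aggregate six per-category counts (rows 1-6) into totals and
        percentages."""
        if len(hydrophilic) != 6 or len(hydrophobic) != 6:
            raise ValueError("expected six per-category counts (rows 1-6)")
        counts: dict[str, dict[str, int]] = {}
        for i, row in enumerate(ROW_KEYS):
            h, l = int(hydrophilic[i]), int(hydrophobic[i])
            counts[row] = {
                "hydrophilic": h,
                "hydrophobic": l,
                "total": h + l,
            }
        percentages: dict[str, dict[str, float]] = {}
        for name, (num_row, den_row) in PCT_DEFS.items():
            percentages[name] = {}
            for col in COLUMNS:
                den = counts[den_row][col]
                pct = 100.0 * counts[num_row][col] / den if den else 0.0
                percentages[name][col] = round_half_away(pct, 1)
        return cls(counts=counts, percentages=percentages, alpha=alpha)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "counts": self.counts,
            "percentages": self.percentages,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for row in ROW_KEYS:
            rows.append(
                {"row": row, "label": ROW_LABELS[row], **self.counts[row]}
            )
        return pd.DataFrame(rows, columns=["row", "label", *COLUMNS])


# ---------------------------------------------------------------------------
# Per-metabolite classification
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceRecord:
    """Everything the cascade concluded about one metabolite."""

    metabolite: str
    category: str  # hydrophilic | hydrophobic
    n_methods: int  # methods contributing a valid RatioSet
    n_methods_detected_both: int
    ratio_sets: dict[str, RatioSet] = field(default_factory=dict)
    t_results: dict[str, TTestResult] = field(default_factory=dict)
    anova: Optional[AnovaResult] = None
    classification: Classification = Classification.SINGLE_METHOD
    direction_discordant: bool = False
    outlier_method: Optional[str] = None
    rescue_candidates: tuple[tuple[str, float], ...] = ()

    @property
    def n_significant(self) -> int:
        return sum(1 for r in self.t_results.values() if r.significant)


def classify(
    dataset: IntegratedDataset,
    alpha: float = 0.05,
    ratio_mode: str = "paired_replicates",
    scale: str = "raw",
    detection_min_replicates: int = 2,
) -> tuple[list[ConcordanceRecord], SummaryTable]:
    """Run the full cascade over a dataset.

    Per metabolite: ``single_method`` when fewer than two methods contribute
    usable ratio groups; else ``concordant`` when the cross-method ANOVA
    accepts homogeneity; else ``rescued_one_outlier`` when omitting one
    method restores it; else ``discordant``.  Direction discordance is
    computed independently of the category.  ``scale="log"`` runs the t-test
    on log intensities and the ANOVA on log ratios (zeros become missing);
    the default is raw values.
    """
    if scale not in ("raw", "log"):
        raise ValueError(f"unknown scale {scale!r}")
    arrays = replicate_arrays(dataset)

    # regroup per (category, metabolite)
    per_metabolite: dict[tuple[str, str], dict[str, dict[str, np.ndarray]]] = {}
    for (category, method_id, metabolite), samples in arrays.items():
        per_metabolite.setdefault((category, metabolite), {})[method_id] = samples

    records: list[ConcordanceRecord] = []
    for (category, metabolite) in sorted(per_metabolite):
        methods = per_metabolite[(category, metabolite)]
        detected_any = False
        both: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for method_id in sorted(methods):
            samples = methods[method_id]
            h = samples.get("HT29", np.full(dataset.max_replicates, np.nan))
            a = samples.get("ASPC1", np.full(dataset.max_replicates, np.nan))
            nh = int(np.sum(~np.isnan(h)))
            na = int(np.sum(~np.isnan(a)))
            if max(nh, na) >= detection_min_replicates:
                detected_any = True
            if min(nh, na) >= detection_min_replicates:
                both[method_id] = (h, a)
        if not detected_any:
            continue

        ratio_sets: dict[str, RatioSet] = {}
        t_results: dict[str, TTestResult] = {}
        for method_id, (h, a) in both.items():
            rs = ratio_replicates(h, a, method_id, metabolite, mode=ratio_mode)
            if rs is not None:
                ratio_sets[method_id] = rs
            th, ta = h, a
            if scale == "log":
                th = np.where(h > 0, h, np.nan)
                ta = np.where(a > 0, a, np.nan)
                th, ta = np.log(th), np.log(ta)
            if (
                int(np.sum(~np.isnan(th))) >= 2
                and int(np.sum(~np.isnan(ta))) >= 2
            ):
                t_results[method_id] = student_t_test(
                    th, ta, alpha=alpha,
                    ratio_mean=rs.mean if rs is not None else None,
                )

        groups = {
            m: (
                tuple(math.log(r) for r in rs.ratios)
                if scale == "log"
                else rs.ratios
            )
            for m, rs in ratio_sets.items()
            if rs.n >= 2
        }
        anova = one_way_anova(list(groups.values())) if len(groups) >= 2 else None

        outlier = None
        candidates: tuple[tuple[str, float], ...] = ()
        if anova is None:
            classification = Classification.SINGLE_METHOD
        elif anova.p_value > alpha:
            classification = Classification.CONCORDANT
        else:
            rescue = leave_one_out_rescue(groups, alpha=alpha)
            if rescue.rescued:
                classification = Classification.RESCUED_ONE_OUTLIER
                outlier = rescue.outlier_method
                candidates = rescue.candidates
            else:
                classification = Classification.DISCORDANT

        records.append(
            ConcordanceRecord(
                metabolite=metabolite,
                category=category,
                n_methods=len(ratio_sets),
                n_methods_detected_both=len(both),
                ratio_sets=ratio_sets,
                t_results=t_results,
                anova=anova,
                classification=classification,
                direction_discordant=direction_discordant(
                    list(t_results.values())
                ),
                outlier_method=outlier,
                rescue_candidates=candidates,
            )
        )

    summary = _summarize(records, alpha)
    return records, summary


def _summarize(records: Sequence[ConcordanceRecord], alpha: float) -> SummaryTable:
    per_cat = {c: [0, 0, 0, 0, 0, 0] for c in CATEGORIES}
    for rec in records:
        rows = per_cat[rec.category]
        rows[0] += 1  # only metabolites detected somewhere become records
        if rec.n_methods_detected_both >= 2:
            rows[1] += 1
        if rec.n_significant >= 2:
            rows[2] += 1
        if rec.direction_discordant:
            rows[3] += 1
        if rec.classification is Classification.CONCORDANT:
            rows[4] += 1
        if rec.classification in (
            Classification.CONCORDANT,
            Classification.RESCUED_ONE_OUTLIER,
        ):
            rows[5] += 1
    return SummaryTable.from_category_counts(
        per_cat["hydrophilic"], per_cat["hydrophobic"], alpha=alpha
    )


def records_to_frame(records: Sequence[ConcordanceRecord]) -> pd.DataFrame:
    """Flatten records into the per-metabolite export table."""
    rows = []
    for rec in records:
        mean_ratios = ";".join(
            f"{m}={rs.mean:.6g}" for m, rs in sorted(rec.ratio_sets.items())
        )
        p_values = ";".join(
            f"{m}={t.p_value:.4g}" for m, t in sorted(rec.t_results.items())
        )
        rows.append(
            {
                "metabolite": rec.metabolite,
                "category": rec.category,
                "n_methods": rec.n_methods,
                "method_mean_ratios": mean_ratios,
                "method_t_p_values": p_values,
                "anova_p": "" if rec.anova is None else f"{rec.anova.p_value:.6g}",
                "classification": rec.classification.value,
                "outlier_method": rec.outlier_method or "",
                "direction_discordant": str(rec.direction_discordant),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "metabolite",
            "category",
            "n_methods",
            "method_mean_ratios",
            "method_t_p_values",
            "anova_p",
            "classification",
            "outlier_method",
            "direction_discordant",
        ],
    )
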
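"""Class-association statistics: 2x2 odds ratios with Woolf (Wald log-OR)
confidence intervals against a baseline class, and Pearson chi-square
comparisons of categorical traits across classes."""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, norm

Z95 = 1.96  # conventional two-sided 95% multiplier


def round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding: half-up at the given number of decimals."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class OddsRatioResult:
    """2x2 odds ratio of a binary trait in one class versus a baseline class.

    ``a``/``b`` are trait-positive/negative counts in the class, ``c``/``d``
    in the baseline; ``corrected`` flags the Haldane–Anscombe +0.5
    adjustment applied when any cell is zero.
    """

    a: int
    b: int
    c: int
    d: int
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    baseline_label: str = "baseline"
    corrected: bool = False


def odds_ratio_woolf(a: int, b: int, c: int, d: int, baseline_label: str = "baseline") -> OddsRatioResult:
    """Cross-product OR with the Woolf 95% CI and a Wald z p-value.

    OR = (a*d)/(b*c); CI = exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).
    Any zero cell triggers the +0.5 continuity correction (flagged).
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("cell counts must be non-negative integers")
    corrected = any(x == 0 for x in cells)
    aa, bb, cc, dd = ((x + 0.5 for x in cells) if corrected else map(float, cells))
    orv = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log(orv)
    p = 2.0 * float(norm.sf(abs(log_or) / se))
    return OddsRatioResult(
        a=int(a),
        b=int(b),
        c=int(c),
        d=int(d),
        or_value=orv,
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        p_value=p,
        baseline_label=baseline_label,
        corrected=corrected,
    )


def _class_counts(assignments, trait, trait_mask=None):
    assignments = np.asarray(assignments)
    trait = np.asarray(trait, dtype=float)
    if trait_mask is None:
        trait_mask = ~np.isnan(trait)
    trait_mask = np.asarray(trait_mask, dtype=bool)
    return assignments[trait_mask], trait[trait_mask].astype(int)


def class_trait_table(
    assignments,
    trait,
    baseline_class: int,
    trait_mask=None,
    class_labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-class OR of a binary trait versus the baseline class, plus totals.

    Children with a missing trait are excluded. Returns one row per class
    (the baseline row carries no OR) and a totals row with the overall
    trait prevalence.
    """
    cls, tr = _class_counts(assignments, trait, trait_mask)
    classes = np.unique(np.asarray(assignments))
    if baseline_class not in classes:
        raise ValueError(f"baseline class {baseline_class} not present in assignments")
    c_pos = int(((cls == baseline_class) & (tr == 1)).sum())
    c_neg = int(((cls == baseline_class) & (tr == 0)).sum())
    if c_pos + c_neg == 0:
        raise ValueError("baseline class has no children with an observed trait")
    rows = []
    for k in classes:
        a = int(((cls == k) & (tr == 1)).sum())
        b = int(((cls == k) & (tr == 0)).sum())
        row = {
            "class": int(k),
            "label": (class_labels or {}).get(int(k), str(int(k))),
            "trait_pos": a,
            "trait_neg": b,
            "percent_pos": 100.0 * a / (a + b) if a + b else np.nan,
        }
        if k == baseline_class:
            row.update(or_value=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan, corrected=False)
            row["label"] = row["label"] + " (baseline)"
        else:
            res = odds_ratio_woolf(a, b, c_pos, c_neg)
            row.update(
                or_value=res.or_value,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                p_value=res.p_value,
                corrected=res.corrected,
            )
        rows.append(row)
    tot_pos, tot_neg = int((tr == 1).sum()), int((tr == 0).sum())
    rows.append(
        {
            "class": -1,
            "label": "total",
            "trait_pos": tot_pos,
            "trait_neg": tot_neg,
            "percent_pos": 100.0 * tot_pos / (tot_pos + tot_neg),
            "or_value": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p_value": np.nan,
            "corrected": False,
        }
    )
    return pd.DataFrame(rows)


def class_categorical_test(
    assignments,
    category,
    baseline_class: int,
    category_mask=None,
) -> pd.DataFrame:
    """Pearson chi-square of a categorical trait, each class vs the baseline.

    For a binary category this is the 1-df uncorrected Pearson test on the
    2x2 table (class, baseline) x category levels.
    """
    assignments = np.asarray(assignments)
    category = np.asarray(category)
    if category_mask is not None:
        m = np.asarray(category_mask, dtype=bool)
        assignments, category = assignments[m], category[m]
    levels = np.unique(category)
    if len(levels) < 2:
        raise ValueError("category needs at least two observed levels")
    classes = np.unique(assignments)
    if baseline_class not in classes:
        raise ValueError(f"baseline class {baseline_class} not present in assignments")
    base_counts = np.array([(category[assignments == baseline_class] == lv).sum() for lv in levels])
    rows = []
    for k in classes:
        if k == baseline_class:
            continue
        counts = np.array([(category[assignments == k] == lv).sum() for lv in levels])
        table = np.vstack([counts, base_counts])
        keep = table.sum(axis=0) > 0
        table = table[:, keep]
        if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
            raise ValueError(
                f"class {k} vs baseline produces a degenerate table; "
                "merge sparse levels or drop the class"
            )
        stat, p, dof, expected = chi2_contingency(table, correction=False)
        if (expected == 0).any():
            raise ValueError("zero expected count; merge sparse category levels")
        rows.append({"class": int(k), "chi2": float(stat), "dof": int(dof), "p_value": float(p)})
    return pd.DataFrame(rows)
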
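"""Characterization of fitted classes: trajectory tables, prevalence
summaries, membership quality, and cross-classification matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from trajmix.inference import FitResult
from trajmix.latent_models import model_implied_prevalence
from trajmix.synthetic_cohort import CohortTable


@dataclass
class ClassProfileTable:
    """Per-class size/share plus observed and model-implied p(symptom, age)."""

    symptoms: tuple[str, ...]
    ages: tuple[int, ...]
    sizes: np.ndarray  # (n,)
    shares: np.ndarray  # (n,)
    observed: np.ndarray  # (n, S, T) observed proportion among non-missing cells
    observed_n: np.ndarray  # (n, S, T) count of non-missing cells
    model_prob: np.ndarray  # (n, S, T) model-implied emission probability

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in range(len(self.sizes)):
            for s, symptom in enumerate(self.symptoms):
                for t, age in enumerate(self.ages):
                    rows.append(
                        {
                            "class": c,
                            "symptom": symptom,
                            "age": age,
                            "observed_prop": self.observed[c, s, t],
                            "observed_n": int(self.observed_n[c, s, t]),
                            "model_prob": self.model_prob[c, s, t],
                            "class_size": int(self.sizes[c]),
                            "class_share": self.shares[c],
                        }
                    )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def profile_table(fit: FitResult, cohort: CohortTable) -> ClassProfileTable:
    """Observed per-class trajectory proportions plus model emissions.

    Children contribute via their hard assignment; observed proportions
    are over non-missing cells only (NaN where a class has no observation
    for a cell). Empty classes keep size 0 but still report emissions.
    """
    if len(fit.assignment) != cohort.n_children:
        raise ValueError("fit assignments do not cover the cohort")
    n = fit.params.n_classes
    N, S, T = cohort.y.shape
    sizes = np.bincount(fit.assignment, minlength=n).astype(int)
    onehot = np.zeros((N, n))
    onehot[np.arange(N), fit.assignment] = 1.0
    pos = np.einsum("ic,ist->cst", onehot, (cohort.y_mask & (cohort.y == 1)).astype(float))
    tot = np.einsum("ic,ist->cst", onehot, cohort.y_mask.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = np.where(tot > 0, pos / np.where(tot > 0, tot, 1.0), np.nan)
    return ClassProfileTable(
        symptoms=cohort.symptoms,
        ages=cohort.ages.ages,
        sizes=sizes,
        shares=sizes / sizes.sum() if sizes.sum() else sizes.astype(float),
        observed=observed,
        observed_n=tot,
        model_prob=model_implied_prevalence(fit.params),
    )


def prevalence_table(cohort: CohortTable) -> pd.DataFrame:
    """Cross-sectional n/N and percent per (symptom, age, cohort) plus pooled.

    Mirrors a cohort-characteristics table: counts run over non-missing
    cells; a fully unobserved cell reports N = 0 and NaN percent. A
    "female" row is included when sex is recorded.
    """
    labels = [str(v) for v in np.unique(cohort.cohort)] + ["joint"]
    rows = []

    def add_row(characteristic, age, values, mask):
        for label in labels:
            sel = np.ones(cohort.n_children, dtype=bool) if label == "joint" else cohort.cohort == label
            N = int(mask[sel].sum())
            n = int((values[sel] & mask[sel]).sum())
            rows.append(
                {
                    "characteristic": characteristic,
                    "age": age,
                    "cohort": label,
                    "n": n,
                    "N": N,
                    "percent": 100.0 * n / N if N else np.nan,
                }
            )

    if cohort.sex is not None:
        add_row("female", None, cohort.sex == 1, cohort.sex_mask)
    for s, symptom in enumerate(cohort.symptoms):
        for t, age in enumerate(cohort.ages.ages):
            add_row(symptom, age, cohort.y[:, s, t] == 1, cohort.y_mask[:, s, t])
    return pd.DataFrame(rows)


def membership_quality(fit: FitResult) -> np.ndarray:
    """Row-normalized matrix M[k, c] = mean posterior probability of class c
    among children assigned to class k; the diagonal is assignment certainty."""
    n = fit.params.n_classes
    out = np.full((n, n), np.nan)
    for k in range(n):
        sel = fit.assignment == k
        if sel.any():
            out[k] = fit.membership[sel].mean(axis=0)
    return out


def cross_tabulate(
    assignments_a: pd.Series, assignments_b: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Contingency table of two classifications over their common children,
    plus the chi-square independence p-value.

    Inputs are Series indexed by child id. Raises on disjoint id sets.
    """
    a = pd.Series(assignments_a)
    b = pd.Series(assignments_b)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("the two classifications share no child ids")
    table = pd.crosstab(a.loc[common], b.loc[common])
    # drop all-zero rows/cols before the test (chi2 needs positive margins)
    trimmed = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if trimmed.shape[0] < 2 or trimmed.shape[1] < 2:
        p = 1.0
    else:
        p = float(chi2_contingency(trimmed.to_numpy(), correction=False)[1])
    return table, p


def label_classes(
    model_prob: np.ndarray, symptoms: tuple[str, ...], ages: tuple[int, ...]
) -> list[str]:
    """Heuristic, threshold-based class labels from emission curves.

    Interpretive convenience only — real studies label classes by
    inspection; these rules are documented thresholds, not ground truth.
    """
    s_idx = {s: i for i, s in enumerate(symptoms)}
    labels = []
    half = len(ages) // 2
    for c in range(model_prob.shape[0]):
        p = model_prob[c]
        ecz = p[s_idx.get("eczema", 0)]
        whz = p[s_idx.get("wheeze", s_idx.get("asthma", 1))]
        rhi = p[s_idx.get("rhinitis", 2)]
        has_e, has_w = ecz.max() > 0.5, whz.max() > 0.5
        late_r = rhi[half:].max() > 0.5
        if not (has_e or has_w or late_r):
            labels.append("no_disease")
        elif has_e and has_w and late_r and ecz[0] >= whz[0]:
            labels.append("atopic_march")
        elif has_e and has_w:
            labels.append("persistent_eczema_wheeze")
        elif has_e and late_r:
            labels.append("eczema_later_rhinitis")
        elif has_w and late_r:
            labels.append("wheeze_later_rhinitis")
        elif has_w and whz[-2:].max() < 0.3:
            labels.append("transient_wheeze")
        elif has_w:
            labels.append("wheeze_only")
        elif has_e:
            labels.append("eczema_only")
        else:
            labels.append("rhinitis_only")
    return labels


def plot_profiles(profiles: ClassProfileTable, path, labels: list[str] | None = None) -> None:
    """One panel per class with the per-symptom trajectory curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(profiles.sizes)
    ncol = min(4, n)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False)
    for c in range(n):
        ax = axes[c // ncol][c % ncol]
        for s, symptom in enumerate(profiles.symptoms):
            ax.plot(profiles.ages, profiles.model_prob[c, s], marker="o", label=symptom)
        title = labels[c] if labels else f"class {c}"
        ax.set_title(f"{title} (n={profiles.sizes[c]}, {100 * profiles.shares[c]:.1f}%)", fontsize=8)
        ax.set_ylim(0, 1)
    for j in range(n, nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
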
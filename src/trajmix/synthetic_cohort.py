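"""Synthetic birth cohorts, derived clinical variables, and inclusion filters.

Real individual-level cohort data are not distributable, so this module
generates cohorts with the same statistical shape: two cohorts of
configurable size, per-child binary symptom panels drawn from a latent
class mixture, cohort-specific structural missingness (e.g. rhinitis
never collected at the first two ages in the larger cohort), independent
item missingness, and optional monotone attrition.

Missing values are always carried as an explicit boolean mask; value
arrays hold 0 where unobserved and are never consulted through the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from trajmix import latent_models
from trajmix.latent_models import ModelParams, ModelSpec

SYMPTOMS = ("eczema", "wheeze", "rhinitis")
DEFAULT_AGES = (1, 3, 5, 8, 11)


@dataclass(frozen=True)
class AgeGrid:
    """Ordered nominal follow-up ages (years)."""

    ages: tuple[int, ...] = DEFAULT_AGES

    def __post_init__(self) -> None:
        ages = tuple(self.ages)
        object.__setattr__(self, "ages", ages)
        if len(ages) < 2:
            raise ValueError("AgeGrid needs at least two ages")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("ages must be strictly increasing")

    def __len__(self) -> int:
        return len(self.ages)

    def index(self, age: int) -> int:
        return self.ages.index(age)


@dataclass(frozen=True)
class MissingnessPlan:
    """Which cells go unobserved, and how often.

    ``structural`` cells — (cohort label, symptom, age) — are never
    observed by design. ``item_rate`` independently blanks each remaining
    cell. ``attrition`` optionally gives a per-age probability of dropping
    out at that age; once dropped, all later cells are missing.
    """

    structural: frozenset[tuple[str, str, int]] = frozenset()
    item_rate: float = 0.0
    attrition: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "structural", frozenset(self.structural))
        if not 0.0 <= self.item_rate <= 1.0:
            raise ValueError("item_rate must be in [0, 1]")
        if self.attrition is not None:
            att = tuple(self.attrition)
            object.__setattr__(self, "attrition", att)
            if any(not 0.0 <= p <= 1.0 for p in att):
                raise ValueError("attrition probabilities must be in [0, 1]")


@dataclass
class CohortTable:
    """Per-child longitudinal symptom panel with explicit missingness mask.

    ``y`` has shape (N, S, T) over ``symptoms`` x ``ages``; ``y_mask`` is
    True where the cell was observed. Auxiliary variables (sex, skin-prick
    wheals, steroid-prescription flag, asthma components) are optional and
    each carries its own mask.
    """

    ages: AgeGrid
    symptoms: tuple[str, ...]
    child_id: np.ndarray
    cohort: np.ndarray
    y: np.ndarray
    y_mask: np.ndarray
    sex: np.ndarray | None = None
    sex_mask: np.ndarray | None = None
    allergens: tuple[str, ...] = ()
    wheal: np.ndarray | None = None  # (N, A, T) mm
    wheal_mask: np.ndarray | None = None
    neg_control: np.ndarray | None = None  # (N, T) mm
    neg_control_mask: np.ndarray | None = None
    steroid_rx_by_age3: np.ndarray | None = None
    steroid_rx_mask: np.ndarray | None = None
    med_use: np.ndarray | None = None  # (N, T)
    med_use_mask: np.ndarray | None = None
    dx_asthma: np.ndarray | None = None  # (N, T), "diagnosed ever" by that age
    dx_asthma_mask: np.ndarray | None = None

    @property
    def n_children(self) -> int:
        return len(self.child_id)

    def validate(self) -> None:
        N, S, T = self.y.shape
        if S != len(self.symptoms) or T != len(self.ages):
            raise ValueError("y shape inconsistent with symptoms/ages")
        if self.y_mask.shape != self.y.shape:
            raise ValueError("y_mask shape mismatch")
        observed = self.y[self.y_mask]
        if observed.size and not np.isin(observed, (0, 1)).all():
            raise ValueError("observed symptom values must be 0/1")
        if self.wheal is not None and (self.wheal[self.wheal_mask] < 0).any():
            raise ValueError("wheal diameters must be >= 0 mm")

    def subset(self, idx: np.ndarray) -> "CohortTable":
        """Row-subset every per-child array (boolean or integer index)."""

        def take(a):
            return None if a is None else a[idx]

        return CohortTable(
            ages=self.ages,
            symptoms=self.symptoms,
            child_id=self.child_id[idx],
            cohort=self.cohort[idx],
            y=self.y[idx],
            y_mask=self.y_mask[idx],
            sex=take(self.sex),
            sex_mask=take(self.sex_mask),
            allergens=self.allergens,
            wheal=take(self.wheal),
            wheal_mask=take(self.wheal_mask),
            neg_control=take(self.neg_control),
            neg_control_mask=take(self.neg_control_mask),
            steroid_rx_by_age3=take(self.steroid_rx_by_age3),
            steroid_rx_mask=take(self.steroid_rx_mask),
            med_use=take(self.med_use),
            med_use_mask=take(self.med_use_mask),
            dx_asthma=take(self.dx_asthma),
            dx_asthma_mask=take(self.dx_asthma_mask),
        )

    # -- wide CSV dialect ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, object] = {"child_id": self.child_id, "cohort": self.cohort}
        if self.sex is not None:
            cols["sex"] = _masked_series(self.sex, self.sex_mask)
        for s, name in enumerate(self.symptoms):
            for t, age in enumerate(self.ages.ages):
                cols[f"{name}_{age}"] = _masked_series(self.y[:, s, t], self.y_mask[:, s, t])
        for a, allergen in enumerate(self.allergens):
            for t, age in enumerate(self.ages.ages):
                cols[f"wheal_{allergen}_{age}"] = _masked_series(
                    self.wheal[:, a, t], self.wheal_mask[:, a, t]
                )
        if self.neg_control is not None:
            for t, age in enumerate(self.ages.ages):
                cols[f"negctl_{age}"] = _masked_series(self.neg_control[:, t], self.neg_control_mask[:, t])
        if self.steroid_rx_by_age3 is not None:
            cols["steroidrx3"] = _masked_series(self.steroid_rx_by_age3, self.steroid_rx_mask)
        for arr, mask, prefix in (
            (self.med_use, self.med_use_mask, "meduse"),
            (self.dx_asthma, self.dx_asthma_mask, "dxasthma"),
        ):
            if arr is not None:
                for t, age in enumerate(self.ages.ages):
                    cols[f"{prefix}_{age}"] = _masked_series(arr[:, t], mask[:, t])
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        ages: AgeGrid | None = None,
        symptoms: Sequence[str] = SYMPTOMS,
    ) -> "CohortTable":
        ages = ages or AgeGrid()
        required = ["child_id", "cohort"]
        for col in required:
            if col not in frame.columns:
                raise ValueError(f"cohort table is missing required column {col!r}")
        N = len(frame)
        S, T = len(symptoms), len(ages)
        y = np.zeros((N, S, T), dtype=np.int8)
        y_mask = np.zeros((N, S, T), dtype=bool)
        for s, name in enumerate(symptoms):
            for t, age in enumerate(ages.ages):
                col = f"{name}_{age}"
                if col not in frame.columns:
                    raise ValueError(f"cohort table is missing symptom column {col!r}")
                y[:, s, t], y_mask[:, s, t] = _parse_binary(frame[col], col)
        kwargs: dict = {}
        if "sex" in frame.columns:
            kwargs["sex"], kwargs["sex_mask"] = _parse_binary(frame["sex"], "sex")
        allergens = sorted(
            {c.split("_")[1] for c in frame.columns if c.startswith("wheal_")}
        )
        if allergens:
            wheal = np.zeros((N, len(allergens), T))
            wheal_mask = np.zeros((N, len(allergens), T), dtype=bool)
            for a, allergen in enumerate(allergens):
                for t, age in enumerate(ages.ages):
                    col = f"wheal_{allergen}_{age}"
                    if col in frame.columns:
                        vals = pd.to_numeric(frame[col], errors="coerce")
                        wheal_mask[:, a, t] = vals.notna().to_numpy()
                        wheal[:, a, t] = vals.fillna(0.0).to_numpy()
            kwargs.update(allergens=tuple(allergens), wheal=wheal, wheal_mask=wheal_mask)
        if any(c.startswith("negctl_") for c in frame.columns):
            neg = np.zeros((N, T))
            neg_mask = np.zeros((N, T), dtype=bool)
            for t, age in enumerate(ages.ages):
                col = f"negctl_{age}"
                if col in frame.columns:
                    vals = pd.to_numeric(frame[col], errors="coerce")
                    neg_mask[:, t] = vals.notna().to_numpy()
                    neg[:, t] = vals.fillna(0.0).to_numpy()
            kwargs.update(neg_control=neg, neg_control_mask=neg_mask)
        if "steroidrx3" in frame.columns:
            kwargs["steroid_rx_by_age3"], kwargs["steroid_rx_mask"] = _parse_binary(
                frame["steroidrx3"], "steroidrx3"
            )
        for prefix, key in (("meduse", "med_use"), ("dxasthma", "dx_asthma")):
            if any(c.startswith(prefix + "_") for c in frame.columns):
                arr = np.zeros((N, T), dtype=np.int8)
                m = np.zeros((N, T), dtype=bool)
                for t, age in enumerate(ages.ages):
                    col = f"{prefix}_{age}"
                    if col in frame.columns:
                        arr[:, t], m[:, t] = _parse_binary(frame[col], col)
                kwargs[key] = arr
                kwargs[key + "_mask"] = m
        table = cls(
            ages=ages,
            symptoms=tuple(symptoms),
            child_id=frame["child_id"].astype(str).to_numpy(),
            cohort=frame["cohort"].astype(str).to_numpy(),
            y=y,
            y_mask=y_mask,
            **kwargs,
        )
        table.validate()
        return table

    @classmethod
    def from_csv(cls, path, ages: AgeGrid | None = None, symptoms: Sequence[str] = SYMPTOMS):
        return cls.from_frame(pd.read_csv(path, na_values=["NA"]), ages=ages, symptoms=symptoms)


def _masked_series(values: np.ndarray, mask: np.ndarray) -> pd.Series:
    out = pd.Series(values.astype(object))
    out[~mask] = pd.NA
    return out


def _parse_binary(col: pd.Series, name: str) -> tuple[np.ndarray, np.ndarray]:
    vals = pd.to_numeric(col, errors="coerce")
    bad = vals.notna() & ~vals.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"column {name!r} row {row}: expected 0/1/NA, got {col.iloc[row]!r}")
    mask = vals.notna().to_numpy()
    return vals.fillna(0).to_numpy().astype(np.int8), mask


@dataclass
class GenerativeTruth:
    """Everything needed to simulate a cohort: model, sizes, missingness, seed."""

    model_spec: ModelSpec
    params: ModelParams
    cohort_sizes: tuple[int, ...]
    missingness: MissingnessPlan = field(default_factory=MissingnessPlan)
    seed: int = 0
    ages: AgeGrid = field(default_factory=AgeGrid)
    symptoms: tuple[str, ...] = SYMPTOMS
    sex_female_prob: float = 0.49
    #: Optional per-class probability of atopic sensitisation; when set,
    #: a single-allergen skin-prick wheal panel is simulated at the
    #: penultimate age so that derive_sensitised recovers the trait.
    sens_prob_by_class: np.ndarray | None = None

    def validate(self) -> None:
        self.params.validate()
        if any(n < 0 for n in self.cohort_sizes):
            raise ValueError("cohort sizes must be non-negative")
        S, T = self.params.shape
        if S != len(self.symptoms) or T != len(self.ages):
            raise ValueError("params shape does not match symptoms/ages")


def cohort_labels(n_cohorts: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n_cohorts)]


def generate_cohort(truth: GenerativeTruth) -> tuple[CohortTable, np.ndarray]:
    """Simulate a cohort from the truth; returns (cohort, true class labels).

    The labels are a side channel for recovery tests and are not stored on
    the table itself.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    N = int(sum(truth.cohort_sizes))
    labels = cohort_labels(len(truth.cohort_sizes))
    cohort_col = np.repeat(labels, truth.cohort_sizes)
    y, true_class = latent_models.sample_panels(truth.params, N, rng)
    S, T = y.shape[1], y.shape[2]

    y_mask = np.ones((N, S, T), dtype=bool)
    plan = truth.missingness
    for cohort, symptom, age in plan.structural:
        if symptom not in truth.symptoms or age not in truth.ages.ages:
            raise ValueError(f"structural cell ({cohort}, {symptom}, {age}) not on the grid")
        sel = cohort_col == cohort
        y_mask[sel, truth.symptoms.index(symptom), truth.ages.index(age)] = False
    if plan.attrition is not None:
        dropped = np.zeros(N, dtype=bool)
        for t, p in enumerate(plan.attrition[:T]):
            dropped |= rng.random(N) < p
            y_mask[dropped, :, t] = False
    if plan.item_rate > 0:
        y_mask &= rng.random((N, S, T)) >= plan.item_rate
    y = np.where(y_mask, y, 0).astype(np.int8)

    sex = (rng.random(N) < truth.sex_female_prob).astype(np.int8)  # 1 = female
    table = CohortTable(
        ages=truth.ages,
        symptoms=truth.symptoms,
        child_id=np.array([f"c{i:06d}" for i in range(N)]),
        cohort=cohort_col,
        y=y,
        y_mask=np.ascontiguousarray(y_mask),
        sex=sex,
        sex_mask=np.ones(N, dtype=bool),
    )
    if truth.sens_prob_by_class is not None:
        t_sens = T - 2 if T >= 2 else 0
        sensitised = rng.random(N) < np.asarray(truth.sens_prob_by_class)[true_class]
        wheal = np.zeros((N, 1, T))
        wheal_mask = np.zeros((N, 1, T), dtype=bool)
        neg = np.zeros((N, T))
        neg_mask = np.zeros((N, T), dtype=bool)
        neg[:, t_sens] = 1.0
        neg_mask[:, t_sens] = True
        wheal[:, 0, t_sens] = np.where(sensitised, 1.0 + rng.uniform(3.0, 6.0, N), rng.uniform(0.0, 2.0, N))
        wheal_mask[:, 0, t_sens] = True
        table.allergens = ("mix",)
        table.wheal, table.wheal_mask = wheal, wheal_mask
        table.neg_control, table.neg_control_mask = neg, neg_mask
    table.validate()
    return table, true_class


def save_truth_labels(path, child_id: np.ndarray, true_class: np.ndarray) -> None:
    pd.DataFrame({"child_id": child_id, "true_class": true_class}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# derived clinical variables
# ---------------------------------------------------------------------------


def derive_asthma(wheeze_t, med_use_t, dx_ever_t):
    """Current asthma: any two of {current wheeze, medication use, diagnosis ever}.

    Inputs are 0/1 or None (missing). Missingness propagates unless two
    observed features are already positive (the decision is then forced).
    Returns 0, 1, or None.
    """
    feats = (wheeze_t, med_use_t, dx_ever_t)
    n_pos = sum(1 for f in feats if f == 1)
    if n_pos >= 2:
        return 1
    if any(f is None for f in feats):
        # with one positive at most, a missing feature could still flip it
        return None
    return 0


def derive_sensitised(wheals_t: Iterable[float], neg_control_t: float | None):
    """Sensitised: any allergen wheal >= 3 mm above the negative control.

    Returns None when no allergen measurement is available or the control
    is missing.
    """
    wheals = [w for w in wheals_t if w is not None]
    if not wheals or neg_control_t is None:
        return None
    if any(w < 0 for w in wheals) or neg_control_t < 0:
        raise ValueError("wheal diameters must be >= 0 mm")
    return int(max(wheals) - neg_control_t >= 3.0)


def derive_asthma_panel(cohort: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized derive_asthma over (N, T); returns (values, mask)."""
    if cohort.med_use is None or cohort.dx_asthma is None:
        raise ValueError("cohort lacks med_use/dx_asthma columns needed to derive asthma")
    w_idx = cohort.symptoms.index("wheeze")
    w, wm = cohort.y[:, w_idx, :], cohort.y_mask[:, w_idx, :]
    m, mm = cohort.med_use, cohort.med_use_mask
    d, dm = cohort.dx_asthma, cohort.dx_asthma_mask
    n_pos = (w & wm) + (m & mm) + (d & dm)
    all_obs = wm & mm & dm
    value = (n_pos >= 2).astype(np.int8)
    mask = (n_pos >= 2) | all_obs
    return value, mask


def with_asthma_panel(cohort: CohortTable) -> CohortTable:
    """Replace the wheeze panel by derived current asthma (symptom renamed)."""
    value, mask = derive_asthma_panel(cohort)
    w_idx = cohort.symptoms.index("wheeze")
    y = cohort.y.copy()
    y_mask = cohort.y_mask.copy()
    y[:, w_idx, :] = np.where(mask, value, 0)
    y_mask[:, w_idx, :] = mask
    symptoms = tuple("asthma" if s == "wheeze" else s for s in cohort.symptoms)
    return replace(cohort, y=y, y_mask=y_mask, symptoms=symptoms)


def sensitised_trait(cohort: CohortTable, age: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-child sensitisation indicator at one age; returns (values, mask)."""
    if cohort.wheal is None or cohort.neg_control is None:
        raise ValueError("cohort has no skin-prick data")
    t = cohort.ages.index(age)
    diff = cohort.wheal[:, :, t] - cohort.neg_control[:, None, t]
    obs = cohort.wheal_mask[:, :, t] & cohort.neg_control_mask[:, None, t]
    any_obs = obs.any(axis=1)
    value = np.where(obs, diff, -np.inf).max(axis=1, initial=-np.inf) >= 3.0
    return value.astype(np.int8), any_obs


# ---------------------------------------------------------------------------
# inclusion filters
# ---------------------------------------------------------------------------


def structural_cells(cohort: CohortTable) -> set[tuple[str, str, int]]:
    """Infer structural cells: (cohort, symptom, age) with zero observations."""
    out: set[tuple[str, str, int]] = set()
    for label in np.unique(cohort.cohort):
        sel = cohort.cohort == label
        counts = cohort.y_mask[sel].sum(axis=0)  # (S, T)
        for s, symptom in enumerate(cohort.symptoms):
            for t, age in enumerate(cohort.ages.ages):
                if counts[s, t] == 0:
                    out.add((str(label), symptom, age))
    return out


def filter_min_timepoints(
    cohort: CohortTable,
    k: int = 2,
    exempt_structural: bool = True,
    structural: set[tuple[str, str, int]] | None = None,
) -> CohortTable:
    """Keep children with >= k observed time points for every symptom.

    Cells that are structurally unobserved for a child's cohort are, by
    default, excluded from the requirement: a symptom collected at only m
    ages requires min(k, m) observations (a symptom never collected is
    fully exempt). Pass ``exempt_structural=False`` for the strict rule.
    ``structural`` may supply the design cells explicitly; otherwise they
    are inferred as cells with zero observations within a cohort.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    N, S, T = cohort.y.shape
    counts = cohort.y_mask.sum(axis=2)  # (N, S)
    required = np.full((N, S), k, dtype=int)
    if exempt_structural:
        cells = structural if structural is not None else structural_cells(cohort)
        avail = np.full((N, S), T, dtype=int)
        for label, symptom, age in cells:
            if symptom in cohort.symptoms and age in cohort.ages.ages:
                sel = cohort.cohort == label
                avail[sel, cohort.symptoms.index(symptom)] -= 1
        required = np.minimum(required, avail)
    keep = (counts >= required).all(axis=1)
    return cohort.subset(keep)


def filter_mild_eczema(cohort: CohortTable, early_ages: tuple[int, ...] = (1, 3)) -> CohortTable:
    """Drop children with early mild eczema (reported but never steroid-treated).

    Dropped: reported eczema at an early age with steroid_rx_by_age3 == 0,
    or with the prescription flag missing; also children whose early
    eczema status is entirely missing. Children with confirmed
    (steroid-treated) early eczema, or without early eczema, are retained.
    """
    if cohort.steroid_rx_by_age3 is None:
        raise ValueError("cohort lacks the steroid_rx_by_age3 column")
    e_idx = cohort.symptoms.index("eczema")
    t_idx = [cohort.ages.index(a) for a in early_ages if a in cohort.ages.ages]
    vals = cohort.y[:, e_idx, t_idx]
    obs = cohort.y_mask[:, e_idx, t_idx]
    early_pos = ((vals == 1) & obs).any(axis=1)
    any_obs = obs.any(axis=1)
    rx = cohort.steroid_rx_by_age3
    rx_obs = cohort.steroid_rx_mask
    drop = early_pos & ~((rx == 1) & rx_obs)  # mild or unconfirmed severity
    drop |= ~any_obs  # early eczema status unknown
    return cohort.subset(~drop)


# ---------------------------------------------------------------------------
# default synthetic truth (eight trajectory classes)
# ---------------------------------------------------------------------------

#: Class shares of the default eight-class truth (normalized).
DEFAULT_CLASS_WEIGHTS = np.array(
    [0.513, 0.031, 0.027, 0.047, 0.057, 0.077, 0.153, 0.096]
) / sum([0.513, 0.031, 0.027, 0.047, 0.057, 0.077, 0.153, 0.096])

DEFAULT_CLASS_NAMES = (
    "no_disease",
    "atopic_march",
    "persistent_eczema_wheeze",
    "eczema_later_rhinitis",
    "wheeze_later_rhinitis",
    "transient_wheeze",
    "eczema_only",
    "rhinitis_only",
)

# Emission curves (eczema, wheeze, rhinitis) x ages (1, 3, 5, 8, 11).
# Implementer-chosen values consistent with the qualitative class
# descriptions; not ground truth from any study.
DEFAULT_PROFILES = np.array(
    [
        [  # no disease
            [0.03, 0.03, 0.02, 0.02, 0.02],
            [0.04, 0.03, 0.02, 0.02, 0.02],
            [0.01, 0.01, 0.02, 0.04, 0.05],
        ],
        [  # atopic march: eczema high, wheeze rising, rhinitis ~0 -> ~1 by age 8
            [0.85, 0.90, 0.90, 0.85, 0.80],
            [0.25, 0.50, 0.75, 0.90, 0.90],
            [0.02, 0.15, 0.60, 0.95, 0.95],
        ],
        [  # persistent eczema and wheeze, little rhinitis
            [0.80, 0.85, 0.85, 0.80, 0.75],
            [0.75, 0.80, 0.80, 0.75, 0.70],
            [0.03, 0.05, 0.08, 0.10, 0.12],
        ],
        [  # persistent eczema with later-onset rhinitis, low wheeze
            [0.70, 0.85, 0.95, 0.90, 0.85],
            [0.08, 0.07, 0.06, 0.06, 0.05],
            [0.02, 0.10, 0.55, 0.95, 0.95],
        ],
        [  # persistent wheeze with later-onset rhinitis, low declining eczema
            [0.20, 0.15, 0.10, 0.06, 0.05],
            [0.85, 0.90, 0.90, 0.90, 0.85],
            [0.03, 0.10, 0.40, 0.75, 0.95],
        ],
        [  # transient wheeze: remits by age 8
            [0.08, 0.06, 0.05, 0.04, 0.04],
            [0.90, 0.90, 0.60, 0.06, 0.04],
            [0.02, 0.03, 0.04, 0.06, 0.08],
        ],
        [  # eczema only: peaks at age 5, declines afterwards
            [0.70, 0.80, 0.85, 0.70, 0.55],
            [0.06, 0.05, 0.04, 0.03, 0.03],
            [0.02, 0.03, 0.05, 0.08, 0.10],
        ],
        [  # rhinitis only: rises from age 5
            [0.04, 0.03, 0.03, 0.03, 0.03],
            [0.05, 0.04, 0.03, 0.03, 0.03],
            [0.05, 0.20, 0.60, 0.90, 0.95],
        ],
    ]
)

#: Per-class sensitisation probabilities used when simulating skin-prick
#: data (chosen to give a strong class-trait gradient).
DEFAULT_SENS_PROBS = np.array([0.07, 0.71, 0.30, 0.52, 0.46, 0.10, 0.14, 0.32])

#: Structural design: rhinitis not collected at ages 1 and 3 in cohort A
#: (the large, ALSPAC-like cohort).
DEFAULT_STRUCTURAL = frozenset({("A", "rhinitis", 1), ("A", "rhinitis", 3)})

DEFAULT_COHORT_SIZES = (8665, 1136)


def default_truth(
    seed: int = 0,
    cohort_sizes: tuple[int, ...] = DEFAULT_COHORT_SIZES,
    item_rate: float = 0.05,
    with_sensitisation: bool = True,
) -> GenerativeTruth:
    """Eight-class latent-profile truth emulating the two-cohort design."""
    spec = ModelSpec(family="latent_profile", n_classes=8)
    params = ModelParams("latent_profile", DEFAULT_CLASS_WEIGHTS.copy(), emit=DEFAULT_PROFILES.copy())
    return GenerativeTruth(
        model_spec=spec,
        params=params,
        cohort_sizes=tuple(cohort_sizes),
        missingness=MissingnessPlan(structural=DEFAULT_STRUCTURAL, item_rate=item_rate),
        seed=seed,
        sens_prob_by_class=DEFAULT_SENS_PROBS if with_sensitisation else None,
    )
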
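"""Data-driven selection of sensory cortical hierarchies from structural MRI.

Anatomically plausible orderings of each sensory system (auditory, visual,
somatosensory) are enumerated under constraints from the primate anatomy
literature: within each system, two pairs of regions may swap adjacent
levels while the remaining regions are fixed, giving exactly four sensory
candidates; the winner is then extended with two downstream prefrontal
regions that may take levels 8 or 9, giving two extended candidates.

Each candidate ordering is scored by a linear mixed-effects model that
predicts hierarchical level from the T1w/T2w ratio (a myelin proxy, lower at
higher levels) and cortical thickness (higher at higher levels), with
per-subject random intercepts and independent random slopes. Because every
candidate has the same dimensionality, goodness of fit (R^2) alone decides
the winner. Significance of the winning fit comes from a permutation null in
which levels are randomly reassigned across regions, and the selected
hierarchy is validated against any external parcel metric (e.g. INT, layer-IV
gene expression) with Spearman correlations.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams

__all__ = [
    "StructuralCohort",
    "HierarchyOrdering",
    "OrderingFit",
    "SYSTEM_CONSTRAINTS",
    "enumerate_sensory_candidates",
    "enumerate_pfc_extensions",
    "score_ordering",
    "select_hierarchy",
    "ordering_permutation_null",
    "spearman_validate",
]


# ---------------------------------------------------------------------------
# containers and constraint tables
# ---------------------------------------------------------------------------


@dataclass
class StructuralCohort:
    """Per-subject parcel-wise structural maps (subjects x parcels)."""

    t1w_t2w: pd.DataFrame
    thickness: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.t1w_t2w.columns.equals(self.thickness.columns) or (
            self.t1w_t2w.shape != self.thickness.shape
        ):
            raise ValueError("t1w_t2w and thickness must share subjects and parcels")
        if self.t1w_t2w.isna().all().any():
            raise ValueError("a parcel is entirely missing in t1w_t2w")

    @property
    def subject_ids(self):
        return self.t1w_t2w.index

    @property
    def parcel_ids(self):
        return self.t1w_t2w.columns

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "StructuralCohort":
        """Build from a long CSV table (subject_id, parcel, t1w_t2w, thickness)."""
        t1 = table.pivot(index="subject_id", columns="parcel", values="t1w_t2w")
        th = table.pivot(index="subject_id", columns="parcel", values="thickness")
        return cls(t1w_t2w=t1, thickness=th)


@dataclass(frozen=True)
class HierarchyOrdering:
    """Mapping parcel -> integer level (1..L) for one sensory system."""

    assignment: tuple  # tuple of (parcel, level), kept hashable
    system_tag: str = "custom"

    @classmethod
    def from_dict(cls, mapping: dict, system_tag: str = "custom") -> "HierarchyOrdering":
        items = tuple(sorted(mapping.items(), key=lambda kv: kv[1]))
        levels = sorted(level for _, level in items)
        if levels != list(range(1, len(levels) + 1)):
            raise ValueError("levels must be a permutation of 1..L")
        return cls(assignment=items, system_tag=system_tag)

    def to_dict(self) -> dict:
        return dict(self.assignment)

    @property
    def parcels(self) -> list:
        return [p for p, _ in self.assignment]

    @property
    def levels(self) -> np.ndarray:
        return np.array([lv for _, lv in self.assignment])

    @property
    def n_levels(self) -> int:
        return len(self.assignment)

    def level_of(self, parcel) -> int:
        return dict(self.assignment)[parcel]


@dataclass
class OrderingFit:
    """Goodness of fit of one candidate ordering."""

    ordering: HierarchyOrdering
    r_squared: float
    converged: bool = True
    fixed_params: dict = field(default_factory=dict)


# Constraint tables: fixed level assignments plus pairs of regions allowed to
# swap between two adjacent levels. The listed order of each swap pair is the
# canonical (first-enumerated) assignment.
SYSTEM_CONSTRAINTS = {
    "auditory": {
        "fixed": {"A1": 1, "A4": 6, "A5": 7},
        "swaps": [(("LBelt", "MBelt"), (2, 3)), (("PBelt", "RI"), (4, 5))],
        "pfc": ("8a", "46"),
    },
    "visual": {
        "fixed": {"V1": 1, "V2": 2, "V3": 3},
        "swaps": [(("V4", "MT"), (4, 5)), (("V6", "V7"), (6, 7))],
        "pfc": ("8a", "46"),
    },
    "somatosensory": {
        "fixed": {"5m": 5, "7b": 6, "7a": 7},
        "swaps": [(("3b", "3a"), (1, 2)), (("1", "2"), (3, 4))],
        "pfc": ("8a", "46"),
    },
    # ventral-stream variant of the auditory hierarchy: same sensory cortex,
    # ventral prefrontal endpoints
    "auditory_ventral": {
        "fixed": {"A1": 1, "A4": 6, "A5": 7},
        "swaps": [(("LBelt", "MBelt"), (2, 3)), (("PBelt", "RI"), (4, 5))],
        "pfc": ("10", "12vl"),
    },
}


def enumerate_sensory_candidates(system: str) -> list[HierarchyOrdering]:
    """The four candidate 7-level orderings of a sensory system."""
    if system not in SYSTEM_CONSTRAINTS:
        raise ValueError(
            f"unknown system {system!r}; valid tags: {sorted(SYSTEM_CONSTRAINTS)}"
        )
    spec = SYSTEM_CONSTRAINTS[system]
    candidates = []
    # for each swap pair, either the listed order or the flipped one
    for flips in itertools.product([False, True], repeat=len(spec["swaps"])):
        mapping = dict(spec["fixed"])
        for ((a, b), (la, lb)), flip in zip(spec["swaps"], flips):
            if flip:
                a, b = b, a
            mapping[a] = la
            mapping[b] = lb
        candidates.append(HierarchyOrdering.from_dict(mapping, system_tag=system))
    return candidates


def enumerate_pfc_extensions(
    winner: HierarchyOrdering, system: str | None = None
) -> list[HierarchyOrdering]:
    """The two 9-level extensions adding the prefrontal pair at levels 8/9."""
    system = system or winner.system_tag
    if system not in SYSTEM_CONSTRAINTS:
        raise ValueError(
            f"unknown system {system!r}; valid tags: {sorted(SYSTEM_CONSTRAINTS)}"
        )
    p1, p2 = SYSTEM_CONSTRAINTS[system]["pfc"]
    out = []
    for first, second in ((p1, p2), (p2, p1)):
        mapping = winner.to_dict()
        mapping[first] = 8
        mapping[second] = 9
        out.append(HierarchyOrdering.from_dict(mapping, system_tag=system))
    return out


# ---------------------------------------------------------------------------
# mixed-model scoring
# ---------------------------------------------------------------------------


def _long_table(ordering: HierarchyOrdering, cohort: StructuralCohort) -> pd.DataFrame:
    parcels = ordering.parcels
    missing = [p for p in parcels if p not in cohort.parcel_ids]
    if missing:
        raise ValueError(f"ordering parcels absent from cohort: {missing}")
    t1 = cohort.t1w_t2w[parcels]
    th = cohort.thickness[parcels]
    n_sub = len(cohort.subject_ids)
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_sub), len(parcels)),
        "level": np.tile(ordering.levels.astype(float), n_sub),
        "t1w": t1.to_numpy().reshape(-1),
        "thick": th.to_numpy().reshape(-1),
    }).dropna()
    # z-score predictors for numerically stable variance-component estimation
    for col in ("t1w", "thick"):
        sd = long[col].std()
        long[col] = (long[col] - long[col].mean()) / (sd if sd > 0 else 1.0)
    return long


def score_ordering(
    ordering: HierarchyOrdering,
    cohort: StructuralCohort,
    conditional: bool = True,
) -> OrderingFit:
    """Fit level ~ t1w_t2w + thickness with per-subject random effects.

    The model has fixed effects for both structural predictors and, per
    subject, a random intercept and independent random slopes (diagonal
    random-effects covariance). R^2 is the squared Pearson correlation
    between observed levels and predictions; ``conditional`` includes the
    estimated random effects in the prediction (the default), otherwise only
    the fixed effects are used (marginal R^2).

    Non-convergence falls back to a random-intercept-only model and finally
    to OLS, with ``converged=False``.
    """
    if len(cohort.subject_ids) < 2:
        raise ValueError("need >= 2 subjects")
    long = _long_table(ordering, cohort)
    exog = sm.add_constant(long[["t1w", "thick"]].to_numpy())
    endog = long["level"].to_numpy()
    groups = long["subject"].to_numpy()

    def _try_mixed(exog_re):
        """Fit and predict; None on any numerical failure (singular
        random-effects covariance, non-convergence, ...)."""
        try:
            if exog_re is not None:
                model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
                free = MixedLMParams.from_components(
                    fe_params=np.ones(3), cov_re=np.eye(exog_re.shape[1])
                )
                fit = model.fit(free=free, reml=True, method="lbfgs", maxiter=200)
            else:
                model = sm.MixedLM(endog, exog, groups=groups)
                fit = model.fit(reml=True, method="lbfgs", maxiter=200)
            if not fit.converged:
                return None
            pred = (np.asarray(fit.fittedvalues, dtype=float) if conditional
                    else exog @ np.asarray(fit.fe_params))
            if not np.all(np.isfinite(pred)):
                return None
            return pred, np.asarray(fit.fe_params)
        except (np.linalg.LinAlgError, ValueError):
            return None

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = _try_mixed(exog)
        if out is None:  # random-intercept-only fallback
            converged = False
            out = _try_mixed(None)
    if out is not None:
        pred, params = out
        fe = dict(zip(["const", "t1w", "thick"], params))
    else:  # OLS last resort
        ols = sm.OLS(endog, exog).fit()
        pred, converged = ols.fittedvalues, False
        fe = dict(zip(["const", "t1w", "thick"], ols.params))

    if np.std(pred) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(endog, pred)[0, 1] ** 2)
    return OrderingFit(ordering=ordering, r_squared=r2, converged=converged,
                       fixed_params=fe)


def select_hierarchy(
    system: str, cohort: StructuralCohort, conditional: bool = True
) -> dict:
    """Two-stage model comparison: 4 sensory candidates, then 2 PFC extensions.

    Returns a dict with ``winner`` (the 9-level :class:`HierarchyOrdering`),
    ``winner_fit`` and ``candidate_fits`` (all six fits in enumeration
    order). Ties break to the first candidate in canonical enumeration order
    with a warning.
    """
    sensory = enumerate_sensory_candidates(system)
    fits = [score_ordering(o, cohort, conditional=conditional) for o in sensory]
    best = _argmax_with_tie_warning([f.r_squared for f in fits], "sensory candidates")
    extensions = enumerate_pfc_extensions(sensory[best], system)
    ext_fits = [score_ordering(o, cohort, conditional=conditional) for o in extensions]
    best_ext = _argmax_with_tie_warning(
        [f.r_squared for f in ext_fits], "PFC extensions"
    )
    return {
        "winner": extensions[best_ext],
        "winner_fit": ext_fits[best_ext],
        "candidate_fits": fits + ext_fits,
    }


def _argmax_with_tie_warning(values, label: str) -> int:
    values = np.asarray(values, dtype=float)
    best = int(values.argmax())
    if (values == values[best]).sum() > 1:
        warnings.warn(f"tie among {label}; keeping the first in enumeration order",
                      stacklevel=3)
    return best


# ---------------------------------------------------------------------------
# permutation null and validation
# ---------------------------------------------------------------------------


def ordering_permutation_null(
    cohort: StructuralCohort,
    winner_fit: OrderingFit,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    conditional: bool = True,
) -> dict:
    """One-sided permutation p for a winning ordering's R^2.

    The null reassigns the levels 1..L uniformly at random across all regions
    of the scored hierarchy and refits the mixed model; with ``exhaustive``
    every one of the L! assignments is scored instead (small L only).
    p = (1 + #{null R^2 >= observed}) / (n_perm + 1).
    """
    ordering = winner_fit.ordering
    parcels = ordering.parcels
    n_levels = ordering.n_levels
    rng = np.random.default_rng(seed)
    if exhaustive:
        perms = list(itertools.permutations(range(1, n_levels + 1)))
        if math.factorial(n_levels) > 50000:
            raise ValueError("refusing exhaustive enumeration of this size")
    else:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        perms = [rng.permutation(n_levels) + 1 for _ in range(n_perm)]
    null = np.empty(len(perms))
    for i, perm in enumerate(perms):
        mapping = dict(zip(parcels, perm))
        null[i] = score_ordering(
            HierarchyOrdering.from_dict(mapping, system_tag=ordering.system_tag),
            cohort, conditional=conditional,
        ).r_squared
    n_eff = len(perms)
    p = (1 + int((null >= winner_fit.r_squared - 1e-12).sum())) / (n_eff + 1)
    return {"p": p, "null_r_squared": null, "observed": winner_fit.r_squared}


def spearman_validate(
    ordering: HierarchyOrdering,
    parcel_metric: dict | pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Spearman correlation of hierarchical level with any parcel metric.

    Returns rho, the parametric two-sided p, and a two-sided permutation p
    from random reassignments of levels across regions. Used e.g. to check
    that higher levels carry longer INT, or lower layer-IV gene expression.
    """
    metric = pd.Series(parcel_metric)
    parcels = [p for p in ordering.parcels if p in metric.index and np.isfinite(metric[p])]
    if len(parcels) < 4:
        raise ValueError("need >= 4 parcels with metric values")
    levels = np.array([ordering.level_of(p) for p in parcels], dtype=float)
    values = metric[parcels].to_numpy(dtype=float)
    if np.all(values == values[0]):
        warnings.warn("metric is constant across parcels; rho undefined", stacklevel=2)
        return {"rho": np.nan, "p_parametric": np.nan, "p_permutation": np.nan}
    rho, p_par = stats.spearmanr(levels, values)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stats.spearmanr(rng.permutation(levels), values)[0]
    p_perm = (1 + int((np.abs(null) >= abs(rho) - 1e-12).sum())) / (n_perm + 1)
    return {"rho": float(rho), "p_parametric": float(p_par), "p_permutation": p_perm}
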
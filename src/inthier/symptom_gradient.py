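"""Symptom-specific hierarchical-gradient inference.

Two regression stages link parcel-wise intrinsic neural timescales (INT) to
psychotic symptoms:

* **M1** — mass-univariate OLS per parcel. ``M1_exploratory`` predicts INT
  from diagnosis; ``M1_primary`` predicts INT (patients only) from seven
  symptom severities (hallucinations, delusions, conceptual disorganization,
  emotional withdrawal, social withdrawal, blunted affect, alogia; 0-5),
  both controlling for age, gender, mean framewise displacement and
  acquisition site.
* **M2** — a second-stage OLS over the hierarchy: the per-parcel
  t-statistics of hallucination and delusion severity, sampled at the 9
  levels of the auditory, visual and somatosensory hierarchies (prefrontal
  levels 8-9 shared across systems), are modelled as symptom x level x
  system with full interactions (12 coefficients over 54 points, residual
  df 42). The symptom-by-level interaction is the test of symptom-specific
  gradient compression/expansion.

Inference is non-parametric: permutation tests that jointly reshuffle the
symptom block across patients (preserving inter-symptom correlation),
set-level tests over conjunctions of effects, and BCa bootstrap intervals
resampling patients at the M1 level. Exemplary-case profiles and the
rank-binned data-driven hierarchy control complete the analysis surface.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hierarchy_selection import HierarchyOrdering

__all__ = [
    "SYMPTOM_COLUMNS",
    "COVARIATE_COLUMNS",
    "ParcelEffectTable",
    "GradientModelResult",
    "ExemplaryCaseProfile",
    "rescale_panss",
    "build_design",
    "fit_parcelwise_glm",
    "build_gradient_table",
    "fit_gradient_glm",
    "permutation_null_gradient",
    "set_level_test",
    "bca_ci",
    "diagnosis_overall_test",
    "exemplary_profiles",
    "rank_binned_profile",
]

SYMPTOM_COLUMNS = [
    "hallucinations",
    "delusions",
    "conceptual_disorganization",
    "emotional_withdrawal",
    "social_withdrawal",
    "blunted_affect",
    "alogia",
]
COVARIATE_COLUMNS = ["age", "gender", "mean_fd", "site"]


def rescale_panss(scores) -> np.ndarray:
    """Map PANSS item scores (1-7) onto the SAPS/SANS 0-5 severity scale:
    subtract one point and merge the two most severe levels."""
    scores = np.asarray(scores)
    return np.minimum(np.maximum(scores - 1, 0), 5)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ParcelEffectTable:
    """Per-parcel OLS results: coefficients and t-statistics per predictor."""

    coefficients: pd.DataFrame  # predictors x parcels
    tstats: pd.DataFrame  # predictors x parcels
    df_resid: int
    model: str  # 'M1_exploratory' | 'M1_primary'
    design: pd.DataFrame  # subjects x predictors actually used
    subjects: pd.Index


@dataclass
class GradientModelResult:
    """Second-stage (M2) OLS summary over the hierarchical-gradient design."""

    params: pd.Series
    tvalues: pd.Series
    f_squared: pd.Series
    df_resid: int
    omnibus_f: float
    omnibus_p: float
    df_model: int
    description: str
    r_squared: float
    permutation_p: pd.Series | None = None
    bca_ci: pd.DataFrame | None = None


@dataclass
class ExemplaryCaseProfile:
    """Fitted INT per hierarchy level for extreme symptom-score settings."""

    fitted: pd.DataFrame  # cases x levels, seconds
    delta: pd.DataFrame  # cases 2..4 x levels, seconds vs the (0,0) case
    levels: np.ndarray
    parcels: list


# ---------------------------------------------------------------------------
# M1: mass-univariate parcel-wise regression
# ---------------------------------------------------------------------------


def _dummy_code(cohort: pd.DataFrame) -> pd.DataFrame:
    """Covariate block: age, gender dummy, mean FD, treatment-coded site with
    the largest site as reference."""
    cov = pd.DataFrame(index=cohort.index)
    cov["age"] = cohort["age"].astype(float)
    gender = cohort["gender"]
    if gender.dtype == object:
        gender = (gender == sorted(gender.unique())[-1]).astype(float)
    cov["gender"] = gender.astype(float)
    cov["mean_fd"] = cohort["mean_fd"].astype(float)
    site = cohort["site"].astype(str)
    reference = site.value_counts().idxmax()
    for lvl in sorted(site.unique()):
        if lvl != reference:
            cov[f"site[{lvl}]"] = (site == lvl).astype(float)
    return cov


def build_design(cohort: pd.DataFrame, design: str) -> tuple[pd.DataFrame, pd.Index]:
    """Design matrix for M1; returns (X, row index of subjects used)."""
    if design == "M1_primary":
        rows = cohort.index[cohort["diagnosis"].astype(int) == 1]
        sub = cohort.loc[rows]
        x = pd.concat(
            [sub[SYMPTOM_COLUMNS].astype(float), _dummy_code(sub)], axis=1
        )
    elif design == "M1_exploratory":
        rows = cohort.index
        sub = cohort.loc[rows]
        x = pd.concat(
            [sub[["diagnosis"]].astype(float), _dummy_code(sub)], axis=1
        )
    else:
        raise ValueError("design must be 'M1_primary' or 'M1_exploratory'")
    x.insert(0, "const", 1.0)
    return x, rows


def _collinear_columns(x: np.ndarray, names) -> list:
    """Columns linearly dependent on the columns before them."""
    bad = []
    for j in range(1, x.shape[1]):
        prev = x[:, :j]
        col = x[:, j]
        resid = col - prev @ np.linalg.lstsq(prev, col, rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(col), 1.0):
            bad.append(names[j])
    return bad


def _ols_all_parcels(x: np.ndarray, y: np.ndarray):
    """Vectorised OLS of every column of y on x: betas, t-stats, df."""
    n, p = x.shape
    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = n - np.linalg.matrix_rank(x)
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    return beta, t, df


def fit_parcelwise_glm(
    int_matrix: pd.DataFrame, cohort: pd.DataFrame, design: str = "M1_primary"
) -> ParcelEffectTable:
    """Mass-univariate OLS of hemisphere-averaged parcel INT on the design.

    ``int_matrix`` is subjects x parcels, row-aligned with ``cohort``.
    Raises on rank deficiency, naming the collinear columns.
    """
    x_frame, rows = build_design(cohort, design)
    y = int_matrix.loc[rows].to_numpy(dtype=float)
    x = x_frame.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, list(x_frame.columns))
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    if np.isnan(x).any():
        raise ValueError("missing covariate values in the design")
    beta, t, df = _ols_all_parcels(x, y)
    parcels = int_matrix.columns
    return ParcelEffectTable(
        coefficients=pd.DataFrame(beta, index=x_frame.columns, columns=parcels),
        tstats=pd.DataFrame(t, index=x_frame.columns, columns=parcels),
        df_resid=int(df),
        model=design,
        design=x_frame,
        subjects=rows,
    )


# ---------------------------------------------------------------------------
# M2: hierarchical-gradient model
# ---------------------------------------------------------------------------


def build_gradient_table(
    effects: ParcelEffectTable,
    hierarchies: dict,
    symptoms: tuple = ("hallucinations", "delusions"),
) -> pd.DataFrame:
    """Long table of M1 t-statistics per (symptom, system, level).

    Prefrontal parcels shared across systems contribute one point per
    system, so 2 symptoms x 9 levels x 3 systems gives 54 points.
    """
    rows = []
    for symptom in symptoms:
        if symptom not in effects.tstats.index:
            raise ValueError(f"predictor {symptom!r} missing from the effect table")
        for system, ordering in hierarchies.items():
            for parcel, level in ordering.assignment:
                if parcel not in effects.tstats.columns:
                    raise ValueError(
                        f"missing cell: ({symptom}, level {level}, {system}) — "
                        f"parcel {parcel!r} absent"
                    )
                rows.append(
                    (symptom, system, level, parcel,
                     float(effects.tstats.loc[symptom, parcel]))
                )
    return pd.DataFrame(rows, columns=["symptom", "system", "level", "parcel", "t"])


def _m2_design(
    table: pd.DataFrame, ref_symptom: str, ref_system: str
) -> pd.DataFrame:
    """Treatment-coded full-interaction design symptom * level * system."""
    symptoms = [s for s in table["symptom"].unique() if s != ref_symptom]
    systems = [s for s in table["system"].unique() if s != ref_system]
    if ref_symptom not in set(table["symptom"]):
        raise ValueError(f"reference symptom {ref_symptom!r} not in the table")
    if ref_system not in set(table["system"]):
        raise ValueError(f"reference system {ref_system!r} not in the table")
    x = pd.DataFrame(index=table.index)
    x["Intercept"] = 1.0
    level = table["level"].astype(float)
    for s in symptoms:
        x[f"sym[{s}]"] = (table["symptom"] == s).astype(float)
    x["level"] = level
    for g in systems:
        x[f"sys[{g}]"] = (table["system"] == g).astype(float)
    for s in symptoms:
        x[f"sym[{s}]:level"] = x[f"sym[{s}]"] * level
    for s in symptoms:
        for g in systems:
            x[f"sym[{s}]:sys[{g}]"] = x[f"sym[{s}]"] * x[f"sys[{g}]"]
    for g in systems:
        x[f"level:sys[{g}]"] = level * x[f"sys[{g}]"]
    for s in symptoms:
        for g in systems:
            x[f"sym[{s}]:level:sys[{g}]"] = x[f"sym[{s}]"] * level * x[f"sys[{g}]"]
    return x


def fit_gradient_glm(
    effects: ParcelEffectTable,
    hierarchies: dict,
    symptoms: tuple = ("hallucinations", "delusions"),
    reference: dict | None = None,
    compute_f2: bool = True,
) -> GradientModelResult:
    """Second-stage OLS with full symptom x level x system interactions.

    ``reference`` selects the implicit levels, e.g. ``{"symptom":
    "hallucinations", "system": "auditory"}``: the ``level`` main effect is
    then the hallucination hierarchical-gradient slope in the auditory
    system, and ``sym[delusions]:level`` the auditory symptom-by-level
    interaction. Works for any number of symptoms (specificity variants) and
    systems (e.g. dorsal vs ventral stream comparisons).
    """
    table = build_gradient_table(effects, hierarchies, symptoms)
    reference = reference or {}
    ref_symptom = reference.get("symptom", symptoms[0])
    ref_system = reference.get("system", sorted(hierarchies)[0])
    x_frame = _m2_design(table, ref_symptom, ref_system)
    x = x_frame.to_numpy(dtype=float)
    y = table["t"].to_numpy(dtype=float)
    n, p = x.shape

    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df_resid = n - p
    sigma2 = (resid**2).sum() / df_resid
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / np.sqrt(np.diag(xtx_inv) * sigma2)

    ss_tot = ((y - y.mean()) ** 2).sum()
    ss_res = (resid**2).sum()
    r2_full = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    df_model = p - 1
    if ss_tot > 0 and r2_full < 1.0:
        f_stat = (r2_full / df_model) / ((1 - r2_full) / df_resid)
        f_p = float(stats.f.sf(f_stat, df_model, df_resid))
    else:
        f_stat, f_p = np.inf, 0.0

    f2 = pd.Series(np.nan, index=x_frame.columns)
    if compute_f2:
        for j, name in enumerate(x_frame.columns):
            if name == "Intercept":
                continue
            x_red = np.delete(x, j, axis=1)
            beta_r = np.linalg.lstsq(x_red, y, rcond=None)[0]
            ss_res_r = ((y - x_red @ beta_r) ** 2).sum()
            r2_red = 1.0 - ss_res_r / ss_tot if ss_tot > 0 else 0.0
            f2[name] = max((r2_full - r2_red), 0.0) / max(1 - r2_full, 1e-12)

    return GradientModelResult(
        params=pd.Series(beta, index=x_frame.columns),
        tvalues=pd.Series(t, index=x_frame.columns),
        f_squared=f2,
        df_resid=df_resid,
        omnibus_f=float(f_stat),
        omnibus_p=f_p,
        df_model=df_model,
        description=(
            f"t ~ symptom * level * system (refs: {ref_symptom}, {ref_system}); "
            f"{len(symptoms)} symptoms x {table['level'].nunique()} levels x "
            f"{table['system'].nunique()} systems, n={n}"
        ),
        r_squared=float(r2_full),
    )


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------


class _M2Engine:
    """Vectorised M1_primary -> M2 refitter for permutation/bootstrap loops.

    Precomputes the patient design matrix, the (fixed) M2 design, and the
    mapping from M2 table rows to (symptom predictor, parcel) pairs; each
    surrogate then costs two small least-squares solves. Numerically
    identical to the public fit_parcelwise_glm + fit_gradient_glm path
    (uses pinv throughout so bootstrap draws that lose a dummy's variance
    degrade gracefully instead of erroring).
    """

    def __init__(self, int_matrix, cohort, hierarchies, symptoms, reference):
        x_frame, rows = build_design(cohort, "M1_primary")
        self.x = x_frame.to_numpy(dtype=float)
        self.columns = list(x_frame.columns)
        self.sym_idx = [self.columns.index(s) for s in SYMPTOM_COLUMNS]
        self.patients = rows

        m1_stub = fit_parcelwise_glm(int_matrix, cohort, "M1_primary")
        table = build_gradient_table(m1_stub, hierarchies, symptoms)
        reference = reference or {}
        ref_symptom = reference.get("symptom", symptoms[0])
        ref_system = reference.get("system", sorted(hierarchies)[0])
        x2_frame = _m2_design(table, ref_symptom, ref_system)
        self.terms = list(x2_frame.columns)
        self.x2 = x2_frame.to_numpy(dtype=float)
        self.xtx2_inv = np.linalg.pinv(self.x2.T @ self.x2)
        self.hat2 = self.xtx2_inv @ self.x2.T
        self.diag2 = np.diag(self.xtx2_inv)
        self.df2 = self.x2.shape[0] - self.x2.shape[1]

        self.parcels = list(dict.fromkeys(table["parcel"]))
        self.y = int_matrix.loc[rows, self.parcels].to_numpy(dtype=float)
        parcel_pos = {p: j for j, p in enumerate(self.parcels)}
        self.row_sym = np.array(
            [self.columns.index(s) for s in table["symptom"]]
        )
        self.row_parcel = np.array([parcel_pos[p] for p in table["parcel"]])

    def tvalues(self, x: np.ndarray | None = None, y: np.ndarray | None = None
                ) -> np.ndarray:
        x = self.x if x is None else x
        y = self.y if y is None else y
        xtx_inv = np.linalg.pinv(x.T @ x)
        beta = xtx_inv @ x.T @ y
        resid = y - x @ beta
        df = x.shape[0] - np.linalg.matrix_rank(x)
        sigma2 = (resid**2).sum(axis=0) / df
        se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
        with np.errstate(invalid="ignore", divide="ignore"):
            t1 = beta / se
        y2 = t1[self.row_sym, self.row_parcel]
        beta2 = self.hat2 @ y2
        resid2 = y2 - self.x2 @ beta2
        s2 = (resid2**2).sum() / self.df2
        with np.errstate(invalid="ignore", divide="ignore"):
            return beta2 / np.sqrt(self.diag2 * s2)


def _pipeline_m2(
    int_matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    hierarchies: dict,
    symptoms: tuple,
    reference: dict | None,
    compute_f2: bool = False,
) -> GradientModelResult:
    m1 = fit_parcelwise_glm(int_matrix, cohort, "M1_primary")
    return fit_gradient_glm(m1, hierarchies, symptoms, reference,
                            compute_f2=compute_f2)


def permutation_null_gradient(
    int_matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    hierarchies: dict,
    terms: list | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    symptoms: tuple = ("hallucinations", "delusions"),
    reference: dict | None = None,
    exhaustive: bool = False,
) -> dict:
    """Permutation test of M2 terms by shuffling the symptom block.

    Each surrogate jointly permutes the rows of the seven-symptom block
    across patients — preserving the inter-symptom correlation matrix
    exactly — then refits M1_primary at every parcel and M2 on the resulting
    t-statistics. Two-sided p = (1 + #{|null| >= |observed|}) / (n_perm + 1).

    With ``exhaustive`` every one of the n_patients! row permutations is
    used (tiny cohorts only). Returns observed result, per-term p, and the
    stored null draws (needed for :func:`set_level_test`).
    """
    observed = _pipeline_m2(int_matrix, cohort, hierarchies, symptoms, reference,
                            compute_f2=True)
    terms = list(terms) if terms is not None else list(observed.tvalues.index)
    unknown = [t for t in terms if t not in observed.tvalues.index]
    if unknown:
        raise ValueError(f"unknown M2 terms: {unknown}")

    patients = cohort.index[cohort["diagnosis"].astype(int) == 1]
    rng = np.random.default_rng(seed)
    if exhaustive:
        if math.factorial(len(patients)) > 50000:
            raise ValueError("refusing exhaustive enumeration of this size")
        perms = [np.array(p) for p in itertools.permutations(range(len(patients)))]
    else:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        perms = [rng.permutation(len(patients)) for _ in range(n_perm)]

    engine = _M2Engine(int_matrix, cohort, hierarchies, symptoms, reference)
    term_idx = [engine.terms.index(t) for t in terms]
    block = engine.x[:, engine.sym_idx].copy()
    null = np.empty((len(perms), len(terms)))
    x = engine.x.copy()
    for i, perm in enumerate(perms):
        x[:, engine.sym_idx] = block[perm]
        null[i] = engine.tvalues(x=x)[term_idx]

    obs = observed.tvalues[terms].to_numpy()
    p = (1 + (np.abs(null) >= np.abs(obs)[None, :] - 1e-12).sum(axis=0)) / (
        len(perms) + 1
    )
    observed.permutation_p = pd.Series(p, index=terms)
    return {
        "observed": observed,
        "p": observed.permutation_p,
        "null_draws": pd.DataFrame(null, columns=terms),
    }


def set_level_test(
    null_draws: pd.DataFrame,
    observed: pd.Series,
    predicate: list,
) -> dict:
    """Probability of spuriously obtaining a whole set of significant effects.

    ``predicate`` is a conjunction of clauses; each clause is a dict
    ``{"terms": [(term, sign), ...], "min_count": k}`` requiring at least k
    of the listed effects to be "significant with the expected sign". A term
    counts as significant within a surrogate (or in the observed data) when
    it falls beyond the two-sided 95% plug-in threshold of its own null
    distribution — beyond the 97.5th percentile for sign +1, below the 2.5th
    for sign -1. The set-level p is the add-one fraction of surrogates
    satisfying every clause.
    """
    for clause in predicate:
        for term, _sign in clause["terms"]:
            if term not in null_draws.columns:
                raise ValueError(f"predicate references unknown term {term!r}")
    lo = null_draws.quantile(0.025)
    hi = null_draws.quantile(0.975)

    def _hits(values) -> bool:
        for clause in predicate:
            count = 0
            for term, sign in clause["terms"]:
                v = values[term]
                if sign > 0 and v >= hi[term]:
                    count += 1
                elif sign < 0 and v <= lo[term]:
                    count += 1
            if count < clause.get("min_count", len(clause["terms"])):
                return False
        return True

    n_perm = len(null_draws)
    n_sat = sum(_hits(null_draws.iloc[i]) for i in range(n_perm))
    p = (1 + n_sat) / (n_perm + 1)
    return {"p": p, "observed_satisfies": _hits(observed),
            "n_surrogates_satisfying": int(n_sat)}


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------


def _bca_interval(boot: np.ndarray, jack: np.ndarray, observed: float,
                  alpha: float = 0.05) -> tuple[float, float, bool]:
    """Accelerated bias-corrected percentile interval for one statistic."""
    boot = boot[np.isfinite(boot)]
    if boot.size == 0 or np.ptp(boot) == 0:
        return observed, observed, True  # degenerate, collapses to a point
    frac = ((boot < observed).sum() + 0.5 * (boot == observed).sum()) / boot.size
    frac = min(max(frac, 1.0 / (boot.size + 1)), boot.size / (boot.size + 1.0))
    z0 = stats.norm.ppf(frac)
    d = jack.mean() - jack
    denom = 6.0 * (d**2).sum() ** 1.5
    a = (d**3).sum() / denom if denom > 0 else 0.0
    out = []
    for z_alpha in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha))
        out.append(np.quantile(boot, stats.norm.cdf(adj)))
    return float(out[0]), float(out[1]), False


def bca_ci(
    int_matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    hierarchies: dict,
    terms: list,
    n_boot: int = 1000,
    seed: int = 0,
    symptoms: tuple = ("hallucinations", "delusions"),
    reference: dict | None = None,
    alpha: float = 0.05,
) -> dict:
    """BCa 95% bootstrap intervals for M2 term t-statistics.

    Patients are resampled with replacement; M1_primary and M2 are refit per
    draw. The bias correction z0 comes from the position of the observed
    statistic in the bootstrap CDF; the acceleration a from the skewness of
    leave-one-patient-out jackknife estimates. A draw in which a site level
    (or any dummy) has no variance drops that column for the draw and is
    flagged; a degenerate bootstrap distribution collapses the interval to a
    point with a flag.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    observed = _pipeline_m2(int_matrix, cohort, hierarchies, symptoms, reference)
    unknown = [t for t in terms if t not in observed.tvalues.index]
    if unknown:
        raise ValueError(f"unknown M2 terms: {unknown}")
    obs = observed.tvalues[terms]

    patients = cohort.index[cohort["diagnosis"].astype(int) == 1]
    controls = cohort.index[cohort["diagnosis"].astype(int) == 0]
    rng = np.random.default_rng(seed)

    del controls  # M1_primary uses patients only; controls never enter
    engine = _M2Engine(int_matrix, cohort, hierarchies, symptoms, reference)
    term_idx = [engine.terms.index(t) for t in terms]
    n_pat = len(patients)
    # site dummies present in the full design; a draw in which one loses all
    # its variance keeps the (pinv-handled) column and is flagged
    site_cols = [j for j, c in enumerate(engine.columns) if c.startswith("site[")]

    def _refit(row_idx):
        x = engine.x[row_idx]
        lost_site = any(x[:, j].std() == 0 for j in site_cols)
        vals = engine.tvalues(x=x, y=engine.y[row_idx])
        if not np.all(np.isfinite(vals[term_idx])):
            return None, lost_site
        return vals[term_idx], lost_site

    dropped_draws = 0
    site_flagged_draws = 0
    boot = np.full((n_boot, len(terms)), np.nan)
    for b in range(n_boot):
        draw = rng.integers(0, n_pat, size=n_pat)
        vals, lost_site = _refit(draw)
        site_flagged_draws += lost_site
        if vals is None:
            dropped_draws += 1
        else:
            boot[b] = vals

    jack = np.full((n_pat, len(terms)), np.nan)
    for i in range(n_pat):
        vals, _ = _refit(np.delete(np.arange(n_pat), i))
        if vals is not None:
            jack[i] = vals

    intervals, flags = {}, {}
    for j, term in enumerate(terms):
        jk = jack[:, j][np.isfinite(jack[:, j])]
        lo, hi, degenerate = _bca_interval(boot[:, j], jk, float(obs[term]), alpha)
        intervals[term] = (lo, hi)
        flags[term] = degenerate
    ci = pd.DataFrame(intervals, index=["lower", "upper"]).T
    observed.bca_ci = ci
    return {
        "observed": observed,
        "ci": ci,
        "degenerate": flags,
        "n_dropped_draws": dropped_draws,
        "n_site_flagged_draws": site_flagged_draws,
        "bootstrap_draws": pd.DataFrame(boot, columns=terms),
    }


# ---------------------------------------------------------------------------
# diagnosis-level overall test, exemplary cases, rank-binned control
# ---------------------------------------------------------------------------


def diagnosis_overall_test(
    int_matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Overall diagnosis effect: count of parcels with |t_diagnosis| beyond
    the two-sided Student threshold, against a diagnosis-shuffled null."""
    m1 = fit_parcelwise_glm(int_matrix, cohort, "M1_exploratory")
    t_crit = stats.t.ppf(1 - alpha / 2, m1.df_resid)
    t_obs = m1.tstats.loc["diagnosis"]
    count_obs = int((t_obs.abs() > t_crit).sum())
    n_negative = int((t_obs[t_obs.abs() > t_crit] < 0).sum())

    rng = np.random.default_rng(seed)
    labels = cohort["diagnosis"].to_numpy()
    null = np.empty(n_perm, dtype=int)
    shuffled = cohort.copy()
    for i in range(n_perm):
        shuffled["diagnosis"] = labels[rng.permutation(len(labels))]
        t_null = fit_parcelwise_glm(int_matrix, shuffled, "M1_exploratory").tstats.loc[
            "diagnosis"
        ]
        null[i] = int((t_null.abs() > t_crit).sum())
    p = (1 + int((null >= count_obs).sum())) / (n_perm + 1)
    return {
        "n_significant_parcels": count_obs,
        "n_parcels": int_matrix.shape[1],
        "n_negative": n_negative,
        "p": p,
        "tstats": t_obs,
        "null_counts": null,
    }


#: symptom-score settings of the four exemplary cases (hallucinations, delusions)
EXEMPLARY_CASES = {
    "none": (0, 0),
    "hallucinations": (5, 0),
    "delusions": (0, 5),
    "both": (5, 5),
}


def exemplary_profiles(
    effects: ParcelEffectTable,
    cohort: pd.DataFrame,
    hierarchy: HierarchyOrdering,
) -> ExemplaryCaseProfile:
    """Fitted INT per level for extreme (hallucination, delusion) settings.

    For each hierarchy parcel, the M1_primary fit is evaluated with the two
    symptoms at the case's scores {0,5} and every other predictor (other
    symptoms, covariates, site dummies) at the patient-sample mean. ΔINT is
    the difference of cases 2-4 from the 'none' case; by linearity the
    'both' profile is exactly the sum of the single-symptom profiles.
    """
    if effects.model != "M1_primary":
        raise ValueError("exemplary profiles require M1_primary coefficients")
    missing = [p for p in hierarchy.parcels if p not in effects.coefficients.columns]
    if missing:
        raise ValueError(f"M1 coefficients missing for parcels: {missing}")
    mean_x = effects.design.mean(axis=0)

    fitted = {}
    for case, (hall, delu) in EXEMPLARY_CASES.items():
        x = mean_x.copy()
        x["hallucinations"] = float(hall)
        x["delusions"] = float(delu)
        x["const"] = 1.0
        coef = effects.coefficients[hierarchy.parcels]
        fitted[case] = x.to_numpy() @ coef.to_numpy()
    levels = hierarchy.levels
    fitted = pd.DataFrame(fitted, index=levels).T
    delta = fitted.loc[["hallucinations", "delusions", "both"]] - fitted.loc["none"]
    return ExemplaryCaseProfile(
        fitted=fitted, delta=delta, levels=levels, parcels=hierarchy.parcels
    )


def rank_binned_profile(
    voxel_tstats: np.ndarray,
    reference_int: np.ndarray,
    n_bins: int = 10,
) -> dict:
    """Data-driven hierarchy control: bin voxels by reference-INT rank.

    Voxels are ranked by a reference INT map, split into ``n_bins`` equally
    sized bins (floor(V/n_bins) voxels each; any remainder joins the last
    bin with a warning), and the mean M1 t-statistic per bin is regressed on
    the bin index (bin index standing in for hierarchical level).
    """
    t = np.asarray(voxel_tstats, dtype=float)
    ref = np.asarray(reference_int, dtype=float)
    if t.shape != ref.shape:
        raise ValueError("voxel t and reference INT must be parallel")
    v = t.size
    if n_bins > v:
        raise ValueError(f"n_bins={n_bins} exceeds the {v} available voxels")
    per_bin = v // n_bins
    if v % n_bins:
        warnings.warn(
            f"{v % n_bins} leftover voxel(s) assigned to the last bin", stacklevel=2
        )
    order = np.argsort(ref, kind="stable")
    bin_means = np.empty(n_bins)
    for b in range(n_bins):
        stop = (b + 1) * per_bin if b < n_bins - 1 else v
        bin_means[b] = t[order[b * per_bin : stop]].mean()
    idx = np.arange(1, n_bins + 1, dtype=float)
    fit = stats.linregress(idx, bin_means)
    return {
        "bin_means": bin_means,
        "bin_index": idx,
        "voxels_per_bin": per_bin,
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "slope_p": float(fit.pvalue),
    }
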
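"""Synthetic inputs with the statistical structure the analysis assumes.

Every pipeline stage is testable without downloads: Ornstein–Uhlenbeck
time series with known ground-truth timescales, patient cohorts with
correlated ordinal symptom scores and hierarchy-structured INT effects,
structural maps carrying myelin/thickness gradients with subject random
effects, and FLN/SLN tract-tracing matrices consistent with a known
hierarchy. All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .biophysical_model import ConnectivityData, HierarchyValues
from .hierarchy_selection import HierarchyOrdering, StructuralCohort
from .int_core import BoldTimeSeries
from .symptom_gradient import SYMPTOM_COLUMNS

__all__ = [
    "TimeSeriesSpec",
    "CohortSpec",
    "TracingSpec",
    "default_hierarchies",
    "gen_timeseries",
    "gen_cohort",
    "gen_structural_maps",
    "gen_connectivity",
]


def default_hierarchies() -> dict:
    """The three 9-level sensory hierarchies used as generator ground truth
    (winning orderings: belt regions in listed order, PFC at 8a=8, 46=9)."""
    return {
        "auditory": HierarchyOrdering.from_dict(
            {"A1": 1, "LBelt": 2, "MBelt": 3, "PBelt": 4, "RI": 5,
             "A4": 6, "A5": 7, "8a": 8, "46": 9}, "auditory"),
        "visual": HierarchyOrdering.from_dict(
            {"V1": 1, "V2": 2, "V3": 3, "V4": 4, "MT": 5,
             "V6": 6, "V7": 7, "8a": 8, "46": 9}, "visual"),
        "somatosensory": HierarchyOrdering.from_dict(
            {"3b": 1, "3a": 2, "1": 3, "2": 4, "5m": 5,
             "7b": 6, "7a": 7, "8a": 8, "46": 9}, "somatosensory"),
    }


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesSpec:
    """Per-unit OU timescales (s), sampling and noise for gen_timeseries."""

    timescales: tuple
    tr: float = 0.72
    duration: float = 864.0  # 1200 frames at the 0.72 s TR
    obs_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(tau < 0 for tau in self.timescales):
            raise ValueError("timescales must be >= 0")
        if self.duration < 100 * self.tr:
            raise ValueError("duration must be >= 100 TR")


def gen_timeseries(spec: TimeSeriesSpec) -> tuple[BoldTimeSeries, dict]:
    """Stationary OU processes sampled at TR, exact discretisation.

    x_{t+1} = phi x_t + sqrt(1 - phi^2) eps with phi = exp(-TR/tau), unit
    stationary variance, plus white observation noise. The ground truth
    records tau, phi, and the implied discrete-sum INT TR*phi/(1-phi)
    (without observation noise).
    """
    rng = np.random.default_rng(spec.seed)
    tau = np.asarray(spec.timescales, dtype=float)
    with np.errstate(divide="ignore"):
        phi = np.where(tau > 0, np.exp(-spec.tr / np.where(tau > 0, tau, 1.0)), 0.0)
    n = int(round(spec.duration / spec.tr))
    eps = rng.standard_normal((n, tau.size))
    x = np.empty((n, tau.size))
    x[0] = rng.standard_normal(tau.size)
    innov_sd = np.sqrt(1 - phi**2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov_sd * eps[t]
    if spec.obs_noise_sd > 0:
        x = x + spec.obs_noise_sd * rng.standard_normal(x.shape)
    truth = {
        "tau": tau,
        "phi": phi,
        "int_discrete": spec.tr * phi / (1 - phi),
    }
    return BoldTimeSeries(data=x, tr=spec.tr), truth


# ---------------------------------------------------------------------------
# ordinal-score copula calibration
# ---------------------------------------------------------------------------

#: default severity-category probabilities for scores 0..5 (mean ~2.4, the
#: coarse shape of hallucination/delusion severity in mixed psychosis samples)
DEFAULT_SCORE_PROBS = (0.15, 0.17, 0.20, 0.20, 0.16, 0.12)


def _grade_scores(probs: np.ndarray) -> np.ndarray:
    """Population midrank score of each category (for tied-rank Spearman)."""
    cum = np.concatenate([[0.0], np.cumsum(probs)])
    return cum[:-1] + probs / 2


def _discretised_spearman(latent_rho: float, probs: np.ndarray) -> float:
    """Population Spearman (grade) correlation of two 0..5 scores obtained by
    thresholding a bivariate standard normal at the category quantiles."""
    cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
    grid = np.concatenate([[-8.5], cuts, [8.5]])
    mvn = stats.multivariate_normal(mean=[0, 0],
                                    cov=[[1, latent_rho], [latent_rho, 1]])
    pts = np.array([[a, b] for a in grid for b in grid])
    cdf = mvn.cdf(pts).reshape(grid.size, grid.size)
    cell = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    cell = np.clip(cell, 0, None)
    cell /= cell.sum()
    u = _grade_scores(probs)
    mu = float(probs @ u)
    var = float(probs @ u**2 - mu**2)
    cov = float(u @ cell @ u - mu * mu)
    return cov / var


@functools.lru_cache(maxsize=32)
def _calibrate_latent_rho(target: float, probs: tuple) -> float:
    """Latent normal correlation reproducing a target rank correlation of
    the thresholded scores; errors when the target is unattainable."""
    probs_arr = np.asarray(probs, dtype=float)
    bound = _discretised_spearman(0.999, probs_arr)
    if abs(target) > bound:
        raise ValueError(
            f"target rank correlation {target} infeasible after discretisation; "
            f"attainable bound is ±{bound:.3f}"
        )
    if target == 0:
        return 0.0
    return float(optimize.brentq(
        lambda r: _discretised_spearman(r, probs_arr) - target, -0.999, 0.999,
        xtol=1e-4,
    ))


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Study conditions for the synthetic psychosis cohort.

    Symptom effects are (intercept, slope) of the per-score-point INT change
    (seconds) as a function of hierarchical level, applied to the parcels of
    the listed systems: the hallucination profile adds INT at low levels
    (gradient compression), the delusion profile at high levels (gradient
    expansion), mirroring the effect structure the analysis is built to
    detect. ``diagnosis_effect_pct`` scales patients' base INT globally.
    """

    n_patients: int = 127
    n_controls: int = 158
    target_rank_corr: float = 0.62
    other_symptom_latent_corr: float = 0.3
    score_probs: tuple = DEFAULT_SCORE_PROBS
    base_intercept: float = 0.55  # s at level 0
    base_slope: float = 0.05  # s per level
    filler_int: float = 0.80  # s, parcels outside the hierarchies
    hallucination_effect: tuple = (0.020, -0.004)  # s/point: a + b*level
    hallucination_systems: tuple = ("auditory",)
    delusion_effect: tuple = (-0.020, 0.004)
    delusion_systems: tuple = ("auditory", "somatosensory")
    diagnosis_effect_pct: float = -5.0
    subject_sd: float = 0.08  # between-subject INT offset, s
    noise_sd: float = 0.10  # within-parcel residual, s
    n_parcels: int = 188
    n_sites: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if abs(sum(self.score_probs) - 1) > 1e-9:
            raise ValueError("score_probs must sum to 1")


def _draw_scores(rng, n: int, spec: CohortSpec) -> pd.DataFrame:
    """Seven 0..5 symptom scores from a thresholded Gaussian copula; the
    hallucination–delusion pair is calibrated to the target rank
    correlation, remaining pairs share a common moderate latent correlation."""
    latent_rho = _calibrate_latent_rho(spec.target_rank_corr, tuple(spec.score_probs))
    k = len(SYMPTOM_COLUMNS)
    cov = np.full((k, k), spec.other_symptom_latent_corr)
    np.fill_diagonal(cov, 1.0)
    cov[0, 1] = cov[1, 0] = latent_rho
    latent = rng.multivariate_normal(np.zeros(k), cov, size=n,
                                     method="cholesky")
    cuts = stats.norm.ppf(np.cumsum(spec.score_probs)[:-1])
    scores = np.searchsorted(cuts, latent).astype(int)
    return pd.DataFrame(scores, columns=SYMPTOM_COLUMNS)


def _parcel_levels(hierarchies: dict) -> pd.DataFrame:
    rows = []
    for system, ordering in hierarchies.items():
        for parcel, level in ordering.assignment:
            rows.append((system, parcel, level))
    return pd.DataFrame(rows, columns=["system", "parcel", "level"])


def gen_cohort(spec: CohortSpec, hierarchies: dict | None = None):
    """Generate (int_matrix, cohort table, ground truth) for the cohort.

    The INT of subject s at parcel p is the system gradient at p's level,
    scaled by the diagnosis effect for patients, plus score-weighted
    level-profile symptom effects (patients only, through their scores),
    covariate effects, a subject random offset and Gaussian noise. A parcel
    appearing in several affected systems receives each symptom effect once
    (levels agree across systems by construction).
    """
    rng = np.random.default_rng(spec.seed)
    hierarchies = hierarchies or default_hierarchies()
    levels = _parcel_levels(hierarchies)
    hierarchy_parcels = levels.drop_duplicates("parcel").set_index("parcel")["level"]

    n_total = spec.n_patients + spec.n_controls
    diagnosis = np.r_[np.ones(spec.n_patients, int), np.zeros(spec.n_controls, int)]

    scores = _draw_scores(rng, spec.n_patients, spec)
    scores = pd.concat(
        [scores, pd.DataFrame(0, index=range(spec.n_controls),
                              columns=SYMPTOM_COLUMNS)],
        ignore_index=True,
    )

    age = np.clip(rng.normal(38, 12, n_total), 18, 65)
    gender = rng.binomial(1, 0.7, n_total)
    mean_fd = np.exp(rng.normal(np.log(0.15), 0.4, n_total))
    site_probs = np.array([0.3, 0.3, 0.2, 0.2][: spec.n_sites], dtype=float)
    site_probs /= site_probs.sum()
    site = rng.choice([f"site{i+1}" for i in range(spec.n_sites)], size=n_total,
                      p=site_probs)
    cohort = pd.concat([pd.DataFrame({
        "diagnosis": diagnosis, "age": age, "gender": gender,
        "mean_fd": mean_fd, "site": site,
    }), scores], axis=1)

    parcel_names = list(hierarchy_parcels.index)
    n_filler = max(spec.n_parcels - len(parcel_names), 0)
    parcel_names += [f"parcel_{i:03d}" for i in range(n_filler)]

    base = np.empty(len(parcel_names))
    base[: len(hierarchy_parcels)] = (
        spec.base_intercept + spec.base_slope * hierarchy_parcels.to_numpy()
    )
    base[len(hierarchy_parcels):] = spec.filler_int

    int_mat = np.tile(base, (n_total, 1))
    # global diagnosis effect (percent of base INT)
    int_mat[diagnosis == 1] *= 1 + spec.diagnosis_effect_pct / 100.0

    # symptom effects over the union of affected-system hierarchy parcels
    effect_profiles = {
        "hallucinations": (spec.hallucination_effect, spec.hallucination_systems),
        "delusions": (spec.delusion_effect, spec.delusion_systems),
    }
    truth_effects = {}
    for symptom, ((a, b), systems) in effect_profiles.items():
        affected = levels[levels["system"].isin(systems)].drop_duplicates("parcel")
        cols = [parcel_names.index(p) for p in affected["parcel"]]
        per_point = a + b * affected["level"].to_numpy()
        int_mat[:, cols] += np.outer(scores[symptom].to_numpy(), per_point)
        truth_effects[symptom] = dict(zip(affected["parcel"], per_point))

    # covariate effects and noise
    int_mat += (-0.002 * (age - 40) + 0.01 * gender - 0.3 * (mean_fd - 0.15))[:, None]
    site_offsets = dict(zip(sorted(set(site)),
                            [0.0, 0.02, -0.02, 0.01][: spec.n_sites]))
    int_mat += np.array([site_offsets[s] for s in site])[:, None]
    int_mat += rng.normal(0, spec.subject_sd, n_total)[:, None]
    int_mat += rng.normal(0, spec.noise_sd, int_mat.shape)
    int_mat = np.clip(int_mat, 0.0, None)

    int_matrix = pd.DataFrame(int_mat, columns=parcel_names)
    truth = {
        "latent_rho": _calibrate_latent_rho(spec.target_rank_corr,
                                            tuple(spec.score_probs)),
        "effects": truth_effects,
        "hierarchies": hierarchies,
        "diagnosis_effect_pct": spec.diagnosis_effect_pct,
        "base": dict(zip(parcel_names, base)),
    }
    return int_matrix, cohort, truth


# ---------------------------------------------------------------------------
# structural maps
# ---------------------------------------------------------------------------


def gen_structural_maps(
    ordering: HierarchyOrdering,
    n_subjects: int = 20,
    myelin: tuple = (1.7, -0.05),
    thickness: tuple = (2.2, 0.08),
    subject_intercept_sd: tuple = (0.05, 0.10),
    subject_slope_sd: tuple = (0.005, 0.010),
    noise_sd: tuple = (0.05, 0.10),
    seed: int = 0,
) -> StructuralCohort:
    """Structural cohort with hierarchy gradients plus subject random effects.

    T1w/T2w decreases and cortical thickness increases with hierarchical
    level ((intercept, slope) pairs), each subject drawing a random
    intercept and a random slope perturbation, plus residual noise.
    """
    rng = np.random.default_rng(seed)
    levels = ordering.levels.astype(float)
    out = []
    for (icpt, slope), i_sd, s_sd, e_sd in zip(
        (myelin, thickness), subject_intercept_sd, subject_slope_sd, noise_sd
    ):
        subj_icpt = rng.normal(0, i_sd, n_subjects)
        subj_slope = rng.normal(0, s_sd, n_subjects)
        vals = (icpt + subj_icpt[:, None]
                + np.outer(slope + subj_slope, levels)
                + rng.normal(0, e_sd, (n_subjects, levels.size)))
        out.append(pd.DataFrame(vals, columns=ordering.parcels))
    return StructuralCohort(t1w_t2w=out[0], thickness=out[1])


# ---------------------------------------------------------------------------
# tract-tracing connectivity
# ---------------------------------------------------------------------------


@dataclass
class TracingSpec:
    """Generator settings for synthetic FLN/SLN matrices.

    The default network holds the six nodes matched to hierarchy levels
    (V1, V2, V4, MT, 8l, 46d, with hierarchy values compressed at the
    bottom, as empirical SLN-derived values are) plus eight unperturbed
    association nodes high in the hierarchy. The association cluster
    carries the near-critical slow mode that gives the model its seconds-
    scale top timescales — standing in for the many association areas of a
    full cortical graph — while the perturbable matched nodes stay clear of
    the instability.
    """

    n_nodes: int = 14
    h: tuple | None = None  # true hierarchy values; default matched levels
    fln_decay: float = 1.0  # log-FLN decay per unit hierarchy distance
    fln_asym: float = 2.3  # feedforward dominance of labeled-neuron counts
    fln_log_sd: float = 0.3
    sln_slope: float = 4.0  # logistic-link slope on hierarchy differences
    sln_noise_sd: float = 0.2  # logit-scale link noise
    seed: int = 0
    node_names: tuple | None = None

    #: matched nodes and their hierarchy levels (1..9)
    MATCHED = ("V1", "V2", "V4", "MT", "8l", "46d")
    MATCHED_LEVELS = (1, 2, 4, 5, 8, 9)

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")

    def resolved_names(self) -> list:
        if self.node_names:
            return list(self.node_names)
        if self.n_nodes >= 6:
            return list(self.MATCHED) + [
                f"assoc{i:02d}" for i in range(self.n_nodes - 6)
            ]
        return [f"node{i:02d}" for i in range(self.n_nodes)]

    def resolved_h(self) -> np.ndarray:
        if self.h is not None:
            return np.asarray(self.h, dtype=float)
        if self.n_nodes >= 6:
            lv = np.asarray(self.MATCHED_LEVELS, dtype=float)
            matched = ((lv - 1) / 8) ** 2  # bottom-compressed, like SLN fits
            extra = np.linspace(0.85, 1.0, self.n_nodes - 6)
            return np.concatenate([matched, extra])
        return np.linspace(0, 1, self.n_nodes)


def gen_connectivity(spec: TracingSpec) -> tuple[ConnectivityData, HierarchyValues]:
    """FLN/SLN matrices consistent with a known hierarchy.

    FLN: row-normalised log-normal weights whose log-mean decays with
    hierarchy distance (stronger connections between nearby levels) and
    favours feedforward projections (``fln_asym``; ascending projections
    dominate retrograde label counts, which keeps the loop gains of a small
    row-normalised network in the regime of a full cortical graph). SLN:
    logistic of the hierarchy difference (target minus source) with
    logit-scale link noise, clipped to (0.01, 0.99); feedforward
    projections (low -> high) have high SLN.
    """
    rng = np.random.default_rng(spec.seed)
    h = spec.resolved_h()
    n = spec.n_nodes
    dist = np.abs(h[:, None] - h[None, :])
    logw = (-spec.fln_decay * dist + spec.fln_asym * (h[:, None] - h[None, :])
            + spec.fln_log_sd * rng.standard_normal((n, n)))
    fln = np.exp(logw)
    np.fill_diagonal(fln, 0.0)
    fln /= fln.sum(axis=1, keepdims=True)

    logit_sln = spec.sln_slope * (h[:, None] - h[None, :])
    if spec.sln_noise_sd > 0:
        logit_sln = logit_sln + spec.sln_noise_sd * rng.standard_normal((n, n))
    sln = np.clip(special.expit(logit_sln), 0.01, 0.99)
    np.fill_diagonal(sln, 0.5)

    conn = ConnectivityData(fln=fln, sln=sln, node_names=spec.resolved_names())
    return conn, HierarchyValues(h=h)
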
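"""Intrinsic neural timescale (INT) estimation from resting-state fMRI.

The INT of a voxel or parcel summarises how slowly its spontaneous activity
decorrelates: the autocorrelation function (ACF) of the demeaned signal is
estimated at integer lags and the coefficients of the initial positive period
(lag 1 up to, but not including, the first non-positive coefficient) are
summed and scaled by the repetition time, giving a timescale in seconds.
Longer INT indicates a wider temporal-integration window; across the cortex
INT increases from sensory to association areas, forming the hierarchy the
rest of this package works with.

The module covers the single-subject chain: nuisance cleaning of the BOLD
signal (confound regression, band-pass, motion censoring), ACF/INT
estimation, parcel aggregation, and test–retest reliability via ICC(2,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, signal

__all__ = [
    "BoldTimeSeries",
    "AcfProfile",
    "IntMap",
    "IntEstimate",
    "ParcelScheme",
    "clean_timeseries",
    "estimate_acf",
    "estimate_int",
    "parcellate_map",
    "icc_reliability",
    "load_bold_nifti",
    "load_labels_nifti",
    "load_confounds_tsv",
    "save_int_nifti",
    "int_map_to_frame",
]

#: Minimum number of retained timepoints for any ACF/INT estimate.
MIN_TIMEPOINTS = 8

#: Default band for resting-state band-pass filtering (Hz).
DEFAULT_BAND = (0.01, 0.1)

#: Default framewise-displacement censoring threshold (mm).
DEFAULT_FD_THRESHOLD = 0.3

#: Lag horizon for ACF estimation (seconds); the INT sum stops at the first
#: non-positive coefficient anyway, this only bounds the computed profile.
ACF_HORIZON_S = 100.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BoldTimeSeries:
    """A (timepoints x units) sampled signal with TR and a censor mask.

    ``censor_mask`` is True for retained frames. Units are voxels, vertices
    or parcels; the estimator does not care.
    """

    data: np.ndarray
    tr: float
    censor_mask: np.ndarray | None = None
    unit_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (timepoints x units)")
        if self.data.shape[0] == 1 and self.data.shape[1] > 1:
            # accept a single 1-D series given as a row
            self.data = self.data.T
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if self.censor_mask is None:
            self.censor_mask = np.ones(self.n_timepoints, dtype=bool)
        else:
            self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
            if self.censor_mask.shape != (self.n_timepoints,):
                raise ValueError("censor_mask length must equal timepoint count")
        if self.unit_ids is None:
            self.unit_ids = np.arange(self.n_units)
        else:
            self.unit_ids = np.asarray(self.unit_ids)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]

    @property
    def n_retained(self) -> int:
        return int(self.censor_mask.sum())


@dataclass
class AcfProfile:
    """Per-unit autocorrelation coefficients at lags 1..K.

    ``first_nonpositive_lag`` holds, per unit, the lag index of the first
    coefficient <= 0 (or K+1 when all K coefficients are positive).
    """

    coefficients: np.ndarray  # (K, units)
    first_nonpositive_lag: np.ndarray  # (units,)
    tr: float

    @property
    def n_lags(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class IntMap:
    """INT values in seconds per unit, tagged with the space they live in."""

    values: np.ndarray
    space_tag: str = "voxel"
    unit_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.unit_ids is None:
            self.unit_ids = np.arange(self.values.shape[-1])
        else:
            self.unit_ids = np.asarray(self.unit_ids)


@dataclass
class IntEstimate:
    """Bundle returned by :func:`estimate_int`."""

    acf: AcfProfile
    int_map: IntMap
    undefined: np.ndarray  # True where the ACF (hence INT) is undefined
    exp_timescale: np.ndarray | None = None  # seconds, from exponential fit


@dataclass
class ParcelScheme:
    """Unit -> parcel assignment plus optional left/right pairing.

    ``labels`` is an integer vector parallel to the units of the map being
    parcellated; 0 (or ``background``) marks unassigned units.
    The reference scheme of this package is HCP-MMP-style: 180 cortical
    parcels per hemisphere collapsed to 180 by left/right averaging, plus 8
    subcortical parcels (188 total).
    """

    labels: np.ndarray
    parcel_names: dict = field(default_factory=dict)
    hemisphere_pairs: dict = field(default_factory=dict)
    background: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        seen_left = list(self.hemisphere_pairs.keys())
        seen_right = list(self.hemisphere_pairs.values())
        if len(set(seen_left)) != len(seen_left) or len(set(seen_right)) != len(seen_right):
            raise ValueError("each parcel may appear at most once per hemisphere pairing")
        if set(seen_left) & set(seen_right):
            raise ValueError("a parcel cannot be both a left and a right member of a pair")


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------


def _with_derivatives(confounds: np.ndarray) -> np.ndarray:
    """Append first (backward-difference) derivatives of each confound."""
    deriv = np.diff(confounds, axis=0, prepend=confounds[:1])
    return np.column_stack([confounds, deriv])


def censor_mask_from_fd(
    fd: np.ndarray, threshold: float = DEFAULT_FD_THRESHOLD
) -> np.ndarray:
    """True for retained frames; FD > threshold drops the frame and both
    immediate neighbours."""
    fd = np.asarray(fd, dtype=float)
    bad = fd > threshold
    bad = bad | np.roll(bad, 1) | np.roll(bad, -1)
    # np.roll wraps around; the first and last frames have no neighbour on
    # one side, undo the wrap-around contamination
    if fd.size >= 2:
        bad[0] = (fd[0] > threshold) or (fd[1] > threshold)
        bad[-1] = (fd[-1] > threshold) or (fd[-2] > threshold)
    return ~bad


def clean_timeseries(
    series: BoldTimeSeries,
    confounds: np.ndarray | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    fd: np.ndarray | None = None,
    fd_threshold: float = DEFAULT_FD_THRESHOLD,
    add_derivatives: bool = True,
) -> BoldTimeSeries:
    """Confound regression, band-pass filtering, and motion censoring.

    Confounds (plus their first derivatives unless ``add_derivatives`` is
    False) and an intercept are regressed out of every unit; residuals are
    band-pass filtered with a zero-phase second-order Butterworth; frames
    whose framewise displacement exceeds ``fd_threshold`` are censored along
    with both immediate neighbours. Filtering runs on the contiguous series;
    censoring only updates the mask.

    Raises
    ------
    ValueError
        If fewer retained frames remain than confound regressors + 8
        ("insufficient degrees of freedom"), or band edges are invalid.
    """
    y = series.data
    n_t = series.n_timepoints

    n_conf = 0
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != n_t:
            if confounds.shape[1] == n_t:
                confounds = confounds.T
            else:
                raise ValueError("confound matrix row count must equal timepoint count")
        if add_derivatives:
            confounds = _with_derivatives(confounds)
        n_conf = confounds.shape[1]
        design = np.column_stack([np.ones(n_t), confounds])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        y = y - design @ beta
    else:
        y = y - y.mean(axis=0, keepdims=True)

    low, high = band
    nyquist = 0.5 / series.tr
    if not 0 < low < high < nyquist:
        raise ValueError(
            f"band must satisfy 0 < low < high < Nyquist ({nyquist:.4g} Hz); got {band}"
        )
    sos = signal.butter(2, [low, high], btype="bandpass", fs=1.0 / series.tr, output="sos")
    y = signal.sosfiltfilt(sos, y, axis=0)

    mask = series.censor_mask.copy()
    if fd is not None:
        fd = np.asarray(fd, dtype=float)
        if fd.shape != (n_t,):
            raise ValueError("fd vector length must equal timepoint count")
        mask &= censor_mask_from_fd(fd, fd_threshold)

    n_retained = int(mask.sum())
    if n_retained < n_conf + MIN_TIMEPOINTS:
        raise ValueError(
            "insufficient degrees of freedom after motion censoring: "
            f"{n_retained} retained frames for {n_conf} confound regressors"
        )
    return replace(series, data=y, censor_mask=mask)


# ---------------------------------------------------------------------------
# ACF / INT estimation
# ---------------------------------------------------------------------------


def _default_max_lag(n_retained: int, tr: float) -> int:
    return int(min(n_retained - 1, np.ceil(ACF_HORIZON_S / tr)))


def estimate_acf(
    series: BoldTimeSeries,
    max_lag: int | None = None,
    censor_mode: str = "pairwise",
) -> AcfProfile:
    """Biased sample ACF of the demeaned signal at lags 1..K, per unit.

    ACF_k = sum_t (y_t - ybar)(y_{t-k} - ybar) / sum_t (y_t - ybar)^2,
    the denominator running over all retained frames (no lag-dependent
    normalisation). With censoring, ``censor_mode='pairwise'`` lets a lag-k
    product contribute only when both frames are retained, while
    ``'concatenate'`` compacts retained frames and treats them as contiguous.

    Units with zero variance get NaN coefficients (undefined ACF).
    """
    if censor_mode not in ("pairwise", "concatenate"):
        raise ValueError("censor_mode must be 'pairwise' or 'concatenate'")
    mask = series.censor_mask
    n_ret = int(mask.sum())
    if n_ret < MIN_TIMEPOINTS:
        raise ValueError(f"need >= {MIN_TIMEPOINTS} retained timepoints, got {n_ret}")
    if max_lag is None:
        max_lag = _default_max_lag(n_ret, series.tr)
    max_lag = int(min(max_lag, n_ret - 1))

    if censor_mode == "concatenate":
        y = series.data[mask]
        ybar = y.mean(axis=0)
        z = y - ybar
    else:
        y = series.data
        ybar = series.data[mask].mean(axis=0)
        # zeroing censored frames removes them from numerator cross-products
        # (a product survives only if both of its frames are retained) and
        # from the denominator
        z = (y - ybar) * mask[:, None]

    denom = (z**2).sum(axis=0)
    ok = denom > 0
    coeffs = np.full((max_lag, series.n_units), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in range(1, max_lag + 1):
            coeffs[k - 1] = (z[k:] * z[:-k]).sum(axis=0) / np.where(ok, denom, np.nan)

    nonpos = coeffs <= 0
    any_nonpos = nonpos.any(axis=0)
    first = np.where(any_nonpos, nonpos.argmax(axis=0) + 1, max_lag + 1)
    first = np.where(ok, first, 1).astype(int)
    return AcfProfile(coefficients=coeffs, first_nonpositive_lag=first, tr=series.tr)


def int_from_acf(acf: AcfProfile, space_tag: str = "voxel",
                 unit_ids: np.ndarray | None = None) -> tuple[IntMap, np.ndarray]:
    """INT = TR * sum_{k=1}^{N} ACF_k with N = first_nonpositive_lag - 1.

    Returns the map and an ``undefined`` mask (constant series). INT is 0,
    not missing, when ACF_1 <= 0.
    """
    coeffs = acf.coefficients
    undefined = np.isnan(coeffs[0])
    n_lags, n_units = coeffs.shape
    lag_idx = np.arange(1, n_lags + 1)[:, None]
    include = lag_idx < acf.first_nonpositive_lag[None, :]
    summed = np.where(include, np.nan_to_num(coeffs), 0.0).sum(axis=0)
    values = acf.tr * summed
    values[undefined] = np.nan
    return IntMap(values=values, space_tag=space_tag, unit_ids=unit_ids), undefined


def _fit_exp_timescales(acf: AcfProfile) -> np.ndarray:
    """Decay constant tau (s) of A*exp(-k*TR/tau) fit to the initial positive
    ACF segment, per unit; NaN where fewer than 2 positive lags exist."""
    n_lags, n_units = acf.coefficients.shape
    tau = np.full(n_units, np.nan)
    lags_s = np.arange(1, n_lags + 1) * acf.tr
    for u in range(n_units):
        n = acf.first_nonpositive_lag[u] - 1
        if n < 2:
            continue
        t = lags_s[:n]
        a = acf.coefficients[:n, u]
        # log-linear initialisation, then nonlinear refinement
        slope, intercept = np.polyfit(t, np.log(a), 1)
        tau0 = -1.0 / slope if slope < 0 else t[-1]
        try:
            popt, _ = optimize.curve_fit(
                lambda t_, amp, tau_: amp * np.exp(-t_ / tau_),
                t, a, p0=(float(np.exp(intercept)), float(max(tau0, acf.tr / 10))),
                maxfev=2000,
            )
            tau[u] = popt[1]
        except RuntimeError:
            tau[u] = max(tau0, 0.0)
    return tau


def estimate_int(
    series: BoldTimeSeries,
    exp_fit: bool = False,
    max_lag: int | None = None,
    censor_mode: str = "pairwise",
    space_tag: str = "voxel",
) -> IntEstimate:
    """Estimate per-unit INT (seconds) from a cleaned time series.

    See :func:`estimate_acf` and :func:`int_from_acf` for the two stages.
    When ``exp_fit`` is set, the decay constant of a least-squares
    exponential fit to the initial positive ACF segment is also returned as
    a comparator timescale.
    """
    acf = estimate_acf(series, max_lag=max_lag, censor_mode=censor_mode)
    int_map, undefined = int_from_acf(acf, space_tag=space_tag, unit_ids=series.unit_ids)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} unit(s) have zero variance; "
            "their ACF is undefined and INT is reported missing",
            stacklevel=2,
        )
    exp_tau = _fit_exp_timescales(acf) if exp_fit else None
    return IntEstimate(acf=acf, int_map=int_map, undefined=undefined, exp_timescale=exp_tau)


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------


def parcellate_map(
    int_map: IntMap, scheme: ParcelScheme, hemi_average: bool = False
) -> IntMap:
    """Aggregate a unit-level map to parcels by unweighted means.

    Missing unit values are excluded from the mean; an empty parcel yields a
    missing value with a warning (never zero). With ``hemi_average``, paired
    left/right parcels are averaged into a single value keyed by the left
    member.
    """
    labels = scheme.labels
    if labels.shape != int_map.values.shape:
        raise ValueError("scheme labels must be parallel to the map units")
    frame = pd.DataFrame({"parcel": labels, "value": int_map.values})
    frame = frame[frame["parcel"] != scheme.background]
    means = frame.groupby("parcel")["value"].mean()

    all_parcels = sorted(
        set(np.unique(labels)) - {scheme.background} | set(scheme.parcel_names)
    )
    values = means.reindex(all_parcels)
    missing_parcels = values.index[values.isna()].tolist()
    if missing_parcels:
        warnings.warn(f"empty parcel(s) {missing_parcels}: value reported missing",
                      stacklevel=2)

    if hemi_average and scheme.hemisphere_pairs:
        merged_ids, merged_vals = [], []
        rights = set(scheme.hemisphere_pairs.values())
        for pid in values.index:
            if pid in rights:
                continue
            if pid in scheme.hemisphere_pairs:
                other = scheme.hemisphere_pairs[pid]
                pair = values.reindex([pid, other])
                merged_vals.append(float(pair.mean()))
            else:
                merged_vals.append(float(values.loc[pid]))
            merged_ids.append(pid)
        return IntMap(values=np.array(merged_vals), space_tag="parcel",
                      unit_ids=np.array(merged_ids))
    return IntMap(values=values.to_numpy(), space_tag="parcel",
                  unit_ids=values.index.to_numpy())


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------


def icc_reliability(maps_a: np.ndarray, maps_b: np.ndarray) -> dict:
    """ICC(2,1) per unit across subjects, for two measurements per subject.

    ``maps_a`` and ``maps_b`` are (subjects x units) stacks of INT maps
    (e.g. split-half estimates). The two-way random-effects, single-measure
    intraclass correlation (Shrout & Fleiss) is computed unit-wise from the
    two-way ANOVA mean squares; units with zero between-subject variance are
    flagged undefined (NaN).

    Returns a dict with ``icc`` (per unit), ``median`` and ``iqr``.
    """
    a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("the two map stacks must have identical shapes")
    n, n_units = a.shape
    if n < 2:
        raise ValueError("need >= 2 subjects for ICC")
    k = 2
    x = np.stack([a, b], axis=1)  # (subjects, raters, units)

    grand = x.mean(axis=(0, 1))
    row_mean = x.mean(axis=1)  # (subjects, units)
    col_mean = x.mean(axis=0)  # (raters, units)

    ss_rows = k * ((row_mean - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_mean - grand) ** 2).sum(axis=0)
    ss_total = ((x - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (msr - mse) / denom
    no_var = row_mean.var(axis=0) <= 0
    icc = np.where(no_var | (denom == 0), np.nan, icc)
    if np.isnan(icc).any():
        warnings.warn(
            f"{int(np.isnan(icc).sum())} unit(s) have zero between-subject "
            "variance; ICC undefined there", stacklevel=2)
    q25, q50, q75 = np.nanpercentile(icc, [25, 50, 75])
    return {"icc": icc, "median": float(q50), "iqr": float(q75 - q25)}


# ---------------------------------------------------------------------------
# I/O (thin nibabel / pandas wrappers)
# ---------------------------------------------------------------------------


def load_bold_nifti(path, tr: float | None = None) -> tuple[BoldTimeSeries, tuple]:
    """Load a 4-D NIfTI as (timepoints x voxels); returns the series and the
    spatial shape needed to write results back out."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI time series")
    shape = data.shape[:3]
    series = data.reshape(-1, data.shape[3]).T
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    return BoldTimeSeries(data=series, tr=tr), shape


def load_labels_nifti(path) -> np.ndarray:
    """Load a 3-D integer label volume, flattened to match load_bold_nifti."""
    import nibabel as nib

    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    return np.round(labels).astype(int).reshape(-1)


def load_confounds_tsv(path, fd_column: str = "framewise_displacement"):
    """Read a confound table; returns (confound matrix, fd vector or None)."""
    table = pd.read_csv(path, sep="\t")
    fd = None
    if fd_column in table.columns:
        fd = table.pop(fd_column).to_numpy(dtype=float)
        fd = np.nan_to_num(fd)
    return table.to_numpy(dtype=float), fd


def save_int_nifti(int_map: IntMap, shape: tuple, path, affine=None) -> None:
    """Write a voxel-space INT map back into a 3-D NIfTI volume."""
    import nibabel as nib

    vol = np.full(int(np.prod(shape)), np.nan)
    vol[np.asarray(int_map.unit_ids, dtype=int)] = int_map.values
    img = nib.Nifti1Image(vol.reshape(shape).astype(np.float32),
                          affine if affine is not None else np.eye(4))
    nib.save(img, str(path))


def int_map_to_frame(int_map: IntMap, subject_id: str = "sub-01") -> pd.DataFrame:
    """Long-format table (subject_id, parcel, int_seconds) for CSV export."""
    return pd.DataFrame({
        "subject_id": subject_id,
        "parcel": int_map.unit_ids,
        "int_seconds": int_map.values,
    })
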
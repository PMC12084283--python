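"""Masting metrics, circular day-of-year timing, and PCA of species means.

Five metrics summarise interannual reproductive behaviour of each species
and phenophase, each computed on annual intensity series (mean ordinal
score per August-July phenological year):

* **intensity** -- mean annual intensity.
* **CV** -- sample standard deviation / mean of annual intensity;
  CV > 1 is the conventional masting flag.
* **volatility** -- frequency-weighted periodogram mass of the annual
  series; rises with variance and with alternating (high-frequency)
  dynamics. Unit-sensitive: not comparable across studies that score
  intensity on different scales.
* **synchrony** -- mean pairwise Pearson correlation among conspecific
  trees; > 0.2 is the conventional masting flag.
* **failures** -- proportion of years with intensity exactly zero.

Metrics are computed per tree and averaged to the species level by
default; a pooled-species-series variant is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from mastpheno.io import PHENOPHASES, _doy_365_vec, annual_series_matrix, annualize

logger = logging.getLogger(__name__)

METRIC_NAMES = ("intensity", "cv", "volatility", "synchrony", "failures")

#: fixed circular modulus for day-of-year statistics
DOY_MODULUS = 365.0


def intensity_metric(values) -> float:
    """Mean of the non-missing annual intensity values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("intensity_metric: all values missing")
    return float(v.mean())


def cv_metric(values) -> float:
    """Coefficient of variation: sample sd (n-1 denominator) over mean.

    Returns NaN with a warning when the mean is zero (an all-zero
    reproducer has no defined CV).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("cv_metric: need >= 2 non-missing years")
    m = v.mean()
    if m == 0.0:
        warnings.warn("cv_metric: zero-mean series, CV undefined", stacklevel=2)
        return float("nan")
    return float(v.std(ddof=1) / m)


def volatility_metric(values, gap_policy: str = "error") -> float:
    """Frequency-weighted periodogram mass of an annual intensity series.

    With the mean-centred series y_1..y_T and periodogram
    I(f_k) = |sum_t y_t exp(-2*pi*i*k*t/T)|^2 / T at the Fourier
    frequencies f_k = k/T (k = 1..floor(T/2)), the volatility is

        v = (2/T) * sum_k f_k * I(f_k).

    It is zero for constant series, scales with squared amplitude, and
    weights high-frequency (alternating / lagged) variation more heavily
    than slow trends of equal variance.

    Parameters
    ----------
    values
        Annual series in consecutive-year order; NaN marks missing years.
    gap_policy
        ``"error"`` (default) raises on interior missing years --
        periodograms of gapped series are ill-defined; ``"interpolate"``
        fills interior gaps linearly.

    Series shorter than 4 observed years return NaN.
    """
    v = np.asarray(values, dtype=float)
    # trim leading/trailing missing years
    obs = ~np.isnan(v)
    if obs.sum() < 4:
        return float("nan")
    first, last = np.flatnonzero(obs)[[0, -1]]
    v = v[first : last + 1]
    if np.isnan(v).any():
        if gap_policy == "interpolate":
            idx = np.arange(v.size)
            nan = np.isnan(v)
            v = v.copy()
            v[nan] = np.interp(idx[nan], idx[~nan], v[~nan])
        else:
            raise ValueError(
                "volatility_metric: interior missing years; pass "
                "gap_policy='interpolate' to fill linearly"
            )
    T = v.size
    y = v - v.mean()
    spec = np.abs(np.fft.rfft(y)[1 : T // 2 + 1]) ** 2 / T
    freqs = np.arange(1, T // 2 + 1) / T
    return float(2.0 / T * np.sum(freqs * spec))


def failure_metric(values) -> float:
    """Proportion of non-missing years with intensity exactly zero."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("failure_metric: all values missing")
    return float(np.mean(v == 0.0))


def synchrony_metric(matrix: pd.DataFrame, min_overlap: int = 3):
    """Pairwise-Pearson synchrony among conspecific trees.

    Parameters
    ----------
    matrix
        Tree x pheno-year intensity matrix (NaN = missing), one species.
    min_overlap
        Minimum shared non-missing years for a pair to count.

    Returns
    -------
    (per_tree, species_value) where ``per_tree`` is a Series of each
    tree's mean correlation with its conspecific partners and
    ``species_value`` is the mean over trees. Pairs involving a
    zero-variance series are skipped and logged; returns (empty, NaN)
    when no valid pair exists.
    """
    trees = list(matrix.index)
    pair_r: dict[str, list[float]] = {t: [] for t in trees}
    n_skipped = 0
    for a, b in combinations(trees, 2):
        xa = matrix.loc[a].to_numpy(dtype=float)
        xb = matrix.loc[b].to_numpy(dtype=float)
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        if ok.sum() < min_overlap:
            continue
        va, vb = xa[ok], xb[ok]
        if va.std() == 0.0 or vb.std() == 0.0:
            n_skipped += 1
            continue
        r = float(np.corrcoef(va, vb)[0, 1])
        pair_r[a].append(r)
        pair_r[b].append(r)
    if n_skipped:
        logger.info("synchrony: skipped %d zero-variance pairs", n_skipped)
    per_tree = pd.Series(
        {t: np.mean(rs) for t, rs in pair_r.items() if rs}, dtype=float
    )
    species = float(per_tree.mean()) if len(per_tree) else float("nan")
    return per_tree, species


def synchrony_pair_mean(matrix: pd.DataFrame, min_overlap: int = 3) -> float:
    """Species synchrony as the plain mean over unordered valid pairs."""
    rs = []
    for a, b in combinations(matrix.index, 2):
        xa = matrix.loc[a].to_numpy(dtype=float)
        xb = matrix.loc[b].to_numpy(dtype=float)
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        if ok.sum() < min_overlap:
            continue
        va, vb = xa[ok], xb[ok]
        if va.std() == 0.0 or vb.std() == 0.0:
            continue
        rs.append(float(np.corrcoef(va, vb)[0, 1]))
    return float(np.mean(rs)) if rs else float("nan")


@dataclass
class DOYSummary:
    """Circular day-of-year timing of the most intense phenological activity."""

    species: str
    phenophase: str
    mean_doy: float
    sd_doy: float
    window: tuple[float, float]
    diffuse: bool
    r_bar: float
    n: int


def circular_mean_sd_doy(doys) -> tuple[float, float, float]:
    """Circular mean, circular sd (days) and mean resultant length of DOYs.

    Angles are theta = 2*pi*doy/365; the circular sd is
    sqrt(-2 ln R_bar) * 365 / (2*pi).
    """
    theta = 2.0 * np.pi * np.asarray(doys, dtype=float) / DOY_MODULUS
    c, s = np.cos(theta).mean(), np.sin(theta).mean()
    r_bar = float(np.hypot(c, s))
    mean_doy = float(np.arctan2(s, c) % (2.0 * np.pi) * DOY_MODULUS / (2.0 * np.pi))
    if r_bar <= 0.0:
        return mean_doy, float("inf"), r_bar
    sd_doy = float(np.sqrt(max(-2.0 * np.log(r_bar), 0.0)) * DOY_MODULUS / (2.0 * np.pi))
    return mean_doy, sd_doy, r_bar


def circular_doy(
    table: pd.DataFrame,
    species: str,
    phenophase: str,
    r_floor: float = 0.05,
    window_k: float = 1.5,
) -> DOYSummary:
    """Timing summary of a species' phenophase on the 365-day circle.

    The qualifying set is all of the species' observations of the
    phenophase whose score strictly exceeds the species-phenophase mean
    score (zeros included in that mean), i.e. the most intense period of
    activity. Each qualifying observation is unweighted.

    A summary with mean resultant length below ``r_floor`` is flagged
    diffuse (activity spread around the whole year).
    """
    sub = table.loc[
        (table["species"] == species) & (table["phenophase"] == phenophase)
    ]
    if len(sub) == 0:
        raise ValueError(f"no observations for {species}/{phenophase}")
    threshold = sub["score"].mean()
    qual = sub.loc[sub["score"] > threshold]
    if len(qual) < 3:
        raise ValueError(
            f"{species}/{phenophase}: fewer than 3 observations above the "
            f"mean intensity {threshold:.3f}"
        )
    doys = _doy_365_vec(qual["date"])
    mean_doy, sd_doy, r_bar = circular_mean_sd_doy(doys)
    diffuse = r_bar < r_floor or 2 * window_k * sd_doy >= DOY_MODULUS
    lo = (mean_doy - window_k * sd_doy) % DOY_MODULUS
    hi = (mean_doy + window_k * sd_doy) % DOY_MODULUS
    return DOYSummary(
        species=species,
        phenophase=phenophase,
        mean_doy=mean_doy,
        sd_doy=sd_doy,
        window=(lo, hi),
        diffuse=bool(diffuse),
        r_bar=r_bar,
        n=len(qual),
    )


def doy_table(
    table: pd.DataFrame, phenophases=PHENOPHASES, r_floor: float = 0.05
) -> pd.DataFrame:
    """DOY timing summaries for every species x phenophase with enough data."""
    rows = []
    for species in sorted(table["species"].unique()):
        for ph in phenophases:
            try:
                s = circular_doy(table, species, ph, r_floor=r_floor)
            except ValueError as exc:
                logger.info("doy_table: skipping %s/%s (%s)", species, ph, exc)
                continue
            rows.append(
                {
                    "species": s.species,
                    "phenophase": s.phenophase,
                    "mean_doy": s.mean_doy,
                    "sd_doy": s.sd_doy,
                    "window_lo": s.window[0],
                    "window_hi": s.window[1],
                    "diffuse": s.diffuse,
                }
            )
    return pd.DataFrame(rows)


def _species_metrics_row(
    matrix: pd.DataFrame, gap_policy: str, aggregation: str
) -> dict:
    """All five metrics for one species x phenophase intensity matrix."""

    def per_tree(fn, **kw):
        vals = []
        for t in matrix.index:
            row = matrix.loc[t].to_numpy(dtype=float)
            if np.all(np.isnan(row)):
                continue
            try:
                vals.append(fn(row, **kw))
            except ValueError as exc:
                logger.info("metric %s skipped tree %s: %s", fn.__name__, t, exc)
        return float(np.nanmean(vals)) if vals else float("nan")

    if aggregation == "pooled":
        pooled = matrix.mean(axis=0, skipna=True).to_numpy(dtype=float)
        intensity = intensity_metric(pooled)
        cv = cv_metric(pooled)
        volatility = volatility_metric(pooled, gap_policy=gap_policy)
        failures = failure_metric(pooled)
    else:
        intensity = per_tree(intensity_metric)
        cv = per_tree(cv_metric)
        volatility = per_tree(volatility_metric, gap_policy=gap_policy)
        failures = per_tree(failure_metric)
    _, synchrony = synchrony_metric(matrix)
    return {
        "intensity": intensity,
        "cv": cv,
        "volatility": volatility,
        "synchrony": synchrony,
        "failures": failures,
    }


def metrics_table(
    table: pd.DataFrame,
    roster: pd.DataFrame,
    phenophases=("flower", "fruit"),
    min_months: int = 6,
    gap_policy: str = "interpolate",
    aggregation: str = "tree_mean",
    cv_flag: float = 1.0,
    sync_flag: float = 0.2,
) -> pd.DataFrame:
    """Species x phenophase table of the five masting metrics plus flags.

    ``cv_gt_1`` and ``sync_gt_0.2`` are the conventional masting
    diagnosis flags (thresholds configurable).
    """
    rows = []
    for ph in phenophases:
        annual = annualize(table, roster, ph, min_months=min_months)
        for species, grp in annual.groupby("species"):
            matrix = annual_series_matrix(grp)
            row = _species_metrics_row(matrix, gap_policy, aggregation)
            row.update(
                species=species,
                phenophase=ph,
                cv_gt_1=bool(row["cv"] > cv_flag) if np.isfinite(row["cv"]) else False,
                **{
                    "sync_gt_0.2": bool(row["synchrony"] > sync_flag)
                    if np.isfinite(row["synchrony"])
                    else False
                },
            )
            rows.append(row)
    cols = ["species", "phenophase", *METRIC_NAMES, "cv_gt_1", "sync_gt_0.2"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["phenophase", "species"], ignore_index=True
    )


@dataclass
class PCAResult:
    """Principal components of the standardized species-mean metrics."""

    loadings: pd.DataFrame  # metrics x components
    scores: pd.DataFrame  # species x components
    variance_explained: np.ndarray
    dropped_metrics: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "loadings": {c: self.loadings[c].to_dict() for c in self.loadings},
            "scores": {c: self.scores[c].to_dict() for c in self.scores},
            "variance_explained": [float(v) for v in self.variance_explained],
            "dropped_metrics": self.dropped_metrics,
        }


def pca_metrics(metrics: pd.DataFrame, phenophase: str) -> PCAResult:
    """PCA of species-mean masting metrics (correlation-matrix scaling).

    Columns are centred and scaled to unit (sample) variance before the
    decomposition, so component variances are eigenvalues of the metric
    correlation matrix. Species with any missing metric are dropped with
    a log message; constant metric columns are dropped with a warning.
    """
    sub = metrics.loc[metrics["phenophase"] == phenophase].set_index("species")
    X = sub[list(METRIC_NAMES)].astype(float)
    complete = X.notna().all(axis=1)
    if (~complete).any():
        logger.info(
            "pca_metrics(%s): dropping incomplete species %s",
            phenophase, list(X.index[~complete]),
        )
    X = X.loc[complete]
    if len(X) < 3:
        raise ValueError("pca_metrics: need >= 3 species with complete metrics")
    sd = X.std(ddof=1)
    constant = sd[sd == 0.0].index.tolist()
    if constant:
        warnings.warn(f"pca_metrics: dropping constant metric columns {constant}", stacklevel=2)
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    Z = (X - X.mean()) / sd
    u, s, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    eigvals = s**2 / (len(X) - 1)
    var_exp = eigvals / eigvals.sum()
    pcs = [f"PC{i+1}" for i in range(len(s))]
    loadings = pd.DataFrame(vt.T, index=X.columns, columns=pcs)
    scores = pd.DataFrame(u * s, index=X.index, columns=pcs)
    return PCAResult(
        loadings=loadings,
        scores=scores,
        variance_explained=var_exp,
        dropped_metrics=constant,
    )
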
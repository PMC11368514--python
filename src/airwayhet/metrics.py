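"""Per-subject caliber summaries and their cohort-level description.

A subject's 19 percent-predicted lumen diameters are reduced to

* **mean airway tree caliber** — the arithmetic (default) or geometric mean
  of the percent-predicted values; an index of dysanapsis;
* **airway tree caliber heterogeneity** — the sample standard deviation
  (denominator n-1) of the same values;
* **CoV** — heterogeneity divided by mean caliber, a single ratio measure.

Cohort-level helpers: quartile coding of a summary statistic (lowest
quartile = reference group Q1), a Gaussian kernel density of the pooled
percent-predicted distribution, and the Spearman correlation between
heterogeneity and mean caliber with a Fisher-z confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateExposureError,
    InsufficientSitesError,
    ProfileError,
    UndefinedCorrelationError,
)
from .sites import AIRWAY_SITES, N_SITES, validate_site


@dataclass(frozen=True)
class CaliberProfile:
    """A subject's percent-predicted lumen diameters by airway site.

    ``values`` maps each site label to a percent-predicted diameter (%);
    sites without a measurement are simply absent. All stored values are
    strictly positive.
    """

    subject_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for site, v in self.values.items():
            validate_site(site)
            if not np.isfinite(v) or v <= 0:
                raise ProfileError(
                    f"percent-predicted value at site {site!r} must be a "
                    f"positive finite number, got {v!r}"
                )
        if len(self.values) == 0:
            raise ProfileError(
                f"subject {self.subject_id!r}: profile has no measured sites"
            )

    @property
    def n_sites(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        """Values in canonical site order (measured sites only)."""
        return np.array(
            [self.values[s] for s in AIRWAY_SITES if s in self.values]
        )


@dataclass(frozen=True)
class CaliberSummary:
    """Mean caliber, heterogeneity SD and CoV of one profile."""

    subject_id: str
    mean_caliber: float
    heterogeneity_sd: float
    cov: float
    mean_kind: str
    n_sites: int


def summarize_profile(
    profile: CaliberProfile,
    mean_kind: str = "arithmetic",
    min_sites: int = N_SITES,
) -> CaliberSummary:
    """Reduce a percent-predicted profile to mean / SD / CoV.

    The heterogeneity SD always uses the sample (n-1) denominator. The CoV
    is ``heterogeneity_sd / mean_caliber`` for whichever mean kind is
    requested; the exact identity ``cov * mean == sd`` holds for the
    arithmetic mean.

    Raises
    ------
    InsufficientSitesError
        If fewer than ``min_sites`` sites are measured, or if only one is
        (the SD is then undefined).
    """
    if mean_kind not in ("arithmetic", "geometric"):
        raise ValueError(f"mean_kind must be arithmetic|geometric, got {mean_kind!r}")
    n = profile.n_sites
    if n < min_sites:
        raise InsufficientSitesError(
            f"subject {profile.subject_id!r}: {n} measured sites < "
            f"required minimum {min_sites}"
        )
    if n == 1:
        raise InsufficientSitesError(
            f"subject {profile.subject_id!r}: SD undefined for a single site"
        )
    x = profile.as_array()
    sd = float(np.std(x, ddof=1))
    if mean_kind == "arithmetic":
        mean = float(np.mean(x))
    else:
        mean = float(np.exp(np.mean(np.log(x))))
    return CaliberSummary(
        subject_id=profile.subject_id,
        mean_caliber=mean,
        heterogeneity_sd=sd,
        cov=sd / mean,
        mean_kind=mean_kind,
        n_sites=n,
    )


def summarize_cohort(
    percent_predicted: pd.DataFrame,
    mean_kind: str = "arithmetic",
    min_sites: int = N_SITES,
) -> pd.DataFrame:
    """Vectorised profile summaries for a cohort.

    ``percent_predicted`` has one row per subject (index = subject id) and
    one column per airway site; missing sites are NaN. Returns a frame with
    columns ``mean_caliber, heterogeneity_sd, cov, n_sites`` indexed like
    the input. Agrees exactly with :func:`summarize_profile` row by row.
    """
    cols = [c for c in percent_predicted.columns if c in AIRWAY_SITES]
    vals = percent_predicted[cols].to_numpy(dtype=float)
    n_sites = np.sum(np.isfinite(vals), axis=1)
    bad = n_sites < max(min_sites, 2)
    if np.any(bad):
        which = percent_predicted.index[bad][:5].tolist()
        raise InsufficientSitesError(
            f"{int(bad.sum())} subjects have fewer than "
            f"{max(min_sites, 2)} measured sites (e.g. {which})"
        )
    if np.any(vals[np.isfinite(vals)] <= 0):
        raise ProfileError("percent-predicted values must be strictly positive")
    sd = np.nanstd(vals, axis=1, ddof=1)
    if mean_kind == "arithmetic":
        mean = np.nanmean(vals, axis=1)
    elif mean_kind == "geometric":
        mean = np.exp(np.nanmean(np.log(vals), axis=1))
    else:
        raise ValueError(f"mean_kind must be arithmetic|geometric, got {mean_kind!r}")
    return pd.DataFrame(
        {
            "mean_caliber": mean,
            "heterogeneity_sd": sd,
            "cov": sd / mean,
            "n_sites": n_sites,
        },
        index=percent_predicted.index,
    )


def assign_quartiles(values) -> np.ndarray:
    """Label each value Q1..Q4 by sample quartile (Q1 = lowest, reference).

    Cut points are the 25/50/75th percentiles under the linear-interpolation
    quantile definition. Intervals are closed on the left: a value exactly
    equal to a cut point joins the lower group.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise DegenerateExposureError(
            f"need >=8 values to form quartiles, got {x.size}"
        )
    if np.all(x == x[0]):
        raise DegenerateExposureError("all values identical; quartiles undefined")
    cuts = np.quantile(x, [0.25, 0.5, 0.75])
    idx = np.searchsorted(cuts, x, side="left")
    labels = np.array(["Q1", "Q2", "Q3", "Q4"])
    return labels[idx]


@dataclass(frozen=True)
class DensityCurve:
    """Gaussian kernel density estimate of pooled percent-predicted values."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    n = x.size
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return float(0.9 * scale * n ** (-0.2))


def density_curve(values, bandwidth: float | None = None, n_grid: int = 512) -> DensityCurve:
    """Gaussian-kernel density on a grid spanning [min-3h, max+3h].

    Each observation contributes a Normal(x_i, h^2) kernel with equal weight
    1/n; with the 3-bandwidth margin the trapezoidal integral over the grid
    is 1 to within ~0.3%.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.all(x == x[0]):
        raise DegenerateExposureError(
            "kernel density needs >=2 distinct values (bandwidth would be 0)"
        )
    h = float(bandwidth) if bandwidth is not None else silverman_bandwidth(x)
    if h <= 0:
        raise DegenerateExposureError(f"bandwidth must be positive, got {h}")
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, n_grid)
    z = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))
    return DensityCurve(grid=grid, density=dens, bandwidth=h)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def spearman_with_ci(x, y, alpha: float = 0.05) -> SpearmanResult:
    """Spearman rank correlation with a Fisher-z confidence interval.

    Midranks handle ties. The CI and two-sided p use the Fisher transform
    z = atanh(rho) with the rank-correlation variance adjustment
    1.06/(n-3) (Fieller-Hartley-Pearson).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need n >= 4 for a Spearman CI, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("constant input; correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    se = np.sqrt(1.06 / (n - 3))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    # atanh is infinite at |rho| = 1 (perfect monotone agreement): the CI
    # degenerates to the point and p to 0.
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    z = np.arctanh(rho_c)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    if abs(rho) == 1.0:
        lo, hi, p = rho, rho, 0.0
    else:
        p = float(2 * stats.norm.sf(abs(z) / se))
    return SpearmanResult(rho=rho, ci_low=float(lo), ci_high=float(hi), p_value=p, n=n)


def distribution_report(values) -> dict[str, float]:
    """Descriptive skewness/kurtosis report for visual Gaussianity checks."""
    x = np.asarray(values, dtype=float)
    return {
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "skewness": float(stats.skew(x)),
        "excess_kurtosis": float(stats.kurtosis(x)),
    }
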
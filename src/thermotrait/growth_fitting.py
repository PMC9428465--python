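"""Logistic growth-curve fitting for plate-reader OD600 time series.

Microbial batch growth in a well is summarised by the logistic model

    N(t) = K / (1 + A e^{-r t}),    A = (K - N0) / N0,

with carrying capacity ``K`` (OD600), initial biomass ``N0`` (OD600) and
exponential growth rate ``r`` (h^-1).  Wells are first blank-corrected
(subtracting the mean OD of medium-only wells at the matching temperature
and nearest time point), each (taxon, temperature, replicate) series is
fitted by bounded non-linear least squares from multiple random starts, and
rates are averaged over technical replicates per taxon x temperature.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

#: Column order of a tidy plate-series table.
PLATE_COLUMNS = ["taxon", "temp_c", "replicate", "time_h", "od600", "is_blank"]

#: Replicates whose blank-corrected OD never reaches this value are treated
#: as non-growing (signal indistinguishable from baseline drift) and are
#: excluded from rate averaging rather than given a meaningless rate.
MIN_GROWTH_OD = 0.05


class BlankCorrectionError(ValueError):
    """Raised when a temperature group has no blank wells to correct against."""


class UnidentifiableSeriesError(ValueError):
    """Raised for series that cannot constrain the logistic parameters."""


def logistic_od(time_h, r_per_h: float, carrying_k: float, n0: float):
    """Logistic biomass N(t) = K / (1 + A e^{-rt}) with A = (K - N0)/N0."""
    t = np.asanyarray(time_h, dtype=float)
    a = (carrying_k - n0) / n0
    return carrying_k / (1.0 + a * np.exp(-r_per_h * t))


@dataclasses.dataclass(frozen=True)
class LogisticFit:
    """Least-squares logistic parameters for one well series."""

    r_per_h: float
    K: float
    N0: float
    rss: float
    n_points: int
    converged: bool

    @property
    def A(self) -> float:
        """Derived shape parameter (K - N0)/N0."""
        return (self.K - self.N0) / self.N0

    def predict(self, time_h):
        return logistic_od(time_h, self.r_per_h, self.K, self.N0)


def blank_correct(plate: pd.DataFrame) -> pd.DataFrame:
    """Subtract mean blank OD from sample wells, per temperature.

    For every non-blank record, the mean OD of the blank wells at the same
    temperature and the nearest blank time point is subtracted; corrected
    values are floored at 0.  Blank records are removed from the output.

    Raises
    ------
    BlankCorrectionError
        If any temperature present in the samples has no blank wells.
    """
    plate = plate.copy()
    blanks = plate[plate["is_blank"].astype(bool)]
    samples = plate[~plate["is_blank"].astype(bool)]
    missing = sorted(set(samples["temp_c"]) - set(blanks["temp_c"]))
    if missing:
        raise BlankCorrectionError(
            f"no blank wells at temperature(s) {missing} degC"
        )
    out = []
    for temp, sub in samples.groupby("temp_c", sort=True):
        blank_mean = (
            blanks[blanks["temp_c"] == temp]
            .groupby("time_h")["od600"].mean().sort_index()
        )
        b_times = blank_mean.index.to_numpy(dtype=float)
        b_vals = blank_mean.to_numpy(dtype=float)
        idx = np.searchsorted(b_times, sub["time_h"].to_numpy(dtype=float))
        idx = np.clip(idx, 1, len(b_times) - 1) if len(b_times) > 1 else np.zeros(
            len(sub), dtype=int)
        if len(b_times) > 1:
            left = b_times[idx - 1]
            right = b_times[idx]
            t = sub["time_h"].to_numpy(dtype=float)
            idx = np.where(np.abs(t - left) <= np.abs(right - t), idx - 1, idx)
        corrected = sub["od600"].to_numpy(dtype=float) - b_vals[idx]
        sub = sub.copy()
        sub["od600"] = np.maximum(corrected, 0.0)
        out.append(sub)
    result = pd.concat(out, ignore_index=True)
    return result[PLATE_COLUMNS]


def _heuristic_start(times, od):
    """Moment-style initial guess: K from the max OD, r from early log-slope."""
    od_pos = od[od > 0]
    k0 = float(od.max())
    n0 = float(od_pos.min()) if od_pos.size else 1e-3
    n0 = min(n0, 0.9 * k0)
    # crude exponential-phase slope on the first half of positive points
    mask = od > 0
    if mask.sum() >= 2:
        t_e, y_e = times[mask], np.log(od[mask])
        half = max(2, mask.sum() // 2)
        slope = np.polyfit(t_e[:half], y_e[:half], 1)[0]
        r0 = float(np.clip(slope, 0.02, 3.0))
    else:
        r0 = 0.5
    return np.array([r0, k0, n0 / k0])


def fit_logistic(
    times: Sequence[float],
    od: Sequence[float],
    n_starts: int = 50,
    seed=0,
) -> LogisticFit:
    """Fit the logistic model to one OD600 time series.

    The series is fitted with parameters ``(r, K, f)`` where ``N0 = f K``
    and ``f`` is box-bounded in (0, 1): this enforces ``K > N0 > 0`` exactly,
    and ``r > 0`` is enforced by its own bound.  One moment-based start plus
    ``n_starts`` random starts (r uniform in 0.01-3 h^-1, K in 0.5-2x the
    max OD, N0 up to 2x the smallest positive OD) are run; the lowest-RSS
    converged solution is kept.

    Raises
    ------
    UnidentifiableSeriesError
        For constant series or series without at least two distinct times.
    ValueError
        For fewer than 4 points, negative times, or non-finite ODs.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and od must be equal-length 1-D sequences")
    if t.size < 4:
        raise ValueError(f"need >=4 time points, have {t.size}")
    if np.any(t < 0):
        raise ValueError("negative time values")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(t)):
        raise ValueError("non-finite values in series")
    if np.unique(y).size < 2:
        raise UnidentifiableSeriesError("constant OD series cannot be fitted")
    if np.unique(t).size < 2:
        raise UnidentifiableSeriesError("need at least two distinct time points")

    od_max = float(y.max())
    od_min_pos = float(y[y > 0].min()) if np.any(y > 0) else 1e-4

    # fit in (r, K, f) with N0 = f*K
    def residuals(theta):
        r, k, f = theta
        return logistic_od(t, r, k, f * k) - y

    lo = np.array([1e-6, max(od_max * 0.05, 1e-8), 1e-9])
    hi = np.array([20.0, od_max * 5.0 + 1e-6, 1.0 - 1e-9])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = [_heuristic_start(t, y)]
    r_s = rng.uniform(0.01, 3.0, n_starts)
    k_s = rng.uniform(0.5, 2.0, n_starts) * od_max
    n0_s = rng.uniform(1e-4, 2.0 * od_min_pos, n_starts)
    for i in range(n_starts):
        starts.append(np.array([r_s[i], k_s[i], min(n0_s[i] / k_s[i], 0.999)]))

    best = None
    any_success = False
    for theta0 in starts:
        theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)
        try:
            res = optimize.least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=400,
            )
        except Exception:  # pragma: no cover
            continue
        rss = float(np.sum(res.fun ** 2))
        any_success = any_success or bool(res.success)
        if res.success and (best is None or rss < best[0]):
            best = (rss, res.x.copy())
    if best is None:
        return LogisticFit(np.nan, np.nan, np.nan, np.inf, t.size, False)
    rss, (r, k, f) = best
    return LogisticFit(
        r_per_h=float(r), K=float(k), N0=float(f * k),
        rss=rss, n_points=int(t.size), converged=True,
    )


def growth_rate_table(
    plate: pd.DataFrame,
    n_starts: int = 50,
    seed: int = 0,
    min_growth_od: float = MIN_GROWTH_OD,
) -> pd.DataFrame:
    """Fit every (taxon, temperature, replicate) series and average r per group.

    The input must already be blank-corrected (no blank rows).  Replicates
    whose fit fails, or whose corrected OD never exceeds ``min_growth_od``
    (no measurable growth, so the rate is noise), are excluded and logged
    with a reason code.  Groups where every replicate is excluded are
    emitted with a missing rate and a warning.

    Returns a DataFrame ``taxon, temp_c, mean_r_per_h, n_reps_used``.
    """
    if plate["is_blank"].astype(bool).any():
        raise ValueError("plate contains blank rows; run blank_correct first")
    rows = []
    grouped = plate.groupby(["taxon", "temp_c"], sort=True)
    for gi, ((taxon, temp), group) in enumerate(grouped):
        rates = []
        for replicate, series in group.groupby("replicate", sort=True):
            series = series.sort_values("time_h")
            od_max = float(series["od600"].max())
            if od_max < min_growth_od:
                logger.info("excluding %s @%s degC rep %s: no_growth "
                            "(max OD %.3g)", taxon, temp, replicate, od_max)
                continue
            try:
                fit = fit_logistic(
                    series["time_h"].to_numpy(), series["od600"].to_numpy(),
                    n_starts=n_starts,
                    seed=np.random.default_rng(
                        np.random.SeedSequence(entropy=seed,
                                               spawn_key=(gi, int(replicate)))
                    ),
                )
            except (UnidentifiableSeriesError, ValueError) as exc:
                logger.info("excluding %s @%s degC rep %s: unfittable (%s)",
                            taxon, temp, replicate, exc)
                continue
            if not fit.converged:
                logger.info("excluding %s @%s degC rep %s: no_convergence",
                            taxon, temp, replicate)
                continue
            rates.append(fit.r_per_h)
        if not rates:
            logger.warning("all replicates excluded for %s @%s degC; "
                           "emitting missing rate", taxon, temp)
            rows.append({"taxon": taxon, "temp_c": temp,
                         "mean_r_per_h": np.nan, "n_reps_used": 0})
        else:
            rows.append({"taxon": taxon, "temp_c": temp,
                         "mean_r_per_h": float(np.mean(rates)),
                         "n_reps_used": len(rates)})
    return pd.DataFrame(rows)
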
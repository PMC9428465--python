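"""Sharpe-Schoolfield thermal performance curves and derived thermal traits.

A thermal performance curve (TPC) describes how a fitness component — here
the exponential population growth rate ``r`` (h^-1) of a bacterial isolate —
changes with temperature: an approximately Boltzmann-Arrhenius rise up to an
optimum, followed by a sharp decline driven by temperature-induced enzyme
inactivation.  The high-temperature-deactivation Sharpe-Schoolfield model
parameterises this on the log scale as

    ln r(T) = E_a * (1/(k*T_c) - 1/(k*T)) + ln r(T_c)
              - ln(1 + exp(E_h * (1/(k*T_h) - 1/(k*T))))

with temperatures in Kelvin, the Boltzmann constant ``k`` in eV/K, the
activation energy ``E_a`` (eV) setting the steepness of the rising limb, the
deactivation energy ``E_h`` (eV) the steepness of the falling limb, ``T_h``
(K) the temperature at which half the enzyme pool is inactivated, and
``r(T_c)`` the rate at a reference temperature ``T_c`` (18 degC here).

Setting the temperature derivative to zero gives the closed-form optimum

    T_opt = E_h * T_h / (E_h + k * T_h * ln(E_h/E_a - 1)),

defined whenever ``E_h > E_a > 0``.

Curves are fitted to ln-rate data by non-linear least squares from many
random starting points, retaining the converged fit with the lowest AIC.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

#: Boltzmann constant in eV per Kelvin, the value conventional in metabolic
#: ecology (4 significant figures: 8.617e-5; the rounded 8.62e-5 is standard
#: in the TPC literature and is used throughout this package).
BOLTZMANN_EV_PER_K: float = 8.62e-5

ZERO_C_IN_K: float = 273.15

#: Default reference temperature for r(T_c): 18 degC.
DEFAULT_TREF_C: float = 18.0


class InsufficientDataError(ValueError):
    """Raised when too few usable (temperature, rate) pairs remain to fit."""


class TPCFitError(RuntimeError):
    """Raised when no random restart converges to a valid fit.

    Carries the diagnostics of the best attempt (if any) in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def to_kelvin(temp_c):
    """Convert Celsius to Kelvin (array-aware)."""
    return np.asanyarray(temp_c, dtype=float) + ZERO_C_IN_K


def to_celsius(temp_k):
    """Convert Kelvin to Celsius (array-aware)."""
    return np.asanyarray(temp_k, dtype=float) - ZERO_C_IN_K


def sharpe_schoolfield_ln_rate(
    temp_c,
    ea_ev: float,
    eh_ev: float,
    th_k: float,
    ln_r_tc: float,
    tc_k: float = DEFAULT_TREF_C + ZERO_C_IN_K,
):
    """Evaluate the Sharpe-Schoolfield model, returning ln r(T).

    Parameters
    ----------
    temp_c
        Temperature(s) in degrees Celsius (must exceed absolute zero).
    ea_ev, eh_ev
        Activation / deactivation energies in eV.
    th_k
        Half-inactivation temperature in Kelvin.
    ln_r_tc
        Natural log of the growth rate at the reference temperature.
    tc_k
        Reference temperature in Kelvin (default 291.15 K = 18 degC).

    Notes
    -----
    The inactivation term ``ln(1 + exp(x))`` is evaluated as
    ``logaddexp(0, x)`` so the expression stays finite for arbitrarily large
    exponents (far above ``T_h`` the raw ``exp`` would overflow).
    """
    t_k = to_kelvin(temp_c)
    if np.any(t_k <= 0):
        raise ValueError("temperature below absolute zero")
    k = BOLTZMANN_EV_PER_K
    rise = ea_ev * (1.0 / (k * tc_k) - 1.0 / (k * t_k)) + ln_r_tc
    inactivation = np.logaddexp(0.0, eh_ev * (1.0 / (k * th_k) - 1.0 / (k * t_k)))
    return rise - inactivation


def compute_topt(ea_ev: float, eh_ev: float, th_k: float) -> float:
    """Closed-form optimum temperature of the Sharpe-Schoolfield TPC, in Kelvin.

    ``T_opt = E_h T_h / (E_h + k T_h ln(E_h/E_a - 1))``.  The caller converts
    to Celsius by subtracting 273.15.

    Raises
    ------
    ValueError
        If ``E_h <= E_a`` (the log argument is non-positive and no interior
        maximum exists) or if ``E_a`` or ``T_h`` is non-positive.
    """
    if not (ea_ev > 0.0):
        raise ValueError(f"E_a must be positive, got {ea_ev}")
    if not (th_k > 0.0):
        raise ValueError(f"T_h must be positive, got {th_k}")
    if not (eh_ev > ea_ev):
        raise ValueError(
            f"T_opt requires E_h > E_a (got E_h={eh_ev}, E_a={ea_ev})"
        )
    k = BOLTZMANN_EV_PER_K
    return eh_ev * th_k / (eh_ev + k * th_k * np.log(eh_ev / ea_ev - 1.0))


def aic_from_rss(rss: float, n_points: int, n_params: int) -> float:
    """AIC of a Gaussian-error least-squares fit from its residual sum of squares.

    ``AIC = n ln(rss/n) + 2 (p + 1)`` — the error variance counts as the
    extra parameter.  A zero ``rss`` (perfect fit) returns ``-inf`` with a
    warning rather than raising, so that exact synthetic data can still be
    ranked.
    """
    if n_points <= n_params:
        raise ValueError("need more points than parameters for an AIC")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0.0:
        warnings.warn("rss is exactly zero; AIC is -inf", RuntimeWarning, stacklevel=2)
        return -np.inf
    return n_points * np.log(rss / n_points) + 2.0 * (n_params + 1)


def quasi_r2(observed, fitted) -> float:
    """1 - SS_res/SS_tot on whatever scale the inputs share (here: ln rate).

    Returns NaN (with a warning) when the observations have zero variance.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero total variance; quasi-r2 undefined", RuntimeWarning,
                      stacklevel=2)
        return np.nan
    ss_res = float(np.sum((obs - fit) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclasses.dataclass(frozen=True)
class TPCFit:
    """A fitted Sharpe-Schoolfield curve plus derived traits and diagnostics.

    ``restart_aics`` holds the AIC of every converged, valid (``E_h > E_a``)
    restart, so the minimum-AIC retention rule is assertable after the fact.
    """

    taxon_id: str
    ea_ev: float
    eh_ev: float
    th_k: float
    ln_r_tc: float
    tc_k: float
    topt_c: float
    aic: float
    quasi_r2: float
    n_temps_used: int
    rss: float
    restart_aics: tuple = ()
    n_converged: int = 0
    excluded_temps_c: tuple = ()
    k_ev_per_k: float = BOLTZMANN_EV_PER_K

    def ln_rate(self, temp_c):
        """ln r(T) of the fitted curve at temperature(s) in Celsius."""
        return sharpe_schoolfield_ln_rate(
            temp_c, self.ea_ev, self.eh_ev, self.th_k, self.ln_r_tc, self.tc_k
        )

    def rate(self, temp_c):
        """r(T) in h^-1 of the fitted curve at temperature(s) in Celsius."""
        return np.exp(self.ln_rate(temp_c))


def eval_ln_rate(fit: TPCFit, temp_c):
    """Evaluate a fitted TPC's ln-rate at temperature(s) in Celsius."""
    return fit.ln_rate(temp_c)


def _draw_starts(rng, n_starts, t_k_min, t_k_max, y_min, y_max):
    """Uniform random starting points; Eh <= Ea draws are rejected and redrawn."""
    starts = np.empty((n_starts, 4))
    starts[:, 0] = rng.uniform(0.05, 2.0, n_starts)          # Ea (eV)
    starts[:, 1] = rng.uniform(0.2, 10.0, n_starts)          # Eh (eV)
    starts[:, 2] = rng.uniform(t_k_min, t_k_max + 20.0, n_starts)  # Th (K)
    starts[:, 3] = rng.uniform(y_min - 2.0, y_max + 2.0, n_starts)  # ln r(Tc)
    bad = starts[:, 1] <= starts[:, 0]
    while np.any(bad):
        n_bad = int(bad.sum())
        starts[bad, 0] = rng.uniform(0.05, 2.0, n_bad)
        starts[bad, 1] = rng.uniform(0.2, 10.0, n_bad)
        bad = starts[:, 1] <= starts[:, 0]
    return starts


def fit_tpc(
    temps_c: Sequence[float],
    rates_per_h: Sequence[float],
    n_starts: int = 1000,
    seed=None,
    tref_c: float = DEFAULT_TREF_C,
    taxon_id: str = "",
    max_nfev: int = 500,
) -> TPCFit:
    """Fit the Sharpe-Schoolfield model to growth rates across temperature.

    The fit minimises squared residuals of ``ln(rate)`` against the model by
    trust-region-reflective least squares from ``n_starts`` random starting
    points drawn uniformly (activation energy 0.05-2 eV, deactivation energy
    0.2-10 eV, half-inactivation temperature spanning the assay range plus
    20 K, reference ln-rate within 2 log units of the data range); the
    converged fit with the lowest AIC — among fits satisfying ``E_h > E_a``,
    which the closed-form optimum requires — is retained.

    Pairs with non-positive rate are excluded before fitting (the response is
    a logarithm); the excluded temperatures are recorded on the result and
    logged.  At least 5 usable pairs with distinct temperatures are required.

    Parameters
    ----------
    temps_c, rates_per_h
        Assay temperatures (Celsius) and the growth rates (h^-1) measured
        there, typically replicate means.
    n_starts
        Number of random restarts.
    seed
        Integer seed or ``numpy.random.Generator``; fixes the restart draw.
    tref_c
        Reference temperature for ``r(T_c)`` in Celsius (default 18).
    """
    temps = np.asarray(temps_c, dtype=float)
    rates = np.asarray(rates_per_h, dtype=float)
    if temps.shape != rates.shape or temps.ndim != 1:
        raise ValueError("temps_c and rates_per_h must be equal-length 1-D")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    usable = np.isfinite(rates) & (rates > 0.0) & np.isfinite(temps)
    excluded = tuple(np.sort(temps[~usable]).tolist())
    if excluded:
        logger.info(
            "fit_tpc[%s]: excluding %d temperature(s) with non-positive or "
            "missing rate: %s", taxon_id, len(excluded), excluded
        )
    temps, rates = temps[usable], rates[usable]
    if np.unique(temps).size != temps.size:
        raise ValueError("assay temperatures must be distinct")
    if temps.size < 5:
        raise InsufficientDataError(
            f"need >=5 usable (temperature, rate) pairs, have {temps.size}"
        )

    order = np.argsort(temps)
    temps, rates = temps[order], rates[order]
    y = np.log(rates)
    tc_k = tref_c + ZERO_C_IN_K
    t_k = to_kelvin(temps)

    def residuals(theta):
        ea, eh, th, lrtc = theta
        return sharpe_schoolfield_ln_rate(temps, ea, eh, th, lrtc, tc_k) - y

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = _draw_starts(rng, n_starts, float(t_k.min()), float(t_k.max()),
                          float(y.min()), float(y.max()))
    lo = np.array([1e-4, 1e-4, 200.0, y.min() - 10.0])
    hi = np.array([12.0, 40.0, 500.0, y.max() + 10.0])
    starts = np.clip(starts, lo + 1e-9, hi - 1e-9)

    n = temps.size
    best = None  # (aic, theta, rss)
    restart_aics = []
    n_converged = 0
    best_attempt = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for theta0 in starts:
            try:
                res = optimize.least_squares(
                    residuals, theta0, bounds=(lo, hi), method="trf",
                    ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=max_nfev,
                )
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            rss = float(np.sum(res.fun ** 2))
            if best_attempt is None or rss < best_attempt["rss"]:
                best_attempt = {"rss": rss, "theta": res.x.tolist(),
                                "success": bool(res.success)}
            if not res.success:
                continue
            n_converged += 1
            if res.x[1] <= res.x[0]:  # Eh <= Ea: no interior optimum
                continue
            aic = aic_from_rss(rss, n, 4)
            restart_aics.append(aic)
            if best is None or aic < best[0]:
                best = (aic, res.x.copy(), rss)

    if best is None:
        raise TPCFitError(
            f"no restart converged to a valid (E_h > E_a) fit for {taxon_id!r}",
            diagnostics={"n_converged": n_converged, "best_attempt": best_attempt,
                         "n_starts": n_starts},
        )

    aic, theta, rss = best
    ea, eh, th, lrtc = (float(v) for v in theta)
    fitted = sharpe_schoolfield_ln_rate(temps, ea, eh, th, lrtc, tc_k)
    return TPCFit(
        taxon_id=taxon_id,
        ea_ev=ea,
        eh_ev=eh,
        th_k=th,
        ln_r_tc=lrtc,
        tc_k=tc_k,
        topt_c=float(to_celsius(compute_topt(ea, eh, th))),
        aic=float(aic),
        quasi_r2=float(quasi_r2(y, fitted)),
        n_temps_used=int(n),
        rss=float(rss),
        restart_aics=tuple(restart_aics),
        n_converged=n_converged,
        excluded_temps_c=excluded,
    )


def fit_tpc_table(rates_table, n_starts: int = 1000, seed=None,
                  tref_c: float = DEFAULT_TREF_C, max_nfev: int = 500):
    """Fit one TPC per taxon from a tidy growth-rate table.

    ``rates_table`` is a DataFrame with columns ``taxon, temp_c,
    mean_r_per_h`` (missing rates allowed; they are excluded per taxon).
    Returns ``(fits, table)``: a dict of ``TPCFit`` by taxon and a tidy
    DataFrame of the fitted traits.  Each taxon gets an independent
    deterministic substream of ``seed``.
    """
    import pandas as pd

    fits: dict[str, TPCFit] = {}
    rows = []
    taxa = sorted(rates_table["taxon"].unique())
    for i, taxon in enumerate(taxa):
        sub = rates_table[rates_table["taxon"] == taxon]
        child = np.random.default_rng(
            np.random.SeedSequence(entropy=0 if seed is None else int(seed),
                                   spawn_key=(i,))
        )
        try:
            fit = fit_tpc(
                sub["temp_c"].to_numpy(), sub["mean_r_per_h"].to_numpy(),
                n_starts=n_starts, seed=child, tref_c=tref_c,
                taxon_id=str(taxon), max_nfev=max_nfev,
            )
        except (InsufficientDataError, TPCFitError) as exc:
            logger.warning("fit_tpc_table: skipping %s (%s)", taxon, exc)
            continue
        fits[str(taxon)] = fit
        rows.append({
            "taxon": taxon, "ea_ev": fit.ea_ev, "eh_ev": fit.eh_ev,
            "th_k": fit.th_k, "ln_r_tc": fit.ln_r_tc, "topt_c": fit.topt_c,
            "aic": fit.aic, "quasi_r2": fit.quasi_r2,
            "n_temps_used": fit.n_temps_used,
        })
    return fits, pd.DataFrame(rows)
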
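"""Selective-sweep dynamics: subclone fixation, hitch-hiker spectra, selection fits.

Three deterministic trajectory models describe a subclone under selection in a
tumor of constant population size ``N``:

* **Fixation model** — a subclone growing at rate ratio ``s`` relative to the
  host tumor occupies fraction ``x(t) = e^{st} / (e^t + e^{st})`` at time
  ``t`` (generations), starting from equal sizes at ``t = 0``.
* **Adaptive trajectory** — a new beneficial variant that has escaped
  stochastic loss (established, at frequency ``~1/(2Ns)``) follows logistic
  growth ``n(t) = e^{st} / (e^{st} + 2Ns)``.
* **Hitch-hiker spectrum** — neutral passengers arising on the sweeping clone
  at rate ``mu`` per generation reach frequencies
  ``n_i(t) = e^{-mu t} (mu / (i s))^{1 - mu/s}`` for the ``i``-th passenger,
  ``i >= 1``.  A fast ("hard") sweep leaves fewer, rarer hitch-hikers than a
  slow ("soft") sweep stopped at the same driver frequency.

``estimate_selection`` inverts the spectrum: given a tumor's driver cancer
cell fraction and its subclonal passenger frequencies, it grid-searches the
fitness ``s`` whose predicted rank-frequency spectrum best matches the
observed one, and labels the sweep regime (HARD / SOFT / NEUTRAL).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .ccf import CCFRecord, CLONAL_THRESHOLD

__all__ = [
    "SweepParams",
    "SweepSpectrum",
    "SelectionEstimate",
    "SelectionFitConfig",
    "Regime",
    "subclone_fraction",
    "subclone_fraction_general",
    "fixation_grid",
    "establishment_frequency",
    "adaptive_frequency",
    "time_to_frequency",
    "passenger_frequency",
    "simulate_sweep_spectrum",
    "estimate_selection",
]


class Regime(str, Enum):
    HARD = "HARD"
    SOFT = "SOFT"
    NEUTRAL = "NEUTRAL"


@dataclass
class SweepParams:
    """Parameters of a selective sweep.

    s
        Fitness: ratio of subclone to host growth rates (> 0; 1 = neutral).
    N
        Constant population size in cells.
    mu
        Rate at which neutral passengers arise on the sweeping clone,
        per generation.
    t
        Time in generations.
    t_sc
        Generation at which the subclone arose.
    f0
        Initial subclone fraction at ``t_sc``.
    """

    s: float
    N: float = 1e6
    mu: float = 0.001
    t: float = 0.0
    t_sc: float = 0.0
    f0: float = 0.5

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"s must be positive, got {self.s}")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if not (0.0 < self.f0 < 1.0):
            raise ValueError(f"f0 must be in (0, 1), got {self.f0}")


@dataclass
class SweepSpectrum:
    """Driver frequency plus the ordered hitch-hiker frequencies at ``t_obs``."""

    driver_freq: float
    passenger_freqs: np.ndarray
    t_obs: float
    params: SweepParams


@dataclass
class SelectionEstimate:
    """Result of fitting the sweep model to one tumor's passenger spectrum."""

    s_hat: float | None
    mu_hat: float | None
    objective: float | None
    regime: Regime | None
    n_passengers_used: int
    flag: str | None = None


@dataclass
class SelectionFitConfig:
    """Grid and thresholds for :func:`estimate_selection`."""

    s_max: float = 5.0
    s_step: float = 0.01
    mu: float = 0.001
    mu_grid: Sequence[float] | None = None  # profile mu over this grid if set
    N: float = 1e6
    min_passengers: int = 5
    hard_cut: float = 1.5
    neutral_tol: float = 0.05
    clonal_threshold: float = CLONAL_THRESHOLD
    objective: str = "rank"  # "rank" (log rank-frequency SSE) or "binned"
    n_bins: int = 10


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def subclone_fraction(s: float, t: float) -> float:
    """Subclone fraction ``e^{st} / (e^t + e^{st})``, evaluated in log space.

    Algebraically ``1 / (1 + e^{(1-s)t})``: 0.5 at ``t = 0`` and for ``s = 1``
    at any time; sweeps to 1 for ``s > 1``.
    """
    return float(expit((s - 1.0) * t))


def subclone_fraction_general(s: float, t: float, t_sc: float = 0.0, f0: float = 0.5) -> float:
    """Subclone fraction for a clone arising at ``t_sc`` with initial fraction ``f0``.

    ``f0 e^{s(t - t_sc)} / ((1 - f0) e^{t - t_sc} + f0 e^{s(t - t_sc)})``;
    reduces to :func:`subclone_fraction` when ``f0 = 0.5`` and ``t_sc = 0``.
    """
    if t < t_sc:
        raise ValueError(f"t={t} precedes subclone origin t_sc={t_sc}")
    if not (0.0 < f0 < 1.0):
        raise ValueError(f"f0 must be in (0, 1), got {f0}")
    tau = t - t_sc
    # logit form keeps the expression stable for large s*tau
    return float(expit((s - 1.0) * tau + math.log(f0 / (1.0 - f0))))


def fixation_grid(
    s_values: Sequence[float],
    t_sc_values: Sequence[float],
    tumor_age: float,
    f0: float = 0.5,
    fixation_ccf: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Subclone fraction at ``tumor_age`` over an (s, t_sc) grid, plus fixation flags.

    Fixation is operationalized as subclone fraction strictly above
    ``fixation_ccf`` (the clonality threshold).  Returns ``(fractions,
    fixed)`` arrays of shape ``(len(s_values), len(t_sc_values))``.
    """
    if tumor_age <= max(t_sc_values):
        raise ValueError("tumor_age must exceed every subclone origin time")
    fractions = np.empty((len(s_values), len(t_sc_values)))
    for a, s in enumerate(s_values):
        for b, t_sc in enumerate(t_sc_values):
            fractions[a, b] = subclone_fraction_general(s, tumor_age, t_sc, f0)
    return fractions, fractions > fixation_ccf


def establishment_frequency(N: float, s: float) -> float:
    """Frequency ``1/(2Ns)`` beyond which a fit variant escapes stochastic loss."""
    if N * s <= 0:
        raise ValueError("N * s must be positive")
    return 1.0 / (2.0 * N * s)


def adaptive_frequency(s: float, t: float, N: float) -> float:
    """Logistic frequency ``e^{st} / (e^{st} + 2Ns)`` of an established driver."""
    if N * s <= 0:
        raise ValueError("N * s must be positive")
    return float(expit(s * t - math.log(2.0 * N * s)))


def time_to_frequency(
    freq: float, s: float, N: float, tol: float = 1e-10
) -> float:
    """Invert :func:`adaptive_frequency`: generations for the driver to reach ``freq``.

    Solved by bisection to ``tol``.  ``freq`` at or below the establishment
    frequency is unreachable from a positive time and raises.
    """
    f_start = adaptive_frequency(s, 0.0, N)
    if freq <= f_start:
        raise ValueError(
            f"frequency {freq} not above the starting frequency {f_start:.3g} "
            f"(~establishment 1/(2Ns))"
        )
    if freq >= 1.0:
        raise ValueError("frequency must be < 1 (asymptote)")
    hi = 1.0
    while adaptive_frequency(s, hi, N) < freq:
        hi *= 2.0
    return float(brentq(lambda t: adaptive_frequency(s, t, N) - freq, 0.0, hi, xtol=tol))


def passenger_frequency(i: int, t: float, s: float, mu: float) -> float:
    """Frequency of the ``i``-th hitch-hiker: ``e^{-mu t} (mu/(is))^{1 - mu/s}``.

    Valid for ``i >= 1`` and ``0 < mu <= s`` (beyond ``mu = s`` the exponent
    flips sign and the expression leaves the model's regime).  Clipped to
    [0, 1].
    """
    if i < 1:
        raise ValueError(f"passenger index i must be >= 1, got {i}")
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if mu > s:
        raise ValueError(f"mu={mu} > s={s}: outside the model's stated regime")
    log_val = -mu * t + (1.0 - mu / s) * (math.log(mu) - math.log(i * s))
    return float(np.clip(math.exp(log_val), 0.0, 1.0))


def passenger_spectrum(n: int, t: float, s: float, mu: float) -> np.ndarray:
    """Vectorized :func:`passenger_frequency` for ``i = 1..n``."""
    i = np.arange(1, n + 1, dtype=float)
    if mu <= 0 or mu > s:
        raise ValueError(f"require 0 < mu <= s, got mu={mu}, s={s}")
    log_val = -mu * t + (1.0 - mu / s) * (np.log(mu) - np.log(i * s))
    return np.clip(np.exp(log_val), 0.0, 1.0)


def simulate_sweep_spectrum(
    params: SweepParams,
    n_passengers: int,
    stop_at_driver_ccf: float,
    seed: int | None = None,
) -> SweepSpectrum:
    """Deterministic sweep spectrum at the time the driver reaches a target CCF.

    ``t_obs`` solves ``adaptive_frequency(s, t, N) = stop_at_driver_ccf``;
    passenger frequencies are evaluated at ``t_obs`` for ``i = 1..n``.  A
    requested CCF of 1 (the asymptote) is replaced by ``1 - 1e-9`` with a
    warning.  ``seed`` is accepted for interface symmetry with the noisy
    read-count layer; the spectrum itself is deterministic.
    """
    if not (0.0 < stop_at_driver_ccf <= 1.0):
        raise ValueError(f"stop_at_driver_ccf must be in (0, 1], got {stop_at_driver_ccf}")
    if stop_at_driver_ccf == 1.0:
        warnings.warn("driver CCF 1.0 is an asymptote; using 1 - 1e-9", stacklevel=2)
        stop_at_driver_ccf = 1.0 - 1e-9
    t_obs = time_to_frequency(stop_at_driver_ccf, params.s, params.N)
    freqs = passenger_spectrum(n_passengers, t_obs, params.s, params.mu)
    return SweepSpectrum(
        driver_freq=stop_at_driver_ccf,
        passenger_freqs=freqs,
        t_obs=t_obs,
        params=params,
    )


# ---------------------------------------------------------------------------
# selection-strength estimation
# ---------------------------------------------------------------------------


def _subclonal_ccfs(
    records: Sequence[CCFRecord] | Sequence[float] | np.ndarray,
    threshold: float,
) -> np.ndarray:
    if len(records) and isinstance(records[0], CCFRecord):
        vals = np.array(
            [r.ccf for r in records if r.ccf is not None], dtype=float
        )
    else:
        vals = np.asarray(records, dtype=float)
    return np.sort(vals[(vals > 0.0) & (vals <= threshold)])[::-1]


def _rank_objective(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared log-difference between observed and model rank spectra."""
    pred = np.clip(predicted, 1e-300, 1.0)
    return float(np.mean((np.log(observed) - np.log(pred)) ** 2))


def _binned_objective(
    observed: np.ndarray, predicted: np.ndarray, n_bins: int, alpha: float = 0.5
) -> float:
    """Negative multinomial log-likelihood of the observed CCF histogram.

    Bins are the ``n_bins`` equal bins on [0, 1] shared with the diversity
    index; expected bin mass comes from binning the model spectrum, with
    add-``alpha`` smoothing so empty model bins stay finite.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    obs_counts, _ = np.histogram(np.clip(observed, 0.0, 1.0), bins=edges)
    mod_counts, _ = np.histogram(np.clip(predicted, 0.0, 1.0), bins=edges)
    p = (mod_counts + alpha) / (mod_counts.sum() + alpha * n_bins)
    return float(-(obs_counts * np.log(p)).sum())


def estimate_selection(
    ccf_records: Sequence[CCFRecord] | Sequence[float] | np.ndarray,
    driver_ccf: float,
    config: SelectionFitConfig | None = None,
) -> SelectionEstimate:
    """Estimate the driver's fitness ``s`` from a tumor's passenger spectrum.

    The driver CCF fixes the observation time ``t_obs(s)`` for each candidate
    ``s`` on the grid ``[1.0, s_max]``; the model's hitch-hiker rank spectrum
    at ``t_obs`` is compared with the observed subclonal CCFs, ranked in
    decreasing order.  The default objective is the mean squared difference
    of log frequencies by rank; a binned multinomial likelihood on the 10-bin
    CCF histogram is available as ``objective="binned"``.  ``mu`` is fixed by
    default and can be profiled over ``config.mu_grid``.

    Regime: NEUTRAL when the fitted ``s`` is within ``neutral_tol`` of 1,
    HARD at or above ``hard_cut``, SOFT in between.  Too few subclonal
    passengers returns a flagged estimate with no regime.
    """
    cfg = config or SelectionFitConfig()
    obs = _subclonal_ccfs(ccf_records, cfg.clonal_threshold)
    if len(obs) < cfg.min_passengers:
        return SelectionEstimate(
            s_hat=None,
            mu_hat=None,
            objective=None,
            regime=None,
            n_passengers_used=len(obs),
            flag=f"too few subclonal passengers ({len(obs)} < {cfg.min_passengers})",
        )
    # a clonal driver only says the sweep completed; evaluate the spectrum at
    # the time the driver reached the clonality threshold (the hitch-hiker
    # model describes variation generated during the sweep, not after fixation)
    driver = min(max(driver_ccf, 0.0), cfg.clonal_threshold)
    s_grid = np.arange(1.0, cfg.s_max + cfg.s_step / 2, cfg.s_step)
    mu_grid = list(cfg.mu_grid) if cfg.mu_grid is not None else [cfg.mu]
    K = len(obs)

    best: tuple[float, float, float] | None = None  # (objective, s, mu)
    for s in s_grid:
        s = float(s)
        try:
            t_obs = time_to_frequency(driver, s, cfg.N)
        except ValueError:
            continue  # driver CCF unreachable at this s (e.g. below establishment)
        for mu in mu_grid:
            if not (0.0 < mu <= s):
                continue
            pred = passenger_spectrum(K, t_obs, s, mu)
            if cfg.objective == "rank":
                obj = _rank_objective(obs, pred)
            elif cfg.objective == "binned":
                obj = _binned_objective(obs, pred, cfg.n_bins)
            else:
                raise ValueError(f"unknown objective {cfg.objective!r}")
            if best is None or obj < best[0]:
                best = (obj, s, mu)
    if best is None:
        return SelectionEstimate(
            s_hat=None,
            mu_hat=None,
            objective=None,
            regime=None,
            n_passengers_used=K,
            flag="no feasible (s, mu) on the grid",
        )
    obj, s_hat, mu_hat = best
    if s_hat - 1.0 < cfg.neutral_tol:
        regime = Regime.NEUTRAL
    elif s_hat >= cfg.hard_cut:
        regime = Regime.HARD
    else:
        regime = Regime.SOFT
    return SelectionEstimate(
        s_hat=s_hat,
        mu_hat=mu_hat,
        objective=obj,
        regime=regime,
        n_passengers_used=K,
    )
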
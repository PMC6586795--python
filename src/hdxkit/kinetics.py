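"""Opening kinetics and correlated-amide counts from bimodal time courses.

For a peptide exchanging through a concerted opening, the relative
abundance of the low-mass (still-closed) population decays as
``y = exp(-k_op * t)``; fitting that one-parameter decay to the replicate
mean abundances yields the opening rate ``k_op``, the closed-state
half-life ``t_1/2 = ln 2 / k_op``, and an asymptotic 95% confidence
interval.  The mass gap between the two populations, corrected for the
measured per-peptide back-exchange, gives the number of amides exchanging
in a single correlated event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .envelopes import DEUTERIUM_MASS_SHIFT

__all__ = [
    "BackExchangeRecord",
    "KineticFit",
    "BelowDetectionError",
    "BoundaryError",
    "back_exchange",
    "theoretical_max_mass",
    "count_correlated_amides",
    "correlated_amide_range",
    "fit_opening_rate",
    "half_life",
    "normalize_uptake",
    "write_kinetics_table",
]


class BelowDetectionError(RuntimeError):
    """No measurable decay of the low-mass population in the sampled window."""


class BoundaryError(RuntimeError):
    """The fitted rate ran into the k <= 0 boundary."""


def theoretical_max_mass(
    m_0: float,
    max_uptake: int,
    label_fraction: float = 0.752,
    scaled: bool = True,
) -> float:
    """Theoretical maximum peptide mass at full labeling.

    With ``scaled=True`` (default) the maximum is taken at the labeling
    deuterium fraction actually present in solution, so a lossless
    maximum-labeled control measures 0% back-exchange.  ``scaled=False``
    uses the full 100%-D ceiling instead.
    """
    f = label_fraction if scaled else 1.0
    return m_0 + max_uptake * f * DEUTERIUM_MASS_SHIFT


def back_exchange(
    m_maxlabel: float, m_0: float, m_max: float, clamp: bool = False
) -> float:
    """Percent deuterium lost between quench and detection.

    ``BE(%) = (1 - (m_maxlabel - m_0) / (m_max - m_0)) * 100`` from the
    maximum-labeled control, the undeuterated mass, and the theoretical
    maximum.  Values outside [0, 100] are possible with noisy controls and
    are clamped only on request.
    """
    if m_max <= m_0:
        raise ZeroDivisionError("m_max must exceed m_0")
    be = (1.0 - (m_maxlabel - m_0) / (m_max - m_0)) * 100.0
    if clamp:
        be = min(max(be, 0.0), 100.0)
    return be


@dataclass(frozen=True)
class BackExchangeRecord:
    """Per-peptide back-exchange bookkeeping."""

    peptide_id: str
    m_0: float
    m_maxlabel: float
    m_max: float
    be_percent: float
    out_of_range: bool

    @classmethod
    def from_masses(
        cls,
        peptide_id: str,
        m_0: float,
        m_maxlabel: float,
        max_uptake: int,
        label_fraction: float = 0.752,
        scaled: bool = True,
        clamp: bool = True,
    ) -> "BackExchangeRecord":
        m_max = theoretical_max_mass(m_0, max_uptake, label_fraction, scaled)
        raw = back_exchange(m_maxlabel, m_0, m_max, clamp=False)
        out = not 0.0 <= raw <= 100.0
        return cls(
            peptide_id=peptide_id,
            m_0=m_0,
            m_maxlabel=m_maxlabel,
            m_max=m_max,
            be_percent=min(max(raw, 0.0), 100.0) if clamp else raw,
            out_of_range=out,
        )


def count_correlated_amides(delta_hdx: float, be_percent: float) -> float:
    """Back-exchange-corrected mass gap between the two populations.

    ``#NHs = dHDX * 100 / (100 - BE)`` — the high-minus-low population
    mass difference restored to its value at zero back-exchange, in the
    same units as *delta_hdx* (Da).
    """
    if be_percent >= 100.0:
        raise ValueError("back-exchange of 100% leaves nothing to correct")
    return delta_hdx * 100.0 / (100.0 - be_percent)


def correlated_amide_range(
    delta_hdx: float,
    be_percent: float,
    label_fraction: float = 0.752,
) -> tuple[int, int]:
    """Integer range of amides exchanging in one correlated event.

    The corrected mass gap is converted to an amide count by dividing by
    the mass carried per fully participating amide — the H-to-D shift
    scaled by the labeling deuterium fraction, since even a complete
    exchanger equilibrates only to the solution's deuterium content.  The
    replicate-mean count is reported as its [floor, ceil] bracket.
    """
    corrected = count_correlated_amides(delta_hdx, be_percent)
    count = corrected / (label_fraction * DEUTERIUM_MASS_SHIFT)
    return int(math.floor(count)), int(math.ceil(count))


@dataclass(frozen=True)
class KineticFit:
    """Exponential-decay fit of the low-mass population abundance."""

    k_op: float  # s^-1
    ci95: tuple[float, float]  # s^-1
    t_half_min: float
    t_half_ci_min: tuple[float, float]
    r_squared: float
    n_points: int
    state: str = ""
    amide_range: tuple[int, int] | None = None


def fit_opening_rate(
    times_s: np.ndarray,
    abundances: np.ndarray,
    sds: np.ndarray | None = None,
    state: str = "",
    detection_floor: float = 0.95,
    ci_method: str = "asymptotic",
    n_boot: int = 1000,
    seed: int = 0,
) -> KineticFit:
    """Unweighted least-squares fit of ``y = exp(-k * t)``.

    *times_s* are labeling times in seconds and *abundances* the replicate
    mean low-mass fractions.  The 95% CI comes from the asymptotic
    (linearized) standard error with Student's t at ``n - 1`` degrees of
    freedom, or — with ``ci_method="bootstrap"`` — from a seeded residual
    bootstrap (percentile interval over *n_boot* refits); *sds* are
    accepted for bookkeeping but the fit itself is unweighted.  A series
    that never drops below *detection_floor* carries no rate information
    within the sampled window and raises :class:`BelowDetectionError`.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(abundances, dtype=float)
    if t.size != y.size:
        raise ValueError("times and abundances must have equal length")
    if t.size < 3:
        raise ValueError("at least 3 time points required")
    if np.any(y < -0.1) or np.any(y > 1.1):
        raise ValueError("abundances must be (approximately) in [0, 1]")
    if float(np.min(y)) > detection_floor:
        raise BelowDetectionError(
            "low-mass population does not decay within the sampled times"
        )

    # log-linear initial guess from the clearly decaying points
    pos = y > 1e-3
    if np.count_nonzero(pos) >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        k0 = max(-slope, 1e-8)
    else:
        k0 = math.log(2.0) / max(float(np.median(t)), 1e-9)

    def model(tt: np.ndarray, k: float) -> np.ndarray:
        return np.exp(-k * tt)

    popt, pcov = optimize.curve_fit(
        model, t, y, p0=[k0], maxfev=10000, full_output=False
    )
    k = float(popt[0])
    if k <= 0:
        raise BoundaryError(f"fitted rate {k:.3g} s^-1 is not positive")

    resid = y - model(t, k)
    rss = float(resid @ resid)
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / sstot if sstot > 0 else 1.0

    if ci_method == "asymptotic":
        se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
        tcrit = float(stats.t.ppf(0.975, t.size - 1))
        ci = (k - tcrit * se, k + tcrit * se)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        ks = []
        for _ in range(n_boot):
            yb = model(t, k) + rng.choice(resid, size=resid.size, replace=True)
            try:
                kb = float(
                    optimize.curve_fit(model, t, yb, p0=[k], maxfev=10000)[0][0]
                )
            except RuntimeError:
                continue
            ks.append(kb)
        ci = tuple(float(q) for q in np.percentile(ks, [2.5, 97.5]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    t_half = half_life(k)
    t_half_ci = (
        half_life(ci[1]) if ci[1] > 0 else 0.0,
        half_life(ci[0]) if ci[0] > 0 else math.inf,
    )
    return KineticFit(
        k_op=k,
        ci95=ci,
        t_half_min=t_half,
        t_half_ci_min=t_half_ci,
        r_squared=r2,
        n_points=int(t.size),
        state=state,
    )


def half_life(k_op: float) -> float:
    """Closed-state half-life in minutes, ``ln 2 / k_op / 60``."""
    if k_op <= 0:
        raise ValueError("k_op must be positive")
    return math.log(2.0) / k_op / 60.0


def normalize_uptake(uptake: float, be_percent: float) -> float:
    """Rescale measured uptake to its zero-back-exchange value.

    Used to put measuring days with different back-exchange on a common
    scale: ``uptake * 100 / (100 - BE)``.
    """
    if be_percent >= 100.0:
        raise ValueError("back-exchange of 100% leaves nothing to normalize")
    return uptake * 100.0 / (100.0 - be_percent)


def write_kinetics_table(
    results: list[dict],
    path: str | Path,
) -> None:
    """Write a per-peptide, per-state kinetic summary CSV.

    Each entry is either a successful fit (dict with ``peptide_id, state,
    fit: KineticFit``) or a failure (``peptide_id, state, reason``), which
    is rendered as ``N.D.`` with the reason.
    """
    import pandas as pd

    rows = []
    for res in results:
        if "fit" in res and res["fit"] is not None:
            fit: KineticFit = res["fit"]
            lo, hi = fit.amide_range or (None, None)
            rows.append(
                {
                    "peptide_id": res["peptide_id"],
                    "state": res["state"],
                    "r_squared": round(fit.r_squared, 4),
                    "k_op_s": fit.k_op,
                    "k_op_ci_low": fit.ci95[0],
                    "k_op_ci_high": fit.ci95[1],
                    "t_half_min": fit.t_half_min,
                    "t_half_ci_low": fit.t_half_ci_min[0],
                    "t_half_ci_high": fit.t_half_ci_min[1],
                    "nhs_low": lo,
                    "nhs_high": hi,
                    "status": "ok",
                }
            )
        else:
            rows.append(
                {
                    "peptide_id": res["peptide_id"],
                    "state": res["state"],
                    "status": f"N.D. ({res.get('reason', 'unknown')})",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
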
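"""Deconvolution of HDX isotopic envelopes into one or two populations.

A peptide exchanging purely by EX2 shows a single, gradually shifting
envelope that is well described by ``amplitude * [natural (*) Binomial(N, p)]``
with ``N`` the exchangeable-amide count and ``p`` the mean per-site
deuteration.  Concerted (EX1) opening instead produces a superposition of a
low-mass (still closed) and a high-mass (opened-and-exchanged) binomial
population.  This module fits both models by least squares on the stick
intensities, selects between them with a nested-model F-test, and
classifies the exchange regime (EX2 / EX1 / EXX / uncharacterized) from
the fits across the labeling time course.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .envelopes import (
    DEUTERIUM_MASS_SHIFT,
    IsotopicEnvelope,
    Peptide,
    natural_isotope_envelope,
    peptide_composition,
)

__all__ = [
    "PopulationFit",
    "ModelSelection",
    "RegimeCall",
    "TimepointFit",
    "FitFailureError",
    "UnderdeterminedError",
    "PeptideEnvelopeModel",
    "fit_unimodal",
    "fit_bimodal",
    "select_model",
    "fit_timecourse",
    "low_mass_abundance_series",
    "abundance_series_for_kinetics",
    "classify_regime",
]

#: deterministic multi-start grid for per-site deuteration fractions
START_GRID = (0.05, 0.2, 0.4, 0.6, 0.75)
#: average spacing (Da) between adjacent aggregated isotope peaks; used
#: only to assign observed peaks to integer bins, where +/-0.3 Da slack
#: makes the exact value uncritical
BIN_SPACING = 1.0045


class FitFailureError(RuntimeError):
    """All optimizer starts failed; the spectrum cannot be deconvolved."""


class UnderdeterminedError(ValueError):
    """Fewer informative peaks than free parameters."""


@dataclass(frozen=True)
class PopulationFit:
    """Result of a 1- or 2-binomial deconvolution of one envelope."""

    peptide_id: str
    n_populations: int
    p_low: float
    p_high: float
    abundance_low: float
    centroid_low: float
    centroid_high: float
    amplitude: float
    rss: float
    n_points: int
    tss: float  # total observed intensity power, for relative-scale guards

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_low <= self.p_high <= 1.0:
            raise ValueError("population fractions must satisfy 0 <= p_low <= p_high <= 1")
        if not 0.0 <= self.abundance_low <= 1.0:
            raise ValueError("abundance_low must lie in [0, 1]")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")
        if self.n_populations == 1 and (
            self.abundance_low != 1.0 or self.p_low != self.p_high
        ):
            raise ValueError("unimodal fit must have abundance_low=1 and p_low=p_high")

    @property
    def separation(self) -> float:
        return self.p_high - self.p_low


@dataclass(frozen=True)
class ModelSelection:
    """Outcome of the unimodal-vs-bimodal nested F-test."""

    preferred: str  # "unimodal" | "bimodal"
    p_value: float
    f_stat: float
    separation_ok: bool
    reason: str


class PeptideEnvelopeModel:
    """Cached natural envelope and binomial-mixture basis for one peptide."""

    def __init__(self, peptide: Peptide, threshold: float = 0.999):
        if peptide.max_uptake < 1:
            raise ValueError(f"{peptide.id}: no exchangeable amides to fit")
        self.peptide = peptide
        self.natural = natural_isotope_envelope(
            peptide_composition(peptide.sequence), threshold=threshold
        )
        self.n = peptide.max_uptake
        self.mono = float(self.natural.masses[0])

    def observed_vector(self, envelope: IsotopicEnvelope) -> np.ndarray:
        """Observed intensities on the integer extra-nucleon bin grid.

        Normalized to unit total so that fits (and hence abundances and
        model selection) are invariant to global intensity scaling.
        """
        bins = np.rint((envelope.neutral_masses - self.mono) / BIN_SPACING).astype(int)
        if bins[0] < 0:
            bins = bins - bins[0]  # tolerate small global mass offsets
        y = np.zeros(bins[-1] + 1)
        np.add.at(y, bins, envelope.intensity)
        return y / y.sum()

    def _shape(self, layer: np.ndarray, nbins: int) -> np.ndarray:
        shape = np.convolve(self.natural.probs, layer)
        if shape.size < nbins:
            shape = np.pad(shape, (0, nbins - shape.size))
        return shape[:nbins]

    def unimodal_shape(self, p: float, nbins: int) -> np.ndarray:
        layer = stats.binom.pmf(np.arange(self.n + 1), self.n, p)
        return self._shape(layer, nbins)

    def bimodal_shape(self, w: float, p1: float, p2: float, nbins: int) -> np.ndarray:
        k = np.arange(self.n + 1)
        layer = w * stats.binom.pmf(k, self.n, p1) + (1 - w) * stats.binom.pmf(
            k, self.n, p2
        )
        return self._shape(layer, nbins)

    def centroid_at(self, p: float) -> float:
        """Neutral-mass centroid of a binomial population at fraction p."""
        return self.natural.centroid + DEUTERIUM_MASS_SHIFT * self.n * p


def _profile_amplitude(shape: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form least-squares amplitude and the resulting RSS."""
    ss = float(shape @ shape)
    a = max(float(shape @ y) / ss, 0.0) if ss > 0 else 0.0
    r = y - a * shape
    return a, float(r @ r)


def fit_unimodal(
    envelope: IsotopicEnvelope,
    peptide: Peptide,
    model: PeptideEnvelopeModel | None = None,
) -> PopulationFit:
    """Fit a single binomial population to the envelope."""
    model = model or PeptideEnvelopeModel(peptide)
    y = model.observed_vector(envelope)
    if y.size < 2:
        raise UnderdeterminedError("need at least 2 peaks for the unimodal fit")
    nbins = y.size

    def residual(x: np.ndarray) -> np.ndarray:
        shape = model.unimodal_shape(x[0], nbins)
        a, _ = _profile_amplitude(shape, y)
        return y - a * shape

    best = None
    for p0 in START_GRID:
        sol = optimize.least_squares(
            residual, x0=[p0], bounds=([0.0], [1.0]), xtol=1e-14, ftol=1e-14
        )
        rss = float(sol.fun @ sol.fun)
        if best is None or rss < best[0] - 1e-15 or (
            abs(rss - best[0]) <= 1e-15 and sol.x[0] < best[1]
        ):
            best = (rss, float(sol.x[0]))
    rss, p = best
    a, _ = _profile_amplitude(model.unimodal_shape(p, nbins), y)
    c = model.centroid_at(p)
    return PopulationFit(
        peptide_id=peptide.id,
        n_populations=1,
        p_low=p,
        p_high=p,
        abundance_low=1.0,
        centroid_low=c,
        centroid_high=c,
        amplitude=a,
        rss=rss,
        n_points=int(nbins),
        tss=float(y @ y),
    )


def fit_bimodal(
    envelope: IsotopicEnvelope,
    peptide: Peptide,
    model: PeptideEnvelopeModel | None = None,
    grid: tuple[float, ...] = START_GRID,
) -> PopulationFit:
    """Fit a two-binomial mixture (abundance, p_low, p_high, amplitude).

    The optimizer is restarted from a deterministic grid of (p_low, p_high)
    pairs; ties between starts are broken by lowest RSS, then lowest p_low.
    The populations are sorted so that ``p_low <= p_high`` on return.
    """
    model = model or PeptideEnvelopeModel(peptide)
    y = model.observed_vector(envelope)
    if np.count_nonzero(y) < 5:
        raise UnderdeterminedError("need at least 5 informative peaks for a bimodal fit")
    nbins = y.size

    def residual(x: np.ndarray) -> np.ndarray:
        shape = model.bimodal_shape(x[0], x[1], x[2], nbins)
        a, _ = _profile_amplitude(shape, y)
        return y - a * shape

    starts = [(0.5, lo, hi) for lo in grid for hi in grid if lo < hi]
    starts += [(0.5, p, p) for p in grid]  # degenerate starts keep RSS <= unimodal
    best = None
    failures = 0
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residual,
                x0=np.asarray(x0),
                bounds=([0.0] * 3, [1.0] * 3),
                xtol=1e-14,
                ftol=1e-14,
            )
        except Exception:
            failures += 1
            continue
        rss = float(sol.fun @ sol.fun)
        w, p1, p2 = (float(v) for v in sol.x)
        if p1 > p2:
            p1, p2, w = p2, p1, 1.0 - w
        if best is None or rss < best[0] - 1e-15 or (
            abs(rss - best[0]) <= 1e-15 and p1 < best[2]
        ):
            best = (rss, w, p1, p2)
    if best is None:
        raise FitFailureError(
            f"{peptide.id}: all {failures} bimodal starts failed to converge"
        )
    rss, w, p1, p2 = best
    a, _ = _profile_amplitude(model.bimodal_shape(w, p1, p2, nbins), y)
    return PopulationFit(
        peptide_id=peptide.id,
        n_populations=2,
        p_low=p1,
        p_high=p2,
        abundance_low=w,
        centroid_low=model.centroid_at(p1),
        centroid_high=model.centroid_at(p2),
        amplitude=a,
        rss=rss,
        n_points=int(nbins),
        tss=float(y @ y),
    )


def select_model(
    uni: PopulationFit,
    bi: PopulationFit,
    max_uptake: int,
    alpha: float = 0.05,
    min_separation_amides: float = 2.0,
) -> ModelSelection:
    """Nested-model F-test between the 1- and 2-population fits.

    The bimodal model is preferred only when the F-test rejects at *alpha*
    (2 extra parameters, ``n_points - 4`` residual df) AND the fitted
    populations are separated by at least *min_separation_amides*
    deuteriums — a mass split smaller than that is not a credible
    two-population spectrum at peptide resolution.
    """
    separation = bi.separation
    sep_needed = min_separation_amides / max_uptake
    separation_ok = separation >= sep_needed
    df2 = bi.n_points - 4
    if df2 < 1:
        return ModelSelection("unimodal", 1.0, 0.0, separation_ok, "insufficient df")
    # a unimodal fit already at numerical perfection cannot be improved upon
    if uni.rss <= 1e-14 * max(uni.tss, 1e-300):
        return ModelSelection("unimodal", 1.0, 0.0, separation_ok, "unimodal exact")
    rss_bi = max(bi.rss, 0.0)
    if rss_bi >= uni.rss:
        return ModelSelection("unimodal", 1.0, 0.0, separation_ok, "no RSS improvement")
    if rss_bi <= 1e-300:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = ((uni.rss - rss_bi) / 2.0) / (rss_bi / df2)
        p_value = float(stats.f.sf(f_stat, 2, df2))
    if p_value < alpha and separation_ok:
        return ModelSelection("bimodal", p_value, f_stat, True, "F-test")
    reason = "separation below threshold" if p_value < alpha else "F-test not significant"
    return ModelSelection("unimodal", p_value, f_stat, separation_ok, reason)


@dataclass(frozen=True)
class TimepointFit:
    """Both fits plus the model choice for one envelope."""

    time_min: float
    replicate: int
    uni: PopulationFit | None
    bi: PopulationFit | None
    selection: ModelSelection | None
    error: str | None = None

    @property
    def bimodal_preferred(self) -> bool:
        return self.selection is not None and self.selection.preferred == "bimodal"


@dataclass(frozen=True)
class RegimeCall:
    """Exchange-regime classification with its supporting evidence."""

    regime: str  # EX2 | EX1 | EXX | uncharacterized
    evidence: dict[float, float]  # time (min) -> mean model-selection p-value
    low_mass_drift_da: float


def fit_timecourse(
    envelopes: dict[tuple[float, int], IsotopicEnvelope],
    peptide: Peptide,
    alpha: float = 0.05,
    min_separation_amides: float = 2.0,
) -> list[TimepointFit]:
    """Fit and model-select every (time, replicate) envelope of a peptide."""
    model = PeptideEnvelopeModel(peptide)
    records = []
    for (t_min, rep), env in sorted(envelopes.items()):
        try:
            uni = fit_unimodal(env, peptide, model=model)
            bi = fit_bimodal(env, peptide, model=model)
            sel = select_model(
                uni,
                bi,
                peptide.max_uptake,
                alpha=alpha,
                min_separation_amides=min_separation_amides,
            )
            records.append(TimepointFit(t_min, rep, uni, bi, sel))
        except UnderdeterminedError as exc:
            records.append(TimepointFit(t_min, rep, None, None, None, error=str(exc)))
        except FitFailureError as exc:
            records.append(TimepointFit(t_min, rep, None, None, None, error=str(exc)))
    return records


def _bimodal_times(records: list[TimepointFit]) -> list[float]:
    """Times at which the majority of replicate fits prefer bimodality."""
    times = sorted({r.time_min for r in records})
    out = []
    for t in times:
        reps = [r for r in records if r.time_min == t and r.error is None]
        if reps and sum(r.bimodal_preferred for r in reps) * 2 > len(reps):
            out.append(t)
    return out


def low_mass_abundance_series(records: list[TimepointFit]):
    """Replicate mean and SD of the low-mass abundance per labeling time.

    Only times at which the bimodal model is preferred contribute; other
    times appear as gaps.  Returns a DataFrame with columns
    ``time_min, abundance_mean, abundance_sd, n``.
    """
    import pandas as pd

    rows = []
    for t in _bimodal_times(records):
        vals = [
            r.bi.abundance_low
            for r in records
            if r.time_min == t and r.bimodal_preferred
        ]
        rows.append(
            {
                "time_min": t,
                "abundance_mean": float(np.mean(vals)),
                "abundance_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows, columns=["time_min", "abundance_mean", "abundance_sd", "n"])


def abundance_series_for_kinetics(records: list[TimepointFit]):
    """Low-mass abundance at *every* time point, for opening-rate fitting.

    Where the bimodal model is preferred the fitted mixture weight is used
    directly.  Where a time point is effectively unimodal (fully closed
    before the transition, or fully opened after it) the abundance is
    imputed as 1 or 0 according to whether the unimodal deuteration
    fraction is closer to the low- or high-mass population seen at the
    bimodal time points.
    """
    import pandas as pd

    bimodal_recs = [r for r in records if r.bimodal_preferred]
    if len({r.time_min for r in bimodal_recs}) < 2:
        return pd.DataFrame(columns=["time_min", "abundance_mean", "abundance_sd", "n"])
    p_low_ref = float(np.median([r.bi.p_low for r in bimodal_recs]))
    p_high_ref = float(np.median([r.bi.p_high for r in bimodal_recs]))
    rows = []
    for t in sorted({r.time_min for r in records}):
        vals = []
        for r in records:
            if r.time_min != t or r.error is not None:
                continue
            if r.bimodal_preferred:
                vals.append(r.bi.abundance_low)
            else:
                p = r.uni.p_low
                vals.append(1.0 if abs(p - p_low_ref) <= abs(p - p_high_ref) else 0.0)
        if vals:
            rows.append(
                {
                    "time_min": t,
                    "abundance_mean": float(np.mean(vals)),
                    "abundance_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows, columns=["time_min", "abundance_mean", "abundance_sd", "n"])


def classify_regime(
    records: list[TimepointFit], drift_threshold_da: float = 1.0
) -> RegimeCall:
    """Call EX2 / EX1 / EXX / uncharacterized from a fitted time course.

    EX1 requires a preferred bimodal model at two or more labeling times
    with the low-mass population staying put (centroid drift at most
    *drift_threshold_da*); a drifting low-mass population is EXX; a time
    course that is unimodal throughout is EX2; anything prevented by fit
    failures or supported at a single time only is uncharacterized.
    """
    evidence: dict[float, float] = {}
    for t in sorted({r.time_min for r in records}):
        ps = [r.selection.p_value for r in records if r.time_min == t and r.selection]
        if ps:
            evidence[t] = float(np.mean(ps))
    times_bi = _bimodal_times(records)
    drift = 0.0
    if times_bi:
        per_time = [
            float(
                np.mean(
                    [
                        r.bi.centroid_low
                        for r in records
                        if r.time_min == t and r.bimodal_preferred
                    ]
                )
            )
            for t in times_bi
        ]
        drift = float(max(per_time) - min(per_time))
    if len(times_bi) >= 2:
        regime = "EX1" if drift <= drift_threshold_da else "EXX"
    elif any(r.error is not None for r in records) or len(times_bi) == 1:
        regime = "uncharacterized"
    else:
        regime = "EX2"
    return RegimeCall(regime=regime, evidence=evidence, low_mass_drift_da=drift)
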
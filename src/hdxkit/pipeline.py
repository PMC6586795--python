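"""End-to-end peptide analysis: envelopes -> regime -> opening kinetics.

Glue around the per-module operations: for each peptide and state, fit
every (time, replicate) envelope, classify the exchange regime, and — for
concerted exchangers — extract the opening rate, half-life and the
back-exchange-corrected correlated-amide count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bimodal as _bimodal
from . import kinetics as _kinetics
from .envelopes import DEUTERIUM_MASS_SHIFT, Peptide
from .synthetic import StudyTables

__all__ = ["PeptideStateResult", "analyze_peptide_state", "analyze_study"]


@dataclass
class PeptideStateResult:
    """Full analysis of one peptide in one state."""

    peptide: Peptide
    state: str
    regime: _bimodal.RegimeCall
    records: list[_bimodal.TimepointFit]
    abundance_series: pd.DataFrame
    kinetic_fit: _kinetics.KineticFit | None
    failure_reason: str | None
    back_exchange: _kinetics.BackExchangeRecord | None
    delta_hdx_da: float | None  # mean high-minus-low population mass gap
    amide_range: tuple[int, int] | None


def _mean_population_gap(
    records: list[_bimodal.TimepointFit], max_uptake: int
) -> float | None:
    gaps = [
        (r.bi.p_high - r.bi.p_low) * max_uptake * DEUTERIUM_MASS_SHIFT
        for r in records
        if r.bimodal_preferred
    ]
    return float(np.mean(gaps)) if gaps else None


def analyze_peptide_state(
    peptide: Peptide,
    envelopes: dict[tuple[float, int], "object"],
    state: str,
    label_fraction: float,
    m0: float | None = None,
    m_maxlabel: float | None = None,
    drift_threshold_da: float = 1.0,
) -> PeptideStateResult:
    """Analyze one peptide's labeling time course in one state.

    *envelopes* maps (time in minutes, replicate) to the observed
    :class:`~hdxkit.envelopes.IsotopicEnvelope`.  When the undeuterated
    and maximum-labeled control masses are given, back-exchange is
    measured and the correlated-amide count corrected with it; otherwise
    zero back-exchange is assumed.
    """
    records = _bimodal.fit_timecourse(envelopes, peptide)
    regime = _bimodal.classify_regime(records, drift_threshold_da=drift_threshold_da)
    series = _bimodal.abundance_series_for_kinetics(records)

    be_record = None
    be_pct = 0.0
    if m0 is not None and m_maxlabel is not None:
        be_record = _kinetics.BackExchangeRecord.from_masses(
            peptide.id, m0, m_maxlabel, peptide.max_uptake, label_fraction
        )
        be_pct = be_record.be_percent

    fit = None
    reason = None
    amide_range = None
    gap = _mean_population_gap(records, peptide.max_uptake)
    if regime.regime in ("EX1", "EXX") and len(series) >= 3:
        try:
            fit = _kinetics.fit_opening_rate(
                series["time_min"].to_numpy() * 60.0,
                series["abundance_mean"].to_numpy(),
                sds=series["abundance_sd"].to_numpy(),
                state=state,
            )
        except (_kinetics.BelowDetectionError, _kinetics.BoundaryError) as exc:
            reason = str(exc)
    elif regime.regime in ("EX1", "EXX"):
        reason = "too few quantifiable time points"
    else:
        reason = f"regime {regime.regime}: no concerted transition to fit"

    if gap is not None and be_pct < 100.0:
        amide_range = _kinetics.correlated_amide_range(gap, be_pct, label_fraction)
        if fit is not None:
            fit = _kinetics.KineticFit(
                k_op=fit.k_op,
                ci95=fit.ci95,
                t_half_min=fit.t_half_min,
                t_half_ci_min=fit.t_half_ci_min,
                r_squared=fit.r_squared,
                n_points=fit.n_points,
                state=fit.state,
                amide_range=amide_range,
            )
    return PeptideStateResult(
        peptide=peptide,
        state=state,
        regime=regime,
        records=records,
        abundance_series=series,
        kinetic_fit=fit,
        failure_reason=reason,
        back_exchange=be_record,
        delta_hdx_da=gap,
        amide_range=amide_range,
    )


def analyze_study(tables: StudyTables) -> list[PeptideStateResult]:
    """Run the peptide-state analysis over a full (synthetic) study."""
    from .synthetic import MAXLABEL_STATE, UNDEUTERATED_STATE

    uptake = tables.uptake
    results = []
    for pep in tables.peptides:
        nd = uptake[
            (uptake["peptide_id"] == pep.id) & (uptake["state"] == UNDEUTERATED_STATE)
        ]["centroid_mass_da"]
        md = uptake[
            (uptake["peptide_id"] == pep.id) & (uptake["state"] == MAXLABEL_STATE)
        ]["centroid_mass_da"]
        m0 = float(nd.mean()) if len(nd) else None
        mmax = float(md.mean()) if len(md) else None
        for state in tables.design.states:
            envs = {
                (t, rep): env
                for (pid, st, t, rep), env in tables.envelopes.items()
                if pid == pep.id and st == state
            }
            if not envs:
                continue
            results.append(
                analyze_peptide_state(
                    pep,
                    envs,
                    state,
                    tables.design.label_fraction,
                    m0=m0,
                    m_maxlabel=mmax,
                )
            )
    return results
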
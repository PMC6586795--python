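"""Differential HDX statistics between liganded states.

Per peptide and labeling time the deuterium-uptake difference between a
reference (less-liganded) and a perturbed state is tested with a
homoscedastic or heteroscedastic two-sample t-test (alpha = 0.01), the
variant chosen by an F-test on the replicate variances (alpha = 0.05).  A
peptide is only called significantly changed when two *consecutive* time
points are significant and the difference also clears a global magnitude
threshold ``t * sigma / sqrt(n)`` built from the pooled propagated SD of
all differences.  Positive differences (reference minus perturbed) mean
reduced exchange — protection — upon ligand binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StateComparison",
    "ThresholdSpec",
    "TTestOutcome",
    "delta_uptake",
    "variance_gate",
    "state_t_test",
    "consecutive_rule",
    "global_threshold",
    "compare_states",
    "classify_regions",
]


def delta_uptake(
    ref_replicates: np.ndarray, pert_replicates: np.ndarray
) -> tuple[float, float]:
    """Mean uptake difference (reference - perturbed) and its propagated SD.

    The SD combines the two sample SDs (ddof=1) in quadrature.
    """
    ref = np.asarray(ref_replicates, float)
    pert = np.asarray(pert_replicates, float)
    if ref.size < 2 or pert.size < 2:
        raise ValueError("at least 2 replicates per state required")
    sd = float(np.sqrt(np.var(ref, ddof=1) + np.var(pert, ddof=1)))
    return float(ref.mean() - pert.mean()), sd


def variance_gate(
    ref: np.ndarray, pert: np.ndarray, alpha: float = 0.05
) -> bool:
    """True when the replicate variances are compatible (two-sided F-test).

    Two zero-variance samples are treated as equal-variance by convention.
    """
    ref = np.asarray(ref, float)
    pert = np.asarray(pert, float)
    if ref.size < 2 or pert.size < 2:
        raise ValueError("at least 2 replicates per state required")
    v1, v2 = np.var(ref, ddof=1), np.var(pert, ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        return True
    if v2 == 0.0 or v1 == 0.0:
        return False
    f = v1 / v2
    d1, d2 = ref.size - 1, pert.size - 1
    p = 2.0 * min(stats.f.sf(f, d1, d2), stats.f.cdf(f, d1, d2))
    return min(p, 1.0) >= alpha


@dataclass(frozen=True)
class TTestOutcome:
    p_value: float
    variant: str  # "homoscedastic" | "heteroscedastic"


def state_t_test(
    ref: np.ndarray,
    pert: np.ndarray,
    gate_alpha: float = 0.05,
    equal_var: bool | None = None,
) -> TTestOutcome:
    """Two-sided two-sample t-test, variant gated by the variance F-test.

    With both samples at zero variance the p-value degenerates to 1.0 for
    equal means and 0.0 otherwise.
    """
    ref = np.asarray(ref, float)
    pert = np.asarray(pert, float)
    if ref.size < 2 or pert.size < 2:
        raise ValueError("at least 2 replicates per state required")
    if equal_var is None:
        equal_var = variance_gate(ref, pert, alpha=gate_alpha)
    variant = "homoscedastic" if equal_var else "heteroscedastic"
    if np.var(ref, ddof=1) == 0.0 and np.var(pert, ddof=1) == 0.0:
        return TTestOutcome(1.0 if ref.mean() == pert.mean() else 0.0, variant)
    res = stats.ttest_ind(ref, pert, equal_var=equal_var)
    return TTestOutcome(float(res.pvalue), variant)


def consecutive_rule(pvals: np.ndarray, alpha: float = 0.01) -> bool:
    """True iff some *adjacent* pair of time points is jointly significant."""
    p = np.asarray(pvals, float)
    if p.size < 2:
        raise ValueError("at least 2 time points required")
    sig = p < alpha
    return bool(np.any(sig[:-1] & sig[1:]))


@dataclass(frozen=True)
class ThresholdSpec:
    """Global magnitude threshold ``t * sigma / sqrt(n)`` on |dHDX|."""

    confidence: float
    n: int
    t_crit: float
    sigma_pooled: float
    threshold: float


@dataclass
class StateComparison:
    """Per-peptide, per-time differential records between two states.

    ``table`` columns: peptide_id, time_min, delta_hdx (Da, reference -
    perturbed), propagated_sd, p_value, variant.
    """

    reference: str
    perturbed: str
    table: pd.DataFrame


def compare_states(
    uptake: pd.DataFrame,
    reference: str,
    perturbed: str,
    gate_alpha: float = 0.05,
) -> StateComparison:
    """Build the full differential table from per-replicate uptake values.

    *uptake* must carry columns ``peptide_id, state, exposure_min,
    uptake_da`` with one row per replicate.  The sign convention is
    reference minus perturbed, with the reference conventionally the
    less-liganded state so that positive values indicate protection upon
    binding.
    """
    rows = []
    sub = uptake[uptake["state"].isin([reference, perturbed])]
    for (pid, t), grp in sub.groupby(["peptide_id", "exposure_min"], sort=True):
        ref = grp.loc[grp["state"] == reference, "uptake_da"].to_numpy()
        pert = grp.loc[grp["state"] == perturbed, "uptake_da"].to_numpy()
        if ref.size < 2 or pert.size < 2:
            continue
        d, sd = delta_uptake(ref, pert)
        res = state_t_test(ref, pert, gate_alpha=gate_alpha)
        rows.append(
            {
                "peptide_id": pid,
                "time_min": float(t),
                "delta_hdx": d,
                "propagated_sd": sd,
                "p_value": res.p_value,
                "variant": res.variant,
            }
        )
    return StateComparison(
        reference=reference, perturbed=perturbed, table=pd.DataFrame(rows)
    )


def global_threshold(
    comparison: StateComparison, n: int = 3, confidence: float = 0.95
) -> ThresholdSpec:
    """Magnitude threshold from the pooled propagated SD of all differences.

    ``sigma_pooled`` is the root-mean-square of the propagated SDs over
    every peptide x time record of the comparison; the critical value is
    the two-sided Student's t quantile at ``n - 1`` degrees of freedom
    (4.303 for n = 3 at 95%), giving ``threshold = t * sigma / sqrt(n)``.
    """
    sds = comparison.table["propagated_sd"].to_numpy() if len(comparison.table) else []
    if len(sds) == 0:
        raise ValueError("empty comparison")
    sigma = float(np.sqrt(np.mean(np.square(sds))))
    t_crit = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))
    return ThresholdSpec(
        confidence=confidence,
        n=n,
        t_crit=t_crit,
        sigma_pooled=sigma,
        threshold=t_crit * sigma / np.sqrt(n),
    )


def classify_regions(
    comparison: StateComparison,
    threshold: ThresholdSpec | float,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Call each peptide stabilized / destabilized / unchanged.

    A peptide is stabilized (protection upon binding) when two adjacent
    time points are both significant at *alpha* AND both exceed
    +threshold; destabilized symmetrically below -threshold.  Anything
    else — including significance with inconsistent signs — is unchanged.
    Returns columns ``peptide_id, classification, supporting_times``.
    """
    thr = threshold.threshold if isinstance(threshold, ThresholdSpec) else float(threshold)
    out = []
    for pid, grp in comparison.table.groupby("peptide_id", sort=True):
        grp = grp.sort_values("time_min")
        p = grp["p_value"].to_numpy()
        d = grp["delta_hdx"].to_numpy()
        t = grp["time_min"].to_numpy()
        sig = p < alpha
        stab_pairs = [
            (t[i], t[i + 1])
            for i in range(len(t) - 1)
            if sig[i] and sig[i + 1] and d[i] > thr and d[i + 1] > thr
        ]
        destab_pairs = [
            (t[i], t[i + 1])
            for i in range(len(t) - 1)
            if sig[i] and sig[i + 1] and d[i] < -thr and d[i + 1] < -thr
        ]
        if stab_pairs and destab_pairs:
            # contradictory adjacent windows: keep the larger-magnitude one
            mag_s = max(abs(d[np.searchsorted(t, a)]) for a, _ in stab_pairs)
            mag_d = max(abs(d[np.searchsorted(t, a)]) for a, _ in destab_pairs)
            cls, pairs = (
                ("stabilized", stab_pairs)
                if mag_s >= mag_d
                else ("destabilized", destab_pairs)
            )
        elif stab_pairs:
            cls, pairs = "stabilized", stab_pairs
        elif destab_pairs:
            cls, pairs = "destabilized", destab_pairs
        else:
            cls, pairs = "unchanged", []
        out.append(
            {
                "peptide_id": pid,
                "classification": cls,
                "supporting_times": ";".join(f"{a:g}-{b:g}" for a, b in pairs),
            }
        )
    return pd.DataFrame(out, columns=["peptide_id", "classification", "supporting_times"])
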
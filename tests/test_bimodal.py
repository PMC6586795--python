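"""Bimodal deconvolution: generate-and-refit oracles and model selection."""

import numpy as np
import pytest
from scipy import stats

from hdxkit.bimodal import (
    PeptideEnvelopeModel,
    UnderdeterminedError,
    classify_regime,
    fit_bimodal,
    fit_timecourse,
    fit_unimodal,
    low_mass_abundance_series,
    select_model,
)
from hdxkit.envelopes import (
    DeuterationDistribution,
    IsotopicEnvelope,
    Peptide,
    deuterated_envelope,
    envelope_from_layer,
)
from hdxkit.synthetic import (
    PeptideModel,
    StudyDesign,
    build_study,
    ex1_site_model,
    ex2_site_model,
    random_protein,
)


def mixture_envelope(model, w, p1, p2, charge=2, noise_sd=0.0, rng=None):
    """Synthesize a two-binomial-population envelope.

    Noise is multiplicative (the study generator's model): each stick is
    scaled by 1 + N(0, noise_sd).
    """
    k = np.arange(model.n + 1)
    layer = w * stats.binom.pmf(k, model.n, p1) + (1 - w) * stats.binom.pmf(
        k, model.n, p2
    )
    env = envelope_from_layer(model.natural, DeuterationDistribution(layer), charge)
    intensity = env.intensity.copy()
    if noise_sd:
        intensity *= np.clip(1.0 + rng.normal(0, noise_sd, intensity.size), 0, None)
    return IsotopicEnvelope(mz=env.mz, intensity=intensity, charge=charge)


@pytest.fixture(scope="module")
def model(myoglobin_peptide):
    return PeptideEnvelopeModel(myoglobin_peptide)


class TestUnimodalFit:
    def test_recovers_generating_fraction(self, myoglobin_peptide, model):
        env = deuterated_envelope(model.natural, np.full(model.n, 0.3), charge=2)
        fit = fit_unimodal(env, myoglobin_peptide, model=model)
        assert fit.p_low == pytest.approx(0.3, abs=1e-6)
        assert fit.n_populations == 1 and fit.abundance_low == 1.0

    def test_undeuterated_gives_zero(self, myoglobin_peptide, model):
        env = deuterated_envelope(model.natural, np.zeros(model.n), charge=2)
        fit = fit_unimodal(env, myoglobin_peptide, model=model)
        assert fit.p_low == pytest.approx(0.0, abs=1e-4)

    def test_full_label_control_recovers_label_fraction(
        self, myoglobin_peptide, model
    ):
        env = deuterated_envelope(model.natural, np.full(model.n, 0.752), charge=2)
        fit = fit_unimodal(env, myoglobin_peptide, model=model)
        assert fit.p_low == pytest.approx(0.752, abs=1e-6)


class TestBimodalFit:
    def test_recovers_mixture_parameters(self, myoglobin_peptide, model):
        env = mixture_envelope(model, 0.6, 0.1, 0.7)
        fit = fit_bimodal(env, myoglobin_peptide, model=model)
        assert fit.abundance_low == pytest.approx(0.6, abs=1e-3)
        assert fit.p_low == pytest.approx(0.1, abs=1e-3)
        assert fit.p_high == pytest.approx(0.7, abs=1e-3)

    def test_unimodal_input_collapses_and_selection_prefers_unimodal(
        self, myoglobin_peptide, model
    ):
        env = deuterated_envelope(model.natural, np.full(model.n, 0.4), charge=2)
        uni = fit_unimodal(env, myoglobin_peptide, model=model)
        bi = fit_bimodal(env, myoglobin_peptide, model=model)
        sel = select_model(uni, bi, myoglobin_peptide.max_uptake)
        assert sel.preferred == "unimodal"

    def test_strong_overlap_fails_separation_diagnostic(
        self, myoglobin_peptide, model
    ):
        env = mixture_envelope(model, 0.5, 0.30, 0.35)
        uni = fit_unimodal(env, myoglobin_peptide, model=model)
        bi = fit_bimodal(env, myoglobin_peptide, model=model)
        sel = select_model(uni, bi, myoglobin_peptide.max_uptake)
        # 0.05 separation < 2 deuteriums across 19 amides: not a credible split
        assert not sel.separation_ok
        assert sel.preferred == "unimodal"

    def test_underdetermined_spectrum_rejected(self, myoglobin_peptide, model):
        env = IsotopicEnvelope(
            mz=np.array([500.0, 500.5, 501.0]),
            intensity=np.array([1.0, 0.5, 0.2]),
            charge=2,
        )
        with pytest.raises(UnderdeterminedError):
            fit_bimodal(env, myoglobin_peptide, model=model)

    def test_abundance_invariant_to_intensity_scaling(
        self, myoglobin_peptide, model
    ):
        env = mixture_envelope(model, 0.35, 0.05, 0.6)
        scaled = IsotopicEnvelope(
            mz=env.mz, intensity=env.intensity * 3.7e4, charge=env.charge
        )
        f1 = fit_bimodal(env, myoglobin_peptide, model=model)
        f2 = fit_bimodal(scaled, myoglobin_peptide, model=model)
        assert f1.abundance_low == pytest.approx(f2.abundance_low, abs=1e-9)


class TestModelSelection:
    def test_df_guard_keeps_unimodal(self, myoglobin_peptide, model):
        env = mixture_envelope(model, 0.6, 0.1, 0.7)
        uni = fit_unimodal(env, myoglobin_peptide, model=model)
        bi = fit_bimodal(env, myoglobin_peptide, model=model)
        # pretend the spectrum only had 4 peaks: no residual df for the F-test
        from dataclasses import replace

        starved = replace(bi, n_points=4)
        sel = select_model(uni, starved, myoglobin_peptide.max_uptake)
        assert sel.preferred == "unimodal" and sel.reason == "insufficient df"

    def test_noise_free_mixture_prefers_bimodal(self, myoglobin_peptide, model):
        env = mixture_envelope(model, 0.6, 0.1, 0.7)
        uni = fit_unimodal(env, myoglobin_peptide, model=model)
        bi = fit_bimodal(env, myoglobin_peptide, model=model)
        sel = select_model(uni, bi, myoglobin_peptide.max_uptake)
        assert sel.preferred == "bimodal" and sel.p_value < 1e-10

    def test_type_i_error_rate_at_most_alpha(self, myoglobin_peptide, model):
        """On unimodal truth with noise, bimodal is picked in <= 5% of trials."""
        rng = np.random.default_rng(2024)
        n_trials, hits = 400, 0
        for _ in range(n_trials):
            p = rng.uniform(0.15, 0.6)
            env = mixture_envelope(model, 1.0, p, p, noise_sd=0.01, rng=rng)
            uni = fit_unimodal(env, myoglobin_peptide, model=model)
            bi = fit_bimodal(env, myoglobin_peptide, model=model)
            hits += select_model(uni, bi, myoglobin_peptide.max_uptake).preferred == "bimodal"
        assert hits / n_trials <= 0.05


def _ex1_records(k_op=0.0019, noise=0.0, jitter=0.0, seed=1):
    design = StudyDesign(states=("apo",))
    seq = random_protein(60, seed=5)
    pep = Peptide.from_sequence("p1", seq[9:25], 10)
    pm = PeptideModel(
        peptide=pep, states={"apo": ex1_site_model(pep.max_uptake, k_op=k_op)}
    )
    tables = build_study(
        design, [pm], noise_intensity=noise, centroid_jitter_da=jitter, seed=seed
    )
    envs = {
        (t, r): env for (pid, st, t, r), env in tables.envelopes.items() if st == "apo"
    }
    return pep, design, fit_timecourse(envs, pep)


class TestTimecourse:
    def test_ex1_low_mass_series_matches_exponential(self):
        pep, design, records = _ex1_records()
        series = low_mass_abundance_series(records)
        for _, row in series.iterrows():
            expected = np.exp(-0.0019 * row["time_min"] * 60.0)
            assert row["abundance_mean"] == pytest.approx(expected, abs=1e-3)

    def test_ex1_classification(self):
        _, _, records = _ex1_records()
        assert classify_regime(records).regime == "EX1"

    def test_ex2_classification(self):
        design = StudyDesign(states=("apo",))
        seq = random_protein(60, seed=5)
        pep = Peptide.from_sequence("p1", seq[9:25], 10)
        pm = PeptideModel(
            peptide=pep, states={"apo": ex2_site_model(pep.max_uptake, 0.002)}
        )
        tables = build_study(
            design, [pm], noise_intensity=0.0, centroid_jitter_da=0.0, seed=1
        )
        envs = {
            (t, r): env
            for (pid, st, t, r), env in tables.envelopes.items()
            if st == "apo"
        }
        records = fit_timecourse(envs, pep)
        call = classify_regime(records)
        assert call.regime == "EX2"
        assert low_mass_abundance_series(records).empty

    def test_exx_classification_via_low_mass_drift(self):
        design = StudyDesign(states=("apo",))
        seq = random_protein(60, seed=5)
        pep = Peptide.from_sequence("p1", seq[9:25], 10)
        pm = PeptideModel(
            peptide=pep,
            states={
                "apo": ex1_site_model(
                    pep.max_uptake, k_op=0.002, background_rate=5e-5
                )
            },
        )
        tables = build_study(
            design, [pm], noise_intensity=0.0, centroid_jitter_da=0.0, seed=1
        )
        envs = {
            (t, r): env
            for (pid, st, t, r), env in tables.envelopes.items()
            if st == "apo"
        }
        call = classify_regime(fit_timecourse(envs, pep))
        assert call.regime == "EXX"
        assert call.low_mass_drift_da > 1.0
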
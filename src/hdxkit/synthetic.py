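"""Synthetic HDX-MS studies with known ground truth.

The generator emulates the structure of a bottom-up, peptide-level HDX
experiment on a membrane transporter measured in several liganded states:

* uncorrelated (EX2) exchange — every backbone amide exchanges
  independently at its own protected intrinsic rate, so the envelope is a
  gradually shifting binomial;
* concerted (EX1) exchange — a cooperative opening with rate ``k_op``
  exposes a set of amides at once, producing a low-mass (still closed) and
  a high-mass (opened and exchanged) population whose relative abundances
  follow ``exp(-k_op * t)``;
* mixed (EXX) exchange — EX1 plus a background of EX2, which makes the
  low-mass population itself drift.

Labeling uses a sub-unity deuterium fraction (default 75.2%, the value
obtained by diluting a protonated sample 1:4 with 94% D2O buffer), and a
uniform per-site back-exchange loss is applied after labeling.  Every
output is a deterministic function of (seed, design, site models).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .envelopes import (
    DEUTERIUM_MASS_SHIFT,
    DeuterationDistribution,
    IsotopicEnvelope,
    NaturalEnvelope,
    Peptide,
    centroid_mass,
    envelope_from_layer,
    natural_isotope_envelope,
    peptide_composition,
    poisson_binomial,
)

__all__ = [
    "StudyDesign",
    "SiteModel",
    "PeptideModel",
    "GroundTruth",
    "StudyTables",
    "simulate_ex2_probs",
    "simulate_ex1_mixture",
    "build_study",
    "render_study",
    "random_protein",
    "ex1_site_model",
    "ex2_site_model",
]

#: reserved state labels in uptake tables
UNDEUTERATED_STATE = "ND"
MAXLABEL_STATE = "maxD"


def _labeling_fraction(
    sample_volumes: float = 1.0,
    buffer_volumes: float = 4.0,
    buffer_d_fraction: float = 0.94,
) -> float:
    """Deuterium fraction of the labeling mix.

    One volume of protonated sample diluted with four volumes of 94% D2O
    buffer gives 4 * 0.94 / 5 = 75.2% deuterium during exchange.
    """
    return buffer_volumes * buffer_d_fraction / (sample_volumes + buffer_volumes)


@dataclass(frozen=True)
class StudyDesign:
    """Layout of an HDX study: states, exposures, replication, labeling."""

    states: tuple[str, ...] = ("apo", "Na+", "Na+ + DA")
    times_min: tuple[float, ...] = (0.25, 1.0, 10.0, 60.0, 480.0)
    replicates: int = 3
    label_fraction: float = _labeling_fraction()
    temperature_c: float = 25.0
    ph: float = 7.4

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and > 0")
        if not 0.0 < self.label_fraction <= 1.0:
            raise ValueError("label_fraction must be in (0, 1]")
        if self.replicates < 2:
            raise ValueError("at least 2 replicates required")
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state labels")
        for reserved in (UNDEUTERATED_STATE, MAXLABEL_STATE):
            if reserved in self.states:
                raise ValueError(f"state label {reserved!r} is reserved")

    labeling_fraction = staticmethod(_labeling_fraction)

    @property
    def times_s(self) -> np.ndarray:
        return np.asarray(self.times_min, float) * 60.0


@dataclass(frozen=True)
class SiteModel:
    """Per-site exchange model for one peptide in one state.

    ``k_ch`` are intrinsic chemical exchange rates (s^-1) and ``protection``
    the dimensionless protection factors, so the observed EX2 rate at site i
    is ``k_ch[i] / protection[i]``.  For EX1/EXX, ``k_op`` is the concerted
    opening rate and ``cooperative`` maps site index -> occupancy weight in
    (0, 1]; fractional weights model partially participating amides, and the
    effective cooperative amide count is the sum of the weights.
    """

    k_ch: np.ndarray
    protection: np.ndarray
    regime: str = "EX2"
    k_op: float | None = None
    cooperative: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_ch", np.asarray(self.k_ch, float))
        object.__setattr__(self, "protection", np.asarray(self.protection, float))
        if self.k_ch.shape != self.protection.shape:
            raise ValueError("k_ch and protection must have equal length")
        if np.any(self.k_ch < 0):
            raise ValueError("k_ch must be >= 0")
        if np.any(self.protection < 1):
            raise ValueError("protection factors must be >= 1")
        if self.regime not in ("EX2", "EX1", "EXX"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime != "EX2":
            if self.k_op is None or self.k_op <= 0:
                raise ValueError("EX1/EXX require k_op > 0")
            if not self.cooperative:
                raise ValueError("EX1/EXX require a non-empty cooperative site set")
            for i, w in self.cooperative.items():
                if not 0 <= i < self.k_ch.size:
                    raise ValueError(f"cooperative site {i} out of range")
                if not 0.0 < w <= 1.0:
                    raise ValueError("cooperative weights must be in (0, 1]")

    @property
    def n_sites(self) -> int:
        return self.k_ch.size

    @property
    def cooperative_amides(self) -> float:
        return float(sum(self.cooperative.values()))


def ex2_site_model(n_sites: int, rate: float | np.ndarray) -> SiteModel:
    """Uniformly protected EX2 model with observed per-site rate(s) (s^-1)."""
    return SiteModel(
        k_ch=np.broadcast_to(np.asarray(rate, float), (n_sites,)).copy(),
        protection=np.ones(n_sites),
    )


def ex1_site_model(
    n_sites: int,
    k_op: float,
    cooperative_amides: float | None = None,
    background_rate: float = 0.0,
) -> SiteModel:
    """Concerted-opening model.

    By default the cooperative unit spans all exchangeable amides.  A
    fractional ``cooperative_amides`` assigns full weight to the integer
    part and the remainder to one further site.  A nonzero
    ``background_rate`` adds uncorrelated EX2 exchange to every site,
    which turns the regime into EXX.
    """
    if cooperative_amides is None:
        cooperative_amides = float(n_sites)
    if not 0 < cooperative_amides <= n_sites:
        raise ValueError("cooperative_amides must be in (0, n_sites]")
    coop: dict[int, float] = {}
    whole = int(np.floor(cooperative_amides))
    for i in range(whole):
        coop[i] = 1.0
    frac = cooperative_amides - whole
    if frac > 1e-12:
        coop[whole] = frac
    return SiteModel(
        k_ch=np.full(n_sites, background_rate),
        protection=np.ones(n_sites),
        regime="EXX" if background_rate > 0 else "EX1",
        k_op=k_op,
        cooperative=coop,
    )


@dataclass(frozen=True)
class PeptideModel:
    """A peptide plus one exchange model per study state."""

    peptide: Peptide
    states: dict[str, SiteModel]
    back_exchange: float = 0.0  # fractional loss in [0, 1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.back_exchange < 1.0:
            raise ValueError("back_exchange must be in [0, 1)")
        for label, model in self.states.items():
            if model.n_sites != self.peptide.max_uptake:
                raise ValueError(
                    f"{self.peptide.id}/{label}: site model has {model.n_sites} "
                    f"sites, peptide has {self.peptide.max_uptake}"
                )


def simulate_ex2_probs(
    site: SiteModel, t: float, label_fraction: float
) -> np.ndarray:
    """Per-site deuteration probability under uncorrelated exchange.

    ``p_i(t) = f * (1 - exp(-(k_ch_i / P_i) * t))`` — each probability
    saturates at the labeling deuterium fraction f.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    rates = site.k_ch / site.protection
    return label_fraction * -np.expm1(-rates * t)


def simulate_ex1_mixture(
    site: SiteModel, t: float, label_fraction: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Two-population mixture for concerted exchange.

    Returns ``(closed_fraction, open_probs, closed_probs)`` where
    ``closed_fraction = exp(-k_op * t)``.  The opened population carries
    the cooperative sites at the labeling fraction (scaled by their
    occupancy weight) on top of the EX2 background; the closed population
    sees the background only.  Open-state refolding is treated as
    instantaneous exchange: the closing rate never appears as a simulated
    quantity.
    """
    if site.regime == "EX2":
        raise ValueError("EX1 mixture undefined for an EX2 site model")
    if t < 0:
        raise ValueError("t must be >= 0")
    closed_fraction = float(np.exp(-site.k_op * t))
    background = simulate_ex2_probs(site, t, label_fraction)
    open_probs = background.copy()
    for i, w in site.cooperative.items():
        open_probs[i] = background[i] + w * (label_fraction - background[i])
    return closed_fraction, open_probs, background


@dataclass
class GroundTruth:
    """Per-peptide generating parameters, keyed by (peptide id, state)."""

    design: StudyDesign
    records: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "design": {
                "states": list(self.design.states),
                "times_min": list(self.design.times_min),
                "replicates": self.design.replicates,
                "label_fraction": self.design.label_fraction,
            },
            "peptides": self.records,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class StudyTables:
    """In-memory rendering of a synthetic study."""

    design: StudyDesign
    peptides: list[Peptide]
    uptake: pd.DataFrame
    envelopes: dict[tuple[str, str, float, int], IsotopicEnvelope]
    truth: GroundTruth
    sequence: str


def random_protein(length: int, seed: int, proline_fraction: float = 0.04) -> str:
    """A random sequence over the 20 standard residues (seeded)."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNQRSTVWY"))
    seq = rng.choice(alphabet, size=length)
    is_pro = rng.random(length) < proline_fraction
    seq[is_pro] = "P"
    return "".join(seq)


def _mixture_envelope(
    natural: NaturalEnvelope,
    weights_probs: list[tuple[float, np.ndarray]],
    charge: int,
) -> IsotopicEnvelope:
    """Population-weighted envelope, mixed at the deuteration-layer level.

    Mixing the deuterium-count distributions before the natural-envelope
    convolution keeps per-bin mean masses exact for two-population spectra.
    """
    layers = [
        (w, poisson_binomial(probs).probs) for w, probs in weights_probs if w > 1e-12
    ]
    size = max(layer.size for _, layer in layers)
    mixed = np.zeros(size)
    for w, layer in layers:
        mixed[: layer.size] += w * layer
    mixed /= mixed.sum()
    return envelope_from_layer(
        natural, DeuterationDistribution(probs=mixed), charge=charge
    )


def _site_probs_at(
    model: SiteModel, t_s: float, label_fraction: float, retention: float
) -> list[tuple[float, np.ndarray]]:
    """(weight, per-site probabilities) mixture after back-exchange."""
    if model.regime == "EX2":
        return [(1.0, retention * simulate_ex2_probs(model, t_s, label_fraction))]
    closed, open_p, closed_p = simulate_ex1_mixture(model, t_s, label_fraction)
    return [(closed, retention * closed_p), (1.0 - closed, retention * open_p)]


def build_study(
    design: StudyDesign,
    peptide_models: list[PeptideModel],
    noise_intensity: float = 0.01,
    centroid_jitter_da: float = 0.02,
    seed: int = 0,
    charge: int = 2,
    sequence: str | None = None,
    with_envelopes: bool = True,
) -> StudyTables:
    """Render a complete synthetic study in memory.

    For each peptide x state x time x replicate an isotopic envelope is
    built (mixture-weighted for EX1/EXX), back-exchange retention is applied
    to the deuteration probabilities, multiplicative Gaussian noise is added
    to stick intensities, and a Gaussian neutral-mass jitter (default
    0.02 Da) shifts the whole envelope.  Undeuterated ("ND") and
    maximum-labeled ("maxD") control rows are included.  With
    ``with_envelopes=False`` only the uptake table is produced and the
    centroid is the closed-form mean mass plus jitter (the small
    intensity-noise contribution to centroids is omitted).
    """
    ids = [pm.peptide.id for pm in peptide_models]
    if len(set(ids)) != len(ids):
        raise ValueError("overlapping peptide ids")
    for pm in peptide_models:
        missing = set(design.states) - set(pm.states)
        if missing:
            raise ValueError(f"{pm.peptide.id}: no site model for {sorted(missing)}")

    if sequence is None:
        length = max(pm.peptide.end for pm in peptide_models)
        seq = list(random_protein(length, seed=seed ^ 0x5EED))
        for pm in peptide_models:
            seq[pm.peptide.start - 1 : pm.peptide.end] = pm.peptide.sequence
        sequence = "".join(seq)

    rng = np.random.default_rng(seed)
    f = design.label_fraction
    rows: list[dict] = []
    envelopes: dict[tuple[str, str, float, int], IsotopicEnvelope] = {}
    truth = GroundTruth(design=design)

    def emit(pep: Peptide, natural, state, exposure_min, rep, mixture):
        jitter = float(rng.normal(0.0, centroid_jitter_da)) if centroid_jitter_da else 0.0
        if with_envelopes:
            env = _mixture_envelope(natural, mixture, charge)
            intensity = env.intensity.copy()
            if noise_intensity:
                intensity *= np.clip(
                    1.0 + rng.normal(0.0, noise_intensity, intensity.size), 0.0, None
                )
            env = IsotopicEnvelope(
                mz=env.mz + jitter / charge, intensity=intensity, charge=charge
            )
            envelopes[(pep.id, state, exposure_min, rep)] = env
            mass = centroid_mass(env)
        else:
            mono = natural.centroid
            mean_d = sum(w * probs.sum() for w, probs in mixture)
            mass = mono + mean_d * DEUTERIUM_MASS_SHIFT + jitter
        rows.append(
            {
                "peptide_id": pep.id,
                "sequence": pep.sequence,
                "start": pep.start,
                "end": pep.end,
                "state": state,
                "exposure_min": exposure_min,
                "replicate": rep,
                "centroid_mass_da": mass,
                "charge": charge,
            }
        )

    for pm in peptide_models:
        pep = pm.peptide
        natural = natural_isotope_envelope(peptide_composition(pep.sequence))
        retention = 1.0 - pm.back_exchange
        n_sites = pep.max_uptake
        for rep in range(1, design.replicates + 1):
            emit(pep, natural, UNDEUTERATED_STATE, 0.0, rep, [(1.0, np.zeros(n_sites))])
            emit(
                pep,
                natural,
                MAXLABEL_STATE,
                1440.0,
                rep,
                [(1.0, np.full(n_sites, retention * f))],
            )
        for state in design.states:
            model = pm.states[state]
            for t_min in design.times_min:
                mixture = _site_probs_at(model, t_min * 60.0, f, retention)
                for rep in range(1, design.replicates + 1):
                    emit(pep, natural, state, t_min, rep, mixture)
            truth.records.setdefault(pep.id, {})[state] = {
                "regime": model.regime,
                "k_op": model.k_op,
                "cooperative_amides": model.cooperative_amides or None,
                "back_exchange": pm.back_exchange,
                "max_uptake": n_sites,
            }

    uptake = pd.DataFrame(rows)
    return StudyTables(
        design=design,
        peptides=[pm.peptide for pm in peptide_models],
        uptake=uptake,
        envelopes=envelopes,
        truth=truth,
        sequence=sequence,
    )


def render_study(
    design: StudyDesign,
    peptide_models: list[PeptideModel],
    outdir: str | Path,
    noise_intensity: float = 0.01,
    centroid_jitter_da: float = 0.02,
    seed: int = 0,
    charge: int = 2,
    sequence: str | None = None,
) -> StudyTables:
    """Render a study and write every artefact to *outdir*.

    Produces ``uptake.csv`` (the uptake-table dialect), one peak-list TSV
    per envelope under ``spectra/``, ``protein.fasta`` and
    ``ground_truth.json``.  Identical inputs yield byte-identical outputs.
    """
    from . import io as _io  # local import to avoid a cycle

    tables = build_study(
        design,
        peptide_models,
        noise_intensity=noise_intensity,
        centroid_jitter_da=centroid_jitter_da,
        seed=seed,
        charge=charge,
        sequence=sequence,
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_uptake_table(tables.uptake, outdir / "uptake.csv")
    specdir = outdir / "spectra"
    specdir.mkdir(exist_ok=True)
    for (pid, state, t_min, rep), env in sorted(tables.envelopes.items()):
        name = f"{pid}__{state.replace(' ', '_').replace('+', 'p')}__t{t_min:g}__r{rep}.tsv"
        _io.write_peak_list(env, specdir / name)
    _io.write_fasta(tables.sequence, outdir / "protein.fasta", record_id="synthetic")
    tables.truth.to_json(outdir / "ground_truth.json")
    return tables
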
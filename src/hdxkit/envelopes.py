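"""Isotope-distribution mathematics for peptide-level HDX-MS.

Everything here works in *neutral mass* space; charge enters only when an
:class:`IsotopicEnvelope` is rendered to (or read from) an m/z axis.

The model of a (partially) deuterated peptide envelope is the convolution
of two discrete layers:

* the natural isotopologue distribution of the peptide's elemental
  composition (aggregated per extra nucleon), and
* the distribution of incorporated deuterium counts — a Poisson-binomial
  over the per-site exchange probabilities, each deuterium adding the
  H-to-D mass difference of 1.00628 Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "DEUTERIUM_MASS_SHIFT",
    "InvalidSequenceError",
    "Peptide",
    "IsotopicEnvelope",
    "DeuterationDistribution",
    "NaturalEnvelope",
    "exchangeable_amides",
    "peptide_composition",
    "natural_isotope_envelope",
    "poisson_binomial",
    "envelope_from_layer",
    "deuterated_envelope",
    "centroid_mass",
    "deuterium_uptake",
]

PROTON_MASS = 1.007276
#: mass(2H) - mass(1H); added per incorporated deuterium
DEUTERIUM_MASS_SHIFT = 1.00628

_STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class InvalidSequenceError(ValueError):
    """Raised for sequences containing non-standard amino-acid letters."""


def exchangeable_amides(sequence: str, n_term_exclusion: int = 1) -> int:
    """Count backbone amide hydrogens able to retain deuterium.

    The N-terminal residue and all prolines (which lack an amide hydrogen)
    are excluded.  ``n_term_exclusion=2`` switches to the alternative
    convention that also discounts the second residue for rapid
    back-exchange; the default follows the single-residue rule.
    """
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    bad = set(sequence) - _STANDARD_AA
    if bad:
        raise InvalidSequenceError(f"non-standard residue(s): {sorted(bad)!r}")
    if n_term_exclusion not in (1, 2):
        raise ValueError("n_term_exclusion must be 1 or 2")
    tail = sequence[n_term_exclusion:]
    return max(len(tail) - tail.count("P"), 0)


@dataclass(frozen=True)
class Peptide:
    """An identified proteolytic fragment with a 1-based inclusive span."""

    id: str
    sequence: str
    start: int
    end: int
    max_uptake: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.id}: end {self.end} < start {self.start}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} does not "
                f"match span {self.start}-{self.end}"
            )
        if self.max_uptake != exchangeable_amides(self.sequence):
            raise ValueError(
                f"{self.id}: max_uptake {self.max_uptake} inconsistent with "
                f"sequence (expected {exchangeable_amides(self.sequence)})"
            )

    @classmethod
    def from_sequence(cls, id: str, sequence: str, start: int) -> "Peptide":
        return cls(
            id=id,
            sequence=sequence,
            start=start,
            end=start + len(sequence) - 1,
            max_uptake=exchangeable_amides(sequence),
        )


@dataclass(frozen=True)
class IsotopicEnvelope:
    """A stick spectrum (m/z, intensity) at a known positive charge."""

    mz: np.ndarray
    intensity: np.ndarray
    charge: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size == 0:
            raise ValueError("empty envelope")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        if not np.any(self.intensity > 0):
            raise ValueError("all-zero intensity")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")

    @property
    def neutral_masses(self) -> np.ndarray:
        return (self.mz - PROTON_MASS) * self.charge


@dataclass(frozen=True)
class DeuterationDistribution:
    """P(exactly d deuteriums incorporated), d = 0..N."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if np.any(self.probs < 0):
            raise ValueError("negative probability")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def mean(self) -> float:
        return float(np.arange(self.probs.size) @ self.probs)


@dataclass(frozen=True)
class NaturalEnvelope:
    """Aggregated natural isotopologue distribution of one composition.

    ``masses[k]`` is the abundance-weighted mean neutral mass of all
    isotopologues carrying ``k`` extra nucleons; ``probs[k]`` their total
    probability.
    """

    masses: np.ndarray
    probs: np.ndarray

    @property
    def centroid(self) -> float:
        return float(self.masses @ self.probs)


def peptide_composition(sequence: str) -> dict[str, int]:
    """Elemental composition of the neutral peptide (residues + one water).

    Side-chain exchangeable hydrogens are counted as ordinary protium: in
    bottom-up HDX they are assumed fully back-exchanged by the time of
    measurement.
    """
    if set(sequence) - _STANDARD_AA:
        raise InvalidSequenceError(f"non-standard residue(s) in {sequence!r}")
    return dict(_pmass.Composition(sequence=sequence))


def _atom_isotopes(element: str) -> list[tuple[int, float, float]]:
    """(extra nucleons, mass, abundance) for one atom of *element*."""
    try:
        table = _pmass.nist_mass[element]
    except KeyError:
        raise ValueError(f"unknown element symbol: {element!r}") from None
    isotopes = [(a, m, p) for a, (m, p) in table.items() if a != 0 and p > 0.0]
    if not isotopes:
        raise ValueError(f"no stable isotopes tabulated for {element!r}")
    isotopes.sort()
    a0 = isotopes[0][0]
    return [(a - a0, m, p) for a, m, p in isotopes]


def natural_isotope_envelope(
    composition: dict[str, int], threshold: float = 0.999
) -> NaturalEnvelope:
    """Aggregated isotopologue distribution from terrestrial abundances.

    Atoms are convolved one element at a time with probability tracked per
    extra-nucleon bin and the mean mass of each bin carried alongside.  The
    tail is truncated once the cumulative probability of the leading bins
    reaches *threshold*, then renormalized.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if any(n < 0 for n in composition.values()):
        raise ValueError("negative atom count")

    probs = np.array([1.0])
    wmass = np.array([0.0])  # probability-weighted mass sum per bin
    for element, count in sorted(composition.items()):
        if count == 0:
            continue
        iso = _atom_isotopes(element)
        for _ in range(count):
            width = max(da for da, _, _ in iso)
            new_p = np.zeros(probs.size + width)
            new_w = np.zeros_like(new_p)
            for da, m, p in iso:
                new_p[da : da + probs.size] += probs * p
                new_w[da : da + probs.size] += (wmass + probs * m) * p
            keep = new_p > 1e-16
            keep[: int(np.argmax(keep)) + 1] = True  # never drop the head
            last = np.nonzero(keep)[0][-1] + 1
            probs, wmass = new_p[:last], new_w[:last]

    cum = np.cumsum(probs)
    ncut = int(np.searchsorted(cum, threshold)) + 1
    probs, wmass = probs[:ncut], wmass[:ncut]
    with np.errstate(invalid="ignore"):
        masses = np.where(probs > 0, wmass / np.maximum(probs, 1e-300), 0.0)
    probs = probs / probs.sum()
    return NaturalEnvelope(masses=masses, probs=probs)


def poisson_binomial(site_probs: np.ndarray) -> DeuterationDistribution:
    """Distribution of the number of deuterated sites.

    Exact dynamic programme over independent, non-identical per-site
    probabilities; reduces to the binomial when all sites are equal.
    """
    site_probs = np.asarray(site_probs, dtype=float)
    if np.any((site_probs < 0) | (site_probs > 1)):
        raise ValueError("site probabilities must lie in [0, 1]")
    probs = np.array([1.0])
    for p in site_probs:
        nxt = np.zeros(probs.size + 1)
        nxt[:-1] += probs * (1.0 - p)
        nxt[1:] += probs * p
        probs = nxt
    return DeuterationDistribution(probs=probs)


def envelope_from_layer(
    natural: NaturalEnvelope,
    layer: DeuterationDistribution,
    charge: int = 1,
) -> IsotopicEnvelope:
    """Convolve a natural envelope with a deuterium-count distribution.

    Each incorporated deuterium adds :data:`DEUTERIUM_MASS_SHIFT` to the
    neutral mass and one nucleon to the aggregation bin.  The result is
    rendered at *charge* as ``mz = (M + z * proton) / z``.
    """
    n_nat, n_d = natural.probs.size, layer.probs.size
    probs = np.zeros(n_nat + n_d - 1)
    wmass = np.zeros_like(probs)
    for d, pd in enumerate(layer.probs):
        if pd == 0.0:
            continue
        probs[d : d + n_nat] += natural.probs * pd
        wmass[d : d + n_nat] += (natural.masses + d * DEUTERIUM_MASS_SHIFT) * (
            natural.probs * pd
        )
    keep = probs > 0
    masses = wmass[keep] / probs[keep]
    mz = (masses + charge * PROTON_MASS) / charge
    return IsotopicEnvelope(mz=mz, intensity=probs[keep], charge=charge)


def deuterated_envelope(
    natural: NaturalEnvelope,
    site_probs: np.ndarray,
    charge: int = 1,
) -> IsotopicEnvelope:
    """Envelope of a peptide deuterated with the given per-site probabilities."""
    return envelope_from_layer(natural, poisson_binomial(site_probs), charge=charge)


def centroid_mass(envelope: IsotopicEnvelope) -> float:
    """Intensity-weighted mean m/z converted to neutral mass (Da)."""
    total = envelope.intensity.sum()
    if total <= 0:
        raise ValueError("cannot centroid an all-zero envelope")
    centroid_mz = float(envelope.mz @ envelope.intensity) / total
    return (centroid_mz - PROTON_MASS) * envelope.charge


def deuterium_uptake(mass_t: float, mass_undeuterated: float) -> float:
    """Mass increase relative to the undeuterated centroid (Da).

    Slightly negative values are legitimate noise and are not clamped.
    """
    if mass_t <= 0 or mass_undeuterated <= 0:
        raise ValueError("masses must be positive")
    return mass_t - mass_undeuterated
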
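"""Seeded generator of a two-species labelled co-culture dataset.

Emulates the statistical structure of a yeast-like / lactic-acid-
bacterium-like community grown on lactose with three labelling regimes
(unlabelled, galactose moiety 13C-labelled, glucose moiety 13C-labelled)
in three biological replicates:

* random proteomes for two member species plus a decoy proteome of the
  same composition (standing in for foreign-organism sequences),
* per-peptide MS1 envelopes whose 13C enrichment follows a per-species,
  per-condition, per-amino-acid labelling table, with Bernoulli
  replicate dropout and multiplicative log-normal peak noise,
* supernatant metabolite MIDs (pyruvate, lactate, glutamate) convolved
  with natural abundance.

The generator's ground truth (true per-peptide RIA, true MIDs) is
returned separately and never consumed by the analysis stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .isotope_core import (
    NATURAL_C13,
    ElementalComposition,
    isotopic_distribution,
    parse_formula,
    peptide_composition,
    residue_composition,
)
from .aa_regression import RESIDUE_ORDER
from .proteome_tools import tryptic_digest

__all__ = [
    "CONDITIONS",
    "MEDIUM_AMINO_ACIDS",
    "BIOSYNTHESIZED_AMINO_ACIDS",
    "LabellingScenario",
    "GroundTruth",
    "generate_proteomes",
    "default_scenario",
    "synthesize_observations",
    "true_peptide_ria",
]

CONDITIONS = ("unlabelled", "gal_labelled", "glc_labelled")

# Amino acids supplied by the defined co-culture medium stay essentially
# unlabelled in every regime; the set below is a declared stand-in for
# the 8 medium amino acids (disjoint from the biosynthesized set).
MEDIUM_AMINO_ACIDS = frozenset("FHKMRVWY")

# Amino acids biosynthesized from the labelled carbon source; alanine,
# glycine and cysteine sit closest to glycolysis and get the strongest
# enrichment weight.
BIOSYNTHESIZED_AMINO_ACIDS = frozenset("GAEQSTDC")

# Average proteome residue frequencies (UniProt-style background), in
# RESIDUE_ORDER. Used for random protein generation.
_BACKGROUND_FREQUENCIES = np.array(
    [
        8.25, 1.38, 5.45, 6.75, 3.86, 7.07, 2.27, 5.96, 5.84, 9.66,
        2.42, 4.06, 4.70, 3.93, 5.53, 6.56, 5.34, 6.87, 1.08, 2.92,
    ]
)
_BACKGROUND_FREQUENCIES = _BACKGROUND_FREQUENCIES / _BACKGROUND_FREQUENCIES.sum()

# Relative enrichment weights per residue for labelled conditions:
# glycolysis-proximal amino acids (Ala, Gly, Cys) carry the strongest
# enrichment when the galactose moiety is labelled (label enters via
# glycolysis), and a weaker one under glucose-moiety labelling; other
# biosynthesized amino acids are intermediate, remaining ones low, and
# medium-supplied ones zero (natural abundance only). The two labelled
# conditions therefore differ in profile shape, not only in overall
# labelling degree.
_GLYCOLYTIC = frozenset("AGC")


def _base_enrichment_profile(condition: str) -> np.ndarray:
    glycolytic_weight = 1.0 if condition == "gal_labelled" else 0.55
    weights = np.zeros(len(RESIDUE_ORDER))
    for i, aa in enumerate(RESIDUE_ORDER):
        if aa in MEDIUM_AMINO_ACIDS:
            weights[i] = 0.0
        elif aa in _GLYCOLYTIC:
            weights[i] = glycolytic_weight
        elif aa in BIOSYNTHESIZED_AMINO_ACIDS:
            weights[i] = 0.7
        else:
            weights[i] = 0.25
    return weights


# Ground-truth corrected MIDs per metabolite and condition. Fragment
# formulas are synthetic stand-ins for TBDMS-derivatized GC-MS fragments
# (unlabelled derivatization carbon and silicon included); the labelled
# fractions parameterize the generator after the study design: ~70% of
# pyruvate/lactate fully labelled under glucose-moiety labelling vs ~40%
# under galactose-moiety labelling, glutamate ~60% labelled (mostly 4-5
# carbons) under galactose vs ~40% (1-3 carbons) under glucose.
_METABOLITE_FRAGMENTS: dict[str, tuple[str, int]] = {
    "pyruvate": ("C9H18NO3Si", 3),
    "lactate": ("C9H21O3Si2", 3),
    "glutamate": ("C17H36NO4Si2", 5),
}

_METABOLITE_TRUE_MIDS: dict[tuple[str, str], tuple[float, ...]] = {
    ("pyruvate", "unlabelled"): (1.0, 0.0, 0.0, 0.0),
    ("pyruvate", "gal_labelled"): (0.60, 0.0, 0.0, 0.40),
    ("pyruvate", "glc_labelled"): (0.30, 0.0, 0.0, 0.70),
    ("lactate", "unlabelled"): (1.0, 0.0, 0.0, 0.0),
    ("lactate", "gal_labelled"): (0.60, 0.0, 0.0, 0.40),
    ("lactate", "glc_labelled"): (0.30, 0.0, 0.0, 0.70),
    ("glutamate", "unlabelled"): (1.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    ("glutamate", "gal_labelled"): (0.40, 0.0, 0.0, 0.0, 0.30, 0.30),
    ("glutamate", "glc_labelled"): (0.60, 0.15, 0.15, 0.10, 0.0, 0.0),
}

# Species-level median true-RIA targets per labelled condition: the
# yeast-like species A takes most of its carbon from the galactose
# moiety, the bacterium-like species B preferentially uses the glucose
# moiety while relying substantially on (unlabelled) medium and
# partner-supplied amino acids.
MEDIAN_RIA_TARGETS: dict[tuple[str, str], float] = {
    ("speciesA", "gal_labelled"): 0.30,
    ("speciesA", "glc_labelled"): 0.05,
    ("speciesB", "gal_labelled"): 0.15,
    ("speciesB", "glc_labelled"): 0.19,
}


@dataclass
class LabellingScenario:
    """Per species x condition x amino-acid 13C fractions plus noise and
    detection parameters; the generator's ground truth."""

    aa_fractions: dict[tuple[str, str], np.ndarray]  # (species, condition) -> 20 floats
    metabolite_mids: dict[tuple[str, str], tuple[float, ...]]
    metabolite_fragments: dict[str, tuple[str, int]]
    n_replicates: int = 3
    detection_probability: float = 0.85
    noise_sd: float = 0.05
    mid_noise_sd: float = 0.02
    seed: int = 0

    def fractions(self, species: str, condition: str) -> np.ndarray:
        return self.aa_fractions[(species, condition)]

    def to_json(self) -> str:
        payload = {
            "schema_version": 1,
            "aa_fractions": {
                f"{sp}|{cond}": list(map(float, f))
                for (sp, cond), f in sorted(self.aa_fractions.items())
            },
            "metabolite_mids": {
                f"{met}|{cond}": list(map(float, mid))
                for (met, cond), mid in sorted(self.metabolite_mids.items())
            },
            "metabolite_fragments": {
                met: list(frag) for met, frag in sorted(self.metabolite_fragments.items())
            },
            "n_replicates": self.n_replicates,
            "detection_probability": self.detection_probability,
            "noise_sd": self.noise_sd,
            "mid_noise_sd": self.mid_noise_sd,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)


@dataclass
class GroundTruth:
    """True per-peptide RIAs and true MIDs; written to its own file and
    never read by any analysis stage."""

    peptide_ria: dict[tuple[str, str, str], float]  # (peptide, species, condition)
    metabolite_mids: dict[tuple[str, str], tuple[float, ...]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "peptide_ria": {
                    f"{p}|{sp}|{cond}": v
                    for (p, sp, cond), v in sorted(self.peptide_ria.items())
                },
                "metabolite_mids": {
                    f"{met}|{cond}": list(map(float, mid))
                    for (met, cond), mid in sorted(self.metabolite_mids.items())
                },
            },
            indent=2,
        )


def generate_proteomes(
    seed: int,
    n_proteins: int = 25,
    length_range: tuple[int, int] = (200, 400),
) -> dict[str, list[tuple[str, str]]]:
    """Random proteomes for speciesA, speciesB and a decoy species.

    Residues are drawn i.i.d. from a fixed background frequency table;
    protein lengths are uniform over `length_range`. The decoy proteome
    uses a disjoint sub-seed, emulating foreign-organism sequences.
    Deterministic for a given seed.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 50 or hi < lo:
        raise ValueError("protein lengths must be >= 50 and ordered")
    residues = np.array(list(RESIDUE_ORDER))
    proteomes: dict[str, list[tuple[str, str]]] = {}
    for offset, species in enumerate(("speciesA", "speciesB", "decoy")):
        rng = np.random.default_rng([seed, offset])
        records = []
        for i in range(n_proteins):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(residues, size=length, p=_BACKGROUND_FREQUENCIES))
            records.append((f"{species[:3]}_{i:04d}", seq))
        proteomes[species] = records
    return proteomes


_RESIDUE_CARBONS = np.array(
    [residue_composition(aa).carbons for aa in RESIDUE_ORDER], dtype=float
)


def _carbon_weight_matrix(peptides: Sequence[str]) -> np.ndarray:
    """Row per peptide: o_AP * c_A for each amino acid A."""
    matrix = np.zeros((len(peptides), len(RESIDUE_ORDER)))
    for row, peptide in enumerate(peptides):
        for i, aa in enumerate(RESIDUE_ORDER):
            matrix[row, i] = peptide.count(aa) * _RESIDUE_CARBONS[i]
    return matrix


def true_peptide_ria(peptide: str, fractions: np.ndarray) -> float:
    """Carbon-weighted mean of per-residue 13C fractions:
    sum_A o_AP c_A f_A / sum_A o_AP c_A."""
    weights = _carbon_weight_matrix([peptide])[0]
    return float(weights @ fractions / weights.sum())


def _digest_species_peptides(
    proteomes: Mapping[str, Sequence[tuple[str, str]]],
) -> dict[str, list[str]]:
    out = {}
    for species in ("speciesA", "speciesB"):
        seen: dict[str, None] = {}
        for _, seq in proteomes[species]:
            for peptide in tryptic_digest(seq):
                seen.setdefault(peptide, None)
        out[species] = list(seen)
    return out


def _calibrate_fractions(
    peptides: Sequence[str], target_median: float, profile: np.ndarray, cap: float = 0.95
) -> np.ndarray:
    """Scale the enrichment profile so the median true RIA over the
    peptide set hits the target. The median is monotone in the scale, so
    bisection converges; medium amino acids stay at natural abundance."""

    weights = _carbon_weight_matrix(peptides)
    totals = weights.sum(axis=1)

    def fractions_at(scale: float) -> np.ndarray:
        return NATURAL_C13 + scale * profile * (cap - NATURAL_C13)

    def median_at(scale: float) -> float:
        return float(np.median(weights @ fractions_at(scale) / totals))

    lo, hi = 0.0, 1.0
    if median_at(hi) < target_median:
        return fractions_at(hi)
    for _ in range(50):
        mid = (lo + hi) / 2
        if median_at(mid) < target_median:
            lo = mid
        else:
            hi = mid
    return fractions_at((lo + hi) / 2)


def default_scenario(
    proteomes: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    seed: int = 0,
) -> LabellingScenario:
    """The default two-species labelling scenario.

    Per-amino-acid 13C fractions are calibrated against the digest
    peptides of the given proteomes (default proteomes if none are
    passed) so that the species-level median true RIA matches the
    scenario targets: ~0.30 / ~0.05 for the yeast-like species A under
    galactose- / glucose-moiety labelling and ~0.15 / ~0.19 for the
    bacterium-like species B. The unlabelled condition stays at natural
    abundance throughout, as do medium-supplied amino acids in every
    condition.
    """
    if proteomes is None:
        proteomes = generate_proteomes(seed=seed)
    peptides = _digest_species_peptides(proteomes)
    natural = np.full(len(RESIDUE_ORDER), NATURAL_C13)
    aa_fractions: dict[tuple[str, str], np.ndarray] = {}
    for species in ("speciesA", "speciesB"):
        aa_fractions[(species, "unlabelled")] = natural.copy()
        for condition in ("gal_labelled", "glc_labelled"):
            target = MEDIAN_RIA_TARGETS[(species, condition)]
            aa_fractions[(species, condition)] = _calibrate_fractions(
                peptides[species], target, _base_enrichment_profile(condition)
            )
    return LabellingScenario(
        aa_fractions=aa_fractions,
        metabolite_mids=dict(_METABOLITE_TRUE_MIDS),
        metabolite_fragments=dict(_METABOLITE_FRAGMENTS),
        seed=seed,
    )


def synthesize_observations(
    proteomes: Mapping[str, Sequence[tuple[str, str]]],
    scenario: LabellingScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the peptide-envelope and metabolite-MID tables.

    For every digest peptide of each member species, condition and
    replicate: detect with the scenario's Bernoulli probability and, if
    detected, emit the forward-model envelope at the peptide's true RIA
    with multiplicative log-normal peak noise. Metabolite MIDs are the
    natural-abundance convolution of the true MID with analogous noise.
    All randomness derives from the scenario seed.
    """
    rng = np.random.default_rng([scenario.seed, 1000])
    peptides = _digest_species_peptides(proteomes)
    columns: dict[str, list] = {
        "peptide": [], "species": [], "condition": [],
        "replicate": [], "offset": [], "intensity": [],
    }
    truth_ria: dict[tuple[str, str, str], float] = {}
    for species in ("speciesA", "speciesB"):
        species_peptides = peptides[species]
        weights = _carbon_weight_matrix(species_peptides)
        totals = weights.sum(axis=1)
        compositions = [peptide_composition(p) for p in species_peptides]
        for condition in CONDITIONS:
            fractions = scenario.fractions(species, condition)
            rias = weights @ fractions / totals
            for peptide, comp, ria in zip(species_peptides, compositions, rias):
                truth_ria[(peptide, species, condition)] = float(ria)
                envelope = isotopic_distribution(comp, float(ria)).as_array()
                size = envelope.size
                detected = rng.random(scenario.n_replicates) < scenario.detection_probability
                for replicate in np.flatnonzero(detected) + 1:
                    noisy = envelope * rng.lognormal(0.0, scenario.noise_sd, size=size)
                    columns["peptide"].append(np.full(size, peptide, dtype=object))
                    columns["species"].append(np.full(size, species, dtype=object))
                    columns["condition"].append(np.full(size, condition, dtype=object))
                    columns["replicate"].append(np.full(size, int(replicate)))
                    columns["offset"].append(np.arange(size))
                    columns["intensity"].append(noisy)
    envelope_rows = {
        name: np.concatenate(chunks) if chunks else np.array([])
        for name, chunks in columns.items()
    }
    mid_rows: list[dict] = []
    from .mid_tools import correction_matrix  # local import avoids cycle at module load

    for (metabolite, condition), true_mid in sorted(scenario.metabolite_mids.items()):
        formula, n_tracer = scenario.metabolite_fragments[metabolite]
        fragment = parse_formula(formula)
        window = n_tracer + 3  # observe a couple of natural +1/+2 offsets past Mn
        matrix = correction_matrix(fragment, n_tracer, n_observed=window)
        raw = matrix @ np.asarray(true_mid)
        for replicate in range(1, scenario.n_replicates + 1):
            noisy = raw * rng.lognormal(0.0, scenario.mid_noise_sd, size=raw.size)
            for offset, intensity in enumerate(noisy):
                mid_rows.append(
                    {
                        "metabolite": metabolite,
                        "fragment_formula": formula,
                        "n_tracer_carbons": n_tracer,
                        "condition": condition,
                        "replicate": replicate,
                        "m_offset": offset,
                        "intensity": intensity,
                    }
                )
    envelopes = pd.DataFrame(envelope_rows)
    envelopes = envelopes.astype({"replicate": int, "offset": int, "intensity": float})
    mids = pd.DataFrame(mid_rows)
    truth = GroundTruth(
        peptide_ria=truth_ria, metabolite_mids=dict(scenario.metabolite_mids)
    )
    return envelopes, mids, truth
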
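"""Elemental compositions and aggregated isotopic-distribution arithmetic.

This is the computational kernel shared by the peptide-envelope forward
model (used when estimating the relative isotope abundance, RIA, of a
peptide from its MS1 envelope) and by the natural-abundance correction of
metabolite mass-isotopologue distributions.

The model is the aggregated nominal-mass one: every species carrying k
extra neutrons is pooled into a single intensity at integer mass offset k.
Fine isotopic structure, exact masses and charge states are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom

__all__ = [
    "NATURAL_ISOTOPE_PATTERNS",
    "NATURAL_C13",
    "ElementalComposition",
    "IsotopeEnvelope",
    "AminoAcidTable",
    "load_residue_table",
    "residue_composition",
    "parse_formula",
    "peptide_composition",
    "carbon_count",
    "isotopic_distribution",
    "mix_envelopes",
]

# Single-atom isotope patterns over nominal mass offsets (0, +1, +2, ...).
# IUPAC representative natural abundances; 36S sits at offset +4 (two
# neutrons heavier than 34S), hence the explicit zero at +3.
NATURAL_C13 = 0.0107
NATURAL_ISOTOPE_PATTERNS: dict[str, np.ndarray] = {
    "C": np.array([1.0 - NATURAL_C13, NATURAL_C13]),
    "H": np.array([1.0 - 0.000115, 0.000115]),
    "N": np.array([1.0 - 0.00364, 0.00364]),
    "O": np.array([1.0 - 0.00038 - 0.00205, 0.00038, 0.00205]),
    "S": np.array([1.0 - 0.0075 - 0.0425 - 0.0001, 0.0075, 0.0425, 0.0, 0.0001]),
    # Si appears in TBDMS-derivatized metabolite fragments, never in peptides.
    "Si": np.array([0.92223, 0.04685, 0.03092]),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

DEFAULT_TRUNCATION = 1e-6


@dataclass(frozen=True)
class ElementalComposition:
    """Element symbol -> non-negative atom count.

    Supports element-wise addition, which is what makes envelope
    convolution associative over compositions.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, n in dict(self.counts).items():
            if element not in NATURAL_ISOTOPE_PATTERNS:
                raise ValueError(f"unknown element symbol: {element!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {element}: {n}")
            if n > 0:
                clean[element] = n
        object.__setattr__(self, "counts", clean)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) + n
        return ElementalComposition(merged)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    @property
    def carbons(self) -> int:
        return self.counts.get("C", 0)

    @property
    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def heavy_capacity(self) -> int:
        """Maximum total extra-neutron offset the composition can carry."""
        cap = 0
        for element, n in self.counts.items():
            cap += n * (len(NATURAL_ISOTOPE_PATTERNS[element]) - 1)
        return cap

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n > 1 else ''}" for el, n in sorted(self.counts.items())
        )


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Relative intensities indexed by nominal mass offset 0, 1, 2, ...

    Normalized to unit sum; trailing entries below the truncation
    threshold used at construction have been dropped.
    """

    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("envelope must be a non-empty 1-D intensity vector")
        if np.any(arr < 0):
            raise ValueError("envelope intensities must be non-negative")
        object.__setattr__(self, "intensities", tuple(arr.tolist()))

    @classmethod
    def from_raw(
        cls, intensities: Sequence[float], threshold: float = DEFAULT_TRUNCATION
    ) -> "IsotopeEnvelope":
        """Normalize a raw intensity vector and drop the sub-threshold tail."""
        arr = np.asarray(intensities, dtype=float)
        total = arr.sum()
        if total <= 0:
            raise ValueError("envelope has zero total intensity")
        arr = arr / total
        keep = arr.size
        while keep > 1 and arr[keep - 1] < threshold:
            keep -= 1
        arr = arr[:keep]
        arr = arr / arr.sum()
        return cls(tuple(arr.tolist()))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.intensities, dtype=float)

    def __len__(self) -> int:
        return len(self.intensities)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.intensities, dtype=dtype)

    def mean_offset(self) -> float:
        arr = self.as_array()
        return float(np.dot(np.arange(arr.size), arr))


class AminoAcidTable:
    """Residue symbol -> residue ElementalComposition for the 20 standard
    amino acids, loaded from the packaged TSV resource.

    Residue formulas are the amino acid minus one water; a peptide's
    composition is the residue sum plus one water.
    """

    WATER = None  # set after class definition

    def __init__(self, residues: Mapping[str, ElementalComposition]):
        if sorted(residues) != sorted("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("residue table must contain exactly the 20 standard residues")
        self._residues = dict(residues)

    def __getitem__(self, residue: str) -> ElementalComposition:
        try:
            return self._residues[residue]
        except KeyError:
            raise KeyError(f"non-standard residue: {residue!r}") from None

    def __contains__(self, residue: str) -> bool:
        return residue in self._residues

    def residues(self) -> dict[str, ElementalComposition]:
        return dict(self._residues)


def parse_formula(text: str) -> ElementalComposition:
    """Parse a chemical formula string such as ``"C3H4O3"``.

    An omitted count means 1. Elements are restricted to those with a
    known isotope pattern (C, H, N, O, S, Si).
    """
    if not text or not isinstance(text, str):
        raise ValueError("empty or non-string formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos or match.group(0) == "":
            break
        element, digits = match.group(1), match.group(2)
        if element not in NATURAL_ISOTOPE_PATTERNS:
            raise ValueError(f"unknown element symbol {element!r} in formula {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed formula: {text!r}")
    return ElementalComposition(counts)


def load_residue_table() -> AminoAcidTable:
    with resources.files("crossfeed_sip.data").joinpath("residues.tsv").open() as fh:
        header = fh.readline()
        assert header.strip().split("\t") == ["residue", "formula"]
        residues = {}
        for line in fh:
            if not line.strip():
                continue
            residue, formula = line.strip().split("\t")
            residues[residue] = parse_formula(formula)
    return AminoAcidTable(residues)


_RESIDUE_TABLE = load_residue_table()
AminoAcidTable.WATER = parse_formula("H2O")


def residue_composition(residue: str) -> ElementalComposition:
    """Composition of a single residue (amino acid minus water)."""
    return _RESIDUE_TABLE[residue]


def peptide_composition(sequence: str) -> ElementalComposition:
    """Elemental composition of a peptide: residue sum plus one water.

    Ambiguous one-letter codes (B, Z, X, ...) are rejected: they have no
    unique elemental formula.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    counts: dict[str, int] = {"H": 2, "O": 1}
    for residue in sequence:
        comp = _RESIDUE_TABLE[residue]  # raises KeyError on non-standard letters
        for element, n in comp.counts.items():
            counts[element] = counts.get(element, 0) + n
    return ElementalComposition(counts)


def carbon_count(x: str | ElementalComposition) -> int:
    """Number of carbon atoms in a peptide sequence or a composition.

    For a single residue letter this equals the residue's carbon count
    (peptide water adds no carbon).
    """
    if isinstance(x, ElementalComposition):
        return x.carbons
    return peptide_composition(x).carbons


def _poly_power(base: np.ndarray, n: int) -> np.ndarray:
    """(sum_k base[k] z^k)^n by binary exponentiation over convolutions."""
    result = np.array([1.0])
    factor = np.asarray(base, dtype=float)
    while n > 0:
        if n & 1:
            result = np.convolve(result, factor)
        n >>= 1
        if n:
            factor = np.convolve(factor, factor)
    return result


def natural_pattern_excluding_carbon(comp: ElementalComposition) -> np.ndarray:
    """Aggregated natural-abundance pattern of all non-carbon atoms.

    Cached building block: carbon is the only element whose isotope
    probability varies during RIA fitting, so the rest of the envelope
    can be convolved once per composition.
    """
    poly = np.array([1.0])
    for element, n in sorted(comp.counts.items()):
        if element == "C":
            continue
        poly = np.convolve(poly, _poly_power(NATURAL_ISOTOPE_PATTERNS[element], n))
    return poly


def carbon_pattern(n_carbons: int, c13_fraction: float) -> np.ndarray:
    """Binomial pattern of n carbons with per-carbon 13C probability."""
    if n_carbons == 0:
        return np.array([1.0])
    return binom.pmf(np.arange(n_carbons + 1), n_carbons, c13_fraction)


def isotopic_distribution(
    comp: ElementalComposition,
    c13_fraction: float = NATURAL_C13,
    threshold: float = DEFAULT_TRUNCATION,
) -> IsotopeEnvelope:
    """Aggregated isotope envelope of a composition at a given 13C level.

    Carbon follows an independent Bernoulli(c13_fraction) per atom; H, N,
    O, S (and Si) stay at natural abundance. The result is the
    convolution of the per-element patterns, normalized to unit sum and
    truncated at `threshold` relative intensity from the tail.
    """
    if not (0.0 <= c13_fraction <= 1.0):
        raise ValueError(f"c13_fraction outside [0, 1]: {c13_fraction}")
    if not (0.0 < threshold <= 0.01):
        raise ValueError(f"truncation threshold outside (0, 0.01]: {threshold}")
    poly = np.convolve(
        carbon_pattern(comp.carbons, c13_fraction),
        natural_pattern_excluding_carbon(comp),
    )
    return IsotopeEnvelope.from_raw(poly, threshold=threshold)


def mix_envelopes(
    components: Iterable[tuple[IsotopeEnvelope | Sequence[float], float]],
) -> IsotopeEnvelope:
    """Weighted mixture of envelopes, renormalized to unit sum.

    Models coexisting molecular populations (e.g. pre-existing unlabelled
    and newly synthesized labelled protein) observed in one MS1 pattern.
    """
    components = list(components)
    if not components:
        raise ValueError("no envelopes to mix")
    arrays = []
    weights = []
    for envelope, weight in components:
        if weight < 0:
            raise ValueError("mixture weights must be non-negative")
        arrays.append(np.asarray(envelope, dtype=float))
        weights.append(float(weight))
    if sum(weights) <= 0:
        raise ValueError("at least one mixture weight must be positive")
    size = max(a.size for a in arrays)
    total = np.zeros(size)
    for arr, weight in zip(arrays, weights):
        total[: arr.size] += weight * arr
    return IsotopeEnvelope.from_raw(total, threshold=1e-300)
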
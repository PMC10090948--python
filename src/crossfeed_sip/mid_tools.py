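"""Natural-isotope-abundance correction of GC-MS mass-isotopologue
distributions (MIDs) and labelled-fraction summaries.

A measured MID of a derivatized metabolite fragment mixes the tracer
signal with heavy isotopes occurring naturally in every atom of the
fragment (including the unlabelled carbon and silicon contributed by
TBDMS/MeOx derivatization). Correction inverts the linear mixing
M_obs = C x, where column j of C is the natural envelope of the
fragment with j tracer carbons fixed as 13C, by non-negative least
squares, which keeps corrected fractions physical on noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .isotope_core import ElementalComposition, isotopic_distribution

__all__ = ["MIDVector", "correction_matrix", "correct_mid", "labelled_fraction"]


@dataclass(frozen=True)
class MIDVector:
    """Mass-isotopologue distribution M0..Mn of one metabolite fragment.

    n_tracer_carbons is the number of carbons that can carry tracer
    label (the metabolite backbone carbons present in the fragment);
    the remaining fragment atoms are derivatization- or skeleton-derived
    and always at natural abundance.
    """

    metabolite: str
    fragment: ElementalComposition
    n_tracer_carbons: int
    intensities: tuple[float, ...]
    state: str = "raw"  # "raw" | "corrected"

    def __post_init__(self) -> None:
        if self.n_tracer_carbons > self.fragment.carbons:
            raise ValueError("n_tracer_carbons exceeds fragment carbon count")
        if self.n_tracer_carbons < 0:
            raise ValueError("n_tracer_carbons must be >= 0")
        arr = np.asarray(self.intensities, dtype=float)
        if np.any(arr < 0):
            raise ValueError("MID intensities must be non-negative")
        object.__setattr__(self, "intensities", tuple(arr.tolist()))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.intensities, dtype=float)


def correction_matrix(
    fragment: ElementalComposition,
    n_tracer: int,
    n_observed: int | None = None,
    threshold: float = 1e-9,
) -> np.ndarray:
    """Natural-abundance mixing matrix, shape (n_observed, n_tracer + 1).

    Column j is the aggregated isotope envelope of the fragment with j
    tracer carbons fixed as 13C (a +j mass shift convolved with the
    natural envelope of the remaining atoms), truncated or zero-padded
    to the observed window.
    """
    if n_tracer > fragment.carbons:
        raise ValueError("n_tracer exceeds fragment carbon count")
    if n_observed is None:
        n_observed = n_tracer + 1
    matrix = np.zeros((n_observed, n_tracer + 1))
    for j in range(n_tracer + 1):
        remaining = dict(fragment.counts)
        remaining["C"] = fragment.carbons - j
        envelope = isotopic_distribution(
            ElementalComposition(remaining), threshold=threshold
        ).as_array()
        # shift by the j fixed 13C atoms, clip to the observed window
        width = min(envelope.size, n_observed - j)
        if width > 0:
            matrix[j : j + width, j] = envelope[:width]
    return matrix


def correct_mid(raw: MIDVector, threshold: float = 1e-9) -> MIDVector:
    """Remove natural heavy-isotope contributions from a raw MID.

    Solves correction_matrix @ x = raw by non-negative least squares and
    renormalizes x to unit sum. The corrected vector has exactly
    n_tracer_carbons + 1 entries (M0..Mn)."""
    if raw.state != "raw":
        raise ValueError("correct_mid expects a raw-state MID")
    observed = raw.as_array()
    if observed.sum() <= 0:
        raise ValueError("all-zero MID")
    matrix = correction_matrix(
        raw.fragment, raw.n_tracer_carbons, n_observed=observed.size, threshold=threshold
    )
    fractions, _ = nnls(matrix, observed / observed.sum())
    total = fractions.sum()
    if total <= 0:
        raise ValueError("correction produced an all-zero solution")
    fractions = fractions / total
    return replace(raw, intensities=tuple(fractions.tolist()), state="corrected")


@dataclass(frozen=True)
class LabelledFractions:
    """Per-isotopologue fractions of a corrected MID.

    total_labelled = 1 - M0; fully_labelled is the Mn fraction (all
    tracer carbons 13C), e.g. M3 for a three-carbon metabolite."""

    metabolite: str
    fractions: tuple[float, ...]  # M0..Mn
    total_labelled: float
    fully_labelled: float


def labelled_fraction(corrected: MIDVector) -> LabelledFractions:
    if corrected.state != "corrected":
        raise ValueError("labelled_fraction expects a corrected MID")
    fractions = corrected.as_array()
    return LabelledFractions(
        metabolite=corrected.metabolite,
        fractions=tuple(fractions.tolist()),
        total_labelled=float(1.0 - fractions[0]),
        fully_labelled=float(fractions[-1]),
    )
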
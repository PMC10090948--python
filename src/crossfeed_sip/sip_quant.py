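"""Per-peptide relative isotope abundance (RIA) estimation from MS1
envelopes, replicate-consistency filtering and median summarization.

RIA is the fraction of a peptide's carbon atoms that are 13C. It is
estimated by fitting the single-enrichment forward model from
:mod:`crossfeed_sip.isotope_core` to the observed envelope by least
squares. The reported value includes the natural 13C baseline, so
unlabelled material fits at roughly 0.0107 rather than 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .isotope_core import (
    ElementalComposition,
    IsotopeEnvelope,
    carbon_pattern,
    natural_pattern_excluding_carbon,
)

__all__ = [
    "PeptideObservation",
    "PeptideSummary",
    "estimate_ria",
    "replicate_cv",
    "filter_and_summarize",
    "ria_distribution",
    "CV_THRESHOLD",
]

CV_THRESHOLD = 0.40
_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class PeptideObservation:
    """One peptide in one condition and replicate, with its observed MS1
    envelope and (once estimated) its RIA."""

    peptide: str
    species: str
    condition: str
    replicate: int
    envelope: IsotopeEnvelope | None = None
    ria: float | None = None


@dataclass
class PeptideSummary:
    """Replicate-level RIA values for one peptide x species x condition
    group, with the coefficient of variation, the median RIA and the
    filter verdict (kept / removed_cv / removed_support)."""

    peptide: str
    species: str
    condition: str
    replicate_rias: dict[int, float]
    cv: float | None
    median_ria: float | None
    filter_flag: str


def _model_sse(observed: np.ndarray, model: np.ndarray) -> float:
    size = max(observed.size, model.size)
    obs = np.zeros(size)
    obs[: observed.size] = observed
    mod = np.zeros(size)
    mod[: model.size] = model
    diff = obs - mod
    return float(diff @ diff)


@lru_cache(maxsize=512)
def _grid_models(comp: ElementalComposition, grid_step: float) -> tuple[np.ndarray, np.ndarray]:
    """Forward-model envelopes for the coarse enrichment grid.

    Cached per composition: one peptide is typically fitted once per
    condition and replicate, so the grid models are reused many times.
    """
    n_carbons = comp.carbons
    background = natural_pattern_excluding_carbon(comp)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    carbon = binom.pmf(
        np.arange(n_carbons + 1)[None, :], n_carbons, grid[:, None]
    )
    size = n_carbons + background.size
    models = np.empty((grid.size, size))
    for i in range(grid.size):
        models[i] = np.convolve(carbon[i], background)
    models /= models.sum(axis=1, keepdims=True)
    return grid, models


def estimate_ria(
    envelope: IsotopeEnvelope | Sequence[float],
    comp: ElementalComposition,
    grid_step: float = 0.01,
    tol: float = 1e-4,
) -> float:
    """Estimate the 13C enrichment r* that best explains an envelope.

    Minimizes the unweighted squared distance between the normalized
    observed envelope and the forward-model envelope over r in [0, 1]:
    a coarse grid (default step 0.01) locates the basin, golden-section
    search refines it to |dr| < `tol`. Ties break toward the smaller r.
    """
    arr = np.asarray(envelope, dtype=float)
    if arr.size == 0 or arr.sum() <= 0:
        raise ValueError("empty or zero envelope")
    arr = arr / arr.sum()
    n_carbons = comp.carbons
    if n_carbons < 1:
        raise ValueError("composition must contain at least one carbon")
    background = natural_pattern_excluding_carbon(comp)

    def sse(r: float) -> float:
        model = np.convolve(carbon_pattern(n_carbons, r), background)
        model = model / model.sum()
        return _model_sse(arr, model)

    grid, models = _grid_models(comp, grid_step)
    size = max(arr.size, models.shape[1])
    obs = np.zeros(size)
    obs[: arr.size] = arr
    padded = np.zeros((models.shape[0], size))
    padded[:, : models.shape[1]] = models
    grid_sse = ((padded - obs) ** 2).sum(axis=1)
    best_idx = int(np.argmin(grid_sse))  # argmin takes the first (smaller r) on ties
    lo = max(0.0, grid[best_idx] - grid_step)
    hi = min(1.0, grid[best_idx] + grid_step)

    # Golden-section search on the bracketed basin.
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = sse(c), sse(d)
    while b - a > tol:
        if fc <= fd:  # ties move toward smaller r
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = sse(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = sse(d)
    candidates = [(sse(a), a), (fc, c), (fd, d), (sse(b), b)]
    best = min(candidates, key=lambda t: (t[0], t[1]))
    return float(best[1])


def replicate_cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample standard deviation over mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV requires at least two replicate values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(values.std(ddof=1) / mean)


def filter_and_summarize(
    groups: Mapping[tuple[str, str, str], Mapping[int, float]],
    n_replicates: int = 3,
    cv_threshold: float = CV_THRESHOLD,
) -> list[PeptideSummary]:
    """Apply the replicate-support and CV filters and take median RIAs.

    `groups` maps (peptide, species, condition) to {replicate: RIA}.
    Verdicts: one replicate only -> removed_support; exactly
    `n_replicates - 1` of `n_replicates` replicates with CV above the
    threshold -> removed_cv; everything else is kept with the median RIA
    over the available replicates.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    summaries = []
    for (peptide, species, condition), rias in sorted(groups.items()):
        values = [rias[r] for r in sorted(rias)]
        cv = replicate_cv(values) if len(values) >= 2 and np.mean(values) > 0 else None
        if len(values) < 2:
            flag, median = "removed_support", None
        elif len(values) == n_replicates - 1 and cv is not None and cv > cv_threshold:
            flag, median = "removed_cv", None
        else:
            flag, median = "kept", float(np.median(values))
        summaries.append(
            PeptideSummary(
                peptide=peptide,
                species=species,
                condition=condition,
                replicate_rias=dict(rias),
                cv=cv,
                median_ria=median,
                filter_flag=flag,
            )
        )
    return summaries


@dataclass(frozen=True)
class RiaDistribution:
    species: str
    condition: str
    n: int
    median: float
    q1: float
    q3: float


def ria_distribution(
    summaries: Iterable[PeptideSummary], species: str, condition: str
) -> RiaDistribution:
    """Distribution summary (n, median, quartiles) of kept median RIAs
    for one species x condition group, as drawn in RIA box plots."""
    values = [
        s.median_ria
        for s in summaries
        if s.species == species and s.condition == condition and s.filter_flag == "kept"
    ]
    if not values:
        raise ValueError(f"no kept summaries for {species}/{condition}")
    arr = np.asarray(values, dtype=float)
    q1, median, q3 = np.percentile(arr, [25, 50, 75])
    return RiaDistribution(species, condition, arr.size, float(median), float(q1), float(q3))
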
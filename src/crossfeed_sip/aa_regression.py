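"""Amino-acid contribution analysis.

Peptide labelling aggregates the labelling of its constituent amino
acids. For each peptide P and amino acid A the standardized predictor is

    stvalue(A, P) = o_AP * c_A / len(P)

where o_AP is the occurrence count of A in P, c_A the residue carbon
count and len(P) the peptide length. Regressing median peptide RIAs on
the 20 standardized values (ordinary least squares with intercept)
yields one coefficient per amino acid per species x condition; amino
acids supplied unlabelled by the medium come out near zero while
biosynthesized ones carry the label. Principal component analysis over
the coefficient profiles then gives a global comparison of the
species x labelling-regime groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .isotope_core import residue_composition
from .sip_quant import PeptideSummary

__all__ = [
    "RESIDUE_ORDER",
    "stvalue",
    "build_design",
    "fit_aa_contributions",
    "pca_coefficient_profiles",
    "CoefficientProfile",
    "PCAResult",
]

# Fixed residue ordering for coefficient vectors and serialized outputs.
RESIDUE_ORDER = "ACDEFGHIKLMNPQRSTVWY"

_RESIDUE_CARBONS = {aa: residue_composition(aa).carbons for aa in RESIDUE_ORDER}


def stvalue(peptide: str, amino_acid: str) -> float:
    """Standardized value of one amino acid in one peptide:
    occurrences x residue carbons / peptide length."""
    if amino_acid not in _RESIDUE_CARBONS:
        raise ValueError(f"invalid residue symbol: {amino_acid!r}")
    if not peptide or set(peptide) - set(RESIDUE_ORDER):
        raise ValueError(f"invalid peptide: {peptide!r}")
    return peptide.count(amino_acid) * _RESIDUE_CARBONS[amino_acid] / len(peptide)


def build_design(summaries: Sequence[PeptideSummary]) -> pd.DataFrame:
    """Design matrix for one species x condition group.

    One row per distinct kept peptide: the 20 standardized values, the
    peptide length and the median RIA as response.
    """
    kept = [s for s in summaries if s.filter_flag == "kept"]
    if not kept:
        raise ValueError("no kept peptide summaries to build a design from")
    rows = {}
    for summary in kept:
        if summary.peptide in rows:
            continue
        row = {f"st_{aa}": stvalue(summary.peptide, aa) for aa in RESIDUE_ORDER}
        row["lenp"] = len(summary.peptide)
        row["ria"] = summary.median_ria
        rows[summary.peptide] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "peptide"
    return frame


@dataclass
class CoefficientProfile:
    """Fitted amino-acid contribution coefficients for one
    species x condition group, in RESIDUE_ORDER."""

    species: str
    condition: str
    coefficients: np.ndarray  # length 20
    intercept: float
    r_squared: float
    n: int
    absent_residues: frozenset[str] = field(default_factory=frozenset)

    @property
    def label(self) -> str:
        return f"{self.species}/{self.condition}"


def fit_aa_contributions(
    design: pd.DataFrame, species: str = "", condition: str = ""
) -> CoefficientProfile:
    """Ordinary least squares of RIA on the 20 standardized values.

    Residues absent from every peptide produce identically-zero columns;
    they get coefficient 0 and are flagged rather than left to the
    pseudo-inverse.
    """
    if len(design) < 2:
        raise ValueError("need at least two design rows to fit")
    X_full = design[[f"st_{aa}" for aa in RESIDUE_ORDER]].to_numpy(dtype=float)
    y = design["ria"].to_numpy(dtype=float)
    present = X_full.any(axis=0)
    absent = frozenset(aa for aa, p in zip(RESIDUE_ORDER, present) if not p)
    X = np.column_stack([np.ones(len(y)), X_full[:, present]])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coefficients = np.zeros(len(RESIDUE_ORDER))
    coefficients[present] = beta[1:]
    residuals = y - X @ beta
    ss_res = float(residuals @ residuals)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return CoefficientProfile(
        species=species,
        condition=condition,
        coefficients=coefficients,
        intercept=float(beta[0]),
        r_squared=r_squared,
        n=len(y),
        absent_residues=absent,
    )


@dataclass
class PCAResult:
    labels: list[str]
    scores: np.ndarray  # n_profiles x 2
    loadings: np.ndarray  # 20 x 2
    explained_variance_ratio: np.ndarray | None
    degenerate: bool = False


def pca_coefficient_profiles(profiles: Sequence[CoefficientProfile]) -> PCAResult:
    """PCA of coefficient profiles on 2 components.

    Column-centered, unscaled (the coefficients share units). The sign
    convention makes the largest-magnitude loading of each component
    positive, so scores are reproducible across runs and input orders.
    Identical profiles have no variance to decompose and are reported as
    degenerate with all-zero scores.
    """
    if len(profiles) < 3:
        raise ValueError("PCA needs at least three coefficient profiles")
    labels = [p.label for p in profiles]
    matrix = np.vstack([p.coefficients for p in profiles])
    centered = matrix - matrix.mean(axis=0)
    if not np.any(np.abs(centered) > 1e-12):
        return PCAResult(
            labels=labels,
            scores=np.zeros((len(profiles), 2)),
            loadings=np.zeros((matrix.shape[1], 2)),
            explained_variance_ratio=None,
            degenerate=True,
        )
    # SVD is deterministic up to sign; the convention below fixes it.
    _, singular, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = vt[:2].T
    if loadings.shape[1] < 2:  # fewer than 2 non-trivial directions
        loadings = np.pad(loadings, ((0, 0), (0, 2 - loadings.shape[1])))
        singular = np.pad(singular, (0, 2 - singular.size))
    for j in range(2):
        pivot = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[pivot, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = centered @ loadings
    variance = singular**2
    explained = variance[:2] / variance.sum() if variance.sum() > 0 else None
    return PCAResult(
        labels=labels,
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=explained,
        degenerate=False,
    )


def profiles_to_frame(profiles: Iterable[CoefficientProfile]) -> pd.DataFrame:
    """Serialize coefficient profiles as a long TSV-ready table."""
    rows = []
    for profile in profiles:
        for aa, coefficient in zip(RESIDUE_ORDER, profile.coefficients):
            rows.append(
                {
                    "species": profile.species,
                    "condition": profile.condition,
                    "residue": aa,
                    "coefficient": coefficient,
                    "intercept": profile.intercept,
                    "r2": profile.r_squared,
                    "n": profile.n,
                }
            )
    return pd.DataFrame(rows)
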
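"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from crossfeed_sip.isotope_core import (
    NATURAL_ISOTOPE_PATTERNS,
    ElementalComposition,
)
from crossfeed_sip.pipeline import RunConfig, run_pipeline
from crossfeed_sip.aa_regression import RESIDUE_ORDER


def enumerate_envelope(comp: ElementalComposition, c13_fraction: float) -> np.ndarray:
    """Exhaustive isotopologue enumeration oracle.

    Enumerates, per element, every way of distributing its atoms over
    its isotope classes (multinomial weights), then combines elements by
    brute-force cartesian product — no convolution involved. Only
    feasible for small compositions.
    """
    per_element: list[dict[int, float]] = []
    for element, n_atoms in sorted(comp.counts.items()):
        probs = np.array(NATURAL_ISOTOPE_PATTERNS[element], dtype=float)
        if element == "C":
            probs = np.array([1.0 - c13_fraction, c13_fraction])
        k = probs.size
        dist: dict[int, float] = {}
        for cuts in itertools.combinations(range(n_atoms + k - 1), k - 1):
            counts = []
            prev = -1
            for cut in cuts:
                counts.append(cut - prev - 1)
                prev = cut
            counts.append(n_atoms + k - 2 - prev)
            weight = math.factorial(n_atoms)
            for c, p in zip(counts, probs):
                weight = weight / math.factorial(c) * (p**c)
            offset = sum(i * c for i, c in enumerate(counts))
            dist[offset] = dist.get(offset, 0.0) + weight
        per_element.append(dist)
    total: dict[int, float] = {0: 1.0}
    for dist in per_element:
        combined: dict[int, float] = {}
        for (o1, w1), (o2, w2) in itertools.product(total.items(), dist.items()):
            combined[o1 + o2] = combined.get(o1 + o2, 0.0) + w1 * w2
        total = combined
    size = max(total) + 1
    out = np.zeros(size)
    for offset, weight in total.items():
        out[offset] = weight
    return out / out.sum()


def brute_force_digest(protein: str, max_missed: int, min_length: int) -> set[str]:
    """Digest oracle: all substrings bounded by valid cleavage sites
    (after K/R not before P, or the protein termini) whose internal
    cleavage-site count is at most max_missed."""
    bounds = [0]
    for i in range(len(protein) - 1):
        if protein[i] in "KR" and protein[i + 1] != "P":
            bounds.append(i + 1)
    bounds.append(len(protein))
    products = set()
    for a, b in itertools.combinations(range(len(bounds)), 2):
        missed = b - a - 1
        peptide = protein[bounds[a] : bounds[b]]
        if missed <= max_missed and len(peptide) >= min_length:
            products.add(peptide)
    return products


def random_peptides(rng: np.random.Generator, n: int, min_len: int = 7,
                    max_len: int = 30) -> list[str]:
    residues = np.array(list(RESIDUE_ORDER))
    return [
        "".join(rng.choice(residues, size=int(rng.integers(min_len, max_len + 1))))
        for _ in range(n)
    ]


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One small synthetic end-to-end run shared across tests."""
    outdir = tmp_path_factory.mktemp("run")
    config = RunConfig(
        outdir=str(outdir),
        seed=1,
        n_proteins=6,
        protein_length_range=(150, 250),
        make_plots=True,
    )
    report = run_pipeline(config)
    return config, report, outdir
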
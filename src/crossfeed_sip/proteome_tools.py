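"""Proteome handling: FASTA I/O, in-silico tryptic digestion, species-unique
peptide assignment against target and decoy proteomes, protein inference and
the incorporation false positive rate (iFPR).

Species assignment mirrors the protein-SIP strategy for a two-member
community: a peptide is informative only if it maps to exactly one target
species; peptides found in a decoy proteome (foreign organisms) flag
potential incorrect assignments, and their rate over all identified
peptides is the iFPR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_MAX_MISSED = 2
DEFAULT_MIN_LENGTH = 7

__all__ = [
    "ProteomeIndex",
    "SpeciesAssignment",
    "read_fasta",
    "write_fasta",
    "tryptic_digest",
    "build_index",
    "assign_species",
    "infer_proteins",
    "compute_ifpr",
    "DEFAULT_MAX_MISSED",
    "DEFAULT_MIN_LENGTH",
]


@dataclass
class ProteomeIndex:
    """Digest-peptide index of one proteome.

    Maps each tryptic peptide to the set of parent protein identifiers;
    provenance distinguishes target species from decoy databases.
    """

    species: str
    peptides: dict[str, set[str]]
    provenance: str  # "target" | "decoy"

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.peptides


@dataclass(frozen=True)
class SpeciesAssignment:
    """Verdict for one peptide against all indexed proteomes.

    verdict is one of ``species:<label>``, ``shared``, ``decoy``,
    ``unmapped``. A decoy hit dominates every other match because it
    flags a false-positive candidate.
    """

    peptide: str
    verdict: str
    proteins: frozenset[str] = field(default_factory=frozenset)

    @property
    def species(self) -> str | None:
        if self.verdict.startswith("species:"):
            return self.verdict.split(":", 1)[1]
        return None


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped) FASTA file.

    Returns (identifier, sequence) pairs in file order; sequences are
    upper-cased and a trailing stop '*' is stripped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[tuple[str, str]] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().rstrip("*")
        if not seq:
            raise ValueError(f"FASTA record {record.id!r} has an empty sequence")
        records.append((record.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for identifier, seq in records:
            fh.write(f">{identifier}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _cleavage_sites(protein: str) -> list[int]:
    """Indices after which trypsin cuts: after K/R unless followed by P."""
    sites = []
    for i, residue in enumerate(protein[:-1]):
        if residue in "KR" and protein[i + 1] != "P":
            sites.append(i + 1)
    return sites


def tryptic_digest(
    protein: str,
    max_missed: int = DEFAULT_MAX_MISSED,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[str]:
    """In-silico tryptic digestion.

    Cleaves after K or R except before P, returns the unique products
    with at most `max_missed` internal missed cleavages and length >=
    `min_length`, in order of first occurrence.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    invalid = set(protein) - STANDARD_RESIDUES
    if invalid:
        raise ValueError(f"invalid residue letters: {sorted(invalid)}")
    bounds = [0] + _cleavage_sites(protein) + [len(protein)]
    seen: dict[str, None] = {}
    for start_idx in range(len(bounds) - 1):
        for end_idx in range(start_idx + 1, min(start_idx + 2 + max_missed, len(bounds))):
            peptide = protein[bounds[start_idx] : bounds[end_idx]]
            if len(peptide) >= min_length:
                seen.setdefault(peptide, None)
    return list(seen)


def build_index(
    proteomes: Sequence[tuple[str, Sequence[tuple[str, str]], str]],
    max_missed: int = DEFAULT_MAX_MISSED,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[ProteomeIndex]:
    """Digest every proteome into a peptide -> proteins index.

    `proteomes` holds (species label, FASTA records, provenance) triples
    with provenance "target" or "decoy". Proteins containing ambiguous
    residues (B/Z/X/...) are skipped entirely: their peptides have no
    unique elemental composition downstream.
    """
    if not proteomes:
        raise ValueError("empty proteome list")
    labels = [label for label, _, _ in proteomes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species labels")
    indices = []
    for label, records, provenance in proteomes:
        if provenance not in ("target", "decoy"):
            raise ValueError(f"provenance must be 'target' or 'decoy', got {provenance!r}")
        peptides: dict[str, set[str]] = {}
        for protein_id, seq in records:
            if set(seq) - STANDARD_RESIDUES:
                continue
            for peptide in tryptic_digest(seq, max_missed, min_length):
                peptides.setdefault(peptide, set()).add(protein_id)
        indices.append(ProteomeIndex(species=label, peptides=peptides, provenance=provenance))
    return indices


def assign_species(peptide: str, indices: Sequence[ProteomeIndex]) -> SpeciesAssignment:
    """Assign one peptide to a species, shared, decoy or unmapped.

    Decoy matches dominate (conservative false-positive accounting), a
    single target hit gives a species verdict, two or more target hits
    give ``shared``.
    """
    if not peptide:
        raise ValueError("empty peptide")
    decoy_proteins: set[str] = set()
    target_hits: dict[str, set[str]] = {}
    for index in indices:
        proteins = index.peptides.get(peptide)
        if proteins is None:
            continue
        if index.provenance == "decoy":
            decoy_proteins |= proteins
        else:
            target_hits[index.species] = set(proteins)
    if decoy_proteins:
        return SpeciesAssignment(peptide, "decoy", frozenset(decoy_proteins))
    if len(target_hits) == 1:
        (species, proteins), = target_hits.items()
        return SpeciesAssignment(peptide, f"species:{species}", frozenset(proteins))
    if len(target_hits) >= 2:
        all_proteins = frozenset().union(*target_hits.values())
        return SpeciesAssignment(peptide, "shared", all_proteins)
    return SpeciesAssignment(peptide, "unmapped")


def infer_proteins(assignments: Iterable[SpeciesAssignment]) -> dict[str, set[str]]:
    """Protein inference: report a protein iff at least two distinct
    species-unique peptides map to it."""
    support: dict[tuple[str, str], set[str]] = {}
    for assignment in assignments:
        species = assignment.species
        if species is None:
            continue
        for protein in assignment.proteins:
            support.setdefault((species, protein), set()).add(assignment.peptide)
    inferred: dict[str, set[str]] = {}
    for (species, protein), peptides in support.items():
        if len(peptides) >= 2:
            inferred.setdefault(species, set()).add(protein)
    return inferred


def compute_ifpr(n_decoy_labelled: int, n_total: int) -> float:
    """Incorporation false positive rate: decoy-flagged / total peptides."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_decoy_labelled <= n_total):
        raise ValueError("n_decoy_labelled must be in [0, n_total]")
    return n_decoy_labelled / n_total
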
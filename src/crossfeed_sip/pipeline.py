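"""End-to-end orchestration: generate (or load) data, assign species,
estimate RIAs, filter, regress, run PCA, correct metabolite MIDs and
write a run report.

Every stage writes a plain TSV/JSON artifact into the run directory so
each step is independently inspectable and re-runnable; the report
collects counts and summaries that are all traceable to those files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import aa_regression, mid_tools, proteome_tools, sip_quant, synthetic_community
from .isotope_core import parse_formula, peptide_composition

logger = logging.getLogger("crossfeed_sip")

LABELLED_CONDITIONS = ("gal_labelled", "glc_labelled")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "make_report"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either `synthetic` is true (a scenario is generated from `seed`) or
    explicit input paths are given: target/decoy FASTA files plus an
    envelope TSV and optionally a MID TSV.
    """

    outdir: str
    seed: int = 0
    synthetic: bool = True
    n_proteins: int = 25
    protein_length_range: tuple[int, int] = (200, 400)
    target_fastas: dict[str, str] = field(default_factory=dict)  # species -> path
    decoy_fastas: dict[str, str] = field(default_factory=dict)
    envelope_path: str | None = None
    mid_path: str | None = None
    max_missed: int = proteome_tools.DEFAULT_MAX_MISSED
    min_length: int = proteome_tools.DEFAULT_MIN_LENGTH
    cv_threshold: float = sip_quant.CV_THRESHOLD
    n_replicates: int = 3
    make_plots: bool = True

    def validate(self) -> None:
        if not self.synthetic:
            if not self.target_fastas or self.envelope_path is None:
                raise ValueError(
                    "non-synthetic runs need target_fastas and envelope_path"
                )
            for path in [*self.target_fastas.values(), *self.decoy_fastas.values(),
                         self.envelope_path, self.mid_path]:
                if path is not None and not Path(path).exists():
                    raise FileNotFoundError(path)
        if not (0 < self.cv_threshold < 10):
            raise ValueError("cv_threshold out of range")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        if "protein_length_range" in payload:
            payload["protein_length_range"] = tuple(payload["protein_length_range"])
        return cls(**payload)


@dataclass
class RunReport:
    """Per-stage record counts and headline summaries of a run."""

    n_observed_peptides: int
    assignment_counts: dict[str, int]  # species:<label>/shared/decoy/unmapped
    ifpr: float
    n_summaries: int
    filter_counts: dict[str, int]
    ria_distributions: list[dict]
    profiles: list[dict]
    pca: dict | None
    mids: list[dict]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _simulate_stage(config: RunConfig, outdir: Path):
    proteomes = synthetic_community.generate_proteomes(
        seed=config.seed,
        n_proteins=config.n_proteins,
        length_range=config.protein_length_range,
    )
    scenario = synthetic_community.default_scenario(proteomes, seed=config.seed)
    scenario.n_replicates = config.n_replicates
    envelopes, mids, truth = synthetic_community.synthesize_observations(
        proteomes, scenario
    )
    for species, records in proteomes.items():
        proteome_tools.write_fasta(records, outdir / f"{species}.fasta")
    envelopes.to_csv(outdir / "envelopes.tsv", sep="\t", index=False)
    mids.to_csv(outdir / "mids.tsv", sep="\t", index=False)
    (outdir / "ground_truth.json").write_text(truth.to_json())
    (outdir / "scenario.json").write_text(scenario.to_json())
    return proteomes, envelopes, mids


def _load_inputs(config: RunConfig):
    proteomes = {
        species: proteome_tools.read_fasta(path)
        for species, path in config.target_fastas.items()
    }
    decoys = {
        species: proteome_tools.read_fasta(path)
        for species, path in config.decoy_fastas.items()
    }
    envelopes = pd.read_csv(config.envelope_path, sep="\t")
    mids = pd.read_csv(config.mid_path, sep="\t") if config.mid_path else pd.DataFrame()
    return proteomes, decoys, envelopes, mids


def _assign_stage(envelopes, indices, outdir: Path):
    peptides = sorted(envelopes["peptide"].unique())
    assignments = {p: proteome_tools.assign_species(p, indices) for p in peptides}
    frame = pd.DataFrame(
        {
            "peptide": peptides,
            "verdict": [assignments[p].verdict for p in peptides],
            "species": [assignments[p].species or "" for p in peptides],
            "protein_ids": [
                ";".join(sorted(assignments[p].proteins)) for p in peptides
            ],
        }
    )
    frame.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    return assignments


def _ria_stage(envelopes, assignments, outdir: Path) -> pd.DataFrame:
    """Estimate one RIA per peptide x condition x replicate observation.

    Only species-unique peptides are carried forward: shared peptides
    have no species identity and decoy hits are false-positive flags.
    """
    rows = []
    comp_cache = {}
    grouped = envelopes.sort_values("offset").groupby(
        ["peptide", "condition", "replicate"], sort=True
    )
    for (peptide, condition, replicate), group in grouped:
        assignment = assignments[peptide]
        species = assignment.species
        if species is None:
            continue
        if peptide not in comp_cache:
            comp_cache[peptide] = peptide_composition(peptide)
        intensities = np.zeros(int(group["offset"].max()) + 1)
        intensities[group["offset"].to_numpy()] = group["intensity"].to_numpy()
        ria = sip_quant.estimate_ria(intensities, comp_cache[peptide])
        rows.append(
            {
                "peptide": peptide,
                "species": species,
                "condition": condition,
                "replicate": replicate,
                "ria": ria,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "ria.tsv", sep="\t", index=False)
    return frame


def _filter_stage(ria_frame, config: RunConfig, outdir: Path):
    groups: dict[tuple[str, str, str], dict[int, float]] = {}
    for row in ria_frame.itertuples():
        groups.setdefault((row.peptide, row.species, row.condition), {})[
            int(row.replicate)
        ] = row.ria
    summaries = sip_quant.filter_and_summarize(
        groups, n_replicates=config.n_replicates, cv_threshold=config.cv_threshold
    )
    frame = pd.DataFrame(
        [
            {
                "peptide": s.peptide,
                "species": s.species,
                "condition": s.condition,
                **{
                    f"ria_rep{r}": s.replicate_rias.get(r, np.nan)
                    for r in range(1, config.n_replicates + 1)
                },
                "cv": np.nan if s.cv is None else s.cv,
                "median_ria": np.nan if s.median_ria is None else s.median_ria,
                "filter_flag": s.filter_flag,
            }
            for s in summaries
        ]
    )
    frame.to_csv(outdir / "summaries.tsv", sep="\t", index=False)
    return summaries


def _regression_stage(summaries, outdir: Path):
    profiles = []
    group_labels = sorted(
        {(s.species, s.condition) for s in summaries if s.condition in LABELLED_CONDITIONS}
    )
    for species, condition in group_labels:
        group = [
            s
            for s in summaries
            if s.species == species and s.condition == condition and s.filter_flag == "kept"
        ]
        if len(group) < 2:
            logger.warning("skipping regression for %s/%s: %d kept peptides",
                           species, condition, len(group))
            continue
        design = aa_regression.build_design(group)
        profiles.append(aa_regression.fit_aa_contributions(design, species, condition))
    if profiles:
        aa_regression.profiles_to_frame(profiles).to_csv(
            outdir / "profiles.tsv", sep="\t", index=False
        )
    return profiles


def _pca_stage(profiles, outdir: Path):
    if len(profiles) < 3:
        logger.warning("skipping PCA: only %d coefficient profiles", len(profiles))
        return None
    result = aa_regression.pca_coefficient_profiles(profiles)
    explained = (
        [np.nan, np.nan]
        if result.explained_variance_ratio is None
        else list(result.explained_variance_ratio)
    )
    frame = pd.DataFrame(
        {
            "profile": result.labels,
            "pc1": result.scores[:, 0],
            "pc2": result.scores[:, 1],
            "explained_variance_1": explained[0],
            "explained_variance_2": explained[1],
        }
    )
    frame.to_csv(outdir / "pca.tsv", sep="\t", index=False)
    return result


def _mid_stage(mids: pd.DataFrame, outdir: Path) -> list[dict]:
    if mids.empty:
        logger.warning("no MID table: metabolite section omitted")
        return []
    rows = []
    grouped = mids.sort_values("m_offset").groupby(
        ["metabolite", "condition", "replicate"], sort=True
    )
    for (metabolite, condition, replicate), group in grouped:
        formula = group["fragment_formula"].iloc[0]
        n_tracer = int(group["n_tracer_carbons"].iloc[0])
        intensities = np.zeros(int(group["m_offset"].max()) + 1)
        intensities[group["m_offset"].to_numpy()] = group["intensity"].to_numpy()
        raw = mid_tools.MIDVector(
            metabolite=metabolite,
            fragment=parse_formula(formula),
            n_tracer_carbons=n_tracer,
            intensities=tuple(intensities),
            state="raw",
        )
        corrected = mid_tools.correct_mid(raw)
        fractions = mid_tools.labelled_fraction(corrected)
        row = {
            "metabolite": metabolite,
            "condition": condition,
            "replicate": int(replicate),
            **{f"M{i}": v for i, v in enumerate(fractions.fractions)},
            "total_labelled": fractions.total_labelled,
            "fully_labelled": fractions.fully_labelled,
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "mids_corrected.tsv", sep="\t", index=False)
    return rows


def make_report(
    envelopes, assignments, summaries, profiles, pca_result, mid_rows, outdir: Path,
    make_plots: bool = True,
) -> RunReport:
    """Assemble the run report and, optionally, the summary figures."""
    assignment_counts: dict[str, int] = {}
    for assignment in assignments.values():
        assignment_counts[assignment.verdict] = (
            assignment_counts.get(assignment.verdict, 0) + 1
        )
    n_total = len(assignments)
    ifpr = proteome_tools.compute_ifpr(assignment_counts.get("decoy", 0), n_total)
    filter_counts: dict[str, int] = {}
    for s in summaries:
        filter_counts[s.filter_flag] = filter_counts.get(s.filter_flag, 0) + 1
    distributions = []
    for species, condition in sorted({(s.species, s.condition) for s in summaries}):
        try:
            dist = sip_quant.ria_distribution(summaries, species, condition)
        except ValueError:
            continue
        distributions.append(asdict(dist))
    profile_dicts = [
        {
            "species": p.species,
            "condition": p.condition,
            "coefficients": list(map(float, p.coefficients)),
            "intercept": p.intercept,
            "r2": p.r_squared,
            "n": p.n,
        }
        for p in profiles
    ]
    pca_dict = None
    if pca_result is not None:
        pca_dict = {
            "labels": pca_result.labels,
            "scores": pca_result.scores.tolist(),
            "explained_variance_ratio": (
                None
                if pca_result.explained_variance_ratio is None
                else list(map(float, pca_result.explained_variance_ratio))
            ),
            "degenerate": pca_result.degenerate,
        }
    report = RunReport(
        n_observed_peptides=n_total,
        assignment_counts=assignment_counts,
        ifpr=ifpr,
        n_summaries=len(summaries),
        filter_counts=filter_counts,
        ria_distributions=distributions,
        profiles=profile_dicts,
        pca=pca_dict,
        mids=mid_rows,
    )
    (outdir / "report.json").write_text(report.to_json())
    if make_plots:
        _write_plots(distributions, profiles, pca_result, mid_rows, outdir)
    return report


def _write_plots(distributions, profiles, pca_result, mid_rows, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if distributions:
        fig, ax = plt.subplots(figsize=(7, 4))
        labels = [f"{d['species']}\n{d['condition']}" for d in distributions]
        medians = [d["median"] for d in distributions]
        q1 = [d["q1"] for d in distributions]
        q3 = [d["q3"] for d in distributions]
        x = np.arange(len(labels))
        ax.errorbar(
            x, medians,
            yerr=[np.subtract(medians, q1), np.subtract(q3, medians)],
            fmt="o", capsize=4,
        )
        for xi, d in zip(x, distributions):
            ax.annotate(str(d["n"]), (xi, d["q3"]), textcoords="offset points",
                        xytext=(0, 6), ha="center")
        ax.set_xticks(x, labels, fontsize=8)
        ax.set_ylabel("median RIA (quartiles)")
        fig.tight_layout()
        fig.savefig(outdir / "ria_distributions.svg")
        plt.close(fig)
    if profiles:
        fig, axes = plt.subplots(
            len(profiles), 1, figsize=(8, 2.2 * len(profiles)), sharex=True, squeeze=False
        )
        x = np.arange(len(aa_regression.RESIDUE_ORDER))
        for ax, profile in zip(axes[:, 0], profiles):
            ax.bar(x, profile.coefficients)
            ax.set_title(profile.label, fontsize=8)
        axes[-1, 0].set_xticks(x, list(aa_regression.RESIDUE_ORDER))
        fig.tight_layout()
        fig.savefig(outdir / "aa_coefficients.svg")
        plt.close(fig)
    if pca_result is not None and not pca_result.degenerate:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(pca_result.scores[:, 0], pca_result.scores[:, 1])
        for label, (pc1, pc2) in zip(pca_result.labels, pca_result.scores[:, :2]):
            ax.annotate(label, (pc1, pc2), fontsize=7)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        fig.tight_layout()
        fig.savefig(outdir / "pca.svg")
        plt.close(fig)
    if mid_rows:
        frame = pd.DataFrame(mid_rows)
        grouped = frame.groupby(["metabolite", "condition"])["total_labelled"].mean()
        fig, ax = plt.subplots(figsize=(7, 4))
        grouped.plot.bar(ax=ax)
        ax.set_ylabel("mean total labelled fraction")
        fig.tight_layout()
        fig.savefig(outdir / "mid_labelled_fractions.svg")
        plt.close(fig)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage in order and return the report.

    Identical config and seed reproduce identical outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.synthetic:
        proteomes, envelopes, mids = _simulate_stage(config, outdir)
        targets = [
            (sp, proteomes[sp], "target") for sp in ("speciesA", "speciesB")
        ]
        decoys = [("decoy", proteomes["decoy"], "decoy")]
    else:
        target_records, decoy_records, envelopes, mids = _load_inputs(config)
        targets = [(sp, recs, "target") for sp, recs in target_records.items()]
        decoys = [(sp, recs, "decoy") for sp, recs in decoy_records.items()]
    indices = proteome_tools.build_index(
        [*targets, *decoys], max_missed=config.max_missed, min_length=config.min_length
    )
    assignments = _assign_stage(envelopes, indices, outdir)
    ria_frame = _ria_stage(envelopes, assignments, outdir)
    summaries = _filter_stage(ria_frame, config, outdir)
    profiles = _regression_stage(summaries, outdir)
    pca_result = _pca_stage(profiles, outdir)
    mid_rows = _mid_stage(mids, outdir)
    return make_report(
        envelopes, assignments, summaries, profiles, pca_result, mid_rows, outdir,
        make_plots=config.make_plots,
    )
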
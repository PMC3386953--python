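"""End-to-end orchestration: simulate -> preprocess -> expression ->
splicing -> enrichment, driven by a single config, with deterministic
outputs for a fixed seed.

Every run writes its resolved configuration next to the outputs.  The run
report deliberately carries no wall-clock timestamp so that two runs with
the same config and seed produce byte-identical output trees; timing goes
to the log instead.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, ExonSpliceError
from .expression import (
    fold_change_filter,
    moderated_t_test,
    summarize_transcripts,
    venn_partition,
)
from .enrichment import annotation_enrichment, footprint_overlap_test
from .model_io import (
    IntensityMatrix,
    ProbeAnnotation,
    SampleDesign,
    read_design_tsv,
    read_gmt,
    read_intensity_tsv,
    read_probe_annotation,
    write_design_tsv,
    write_gene_list,
    write_intensity_tsv,
    write_probe_annotation,
)
from .preprocess import (
    apply_probe_effects,
    background_correct,
    detect_present,
    drop_cross_hyb,
    estimate_probe_effects,
)
from .splicing import consensus_splicing_calls, mads_test, midas_test, splicing_index
from .synthetic import SimulationConfig, simulate_experiment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; see :func:`load_pipeline_config`."""

    out_dir: str
    seed: int = 0
    # either simulate...
    simulation: SimulationConfig | None = None
    # ...or read these three
    intensities: str | None = None
    annotation: str | None = None
    design: str | None = None
    # optional enrichment inputs
    gene_sets: str | None = None  # GMT for GO-style enrichment
    footprint_targets: str | None = None  # GMT of splicing-factor targets
    # contrasts as (condition_a, condition_b) pairs; None = all vs previous
    contrasts: list[tuple[str, str]] | None = None
    fold_threshold: float = 2.0
    alpha_expression: float = 0.05
    alpha_splicing: float = 0.01
    z_threshold: float = 2.0
    min_replicates: int = 3
    min_genes: int = 10
    floor_epsilon: float = 1.0
    require_present: bool = True
    strict_fold: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha_splicing < 1:
            raise ConfigError("alpha_splicing must be in (0, 1)")
        if not 0 < self.alpha_expression <= 1:
            raise ConfigError("alpha_expression must be in (0, 1]")
        if self.fold_threshold <= 1:
            raise ConfigError("fold_threshold must be > 1")
        if self.min_genes < 1:
            raise ConfigError("min_genes must be >= 1")
        has_sim = self.simulation is not None
        has_files = all(
            x is not None for x in (self.intensities, self.annotation, self.design)
        )
        if not has_sim and not has_files:
            raise ConfigError(
                "config must provide either a simulation section or "
                "intensities+annotation+design paths"
            )
        for name in ("intensities", "annotation", "design", "gene_sets",
                     "footprint_targets"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")


def load_pipeline_config(path: str | Path, **overrides: Any) -> PipelineConfig:
    """Load a YAML pipeline config; keyword overrides win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    raw.update(overrides)
    sim = raw.pop("simulation", None)
    if sim is not None:
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(sim) - known
        if bad:
            raise ConfigError(f"unknown simulation keys: {sorted(bad)}")
        sim = SimulationConfig(**sim)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    bad = set(raw) - known
    if bad:
        raise ConfigError(f"unknown config keys: {sorted(bad)}")
    if raw.get("contrasts"):
        raw["contrasts"] = [parse_contrast(c) for c in raw["contrasts"]]
    return PipelineConfig(simulation=sim, **raw)


def parse_contrast(spec: Any) -> tuple[str, str]:
    """Accept 'B:A' strings (b over a) or (a, b) pairs."""
    if isinstance(spec, str):
        parts = spec.split(":")
        if len(parts) != 2 or not all(parts):
            raise ConfigError(f"bad contrast {spec!r}; expected 'B:A'")
        return (parts[1], parts[0])
    pair = tuple(spec)
    if len(pair) != 2:
        raise ConfigError(f"bad contrast {spec!r}")
    return (str(pair[0]), str(pair[1]))


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    seed: int
    version: str
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    contrasts: dict[str, dict[str, Any]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _contrast_tag(pair: tuple[str, str]) -> str:
    return f"{pair[1]}_vs_{pair[0]}"


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage; stage failures abort with the stage name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, version=__version__)
    stage = "setup"
    try:
        # -- inputs ---------------------------------------------------------
        stage = "simulate" if config.simulation is not None else "load"
        if config.simulation is not None:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            matrix, annotation, design, truth = simulate_experiment(sim_cfg)
            write_intensity_tsv(matrix, out / "intensities.tsv")
            write_probe_annotation(annotation, out / "annotation.tsv")
            write_design_tsv(design, out / "design.tsv")
            _write_truth(truth, out)
        else:
            matrix = read_intensity_tsv(config.intensities)
            annotation = read_probe_annotation(config.annotation)
            design = read_design_tsv(config.design)
        report.stages[stage] = {
            "n_probes": matrix.shape[0],
            "n_samples": matrix.shape[1],
            "n_transcripts": len(annotation.transcript_ids),
            "n_probesets": len(annotation.probeset_ids),
        }

        # -- preprocess -----------------------------------------------------
        stage = "preprocess"
        presence = detect_present(
            matrix,
            annotation,
            design,
            z_threshold=config.z_threshold,
            min_replicates=config.min_replicates,
        )
        corrected = background_correct(
            matrix, annotation, floor_epsilon=config.floor_epsilon
        )
        corrected, xhyb_report = drop_cross_hyb(corrected, annotation)
        genomic_ids = [
            p
            for p in corrected.values.index
            if p in set(annotation.genomic["probe_id"])
        ]
        corrected = corrected.subset_probes(genomic_ids)
        effects = estimate_probe_effects(corrected, annotation)
        corrected = apply_probe_effects(corrected, effects)
        write_intensity_tsv(corrected, out / "corrected.tsv")
        effects.affinities.rename_axis("probe_id").to_csv(
            out / "probe_effects.tsv", sep="\t", lineterminator="\n"
        )
        presence.present.rename_axis("transcript_id").to_csv(
            out / "presence.tsv", sep="\t", lineterminator="\n"
        )
        report.stages[stage] = {
            "n_cross_hyb_removed": len(xhyb_report.removed_probes),
            "n_probesets_emptied": len(xhyb_report.emptied_probesets),
            "n_present_any": int(presence.present.any(axis=1).sum()),
            "probe_effects_converged": effects.converged,
        }

        # -- presence Venn --------------------------------------------------
        stage = "presence_venn"
        conditions = design.conditions
        venn = venn_partition(
            {c: presence.present_transcripts(c) for c in conditions}
        )
        (out / "presence_venn.json").write_text(
            json.dumps(
                {"|".join(k): len(v) for k, v in sorted(venn.regions.items())},
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        report.stages[stage] = {
            "|".join(k): len(v) for k, v in sorted(venn.regions.items())
        }

        # -- expression -----------------------------------------------------
        stage = "expression"
        expr = summarize_transcripts(corrected, annotation)
        expr.to_csv(out / "expression.tsv", sep="\t", lineterminator="\n")
        contrasts = config.contrasts or [
            (conditions[i], conditions[j])
            for i in range(len(conditions))
            for j in range(i + 1, len(conditions))
        ]
        tx2gene = annotation.transcript_to_gene()
        for pair in contrasts:
            tag = _contrast_tag(pair)
            de = moderated_t_test(expr, design, pair)
            de = fold_change_filter(
                de,
                threshold_fold=config.fold_threshold,
                alpha=config.alpha_expression,
                strict=config.strict_fold,
            )
            de.table.rename_axis("transcript_id").to_csv(
                out / f"de_{tag}.tsv", sep="\t", lineterminator="\n"
            )
            sig_tx = de.significant_transcripts()
            report.contrasts.setdefault(tag, {})["n_de_transcripts"] = len(
                sig_tx
            )
            report.contrasts[tag]["n_de_genes"] = len(
                {tx2gene[t] for t in sig_tx}
            )

        # -- splicing -------------------------------------------------------
        stage = "splicing"
        for pair in contrasts:
            tag = _contrast_tag(pair)
            si = splicing_index(
                corrected,
                expr,
                annotation,
                presence=presence if config.require_present else None,
                conditions=pair if config.require_present else None,
            )
            p_midas = midas_test(si, design, conditions=pair)["p_value"]
            p_mads = mads_test(si, design, pair)["p_value"]
            calls = consensus_splicing_calls(
                p_midas,
                p_mads,
                si.probeset_to_transcript,
                alpha=config.alpha_splicing,
            )
            calls.table.to_csv(
                out / f"as_calls_{tag}.tsv", sep="\t", lineterminator="\n"
            )
            as_tx = calls.called_transcripts
            rep = report.contrasts.setdefault(tag, {})
            rep["n_probesets_tested"] = int(len(calls.table))
            rep["n_as_probesets"] = len(calls.called_probesets)
            rep["n_as_transcripts"] = len(as_tx)
            as_genes = sorted({tx2gene[t] for t in as_tx})
            rep["n_as_genes"] = len(as_genes)
            if rep.get("n_de_genes"):
                rep["as_to_de_gene_ratio"] = rep["n_as_genes"] / rep["n_de_genes"]
            write_gene_list(as_genes, out / f"as_genes_{tag}.txt")

            # -- enrichment per contrast ---------------------------------
            # universe = genes present in either compared condition
            universe = sorted(
                {
                    tx2gene[t]
                    for c in pair
                    for t in presence.present_transcripts(c)
                    if t in tx2gene.index
                }
            )
            write_gene_list(universe, out / f"universe_{tag}.txt")
            if config.gene_sets and as_genes:
                sets = read_gmt(config.gene_sets)
                table = annotation_enrichment(
                    [g for g in as_genes if g in set(universe)],
                    sets,
                    universe,
                    min_genes=config.min_genes,
                )
                table.to_csv(
                    out / f"enrichment_{tag}.tsv",
                    sep="\t",
                    index=False,
                    lineterminator="\n",
                )
                rep["n_enriched_sets"] = int(
                    (table["p_adjusted"] < config.alpha_expression).sum()
                ) if len(table) else 0
            if config.footprint_targets and as_genes:
                targets = read_gmt(config.footprint_targets)
                fp_rows = []
                for gs in targets:
                    try:
                        res = footprint_overlap_test(
                            [g for g in as_genes if g in set(universe)],
                            gs.members,
                            universe,
                        )
                    except ExonSpliceError as exc:
                        logger.warning(
                            "footprint %s skipped: %s", gs.name, exc
                        )
                        continue
                    fp_rows.append(
                        {
                            "target_set": gs.name,
                            "universe_size": res.universe_size,
                            "target_size": res.target_size,
                            "query_size": res.query_size,
                            "overlap": res.overlap,
                            "expected": res.expected,
                            "p_value": res.p_value,
                            "overlap_genes": ",".join(res.overlap_genes),
                        }
                    )
                pd.DataFrame(fp_rows).to_csv(
                    out / f"footprint_{tag}.tsv",
                    sep="\t",
                    index=False,
                    lineterminator="\n",
                )
    except ExonSpliceError as exc:
        (out / "INCOMPLETE").write_text(f"failed at stage {stage}: {exc}\n")
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    # -- provenance ---------------------------------------------------------
    resolved = dataclasses.asdict(config)
    (out / "config.resolved.yaml").write_text(
        yaml.safe_dump(resolved, sort_keys=True)
    )
    (out / "run_report.json").write_text(report.to_json() + "\n")
    return report


def _write_truth(truth, out: Path) -> None:
    truth.abundance.rename_axis("transcript_id").to_csv(
        out / "truth_abundance.tsv", sep="\t", lineterminator="\n"
    )
    truth.psi.rename_axis("probeset_id").to_csv(
        out / "truth_psi.tsv", sep="\t", lineterminator="\n"
    )
    truth.presence.rename_axis("transcript_id").to_csv(
        out / "truth_presence.tsv", sep="\t", lineterminator="\n"
    )
    truth.affinity.rename_axis("probe_id").to_csv(
        out / "truth_affinity.tsv", sep="\t", lineterminator="\n"
    )
    (out / "truth_events.json").write_text(
        json.dumps(
            {
                "de_transcripts": truth.de_transcripts,
                "as_transcripts": truth.as_transcripts,
                "as_probesets": truth.as_probesets,
                "cross_hyb_probes": truth.cross_hyb_probes,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
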
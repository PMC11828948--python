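"""End-to-end orchestration and programmatic fixture generation."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import diagnostics, io, scoring
from .containers import ScreenCounts
from .simulate import SimConfig, build_sim_library, simulate_counts, simulate_fastq, simulate_truth

log = logging.getLogger("cas13gi")

__all__ = ["PipelineParams", "run_pipeline", "make_fixtures"]


@dataclass
class PipelineParams:
    pseudocount: float = 1.0
    low_count_fraction: float = 0.10
    gi_threshold: float = scoring.GI_THRESHOLD
    fdr_threshold: float = scoring.FDR_THRESHOLD
    filter_mode: str = "signed"
    permutations: int = 999

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _write_scores(result: scoring.ScoreResult, out: Path) -> list[Path]:
    paths = []

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=kw.pop("index", False))
        paths.append(p)

    # tau in log2 units relative to NTC-NTC; GI in the same tau units
    save(result.tau.tau, "tau.tsv", index=True)
    save(result.phenotypes, "phenotypes.tsv")
    save(result.guide_gi, "guide_gi.tsv")
    save(result.records, "gi_records.tsv")
    save(result.edges, "network_edges.tsv")
    return paths


def run_pipeline(
    config: SimConfig,
    out_dir: str | Path,
    params: PipelineParams | None = None,
    resume: bool = False,
) -> dict:
    """simulate -> score -> diagnose on one synthetic screen.

    Writes each stage's outputs plus a manifest of parameters, seed and
    output hashes; identical config and seed reproduce identical outputs.
    With ``resume``, stages whose outputs already exist are skipped.
    """
    params = params or PipelineParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_outputs: dict[str, list[Path]] = {}

    # --- design + simulate
    counts_paths = [out / "counts.tsv", out / "samples.tsv", out / "annotations.tsv"]
    lib_path = out / "library_elements.csv"
    if resume and all(p.exists() for p in counts_paths + [lib_path]):
        log.info("simulate: outputs present, skipping")
        library = io.read_library_csv(lib_path, config.strategy)
        screen = ScreenCounts.read(*counts_paths)
        truth = simulate_truth(config, library)
    else:
        log.info("simulate: strategy=%s seed=%d", config.strategy, config.seed)
        library = build_sim_library(config)
        truth = simulate_truth(config, library)
        screen = simulate_counts(truth, library, config)
        io.write_elements_csv(library.elements, lib_path)
        io.write_constructs_csv(library, out / "library_constructs.csv")
        screen.write(*counts_paths)
        truth_df = pd.DataFrame(
            [dict(gene=g, condition=c, effect=v) for (g, c), v in truth.gene_effect.items()]
        )
        truth_df.to_csv(out / "truth_gene_effects.tsv", sep="\t", index=False)
    stage_outputs["design"] = [lib_path, out / "library_constructs.csv"]
    stage_outputs["simulate"] = counts_paths + [out / "truth_gene_effects.tsv"]

    # --- score
    score_done = (out / "gi_records.tsv").exists()
    if resume and score_done:
        log.info("score: outputs present, skipping")
        stage_outputs["score"] = [out / "gi_records.tsv"]
        result = None
    else:
        log.info("score: %d constructs", len(screen.counts))
        result = scoring.score_screen(
            screen,
            pseudocount=params.pseudocount,
            low_count_fraction=params.low_count_fraction,
            gi_threshold=params.gi_threshold,
            fdr_threshold=params.fdr_threshold,
            filter_mode=params.filter_mode,
        )
        stage_outputs["score"] = _write_scores(result, out)

    # --- diagnose
    diag_path = out / "diagnostics.json"
    if result is not None and not (resume and diag_path.exists()):
        log.info("diagnose")
        summary: dict = {}
        for condition in result.tau.conditions():
            entry: dict = {}
            try:
                entry["replicate_r"] = diagnostics.replicate_correlation(result.tau, condition)
            except ValueError:
                entry["replicate_r"] = None
            try:
                r, _ = diagnostics.position_correlation(result.phenotypes, condition)
                entry["position_r"] = None if pd.isna(r) else r
            except ValueError:
                entry["position_r"] = None
            reports = {}
            for orientation in scoring.ORIENTATIONS:
                prof = diagnostics.partner_profiles(result.tau, orientation, condition)
                if prof.shape[0] >= 2 and prof.shape[1] >= diagnostics.MIN_SHARED:
                    rep = diagnostics.interference_score(
                        prof, permutations=params.permutations,
                        seed=config.seed, orientation=orientation,
                    )
                    reports[orientation] = rep
                    entry[f"interference_score_{orientation}"] = rep.score
                    entry[f"interference_p_{orientation}"] = rep.p_value
            if len(reports) == 2:
                entry["orientation_asymmetry"] = diagnostics.orientation_asymmetry(
                    reports["pos1"], reports["pos2"]
                )
            summary[condition] = entry
        with open(diag_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        stage_outputs["diagnose"] = [diag_path]

    manifest_path = out / "manifest.json"
    io.write_manifest(
        manifest_path, stage_outputs,
        params=dict(params.as_dict(), strategy=config.strategy), seed=config.seed,
    )
    return dict(out_dir=str(out), manifest=str(manifest_path),
                stages=sorted(stage_outputs))


def make_fixtures(size: str, seed: int, out_dir: str | Path) -> Path:
    """Generate a self-contained test fixture directory.

    ``tiny``: 2 genes x 3 guides + 4 NTCs, 1 replicate, counts only.
    ``small``: 6 genes x 9 guides + 10 NTCs, 2 replicates, counts + FASTQ.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if size == "tiny":
        config = SimConfig(
            genes=("GENEA", "GENEB"), guides_per_gene=3, ntc_count=4,
            replicates=1, coverage=300, seed=seed,
        )
        fastq = False
    elif size == "small":
        config = SimConfig(
            genes=("ABL1", "GAB2", "SOS1", "PTPN1", "NF1", "SPRED2"),
            guides_per_gene=9, ntc_count=10, replicates=2,
            coverage=300, seed=seed,
        )
        fastq = True
    else:
        raise ValueError(f"unknown fixture size {size!r}")

    library = build_sim_library(config)
    truth = simulate_truth(config, library)
    screen = simulate_counts(truth, library, config)
    io.write_elements_csv(library.elements, out / "library_elements.csv")
    io.write_constructs_csv(library, out / "library_constructs.csv")
    screen.write(out / "counts.tsv", out / "samples.tsv", out / "annotations.tsv")
    eff = pd.Series(truth.guide_efficiency, name="efficiency")
    eff.rename_axis("element_id").to_csv(out / "truth_efficiencies.tsv", sep="\t")
    (out / "config.json").write_text(config.to_json())
    if fastq:
        truth_counts, report = simulate_fastq(
            truth, library, config, out / "reads_R1.fastq", out / "reads_R2.fastq",
            n_reads=2000,
        )
        truth_counts.to_csv(out / "truth_read_counts.tsv", sep="\t")
        (out / "fastq_report.json").write_text(json.dumps(report))
    return out
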
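"""End-to-end pipeline orchestration with a reproducible run manifest.

Stages run in a fixed order (simulate, diffexp, map-ids, integrate,
prioritize, crossstudy, enrich), each optional, each reading and
writing TSV files under the run's output directory.  The manifest
records the package version, every threshold applied, per-stage row
counts and a content digest for every output file, so that two runs
with the same configuration are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .datasets import reference_external_tables
from .enrichment import build_term_network, hypergeom_enrich
from .idmap import resolve_ids
from .integration import cross_study_overlap, merge_omics, prioritize
from .matrix import IntensityMatrix, read_tsv, write_tsv
from .proteomics import classify_significant, run_differential
from .simulate import SimConfig, write_simulation

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = (
    "simulate", "diffexp", "map_ids", "integrate", "prioritize", "crossstudy", "enrich",
)


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    File paths default to the names the simulate stage writes, so a
    fully synthetic run needs only an output directory and a seed.
    All thresholds are echoed into the run manifest.
    """

    outdir: str = "rvomics_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # synthetic-data scale
    n_proteins: int = 3100
    n_per_group: int = 5
    frac_de: float = 0.10
    # proteomic preprocessing / statistics
    quantile: float = 0.01
    min_pos: int = 3
    ordinary_t: bool = False
    median_normalize: bool = False
    # significance and prioritization thresholds
    q_max: float = 0.05
    z_abs: float = 1.96
    t_fdr: float = 0.05
    t_fc: float = 1.5
    jaccard_min: float = 0.25
    # optional explicit inputs (override the simulate-stage outputs)
    matrix_path: str | None = None
    design_path: str | None = None
    transcripts_path: str | None = None
    mapping_path: str | None = None
    annotation_path: str | None = None
    overrides_path: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        data.update(overrides)
        return cls(**data)

    def to_toml(self, path: str | Path) -> None:
        """Serialize losslessly as flat TOML (round-trips via from_toml)."""
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            elif isinstance(v, (int, float)):
                lines.append(f"{f.name} = {v}")
            elif isinstance(v, tuple):
                items = ", ".join(json.dumps(x) for x in v)
                lines.append(f"{f.name} = [{items}]")
            else:
                lines.append(f"{f.name} = {json.dumps(v)}")
        Path(path).write_text("\n".join(lines) + "\n")

    def thresholds(self) -> dict[str, float | int | bool]:
        return {
            "quantile": self.quantile, "min_pos": self.min_pos,
            "ordinary_t": self.ordinary_t, "median_normalize": self.median_normalize,
            "q_max": self.q_max, "z_abs": self.z_abs, "t_fdr": self.t_fdr,
            "t_fc": self.t_fc, "jaccard_min": self.jaccard_min,
        }

    def path(self, name: str, default: str) -> Path:
        explicit = getattr(self, f"{name}_path", None)
        return Path(explicit) if explicit else Path(self.outdir) / default


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest.

    Raises FileNotFoundError naming the stage whose required upstream
    output is missing.  No stage mutates its inputs; every output file
    is recorded in the manifest with a sha256 digest.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": cfg.thresholds(),
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, counts: dict, outputs: list[Path]) -> None:
        manifest["stages"][stage] = counts
        for p in outputs:
            manifest["outputs"][p.name] = _sha256(p)
        log.info("stage %s: %s", stage, counts)

    def require(path: Path, stage: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs missing input {path.name!r}; "
                f"run the upstream stage or point the config at an existing file"
            )
        return path

    if "simulate" in cfg.stages:
        sim = SimConfig(
            n_proteins=cfg.n_proteins, n_per_group=cfg.n_per_group,
            frac_de=cfg.frac_de, seed=cfg.seed,
        )
        paths = write_simulation(sim, outdir)
        record("simulate", {"n_proteins": sim.n_proteins}, list(paths.values()))

    if "diffexp" in cfg.stages:
        matrix = IntensityMatrix.from_tsv(
            require(cfg.path("matrix", "intensities.tsv"), "diffexp"),
            require(cfg.path("design", "design.tsv"), "diffexp"),
        )
        stats_df, dropped = run_differential(
            matrix, quantile=cfg.quantile, min_pos=cfg.min_pos,
            ordinary=cfg.ordinary_t, median_normalize=cfg.median_normalize,
        )
        significant, stringent = classify_significant(stats_df, cfg.q_max, cfg.z_abs)
        stats_df["significant"] = stats_df["accession"].isin(significant)
        stats_df["stringent"] = stats_df["accession"].isin(stringent)
        stats_path = outdir / "protein_stats.tsv"
        dropped_path = outdir / "dropped_proteins.tsv"
        write_tsv(stats_df, stats_path)
        write_tsv(pd.DataFrame({"accession": dropped}), dropped_path)
        record(
            "diffexp",
            {"tested": len(stats_df), "dropped": len(dropped),
             "significant": len(significant), "stringent": len(stringent)},
            [stats_path, dropped_path],
        )

    if "map_ids" in cfg.stages:
        stats_df = read_tsv(require(outdir / "protein_stats.tsv", "map_ids"))
        mapping = read_tsv(require(cfg.path("mapping", "mapping.tsv"), "map_ids"))
        overrides = None
        if cfg.overrides_path:
            overrides = read_tsv(Path(cfg.overrides_path))
        annotated, unmapped = resolve_ids(stats_df, mapping, overrides)
        ann_path = outdir / "protein_stats_annotated.tsv"
        unmapped_path = outdir / "unmapped_accessions.tsv"
        write_tsv(annotated, ann_path)
        write_tsv(pd.DataFrame({"accession": unmapped}), unmapped_path)
        record("map_ids", {"annotated": len(annotated), "unmapped": len(unmapped)},
               [ann_path, unmapped_path])

    if "integrate" in cfg.stages:
        annotated = read_tsv(require(outdir / "protein_stats_annotated.tsv", "integrate"))
        transcripts = read_tsv(
            require(cfg.path("transcripts", "transcripts.tsv"), "integrate")
        )
        sig = set(annotated.loc[annotated["significant"], "accession"])
        pairs, venn = merge_omics(annotated, transcripts, sig, cfg.t_fdr)
        pairs_path = outdir / "concordance_pairs.tsv"
        venn_path = outdir / "venn_counts.json"
        write_tsv(pairs, pairs_path)
        venn_path.write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")
        counts = pairs["concordance"].value_counts().to_dict()
        record("integrate", {"pairs": len(pairs), **venn, **counts},
               [pairs_path, venn_path])

    if "prioritize" in cfg.stages:
        pairs = read_tsv(require(outdir / "concordance_pairs.tsv", "prioritize"))
        targets = prioritize(pairs, cfg.q_max, cfg.z_abs, cfg.t_fdr, cfg.t_fc)
        targets_path = outdir / "prioritized_targets.tsv"
        write_tsv(targets, targets_path)
        record("prioritize", {"targets": len(targets)}, [targets_path])

    if "crossstudy" in cfg.stages:
        targets = read_tsv(require(outdir / "prioritized_targets.tsv", "crossstudy"))
        # prefer external tables present in the run directory (written by the
        # simulate stage or supplied by the user); else the bundled reference
        ext_paths = sorted(outdir.glob("external_study_*.tsv"))
        if ext_paths:
            externals = {
                p.stem.removeprefix("external_study_"): read_tsv(p, dtype=str)
                for p in ext_paths
            }
        else:
            externals = reference_external_tables()
        reports = []
        summary = {}
        for study, ext in sorted(externals.items()):
            n_common, agreement, report = cross_study_overlap(targets, ext)
            report.insert(0, "study", study)
            reports.append(report)
            summary[study] = n_common
        report_path = outdir / "cross_study_report.tsv"
        write_tsv(pd.concat(reports, ignore_index=True), report_path)
        record("crossstudy", summary, [report_path])

    if "enrich" in cfg.stages:
        annotated = read_tsv(require(outdir / "protein_stats_annotated.tsv", "enrich"))
        ann = read_tsv(require(cfg.path("annotation", "annotation.tsv"), "enrich"))
        universe = set(annotated["symbol"].dropna())
        selected = set(
            annotated.loc[annotated["significant"], "symbol"].dropna()
        ) & universe
        results = hypergeom_enrich(selected, universe, ann, q_max=cfg.q_max)
        results_path = outdir / "enrichment_results.tsv"
        write_tsv(results, results_path)
        outputs = [results_path]
        if (results["q"] < cfg.q_max).any():
            graph = build_term_network(
                results, ann, selected=selected,
                jaccard_min=cfg.jaccard_min, q_max=cfg.q_max,
            )
            nodes = pd.DataFrame(
                [{"go_id": n, **d} for n, d in graph.nodes(data=True)]
            ).sort_values("go_id", kind="stable")
            edges = pd.DataFrame(
                [{"source": min(a, b), "target": max(a, b), "weight": d["weight"]}
                 for a, b, d in graph.edges(data=True)]
            )
            if not edges.empty:
                edges = edges.sort_values(["source", "target"], kind="stable")
            nodes_path = outdir / "term_network_nodes.tsv"
            edges_path = outdir / "term_network_edges.tsv"
            write_tsv(nodes, nodes_path)
            write_tsv(edges, edges_path)
            outputs += [nodes_path, edges_path]
        record(
            "enrich",
            {"terms_tested": len(results),
             "enriched": int((results["q"] < cfg.q_max).sum())},
            outputs,
        )

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
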
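"""End-to-end pipeline: simulate -> map probes -> summarize -> call ->
contrast -> cluster (-> enrich -> qPCR), with a run manifest.

Each stage writes its table under the output directory and records its
row count in ``manifest.json``; all randomness flows from the single
configured seed.  A stage failure aborts the run with the failing stage
named and leaves a ``FAILED`` marker beside the partial outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io
from .calls import build_call_table, count_calls
from .clustering import (
    build_profile_matrix,
    hierarchical_cluster,
    principal_components,
    variance_filter,
)
from .contrasts import BUILTIN_CONTRASTS, ContrastDefinition, build_all_contrasts
from .correspondence import build_correspondence, collapse_to_genes
from .enrichment import enrichment_report
from .platform_stats import summarize_genes
from .simulate import (
    SimulationConfig,
    generate_affymetrix,
    generate_agilent,
    generate_sequences,
    generate_truth,
)

CLUSTER_METRICS = ("pearson", "covariance", "cosine")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Thresholds, contrast recipes and simulation settings for one run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    up_threshold: float = 0.6
    neutral_threshold: float = 0.3
    detection_alpha: float = 0.06
    signal_floor: float = 50.0
    variance_keep: float = 0.5
    enrichment_alpha: float = 0.05
    contrasts: dict[str, ContrastDefinition] = field(
        default_factory=lambda: dict(BUILTIN_CONTRASTS)
    )
    term_table: str | None = None  # optional two-column TSV (at_id, term_id)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = SimulationConfig(**raw.pop("simulation", {}))
        contrasts = {
            name: ContrastDefinition(name=name, **spec)
            for name, spec in raw.pop("contrasts", {}).items()
        } or dict(BUILTIN_CONTRASTS)
        return cls(simulation=sim, contrasts=contrasts, **raw)

    def echo(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "up_threshold",
                "neutral_threshold",
                "detection_alpha",
                "signal_floor",
                "variance_keep",
                "enrichment_alpha",
                "term_table",
            )
        }
        d["simulation"] = self.simulation.to_dict()
        d["contrasts"] = {
            name: {
                "required_up": sorted(c.required_up),
                "required_not_up": sorted(c.required_not_up),
                "required_down": sorted(c.required_down),
                "required_not_down": sorted(c.required_not_down),
            }
            for name, c in self.contrasts.items()
        }
        return d


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages on a simulated dataset; returns the result bundle.

    The bundle maps stage names to in-memory results (DataFrames, gene
    lists, Dendrograms); tables are also written under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.simulation.seed,
        "version": __version__,
        "config": config.echo(),
        "stages": {},
    }
    bundle: dict = {}
    stage = "simulate"
    try:
        truth = generate_truth(config.simulation)
        comparisons, detection = generate_affymetrix(truth, config.simulation)
        dyeswap = generate_agilent(truth, config.simulation)
        transcripts, probe_sets, long_probes = generate_sequences(
            truth, config.simulation
        )
        io.write_table(truth.to_frame(), out / "truth.tsv")
        io.write_table(comparisons, out / "comparisons.tsv")
        io.write_table(detection, out / "detection.tsv")
        io.write_table(dyeswap, out / "dyeswap.tsv")
        io.write_fasta(transcripts, out / "transcripts.fasta")
        bundle["truth"] = truth
        manifest["stages"][stage] = {
            "genes": len(truth.gene_ids),
            "comparison_rows": len(comparisons),
            "dyeswap_rows": len(dyeswap),
        }

        stage = "map-probes"
        pairs = build_correspondence(probe_sets, long_probes, transcripts)
        signal = dyeswap.groupby("probe_id")[["cy3", "cy5"]].mean().sum(axis=1)
        collapsed = collapse_to_genes(pairs, mean_signal=signal.to_dict())
        gene_map = pd.DataFrame(
            [(g, ps, pr) for g, (ps, pr) in collapsed.items()],
            columns=["at_id", "probe_set_id", "probe_id"],
        )
        io.write_pairs(pairs, out / "pairs.tsv")
        io.write_table(gene_map, out / "gene_map.tsv")
        bundle["gene_map"] = gene_map
        manifest["stages"][stage] = {"pairs": len(pairs), "genes": len(gene_map)}

        stage = "summarize"
        summary = summarize_genes(
            comparisons,
            detection,
            dyeswap,
            gene_map,
            signal_floor=config.signal_floor,
            detection_alpha=config.detection_alpha,
        )
        io.write_table(summary, out / "summary.tsv")
        bundle["summary"] = summary
        manifest["stages"][stage] = {
            "rows": len(summary),
            "present_genes": int(
                summary.drop_duplicates("at_id")["present"].sum()
            ),
        }

        stage = "call"
        calls = build_call_table(
            summary, config.up_threshold, config.neutral_threshold
        )
        counts = count_calls(calls)
        io.write_table(calls, out / "calls.tsv")
        io.write_table(counts, out / "call_counts.tsv")
        bundle["calls"] = calls
        bundle["call_counts"] = counts
        manifest["stages"][stage] = {"rows": len(calls)}

        stage = "contrast"
        contrast_sets = build_all_contrasts(calls, config.contrasts)
        for name, genes in contrast_sets.items():
            io.write_table(pd.DataFrame({"at_id": genes}), out / f"contrast_{name}.tsv")
        bundle["contrasts"] = contrast_sets
        manifest["stages"][stage] = {k: len(v) for k, v in contrast_sets.items()}

        stage = "cluster"
        matrix = variance_filter(
            build_profile_matrix(summary[summary["present"]]), config.variance_keep
        )
        bundle["dendrograms"] = {}
        for metric in CLUSTER_METRICS:
            dend = hierarchical_cluster(matrix, metric)
            io.write_newick(dend.to_newick(), out / f"dendrogram_{metric}.newick")
            bundle["dendrograms"][metric] = dend
        pca = principal_components(matrix)
        io.write_table(pca.reset_index(names="sample"), out / "pca.tsv")
        bundle["pca"] = pca
        manifest["stages"][stage] = {
            "genes_after_filter": len(matrix),
            "samples": matrix.shape[1],
        }

        stage = "enrich"
        if config.term_table is not None:
            terms = io.read_table(config.term_table, ["at_id", "term_id"])
            gene_terms = terms.groupby("at_id")["term_id"].agg(set).to_dict()
            background = summary.loc[summary["present"], "at_id"].unique().tolist()
            reports = {}
            for name, genes in contrast_sets.items():
                rep = enrichment_report(
                    genes, background, gene_terms, config.enrichment_alpha
                )
                io.write_table(rep, out / f"enrichment_{name}.tsv")
                reports[name] = rep
            bundle["enrichment"] = reports
            manifest["stages"][stage] = {k: len(v) for k, v in reports.items()}
        else:
            manifest["stages"][stage] = "skipped (no term table configured)"
    except Exception as exc:
        (out / "FAILED").write_text(f"stage '{stage}' failed: {exc}\n")
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle
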
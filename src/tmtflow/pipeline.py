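"""End-to-end pipeline orchestration.

Runs filter -> log2 -> normalize -> rollup -> differential (-> integrate
when array data are supplied), writes every intermediate table as TSV,
and records all stage counts in a machine-readable JSON report.  The run
is fully deterministic: the same inputs and configuration produce
byte-identical output files (no timestamps or unordered dictionaries in
anything written to disk).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, SampleDesign
from . import io as tio
from .peptides import filter_peptides, log2_transform, select_reference_sample, \
    normalize_to_reference
from .rollup import build_peptide_protein_map, rollup_proteins
from .stats import differential_table, call_significant, sd_filter, \
    hierarchical_cluster, ClusterResult
from .integrate import match_probes_to_proteins, global_concordance, \
    per_pair_concordance, overlap_sets

__all__ = ["PipelineResult", "run_pipeline"]


class StageError(RuntimeError):
    """An identifiable pipeline stage failed."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    """Bundle of every table the pipeline produced, plus the report."""

    filtered_peptides: pd.DataFrame
    peptide_matrix: pd.DataFrame
    normalization_offsets: pd.Series
    protein_matrix: pd.DataFrame
    protein_metadata: pd.DataFrame
    differential_proteins: pd.DataFrame
    protein_cluster: ClusterResult | None
    report: dict
    differential_genes: pd.DataFrame | None = None
    matched_pairs: object | None = None
    concordance: object | None = None


def run_pipeline(config: RunConfig, design: SampleDesign,
                 peptides: pd.DataFrame,
                 expression: pd.DataFrame | None = None,
                 mapping: pd.DataFrame | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full processing chain on in-memory tables.

    Parameters
    ----------
    peptides :
        Internal-format peptide table (see :func:`tmtflow.io.read_peptide_table`).
    expression, mapping :
        Optional probe x sample log2 matrix and probe-to-protein mapping;
        when both are given the gene-protein integration stages run too.
    out_dir :
        When given, every intermediate table is written there as TSV plus
        a ``report.json``.

    Raises
    ------
    StageError
        Wrapping the failing stage's name and original cause.
    """
    config.validate()
    report: dict = {"config": config.to_dict(),
                    "design": design.to_frame().to_dict(orient="list")}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                return False
        return _Ctx()

    with stage("filter"):
        filtered, freport = filter_peptides(peptides, design,
                                            config.pep_threshold,
                                            config.max_missing)
        report["filter"] = freport.to_dict()

    with stage("log2"):
        pep_mat = log2_transform(filtered, design)

    with stage("normalize"):
        if config.normalization == "rank_order_scale":
            reference = select_reference_sample(pep_mat)
            pep_mat, offsets = normalize_to_reference(pep_mat, reference)
        else:
            reference = None
            offsets = pd.Series(0.0, index=pep_mat.columns)
        report["normalization"] = {
            "method": config.normalization,
            "reference_sample": reference,
            "offsets": {s: float(o) for s, o in offsets.items()},
        }

    with stage("rollup"):
        pmap = build_peptide_protein_map(filtered)
        prot_mat, prot_meta = rollup_proteins(pep_mat, pmap)
        report["rollup"] = {
            "n_proteins": int(len(prot_mat)),
            "n_mapped_peptides": int(pmap.parent_counts.size),
            "n_shared_peptides": int((pmap.parent_counts > 1).sum()),
            "single_peptide_proteins": int(prot_meta["single_peptide_flag"].sum()),
            "peptides_per_protein": (float(pmap.parent_counts.size / len(prot_mat))
                                     if len(prot_mat) else None),
        }

    with stage("differential"):
        diff = differential_table(prot_mat, design)
        diff = call_significant(diff, config.p_threshold,
                                config.fc_linear_threshold, config.use_fc_filter)
        report["differential_proteins"] = _de_counts(diff, config)

    protein_cluster = None
    with stage("cluster"):
        try:
            protein_cluster = hierarchical_cluster(prot_mat)
            report["protein_cluster"] = {
                "leaf_order": protein_cluster.sample_order,
                "two_cut_labels": protein_cluster.labels,
                "n_features_used": protein_cluster.n_features_used,
            }
        except ValueError:
            report["protein_cluster"] = None

    diff_genes = None
    matched = None
    concordance = None
    if expression is not None and mapping is not None:
        with stage("gene_differential"):
            diff_genes = differential_table(expression, design)
            diff_genes = call_significant(diff_genes, config.p_threshold,
                                          config.fc_linear_threshold,
                                          config.use_fc_filter)
            variable = sd_filter(expression, config.sd_probe_threshold)
            report["gene_expression"] = {
                "n_probes": int(len(expression)),
                "n_variable_probes": int(len(variable)),
                "differential_genes": _de_counts(diff_genes, config),
            }

        with stage("integration"):
            matched = match_probes_to_proteins(expression, mapping, prot_mat)
            gc = global_concordance(matched)
            concordance = per_pair_concordance(matched, config.p_threshold,
                                               config.corr_r_threshold)
            de_prot = set(diff.index[diff["p"] < config.p_threshold]) & \
                set(matched.pairs.index)
            # gene-level calls keyed by matched protein via the chosen probe
            probe_of = matched.pairs["probe_id"]
            gene_p = diff_genes.loc[probe_of.to_numpy(), "p"]
            gene_p.index = probe_of.index
            de_gene = set(gene_p.index[gene_p < config.p_threshold])
            gene_fc = diff_genes.loc[probe_of.to_numpy(), "log2fc"]
            gene_fc.index = probe_of.index
            signs = {
                "protein": diff["log2fc"].to_dict(),
                "gene": gene_fc.to_dict(),
            }
            overlap = overlap_sets({"protein": de_prot, "gene": de_gene}, signs)
            report["integration"] = {
                "n_matched": int(len(matched)),
                "global_pearson_r": gc["pearson"].r,
                "global_pearson_p": gc["pearson"].p,
                "global_spearman_r": gc["spearman"].r,
                "global_spearman_p": gc["spearman"].p,
                "per_pair": concordance.to_dict(),
                "de_overlap": overlap.to_dict(),
            }

    result = PipelineResult(
        filtered_peptides=filtered,
        peptide_matrix=pep_mat,
        normalization_offsets=offsets,
        protein_matrix=prot_mat,
        protein_metadata=prot_meta,
        differential_proteins=diff,
        protein_cluster=protein_cluster,
        report=report,
        differential_genes=diff_genes,
        matched_pairs=matched,
        concordance=concordance,
    )
    if out_dir is not None:
        _write_outputs(result, design, Path(out_dir))
    return result


def _de_counts(diff: pd.DataFrame, config: RunConfig) -> dict:
    return {
        "n_features": int(len(diff)),
        "called": int(diff["called"].sum()),
        "p<0.05": int((diff["p"] < 0.05).sum()),
        "p<0.01": int((diff["p"] < 0.01).sum()),
        "p<0.001": int((diff["p"] < 0.001).sum()),
        "p_threshold": config.p_threshold,
        "fc_linear_threshold": config.fc_linear_threshold,
        "use_fc_filter": config.use_fc_filter,
    }


def _write_outputs(result: PipelineResult, design: SampleDesign,
                   out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tio.write_peptide_table(result.filtered_peptides,
                            out_dir / "peptides_filtered.tsv", design)
    tio.write_expression_matrix(result.peptide_matrix,
                                out_dir / "peptides_log2_normalized.tsv",
                                index_label="sequence")
    tio.write_expression_matrix(result.protein_matrix,
                                out_dir / "proteins_log2.tsv",
                                index_label="protein")
    result.protein_metadata.to_csv(out_dir / "proteins_metadata.tsv", sep="\t")
    result.differential_proteins.to_csv(out_dir / "differential_proteins.tsv",
                                        sep="\t", float_format="%.10g", na_rep="")
    if result.differential_genes is not None:
        result.differential_genes.to_csv(out_dir / "differential_genes.tsv",
                                         sep="\t", float_format="%.10g", na_rep="")
    if result.concordance is not None:
        result.concordance.per_pair.to_csv(out_dir / "concordance_per_pair.tsv",
                                           sep="\t", float_format="%.10g",
                                           na_rep="")
    if result.protein_cluster is not None:
        (out_dir / "protein_cluster.nwk").write_text(
            result.protein_cluster.newick + "\n")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True, default=_json_safe)
        fh.write("\n")


def _json_safe(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
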
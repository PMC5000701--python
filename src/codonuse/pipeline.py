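"""Per-strain and cross-strain orchestration of the full analysis.

``run_strain`` takes one CDS FASTA through: inclusion filter -> codon
counting -> per-gene metrics (GC partitions, ENc, CAI) -> genome RSCU and
preferred codons -> optimal-codon chi-squared contrast -> correspondence
analysis -> neutrality fit -> ENc/GC3s correlation -> top-5% CAI
prediction.  ``run_cohort`` adds the cross-strain stages: cohort mean
RSCU, the RSCU dendrogram and the ortholog-sharing report, plus a summary
table of mean +/- SD per strain for GC%, GC3s%, ENc and CAI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import codon_metrics as cm
from . import highly_expressed as he
from . import multivariate as mv
from .sequence_io import (
    CdsFilterReport,
    CodingSequence,
    CodonCountTable,
    count_codons,
    filter_cds,
    pool_counts,
    read_cds_fasta,
    write_counts_tsv,
)

log = logging.getLogger("codonuse")


class PipelineError(RuntimeError):
    """Stage failure with the stage name attached."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class StrainReport:
    genome_id: str
    filter_report: CdsFilterReport
    gene_metrics: pd.DataFrame
    genome_rscu: pd.Series  # 59-dim
    rscu_table: pd.DataFrame  # Table-1-shaped (aa, codon, RSCU, flags)
    preferred: set[str]
    optimal: cm.OptimalCodonResult
    coa: mv.CoaResult
    neutrality: mv.NeutralityFit
    enc_gc3s: tuple[float, float]  # Spearman rho, p
    prediction: he.ExpressionPrediction
    cai_model: cm.CaiModel
    counts: list[CodonCountTable]
    sequences: list[CodingSequence]


def _split_by_cai(
    counts: Sequence[CodonCountTable], cai_values: pd.Series, frac: float = 0.10
) -> tuple[list[CodonCountTable], list[CodonCountTable]]:
    """Top/bottom-``frac`` gene groups by CAI (deterministic tie-break by id)."""
    order = cai_values.sort_index().sort_values(ascending=False, kind="stable")
    k = max(1, int(np.ceil(frac * len(order))))
    top = set(order.index[:k])
    bottom = set(order.index[-k:])
    by_id = {t.label: t for t in counts}
    return [by_id[g] for g in sorted(top)], [by_id[g] for g in sorted(bottom)]


def run_strain(
    source: str | Path | Sequence[CodingSequence],
    genome_id: str | None = None,
    min_codons: int = 100,
    start_codons: Sequence[str] = ("ATG",),
    top_fraction: float = 0.05,
    alpha: float = 0.01,
    reference_list: str | Path | None = None,
    out_dir: str | Path | None = None,
    percent: bool = False,
) -> StrainReport:
    """Run the complete single-strain analysis; optionally write TSV outputs."""
    if isinstance(source, (str, Path)):
        seqs = read_cds_fasta(source, genome_id=genome_id)
    else:
        seqs = list(source)
    gid = genome_id or (seqs[0].genome_id if seqs else "genome")
    log.info("%s: %d CDS read", gid, len(seqs))

    kept, report = filter_cds(seqs, min_codons=min_codons, start_codons=start_codons)
    log.info("%s: filter kept %d / %d", gid, report.n_passing, report.n_input)
    if not kept:
        raise PipelineError(
            "filter",
            f"no CDS passed the inclusion filter in {gid} (rejections: {report.rejections})",
        )

    counts = [count_codons(s) for s in kept]
    pooled = pool_counts(counts, gid)

    if reference_list is not None:
        ref = he.load_reference_list(reference_list, kept)
    else:
        try:
            ref = he.select_reference(kept)
        except ValueError as exc:
            raise PipelineError("reference", str(exc)) from exc
    log.info("%s: %d reference (ribosomal) genes", gid, len(ref.sequences))
    ref_counts = [count_codons(s) for s in ref.sequences]
    model = cm.cai_weights(ref_counts, label=f"{gid} ribosomal proteins")

    metrics = cm.gene_metrics_table(counts, cai_model=model)
    if metrics["enc"].isna().any():
        log.warning("%s: %d genes with unscorable ENc", gid, int(metrics["enc"].isna().sum()))

    high, low = _split_by_cai(counts, metrics["cai"])
    optimal = cm.optimal_codons(high, low, alpha=alpha)

    matrix = mv.build_rscu_matrix(counts)
    if matrix.n_imputed:
        log.info("%s: %d RSCU entries imputed at 1.0", gid, matrix.n_imputed)
    coa = mv.correspondence_analysis(matrix, n_axes=2)

    parts = [
        cm.GcPartition(r.gc, r.p1, r.p2, r.p3, r.p12, r.gc3s)
        for r in metrics.itertuples()
    ]
    neut = mv.neutrality_fit(parts)
    rho_p = mv.enc_gc3s_correlation(list(zip(metrics["enc"], metrics["gc3s"])))

    pred = he.predict_highly_expressed(
        metrics["cai"],
        fraction=top_fraction,
        genome_id=gid,
        reference_ids=[s.gene_id for s in ref.sequences],
    )
    log.info("%s: CAI cutoff %.3f, %d genes predicted", gid, pred.cutoff, len(pred.predicted))

    strain = StrainReport(
        genome_id=gid,
        filter_report=report,
        gene_metrics=metrics,
        genome_rscu=mv.genome_rscu_vector(counts, gid),
        rscu_table=cm.rscu_table(pooled, optimal=optimal.optimal_set),
        preferred=cm.preferred_codons(cm.rscu(pooled)),
        optimal=optimal,
        coa=coa,
        neutrality=neut,
        enc_gc3s=rho_p,
        prediction=pred,
        cai_model=model,
        counts=counts,
        sequences=kept,
    )
    if out_dir is not None:
        write_strain_outputs(strain, out_dir, percent=percent)
    return strain


@dataclass
class CohortReport:
    strains: list[StrainReport]
    mean_rscu: pd.DataFrame  # Table-1-shaped cohort mean
    dendrogram: mv.Dendrogram
    sharing: he.OrthologSharingReport
    summary: pd.DataFrame  # per-strain mean +/- SD of GC%, GC3s%, ENc, CAI


def summary_table(strains: Sequence[StrainReport], percent: bool = True) -> pd.DataFrame:
    """Per-strain mean and SD of GC, GC3s, ENc and CAI (GC columns in % by default)."""
    scale = 100.0 if percent else 1.0
    rows = []
    for s in strains:
        m = s.gene_metrics
        rows.append(
            {
                "strain": s.genome_id,
                "n_genes": len(m),
                "gc_mean": m["gc"].mean() * scale,
                "gc_sd": m["gc"].std(ddof=1) * scale,
                "gc3s_mean": m["gc3s"].mean() * scale,
                "gc3s_sd": m["gc3s"].std(ddof=1) * scale,
                "enc_mean": m["enc"].mean(),
                "enc_sd": m["enc"].std(ddof=1),
                "cai_mean": m["cai"].mean(),
                "cai_sd": m["cai"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows).set_index("strain")


def run_cohort(
    sources: Sequence[str | Path | Sequence[CodingSequence]],
    genome_ids: Sequence[str] | None = None,
    out_dir: str | Path | None = None,
    percent: bool = True,
    **strain_kwargs,
) -> CohortReport:
    """Run every strain, then the cross-strain clustering and sharing stages."""
    if len(sources) < 2:
        raise PipelineError("cohort", "need at least 2 strains")
    strains = []
    for i, src in enumerate(sources):
        gid = genome_ids[i] if genome_ids else None
        strains.append(run_strain(src, genome_id=gid, **strain_kwargs))

    rscu_cols = {s.genome_id: s.rscu_table["rscu"] for s in strains}
    mean = pd.DataFrame(rscu_cols).mean(axis=1)
    mean_rscu = strains[0].rscu_table[["aa"]].copy()
    mean_rscu["rscu_mean"] = mean
    mean_rscu["preferred"] = mean_rscu["rscu_mean"] > 1.0

    dendro = mv.cluster_genomes({s.genome_id: s.genome_rscu for s in strains})

    symbol_map: dict[str, str] = {}
    for s in strains:
        for seq in s.sequences:
            if seq.gene:
                symbol_map[seq.gene_id] = seq.gene
    sharing = he.shared_orthologs([s.prediction for s in strains], symbol_map)

    cohort = CohortReport(strains, mean_rscu, dendro, sharing, summary_table(strains, percent))
    if out_dir is not None:
        write_cohort_outputs(cohort, out_dir, percent=percent)
    return cohort


# ---------------------------------------------------------------------------
# TSV emission

def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_strain_outputs(strain: StrainReport, out_dir: str | Path, percent: bool = False) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gid = strain.genome_id
    metrics = strain.gene_metrics.copy()
    if percent:
        for col in ("gc", "gc3s", "p1", "p2", "p3", "p12"):
            metrics[col] = metrics[col] * 100.0
    _fmt(metrics, out / f"{gid}.metrics.tsv")
    _fmt(strain.rscu_table, out / f"{gid}.rscu.tsv")
    _fmt(strain.optimal.table, out / f"{gid}.optimal_codons.tsv")
    _fmt(strain.coa.row_coords, out / f"{gid}.coa_genes.tsv")
    inertia = pd.DataFrame(
        {
            "inertia": strain.coa.inertia,
            "relative_inertia": strain.coa.relative_inertia,
        }
    )
    inertia.index = [f"axis{i+1}" for i in range(len(inertia))]
    _fmt(inertia, out / f"{gid}.coa_inertia.tsv")
    pred = pd.DataFrame(
        {
            "cai": strain.prediction.cai,
            "predicted": [g in set(strain.prediction.predicted) for g in strain.prediction.cai.index],
        }
    )
    _fmt(pred, out / f"{gid}.highly_expressed.tsv")
    write_counts_tsv(strain.counts, out / f"{gid}.counts.tsv")
    with open(out / f"{gid}.neutrality.txt", "w") as fh:
        n = strain.neutrality
        fh.write(
            f"slope\t{n.slope:.6g}\nintercept\t{n.intercept:.6g}\n"
            f"spearman_rho\t{n.rho:.6g}\nrho_pvalue\t{n.rho_pvalue:.6g}\nn_genes\t{n.n_genes}\n"
        )


def write_cohort_outputs(cohort: CohortReport, out_dir: str | Path, percent: bool = True) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _fmt(cohort.summary, out / "summary.tsv")
    _fmt(cohort.mean_rscu, out / "cohort_rscu.tsv")
    _fmt(cohort.dendrogram.merge_table(), out / "cluster_merges.tsv")
    (out / "cluster.nwk").write_text(cohort.dendrogram.to_newick() + "\n")
    _fmt(cohort.sharing.to_frame().set_index("symbol"), out / "ortholog_sharing.tsv")
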
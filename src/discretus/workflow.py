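"""End-to-end per-dataset analysis glue used by the CLI and the tests."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import discreteness, diversification, gmyc, io_core, popgen


@dataclass
class DatasetAnalysis:
    """Everything the pipeline derives from one gene tree + alignment."""

    name: str
    tree: io_core.UltrametricTree          # haplotype tree (post-collapse)
    haplotypes: io_core.HaplotypeAlignment
    fit: gmyc.GMYCFit
    partition: gmyc.SpeciesPartition
    distance_matrix: io_core.DistanceMatrix
    metrics: pd.DataFrame
    species_tree: diversification.SpeciesTree
    summary: discreteness.DatasetSummary


def analyze_dataset(
    tree: io_core.UltrametricTree,
    records: Sequence[io_core.SequenceRecord],
    name: str = "",
    clade: str = "",
    habitat: str = "",
    seq_lengths: dict[str, int] | None = None,
    df: int = 2,
) -> DatasetAnalysis:
    """Collapse haplotypes, delimit species, and compute per-species
    metrics plus the pruned species tree."""
    hap_tree, hap = io_core.collapse_and_prune(tree, records)
    fit = gmyc.fit_gmyc(hap_tree, df=df)
    partition = gmyc.extract_partition(fit, hap_tree)
    dm = io_core.p_distance_matrix(hap)
    meta = {"dataset": name, "clade": clade, "habitat": habitat}
    metrics = discreteness.metrics_table(
        partition, hap_tree, dm, hap.multiplicity, meta
    )
    if seq_lengths is None:
        seq_lengths = {r.id: r.length for r in records}
    species_tree = diversification.prune_to_species(
        hap_tree, partition, seq_lengths
    )
    summary = discreteness.dataset_summary(partition, hap.multiplicity, meta)
    return DatasetAnalysis(
        name=name,
        tree=hap_tree,
        haplotypes=hap,
        fit=fit,
        partition=partition,
        distance_matrix=dm,
        metrics=metrics,
        species_tree=species_tree,
        summary=summary,
    )


def popgen_table(analysis: DatasetAnalysis) -> pd.DataFrame:
    """Neutrality statistics per delimited species (multiplicity-expanded)."""
    hap = analysis.haplotypes
    seq_of = {r.id: r.seq for r in hap.records}
    rows = []
    for sp, tips in analysis.partition.clusters.items():
        seqs: list[str] = []
        for t in tips:
            seqs.extend([seq_of[t]] * hap.multiplicity[t])
        row = {"dataset": analysis.name, "species_id": sp}
        if len(seqs) < 2:
            row.update(
                {
                    k: float("nan")
                    for k in (
                        "n", "S", "k_bar", "theta_W", "eta", "eta_s", "K",
                        "D", "D_star", "F_star", "Fs", "R2",
                    )
                }
            )
            row["n"] = len(seqs)
        else:
            row.update(popgen.neutrality_stats(seqs).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def load_dataset_dir(path: str | Path):
    """Read one bundle directory (gene_tree.nwk, alignment.fasta, meta.tsv)."""
    path = Path(path)
    tree = io_core.read_newick(path / "gene_tree.nwk")
    records = io_core.read_fasta(path / "alignment.fasta")
    meta = io_core.read_metadata(path / "meta.tsv")
    io_core.attach_metadata(records, meta)
    return tree, records, meta


def analyze_dataset_dir(path: str | Path, df: int = 2) -> DatasetAnalysis:
    path = Path(path)
    tree, records, meta = load_dataset_dir(path)
    seq_lengths = dict(zip(meta["id"], meta["seq_length"].astype(int)))
    return analyze_dataset(
        tree,
        records,
        name=path.name,
        clade=str(meta["clade"].iloc[0]),
        habitat=str(meta["habitat"].iloc[0]),
        seq_lengths=seq_lengths,
        df=df,
    )


__all__ = [
    "DatasetAnalysis",
    "analyze_dataset",
    "analyze_dataset_dir",
    "load_dataset_dir",
    "popgen_table",
]
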
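"""Per-cluster discreteness metrics and dataset-level sampling summaries.

Intraspecific cohesion is measured by nucleotide diversity (mean pairwise
p-distance among a cluster's haplotypes) and by the cluster's basal node
age; interspecific separation by the minimum raw distance and the minimum
patristic distance (halved, i.e. divergence time) to any heterospecific
tip.  Singletons carry ``nan`` sentinels for the intraspecific metrics.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import UnknownTipError
from .gmyc import SpeciesPartition
from .io_core import DistanceMatrix, UltrametricTree


@dataclass
class ClusterSummary:
    species_id: str
    n_haplotypes: int
    n_sequences: int
    pi: float
    tmrca: float
    nn_raw: float
    nn_phylo: float


@dataclass
class DatasetSummary:
    dataset: str
    clade: str
    habitat: str
    n_entities: int
    mean_sequences_per_cluster: float
    mean_haplotypes_per_cluster: float
    singleton_proportion: float
    single_sample_singleton_proportion: float


def cluster_pi(
    partition: SpeciesPartition,
    dm: DistanceMatrix,
    multiplicity: Mapping[str, int] | None = None,
    weighted: bool = False,
) -> dict[str, float]:
    """Mean within-cluster pairwise p-distance per species.

    By default each haplotype pair counts once (unweighted); with
    ``weighted=True`` pairs are weighted by the product of multiplicities.
    Singletons map to ``nan``.
    """
    out: dict[str, float] = {}
    for sp, tips in partition.clusters.items():
        for t in tips:
            if t not in dm._index:
                raise UnknownTipError(t)
        if len(tips) < 2:
            out[sp] = float("nan")
            continue
        if weighted and multiplicity is not None:
            num = den = 0.0
            for a, b in itertools.combinations(tips, 2):
                w = multiplicity[a] * multiplicity[b]
                num += w * dm.loc(a, b)
                den += w
            out[sp] = num / den
        else:
            sub = dm.submatrix(tips)
            iu = np.triu_indices(len(tips), 1)
            out[sp] = float(np.nanmean(sub[iu]))
    return out


def cluster_tmrca(
    partition: SpeciesPartition, tree: UltrametricTree
) -> dict[str, float]:
    """Basal node age of each cluster; ``nan`` for singletons."""
    out: dict[str, float] = {}
    for sp, tips in partition.clusters.items():
        out[sp] = (
            float("nan") if len(tips) < 2 else tree.mrca_age(tips)
        )
    return out


def nearest_neighbor(
    partition: SpeciesPartition,
    dm: DistanceMatrix,
    tree: UltrametricTree,
) -> dict[str, dict[str, float]]:
    """Minimum raw and phylogenetic (patristic / 2) distance to any
    heterospecific tip, per species."""
    if partition.n_entities < 2:
        warnings.warn(
            "nearest-neighbor distances undefined with a single species",
            stacklevel=2,
        )
        return {
            sp: {"nn_raw": float("nan"), "nn_phylo": float("nan")}
            for sp in partition.clusters
        }
    pat = tree.patristic_matrix()
    tip_species = partition.tip_to_species
    labels = pat.labels
    sp_of = np.array([tip_species[lab] for lab in labels])
    raw = dm.submatrix(labels)
    out: dict[str, dict[str, float]] = {}
    for sp in partition.clusters:
        own = sp_of == sp
        other = ~own
        raw_block = raw[np.ix_(own, other)]
        pat_block = pat.values[np.ix_(own, other)]
        out[sp] = {
            "nn_raw": float(np.nanmin(raw_block)),
            "nn_phylo": float(np.min(pat_block) / 2.0),
        }
    return out


def cluster_summaries(
    partition: SpeciesPartition,
    tree: UltrametricTree,
    dm: DistanceMatrix,
    multiplicity: Mapping[str, int],
) -> list[ClusterSummary]:
    pis = cluster_pi(partition, dm, multiplicity)
    tmrcas = cluster_tmrca(partition, tree)
    nns = nearest_neighbor(partition, dm, tree)
    out = []
    for sp, tips in partition.clusters.items():
        out.append(
            ClusterSummary(
                species_id=sp,
                n_haplotypes=len(tips),
                n_sequences=sum(multiplicity[t] for t in tips),
                pi=pis[sp],
                tmrca=tmrcas[sp],
                nn_raw=nns[sp]["nn_raw"],
                nn_phylo=nns[sp]["nn_phylo"],
            )
        )
    return out


def dataset_summary(
    partition: SpeciesPartition,
    multiplicity: Mapping[str, int],
    meta: Mapping[str, str] | None = None,
) -> DatasetSummary:
    """Dataset-level sampling structure.

    Singletons (one haplotype) split into single-sample specimens
    (multiplicity 1) and collapsed clones (multiplicity > 1).
    """
    meta = meta or {}
    n_entities = partition.n_entities
    seq_counts = [
        sum(multiplicity[t] for t in tips)
        for tips in partition.clusters.values()
    ]
    hap_counts = [len(tips) for tips in partition.clusters.values()]
    singles = [
        tips for tips in partition.clusters.values() if len(tips) == 1
    ]
    single_sample = [
        tips for tips in singles if multiplicity[tips[0]] == 1
    ]
    return DatasetSummary(
        dataset=str(meta.get("dataset", "")),
        clade=str(meta.get("clade", "")),
        habitat=str(meta.get("habitat", "")),
        n_entities=n_entities,
        mean_sequences_per_cluster=float(np.mean(seq_counts)),
        mean_haplotypes_per_cluster=float(np.mean(hap_counts)),
        singleton_proportion=len(singles) / n_entities,
        single_sample_singleton_proportion=(
            len(single_sample) / n_entities
        ),
    )


def metrics_table(
    partition: SpeciesPartition,
    tree: UltrametricTree,
    dm: DistanceMatrix,
    multiplicity: Mapping[str, int],
    meta: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Tidy one-row-per-species table for export and group comparison."""
    meta = meta or {}
    rows = []
    for cs in cluster_summaries(partition, tree, dm, multiplicity):
        rows.append(
            {
                "dataset": meta.get("dataset", ""),
                "clade": meta.get("clade", ""),
                "habitat": meta.get("habitat", ""),
                "species_id": cs.species_id,
                "n_sequences": cs.n_sequences,
                "n_haplotypes": cs.n_haplotypes,
                "pi": cs.pi,
                "tmrca": cs.tmrca,
                "nn_raw": cs.nn_raw,
                "nn_phylo": cs.nn_phylo,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "ClusterSummary",
    "DatasetSummary",
    "cluster_pi",
    "cluster_tmrca",
    "nearest_neighbor",
    "cluster_summaries",
    "dataset_summary",
    "metrics_table",
]
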
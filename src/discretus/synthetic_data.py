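"""Generators for species trees, gene trees and alignments.

The generators emulate the sampling structure the analysis assumes: a
constant-rate birth-death species tree, independent within-species
coalescent genealogies grafted onto it, and Jukes-Cantor sequence
evolution.  Two presets mirror the contrast studied by the pipeline: an
``asexual_like`` group (faster diversification, few samples per species,
many singletons) and a ``sexual_like`` group (slower diversification,
well-sampled clusters).

All randomness flows through :class:`numpy.random.Generator`; a fixed seed
reproduces every artifact bit-for-bit.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .io_core import (
    SequenceRecord,
    UltrametricTree,
    write_fasta,
    write_newick,
)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# light-weight tree assembly
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "age", "children")

    def __init__(self, label: str | None, age: float,
                 children: list["_Node"] | None = None) -> None:
        self.label = label
        self.age = age
        self.children = children or []


def _newick(node: _Node, parent_age: float | None = None) -> str:
    if node.children:
        inner = ",".join(_newick(c, node.age) for c in node.children)
        body = f"({inner})"
    else:
        body = node.label
    if parent_age is None:
        return body + ";"
    return f"{body}:{parent_age - node.age:.12g}"


def _merge_backward(
    tips: list[_Node], merge_ages: Sequence[float], rng: np.random.Generator
) -> _Node:
    """Join lineages pairwise at the given ascending ages (uniform picks)."""
    active = list(tips)
    for age in merge_ages:
        i, j = rng.choice(len(active), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        node = _Node(None, float(age), [active[i], active[j]])
        active[i] = node
        del active[j]
    if len(active) != 1:
        raise RuntimeError("merge bookkeeping failed")
    return active[0]


def _to_ultrametric(root: _Node) -> UltrametricTree:
    return UltrametricTree.from_newick_string(_newick(root), tolerance=1e-6)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# species trees
# ---------------------------------------------------------------------------

def _yule_branching_ages(
    r: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Internal-node ages (descending) of a pure-birth tree with n tips.

    Inter-event intervals with k lineages are Exp(k*r), including the final
    interval between the last split and the present.
    """
    ks = np.arange(2, n + 1)
    gaps = rng.exponential(1.0 / (ks * r))
    total = gaps.sum()
    ages = total - np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    return ages  # descending; ages[0] is the crown age


def _bd_crown_age(
    lam: float, mu: float, n: int, rng: np.random.Generator
) -> float:
    """Crown age draw for a birth-death tree conditioned on n sampled tips."""
    r = lam - mu

    def log_density(t: np.ndarray) -> np.ndarray:
        ert = np.exp(-r * t)
        denom = lam - mu * ert
        p0 = mu * (1.0 - ert) / denom
        u = lam * (1.0 - ert) / denom
        with np.errstate(divide="ignore"):
            return (
                2.0 * np.log1p(-p0)
                + 2.0 * np.log1p(-u)
                + (n - 2) * np.log(u)
            )

    t_hi = 10.0 / r
    while True:  # extend until the tail is negligible
        if log_density(np.array([t_hi]))[0] < log_density(
            np.array([2.0 / r])
        )[0] - 40.0:
            break
        t_hi *= 2.0
    grid = np.linspace(1e-8 / r, t_hi, 4096)
    logf = log_density(grid)
    f = np.exp(logf - logf.max())
    cdf = np.cumsum(f)
    cdf /= cdf[-1]
    return float(np.interp(rng.random(), cdf, grid))


def _bd_branching_ages(
    r: float, eps: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Descending branching ages for a reconstructed birth-death tree
    conditioned on n tips."""
    lam = r / (1.0 - eps)
    mu = lam * eps
    T = _bd_crown_age(lam, mu, n, rng)
    if n == 2:
        return np.array([T])
    u = rng.random(n - 2)
    scale = (1.0 - np.exp(-r * T)) / (1.0 - eps * np.exp(-r * T))
    y = u * scale
    t = -np.log((1.0 - y) / (1.0 - y * eps)) / r
    return np.concatenate([[T], np.sort(t)[::-1]])


def simulate_bd_tree(
    r: float,
    eps: float,
    n_species: int,
    seed: int | np.random.Generator,
    label_prefix: str = "sp",
) -> UltrametricTree:
    """Reconstructed constant-rate birth-death tree with exactly
    ``n_species`` tips; branch lengths share the time units of ``r``.

    With ``eps == 0`` the tree is generated by the forward pure-birth
    construction (independent exponential inter-event intervals); with
    ``eps > 0`` the crown age is drawn from its conditional density and the
    remaining branching times from their i.i.d. conditional distribution.
    """
    if r <= 0 or not (0.0 <= eps < 1.0) or n_species < 2:
        raise DomainError("need r > 0, 0 <= eps < 1, n_species >= 2")
    rng = _as_rng(seed)
    if eps == 0.0:
        ages = _yule_branching_ages(r, n_species, rng)
    else:
        ages = _bd_branching_ages(r, eps, n_species, rng)
    tips = [
        _Node(f"{label_prefix}{i + 1}", 0.0) for i in range(n_species)
    ]
    root = _merge_backward(tips, np.sort(ages), rng)
    return _to_ultrametric(root)


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

def _coalescent_subtree(
    labels: list[str],
    depth: float,
    rng: np.random.Generator,
    max_age: float | None,
) -> _Node:
    """Kingman coalescent for one species: pairwise rate 2/depth, so the
    expected TMRCA of k samples is depth * (1 - 1/k)."""
    k = len(labels)
    if k == 1:
        return _Node(labels[0], 0.0)
    for _attempt in range(1000):
        js = np.arange(k, 1, -1)
        waits = rng.exponential(depth / (js * (js - 1.0)))
        ages = np.cumsum(waits)
        if max_age is None or ages[-1] < max_age:
            break
    else:
        warnings.warn(
            "within-species genealogy repeatedly exceeded the species stem; "
            "rescaling it to fit",
            stacklevel=2,
        )
        ages = ages / ages[-1] * 0.95 * max_age
    return _merge_backward([_Node(lab, 0.0) for lab in labels], ages, rng)


def simulate_gene_tree(
    species_tree: UltrametricTree,
    coalescent_depth: float,
    samples_per_species: int | Mapping[str, int],
    seed: int | np.random.Generator,
) -> tuple[UltrametricTree, dict[str, str]]:
    """Graft independent within-species coalescents onto a species tree.

    Returns the gene tree together with the true tip-to-species map.  Each
    species' genealogy is conditioned (by rejection) to coalesce within the
    species stem, so well-separated species trees yield monophyletic
    clusters by construction; a warning is emitted when the condition has
    to be enforced by rescaling.  A species sampled once keeps its original
    tip label, so one-sample-per-species input reproduces the species tree.
    """
    if coalescent_depth <= 0:
        raise DomainError("coalescent_depth must be positive")
    rng = _as_rng(seed)
    if isinstance(samples_per_species, Mapping):
        counts = dict(samples_per_species)
    else:
        counts = {
            lab: int(samples_per_species)
            for lab in species_tree.tip_labels
        }
    for lab, k in counts.items():
        if k < 1:
            raise DomainError(f"species {lab} assigned {k} samples")

    truth: dict[str, str] = {}

    def build(node, parent_age: float | None) -> _Node:
        if node.is_leaf():
            lab = node.taxon.label if node.taxon else node.label
            k = counts[lab]
            if k == 1:
                labels = [lab]
            else:
                labels = [f"{lab}_{j + 1}" for j in range(k)]
            for tip_lab in labels:
                truth[tip_lab] = lab
            stem_top = (
                parent_age if parent_age is not None else float("inf")
            )
            return _coalescent_subtree(labels, coalescent_depth, rng, stem_top)
        kids = node.child_nodes()
        age = species_tree.age(node)
        return _Node(None, age, [build(k_, age) for k_ in kids])

    root = build(species_tree.dendropy_tree.seed_node, None)
    return _to_ultrametric(root), truth


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def evolve_sequences(
    gene_tree: UltrametricTree,
    subst_rate: float,
    seq_length: int,
    seed: int | np.random.Generator,
) -> list[SequenceRecord]:
    """Jukes-Cantor evolution along the gene tree.

    Per edge of duration ``t`` each site changes with probability
    ``(3/4) * (1 - exp(-(4/3) * subst_rate * t))``, uniformly to one of the
    other three bases.
    """
    if subst_rate < 0 or seq_length < 1:
        raise DomainError("need subst_rate >= 0 and seq_length >= 1")
    rng = _as_rng(seed)
    tree = gene_tree.dendropy_tree
    seqs: dict[int, np.ndarray] = {}
    records: list[SequenceRecord] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seq = rng.integers(0, 4, size=seq_length)
        else:
            t = node.edge.length or 0.0
            p_change = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * subst_rate * t))
            seq = seqs[id(node.parent_node)].copy()
            hit = rng.random(seq_length) < p_change
            n_hit = int(hit.sum())
            if n_hit:
                seq[hit] = (seq[hit] + rng.integers(1, 4, size=n_hit)) % 4
        seqs[id(node)] = seq
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            records.append(
                SequenceRecord(id=label, seq="".join(_BASES[seq]))
            )
    records.sort(key=lambda r: r.id)
    return records


def expected_p_distance(subst_rate: float, patristic_time: float) -> float:
    """Closed-form JC expectation used as a simulation oracle."""
    return 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * subst_rate * patristic_time))


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Calibration of one sampling scenario (one group of datasets)."""

    name: str
    clade: str                      # "asexual" or "sexual"
    n_datasets: int
    r: float                        # net diversification, Myr^-1
    eps: float = 0.0
    n_species: int = 12
    coalescent_depth: float = 0.8   # expected within-species TMRCA, Myr
    samples_mean: float = 8.0
    samples_dispersion: float = 5.0
    singleton_target: float = 0.3   # proportion of species sampled once
    seq_length: int = 600
    subst_rate: float = 0.01        # per site per Myr
    limnoterrestrial_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.r <= 0 or not (0 <= self.eps < 1):
            raise DomainError("rates out of domain")
        if not (0 <= self.singleton_target <= 1):
            raise DomainError("singleton_target must lie in [0, 1]")


#: group-level defaults; diversification rates and sampling means follow the
#: asymmetric design the pipeline is meant to resolve
PRESETS: dict[str, ScenarioConfig] = {
    "asexual_like": ScenarioConfig(
        name="asexual_like",
        clade="asexual",
        n_datasets=6,
        r=0.072,
        samples_mean=5.63,
        singleton_target=0.45,
        limnoterrestrial_fraction=0.7,
    ),
    "sexual_like": ScenarioConfig(
        name="sexual_like",
        clade="sexual",
        n_datasets=7,
        r=0.048,
        samples_mean=16.4,
        singleton_target=0.15,
    ),
}


def draw_samples_per_species(
    config: ScenarioConfig, n_species: int, rng: np.random.Generator
) -> dict[str, int]:
    """Sample counts: singletons with probability ``singleton_target``,
    otherwise 2 + a negative-binomial surplus tuned to hit
    ``samples_mean`` on average."""
    s0 = config.singleton_target
    extra_mean = (config.samples_mean - s0 - 2.0 * (1.0 - s0)) / max(
        1.0 - s0, 1e-12
    )
    extra_mean = max(extra_mean, 0.0)
    counts: dict[str, int] = {}
    size = config.samples_dispersion
    for i in range(n_species):
        if rng.random() < s0:
            k = 1
        elif extra_mean == 0.0:
            k = 2
        else:
            p = size / (size + extra_mean)
            k = 2 + int(rng.negative_binomial(size, p))
        counts[f"sp{i + 1}"] = k
    return counts


@dataclass
class DatasetBundle:
    """One simulated dataset with its generating truth."""

    name: str
    clade: str
    habitat: str
    species_tree: UltrametricTree
    gene_tree: UltrametricTree
    truth: dict[str, str]
    records: list[SequenceRecord]
    meta: pd.DataFrame
    r: float
    eps: float
    samples_per_species: dict[str, int]


@dataclass
class ScenarioBundle:
    config: ScenarioConfig
    datasets: list[DatasetBundle] = field(default_factory=list)


def make_scenario(
    preset: str | ScenarioConfig,
    seed: int | np.random.Generator,
    overrides: dict | None = None,
) -> ScenarioBundle:
    """Generate a full group of datasets for a preset.

    ``overrides`` replaces individual :class:`ScenarioConfig` fields (e.g.
    ``{"n_species": 6}`` for a desk-scale run).
    """
    if isinstance(preset, ScenarioConfig):
        config = preset
    else:
        if preset not in PRESETS:
            raise DomainError(
                f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
            )
        config = PRESETS[preset]
    if overrides:
        config = dataclasses.replace(config, **overrides)
    rng = _as_rng(seed)
    bundle = ScenarioBundle(config=config)
    for d in range(config.n_datasets):
        name = f"{config.name}_{d + 1}"
        habitat = (
            "limnoterrestrial"
            if rng.random() < config.limnoterrestrial_fraction
            else "aquatic"
        )
        species_tree = simulate_bd_tree(
            config.r, config.eps, config.n_species, rng
        )
        counts = draw_samples_per_species(config, config.n_species, rng)
        gene_tree, truth = simulate_gene_tree(
            species_tree, config.coalescent_depth, counts, rng
        )
        records = evolve_sequences(
            gene_tree, config.subst_rate, config.seq_length, rng
        )
        meta = pd.DataFrame(
            {
                "id": [rec.id for rec in records],
                "dataset": name,
                "clade": config.clade,
                "habitat": habitat,
                "seq_length": rng.integers(450, 659, size=len(records)),
            }
        )
        for rec in records:
            rec.meta = {
                "dataset": name,
                "clade": config.clade,
                "habitat": habitat,
                "seq_length": int(
                    meta.loc[meta["id"] == rec.id, "seq_length"].iloc[0]
                ),
            }
        bundle.datasets.append(
            DatasetBundle(
                name=name,
                clade=config.clade,
                habitat=habitat,
                species_tree=species_tree,
                gene_tree=gene_tree,
                truth=truth,
                records=records,
                meta=meta,
                r=config.r,
                eps=config.eps,
                samples_per_species=counts,
            )
        )
    return bundle


# ---------------------------------------------------------------------------
# bundle persistence
# ---------------------------------------------------------------------------

def write_bundle(bundle: ScenarioBundle, outdir: str | Path) -> None:
    """Write ``<dataset>/gene_tree.nwk``, ``alignment.fasta``, ``meta.tsv``
    and ``truth.json`` for every dataset."""
    outdir = Path(outdir)
    for ds in bundle.datasets:
        d = outdir / ds.name
        d.mkdir(parents=True, exist_ok=True)
        write_newick(ds.gene_tree, d / "gene_tree.nwk")
        write_newick(ds.species_tree, d / "species_tree.nwk")
        write_fasta(ds.records, d / "alignment.fasta")
        ds.meta.to_csv(d / "meta.tsv", sep="\t", index=False)
        truth = {
            "tip_to_species": ds.truth,
            "r": ds.r,
            "eps": ds.eps,
            "n_species": len(ds.samples_per_species),
            "samples_per_species": ds.samples_per_species,
            "clade": ds.clade,
            "habitat": ds.habitat,
        }
        (d / "truth.json").write_text(json.dumps(truth, indent=1))


__all__ = [
    "ScenarioConfig",
    "ScenarioBundle",
    "DatasetBundle",
    "PRESETS",
    "simulate_bd_tree",
    "simulate_gene_tree",
    "evolve_sequences",
    "expected_p_distance",
    "draw_samples_per_species",
    "make_scenario",
    "write_bundle",
]
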
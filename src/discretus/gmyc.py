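"""Single-threshold mixed Yule/coalescent species delimitation.

The model classifies branching events on an ultrametric gene tree into a
diversification class (older than a threshold time ``T``) and a coalescent
class (younger than ``T``, operating independently inside each cluster
founded by a branch crossing ``T``).  Waiting times between successive
events are modelled as exponentials whose rate sums the per-class hazards:

* diversification class: ``lambda_div * k**p_div`` with ``k`` lineages
  rootward of ``T``; tipward of ``T`` the ``m + 1`` crossing species
  lineages keep contributing event-free exposure,
* coalescent class: ``lambda_coal * sum_j (c_j * (c_j - 1))**p_coal`` over
  clusters ``j`` with ``c_j`` lineages (only tipward of ``T``).

Each inter-event segment is paired with the event at its rootward end and
all lineage counts are taken within that segment (the counts just tipward
of the event), which makes the one-class null model the classical
coalescent likelihood.  The event density uses the full hazard of the
class in which the event occurs.  The null model is a single class with
hazard ``lambda * (k*(k-1))**p`` over the whole tree; it is reproduced
exactly by the degenerate "one cluster" threshold placed at the root, so
the maximized two-class likelihood can never fall below the null one.

Rates are profiled out analytically (they enter the likelihood linearly in
log space), leaving a 1-D bounded search over each scaling exponent in
``[0, 2]``; the threshold itself is profiled over midpoints between
consecutive distinct node ages.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .errors import DomainError, FitError, InsufficientDataError
from .io_core import UltrametricTree

P_BOUNDS = (0.0, 2.0)

_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# event bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class _TreeEvents:
    """Internal nodes sorted by age (root first) with parent pointers."""

    ages: np.ndarray           # descending internal-node ages, length n-1
    parent: np.ndarray         # index of parent event, -1 for the root
    nodes: list                # dendropy nodes in the same order
    n_tips: int

    @property
    def n_events(self) -> int:
        return len(self.ages)


def _tree_events(tree: UltrametricTree) -> _TreeEvents:
    internals = list(tree.dendropy_tree.preorder_internal_node_iter())
    ages = np.array([tree.age(n) for n in internals])
    order = np.argsort(-ages, kind="stable")
    nodes = [internals[i] for i in order]
    ages = ages[order]
    index = {id(node): i for i, node in enumerate(nodes)}
    parent = np.empty(len(nodes), dtype=int)
    for i, node in enumerate(nodes):
        parent[i] = index[id(node.parent_node)] if node.parent_node else -1
    return _TreeEvents(
        ages=ages, parent=parent, nodes=nodes, n_tips=tree.n_tips
    )


def _coal_clusters(events: _TreeEvents, m: int) -> np.ndarray:
    """Cluster label for each coalescent event under a threshold cutting
    after the ``m`` oldest events.

    The label of event ``i >= m`` is the index of the rootmost coalescent
    ancestor event on its path (the event just below the crossing branch).
    """
    n_ev = events.n_events
    cluster = np.empty(n_ev, dtype=int)
    for i in range(m, n_ev):
        p = events.parent[i]
        cluster[i] = i if p < m else cluster[p]
    return cluster


@dataclass
class _CandidateData:
    """Precomputed arrays for the profiled likelihood at one threshold.

    Coalescent segments are flattened: ``pairs`` holds every cluster pair
    count ``c*(c-1) >= 2`` of every segment, ``w_pairs`` the matching
    segment width, and ``seg_starts[i]`` the offset of the segment paired
    with the i-th coalescent event (the event density uses the summed
    hazard of all clusters in that segment).
    """

    m: int                     # number of diversification events
    threshold: float
    k_div: np.ndarray          # lineage counts for div segments (2..m+1)
    w_div: np.ndarray          # widths of div segments
    pairs: np.ndarray          # flattened cluster pair counts (>= 2 only)
    w_pairs: np.ndarray        # matching segment widths
    seg_starts: np.ndarray     # segment offsets into ``pairs``, per event


def _candidate_data(events: _TreeEvents, m: int, threshold: float) -> _CandidateData:
    ages = events.ages
    n_ev = events.n_events
    # diversification side: segments S_2 .. S_{m+1}, the last truncated at T
    k_div = np.arange(2, m + 2, dtype=float)
    if m > 0:
        widths = [ages[k - 2] - ages[k - 1] for k in range(2, m + 1)]
        widths.append(ages[m - 1] - threshold)
        w_div = np.array(widths)
    else:
        w_div = np.empty(0)
    # coalescent side: walk events m .. n_ev-1, maintaining cluster sizes
    cluster = _coal_clusters(events, m)
    counts: dict[int, int] = {}
    pairs: list[float] = []
    w_pairs: list[float] = []
    seg_starts: list[int] = []
    for i in range(m, n_ev):
        lo = ages[i + 1] if i + 1 < n_ev else 0.0
        width = ages[i] - lo
        counts[cluster[i]] = counts.get(cluster[i], 1) + 1
        seg_starts.append(len(pairs))
        for cj in counts.values():
            if cj >= 2:
                pairs.append(cj * (cj - 1))
                w_pairs.append(width)
    return _CandidateData(
        m=m,
        threshold=threshold,
        k_div=k_div,
        w_div=w_div,
        pairs=np.asarray(pairs, dtype=float),
        w_pairs=np.asarray(w_pairs, dtype=float),
        seg_starts=np.asarray(seg_starts, dtype=int),
    )


# ---------------------------------------------------------------------------
# profiled likelihood pieces
# ---------------------------------------------------------------------------

def _profiled_class_loglik(
    pairs: np.ndarray,
    widths: np.ndarray,
    seg_starts: np.ndarray,
    p: float,
    extra_pairs: np.ndarray | None = None,
    extra_widths: np.ndarray | None = None,
) -> tuple[float, float]:
    """Maximized-over-rate log-likelihood of one event class at exponent p.

    The class hazard in a segment is ``rate * sum_j pairs_j**p`` over that
    segment's flattened entries; each event's density uses the summed
    hazard of its own segment.  ``extra_pairs``/``extra_widths`` add
    event-free exposure (e.g. the species-lineage hazard tipward of the
    threshold).  With ``E`` events and exposure ``S(p)`` the rate MLE is
    ``E / S(p)``.
    """
    n_evt = len(seg_starts)
    if n_evt == 0:
        return 0.0, float("nan")
    powered = pairs**p
    exposure = float(np.dot(powered, widths))
    if extra_pairs is not None:
        exposure += float(np.dot(extra_pairs**p, extra_widths))
    if exposure <= 0:
        return -np.inf, float("nan")
    rate = n_evt / exposure
    seg_sums = np.add.reduceat(powered, seg_starts)
    loglik = (
        n_evt * np.log(rate) + float(np.sum(np.log(seg_sums))) - n_evt
    )
    return loglik, rate


def _maximize_exponent(
    pairs: np.ndarray,
    widths: np.ndarray,
    seg_starts: np.ndarray,
    extra_pairs: np.ndarray | None = None,
    extra_widths: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """1-D bounded search over the scaling exponent; returns
    ``(loglik, rate_hat, p_hat)``."""
    if len(seg_starts) == 0:
        return 0.0, float("nan"), float("nan")

    def neg(p: float) -> float:
        return -_profiled_class_loglik(
            pairs, widths, seg_starts, p, extra_pairs, extra_widths
        )[0]

    res = minimize_scalar(
        neg, bounds=P_BOUNDS, method="bounded", options={"xatol": 1e-8}
    )
    if not res.success:  # pragma: no cover - bounded search rarely fails
        raise FitError(f"exponent search failed: {res.message}")
    p_hat = float(res.x)
    # guard against interior local issues: compare with the boundary values
    best_ll, best_p = -float(res.fun), p_hat
    for p_edge in P_BOUNDS:
        ll_edge = _profiled_class_loglik(
            pairs, widths, seg_starts, p_edge, extra_pairs, extra_widths
        )[0]
        if ll_edge > best_ll + 1e-12:
            best_ll, best_p = ll_edge, p_edge
    ll, rate = _profiled_class_loglik(
        pairs, widths, seg_starts, best_p, extra_pairs, extra_widths
    )
    return ll, rate, best_p


def _segment_widths(ages: np.ndarray) -> np.ndarray:
    bounds = np.concatenate([ages, [0.0]])
    return bounds[:-1] - bounds[1:]


def _fit_null(events: _TreeEvents) -> tuple[float, float, float]:
    """Single-class coalescent null: hazard lambda * (k*(k-1))**p."""
    n = events.n_tips
    k = np.arange(2, n + 1, dtype=float)
    counts = k * (k - 1.0)
    widths = _segment_widths(events.ages)
    return _maximize_exponent(counts, widths, np.arange(n - 1))


def _fit_candidate(
    events: _TreeEvents, data: _CandidateData
) -> dict[str, float]:
    # the m+1 species lineages keep diversification exposure (no events)
    # over [0, T]; this is what penalizes spuriously young thresholds
    ll_div, lam_div, p_div = _maximize_exponent(
        data.k_div,
        data.w_div,
        np.arange(data.m),
        extra_pairs=np.array([data.m + 1.0]),
        extra_widths=np.array([data.threshold]),
    )
    ll_coal, lam_coal, p_coal = _maximize_exponent(
        data.pairs, data.w_pairs, data.seg_starts
    )
    return {
        "loglik": ll_div + ll_coal,
        "lambda_div": lam_div,
        "p_div": p_div,
        "lambda_coal": lam_coal,
        "p_coal": p_coal,
    }


# ---------------------------------------------------------------------------
# public likelihood (direct, un-profiled evaluation)
# ---------------------------------------------------------------------------

def gmyc_likelihood(
    tree: UltrametricTree,
    threshold_T: float,
    params: dict,
    unified_bookkeeping: bool = False,
) -> float:
    """Log-likelihood of the two-class model at an arbitrary threshold.

    ``params`` holds ``lambda_div, p_div, lambda_coal, p_coal``.  With
    ``unified_bookkeeping=True`` both classes use the total-lineage pair
    count ``k*(k-1)`` (no per-cluster bookkeeping), in which case equal
    rates and exponents reproduce the one-class null likelihood exactly.
    """
    lam_d = float(params["lambda_div"])
    p_d = float(params["p_div"])
    lam_c = float(params["lambda_coal"])
    p_c = float(params["p_coal"])
    if lam_d <= 0 or lam_c <= 0:
        raise DomainError("rates must be positive")
    events = _tree_events(tree)
    ages = events.ages
    root_age = float(ages[0])
    if not (0.0 < threshold_T < root_age):
        raise DomainError(
            f"threshold {threshold_T} outside (0, root age {root_age})"
        )
    m = int(np.sum(ages > threshold_T))
    cluster = _coal_clusters(events, m)
    counts: dict[int, int] = {}
    loglik = 0.0
    n_ev = events.n_events
    for i in range(n_ev):
        lo = ages[i + 1] if i + 1 < n_ev else 0.0
        hi = ages[i]
        k = i + 2  # lineages in the segment tipward of event i
        if i < m:
            # diversification event: density uses the class hazard
            base = k * (k - 1) if unified_bookkeeping else k
            loglik += np.log(lam_d * base**p_d)
        else:
            counts[cluster[i]] = counts.get(cluster[i], 1) + 1
            if unified_bookkeeping:
                hazard_evt = lam_c * (k * (k - 1.0)) ** p_c
            else:
                # coalescent event: density uses the summed hazard of all
                # clusters in the segment tipward of the event
                hazard_evt = lam_c * sum(
                    (c * (c - 1.0)) ** p_c
                    for c in counts.values()
                    if c >= 2
                )
            loglik += np.log(hazard_evt)
        # survival over the segment (hi -> lo), split at the threshold
        div_hi, div_lo = hi, max(lo, threshold_T)
        coal_hi, coal_lo = min(hi, threshold_T), lo
        if div_hi > div_lo:
            base = k * (k - 1) if unified_bookkeeping else k
            loglik -= lam_d * base**p_d * (div_hi - div_lo)
        if coal_hi > coal_lo:
            if not unified_bookkeeping:
                # the m+1 species lineages keep diversification exposure
                # tipward of the threshold (no events occur there)
                loglik -= lam_d * (m + 1.0) ** p_d * (coal_hi - coal_lo)
            if unified_bookkeeping:
                hazard = lam_c * (k * (k - 1.0)) ** p_c
            else:
                # clusters not yet split hold one lineage and cannot coalesce
                hazard = lam_c * sum(
                    (c * (c - 1.0)) ** p_c
                    for c in counts.values()
                    if c >= 2
                )
            loglik -= hazard * (coal_hi - coal_lo)
    return float(loglik)


def null_likelihood(tree: UltrametricTree, lam: float, p: float) -> float:
    """One-class coalescent log-likelihood (hazard lambda * (k(k-1))**p)."""
    if lam <= 0:
        raise DomainError("rate must be positive")
    events = _tree_events(tree)
    n = events.n_tips
    k = np.arange(2, n + 1, dtype=float)
    counts = k * (k - 1.0)
    widths = _segment_widths(events.ages)
    return float(
        np.sum(np.log(lam * counts**p)) - lam * np.dot(counts**p, widths)
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class GMYCFit:
    """Result of the two-class threshold model fit."""

    threshold_T: float
    lambda_div: float
    p_div: float
    lambda_coal: float
    p_coal: float
    loglik_null: float
    loglik_gmyc: float
    lr_chi2: float
    df: int
    p_value: float
    n_entities: int
    null_lambda: float = float("nan")
    null_p: float = float("nan")
    m_div_events: int = 0
    candidate_thresholds: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )
    candidate_logliks: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )

    def as_dict(self) -> dict:
        return {
            "threshold_T": self.threshold_T,
            "lambda_div": self.lambda_div,
            "p_div": self.p_div,
            "lambda_coal": self.lambda_coal,
            "p_coal": self.p_coal,
            "loglik_null": self.loglik_null,
            "loglik_gmyc": self.loglik_gmyc,
            "lr_chi2": self.lr_chi2,
            "df": self.df,
            "p_value": self.p_value,
            "n_entities": self.n_entities,
        }


def fit_gmyc(tree: UltrametricTree, df: int = 2) -> GMYCFit:
    """Fit the null and two-class models and run the likelihood-ratio test.

    ``df`` selects the chi-square convention: 2 (threshold profiled, the
    default) or 3 (threshold counted as a parameter).
    """
    if df not in (2, 3):
        raise DomainError("df must be 2 or 3")
    if tree.n_tips < 4:
        raise InsufficientDataError(
            f"GMYC fit needs >= 4 tips, got {tree.n_tips}"
        )
    events = _tree_events(tree)
    ll_null, lam_null, p_null = _fit_null(events)

    ages = events.ages
    best = {
        "loglik": ll_null,
        "lambda_div": float("nan"),
        "p_div": float("nan"),
        "lambda_coal": lam_null,
        "p_coal": p_null,
    }
    best_m, best_T = 0, float(ages[0])
    cand_T = [best_T]
    cand_ll = [ll_null]
    for m in range(1, events.n_events):
        if ages[m - 1] - ages[m] <= _TIE_TOL * max(ages[0], 1.0):
            continue  # tied ages cannot be separated by a threshold
        threshold = 0.5 * (ages[m - 1] + ages[m])
        data = _candidate_data(events, m, threshold)
        fit = _fit_candidate(events, data)
        cand_T.append(threshold)
        cand_ll.append(fit["loglik"])
        # ties broken toward the youngest threshold (most clusters)
        if fit["loglik"] >= best["loglik"] - 1e-9:
            if fit["loglik"] > best["loglik"] + 1e-9 or m > best_m:
                best = fit
                best_m, best_T = m, threshold
    if best["loglik"] < ll_null - 1e-6:
        raise FitError("two-class likelihood fell below the null likelihood")
    lr = max(2.0 * (best["loglik"] - ll_null), 0.0)
    p_value = float(chi2.sf(lr, df)) if lr > 0 else 1.0
    return GMYCFit(
        threshold_T=best_T,
        lambda_div=best["lambda_div"],
        p_div=best["p_div"],
        lambda_coal=best["lambda_coal"],
        p_coal=best["p_coal"],
        loglik_null=ll_null,
        loglik_gmyc=best["loglik"],
        lr_chi2=lr,
        df=df,
        p_value=p_value,
        n_entities=best_m + 1,
        null_lambda=lam_null,
        null_p=p_null,
        m_div_events=best_m,
        candidate_thresholds=np.asarray(cand_T),
        candidate_logliks=np.asarray(cand_ll),
    )


# ---------------------------------------------------------------------------
# partition extraction
# ---------------------------------------------------------------------------

@dataclass
class SpeciesPartition:
    """Assignment of tips to delimited clusters, singletons flagged."""

    clusters: dict[str, list[str]]
    singletons: set[str]
    fit: GMYCFit | None = None

    @property
    def n_entities(self) -> int:
        return len(self.clusters)

    @property
    def tip_to_species(self) -> dict[str, str]:
        return {
            tip: sp for sp, tips in self.clusters.items() for tip in tips
        }

    def species_of(self, tip: str) -> str:
        return self.tip_to_species[tip]


def partition_at_threshold(
    tree: UltrametricTree, threshold_T: float, fit: GMYCFit | None = None
) -> SpeciesPartition:
    """Partition tips by the branches crossing ``threshold_T``."""
    dtree = tree.dendropy_tree
    root = dtree.seed_node
    founders = []
    if threshold_T >= tree.age(root):
        founders = [root]
    else:
        for node in dtree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if tree.age(node) < threshold_T <= tree.age(node.parent_node):
                founders.append(node)
    founders.sort(
        key=lambda nd: (-tree.age(nd), _node_label(nd))
    )
    clusters: dict[str, list[str]] = {}
    singletons: set[str] = set()
    for i, node in enumerate(founders, start=1):
        sp = f"sp{i}"
        tips = sorted(
            leaf.taxon.label if leaf.taxon else leaf.label
            for leaf in node.leaf_iter()
        )
        clusters[sp] = tips
        if len(tips) == 1:
            singletons.add(sp)
    return SpeciesPartition(clusters=clusters, singletons=singletons, fit=fit)


def _node_label(node) -> str:
    leaf = next(node.leaf_iter())
    return leaf.taxon.label if leaf.taxon else str(leaf.label)


def extract_partition(fit: GMYCFit, tree: UltrametricTree) -> SpeciesPartition:
    part = partition_at_threshold(tree, fit.threshold_T, fit=fit)
    if part.n_entities != fit.n_entities:  # pragma: no cover - consistency
        raise FitError(
            f"partition has {part.n_entities} entities but the fit "
            f"reported {fit.n_entities}"
        )
    return part


# ---------------------------------------------------------------------------
# subsample-and-refit utility
# ---------------------------------------------------------------------------

@dataclass
class SubsampleSummary:
    fraction: float
    reps: int
    skipped: int
    p_values: np.ndarray
    n_entities: np.ndarray

    @property
    def mean_p_value(self) -> float:
        return float(np.mean(self.p_values)) if len(self.p_values) else float("nan")


def subsample_refit(
    tree: UltrametricTree,
    fraction: float,
    reps: int,
    seed: int | np.random.Generator,
    aln=None,
    df: int = 2,
) -> SubsampleSummary:
    """Randomly delete tips, refit, and summarize model-fit deterioration.

    ``fraction`` is the proportion of tips retained per replicate; pruned
    trees with fewer than 4 tips are skipped and counted.
    """
    if not (0.0 < fraction <= 1.0):
        raise DomainError("fraction must lie in (0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    labels = tree.tip_labels
    n_keep = int(round(fraction * len(labels)))
    p_values: list[float] = []
    n_entities: list[int] = []
    skipped = 0
    for _ in range(reps):
        if n_keep >= len(labels):
            sub = tree
        else:
            keep = rng.choice(labels, size=n_keep, replace=False)
            if n_keep < 4:
                skipped += 1
                continue
            sub = tree.prune_to(sorted(keep))
        try:
            fit = fit_gmyc(sub, df=df)
        except InsufficientDataError:
            skipped += 1
            continue
        p_values.append(fit.p_value)
        n_entities.append(fit.n_entities)
    return SubsampleSummary(
        fraction=fraction,
        reps=reps,
        skipped=skipped,
        p_values=np.asarray(p_values),
        n_entities=np.asarray(n_entities, dtype=int),
    )


__all__ = [
    "GMYCFit",
    "SpeciesPartition",
    "SubsampleSummary",
    "gmyc_likelihood",
    "null_likelihood",
    "fit_gmyc",
    "extract_partition",
    "partition_at_threshold",
    "subsample_refit",
]
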
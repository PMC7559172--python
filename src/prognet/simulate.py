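"""Synthetic inputs with known ground truth for every pipeline stage.

Generators cover (a) study tables drawn from a normal random-effects model
on the log-HR scale, (b) the same with p-value-dependent study suppression
(funnel asymmetry), (c) random background graphs with planted dense
modules, and (d) gene-set universes with planted enriched terms.  Every
generator is a pure function of its config and seed; identical calls are
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .io import StudyRecord

__all__ = [
    "MetaSimConfig",
    "GraphSimConfig",
    "simulate_meta",
    "simulate_biased_meta",
    "simulate_ppi",
    "simulate_annotation",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MetaSimConfig:
    """Random-effects data-generating process for study-level log HRs.

    True study effects are ``theta_i ~ N(mu, tau2)``; per-study standard
    errors are Uniform(se_low, se_high); observed ``y_i ~ N(theta_i, se_i^2)``.
    """

    k_studies: int
    mu: float
    tau2: float
    se_low: float
    se_high: float
    seed: int

    def __post_init__(self) -> None:
        if self.k_studies < 2:
            raise ValueError("k_studies must be >= 2")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if not (0 < self.se_low <= self.se_high):
            raise ValueError("need 0 < se_low <= se_high")


def _draw_study(rng: np.random.Generator, cfg: MetaSimConfig, idx: int):
    theta = rng.normal(cfg.mu, math.sqrt(cfg.tau2))
    se = rng.uniform(cfg.se_low, cfg.se_high)
    y = rng.normal(theta, se)
    n = int(rng.integers(30, 400))
    # emit as a published-style HR with 95% CI, rounded to 6 decimals
    hr = round(math.exp(y), 6)
    lo = round(math.exp(y - _Z95 * se), 6)
    hi = round(math.exp(y + _Z95 * se), 6)
    record = StudyRecord(
        study_id=f"sim_{idx + 1:03d}",
        hr=hr,
        ci_lower=lo,
        ci_upper=hi,
        ethnicity="Asian" if idx % 2 == 0 else "non-Asian",
        specimen="tissue" if idx % 2 == 0 else "serum",
        n_patients=n,
    )
    return record, theta, y, se


def simulate_meta(config: MetaSimConfig) -> tuple[list[StudyRecord], dict]:
    """Draw a study table from the random-effects model.

    Returns the records plus a truth record with ``mu``, ``tau2`` and the
    per-study latent effects, observed log HRs and SEs.
    """
    rng = np.random.default_rng(config.seed)
    records, thetas, ys, ses = [], [], [], []
    for i in range(config.k_studies):
        rec, theta, y, se = _draw_study(rng, config, i)
        records.append(rec)
        thetas.append(theta)
        ys.append(y)
        ses.append(se)
    truth = {
        "mu": config.mu,
        "tau2": config.tau2,
        "theta": thetas,
        "y": ys,
        "se": ses,
    }
    return records, truth


def simulate_biased_meta(
    config: MetaSimConfig,
    suppress_if_p_above: float = 0.05,
    suppress_prob: float = 0.9,
    max_attempts_per_study: int = 200,
) -> list[StudyRecord]:
    """Study table with publication-bias-style selective suppression.

    Candidate studies are generated from the same stream as
    :func:`simulate_meta`; each candidate whose two-sided p-value exceeds
    ``suppress_if_p_above`` is dropped with probability ``suppress_prob``
    (suppression coins come from an independent stream, so
    ``suppress_prob=0`` reproduces :func:`simulate_meta` exactly).
    Generation continues until ``k_studies`` survive or the attempt cap is
    reached.
    """
    if not (0 <= suppress_if_p_above <= 1 and 0 <= suppress_prob <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    coin_rng = np.random.default_rng((config.seed + 1) % 2**31)
    survivors: list[StudyRecord] = []
    attempts = 0
    limit = max_attempts_per_study * config.k_studies
    while len(survivors) < config.k_studies:
        if attempts >= limit:
            raise RuntimeError(
                "suppression too strong: attempt cap reached before "
                f"{config.k_studies} studies survived"
            )
        rec, _, y, se = _draw_study(rng, config, len(survivors))
        attempts += 1
        p = 2.0 * stats.norm.sf(abs(y / se))
        if p > suppress_if_p_above and coin_rng.uniform() < suppress_prob:
            continue
        survivors.append(rec)
    return survivors


@dataclass(frozen=True)
class GraphSimConfig:
    """Background G(n, p) graph with planted dense modules.

    ``planted_modules`` is a list of ``(size, internal_density)`` pairs;
    planted nodes are disjoint and occupy the first node labels.  Edge
    confidence scores are Uniform(0.4, 1.0) inside planted modules and
    Uniform(0.15, 0.9) elsewhere.
    """

    n_nodes: int
    background_edge_prob: float
    planted_modules: tuple = ()
    inter_module_edges: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.background_edge_prob <= 1):
            raise ValueError("background_edge_prob must lie in [0, 1]")
        total = sum(s for s, _ in self.planted_modules)
        if total > self.n_nodes:
            raise ValueError("planted module sizes exceed n_nodes")
        for s, d in self.planted_modules:
            if s < 2 or not (0 < d <= 1):
                raise ValueError("module sizes must be >= 2, densities in (0, 1]")


def simulate_ppi(config: GraphSimConfig) -> tuple[nx.Graph, list[set[str]]]:
    """Generate the scored network and return it with planted memberships."""
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_nodes)))
    names = [f"G{i:0{width}d}" for i in range(config.n_nodes)]
    graph = nx.Graph()
    graph.add_nodes_from(names)
    memberships: list[set[str]] = []
    cursor = 0
    planted_nodes: set[str] = set()
    for size, density in config.planted_modules:
        members = names[cursor : cursor + size]
        cursor += size
        memberships.append(set(members))
        planted_nodes.update(members)
        pairs = [
            (members[i], members[j])
            for i in range(size)
            for j in range(i + 1, size)
        ]
        n_internal = int(round(density * len(pairs)))
        chosen = rng.choice(len(pairs), size=n_internal, replace=False)
        for idx in chosen:
            a, b = pairs[idx]
            graph.add_edge(a, b, score=float(rng.uniform(0.4, 1.0)))
    # background edges avoid planted-planted pairs: modules touch the rest of
    # the graph only through sparse explicit inter-module connections
    for i in range(config.n_nodes):
        for j in range(i + 1, config.n_nodes):
            a, b = names[i], names[j]
            if a in planted_nodes and b in planted_nodes:
                continue
            if rng.uniform() < config.background_edge_prob:
                graph.add_edge(a, b, score=float(rng.uniform(0.15, 0.9)))
    # explicit sparse module-to-background connections
    background = [v for v in names if v not in planted_nodes]
    if config.inter_module_edges and planted_nodes and background:
        for _ in range(config.inter_module_edges):
            a = str(rng.choice(sorted(planted_nodes)))
            b = str(rng.choice(background))
            if a != b and not graph.has_edge(a, b):
                graph.add_edge(a, b, score=float(rng.uniform(0.15, 0.9)))
    return graph, memberships


def simulate_annotation(
    universe_size: int,
    n_terms: int,
    term_size_range: tuple[int, int],
    planted: Sequence[tuple[int, int]] = (),
    query_size: int = 100,
    seed: int = 0,
) -> tuple[dict[str, set[str]], list[str], dict]:
    """Gene-set collection plus a query list with planted enriched terms.

    ``planted`` holds ``(term_index, query_overlap)`` pairs: the query is
    forced to contain exactly that many genes of each planted term; the
    remaining query genes are drawn uniformly from the rest of the universe,
    so non-planted terms overlap at hypergeometric-null rates.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:05d}" for i in range(universe_size)]
    lo, hi = term_size_range
    if not (1 <= lo <= hi <= universe_size):
        raise ValueError("invalid term_size_range")
    collection: dict[str, set[str]] = {}
    term_names = [f"TERM{i:04d}" for i in range(n_terms)]
    for name in term_names:
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe_size, size=size, replace=False)
        collection[name] = {genes[i] for i in members}
    query: set[str] = set()
    for term_idx, overlap in planted:
        term_genes = sorted(collection[term_names[term_idx]])
        if overlap > min(len(term_genes), query_size):
            raise ValueError(
                f"infeasible overlap {overlap} for term {term_names[term_idx]}"
            )
        picked = rng.choice(len(term_genes), size=overlap, replace=False)
        query.update(term_genes[i] for i in picked)
    planted_gene_pool = set().union(
        *(collection[term_names[i]] for i, _ in planted)
    ) if planted else set()
    filler = [g for g in genes if g not in planted_gene_pool and g not in query]
    need = query_size - len(query)
    if need < 0:
        raise ValueError("planted overlaps exceed query_size")
    extra = rng.choice(len(filler), size=need, replace=False)
    query.update(filler[i] for i in extra)
    truth = {
        "planted_terms": [term_names[i] for i, _ in planted],
        "planted_overlaps": {term_names[i]: o for i, o in planted},
    }
    return collection, sorted(query), truth
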
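"""Group-level inference on centrality profiles.

Three statistical layers sit on top of the network construction:

- **Jackknife reliability.**  Each group's networks are rebuilt with every
  subject left out in turn; the leave-one-out spread gives a jackknife
  standard error and a normal-quantile confidence interval (99% by default,
  z = 2.576) per node and measure.  Reliability is reported, not enforced:
  node-measures whose observed value falls outside the envelope are flagged.

- **Permutation tests.**  For each group pair, subjects are pooled and
  reshuffled into pseudo-groups of the original sizes (covariates travel
  with their subjects); both partial-correlation matrices and top-E networks
  are rebuilt and all four centralities recomputed per reshuffle.  Two-sided
  p-values use the add-one rule ``(1 + #{|d_perm| >= |d_obs|}) / (n_perm + 1)``
  and are therefore strictly in (0, 1].  By default every replicate —
  including the observed split — derives its own pairwise-matched edge
  count, which keeps the test exact; anchoring replicates at the observed
  edge count is available as a config switch for sensitivity analyses.

- **Multi-measure decision rule.**  A node differs between groups only if
  the permutation p-values are <= alpha for at least three of the four
  measures (two of four for a-priori regions).  Under an independence
  approximation the chance bound for the 3-of-4 rule at alpha = 0.05 is
  0.05^3 = 0.000125; the measures are correlated in practice, so the bound
  is reported as stated, not attained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.stats import chi2_contingency

from covnet.centrality import MEASURES, CentralityTable, centrality_matrix
from covnet.cohort import RegionSet, ThicknessCohort
from covnet.network import (
    BinaryNetwork,
    binarize_top_edges_values,
    minimum_edge_count,
    partial_corr_values,
    partial_correlation_matrix,
    PartialCorrelationMatrix,
)
from covnet.screening import ScreenResult, screen_regions

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class GroupData:
    """One group's subjects: thickness rows plus their covariate rows."""

    label: str
    thickness: np.ndarray
    covariates: np.ndarray | None

    @property
    def n(self) -> int:
        return self.thickness.shape[0]

    @property
    def k(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]


@dataclass(frozen=True)
class JackknifeEnvelope:
    """Leave-one-out reliability envelope for one group's centralities.

    Arrays are 4 × p in the fixed measure order (degree, betweenness,
    closeness, eigenvector).
    """

    group: str
    mean: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_replicates: int
    z: float

    def covers(self, observed: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        """Boolean 4 × p mask: observed value inside the envelope."""
        return (observed >= self.ci_low - atol) & (observed <= self.ci_high + atol)


@dataclass(frozen=True)
class PermutationComparison:
    """Permutation test of one group pair across all nodes and measures."""

    group_pair: tuple[str, str]
    delta_obs: Mapping[str, np.ndarray]  # measure -> p-vector, first - second
    p_values: Mapping[str, np.ndarray]  # measure -> p-vector in (0, 1]
    n_permutations: int
    seed: int
    n_redrawn: int = 0


@dataclass(frozen=True)
class NodeDecision:
    """Significance decision for one node in one group-pair comparison."""

    node: str
    a_priori: bool
    measures_passing: int
    significant: bool
    direction: str  # group label, "mixed", or "none"


@dataclass(frozen=True)
class GroupComparisonReport:
    """Everything the pipeline produced for one cohort."""

    regions: RegionSet
    group_sizes: Mapping[str, int]
    screen: ScreenResult
    e_target: int
    min_edge_counts: Mapping[str, int]
    wiring_costs: Mapping[str, float]
    networks: Mapping[str, "BinaryNetwork"]
    centralities: Mapping[str, CentralityTable]
    jackknives: Mapping[str, JackknifeEnvelope]
    comparisons: tuple[PermutationComparison, ...]
    decisions: Mapping[tuple[str, str], tuple[NodeDecision, ...]]
    reliability_flags: Mapping[str, tuple[tuple[str, str], ...]]
    config: "PipelineConfig"

    def significant_nodes(self, pair: tuple[str, str]) -> tuple[str, ...]:
        return tuple(d.node for d in self.decisions[pair] if d.significant)

    def manifest(self) -> dict:
        """JSON-serializable run summary."""
        cfg = asdict(self.config)
        return {
            "n_regions": len(self.regions),
            "group_sizes": dict(self.group_sizes),
            "excluded_regions": list(self.screen.excluded_regions),
            "e_target": self.e_target,
            "min_edge_counts": dict(self.min_edge_counts),
            "wiring_costs": dict(self.wiring_costs),
            "comparisons": [
                {
                    "pair": list(c.group_pair),
                    "n_permutations": c.n_permutations,
                    "n_redrawn": c.n_redrawn,
                    "significant_nodes": list(self.significant_nodes(c.group_pair)),
                }
                for c in self.comparisons
            ],
            "reliability_flags": {
                g: [list(t) for t in flags]
                for g, flags in self.reliability_flags.items()
            },
            "config": cfg,
        }


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration."""

    covariates: tuple[str, ...] | None = None  # None = use all cohort covariates
    a_priori_regions: tuple[str, ...] = ()
    variance_alpha: float = 0.01
    perm_alpha: float = 0.05
    n_perm: int = 10000
    seed: int = 0
    cost_override: float | None = None
    recompute_cost_in_permutations: bool = True
    jackknife: bool = True
    jackknife_z: float = 2.576  # normal quantile for a 99% CI

    def __post_init__(self) -> None:
        if self.covariates is not None:
            object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "a_priori_regions", tuple(self.a_priori_regions))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


# ---------------------------------------------------------------------------
# building blocks


def _build_centralities(
    thickness: np.ndarray, covariates: np.ndarray | None, e_target: int
) -> np.ndarray:
    """Partial correlations → top-E network → 4 × p centrality matrix."""
    values = partial_corr_values(thickness, covariates)
    adj = binarize_top_edges_values(values, e_target)
    return centrality_matrix(adj)


def jackknife_envelope(
    group: GroupData, e_target: int, z: float = 2.576
) -> JackknifeEnvelope:
    """Leave-one-out envelope for one group at a fixed edge count.

    ``SE = sqrt(((n - 1) / n) * sum_i (theta_i - theta_bar)^2)`` with
    ``theta_i`` the statistic recomputed without subject ``i``; the interval
    is ``theta_bar ± z * SE`` (z = 2.576 for 99%).
    """
    n = group.n
    if n < group.k + 4:
        raise ValueError(
            f"jackknife needs n >= k + 4 (group {group.label!r}: n={n}, k={group.k})"
        )
    reps = []
    for i in range(n):
        keep = np.arange(n) != i
        cov = None if group.covariates is None else group.covariates[keep]
        try:
            reps.append(_build_centralities(group.thickness[keep], cov, e_target))
        except ValueError as err:
            raise ValueError(
                f"jackknife replicate {i} (group {group.label!r}) failed: {err}"
            ) from err
    reps_arr = np.stack(reps)  # n x 4 x p
    mean = reps_arr.mean(axis=0)
    se = np.sqrt((n - 1) / n * ((reps_arr - mean) ** 2).sum(axis=0))
    return JackknifeEnvelope(
        group.label, mean, se, mean - z * se, mean + z * se, n, z
    )


def permutation_test(
    group_a: GroupData,
    group_b: GroupData,
    e_target: int | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    recompute_cost: bool = True,
) -> PermutationComparison:
    """Permutation test of centrality differences between two groups.

    Pools the two groups' subjects, reshuffles them into pseudo-groups of
    the original sizes, rebuilds both networks, and recomputes all four
    centralities per reshuffle.  Deterministic given ``seed`` and invariant
    (up to the sign of the observed differences) under swapping the two
    groups.

    With ``recompute_cost=True`` (the default) each replicate re-derives the
    matched edge count from its own pseudo-groups, exactly as the observed
    groups did.  This keeps the test statistic a label-symmetric function of
    the pooled data, which is required for the permutation test to be exact.
    Reusing the observed edge count (``recompute_cost=False``) anchors every
    replicate at the observed percolation threshold — a point chosen from
    the observed split, where path-based measures are systematically extreme
    — and is measurably anti-conservative for betweenness; it is kept as an
    option for sensitivity analyses only.
    """
    # Canonical internal order so (A, B) and (B, A) share one null stream.
    flipped = group_b.label < group_a.label
    first, second = (group_b, group_a) if flipped else (group_a, group_b)

    if recompute_cost:
        # The statistic must be the same function of any split: centralities
        # at the split's own pairwise-matched edge count.
        v_first = partial_corr_values(first.thickness, first.covariates)
        v_second = partial_corr_values(second.thickness, second.covariates)
        e_obs = max(minimum_edge_count(v_first)[0], minimum_edge_count(v_second)[0])
        obs_first = centrality_matrix(binarize_top_edges_values(v_first, e_obs))
        obs_second = centrality_matrix(binarize_top_edges_values(v_second, e_obs))
    else:
        if e_target is None:
            raise ValueError("e_target is required when recompute_cost=False")
        obs_first = _build_centralities(first.thickness, first.covariates, e_target)
        obs_second = _build_centralities(second.thickness, second.covariates, e_target)
    delta = obs_first - obs_second  # 4 x p
    abs_delta = np.abs(delta)

    pooled_t = np.vstack([first.thickness, second.thickness])
    if first.covariates is None:
        pooled_c = None
    else:
        pooled_c = np.vstack([first.covariates, second.covariates])
    n_first, n_tot = first.n, first.n + second.n

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(delta)
    done = 0
    draws = 0
    redrawn = 0
    max_draws = 10 * n_perm
    while done < n_perm:
        if draws >= max_draws:
            raise RuntimeError(
                f"permutation test aborted: {redrawn} of {draws} replicates "
                f"lacked {e_target} positive edges"
            )
        draws += 1
        perm = rng.permutation(n_tot)
        ia, ib = perm[:n_first], perm[n_first:]
        ca = None if pooled_c is None else pooled_c[ia]
        cb = None if pooled_c is None else pooled_c[ib]
        try:
            if recompute_cost:
                va = partial_corr_values(pooled_t[ia], ca)
                vb = partial_corr_values(pooled_t[ib], cb)
                e_rep = max(minimum_edge_count(va)[0], minimum_edge_count(vb)[0])
                cent_a = centrality_matrix(binarize_top_edges_values(va, e_rep))
                cent_b = centrality_matrix(binarize_top_edges_values(vb, e_rep))
            else:
                cent_a = _build_centralities(pooled_t[ia], ca, e_target)
                cent_b = _build_centralities(pooled_t[ib], cb, e_target)
        except ValueError:  # not connectable / insufficient positive edges

            redrawn += 1
            continue
        exceed += np.abs(cent_a - cent_b) >= abs_delta
        done += 1
    if redrawn:
        logger.info("permutation test %s vs %s: %d replicate(s) redrawn",
                    group_a.label, group_b.label, redrawn)

    p = (1.0 + exceed) / (n_perm + 1.0)
    sign = -1.0 if flipped else 1.0
    return PermutationComparison(
        (group_a.label, group_b.label),
        {m: sign * delta[i] for i, m in enumerate(MEASURES)},
        {m: p[i] for i, m in enumerate(MEASURES)},
        n_perm,
        seed,
        redrawn,
    )


def decide_significance(
    pvals: Sequence[float],
    a_priori: bool = False,
    alpha: float = 0.05,
) -> tuple[int, bool]:
    """Apply the conservative multi-measure rule to four p-values.

    Returns ``(measures_passing, significant)``: significant iff at least
    three of the four p-values are <= alpha, or at least two for an
    a-priori region.
    """
    pvals = list(pvals)
    if len(pvals) != 4 or any(not (0 < p <= 1) for p in pvals):
        raise ValueError("need four p-values in (0, 1]")
    passing = sum(p <= alpha for p in pvals)
    required = 2 if a_priori else 3
    return passing, passing >= required


def chance_bound(alpha: float, measures_required: int) -> float:
    """Independence product bound alpha**measures_required, for reporting."""
    if not 0 < alpha <= 1 or measures_required < 1:
        raise ValueError("alpha in (0, 1], measures_required >= 1")
    return alpha ** measures_required


def contingency_chi_square(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence on an r × c contingency table.

    No continuity correction; ``df = (r - 1)(c - 1)``.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# orchestration


def _decide_nodes(
    comp: PermutationComparison,
    regions: RegionSet,
    alpha: float,
) -> tuple[NodeDecision, ...]:
    label_a, label_b = comp.group_pair
    decisions = []
    for i, node in enumerate(regions.labels):
        pvals = [comp.p_values[m][i] for m in MEASURES]
        apr = regions.a_priori[i]
        passing, significant = decide_significance(pvals, apr, alpha)
        signs = [
            np.sign(comp.delta_obs[m][i])
            for m in MEASURES
            if comp.p_values[m][i] <= alpha
        ]
        if not signs:
            direction = "none"
        else:
            total = sum(signs)
            direction = label_a if total > 0 else label_b if total < 0 else "mixed"
        decisions.append(NodeDecision(node, apr, passing, significant, direction))
    return tuple(decisions)


def run_pipeline(cohort: ThicknessCohort, config: PipelineConfig) -> GroupComparisonReport:
    """Variance screen → per-group networks at matched cost → centralities →
    jackknife envelopes → pairwise permutation tests → decisions."""
    if config.covariates is not None:
        cohort = cohort.select_covariates(config.covariates)

    screen = screen_regions(cohort, config.variance_alpha)
    cohort = screen.apply(cohort)
    regions = cohort.regions
    if config.a_priori_regions:
        regions = regions.with_a_priori(
            [r for r in config.a_priori_regions if r in regions.labels]
        )
    p = len(regions)

    groups = cohort.group_labels
    data = {
        g: GroupData(g, *cohort.group_slice(g)) for g in groups
    }
    pcms: dict[str, PartialCorrelationMatrix] = {
        g: partial_correlation_matrix(d.thickness, d.covariates, regions.labels)
        for g, d in data.items()
    }
    min_counts = {g: minimum_edge_count(pcms[g])[0] for g in groups}
    if config.cost_override is not None:
        e_target = int(round(config.cost_override * p * (p - 1) / 2))
    else:
        e_target = max(min_counts.values())

    centralities: dict[str, CentralityTable] = {}
    networks: dict[str, BinaryNetwork] = {}
    observed: dict[str, np.ndarray] = {}
    costs: dict[str, float] = {}
    for g in groups:
        adj = binarize_top_edges_values(pcms[g].values, e_target)
        networks[g] = BinaryNetwork(adj, regions.labels)
        mat = centrality_matrix(adj)
        observed[g] = mat
        centralities[g] = CentralityTable(
            regions.labels, mat[0], mat[1], mat[2], mat[3]
        )
        costs[g] = e_target / (p * (p - 1) / 2)

    jackknives: dict[str, JackknifeEnvelope] = {}
    reliability: dict[str, tuple[tuple[str, str], ...]] = {}
    if config.jackknife:
        for g in groups:
            env = jackknife_envelope(data[g], e_target, config.jackknife_z)
            jackknives[g] = env
            inside = env.covers(observed[g])
            flags = [
                (regions.labels[j], MEASURES[mi])
                for mi in range(4)
                for j in range(p)
                if not inside[mi, j]
            ]
            if flags:
                logger.warning(
                    "group %s: %d node-measure value(s) outside the jackknife "
                    "envelope", g, len(flags),
                )
            reliability[g] = tuple(flags)

    comparisons = []
    decisions: dict[tuple[str, str], tuple[NodeDecision, ...]] = {}
    for idx, (ga, gb) in enumerate(combinations(groups, 2)):
        sub_seed = int(
            np.random.SeedSequence([config.seed, idx]).generate_state(1)[0] % (2**31)
        )
        comp = permutation_test(
            data[ga], data[gb], e_target,
            n_perm=config.n_perm, seed=sub_seed,
            recompute_cost=config.recompute_cost_in_permutations,
        )
        comparisons.append(comp)
        decisions[(ga, gb)] = _decide_nodes(comp, regions, config.perm_alpha)

    return GroupComparisonReport(
        regions=regions,
        group_sizes={g: data[g].n for g in groups},
        screen=screen,
        e_target=e_target,
        min_edge_counts=min_counts,
        wiring_costs=costs,
        networks=networks,
        centralities=centralities,
        jackknives=jackknives,
        comparisons=tuple(comparisons),
        decisions=decisions,
        reliability_flags=reliability,
        config=config,
    )


def write_manifest(report: GroupComparisonReport, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.manifest(), fh, indent=2)
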
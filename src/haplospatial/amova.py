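"""Distance-based population structure: pairwise PhiST and hierarchical AMOVA.

The analysis of molecular variance partitions the total molecular variance of
a sample into hierarchical components — among groups of populations, among
populations within groups, and within populations — from a matrix of
pairwise inter-individual distances.  Following the convention of the
standard haplotype-data software, the number of pairwise sequence
differences is used directly as the squared distance in the sums-of-squares
decomposition.  Phi-statistics are the molecular analogues of F-statistics:

    Phi_ST = (sigma2_a + sigma2_b) / sigma2_total     (three-level)
    Phi_ST = sigma2_among / sigma2_total              (two populations)

Significance is assessed by permutation: individuals are shuffled between
populations (Phi_ST, Phi_SC) or whole populations between groups (Phi_CT),
and the P-value is the fraction of permuted statistics at least as large as
the observed one, with the observed arrangement counted once so P is always
in (0, 1].

Negative variance components can arise (the estimators are method-of-moments)
and are reported as computed, flagged, never truncated, so the percentage
decomposition stays algebraically exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PopulationSet", "StructureResult", "AmovaResult",
           "pairwise_phist", "pairwise_phist_matrix", "amova"]


@dataclass
class PopulationSet:
    """Population (and optional group) assignment of indexed individuals.

    ``populations`` maps a population name to the indices of its members in
    the distance matrix; ``groups`` maps population name -> group name and,
    when present, must cover every population.
    """

    populations: dict[str, list[int]]
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, idx in self.populations.items():
            if not idx:
                raise ValueError(f"population {name!r} is empty")
            overlap = seen & set(idx)
            if overlap:
                raise ValueError(f"individuals in several populations: {overlap}")
            seen |= set(idx)
        if self.groups is not None:
            missing = set(self.populations) - set(self.groups)
            if missing:
                raise ValueError(f"populations without a group: {missing}")

    @property
    def n(self) -> int:
        return sum(len(v) for v in self.populations.values())


def _ssd(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared deviations for one stratum: (1/n) * sum_{i<j} d2_ij."""
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * len(idx)))


def _two_level_components(d2, pops):
    """Variance components for populations with no group level.

    Returns (sigma2_among, sigma2_within); either may be negative.
    """
    all_idx = np.concatenate(pops)
    n = len(all_idx)
    n_pops = len(pops)
    ssd_total = _ssd(d2, all_idx)
    ssd_within = sum(_ssd(d2, p) for p in pops)
    ssd_among = ssd_total - ssd_within
    df_within = n - n_pops
    df_among = n_pops - 1
    sizes = np.array([len(p) for p in pops], dtype=float)
    if df_within == 0:  # every population a singleton
        return np.nan, np.nan
    sigma_w = ssd_within / df_within
    n_c = (n - (sizes ** 2).sum() / n) / df_among
    sigma_a = (ssd_among / df_among - sigma_w) / n_c
    return sigma_a, sigma_w


def _phist_two_level(d2, pops) -> float:
    sigma_a, sigma_w = _two_level_components(d2, pops)
    total = sigma_a + sigma_w
    if not np.isfinite(total) or total == 0.0:
        return 0.0
    return sigma_a / total


def pairwise_phist(pop_a: list[int], pop_b: list[int],
                   distance_matrix: np.ndarray, n_perm: int = 10_000,
                   rng: np.random.Generator | int | None = None,
                   squared: bool = True) -> tuple[float, float]:
    """PhiST between two populations with a permutation P-value.

    ``distance_matrix`` holds inter-individual distances indexed by the
    members' integer ids; with ``squared=True`` (default, the pairwise
    difference-count convention) entries enter the decomposition as-is,
    otherwise they are squared first.  P = (1 + #{Phi_perm >= Phi_obs}) /
    (1 + n_perm), permuting individuals between the two populations.
    A population of size < 2 degrades the within-population estimate; the
    statistic is still returned with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    d2 = np.asarray(distance_matrix, dtype=float)
    if not squared:
        d2 = d2 ** 2
    pop_a = np.asarray(pop_a, dtype=int)
    pop_b = np.asarray(pop_b, dtype=int)
    if min(len(pop_a), len(pop_b)) < 2:
        warnings.warn("population with fewer than 2 members: the "
                      "within-population variance is poorly estimated")
    obs = _phist_two_level(d2, [pop_a, pop_b])
    pooled = np.concatenate([pop_a, pop_b])
    n_a = len(pop_a)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        hits += _phist_two_level(d2, [perm[:n_a], perm[n_a:]]) >= obs
    p = (1 + hits) / (1 + n_perm)
    return float(obs), float(p)


def pairwise_phist_matrix(population_set: PopulationSet,
                          distance_matrix: np.ndarray, n_perm: int = 10_000,
                          rng=None, squared: bool = True,
                          ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """All population pairs: returns (names, PhiST matrix, P matrix)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    names = list(population_set.populations)
    k = len(names)
    phi = np.zeros((k, k))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            phi[i, j], p[i, j] = pairwise_phist(
                population_set.populations[names[i]],
                population_set.populations[names[j]],
                distance_matrix, n_perm=n_perm, rng=rng, squared=squared)
            phi[j, i], p[j, i] = phi[i, j], p[i, j]
    return names, phi, p


@dataclass
class AmovaResult:
    """Three-level AMOVA table."""

    sigma2_among_groups: float
    sigma2_among_pops: float
    sigma2_within: float
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_phi_ct: float | None = None
    p_phi_sc: float | None = None
    p_phi_st: float | None = None
    negative_components: bool = field(init=False)
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.negative_components = bool(
            min(self.sigma2_among_groups, self.sigma2_among_pops,
                self.sigma2_within) < 0)

    @property
    def total(self) -> float:
        return (self.sigma2_among_groups + self.sigma2_among_pops
                + self.sigma2_within)

    @property
    def percentages(self) -> tuple[float, float, float]:
        t = self.total
        if t == 0.0:
            return (0.0, 0.0, 100.0)
        return (100 * self.sigma2_among_groups / t,
                100 * self.sigma2_among_pops / t,
                100 * self.sigma2_within / t)

    def to_dict(self) -> dict:
        ag, ap, wp = self.percentages
        return {
            "variance_components": {
                "among_groups": self.sigma2_among_groups,
                "among_populations_within_groups": self.sigma2_among_pops,
                "within_populations": self.sigma2_within,
            },
            "percentages": {"among_groups": ag,
                            "among_populations_within_groups": ap,
                            "within_populations": wp},
            "phi_statistics": {"phi_ct": self.phi_ct, "phi_sc": self.phi_sc,
                               "phi_st": self.phi_st},
            "p_values": {"phi_ct": self.p_phi_ct, "phi_sc": self.p_phi_sc,
                         "phi_st": self.p_phi_st},
            "negative_components": self.negative_components,
            "degenerate": self.degenerate,
        }


# backwards-friendly alias used in result bundles
StructureResult = AmovaResult


def _three_level_components(d2, groups):
    """Variance components for groups of populations (lists of index arrays).

    ``groups`` is a list of groups, each a list of population index arrays.
    Returns (sigma_a, sigma_b, sigma_c): among groups, among populations
    within groups, within populations.
    """
    pops = [p for g in groups for p in g]
    all_idx = np.concatenate(pops)
    n = len(all_idx)
    n_pops = len(pops)
    n_groups = len(groups)

    ssd_total = _ssd(d2, all_idx)
    ssd_wp = sum(_ssd(d2, p) for p in pops)
    ssd_wg = sum(_ssd(d2, np.concatenate(g)) for g in groups)
    ssd_ap = ssd_wg - ssd_wp          # among populations within groups
    ssd_ag = ssd_total - ssd_wg       # among groups

    df_wp = n - n_pops
    df_ap = n_pops - n_groups
    df_ag = n_groups - 1
    if df_wp == 0 or df_ap == 0 or df_ag == 0:
        raise ValueError("degenerate design: need >=2 groups, more "
                         "populations than groups, and non-singleton totals")

    sizes = {id(p): len(p) for p in pops}
    group_sizes = np.array([sum(len(p) for p in g) for g in groups], float)
    sum_sq_all = sum(len(p) ** 2 for p in pops)
    sum_sq_by_group = [sum(len(p) ** 2 for p in g) for g in groups]

    n1 = (n - sum(s / gs for s, gs in zip(sum_sq_by_group, group_sizes))) / df_ap
    n2 = (sum(s / gs for s, gs in zip(sum_sq_by_group, group_sizes))
          - sum_sq_all / n) / df_ag
    n3 = (n - (group_sizes ** 2).sum() / n) / df_ag

    ms_wp = ssd_wp / df_wp
    ms_ap = ssd_ap / df_ap
    ms_ag = ssd_ag / df_ag

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def _phis(sigma_a, sigma_b, sigma_c):
    total = sigma_a + sigma_b + sigma_c
    if total == 0.0:
        return 0.0, 0.0, 0.0
    phi_ct = sigma_a / total
    denom = sigma_b + sigma_c
    phi_sc = sigma_b / denom if denom != 0 else 0.0
    phi_st = (sigma_a + sigma_b) / total
    return phi_ct, phi_sc, phi_st


def amova(population_set: PopulationSet, distance_matrix: np.ndarray,
          n_perm: int = 10_000, rng=None, squared: bool = True) -> AmovaResult:
    """Hierarchical AMOVA with permutation P-values.

    Requires a group map covering >= 2 groups.  Singleton groups (one
    population) make the among-populations stratum degenerate for that group;
    the result is flagged.  Permutation schemes: Phi_ST permutes individuals
    across all populations; Phi_SC permutes individuals among populations
    within their group; Phi_CT permutes whole populations among groups
    (group sizes in populations preserved).
    """
    if population_set.groups is None:
        raise ValueError("three-level AMOVA needs a population->group map")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    d2 = np.asarray(distance_matrix, dtype=float)
    if not squared:
        d2 = d2 ** 2

    group_names = list(dict.fromkeys(population_set.groups.values()))
    if len(group_names) < 2:
        raise ValueError("need >= 2 groups")
    by_group = {g: [] for g in group_names}
    for pop, idx in population_set.populations.items():
        by_group[population_set.groups[pop]].append(np.asarray(idx, int))
    groups = [by_group[g] for g in group_names]
    degenerate = any(len(g) == 1 for g in groups)

    sigma_a, sigma_b, sigma_c = _three_level_components(d2, groups)
    phi_ct, phi_sc, phi_st = _phis(sigma_a, sigma_b, sigma_c)

    pops = [p for g in groups for p in g]
    pop_sizes = [len(p) for p in pops]
    pops_per_group = [len(g) for g in groups]
    all_idx = np.concatenate(pops)

    def split(flat, sizes):
        out, k = [], 0
        for s in sizes:
            out.append(flat[k:k + s])
            k += s
        return out

    hits_st = hits_sc = hits_ct = 0
    for _ in range(n_perm):
        # Phi_ST: individuals shuffled across everything
        perm = rng.permutation(all_idx)
        g_st = split(split(perm, pop_sizes), pops_per_group)
        s = _three_level_components(d2, g_st)
        hits_st += _phis(*s)[2] >= phi_st

        # Phi_SC: individuals shuffled among populations within each group
        g_sc = []
        for g in groups:
            flat = rng.permutation(np.concatenate(g))
            g_sc.append(split(flat, [len(p) for p in g]))
        s = _three_level_components(d2, g_sc)
        hits_sc += _phis(*s)[1] >= phi_sc

        # Phi_CT: whole populations shuffled among groups
        order = rng.permutation(len(pops))
        g_ct = split([pops[i] for i in order], pops_per_group)
        s = _three_level_components(d2, g_ct)
        hits_ct += _phis(*s)[0] >= phi_ct

    denom = 1 + n_perm
    return AmovaResult(
        sigma2_among_groups=float(sigma_a),
        sigma2_among_pops=float(sigma_b),
        sigma2_within=float(sigma_c),
        phi_ct=float(phi_ct), phi_sc=float(phi_sc), phi_st=float(phi_st),
        p_phi_ct=(1 + hits_ct) / denom,
        p_phi_sc=(1 + hits_sc) / denom,
        p_phi_st=(1 + hits_st) / denom,
        degenerate=degenerate,
    )
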
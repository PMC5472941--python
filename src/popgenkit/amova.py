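"""Hierarchical analysis of molecular variance (AMOVA).

Variance is partitioned among groups, among populations within groups, and
within populations from a squared-Euclidean genotype distance matrix
(locus-wise squared dosage differences, rescaled for missing data), with
permutation significance per level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PreconditionError
from .genotype_io import MISSING, GenotypePanel, PopulationMap


@dataclass
class AmovaResult:
    ssd_among_groups: float
    ssd_among_pops: float  # among populations within groups
    ssd_within_pops: float
    df_among_groups: int
    df_among_pops: int
    df_within_pops: int
    sigma2_a: float  # among groups
    sigma2_b: float  # among populations within groups
    sigma2_c: float  # within populations
    phi_ct: float
    phi_sc: float
    phi_st: float
    percent: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    perm_counts: dict[str, int] = field(default_factory=dict)
    n_permutations: int = 0
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among_groups", "among_pops_within_groups", "within_pops"],
                "df": [self.df_among_groups, self.df_among_pops, self.df_within_pops],
                "ssd": [self.ssd_among_groups, self.ssd_among_pops, self.ssd_within_pops],
                "variance": [self.sigma2_a, self.sigma2_b, self.sigma2_c],
                "percent": [
                    self.percent.get("among_groups", np.nan),
                    self.percent.get("among_pops", np.nan),
                    self.percent.get("within_pops", np.nan),
                ],
                "phi": [self.phi_ct, self.phi_sc, self.phi_st],
                "p": [
                    self.p_values.get("among_groups", np.nan),
                    self.p_values.get("among_pops", np.nan),
                    self.p_values.get("within_pops", np.nan),
                ],
            }
        )


def genotype_distance_matrix(panel: GenotypePanel) -> np.ndarray:
    """Pairwise squared-Euclidean dosage distance between samples.

    d(i, j) = sum over comparable loci of (g_i - g_j)^2, rescaled by
    L / L_comparable when genotypes are missing.
    """
    g = panel.genotypes.astype(float).T  # samples x loci
    valid = g != MISSING
    gz = np.where(valid, g, 0.0)
    sq = gz**2
    v = valid.astype(float)
    cross = gz @ gz.T
    s_i = sq @ v.T
    raw = s_i + s_i.T - 2.0 * cross
    comparable = v @ v.T
    L = float(panel.n_variants)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(comparable > 0, raw * (L / comparable), 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def _ssd_decomposition(d: np.ndarray, pop_of: np.ndarray, group_of_pop: dict):
    """Excoffier-style SSD decomposition from a squared distance matrix."""
    n_total = d.shape[0]
    iu = np.triu_indices(n_total, k=1)
    ssd_total = d[iu].sum() / n_total

    pops = list(dict.fromkeys(pop_of))
    ssd_wp = 0.0
    within_group_sum = 0.0
    groups = list(dict.fromkeys(group_of_pop[p] for p in pops))
    group_sizes: dict = {g: 0 for g in groups}
    pop_sizes: dict = {}
    for p in pops:
        idx = np.where(pop_of == p)[0]
        pop_sizes[p] = len(idx)
        group_sizes[group_of_pop[p]] += len(idx)
        if len(idx) > 1:
            sub = d[np.ix_(idx, idx)]
            ssd_wp += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    for grp in groups:
        idx = np.where(np.array([group_of_pop[p] for p in pop_of]) == grp)[0]
        if len(idx) > 1:
            sub = d[np.ix_(idx, idx)]
            within_group_sum += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ssd_ap = within_group_sum - ssd_wp
    ssd_ag = ssd_total - within_group_sum
    return ssd_total, ssd_ag, ssd_ap, ssd_wp, pops, groups, pop_sizes, group_sizes, n_total


def _variance_components(d, pop_of, group_of_pop):
    (
        ssd_total,
        ssd_ag,
        ssd_ap,
        ssd_wp,
        pops,
        groups,
        pop_sizes,
        group_sizes,
        n_total,
    ) = _ssd_decomposition(d, pop_of, group_of_pop)
    n_pops, n_groups = len(pops), len(groups)
    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = n_total - n_pops
    if df_wp <= 0:
        raise PreconditionError("every population has a single sample; within-population variance undefined")

    sum_np2 = sum(v**2 for v in pop_sizes.values())
    sum_np2_by_group = {
        grp: sum(pop_sizes[p] ** 2 for p in pops if group_of_pop[p] == grp)
        for grp in groups
    }
    # Expected-mean-square coefficients (Excoffier, Smouse & Quattro 1992).
    n_coef = (
        (n_total - sum(sum_np2_by_group[g] / group_sizes[g] for g in groups)) / df_ap
        if df_ap > 0
        else 0.0
    )
    n_prime = (
        (sum(sum_np2_by_group[g] / group_sizes[g] for g in groups) - sum_np2 / n_total) / df_ag
        if df_ag > 0
        else 0.0
    )
    n_dprime = (
        (n_total - sum(v**2 for v in group_sizes.values()) / n_total) / df_ag
        if df_ag > 0
        else 0.0
    )

    ms_wp = ssd_wp / df_wp
    sigma2_c = ms_wp
    if df_ap > 0 and n_coef > 0:
        sigma2_b = (ssd_ap / df_ap - sigma2_c) / n_coef
    else:
        sigma2_b = 0.0
    if df_ag > 0 and n_dprime > 0:
        sigma2_a = (ssd_ag / df_ag - sigma2_c - n_prime * sigma2_b) / n_dprime
    else:
        sigma2_a = 0.0
    return (
        ssd_total,
        ssd_ag,
        ssd_ap,
        ssd_wp,
        df_ag,
        df_ap,
        df_wp,
        sigma2_a,
        sigma2_b,
        sigma2_c,
    )


def amova(
    panel: GenotypePanel,
    popmap: PopulationMap,
    grouping: dict | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    distance: np.ndarray | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA with permutation p-values.

    ``grouping`` maps population -> group (defaults to the popmap's
    hierarchy).  Permutation schemes: among-group significance permutes
    whole populations among groups; among-population significance permutes
    individuals among populations within their group; the within/total
    (Phi_ST) level permutes individuals across all populations.
    """
    samples = [s for s in panel.samples if s in popmap.sample_to_pop]
    if len(samples) != panel.n_samples:
        panel = panel.subset(sample_idx=panel.sample_indices(samples))
    pop_of = np.array([popmap.sample_to_pop[s] for s in panel.samples], dtype=object)
    group_of_pop = dict(grouping or popmap.pop_to_group)
    pops = list(dict.fromkeys(pop_of))
    groups = list(dict.fromkeys(group_of_pop[p] for p in pops))
    if len(groups) < 2:
        raise PreconditionError("AMOVA needs >= 2 groups")
    for grp in groups:
        members = [p for p in pops if group_of_pop[p] == grp]
        if all(np.sum(pop_of == p) <= 1 for p in members):
            raise PreconditionError(
                f"group {grp!r} has only single-sample populations; degenerate design"
            )

    d = genotype_distance_matrix(panel) if distance is None else distance
    (
        ssd_total,
        ssd_ag,
        ssd_ap,
        ssd_wp,
        df_ag,
        df_ap,
        df_wp,
        s2a,
        s2b,
        s2c,
    ) = _variance_components(d, pop_of, group_of_pop)

    total_var = s2a + s2b + s2c
    degenerate = total_var <= 0
    if degenerate:
        phi_ct = phi_sc = phi_st = float("nan")
        percent = {k: float("nan") for k in ("among_groups", "among_pops", "within_pops")}
    else:
        phi_ct = s2a / total_var
        phi_sc = s2b / (s2b + s2c) if (s2b + s2c) != 0 else float("nan")
        phi_st = (s2a + s2b) / total_var
        percent = {
            "among_groups": 100.0 * s2a / total_var,
            "among_pops": 100.0 * s2b / total_var,
            "within_pops": 100.0 * s2c / total_var,
        }

    p_values: dict[str, float] = {}
    perm_counts: dict[str, int] = {}
    if n_perm > 0 and not degenerate:
        rng = np.random.default_rng(seed)
        group_arr = np.array([group_of_pop[p] for p in pop_of], dtype=object)

        # Phi_CT: permute whole populations among groups.
        count_ag = 0
        group_assignment = [group_of_pop[p] for p in pops]
        for _ in range(n_perm):
            perm = rng.permutation(group_assignment)
            gmap_perm = dict(zip(pops, perm))
            try:
                comp = _variance_components(d, pop_of, gmap_perm)
            except PreconditionError:
                continue
            tv = comp[7] + comp[8] + comp[9]
            stat = comp[7] / tv if tv > 0 else 0.0
            if stat >= phi_ct - 1e-12:
                count_ag += 1
        p_values["among_groups"] = (count_ag + 1) / (n_perm + 1)
        perm_counts["among_groups"] = count_ag

        # Phi_SC: permute individuals among populations within groups.
        count_ap = 0
        for _ in range(n_perm):
            pop_perm = pop_of.copy()
            for grp in groups:
                idx = np.where(group_arr == grp)[0]
                pop_perm[idx] = rng.permutation(pop_of[idx])
            comp = _variance_components(d, pop_perm, group_of_pop)
            denom = comp[8] + comp[9]
            stat = comp[8] / denom if denom > 0 else 0.0
            obs = phi_sc if np.isfinite(phi_sc) else 0.0
            if stat >= obs - 1e-12:
                count_ap += 1
        p_values["among_pops"] = (count_ap + 1) / (n_perm + 1)
        perm_counts["among_pops"] = count_ap

        # Phi_ST: permute individuals across all populations.
        count_wp = 0
        for _ in range(n_perm):
            pop_perm = rng.permutation(pop_of)
            comp = _variance_components(d, pop_perm, group_of_pop)
            tv = comp[7] + comp[8] + comp[9]
            stat = (comp[7] + comp[8]) / tv if tv > 0 else 0.0
            if stat >= phi_st - 1e-12:
                count_wp += 1
        p_values["within_pops"] = (count_wp + 1) / (n_perm + 1)
        perm_counts["within_pops"] = count_wp

    return AmovaResult(
        ssd_among_groups=ssd_ag,
        ssd_among_pops=ssd_ap,
        ssd_within_pops=ssd_wp,
        df_among_groups=df_ag,
        df_among_pops=df_ap,
        df_within_pops=df_wp,
        sigma2_a=s2a,
        sigma2_b=s2b,
        sigma2_c=s2c,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        phi_st=phi_st,
        percent=percent,
        p_values=p_values,
        perm_counts=perm_counts,
        n_permutations=n_perm,
        degenerate=degenerate,
    )


def group_rotation_scan(
    panel: GenotypePanel,
    popmap: PopulationMap,
    fixed_pops: list[str],
    rotating_pops: list[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """AMOVA for each grouping (fixed_pops + X) vs rest, X in rotating_pops.

    Returns one row per rotation with the variance components, percentages
    and a flag for whether the among-group component exceeds the
    among-population-within-group component.
    """
    if not rotating_pops:
        raise PreconditionError("rotating_pops must be nonempty")
    overlap = set(fixed_pops) & set(rotating_pops)
    if overlap:
        raise PreconditionError(f"rotating populations overlap fixed set: {sorted(overlap)}")
    all_pops = popmap.populations
    d = genotype_distance_matrix(panel)
    rows = []
    for x in rotating_pops:
        grouping = {
            p: ("group1" if p in set(fixed_pops) | {x} else "group2") for p in all_pops
        }
        res = amova(panel, popmap, grouping=grouping, n_perm=n_perm, seed=seed, distance=d)
        rows.append(
            {
                "rotated_pop": x,
                "sigma2_among_groups": res.sigma2_a,
                "sigma2_among_pops": res.sigma2_b,
                "sigma2_within": res.sigma2_c,
                "pct_among_groups": res.percent.get("among_groups", np.nan),
                "pct_among_pops": res.percent.get("among_pops", np.nan),
                "p_among_groups": res.p_values.get("among_groups", np.nan),
                "among_groups_exceeds_among_pops": bool(res.sigma2_a > res.sigma2_b),
            }
        )
    return pd.DataFrame(rows)
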
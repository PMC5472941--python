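"""LD-decay effective population size and F_ST-based divergence time.

Ne at recombination distance c (in Morgans) is 1/(4c) * (1/r2_adj - 2),
where r2_adj is the mean pairwise dosage r^2 adjusted for chance LD by
subtracting 1/n (n diploid individuals); the corresponding look-back time
is t = 1/(2c) generations.  Divergence time T_F = 2 * Ne_harmonic * F_ST.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, PreconditionError
from .genotype_io import MISSING, GeneticMap, GenotypePanel, PopulationMap

logger = logging.getLogger(__name__)

DEFAULT_GENERATION_YEARS = 25.0


@dataclass
class NeTrajectory:
    """Per-bin LD-decay Ne estimates; ``table`` columns: c_cM, c_morgans,
    t_generations, t_years, mean_r2_adj, n_pairs, ne."""

    table: pd.DataFrame
    n_samples: int
    generation_years: float


@dataclass
class DivergenceEstimate:
    t_f_generations: float
    t_f_years: float
    fst_used: float
    ne_harmonic: float
    generation_years: float


def adjust_r2(r2_raw: float | np.ndarray, n_samples: int) -> float | np.ndarray:
    """Chance-LD adjustment: r2_adj = r2_raw - 1/n (may be <= 0)."""
    if n_samples < 2:
        raise PreconditionError(f"need >= 2 samples for the 1/n adjustment, got {n_samples}")
    return r2_raw - 1.0 / n_samples


def ne_from_r2(r2_adj: float, c_morgans: float) -> float:
    """Point formula Ne = 1/(4c) * (1/r2_adj - 2)."""
    return (1.0 / (4.0 * c_morgans)) * (1.0 / r2_adj - 2.0)


def generations_to_years(t_gen: float, g: float = DEFAULT_GENERATION_YEARS) -> float:
    """Convert generations to years at ``g`` years per generation."""
    if t_gen < 0:
        raise PreconditionError("t_gen must be >= 0")
    return t_gen * g


def _default_bins(c_min_cm: float = 0.01, c_max_cm: float = 0.25, n_bins: int = 25) -> np.ndarray:
    return np.geomspace(c_min_cm, c_max_cm, n_bins + 1)


def ld_ne(
    panel: GenotypePanel,
    gmap: GeneticMap,
    popmap: PopulationMap | None = None,
    population: str | list[str] | None = None,
    bins_cm: np.ndarray | None = None,
    maf_min: float = 0.05,
    min_n: int = 10,
    g: float = DEFAULT_GENERATION_YEARS,
) -> NeTrajectory:
    """Historical Ne trajectory from LD decay.

    For each recombination-distance bin (default 25 log-spaced bins over
    0.01-0.25 cM) the mean dosage r^2 over intra-chromosomal pairs in the
    bin is adjusted by 1/n, then Ne = 1/(4c)(1/r2_adj - 2) with c the mean
    pair distance in Morgans, and t = 1/(2c) generations.  Bins where the
    adjusted r^2 implies Ne <= 0 are dropped (logged).  Pairs are restricted
    to variants with MAF >= ``maf_min``.
    """
    if population is None:
        sample_idx = np.arange(panel.n_samples)
    elif isinstance(population, str):
        if popmap is None:
            raise PreconditionError("population label requires a PopulationMap")
        sample_idx = panel.sample_indices(popmap.samples_of(population))
    else:
        sample_idx = panel.sample_indices(population)
    n = len(sample_idx)
    if n < min_n:
        raise PreconditionError(f"population has {n} samples, need >= {min_n}")

    if bins_cm is None:
        bins_cm = _default_bins()
    bins_cm = np.asarray(bins_cm, dtype=float)
    c_max = bins_cm[-1]

    g_mat = panel.genotypes[:, sample_idx].astype(float)
    g_mat[g_mat == MISSING] = np.nan
    freqs = np.nanmean(g_mat, axis=1) / 2.0
    maf = np.minimum(freqs, 1 - freqs)
    chroms = panel.chroms
    positions = panel.positions

    dist_all: list[np.ndarray] = []
    r2_all: list[np.ndarray] = []
    for chrom in dict.fromkeys(chroms):
        vidx = np.where((chroms == chrom) & (maf >= maf_min))[0]
        if len(vidx) < 2:
            continue
        cm_pos = np.asarray(gmap.cm(chrom, positions[vidx]), dtype=float)
        sub = g_mat[vidx]
        has_missing = np.isnan(sub).any()
        if not has_missing:
            sd = sub.std(axis=1)
            ok = sd > 0
            vidx, cm_pos, sub = vidx[ok], cm_pos[ok], sub[ok]
            if len(vidx) < 2:
                continue
            corr = np.corrcoef(sub) ** 2
        ii, jj = np.triu_indices(len(vidx), k=1)
        d = np.abs(cm_pos[jj] - cm_pos[ii])
        in_range = (d > 0) & (d <= c_max)
        ii, jj, d = ii[in_range], jj[in_range], d[in_range]
        if has_missing:
            r2 = np.empty(len(ii))
            for k, (ai, bj) in enumerate(zip(ii, jj)):
                mask = ~np.isnan(sub[ai]) & ~np.isnan(sub[bj])
                if mask.sum() < 3 or sub[ai, mask].std() == 0 or sub[bj, mask].std() == 0:
                    r2[k] = np.nan
                else:
                    r2[k] = np.corrcoef(sub[ai, mask], sub[bj, mask])[0, 1] ** 2
        else:
            r2 = corr[ii, jj]
        good = np.isfinite(r2)
        dist_all.append(d[good])
        r2_all.append(r2[good])

    if not dist_all or sum(len(d) for d in dist_all) == 0:
        raise InsufficientDataError("no intra-chromosomal pairs within the distance range")
    dist = np.concatenate(dist_all)
    r2 = np.concatenate(r2_all)

    rows = []
    n_dropped = 0
    for lo, hi in zip(bins_cm[:-1], bins_cm[1:]):
        sel = (dist >= lo) & (dist < hi)
        n_pairs = int(sel.sum())
        if n_pairs == 0:
            continue
        c_cm = float(dist[sel].mean())
        c_m = c_cm / 100.0
        r2_adj = adjust_r2(float(r2[sel].mean()), n)
        if r2_adj <= 0 or (1.0 / r2_adj - 2.0) <= 0:
            n_dropped += 1
            continue
        ne = ne_from_r2(r2_adj, c_m)
        t_gen = 1.0 / (2.0 * c_m)
        rows.append(
            {
                "c_cM": c_cm,
                "c_morgans": c_m,
                "t_generations": t_gen,
                "t_years": t_gen * g,
                "mean_r2_adj": r2_adj,
                "n_pairs": n_pairs,
                "ne": ne,
            }
        )
    if n_dropped:
        logger.info("ld_ne: dropped %d bins with non-positive adjusted r^2 signal", n_dropped)
    if not rows:
        raise InsufficientDataError("no usable distance bins")
    table = pd.DataFrame(rows).sort_values("c_cM", ignore_index=True)
    return NeTrajectory(table=table, n_samples=n, generation_years=g)


def tf_divergence(
    fst: float,
    ne_a: float,
    ne_b: float,
    g: float = DEFAULT_GENERATION_YEARS,
) -> DivergenceEstimate:
    """Divergence time T_F = 2 * Ne_harmonic * F_ST generations.

    Ne_harmonic is the harmonic mean of the two population sizes; negative
    F_ST is clamped to 0 with a warning.
    """
    if ne_a <= 0 or ne_b <= 0:
        raise PreconditionError("effective sizes must be positive")
    if fst < 0:
        logger.warning("tf_divergence: clamping negative F_ST %.4g to 0", fst)
        fst = 0.0
    ne_harm = 2.0 / (1.0 / ne_a + 1.0 / ne_b)
    t_gen = 2.0 * ne_harm * fst
    return DivergenceEstimate(
        t_f_generations=t_gen,
        t_f_years=t_gen * g,
        fst_used=fst,
        ne_harmonic=ne_harm,
        generation_years=g,
    )
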
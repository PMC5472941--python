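"""Between-population differentiation and admixture statistics.

Weir & Cockerham (1984) variance-component F_ST, the population branch
statistic, f3/f4 with block-jackknife standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, PreconditionError
from .genotype_io import MISSING, GenotypePanel, PopulationMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------


@dataclass
class FstEstimate:
    """Ratio-of-sums W&C theta plus per-locus variance components."""

    theta: float
    a: np.ndarray  # among-population component, per locus
    b: np.ndarray  # among-individual-within-population
    c: np.ndarray  # within-individual
    locus_index: np.ndarray  # indices of loci used, into the input panel
    n_loci_used: int

    def per_locus_theta(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)


def _pop_stats(panel: GenotypePanel, idx: np.ndarray):
    """Per-locus (n genotyped, counted-allele freq, observed het) for a
    sample-index set."""
    g = panel.genotypes[:, idx]
    ok = g != MISSING
    n = ok.sum(axis=1).astype(float)
    tot = np.where(ok, g, 0).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, tot / (2 * n), np.nan)
        h = np.where(n > 0, np.where(ok, g == 1, False).sum(axis=1) / n, np.nan)
    return n, p, h


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """W&C (1984) a/b/c for r populations at each locus.

    ``n``, ``p``, ``h`` have shape (r, L): per-population sample sizes,
    allele frequencies and observed heterozygosities.
    """
    r = n.shape[0]
    nbar = n.mean(axis=0)
    nc = (n.sum(axis=0) - (n**2).sum(axis=0) / n.sum(axis=0)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2.0
    return a, b, c, pbar


def weir_cockerham_fst(
    panel: GenotypePanel,
    pop_a: str | list[str],
    pop_b: str | list[str],
    popmap: PopulationMap | None = None,
    min_n: int = 5,
) -> FstEstimate:
    """Two-population Weir & Cockerham theta (ratio of sums over loci).

    Loci monomorphic in the pooled sample, or with either population fully
    missing, are skipped.  Populations may be given as labels (with a
    ``popmap``) or explicit sample-id lists.
    """

    def resolve(pop):
        if isinstance(pop, str):
            if popmap is None:
                raise PreconditionError("population label requires a PopulationMap")
            return pop, popmap.samples_of(pop)
        return ",".join(map(str, pop[:3])) + ("..." if len(pop) > 3 else ""), list(pop)

    name_a, samples_a = resolve(pop_a)
    name_b, samples_b = resolve(pop_b)
    for name, samples in ((name_a, samples_a), (name_b, samples_b)):
        if len(samples) < min_n:
            raise PreconditionError(
                f"population {name!r} has {len(samples)} samples, need >= {min_n}"
            )
    ia = panel.sample_indices(samples_a)
    ib = panel.sample_indices(samples_b)
    na, pa, ha = _pop_stats(panel, ia)
    nb, pb, hb = _pop_stats(panel, ib)

    n = np.vstack([na, nb])
    p = np.vstack([pa, pb])
    h = np.vstack([ha, hb])
    usable = (na > 0) & (nb > 0)
    a, b, c, pbar = _wc_components(n, p, h)
    poly = usable & (pbar > 0) & (pbar < 1)
    keep = poly & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    idx = np.where(keep)[0]
    a, b, c = a[idx], b[idx], c[idx]
    denom = (a + b + c).sum()
    theta = float(a.sum() / denom) if denom != 0 else float("nan")
    return FstEstimate(theta=theta, a=a, b=b, c=c, locus_index=idx, n_loci_used=len(idx))


def pairwise_fst_matrix(
    panel: GenotypePanel,
    popmap: PopulationMap,
    min_n: int = 5,
) -> tuple[pd.DataFrame, list[str]]:
    """Symmetric W&C theta matrix over populations with >= min_n samples.

    Returns (matrix, excluded-population list); the diagonal is zero.
    """
    eligible, excluded = [], []
    for pop in popmap.populations:
        samples = [s for s in popmap.samples_of(pop) if s in set(panel.samples)]
        (eligible if len(samples) >= min_n else excluded).append(pop)
    if len(eligible) < 2:
        raise PreconditionError(
            f"need >= 2 populations with >= {min_n} samples, have {len(eligible)}"
        )
    mat = pd.DataFrame(0.0, index=eligible, columns=eligible)
    for i, pa in enumerate(eligible):
        for pb in eligible[i + 1 :]:
            est = weir_cockerham_fst(panel, pa, pb, popmap=popmap, min_n=min_n)
            mat.loc[pa, pb] = mat.loc[pb, pa] = est.theta
    return mat, excluded


# ---------------------------------------------------------------------------
# PBS
# ---------------------------------------------------------------------------


@dataclass
class PbsValue:
    pbs: float
    t_ab: float
    t_ac: float
    t_bc: float


def pbs(fst_ab: float, fst_ac: float, fst_bc: float) -> PbsValue:
    """Population branch statistic for focal population A.

    T = -ln(1 - F_ST); PBS = (T_AB + T_AC - T_BC) / 2.  Negative F_ST inputs
    are clamped to 0 before the log (logged).
    """
    values = [fst_ab, fst_ac, fst_bc]
    for v in values:
        if v >= 1.0:
            raise DomainError(f"F_ST = {v} >= 1 is outside the PBS domain")
    clamped = [max(v, 0.0) for v in values]
    if clamped != values:
        logger.info("pbs: clamped negative F_ST input(s) to 0")
    t_ab, t_ac, t_bc = (-np.log(1.0 - v) for v in clamped)
    return PbsValue(pbs=float((t_ab + t_ac - t_bc) / 2.0), t_ab=float(t_ab), t_ac=float(t_ac), t_bc=float(t_bc))


def pbs_scan(
    panel: GenotypePanel,
    focal: str,
    sister: str,
    outgroup: str,
    popmap: PopulationMap,
    min_n: int = 5,
) -> pd.DataFrame:
    """Per-locus PBS track for ``focal`` against ``sister`` and ``outgroup``."""
    est_ab = weir_cockerham_fst(panel, focal, sister, popmap, min_n=min_n)
    est_ac = weir_cockerham_fst(panel, focal, outgroup, popmap, min_n=min_n)
    est_bc = weir_cockerham_fst(panel, sister, outgroup, popmap, min_n=min_n)
    common = np.intersect1d(
        np.intersect1d(est_ab.locus_index, est_ac.locus_index), est_bc.locus_index
    )

    def theta_at(est: FstEstimate, loci: np.ndarray) -> np.ndarray:
        lut = {int(l): k for k, l in enumerate(est.locus_index)}
        th = est.per_locus_theta()
        return np.array([th[lut[int(l)]] for l in loci])

    rows = []
    chroms, positions = panel.chroms, panel.positions
    for locus, tab, tac, tbc in zip(
        common, theta_at(est_ab, common), theta_at(est_ac, common), theta_at(est_bc, common)
    ):
        if any(not np.isfinite(x) or x >= 1 for x in (tab, tac, tbc)):
            continue
        val = pbs(tab, tac, tbc)
        rows.append(
            {
                "chrom": chroms[locus],
                "pos": int(positions[locus]),
                "fst_ab": tab,
                "fst_ac": tac,
                "fst_bc": tbc,
                "pbs": val.pbs,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Block jackknife
# ---------------------------------------------------------------------------


def block_jackknife(
    per_locus_values: np.ndarray,
    locus_positions: tuple[np.ndarray, np.ndarray],
    block_size: float = 5e6,
    min_blocks: int = 10,
) -> tuple[float, float, float, int]:
    """Delete-one-block weighted jackknife for a genome-wide mean.

    Blocks are contiguous genomic windows of ``block_size`` bp per
    chromosome.  Returns (estimate, se, z, n_blocks); z is NaN when se = 0.
    Uses the weighted jackknife of Busing et al. (1999), which reduces to
    the ordinary delete-one jackknife for equal block sizes.
    """
    values = np.asarray(per_locus_values, dtype=float)
    chroms, positions = locus_positions
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    if not (len(values) == len(chroms) == len(positions)):
        raise PreconditionError("values and positions must align")
    block_key = [(c, int(p // block_size)) for c, p in zip(chroms, positions)]
    blocks: dict[tuple, list[int]] = {}
    for i, key in enumerate(block_key):
        blocks.setdefault(key, []).append(i)
    g = len(blocks)
    if g < min_blocks:
        raise InsufficientDataError(f"only {g} jackknife blocks, need >= {min_blocks}")
    n = float(len(values))
    total = values.sum()
    estimate = total / n
    theta_del = np.empty(g)
    m = np.empty(g)
    for k, idx in enumerate(blocks.values()):
        m[k] = len(idx)
        theta_del[k] = (total - values[idx].sum()) / (n - len(idx))
    h = n / m
    pseudo = h * estimate - (h - 1.0) * theta_del
    theta_jack = g * estimate - ((1.0 - m / n) * theta_del).sum()
    var = np.sum((pseudo - theta_jack) ** 2 / (h - 1.0)) / g
    se = float(np.sqrt(var))
    z = float(estimate / se) if se > 0 else float("nan")
    return float(estimate), se, z, g


# ---------------------------------------------------------------------------
# f-statistics
# ---------------------------------------------------------------------------


@dataclass
class FStatResult:
    statistic: str
    populations: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_loci: int
    block_size: float
    admixture_significant: bool | None = None
    per_locus: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def f3_from_freqs(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, n_c: np.ndarray
) -> np.ndarray:
    """Per-locus f3(C; A, B) with the target finite-sample correction.

    ``n_c`` is the number of genotyped diploid target samples per locus;
    the correction subtracts the sampling variance of the target frequency,
    c(1-c)/(2 n_c - 1).
    """
    return (c - a) * (c - b) - c * (1.0 - c) / (2.0 * n_c - 1.0)


def f4_from_freqs(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Per-locus f4(A, B; C, D) = (a - b)(c - d)."""
    return (a - b) * (c - d)


def _pop_freqs(panel, pops, popmap, min_genotyped=2):
    """Per-locus frequencies and genotyped counts for each population;
    returns (freqs list, counts list, usable-locus mask)."""
    freqs, counts = [], []
    mask = np.ones(panel.n_variants, dtype=bool)
    for pop in pops:
        samples = popmap.samples_of(pop) if isinstance(pop, str) else list(pop)
        idx = panel.sample_indices(samples)
        n, p, _ = _pop_stats(panel, idx)
        freqs.append(p)
        counts.append(n)
        mask &= n >= min_genotyped
    return freqs, counts, mask


def f3(
    target: str | list[str],
    source1: str | list[str],
    source2: str | list[str],
    panel: GenotypePanel,
    popmap: PopulationMap | None = None,
    block_size: float = 5e6,
    min_blocks: int = 10,
    z_threshold: float = -3.0,
) -> FStatResult:
    """f3(target; source1, source2) with block-jackknife uncertainty.

    Significantly negative values (z <= ``z_threshold``) flag the target as
    admixed between populations related to the two sources.
    """
    if isinstance(target, str) and popmap is not None:
        if len(popmap.samples_of(target)) < 2:
            raise PreconditionError("target population needs >= 2 samples for the correction")
    elif not isinstance(target, str) and len(target) < 2:
        raise PreconditionError("target population needs >= 2 samples for the correction")
    (c, a, b), (nc, _, _), mask = _pop_freqs(
        panel, [target, source1, source2], popmap
    )
    idx = np.where(mask)[0]
    per_locus = f3_from_freqs(a[idx], b[idx], c[idx], nc[idx])
    est, se, z, n_blocks = block_jackknife(
        per_locus,
        (panel.chroms[idx], panel.positions[idx]),
        block_size=block_size,
        min_blocks=min_blocks,
    )
    return FStatResult(
        statistic="f3",
        populations=(str(target), str(source1), str(source2)),
        estimate=est,
        se=se,
        z=z,
        n_blocks=n_blocks,
        n_loci=len(idx),
        block_size=block_size,
        admixture_significant=bool(np.isfinite(z) and z <= z_threshold),
        per_locus=per_locus,
    )


def f4(
    pop_a: str | list[str],
    pop_b: str | list[str],
    pop_c: str | list[str],
    pop_d: str | list[str],
    panel: GenotypePanel,
    popmap: PopulationMap | None = None,
    block_size: float = 5e6,
    min_blocks: int = 10,
) -> FStatResult:
    """f4(A, B; C, D) with block-jackknife uncertainty."""
    pops = [pop_a, pop_b, pop_c, pop_d]
    sample_sets = [
        set(popmap.samples_of(p)) if isinstance(p, str) else set(p) for p in pops
    ]
    for i in range(4):
        for j in range(i + 1, 4):
            if sample_sets[i] & sample_sets[j]:
                raise PreconditionError(
                    f"populations {i} and {j} share samples; f4 requires disjoint sets"
                )
    (a, b, c, d), _, mask = _pop_freqs(panel, pops, popmap, min_genotyped=1)
    idx = np.where(mask)[0]
    per_locus = f4_from_freqs(a[idx], b[idx], c[idx], d[idx])
    est, se, z, n_blocks = block_jackknife(
        per_locus,
        (panel.chroms[idx], panel.positions[idx]),
        block_size=block_size,
        min_blocks=min_blocks,
    )
    return FStatResult(
        statistic="f4",
        populations=tuple(str(p) for p in pops),
        estimate=est,
        se=se,
        z=z,
        n_blocks=n_blocks,
        n_loci=len(idx),
        block_size=block_size,
        per_locus=per_locus,
    )
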
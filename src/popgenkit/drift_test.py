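"""Monte-Carlo Wright-Fisher drift null for allele-frequency shifts.

A candidate locus is tested by simulating pure binomial drift from a source
population's allele frequency for a fixed number of generations and asking
how often the simulated final frequency is at least as extreme as the
observed descendant frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

DEFAULT_NE = 11_000
DEFAULT_GENERATIONS = 280
DEFAULT_REPS = 1_000


@dataclass
class DriftTestResult:
    p0: float
    p_obs: float
    ne: int
    generations: int
    reps: int
    tail: str
    p_value: float
    sim_mean: float
    sim_quantiles: dict[str, float] = field(default_factory=dict)
    n_ge_obs: int = 0
    n_le_obs: int = 0
    seed: int | None = None


def wf_drift_final_freq(
    p0: float,
    ne: int,
    generations: int,
    rng: np.random.Generator,
    reps: int = 1,
) -> float | np.ndarray:
    """Final frequency after ``generations`` rounds of binomial resampling.

    Each generation draws Binomial(2*ne, p)/(2*ne); the boundaries 0 and 1
    are absorbing.  Returns a scalar for ``reps == 1``, else an array of
    replicate finals.
    """
    if not (0.0 <= p0 <= 1.0):
        raise DomainError(f"p0 = {p0} outside [0, 1]")
    if ne < 1:
        raise DomainError(f"ne must be >= 1, got {ne}")
    if generations < 0:
        raise DomainError("generations must be >= 0")
    two_ne = 2 * int(ne)
    p = np.full(int(reps), float(p0))
    for _ in range(int(generations)):
        if np.all((p == 0.0) | (p == 1.0)):
            break
        p = rng.binomial(two_ne, p) / two_ne
    return float(p[0]) if reps == 1 else p


def drift_pvalue(
    p0: float,
    p_obs: float,
    ne: int = DEFAULT_NE,
    generations: int = DEFAULT_GENERATIONS,
    reps: int = DEFAULT_REPS,
    tail: str = "upper",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> DriftTestResult:
    """Monte-Carlo drift p-value for one locus.

    ``tail='upper'``: fraction of replicates with final frequency >= p_obs;
    ``'lower'``: <= p_obs; ``'two-sided'``: 2 * min(upper, lower), capped
    at 1.  Reported at resolution 1/reps without continuity correction.
    """
    if not (0.0 <= p_obs <= 1.0):
        raise DomainError(f"p_obs = {p_obs} outside [0, 1]")
    if tail not in ("upper", "lower", "two-sided"):
        raise DomainError(f"unknown tail {tail!r}")
    if reps < 1:
        raise DomainError("reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    finals = wf_drift_final_freq(p0, ne, generations, rng, reps=reps)
    finals = np.atleast_1d(finals)
    n_ge = int(np.sum(finals >= p_obs))
    n_le = int(np.sum(finals <= p_obs))
    upper = n_ge / reps
    lower = n_le / reps
    if tail == "upper":
        p_value = upper
    elif tail == "lower":
        p_value = lower
    else:
        p_value = min(1.0, 2.0 * min(upper, lower))
    qs = np.quantile(finals, [0.025, 0.25, 0.5, 0.75, 0.975])
    return DriftTestResult(
        p0=float(p0),
        p_obs=float(p_obs),
        ne=int(ne),
        generations=int(generations),
        reps=int(reps),
        tail=tail,
        p_value=float(p_value),
        sim_mean=float(finals.mean()),
        sim_quantiles={
            "q2.5": float(qs[0]),
            "q25": float(qs[1]),
            "q50": float(qs[2]),
            "q75": float(qs[3]),
            "q97.5": float(qs[4]),
        },
        n_ge_obs=n_ge,
        n_le_obs=n_le,
        seed=seed,
    )


def drift_test_batch(
    candidate_table: pd.DataFrame,
    p0_column: str = "daf_tbn_target",
    obs_column: str = "daf_shp_target",
    ne: int = DEFAULT_NE,
    generations: int = DEFAULT_GENERATIONS,
    reps: int = DEFAULT_REPS,
    tail: str = "upper",
    seed: int = 0,
) -> pd.DataFrame:
    """One drift test per candidate row.

    The source frequency (``p0_column``) and the observed descendant
    frequency (``obs_column``) are read per row.  Randomness derives from a
    shared base seed with per-row offsets, so results are reproducible and
    independent of row order.
    """
    for col in (p0_column, obs_column):
        if col not in candidate_table.columns:
            raise FormatError(f"candidate table lacks required column {col!r}")
    rows = []
    for offset, (_, row) in enumerate(candidate_table.iterrows()):
        child = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(offset,)))
        res = drift_pvalue(
            float(row[p0_column]),
            float(row[obs_column]),
            ne=ne,
            generations=generations,
            reps=reps,
            tail=tail,
            rng=child,
        )
        out = dict(row)
        out.update(
            {
                "p0": res.p0,
                "p_obs": res.p_obs,
                "ne": res.ne,
                "generations": res.generations,
                "reps": res.reps,
                "tail": res.tail,
                "sim_mean": res.sim_mean,
                "sim_q2.5": res.sim_quantiles["q2.5"],
                "sim_q97.5": res.sim_quantiles["q97.5"],
                "p_value": res.p_value,
            }
        )
        rows.append(out)
    return pd.DataFrame(rows)
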
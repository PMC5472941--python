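"""Synthetic genotype/haplotype panels for testing every pipeline stage.

Two forward Wright-Fisher simulators are provided:

* :func:`simulate_split_frequencies` — independent-locus binomial drift
  along a population tree with piecewise-constant sizes, bottlenecks and
  directional migration (deterministic frequency mixing per generation),
  emitting sampled genotype panels.  This is the substrate for
  allele-frequency statistics (F_ST, f3/f4, T_F, AMOVA, drift tests).
* :func:`simulate_haplotypes` — a recombining diploid forward simulation
  with mutation and optional additive viability selection, emitting phased
  haplotypes plus a linear genetic map for the EHH-family scans.

A documented multi-population preset mirroring a highland/lowland
split-with-gene-flow history is provided by :func:`demography_preset`.
A coalescent convenience wrapper around msprime
(:func:`coalescent_diploid_panel`) supplies equilibrium-LD panels for
LD-decay checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import PreconditionError
from .genotype_io import (
    GeneticMap,
    GenotypePanel,
    HaplotypePanel,
    PopulationMap,
    Variant,
)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class Bottleneck:
    start_gen: int  # generations ago, inclusive (older bound)
    end_gen: int  # generations ago, exclusive (younger bound)
    ne: int


@dataclass
class Branch:
    """One population branch.  ``start_gen`` is the generation (ago) at
    which the branch comes into existence; the root uses the simulation
    horizon.  ``parent`` is None for the root."""

    name: str
    ne: int
    start_gen: int
    parent: str | None = None
    samples: int = 0
    bottlenecks: list[Bottleneck] = field(default_factory=list)

    def ne_at(self, gen: int) -> int:
        for b in self.bottlenecks:
            if b.end_gen <= gen < b.start_gen:
                return b.ne
        return self.ne


@dataclass
class MigrationEdge:
    source: str
    dest: str
    start_gen: int  # older bound, inclusive
    end_gen: int  # younger bound, exclusive (0 = up to the present)
    rate: float  # per-generation fraction of dest replaced by source


@dataclass
class DemographyConfig:
    branches: list[Branch]
    migration: list[MigrationEdge] = field(default_factory=list)
    mutation_rate: float = 1.25e-8
    generation_years: float = 25.0

    def validate(self) -> None:
        errors = []
        names = [b.name for b in self.branches]
        if len(set(names)) != len(names):
            errors.append("duplicate branch names")
        by_name = {b.name: b for b in self.branches}
        roots = [b for b in self.branches if b.parent is None]
        if len(roots) != 1:
            errors.append(f"exactly one root branch required, found {len(roots)}")
        for b in self.branches:
            if b.ne < 1:
                errors.append(f"branch {b.name}: Ne must be >= 1")
            if b.start_gen < 0:
                errors.append(f"branch {b.name}: start_gen must be >= 0")
            if b.parent is not None:
                parent = by_name.get(b.parent)
                if parent is None:
                    errors.append(f"branch {b.name}: unknown parent {b.parent!r}")
                elif parent.start_gen < b.start_gen:
                    errors.append(
                        f"branch {b.name}: split at {b.start_gen} predates parent "
                        f"{b.parent} (starts {parent.start_gen})"
                    )
        for m in self.migration:
            if not (0.0 <= m.rate < 1.0):
                errors.append(f"migration {m.source}->{m.dest}: rate must be in [0, 1)")
            if m.source not in by_name or m.dest not in by_name:
                errors.append(f"migration {m.source}->{m.dest}: unknown population")
            if m.end_gen > m.start_gen:
                errors.append(f"migration {m.source}->{m.dest}: end_gen > start_gen")
        if errors:
            raise PreconditionError("invalid demography config: " + "; ".join(errors))

    @property
    def horizon(self) -> int:
        return max(b.start_gen for b in self.branches)

    def to_json(self) -> str:
        def enc(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            raise TypeError

        return json.dumps(self.__dict__, default=enc, indent=2)


@dataclass
class SimulatedDataset:
    genotypes: GenotypePanel | None
    haplotypes: HaplotypePanel | None
    popmap: PopulationMap
    genetic_map: GeneticMap | None
    truth: dict


def default_ancestral_freqs(L: int, rng: np.random.Generator) -> np.ndarray:
    """SNP-array-like ancestral frequency spectrum: Beta(0.2, 0.2) truncated
    to (0.02, 0.98)."""
    out = np.empty(L)
    todo = np.arange(L)
    while len(todo):
        draw = rng.beta(0.2, 0.2, size=len(todo))
        ok = (draw > 0.02) & (draw < 0.98)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


# ---------------------------------------------------------------------------
# Independent-locus frequency simulator
# ---------------------------------------------------------------------------


def simulate_split_frequencies(
    config: DemographyConfig,
    n_loci: int,
    seed: int = 0,
    ancestral_freqs: np.ndarray | None = None,
    positions_bp_step: int = 50_000,
    chrom: str = "1",
) -> tuple[dict[str, np.ndarray], SimulatedDataset]:
    """Forward binomial drift at independent loci along a population tree.

    Migration edges mix frequencies deterministically each generation
    (p_dest <- (1-m) p_dest + m p_source).  Populations with ``samples > 0``
    are genotyped by binomial draws from their final frequencies.

    Returns (final frequencies per branch, dataset).  The genotype panel is
    born polarized (allele 1 = derived).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if ancestral_freqs is None:
        ancestral_freqs = default_ancestral_freqs(n_loci, rng)
    else:
        ancestral_freqs = np.asarray(ancestral_freqs, dtype=float)
        if len(ancestral_freqs) != n_loci:
            raise PreconditionError("ancestral_freqs length must equal n_loci")

    by_name = {b.name: b for b in config.branches}
    root = next(b for b in config.branches if b.parent is None)
    freqs: dict[str, np.ndarray] = {root.name: ancestral_freqs.copy()}

    for gen in range(config.horizon, 0, -1):
        # splits happening at this generation: children copy parent frequency
        for b in config.branches:
            if b.parent is not None and b.start_gen == gen and b.name not in freqs:
                if b.parent not in freqs:
                    raise PreconditionError(
                        f"branch {b.name} splits from {b.parent} before the parent exists"
                    )
                freqs[b.name] = freqs[b.parent].copy()
        # migration (deterministic mixing), applied before drift
        for m in config.migration:
            if m.end_gen <= gen <= m.start_gen and m.source in freqs and m.dest in freqs:
                freqs[m.dest] = (1.0 - m.rate) * freqs[m.dest] + m.rate * freqs[m.source]
        # drift
        for name in freqs:
            ne = by_name[name].ne_at(gen)
            p = freqs[name]
            freqs[name] = rng.binomial(2 * ne, p) / (2.0 * ne)

    # branches splitting at generation 0 come into existence at the present
    for b in config.branches:
        if b.parent is not None and b.start_gen == 0 and b.name not in freqs:
            if b.parent in freqs:
                freqs[b.name] = freqs[b.parent].copy()

    sampled = [b for b in config.branches if b.samples > 0]
    variants = [
        Variant(chrom, (i + 1) * positions_bp_step, None, "A", "G", "A")
        for i in range(n_loci)
    ]
    samples: list[str] = []
    sample_to_pop: dict[str, str] = {}
    cols: list[np.ndarray] = []
    for b in sampled:
        if b.name not in freqs:
            raise PreconditionError(f"sampled branch {b.name} never became active")
        g = rng.binomial(2, freqs[b.name][:, None], size=(n_loci, b.samples))
        cols.append(g)
        for k in range(b.samples):
            sid = f"{b.name}_{k}"
            samples.append(sid)
            sample_to_pop[sid] = b.name
    panel = None
    if sampled:
        panel = GenotypePanel(
            variants=variants,
            samples=samples,
            genotypes=np.hstack(cols).astype(np.int8),
            counted=np.array(["derived"] * n_loci, dtype=object),
        )
    dataset = SimulatedDataset(
        genotypes=panel,
        haplotypes=None,
        popmap=PopulationMap(sample_to_pop),
        genetic_map=None,
        truth={"seed": seed, "n_loci": n_loci, "config": config.to_json()},
    )
    return freqs, dataset


def panel_from_frequencies(
    freqs: dict[str, np.ndarray],
    samples_per_pop: int | dict[str, int],
    seed: int = 0,
    positions_bp_step: int = 50_000,
    chrom: str = "1",
) -> SimulatedDataset:
    """Binomial-sample a genotype panel from per-population frequency vectors."""
    rng = np.random.default_rng(seed)
    n_loci = len(next(iter(freqs.values())))
    variants = [
        Variant(chrom, (i + 1) * positions_bp_step, None, "A", "G", "A")
        for i in range(n_loci)
    ]
    samples, cols, sample_to_pop = [], [], {}
    for pop, p in freqs.items():
        n = samples_per_pop[pop] if isinstance(samples_per_pop, dict) else samples_per_pop
        cols.append(rng.binomial(2, np.asarray(p)[:, None], size=(n_loci, n)))
        for k in range(n):
            sid = f"{pop}_{k}"
            samples.append(sid)
            sample_to_pop[sid] = pop
    panel = GenotypePanel(
        variants=variants,
        samples=samples,
        genotypes=np.hstack(cols).astype(np.int8),
        counted=np.array(["derived"] * n_loci, dtype=object),
    )
    return SimulatedDataset(
        genotypes=panel,
        haplotypes=None,
        popmap=PopulationMap(sample_to_pop),
        genetic_map=None,
        truth={"seed": seed},
    )


def two_population_split(
    split_generations: int,
    ne: int,
    samples_per_pop: int,
    n_loci: int,
    seed: int = 0,
    migration_rate: float = 0.0,
    names: tuple[str, str] = ("popA", "popB"),
) -> tuple[dict[str, np.ndarray], SimulatedDataset]:
    """Convenience wrapper: one ancestral branch splitting into two."""
    branches = [
        Branch("anc", ne, split_generations + 1, None, 0),
        Branch(names[0], ne, split_generations, "anc", samples_per_pop),
        Branch(names[1], ne, split_generations, "anc", samples_per_pop),
    ]
    migration = []
    if migration_rate > 0:
        migration = [
            MigrationEdge(names[0], names[1], split_generations, 0, migration_rate),
            MigrationEdge(names[1], names[0], split_generations, 0, migration_rate),
        ]
    config = DemographyConfig(branches=branches, migration=migration)
    return simulate_split_frequencies(config, n_loci, seed=seed)


# ---------------------------------------------------------------------------
# Recombining haplotype simulator
# ---------------------------------------------------------------------------


class _ForwardPopulation:
    """Internal state for the recombining forward simulation."""

    def __init__(self, haplotypes: np.ndarray, positions: np.ndarray, segment_length: float):
        self.hap = haplotypes  # (2N, L) uint8
        self.positions = positions
        self.segment_length = segment_length

    def copy(self) -> "_ForwardPopulation":
        return _ForwardPopulation(self.hap.copy(), self.positions, self.segment_length)


def _next_generation(
    state: _ForwardPopulation,
    rng: np.random.Generator,
    recomb_rate: float,
    mutation_rate: float,
    sel_site: int | None = None,
    sel_coef: float = 0.0,
) -> None:
    hap = state.hap
    two_n = hap.shape[0]
    n = two_n // 2
    L = hap.shape[1]
    if sel_site is not None and sel_coef != 0.0:
        dose = hap[0::2, sel_site].astype(float) + hap[1::2, sel_site].astype(float)
        w = 1.0 + sel_coef * dose
        w = np.clip(w, 0.0, None)
        if w.sum() == 0:
            w = np.ones(n)
        prob = w / w.sum()
    else:
        prob = None
    parents = rng.choice(n, size=(n, 2), p=prob)
    lam = recomb_rate * state.segment_length  # expected crossovers per meiosis
    n_cross = rng.poisson(lam, size=(n, 2))
    child = np.empty_like(hap)
    for i in range(n):
        for which in range(2):
            par = parents[i, which]
            h1, h2 = hap[2 * par], hap[2 * par + 1]
            k = n_cross[i, which]
            if rng.random() < 0.5:
                h1, h2 = h2, h1
            if k == 0:
                child[2 * i + which] = h1
            else:
                breaks = np.sort(rng.uniform(0, state.segment_length, size=k))
                seg_id = np.searchsorted(breaks, state.positions)
                child[2 * i + which] = np.where(seg_id % 2 == 0, h1, h2)
    # recurrent mutation: flip alleles at random (haplotype, site) entries
    if mutation_rate > 0:
        n_mut = rng.poisson(mutation_rate * L * two_n)
        if n_mut:
            hi = rng.integers(0, two_n, size=n_mut)
            si = rng.integers(0, L, size=n_mut)
            child[hi, si] = 1 - child[hi, si]
    state.hap = child


def simulate_haplotypes(
    n_diploid: int,
    segment_length: float = 1e6,
    recomb_rate: float = 1e-8,
    mutation_rate: float = 0.0,
    generations: int = 200,
    n_sites: int = 400,
    init_freqs: np.ndarray | None = None,
    selection: tuple[int, float] | None = None,
    sweep_start_freq: float | None = None,
    stop_at_freq: float | None = None,
    seed: int = 0,
    chrom: str = "1",
    pop_name: str = "pop0",
) -> SimulatedDataset:
    """Forward simulation of a recombining diploid population.

    Starts from standing variation at ``n_sites`` fixed positions (initial
    frequencies from the SNP-array-like default spectrum unless supplied,
    haplotypes initialized at linkage equilibrium) and runs ``generations``
    of random mating with Poisson crossovers and optional recurrent
    mutation.  ``selection=(site_index, s)`` applies additive viability
    selection on allele 1 of that site; the allele is (re)seeded at
    ``sweep_start_freq`` on copies of a single founder haplotype so the
    sweep carries a hitchhiking background.  With ``stop_at_freq`` the run
    ends early once the selected allele reaches that frequency.
    """
    if n_diploid < 2:
        raise PreconditionError("need at least 2 diploid individuals")
    if recomb_rate < 0 or mutation_rate < 0:
        raise PreconditionError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(np.arange(1, int(segment_length)), size=n_sites, replace=False))
    if init_freqs is None:
        init_freqs = default_ancestral_freqs(n_sites, rng)
    else:
        init_freqs = np.asarray(init_freqs, dtype=float)
    two_n = 2 * n_diploid
    hap = (rng.random((two_n, n_sites)) < init_freqs).astype(np.int8)

    sel_site: int | None = None
    s = 0.0
    if selection is not None:
        sel_site, s = selection
        if not (0 <= sel_site < n_sites):
            raise PreconditionError("selection site outside segment")
        hap[:, sel_site] = 0
        n_seed = max(1, int(round((sweep_start_freq or 1.0 / two_n) * two_n)))
        founder = int(rng.integers(0, two_n))
        # copy the founder haplotype onto the seeded carriers so the selected
        # allele rises on one background
        carriers = rng.choice(two_n, size=n_seed, replace=False)
        hap[carriers] = hap[founder]
        hap[carriers, sel_site] = 1

    state = _ForwardPopulation(hap, positions.astype(float), float(segment_length))
    gens_run = 0
    for _ in range(generations):
        _next_generation(state, rng, recomb_rate, mutation_rate, sel_site, s)
        gens_run += 1
        if sel_site is not None and stop_at_freq is not None:
            freq = state.hap[:, sel_site].mean()
            if freq >= stop_at_freq or freq == 0.0:
                break

    variants = [
        Variant(chrom, int(p), None, "A", "G", "A") for p in positions
    ]
    sample_names = [f"{pop_name}_{k}" for k in range(n_diploid)]
    hap_panel = HaplotypePanel(
        variants=variants,
        haplotypes=state.hap,
        sample_of_haplotype=[sid for sid in sample_names for _ in range(2)],
        counted=np.array(["derived"] * n_sites, dtype=object),
    )
    gmap = GeneticMap.linear(chrom, int(segment_length), cm_per_mb=recomb_rate * 1e8)
    truth = {
        "seed": seed,
        "n_diploid": n_diploid,
        "segment_length": segment_length,
        "recomb_rate": recomb_rate,
        "mutation_rate": mutation_rate,
        "generations_requested": generations,
        "generations_run": gens_run,
        "selection": None
        if selection is None
        else {
            "site_index": int(sel_site),
            "s": s,
            "position": int(positions[sel_site]),
            "final_freq": float(state.hap[:, sel_site].mean()),
        },
    }
    return SimulatedDataset(
        genotypes=hap_panel.to_genotype_panel(),
        haplotypes=hap_panel,
        popmap=PopulationMap({sid: pop_name for sid in sample_names}),
        genetic_map=gmap,
        truth=truth,
    )


def simulate_sweep_pair(
    n_diploid: int = 800,
    segment_length: float = 16e6,
    recomb_rate: float = 1e-7,
    s: float = 0.05,
    target_freq: float = 0.7,
    seed_freq: float = 0.05,
    ne_background: int = 5000,
    mutation_rate: float = 1.25e-8,
    n_sites_max: int = 2000,
    maf_min: float = 0.02,
    max_generations: int = 500,
    max_tries: int = 60,
    seed: int = 0,
) -> tuple[SimulatedDataset, SimulatedDataset]:
    """A matched (sweep, neutral) pair of populations on a shared variant grid.

    Standing variation with equilibrium LD comes from a coalescent sample
    (msprime, size ``ne_background``); the sampled haplotypes then evolve
    forward as a closed population.  The sweep copy carries additive
    viability selection at the central site, seeded on one founder
    haplotype and retried with fresh sub-seeds until it reaches
    ``target_freq``; the neutral copy runs the same number of generations
    without selection, so both panels share variant grid and drift depth.
    """
    import msprime

    ts = msprime.sim_ancestry(
        samples=n_diploid,
        population_size=ne_background,
        sequence_length=segment_length,
        recombination_rate=recomb_rate,
        random_seed=seed + 1,
    )
    ts = msprime.sim_mutations(ts, rate=mutation_rate, random_seed=seed + 2, model="binary")
    pos_list, rows = [], []
    for var in ts.variants():
        if len(var.alleles) != 2:
            continue
        pos_list.append(int(var.site.position) + 1)
        rows.append(np.asarray(var.genotypes, dtype=np.int8))
    hap0 = np.vstack(rows).T  # (2N, L)
    positions = np.asarray(pos_list, dtype=float)
    keep = np.concatenate([[True], np.diff(positions) > 0])
    freqs0 = hap0.mean(axis=0)
    keep &= (freqs0 >= maf_min) & (freqs0 <= 1 - maf_min)
    if keep.sum() > n_sites_max:  # thin evenly to bound scan cost
        chosen = np.linspace(0, keep.sum() - 1, n_sites_max).round().astype(int)
        idx = np.where(keep)[0][chosen]
        keep = np.zeros_like(keep)
        keep[idx] = True
    hap0, positions = hap0[:, keep], positions[keep]
    n_sites = hap0.shape[1]
    two_n = 2 * n_diploid
    sel_site = int(np.argmin(np.abs(positions - segment_length / 2)))

    state = _ForwardPopulation(hap0, positions, float(segment_length))

    # selected continuation, conditioned on reaching target_freq
    swept = None
    gens_sweep = 0
    for attempt in range(max_tries):
        trial = state.copy()
        rng_s = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(100 + attempt,)))
        founder = int(rng_s.integers(0, two_n))
        n_seed = max(3, int(round(seed_freq * two_n)))
        carriers = rng_s.choice(two_n, size=n_seed, replace=False)
        trial.hap[carriers] = trial.hap[founder]
        trial.hap[:, sel_site] = 0
        trial.hap[carriers, sel_site] = 1
        reached = False
        gens = 0
        for _ in range(max_generations):
            _next_generation(trial, rng_s, recomb_rate, 0.0, sel_site, s)
            gens += 1
            freq = trial.hap[:, sel_site].mean()
            if freq >= target_freq:
                reached = True
                break
            if freq == 0.0:
                break
        if reached:
            swept = trial
            gens_sweep = gens
            break
    if swept is None:
        raise PreconditionError(
            f"sweep failed to reach frequency {target_freq} in {max_tries} attempts"
        )

    # neutral continuation for the same number of generations
    neutral = state.copy()
    rng_n = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    for _ in range(gens_sweep):
        _next_generation(neutral, rng_n, recomb_rate, 0.0)

    def to_dataset(st: _ForwardPopulation, pop_name: str) -> SimulatedDataset:
        variants = [Variant("1", int(p), None, "A", "G", "A") for p in positions]
        names = [f"{pop_name}_{k}" for k in range(n_diploid)]
        hap_panel = HaplotypePanel(
            variants=variants,
            haplotypes=st.hap,
            sample_of_haplotype=[sid for sid in names for _ in range(2)],
            counted=np.array(["derived"] * n_sites, dtype=object),
        )
        return SimulatedDataset(
            genotypes=hap_panel.to_genotype_panel(),
            haplotypes=hap_panel,
            popmap=PopulationMap({sid: pop_name for sid in names}),
            genetic_map=GeneticMap.linear("1", int(segment_length), cm_per_mb=recomb_rate * 1e8),
            truth={
                "seed": seed,
                "selected_site_index": sel_site,
                "selected_position": int(positions[sel_site]),
                "s": s if pop_name == "sweep" else 0.0,
                "generations_run": gens_sweep,
                "selected_final_freq": float(st.hap[:, sel_site].mean()),
            },
        )

    return to_dataset(swept, "sweep"), to_dataset(neutral, "neutral")


# ---------------------------------------------------------------------------
# Coalescent convenience wrapper (equilibrium LD)
# ---------------------------------------------------------------------------


def coalescent_diploid_panel(
    n_diploid: int,
    ne: int,
    sequence_length: float = 5e6,
    recomb_rate: float = 1e-8,
    mutation_rate: float = 1.25e-8,
    seed: int = 1,
    chrom: str = "1",
    pop_name: str = "pop0",
) -> SimulatedDataset:
    """Constant-size equilibrium panel simulated with msprime.

    Used for LD-decay recovery checks, where the forward simulators would
    need prohibitively long burn-ins to reach LD equilibrium.
    """
    import msprime

    ts = msprime.sim_ancestry(
        samples=n_diploid,
        population_size=ne,
        sequence_length=sequence_length,
        recombination_rate=recomb_rate,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(ts, rate=mutation_rate, random_seed=seed + 1, model="binary")
    positions = []
    rows = []
    for var in ts.variants():
        if len(var.alleles) != 2:
            continue
        positions.append(int(var.site.position) + 1)
        rows.append(np.asarray(var.genotypes, dtype=np.int8))
    hap = np.vstack(rows).T  # (2N, L)
    # de-duplicate collided integer positions
    pos_arr = np.asarray(positions, dtype=np.int64)
    keep = np.concatenate([[True], np.diff(pos_arr) > 0])
    pos_arr = pos_arr[keep]
    hap = hap[:, keep]
    variants = [Variant(chrom, int(p), None, "A", "G", "A") for p in pos_arr]
    names = [f"{pop_name}_{k}" for k in range(n_diploid)]
    hap_panel = HaplotypePanel(
        variants=variants,
        haplotypes=hap,
        sample_of_haplotype=[sid for sid in names for _ in range(2)],
        counted=np.array(["derived"] * len(variants), dtype=object),
    )
    return SimulatedDataset(
        genotypes=hap_panel.to_genotype_panel(),
        haplotypes=hap_panel,
        popmap=PopulationMap({sid: pop_name for sid in names}),
        genetic_map=GeneticMap.linear(chrom, int(sequence_length), cm_per_mb=recomb_rate * 1e8),
        truth={"seed": seed, "ne": ne, "engine": "msprime"},
    )


# ---------------------------------------------------------------------------
# Multi-population preset
# ---------------------------------------------------------------------------

#: Directional gene-flow edges of the preset, all defaulting to off.
PRESET_EDGES = {
    "lowland_ea_to_highland_mrca": MigrationEdge("lowland_ea", "highland_mrca", 340, 281, 0.02),
    "lowland_ea_to_highland_a": MigrationEdge("lowland_ea", "highland_a", 150, 0, 0.005),
    "highland_b2_to_highland_a": MigrationEdge("highland_b2", "highland_a", 100, 0, 0.005),
    "highland_a_to_highland_b2": MigrationEdge("highland_a", "highland_b2", 100, 0, 0.005),
    "highland_a_to_highland_b1": MigrationEdge("highland_a", "highland_b1", 80, 0, 0.005),
    "highland_b1_to_highland_a": MigrationEdge("highland_b1", "highland_a", 80, 0, 0.005),
    "lowland_sa_to_highland_b1": MigrationEdge("lowland_sa", "highland_b1", 50, 0, 0.01),
}


def demography_preset(
    seed: int = 0,
    n_loci: int = 5000,
    edges_on: Sequence[str] = (),
    samples_per_pop: int = 20,
    outgroup_samples: int = 20,
) -> tuple[dict[str, np.ndarray], SimulatedDataset]:
    """Six-population highland/lowland preset with toggleable gene flow.

    Topology (times in generations ago): an outgroup splits at 1500; the
    two lowland populations (East-Asian-like and South-Asian-like) split at
    1000; the highland ancestor leaves the East-Asian-like lowland branch
    at 360; highland A (large-population-like) and the highland B pair
    split at 280; B1/B2 split at 150, with a bottleneck on B2.  Gene-flow
    edge names, directions and rates are arbitrary documented defaults for
    testing (see ``PRESET_EDGES``); all edges default to off.
    """
    unknown = set(edges_on) - set(PRESET_EDGES)
    if unknown:
        raise PreconditionError(f"unknown gene-flow edges: {sorted(unknown)}")
    branches = [
        Branch("root", 10_000, 2000, None, 0),
        Branch("outgroup", 10_000, 1500, "root", outgroup_samples),
        Branch("eurasia", 10_000, 1500, "root", 0),
        Branch("lowland_ea", 10_000, 1000, "eurasia", samples_per_pop),
        Branch("lowland_sa", 10_000, 1000, "eurasia", samples_per_pop),
        Branch("highland_mrca", 8_000, 360, "lowland_ea", 0),
        Branch("highland_a", 8_000, 280, "highland_mrca", samples_per_pop),
        Branch("highland_b_mrca", 5_000, 280, "highland_mrca", 0),
        Branch("highland_b1", 5_000, 150, "highland_b_mrca", samples_per_pop),
        Branch(
            "highland_b2",
            3_000,
            150,
            "highland_b_mrca",
            samples_per_pop,
            bottlenecks=[Bottleneck(150, 120, 800)],
        ),
    ]
    migration = [PRESET_EDGES[name] for name in edges_on]
    config = DemographyConfig(branches=branches, migration=migration)
    return simulate_split_frequencies(config, n_loci, seed=seed)
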
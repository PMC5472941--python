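"""Genotype/haplotype panel containers, readers, polarization and QC.

The central data structures are :class:`GenotypePanel` (diploid dosage matrix,
variants x samples, coded 0/1/2 with ``MISSING`` for no-calls),
:class:`HaplotypePanel` (phased 0/1 matrix, haplotypes x variants),
:class:`PopulationMap` (sample -> population -> group hierarchy) and
:class:`GeneticMap` (physical bp -> cM interpolation).

All downstream statistics consume these containers; derived-allele
polarization happens here, once, via :func:`polarize`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DomainError,
    EmptyInputError,
    EmptyOutputError,
    FormatError,
    InsufficientDataError,
    PreconditionError,
)

logger = logging.getLogger(__name__)

#: Missing genotype code in dosage matrices.
MISSING = -1

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP.

    ``ancestral`` is ``None`` when the ancestral state is unknown; otherwise
    it must equal ``ref`` or ``alt``.
    """

    chrom: str
    pos: int
    id: str | None
    ref: str
    alt: str
    ancestral: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DomainError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DomainError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if self.ancestral is not None and self.ancestral not in (self.ref, self.alt):
            raise DomainError(
                f"ancestral allele {self.ancestral!r} is neither ref nor alt "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def derived(self) -> str | None:
        if self.ancestral is None:
            return None
        return self.alt if self.ancestral == self.ref else self.ref


@dataclass
class GenotypePanel:
    """Diploid dosage matrix with per-variant counted-allele bookkeeping.

    ``genotypes[i, j]`` counts copies of the counted allele of variant ``i``
    carried by sample ``j`` (0/1/2, ``MISSING`` for no-call).  ``counted[i]``
    is ``"alt"``, ``"minor"`` or ``"derived"``; after :func:`polarize` every
    variant counts derived copies.
    """

    variants: list[Variant]
    samples: list[str]
    genotypes: np.ndarray
    counted: np.ndarray  # dtype=object, values in {"alt", "minor", "derived"}

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.counted = np.asarray(self.counted, dtype=object)
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise FormatError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if self.counted.shape != (len(self.variants),):
            raise FormatError("counted-allele flags must align with variants")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def is_polarized(self) -> bool:
        return bool(self.n_variants) and all(c == "derived" for c in self.counted)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants], dtype=object)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def sample_indices(self, names: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in panel") from None

    def subset(
        self,
        variant_idx: np.ndarray | None = None,
        sample_idx: np.ndarray | None = None,
    ) -> "GenotypePanel":
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        return GenotypePanel(
            variants=[self.variants[i] for i in vi],
            samples=[self.samples[j] for j in si],
            genotypes=self.genotypes[np.ix_(vi, si)],
            counted=self.counted[vi].copy(),
        )

    # -- frequencies -------------------------------------------------------

    def allele_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Counted-allele frequency per variant; NaN where all samples missing."""
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx]
        ok = g != MISSING
        n = ok.sum(axis=1)
        tot = np.where(ok, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per variant."""
        if self.n_samples == 0:
            return np.zeros(self.n_variants)
        return (self.genotypes != MISSING).mean(axis=1)

    def sample_missing_rate(self) -> np.ndarray:
        if self.n_variants == 0:
            return np.zeros(self.n_samples)
        return (self.genotypes == MISSING).mean(axis=0)


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes, shape (n_haplotypes, n_variants).

    Entries are 0/1 copies of the counted allele; after polarization
    1 = derived.  Each sample contributes exactly two consecutive rows.
    """

    variants: list[Variant]
    haplotypes: np.ndarray
    sample_of_haplotype: list[str]
    counted: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (len(self.sample_of_haplotype), len(self.variants)):
            raise FormatError("haplotype matrix shape mismatch")
        if len(self.sample_of_haplotype) % 2 != 0:
            raise FormatError("each sample must contribute exactly two haplotypes")
        if self.counted is None:
            self.counted = np.array(["alt"] * len(self.variants), dtype=object)
        else:
            self.counted = np.asarray(self.counted, dtype=object)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def samples(self) -> list[str]:
        return self.sample_of_haplotype[::2]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def derived_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def to_genotype_panel(self) -> GenotypePanel:
        g = (self.haplotypes[0::2] + self.haplotypes[1::2]).T
        return GenotypePanel(
            variants=list(self.variants),
            samples=list(self.samples),
            genotypes=g,
            counted=self.counted.copy(),
        )


class PopulationMap:
    """Sample -> population and population -> group assignments."""

    def __init__(
        self,
        sample_to_pop: Mapping[str, str],
        pop_to_group: Mapping[str, str] | None = None,
        pop_meta: Mapping[str, dict] | None = None,
    ) -> None:
        self.sample_to_pop = dict(sample_to_pop)
        self.pop_to_group = dict(pop_to_group or {})
        self.pop_meta = dict(pop_meta or {})
        for pop in set(self.sample_to_pop.values()):
            self.pop_to_group.setdefault(pop, pop)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.sample_to_pop.values():
            seen.setdefault(pop, None)
        return list(seen)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.populations:
            seen.setdefault(self.pop_to_group[pop], None)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        if population not in set(self.sample_to_pop.values()):
            raise KeyError(f"unknown population {population!r}")
        return [s for s, p in self.sample_to_pop.items() if p == population]

    def populations_of_group(self, group: str) -> list[str]:
        return [p for p in self.populations if self.pop_to_group[p] == group]

    def group_of_sample(self, sample: str) -> str:
        return self.pop_to_group[self.sample_to_pop[sample]]

    def restricted_to(self, samples: Sequence[str]) -> "PopulationMap":
        keep = {s: p for s, p in self.sample_to_pop.items() if s in set(samples)}
        return PopulationMap(keep, self.pop_to_group, self.pop_meta)


class GeneticMap:
    """Per-chromosome monotone physical-bp -> cM interpolation."""

    def __init__(self, knots: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> None:
        self._knots: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, cm) in knots.items():
            pos = np.asarray(pos, dtype=np.float64)
            cm = np.asarray(cm, dtype=np.float64)
            order = np.argsort(pos)
            pos, cm = pos[order], cm[order]
            if np.any(np.diff(cm) < 0):
                raise FormatError(f"genetic map not monotone on chromosome {chrom}")
            self._knots[chrom] = (pos, cm)

    @classmethod
    def linear(cls, chrom: str, length_bp: int, cm_per_mb: float = 1.0) -> "GeneticMap":
        pos = np.array([1.0, float(length_bp)])
        cm = pos * cm_per_mb / 1e6
        return cls({chrom: (pos, cm)})

    def cm(self, chrom: str, pos: np.ndarray | float) -> np.ndarray | float:
        if chrom not in self._knots:
            raise KeyError(f"no genetic map for chromosome {chrom!r}")
        kp, kc = self._knots[chrom]
        return np.interp(pos, kp, kc)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._knots)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_vcf(
    path: str, require_ancestral: bool = False
) -> tuple[GenotypePanel, HaplotypePanel | None]:
    """Read biallelic SNPs from a VCF 4.x file.

    Non-SNP and multiallelic records are skipped (count logged).  The
    ancestral allele is taken from the ``AA`` INFO key when present and
    consistent with ref/alt.  When every genotype is phased and called, a
    :class:`HaplotypePanel` is returned alongside the genotype panel.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # malformed header
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)

    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    n_skipped = 0
    n_dropped_aa = 0
    all_phased = True
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        if rec.REF not in _BASES or rec.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        aa = rec.INFO.get("AA")
        if aa is not None:
            aa = str(aa).upper()
            if aa not in (rec.REF, rec.ALT[0]):
                n_dropped_aa += 1
                aa = None
        if require_ancestral and aa is None:
            n_skipped += 1
            continue
        gts = rec.genotypes  # [[a1, a2, phased], ...]
        dose = np.empty(len(samples), dtype=np.int8)
        haps = np.empty(2 * len(samples), dtype=np.int8)
        for j, gt in enumerate(gts):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                dose[j] = MISSING
                haps[2 * j] = haps[2 * j + 1] = -1
                all_phased = False
            else:
                dose[j] = a1 + a2
                haps[2 * j], haps[2 * j + 1] = a1, a2
                if not gt[2]:
                    all_phased = False
        variants.append(
            Variant(rec.CHROM, rec.POS, rec.ID, rec.REF, rec.ALT[0], aa)
        )
        rows.append(dose)
        hap_rows.append(haps)
    if n_skipped or n_dropped_aa:
        logger.info(
            "read_vcf(%s): skipped %d non-biallelic-SNP records, "
            "ignored %d inconsistent AA tags",
            path,
            n_skipped,
            n_dropped_aa,
        )
    if not variants:
        raise EmptyInputError(f"no biallelic SNPs in {path}")

    order = np.lexsort(
        (np.array([v.pos for v in variants]), np.array([v.chrom for v in variants], dtype=object))
    )
    variants = [variants[i] for i in order]
    geno = np.vstack(rows)[order]
    panel = GenotypePanel(
        variants=variants,
        samples=samples,
        genotypes=geno,
        counted=np.array(["alt"] * len(variants), dtype=object),
    )
    hap_panel = None
    if all_phased and len(samples) > 0:
        hap = np.vstack(hap_rows)[order].T  # (n_hap, n_var)
        sample_of_hap = [s for s in samples for _ in range(2)]
        hap_panel = HaplotypePanel(
            variants=list(variants),
            haplotypes=hap,
            sample_of_haplotype=sample_of_hap,
            counted=np.array(["alt"] * len(variants), dtype=object),
        )
    return panel, hap_panel


def read_plink_text(
    ped_path: str, map_path: str, ancestral: Mapping[tuple[str, int], str] | None = None
) -> GenotypePanel:
    """Read a PLINK text PED/MAP pair.

    Counted allele is the minor allele per variant unless an ancestral
    lookup ``{(chrom, pos): allele}`` is supplied, in which case variants
    with a known ancestral state count the derived allele.
    """
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"MAP line has {len(parts)} fields, expected >= 4")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    n_var = len(map_rows)
    if n_var == 0:
        raise EmptyInputError(f"no variants in {map_path}")

    samples: list[str] = []
    allele_cols: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_var:
                raise FormatError(
                    f"PED row for {parts[1] if len(parts) > 1 else '?'} lists "
                    f"{(len(parts) - 6) // 2} genotypes but MAP has {n_var} variants"
                )
            samples.append(parts[1])
            allele_cols.append(
                [(parts[6 + 2 * i], parts[7 + 2 * i]) for i in range(n_var)]
            )
    if not samples:
        raise EmptyInputError(f"no samples in {ped_path}")

    variants: list[Variant] = []
    geno = np.empty((n_var, len(samples)), dtype=np.int8)
    counted_flags: list[str] = []
    for i, (chrom, vid, pos) in enumerate(map_rows):
        pairs = [allele_cols[j][i] for j in range(len(samples))]
        alleles: dict[str, int] = {}
        for a1, a2 in pairs:
            for a in (a1, a2):
                if a != "0":
                    alleles[a] = alleles.get(a, 0) + 1
        if len(alleles) > 2:
            raise FormatError(f"variant {vid} at {chrom}:{pos} has >2 alleles")
        ordered = sorted(alleles.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ordered) == 0:
            major, minor = "N", "N"  # all-missing; placeholder alleles
            ref, alt = "A", "G"
        elif len(ordered) == 1:
            ref = ordered[0][0]
            alt = next(b for b in sorted(_BASES) if b != ref)
            major, minor = ref, alt
        else:
            major, minor = ordered[0][0], ordered[1][0]
            ref, alt = major, minor
        anc = None
        counted = minor
        flag = "minor"
        if ancestral is not None:
            anc_allele = ancestral.get((chrom, pos))
            if anc_allele in (ref, alt):
                anc = anc_allele
                counted = alt if anc == ref else ref
                flag = "derived"
        variants.append(Variant(chrom, pos, vid or None, ref, alt, anc))
        counted_flags.append(flag)
        for j, (a1, a2) in enumerate(pairs):
            if a1 == "0" or a2 == "0":
                geno[i, j] = MISSING
            else:
                geno[i, j] = (a1 == counted) + (a2 == counted)

    order = np.lexsort(
        (np.array([v.pos for v in variants]), np.array([v.chrom for v in variants], dtype=object))
    )
    return GenotypePanel(
        variants=[variants[i] for i in order],
        samples=samples,
        genotypes=geno[order],
        counted=np.array(counted_flags, dtype=object)[order],
    )


def read_population_map(path: str) -> PopulationMap:
    """Read a TSV with columns sample_id, population[, group]."""
    import csv

    sample_to_pop: dict[str, str] = {}
    pop_to_group: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise EmptyInputError(f"empty population map {path}")
        rows = [header] if header and not header[0].lower().startswith("sample") else []
        rows += [r for r in reader if r]
    for r in rows:
        if len(r) < 2:
            raise FormatError(f"population map row too short: {r}")
        sample, pop = r[0], r[1]
        if sample in sample_to_pop:
            raise FormatError(f"sample {sample!r} listed twice in population map")
        sample_to_pop[sample] = pop
        if len(r) >= 3 and r[2]:
            prev = pop_to_group.get(pop)
            if prev is not None and prev != r[2]:
                raise FormatError(f"population {pop!r} assigned to two groups")
            pop_to_group[pop] = r[2]
    return PopulationMap(sample_to_pop, pop_to_group)


def read_genetic_map(path: str) -> GeneticMap:
    """Read a TSV with columns chrom, pos, cM."""
    per_chrom: dict[str, list[tuple[float, float]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].lower() in ("chrom", "#chrom"):
                continue
            if len(parts) < 3:
                raise FormatError(f"genetic map row too short: {line!r}")
            per_chrom.setdefault(parts[0], []).append((float(parts[1]), float(parts[2])))
    if not per_chrom:
        raise EmptyInputError(f"empty genetic map {path}")
    return GeneticMap(
        {
            chrom: (np.array([p for p, _ in rows]), np.array([c for _, c in rows]))
            for chrom, rows in per_chrom.items()
        }
    )


def read_ancestral_table(path: str) -> dict[tuple[str, int], str]:
    """Read a side TSV (chrom, pos, ancestral allele)."""
    table: dict[tuple[str, int], str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].lower() in ("chrom", "#chrom"):
                continue
            table[(parts[0], int(parts[1]))] = parts[2].upper()
    return table


def apply_ancestral(
    panel: GenotypePanel, table: Mapping[tuple[str, int], str]
) -> GenotypePanel:
    """Overwrite ancestral states from a side table; the table wins on conflict."""
    new_variants = []
    n_conflict = 0
    for v in panel.variants:
        anc = table.get((v.chrom, v.pos))
        if anc is not None and anc in (v.ref, v.alt):
            if v.ancestral is not None and v.ancestral != anc:
                n_conflict += 1
            new_variants.append(replace(v, ancestral=anc))
        else:
            new_variants.append(v)
    if n_conflict:
        logger.warning("apply_ancestral: %d conflicts resolved in favour of side table", n_conflict)
    return GenotypePanel(new_variants, list(panel.samples), panel.genotypes.copy(), panel.counted.copy())


# ---------------------------------------------------------------------------
# Polarization and frequencies
# ---------------------------------------------------------------------------


def polarize(panel: GenotypePanel) -> GenotypePanel:
    """Recode the panel so every variant counts derived-allele copies.

    Columns where the counted allele is already the derived allele are left
    untouched; columns where it is the ancestral allele are flipped
    (0 <-> 2, missing preserved).  Variants with unknown ancestral state are
    dropped (count logged).
    """
    keep: list[int] = []
    flip: list[bool] = []
    for i, v in enumerate(panel.variants):
        if v.ancestral is None:
            continue
        keep.append(i)
        if panel.counted[i] == "derived":
            flip.append(False)
        else:
            counted_allele = v.alt if panel.counted[i] == "alt" else None
            if counted_allele is None:
                # "minor" counting from PED input: infer counted base from codes
                # is impossible post hoc; treat counted == alt convention.
                counted_allele = v.alt
            flip.append(counted_allele == v.ancestral)
    n_dropped = panel.n_variants - len(keep)
    if n_dropped:
        logger.info("polarize: dropped %d variants with unknown ancestral state", n_dropped)
    if not keep:
        raise EmptyOutputError("no variants with known ancestral state")
    geno = panel.genotypes[keep].copy()
    flip_arr = np.array(flip)
    sub = geno[flip_arr]
    mask = sub != MISSING
    sub[mask] = 2 - sub[mask]
    geno[flip_arr] = sub
    return GenotypePanel(
        variants=[panel.variants[i] for i in keep],
        samples=list(panel.samples),
        genotypes=geno,
        counted=np.array(["derived"] * len(keep), dtype=object),
    )


def polarize_haplotypes(panel: HaplotypePanel) -> HaplotypePanel:
    """Haplotype analogue of :func:`polarize` (0 = ancestral, 1 = derived)."""
    keep: list[int] = []
    flip: list[bool] = []
    for i, v in enumerate(panel.variants):
        if v.ancestral is None:
            continue
        keep.append(i)
        flip.append(panel.counted[i] != "derived" and v.ancestral == v.alt)
    if not keep:
        raise EmptyOutputError("no variants with known ancestral state")
    hap = panel.haplotypes[:, keep].copy()
    flip_arr = np.array(flip)
    hap[:, flip_arr] = 1 - hap[:, flip_arr]
    return HaplotypePanel(
        variants=[panel.variants[i] for i in keep],
        haplotypes=hap,
        sample_of_haplotype=list(panel.sample_of_haplotype),
        counted=np.array(["derived"] * len(keep), dtype=object),
    )


def derived_allele_freq(
    panel: GenotypePanel,
    population: str | Sequence[str],
    popmap: PopulationMap | None = None,
) -> np.ndarray:
    """Per-variant derived allele frequency in one population.

    ``population`` is either a population label (requires ``popmap``) or an
    explicit sequence of sample identifiers.  Variants where every sample is
    missing get NaN.
    """
    if not panel.is_polarized:
        raise PreconditionError("panel must be polarized before computing DAF")
    if isinstance(population, str):
        if popmap is None:
            raise PreconditionError("population label requires a PopulationMap")
        names = popmap.samples_of(population)
    else:
        names = list(population)
    if not names:
        raise PreconditionError("population is empty")
    idx = panel.sample_indices(names)
    return panel.allele_freq(idx)


# ---------------------------------------------------------------------------
# Relatedness and QC
# ---------------------------------------------------------------------------


def estimate_ibd_pihat(
    panel: GenotypePanel,
    sample_pair: tuple[str, str],
    freqs: np.ndarray | None = None,
    min_shared: int = 200,
) -> float:
    """Method-of-moments PI_HAT for one sample pair.

    Uses PLINK-style IBS0/1/2 expectations given counted-allele frequencies
    (estimated from the whole panel when not supplied), solves for the IBD
    state proportions and returns ``P(IBD=1)/2 + P(IBD=2)`` clamped to [0, 1].
    """
    i, j = panel.sample_indices(sample_pair)
    gi = panel.genotypes[:, i].astype(np.int64)
    gj = panel.genotypes[:, j].astype(np.int64)
    ok = (gi != MISSING) & (gj != MISSING)
    p = panel.allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
    ok &= np.isfinite(p) & (p > 0) & (p < 1)
    if ok.sum() < min_shared:
        raise InsufficientDataError(
            f"only {int(ok.sum())} shared informative variants, need >= {min_shared}"
        )
    gi, gj, p = gi[ok], gj[ok], p[ok]
    q = 1.0 - p
    # Opposite homozygotes are the only IBS0 configuration for biallelic SNPs.
    diff = np.abs(gi - gj)
    ibs0_obs = float(np.sum(diff == 2))
    ibs1_obs = float(np.sum(diff == 1))
    ibs2_obs = float(np.sum(diff == 0))
    n = float(len(p))
    # Expected per-state probabilities (Purcell et al. 2007, without
    # finite-sample allele-count corrections).
    e0_z0 = float(np.sum(2 * p**2 * q**2))
    e1_z0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_z0 = n - e0_z0 - e1_z0
    e1_z1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e2_z1 = n - e1_z1
    z0 = ibs0_obs / e0_z0 if e0_z0 > 0 else 0.0
    z1 = (ibs1_obs - z0 * e1_z0) / e1_z1 if e1_z1 > 0 else 0.0
    z2 = (ibs2_obs - z0 * e2_z0 - z1 * e2_z1) / n
    z0, z1, z2 = max(z0, 0.0), max(z1, 0.0), max(z2, 0.0)
    total = z0 + z1 + z2
    if total > 0:
        z0, z1, z2 = z0 / total, z1 / total, z2 / total
    pihat = z1 / 2.0 + z2
    return float(min(max(pihat, 0.0), 1.0))


@dataclass
class QcRemoval:
    kind: str  # "sample" | "variant"
    identifier: str
    reason: str
    value: float


@dataclass
class QcReport:
    removals: list[QcRemoval] = field(default_factory=list)

    def add(self, kind: str, identifier: str, reason: str, value: float) -> None:
        self.removals.append(QcRemoval(kind, identifier, reason, float(value)))

    def __len__(self) -> int:
        return len(self.removals)


def qc_filter(
    panel: GenotypePanel,
    popmap: PopulationMap | None = None,
    sample_missing_max: float = 0.10,
    pihat_max: float = 0.35,
    call_rate_min: float = 0.90,
    ibd_min_shared: int = 200,
) -> tuple[GenotypePanel, QcReport]:
    """Sample/variant QC in fixed order: missingness -> IBD -> call rate.

    Samples with missing rate > ``sample_missing_max`` are removed first;
    then, for every remaining pair with PI_HAT > ``pihat_max``, the member
    with the higher missing rate is removed; finally variants with call
    rate < ``call_rate_min`` are removed.  Every removal is recorded.
    """
    report = QcReport()
    work = panel

    miss = work.sample_missing_rate()
    keep_s = miss <= sample_missing_max
    for j in np.where(~keep_s)[0]:
        report.add("sample", work.samples[j], "missing_rate", miss[j])
    if not keep_s.all():
        work = work.subset(sample_idx=np.where(keep_s)[0])

    # IBD pass: greedy removal, recompute pihat against remaining set only
    # when both members still present.
    if work.n_samples >= 2:
        freqs = work.allele_freq()
        miss = work.sample_missing_rate()
        removed: set[int] = set()
        for a in range(work.n_samples):
            for b in range(a + 1, work.n_samples):
                if a in removed or b in removed:
                    continue
                try:
                    pihat = estimate_ibd_pihat(
                        work,
                        (work.samples[a], work.samples[b]),
                        freqs=freqs,
                        min_shared=ibd_min_shared,
                    )
                except InsufficientDataError:
                    continue
                if pihat > pihat_max:
                    drop = a if miss[a] >= miss[b] else b
                    removed.add(drop)
                    report.add("sample", work.samples[drop], "ibd_pihat", pihat)
        if removed:
            keep_idx = np.array([k for k in range(work.n_samples) if k not in removed])
            work = work.subset(sample_idx=keep_idx)

    cr = work.call_rate()
    keep_v = cr >= call_rate_min
    for i in np.where(~keep_v)[0]:
        v = work.variants[i]
        report.add("variant", f"{v.chrom}:{v.pos}", "call_rate", cr[i])
    if not keep_v.all():
        work = work.subset(variant_idx=np.where(keep_v)[0])

    if work.n_samples == 0 or work.n_variants == 0:
        logger.warning("qc_filter produced an empty panel")
    return work, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _dosage_r2(g: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of dosage rows; missing handled
    by pairwise-complete observations."""
    gf = g.astype(float)
    gf[g == MISSING] = np.nan
    n_var = gf.shape[0]
    out = np.zeros((n_var, n_var))
    if not np.isnan(gf).any():
        sd = gf.std(axis=1)
        ok = sd > 0
        if ok.sum() >= 2:
            c = np.corrcoef(gf[ok])
            sub = np.zeros((n_var, n_var))
            sub[np.ix_(ok, ok)] = c**2
            out = sub
        np.fill_diagonal(out, 1.0)
        return out
    for a in range(n_var):
        for b in range(a + 1, n_var):
            mask = ~np.isnan(gf[a]) & ~np.isnan(gf[b])
            if mask.sum() < 3:
                continue
            xa, xb = gf[a, mask], gf[b, mask]
            if xa.std() == 0 or xb.std() == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            out[a, b] = out[b, a] = r * r
    np.fill_diagonal(out, 1.0)
    return out


def ld_prune(
    panel: GenotypePanel,
    window: int = 50,
    step: int = 10,
    r2_cut: float = 0.1,
) -> np.ndarray:
    """PLINK-style --indep-pairwise pruning; returns retained variant indices.

    Within each sliding window of ``window`` SNPs (advancing by ``step``),
    while any retained pair has dosage r^2 > ``r2_cut``, the member of the
    worst pair with the lower call rate is dropped (ties broken toward the
    later position).  Deterministic for fixed input.
    """
    call = panel.call_rate()
    chroms = panel.chroms
    keep = np.ones(panel.n_variants, dtype=bool)
    for chrom in dict.fromkeys(chroms):
        idx = np.where(chroms == chrom)[0]
        start = 0
        while start < len(idx):
            widx = idx[start : start + window]
            live = widx[keep[widx]]
            if len(live) >= 2:
                r2 = _dosage_r2(panel.genotypes[live])
                np.fill_diagonal(r2, 0.0)
                while True:
                    present = keep[live]
                    if present.sum() < 2:
                        break
                    sub = np.where(present)[0]
                    r2sub = r2[np.ix_(sub, sub)]
                    amax = np.unravel_index(np.argmax(r2sub), r2sub.shape)
                    if r2sub[amax] <= r2_cut:
                        break
                    va, vb = live[sub[amax[0]]], live[sub[amax[1]]]
                    if call[va] < call[vb]:
                        drop = va
                    elif call[vb] < call[va]:
                        drop = vb
                    else:
                        drop = max(va, vb)  # ties -> later position
                    keep[drop] = False
            if start + window >= len(idx):
                break
            start += step
    return np.where(keep)[0]
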
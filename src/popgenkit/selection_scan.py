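"""Haplotype selection statistics, ROH detection and the DAF screen.

EHH is computed by exhaustive haplotype-class counting outward from a core
marker; iHH integrates EHH by trapezoid over genetic distance; iHS is the
log-ratio of ancestral to derived iHH standardized within derived-frequency
bins; XP-EHH is the cross-population analogue standardized genome-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, PreconditionError, UndefinedStatisticError
from .genotype_io import MISSING, GeneticMap, GenotypePanel, HaplotypePanel

logger = logging.getLogger(__name__)

DEFAULT_TRUNC = 0.05
DEFAULT_MAX_GAP = 200_000

NONSYN_LABELS = frozenset(
    {"missense", "missense_variant", "non-synonymous", "nonsynonymous", "non_synonymous"}
)


# ---------------------------------------------------------------------------
# EHH / iHS / XP-EHH
# ---------------------------------------------------------------------------


@dataclass
class EhhCurve:
    core_index: int
    core_allele: int
    n_carriers: int
    # Ordered outward from the core on each flank: (index, pos, cm, ehh).
    left: list[tuple[int, int, float, float]]
    right: list[tuple[int, int, float, float]]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"index": i, "pos": p, "cm": c, "ehh": e, "flank": "left"}
            for i, p, c, e in reversed(self.left)
        ]
        rows += [
            {"index": i, "pos": p, "cm": c, "ehh": e, "flank": "right"}
            for i, p, c, e in self.right
        ]
        return pd.DataFrame(rows)


def _walk_ehh(
    hap: np.ndarray,
    carriers: np.ndarray,
    core: int,
    direction: int,
    positions: np.ndarray,
    cm: np.ndarray,
    trunc: float,
    max_gap: float,
) -> list[tuple[int, int, float, float]]:
    """One flank of an EHH curve.  Stops after the first marker whose EHH
    drops below ``trunc`` (that marker is included) or before a physical gap
    larger than ``max_gap``."""
    n = len(carriers)
    pair_total = n * (n - 1) / 2.0
    labels = np.zeros(n, dtype=np.int64)
    out: list[tuple[int, int, float, float]] = []
    idx = core + direction
    prev_pos = positions[core]
    while 0 <= idx < hap.shape[1]:
        if abs(int(positions[idx]) - int(prev_pos)) > max_gap:
            break
        col = hap[carriers, idx]
        # refine haplotype classes with this marker
        combo = labels * 2 + col
        _, labels = np.unique(combo, return_inverse=True)
        counts = np.bincount(labels)
        ehh = float((counts * (counts - 1) / 2.0).sum() / pair_total)
        out.append((int(idx), int(positions[idx]), float(cm[idx]), ehh))
        if ehh < trunc:
            break
        prev_pos = positions[idx]
        idx += direction
    return out


def ehh(
    hap: HaplotypePanel,
    core_index: int,
    core_allele: int,
    gmap: GeneticMap | None = None,
    trunc: float = DEFAULT_TRUNC,
    max_gap: float = DEFAULT_MAX_GAP,
) -> EhhCurve:
    """Extended haplotype homozygosity around one core allele.

    At marker x, EHH(x) = sum over core-to-x haplotype classes h of
    C(k_h, 2) / C(n, 2), where n is the carrier count of the core allele.
    EHH = 1 at the core by construction.
    """
    carriers = np.where(hap.haplotypes[:, core_index] == core_allele)[0]
    if len(carriers) < 2:
        raise UndefinedStatisticError(
            f"core allele {core_allele} at index {core_index} has "
            f"{len(carriers)} carriers; EHH needs >= 2"
        )
    positions = hap.positions
    chrom = hap.variants[core_index].chrom
    cm = (
        np.asarray(gmap.cm(chrom, positions), dtype=float)
        if gmap is not None
        else positions / 1e6
    )
    left = _walk_ehh(hap.haplotypes, carriers, core_index, -1, positions, cm, trunc, max_gap)
    right = _walk_ehh(hap.haplotypes, carriers, core_index, +1, positions, cm, trunc, max_gap)
    return EhhCurve(
        core_index=core_index,
        core_allele=core_allele,
        n_carriers=len(carriers),
        left=left,
        right=right,
    )


def _ihh_from_flank(
    core_cm: float, flank: list[tuple[int, int, float, float]], trunc: float
) -> float:
    """Trapezoid integral of one EHH flank over genetic distance (Morgans
    are not needed; cM keep the scale consistent across alleles)."""
    ihh = 0.0
    prev_cm, prev_ehh = core_cm, 1.0
    for _, _, cmx, ehh_x in flank:
        ihh += 0.5 * (prev_ehh + ehh_x) * abs(cmx - prev_cm)
        prev_cm, prev_ehh = cmx, ehh_x
        if ehh_x < trunc:
            break
    return ihh


def integrated_ehh(curve: EhhCurve, core_cm: float, trunc: float = DEFAULT_TRUNC) -> float:
    """iHH: trapezoid integral of the EHH curve over both flanks (cM units)."""
    return _ihh_from_flank(core_cm, curve.left, trunc) + _ihh_from_flank(
        core_cm, curve.right, trunc
    )


@dataclass
class IhsResult:
    table: pd.DataFrame
    bins: np.ndarray


def _standardize_in_bins(
    values: np.ndarray, freqs: np.ndarray, bin_width: float, min_per_bin: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean/unit-sd standardization within frequency bins; sparse bins
    are merged with their neighbours until each stratum has enough scores."""
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    which = np.clip(np.digitize(freqs, edges) - 1, 0, len(edges) - 2)
    finite = np.isfinite(values)
    # merge sparse bins left-to-right
    strata = np.zeros(len(edges) - 1, dtype=int)
    stratum, count = 0, 0
    for b in range(len(edges) - 1):
        strata[b] = stratum
        count += int(np.sum(finite & (which == b)))
        if count >= min_per_bin:
            stratum += 1
            count = 0
    if count and stratum > 0:  # fold trailing sparse stratum into the previous
        strata[strata == stratum] = stratum - 1
    stratum_of = strata[which]
    out = np.full_like(values, np.nan, dtype=float)
    for s in np.unique(stratum_of):
        sel = finite & (stratum_of == s)
        if sel.sum() < 2:
            continue
        mu, sd = values[sel].mean(), values[sel].std()
        if sd > 0:
            out[sel] = (values[sel] - mu) / sd
    return out, stratum_of.astype(float)


def ihs_scan(
    hap: HaplotypePanel,
    gmap: GeneticMap | None = None,
    maf_min: float = 0.05,
    trunc: float = DEFAULT_TRUNC,
    bin_width: float = 0.02,
    max_gap: float = DEFAULT_MAX_GAP,
    min_per_bin: int = 10,
) -> IhsResult:
    """Per-variant iHS over a polarized haplotype panel.

    uiHS = ln(iHH_ancestral / iHH_derived), standardized within
    derived-allele-frequency bins of ``bin_width``.  Variants with either
    iHH = 0 or DAF outside [maf_min, 1 - maf_min] are left unscored.
    """
    daf = hap.derived_freq()
    positions = hap.positions
    rows = []
    for i in range(hap.n_variants):
        if not (maf_min <= daf[i] <= 1.0 - maf_min):
            continue
        chrom = hap.variants[i].chrom
        cm_core = (
            float(gmap.cm(chrom, positions[i])) if gmap is not None else positions[i] / 1e6
        )
        uihs = np.nan
        ihh_a = ihh_d = np.nan
        try:
            curve_a = ehh(hap, i, 0, gmap=gmap, trunc=trunc, max_gap=max_gap)
            curve_d = ehh(hap, i, 1, gmap=gmap, trunc=trunc, max_gap=max_gap)
            ihh_a = integrated_ehh(curve_a, cm_core, trunc)
            ihh_d = integrated_ehh(curve_d, cm_core, trunc)
            if ihh_a > 0 and ihh_d > 0:
                uihs = float(np.log(ihh_a / ihh_d))
        except UndefinedStatisticError:
            pass
        rows.append(
            {
                "chrom": chrom,
                "pos": int(positions[i]),
                "variant_index": i,
                "daf": float(daf[i]),
                "ihh_a": ihh_a,
                "ihh_d": ihh_d,
                "uihs": uihs,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return IhsResult(table=table, bins=np.empty(0))
    std, stratum = _standardize_in_bins(
        table["uihs"].to_numpy(), table["daf"].to_numpy(), bin_width, min_per_bin
    )
    table["ihs"] = std
    table["daf_bin"] = stratum
    return IhsResult(table=table, bins=np.unique(stratum[np.isfinite(stratum)]))


def _pooled_ihh(
    hap: HaplotypePanel,
    core_index: int,
    gmap: GeneticMap | None,
    trunc: float,
    max_gap: float,
) -> float:
    """iHH around a core over all haplotypes of a panel (both alleles pooled)."""
    positions = hap.positions
    chrom = hap.variants[core_index].chrom
    cm = (
        np.asarray(gmap.cm(chrom, positions), dtype=float)
        if gmap is not None
        else positions / 1e6
    )
    carriers = np.arange(hap.n_haplotypes)
    # Classes are defined by alleles strictly outward of the core; the curve
    # is anchored at 1 at the core for both populations, so the convention
    # cancels in the cross-population log-ratio.
    left = _walk_ehh(hap.haplotypes, carriers, core_index, -1, positions, cm, trunc, max_gap)
    right = _walk_ehh(hap.haplotypes, carriers, core_index, +1, positions, cm, trunc, max_gap)
    core_cm = float(cm[core_index])
    return _ihh_from_flank(core_cm, left, trunc) + _ihh_from_flank(core_cm, right, trunc)


def xpehh_scan(
    hap_a: HaplotypePanel,
    hap_b: HaplotypePanel,
    gmap: GeneticMap | None = None,
    trunc: float = DEFAULT_TRUNC,
    max_gap: float = DEFAULT_MAX_GAP,
) -> pd.DataFrame:
    """Cross-population EHH scan: ln(iHH_A / iHH_B), standardized genome-wide.

    Positive standardized scores mean longer haplotypes (stronger sweep
    signal) in population A.  Both panels must share the variant grid.
    """
    if hap_a.n_variants != hap_b.n_variants or any(
        (va.chrom, va.pos) != (vb.chrom, vb.pos)
        for va, vb in zip(hap_a.variants, hap_b.variants)
    ):
        raise PreconditionError("panels must share an identical variant grid")
    positions = hap_a.positions
    rows = []
    for i in range(hap_a.n_variants):
        ihh_a = _pooled_ihh(hap_a, i, gmap, trunc, max_gap)
        ihh_b = _pooled_ihh(hap_b, i, gmap, trunc, max_gap)
        score = np.nan
        if ihh_a > 0 and ihh_b > 0:
            score = float(np.log(ihh_a / ihh_b))
        rows.append(
            {
                "chrom": hap_a.variants[i].chrom,
                "pos": int(positions[i]),
                "variant_index": i,
                "ihh_a": ihh_a,
                "ihh_b": ihh_b,
                "xpehh_raw": score,
            }
        )
    table = pd.DataFrame(rows)
    raw = table["xpehh_raw"].to_numpy()
    finite = np.isfinite(raw)
    std = np.full_like(raw, np.nan)
    if finite.sum() >= 2 and raw[finite].std() > 0:
        std[finite] = (raw[finite] - raw[finite].mean()) / raw[finite].std()
    table["xpehh"] = std
    return table


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------


@dataclass
class RohSegment:
    sample: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def roh_detect(
    panel: GenotypePanel,
    window: int = 50,
    het_allowed: int = 1,
    min_snps: int = 50,
    min_kb: float = 500.0,
) -> list[RohSegment]:
    """Sliding-window run-of-homozygosity calling (PLINK-flavoured).

    A SNP is ROH-eligible for a sample when some overlapping ``window``-SNP
    window contains at most ``het_allowed`` heterozygous calls.  Maximal
    eligible runs are split so no segment carries more than ``het_allowed``
    heterozygotes, then filtered by ``min_snps`` and ``min_kb``.
    """
    segments: list[RohSegment] = []
    chroms = panel.chroms
    positions = panel.positions
    for chrom in dict.fromkeys(chroms):
        vidx = np.where(chroms == chrom)[0]
        pos = positions[vidx]
        g = panel.genotypes[vidx]
        n_var = len(vidx)
        w = min(window, n_var)
        for j, sample in enumerate(panel.samples):
            col = g[:, j]
            het = (col == 1).astype(np.int32)
            # rolling het count over every length-w window
            cs = np.concatenate([[0], np.cumsum(het)])
            wcount = cs[w:] - cs[:-w]  # window starting at each index
            ok_window = wcount <= het_allowed
            eligible = np.zeros(n_var, dtype=bool)
            for s in np.where(ok_window)[0]:
                eligible[s : s + w] = True
            # split eligible runs so each segment has <= het_allowed hets
            i = 0
            while i < n_var:
                if not eligible[i]:
                    i += 1
                    continue
                j2 = i
                hets_seen = 0
                seg_start = i
                while j2 < n_var and eligible[j2]:
                    if het[j2]:
                        if hets_seen + 1 > het_allowed:
                            _maybe_add(
                                segments, sample, chrom, pos, seg_start, j2 - 1, min_snps, min_kb
                            )
                            seg_start = j2 + 1
                            hets_seen = 0
                        else:
                            hets_seen += 1
                    j2 += 1
                if seg_start <= j2 - 1:
                    _maybe_add(segments, sample, chrom, pos, seg_start, j2 - 1, min_snps, min_kb)
                i = j2 + 1
    return segments


def _maybe_add(segments, sample, chrom, pos, a, b, min_snps, min_kb):
    if b < a:
        return
    n = b - a + 1
    start, end = int(pos[a]), int(pos[b])
    if n >= min_snps and (end - start + 1) >= min_kb * 1000:
        segments.append(RohSegment(sample=sample, chrom=chrom, start=start, end=end, n_snps=n))


def roh_total_lengths(segments: list[RohSegment], samples: list[str]) -> pd.Series:
    """Total ROH length (bp) per sample, zero-filled."""
    totals = pd.Series(0.0, index=list(samples))
    for seg in segments:
        if seg.sample in totals.index:
            totals[seg.sample] += seg.length_bp
    return totals


def roh_compare(
    totals_a: pd.Series | np.ndarray, totals_b: pd.Series | np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on per-sample total ROH lengths."""
    a = np.asarray(totals_a, dtype=float)
    b = np.asarray(totals_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise PreconditionError("each population needs >= 3 samples for the comparison")
    stat, p = stats.ranksums(a, b)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Candidate screen and panel AF consistency
# ---------------------------------------------------------------------------

REQUIRED_SCREEN_COLUMNS = ("daf_shp_seq", "daf_tbn_seq", "daf_han_seq", "consequence")


def daf_screen(
    candidate_table: pd.DataFrame,
    daf_hi: float = 0.3,
    daf_lo: float = 0.05,
    nonsyn_labels: frozenset[str] = NONSYN_LABELS,
) -> pd.DataFrame:
    """Screen for non-synonymous variants with population-restricted high DAF.

    Retains rows with a non-synonymous consequence, focal-population
    sequence DAF >= ``daf_hi`` and reference-population sequence DAFs
    <= ``daf_lo``; output sorted by focal DAF descending.  Thresholds are
    explicit assumptions, echoed in the output attrs.
    """
    for col in REQUIRED_SCREEN_COLUMNS:
        if col not in candidate_table.columns:
            raise FormatError(f"candidate table lacks required column {col!r}")
    cons = candidate_table["consequence"].astype(str).str.lower()
    keep = (
        cons.isin(nonsyn_labels)
        & (candidate_table["daf_shp_seq"].astype(float) >= daf_hi)
        & (candidate_table["daf_tbn_seq"].astype(float) <= daf_lo)
        & (candidate_table["daf_han_seq"].astype(float) <= daf_lo)
    )
    out = (
        candidate_table[keep]
        .sort_values("daf_shp_seq", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    out.attrs["thresholds"] = {"daf_hi": daf_hi, "daf_lo": daf_lo}
    return out


def panel_af_correlation(
    daf_seq: np.ndarray, daf_target: np.ndarray
) -> tuple[float, float, float]:
    """OLS slope, Pearson r and two-sided p for sequence vs target-panel AFs."""
    x = np.asarray(daf_seq, dtype=float)
    y = np.asarray(daf_target, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise PreconditionError("need paired vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("zero variance in one of the AF vectors")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue), float(res.pvalue)
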
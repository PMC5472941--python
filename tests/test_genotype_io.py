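import numpy as np
import pytest

from popgenkit import genotype_io as gio
from popgenkit.errors import (
    DomainError,
    EmptyInputError,
    EmptyOutputError,
    FormatError,
    InsufficientDataError,
    PreconditionError,
)
from popgenkit.genotype_io import (
    MISSING,
    GenotypePanel,
    PopulationMap,
    Variant,
    derived_allele_freq,
    estimate_ibd_pihat,
    ld_prune,
    polarize,
    qc_filter,
    read_plink_text,
    read_vcf,
)

from conftest import make_panel


VCF_BODY = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2
1\t100\trs1\tA\tG\t.\t.\tAA=A\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tA\tG\t.\t.\tAA=G\tGT\t0/0\t0/0\t1/1
1\t300\trs3\tC\tT\t.\t.\t.\tGT\t./.\t0/1\t0/0
1\t400\trs4\tC\tCT\t.\t.\t.\tGT\t0/0\t0/0\t0/0
"""


class TestReadVcf:
    def test_direct_encoding(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(VCF_BODY)
        panel, hap = read_vcf(str(p))
        assert panel.n_variants == 3  # indel skipped
        assert list(panel.genotypes[0]) == [0, 1, 2]
        assert hap is None  # unphased

    def test_ancestral_field_copy(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(VCF_BODY)
        panel, _ = read_vcf(str(p))
        assert panel.variants[0].ancestral == "A"
        assert panel.variants[1].ancestral == "G"
        assert panel.variants[2].ancestral is None

    def test_missing_code(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(VCF_BODY)
        panel, _ = read_vcf(str(p))
        assert panel.genotypes[2, 0] == MISSING

    def test_phased_gives_haplotypes(self, tmp_path):
        body = VCF_BODY.replace("0/", "0|").replace("1/1", "1|1").replace(".|.", "./.")
        body = "\n".join(l for l in body.splitlines() if "./." not in l and "\t400\t" not in l)
        p = tmp_path / "ph.vcf"
        p.write_text(body + "\n")
        panel, hap = read_vcf(str(p))
        assert hap is not None
        assert hap.n_haplotypes == 2 * panel.n_samples
        assert list(hap.haplotypes[:, 0]) == [0, 0, 0, 1, 1, 1]

    def test_malformed_header(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("not a vcf at all\n")
        with pytest.raises((FormatError, EmptyInputError)):
            read_vcf(str(p))

    def test_no_biallelic_snps(self, tmp_path):
        lines = VCF_BODY.splitlines()
        p = tmp_path / "empty.vcf"
        p.write_text("\n".join(lines[:5] + [lines[-1]]) + "\n")
        with pytest.raises(EmptyInputError):
            read_vcf(str(p))


class TestReadPlinkText:
    def _write(self, tmp_path, ped, mp):
        pp, mpp = tmp_path / "x.ped", tmp_path / "x.map"
        pp.write_text(ped)
        mpp.write_text(mp)
        return str(pp), str(mpp)

    def test_minor_allele_counting(self, tmp_path):
        ped = "f1 i1 0 0 1 -9 A G\nf2 i2 0 0 1 -9 A A\nf3 i3 0 0 1 -9 A A\n"
        mp = "1 snp1 0 500\n"
        panel = read_plink_text(*self._write(tmp_path, ped, mp))
        # G is minor -> counted; i1 carries one copy
        assert panel.genotypes[0, 0] == 1
        assert panel.counted[0] == "minor"

    def test_missing_genotype(self, tmp_path):
        ped = "f1 i1 0 0 1 -9 0 0\nf2 i2 0 0 1 -9 A G\n"
        mp = "1 snp1 0 500\n"
        panel = read_plink_text(*self._write(tmp_path, ped, mp))
        assert panel.genotypes[0, 0] == MISSING

    def test_length_mismatch(self, tmp_path):
        ped = "f1 i1 0 0 1 -9 A G C C\n"
        mp = "1 snp1 0 500\n1 snp2 0 600\n1 snp3 0 700\n"
        with pytest.raises(FormatError):
            read_plink_text(*self._write(tmp_path, ped, mp))


class TestPolarize:
    def test_ancestral_ref_unchanged(self):
        panel = make_panel([[0, 1, 2]])
        out = polarize(panel)
        assert list(out.genotypes[0]) == [0, 1, 2]
        assert out.counted[0] == "derived"

    def test_ancestral_alt_flipped(self):
        panel = make_panel([[0, 1, 2]])
        panel.variants[0] = Variant("1", 10_000, None, "A", "G", "G")
        out = polarize(panel)
        assert list(out.genotypes[0]) == [2, 1, 0]

    def test_unknown_dropped(self):
        panel = make_panel([[0, 1, 2], [2, 0, 0]])
        panel.variants[1] = Variant("1", 20_000, None, "A", "G", None)
        out = polarize(panel)
        assert out.n_variants == 1

    def test_all_unknown_raises(self):
        panel = make_panel([[0, 1, 2]], ancestral_ref=False)
        with pytest.raises(EmptyOutputError):
            polarize(panel)

    def test_flip_involution(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = MISSING
        panel = make_panel(g)
        for i in range(0, 30, 2):
            panel.variants[i] = Variant("1", (i + 1) * 10_000, None, "A", "G", "G")
        once = polarize(panel)
        # flipping the flip set again restores original codes
        twice_g = once.genotypes.copy()
        for i, v in enumerate(once.variants):
            if v.ancestral == v.alt:
                mask = twice_g[i] != MISSING
                twice_g[i, mask] = 2 - twice_g[i, mask]
        np.testing.assert_array_equal(twice_g, panel.genotypes)

    def test_missing_preserved(self):
        panel = make_panel([[MISSING, 1, 2]])
        panel.variants[0] = Variant("1", 10_000, None, "A", "G", "G")
        out = polarize(panel)
        assert out.genotypes[0, 0] == MISSING


class TestDerivedAlleleFreq:
    def test_table_daf_example(self):
        # 5 diploid samples carrying 5 derived copies in total -> DAF 0.5
        panel = polarize(make_panel([[2, 1, 1, 1, 0]]))
        daf = derived_allele_freq(panel, ["s0", "s1", "s2", "s3", "s4"])
        assert daf[0] == pytest.approx(0.5)

    def test_monomorphic_zero(self):
        panel = polarize(make_panel([[0, 0, 0]]))
        assert derived_allele_freq(panel, ["s0", "s1", "s2"])[0] == 0.0

    def test_missing_excluded(self):
        panel = polarize(make_panel([[2, MISSING, 0]]))
        assert derived_allele_freq(panel, ["s0", "s1", "s2"])[0] == pytest.approx(0.5)

    def test_unknown_population(self, popmap_two):
        panel = polarize(make_panel([[0, 1, 2]]))
        with pytest.raises(KeyError):
            derived_allele_freq(panel, "nope", popmap_two)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(50, 10)).astype(np.int8)
        panel = polarize(make_panel(g))
        daf = derived_allele_freq(panel, panel.samples)
        flipped = GenotypePanel(
            variants=panel.variants,
            samples=panel.samples,
            genotypes=(2 - panel.genotypes).astype(np.int8),
            counted=panel.counted,
        )
        daf_flip = flipped.allele_freq()
        np.testing.assert_allclose(daf, 1 - daf_flip)
        assert np.all((daf >= 0) & (daf <= 1))


class TestIbdPihat:
    @staticmethod
    def _freq_panel(n_loci, n_samples, seed, extra_cols=None):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.1, 0.9, n_loci)
        g = rng.binomial(2, p[:, None], size=(n_loci, n_samples)).astype(np.int8)
        if extra_cols is not None:
            g = np.hstack([g, extra_cols])
        return make_panel(g), p, rng

    def test_duplicate_sample(self):
        panel, _, _ = self._freq_panel(2000, 10, 0)
        dup = panel.genotypes[:, [0]]
        panel2 = make_panel(np.hstack([panel.genotypes, dup]))
        pihat = estimate_ibd_pihat(panel2, ("s0", "s10"))
        assert pihat >= 0.95

    def test_unrelated_pair(self):
        panel, _, _ = self._freq_panel(10_000, 20, 42)
        pihat = estimate_ibd_pihat(panel, ("s0", "s1"))
        assert pihat < 0.05

    def test_parent_offspring(self):
        rng = np.random.default_rng(7)
        n_loci = 10_000
        p = rng.uniform(0.1, 0.9, n_loci)
        pool = rng.binomial(1, p[:, None], size=(n_loci, 40))  # haplotype pool
        parent = pool[:, 0] + pool[:, 1]
        transmitted = np.where(rng.random(n_loci) < 0.5, pool[:, 0], pool[:, 1])
        child = transmitted + rng.binomial(1, p)
        others = pool[:, 2::2] + pool[:, 3::2]
        g = np.column_stack([parent, child, others]).astype(np.int8)
        panel = make_panel(g)
        pihat = estimate_ibd_pihat(panel, ("s0", "s1"))
        assert pihat == pytest.approx(0.5, abs=0.05)

    def test_too_few_variants(self):
        panel, _, _ = self._freq_panel(100, 4, 3)
        with pytest.raises(InsufficientDataError):
            estimate_ibd_pihat(panel, ("s0", "s1"), min_shared=200)


class TestQcFilter:
    def test_high_missing_sample_removed(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(100, 4)).astype(np.int8)
        g[:15, 0] = MISSING  # 15% missing
        panel = make_panel(g)
        out, report = qc_filter(panel, ibd_min_shared=1000)
        assert "s0" not in out.samples
        assert any(r.identifier == "s0" and r.reason == "missing_rate" for r in report.removals)

    def test_low_call_rate_variant_removed(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(50, 20)).astype(np.int8)
        g[2, :3] = MISSING  # 85% call rate; sample missingness only 2%
        panel = make_panel(g)
        out, report = qc_filter(panel, ibd_min_shared=1000)
        assert out.n_variants == 49
        assert any(r.kind == "variant" and r.reason == "call_rate" for r in report.removals)

    def test_clean_panel_unchanged(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(50, 6)).astype(np.int8)
        panel = make_panel(g)
        out, report = qc_filter(panel, ibd_min_shared=1000)
        assert len(report) == 0
        np.testing.assert_array_equal(out.genotypes, panel.genotypes)

    def test_ibd_pair_drops_higher_missing_member(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.2, 0.8, 2000)
        g = rng.binomial(2, p[:, None], size=(2000, 6)).astype(np.int8)
        g[:, 1] = g[:, 0]  # duplicate pair s0/s1
        g[:40, 1] = MISSING  # s1 has more missingness (but < 10%)
        panel = make_panel(g)
        out, report = qc_filter(panel)
        assert "s1" not in out.samples and "s0" in out.samples
        assert any(r.reason == "ibd_pihat" for r in report.removals)

    def test_rerun_is_noop(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=(300, 8)).astype(np.int8)
        g[:50, 0] = MISSING
        g[5, 1:] = MISSING
        panel = make_panel(g)
        once, _ = qc_filter(panel, ibd_min_shared=100)
        twice, report = qc_filter(once, ibd_min_shared=100)
        assert len(report) == 0
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)


class TestLdPrune:
    def test_identical_columns_one_retained(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=(1, 30)).astype(np.int8)
        g = np.vstack([base, base, rng.integers(0, 3, size=(3, 30)).astype(np.int8)])
        panel = make_panel(g)
        kept = ld_prune(panel)
        assert (0 in kept) != (1 in kept)

    def test_independent_loci_mostly_retained(self):
        # n = 200 samples keeps null r^2 well below the 0.1 cutoff
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.9, 500)
        g = rng.binomial(2, p[:, None], size=(500, 200)).astype(np.int8)
        panel = make_panel(g)
        kept = ld_prune(panel)
        assert len(kept) >= 0.95 * 500

    def test_determinism(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, size=(120, 25)).astype(np.int8)
        panel = make_panel(g)
        np.testing.assert_array_equal(ld_prune(panel), ld_prune(panel))

    def test_no_pair_exceeds_cut(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.2, 0.8, 60)
        g = rng.binomial(2, p[:, None], size=(60, 40)).astype(np.int8)
        # inject correlated duplicates
        g[10] = g[9]
        g[33] = np.clip(g[32] + rng.integers(0, 2, 40), 0, 2)
        panel = make_panel(g)
        kept = ld_prune(panel, window=60, r2_cut=0.1)
        sub = panel.genotypes[kept].astype(float)
        r2 = np.corrcoef(sub) ** 2
        np.fill_diagonal(r2, 0.0)
        assert np.nanmax(r2) <= 0.1 + 1e-9


class TestVariantInvariants:
    def test_ref_alt_distinct(self):
        with pytest.raises(DomainError):
            Variant("1", 5, None, "A", "A")

    def test_ancestral_must_match(self):
        with pytest.raises(DomainError):
            Variant("1", 5, None, "A", "G", "C")

    def test_position_positive(self):
        with pytest.raises(DomainError):
            Variant("1", 0, None, "A", "G")


class TestPopulationMap:
    def test_groups_partition(self, popmap_two):
        assert popmap_two.populations == ["popA", "popB"]
        assert popmap_two.groups == ["G1", "G2"]
        assert popmap_two.samples_of("popA") == ["s0", "s1"]

    def test_roundtrip_tsv(self, tmp_path):
        p = tmp_path / "pm.tsv"
        p.write_text("sample_id\tpopulation\tgroup\na\tP1\tG\nb\tP2\tG\n")
        pm = gio.read_population_map(str(p))
        assert pm.sample_to_pop == {"a": "P1", "b": "P2"}
        assert pm.pop_to_group["P1"] == "G"

    def test_duplicate_sample_rejected(self, tmp_path):
        p = tmp_path / "pm.tsv"
        p.write_text("a\tP1\na\tP2\n")
        with pytest.raises(FormatError):
            gio.read_population_map(str(p))


class TestGeneticMap:
    def test_interpolation(self):
        gmap = gio.GeneticMap({"1": (np.array([0.0, 1e6]), np.array([0.0, 1.0]))})
        assert gmap.cm("1", 5e5) == pytest.approx(0.5)

    def test_non_monotone_rejected(self):
        with pytest.raises(FormatError):
            gio.GeneticMap({"1": (np.array([0.0, 1e6]), np.array([1.0, 0.0]))})

    def test_read_tsv(self, tmp_path):
        p = tmp_path / "gm.tsv"
        p.write_text("chrom\tpos\tcM\n1\t1\t0.0\n1\t1000000\t1.0\n")
        gmap = gio.read_genetic_map(str(p))
        assert gmap.cm("1", 500000) == pytest.approx(0.5, abs=1e-5)
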
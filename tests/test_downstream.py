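"""Enrichment, rate profiles, spectra, PCA, SCNA coupling, VAFs, expression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutrec.downstream import (
    SegmentRecord,
    breakpoint_density_rate,
    breakpoint_distance_test,
    cbs_rate_profile,
    expression_association,
    lod_enrichment,
    motif_gain_loss,
    motif_spectrum,
    pca_feature_contributions,
    scna_breakpoints,
    signature_cbs_correlation,
    vaf_compare,
    window_rate_matrix,
)
from mutrec.genome import GenomeSequence, build_masked_genome, revcomp
from mutrec.intervals import IntervalSet
from mutrec.motifs import CbsSite, MotifHit
from mutrec.recurrence import UniformRateModel
from mutrec.variants import MutationRecord


def snv(sample, chrom, pos, ref="A", alt="C", vaf=None):
    return MutationRecord(sample, chrom, pos, ref, alt, vaf=vaf)


class TestLodEnrichment:
    def test_no_enrichment_gives_zero(self):
        r = lod_enrichment(25, 100, 250, 1000)
        assert r.lod == pytest.approx(0.0)

    def test_two_fold_enrichment_is_ln3(self):
        # p1=0.5, p2=0.25: odds 1 vs 1/3
        r = lod_enrichment(50, 100, 250, 1000)
        assert r.lod == pytest.approx(np.log(3), rel=1e-9)
        assert r.z > 0 and r.p_value < 0.05

    def test_depletion_has_negative_sign(self):
        # the TFBS pattern: ~1% of the genome but only 0.58% of mutations
        r = lod_enrichment(58, 10_000, 10_000, 1_000_000)
        assert r.lod < 0 and r.p1 == pytest.approx(0.0058)

    def test_antisymmetry(self):
        a = lod_enrichment(30, 100, 100, 1000)
        b = lod_enrichment(10, 100, 300, 1000)
        assert a.lod == pytest.approx(-b.lod, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            lod_enrichment(5, 10, 1000, 1000)
        with pytest.raises(ValueError):
            lod_enrichment(5, 0, 10, 1000)


class TestCbsRateProfile:
    def make_sites(self, n=100, motif=20, spacing=20_000):
        return [
            CbsSite("chr1", i * spacing, i * spacing + motif, "+", 10.0, False, True)
            for i in range(1, n + 1)
        ]

    def test_rate_arithmetic(self):
        # 22 mutations in 2 Mb of CBS bp from one tumor -> 11 per Mb
        sites = self.make_sites(n=100, motif=20_000, spacing=40_000)  # 2 Mb total CBS
        muts = [snv("s1", "chr1", 40_000 + i) for i in range(22)]
        df = cbs_rate_profile(muts, sites, {"chr1": 100_000_000}, ["s1"], flank_bp=100)
        assert df.cbs_rate_per_mb[0] == pytest.approx(11.0)

    def test_flanks_exclude_cbs_bases_and_fold(self):
        sites = self.make_sites()
        lengths = {"chr1": 10_000_000}
        muts = [snv("s1", "chr1", 20_000 + 5), snv("s1", "chr1", 20_000 + 500)]
        df = cbs_rate_profile(muts, sites, lengths, ["s1"], flank_bp=1000)
        assert df.cbs_bp[0] == 100 * 20
        assert df.flank_bp[0] == 100 * 2000
        assert df.fold[0] == pytest.approx(
            (1 / df.cbs_bp[0]) / (1 / df.flank_bp[0])
        )

    def test_zero_flank_mutations_warns_inf(self):
        sites = self.make_sites(n=5)
        muts = [snv("s1", "chr1", 20_000 + 1)]
        with pytest.warns(UserWarning, match="infinite"):
            df = cbs_rate_profile(muts, sites, {"chr1": 10_000_000}, ["s1"])
        assert np.isinf(df.fold[0])

    def test_grouping_by_subtype(self):
        sites = self.make_sites(n=10)
        groups = {"s1": "CIN", "s2": "GS"}
        muts = [snv("s1", "chr1", 20_005), snv("s2", "chr1", 40_005)]
        df = cbs_rate_profile(muts, sites, {"chr1": 10_000_000}, ["s1", "s2"], group_by=groups)
        assert set(df.group) == {"CIN", "GS"}
        assert (df.n_samples == 1).all()

    def test_empty_cbs_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cbs_rate_profile([], [], {"chr1": 100}, ["s1"])

    def test_position_profile_orients_to_motif_strand(self):
        from mutrec.downstream import cbs_position_profile

        sites = [
            CbsSite("chr1", 10_000, 10_020, "+", 10.0, False, True),
            CbsSite("chr1", 50_000, 50_020, "-", 10.0, False, True),
        ]
        muts = [snv("s", "chr1", 10_013), snv("s", "chr1", 50_007)]
        prof = cbs_position_profile(muts, sites, halfwidth=100)
        assert prof[3] == 2  # +3 from both midpoints after strand flip
        assert prof.sum() == 2


class TestMotifSpectrum:
    def hits(self):
        return [
            MotifHit("chr1", 100, 119, "+", 10.0, 1e-4),
            MotifHit("chr1", 200, 219, "-", 10.0, 1e-4),
        ]

    def test_plus_strand_identity_mapping(self):
        mat = motif_spectrum([snv("s", "chr1", 103, "A", "C")], self.hits())
        assert mat.loc[3, "A>C"] == 1 and mat.to_numpy().sum() == 1

    def test_minus_strand_mirrors_and_complements(self):
        # genomic A>C at offset 3 of a minus-strand 19-mer -> T>G at 15
        mat = motif_spectrum([snv("s", "chr1", 203, "A", "C")], self.hits())
        assert mat.loc[15, "T>G"] == 1

    def test_flank_positions_covered(self):
        mat = motif_spectrum([snv("s", "chr1", 96, "G", "T")], self.hits(), flank=5)
        assert mat.loc[-4, "G>T"] == 1

    def test_out_of_range_ignored_and_columns_conserve(self):
        muts = [snv("s", "chr1", 103, "A", "G"), snv("s", "chr1", 500, "A", "G")]
        mat = motif_spectrum(muts, self.hits())
        assert mat.to_numpy().sum() == 1

    def test_reverse_complement_invariance(self):
        """Flipping the genome and strands reproduces the identical matrix."""
        L = 10_000
        muts = [snv("s", "chr1", 103, "A", "C"), snv("s", "chr1", 210, "C", "T")]
        mat = motif_spectrum(muts, self.hits())
        flipped_hits = [
            MotifHit("chr1", L - h.end, L - h.start, {"+": "-", "-": "+"}[h.strand], h.score, h.p_value)
            for h in self.hits()
        ]
        flipped_muts = [
            MutationRecord(m.sample_id, "chr1", L - 1 - m.pos, revcomp(m.ref), revcomp(m.alt))
            for m in muts
        ]
        mat2 = motif_spectrum(flipped_muts, flipped_hits)
        pd.testing.assert_frame_equal(mat, mat2)


class TestPca:
    def test_identical_profile_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        prof = rng.random(50)
        rates = pd.DataFrame({"t1": prof, "t2": rng.random(50)})
        feats = pd.DataFrame({"f1": prof, "f2": rng.random(50)})
        out = pca_feature_contributions(rates, feats)
        assert out.correlations.loc["t1", "f1"] == pytest.approx(1.0)

    def test_orthogonal_groups_and_contribution_normalization(self):
        rng = np.random.default_rng(1)
        base1, base2 = rng.random(80), rng.random(80)
        rates = pd.DataFrame(
            {f"tA{i}": base1 + 0.05 * rng.random(80) for i in range(4)}
            | {f"tB{i}": base2 + 0.05 * rng.random(80) for i in range(4)}
        )
        feats = pd.DataFrame(
            {f"fA{i}": base1 + 0.05 * rng.random(80) for i in range(3)}
            | {f"fB{i}": base2 + 0.05 * rng.random(80) for i in range(3)}
        )
        out = pca_feature_contributions(rates, feats, n_components=2)
        sums = out.contributions.sum(axis=0)
        ok = ~out.contributions.isna().all(axis=0)
        assert np.allclose(sums[ok], 1.0)
        # the two feature groups separate on the leading component
        pc1 = out.loadings["PC1"]
        ga = pc1[[c for c in pc1.index if c.startswith("fA")]].to_numpy()
        gb = pc1[[c for c in pc1.index if c.startswith("fB")]].to_numpy()
        assert abs(ga.mean() - gb.mean()) > 0.3

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        rates = pd.DataFrame({"t1": rng.random(30), "t2": rng.random(30)})
        feats = pd.DataFrame({"f1": rng.random(30), "f2": np.ones(30), "f3": rng.random(30)})
        with pytest.warns(UserWarning, match="constant"):
            out = pca_feature_contributions(rates, feats)
        assert "f2" not in out.correlations.columns

    def test_small_windows_removed(self, tiny_genome):
        masked = build_masked_genome(tiny_genome, cds=IntervalSet([("chr2", 0, 500)]))
        from mutrec.covariates import CovariateTrack

        track = CovariateTrack.from_records(
            "f", "continuous", [("chr1", 0, 1000, 1.0), ("chr2", 0, 600, 2.0)]
        )
        muts = [snv("a", "chr1", 5), snv("b", "chr1", 10)]
        rates, feats = window_rate_matrix(
            [snv("a", "chr1", 5), snv("b", "chr1", 10)],
            masked, [track], window_bp=1000, min_analyzable_bp=250,
        )
        assert list(rates.index) == ["chr1:0-1000"]  # chr2 window only 100 bp analyzable


class TestScnaBreakpoints:
    def test_nondiploid_thresholds(self):
        segs = [
            SegmentRecord("s1", "chr1", 0, 100, -0.5),
            SegmentRecord("s1", "chr1", 100, 200, 0.1),
            SegmentRecord("s1", "chr1", 200, 300, 0.35),
        ]
        bp = scna_breakpoints(segs)
        assert sorted(bp.pos) == [0, 100, 200, 300]

    def test_rule_matches_direct_arithmetic(self):
        rng = np.random.default_rng(3)
        for lr in rng.normal(0, 0.5, 50):
            segs = [SegmentRecord("s", "chr1", 10, 20, float(lr))]
            emitted = len(scna_breakpoints(segs)) == 2
            assert emitted == (lr <= np.log2(0.75) or lr >= np.log2(1.25))

    def test_terminal_ends_flag(self):
        segs = [SegmentRecord("s1", "chr1", 0, 1000, -0.5)]
        assert len(scna_breakpoints(segs)) == 2
        bp = scna_breakpoints(segs, include_terminal=False, lengths={"chr1": 1000})
        assert bp.empty


class TestBreakpointDistance:
    def test_identical_sets_unit_pvalue(self):
        bp = pd.DataFrame({"sample_id": ["s1"], "chrom": ["chr1"], "pos": [100]})
        sites = [("s1", "chr1", 150), ("s1", "chr1", 300)]
        _, _, _, p = breakpoint_distance_test(sites, list(sites), bp)
        assert p == 1.0

    def test_no_breakpoint_chromosome_is_inf(self):
        bp = pd.DataFrame({"sample_id": ["s1"], "chrom": ["chr1"], "pos": [100]})
        da, _, _, _ = breakpoint_distance_test(
            [("s1", "chr2", 5)], [("s1", "chr1", 100)], bp
        )
        assert np.isinf(da[0])

    def test_planted_coupling_detected(self):
        rng = np.random.default_rng(4)
        rows, near, far = [], [], []
        for i in range(200):
            s = f"s{i}"
            bp_pos = int(rng.integers(0, 10_000_000))
            rows.append({"sample_id": s, "chrom": "chr1", "pos": bp_pos})
            near.append((s, "chr1", bp_pos + int(rng.normal(0, 50_000))))
            far.append((s, "chr1", int(rng.integers(0, 10_000_000))))
        bp = pd.DataFrame(rows)
        da, db, _, p = breakpoint_distance_test(near, far, bp)
        assert np.median(da) < np.median(db) and p < 0.01

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            breakpoint_distance_test([], [("s", "chr1", 1)], pd.DataFrame(columns=["sample_id", "chrom", "pos"]))


class TestBreakpointDensityRate:
    def make(self, factor=2.0, seed=5):
        rng = np.random.default_rng(seed)
        genome = GenomeSequence({"chr1": "A" * 10_000_000})
        masked = build_masked_genome(genome)
        patients = [f"s{i}" for i in range(20)]
        rm = UniformRateModel(1e-5, patients)
        # breakpoints concentrated in the last 3 Mb
        bp_rows = [
            {"sample_id": rng.choice(patients), "chrom": "chr1",
             "pos": int(rng.integers(7_000_000, 10_000_000))}
            for _ in range(60)
        ]
        muts = []
        for p in patients:
            for pos in rng.integers(0, 10_000_000, rng.poisson(100)):
                if pos >= 7_000_000 and rng.random() > 1 / factor:
                    continue  # thin low-density region instead: see below
                muts.append(snv(p, "chr1", int(pos)))
        return masked, rm, pd.DataFrame(bp_rows), muts, patients

    def test_observed_equal_expected_normalizes_to_one(self):
        genome = GenomeSequence({"chr1": "A" * 2_000_000})
        masked = build_masked_genome(genome)
        patients = ["s1", "s2"]
        rm = UniformRateModel(1e-5, patients)
        rng = np.random.default_rng(6)
        muts = [snv(p, "chr1", int(x)) for p in patients for x in rng.integers(0, 2_000_000, 20)]
        bp = pd.DataFrame({"sample_id": ["s1"], "chrom": ["chr1"], "pos": [100]})
        out = breakpoint_density_rate(muts, bp, rm, masked)
        assert out.normalized.sum() / len(out) == pytest.approx(1.0, rel=0.35)

    def test_planted_rate_elevation_in_dense_bins(self):
        rng = np.random.default_rng(7)
        genome = GenomeSequence({"chr1": "A" * 10_000_000})
        masked = build_masked_genome(genome)
        patients = [f"s{i}" for i in range(20)]
        rm = UniformRateModel(1e-5, patients)
        bp = pd.DataFrame(
            [{"sample_id": str(rng.choice(patients)), "chrom": "chr1",
              "pos": int(rng.integers(7_000_000, 10_000_000))} for _ in range(80)]
        )
        muts = []
        for p in patients:
            n_low = rng.poisson(70)  # 7 Mb at 1e-5
            n_high = rng.poisson(60)  # 3 Mb at 2e-5
            muts += [snv(p, "chr1", int(x)) for x in rng.integers(0, 7_000_000, n_low)]
            muts += [snv(p, "chr1", int(x)) for x in rng.integers(7_000_000, 10_000_000, n_high)]
        out = breakpoint_density_rate(muts, bp, rm, masked, group_edges=(1, 10))
        dense = out[out.density_group == "[10,inf)"].normalized.iloc[0]
        sparse = out[out.density_group == "[0,1)"].normalized.iloc[0]
        assert dense / sparse == pytest.approx(2.0, rel=0.25)


class TestVafCompare:
    def diploid(self, samples):
        return {s: IntervalSet([("chr1", 0, 1_000_000)]) for s in samples}

    def test_identical_pairs_unit_pvalue(self):
        samples = [f"s{i}" for i in range(6)]
        h = [snv(s, "chr1", 10, vaf=0.3) for s in samples]
        d = [snv(s, "chr1", 500, vaf=0.3) for s in samples]
        pairs, _, p = vaf_compare(h, d, self.diploid(samples))
        assert p == 1.0 and len(pairs) == 6

    def test_systematic_shift_detected(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(20)]
        h, d = [], []
        for s in samples:
            v = float(rng.uniform(0.1, 0.4))
            d.append(snv(s, "chr1", 500, vaf=v))
            h.append(snv(s, "chr1", 10, vaf=min(1.0, v + 0.2)))
        _, _, p = vaf_compare(h, d, self.diploid(samples))
        assert p < 0.01

    def test_non_diploid_mutations_excluded(self):
        dip = {"s1": IntervalSet([("chr1", 0, 100)])}
        h = [snv("s1", "chr1", 10, vaf=0.3), snv("s1", "chr1", 500, vaf=0.9)]
        d = [snv("s1", "chr1", 50, vaf=0.3)]
        pairs, _, p = vaf_compare(h, d, dip)
        assert pairs.hotspot_vaf[0] == pytest.approx(0.3)  # the 0.9 call is outside

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            vaf_compare([snv("a", "chr1", 1, vaf=0.2)], [snv("b", "chr1", 2, vaf=0.2)],
                        self.diploid(["a", "b"]))


class TestExpressionAssociation:
    def setup_case(self, effect=4.0, n_mut=10, n_wt=30, seed=9, n_genes=6):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n_mut + n_wt)]
        mutated = set(samples[:n_mut])
        genes = [f"g{i}" for i in range(n_genes)]
        base = rng.lognormal(np.log(100), 0.2, size=(n_genes, len(samples)))
        base[0, : n_mut] *= effect  # g0 responds to mutation status
        base[1] = 5.0  # non-expressed everywhere
        expr = pd.DataFrame(base, index=genes, columns=samples)
        locs = pd.DataFrame(
            {"gene_id": genes, "chrom": "chr1",
             "start": np.arange(n_genes) * 100_000 + 1_050_000,
             "end": np.arange(n_genes) * 100_000 + 1_060_000}
        )
        tads = [("chr1", 0, 1_000_000), ("chr1", 1_000_000, 2_000_000),
                ("chr1", 2_000_000, 3_000_000)]
        return mutated, expr, tads, locs

    def test_non_expressed_gene_flagged_and_excluded(self):
        mutated, expr, tads, locs = self.setup_case()
        out = expression_association(mutated, expr, tads, locs, ("chr1", 1_500_000))
        g1 = out[out.gene_id == "g1"].iloc[0]
        assert not g1.expressed and np.isnan(g1.p_value)

    def test_planted_shift_detected_after_bh(self):
        mutated, expr, tads, locs = self.setup_case()
        out = expression_association(mutated, expr, tads, locs, ("chr1", 1_500_000))
        g0 = out[out.gene_id == "g0"].iloc[0]
        assert g0.p_adjusted < 0.05 and g0.log2_fold > 0

    def test_null_labels_give_large_pvalues(self):
        mutated, expr, tads, locs = self.setup_case(effect=1.0, seed=10, n_genes=8)
        out = expression_association(mutated, expr, tads, locs, ("chr1", 1_500_000))
        tested = out[out.expressed]
        assert (tested.p_adjusted > 0.05).all()

    def test_too_few_mutated_samples_rejected(self):
        mutated, expr, tads, locs = self.setup_case(n_mut=2)
        with pytest.raises(ValueError, match="mutated samples"):
            expression_association(mutated, expr, tads, locs, ("chr1", 1_500_000))

    def test_hotspot_outside_tads_rejected(self):
        mutated, expr, tads, locs = self.setup_case()
        with pytest.raises(ValueError, match="outside"):
            expression_association(mutated, expr, tads, locs, ("chr1", 9_999_999))


class TestMotifGainLoss:
    def setup_scorer(self):
        # score = length of the longest A run (a crude single-TF affinity proxy)
        def scorer(seq):
            best = run = 0
            for b in seq:
                run = run + 1 if b == "A" else 0
                best = max(best, run)
            return float(best)

        return scorer

    def test_disrupting_and_none_calls(self):
        rng = np.random.default_rng(11)
        bases = "ACGT"
        genome_seq = "".join(bases[i] for i in rng.integers(0, 4, 5000))
        # plant a strong motif (8 bp A run) and mutate its middle away
        genome_seq = genome_seq[:998] + "AAAAAAAA" + genome_seq[1006:]
        genome = GenomeSequence({"chr1": genome_seq})
        target = MutationRecord("s", "chr1", 1001, genome_seq[1001], "G")
        bg = [
            MutationRecord("b", "chr1", int(p), genome_seq[int(p)],
                           "ACGT"[(("ACGT".index(genome_seq[int(p)])) + 1) % 4])
            for p in rng.integers(0, 4900, 1500)
        ]
        out = motif_gain_loss([target], self.setup_scorer(), genome, bg, context_bp=10,
                              percentile=0.99)
        assert out.call.iloc[0] == "disrupting"
        # a background-typical mutation gets no call
        out2 = motif_gain_loss(bg[:5], self.setup_scorer(), genome, bg, context_bp=10)
        assert (out2.call == "none").all()

    def test_scorer_failures_skipped(self):
        genome = GenomeSequence({"chr1": "ACGT" * 100})

        def flaky(seq):
            raise RuntimeError("no model")

        with pytest.raises(ValueError, match="background"):
            motif_gain_loss([], flaky, genome,
                            [MutationRecord("b", "chr1", 10, "G", "A")] * 5)


class TestSignatureCorrelation:
    def test_identical_vectors(self):
        frac = {f"s{i}": v for i, v in enumerate(np.linspace(0.1, 0.9, 10))}
        sigs = pd.DataFrame({"sig1": list(frac.values())}, index=list(frac))
        out = signature_cbs_correlation(frac, sigs)
        assert out.r[0] == pytest.approx(1.0)

    def test_planted_negative_correlation_recovered(self):
        # sampling-error bound at n=150 is ~2 SE = 0.14; average over seeds to
        # keep the frozen test well inside it
        n, ests = 150, []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            cov = np.array([[1.0, -0.4], [-0.4, 1.0]])
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            frac = {f"s{i}": xy[i, 0] for i in range(n)}
            sigs = pd.DataFrame({"sig1": xy[:, 1]}, index=list(frac))
            out = signature_cbs_correlation(frac, sigs)
            ests.append(out.r[0])
            assert abs(out.r[0] - (-0.4)) < 0.25
        assert abs(np.mean(ests) - (-0.4)) < 0.15

    def test_zero_variance_signature_skipped(self):
        frac = {f"s{i}": v for i, v in enumerate(np.linspace(0, 1, 5))}
        sigs = pd.DataFrame({"flat": [0.5] * 5, "ok": np.linspace(1, 0, 5)}, index=list(frac))
        out = signature_cbs_correlation(frac, sigs)
        assert list(out.signature) == ["ok"]
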
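"""Targeted assays: intron splice fraction, gel formula, qPCR quantification."""

import numpy as np
import pandas as pd
import pytest

from lorespl import assays, simulate
from lorespl.assays import (IntronTarget, QpcrFitError, gel_splice_fraction,
                            intron_splice_fraction, logit_summary, qpcr_fit,
                            qpcr_relative_expression)
from lorespl.simulate import QpcrModelParams, amplification_curve, simulate_qpcr

from conftest import make_alignment, make_header


TARGET = IntronTarget("chrS", 100, 200)


def spanning_reads(n_spliced, n_retained, header=None):
    header = header or make_header()
    out = []
    for i in range(n_spliced):
        out.append(make_alignment("80M100N80M", pos=20, read_id=f"s{i}", header=header))
    for i in range(n_retained):
        out.append(make_alignment("260M", pos=20, read_id=f"r{i}", header=header))
    return out


class TestIntronSpliceFraction:
    def test_mixture_fraction(self):
        frac, spliced, spanning = intron_splice_fraction(spanning_reads(12, 18), TARGET)
        assert (frac, spliced, spanning) == (0.4, 12, 30)

    def test_all_retained_is_zero(self):
        frac, _, spanning = intron_splice_fraction(spanning_reads(0, 10), TARGET)
        assert frac == 0.0 and spanning == 10

    def test_non_spanning_reads_ignored(self):
        # covers only the left flank: no anchor on the right side
        reads = [make_alignment("90M", pos=20, read_id="x")]
        frac, _, spanning = intron_splice_fraction(reads, TARGET)
        assert frac is None and spanning == 0

    def test_monotone_in_spliced_count(self):
        fracs = [intron_splice_fraction(spanning_reads(k, 20 - k), TARGET)[0]
                 for k in range(0, 21, 5)]
        assert fracs == sorted(fracs)

    def test_simulation_recovers_true_rate(self):
        """Across 20 seeded simulations at a 0.62 splice rate the estimate
        stays within the pooled binomial 95% interval."""
        psi = np.array([[0.0], [0.38], [0.0]])  # retention = 1 - splice rate
        hits = 0
        for seed in range(20):
            design = simulate.SimulationDesign(
                n_genes=1, exons_per_gene=4, abundance=80, psi=psi,
                conditions=("a",), replicates_per_condition=1, seed=seed,
                barcode_set={"a_rep1": "ACGTACGTACGTACGTACGTACGT"})
            ref = simulate.make_reference(design)
            alignments, _, _ = simulate.simulate_alignments(design, ref)
            intron = ref.genes[0].introns[1]
            target = IntronTarget(design.chromosome, intron[0], intron[1])
            frac, _, spanning = intron_splice_fraction(alignments, target)
            ci = 1.96 * np.sqrt(0.62 * 0.38 / spanning)
            hits += abs(frac - 0.62) <= ci + 0.02
        assert hits >= 18

    def test_agrees_with_pileup_psi_complement(self):
        """1 - pileup PSI at the intron matches the targeted fraction on the
        same alignments (within 0.05)."""
        from lorespl import pileup as pileup_mod

        psi = np.array([[0.0], [0.3], [0.0]])
        design = simulate.SimulationDesign(
            n_genes=1, exons_per_gene=4, abundance=120, psi=psi,
            conditions=("a",), replicates_per_condition=1, seed=33,
            barcode_set={"a_rep1": "ACGTACGTACGTACGTACGTACGT"})
        ref = simulate.make_reference(design)
        alignments, _, _ = simulate.simulate_alignments(design, ref)
        intron = ref.genes[0].introns[1]
        target = IntronTarget(design.chromosome, intron[0], intron[1])
        frac, _, _ = intron_splice_fraction(alignments, target)
        pile = pileup_mod.build_pileup(alignments, design.chromosome,
                                       len(ref.sequence), "a_rep1")
        mid = (intron[0] + intron[1]) // 2
        pileup_psi = pile.included[mid] / pile.spanning[mid]
        assert frac == pytest.approx(1.0 - pileup_psi, abs=0.05)


class TestLogitSummary:
    def test_constant_fractions_zero_sd(self):
        out = logit_summary([0.5, 0.5, 0.5])
        assert out["logit_sd"] == 0.0
        assert out["mean_fraction"] == pytest.approx(0.5)

    def test_symmetric_pair_back_transforms_to_half(self):
        out = logit_summary([0.25, 0.75])
        assert out["logit_mean"] == pytest.approx(0.0, abs=1e-12)
        assert out["mean_fraction"] == pytest.approx(0.5)

    def test_mean_lies_between_extremes(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            f = rng.uniform(0.05, 0.95, 3)
            out = logit_summary(f)
            assert f.min() <= out["mean_fraction"] <= f.max()

    def test_boundary_fractions_clamped_by_counts(self):
        out = logit_summary([0.0, 1.0], spanning_counts=[9, 9])
        assert out["mean_fraction"] == pytest.approx(0.5)


class TestGelSpliceFraction:
    def test_worked_example(self):
        assert gel_splice_fraction(1000, 500, 500) == 0.375

    def test_extremes(self):
        assert gel_splice_fraction(100, 0, 0) == 0.0
        assert gel_splice_fraction(0, 300, 0) == 1.0

    def test_scale_invariance(self):
        base = gel_splice_fraction(120, 80, 40)
        for c in (0.1, 3.0, 1e4):
            assert gel_splice_fraction(120 * c, 80 * c, 40 * c) == pytest.approx(base)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gel_splice_fraction(0, 0, 0)


class TestQpcrFit:
    PARAMS = QpcrModelParams(k=1500.0, baseline=40.0)

    def test_noiseless_self_consistency(self):
        curve = amplification_curve(100.0, self.PARAMS, 40)
        fit = qpcr_fit(curve)
        assert fit.quantity == pytest.approx(100.0, rel=0.01)

    def test_eight_fold_ratio_recovered(self):
        lo = qpcr_fit(amplification_curve(25.0, self.PARAMS, 40)).quantity
        hi = qpcr_fit(amplification_curve(200.0, self.PARAMS, 40)).quantity
        assert hi / lo == pytest.approx(8.0, rel=0.10)

    def test_flat_curve_raises(self):
        with pytest.raises(QpcrFitError):
            qpcr_fit(np.full(40, 40.0))

    def test_global_fluorescence_rescaling_cancels_in_ratios(self):
        a = amplification_curve(50.0, self.PARAMS, 40)
        b = amplification_curve(400.0, self.PARAMS, 40)
        r1 = qpcr_fit(b).quantity / qpcr_fit(a).quantity
        r2 = qpcr_fit(b * 7.0).quantity / qpcr_fit(a * 7.0).quantity
        assert r2 == pytest.approx(r1, rel=1e-3)


def qpcr_table(quantities, params=QpcrModelParams(k=1500.0, baseline=40.0),
               noise_sd=0.0, seed=0):
    """Curves table from {(sample, gene, bio_rep, tech_rep): quantity}."""
    keyed = {"|".join(map(str, k)): v for k, v in quantities.items()}
    curves = simulate_qpcr(keyed, params, cycles=40, noise_sd=noise_sd, seed=seed)
    parts = curves["curve_id"].str.split("|", expand=True)
    curves[["sample", "gene", "biological_rep", "technical_rep"]] = parts
    return curves


class TestRelativeExpression:
    def test_all_equal_quantities_give_unit_ratio(self):
        quantities = {(s, g, b, t): 50.0
                      for s in ("treated", "baseline") for g in ("TGT", "ACTB")
                      for b in "123" for t in "12"}
        fits = assays.fit_qpcr_table(qpcr_table(quantities))
        rel = qpcr_relative_expression(fits, "TGT", "ACTB", "baseline")
        for sample in ("treated", "baseline"):
            assert rel[sample]["mean_ratio"] == pytest.approx(1.0, rel=1e-3)
            assert rel[sample]["se"] == pytest.approx(0.0, abs=1e-3)

    def test_doubled_target_gives_ratio_two(self):
        quantities = {}
        for s, q in (("treated", 100.0), ("baseline", 50.0)):
            for b in "123":
                for t in "12":
                    quantities[(s, "TGT", b, t)] = q
                    quantities[(s, "ACTB", b, t)] = 50.0
        fits = assays.fit_qpcr_table(qpcr_table(quantities))
        rel = qpcr_relative_expression(fits, "TGT", "ACTB", "baseline")
        assert rel["treated"]["mean_ratio"] == pytest.approx(2.0, rel=0.01)

    def test_fourfold_induction_with_noise(self):
        """3 biological replicates, 20% lognormal noise on every measured
        quantity, known 4-fold induction: the recovered mean ratio averaged
        over 20 seeds lies in (3.0, 5.3), as do most individual seeds."""
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            quantities = {}
            for s, q in (("treated", 200.0), ("baseline", 50.0)):
                for b in "123":
                    for t in "12":
                        quantities[(s, "TGT", b, t)] = q * np.exp(rng.normal(0, 0.2))
                        quantities[(s, "ACTB", b, t)] = 50.0 * np.exp(rng.normal(0, 0.2))
            fits = assays.fit_qpcr_table(qpcr_table(quantities, seed=seed))
            rel = qpcr_relative_expression(fits, "TGT", "ACTB", "baseline")
            ratios.append(rel["treated"]["mean_ratio"])
        assert 3.0 < np.mean(ratios) < 5.3
        assert np.mean([3.0 < r < 5.3 for r in ratios]) >= 0.8
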
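import numpy as np
import pandas as pd
import pytest

from pacscope.integrate import GeneSet
from pacscope.kinetics import fit_decay, fit_standard_curve
from pacscope.quant import trim_polya
from pacscope.signatures import signature_score, zscore_by_gene
from pacscope.simulate import (
    CHROM,
    SimulationConfig,
    reads_to_sites,
    rng_for,
    simulate_annotation,
    simulate_cohort,
    simulate_decay,
    simulate_pac_reads,
    simulate_raw_reads,
    simulate_rnaseq,
)


@pytest.fixture(scope="module")
def small_world():
    cfg = SimulationConfig(seed=11, n_genes=30)
    genome, gtf, truth = simulate_annotation(cfg)
    return cfg, genome, gtf, truth


def downstream_window_a_count(genome, pos, strand):
    seq = genome[CHROM]
    if strand == "+":
        return seq[pos + 1 : pos + 21].count("A")
    return seq[pos - 20 : pos].count("T")


class TestAnnotationSimulation:
    def test_deterministic_from_seed(self, small_world):
        cfg, genome, gtf, truth = small_world
        genome2, gtf2, truth2 = simulate_annotation(SimulationConfig(seed=11, n_genes=30))
        assert genome2[CHROM] == genome[CHROM]
        assert gtf2 == gtf
        assert truth2.to_frame().equals(truth.to_frame())

    def test_gene_count_and_strand_mix(self, small_world):
        cfg, genome, gtf, truth = small_world
        assert sum(line.split("\t")[2] == "gene" for line in gtf.splitlines() if "\t" in line) == 30
        strands = {g.strand for g in truth.genes}
        assert strands == {"+", "-"}

    def test_true_sites_have_clean_downstream_windows(self, small_world):
        # scan oracle over the emitted sequence, including jitter range
        cfg, genome, gtf, truth = small_world
        for g in truth.genes:
            for st in g.sites:
                for jit in range(-cfg.jitter_max, cfg.jitter_max + 1):
                    n_a = downstream_window_a_count(genome, st.pos + jit, g.strand)
                    assert n_a <= 12, (g.gene_id, st.site_class, jit)

    def test_decoy_windows_are_a_rich(self, small_world):
        cfg, genome, gtf, truth = small_world
        for g in truth.genes:
            assert downstream_window_a_count(genome, g.decoy_pos, g.strand) > 12

    def test_hexamer_planted_upstream_of_each_site(self, small_world):
        cfg, genome, gtf, truth = small_world
        seq = genome[CHROM]
        for g in truth.genes:
            for st in g.sites:
                hs = st.hexamer_start
                found = seq[hs : hs + 6]
                assert found == ("AATAAA" if g.strand == "+" else "TTTATT")

    def test_truth_pi_rows_sum_to_one(self, small_world):
        cfg, genome, gtf, truth = small_world
        for g in truth.genes:
            assert sum(g.pi_control.values()) == pytest.approx(1.0)
            assert sum(g.pi_knockdown.values()) == pytest.approx(1.0)

    def test_expected_score_independent_of_expression(self, small_world):
        cfg, genome, gtf, truth = small_world
        g = next(g for g in truth.genes if g.intended_qi)
        before = g.expected_pac_score("downstream10k")
        g.expression_lfc -= 3.0
        try:
            assert g.expected_pac_score("downstream10k") == pytest.approx(before)
        finally:
            g.expression_lfc += 3.0
        assert before == pytest.approx(4.0)  # default usage shift 0.8<->0.2


class TestPacReadSimulation:
    def test_site_frequencies_match_pi(self):
        cfg = SimulationConfig(seed=5, n_genes=8, pac_depth=50000, decoy_rate=0.0)
        genome, gtf, truth = simulate_annotation(cfg)
        reads = simulate_pac_reads(cfg, truth, "lineA")
        arrs = reads["ctrl_rep1"]
        for g in truth.genes:
            lo, hi = min(s.pos for s in g.sites) - 50, max(s.pos for s in g.sites) + 50
            # include the downstream site, which may be far away
            total = 0
            per_site = {}
            for st in g.sites:
                near = np.abs(arrs["pos"] - st.pos) <= cfg.jitter_max
                per_site[st.site_class] = int(near.sum())
                total += int(near.sum())
            for st in g.sites:
                assert abs(per_site[st.site_class] / total - g.pi_control[st.site_class]) < 0.02

    def test_single_site_no_jitter_concentrates(self):
        cfg = SimulationConfig(seed=5, n_genes=4, jitter_sd=0.0, jitter_max=0, decoy_rate=0.0)
        genome, gtf, truth = simulate_annotation(cfg)
        reads = simulate_pac_reads(cfg, truth, "lineA")
        site_positions = {s.pos for g in truth.genes for s in g.sites}
        assert set(reads["ctrl_rep1"]["pos"].tolist()) <= site_positions

    def test_reads_to_sites_conserves_support(self):
        cfg = SimulationConfig(seed=5, n_genes=4)
        genome, gtf, truth = simulate_annotation(cfg)
        reads = simulate_pac_reads(cfg, truth, "lineA")
        sites = reads_to_sites(reads)
        n_reads = sum(len(arrs["pos"]) for arrs in reads.values())
        assert sum(s.total_support for s in sites) == n_reads

    def test_all_true_raw_reads_pass_tail_rule(self, small_world):
        cfg, genome, gtf, truth = small_world
        for name, seq, a_count in simulate_raw_reads(cfg, truth, genome, n_reads_per_gene=3):
            insert, detected, passes = trim_polya(seq, min_a=cfg.tail_min_a)
            assert passes and detected >= a_count


class TestRnaseqSimulation:
    def test_null_gene_means_equal(self, small_world):
        cfg, genome, gtf, truth = small_world
        cm = simulate_rnaseq(cfg, truth, "lineA")
        null_genes = [g.gene_id for g in truth.genes if g.expression_lfc == 0]
        kd = [s for s, c in cm.design.items() if c == "knockdown"]
        ctrl = [s for s, c in cm.design.items() if c == "control"]
        ratio = cm.counts.loc[null_genes, kd].mean().mean() / cm.counts.loc[
            null_genes, ctrl
        ].mean().mean()
        assert ratio == pytest.approx(1.0, abs=0.08)

    def test_knockdown_halves_qi_genes(self, small_world):
        cfg, genome, gtf, truth = small_world
        cm = simulate_rnaseq(cfg, truth, "lineA")
        qi = sorted(truth.qi_genes())
        kd = [s for s, c in cm.design.items() if c == "knockdown"]
        obs = cm.counts.loc[qi, kd].mean(axis=1).mean()
        assert obs == pytest.approx(cfg.rnaseq_mean / 2, rel=0.12)

    def test_seed_reproducibility(self, small_world):
        cfg, genome, gtf, truth = small_world
        cm1 = simulate_rnaseq(cfg, truth, "lineB")
        cm2 = simulate_rnaseq(cfg, truth, "lineB")
        assert cm1.counts.equals(cm2.counts)


class TestDecaySimulation:
    def test_noiseless_round_trip(self):
        cfg = SimulationConfig(seed=3)
        table, truth_k = simulate_decay(cfg, n_genes=10, noise_sd=0.0)
        curve = fit_standard_curve(
            [20.0, 21.0, 22.0, 23.0], np.log10([1, 0.5, 0.25, 0.125])
        )
        for gene, sub in table.groupby("gene"):
            pct = [curve.percent_remaining(ct, cfg.curve_intercept) for ct in sub["ct"]]
            fit = fit_decay(sub["time_h"], pct, t0=cfg.decay_t0)
            assert abs(fit.K - truth_k[gene]) < 1e-6

    def test_noisy_median_error_bounded(self):
        cfg = SimulationConfig(seed=3)
        table, truth_k = simulate_decay(cfg, n_genes=100, noise_sd=0.1)
        curve = fit_standard_curve(
            [20.0, 21.0, 22.0, 23.0], np.log10([1, 0.5, 0.25, 0.125])
        )
        rel_errors = []
        for gene, sub in table.groupby("gene"):
            pct = [curve.percent_remaining(ct, cfg.curve_intercept) for ct in sub["ct"]]
            fit = fit_decay(sub["time_h"], pct, t0=cfg.decay_t0)
            t_true = np.log(2) / truth_k[gene]
            rel_errors.append(abs(fit.t_half - t_true) / t_true)
        assert np.median(rel_errors) < 0.10


class TestReadFileIO:
    def test_sam_round_trip_preserves_three_prime_ends(self, tmp_path):
        cfg = SimulationConfig(seed=21, n_genes=4, pac_depth=50, decoy_rate=0.0)
        genome, gtf, truth = simulate_annotation(cfg)
        reads = simulate_pac_reads(cfg, truth, "lineA")
        one = {"ctrl_rep1": reads["ctrl_rep1"]}
        from pacscope.quant import read_sites_from_sam
        from pacscope.simulate import write_sam

        sam = tmp_path / "ctrl_rep1.sam"
        write_sam(one, genome, sam)
        sites = read_sites_from_sam(sam, "ctrl_rep1")
        got = sorted((s.strand, s.pos) for s in sites for _ in range(s.total_support))
        arrs = one["ctrl_rep1"]
        expected = sorted(
            ("+" if s == 0 else "-", int(p)) for p, s in zip(arrs["pos"], arrs["strand"])
        )
        assert got == expected

    def test_fastq_written_for_raw_reads(self, small_world, tmp_path):
        from pacscope.simulate import write_fastq

        cfg, genome, gtf, truth = small_world
        raw = simulate_raw_reads(cfg, truth, genome, n_reads_per_gene=1)
        fq = tmp_path / "reads.fq"
        write_fastq(raw, fq)
        lines = fq.read_text().splitlines()
        assert len(lines) == 4 * len(raw)
        assert lines[0].startswith("@") and lines[2] == "+"
        assert lines[1].endswith("A" * 25)


class TestDecayTruthWiring:
    def test_manifest_records_decay_constants(self, small_world):
        cfg, genome, gtf, truth = small_world
        table, truth_k = simulate_decay(cfg, n_genes=5, noise_sd=0.0, truth=truth)
        assert list(truth_k.index) == [g.gene_id for g in truth.genes[:5]]
        for g in truth.genes[:5]:
            assert g.decay_k == pytest.approx(truth_k[g.gene_id])


class TestCohortSimulation:
    def set(self, n=20):
        return GeneSet("sig", frozenset(f"SET{i:03d}" for i in range(n)), {"src": "sim"})

    def test_perfect_correlation_at_rho_one(self):
        cfg = SimulationConfig(seed=9, cohort_samples=100)
        em = simulate_cohort(cfg, self.set(), rho=1.0)
        z = zscore_by_gene(em)
        sig = signature_score(z, self.set()).scores
        r = np.corrcoef(sig, z.loc["CPSF1"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_null_rho_uncorrelated(self):
        cfg = SimulationConfig(seed=9, cohort_samples=1000)
        em = simulate_cohort(cfg, self.set(), rho=0.0)
        z = zscore_by_gene(em)
        sig = signature_score(z, self.set()).scores
        r = np.corrcoef(sig, z.loc["CPSF1"])[0, 1]
        assert abs(r) < 0.1

    def test_invalid_rho_rejected(self):
        cfg = SimulationConfig(seed=9)
        with pytest.raises(ValueError):
            simulate_cohort(cfg, self.set(), rho=1.5)

    def test_substreams_independent(self):
        a1 = rng_for(7, "alpha").normal(size=4)
        a2 = rng_for(7, "alpha").normal(size=4)
        b = rng_for(7, "beta").normal(size=4)
        assert np.allclose(a1, a2)
        assert not np.allclose(a1, b)
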
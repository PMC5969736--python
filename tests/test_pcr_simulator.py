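"""Generative model: pool seeding, recombination, PCR switching, emission."""

import numpy as np
import pytest

from crisprcoupler import (
    MoleculePool,
    SimulationParams,
    apply_lentiviral_recombination,
    assign_reads,
    category_probs,
    coupling_fractions_from_counts,
    emit_reads,
    estimate_switch_rate,
    expected_uncoupled_fraction_single_cycle,
    pair_at_risk_probability,
    pool_coupling_fraction,
    seed_pool,
    simulate_pcr,
    simulate_reads,
    splice,
    switch_probability,
    synthetic_count_table,
)


class TestSeedPool:
    def test_uniform_draw_is_multinomial_around_equal_shares(self, paper_design):
        pool = seed_pool(paper_design, 57_000, seed=2)
        assert all(g[0] == g[1] == g[2] == g[3] for g in pool.counts)
        assert sum(pool.counts.values()) == 57_000
        for n in pool.counts.values():
            assert abs(n - 1000) < 200  # ~6 sigma for multinomial p=1/57

    def test_degenerate_weights_single_genotype(self, small_design):
        w = [1.0] + [0.0] * (len(small_design) - 1)
        pool = seed_pool(small_design, 10, weights=w, seed=0)
        cid = small_design.constructs[0].id
        assert pool.counts == {(cid, cid, cid, cid): 10}

    def test_negative_weights_rejected(self, small_design):
        with pytest.raises(ValueError):
            seed_pool(small_design, 10, weights=[-1.0] * len(small_design))

    def test_expected_mode_exact_counts(self, small_design):
        pool = seed_pool(small_design, 8.1e8, seed=0, expected=True)
        assert all(n == pytest.approx(8.1e8 / len(small_design))
                   for n in pool.counts.values())


class TestGeometryHelpers:
    def test_category_probs_sum_to_one(self, small_design):
        p = category_probs(small_design.layout)
        assert p.shape == (5,)
        assert p.sum() == pytest.approx(1.0)

    def test_at_risk_ordering_follows_distance(self, small_design):
        layout = small_design.layout
        bb = pair_at_risk_probability(layout, "sp_barcode", "sa_barcode")
        gb = pair_at_risk_probability(layout, "sp_spacer", "sp_barcode")
        gg = pair_at_risk_probability(layout, "sp_spacer", "sa_spacer_rc")
        assert 0 < bb < gb < gg < 1
        L = len(layout.template)
        assert bb == pytest.approx((17 + 6) / L)        # gap + two half-barcodes
        assert gg == pytest.approx((193 + 20.5) / L)    # gap + half of 20 and 21

    def test_splice_categories(self):
        a = ("a", "a", "a", "a")
        b = ("b", "b", "b", "b")
        assert splice(a, b, 0) == b
        assert splice(a, b, 2) == ("a", "a", "b", "b")
        assert splice(a, b, 4) == a


class TestSimulatePcr:
    def test_pure_doubling_without_switching(self, small_design):
        pool = seed_pool(small_design, 600, seed=1)
        params = SimulationParams(cycles=5, switch_rate=0.0, efficiency=1.0, seed=1)
        out = simulate_pcr(pool, small_design.layout, params)
        assert out.counts == {g: n * 2 ** 5 for g, n in pool.counts.items()}
        assert out.synthesized == 600 * (2 ** 5 - 1)

    def test_zero_rate_identity_through_whole_pipeline(self, small_design, small_refs):
        params = SimulationParams(n_templates=800, cycles=6, switch_rate=0.0,
                                  lenti_switch_rate=0.0, seq_error_rate=0.0, seed=3)
        records, _, pool = simulate_reads(small_design, params, 500)
        assert pool_coupling_fraction(pool, "sp_spacer", "sa_spacer_rc") == 1.0
        _, summary = assign_reads(
            [(r.id, str(r.seq)) for r in records], small_refs, small_design.layout
        )
        assert summary.fully_assigned == summary.total_reads

    def test_single_cycle_chimeras_match_brute_force_and_closed_form(self, small_design):
        """Two templates, one cycle: the chimera fraction agrees with an
        independent molecule-by-molecule simulation and with
        (1-(1-lambda)^L) x P(internal breakpoint) x P(different partner)."""
        layout = small_design.layout
        L = len(layout.template)
        lam = 0.005
        cat_p = category_probs(layout)
        a = (small_design.constructs[0].id,) * 4
        b = (small_design.constructs[1].id,) * 4
        pure = {a, b}
        params = SimulationParams(cycles=1, switch_rate=lam, efficiency=1.0, seed=0)

        rng = np.random.default_rng(99)
        n_rep = 600
        sim_chimeras = naive_chimeras = new_copies = 0
        for rep in range(n_rep):
            pool = MoleculePool({a: 1, b: 1})
            out = simulate_pcr(pool, layout, params, seed=rng)
            sim_chimeras += sum(
                n for g, n in out.counts.items() if g not in pure
            )
            new_copies += 2
            # independent brute-force oracle: molecule-level, explicit events
            molecules = [a, b]
            for src in list(molecules):
                if rng.random() < 1.0 - (1.0 - lam) ** L:
                    x = rng.uniform(0, L)
                    category = int(np.searchsorted(np.cumsum(cat_p), x / L,
                                                   side="right"))
                    partner = molecules[rng.integers(len(molecules))]
                    product = splice(src, partner, category)
                else:
                    product = src
                if product not in pure:
                    naive_chimeras += 1

        q = switch_probability(lam, L)
        expected = q * cat_p[1:4].sum() * 0.5
        se = np.sqrt(expected * (1 - expected) / new_copies)
        assert sim_chimeras / new_copies == pytest.approx(expected, abs=5 * se)
        assert naive_chimeras / new_copies == pytest.approx(expected, abs=5 * se)

    def test_uncoupling_ordered_by_distance(self, small_design):
        """Expected-count amplification: barcode-barcode (17 nt) uncouples
        least, sgRNA-barcode (82 nt) more, sgRNA-sgRNA (193 nt) most."""
        pool = seed_pool(small_design, 1000, expected=True)
        params = SimulationParams(cycles=8, switch_rate=2e-4, mode="expected")
        out = simulate_pcr(pool, small_design.layout, params)
        u_bb = 1 - pool_coupling_fraction(out, "sp_barcode", "sa_barcode")
        u_gb = 1 - pool_coupling_fraction(out, "sp_spacer", "sp_barcode")
        u_gg = 1 - pool_coupling_fraction(out, "sp_spacer", "sa_spacer_rc")
        assert 0 < u_bb < u_gb < u_gg

    def test_uncoupling_monotone_in_rate_and_cycles(self, small_design):
        def uncoupled(rate, cycles):
            pool = seed_pool(small_design, 1000, expected=True)
            params = SimulationParams(cycles=cycles, switch_rate=rate, mode="expected")
            out = simulate_pcr(pool, small_design.layout, params)
            return 1 - pool_coupling_fraction(out, "sp_spacer", "sa_spacer_rc")

        by_rate = [uncoupled(r, 16) for r in (5e-5, 2e-4, 8e-4)]
        assert by_rate == sorted(by_rate) and by_rate[0] < by_rate[-1]
        by_cycles = [uncoupled(2e-4, c) for c in (16, 22, 28)]
        assert by_cycles == sorted(by_cycles) and by_cycles[0] < by_cycles[-1]

    def test_uncoupling_monotone_in_template_count_with_resource_coupling(
        self, small_design
    ):
        """With resource depletion switched on, more input templates deplete
        capacity earlier and raise the effective switch rate."""
        def uncoupled(n_templates):
            pool = seed_pool(small_design, n_templates, expected=True)
            params = SimulationParams(
                cycles=12, switch_rate=1e-4, resource_coupling=5.0,
                resource_capacity=1e5, mode="expected",
            )
            out = simulate_pcr(pool, small_design.layout, params)
            return 1 - pool_coupling_fraction(out, "sp_spacer", "sa_spacer_rc")

        by_templates = [uncoupled(n) for n in (100, 1000, 10_000)]
        assert by_templates == sorted(by_templates)
        assert by_templates[0] < by_templates[-1]

    def test_expected_and_stochastic_modes_agree_in_the_mean(self, small_design):
        layout = small_design.layout
        pool_e = seed_pool(small_design, 2000, expected=True)
        params_e = SimulationParams(cycles=6, switch_rate=3e-4, mode="expected")
        u_expected = 1 - pool_coupling_fraction(
            simulate_pcr(pool_e, layout, params_e), "sp_spacer", "sa_spacer_rc"
        )
        rng = np.random.default_rng(8)
        us = []
        for _ in range(15):
            pool = seed_pool(small_design, 2000, seed=rng)
            params = SimulationParams(cycles=6, switch_rate=3e-4)
            out = simulate_pcr(pool, layout, params, seed=rng)
            us.append(1 - pool_coupling_fraction(out, "sp_spacer", "sa_spacer_rc"))
        assert np.mean(us) == pytest.approx(u_expected, rel=0.25)

    def test_stochastic_pool_cap_directs_to_expected_mode(self, small_design):
        pool = seed_pool(small_design, 1000, seed=0)
        params = SimulationParams(cycles=10, stochastic_pool_cap=10_000)
        with pytest.raises(RuntimeError, match="expected"):
            simulate_pcr(pool, small_design.layout, params)


class TestLentiviralRecombination:
    def test_zero_rate_is_identity(self, small_design):
        pool = seed_pool(small_design, 500, seed=4)
        out = apply_lentiviral_recombination(pool, small_design.layout, 0.0)
        assert out.counts == pool.counts

    def test_two_genotype_closed_form_for_barcode_uncoupling(self, small_design):
        """Barcode-barcode uncoupling needs the crossover category that
        splits exactly between the barcodes, with a different-genotype
        partner: p_rec x P(category 2) x 1/2."""
        layout = small_design.layout
        rho = 1e-3
        a = (small_design.constructs[0].id,) * 4
        b = (small_design.constructs[1].id,) * 4
        pool = MoleculePool({a: 20_000, b: 20_000})
        out = apply_lentiviral_recombination(pool, layout, rho, seed=6)
        assert sum(out.counts.values()) == 40_000  # conserved
        p_rec = switch_probability(rho, len(layout.template))
        expected = p_rec * category_probs(layout)[2] * 0.5
        observed = 1 - pool_coupling_fraction(out, "sp_barcode", "sa_barcode")
        se = np.sqrt(expected / 40_000)
        assert observed == pytest.approx(expected, abs=5 * se)
        # crossovers anywhere between the spacers uncouple the guide pair,
        # so guide-guide uncoupling must exceed barcode-barcode uncoupling
        u_gg = 1 - pool_coupling_fraction(out, "sp_spacer", "sa_spacer_rc")
        assert u_gg > observed


class TestEmitReads:
    def test_seeded_determinism_byte_identical_fastq(self, small_design, tmp_path):
        params = SimulationParams(n_templates=400, cycles=3, switch_rate=1e-4,
                                  seq_error_rate=0.001, seed=17)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        simulate_reads(small_design, params, 300, fastq_path=p1)
        simulate_reads(small_design, params, 300, fastq_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_reads_empty_fastq(self, small_design, tmp_path):
        pool = seed_pool(small_design, 10, seed=0)
        path = tmp_path / "empty.fastq"
        records, truth = emit_reads(pool, small_design, 0, fastq_path=path)
        assert records == [] and truth.empty and path.read_text() == ""

    def test_read_length_below_barcode_span_rejected(self, small_design):
        pool = seed_pool(small_design, 10, seed=0)
        with pytest.raises(ValueError, match="29"):
            emit_reads(pool, small_design, 10, read_length=20)

    def test_stagger_lengths_span_one_to_eight(self, small_design):
        pool = seed_pool(small_design, 100, seed=0)
        _, truth = emit_reads(pool, small_design, 400, seed=1)
        assert truth["stagger_len"].between(1, 8).all()
        assert truth["stagger_len"].nunique() == 8

    def test_barcode_dropout_matches_binomial_error_expectation(
        self, small_design, small_refs
    ):
        """At per-base error rate p, a 6-nt barcode fails exact lookup with
        probability ~ 1 - (1-p)^6 (distance-2 code: single errors cannot
        land on another codeword)."""
        err = 0.003
        params = SimulationParams(n_templates=1000, cycles=2,
                                  seq_error_rate=err, seed=29)
        records, _, _ = simulate_reads(small_design, params, 20_000)
        assignments, _ = assign_reads(
            [(r.id, str(r.seq)) for r in records], small_refs, small_design.layout
        )
        with_anchor = [a for a in assignments if a.sp_bc_id != "ANCHOR_NOT_FOUND"]
        unmapped = sum(a.sp_bc_id == "UNMAPPED" for a in with_anchor)
        expected = 1 - (1 - err) ** 6
        se = np.sqrt(expected * (1 - expected) / len(with_anchor))
        assert unmapped / len(with_anchor) == pytest.approx(expected, abs=5 * se)


class TestRateEstimation:
    def test_inversion_round_trips_the_closed_form(self, small_design):
        layout = small_design.layout
        for lam in (1e-5, 1e-4, 1e-3):
            u = expected_uncoupled_fraction_single_cycle(
                lam, layout, "sp_spacer", "sa_spacer_rc", len(small_design)
            )
            assert estimate_switch_rate(
                u, layout, "sp_spacer", "sa_spacer_rc", len(small_design)
            ) == pytest.approx(lam, rel=1e-9)

    def test_out_of_range_observation_rejected(self, small_design):
        with pytest.raises(ValueError):
            estimate_switch_rate(
                0.9, small_design.layout, "sp_barcode", "sa_barcode",
                len(small_design),
            )


class TestSyntheticCountTable:
    def test_median_recovers_the_generative_target(self):
        ids = [f"C{i:02d}" for i in range(57)]
        for target in (0.64, 0.93):
            counts = synthetic_count_table(target, ids, seed=5)
            report = coupling_fractions_from_counts(counts, {i: i for i in ids})
            assert report.summary.median == pytest.approx(target, abs=0.03)

    def test_shape_and_marginals(self):
        ids = ["a", "b", "c"]
        counts = synthetic_count_table(0.9, ids, mean_reads=500, seed=0)
        assert list(counts.index) == ids and list(counts.columns) == ids
        assert (counts.sum(axis=1) > 0).all()

    def test_invalid_median_rejected(self):
        with pytest.raises(ValueError):
            synthetic_count_table(1.0, ["a", "b"])
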
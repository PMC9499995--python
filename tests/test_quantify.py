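"""Quantification model fit, prediction and window distribution."""

import numpy as np
import pandas as pd
import pytest

from medipspike.io_counts import AlignedFragment, make_windows
from medipspike.quantify import (
    FitError,
    FragmentFeatures,
    QuantModel,
    design_matrix,
    distribute_to_windows,
    fit_model,
    fragment_window_overlaps,
    predict_amount,
    predict_amounts,
    quantify_sample,
    window_counts,
)


def synth_table(rng, n=52, beta=(0.1, 0.001, 0.0, 0.0, 0.0), noise=0.0):
    """Spike-in count table whose amounts follow a known 5-vector."""
    counts = rng.integers(10, 5000, n).astype(float)
    lens = rng.choice([80, 160, 320], n).astype(float)
    gc = rng.choice([0.35, 0.5, 0.65], n)
    cpg = rng.choice([1 / 80, 1 / 40, 1 / 20], n)
    X = design_matrix(counts, lens, gc, cpg)
    y = X @ np.array(beta) + noise * rng.normal(size=n)
    return pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "count": counts,
            "length_bp": lens,
            "gc_content": gc,
            "cpg_fraction": cpg,
            "methylation_status": "methylated",
            "amount_pmol": y,
        }
    )


class TestFit:
    def test_noiseless_two_term_recovery(self, rng):
        t = synth_table(rng)
        m = fit_model(t)
        assert m.beta0 == pytest.approx(0.1, abs=1e-8)
        assert m.beta_reads == pytest.approx(0.001, abs=1e-8)

    def test_noiseless_full_recovery_matches_normal_equations(self, rng):
        beta = (0.05, 2e-4, 3e-5, -0.01, 0.02)
        t = synth_table(rng, beta=beta)
        m = fit_model(t)
        X = design_matrix(t["count"], t["length_bp"], t["gc_content"],
                          t["cpg_fraction"])
        y = t["amount_pmol"].to_numpy()
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(m.coef, oracle, atol=1e-8)
        np.testing.assert_allclose(m.coef, beta, atol=1e-8)
        assert m.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_five_spikeins_rejected(self, rng):
        t = synth_table(rng, n=5)
        with pytest.raises(FitError, match="at least 6"):
            fit_model(t)

    def test_six_spikeins_accepted(self, rng):
        t = synth_table(rng, n=6)
        assert fit_model(t).n_train == 6

    def test_rank_deficient_design_rejected(self, rng):
        t = synth_table(rng, n=10)
        t["length_bp"] = 160
        t["gc_content"] = 0.5  # two constant columns + intercept
        with pytest.raises(FitError, match="rank"):
            fit_model(t)

    def test_unmethylated_excluded_by_default(self, rng):
        t = synth_table(rng, n=20)
        t.loc[10:, "methylation_status"] = "unmethylated"
        t.loc[10:, "amount_pmol"] = 999.0  # would wreck the fit
        m = fit_model(t)
        assert m.n_train == 10
        assert m.beta0 == pytest.approx(0.1, abs=1e-6)


class TestPredict:
    def test_zero_model_predicts_zero(self):
        m = QuantModel(0, 0, 0, 0, 0)
        raw, clamped = predict_amount(m, FragmentFeatures(5, 160, 0.5, 0.0125))
        assert raw == 0 and clamped == 0

    def test_intercept_only(self):
        m = QuantModel(1, 0, 0, 0, 0)
        raw, _ = predict_amount(m, FragmentFeatures(99, 80, 0.35, 0.05))
        assert raw == 1.0

    def test_cube_root_transform(self):
        m = QuantModel(0, 0, 0, 0, 2.0)
        raw, _ = predict_amount(m, FragmentFeatures(0, 0, 0, 1 / 8))
        assert raw == pytest.approx(1.0)  # 2 * (1/8)^(1/3)

    def test_negative_raw_is_clamped(self):
        m = QuantModel(-1, 0, 0, 0, 0)
        raw, clamped = predict_amount(m, FragmentFeatures(0, 0, 0, 0))
        assert raw == -1.0 and clamped == 0.0

    def test_linear_in_reads(self):
        m = QuantModel(0.3, 0.007, 1e-5, 0.2, -0.1)
        f1 = FragmentFeatures(10, 160, 0.5, 0.0125)
        f2 = FragmentFeatures(11, 160, 0.5, 0.0125)
        assert predict_amount(m, f2)[0] - predict_amount(m, f1)[0] == (
            pytest.approx(m.beta_reads)
        )


class TestDistribute:
    def test_fully_contained_fragment_scales_by_length(self):
        track = make_windows({"chr1": 900})
        frags = pd.DataFrame(
            [("chr1", 50, 210)], columns=["chrom", "start", "end"]
        )
        ov = fragment_window_overlaps(frags, track)
        out = distribute_to_windows([0.10], ov, track)
        np.testing.assert_allclose(
            out.windows["amount_pmol"], [0.10 * 160 / 300, 0, 0]
        )

    def test_straddling_fragment_splits_by_overlap(self):
        track = make_windows({"chr1": 900})
        frags = pd.DataFrame(
            [("chr1", 0, 320)], columns=["chrom", "start", "end"]
        )
        ov = fragment_window_overlaps(frags, track)
        out = distribute_to_windows([0.3], ov, track)
        np.testing.assert_allclose(
            out.windows["amount_pmol"], [0.3, 0.3 * 20 / 300, 0]
        )
        assert out.windows["amount_pmol"].sum() == pytest.approx(
            0.3 * 320 / 300
        )

    def test_matches_bruteforce_double_loop(self, rng):
        track = make_windows({"chr1": 3000, "chr2": 1500})
        n = 50
        chroms = rng.choice(["chr1", "chr2"], n)
        starts = rng.integers(0, 1200, n)
        lengths = rng.integers(80, 321, n)
        frags = pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": starts + lengths}
        )
        eta = rng.uniform(0, 1e-3, n)
        out = distribute_to_windows(
            eta, fragment_window_overlaps(frags, track), track
        )
        # O(F x W) oracle
        w = track.windows
        expected = np.zeros(len(w))
        for wi, (wc, ws, we) in enumerate(zip(w.chrom, w.start, w.end)):
            for fi in range(n):
                if frags.chrom[fi] != wc:
                    continue
                ovl = min(int(frags.end[fi]), we) - max(
                    int(frags.start[fi]), ws
                )
                if ovl > 0:
                    expected[wi] += ovl / 300 * eta[fi]
        np.testing.assert_allclose(
            out.windows["amount_pmol_raw"], expected, rtol=1e-12
        )

    def test_total_conserves_amount_times_length_fraction(self, rng):
        track = make_windows({"chr1": 3000})
        starts = rng.integers(0, 2600, 30)
        lengths = rng.integers(80, 321, 30)
        frags = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + lengths}
        )
        eta = rng.uniform(0, 1, 30)
        out = distribute_to_windows(
            eta, fragment_window_overlaps(frags, track), track
        )
        assert out.windows["amount_pmol_raw"].sum() == pytest.approx(
            float((eta * lengths).sum() / 300)
        )


class TestQuantifySample:
    def test_zero_genomic_fragments_all_zero_track(self, catalog52):
        ids = catalog52.ids()
        spike = [
            AlignedFragment(i, 0, 80, f"U{k}", is_spikein=True)
            for n, i in enumerate(ids)
            for k in range(1 + n % 5)
        ]
        genome = {"chr1": "ACGT" * 300}
        track = make_windows({"chr1": 1200})
        out, model = quantify_sample(spike, catalog52, genome, track)
        assert (out.windows["amount_pmol"] == 0).all()
        assert model.n_train == 26

    def test_no_spikeins_is_informative_error(self, catalog52):
        genome = {"chr1": "ACGT" * 300}
        track = make_windows({"chr1": 1200})
        frags = [AlignedFragment("chr1", 0, 160, "AAAAA")]
        with pytest.raises(FitError, match="spike-in"):
            quantify_sample(frags, catalog52, genome, track)

    def test_deterministic_for_identical_inputs(self, catalog52):
        from medipspike.simulate import (
            SimConfig,
            simulate_genomic_sample,
            toy_genome,
        )

        cfg = SimConfig(seed=9, catalog=catalog52, depth=2000,
                        genomic_depth=2000, windows_per_chrom=5)
        genome = toy_genome(cfg)
        frags, _ = simulate_genomic_sample(cfg, genome=genome)
        track = make_windows({k: len(v) for k, v in genome.items()})
        out1, m1 = quantify_sample(frags, catalog52, genome, track)
        out2, m2 = quantify_sample(list(frags), catalog52, genome, track)
        pd.testing.assert_frame_equal(out1.windows, out2.windows)
        assert m1.coef.tolist() == m2.coef.tolist()

    def test_recovers_simulated_truth(self, catalog52):
        from medipspike.simulate import (
            SimConfig,
            simulate_genomic_sample,
            toy_genome,
        )

        cfg = SimConfig(seed=2, catalog=catalog52, depth=20_000,
                        genomic_depth=20_000, windows_per_chrom=15)
        genome = toy_genome(cfg)
        frags, truth = simulate_genomic_sample(cfg, genome=genome)
        track = make_windows({k: len(v) for k, v in genome.items()})
        out, _ = quantify_sample(frags, catalog52, genome, track)
        r = np.corrcoef(
            out.windows["amount_pmol_raw"],
            truth.window_amounts["true_amount"],
        )[0, 1]
        assert r > 0.95
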
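"""Windowed CNA scoring, signature selection and tumor content."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import gliograph as gg
from gliograph.cna import (
    CNASpotProfile,
    EmptyCohortError,
    InsufficientSignatureError,
    SignatureEvent,
    estimate_content,
    malignant_mask,
    qc_filter,
    rescale_to_reference,
    select_signature_events,
    tumor_content,
    windowed_cna,
)


def _adata(X, mito_flags=None, chrom=None):
    X = np.asarray(X, dtype=float)
    n_genes = X.shape[1]
    var = pd.DataFrame(
        {
            "chromosome": chrom if chrom is not None else np.zeros(n_genes, int),
            "is_mito": mito_flags if mito_flags is not None else np.zeros(n_genes, bool),
        },
        index=[f"g{i}" for i in range(n_genes)],
    )
    obs = pd.DataFrame(index=[f"s{i}" for i in range(X.shape[0])])
    return ad.AnnData(X=X, obs=obs, var=var)


class TestQCFilter:
    def test_spot_below_min_genes_removed(self):
        # spot 0 detects 199 genes, spot 1 detects 250
        X = np.zeros((2, 300))
        X[0, :199] = 1
        X[1, :250] = 1
        out = qc_filter(_adata(X), min_genes=200, min_spots_per_gene=1)
        assert list(out.obs_names) == ["s1"]

    def test_mito_fraction_boundary_retained(self):
        # 5% exactly is retained; rule removes only > 5%
        X = np.ones((2, 300))
        mito = np.zeros(300, bool)
        mito[:15] = True  # 15/300 = 5% of counts for spot 0
        X[1, :15] = 2.0  # spot 1: 30/315 > 5%
        out = qc_filter(_adata(X, mito_flags=mito), min_genes=100, min_spots_per_gene=1)
        assert list(out.obs_names) == ["s0"]

    def test_gene_in_two_spots_removed(self):
        X = np.ones((5, 250))
        X[:, 0] = 0
        X[[0, 1], 0] = 1  # gene g0 detected in 2 spots only
        out = qc_filter(_adata(X), min_genes=100, min_spots_per_gene=3)
        assert "g0" not in out.var_names
        assert out.n_vars == 249

    def test_all_spots_removed_raises(self):
        X = np.ones((2, 50))
        with pytest.raises(EmptyCohortError):
            qc_filter(_adata(X), min_genes=200)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            qc_filter(_adata(-np.ones((2, 300))))


class TestWindowedCNA:
    def test_spot_at_reference_mean_scores_one(self):
        rng = np.random.default_rng(0)
        ref_X = rng.poisson(50, size=(4, 200)).astype(float) + 1
        ref = _adata(ref_X)
        # tumor spot = mean CPM profile of the reference
        cpm = ref_X / ref_X.sum(axis=1, keepdims=True) * 1e6
        tum = _adata(cpm.mean(axis=0, keepdims=True) * np.ones((3, 1)))
        prof, _ = windowed_cna(tum, ref, window=100)
        np.testing.assert_allclose(prof.scores.to_numpy(), 1.0, atol=1e-9)

    def test_partial_windows_dropped(self):
        chrom = np.repeat([0, 1], 250)
        X = np.ones((3, 500))
        adata = _adata(X, chrom=chrom)
        prof, _ = windowed_cna(adata, adata.copy(), window=100)
        # 250 genes/chromosome -> 2 full 100-gene windows each, remainder dropped
        assert prof.scores.shape[1] == 4
        assert (prof.window_meta["chromosome"].value_counts() == 2).all()

    def test_gain_windows_score_above_neutral(self, small_sample):
        cfg, adata, truth, ref = small_sample
        prof, _ = windowed_cna(adata, ref)
        means = prof.scores.mean(axis=0)
        chrom = prof.window_meta["chromosome"]
        gain_mean = means[chrom.isin(cfg.gain_chroms).to_numpy()].mean()
        neutral = ~chrom.isin(cfg.gain_chroms + cfg.loss_chroms).to_numpy()
        assert gain_mean > means[neutral].mean()

    def test_empty_reference_rejected(self):
        tum = _adata(np.ones((2, 100)))
        with pytest.raises(ValueError):
            windowed_cna(tum, tum[:0])


def _profile(values_by_window: dict, rescaled=True) -> CNASpotProfile:
    scores = pd.DataFrame(values_by_window)
    meta = pd.DataFrame(
        {"chromosome": range(len(values_by_window)), "gene_start": 0, "gene_end": 99},
        index=list(values_by_window),
    )
    return CNASpotProfile(scores=scores, window_meta=meta, rescaled=rescaled)


class TestRescale:
    def test_reference_endpoints_map_to_band(self):
        ref = _profile({"w0": [0.9, 1.0, 1.1]})
        out = rescale_to_reference(ref, ref)
        np.testing.assert_allclose(out.scores["w0"], [0.98, 1.00, 1.02], atol=1e-12)

    def test_spot_at_reference_mean_maps_to_one(self):
        ref = _profile({"w0": [0.9, 1.0, 1.1]})
        tum = _profile({"w0": [1.0]})
        out = rescale_to_reference(tum, ref)
        assert out.scores["w0"].iloc[0] == pytest.approx(1.0)

    def test_two_half_ranges_above_mean_is_1_04(self):
        ref = _profile({"w0": [0.9, 1.0, 1.1]})
        tum = _profile({"w0": [1.2]})  # 2 half-ranges (0.1 each) above the mean
        out = rescale_to_reference(tum, ref)
        assert out.scores["w0"].iloc[0] == pytest.approx(1.04)

    def test_zero_variance_window_shifted_and_flagged(self, caplog):
        ref = _profile({"w0": [1.3, 1.3]})
        tum = _profile({"w0": [1.4]})
        with caplog.at_level("WARNING", logger="gliograph.cna"):
            out = rescale_to_reference(tum, ref)
        assert out.scores["w0"].iloc[0] == pytest.approx(1.1)
        assert "zero-variance" in caplog.text


class TestSignatureSelection:
    def test_threshold_application(self):
        prof = _profile({"w0": [1.06], "w1": [1.07], "w2": [0.94], "w3": [1.01]})
        events = select_signature_events(prof)
        assert len(events) == 3
        assert sorted(e.direction for e in events) == ["gain", "gain", "loss"]

    def test_exact_1_05_is_not_a_gain(self):
        prof = _profile({"w0": [1.05], "w1": [1.06], "w2": [0.94], "w3": [0.93]})
        events = select_signature_events(prof)
        assert "w0" not in [e.window for e in events]

    def test_insufficient_events_raises(self):
        prof = _profile({"w0": [1.01], "w1": [0.99], "w2": [1.04]})
        with pytest.raises(InsufficientSignatureError):
            select_signature_events(prof)

    def test_tumor_as_its_own_reference_has_no_signature(self, small_sample):
        _, _, _, ref = small_sample
        tum, refp = windowed_cna(ref, ref)
        scaled = rescale_to_reference(tum, refp)
        with pytest.raises(InsufficientSignatureError):
            select_signature_events(scaled)


class TestTumorContent:
    def test_gain_formula_endpoints_and_midpoint(self):
        prof = _profile(
            {"w0": [1.00, 1.05, 1.10], "w1": [1.00, 1.05, 1.10], "w2": [1.00, 1.05, 1.10]}
        )
        events = [SignatureEvent(w, 0, "gain", 1.05) for w in ["w0", "w1", "w2"]]
        c = tumor_content(prof, events)
        np.testing.assert_allclose(c.to_numpy(), [0.0, 0.5, 1.0])

    def test_loss_formula_midpoint(self):
        prof = _profile(
            {"w0": [0.95, 0.90], "w1": [0.95, 0.90], "w2": [0.95, 0.90]}
        )
        events = [SignatureEvent(w, 0, "loss", 0.92) for w in ["w0", "w1", "w2"]]
        c = tumor_content(prof, events)
        assert c.iloc[0] == pytest.approx(0.5)

    def test_average_over_events(self):
        prof = _profile({"w0": [1.04], "w1": [1.05], "w2": [1.06]})
        # per-window max normalizers differ; force per-event contents 0.4/0.5/0.6
        prof.scores = pd.DataFrame(
            {"w0": [1.0, 1.04], "w1": [1.0, 1.05], "w2": [1.0, 1.06]}
        )
        prof.scores.iloc[0] = [1.1, 1.1, 1.1]
        events = [SignatureEvent(w, 0, "gain", 1.05) for w in ["w0", "w1", "w2"]]
        c = tumor_content(prof, events)
        expected = np.mean([0.04 / 0.1, 0.05 / 0.1, 0.06 / 0.1])
        assert c.iloc[1] == pytest.approx(expected)

    def test_degenerate_event_skipped_with_warning(self):
        prof = _profile(
            {"w0": [1.0, 1.0], "w1": [1.0, 1.1], "w2": [1.0, 1.1], "w3": [1.0, 1.1]}
        )
        events = [SignatureEvent(w, 0, "gain", 1.06) for w in prof.scores.columns]
        with pytest.warns(UserWarning, match="degenerate"):
            c = tumor_content(prof, events)
        np.testing.assert_allclose(c.to_numpy(), [0.0, 1.0])

    def test_monotone_in_score_for_gains_and_losses(self):
        a = np.linspace(1.0, 1.2, 11)
        prof_g = _profile({f"w{i}": a for i in range(3)})
        ev_g = [SignatureEvent(f"w{i}", 0, "gain", 1.1) for i in range(3)]
        cg = tumor_content(prof_g, ev_g).to_numpy()
        assert (np.diff(cg) >= 0).all()
        prof_l = _profile({f"w{i}": 2.0 - a for i in range(3)})
        ev_l = [SignatureEvent(f"w{i}", 0, "loss", 0.9) for i in range(3)]
        cl = tumor_content(prof_l, ev_l).to_numpy()
        assert (np.diff(cl) >= 0).all()


class TestMalignantMask:
    def test_boundary_is_strict(self):
        c = pd.Series([0.2, 0.25, 0.9, 0.1])
        mask = malignant_mask(c)
        assert mask.tolist() == [False, True, True, False]

    def test_out_of_range_content_rejected(self):
        with pytest.raises(ValueError):
            malignant_mask(pd.Series([1.2]))

    def test_recall_on_generator_truth(self, small_sample):
        _, adata, _, ref = small_sample
        filtered = qc_filter(adata, min_genes=100)
        content, events, _ = estimate_content(filtered, ref)
        true_c = filtered.obs["true_content"].to_numpy()
        mask = malignant_mask(content).to_numpy()
        assert mask[true_c >= 0.4].mean() >= 0.9


class TestContentRecovery:
    def test_pearson_r_against_generator_truth(self, small_sample):
        _, adata, _, ref = small_sample
        filtered = qc_filter(adata, min_genes=100)
        content, events, _ = estimate_content(filtered, ref)
        assert len(events) >= 3
        r = np.corrcoef(content.to_numpy(), filtered.obs["true_content"])[0, 1]
        assert r >= 0.8
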
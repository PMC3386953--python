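import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exonsplice.errors import ConfigError, IntegrityError
from exonsplice.expression import summarize_transcripts
from exonsplice.model_io import IntensityMatrix, SampleDesign
from exonsplice.preprocess import (
    apply_probe_effects,
    background_correct,
    estimate_probe_effects,
)
from exonsplice.splicing import (
    consensus_splicing_calls,
    mads_test,
    midas_test,
    splicing_index,
)
from exonsplice.synthetic import SimulationConfig, simulate_experiment

from conftest import make_annotation, make_matrix


def design_2x3():
    samples = [f"{c}{r}" for c in "AB" for r in range(1, 4)]
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": samples,
                "condition": [s[0] for s in samples],
                "replicate": [int(s[1]) for s in samples],
            }
        )
    )


@pytest.fixture(scope="module")
def prepared():
    """Simulated experiment with planted AS, preprocessed for splicing."""
    cfg = SimulationConfig(
        n_transcripts=100,
        frac_as_transcripts=0.2,
        delta_inclusion=0.4,
        noise_sd=0.1,
        seed=31,
    )
    m, ann, design, truth = simulate_experiment(cfg)
    c = background_correct(m, ann)
    genomic = set(ann.genomic["probe_id"])
    c = c.subset_probes([p for p in c.values.index if p in genomic])
    effects = estimate_probe_effects(c, ann)
    c = apply_probe_effects(c, effects)
    expr = summarize_transcripts(c, ann)
    si = splicing_index(c, expr, ann)
    return cfg, c, ann, design, truth, expr, si


class TestSplicingIndex:
    def two_probe_case(self):
        ann = make_annotation(
            [
                ("p1", "ps1", "t1", "g1", 1, False, "genomic"),
                ("p2", "ps2", "t1", "g1", 2, False, "genomic"),
            ]
        )
        m = make_matrix(
            [[2.0**6], [2.0**8]], ["p1", "p2"], ["s1"], corrected=True
        )
        expr = summarize_transcripts(m, ann)
        return splicing_index(m, expr, ann)

    def test_probe_at_transcript_mean_gives_zero(self):
        ann = make_annotation(
            [
                ("p1", "ps1", "t1", "g1", 1, False, "genomic"),
                ("p2", "ps2", "t1", "g1", 2, False, "genomic"),
            ]
        )
        m = make_matrix([[64.0], [64.0]], ["p1", "p2"], ["s1"], corrected=True)
        expr = summarize_transcripts(m, ann)
        si = splicing_index(m, expr, ann)
        assert np.allclose(si.probe_si.to_numpy(), 0.0)

    def test_probe_at_twice_geometric_mean(self):
        si = self.two_probe_case()
        # log2 values 6 and 8 -> mean 7 -> SI = -1 and +1
        assert si.probe_si.loc["p1", "s1"] == pytest.approx(-1.0)
        assert si.probe_si.loc["p2", "s1"] == pytest.approx(1.0)

    def test_probe_si_sums_to_zero_per_transcript(self, prepared):
        _, _, ann, _, _, _, si = prepared
        tx = ann.genomic.set_index("probe_id")["transcript_id"]
        sums = si.probe_si.groupby(tx.loc[si.probe_si.index]).sum()
        assert np.abs(sums.to_numpy()).max() < 1e-9

    def test_doubling_one_sample_leaves_si_unchanged(self, prepared):
        _, c, ann, _, _, expr, si = prepared
        tx = ann.genomic["transcript_id"].iloc[0]
        probes = ann.genomic.loc[
            ann.genomic["transcript_id"] == tx, "probe_id"
        ]
        bumped = c.values.copy()
        sample = bumped.columns[0]
        bumped.loc[probes, sample] *= 2.0
        m2 = IntensityMatrix(bumped, is_background_corrected=True)
        expr2 = summarize_transcripts(m2, ann)
        si2 = splicing_index(m2, expr2, ann)
        assert np.allclose(
            si.probe_si.loc[probes], si2.probe_si.loc[probes], atol=1e-12
        )

    def test_missing_expression_rejected(self, prepared):
        _, c, ann, _, _, expr, _ = prepared
        with pytest.raises(IntegrityError, match="expression"):
            splicing_index(c, expr.iloc[:10], ann)

    def test_presence_restriction(self):
        cfg = SimulationConfig(
            n_transcripts=40, frac_absent_transcripts=0.4, seed=13
        )
        m, ann, design, truth = simulate_experiment(cfg)
        from exonsplice.preprocess import detect_present

        presence = detect_present(m, ann, design)
        c = background_correct(m, ann)
        genomic = set(ann.genomic["probe_id"])
        c = c.subset_probes([p for p in c.values.index if p in genomic])
        expr = summarize_transcripts(c, ann)
        pair = ("TCR", "TCR_CD28")
        si = splicing_index(c, expr, ann, presence=presence, conditions=pair)
        kept = set(si.probeset_to_transcript.unique())
        allowed = set(presence.present_in_all(pair))
        assert kept <= allowed


class TestMidas:
    def test_two_group_equals_t_test(self, prepared):
        _, _, _, design, _, _, si = prepared
        pair = ("TCR", "TCR_CD28")
        res = midas_test(si, design, conditions=pair)
        a = si.probeset_si[design.samples_for(pair[0])].to_numpy()
        b = si.probeset_si[design.samples_for(pair[1])].to_numpy()
        t, p_ref = stats.ttest_ind(a, b, axis=1)
        assert np.abs(res["p_value"].to_numpy() - p_ref).max() < 1e-10
        assert np.allclose(res["F"].to_numpy(), t**2, rtol=1e-8)

    def test_degenerate_constant_si(self):
        d = design_2x3()
        si = _make_si(np.zeros((4, 6)), d)
        res = midas_test(si, d)
        assert (res["p_value"] == 1.0).all()
        assert res["degenerate"].all()

    def test_hand_computed_anova(self):
        d = design_2x3()
        vals = np.array([[0.0, 0.1, -0.1, 0.9, 1.0, 1.1]])
        si = _make_si(np.repeat(vals, 2, axis=0), d)
        res = midas_test(si, d)
        # textbook one-way ANOVA by hand:
        ga, gb = [0.0, 0.1, -0.1], [0.9, 1.0, 1.1]
        grand = np.mean(ga + gb)
        ssb = 3 * (np.mean(ga) - grand) ** 2 + 3 * (np.mean(gb) - grand) ** 2
        ssw = sum((x - np.mean(ga)) ** 2 for x in ga) + sum(
            (x - np.mean(gb)) ** 2 for x in gb
        )
        f = (ssb / 1) / (ssw / 4)
        p = stats.f.sf(f, 1, 4)
        assert res["F"].iloc[0] == pytest.approx(f)
        assert res["p_value"].iloc[0] == pytest.approx(p)

    def test_three_group_matches_scipy(self, prepared):
        _, _, _, design, _, _, si = prepared
        res = midas_test(si, design)
        groups = [
            si.probeset_si[design.samples_for(c)].to_numpy()
            for c in design.conditions
        ]
        f_ref, p_ref = stats.f_oneway(*groups, axis=1)
        assert np.allclose(res["p_value"].to_numpy(), p_ref, atol=1e-12)

    def test_single_condition_rejected(self, prepared):
        _, _, _, design, _, _, si = prepared
        with pytest.raises(ConfigError):
            midas_test(si, design, conditions=["TCR"])


def _make_si(values, design):
    from exonsplice.splicing import SplicingIndexMatrix

    n = values.shape[0]
    ps = [f"ps{i}" for i in range(n)]
    return SplicingIndexMatrix(
        probe_si=pd.DataFrame(
            values, index=[f"p{i}" for i in range(n)],
            columns=design.sample_ids,
        ),
        probeset_si=pd.DataFrame(
            values, index=ps, columns=design.sample_ids
        ),
        probe_to_probeset=pd.Series(ps, index=[f"p{i}" for i in range(n)]),
        probeset_to_transcript=pd.Series(
            ["t0"] * n, index=ps
        ),
    )


class TestMads:
    def test_no_shrinkage_equals_ordinary_t(self, prepared):
        _, _, _, design, _, _, si = prepared
        pair = ("TCR", "TCR_CD28")
        res = mads_test(si, design, pair, d0=0.0)
        a = si.probeset_si[design.samples_for(pair[0])].to_numpy()
        b = si.probeset_si[design.samples_for(pair[1])].to_numpy()
        _, p_ref = stats.ttest_ind(b, a, axis=1)
        assert np.abs(res["p_value"].to_numpy() - p_ref).max() < 1e-10

    def test_planted_probeset_significant(self, prepared):
        cfg, _, _, design, truth, _, si = prepared
        pair = cfg.resolved_pair("as_condition_pair")
        res = mads_test(si, design, pair)
        planted_p = res.loc[truth.as_probesets, "p_value"]
        assert (planted_p < 0.01).mean() > 0.9

    def test_probe_level_fisher_variant(self, prepared):
        _, _, _, design, truth, _, si = prepared
        pair = ("TCR", "TCR_CD28")
        res = mads_test(si, design, pair, probe_level=True)
        assert res["p_value"].between(0, 1).all()
        planted_p = res.loc[truth.as_probesets, "p_value"]
        assert (planted_p < 0.01).mean() > 0.9


class TestConsensus:
    def pmaps(self, pairs):
        idx = [f"ps{i}" for i in range(len(pairs))]
        pm = pd.Series([a for a, _ in pairs], index=idx)
        pa = pd.Series([b for _, b in pairs], index=idx)
        ps2tx = pd.Series(["t0"] * len(pairs), index=idx)
        return pm, pa, ps2tx

    def test_conjunction_required(self):
        pm, pa, ps2tx = self.pmaps([(0.005, 0.02)])
        calls = consensus_splicing_calls(pm, pa, ps2tx, alpha=0.01)
        assert calls.called_probesets == []

    def test_both_below_alpha_called(self):
        pm, pa, ps2tx = self.pmaps([(0.005, 0.005)])
        calls = consensus_splicing_calls(pm, pa, ps2tx, alpha=0.01)
        assert calls.called_probesets == ["ps0"]
        assert calls.called_transcripts == ["t0"]

    def test_equals_intersection_of_single_tests(self):
        rng = np.random.default_rng(12)
        pm_v, pa_v = rng.uniform(size=200), rng.uniform(size=200) ** 3
        idx = [f"ps{i}" for i in range(200)]
        pm = pd.Series(pm_v, index=idx)
        pa = pd.Series(pa_v, index=idx)
        ps2tx = pd.Series([f"t{i // 4}" for i in range(200)], index=idx)
        alpha = 0.3
        calls = consensus_splicing_calls(pm, pa, ps2tx, alpha=alpha)
        expected = set(pm.index[pm < alpha]) & set(pa.index[pa < alpha])
        assert set(calls.called_probesets) == expected

    def test_mismatched_universes_listed(self):
        pm, pa, ps2tx = self.pmaps([(0.5, 0.5), (0.5, 0.5)])
        with pytest.raises(IntegrityError, match="ps1"):
            consensus_splicing_calls(pm, pa.iloc[:1], ps2tx)

    def test_transcript_rollup_any_probeset(self, prepared):
        cfg, _, _, design, truth, _, si = prepared
        pair = cfg.resolved_pair("as_condition_pair")
        pm = midas_test(si, design, conditions=pair)["p_value"]
        pa = mads_test(si, design, pair)["p_value"]
        calls = consensus_splicing_calls(
            pm, pa, si.probeset_to_transcript, alpha=0.01
        )
        called_tx_direct = set(
            si.probeset_to_transcript[ps] for ps in calls.called_probesets
        )
        assert set(calls.called_transcripts) == called_tx_direct


def test_midas_null_p_uniform():
    # probeset-level ANOVA p on null data is ~Uniform(0,1)
    from exonsplice.synthetic import simulate_null

    cfg = SimulationConfig(
        n_transcripts=250, exons_per_transcript=(4, 4), seed=77
    )
    m, ann, design, _ = simulate_null(cfg)
    c = background_correct(m, ann)
    genomic = set(ann.genomic["probe_id"])
    c = c.subset_probes([p for p in c.values.index if p in genomic])
    c = apply_probe_effects(c, estimate_probe_effects(c, ann))
    expr = summarize_transcripts(c, ann)
    si = splicing_index(c, expr, ann)
    p = midas_test(si, design, conditions=("TCR", "TCR_CD28"))["p_value"]
    assert len(p) == 1000
    ks = stats.kstest(p, "uniform")
    assert ks.pvalue > 0.01


class TestExpressionInvariance:
    def test_scaling_changes_nothing(self, prepared):
        # the central design property: per-sample transcript-wide scaling
        # is invisible to SI and to both splicing tests
        cfg, c, ann, design, truth, expr, si = prepared
        pair = ("TCR", "TCR_CD28")
        pm1 = midas_test(si, design, conditions=pair)["p_value"]
        pa1 = mads_test(si, design, pair)["p_value"]

        rng = np.random.default_rng(99)
        scaled = c.values.copy()
        for tx in ann.transcript_ids[:30]:
            probes = ann.genomic.loc[
                ann.genomic["transcript_id"] == tx, "probe_id"
            ]
            scaled.loc[probes] *= rng.uniform(0.5, 8.0, size=scaled.shape[1])
        m2 = IntensityMatrix(scaled, is_background_corrected=True)
        expr2 = summarize_transcripts(m2, ann)
        si2 = splicing_index(m2, expr2, ann)
        assert np.allclose(
            si.probe_si.to_numpy(), si2.probe_si.to_numpy(), atol=1e-9
        )
        pm2 = midas_test(si2, design, conditions=pair)["p_value"]
        pa2 = mads_test(si2, design, pair)["p_value"]
        assert np.allclose(pm1, pm2, atol=1e-9)
        assert np.allclose(pa1, pa2, atol=1e-9)
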
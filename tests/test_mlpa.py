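"""MLPA normalization, ratio calling and read-depth concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mircnv import synthetic
from mircnv.config import PipelineConfig
from mircnv.mlpa import MlpaRun, call_mlpa, concordance, normalize_mlpa


def make_run(raw_dict, targets=None):
    raw = pd.DataFrame(raw_dict).T
    probes = [c for c in raw.columns if not c.startswith("ctrl")]
    design = pd.DataFrame({
        "probe": probes + ["ctrl_1", "ctrl_2", "ctrl_3"],
        "target_mir": (targets or [f"mir{i}" for i in range(len(probes))]) + [""] * 3,
        "is_control": [False] * len(probes) + [True] * 3,
    })
    return MlpaRun(raw=raw, probe_design=design)


class TestNormalization:
    def test_probe_equal_to_control_mean_is_one(self):
        run = make_run({"s1": {"p1": 500.0, "ctrl_1": 400.0, "ctrl_2": 500.0,
                               "ctrl_3": 600.0}})
        normalize_mlpa(run, rescale=False)
        assert run.normalized.loc["s1", "p1"] == pytest.approx(1.0)

    def test_rescale_noop_for_identical_samples(self):
        row = {"p1": 800.0, "ctrl_1": 400.0, "ctrl_2": 400.0, "ctrl_3": 400.0}
        run = make_run({"s1": dict(row), "s2": dict(row), "s3": dict(row)})
        plain = normalize_mlpa(make_run({"s1": dict(row), "s2": dict(row),
                                         "s3": dict(row)}), rescale=False)
        rescaled = normalize_mlpa(run, rescale=True)
        assert rescaled.normalized.loc["s1", "p1"] == pytest.approx(
            plain.normalized.loc["s1", "p1"] / 2.0)  # median ratio is 2.0 here
        # with the typical state at ratio 1.0, rescale changes nothing
        run2 = make_run({"s1": {"p1": 400.0, "ctrl_1": 400.0, "ctrl_2": 400.0,
                                "ctrl_3": 400.0},
                         "s2": {"p1": 400.0, "ctrl_1": 400.0, "ctrl_2": 400.0,
                                "ctrl_3": 400.0}})
        normalize_mlpa(run2, rescale=True)
        assert run2.normalized.loc["s1", "p1"] == pytest.approx(1.0)

    def test_zero_control_sample_flagged_invalid(self):
        run = make_run({"bad": {"p1": 100.0, "ctrl_1": 0.0, "ctrl_2": 0.0,
                                "ctrl_3": 0.0},
                        "good": {"p1": 100.0, "ctrl_1": 100.0, "ctrl_2": 100.0,
                                 "ctrl_3": 100.0}})
        normalize_mlpa(run, rescale=False)
        assert run.invalid_samples == ["bad"]
        assert "bad" not in run.normalized.index

    def test_scale_invariance_per_sample(self):
        base = {"p1": 700.0, "p2": 300.0, "ctrl_1": 450.0, "ctrl_2": 500.0,
                "ctrl_3": 550.0}
        run1 = make_run({"s1": dict(base), "s2": dict(base)})
        scaled = {k: 3.7 * v for k, v in base.items()}
        run2 = make_run({"s1": scaled, "s2": dict(base)})
        normalize_mlpa(run1, rescale=False)
        normalize_mlpa(run2, rescale=False)
        pd.testing.assert_frame_equal(run1.normalized, run2.normalized)

    def test_noiseless_ratios_equal_half_copy_number(self, cohort_study):
        """sigma=0: normalized ratios are exactly CN/2."""
        target_regions = _target_map(cohort_study)
        samples = list(cohort_study.mlpa_raw.index)
        raw, design = synthetic.simulate_mlpa(
            cohort_study.cn_truth, target_regions, samples, sigma=0.0, seed=1)
        run = MlpaRun(raw=raw, probe_design=design)
        normalize_mlpa(run, rescale=True)
        for mir, rid in target_regions.items():
            for sample in samples:
                cn = cohort_study.cn_truth.loc[rid, sample]
                ratio = run.normalized.loc[sample, f"probe_{mir}"]
                if cn > 0:
                    assert ratio == pytest.approx(cn / 2.0)

    def test_requires_exactly_three_controls(self):
        raw = pd.DataFrame({"p1": [1.0], "ctrl_1": [1.0]}, index=["s1"])
        design = pd.DataFrame({"probe": ["p1", "ctrl_1"],
                               "target_mir": ["m", ""],
                               "is_control": [False, True]})
        with pytest.raises(ValueError, match="3 control"):
            MlpaRun(raw=raw, probe_design=design)


def _target_map(study):
    design = study.mlpa_design
    targets = design.loc[~design["is_control"], "target_mir"]
    region_by_mir = {m.id: r.region_id for r in study.regions
                     for m in study.mirs if m.id in r.member_mir_ids}
    return {t: region_by_mir[t] for t in targets}


class TestCalling:
    @pytest.mark.parametrize("ratio,expected", [
        (0.49, "deletion"), (0.50, "normal"), (2.00, "normal"),
        (2.01, "duplication"), (1.0, "normal"),
    ])
    def test_threshold_edges(self, ratio, expected):
        run = make_run({"s1": {"p1": 1000.0 * ratio, "ctrl_1": 1000.0,
                               "ctrl_2": 1000.0, "ctrl_3": 1000.0}})
        normalize_mlpa(run, rescale=False)
        calls = call_mlpa(run)
        assert calls.loc[0, "call"] == expected

    def test_dead_probe_is_no_signal_not_deletion(self):
        raw = {f"s{i}": {"p1": 0.0, "p2": 500.0, "ctrl_1": 500.0,
                         "ctrl_2": 500.0, "ctrl_3": 500.0} for i in range(4)}
        run = make_run(raw)
        normalize_mlpa(run)
        calls = call_mlpa(run)
        assert (calls.loc[calls["probe"] == "p1", "call"] == "no_signal").all()

    def test_controls_never_called(self):
        run = make_run({"s1": {"p1": 400.0, "ctrl_1": 500.0, "ctrl_2": 500.0,
                               "ctrl_3": 500.0}})
        normalize_mlpa(run, rescale=False)
        calls = call_mlpa(run)
        assert set(calls["probe"]) == {"p1"}

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(0.05, 5.0, allow_nan=False),  # above the no-signal floor
           st.floats(0, 2.0, allow_nan=False))
    def test_calls_monotone_in_ratio(self, ratio, bump):
        order = {"deletion": 0, "normal": 1, "duplication": 2}

        def call_of(r):
            run = make_run({"s1": {"p1": 1000.0 * r, "ctrl_1": 1000.0,
                                   "ctrl_2": 1000.0, "ctrl_3": 1000.0}})
            normalize_mlpa(run, rescale=False)
            return call_mlpa(run).loc[0, "call"]

        assert order[call_of(ratio + bump)] >= order[call_of(ratio)]


class TestConcordance:
    def test_identical_states_agree_fully(self):
        mlpa_calls = pd.DataFrame({
            "sample": ["s1", "s2"], "probe": ["p1", "p1"],
            "target_mir": ["mirA", "mirA"], "ratio": [0.1, 1.0],
            "call": ["deletion", "normal"],
        })
        geno = pd.DataFrame({
            "region_id": ["r1", "r1"], "accession_id": ["s1", "s2"],
            "cn": [0.0, 2.0], "state": ["loss", "normal"],
        })
        table, rate = concordance(mlpa_calls, geno, {"mirA": "r1"})
        assert rate == 1.0
        assert table.loc["loss", "deletion"] == 1

    def test_one_discordant_of_forty(self):
        samples = [f"s{i}" for i in range(40)]
        mlpa_calls = pd.DataFrame({
            "sample": samples, "probe": ["p1"] * 40,
            "target_mir": ["mirA"] * 40, "ratio": [1.0] * 40,
            "call": ["normal"] * 39 + ["duplication"],
        })
        geno = pd.DataFrame({
            "region_id": ["r1"] * 40, "accession_id": samples,
            "cn": [2.0] * 40, "state": ["normal"] * 40,
        })
        _, rate = concordance(mlpa_calls, geno, {"mirA": "r1"})
        assert rate == pytest.approx(0.975)

    def test_no_shared_accessions_is_an_error(self):
        mlpa_calls = pd.DataFrame({
            "sample": ["x"], "probe": ["p1"], "target_mir": ["mirA"],
            "ratio": [1.0], "call": ["normal"]})
        geno = pd.DataFrame({"region_id": ["r1"], "accession_id": ["y"],
                             "cn": [2.0], "state": ["normal"]})
        with pytest.raises(ValueError):
            concordance(mlpa_calls, geno, {"mirA": "r1"})

    def test_simulated_channels_agree(self, cohort_study, cohort_result):
        """MLPA and read-depth calls from one truth agree >=95%."""
        run = MlpaRun(raw=cohort_study.mlpa_raw,
                      probe_design=cohort_study.mlpa_design.copy())
        normalize_mlpa(run)
        mlpa_calls = call_mlpa(run)
        mir_to_region = _target_map(cohort_study)
        table, rate = concordance(mlpa_calls, cohort_result.calls, mir_to_region)
        assert rate >= 0.95

    def test_noiseless_mlpa_recovers_planted_states_fully(self, cohort_study):
        """sigma=0 panel: every call equals the planted threshold state."""
        target_regions = _target_map(cohort_study)
        samples = list(cohort_study.mlpa_raw.index)
        raw, design = synthetic.simulate_mlpa(
            cohort_study.cn_truth, target_regions, samples, sigma=0.0, seed=1)
        run = MlpaRun(raw=raw, probe_design=design)
        normalize_mlpa(run)
        calls = call_mlpa(run).set_index(["sample", "probe"])["call"]
        config = PipelineConfig()
        for mir, rid in target_regions.items():
            for sample in samples:
                cn = int(cohort_study.cn_truth.loc[rid, sample])
                ratio = cn / 2.0
                if cn == 0:
                    expected = "no_signal"
                elif ratio < config.mlpa_del:
                    expected = "deletion"
                elif ratio > config.mlpa_dup:
                    expected = "duplication"
                else:
                    expected = "normal"
                assert calls[(sample, f"probe_{mir}")] == expected
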
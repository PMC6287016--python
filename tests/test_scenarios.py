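import json

import numpy as np
import pytest

from hpbu.repertoire import Repertoire, train
from hpbu.scenarios import Hierarchy, ScenarioConfig, run_scenario, summarize
from hpbu.synth import CorpusSpec, generate_corpus, save_corpus

from conftest import digit_of_schema


@pytest.fixture(scope="module")
def logs_abcd(repertoire_no4):
    return {sc: run_scenario(ScenarioConfig(scenario=sc, seed=0), repertoire_no4)
            for sc in "abcd"}


class TestConfig:
    def test_scenario_defaults_mirror_study_design(self):
        assert ScenarioConfig(scenario="a").perceived_digit == 5
        assert ScenarioConfig(scenario="b").perceived_digit == 4
        assert ScenarioConfig(scenario="c").produced_digit == 9
        d = ScenarioConfig(scenario="d")
        assert (d.produced_digit, d.feedback_digit) == (1, 3)

    def test_feedback_must_differ_from_production(self):
        with pytest.raises(ValueError):
            ScenarioConfig(scenario="d", produced_digit=3, feedback_digit=3)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(scenario="x")


class TestTraining:
    def test_every_exemplar_becomes_a_sequence(self, repertoire_no4):
        assert len(repertoire_no4.sequences) == 90
        digits = {s.source_digit for s in repertoire_no4.sequences}
        assert digits == set(range(10)) - {4}

    def test_schemas_are_digit_pure(self, repertoire_no4):
        by_id = {s.id: s for s in repertoire_no4.sequences}
        for c in repertoire_no4.schemas:
            assert len({by_id[m].source_digit for m in c.member_sequence_ids}) == 1

    def test_retraining_is_byte_identical(self, tmp_path, model_config):
        corpus = generate_corpus(CorpusSpec(digits=(1, 5), n_per_digit=3, master_seed=2))
        for name in ("a.json", "b.json"):
            train(corpus, model_config).save(tmp_path / name)
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_repertoire_round_trip(self, tmp_path, small_repertoire):
        small_repertoire.save(tmp_path / "rep.json")
        back = Repertoire.load(tmp_path / "rep.json")
        assert [s.id for s in back.sequences] == [s.id for s in small_repertoire.sequences]
        assert back.sequences[0].events == small_repertoire.sequences[0].events
        assert back.config.to_dict() == small_repertoire.config.to_dict()


class TestPerception:
    def test_known_digit_selects_its_schema(self, repertoire_no4, logs_abcd):
        log = logs_abcd["a"]
        assert digit_of_schema(repertoire_no4, log.schema_argmax) == 5

    def test_known_digit_minimizes_free_energy_below_peak(self, logs_abcd):
        fs = logs_abcd["a"].free_energy_sequence
        assert fs[-1] < max(fs)

    def test_unknown_digit_keeps_free_energy_higher(self, logs_abcd):
        assert (
            logs_abcd["b"].terminal_free_energy_sequence
            > logs_abcd["a"].terminal_free_energy_sequence
        )

    def test_unknown_digit_never_concentrates_on_one_sequence(self, logs_abcd):
        posterior = np.asarray(logs_abcd["b"].sequence_posterior)
        assert posterior.max() < 0.5

    def test_perception_emits_no_motor_activity(self, logs_abcd):
        assert logs_abcd["a"].pen == []
        assert logs_abcd["b"].pen == []


class TestProduction:
    def test_congruent_feedback_confirms_strokes(self, logs_abcd):
        log = logs_abcd["c"]
        assert sum(log.event_forwarded) >= 4
        assert len(log.pen) > 50

    def test_incongruent_feedback_confirms_nothing(self, logs_abcd):
        assert sum(logs_abcd["d"].event_forwarded) == 0

    def test_agency_higher_with_congruent_feedback(self, logs_abcd):
        assert logs_abcd["c"].final_soa > logs_abcd["d"].final_soa

    def test_agency_trace_bounded(self, logs_abcd):
        for v in logs_abcd["c"].agency.values:
            assert 0.0 <= v <= 1.0

    def test_intended_sequence_stays_within_intended_schema(
        self, repertoire_no4, logs_abcd
    ):
        log = logs_abcd["c"]
        schema_of = {s.id: s.schema_id for s in repertoire_no4.sequences}
        intended = {s for s in log.intended_sequence if s}
        target = repertoire_no4.schema_of_digit(9)
        assert all(schema_of[s] == target for s in intended)

    def test_round_trip_recovers_produced_digit(self, repertoire_all):
        """Self-consistency: perceiving one's own writing identifies it."""
        log = run_scenario(
            ScenarioConfig(scenario="c", produced_digit=6, seed=0), repertoire_all
        )
        pen = np.asarray(log.pen)
        h = Hierarchy(repertoire_all)
        for t, pos in zip(pen[:, 0], pen[:, 1:3]):
            h.step(float(t), pos)
        h.finish_trial()
        assert digit_of_schema(repertoire_all, h.schema.state.posterior.argmax_label) == 6


class TestLogsAndDeterminism:
    def test_identical_seed_reproduces_trial_log(self, repertoire_no4, logs_abcd):
        again = run_scenario(ScenarioConfig(scenario="d", seed=0), repertoire_no4)
        ref = logs_abcd["d"]
        assert again.to_frame().to_csv(index=False) == ref.to_frame().to_csv(index=False)
        assert np.array_equal(
            np.asarray(again.sequence_posterior), np.asarray(ref.sequence_posterior)
        )

    def test_saved_log_layout(self, tmp_path, logs_abcd):
        out = logs_abcd["c"].save(tmp_path / "c", plots=False)
        assert (out / "trial.csv").exists()
        assert (out / "posteriors.json").exists()
        assert (out / "agency.csv").exists()
        assert (out / "produced.csv").exists()
        meta = json.loads((out / "posteriors.json").read_text())
        assert meta["scenario"] == "c"

    def test_summary_table(self, logs_abcd):
        df = summarize(list(logs_abcd.values()))
        assert len(df) == 4
        row_a = df[df.scenario == "a"].iloc[0]
        assert row_a.final_soa is None or np.isnan(row_a.final_soa)
        row_c = df[df.scenario == "c"].iloc[0]
        assert row_c.final_soa == pytest.approx(logs_abcd["c"].final_soa)
        assert row_c.terminal_free_energy_sequence == pytest.approx(
            logs_abcd["c"].terminal_free_energy_sequence
        )
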
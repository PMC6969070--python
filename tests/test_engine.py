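"""Community cycle: regimes, perturbations, aggregation, I/O."""

from dataclasses import replace

import numpy as np
import pytest
import yaml

import replisim as rs
from replisim.engine import scenario_from_dict, scenario_to_dict

FREQ = rs.TestConfig(framework=rs.FREQUENTIST, sigma_noise=2.0, n=34)
BAYES = rs.TestConfig(framework=rs.BAYESIAN, sigma_noise=1.5, n=34)


def _outcome(evidence, truth=0, cell=(0, 0)):
    return rs.StudyOutcome(
        cell=cell,
        truth=truth,
        t_stat=0.0,
        p_value=1.0,
        bf10=None,
        n_total=34,
        evidence=evidence,
    )


class TestFirstRound:
    def test_runs_hundred_studies(self, rng):
        cfg = rs.ScenarioConfig(test=FREQ, seed=1)
        ls = rs.generate_discovery_landscape(cfg.grid, rng)
        outcomes = rs.run_first_round(cfg, ls, rng)
        assert len(outcomes) == 100
        assert all(o.truth == ls.truth[o.cell] for o in outcomes)

    def test_fraud_declares_everything_significant(self, rng):
        cfg = rs.ScenarioConfig(
            test=FREQ, regime=rs.PUBLIC, perturbation=rs.Perturbation(kind="fraud")
        )
        ls = rs.generate_discovery_landscape(cfg.grid, rng)
        outcomes = rs.run_first_round(cfg, ls, rng)
        assert all(o.evidence == rs.Evidence.SIG_EFFECT for o in outcomes)

    def test_pure_null_world_notable_rate_is_alpha(self, rng):
        """With p_h1 = 0 the notable count is a pure type-I process: ~5."""
        cfg = rs.ScenarioConfig(
            test=FREQ,
            grid=rs.GridSpec(p_h1=0.0),
            perturbation=rs.Perturbation(kind="no_true_effects"),
        )
        counts = []
        for _ in range(500):
            ls = rs.generate_discovery_landscape(cfg.grid, rng)
            outs = rs.run_first_round(cfg, ls, rng)
            counts.append(
                sum(o.evidence == rs.Evidence.SIG_EFFECT for o in outs)
            )
        se = np.sqrt(100 * 0.05 * 0.95 / 500)
        assert abs(np.mean(counts) - 5.0) < 3 * se

    def test_p_hack_uses_inflated_alpha(self, rng):
        base = rs.ScenarioConfig(test=FREQ, grid=rs.GridSpec(p_h1=0.0))
        hack = replace(
            base, perturbation=rs.Perturbation(kind="p_hack", hacked_alpha=0.2)
        )
        notable = {"base": 0, "hack": 0}
        for name, cfg in (("base", base), ("hack", hack)):
            r = np.random.default_rng(99)
            for _ in range(200):
                ls = rs.generate_discovery_landscape(cfg.grid, r)
                outs = rs.run_first_round(cfg, ls, r)
                notable[name] += sum(
                    o.evidence == rs.Evidence.SIG_EFFECT for o in outs
                )
        assert notable["hack"] > 2.5 * notable["base"]


class TestRegimes:
    def test_zero_notables_cost_100(self, rng):
        cfg = rs.ScenarioConfig(test=FREQ)
        outcomes = [_outcome(rs.Evidence.INCONCLUSIVE) for _ in range(100)]
        for apply in (rs.apply_private_regime, rs.apply_public_regime):
            metrics, records = apply(outcomes, cfg, rng)
            assert metrics.total_experiments == 100
            assert metrics.n_replications_run == 0
            assert records == []

    def test_public_cost_never_exceeds_private(self, rng):
        """For the same first-round outcomes, public replications are a
        subset of private ones."""
        cfg = rs.ScenarioConfig(test=FREQ, seed=5)
        ls = rs.generate_discovery_landscape(cfg.grid, rng)
        outcomes = rs.run_first_round(cfg, ls, rng)
        priv, _ = rs.apply_private_regime(outcomes, cfg, rng)
        publ, _ = rs.apply_public_regime(outcomes, cfg, rng)
        assert publ.total_experiments <= priv.total_experiments
        assert priv.total_experiments == 100 + priv.n_notable_first_round

    def test_record_and_metric_invariants(self, rng):
        cfg = rs.ScenarioConfig(test=FREQ, seed=6)
        for regime, apply in (
            (rs.PRIVATE, rs.apply_private_regime),
            (rs.PUBLIC, rs.apply_public_regime),
        ):
            r = np.random.default_rng(8)
            ls = rs.generate_discovery_landscape(cfg.grid, r)
            outcomes = rs.run_first_round(cfg, ls, r)
            metrics, records = apply(outcomes, replace(cfg, regime=regime), r)
            assert metrics.total_experiments == 100 + metrics.n_replications_run
            assert (
                metrics.n_true_interesting
                <= metrics.n_successful_interesting
                <= metrics.n_replications_run
            )
            for rec in records:
                if rec.replication_success:
                    assert rec.replication.evidence == rec.original.evidence
                if rec.counted_true:
                    assert rec.replication_success

    def test_symmetric_null_replicated_regardless_of_interest(self, rng):
        """Convincing Bayesian nulls are notable and must be replicated in
        the private regime even if no one would find them interesting."""
        cfg = rs.ScenarioConfig(
            test=BAYES,
            symmetric_null=True,
            regime=rs.PRIVATE,
            # threshold far above any plausible draw: nothing is interesting
            interest=rs.InterestModel(threshold_percentile=0.999999),
        )
        outcomes = [_outcome(rs.Evidence.SIG_NULL, truth=0) for _ in range(10)]
        outcomes += [_outcome(rs.Evidence.INCONCLUSIVE) for _ in range(90)]
        metrics, records = rs.apply_private_regime(outcomes, cfg, rng)
        assert metrics.n_replications_run == 10
        assert metrics.total_experiments == 110
        # without symmetric_null the same nulls are not notable
        plain = replace(cfg, symmetric_null=False)
        metrics2, _ = rs.apply_private_regime(outcomes, plain, rng)
        assert metrics2.n_replications_run == 0

    def test_double_false_positive_rate_is_alpha_squared(self):
        """A null cell survives first test and private replication at
        ~ alpha^2 = .0025."""
        cfg = rs.ScenarioConfig(test=FREQ, regime=rs.PRIVATE, seed=31)
        rng = np.random.default_rng(31)
        null_studies = 0
        double_hits = 0
        null_notables = 0
        null_published = 0
        for _ in range(400):
            ls = rs.generate_discovery_landscape(cfg.grid, rng)
            outcomes = rs.run_first_round(cfg, ls, rng)
            _, records = rs.apply_private_regime(outcomes, cfg, rng)
            null_studies += sum(o.truth == 0 for o in outcomes)
            for rec in records:
                if rec.original.truth == 0:
                    null_notables += 1
                    null_published += rec.published
                    double_hits += rec.published
        assert null_published / null_notables == pytest.approx(0.05, abs=0.02)
        assert double_hits / null_studies == pytest.approx(0.0025, abs=0.001)

    def test_fraud_public_regime_replication_rate(self):
        """Honest replications of fraudulent null findings succeed at ~alpha."""
        cfg = rs.ScenarioConfig(
            test=FREQ,
            regime=rs.PUBLIC,
            perturbation=rs.Perturbation(kind="fraud"),
            seed=32,
        )
        rng = np.random.default_rng(32)
        replicated = 0
        succeeded = 0
        for _ in range(100):
            metrics, records = rs.run_one_replication(cfg, rng)
            for rec in records:
                if rec.original.truth == 0 and rec.replication is not None:
                    replicated += 1
                    succeeded += rec.replication_success
        assert succeeded / replicated == pytest.approx(0.05, abs=0.02)


class TestRunCondition:
    def test_same_seed_identical_summary(self):
        cfg = rs.ScenarioConfig(test=FREQ, n_replications=20, seed=7)
        a = rs.run_condition(cfg)
        b = rs.run_condition(cfg)
        assert a.metrics == b.metrics
        assert a.per_replication.equals(b.per_replication)

    def test_aggregate_se_definition(self):
        cfg = rs.ScenarioConfig(test=FREQ, n_replications=50, seed=8)
        s = rs.run_condition(cfg)
        col = s.per_replication["total_experiments"]
        assert s.metrics["total_experiments"]["se"] == pytest.approx(
            col.std(ddof=1) / np.sqrt(50)
        )

    def test_single_replication_rerunnable_in_isolation(self):
        cfg = rs.ScenarioConfig(test=FREQ, n_replications=25, seed=9)
        s = rs.run_condition(cfg)
        for i in (0, 13, 24):
            metrics, _ = rs.run_one_replication(cfg, rs.replication_rng(cfg, i))
            row = s.per_replication.iloc[i]
            assert metrics.total_experiments == row["total_experiments"]
            assert metrics.n_true_interesting == row["n_true_interesting"]

    def test_p_hacking_inflates_false_interesting_replications(self):
        """p-hacking yields more interesting replicated effects that are
        not true, relative to the honest baseline."""
        base = rs.ScenarioConfig(
            test=FREQ, regime=rs.PUBLIC, n_replications=400, seed=10
        )
        hacked = replace(
            base, perturbation=rs.Perturbation(kind="p_hack", hacked_alpha=0.2)
        )
        def false_interesting(cfg):
            s = rs.run_condition(cfg)
            return (
                s.mean("n_successful_interesting") - s.mean("n_true_interesting")
            )
        assert false_interesting(hacked) > false_interesting(base)

    def test_validation_rules(self):
        with pytest.raises(ValueError):
            rs.ScenarioConfig(mode=rs.THEORY)  # rho missing
        with pytest.raises(ValueError):
            rs.ScenarioConfig(
                regime=rs.PRIVATE, perturbation=rs.Perturbation(kind="fraud")
            )
        with pytest.raises(ValueError):
            rs.ScenarioConfig(test=FREQ, symmetric_null=True)
        with pytest.raises(ValueError):
            rs.ScenarioConfig(perturbation=rs.Perturbation(kind="no_true_effects"))


class TestEditorialWorkload:
    def test_expected_publication_load(self):
        assert rs.editorial_workload(11.75) == pytest.approx(188.0)

    def test_degenerate_cases(self):
        assert rs.editorial_workload(0.0) == 0.0
        assert rs.editorial_workload(1.0, editor_multiplier=1.0) == 8.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            rs.editorial_workload(-1.0)


class TestIO:
    def test_scenario_yaml_round_trip(self):
        cfg = rs.ScenarioConfig(
            mode=rs.THEORY,
            rho=0.5,
            test=BAYES,
            symmetric_null=True,
            interest=rs.InterestModel(temperature=5.0),
            perturbation=rs.Perturbation(
                kind="optional_stopping",
                stopping=rs.StoppingConfig(batch_size=5),
            ),
            seed=77,
        )
        doc = yaml.safe_load(yaml.safe_dump(scenario_to_dict(cfg)))
        assert scenario_from_dict(doc) == cfg
        assert rs.config_hash(scenario_from_dict(doc)) == rs.config_hash(cfg)

    def test_csv_json_round_trip(self, tmp_path):
        """Re-aggregating the CSV reproduces the JSON summary exactly."""
        import json

        cfg = rs.ScenarioConfig(test=FREQ, n_replications=30, seed=11)
        s = rs.run_condition(cfg)
        csv_path = tmp_path / "run.csv"
        json_path = tmp_path / "run.json"
        rs.write_per_replication_csv(s, csv_path)
        rs.write_summary_json(s, json_path)
        table = rs.read_per_replication_csv(csv_path)
        doc = json.loads(json_path.read_text())
        assert doc["seed"] == 11
        assert doc["config_hash"] == rs.config_hash(cfg)
        for name, agg in doc["metrics"].items():
            assert table[name].mean() == pytest.approx(agg["mean"], rel=1e-12)
            assert table[name].std(ddof=1) / np.sqrt(30) == pytest.approx(
                agg["se"], rel=1e-12
            )
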
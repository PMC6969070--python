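"""Community-level simulation: first round, replication regime, aggregation.

One replication of the community runs a first round of 100 experiments on a
freshly drawn landscape, then applies a replication regime:

* **private** — every notable first-round result is replicated by its own
  investigator before publication; the pair is published only if the
  replication reaches the same evidence category.  Community interest is
  assessed after publication.
* **public** — every notable result is published immediately; the community
  draws an interest decision for each, and only interesting findings are
  replicated (by other, honest labs).

Cost is the total number of experiments (first round + replications);
knowledge is the number of interesting, successfully replicated findings
whose evidence matches the ground truth.  Conditions repeat the cycle for
1000 independent community replications and report means with Monte-Carlo
standard errors.

Perturbations of the idealized community: p-hacking (inflated alpha),
optional stopping (batched retesting), fraud (all first-round results
declared significant; public regime only, replications honest), and a
world with no true effects (p_h1 = 0).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .landscape import (
    DISCOVERY,
    THEORY,
    GridSpec,
    Landscape,
    TheoryQuality,
    generate_discovery_landscape,
    generate_theory_landscape,
    place_theory_window,
    sample_target_cells,
)
from .interest import InterestDraw, InterestModel, draw_interests
from .stattests import (
    BAYESIAN,
    Evidence,
    JZSCalibration,
    StoppingConfig,
    StudyOutcome,
    TestConfig,
)

PRIVATE = "private"
PUBLIC = "public"

PERTURBATION_KINDS = ("none", "p_hack", "optional_stopping", "fraud", "no_true_effects")


@dataclass(frozen=True)
class Perturbation:
    """Departure from the idealized community, if any."""

    kind: str = "none"
    hacked_alpha: float = 0.2
    stopping: Optional[StoppingConfig] = None
    stopping_in_replications: bool = False

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation {self.kind!r}")
        if self.kind == "p_hack" and not 0.0 < self.hacked_alpha < 1.0:
            raise ValueError("hacked_alpha must lie in (0, 1)")
        if self.kind == "optional_stopping" and self.stopping is None:
            object.__setattr__(self, "stopping", StoppingConfig())


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to run one condition reproducibly."""

    mode: str = DISCOVERY
    rho: Optional[float] = None
    grid: GridSpec = field(default_factory=GridSpec)
    test: TestConfig = field(default_factory=TestConfig)
    interest: InterestModel = field(default_factory=InterestModel)
    regime: str = PUBLIC
    n_first_round: int = 100
    n_replications: int = 1000
    symmetric_null: bool = False
    perturbation: Perturbation = field(default_factory=Perturbation)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (DISCOVERY, THEORY):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.regime not in (PRIVATE, PUBLIC):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.mode == THEORY and self.rho is None:
            raise ValueError("theory mode requires rho")
        if self.perturbation.kind == "fraud" and self.regime != PUBLIC:
            raise ValueError("fraud is only simulated under the public regime")
        if self.symmetric_null and self.test.framework != BAYESIAN:
            raise ValueError("symmetric_null requires the Bayesian framework")
        if self.perturbation.kind == "no_true_effects" and self.grid.p_h1 != 0.0:
            raise ValueError("no_true_effects requires p_h1 = 0")
        if self.n_first_round < 1 or self.n_replications < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class RegimeRecord:
    """Trace of one notable finding through its regime."""

    original: StudyOutcome
    interest: Optional[InterestDraw]
    replication: Optional[StudyOutcome]
    published: bool
    replication_success: bool
    counted_true: bool


@dataclass(frozen=True)
class RunMetrics:
    """Cost and knowledge counts for one community replication."""

    total_experiments: int
    n_notable_first_round: int
    n_published: int
    n_replications_run: int
    n_successful_interesting: int
    n_true_interesting: int
    total_participants: int


@dataclass(frozen=True)
class AggregateSummary:
    """Across-replication mean/SD/SE per metric, plus the raw table."""

    scenario: dict
    n_replications: int
    metrics: dict
    per_replication: pd.DataFrame

    def mean(self, name: str) -> float:
        return self.metrics[name]["mean"]

    def se(self, name: str) -> float:
        return self.metrics[name]["se"]


# ---------------------------------------------------------------------------
# study batches (vectorized hot path)
# ---------------------------------------------------------------------------


def _simulate_batch(
    mus: np.ndarray,
    config: TestConfig,
    alpha: float,
    stopping: Optional[StoppingConfig],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray], np.ndarray, np.ndarray]:
    """Run len(mus) studies at once; returns (t, p, bf, n_total, evidence)."""
    from scipy import stats as _st

    m = mus.size
    n = config.n
    sigma = config.sigma_noise
    calib = JZSCalibration.for_config(config) if config.framework == BAYESIAN else None

    x = rng.normal(mus[:, None], sigma, size=(m, n))
    s = x.sum(axis=1)
    ss = (x * x).sum(axis=1)
    counts = np.full(m, n)

    def t_from_sums() -> np.ndarray:
        mean = s / counts
        var = (ss - s * s / counts) / (counts - 1)
        return mean / np.sqrt(var / counts)

    def labels(t: np.ndarray, p: np.ndarray) -> np.ndarray:
        if calib is not None:
            return calib.classify(t)
        out = np.full(m, Evidence.INCONCLUSIVE, dtype=object)
        out[p < alpha] = Evidence.SIG_EFFECT
        return out

    t = t_from_sums()
    p = 2.0 * _st.t.sf(np.abs(t), counts - 1)
    ev = labels(t, p)

    if stopping is not None:
        for _ in range(stopping.max_batches):
            active = ev != Evidence.SIG_EFFECT
            if not active.any():
                break
            k = int(active.sum())
            extra = rng.normal(
                mus[active, None], sigma, size=(k, stopping.batch_size)
            )
            s[active] += extra.sum(axis=1)
            ss[active] += (extra * extra).sum(axis=1)
            counts[active] += stopping.batch_size
            t = t_from_sums()
            p = 2.0 * _st.t.sf(np.abs(t), counts - 1)
            ev = labels(t, p)

    bf = calib.bf10(t) if calib is not None else None
    return t, p, bf, counts, ev


def _make_outcomes(
    rows: np.ndarray,
    cols: np.ndarray,
    mus: np.ndarray,
    t: np.ndarray,
    p: np.ndarray,
    bf: Optional[np.ndarray],
    counts: np.ndarray,
    ev: np.ndarray,
) -> List[StudyOutcome]:
    return [
        StudyOutcome(
            cell=(int(rows[i]), int(cols[i])),
            truth=int(mus[i] != 0),
            t_stat=float(t[i]),
            p_value=float(p[i]),
            bf10=float(bf[i]) if bf is not None else None,
            n_total=int(counts[i]),
            evidence=ev[i],
        )
        for i in range(mus.size)
    ]


def run_first_round(
    config: ScenarioConfig, landscape: Landscape, rng: np.random.Generator
) -> List[StudyOutcome]:
    """First round of n_first_round experiments at random target cells."""
    pert = config.perturbation
    rows, cols = sample_target_cells(landscape, config.n_first_round, rng)
    mus = landscape.truth[rows, cols].astype(float)
    alpha = pert.hacked_alpha if pert.kind == "p_hack" else config.test.alpha
    stopping = pert.stopping if pert.kind == "optional_stopping" else None
    t, p, bf, counts, ev = _simulate_batch(mus, config.test, alpha, stopping, rng)
    if pert.kind == "fraud":
        ev = np.full(mus.size, Evidence.SIG_EFFECT, dtype=object)
    return _make_outcomes(rows, cols, mus, t, p, bf, counts, ev)


def _is_notable(outcome: StudyOutcome, config: ScenarioConfig) -> bool:
    if outcome.evidence == Evidence.SIG_EFFECT:
        return True
    return config.symmetric_null and outcome.evidence == Evidence.SIG_NULL


def _truth_matches(evidence: Evidence, truth: int) -> bool:
    return (evidence == Evidence.SIG_EFFECT and truth == 1) or (
        evidence == Evidence.SIG_NULL and truth == 0
    )


def _replicate(
    originals: Sequence[StudyOutcome],
    config: ScenarioConfig,
    rng: np.random.Generator,
    honest: bool,
) -> List[StudyOutcome]:
    """Replication studies at the original cells, same design and test.

    ``honest`` replications (the public community's) always use the nominal
    alpha and no optional stopping; a dishonest investigator's own private
    replications inherit the p-hacked alpha and, if configured, stopping.
    """
    if not originals:
        return []
    pert = config.perturbation
    rows = np.array([o.cell[0] for o in originals])
    cols = np.array([o.cell[1] for o in originals])
    mus = np.array([float(o.truth) for o in originals])
    alpha = config.test.alpha
    stopping = None
    if not honest:
        if pert.kind == "p_hack":
            alpha = pert.hacked_alpha
        if pert.kind == "optional_stopping" and pert.stopping_in_replications:
            stopping = pert.stopping
    t, p, bf, counts, ev = _simulate_batch(mus, config.test, alpha, stopping, rng)
    return _make_outcomes(rows, cols, mus, t, p, bf, counts, ev)


def _interest_draws(
    model: InterestModel, size: int, rng: np.random.Generator
) -> List[InterestDraw]:
    n_k, p, flags = draw_interests(model, size, rng)
    return [
        InterestDraw(float(n_k[i]), float(p[i]), bool(flags[i])) for i in range(size)
    ]


def _metrics(
    config: ScenarioConfig,
    outcomes: Sequence[StudyOutcome],
    records: Sequence[RegimeRecord],
) -> RunMetrics:
    n_reps_run = sum(r.replication is not None for r in records)
    participants = sum(o.n_total for o in outcomes) + sum(
        r.replication.n_total for r in records if r.replication is not None
    )
    return RunMetrics(
        total_experiments=config.n_first_round + n_reps_run,
        n_notable_first_round=len(records),
        n_published=sum(r.published for r in records),
        n_replications_run=n_reps_run,
        n_successful_interesting=sum(
            r.replication_success and r.interest is not None and r.interest.interesting
            for r in records
        ),
        n_true_interesting=sum(r.counted_true for r in records),
        total_participants=participants,
    )


def apply_private_regime(
    outcomes: Sequence[StudyOutcome],
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> Tuple[RunMetrics, List[RegimeRecord]]:
    """Investigators replicate every notable result before publication.

    A finding is published only if its replication lands in the same
    evidence category; the community's interest draw then applies to the
    published findings.  Cost: 100 + number of notables.
    """
    notables = [o for o in outcomes if _is_notable(o, config)]
    reps = _replicate(notables, config, rng, honest=False)
    published = [r.evidence == o.evidence for o, r in zip(notables, reps)]
    pub_draws = iter(_interest_draws(config.interest, sum(published), rng))
    records = []
    for orig, rep, pub in zip(notables, reps, published):
        draw = next(pub_draws) if pub else None
        interesting = draw is not None and draw.interesting
        records.append(
            RegimeRecord(
                original=orig,
                interest=draw,
                replication=rep,
                published=pub,
                replication_success=pub,
                counted_true=pub
                and interesting
                and _truth_matches(orig.evidence, orig.truth),
            )
        )
    return _metrics(config, outcomes, records), records


def apply_public_regime(
    outcomes: Sequence[StudyOutcome],
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> Tuple[RunMetrics, List[RegimeRecord]]:
    """Notable results are published at once; the community replicates the
    interesting ones.

    Every notable finding is published and receives an interest draw;
    interesting findings are replicated once by honest community labs.
    Cost: 100 + number of interesting notables.
    """
    notables = [o for o in outcomes if _is_notable(o, config)]
    draws = _interest_draws(config.interest, len(notables), rng)
    chosen = [o for o, d in zip(notables, draws) if d.interesting]
    reps = iter(_replicate(chosen, config, rng, honest=True))
    records = []
    for orig, draw in zip(notables, draws):
        rep = next(reps) if draw.interesting else None
        success = rep is not None and rep.evidence == orig.evidence
        records.append(
            RegimeRecord(
                original=orig,
                interest=draw,
                replication=rep,
                published=True,
                replication_success=success,
                counted_true=success and _truth_matches(orig.evidence, orig.truth),
            )
        )
    return _metrics(config, outcomes, records), records


# ---------------------------------------------------------------------------
# condition loop and aggregation
# ---------------------------------------------------------------------------


def _draw_landscape(config: ScenarioConfig, rng: np.random.Generator) -> Landscape:
    if config.mode == DISCOVERY:
        return generate_discovery_landscape(config.grid, rng)
    ls = generate_theory_landscape(config.grid, rng)
    return place_theory_window(ls, TheoryQuality(config.rho), rng)


def run_one_replication(
    config: ScenarioConfig, rng: np.random.Generator
) -> Tuple[RunMetrics, List[RegimeRecord]]:
    """One full community cycle on a freshly drawn landscape."""
    ls = _draw_landscape(config, rng)
    outcomes = run_first_round(config, ls, rng)
    apply = apply_private_regime if config.regime == PRIVATE else apply_public_regime
    return apply(outcomes, config, rng)


def replication_rng(config: ScenarioConfig, index: int) -> np.random.Generator:
    """The RNG used for replication ``index`` — re-runnable in isolation."""
    child = np.random.SeedSequence(config.seed).spawn(config.n_replications)[index]
    return np.random.default_rng(child)


def run_condition(config: ScenarioConfig) -> AggregateSummary:
    """Run n_replications independent community cycles and aggregate.

    Each replication gets its own RNG substream spawned from the scenario
    seed, so the whole condition is reproducible and any single replication
    can be re-run in isolation via :func:`replication_rng`.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_replications)
    rows = []
    for child in children:
        metrics, _ = run_one_replication(config, np.random.default_rng(child))
        rows.append(asdict(metrics))
    table = pd.DataFrame(rows)
    table.insert(0, "replication", np.arange(config.n_replications))
    summary = {
        name: {
            "mean": float(table[name].mean()),
            "sd": float(table[name].std(ddof=1)) if len(table) > 1 else 0.0,
            "se": (
                float(table[name].std(ddof=1) / np.sqrt(len(table)))
                if len(table) > 1
                else 0.0
            ),
        }
        for name in table.columns
        if name != "replication"
    }
    return AggregateSummary(
        scenario=scenario_to_dict(config),
        n_replications=config.n_replications,
        metrics=summary,
        per_replication=table,
    )


def editorial_workload(
    expected_publications: float,
    reviews_per_ms: float = 1.6,
    hours_per_review: float = 5.0,
    editor_multiplier: float = 2.0,
) -> float:
    """Editorial hours implied by the extra publications of the public regime.

    Each manuscript attracts 1.6 reviews of 5 h each; doubling covers the
    editor's time, so 11.75 publications imply 16 x 11.75 = 188 h.
    """
    if min(expected_publications, reviews_per_ms, hours_per_review) < 0:
        raise ValueError("inputs must be nonnegative")
    if editor_multiplier < 0:
        raise ValueError("inputs must be nonnegative")
    return expected_publications * reviews_per_ms * hours_per_review * editor_multiplier


# ---------------------------------------------------------------------------
# config and result I/O
# ---------------------------------------------------------------------------


def scenario_to_dict(config: ScenarioConfig) -> dict:
    doc = asdict(config)
    if config.perturbation.stopping is None:
        doc["perturbation"].pop("stopping")
    return doc


def scenario_from_dict(doc: dict) -> ScenarioConfig:
    doc = dict(doc)
    if "grid" in doc:
        doc["grid"] = GridSpec(**doc["grid"])
    if "test" in doc:
        doc["test"] = TestConfig(**doc["test"])
    if "interest" in doc:
        doc["interest"] = InterestModel(**doc["interest"])
    if "perturbation" in doc:
        pert = dict(doc["perturbation"])
        if pert.get("stopping") is not None:
            pert["stopping"] = StoppingConfig(**pert["stopping"])
        doc["perturbation"] = Perturbation(**pert)
    return ScenarioConfig(**doc)


def config_hash(config: ScenarioConfig) -> str:
    blob = json.dumps(scenario_to_dict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_per_replication_csv(summary: AggregateSummary, path) -> None:
    """One row per replication; seed and config hash in a comment header."""
    config = scenario_from_dict(summary.scenario)
    with open(path, "w") as fh:
        fh.write(f"# seed={config.seed} config_hash={config_hash(config)}\n")
        summary.per_replication.to_csv(fh, index=False)


def read_per_replication_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_summary_json(summary: AggregateSummary, path) -> None:
    config = scenario_from_dict(summary.scenario)
    doc = {
        "scenario": summary.scenario,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "n_replications": summary.n_replications,
        "metrics": summary.metrics,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
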
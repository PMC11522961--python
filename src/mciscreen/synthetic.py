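"""Synthetic two-class screening cohorts.

No public neuropsychological screening cohort ships with this package, so
every pipeline stage is exercised on generated data with the structure such
cohorts have: a battery of bounded test scores whose class means differ
(healthy vs MCI), correlated through a single latent cognitive factor,
with sociodemographics (age 58-93, education 0-22 years, coded sex), and a
missingness mechanism that includes fully score-less records — subjects who
enrolled but refused or never reached the testing stage, carrying only
identifier, evaluation number and sex.

The default battery is illustrative, not a reproduction of any published
battery: eight common test types with plausible ranges and a standardized
healthy-vs-MCI mean shift of 1.2 SD per test.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .schema import BatterySchema, SubjectRecord, TestDefinition, write_cases, dump_schema

__all__ = [
    "SyntheticTest",
    "CohortConfig",
    "default_battery",
    "generate_cohort",
    "inject_missingness",
    "write_cohort",
]

#: Standardized class shift (in SD units) of the default battery.
DEFAULT_EFFECT_SIZE = 1.2


@dataclass(frozen=True)
class SyntheticTest:
    """Generating distribution of one test, per class."""

    test_id: str
    value_min: float
    value_max: float
    healthy_mean: float
    mci_mean: float
    sd: float
    higher_is_better: bool = True
    column_name: str | None = None
    property_name: str | None = None
    var_name: str | None = None

    def __post_init__(self) -> None:
        for label, mean in (("healthy", self.healthy_mean), ("mci", self.mci_mean)):
            if not self.value_min <= mean <= self.value_max:
                raise ValueError(
                    f"test {self.test_id!r}: {label} mean {mean} outside range "
                    f"[{self.value_min}, {self.value_max}]"
                )
        if self.sd <= 0:
            raise ValueError(f"test {self.test_id!r}: sd must be positive")

    def to_definition(self) -> TestDefinition:
        return TestDefinition(
            test_id=self.test_id,
            column_name=self.column_name or self.test_id,
            property_name=self.property_name or f"has_{self.test_id}_score",
            value_min=self.value_min,
            value_max=self.value_max,
            higher_is_better=self.higher_is_better,
            var_name=self.var_name,
        )


def default_battery(effect_size: float = DEFAULT_EFFECT_SIZE) -> tuple[SyntheticTest, ...]:
    """Eight-test illustrative battery; MCI means shifted ``effect_size`` SDs
    in the impaired direction (downward for most tests, upward for the timed
    trail-making test where slower is worse)."""

    def t(test_id, lo, hi, healthy, sd, higher_is_better=True, **kw):
        shift = effect_size * sd * (-1.0 if higher_is_better else 1.0)
        return SyntheticTest(
            test_id=test_id,
            value_min=lo,
            value_max=hi,
            healthy_mean=healthy,
            mci_mean=healthy + shift,
            sd=sd,
            higher_is_better=higher_is_better,
            **kw,
        )

    return (
        t("mmse", 0, 35, 31.0, 2.5),
        t("semantic_fluency", 0, 40, 18.0, 4.5),
        t("rey_figure_copy", 0, 36, 28.0, 5.0),
        t("tmt_a", 10, 300, 55.0, 20.0, higher_is_better=False),
        t("digit_span", 0, 16, 9.0, 2.0),
        t("word_list_recall", 0, 10, 6.5, 1.8),
        t("clock_drawing", 0, 10, 8.0, 1.5),
        t("boston_naming", 0, 60, 48.0, 6.0),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults describe the reference study conditions
    (n = 600, 40% MCI prevalence, 1.2 SD per-test shift, mild correlation)."""

    n_subjects: int = 600
    prevalence: float = 0.4
    tests: tuple[SyntheticTest, ...] = field(default_factory=default_battery)
    correlation: float = 0.3
    missing_rate: float = 0.0
    empty_record_fraction: float = 0.0
    seed: int = 0
    integer_scores: bool = True
    battery_id: str = "synthetic_battery"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation loading must lie in [0, 1)")
        for rate in (self.missing_rate, self.empty_record_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("missingness rates must lie in [0, 1]")
        if not self.tests:
            raise ValueError("config declares no tests")


def _schema_from_config(config: CohortConfig) -> BatterySchema:
    return BatterySchema(
        battery_id=config.battery_id,
        tests=tuple(t.to_definition() for t in config.tests),
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[BatterySchema, list[SubjectRecord], list[int]]:
    """Draw a labeled cohort; deterministic given ``config.seed``.

    Scores follow a one-factor Gaussian model per class: a latent cognitive
    factor z ~ N(0,1) loads on every test (sign-flipped for tests where
    higher means worse), the rest is independent noise, and values are
    truncated to each test's range (and rounded when ``integer_scores``).
    Exactly ``round(prevalence * n)`` records carry the MCI label.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    n_mci = int(round(config.prevalence * n))
    labels = np.array([1] * n_mci + [0] * (n - n_mci), dtype=int)
    labels = labels[rng.permutation(n)]

    loading = config.correlation
    noise_scale = float(np.sqrt(1.0 - loading**2))
    z = rng.standard_normal(n)

    ages = rng.integers(58, 94, n)
    education = rng.integers(0, 23, n)
    sexes = rng.integers(0, 2, n)

    records: list[SubjectRecord] = []
    score_matrix: dict[str, np.ndarray] = {}
    for t in config.tests:
        direction = 1.0 if t.higher_is_better else -1.0
        means = np.where(labels == 1, t.mci_mean, t.healthy_mean)
        eps = rng.standard_normal(n)
        values = means + t.sd * (loading * direction * z + noise_scale * eps)
        values = np.clip(values, t.value_min, t.value_max)
        if config.integer_scores:
            values = np.round(values)
        score_matrix[t.test_id] = values

    for i in range(n):
        records.append(
            SubjectRecord(
                subject_id=f"S{i:04d}",
                evaluation_index=1,
                sex=str(int(sexes[i])),
                age=float(ages[i]),
                education=float(education[i]),
                scores={t.test_id: float(score_matrix[t.test_id][i]) for t in config.tests},
                gold_label=int(labels[i]),
                battery_id=config.battery_id,
            )
        )
    schema = _schema_from_config(config)
    if config.missing_rate > 0 or config.empty_record_fraction > 0:
        records = inject_missingness(
            records,
            config.missing_rate,
            config.empty_record_fraction,
            seed=config.seed + 1,
        )
    return schema, records, [int(v) for v in labels]


def inject_missingness(
    records: Sequence[SubjectRecord],
    missing_rate: float,
    empty_record_fraction: float = 0.0,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Remove scores completely at random; additionally empty a fixed
    fraction of records entirely (demographics are always retained).

    Returns new records; the inputs are never mutated.
    """
    for rate in (missing_rate, empty_record_fraction):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = [copy.deepcopy(r) for r in records]
    n_empty = int(round(empty_record_fraction * len(out)))
    empty_idx = set(
        rng.choice(len(out), size=n_empty, replace=False).tolist()
    ) if n_empty else set()
    for i, r in enumerate(out):
        if i in empty_idx:
            r.scores = {}
            continue
        if missing_rate > 0:
            r.scores = {
                k: v for k, v in r.scores.items() if rng.random() >= missing_rate
            }
    return out


def write_cohort(
    schema: BatterySchema,
    records: Sequence[SubjectRecord],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write schema + cases (+ gold labels inline) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "schema": out_dir / "schema.csv",
        "cases": out_dir / "cases.csv",
    }
    dump_schema(schema, paths["schema"])
    write_cases(records, schema, paths["cases"])
    return paths
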
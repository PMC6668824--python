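"""Synthetic cohorts with a latent three-cluster metacognitive structure.

The generator emulates the statistical structure the downstream analysis
is designed to detect: a cohort of younger and older adults in which the
older adults split into two latent subgroups with *opposite* metacognitive
profiles, while recognition performance itself is uninformative about age.

* Cluster 1 is the young-typical profile: average on everything except an
  elevated item-test fatigue rating.
* Cluster 2 ("confident" older adults) sits above average on postdictions,
  perceived strategy success, postdiction accuracy and associate
  self-efficacy, and below average on associate difficulty.
* Cluster 3 ("doubting" older adults) mirrors Cluster 2 on those scales
  and reports high associate difficulty.

Both older clusters sit below the young cluster on item-test fatigue.

Each raw variable is drawn as ``base_mean + base_sd * (cluster_offset +
Normal(0, residual_sd))`` and clipped to its legal range; draws are
independent across variables given the cluster.  Ground-truth cluster
labels accompany every cohort so that parameter-recovery tests can score
the full pipeline against the generating partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from metamem.datamodel import (
    CANONICAL_COLUMNS,
    MEASURE_RANGES,
    STIMULUS_CONDITIONS,
    ParticipantRecord,
)

__all__ = [
    "DEFAULT_BASE_STATS",
    "OFFSET_COLUMNS",
    "SyntheticConfig",
    "SyntheticCohort",
    "default_effect_pattern",
    "generate",
]

#: Per-column (mean, SD) on the raw scale.  Grand values: the per-test-type
#: young/old summary means and SDs of the study cohort averaged over the two
#: age groups, since only group-level summaries are available.
DEFAULT_BASE_STATS: dict[str, tuple[float, float]] = {
    "recognition_item": (0.510, 0.270),
    "mseq_item": (43.995, 20.780),
    "postdiction_item": (57.690, 20.385),
    "postdiction_accuracy_item": (-0.180, 0.170),
    "strategy_item": (51.160, 24.595),
    "difficulty_item": (3.610, 1.050),
    "effort_item": (3.850, 0.855),
    "fatigue_item": (2.335, 1.110),
    "stamina_item": (1.275, 0.580),
    "recognition_assoc": (0.465, 0.335),
    "mseq_assoc": (54.030, 20.700),
    "postdiction_assoc": (54.200, 24.700),
    "postdiction_accuracy_assoc": (-0.190, 0.200),
    "strategy_assoc": (49.445, 26.765),
    "difficulty_assoc": (3.775, 1.120),
    "effort_assoc": (4.020, 0.835),
    "stamina_assoc": (1.360, 0.725),
    "fatigue_assoc": (2.405, 1.175),
}

#: The nine columns that carry cluster offsets under the default pattern —
#: exactly the variables the cluster ANOVAs are expected to flag.
OFFSET_COLUMNS: tuple[str, ...] = (
    "postdiction_item",
    "postdiction_accuracy_item",
    "strategy_item",
    "fatigue_item",
    "mseq_assoc",
    "postdiction_assoc",
    "postdiction_accuracy_assoc",
    "strategy_assoc",
    "difficulty_assoc",
)


def default_effect_pattern(magnitude: float = 0.9) -> np.ndarray:
    """The 3 x 18 matrix of cluster offsets, in z units of the base SD.

    Rows are clusters 1-3, columns the canonical 18 variables.  Both
    recognition-score columns are zero in every cluster: the clusters
    differ metacognitively, not in performance.  ``magnitude`` scales the
    whole pattern; zero gives the null (no-structure) model.
    """
    pattern = np.zeros((3, len(CANONICAL_COLUMNS)))
    col = {name: j for j, name in enumerate(CANONICAL_COLUMNS)}

    mirrored = (
        "postdiction_item",
        "postdiction_accuracy_item",
        "strategy_item",
        "mseq_assoc",
        "postdiction_assoc",
        "postdiction_accuracy_assoc",
        "strategy_assoc",
    )
    for name in mirrored:
        pattern[1, col[name]] = magnitude   # cluster 2: confident profile
        pattern[2, col[name]] = -magnitude  # cluster 3: the mirror image
    # cluster 3 alone finds the pair task hard; clusters 1 and 2 do not
    pattern[1, col["difficulty_assoc"]] = -magnitude
    pattern[2, col["difficulty_assoc"]] = magnitude
    # Item fatigue: the young cluster is elevated, both older clusters low.
    # The half-magnitude split gives a young-old separation of one
    # `magnitude` (0.9 z by default), the size of the only significant
    # univariate age difference in the study cohort (d = 0.82).
    pattern[0, col["fatigue_item"]] = magnitude / 2.0
    pattern[1, col["fatigue_item"]] = -magnitude / 2.0
    pattern[2, col["fatigue_item"]] = -magnitude / 2.0
    return pattern


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating conditions for a synthetic cohort.

    Defaults reproduce the study cohort's composition: 57 young and 49
    older adults; the older adults split into latent subgroups of 12
    (cluster 2) and 36 (cluster 3) with the remaining 1 older adult
    carrying the young-typical profile, and 1 younger adult carrying the
    cluster-2 profile (the crossovers that make the separation strong but
    imperfect).
    """

    n_young: int = 57
    n_old: int = 49
    old_cluster_sizes: tuple[int, int] = (12, 36)
    crossover_young_into_cluster2: int = 1
    effect_pattern: np.ndarray | None = None
    base_stats: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASE_STATS)
    )
    residual_sd: float = 1.0
    seed: int = 0

    def resolved_pattern(self) -> np.ndarray:
        if self.effect_pattern is None:
            return default_effect_pattern()
        pattern = np.asarray(self.effect_pattern, dtype=float)
        if pattern.shape != (3, len(CANONICAL_COLUMNS)):
            raise ValueError(
                f"effect_pattern must be 3 x {len(CANONICAL_COLUMNS)}, got {pattern.shape}"
            )
        return pattern

    def validate(self) -> None:
        if self.n_young < 1 or self.n_old < 1:
            raise ValueError("group sizes must be positive")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        n2, n3 = self.old_cluster_sizes
        if n2 < 0 or n3 < 0 or n2 + n3 > self.n_old:
            raise ValueError(
                f"old cluster sizes {self.old_cluster_sizes} inconsistent with n_old = {self.n_old}"
            )
        if not (0 <= self.crossover_young_into_cluster2 <= self.n_young):
            raise ValueError("crossover count outside [0, n_young]")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.base_stats]
        if missing:
            raise ValueError(f"base_stats missing column(s) {missing}")
        self.resolved_pattern()


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated records plus the latent truth used to create them."""

    records: tuple[ParticipantRecord, ...]
    truth_labels: np.ndarray  # latent cluster in {1, 2, 3}, aligned with records
    config: SyntheticConfig
    n_clipped: int  # draws that hit a scale boundary and were clipped

    @property
    def n(self) -> int:
        return len(self.records)


def generate(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Draw one cohort under ``config`` (``seed`` overrides ``config.seed``).

    Latent clusters are assigned within each age group (shuffled by the
    seeded generator so cluster is not a function of participant index),
    stimulus condition is assigned uniformly at random and carried as
    metadata, and every variable is drawn independently given the cluster
    and clipped to its legal range.
    """
    if config is None:
        config = SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)
    pattern = config.resolved_pattern()

    n2, n3 = config.old_cluster_sizes
    n_old_c1 = config.n_old - n2 - n3  # older adults with the young-typical profile
    old_labels = np.array([2] * n2 + [3] * n3 + [1] * n_old_c1)
    rng.shuffle(old_labels)
    k = config.crossover_young_into_cluster2
    young_labels = np.array([2] * k + [1] * (config.n_young - k))
    rng.shuffle(young_labels)

    ids = [f"Y{i + 1:03d}" for i in range(config.n_young)] + [
        f"O{i + 1:03d}" for i in range(config.n_old)
    ]
    groups = ["young"] * config.n_young + ["old"] * config.n_old
    labels = np.concatenate([young_labels, old_labels])
    conditions = rng.choice(STIMULUS_CONDITIONS, size=len(ids))

    records = []
    n_clipped = 0
    for pid, group, cond, cluster in zip(ids, groups, conditions, labels):
        measures = {}
        for j, column in enumerate(CANONICAL_COLUMNS):
            mean, sd = config.base_stats[column]
            z = pattern[cluster - 1, j] + rng.normal(0.0, config.residual_sd)
            value = mean + sd * z
            lo, hi = MEASURE_RANGES[column.rpartition("_")[0]]
            clipped = min(max(value, lo), hi)
            if clipped != value:
                n_clipped += 1
            measures[column] = round(clipped, 6)
        records.append(
            ParticipantRecord(
                id=pid, age_group=group, stimulus_condition=str(cond), measures=measures
            )
        )
    return SyntheticCohort(
        records=tuple(records),
        truth_labels=labels.copy(),
        config=config,
        n_clipped=n_clipped,
    )
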
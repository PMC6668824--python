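"""End-to-end orchestration of the analysis.

``run_replication`` executes the full sequence on one cohort — z-score
the 18 measures, train the age classifier, probe hidden activations,
k-means cluster, profile the clusters and run their per-variable ANOVAs,
evaluate by LOOCV with item/associate ablation, and compute the classical
univariate statistics — and returns a single report, optionally
persisting every intermediate artifact (model JSON, hidden-activation and
cluster CSVs, statistics tables) to an output directory.

All randomness funnels through the global seed, which fans out
deterministically to per-stage seeds (synthetic data, training,
clustering, cross-validation), so changing the clustering seed cannot
perturb the trained model.  ``run_robustness`` repeats the train-probe-
cluster core across reinitializations and hidden-layer sizes and reports
how often the qualitative three-cluster structure recurs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from metamem import clustering as cl
from metamem import evaluation as ev
from metamem import univariate as uv
from metamem.datamodel import (
    CANONICAL_COLUMNS,
    FeatureMatrix,
    ParticipantRecord,
    age_targets,
    cohort_to_frame,
    feature_matrix,
    read_cohort,
    write_cohort,
    zscore_normalize,
)
from metamem.perceptron import (
    NetworkParams,
    TrainingConfig,
    hidden_activations,
    train,
)
from metamem.synthetic import SyntheticConfig, generate

__all__ = ["PipelineConfig", "RunReport", "stage_seeds", "run_replication", "run_robustness"]

_STAGES = ("synthetic", "training", "clustering", "loocv")


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Fan a global seed out into independent per-stage seeds (< 2^31)."""
    state = np.random.SeedSequence(global_seed).generate_state(len(_STAGES))
    return {stage: int(s % (2**31)) for stage, s in zip(_STAGES, state)}


@dataclass(frozen=True)
class PipelineConfig:
    """One replication run: data source, training, clustering, evaluation.

    Exactly one of ``data_path`` (a cohort CSV) or ``synthetic`` (a
    generator configuration) must be given.
    """

    seed: int = 0
    data_path: str | None = None
    column_map: dict | None = None
    layout: str = "wide"
    synthetic: SyntheticConfig | None = None
    training: TrainingConfig = field(default_factory=TrainingConfig)
    hidden_units: int = 2
    k: int = 3
    restarts: int = 50
    correction: str = "half_count"
    run_loocv: bool = True
    run_ablation: bool = True
    outdir: str | None = None

    def validate(self) -> None:
        if (self.data_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of data_path / synthetic must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a run configuration from a YAML file.

        Recognized top-level keys: ``seed``, ``data`` (``path``, ``layout``,
        ``column_map``), ``synthetic`` (SyntheticConfig fields), ``training``
        (TrainingConfig fields), ``hidden_units``, ``k``, ``restarts``,
        ``correction``, ``run_loocv``, ``run_ablation``, ``outdir``.
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {
            key: raw[key]
            for key in (
                "seed", "hidden_units", "k", "restarts", "correction",
                "run_loocv", "run_ablation", "outdir",
            )
            if key in raw
        }
        if "data" in raw:
            data = raw["data"]
            kwargs["data_path"] = data["path"]
            kwargs["layout"] = data.get("layout", "wide")
            kwargs["column_map"] = data.get("column_map")
        if "synthetic" in raw:
            syn = dict(raw["synthetic"])
            if "old_cluster_sizes" in syn:
                syn["old_cluster_sizes"] = tuple(syn["old_cluster_sizes"])
            if "effect_pattern" in syn and syn["effect_pattern"] is not None:
                syn["effect_pattern"] = np.asarray(syn["effect_pattern"], dtype=float)
            kwargs["synthetic"] = SyntheticConfig(**syn)
        if "training" in raw:
            kwargs["training"] = TrainingConfig(**raw["training"])
        return cls(**kwargs)


@dataclass
class RunReport:
    """Everything a replication run computes, JSON-serializable."""

    seed: int
    stage_seeds: dict[str, int]
    n: int
    n_young: int
    n_old: int
    resubstitution_accuracy: float
    training_epochs: int
    training_final_error: float
    composition: dict[int, dict[str, int]] | None = None
    significant_variables: list[str] = field(default_factory=list)
    anova_eta_squared: dict[str, float] = field(default_factory=dict)
    loocv_dprime: float | None = None
    loocv_accuracy: float | None = None
    dprime_item: float | None = None
    dprime_associate: float | None = None
    dprime_difference: float | None = None
    stimulus_F: float | None = None
    stimulus_partial_eta_squared: float | None = None
    truth_ari: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_records(config: PipelineConfig, seeds: dict[str, int]):
    if config.data_path is not None:
        return list(read_cohort(config.data_path, config.column_map, config.layout)), None
    cohort = generate(replace(config.synthetic, seed=seeds["synthetic"]))
    return list(cohort.records), cohort


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions must label the same items")
    n = a.size
    cats_a, inv_a = np.unique(a, return_inverse=True)
    cats_b, inv_b = np.unique(b, return_inverse=True)
    table = np.zeros((cats_a.size, cats_b.size), dtype=np.int64)
    np.add.at(table, (inv_a, inv_b), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def run_replication(config: PipelineConfig) -> RunReport:
    """Execute every analysis stage on one cohort and return the report."""
    config.validate()
    seeds = stage_seeds(config.seed)
    records, cohort = _load_records(config, seeds)

    targets = age_targets(records)
    raw = feature_matrix(records)
    features_z = zscore_normalize(raw)

    train_config = replace(config.training, seed=seeds["training"])
    params, history = train(features_z, targets, train_config, h=config.hidden_units)
    accuracy = ev.resubstitution_accuracy(params, features_z, targets)
    hidden = hidden_activations(params, features_z)

    solution = cl.kmeans(
        hidden, k=config.k, restarts=config.restarts, seed=seeds["clustering"]
    )
    if config.k == 3:
        solution = cl.canonicalize_clusters(solution, targets, features_z)
    composition = cl.composition_table(solution.assignments, targets)
    profiles = cl.cluster_profiles(features_z, solution.assignments)
    cluster_sizes = np.bincount(solution.assignments)[1:]
    if np.all(cluster_sizes >= 2):
        anova_rows = cl.cluster_feature_anovas(features_z, solution.assignments)
    else:
        anova_rows = []  # a singleton cluster leaves the per-variable ANOVAs undefined

    report = RunReport(
        seed=config.seed,
        stage_seeds=seeds,
        n=len(records),
        n_young=int(np.sum(targets < 0)),
        n_old=int(np.sum(targets > 0)),
        resubstitution_accuracy=accuracy,
        training_epochs=history.final_epoch + 1,
        training_final_error=float(history.errors[-1]),
        composition={
            int(lab): {"young": int(row["young"]), "old": int(row["old"])}
            for lab, row in composition.iterrows()
        },
        significant_variables=[r.variable for r in anova_rows if r.significant],
        anova_eta_squared={
            r.variable: r.partial_eta_squared for r in anova_rows if r.significant
        },
    )
    if cohort is not None:
        report.truth_ari = adjusted_rand_index(cohort.truth_labels, solution.assignments)

    loocv_config = replace(config.training, seed=seeds["loocv"])
    loocv_all = None
    ablation = None
    if config.run_loocv:
        loocv_all = ev.loocv(
            raw, targets, loocv_config, subset="all",
            h=config.hidden_units, correction=config.correction,
        )
        report.loocv_dprime = loocv_all.dprime_result.dprime
        report.loocv_accuracy = loocv_all.accuracy
    if config.run_ablation:
        ablation = ev.ablation_compare(
            raw, targets, loocv_config, h=config.hidden_units,
            correction=config.correction,
        )
        report.dprime_item = ablation.dprime_item
        report.dprime_associate = ablation.dprime_associate
        report.dprime_difference = ablation.difference

    item = raw.values[:, list(CANONICAL_COLUMNS).index("recognition_item")]
    assoc = raw.values[:, list(CANONICAL_COLUMNS).index("recognition_assoc")]
    stimulus = np.array([r.stimulus_condition for r in records])
    anova = uv.mixed_anova(np.column_stack([item, assoc]), targets, stimulus)
    report.stimulus_F = float(anova.loc["Stimulus", "F"])
    report.stimulus_partial_eta_squared = float(
        anova.loc["Stimulus", "partial_eta_squared"]
    )

    if config.outdir is not None:
        _persist(
            config, records, params, history, hidden, solution, composition,
            profiles, anova_rows, anova, loocv_all, ablation, report,
        )
    return report


def _persist(
    config, records, params, history, hidden, solution, composition, profiles,
    anova_rows, mixed_table, loocv_all, ablation, report,
) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort(records, outdir / "cohort.csv")
    with open(outdir / "model.json", "w") as fh:
        json.dump(
            {
                "params": params.to_dict(),
                "final_error": float(history.errors[-1]),
                "epochs": history.final_epoch + 1,
                "converged": history.converged,
                "error_tail": history.errors[-10:].tolist(),
            },
            fh,
            indent=2,
        )
    ids = [r.id for r in records]
    pd.DataFrame(
        hidden, index=pd.Index(ids, name="id"),
        columns=[f"hidden_{j + 1}" for j in range(hidden.shape[1])],
    ).to_csv(outdir / "hidden_activations.csv")
    pd.DataFrame(
        {"id": ids, "cluster": solution.assignments}
    ).to_csv(outdir / "cluster_assignments.csv", index=False)
    composition.to_csv(outdir / "cluster_composition.csv")
    profiles.to_csv(outdir / "cluster_profiles.csv")
    cl.anova_rows_to_frame(anova_rows).to_csv(outdir / "cluster_anovas.csv")
    mixed_table.to_csv(outdir / "mixed_anova.csv")
    if loocv_all is not None or ablation is not None:
        payload = {}
        for name, res in (
            ("all", loocv_all),
            ("item", None if ablation is None else ablation.item),
            ("associate", None if ablation is None else ablation.associate),
        ):
            if res is None:
                continue
            payload[name] = {
                "dprime": res.dprime_result.dprime,
                "accuracy": res.accuracy,
                "hits": res.dprime_result.hits,
                "misses": res.dprime_result.misses,
                "false_alarms": res.dprime_result.false_alarms,
                "correct_rejections": res.dprime_result.correct_rejections,
                "predictions": {
                    i: int(p) for i, p in zip(res.row_ids, res.predictions)
                },
            }
        with open(outdir / "loocv.json", "w") as fh:
            json.dump(payload, fh, indent=2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def _qualitative_pattern(composition: pd.DataFrame) -> bool:
    """Three clusters; one majority-young, two majority-old (a 2-vs-1 split)."""
    if composition.shape[0] != 3:
        return False
    young_major = (composition["young"] > composition["old"]).sum()
    old_major = (composition["old"] > composition["young"]).sum()
    return young_major == 1 and old_major == 2


def run_robustness(
    config: PipelineConfig,
    runs: int = 20,
    hidden_variants: tuple[int, ...] = (2,),
) -> dict:
    """Repeat the train-probe-cluster core across fresh seeds and architectures.

    Each run regenerates the cohort (when synthetic), retrains from a new
    initialization and reclusters; the summary reports, per hidden-layer
    size, the fraction of runs reproducing the qualitative pattern of one
    predominantly-young cluster and two predominantly-old clusters.
    """
    if runs < 1:
        raise ValueError("runs must be at least 1")
    config.validate()
    summary: dict = {"runs": runs, "variants": {}}
    for h in hidden_variants:
        per_run = []
        for r in range(runs):
            run_config = replace(
                config,
                seed=int((config.seed + 1_000_003 * r) % (2**31)),
                hidden_units=h,
                run_loocv=False,
                run_ablation=False,
                outdir=None,
            )
            report = run_replication(run_config)
            comp = pd.DataFrame(
                {
                    "young": {lab: c["young"] for lab, c in report.composition.items()},
                    "old": {lab: c["old"] for lab, c in report.composition.items()},
                }
            )
            per_run.append(
                {
                    "seed": run_config.seed,
                    "composition": report.composition,
                    "resubstitution_accuracy": report.resubstitution_accuracy,
                    "significant_variables": report.significant_variables,
                    "pattern": _qualitative_pattern(comp),
                }
            )
        summary["variants"][h] = {
            "per_run": per_run,
            "pattern_fraction": float(np.mean([r["pattern"] for r in per_run])),
        }
    return summary
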
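"""The three classification studies on simulated data, plus a seed battery.

* detection — binary bruised/sound models; one run holding out half of the
  L1 rows, one holding out half of the L2 rows, and an overall run holding
  out half of the 1 h L1-L3 rows together with the same fraction of sound
  rows.
* temporal — bruised/sound models restricted to the latent levels L1/L2;
  for each scan time the corresponding rows are split in half, training uses
  all non-excluded rows across 1-72 h, testing the held-out half at that
  time.
* quantitative — the 31-class severity problem (class = level x hours, plus
  sound); tested on the held-out halves of the low-severity classes at 1, 6
  and 18 h, per time block and globally.

Every split is a pure function of (manifest, seed).  One structured log line
per stage goes to the module logger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classification import (FAMILIES, ClassifierSpec, EvaluationReport,
                             evaluate, normalize_speeds, prediction_speed,
                             train)
from .dataset import SpectraTable, assemble_dataset
from .simulate import SimulationConfig, full_manifest

logger = logging.getLogger("brulat")


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared knobs of the three studies."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    families: tuple[str, ...] = FAMILIES
    holdout_fraction: float = 0.5
    n_folds: int = 10
    sound_total: int = 287
    n_per_batch: int = 6
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown classifier families: {sorted(unknown)}")


def build_table(config: ExperimentConfig) -> SpectraTable:
    """Simulate the complete-grid manifest and extract all ROI spectra."""
    manifest = full_manifest(base_seed=config.seed,
                             n_per_batch=config.n_per_batch)
    table = assemble_dataset(manifest, sound_total=config.sound_total,
                             config=config.simulation)
    logger.info("built table: %d rows (%d bruised, %d sound), seed=%d",
                len(table), int((table.labels("status") == "bruised").sum()),
                int((table.labels("status") == "sound").sum()), config.seed)
    return table


def _stratified_half(cells: np.ndarray, eligible: np.ndarray,
                     fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean holdout mask: ``fraction`` of each cell among eligible rows."""
    held = np.zeros(len(cells), dtype=bool)
    for cell in np.unique(cells[eligible]):
        idx = np.flatnonzero(eligible & (cells == cell))
        take = int(round(fraction * len(idx)))
        held[rng.choice(idx, size=take, replace=False)] = True
    return held


def _fit_and_report(families, X_train, y_train, X_test, y_test, n_folds,
                    seed, positive_class=None,
                    measure_speed: bool = False) -> dict[str, EvaluationReport]:
    reports = {}
    for family in families:
        spec = ClassifierSpec(family, seed=seed)
        model, cv_acc = train(spec, X_train, y_train, n_folds=n_folds)
        report = evaluate(model, X_test, y_test,
                          positive_class=positive_class, cv_accuracy=cv_acc)
        if measure_speed:
            report.prediction_speed = prediction_speed(model, X_test)
        reports[family] = report
        logger.info("family=%s cv=%.1f test=%.1f (n_train=%d n_test=%d)",
                    family, cv_acc, report.test_accuracy, len(y_train),
                    len(y_test))
    if measure_speed:
        norm = normalize_speeds([reports[f].prediction_speed for f in families])
        for family, v in zip(families, norm):
            reports[family].normalized_speed = v
    return reports


def run_detection(config: ExperimentConfig,
                  table: SpectraTable | None = None,
                  measure_speed: bool = False) -> dict:
    """Latent-bruise detection: targets detect-L1, detect-L2, overall."""
    table = table if table is not None else build_table(config)
    X = table.X
    status = table.labels("status")
    level = table.labels("level")
    hours = table.labels("hours").astype(int)
    cells = table.labels("class_code")
    for target_level in ("L1", "L2"):
        if not np.any(level == target_level):
            raise ValueError(f"dataset has no rows at target level {target_level}")

    results = {}
    for target_id, target in enumerate(("detect-L1", "detect-L2", "overall")):
        rng = np.random.default_rng((config.seed * 613 + 97 * target_id + 11)
                                    % (2 ** 31))
        if target == "overall":
            eligible = ((np.isin(level, ["L1", "L2", "L3"]) & (hours == 1))
                        | (status == "sound"))
        else:
            eligible = level == target.split("-")[1]
        held = _stratified_half(cells, eligible, config.holdout_fraction, rng)
        results[target] = _fit_and_report(
            config.families, X[~held], status[~held], X[held], status[held],
            config.n_folds, config.seed, positive_class="bruised",
            measure_speed=measure_speed)
        logger.info("detection target=%s: held out %d rows", target,
                    int(held.sum()))
    return results


def run_temporal(config: ExperimentConfig,
                 table: SpectraTable | None = None,
                 test_hours=(1, 6, 18, 48),
                 measure_speed: bool = True) -> dict:
    """Influence of time since impact on detecting L1/L2 bruises."""
    table = table if table is not None else build_table(config)
    keep = np.isin(table.labels("level"), ["L1", "L2", "none"])
    X = table.X[keep]
    status = table.labels("status")[keep]
    hours = table.labels("hours").astype(int)[keep]
    cells = table.labels("class_code")[keep]
    for h in test_hours:
        if not np.any((status == "bruised") & (hours == h)):
            raise ValueError(f"dataset has no bruised rows at {h} h")

    results = {}
    for h in test_hours:
        rng = np.random.default_rng((config.seed * 769 + 13 * h) % (2 ** 31))
        eligible = hours == h
        held = _stratified_half(cells, eligible, config.holdout_fraction, rng)
        results[h] = _fit_and_report(
            config.families, X[~held], status[~held], X[held], status[held],
            config.n_folds, config.seed, positive_class="bruised",
            measure_speed=measure_speed)
        logger.info("temporal h=%d: held out %d rows", h, int(held.sum()))
    return results


def run_quantitative(config: ExperimentConfig,
                     table: SpectraTable | None = None,
                     reduced_groups: dict[str, str] | None = None) -> dict:
    """Severity classification over level-x-hours classes plus sound.

    ``reduced_groups`` optionally maps every class code to a coarser group
    label (must cover all observed classes) before training.  Returns
    per-block reports for the held-out low-severity classes at 1, 6 and 18 h
    and their union ("global").
    """
    table = table if table is not None else build_table(config)
    X = table.X
    labels = table.labels("class_code")
    if reduced_groups is not None:
        missing = set(np.unique(labels)) - set(reduced_groups)
        if missing:
            raise ValueError("grouping map does not cover classes: "
                             f"{sorted(missing)}")
        labels = np.array([reduced_groups[c] for c in labels])

    cells = table.labels("class_code")  # holdout stratified on raw classes
    block_cells = {
        "L11-L31": ["L11", "L21", "L31"],
        "L16-L36": ["L16", "L26", "L36"],
        "L118-L318": ["L118", "L218", "L318"],
    }
    rng = np.random.default_rng((config.seed * 881 + 3) % (2 ** 31))
    eligible = np.isin(cells, sorted({c for v in block_cells.values() for c in v}))
    held = _stratified_half(cells, eligible, config.holdout_fraction, rng)
    logger.info("quantitative: %d classes, held out %d rows",
                len(np.unique(labels)), int(held.sum()))

    trained = {}
    for family in config.families:
        spec = ClassifierSpec(family, seed=config.seed)
        model, cv_acc = train(spec, X[~held], labels[~held],
                              n_folds=config.n_folds)
        trained[family] = (model, cv_acc)

    results: dict = {"classes": np.unique(labels).tolist(), "blocks": {}}
    blocks = dict(block_cells)
    blocks["global"] = sorted({c for v in block_cells.values() for c in v})
    for block, members in blocks.items():
        mask = held & np.isin(cells, members)
        results["blocks"][block] = {
            family: evaluate(model, X[mask], labels[mask], cv_accuracy=cv_acc)
            for family, (model, cv_acc) in trained.items()
        }
    return results


# --------------------------------------------------------------------------
# Seed battery: averaged behaviour across replicate simulations
# --------------------------------------------------------------------------

def run_battery(seeds, config: ExperimentConfig | None = None) -> dict:
    """Run all three studies once per seed and average the headline numbers.

    Returns per-family mean test accuracies for each detection target, each
    temporal instance, and the global quantitative block, plus the per-seed
    values.
    """
    base = config or ExperimentConfig()
    per_seed = []
    for seed in seeds:
        cfg = ExperimentConfig(
            simulation=base.simulation, families=base.families,
            holdout_fraction=base.holdout_fraction, n_folds=base.n_folds,
            sound_total=base.sound_total, n_per_batch=base.n_per_batch,
            seed=int(seed))
        table = build_table(cfg)
        detection = run_detection(cfg, table)
        temporal = run_temporal(cfg, table, measure_speed=False)
        quantitative = run_quantitative(cfg, table)
        per_seed.append({
            "seed": int(seed),
            "detection": {t: {f: r.test_accuracy for f, r in reps.items()}
                          for t, reps in detection.items()},
            "temporal": {h: {f: r.test_accuracy for f, r in reps.items()}
                         for h, reps in temporal.items()},
            "temporal_bruised_fnr": {
                h: {f: _bruised_fnr(r) for f, r in reps.items()}
                for h, reps in temporal.items()},
            "quantitative": {f: r.test_accuracy
                             for f, r in quantitative["blocks"]["global"].items()},
        })

    def _mean(path_fn):
        return float(np.mean([path_fn(s) for s in per_seed]))

    families = base.families
    summary = {
        "detection_mean": {t: {f: _mean(lambda s: s["detection"][t][f])
                               for f in families}
                           for t in ("detect-L1", "detect-L2", "overall")},
        "temporal_mean": {h: {f: _mean(lambda s: s["temporal"][h][f])
                              for f in families}
                          for h in (1, 6, 18, 48)},
        "quantitative_mean": {f: _mean(lambda s: s["quantitative"][f])
                              for f in families},
        "per_seed": per_seed,
    }
    return summary


def _bruised_fnr(report: EvaluationReport) -> float:
    idx = int(np.flatnonzero(report.classes == "bruised")[0])
    v = report.fnr_per_class[idx]
    return float(v) if not np.isnan(v) else 0.0
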
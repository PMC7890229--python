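"""End-to-end seeded pipeline: simulate, screen, train, classify, evaluate.

Used by the ``all`` CLI subcommand and by tests. The qualifying sample
is split half/half into training and held-out sets, stratified by true
category, with a permutation derived from the run seed; filters are
trained on the training half and evaluated on both halves. All outputs
are deterministic functions of (config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import io as dio
from .broad_search import apply_broad_search
from .errors import DataValidationError
from .estimator import DLDPhenotyper
from .metrics import evaluate
from .model import PatientRecord
from .simulate import SimulationConfig, generate_cohort

__all__ = ["stratified_split", "run_all"]


def stratified_split(
    records: List[PatientRecord],
    labels: Dict[str, int],
    seed: int,
) -> Tuple[List[PatientRecord], List[PatientRecord]]:
    """Deterministic half/half split, stratified by category."""
    rng = np.random.default_rng([seed, 1])
    train_ids = set()
    for category in (1, 2, 3, 4):
        ids = sorted(rid for rid, cat in labels.items() if cat == category)
        perm = rng.permutation(len(ids))
        take = (len(ids) + 1) // 2
        train_ids.update(ids[int(i)] for i in perm[:take])
    train = [r for r in records if r.record_id in train_ids]
    test = [r for r in records if r.record_id not in train_ids]
    return train, test


def run_all(
    seed: int,
    out_dir,
    config: Optional[SimulationConfig] = None,
) -> dict:
    """Run the whole pipeline into ``out_dir`` and return the report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SimulationConfig(seed=seed)
    elif config.seed != seed:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})

    records, labels, truth = generate_cohort(config)
    dio.write_events(records, out / "events.csv")
    dio.write_labels(labels, out / "labels.csv")
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")

    result = apply_broad_search(records)
    dio.write_events(result.sample, out / "sample.csv")
    rejects = [
        {"record_id": rid, "reason": reason.value}
        for rid, reason in result.rejections.items()
    ]
    import pandas as pd

    pd.DataFrame(rejects, columns=["record_id", "reason"]).to_csv(
        out / "rejects.csv", index=False
    )

    sample_labels = {r.record_id: labels[r.record_id] for r in result.sample}
    if set(sample_labels) != set(labels):
        raise DataValidationError(
            "broad search and generator ground truth disagree on the sample"
        )
    train, test = stratified_split(result.sample, sample_labels, seed)

    clf = DLDPhenotyper().fit(train, [sample_labels[r.record_id] for r in train])
    dio.write_filters(clf.filters_, out / "filters.json")

    test_results = clf.predict_details(test)
    dio.write_classifications(test_results, out / "classified.csv")

    holdout_report = evaluate(
        {r.record_id: r.category for r in test_results},
        {r.record_id: sample_labels[r.record_id] for r in test},
    )
    train_results = clf.predict_details(train)
    training_report = evaluate(
        {r.record_id: r.category for r in train_results},
        {r.record_id: sample_labels[r.record_id] for r in train},
    )

    report = {
        "seed": int(seed),
        "counts": {
            "generated": len(records),
            "sampled": len(result.sample),
            "rejected": len(result.rejections),
            "train": len(train),
            "holdout": len(test),
        },
        "training": training_report.to_dict(),
        "holdout": holdout_report.to_dict(),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
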
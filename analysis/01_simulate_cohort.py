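#!/usr/bin/env python
"""Simulate the study cohort.

Generates the default synthetic cohort — 9 patients (seven with 3 fMRI
scans, two with 4) plus 9 matched untreated controls — with daily 1-7
process ratings, injected order transitions preceded by critical
fluctuations, and the ground truth of when each transition happened.
Writes ratings.csv, scans.csv, scales.yaml, roi_panel.csv and truth.json
under results/cohort/.
"""

import json
from pathlib import Path

import pandas as pd
import yaml

from ordertrans import (
    DetectionConfig,
    RoiEffect,
    SimulationDesign,
    complexity_series,
    detect_transitions,
    label_intervals,
    mean_complexity,
    simulate_cohort,
    simulate_roi_panel,
    write_ratings,
)

SEED = 42
OUT = Path("results/cohort")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = SimulationDesign(seed=SEED)
    bundle = simulate_cohort(design)

    write_ratings(bundle.ratings, OUT / "ratings.csv")
    pd.DataFrame(
        [(sid, s.group, d)
         for sid, s in sorted(bundle.schedules.items()) for d in s.scan_days],
        columns=["subject", "group", "scan_day"],
    ).to_csv(OUT / "scans.csv", index=False)
    sc = design.scale
    items = next(iter(bundle.ratings.values())).items
    (OUT / "scales.yaml").write_text(yaml.safe_dump(
        {it: {"min": sc.min_value, "max": sc.max_value, "discrete": sc.discrete}
         for it in items}
    ))

    # panel consistent with the detected transition structure
    transitions = {
        sid: detect_transitions(
            mean_complexity(cm := complexity_series(series)), cm.day_index,
            DetectionConfig(), subject_id=sid,
        )
        for sid, series in bundle.ratings.items()
    }
    labels = {
        sid: label_intervals(sched, transitions.get(sid))
        for sid, sched in bundle.schedules.items()
    }
    panel = simulate_roi_panel(bundle.schedules, labels, RoiEffect(), seed=SEED)
    panel.to_frame().to_csv(OUT / "roi_panel.csv", index=False)
    (OUT / "truth.json").write_text(json.dumps(bundle.truth.to_dict(), indent=2))

    n_days = [bundle.ratings[s].n_days for s in sorted(bundle.ratings)]
    print(f"cohort written to {OUT}/")
    print(f"  patients: {design.n_patients}, controls: {design.n_controls}")
    print(f"  daily ratings per patient: {min(n_days)}-{max(n_days)} days")
    print(f"  true transitions: "
          f"{sum(len(v) for v in bundle.truth.transition_days.values())}")


if __name__ == "__main__":
    main()
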
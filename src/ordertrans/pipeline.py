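"""End-to-end study driver: simulate or load → complexity → transition
detection → interval labelling → ROI change contrasts → report bundle.

The pipeline is pure composition: every number in the emitted report can be
reproduced by calling the underlying module functions on the intermediate
CSVs, and a fixed seed makes the whole bundle byte-identical across runs
(timestamps live only in provenance.json).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .complexity import DEFAULT_WINDOW, complexity_series, mean_complexity
from .detection import DetectionConfig, TransitionSet, detect_transitions, label_intervals
from .roi import RoiPanel, compare_intercorrelation, interscan_changes, mean_intercorrelation
from .simulate import RoiEffect, SimulationDesign, simulate_cohort, simulate_roi_panel
from .stats import contrast_report
from .timeseries import RatingScale, load_ratings, load_scales, load_schedules

__all__ = ["RunConfig", "run_study"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"  # CSVs at 6 significant digits; JSON keeps full precision


@dataclass
class RunConfig:
    """Configuration for one study run.

    Exactly one of ``design`` (simulate a cohort) or ``inputs`` (paths to
    ratings/scales/scans/panel CSVs) must be supplied.
    """

    out_dir: str | Path = "results/run"
    design: SimulationDesign | None = None
    roi_effect: RoiEffect = field(default_factory=RoiEffect)
    inputs: dict[str, str] | None = None  # ratings, scales, scans, panel
    window_width: int = DEFAULT_WINDOW
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    seed: int = 0
    make_figures: bool = True

    def __post_init__(self) -> None:
        if (self.design is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of a simulation design or input paths must be given"
            )


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, RatingScale):
        return {"min": o.min_value, "max": o.max_value, "discrete": o.discrete}
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_study(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Returns a dict with the in-memory results (complexity matrices,
    transitions, labels, change table, contrast report, intercorrelation
    summary) keyed by stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if config.design is not None:
            design = config.design
            bundle = simulate_cohort(design)
            ratings, schedules = bundle.ratings, bundle.schedules
            _write_json(out / "truth.json", bundle.truth.to_dict())
        else:
            paths = config.inputs
            scales = load_scales(paths["scales"])
            ratings = load_ratings(paths["ratings"], scales)
            schedules = load_schedules(paths["scans"])

        stage = "complexity"
        matrices = {
            sid: complexity_series(s, config.window_width)
            for sid, s in ratings.items()
        }
        comp_rows, mean_rows = [], []
        for sid, cm in sorted(matrices.items()):
            curve = mean_complexity(cm)
            for i, day in enumerate(cm.day_index):
                for j, item in enumerate(cm.items):
                    if not np.isnan(cm.values[i, j]):
                        comp_rows.append((sid, int(day), item, cm.values[i, j]))
                if not np.isnan(curve[i]):
                    mean_rows.append((sid, int(day), curve[i]))
        pd.DataFrame(comp_rows, columns=["subject", "day", "item", "C"]).to_csv(
            out / "complexity.csv", index=False, float_format=_FLOAT_FMT
        )
        pd.DataFrame(mean_rows, columns=["subject", "day", "mean_C"]).to_csv(
            out / "mean_complexity.csv", index=False, float_format=_FLOAT_FMT
        )

        stage = "detect"
        transitions: dict[str, TransitionSet] = {}
        for sid, cm in sorted(matrices.items()):
            transitions[sid] = detect_transitions(
                mean_complexity(cm), cm.day_index, config.detection, subject_id=sid
            )
        pd.DataFrame(
            [
                (sid, d, v)
                for sid, ts in sorted(transitions.items())
                for d, v in ts.transitions
            ],
            columns=["subject", "day", "peak_mean_C"],
        ).to_csv(out / "transitions.csv", index=False, float_format=_FLOAT_FMT)

        stage = "label"
        labels = {
            sid: label_intervals(sched, transitions.get(sid))
            for sid, sched in sorted(schedules.items())
        }
        pd.DataFrame(
            [
                (l.subject_id, l.interval, l.label,
                 "" if l.transition_day is None else l.transition_day)
                for labs in labels.values()
                for l in labs
            ],
            columns=["subject", "interval", "label", "transition_day"],
        ).to_csv(out / "labels.csv", index=False)

        stage = "roi_panel"
        if config.design is not None:
            panel = simulate_roi_panel(
                schedules, labels, config.roi_effect, seed=config.seed
            )
        else:
            panel = RoiPanel.from_frame(pd.read_csv(config.inputs["panel"]))
        panel.to_frame().to_csv(out / "roi_panel.csv", index=False,
                                float_format=_FLOAT_FMT)

        stage = "contrast"
        changes = interscan_changes(panel, labels)
        changes.to_csv(out / "change_table.csv", index=False,
                       float_format=_FLOAT_FMT)
        report = contrast_report(changes)
        report.to_csv(out / "contrast_report.csv", index=False,
                      float_format=_FLOAT_FMT)
        _write_json(out / "contrast_report.json",
                    report.to_dict(orient="records"))

        stage = "intercorrelation"
        patients = [s for s in panel.subjects if panel.groups[s] == "patient"]
        inter = _intercorrelation_summary(panel, patients, labels)
        _write_json(out / "intercorrelation.json", inter)

        if config.make_figures:
            stage = "figures"
            _figures(out, matrices, transitions, changes)

        stage = "provenance"
        _write_json(out / "provenance.json", _provenance(config))
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {err}"
        ) from err

    return {
        "matrices": matrices,
        "transitions": transitions,
        "labels": labels,
        "panel": panel,
        "change_table": changes,
        "contrast_report": report,
        "intercorrelation": inter,
    }


def _intercorrelation_summary(panel, patients, labels) -> dict:
    """First-vs-last-scan and pre-vs-post-transition mean inter-ROI
    correlations over patients, each with the paired comparison (df = 27
    for 8 ROIs)."""
    mean_first, sd_first, pairs_first = mean_intercorrelation(
        panel, "first", subjects=patients
    )
    mean_last, sd_last, pairs_last = mean_intercorrelation(
        panel, "last", subjects=patients
    )
    cmp_fl = compare_intercorrelation(pairs_first, pairs_last)
    out = {
        "first_scan": {"mean_r": mean_first, "sd_r": sd_first},
        "last_scan": {"mean_r": mean_last, "sd_r": sd_last},
        "first_vs_last": {
            "t": cmp_fl.statistic, "df": cmp_fl.df, "p": cmp_fl.p,
        },
    }
    # pre/post the first order transition, over patients that have one
    pre_rows, post_rows = [], []
    for sid in patients:
        ot = [l for l in labels[sid] if l.label == "OT"]
        if not ot:
            continue
        k = ot[0].interval
        pre_rows.append(panel.counts[sid][k - 1])
        post_rows.append(panel.counts[sid][k])
    if len(pre_rows) >= 3:
        pre = _pairwise_mean(np.asarray(pre_rows))
        post = _pairwise_mean(np.asarray(post_rows))
        out["pre_transition"] = {"mean_r": pre[0], "sd_r": pre[1]}
        out["post_transition"] = {"mean_r": post[0], "sd_r": post[1]}
        cmp_pp = compare_intercorrelation(pre[2], post[2])
        out["pre_vs_post"] = {
            "t": cmp_pp.statistic, "df": cmp_pp.df, "p": cmp_pp.p,
        }
    return out


def _pairwise_mean(mat: np.ndarray):
    from .roi import ROI_LABELS

    n = mat.shape[1]
    vals = {}
    for a in range(n):
        for b in range(a + 1, n):
            key = f"{ROI_LABELS[a]}|{ROI_LABELS[b]}"
            sa, sb = np.std(mat[:, a]), np.std(mat[:, b])
            vals[key] = (
                float(np.corrcoef(mat[:, a], mat[:, b])[0, 1])
                if sa > 0 and sb > 0
                else np.nan
            )
    ser = pd.Series(vals)
    ok = ser.dropna()
    return float(ok.mean()), float(ok.std(ddof=1)), ser


def _figures(out: Path, matrices, transitions, changes: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sids = sorted(matrices)
    ncol = 3
    nrow = -(-len(sids) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 2.5 * nrow),
                             squeeze=False)
    for ax, sid in zip(axes.ravel(), sids):
        cm = matrices[sid]
        curve = mean_complexity(cm)
        ax.plot(cm.day_index, curve, lw=1)
        for d, _ in transitions[sid].transitions:
            ax.axvline(d, color="crimson", ls="--", lw=1)
        ax.set_title(sid, fontsize=9)
    for ax in axes.ravel()[len(sids):]:
        ax.axis("off")
    fig.supxlabel("day")
    fig.supylabel("mean dynamic complexity")
    fig.tight_layout()
    fig.savefig(out / "complexity_curves.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, measure, title in zip(
        axes, ("diff_voxels", "diff_weighted"),
        ("mean |Δ voxels|", "mean |Δ weighted %|"),
    ):
        sub_means = changes.groupby(["subject", "label"], observed=True)[measure].mean()
        grp = sub_means.groupby("label").mean().reindex(["OT", "NOT", "ISI"])
        ax.bar(grp.index, grp.values, color=["crimson", "gold", "grey"])
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out / "group_changes.png", dpi=120)
    plt.close(fig)


def _provenance(config: RunConfig) -> dict:
    import datetime
    import scipy

    cfg = asdict(config)
    cfg["out_dir"] = str(cfg["out_dir"])
    return {
        "config": cfg,
        "seed": config.seed,
        "versions": {
            "ordertrans": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
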
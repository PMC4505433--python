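"""End-to-end orchestration: simulation -> quantification -> statistics -> report.

A single experiment-design mapping (usually loaded from YAML) drives the whole
run: tonicity conditions with their ground-truth membrane fractions, repeats,
cells per image, noise, the control label and the planned comparisons. The run
is deterministic given the design and seed; every output directory records the
seed and a hash of the design.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morphology, profiles, stats
from .scenes import CellSpec, SceneSpec, render_scene

log = logging.getLogger(__name__)

__all__ = ["default_design", "load_design", "validate_design", "run_pipeline"]


def default_design() -> dict:
    """Three-tonicity demonstration design (isotonic control plus two dilutions).

    The membrane fractions encode a threshold response: no translocation at
    the intermediate tonicity, full response at the strongest dilution.
    """
    return {
        "name": "tonicity-threshold-demo",
        "seed": 1,
        "image_shape": [112, 224],
        "pixel_size": 0.2,
        "n_repeats": 3,
        "cells_per_image": 3,
        "n_lines": 3,
        "noise_gaussian_sd": 1.5,
        "total_signal": 1.0e5,
        "cell_radius_um": 5.0,
        # biological variability: repeat-level and cell-level jitter of the
        # membrane fraction, cell-level jitter of the swelling ratio
        "f_repeat_sd": 0.02,
        "f_cell_sd": 0.03,
        "swelling_cell_sd": 0.02,
        "control": "340",
        "comparisons": ["170", "85"],
        "conditions": {
            "340": {"osmolality": 340, "membrane_fraction": 0.09,
                    "swelling_area_ratio": 1.0},
            "170": {"osmolality": 170, "membrane_fraction": 0.09,
                    "swelling_area_ratio": 1.05},
            "85": {"osmolality": 85, "membrane_fraction": 0.33,
                   "swelling_area_ratio": 1.45},
        },
    }


def load_design(path) -> dict:
    with open(path) as fh:
        design = yaml.safe_load(fh)
    validate_design(design)
    return design


def validate_design(design: dict) -> None:
    if not design.get("conditions"):
        raise ValueError("no conditions in design")
    for label, cond in design["conditions"].items():
        if cond.get("osmolality", 1) <= 0:
            raise ValueError(f"condition {label}: osmolality must be > 0")
    control = design.get("control")
    if control is not None and control not in design["conditions"]:
        raise ValueError(f"control {control!r} is not a condition")
    for c in design.get("comparisons", []):
        if c not in design["conditions"]:
            raise ValueError(f"comparison target {c!r} is not a condition")
    if design.get("n_repeats", 1) < 1:
        raise ValueError("n_repeats must be >= 1")


def design_hash(design: dict, seed: int) -> str:
    canon = json.dumps({"design": design, "seed": seed}, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _cell_grid(design: dict) -> list[tuple[float, float]]:
    h, w = design["image_shape"]
    n = design["cells_per_image"]
    max_ratio = max(
        c.get("swelling_area_ratio", 1.0) for c in design["conditions"].values()
    )
    r_max = design["cell_radius_um"] / design["pixel_size"] * math.sqrt(max_ratio)
    margin = r_max + 6
    cols = np.linspace(margin, w - 1 - margin, n)
    if n > 1 and cols[1] - cols[0] < 2 * r_max + 8:
        raise ValueError("image too small for cells_per_image at this radius")
    return [(h / 2.0, float(c)) for c in cols]


def _scene_for(design: dict, cond: dict, seed: int, swelled: bool = False) -> SceneSpec:
    """Scene for one (repeat, condition) with biological jitter.

    The repeat-level offset and per-cell jitter of the membrane fraction model
    day-to-day and cell-to-cell heterogeneity; both are drawn from the scene's
    own seeded generator so the run stays deterministic.
    """
    rng = np.random.default_rng(seed)
    rep_off = rng.normal(0.0, design.get("f_repeat_sd", 0.0))
    ratio0 = cond.get("swelling_area_ratio", 1.0)
    cells = []
    for c in _cell_grid(design):
        f = float(np.clip(
            cond["membrane_fraction"] + rep_off
            + rng.normal(0.0, design.get("f_cell_sd", 0.0)),
            0.0, 1.0,
        ))
        ratio = max(ratio0 + rng.normal(0.0, design.get("swelling_cell_sd", 0.0)),
                    0.5)
        radius = design["cell_radius_um"] * (math.sqrt(ratio) if swelled else 1.0)
        cells.append(
            CellSpec(
                center=c,
                radius=radius,
                membrane_fraction=f,
                total_signal=design["total_signal"],
                swelling_area_ratio=ratio,
            )
        )
    return SceneSpec(
        image_shape=tuple(design["image_shape"]),
        pixel_size=design["pixel_size"],
        cells=tuple(cells),
        noise_gaussian_sd=design.get("noise_gaussian_sd", 0.0),
        seed=int(rng.integers(0, 2**31)),
    )


def run_pipeline(design: dict, out_dir, seed: int | None = None) -> dict:
    """Run the full synthetic experiment described by ``design``.

    For every repeat and condition a scene is rendered and quantified with the
    profile pipeline; per-repeat means feed a repeated-measures ANOVA gate,
    paired t tests of every planned comparison against the control (Bonferroni
    m = number of planned comparisons), area-change measurements, and the
    final translocation table. Writes per-profile and summary CSVs, the table
    in CSV and text form, and a JSON of all test results; returns the summary
    as a dict.
    """
    validate_design(design)
    if seed is None:
        seed = int(design.get("seed", 0))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    labels = list(design["conditions"])
    n_rep = design["n_repeats"]
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_rep * len(labels) * 2).reshape(
        n_rep, len(labels), 2
    )

    per_profile_rows = []
    area_rows = []
    for r in range(n_rep):
        for ci, label in enumerate(labels):
            cond = design["conditions"][label]
            scene_seed = int(seeds[r, ci, 0] % 2**31)
            spec = _scene_for(design, cond, scene_seed)
            scene = render_scene(spec)
            df = profiles.measure_scene_rme(scene, n_lines=design.get("n_lines", 3))
            df["repeat"] = r + 1
            df["condition"] = label
            per_profile_rows.append(df)

            post_seed = int(seeds[r, ci, 1] % 2**31)
            post = render_scene(
                _scene_for(design, cond, post_seed, swelled=True)
            )
            pairs = morphology.measure_swelling(
                scene.channels, post.channels, design["pixel_size"]
            )
            for mobj in pairs:
                area_rows.append(
                    dict(repeat=r + 1, condition=label, cell_id=mobj.cell_id,
                         area_pre_um2=mobj.area_pre, area_post_um2=mobj.area_post,
                         pct=mobj.area_change_pct, transfected=mobj.transfected)
                )

    per_profile = pd.concat(per_profile_rows, ignore_index=True)
    areas = pd.DataFrame(area_rows)

    summaries = {}
    repeat_vectors = {}
    for label in labels:
        agg = profiles.aggregate_rme(per_profile[per_profile["condition"] == label])
        summaries[label] = agg
        repeat_vectors[label] = [
            agg["repeat_means"][r + 1] for r in range(n_rep)
        ]

    comparisons = design.get("comparisons", [])
    control = design.get("control", labels[0])
    m = max(len(comparisons), 1)
    gate = stats.anova_gate([repeat_vectors[c] for c in labels]) if len(labels) >= 3 else None
    gate_passed = gate.passed if gate is not None else True

    rows = []
    tests_json = {}
    if gate is not None:
        tests_json["anova"] = dict(F=gate.F, p=gate.p, kind=gate.kind,
                                   passed=gate.passed)
    for label in comparisons:
        t = stats.paired_t(
            repeat_vectors[control], repeat_vectors[label],
            comparison=f"{label}-vs-{control}", m=m,
        )
        a_sub = areas[(areas["condition"] == label)]
        area_mean = area_sem = None
        area_test = None
        if len(a_sub):
            rep_pct = a_sub.groupby("repeat")["pct"].mean()
            area_mean = float(rep_pct.mean())
            area_sem = (
                float(rep_pct.std(ddof=1) / math.sqrt(len(rep_pct)))
                if len(rep_pct) > 1 else float("nan")
            )
            if len(rep_pct) >= 2:
                area_test = stats.paired_t(
                    [100.0] * len(rep_pct), rep_pct.to_list(),
                    comparison=f"area-{label}", m=m,
                )
        rows.append(
            stats.ReportRow(
                label=label,
                iso_mean=summaries[control]["mean"],
                iso_sem=summaries[control]["sem"],
                hypo_mean=summaries[label]["mean"],
                hypo_sem=summaries[label]["sem"],
                test=t,
                area_mean=area_mean,
                area_sem=area_sem,
                area_test=area_test,
                gate_passed=gate_passed,
            )
        )
        tests_json[t.comparison] = dict(
            statistic=t.statistic, p_raw=t.p_raw, p_corrected=t.p_corrected,
            p_display=t.p_display, n=t.n, paired=t.paired,
            significant=t.significant and gate_passed,
        )

    table = stats.build_report(rows)
    summary_df = pd.DataFrame(
        [
            dict(condition=label, mean_rme=s["mean"], sem=s["sem"],
                 n=s["n_repeats"])
            for label, s in summaries.items()
        ]
    )

    per_profile.to_csv(out_dir / "per_profile.csv", index=False)
    areas.to_csv(out_dir / "areas.csv", index=False)
    summary_df.to_csv(out_dir / "summary.csv", index=False)
    table.to_csv(out_dir / "table1.csv", index=False)
    (out_dir / "table1.txt").write_text(stats.render_report_text(table, m=m))
    meta = dict(seed=seed, config_hash=design_hash(design, seed), design=design)
    (out_dir / "tests.json").write_text(
        json.dumps({"meta": meta, "tests": tests_json}, indent=2, sort_keys=True)
    )
    log.info("pipeline complete: %s", out_dir)
    return dict(
        summaries=summaries, table=table, tests=tests_json, meta=meta,
        calls={r.label: r.translocation for r in rows},
    )
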
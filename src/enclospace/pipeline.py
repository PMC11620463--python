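"""End-to-end analysis: data -> geometry -> budgets -> KDE -> electivity ->
effect models -> test metrics -> report bundle.

A run is driven by a small YAML (or dict) config pointing at either a data
deposit (workbook/CSV directory) or the synthetic generator, and emits CSV
tables plus a JSON run manifest recording the config hash, seeds, row
counts, and every method choice actually used (kernel, barrier mode, cell
size, EMM weighting), so results are auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .budget import aggregate_budget, paired_mean_difference
from .effects import ModelSpec, estimated_marginal_means, fit_condition_model
from .electivity import mean_electivity, zone_use
from .geometry import (
    EnclosureSpec,
    FurnitureElement,
    SurfacePoint,
    build_unfolded_surface,
    complex_enclosure,
    default_map_layout,
    default_zone_partition,
    map_grid_location,
    standard_enclosure,
)
from .kde import (
    isopleth,
    kernel_density,
    element_use,
    optimal_bandwidth,
    range_summary,
    standard_distance,
)
from .observations import ScanDataset, read_dataset
from .synth import SyntheticConfig, generate_study
from .testmetrics import novelty_outcomes, preference_outcomes

__all__ = ["PipelineError", "PipelineResult", "enclosure_from_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def enclosure_from_config(cfg: dict) -> EnclosureSpec:
    """Build an EnclosureSpec from a plain config mapping.

    Expected keys: label, length, width, height, optional substrate_depth
    and furniture (list of {name, footprint: [[x, y], ...], is_hide,
    top_surface}).
    """
    from shapely.geometry import Polygon

    furniture = tuple(
        FurnitureElement(
            name=f["name"],
            footprint=Polygon(f["footprint"]),
            is_hide=bool(f.get("is_hide", False)),
            top_surface=bool(f.get("top_surface", True)),
        )
        for f in cfg.get("furniture", [])
    )
    return EnclosureSpec(
        label=cfg["label"],
        length=float(cfg["length"]),
        width=float(cfg["width"]),
        height=float(cfg["height"]),
        substrate_depth=float(cfg.get("substrate_depth", 0.0)),
        furniture=furniture,
    )


@dataclasses.dataclass
class PipelineResult:
    """All output tables of one run plus the manifest."""

    budget: pd.DataFrame
    budget_differences: pd.DataFrame
    home_ranges: pd.DataFrame
    electivity: pd.DataFrame
    element_use: pd.DataFrame
    effects: pd.DataFrame
    novelty: pd.DataFrame
    preference: pd.DataFrame
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "budget": self.budget,
            "budget_differences": self.budget_differences,
            "home_ranges": self.home_ranges,
            "electivity": self.electivity,
            "element_use": self.element_use,
            "effects": self.effects,
            "novelty": self.novelty,
            "preference": self.preference,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return config
    with open(config) as fh:
        return yaml.safe_load(fh)


def _load_dataset(cfg: dict) -> tuple[ScanDataset, dict]:
    inp = cfg.get("input", {})
    if "synthetic" in inp:
        syn = dict(inp["synthetic"])
        sconf = SyntheticConfig(**syn)
        return generate_study(sconf), {"synthetic": syn}
    if "path" in inp:
        ds = read_dataset(inp["path"], schema_map=inp.get("schema_map"))
        return ds, {"path": str(inp["path"])}
    raise PipelineError("stage input: config must provide input.synthetic or input.path")


def _surface_points(
    locations: pd.DataFrame, spec, layout
) -> list[SurfacePoint]:
    """Map grid fixes onto the unfolded surface, skipping ceiling fixes."""
    pts = []
    for _, row in locations.iterrows():
        if row["element"] == "ceiling":
            continue  # no home on the 2-D diagram; kept in element tallies
        pts.append(map_grid_location(row["grid_x"], row["grid_y"], spec, layout))
    return pts


def _space_use_stage(
    dataset: ScanDataset, kde_cfg: dict
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    specs = {"Standard": standard_enclosure(), "Complex": complex_enclosure()}
    surfaces = {c: build_unfolded_surface(s) for c, s in specs.items()}
    layouts = {c: default_map_layout(s) for c, s in specs.items()}
    levels = kde_cfg.get("isopleths", [0.95, 0.50])
    kernel = kde_cfg.get("kernel", "quartic")
    cell_size = kde_cfg.get("cell_size")

    meta = dataset.sessions[["session_id", "condition"]]
    locs = dataset.locations.merge(meta, on="session_id", how="left")

    hr_rows = []
    subject_points: dict[tuple[str, str], list[SurfacePoint]] = {}
    for (subj, cond), grp in locs.groupby(["subject_id", "condition"], sort=True):
        spec, surface, layout = specs[cond], surfaces[cond], layouts[cond]
        pts = _surface_points(grp, spec, layout)
        subject_points[(subj, cond)] = pts
        if len(pts) < 2:
            continue
        xy = np.asarray([(p.x, p.y) for p in pts])
        sigma = standard_distance(xy)
        if sigma == 0:
            warnings.warn(f"{subj}/{cond}: all fixes coincide; KDE skipped")
            continue
        h = optimal_bandwidth(len(pts), sigma)
        dens = kernel_density(pts, h, surface, cell_size=cell_size, kernel=kernel)
        for level in levels:
            est = isopleth(dens, level)
            proportion, true_area = range_summary(est, surface, spec)
            hr_rows.append({
                "subject_id": subj, "condition": cond, "level": level,
                "n_locations": len(pts), "sigma_cm": sigma, "bandwidth_cm": h,
                "proportion": proportion, "area_cm2": true_area,
            })
    hr = pd.DataFrame(hr_rows)

    # electivity in the Complex condition over the default 7-zone partition
    zones = default_zone_partition(surfaces["Complex"])
    per_subject = {}
    for (subj, cond), pts in subject_points.items():
        if cond != "Complex" or not pts:
            continue
        per_subject[subj] = zone_use(pts, zones)
    if per_subject:
        elect = mean_electivity(per_subject)
        detail = pd.concat(
            [df.assign(subject_id=s) for s, df in per_subject.items()],
            ignore_index=True,
        )
        elect = elect.merge(
            detail.groupby("zone", sort=False)[["r", "p", "W"]].mean().reset_index(),
            on="zone",
        )
    else:
        elect = pd.DataFrame(
            columns=["zone", "mean_E_star", "sd_E_star", "n_subjects", "r", "p", "W"]
        )
    meta_out = {
        "kernel": kernel,
        "barrier": "clip-and-renormalize",
        "cell_size": cell_size if cell_size is not None else "min(side)/200 capped at h/2",
        "isopleths": levels,
        "n_zones": zones.n_zones,
    }
    return hr, elect, meta_out


def _session_response_table(dataset: ScanDataset) -> pd.DataFrame:
    """Per-session responses for the condition models."""
    scans = dataset.scans
    vis = scans[scans["visible"]]
    per = vis.groupby("session_id").agg(
        n_visible=("behavior_state", "size"),
        n_active=("behavior_state", lambda s: int((s != "Inactive").sum())),
    )
    per["prop_active"] = per["n_active"] / per["n_visible"]
    meta = dataset.sessions_with_phase().set_index("session_id")
    out = meta.join(per, how="inner").reset_index()

    locs = dataset.locations.groupby("session_id").agg(
        n_fixes=("element", "size"),
        n_wall=("element", lambda s: int((s == "wall").sum())),
    )
    out = out.merge(locs, left_on="session_id", right_index=True, how="left")
    out["prop_wall"] = out["n_wall"] / out["n_fixes"]
    return out


def _effects_stage(
    dataset: ScanDataset, hr: pd.DataFrame, effects_cfg: dict
) -> pd.DataFrame:
    backend = effects_cfg.get("backend", "auto")
    refs = {"condition": "Standard", "sex": "female"}
    sess = _session_response_table(dataset)
    sex_map = dataset.sessions.drop_duplicates("subject_id").set_index(
        "subject_id"
    )["sex"]

    jobs: list[tuple[str, str, pd.DataFrame, ModelSpec]] = []
    for phase in ("dark", "light"):
        sub = sess[sess["phase"] == phase]
        jobs.append((
            "activity", phase,
            sub.rename(columns={"prop_active": "y"}),
            ModelSpec("y", "binomial", weights="n_visible",
                      reference_levels=refs),
        ))
        wall = sub.dropna(subset=["prop_wall"]).rename(columns={"prop_wall": "y"})
        jobs.append((
            "wall_use", phase, wall,
            ModelSpec("y", "binomial", weights="n_fixes", reference_levels=refs),
        ))
    for level, name in ((0.95, "home_range"), (0.50, "core_area")):
        sub = hr[hr["level"] == level].copy()
        if not sub.empty:
            sub["sex"] = sub["subject_id"].map(sex_map)
            jobs.append((
                name, "all", sub.rename(columns={"area_cm2": "y"}),
                ModelSpec("y", "gaussian", reference_levels=refs),
            ))
    nov = novelty_outcomes(dataset.novelty)
    if not nov.empty:
        nov = nov.rename(columns={"prior_condition": "condition",
                                  "prop_active": "y"})
        nov["sex"] = nov["subject_id"].map(sex_map)
        jobs.append((
            "novelty_activity", "all", nov,
            ModelSpec("y", "binomial", weights="n_scans", reference_levels=refs),
        ))
    if not dataset.feeds.empty:
        fe = (
            dataset.feeds.groupby(["subject_id", "condition"])
            .agg(n=("ate", "size"), n_no=("ate", lambda s: int((~s).sum())))
            .reset_index()
        )
        fe["y"] = fe["n_no"] / fe["n"]
        fe["sex"] = fe["subject_id"].map(sex_map)
        jobs.append((
            "feeding_refusal", "all", fe,
            ModelSpec("y", "binomial", weights="n", reference_levels=refs),
        ))
    if not dataset.weights.empty:
        wt = dataset.weights.rename(columns={"weight_g": "y"}).copy()
        wt["sex"] = wt["subject_id"].map(sex_map)
        jobs.append((
            "weight", "all", wt, ModelSpec("y", "gaussian", reference_levels=refs),
        ))

    rows = []
    for response, phase, df, spec in jobs:
        if df.empty or df["subject_id"].nunique() < 2:
            continue
        try:
            fit = fit_condition_model(df, spec, backend=backend)
        except Exception as exc:
            rows.append({"response": response, "phase": phase,
                         "status": f"failed: {exc}"})
            continue
        if not fit.converged:
            rows.append({"response": response, "phase": phase,
                         "status": "not converged"})
            continue
        summ = estimated_marginal_means(fit)
        for _, e in summ.emms.iterrows():
            rows.append({
                "response": response, "phase": phase, "status": "ok",
                "kind": "emm", "factor": e["factor"], "level": e["level"],
                "estimate": e["emm"], "ci_low": e["ci_low"],
                "ci_high": e["ci_high"],
                "residual_skew": fit.residual_skew,
                "descriptive_fallback": fit.descriptive_fallback,
                "backend": fit.backend,
            })
        keep = summ.contrasts[
            (summ.contrasts["factor"] == "condition")
            & (summ.contrasts["level_a"] == "Complex")
            | (summ.contrasts["factor"] == "sex")
            & (summ.contrasts["level_a"] != summ.contrasts["level_b"])
        ]
        seen = set()
        for _, c in keep.iterrows():
            key = (c["factor"], frozenset((c["level_a"], c["level_b"])))
            if c["factor"] == "sex" and key in seen:
                continue
            seen.add(key)
            rows.append({
                "response": response, "phase": phase, "status": "ok",
                "kind": c["kind"], "factor": c["factor"],
                "level": f"{c['level_a']}:{c['level_b']}",
                "estimate": c["estimate"], "ci_low": c["ci_low"],
                "ci_high": c["ci_high"],
                "residual_skew": fit.residual_skew,
                "descriptive_fallback": fit.descriptive_fallback,
                "backend": fit.backend,
            })
    return pd.DataFrame(rows)


def _budget_differences(budget_subject: pd.DataFrame) -> pd.DataFrame:
    """Paired Complex-vs-Standard differences per behavior x phase."""
    rows = []
    for (phase, behavior), grp in budget_subject.groupby(
        ["phase", "behavior_state"], sort=True
    ):
        wide = grp.pivot_table(index="subject_id", columns="condition",
                               values="mean_proportion")
        if {"Standard", "Complex"} - set(wide.columns):
            continue
        both = wide.dropna()
        if len(both) < 2:
            continue
        pd_ = paired_mean_difference(both["Complex"], both["Standard"])
        rows.append({
            "phase": phase, "behavior_state": behavior,
            "mean_difference": pd_.mean, "sd": pd_.sd,
            "ci_low": pd_.ci_low, "ci_high": pd_.ci_high, "n_pairs": pd_.n_pairs,
        })
    return pd.DataFrame(rows)


def run_pipeline(
    config: str | Path | dict, out_dir: str | Path | None = None
) -> PipelineResult:
    """Run the full analysis described by ``config``.

    Stages: input, budget, space_use, effects, test_metrics.  Any stage
    error aborts with a :class:`PipelineError` naming the stage.  When
    ``out_dir`` is given (or set in the config) all tables and the manifest
    are written there.
    """
    cfg = _load_config(config)
    out_dir = out_dir or cfg.get("out_dir")

    stage = "input"
    try:
        dataset, input_meta = _load_dataset(cfg)

        stage = "budget"
        budget = aggregate_budget(dataset)
        budget_diffs = _budget_differences(budget.subject_level)

        stage = "space_use"
        hr, elect, kde_meta = _space_use_stage(dataset, cfg.get("kde", {}))
        use_subject, use_summary = element_use(dataset)

        stage = "effects"
        effects = _effects_stage(dataset, hr, cfg.get("effects", {}))

        stage = "test_metrics"
        nov = novelty_outcomes(dataset.novelty)
        pref = preference_outcomes(dataset.preference)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    canonical = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest(),
        "input": input_meta,
        "row_counts": dataset.row_counts(),
        "rejected_rows": int(len(dataset.rejects)),
        "decisions": {
            **kde_meta,
            "emm_weighting": "equal over other-factor levels",
            "visible_scan_denominator": True,
            "phase_rule": "dark 17-06, light 07-15, hour 16 excluded",
        },
    }
    result = PipelineResult(
        budget=budget.summary,
        budget_differences=budget_diffs,
        home_ranges=hr,
        electivity=elect,
        element_use=use_summary,
        effects=effects,
        novelty=nov,
        preference=pref,
        manifest=manifest,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
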
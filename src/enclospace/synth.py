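"""Seeded synthetic study datasets with the structure the analysis assumes.

The generator emulates every record stream of the housing-comparison study:
scan-sampled behavior (20 scans per 10-min session, two sessions a day with
hours balanced around the clock), 2-min location fixes on the 600-grid map,
all-occurrence falls, weekly feeding outcomes, body weights, 15-s novelty
-test scans, and a 24-h three-chamber preference trajectory.  Behavior is
binomial on the logit scale with a subject random intercept; locations mix
attraction points at hide elements (truncated bivariate normal) with a
uniform floor background and a per-condition wall affinity; the preference
test is a continuous-time Markov walk over the three chambers.

Defaults are parameterized to the magnitudes of the activity-budget and
space-use tables they emulate (inactivity near 0.96, night hide use near
0.26, higher wall affinity in Standard housing) — they are labeled
defaults, not ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .geometry import (
    EnclosureSpec,
    MapLayout,
    SurfacePoint,
    UnfoldedSurface,
    build_unfolded_surface,
    complex_enclosure,
    default_map_layout,
    standard_enclosure,
)
from .observations import ScanDataset

__all__ = [
    "SyntheticConfig",
    "generate_locations",
    "generate_preference_trajectory",
    "generate_study",
    "surface_point_to_grid",
]

ACTIVE_SPLIT = {
    # relative frequencies among active scans, shaped like the ethogram table
    "Locomotion": 0.20,
    "Climb": 0.30,
    "Active in Place": 0.30,
    "Preen": 0.08,
    "Web Construction": 0.07,
    "Dig/Burrow": 0.04,
    "Other": 0.01,
}


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


@dataclass(frozen=True)
class SyntheticConfig:
    """All dials of the synthetic study; one seed fixes the whole dataset."""

    seed: int = 0
    n_subjects: int = 13
    n_males: int = 3
    sessions_per_condition: int = 48
    scans_per_session: int = 20
    location_fixes: int = 6
    visible_prob: float = 0.98

    #: logit-scale base probability of being INACTIVE on a scan
    inactive_base: float = _logit(0.96)
    #: log-odds shift of *activity* in the Complex condition
    activity_beta: float = -0.5
    #: extra log-odds of activity during light hours (nocturnal animals)
    light_activity_delta: float = -0.3
    #: between-subject SD of the activity random intercept (logit scale)
    subject_tau: float = 0.5

    #: probability a location fix is on a wall flap, per condition
    wall_affinity: dict = field(
        default_factory=lambda: {"Standard": 0.10, "Complex": 0.02}
    )
    #: per-condition floor-mass mixture weights over attraction elements;
    #: the remainder of each condition's floor mass is uniform background
    attraction_weights: dict = field(
        default_factory=lambda: {
            "Standard": {"Cork Bark": 0.65},
            "Complex": {"Log": 0.35, "Branch": 0.25,
                        "Rock Cave": 0.08, "Garden Pot": 0.07},
        }
    )
    #: 2-D spread (cm) of the attraction clusters
    attraction_spread: float = 4.0
    #: probability an attraction-drawn fix is inside the hide (vs nearby)
    hide_occupancy: float = 0.35

    #: mean falls per observation by (condition, phase)
    fall_rates: dict = field(
        default_factory=lambda: {
            ("Standard", "dark"): 0.023, ("Complex", "dark"): 0.003,
            ("Standard", "light"): 0.015, ("Complex", "light"): 0.014,
        }
    )

    eat_prob: float = 0.94
    weight_mean: float = 18.5
    weight_between_sd: float = 2.5
    weight_measure_sd: float = 0.3
    weight_female_shift: float = 1.2

    novelty_scans: int = 40
    #: logit-scale base probability of being active in the novel arena
    novelty_base: float = _logit(0.06)
    #: log-odds shift of novelty activity after the Complex condition
    novelty_beta: float = math.log(2.5)
    novelty_tau: float = 0.5
    novelty_wall_contact: dict = field(
        default_factory=lambda: {"Standard": 0.62, "Complex": 0.56}
    )

    #: preference-test transition rates (per hour)
    selection_exit_rate: float = 0.25
    chamber_exit_rate: float = 0.15
    #: probability a selection-chamber exit goes to the Standard side
    p_standard: float = 0.5
    preference_hours: float = 24.0

    def __post_init__(self) -> None:
        positives = {
            "n_subjects": self.n_subjects,
            "sessions_per_condition": self.sessions_per_condition,
            "scans_per_session": self.scans_per_session,
            "location_fixes": self.location_fixes,
            "attraction_spread": self.attraction_spread,
            "preference_hours": self.preference_hours,
        }
        for name, val in positives.items():
            if not val > 0:
                raise ValueError(f"config field {name!r} must be positive")
        non_negative = {
            "subject_tau": self.subject_tau,
            "novelty_tau": self.novelty_tau,
            "selection_exit_rate": self.selection_exit_rate,
            "chamber_exit_rate": self.chamber_exit_rate,
        }
        for name, val in non_negative.items():
            if val < 0:
                raise ValueError(f"config field {name!r} must be non-negative")
        for name in ("visible_prob", "hide_occupancy", "eat_prob", "p_standard"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"config field {name!r} must be in [0, 1]")
        for cond, wmap in self.attraction_weights.items():
            if sum(wmap.values()) > 1 + 1e-9 or any(w < 0 for w in wmap.values()):
                raise ValueError(
                    f"config field 'attraction_weights[{cond}]' must be "
                    "non-negative and sum to at most 1 (remainder is uniform "
                    "background)"
                )
        for key, rate in self.fall_rates.items():
            if rate < 0:
                raise ValueError(f"config field 'fall_rates[{key}]' must be >= 0")
        for key, p in self.wall_affinity.items():
            if not 0 <= p <= 1:
                raise ValueError(f"config field 'wall_affinity[{key}]' must be in [0, 1]")


def generate_binomial_sessions(
    rng: np.random.Generator,
    n_subjects: int = 12,
    sessions_per_condition: int = 48,
    scans: int = 20,
    beta: float = math.log(2.5),
    tau: float = 0.5,
    base: float = _logit(0.04),
) -> pd.DataFrame:
    """Session-level binomial responses with a known condition effect.

    The minimal data-generating process behind the behavior models: each
    subject gets a logit-scale random intercept (SD ``tau``); each session
    in the Complex condition shifts the log-odds by ``beta``; the response
    is the proportion of ``scans`` successes.  Used for parameter-recovery
    studies of the effect models.
    """
    rows = []
    for i in range(n_subjects):
        u = rng.normal(0.0, tau)
        sex = "male" if i % 4 == 0 else "female"
        for condition in ("Standard", "Complex"):
            eta = base + u + (beta if condition == "Complex" else 0.0)
            p = 1.0 / (1.0 + math.exp(-eta))
            succ = rng.binomial(scans, p, sessions_per_condition)
            for k in succ:
                rows.append({
                    "subject_id": f"S{i:02d}", "sex": sex,
                    "condition": condition, "y": k / scans, "n": scans,
                })
    return pd.DataFrame(rows)


def surface_point_to_grid(
    p: SurfacePoint, surface: UnfoldedSurface, layout: MapLayout
) -> tuple[float, float]:
    """Invert the map-layout scaling: unfolded-plane point -> grid units."""
    gx0, gy0, gx1, gy1 = layout.regions[p.panel]
    x0, y0, x1, y1 = surface.panels[p.panel].bounds
    gx = gx0 + (p.x - x0) / (x1 - x0) * (gx1 - gx0)
    gy = gy0 + (p.y - y0) / (y1 - y0) * (gy1 - gy0)
    # keep strictly inside the half-open grid
    eps = 1e-6
    return min(gx, layout.grid_size - eps), min(gy, layout.grid_size - eps)


def _enclosure_for(condition: str) -> EnclosureSpec:
    return standard_enclosure() if condition == "Standard" else complex_enclosure()


def generate_locations(
    subject_id: str,
    condition: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    n: int,
) -> pd.DataFrame:
    """Draw ``n`` location fixes for one subject in one condition.

    Wall fixes (probability = the condition's wall affinity) are uniform
    over the flaps; floor fixes mix truncated normals centred on hide
    elements with a uniform background.  Returns canonical location-stream
    columns except session/timestamp, which the caller attaches.
    """
    spec = _enclosure_for(condition)
    surface = build_unfolded_surface(spec)
    layout = default_map_layout(spec)
    hides = {f.name: f for f in spec.furniture}
    wmap = config.attraction_weights.get(condition, {})
    names = [k for k in wmap if k in hides]
    weights = np.array([wmap[k] for k in names], dtype=float)
    background = 1.0 - weights.sum() if len(names) else 1.0

    flaps = list(surface.wall_flaps.items())
    flap_areas = np.array([g.area for _, g in flaps])
    flap_p = flap_areas / flap_areas.sum()

    rows = []
    for _ in range(n):
        if rng.random() < config.wall_affinity.get(condition, 0.0):
            k = rng.choice(len(flaps), p=flap_p)
            panel, poly = flaps[k]
            x0, y0, x1, y1 = poly.bounds
            pt = SurfacePoint(rng.uniform(x0, x1), rng.uniform(y0, y1), panel)
            element, usage, detail = "wall", "Open Space", None
        else:
            u = rng.random() * (weights.sum() + background)
            target = None
            acc = 0.0
            for nm, w in zip(names, weights):
                acc += w
                if u < acc:
                    target = nm
                    break
            if target is None:
                x = rng.uniform(0, spec.length)
                y = rng.uniform(0, spec.width)
                pt = SurfacePoint(x, y, "floor")
                element, usage, detail = "ground", "Open Space", None
            else:
                f = hides[target]
                cx, cy = f.footprint.centroid.x, f.footprint.centroid.y
                s = config.attraction_spread
                for _ in range(1000):  # rejection-sample into the floor
                    x = rng.normal(cx, s)
                    y = rng.normal(cy, s)
                    if 0 <= x <= spec.length and 0 <= y <= spec.width:
                        break
                else:  # pragma: no cover - would need absurd spread
                    x, y = cx, cy
                pt = SurfacePoint(x, y, "floor")
                if f.is_hide and rng.random() < config.hide_occupancy:
                    element, usage, detail = "furniture", "In Hide", target
                elif f.footprint.covers(Point(x, y)) and f.top_surface:
                    element, usage, detail = "furniture", "On Furniture", target
                else:
                    element, usage, detail = "ground", "Open Space", None
        gx, gy = surface_point_to_grid(pt, surface, layout)
        rows.append({
            "subject_id": subject_id,
            "grid_x": gx,
            "grid_y": gy,
            "element": element,
            "element_detail": detail,
            "usage": usage,
        })
    return pd.DataFrame(rows)


def generate_preference_trajectory(
    subject_id: str, config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """One 24-h continuous-time Markov walk over the three chambers.

    Starts in the selection chamber; exits occur at ``selection_exit_rate``
    (going Standard with probability ``p_standard``) and chambers are left
    at ``chamber_exit_rate`` back to the selection chamber.  Symmetric rates
    give no preference in expectation; the stationary dwell ratio between
    the housing chambers is ``p_standard : 1 - p_standard`` when their exit
    rates are equal.
    """
    horizon = config.preference_hours * 3600.0
    t = 0.0
    chamber = "Selection"
    rows = []
    while t < horizon:
        rate = (
            config.selection_exit_rate
            if chamber == "Selection"
            else config.chamber_exit_rate
        ) / 3600.0
        dwell = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        end = min(t + dwell, horizon)
        rows.append({"subject_id": subject_id, "chamber": chamber,
                     "start_s": t, "end_s": end})
        t = end
        if t >= horizon:
            break
        if chamber == "Selection":
            chamber = "Standard" if rng.random() < config.p_standard else "Complex"
        else:
            chamber = "Selection"
    return pd.DataFrame(rows)


def generate_study(config: SyntheticConfig) -> ScanDataset:
    """Generate the complete synthetic study for one seed.

    Condition order is counterbalanced across subjects; session hours are
    balanced around the clock (every hour observed twice per condition, the
    to-be-excluded 1600 hour included, as in a real around-the-clock
    design).  Identical config (and seed) yields an identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    subjects = [f"T{i + 1:02d}" for i in range(config.n_subjects)]
    sexes = {
        s: ("male" if i < config.n_males else "female")
        for i, s in enumerate(subjects)
    }
    u_act = {s: rng.normal(0.0, config.subject_tau) for s in subjects}
    u_nov = {s: rng.normal(0.0, config.novelty_tau) for s in subjects}

    active_states = list(ACTIVE_SPLIT)
    active_p = np.array(list(ACTIVE_SPLIT.values()))
    active_p = active_p / active_p.sum()

    sessions, scans, locations, events = [], [], [], []
    feeds, weights, novelty, preference = [], [], [], []

    n_sess = config.sessions_per_condition
    for i, subj in enumerate(subjects):
        order = ("Standard", "Complex") if i % 2 == 0 else ("Complex", "Standard")
        base_w = config.weight_mean + (
            config.weight_female_shift if sexes[subj] == "female" else
            -config.weight_female_shift
        ) + rng.normal(0.0, config.weight_between_sd)
        for block, condition in enumerate(order):
            day0 = block * 35  # four-week block plus acclimation gap
            for k in range(n_sess):
                day = day0 + k // 2
                hour = (k * 7) % 24  # co-prime step balances hours 0-23
                phase = "light" if 7 <= hour <= 15 else "dark"
                sid = f"{subj}-{condition}-{k:02d}"
                date = f"2024-{1 + day // 28:02d}-{1 + day % 28:02d}"
                sessions.append({
                    "session_id": sid, "subject_id": subj, "sex": sexes[subj],
                    "condition": condition, "date": date, "hour": hour,
                })
                # behavior scans
                eta = -(config.inactive_base) + u_act[subj]
                if condition == "Complex":
                    eta += config.activity_beta
                if phase == "light":
                    eta += config.light_activity_delta
                p_active = 1.0 / (1.0 + math.exp(-eta))
                for s_i in range(config.scans_per_session):
                    visible = rng.random() < config.visible_prob
                    if rng.random() < p_active:
                        state = active_states[rng.choice(len(active_states), p=active_p)]
                    else:
                        state = "Inactive"
                    scans.append({
                        "subject_id": subj, "session_id": sid,
                        "timestamp": f"{date}T{hour:02d}:{(s_i * 30) // 60:02d}:{(s_i * 30) % 60:02d}",
                        "behavior_state": state, "visible": bool(visible),
                    })
                # location fixes
                loc = generate_locations(
                    subj, condition, config, rng, config.location_fixes
                )
                loc["session_id"] = sid
                loc["timestamp"] = [
                    f"{date}T{hour:02d}:{(j * 120) // 60:02d}:00"
                    for j in range(len(loc))
                ]
                locations.append(loc)
                # falls
                lam = config.fall_rates.get(
                    (condition, "light" if 7 <= hour <= 15 else "dark"), 0.0
                )
                for _ in range(rng.poisson(lam)):
                    events.append({
                        "subject_id": subj, "session_id": sid,
                        "timestamp": f"{date}T{hour:02d}:05:00",
                        "event_type": "fall",
                    })
            # weekly feeds and start/end weights for this block
            for wk in range(4):
                feeds.append({
                    "subject_id": subj, "condition": condition,
                    "date": f"2024-{1 + (day0 + wk * 7) // 28:02d}-{1 + (day0 + wk * 7) % 28:02d}",
                    "ate": bool(rng.random() < config.eat_prob),
                })
            for point in ("start", "end"):
                weights.append({
                    "subject_id": subj, "condition": condition, "point": point,
                    "weight_g": round(base_w + rng.normal(0.0, config.weight_measure_sd), 2),
                })
            # novelty test after each housing block
            env = ("A", "B")[(i + block) % 2]
            eta_n = config.novelty_base + u_nov[subj]
            if condition == "Complex":
                eta_n += config.novelty_beta
            p_act = 1.0 / (1.0 + math.exp(-eta_n))
            p_wall = config.novelty_wall_contact.get(condition, 0.5)
            for s_i in range(config.novelty_scans):
                active = rng.random() < p_act
                novelty.append({
                    "subject_id": subj, "prior_condition": condition,
                    "environment": env,
                    "timestamp": f"2024-03-01T12:{(s_i * 15) // 60:02d}:{(s_i * 15) % 60:02d}",
                    "behavior_state": "Locomotion" if active else "Inactive",
                    "contact": "wall contact" if rng.random() < p_wall else "open space",
                })
        preference.append(generate_preference_trajectory(subj, config, rng))

    return ScanDataset(
        sessions=pd.DataFrame(sessions),
        scans=pd.DataFrame(scans),
        locations=pd.concat(locations, ignore_index=True)[
            ["subject_id", "session_id", "timestamp", "grid_x", "grid_y",
             "element", "element_detail", "usage"]
        ],
        events=pd.DataFrame(
            events, columns=["subject_id", "session_id", "timestamp", "event_type"]
        ),
        feeds=pd.DataFrame(feeds),
        weights=pd.DataFrame(weights),
        novelty=pd.DataFrame(novelty),
        preference=pd.concat(preference, ignore_index=True)[
            ["subject_id", "chamber", "start_s", "end_s"]
        ],
    )
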
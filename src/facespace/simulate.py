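"""Synthetic face-detection-task (FDT) and battery data with known truth.

The generator reproduces the task design — per participant 576 trials in
11 blocks: 480 upright-face go trials (12 identities x 40 occurrences,
each identity shown from each of 10 viewing angles exactly 4 times), 48
inverted faces and 48 chairs as no-go trials, in randomized order — and
an RT model in which repeated exposure to an identity drives RTs down an
exponential curve toward a fixed asymptote:

    RT(n) = RT_inf + (RT0 - RT_inf) * exp(-alpha * n)

The first presentation of an identity *is* the anchor RT0 (no learning
has happened yet); presentations n >= 2 follow the curve.  On top of the
curve sit a constant typicality offset (distinctive faces slower), a
participant random intercept, a gender offset, an optional linear
coupling between the typicality effect and the participant's composite
ability rank, and i.i.d. Gaussian trial noise.  Go responses occur with
the configured hit probability, false alarms on no-go stimuli with the
configured false-alarm probability; simulated RTs exceeding the response
deadline become misses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .battery import aggregate_score
from .config import BATTERY_RANGES, BATTERY_TESTS, SimulationConfig

TRIAL_COLUMNS = [
    "participant_id",
    "block",
    "trial_index",
    "stimulus_category",
    "identity_id",
    "typicality",
    "viewing_angle",
    "occurrence",
    "responded",
    "correct",
    "rt_ms",
]


@dataclass
class SimulatedData:
    """Bundle of simulated trials, battery scores and ground truth."""

    trials: pd.DataFrame
    battery: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.csv", index=False)
        self.battery.to_csv(out / "battery.csv", index=False)
        self.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        (out / "sim_config.json").write_text(self.config.to_json())


def _participant_ids(n: int) -> np.ndarray:
    width = max(3, len(str(n)))
    return np.array([f"p{i + 1:0{width}d}" for i in range(n)])


def _draw_participants(cfg: SimulationConfig, rng: np.random.Generator):
    """Draw participant-level ground truth: gender, intercept, alphas,
    battery scores and the resulting composite mean rank."""
    n = cfg.n_participants
    pid = _participant_ids(n)
    gender = np.where(rng.integers(0, 2, size=n) == 0, "female", "male")
    intercept = cfg.baseline_rt_mean + rng.normal(
        0.0, cfg.baseline_rt_between_sd, size=n
    )
    # keep the anchor strictly above the asymptote (degenerate draws only)
    intercept = np.maximum(intercept, cfg.rt_asymptote + 1.0)
    a_dev = rng.normal(0.0, cfg.alpha_between_sd, size=n)
    alpha_typ = np.maximum(cfg.alpha_typical_mean + a_dev, 0.0)
    alpha_dis = np.maximum(cfg.alpha_distinctive_mean + a_dev, 0.0)

    # battery: multivariate normal on the configured moments, clipped to
    # each test's legal range (scores kept continuous; the rank-based
    # composite is insensitive to the granularity of the raw scale)
    corr = np.asarray(cfg.battery_corr, dtype=float)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(4))
    z = rng.standard_normal((n, 4)) @ L.T
    scores = np.asarray(cfg.battery_means) + z * np.asarray(cfg.battery_sds)
    battery = pd.DataFrame({"participant_id": pid})
    for k, t in enumerate(BATTERY_TESTS):
        lo, hi = BATTERY_RANGES[t]
        battery[t] = np.clip(scores[:, k], lo, hi)
    if cfg.battery_missing_rate > 0:
        miss = rng.random((n, 4)) < cfg.battery_missing_rate
        # never blank a participant's final remaining test
        for i in range(n):
            if miss[i].all():
                miss[i, rng.integers(0, 4)] = False
        for k, t in enumerate(BATTERY_TESTS):
            battery.loc[miss[:, k], t] = np.nan
    battery["gender"] = gender

    if n >= 2:
        composite = aggregate_score(battery).table.set_index("participant_id")
        mean_rank = composite.loc[pid, "mean_rank"].to_numpy(float)
    else:
        mean_rank = np.ones(n)
    centred_rank = mean_rank - (n + 1) / 2.0
    typ_effect = cfg.typicality_offset + cfg.ability_rt_coupling * centred_rank

    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "gender": gender,
            "true_rt0": intercept,
            "alpha_typical": alpha_typ,
            "alpha_distinctive": alpha_dis,
            "true_typ_effect_ms": typ_effect,
            "composite_mean_rank": mean_rank,
        }
    )
    return participants, battery


def _rng_pair(cfg: SimulationConfig):
    """Independent child generators for participants and trials, so that
    battery-only and trial-only simulation stay mutually consistent."""
    ss = np.random.SeedSequence(cfg.seed)
    child_p, child_t = ss.spawn(2)
    return np.random.default_rng(child_p), np.random.default_rng(child_t)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedData:
    """Simulate the full dataset: trials, battery and ground truth."""
    rng_p, rng_t = _rng_pair(cfg)
    participants, battery = _draw_participants(cfg, rng_p)
    trials = _simulate_trials(cfg, participants, rng_t)

    n_id = cfg.n_identities
    typicality = np.array(
        ["typical"] * (n_id // 2) + ["distinctive"] * (n_id // 2)
    )
    gt_rows = []
    for _, p in participants.iterrows():
        for j in range(n_id):
            typ = typicality[j]
            gt_rows.append(
                {
                    "participant_id": p["participant_id"],
                    "identity_id": j + 1,
                    "typicality": typ,
                    "true_alpha": p["alpha_typical"]
                    if typ == "typical"
                    else p["alpha_distinctive"],
                    "true_rt0": p["true_rt0"],
                    "true_typ_effect_ms": p["true_typ_effect_ms"],
                    "gender": p["gender"],
                    "composite_mean_rank": p["composite_mean_rank"],
                }
            )
    ground_truth = pd.DataFrame(gt_rows)
    return SimulatedData(
        trials=trials, battery=battery, ground_truth=ground_truth, config=cfg
    )


def simulate_fdt(cfg: SimulationConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate trial records only; returns (trials, ground_truth)."""
    data = simulate_dataset(cfg)
    return data.trials, data.ground_truth


def simulate_battery(cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate the battery score table only."""
    rng_p, _ = _rng_pair(cfg)
    _, battery = _draw_participants(cfg, rng_p)
    return battery


def _decay_factors(alpha: float, n_occ: int) -> np.ndarray:
    """Operational learning curve: occurrence 1 is the RT0 anchor,
    occurrences n >= 2 decay as exp(-alpha * n)."""
    n = np.arange(1, n_occ + 1, dtype=float)
    e = np.exp(-alpha * n)
    e[0] = 1.0
    return e


def _simulate_trials(
    cfg: SimulationConfig,
    participants: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_id = cfg.n_identities
    n_occ = cfg.n_occurrences
    half = n_id // 2
    per_angle = n_occ // cfg.n_viewing_angles
    frames = []
    for _, p in participants.iterrows():
        # stimulus stream: each identity n_occ times, plus no-go stimuli
        ident = np.repeat(np.arange(1, n_id + 1), n_occ)
        cat = np.concatenate(
            [
                np.repeat("upright_face", cfg.n_go_trials),
                np.repeat("inverted_face", cfg.n_inverted),
                np.repeat("chair", cfg.n_chairs),
            ]
        )
        ident_full = np.concatenate(
            [ident, np.full(cfg.n_inverted + cfg.n_chairs, 0)]
        )
        order = rng.permutation(cfg.n_trials)
        cat = cat[order]
        ident_full = ident_full[order]

        occurrence = np.zeros(cfg.n_trials, dtype=int)
        counters = np.zeros(n_id + 1, dtype=int)
        for k in range(cfg.n_trials):
            j = ident_full[k]
            if j > 0:
                counters[j] += 1
                occurrence[k] = counters[j]

        # per-identity angle schedule: every angle exactly per_angle times
        angle_sched = {
            j: rng.permutation(
                np.repeat(np.arange(1, cfg.n_viewing_angles + 1), per_angle)
            )
            for j in range(1, n_id + 1)
        }
        angle = np.zeros(cfg.n_trials, dtype=int)
        go_mask = ident_full > 0
        angle[go_mask] = [
            angle_sched[j][o - 1]
            for j, o in zip(ident_full[go_mask], occurrence[go_mask])
        ]

        is_distinctive = go_mask & (ident_full > half)
        typicality = np.where(
            go_mask,
            np.where(is_distinctive, "distinctive", "typical"),
            "",
        )

        # deterministic RT component
        rt0 = float(p["true_rt0"])
        male = p["gender"] == "male"
        decay_t = _decay_factors(float(p["alpha_typical"]), n_occ)
        decay_d = _decay_factors(float(p["alpha_distinctive"]), n_occ)
        # no-go (false-alarm) responses share the general practice
        # speed-up: decay at the occurrence-equivalent task position, so
        # hits and false alarms follow the same time course (no built-in
        # speed-accuracy trade-off)
        alpha_bar = 0.5 * (
            float(p["alpha_typical"]) + float(p["alpha_distinctive"])
        )
        positions = np.arange(1, cfg.n_trials + 1, dtype=float)
        v_occ = positions * cfg.n_occurrences / cfg.n_trials
        rt_det = (rt0 - cfg.rt_asymptote) * np.exp(-alpha_bar * v_occ)
        occ_idx = np.maximum(occurrence - 1, 0)
        rt_det[go_mask] = (rt0 - cfg.rt_asymptote) * np.where(
            is_distinctive[go_mask],
            decay_d[occ_idx[go_mask]],
            decay_t[occ_idx[go_mask]],
        )
        rt = cfg.rt_asymptote + rt_det
        rt = rt + np.where(is_distinctive, float(p["true_typ_effect_ms"]), 0.0)
        # gender_rt_offset is the male - female difference, applied
        # symmetrically so the configured baseline stays the grand mean
        rt = rt + (0.5 if male else -0.5) * cfg.gender_rt_offset
        rt = rt + rng.normal(0.0, cfg.trial_noise_sd, size=cfg.n_trials)

        # response model: hits on go trials, false alarms on no-go trials;
        # RTs beyond the deadline are never registered as responses
        u = rng.random(cfg.n_trials)
        respond = np.where(
            go_mask, u < cfg.hit_rate_target, u < cfg.fa_rate_target
        )
        respond &= rt <= cfg.response_deadline_ms
        correct = np.where(go_mask, respond, ~respond)

        n_tr = cfg.n_trials
        block_sizes = [len(c) for c in np.array_split(np.arange(n_tr), cfg.n_blocks)]
        block = np.repeat(np.arange(1, cfg.n_blocks + 1), block_sizes)

        frames.append(
            pd.DataFrame(
                {
                    "participant_id": p["participant_id"],
                    "block": block,
                    "trial_index": np.arange(1, n_tr + 1),
                    "stimulus_category": cat,
                    "identity_id": np.where(go_mask, ident_full, np.nan),
                    "typicality": np.where(go_mask, typicality, None),
                    "viewing_angle": np.where(go_mask, angle, np.nan),
                    "occurrence": np.where(go_mask, occurrence, np.nan),
                    "responded": np.where(respond, "go", "nogo"),
                    "correct": correct,
                    "rt_ms": np.where(respond, rt, np.nan),
                }
            )
        )
    trials = pd.concat(frames, ignore_index=True)
    for col in ("identity_id", "viewing_angle", "occurrence"):
        trials[col] = trials[col].astype("Int64")
    return trials[TRIAL_COLUMNS]


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table written by this package (CSV, empty = missing)."""
    trials = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    for col in ("identity_id", "viewing_angle", "occurrence"):
        trials[col] = trials[col].astype("Int64")
    trials["correct"] = trials["correct"].astype(bool)
    return trials


def read_battery(path: str | Path) -> pd.DataFrame:
    battery = pd.read_csv(path)
    if "participant_id" not in battery.columns:
        raise ValueError("battery table missing participant_id column")
    return battery
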
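"""End-to-end pipeline: simulate a dataset, analyze batteries/sessions, compare blocks.

All interchange is delimited text (CSV with explicit header schemas, units in
column names) plus a JSON manifest recording seed, configuration and the
latent ground truth, so recovery of configured effects is checkable.  Every
analysis artifact embeds the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cohort as syn
from .changes import change_scores, compare_blocks, fit_adjusted_regression
from .gasex import GasSeries
from .lactate import LactateProfile, LactateStep
from .load import ZoneScheme, summarize_session, summarize_week
from .outcomes import INDEX_INDICATORS, IndexBasis, assemble_battery, endurance_index

log = logging.getLogger("cyclephys")

__all__ = ["RunConfig", "cmd_simulate", "cmd_analyze", "cmd_compare"]

OUTCOME_COLUMNS = [
    "po_4mmol", "po_vo2max", "po_15min", "po_10sec", "vo2max_rel",
    "frac_util_4mmol", "frac_util_15min",
    "ge_fresh_3rd", "ge_fresh_2nd", "ge_tired_3rd", "ge_tired_2nd",
    "body_mass",
]


@dataclass
class RunConfig:
    """Serializable pipeline configuration; the hash stamps every artifact."""

    seed: int = 1
    n_participants: int = 22
    zone_basis: str = "percent_po_40min"
    index_reference: str = "pooled"   # maxima over both blocks and timepoints
    simulate_sessions: bool = True
    effects: Optional[dict] = None    # None -> study-condition defaults
    verbosity: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def effect_config(self) -> syn.EffectConfig:
        if self.effects is None:
            return syn.default_effect_config(self.seed)
        blocks = {
            b: {k: tuple(v) for k, v in eff.items()} for b, eff in self.effects["blocks"].items()
        }
        kwargs = {k: v for k, v in self.effects.items() if k != "blocks"}
        return syn.EffectConfig(blocks=blocks, seed=self.seed, **kwargs)


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def battery_table(
    n: int, seed: int, cfg: Optional[syn.EffectConfig] = None
) -> pd.DataFrame:
    """Simulate and analyze all batteries in memory: one row per rider × block × timepoint.

    The battery-level shortcut through the pipeline (no session time series,
    no file round-trip); used for effect-recovery simulations.
    """
    cfg = cfg if cfg is not None else syn.default_effect_config(seed)
    rows = []
    for i, rec in enumerate(syn.simulate_study(n, seed, cfg)):
        part = rec["participant"]
        for j, ((block, tp), phys) in enumerate(rec["phys"].items()):
            rng = syn.rng_for(seed, syn._TRIAL, i, j)
            mass = phys.body_mass + rng.normal(0.0, 0.15)
            raw = syn.simulate_battery(phys, part, rng, cfg)
            rows.append(
                assemble_battery(
                    participant_id=part.id, block=block, timepoint=tp, body_mass=mass,
                    profile=raw.profile, tired_steps=raw.tired_steps,
                    sprint_power=raw.sprint_power, sprint_period=1.0,
                    vo2max_series=raw.vo2max_series, time_trial=raw.time_trial,
                ).to_row()
            )
    return pd.DataFrame(rows)


def scores_from_battery(battery: pd.DataFrame) -> pd.DataFrame:
    """Long-format change scores (all outcomes incl. the index) from a battery table."""
    battery = battery.copy()
    basis = IndexBasis.from_observations(battery)
    battery["endurance_index"] = [
        endurance_index({k: row[k] for k in INDEX_INDICATORS}, basis)
        for _, row in battery.iterrows()
    ]
    long = battery.melt(
        id_vars=["participant_id", "block", "timepoint"],
        value_vars=OUTCOME_COLUMNS + ["endurance_index"],
        var_name="outcome", value_name="value",
    )
    pre = long[long["timepoint"] == "pre"].drop(columns="timepoint")
    post = long[long["timepoint"] == "post"].drop(columns="timepoint")
    scores, _ = change_scores(pre, post)
    return scores


# ---------------------------------------------------------------------------
# simulate


def _profile_rows(profile: LactateProfile, block: str, timepoint: str, state: str,
                  duration_s: float = 330.0) -> list[dict]:
    return [
        {
            "participant_id": profile.participant_id,
            "timepoint": timepoint,
            "block": block,
            "state": state,
            "step_index": i,
            "power_w": s.power,
            "duration_s": duration_s,
            "lactate_mmol_l": round(s.lactate, 4),
            "vo2_ml_min": round(s.vo2, 2),
            "rer": round(s.rer, 4),
            "hr_bpm": round(s.hr, 1),
        }
        for i, s in enumerate(profile.steps)
    ]


def _series_rows(series: GasSeries, ids: dict, test: str) -> pd.DataFrame:
    n = series.n
    df = pd.DataFrame(
        {
            "t_s": np.arange(n) * series.sample_period,
            "segment": series.segments,
            "power_w": np.round(series.power, 2),
            "hr_bpm": np.round(series.hr, 1),
            "vo2_ml_min": np.round(series.vo2, 2),
            "rer": np.round(series.rer, 4),
        }
    )
    df.insert(0, "test", test)
    df.insert(0, "sample_period_s", series.sample_period)
    for k, v in reversed(ids.items()):
        df.insert(0, k, v)
    return df


def cmd_simulate(config: RunConfig, out_dir: str | Path, force: bool = False) -> Path:
    """Generate a full synthetic dataset directory; deterministic given the seed."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is non-empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.effect_config()
    study = syn.simulate_study(config.n_participants, config.seed, cfg)
    h = config.config_hash

    cohort_rows, step_rows, trial_frames, session_frames = [], [], [], []
    rpe_rows, log_rows, mass_rows, truth = [], [], [], {}
    for i, rec in enumerate(study):
        part = rec["participant"]
        cohort_rows.append(
            {"participant_id": part.id, "sex": part.sex,
             "body_mass_kg": round(part.body_mass, 2), "height_cm": round(part.height, 1)}
        )
        truth[part.id] = {
            f"{block}_{tp}": dataclasses.asdict(phys)
            for (block, tp), phys in rec["phys"].items()
        }
        for j, ((block, tp), phys) in enumerate(rec["phys"].items()):
            rng = syn.rng_for(config.seed, syn._TRIAL, i, j)
            mass_rows.append(
                {"participant_id": part.id, "block": block, "timepoint": tp,
                 "body_mass_kg": round(phys.body_mass + rng.normal(0.0, 0.15), 2)}
            )
            raw = syn.simulate_battery(phys, part, rng, cfg)
            step_rows += _profile_rows(raw.profile, block, tp, "fresh")
            tired = LactateProfile(part.id, raw.tired_steps)
            step_rows += _profile_rows(tired, block, tp, "tired")
            ids = {"participant_id": part.id, "block": block, "timepoint": tp}
            trial_frames.append(_series_rows(raw.vo2max_series, ids, "vo2max"))
            trial_frames.append(_series_rows(raw.time_trial, ids, "tt15"))
            sprint = GasSeries(1.0, raw.sprint_power,
                               np.full(raw.sprint_power.size, np.nan),
                               np.full(raw.sprint_power.size, np.nan),
                               np.full(raw.sprint_power.size, np.nan),
                               np.full(raw.sprint_power.size, "work-sprint", dtype=object))
            trial_frames.append(_series_rows(sprint, ids, "sprint"))
        if config.simulate_sessions:
            orders = {"MIT": syn.MIT_SESSION_ORDER, "HIT": syn.HIT_SESSION_ORDER}
            for block, order in orders.items():
                for s_idx, name in enumerate(order):
                    rng = syn.rng_for(config.seed, syn._SESSION, i, ord(block[0]), s_idx)
                    gas = s_idx in syn.GAS_SESSIONS[block]
                    phys = rec["phys"][(block, "pre")]
                    series, rpe, srpe = syn.simulate_session(
                        phys, part, name, rng, cfg, measure_gas=gas
                    )
                    ids = {"participant_id": part.id, "block": block,
                           "session_index": s_idx + 1}
                    session_frames.append(_series_rows(series, ids, name))
                    rpe_rows += [
                        {"participant_id": part.id, "block": block,
                         "session_index": s_idx + 1, "interval": k + 1,
                         "rpe_borg": round(r, 1), "srpe": round(srpe, 1)}
                        for k, r in enumerate(rpe)
                    ]
        # simple weekly training log around each block (endurance + strength/core)
        rng = syn.rng_for(config.seed, 9, i)
        for block in ("MIT", "HIT"):
            for zone, hours in enumerate([4.5, 4.9, 4.0, 5.7, 0.5], start=1):
                log_rows.append(
                    {"participant_id": part.id, "date": f"{block}-week",
                     "activity": "endurance", "zone_or_percent": zone,
                     "duration_min": round(max(rng.normal(hours * 60, 30), 0.0), 1),
                     "feeling_legs": round(float(np.clip(rng.normal(4.7, 0.7), 1, 9)), 1)}
                )
            log_rows.append(
                {"participant_id": part.id, "date": f"{block}-week", "activity": "strength",
                 "zone_or_percent": np.nan,
                 "duration_min": round(max(rng.normal(9.0, 5.0), 0.0), 1),
                 "feeling_legs": np.nan}
            )

    _write_csv(pd.DataFrame(cohort_rows), out / "cohort.csv", h)
    _write_csv(pd.DataFrame(mass_rows), out / "test_days.csv", h)
    _write_csv(pd.DataFrame(step_rows), out / "step_tests.csv", h)
    _write_csv(pd.concat(trial_frames, ignore_index=True), out / "trials.csv", h)
    if session_frames:
        _write_csv(pd.concat(session_frames, ignore_index=True), out / "sessions.csv", h)
        _write_csv(pd.DataFrame(rpe_rows), out / "rpe.csv", h)
    _write_csv(pd.DataFrame(log_rows), out / "training_log.csv", h)
    manifest = {"config": json.loads(config.to_json()), "config_hash": h, "ground_truth": truth}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# analyze


def _profile_from_rows(rows: pd.DataFrame) -> LactateProfile:
    steps = [
        LactateStep(power=r.power_w, lactate=r.lactate_mmol_l,
                    vo2=r.vo2_ml_min, rer=r.rer, hr=r.hr_bpm)
        for r in rows.sort_values("step_index").itertuples()
    ]
    return LactateProfile(str(rows["participant_id"].iloc[0]), steps)


def _series_from_rows(rows: pd.DataFrame) -> GasSeries:
    rows = rows.sort_values("t_s")
    return GasSeries(
        sample_period=float(rows["sample_period_s"].iloc[0]),
        power=rows["power_w"].to_numpy(),
        vo2=rows["vo2_ml_min"].to_numpy(),
        rer=rows["rer"].to_numpy(),
        hr=rows["hr_bpm"].to_numpy(),
        segments=rows["segment"].to_numpy(dtype=object),
    )


def cmd_analyze(dataset_dir: str | Path, out_dir: str | Path, force: bool = False) -> Path:
    """Compute battery results, session summaries and week summaries from a dataset.

    Per-record failures are logged and skipped; the run continues and reports
    how many records were excluded.
    """
    data = Path(dataset_dir)
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is non-empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((data / "manifest.json").read_text())
    h = manifest["config_hash"]
    config = RunConfig.from_json(json.dumps(manifest["config"]))

    cohort_df = _read_csv(data / "cohort.csv")
    steps_df = _read_csv(data / "step_tests.csv")
    trials_df = _read_csv(data / "trials.csv")
    required = {"participant_id", "block", "timepoint", "state", "power_w", "lactate_mmol_l"}
    if not required.issubset(steps_df.columns):
        raise ValueError(f"step_tests.csv missing columns {sorted(required - set(steps_df.columns))}")
    mass_df = _read_csv(data / "test_days.csv") if (data / "test_days.csv").exists() else None
    if mass_df is not None:
        mass_day = mass_df.set_index(["participant_id", "block", "timepoint"])["body_mass_kg"]
    mass = cohort_df.set_index("participant_id")["body_mass_kg"]

    def _mass(pid, block, tp) -> float:
        if mass_df is not None:
            try:
                return float(mass_day.loc[(pid, block, tp)])
            except KeyError:
                pass
        return float(mass.loc[pid])

    battery_rows, n_failed = [], 0
    for (pid, block, tp), grp in trials_df.groupby(["participant_id", "block", "timepoint"]):
        try:
            fresh = steps_df.query(
                "participant_id == @pid and block == @block and timepoint == @tp and state == 'fresh'"
            )
            tired_rows = steps_df.query(
                "participant_id == @pid and block == @block and timepoint == @tp and state == 'tired'"
            )
            bad = fresh[["power_w", "lactate_mmol_l", "vo2_ml_min"]].isna().any(axis=1)
            if bad.any():
                log.warning("excluding %d corrupt step rows for %s/%s/%s", bad.sum(), pid, block, tp)
                fresh = fresh[~bad]
            profile = _profile_from_rows(fresh)
            tired = _profile_from_rows(tired_rows).steps
            sprint = grp[grp["test"] == "sprint"].sort_values("t_s")
            result = assemble_battery(
                participant_id=str(pid), block=str(block), timepoint=str(tp),
                body_mass=_mass(pid, block, tp),
                profile=profile, tired_steps=tired,
                sprint_power=sprint["power_w"].to_numpy(),
                sprint_period=float(sprint["sample_period_s"].iloc[0]),
                vo2max_series=_series_from_rows(grp[grp["test"] == "vo2max"]),
                time_trial=_series_from_rows(grp[grp["test"] == "tt15"]),
            )
            battery_rows.append(result.to_row())
        except Exception as exc:  # keep going; report at the end
            n_failed += 1
            log.warning("battery failed for %s/%s/%s: %s", pid, block, tp, exc)
    battery = pd.DataFrame(battery_rows)
    if n_failed:
        log.warning("%d battery records excluded", n_failed)

    session_rows = []
    sessions_path = data / "sessions.csv"
    if sessions_path.exists() and not battery.empty:
        sessions_df = _read_csv(sessions_path)
        rpe_df = _read_csv(data / "rpe.csv") if (data / "rpe.csv").exists() else None
        refs = battery[battery["timepoint"] == "pre"].set_index(["participant_id", "block"])
        # HRmax reference: highest HR observed during the pre incremental test
        hrmax = (
            trials_df[trials_df["test"] == "vo2max"]
            .groupby(["participant_id", "block", "timepoint"])["hr_bpm"]
            .max()
        )
        for (pid, block, s_idx), grp in sessions_df.groupby(
            ["participant_id", "block", "session_index"]
        ):
            try:
                ref = refs.loc[(pid, block)]
                bm = float(mass.loc[pid])
                rpe_vals = None
                srpe = float("nan")
                if rpe_df is not None:
                    sel = rpe_df.query(
                        "participant_id == @pid and block == @block and session_index == @s_idx"
                    )
                    if len(sel):
                        rpe_vals = sel["rpe_borg"].to_numpy()
                        srpe = float(sel["srpe"].iloc[0])
                summ = summarize_session(
                    _series_from_rows(grp),
                    participant_id=str(pid),
                    vo2max=float(ref["vo2max_rel"] * bm),
                    hr_max=float(hrmax.loc[(pid, block, "pre")]),
                    po_vo2max_ref=float(ref["po_vo2max"] * bm),
                    body_mass=bm,
                    rpe_per_interval=rpe_vals,
                    srpe=srpe,
                )
                row = dataclasses.asdict(summ)
                row.update({"block": block, "session_index": s_idx,
                            "prescription": grp["test"].iloc[0]})
                session_rows.append(row)
            except Exception as exc:
                n_failed += 1
                log.warning("session summary failed for %s/%s/%s: %s", pid, block, s_idx, exc)
    sessions = pd.DataFrame(session_rows)

    week_rows = []
    log_path = data / "training_log.csv"
    if log_path.exists():
        logs = _read_csv(log_path)
        for (pid, date), grp in logs.groupby(["participant_id", "date"]):
            w = summarize_week(grp, ZoneScheme(basis=config.zone_basis))
            week_rows.append(
                {"participant_id": pid, "week": date,
                 **{f"zone{z}_min": w.zone_min[z - 1] for z in range(1, 6)},
                 "trimp": w.trimp, "strength_min": w.strength_min,
                 "core_min": w.core_min, "total_min": w.total_min,
                 "feeling_legs": w.feeling_legs, "n_rejected": w.n_rejected}
            )

    _write_csv(battery, out / "battery.csv", h)
    if not sessions.empty:
        _write_csv(sessions, out / "session_summaries.csv", h)
    if week_rows:
        _write_csv(pd.DataFrame(week_rows), out / "week_summaries.csv", h)
    (out / "analyze_report.json").write_text(
        json.dumps({"config_hash": h, "n_batteries": len(battery), "n_failed": n_failed})
    )
    return out


# ---------------------------------------------------------------------------
# compare


def _hms(seconds: float) -> str:
    m, s = divmod(int(round(seconds)), 60)
    return f"{m:02d}:{s:02d}"


def cmd_compare(results_dir: str | Path, out_dir: str | Path, force: bool = False) -> Path:
    """Change analysis: per-outcome block comparison, index, text report, JSON fits."""
    res = Path(results_dir)
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is non-empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    battery = _read_csv(res / "battery.csv")
    required = {"participant_id", "block", "timepoint"} | set(OUTCOME_COLUMNS)
    missing = required - set(battery.columns)
    if missing:
        raise ValueError(f"battery table missing columns {sorted(missing)}")
    if set(battery["timepoint"]) != {"pre", "post"}:
        raise ValueError("need both 'pre' and 'post' timepoints to compare")

    # composite index over the pooled reference set (both blocks and timepoints)
    basis = IndexBasis.from_observations(battery)
    battery = battery.copy()
    battery["endurance_index"] = [
        endurance_index({k: row[k] for k in INDEX_INDICATORS}, basis)
        for _, row in battery.iterrows()
    ]

    outcomes = OUTCOME_COLUMNS + ["endurance_index"]
    long = battery.melt(
        id_vars=["participant_id", "block", "timepoint"],
        value_vars=outcomes, var_name="outcome", value_name="value",
    )
    pre = long[long["timepoint"] == "pre"].drop(columns="timepoint")
    post = long[long["timepoint"] == "post"].drop(columns="timepoint")
    scores, n_unmatched = change_scores(pre, post)

    comparisons = {}
    lines = ["outcome                 MIT pre    MIT post   HIT pre    HIT post   bxt_p   ES (label)"]
    for oc in outcomes:
        try:
            cmp_ = compare_blocks(scores, oc)
        except ValueError as exc:
            log.warning("comparison skipped for %s: %s", oc, exc)
            continue
        comparisons[oc] = dataclasses.asdict(cmp_)
        sub = scores[scores["outcome"] == oc]
        cell = {}
        for b in ("MIT", "HIT"):
            for tp, col in (("pre", "pre"), ("post", "post")):
                v = sub[sub["block"] == b][col]
                cell[(b, tp)] = f"{v.mean():.2f}"
        lines.append(
            f"{oc:<22}  {cell[('MIT','pre')]:<9} {cell[('MIT','post')]:<9} "
            f"{cell[('HIT','pre')]:<9} {cell[('HIT','post')]:<9} "
            f"{cmp_.contrast_p:5.2f}   {cmp_.d:5.2f} ({cmp_.d_label})"
        )

    fits = {}
    sess_path = res / "session_summaries.csv"
    if sess_path.exists():
        sess = _read_csv(sess_path)
        dv = scores.query("outcome == 'vo2max_rel'")
        dm = scores.query("outcome == 'body_mass'")
        for block in ("MIT", "HIT"):
            gas = sess[(sess["block"] == block) & sess["pct_vo2max"].notna()]
            agg = gas.groupby("participant_id").agg(
                minutes_ge90=("time_ge90_vo2max_s", lambda s: s.mean() / 60.0),
                pct_vo2max=("pct_vo2max", "mean"),
            )
            dvb = dv[dv["block"] == block].set_index("participant_id")
            dmb = dm[dm["block"] == block].set_index("participant_id")
            data = agg.join(dvb["delta"].rename("delta_vo2max")).join(
                dvb["pre"].rename("baseline_vo2max")
            ).join(dmb["delta"].rename("delta_body_mass")).dropna()
            for predictor in ("minutes_ge90", "pct_vo2max"):
                try:
                    fit = fit_adjusted_regression(
                        data, "delta_vo2max", predictor,
                        covariates=["baseline_vo2max", "delta_body_mass"],
                    )
                    fits[f"{block}_{predictor}"] = dataclasses.asdict(fit)
                except ValueError as exc:
                    log.warning("regression skipped (%s, %s): %s", block, predictor, exc)

    _write_csv(scores, out / "change_scores.csv", "compare")
    (out / "comparisons.json").write_text(json.dumps(
        {"comparisons": comparisons, "regressions": fits,
         "index_basis": dict(basis.maxima), "n_unmatched": n_unmatched},
        indent=1, sort_keys=True, default=float))
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return out
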
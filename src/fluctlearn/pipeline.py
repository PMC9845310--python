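"""Configuration handling and the end-to-end analysis pipeline.

A single YAML file configures everything: the energy model, the rotation
protocol, the simulated learner, the estimators, and the negative
controls.  ``run_pipeline`` chains simulation (optional), per-participant
fitting, work extraction, the Crooks and Jarzynski estimators, hysteresis
and adaptation summaries, and the two controls, writing CSV/JSON artifacts
plus a report with the config hash and every seed used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diagnostics import (
    adaptation_fraction,
    hysteresis_table,
    randomized_control,
    trajectory_from_trials,
)
from .energy import EnergyModel
from .errors import ConfigError, FluctlearnError
from .fluctuation import crooks_curve, jarzynski
from .io import trials_from_run, write_trials
from .participant import equilibration_check, fit_participant
from .protocol import Protocol, build_protocol
from .simulate import LearnerConfig, simulate_cohort
from .work import extract_work_samples

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "model_from_config",
    "protocol_from_config",
    "learner_from_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "energy": {
        "kind": "exp_quad",
        "beta": 1.0,
        "bias_deg": 0.0,
        "support_deg": [-90.0, 90.0],
        "sigma_deg": 4.0,
    },
    "protocol": {
        "theta_peak_deg": 60.0,
        "forward_length": 25,
        "plateau_length": 8,
        "n_cycles": 20,
        "baseline_length": 100,
    },
    "learner": {"proposal_scale_deg": 10.0, "steps_per_trial": 3, "init": "equilibrium"},
    "cohort": {
        "n_participants": 10,
        "beta_range": [6.0, 9.0],
        "bias_range": [-3.0, 3.0],
        "support_halfwidth_deg": 45.0,
        "theta_peak_deg": 30.0,
        "steps_per_trial": 300,
    },
    "estimators": {"n_boot": 1000, "level": 0.99, "bandwidth_rule": "silverman"},
    "controls": {"mexican_hat_sigma_deg": 4.0, "mexican_hat_beta": 1.0, "n_randomizations": 20},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Load a YAML config, merged over the package defaults."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: top level of the config must be a mapping")
    return _merge(DEFAULT_CONFIG, user)


def model_from_config(cfg: dict) -> EnergyModel:
    e = cfg["energy"]
    return EnergyModel(
        kind=e["kind"],
        beta=float(e["beta"]),
        bias=float(e["bias_deg"]),
        support=tuple(float(v) for v in e["support_deg"]),
        sigma=float(e.get("sigma_deg", 4.0)),
    )


def protocol_from_config(cfg: dict) -> Protocol:
    p = cfg["protocol"]
    return build_protocol(
        theta_peak=float(p["theta_peak_deg"]),
        forward_length=int(p["forward_length"]),
        plateau_length=int(p["plateau_length"]),
        n_cycles=int(p["n_cycles"]),
        baseline_length=int(p["baseline_length"]),
        forward_angles=p.get("forward_angles"),
    )


def learner_from_config(cfg: dict) -> LearnerConfig:
    l = cfg["learner"]
    return LearnerConfig(
        proposal_scale=float(l["proposal_scale_deg"]),
        steps_per_trial=int(l["steps_per_trial"]),
        init=str(l["init"]),
    )


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


@contextmanager
def _stage(name: str):
    logger.info("stage %s", name)
    try:
        yield
    except FluctlearnError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc


def _plateau_responses(records: pd.DataFrame, protocol: Protocol) -> np.ndarray:
    f_lo, f_hi = protocol.forward_range
    b_lo, b_hi = protocol.backward_range
    plateau_idx = [
        i
        for i in range(1, protocol.cycle_length + 1)
        if not (f_lo <= i <= f_hi or b_lo <= i <= b_hi)
    ]
    main = records[records["block"] == "main"]
    return main[main["trial_index"].isin(plateau_idx)]["response_deg"].to_numpy(dtype=float)


def run_pipeline(config: dict | str | Path | None, out_dir, seed=None, trials=None) -> dict:
    """Run the full analysis; returns the report dict written to report.json.

    ``config`` is a config dict or a YAML path (``None`` for defaults).
    ``trials`` is an optional observed trial table (DataFrame); when absent
    a cohort is simulated from the config's ``cohort`` section.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    cfg = _merge(DEFAULT_CONFIG, cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(
            ["cohort", "crooks", "jarzynski", "mexican", "randomized"], ss.spawn(5)
        )
    }
    protocol = protocol_from_config(cfg)
    learner = learner_from_config(cfg)
    est = cfg["estimators"]
    n_boot, level = int(est["n_boot"]), float(est["level"])

    with _stage("simulate"):
        if trials is None:
            co = cfg["cohort"]
            cohort_protocol = protocol
            if co.get("theta_peak_deg") is not None:
                pcfg = dict(cfg["protocol"], theta_peak_deg=co["theta_peak_deg"])
                cohort_protocol = protocol_from_config({"protocol": pcfg})
            protocol = cohort_protocol
            cohort_learner = LearnerConfig(
                proposal_scale=learner.proposal_scale,
                steps_per_trial=int(co.get("steps_per_trial", learner.steps_per_trial)),
                init=learner.init,
            )
            runs = simulate_cohort(
                protocol,
                cohort_learner,
                n_participants=int(co["n_participants"]),
                beta_range=tuple(co["beta_range"]),
                bias_range=tuple(co["bias_range"]),
                support_halfwidth=float(co.get("support_halfwidth_deg", 90.0)),
                seed=seeds["cohort"],
            )
            trials = pd.concat(
                [trials_from_run(protocol, traj) for _, _, traj in runs], ignore_index=True
            )
        write_trials(trials, out / "trials.csv")

    pids = list(trials["participant_id"].unique())
    fits, works, jz_rows, adapt_rows, hyst_frames, crooks_frames = {}, {}, [], [], [], []

    with _stage("fit"):
        for pid in pids:
            rec = trials[trials["participant_id"] == pid]
            baseline = rec[rec["block"] == "baseline"]["response_deg"].to_numpy(dtype=float)
            fit = fit_participant(baseline)
            eq = equilibration_check(_plateau_responses(rec, protocol), fit)
            fits[pid] = (fit, eq)

    with _stage("work"):
        for pid in pids:
            rec = trials[trials["participant_id"] == pid]
            traj = trajectory_from_trials(rec, protocol)
            works[pid] = extract_work_samples(fits[pid][0].model(), protocol, traj)
        pd.concat([w.to_frame() for w in works.values()], ignore_index=True).to_csv(
            out / "work_samples.csv", index=False
        )

    with _stage("estimators"):
        for i, pid in enumerate(pids):
            fit, eq = fits[pid]
            jz = jarzynski(
                works[pid], beta=fit.beta_hat, n_boot=n_boot, level=level,
                seed=seeds["jarzynski"] + i,
            )
            jz_rows.append({"participant_id": pid, **jz.to_dict()})
            cc = crooks_curve(
                works[pid], beta=fit.beta_hat, n_boot=n_boot, level=level,
                seed=seeds["crooks"] + i,
            )
            crooks_frames.append(cc.to_frame().assign(participant_id=pid))

    with _stage("diagnostics"):
        for pid in pids:
            rec = trials[trials["participant_id"] == pid]
            hyst_frames.append(hysteresis_table(rec, protocol).assign(participant_id=pid))
            frac = adaptation_fraction(rec, protocol, bias=fits[pid][0].bias_hat)
            adapt_rows.append(
                {"participant_id": pid, "adaptation_fraction": frac, "well_adapted": frac >= 0.5}
            )

    mex_flags, rand_mean = {}, None
    with _stage("controls"):
        ctl = cfg["controls"]
        for pid in pids:
            fit, _ = fits[pid]
            mex_model = fit.model(
                kind="mexican_hat",
                beta=float(ctl["mexican_hat_beta"]),
                sigma=float(ctl["mexican_hat_sigma_deg"]),
            )
            rec = trials[trials["participant_id"] == pid]
            traj = trajectory_from_trials(rec, protocol)
            w_mex = extract_work_samples(mex_model, protocol, traj)
            mex_flags[pid] = jarzynski(
                w_mex, beta=mex_model.beta, n_boot=n_boot, level=level, seed=seeds["mexican"]
            ).consistent
        n_rand = int(ctl["n_randomizations"])
        counts = []
        for r in range(n_rand):
            shuffled = randomized_control(trials, seed=seeds["randomized"] + r)
            n_cons = 0
            for pid in pids:
                fit, _ = fits[pid]
                traj = trajectory_from_trials(
                    shuffled[shuffled["participant_id"] == pid], protocol
                )
                w_r = extract_work_samples(fit.model(), protocol, traj)
                jr = jarzynski(
                    w_r, beta=fit.beta_hat, n_boot=n_boot, level=level,
                    seed=seeds["randomized"] + 1000 + r,
                )
                n_cons += int(jr.consistent)
            counts.append(n_cons)
        rand_mean = float(np.mean(counts)) if counts else None

    with _stage("write"):
        pd.DataFrame(
            [
                {
                    "participant_id": pid,
                    "beta_hat": fit.beta_hat,
                    "bias_hat": fit.bias_hat,
                    "support_lo": fit.support_hat[0],
                    "support_hi": fit.support_hat[1],
                    "loglik": fit.loglik,
                    "at_bound": fit.at_bound or "",
                    "equilibration_ks": eq.ks_distance,
                    "equilibration_pass": eq.passed,
                }
                for pid, (fit, eq) in fits.items()
            ]
        ).to_csv(out / "fits.csv", index=False)
        pd.DataFrame(jz_rows).to_csv(out / "jarzynski.csv", index=False)
        pd.concat(crooks_frames, ignore_index=True).to_csv(out / "crooks.csv", index=False)
        pd.concat(hyst_frames, ignore_index=True).to_csv(out / "hysteresis.csv", index=False)
        pd.DataFrame(adapt_rows).to_csv(out / "adaptation.csv", index=False)

        report = {
            "config": cfg,
            "config_hash": config_hash(cfg),
            "seed": seed,
            "stage_seeds": seeds,
            "n_participants": len(pids),
            "jarzynski_consistent": {
                row["participant_id"]: row["consistent"] for row in jz_rows
            },
            "controls": {
                "mexican_hat_consistent": mex_flags,
                "randomized_mean_consistent": rand_mean,
            },
        }
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
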
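"""End-to-end orchestration: simulate -> fit behavior -> simulate neurons ->
analyze -> decode -> report.

All randomness flows from a single root seed expanded into per-stage child
seeds, so a pipeline run is reproducible end to end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agents as ag
from .behavior import HistoryWeightModel, add_utility, compute_decision_variables
from .choicemodels import ChoiceModel, compare_choice_models, matching_analysis
from .decoding import control_zscores, decode
from .io import (write_counts, write_population, write_session, write_weights)
from .neural import (ResponseRegression, angle_classification, results_table,
                     task_relatedness)
from .neurons import make_population, simulate_counts
from .task import Session, TaskConfig, simulate_session
from .variables import variable_frame

__all__ = ["PipelineConfig", "run_pipeline", "make_agent"]

log = logging.getLogger("varisk")


def make_agent(name: str, **kwargs):
    table = {"logistic": ag.LogisticAgent, "history": ag.HistoryAgent,
             "rl": ag.RLAgent, "random": ag.RandomAgent,
             "alternating": ag.AlternatingAgent, "fixed": ag.FixedAgent}
    if name not in table:
        raise ValueError(f"unknown agent {name!r}")
    return table[name](**kwargs)


DEFAULT_POPULATION = [
    {"n": 10, "variables": ["object_risk_A"], "gain": 6.0},
    {"n": 5, "variables": ["object_risk_B"], "gain": 6.0},
    {"n": 5, "variables": ["action_risk_L"], "gain": 6.0},
    {"n": 5, "variables": ["object_risk_A", "object_value_A"], "gain": 6.0},
    {"n": 5, "variables": []},
]


@dataclass
class PipelineConfig:
    """Configuration of a full demo/analysis run."""

    seed: int = 0
    n_trials: int = 800
    agent: str = "logistic"
    agent_kwargs: dict = field(default_factory=dict)
    task: dict = field(default_factory=dict)
    population: list = field(default_factory=lambda: DEFAULT_POPULATION)
    run_model_comparison: bool = True
    run_decoding: bool = True
    decoding_iterations: int = 10
    out_dir: str = "varisk_out"

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full chain and write all artifacts; returns the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: np.random.default_rng(s) for name, s in zip(
        ("behavior", "neurons", "analysis", "decoding"), ss.spawn(4))}

    # --- stage 1: behavior -------------------------------------------------
    log.info("stage=simulate-behavior n_trials=%d agent=%s",
             config.n_trials, config.agent)
    task_cfg = TaskConfig(**config.task)
    agent = make_agent(config.agent, **config.agent_kwargs)
    session = simulate_session(task_cfg, agent, seeds["behavior"],
                               n_trials=config.n_trials)
    write_session(session, out / "session.csv", out / "task_config.json")

    # --- stage 2: behavioral fits -----------------------------------------
    obj_w = HistoryWeightModel(session, domain="object").fit()
    act_w = HistoryWeightModel(session, domain="action").fit()
    write_weights(obj_w, out / "weights_object.json")
    write_weights(act_w, out / "weights_action.json")
    dv = compute_decision_variables(session, obj_w, act_w)
    choice_fit = ChoiceModel(dv, session).fit()
    add_utility(dv, choice_fit)
    dv.df.to_csv(out / "decision_variables.csv", index=False)
    match = matching_analysis(session)
    report = {
        "seed": config.seed,
        "n_trials": session.n_trials,
        "choice_model": {
            "beta_value": choice_fit.beta_value,
            "beta_risk": choice_fit.beta_risk,
            "bias": choice_fit.bias,
            "aic": choice_fit.aic,
        },
        "matching_slope": match.slope,
    }
    if config.run_model_comparison:
        table = compare_choice_models(session)
        table.to_csv(out / "model_comparison.csv")
        report["best_model"] = int(table.index[table["best"]][0])

    # --- stage 3: synthetic neurons ---------------------------------------
    specs = make_population(config.population, seeds["neurons"])
    write_population(specs, out / "population.json")
    counts = simulate_counts(session, dv, specs, seeds["neurons"])
    write_counts(counts, out / "epoch_counts.csv")

    # --- stage 4: neuronal analysis ---------------------------------------
    related = task_relatedness(counts)
    reg = ResponseRegression(counts, session, dv, model="subjective_risk")
    fits = reg.fit_all()
    table = results_table(fits)
    table.to_csv(out / "response_regression.csv", index=False)
    risk_neurons = table[table["codes_risk"]]["neuron"].unique()
    frame = variable_frame(session, dv)
    labels = []
    vmask = reg.valid
    for ni, nid in enumerate(counts.neuron_ids):
        y = counts.counts[ni, vmask, counts.epoch_index("Cue")] / 0.5
        lab = angle_classification(
            y, frame["object_risk_A"].to_numpy()[vmask],
            frame["object_risk_B"].to_numpy()[vmask], neuron=nid, epoch="Cue")
        labels.append({"neuron": nid, "category": lab.category,
                       "angle": lab.angle, "significant": lab.significant})
    pd.DataFrame(labels).to_csv(out / "angle_labels.csv", index=False)

    truth = {s.neuron_id: sorted(s.gain_map) for s in specs}
    detected = {nid: nid in set(risk_neurons) for nid in counts.neuron_ids}
    confusion = {"tuned_detected": 0, "tuned_missed": 0,
                 "untuned_detected": 0, "untuned_clean": 0}
    for nid in counts.neuron_ids:
        tuned = any(v.startswith("object_risk") for v in truth[nid])
        if tuned and detected[nid]:
            confusion["tuned_detected"] += 1
        elif tuned:
            confusion["tuned_missed"] += 1
        elif detected[nid]:
            confusion["untuned_detected"] += 1
        else:
            confusion["untuned_clean"] += 1
    report["n_task_related_responses"] = int(related["task_related"].sum())
    report["n_object_risk_neurons"] = int(len(risk_neurons))
    report["risk_detection_confusion"] = confusion

    # --- stage 5: decoding -------------------------------------------------
    if config.run_decoding:
        z = control_zscores(counts, "Cue")
        risk = frame["object_risk_A"].to_numpy()
        res = decode(z, risk, seeds["decoding"], classifier="svm",
                     n_iterations=config.decoding_iterations,
                     valid=dv.valid, max_per_group=25, n_null=50,
                     variable="object_risk_A", epoch="Cue")
        report["decoding"] = {"accuracy": res.accuracy, "sem": res.sem,
                              "null_mean": float(np.mean(res.null)),
                              "p_vs_null": res.p_vs_null()}

    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
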
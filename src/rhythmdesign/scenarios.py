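"""Scenario runner: end-to-end desk-scale design studies.

Each scenario bundles a design question (rest-window constraints,
multi-frequency optimality, Nyquist blindspots, timing jitter, permutation
benchmarking) into a reproducible run that writes designs, result tables
and a JSON summary of headline numbers to an output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import __version__
from .cosinor import equispaced_design
from .gridsearch import (
    ConstraintMask,
    Partition,
    brute_force_optimal,
    check_equiphase_design,
    equiphase_construct,
    naive_constrained_design,
)
from .io import write_design
from .permtest import permutation_power
from .power import (
    PowerSpec,
    multifreq_objective,
    worstcase_eigenvalue,
    worstcase_power_over_acrophase,
)
from .stochastic import DEConfig, differential_evolution, jitter_robustness_curve

logger = logging.getLogger("rhythmdesign")

SCENARIO_TAGS = ("rest_window", "bifrequency", "trifrequency",
                 "nyquist_window", "jitter", "permpower")


@dataclass
class ScenarioConfig:
    tag: str
    out_dir: str | Path = "scenario_out"
    seed: int = 0
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.tag not in SCENARIO_TAGS:
            raise ValueError(
                f"unknown scenario {self.tag!r}; expected one of {SCENARIO_TAGS}"
            )


def _rest_window(cfg: ScenarioConfig, out: Path) -> dict:
    p = cfg.params
    n = int(p.get("n", 8))
    n_t = int(p.get("grid", 48))
    study_hours = float(p.get("study_hours", 24.0))
    windows = [float(w) for w in p.get("windows_hours", [8.0])]
    spec = PowerSpec(alpha=float(p.get("alpha", 0.05)),
                     amplitude=float(p.get("amplitude", 2.5)),
                     sigma=float(p.get("sigma", 1.0)))
    frequency = float(p.get("frequency", 1.0))
    n_phase = int(p.get("phase_grid", 512))
    partition = Partition(n_t)
    reference = worstcase_eigenvalue(equispaced_design(n), frequency)
    summary = {}
    for hours in windows:
        length_slots = int(round(hours / study_hours * n_t))
        constraint = ConstraintMask.rest_window(n_t, 0, length_slots)
        naive = naive_constrained_design(n, partition, constraint)
        optimal = brute_force_optimal(n, partition, [frequency], constraint)
        *_, d_naive = worstcase_power_over_acrophase(naive, frequency, spec, n_phase)
        *_, d_opt = worstcase_power_over_acrophase(
            optimal.design, frequency, spec, n_phase)
        key = f"window_{hours:g}h"
        summary[key] = {
            "delta_naive_pp": d_naive,
            "delta_optimal_pp": d_opt,
            "relative_noncentrality_naive":
                worstcase_eigenvalue(naive, frequency) / reference,
            "relative_noncentrality_optimal": optimal.objective / reference,
        }
        write_design(naive, out / f"naive_{hours:g}h.csv")
        write_design(optimal.design, out / f"optimal_{hours:g}h.csv")
    return summary


def _multifreq(cfg: ScenarioConfig, out: Path) -> dict:
    p = cfg.params
    if cfg.tag == "bifrequency":
        n = int(p.get("n", 12))
        freqs = [int(f) for f in p.get("frequencies", [1, 12])]
    else:
        n = int(p.get("n", 36))
        freqs = [int(f) for f in p.get("frequencies", [1, 12, 336])]
    design = equiphase_construct(n, freqs)
    checks = check_equiphase_design(design, freqs)
    write_design(design, out / f"{cfg.tag}_design.csv")
    return {
        "n": n,
        "frequencies": freqs,
        "j_value": multifreq_objective(design, freqs).j_value,
        "per_frequency": {
            str(f): {"xi_min": c["xi_min"], "equiphase": bool(c["equiphase"])}
            for f, c in checks.items()
        },
    }


def _nyquist_window(cfg: ScenarioConfig, out: Path) -> dict:
    p = cfg.params
    n = int(p.get("n", 12))
    f_max = int(p.get("f_max", n // 2))
    freqs = list(range(1, f_max + 1))
    spec = PowerSpec(alpha=float(p.get("alpha", 0.05)),
                     amplitude=float(p.get("amplitude", 1.0)),
                     sigma=float(p.get("sigma", 1.0)))
    config = DEConfig(
        pop_size=int(p.get("pop_size", 50)),
        n_iter=int(p.get("n_iter", 100)),
        seed=cfg.seed,
    )
    result = differential_evolution(
        lambda d: multifreq_objective(d, freqs).j_value, n, config)
    write_design(result.design, out / "de_design.csv")
    equi = multifreq_objective(equispaced_design(n), freqs, spec=spec)
    opt = multifreq_objective(result.design, freqs, spec=spec)
    return {
        "frequencies": freqs,
        "j_equispaced": equi.j_value,
        "j_optimized": opt.j_value,
        "worst_power_equispaced": equi.worst_case_power,
        "worst_power_optimized": opt.worst_case_power,
    }


def _jitter(cfg: ScenarioConfig, out: Path) -> dict:
    p = cfg.params
    n = int(p.get("n", 24))
    f_max = int(p.get("f_max", n // 2))
    freqs = list(range(1, f_max + 1))
    spec = PowerSpec(alpha=float(p.get("alpha", 0.05)),
                     amplitude=float(p.get("amplitude", 1.0)),
                     sigma=float(p.get("sigma", 1.0)))
    noise_grid = [float(x) for x in p.get("noise_grid", [0.0, 0.002, 0.005, 0.01])]
    n_rep = int(p.get("n_rep", 50))
    config = DEConfig(pop_size=int(p.get("pop_size", 40)),
                      n_iter=int(p.get("n_iter", 60)), seed=cfg.seed)
    irregular = differential_evolution(
        lambda d: multifreq_objective(d, freqs).j_value, n, config).design
    tables = {}
    for name, design in [("equispaced", equispaced_design(n)),
                         ("irregular", irregular)]:
        tbl = jitter_robustness_curve(design, freqs, spec, noise_grid,
                                      n_rep=n_rep, seed=cfg.seed)
        tbl.to_csv(out / f"jitter_{name}.csv", index=False)
        tables[name] = tbl
    return {
        name: {"power_at_zero_noise": float(tbl["median"].iloc[0]),
               "power_at_max_noise": float(tbl["median"].iloc[-1])}
        for name, tbl in tables.items()
    }


def _permpower(cfg: ScenarioConfig, out: Path) -> dict:
    p = cfg.params
    n = int(p.get("n", 12))
    design = equispaced_design(n)
    freqs = np.asarray(p.get("frequencies", list(range(1, n // 2 + 1))), float)
    phis = np.linspace(0, 2 * np.pi, int(p.get("n_acro", 4)), endpoint=False)
    table = permutation_power(
        design, freqs, phis,
        amplitude=float(p.get("amplitude", 2.0)),
        sigma=float(p.get("sigma", 1.0)),
        alpha=float(p.get("alpha", 0.05)),
        n_samp=int(p.get("n_samp", 50)),
        n_perm=int(p.get("n_perm", 50)),
        statistic_kind=p.get("statistic", "Tinf"),
        seed=cfg.seed,
    )
    table.to_csv(out / "permutation_power.csv", index=False)
    worst = table.groupby("frequency")["min_power"].first()
    return {"min_power_per_frequency": {f"{f:g}": float(v)
                                        for f, v in worst.items()}}


_RUNNERS = {
    "rest_window": _rest_window,
    "bifrequency": _multifreq,
    "trifrequency": _multifreq,
    "nyquist_window": _nyquist_window,
    "jitter": _jitter,
    "permpower": _permpower,
}


def run_scenario(config: ScenarioConfig) -> dict:
    """Run a scenario, write its artefacts, and return the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    start = time.time()
    summary = _RUNNERS[config.tag](config, out)
    runtime = time.time() - start
    payload = {
        "scenario": config.tag,
        "seed": config.seed,
        "params": config.params,
        "version": __version__,
        "runtime_seconds": round(runtime, 3),
        "summary": summary,
    }
    (out / "summary.json").write_text(json.dumps(payload, indent=2) + "\n")
    logger.info("scenario %s finished in %.2fs -> %s", config.tag, runtime, out)
    return payload
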
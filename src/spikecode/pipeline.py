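"""End-to-end orchestration: configuration, behavior summary, report bundle."""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import coding, dynamics, information, periodicity, variance
from .data import (CLASSES, NeuronRecord, population_tensor, read_session,
                   write_session)
from .simulate import SimulationSpec, simulate_population

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Every analysis parameter, with the study defaults; fully serialisable."""

    input_dir: str = ""
    output_dir: str = "out"
    task: str = "TPDT"
    window_ms: float = 200.0
    step_ms: float = 50.0
    t_start: float = -1.0
    t_end: float = 7.5
    alpha_roc: float = 0.05
    alpha_info: float = 0.01
    n_perm_roc: int = 1000
    n_perm_info: int = 1000
    stability_bins: int = 4
    profile_run_bins: int = 4
    info_threshold_bits: float = 0.25
    latency_consecutive: int = 5
    latency_step_ms: float = 10.0
    autocorr_bin_ms: float = 40.0
    autocorr_step_ms: float = 20.0
    fit_min_lag_ms: float = 40.0
    fit_max_lag_ms: float = 960.0
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def validate(self) -> None:
        if not self.input_dir:
            raise ValueError("input_dir is required")
        if not Path(self.input_dir).exists():
            raise ValueError(f"input_dir {self.input_dir!r} does not exist")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed (crc32 of the stage name mixed in)."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


def summarize_behavior(neurons: Sequence[NeuronRecord]) -> pd.DataFrame:
    """Percent-correct per session, task and class (and overall).

    One row per (session, task) plus per-class columns; a final row gives
    the mean and SD across sessions.
    """
    rows = []
    by_session: dict[tuple[str, str], list] = {}
    for nr in neurons:
        for tr in nr.trials:
            by_session.setdefault((nr.session_id, tr.task), []).append(tr)
    if not by_session:
        raise ValueError("no trials")
    for (ses, task), trials in sorted(by_session.items()):
        row = {"session_id": ses, "task": task,
               "percent_correct": 100.0 * np.mean(
                   [t.outcome == "hit" for t in trials])}
        for c in CLASSES:
            ct = [t for t in trials if t.class_label == c]
            if not ct:
                logger.warning("session %s/%s: class %s empty", ses, task, c)
                row[f"percent_{c}"] = np.nan
            else:
                row[f"percent_{c}"] = 100.0 * np.mean(
                    [t.outcome == "hit" for t in ct])
        rows.append(row)
    df = pd.DataFrame(rows)
    for task in df["task"].unique():
        sub = df[df["task"] == task]
        rows.append({"session_id": "MEAN", "task": task,
                     "percent_correct": sub["percent_correct"].mean(),
                     **{f"percent_{c}": sub[f"percent_{c}"].mean()
                        for c in CLASSES},
                     "sd_across_sessions": sub["percent_correct"].std(ddof=0)})
    return pd.DataFrame(rows)


def neuron_info_profile(nr: NeuronRecord, cfg: AnalysisConfig,
                        rng: np.random.Generator) -> information.NeuronInfoProfile:
    iper = periodicity.periodicity_info(nr, "P1", cfg.task,
                                        n_perm=cfg.n_perm_info,
                                        alpha=cfg.alpha_info, seed=rng)
    i1p1 = information.info_1s(nr, "P1", cfg.task, n_perm=cfg.n_perm_info,
                               alpha=cfg.alpha_info, seed=rng)
    i1p2 = information.info_1s(nr, "P2", cfg.task, n_perm=cfg.n_perm_info,
                               alpha=cfg.alpha_info, seed=rng)
    return information.NeuronInfoProfile(
        neuron_id=nr.neuron_id, i_per=iper.bits,
        i_per_significant=iper.significant, i_1s_p1=i1p1.bits,
        i_1s_p1_significant=i1p1.significant, i_1s_p2=i1p2.bits,
        i_1s_p2_significant=i1p2.significant)


def run_full_analysis(config: AnalysisConfig,
                      neurons: Sequence[NeuronRecord] | None = None) -> dict:
    """Run every analysis stage and write machine-readable tables.

    Deterministic under a fixed config seed; any stage failure aborts with
    the stage name while earlier outputs remain on disk.
    """
    config.validate()
    if neurons is None:
        neurons = read_session(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    bundle: dict = {"config": config}
    stage = "behavior"
    try:
        t0 = time.perf_counter()
        behavior = summarize_behavior(neurons)
        behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
        bundle["behavior"] = behavior
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "coding"
        rng = np.random.default_rng(stage_seed(config.seed, stage))
        results, rows = [], []
        for nr in neurons:
            res = coding.neuron_coding_masks(
                nr, alpha=config.alpha_roc, n_perm=config.n_perm_roc,
                stability=config.stability_bins, window_ms=config.window_ms,
                step_ms=config.step_ms, t_start=config.t_start,
                t_end=config.t_end, task=config.task, seed=rng)
            results.append(res)
            series = res["series"]
            for bc, word, lab in zip(series.bin_centers,
                                     series.word_strings(), res["labels"]):
                rows.append({"neuron_id": nr.neuron_id, "bin_center_s": bc,
                             "word": word, "profile": lab})
        pd.DataFrame(rows).to_csv(out / "coding.tsv", sep="\t", index=False)
        fractions = {p: coding.population_coding_fraction(results, p)
                     for p in coding.PROFILES}
        frac_df = pd.DataFrame({"bin_center_s": results[0]["series"].bin_centers,
                                **fractions})
        frac_df.to_csv(out / "coding_fractions.tsv", sep="\t", index=False)
        bundle["coding_fractions"] = frac_df

        stage = "variance"
        pop = population_tensor(neurons, True, config.window_ms,
                                config.step_ms, config.t_start, config.t_end,
                                config.task)
        vs = variance.variance_series(pop)
        pd.DataFrame({"bin_center_s": vs.bin_centers, "var_cod": vs.var_cod,
                      "var_p1": vs.var_p1, "var_p2": vs.var_p2,
                      "var_dec": vs.var_dec}).to_csv(
            out / "variance.tsv", sep="\t", index=False)
        bundle["variance"] = vs

        stage = "information"
        rng = np.random.default_rng(stage_seed(config.seed, stage))
        profiles = [neuron_info_profile(nr, config, rng) for nr in neurons]
        profiles = information.classify_neurons(profiles,
                                                config.info_threshold_bits)
        pd.DataFrame([asdict(p) for p in profiles]).to_csv(
            out / "profiles.tsv", sep="\t", index=False)
        bundle["profiles"] = profiles

        stage = "latency"
        rng = np.random.default_rng(stage_seed(config.seed, stage))
        lat_rows = []
        for nr in neurons:
            r = dynamics.response_latency(nr, config.window_ms,
                                          config.latency_step_ms,
                                          config.latency_consecutive,
                                          config.alpha_roc,
                                          n_perm=config.n_perm_roc, seed=rng,
                                          task=config.task)
            c = dynamics.coding_latency(nr, config.window_ms,
                                        config.latency_step_ms,
                                        config.latency_consecutive,
                                        config.alpha_roc,
                                        n_perm=config.n_perm_roc, seed=rng,
                                        task=config.task)
            lat_rows.append({"neuron_id": nr.neuron_id,
                             "response_latency_ms": r.latency_ms,
                             "coding_latency_ms": c.latency_ms})
        pd.DataFrame(lat_rows).to_csv(out / "latency.tsv", sep="\t", index=False)
        bundle["latencies"] = pd.DataFrame(lat_rows)

        stage = "timescale"
        mats = [dynamics.basal_count_matrix(nr, config.autocorr_bin_ms,
                                            config.autocorr_step_ms)
                for nr in neurons]
        lags, aut = dynamics.population_autocorrelation(
            mats, config.autocorr_bin_ms, config.autocorr_step_ms)
        fit = dynamics.fit_timescale(lags, aut, config.fit_min_lag_ms,
                                     config.fit_max_lag_ms,
                                     seed=stage_seed(config.seed, stage))
        (out / "tau.json").write_text(json.dumps(
            {"tau_ms": fit.tau_ms, "amplitude": fit.amplitude,
             "offset": fit.offset}, indent=2))
        bundle["timescale"] = fit

        stage = "choice_probability"
        cp_rows = []
        decision_coders = [nr for nr, res in zip(neurons, results)
                           if res["coder_flags"]["decision"]]
        cp_curves = []
        for nr in decision_coders:
            centers, cp, excl = coding.choice_probability(
                nr, config.window_ms, config.step_ms)
            if excl:
                logger.info("CP: neuron %s excluded classes %s",
                            nr.neuron_id, excl)
            if not np.all(np.isnan(cp)):
                cp_curves.append(cp)
                for bc, v in zip(centers, cp):
                    cp_rows.append({"neuron_id": nr.neuron_id,
                                    "bin_center_s": bc, "cp": v})
        pd.DataFrame(cp_rows).to_csv(out / "cp.tsv", sep="\t", index=False)
        bundle["cp_mean"] = (np.nanmean(np.stack(cp_curves), axis=0)
                             if cp_curves else None)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle


def simulate_session_to_dir(spec: SimulationSpec, out_dir: str | Path) -> None:
    """Simulate a session and write the TSV session plus ground truth."""
    neurons, truth = simulate_population(spec)
    write_session(neurons, out_dir)
    truth.to_csv(Path(out_dir) / "ground_truth.tsv", sep="\t", index=False)
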
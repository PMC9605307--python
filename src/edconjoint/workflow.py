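"""End-to-end pipeline: design -> ratings -> models -> mindsets -> PVI.

A single config drives everything; every stage seed is derived explicitly
from the config seed and echoed, together with all effective defaults, into a
manifest so a rerun of the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .design import generate_design, save_design, validate_design
from .deconstruct import fit_panel
from .instrument import default_instrument, load_instrument
from .mindsets import (cluster_respondents, compare_mindsets, mindset_report,
                       select_k, split_half_reliability)
from .pvi import build_pvi
from .simulate import (DEFAULT_HETEROGENEITY_SD, DEFAULT_N_PER_MINDSET,
                       RatingsTable, SimulationConfig,
                       reference_mindset_profiles, simulate_responses)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, with all seeds explicit."""

    output_dir: str
    instrument_path: str | None = None  # None -> bundled ED instrument
    mode: str = "simulate"              # "simulate" | "external"
    ratings_path: str | None = None     # required for mode="external"
    n_per_mindset: tuple[int, ...] = DEFAULT_N_PER_MINDSET
    heterogeneity_sd: float = DEFAULT_HETEROGENEITY_SD
    n_vignettes: int = 48
    size_range: tuple[int, int] = (2, 4)
    k: int | None = 3                   # None -> silhouette sweep over k_range
    k_range: tuple[int, int] = (2, 6)
    restarts: int = 50
    pvi_n_sim: int = 5000
    pvi_noise_sd: float = 10.0
    pvi_candidates: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("simulate", "external"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "external" and not self.ratings_path:
            raise ConfigError("mode='external' requires ratings_path")
        if self.mode == "external" and self.ratings_path and \
                not Path(self.ratings_path).exists():
            raise ConfigError(f"ratings file {self.ratings_path} not found")
        if self.instrument_path and not Path(self.instrument_path).exists():
            raise ConfigError(f"instrument file {self.instrument_path} not found")
        if self.k is None and self.k_range[0] >= self.k_range[1]:
            raise ConfigError("empty k_range")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        for key in ("n_per_mindset", "size_range", "k_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    config: PipelineConfig
    book: Any
    ratings: RatingsTable
    respondent_models: dict
    total_panel: Any
    solution: Any
    anova: pd.DataFrame
    reliability: tuple[float, float]
    pvi: Any
    manifest: dict


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ["design", "simulate", "cluster", "reliability", "pvi"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1))
            for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order and write the artifact bundle.

    Outputs under ``config.output_dir``: design.csv/json, ratings.csv,
    truth.csv (simulated mode), respondent_models.csv, total_panel.csv,
    mindset_report.csv, anova.csv, reliability.json, pvi.json, manifest.json.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    def stage(name):
        logger.info("stage: %s", name)

    stage("instrument")
    instrument = (load_instrument(config.instrument_path)
                  if config.instrument_path else default_instrument())

    stage("design")
    if config.mode == "simulate":
        n_respondents = int(sum(config.n_per_mindset))
    else:
        ratings_df = pd.read_csv(config.ratings_path)
        n_respondents = ratings_df.respondent_id.nunique()
    book = generate_design(instrument, n_respondents, seed=seeds["design"],
                           n_vignettes=config.n_vignettes,
                           size_range=config.size_range)
    save_design(book, out / "design.csv")
    save_design(book, out / "design.json")

    stage("ratings")
    if config.mode == "simulate":
        sim_cfg = SimulationConfig(
            n_per_mindset=tuple(config.n_per_mindset),
            respondent_heterogeneity_sd=config.heterogeneity_sd,
            seed=seeds["simulate"],
        )
        ratings = simulate_responses(book, reference_mindset_profiles(), sim_cfg)
        ratings.save(out / "ratings.csv", out / "truth.csv")
    else:
        ratings = RatingsTable(ratings=ratings_df)
        ratings.validate()

    stage("deconstruct")
    models, total_panel, data = fit_panel(book, ratings)
    rm_rows = []
    for rid, m in models.items():
        rm_rows.append({"respondent_id": rid, "term": "Additive constant",
                        "coefficient": m.constant})
        rm_rows.extend({"respondent_id": rid, "term": mid, "coefficient": b}
                       for mid, b in m.coefficients.items())
    pd.DataFrame(rm_rows).to_csv(out / "respondent_models.csv", index=False,
                                 float_format=FLOAT_FORMAT)
    total_panel.to_frame().to_csv(out / "total_panel.csv", index=False,
                                  float_format=FLOAT_FORMAT)

    stage("mindsets")
    model_list = list(models.values())
    silhouette_by_k = None
    k = config.k
    if k is None:
        k, silhouette_by_k = select_k(
            model_list, range(config.k_range[0], config.k_range[1] + 1),
            seed=seeds["cluster"], restarts=config.restarts)
    solution = cluster_respondents(model_list, k=k, seed=seeds["cluster"],
                                   restarts=config.restarts, data=data)
    solution.silhouette_by_k = silhouette_by_k
    anova = compare_mindsets(solution)
    anova.to_csv(out / "anova.csv", index=False, float_format=FLOAT_FORMAT)
    mindset_report(solution, anova).to_csv(out / "mindset_report.csv",
                                           index=False, float_format=FLOAT_FORMAT)

    stage("reliability")
    rel = split_half_reliability(model_list, seed=seeds["reliability"], data=data)
    (out / "reliability.json").write_text(
        json.dumps({"r_half1_vs_total": rel[0], "r_half2_vs_total": rel[1]},
                   indent=1), encoding="utf-8")

    stage("pvi")
    pvi = build_pvi(solution, n_sim=config.pvi_n_sim,
                    answer_noise_sd=config.pvi_noise_sd,
                    n_candidate_subsets=config.pvi_candidates,
                    seed=seeds["pvi"])
    pvi.save(out / "pvi.json")

    manifest = {
        "package_version": __version__,
        "config": {k_: (list(v) if isinstance(v, tuple) else v)
                   for k_, v in asdict(config).items()},
        "stage_seeds": seeds,
        "n_respondents": n_respondents,
        "k": k,
        "base_sizes": solution.base_sizes,
        "design_ok": validate_design(book).all_ok,
        "pvi_questions": list(pvi.question_ids),
        "pvi_estimated_accuracy": pvi.estimated_accuracy,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                       encoding="utf-8")
    return PipelineResult(config=config, book=book, ratings=ratings,
                          respondent_models=models, total_panel=total_panel,
                          solution=solution, anova=anova, reliability=rel,
                          pvi=pvi, manifest=manifest)
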
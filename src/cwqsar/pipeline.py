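"""End-to-end modelling: split search, optimization, reporting.

Stage 1 selects the data split with the Las Vegas search; stage 2 runs
the full Monte Carlo optimization on the selected split, fits the final
C0/C1 line on the active training block, and assembles per-set metrics,
the applicability-domain report and the per-compound prediction table.
A single master seed drives both stages (subsystem seeds are derived from
it), so a fixed configuration reproduces every artifact exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .attributes import build_attribute_dictionary
from .dataset import Dataset
from .diagnostics import DefectReport, build_defect_report
from .errors import ConfigurationError
from .labels import SET_LABELS
from .metrics import MetricsReport, evaluate_set
from .model import ModelConfig, QsarModel, descriptor_profile, fit_regression
from .optimizer import OptimizationTrace, OptimizerConfig, optimize
from .splitting import EQUAL_PROPORTIONS, SplitAssignment, las_vegas_select


@dataclass
class PipelineConfig:
    """Everything a full run needs besides the data."""

    t: int = 3
    n_epochs: int = 15
    target_function: str = "TF1"
    seed: int = 0
    k_splits: int = 10
    probe_epochs: int = 3
    proportions: tuple = EQUAL_PROPORTIONS
    step_magnitude: float = 0.5
    initial_weight: float = 1.0
    split_criterion: str = "iic_cii"


@dataclass
class PipelineResult:
    split: Optional[SplitAssignment]
    model: QsarModel
    trace: OptimizationTrace
    metrics: dict[str, MetricsReport]
    defect_report: DefectReport
    predictions: pd.DataFrame
    candidate_scores: list = field(default_factory=list)


def _derived_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds below 2^31 derived from the master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def fit_split(labeled: Dataset, config: PipelineConfig, seed: Optional[int] = None) -> PipelineResult:
    """Stage 2: optimize weights on an already-labeled dataset and report."""
    opt_seed = config.seed if seed is None else seed
    dictionary = build_attribute_dictionary(labeled, config.t)
    opt_config = OptimizerConfig(
        t=config.t,
        n_epochs=config.n_epochs,
        target_function=config.target_function,
        seed=opt_seed,
        step_magnitude=config.step_magnitude,
        initial_weight=config.initial_weight,
    )
    weights, trace = optimize(labeled, dictionary, opt_config)

    profiles = {r.id: descriptor_profile(r.smiles, weights) for r in labeled}
    active = labeled.subset("active")
    c0, c1 = fit_regression(
        [profiles[r.id][0] for r in active], [r.endpoint for r in active]
    )
    defect_report = build_defect_report(labeled, dictionary)
    model = QsarModel(
        weights=weights,
        c0=c0,
        c1=c1,
        config=ModelConfig(config.t, config.n_epochs, config.target_function, opt_seed),
        dictionary=dictionary,
        d_bar=defect_report.d_bar,
    )

    metrics: dict[str, MetricsReport] = {}
    for label in SET_LABELS:
        block = labeled.subset(label)
        if len(block) < 2 or any(r.endpoint is None for r in block):
            continue
        obs = np.asarray([r.endpoint for r in block])
        dcw = np.asarray([profiles[r.id][0] for r in block])
        calc = c0 + c1 * dcw
        metrics[label] = evaluate_set(obs, calc, dcw_values=dcw)

    predictions = pd.DataFrame(
        {
            "id": [r.id for r in labeled],
            "smiles": [r.smiles for r in labeled],
            "set": [r.set_label for r in labeled],
            "endpoint": [r.endpoint for r in labeled],
            "dcw": [profiles[r.id][0] for r in labeled],
            "predicted": [c0 + c1 * profiles[r.id][0] for r in labeled],
            "n_unseen_attributes": [profiles[r.id][1] for r in labeled],
            "defect": [defect_report.compound_defects[r.id] for r in labeled],
            "in_domain": [defect_report.in_domain_flags[r.id] for r in labeled],
        }
    )
    return PipelineResult(None, model, trace, metrics, defect_report, predictions)


def run_full_pipeline(dataset: Dataset, config: PipelineConfig) -> PipelineResult:
    """Stage 1 (Las Vegas split search) followed by stage 2 (model build)."""
    if len(dataset) < 8:
        raise ConfigurationError(f"dataset too small: n={len(dataset)}")
    lv_seed, opt_seed = _derived_seeds(config.seed, 2)
    split = las_vegas_select(
        dataset,
        k=config.k_splits,
        probe_epochs=config.probe_epochs,
        t=config.t,
        seed=lv_seed,
        proportions=config.proportions,
        criterion=config.split_criterion,
    )
    labeled = split.apply(dataset)
    result = fit_split(labeled, config, seed=opt_seed)
    result.split = split
    result.candidate_scores = split.candidate_scores
    return result
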
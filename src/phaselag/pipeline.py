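"""End-to-end two-session reliability experiment.

For every subject and session the pipeline cuts/samples epochs according
to each segmentation scheme, derives PLI and dbWPLI connectivity matrices
from Hanning-tapered Fourier coefficients, averages them over the
analysis band, reduces each matrix to whole-brain connectivity and the
surrogate-normalised graph metrics, and finally computes one ICC(3,1)
per (scheme combination x method x metric) cell across subjects.
Subjects lacking enough epochs for a combination are excluded from that
cell only (per-approach subsamples); cells with fewer than 3 surviving
subjects are marked unavailable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .config import PopulationConfig
from .connectivity import (ALPHA_BAND, dbwpli_matrix, fourier_coefficients,
                           pli_matrix, whole_brain)
from .graph import surrogate_normalise
from .segmentation import (CONSTANT_AMOUNT_PARENTS, InsufficientDataError,
                           SegmentationScheme, cut_epochs, nested_resegment,
                           sample_epochs, table_schemes)
from .synthetic import make_population, session_seed, simulate_session
from .reliability import icc_3_1

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "run_scheme",
    "icc_table_from_scores",
    "WHOLE_BRAIN",
    "GRAPH_METRICS",
    "ALL_METRICS",
]

WHOLE_BRAIN = "whole_brain"
GRAPH_METRICS = ("c_w_norm", "l_w_norm", "swi")
ALL_METRICS = (WHOLE_BRAIN,) + GRAPH_METRICS

_MATRIX_FUNCS = {"pli": pli_matrix, "dbwpli": dbwpli_matrix}


@dataclass(frozen=True)
class ExperimentConfig:
    """What to compute on top of a simulated population."""

    population: PopulationConfig
    approaches: Tuple[str, ...] = ("long_epochs", "short_epochs",
                                   "constant_amount")
    methods: Tuple[str, ...] = ("pli", "dbwpli")
    metrics: Tuple[str, ...] = ALL_METRICS
    band: Tuple[float, float] = ALPHA_BAND
    n_surrogates: int = 1000

    def __post_init__(self):
        known = set(table_schemes())
        if not set(self.approaches) <= known:
            raise ValueError(f"approaches must be a subset of {sorted(known)}")
        if not set(self.methods) <= set(_MATRIX_FUNCS):
            raise ValueError("methods must be a subset of {'pli', 'dbwpli'}")
        if not set(self.metrics) <= set(ALL_METRICS):
            raise ValueError(f"metrics must be a subset of {ALL_METRICS}")


@dataclass
class ExperimentResult:
    """Tidy per-subject scores, the ICC table, and run provenance."""

    scores: pd.DataFrame
    icc_table: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _metric_values(matrix, metrics: Sequence[str], n_surrogates: int,
                   seed: int) -> dict:
    out = {}
    if WHOLE_BRAIN in metrics:
        out[WHOLE_BRAIN] = whole_brain(matrix)
    graph_wanted = [m for m in metrics if m in GRAPH_METRICS]
    if graph_wanted:
        gm = surrogate_normalise(np.abs(matrix.weights),
                                 n_surrogates=n_surrogates, seed=seed)
        for m in graph_wanted:
            out[m] = getattr(gm, m)
    return out


def _combo_epochs(scheme: SegmentationScheme, epoch_cache: dict,
                  base_seed: int, subject_id: int, session_id: int,
                  exclusions: list):
    """Yield (combo, EpochSet) for every combination the data supports.

    The constant-amount design selects 20 six-second parent epochs once
    and re-segments them, so all its combinations share identical samples;
    the other designs draw each combination independently.  Selection
    seeds derive from the global seed and the (subject, session, length,
    n) cell, independent of the data-generation streams.
    """
    if scheme.approach == "constant_amount":
        try:
            parents = sample_epochs(
                epoch_cache[6], CONSTANT_AMOUNT_PARENTS,
                seed=derive_seed(base_seed, 3, subject_id, session_id, 6, 0))
        except InsufficientDataError:
            exclusions.append(dict(subject=subject_id, session=session_id,
                                   approach=scheme.approach, n_epochs=None,
                                   epoch_length=None,
                                   reason="fewer than "
                                   f"{CONSTANT_AMOUNT_PARENTS} 6-s epochs"))
            return
        for n, length in scheme.combos:
            yield (n, length), (parents if length == 6
                                else nested_resegment(parents, length))
    else:
        for n, length in scheme.combos:
            try:
                selected = sample_epochs(
                    epoch_cache[length], n,
                    seed=derive_seed(base_seed, 3, subject_id, session_id,
                                     length, n))
            except InsufficientDataError:
                exclusions.append(dict(subject=subject_id,
                                       session=session_id,
                                       approach=scheme.approach,
                                       n_epochs=n, epoch_length=length,
                                       reason="insufficient epochs"))
                continue
            yield (n, length), selected


def _collect_scores(population: PopulationConfig,
                    schemes: Dict[str, SegmentationScheme],
                    methods: Sequence[str], metrics: Sequence[str],
                    band: Tuple[float, float], n_surrogates: int,
                    exclusions: list) -> pd.DataFrame:
    needed_lengths = sorted({l for s in schemes.values()
                             for l in s.epoch_lengths}
                            | ({6} if "constant_amount" in schemes else set()))
    rows = []
    for model in make_population(population):
        for session_id in (1, 2):
            rec = simulate_session(
                model, population, session_id,
                seed=session_seed(population, model.subject_id, session_id))
            epoch_cache = {l: cut_epochs(rec, l) for l in needed_lengths}
            for approach, scheme in schemes.items():
                for combo, selected in _combo_epochs(
                        scheme, epoch_cache, population.seed,
                        model.subject_id, session_id, exclusions):
                    n, length = combo
                    coeffs = fourier_coefficients(selected)
                    for method in methods:
                        matrix = _MATRIX_FUNCS[method](coeffs, band=band)
                        gseed = derive_seed(population.seed, 4,
                                            model.subject_id, session_id,
                                            length, n,
                                            0 if method == "pli" else 1)
                        values = _metric_values(matrix, metrics,
                                                n_surrogates, gseed)
                        for metric, value in values.items():
                            rows.append(dict(
                                subject=model.subject_id,
                                session=session_id, approach=approach,
                                n_epochs=n, epoch_length=length,
                                method=method, metric=metric, value=value))
    return pd.DataFrame(rows)


def run_scheme(population: PopulationConfig, scheme: SegmentationScheme,
               methods: Sequence[str] = ("pli", "dbwpli"),
               metrics: Sequence[str] = (WHOLE_BRAIN,),
               band: Tuple[float, float] = ALPHA_BAND,
               n_surrogates: int = 1000) -> ExperimentResult:
    """Run the pipeline for a single segmentation scheme.

    ``scheme`` may carry any (n_epochs, epoch_length) grid — e.g. a single
    combination, or an epoch-number sweep at fixed length — with the
    selection semantics of its ``approach``.
    """
    exclusions: list = []
    scores = _collect_scores(population, {scheme.approach: scheme}, methods,
                             metrics, band, n_surrogates, exclusions)
    return ExperimentResult(scores=scores,
                            icc_table=icc_table_from_scores(scores),
                            manifest=dict(population=population.to_dict(),
                                          exclusions=exclusions))


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Simulate the cohort and compute the full reliability table."""
    pop = config.population
    schemes = {a: table_schemes()[a] for a in config.approaches}
    exclusions: list = []
    scores = _collect_scores(pop, schemes, config.methods, config.metrics,
                             config.band, config.n_surrogates, exclusions)
    manifest = dict(
        population=pop.to_dict(),
        experiment={k: v for k, v in dataclasses.asdict(config).items()
                    if k != "population"},
        exclusions=exclusions,
    )
    return ExperimentResult(scores=scores,
                            icc_table=icc_table_from_scores(scores),
                            manifest=manifest)


def icc_table_from_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """One ICC(3,1) row per (approach, combo, method, metric) cell.

    Only subjects with finite values in both sessions enter a cell; cells
    with fewer than 3 such subjects are marked unavailable.
    """
    cells = []
    group_cols = ["approach", "n_epochs", "epoch_length", "method", "metric"]
    if scores.empty:
        return pd.DataFrame(columns=group_cols)
    for keys, g in scores.groupby(group_cols, sort=True):
        wide = g.pivot_table(index="subject", columns="session",
                             values="value", aggfunc="first")
        wide = wide.reindex(columns=[1, 2]).dropna()
        wide = wide[np.isfinite(wide).all(axis=1)]
        row = dict(zip(group_cols, keys))
        if len(wide) < 3:
            row.update(icc=np.nan, icc_clipped=np.nan, ci_low=np.nan,
                       ci_high=np.nan, p_value=np.nan,
                       n_subjects=len(wide), category="unavailable")
        else:
            res = icc_3_1(wide.to_numpy())
            row.update(icc=res.icc, icc_clipped=res.icc_clipped,
                       ci_low=res.ci_low, ci_high=res.ci_high,
                       p_value=res.p_value, n_subjects=res.n_subjects,
                       category=res.category)
        cells.append(row)
    return pd.DataFrame(cells)
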
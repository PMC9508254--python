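"""Monte-Carlo validation of network metrics against spatial null models.

The workflow: simulate a battery of replicate patterns under each null
model, label crowns by random labelling, build the requested competition
networks per replicate, and collect the metric bundles.  Metrics are then
judged on whether they *distinguish* the ecological process groups —
cluster (Matérn, Thomas), random (CSR) and Gibbs (hard-core, Strauss) —
via one-way ANOVA with Tukey HSD pairwise comparisons plus a simple
range-overlap screen.  An observed stem map can be placed against the same
null distributions with model parameters estimated from the data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError
from .network_build import as_tree_table, build_cl, build_cs, build_wcl
from .network_metrics import MetricSet, metric_set
from .point_process import (CrownDistribution, MarkedPattern, NullModelConfig,
                            Window, assign_crown_radii, fit_crown_gamma,
                            simulate)

__all__ = [
    "MODEL_ORDER", "CLUSTER_MODELS", "GIBBS_MODELS", "MODEL_GROUPS",
    "SimulationBatch", "ComparisonReport", "EmpiricalComparison",
    "default_configs", "run_null_battery", "compare_models",
    "classify_metric", "empirical_vs_null", "sensitivity_sweep",
]

logger = logging.getLogger(__name__)

MODEL_ORDER = ("CSR", "MATERN", "THOMAS", "HARDCORE", "STRAUSS")
CLUSTER_MODELS = ("MATERN", "THOMAS")
GIBBS_MODELS = ("HARDCORE", "STRAUSS")
MODEL_GROUPS = {"cluster": CLUSTER_MODELS, "csr": ("CSR",), "gibbs": GIBBS_MODELS}

_METRIC_FIELDS = ("N", "E", "k", "C", "D", "L", "k_weighted")

_NET_BUILDERS = {
    "CS": lambda trees: build_cs(trees),
    "CL": lambda trees: build_cl(trees),
    "WCL": lambda trees: build_wcl(trees),
}


def default_configs(kappa: float = 0.015, **overrides) -> dict:
    """The five default null-model configurations."""
    return {name: NullModelConfig(model=name, kappa=kappa, **overrides)
            for name in MODEL_ORDER}


@dataclass
class SimulationBatch:
    """Per-(model, network) metric distributions over replicates."""

    metrics: dict                      # (model, net_type) -> list[MetricSet]
    configs: dict                      # model -> NullModelConfig
    crown_dist: CrownDistribution
    n_sim: int
    seed: int
    window: Window
    net_types: tuple
    n_undirected: int = 0
    n_directed: int = 0
    failed: dict = field(default_factory=dict)  # (model) -> dropped replicate count

    @property
    def models(self) -> tuple:
        return tuple(self.configs)

    def values(self, metric: str, net_type: str, model: str) -> np.ndarray:
        sets = self.metrics[(model, net_type)]
        return np.array([getattr(m, metric) for m in sets], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (model, net), sets in self.metrics.items():
            for rep, m in enumerate(sets):
                row = {"model": model, "net_type": net, "replicate": rep}
                row.update({f: getattr(m, f) for f in _METRIC_FIELDS})
                rows.append(row)
        return pd.DataFrame(rows)


def _one_replicate(cfg, window, crown_dist, net_types, seed, rep, retry,
                   path_length):
    pattern = simulate(cfg, window,
                       seed=np.random.default_rng([seed, rep, retry, 11]))
    labelled = assign_crown_radii(pattern, crown_dist,
                                  seed=np.random.default_rng([seed, rep, 13]))
    out = {}
    for net in net_types:
        built = _NET_BUILDERS[net](labelled)
        out[net] = metric_set(built, path_length=path_length)
    return out


def run_null_battery(model_configs: Optional[dict] = None,
                     crown_dist: Optional[CrownDistribution] = None,
                     net_types: Sequence[str] = ("CS", "CL", "WCL"),
                     n_sim: int = 199, seed: int = 0,
                     window: Optional[Window] = None,
                     path_length: bool = True) -> SimulationBatch:
    """Simulate ``n_sim`` replicates per model and collect network metrics.

    Replicate ``i`` of every model draws from the stream keyed by
    ``(seed, i)`` (marks use an independent stream), so the whole battery
    is reproducible, distinct master seeds give unrelated batteries, and
    comparisons between models are partially paired.  A replicate whose
    simulation fails is retried once and otherwise dropped with a log
    entry.
    """
    if n_sim < 2:
        raise ParameterError("n_sim must be at least 2")
    for net in net_types:
        if net not in _NET_BUILDERS:
            raise ParameterError(f"unknown network type {net!r}")
    window = Window(0.0, 200.0, 0.0, 200.0) if window is None else window
    crown_dist = CrownDistribution() if crown_dist is None else crown_dist
    configs = default_configs() if model_configs is None else dict(model_configs)

    metrics = {(m, net): [] for m in configs for net in net_types}
    failed = {}
    n_undirected = n_directed = 0
    for model, cfg in configs.items():
        for rep in range(n_sim):
            try:
                sets = _one_replicate(cfg, window, crown_dist, net_types,
                                      seed, rep, 0, path_length)
            except Exception as first:  # retry once with a shifted stream
                logger.warning("replicate %d of %s failed (%s); retrying", rep, model, first)
                try:
                    sets = _one_replicate(cfg, window, crown_dist, net_types,
                                          seed, rep, 1, path_length)
                except Exception as second:
                    logger.error("replicate %d of %s dropped: %s", rep, model, second)
                    failed[model] = failed.get(model, 0) + 1
                    continue
            for net, mset in sets.items():
                metrics[(model, net)].append(mset)
                if net == "WCL":
                    n_directed += 1
                else:
                    n_undirected += 1
    return SimulationBatch(metrics, configs, crown_dist, n_sim, seed, window,
                           tuple(net_types), n_undirected, n_directed, failed)


@dataclass
class ComparisonReport:
    """ANOVA + Tukey + range-overlap comparison of one metric across models."""

    metric: str
    net_type: str
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame          # columns: model_a, model_b, meandiff, p_adj, reject
    ranges: pd.DataFrame         # per model: min, max
    overlap: pd.DataFrame        # boolean matrix of pairwise range overlap
    distinguishing: bool


def _group_of(model: str) -> str:
    for g, members in MODEL_GROUPS.items():
        if model in members:
            return g
    return "other"


def compare_models(batch: SimulationBatch, metric: str,
                   net_type: str = "CS", alpha: float = 0.05) -> ComparisonReport:
    """One-way ANOVA across models with Tukey HSD and a range-overlap screen."""
    models = [m for m in batch.models if (m, net_type) in batch.metrics]
    if len(models) < 2:
        raise ParameterError("need at least two models to compare")
    groups = {m: batch.values(metric, net_type, m) for m in models}
    groups = {m: v[np.isfinite(v)] for m, v in groups.items()}
    if any(v.size < 2 for v in groups.values()):
        raise DataError("every model needs at least two finite replicates")

    all_const = all(np.ptp(v) == 0 for v in groups.values())
    means = {m: float(v.mean()) for m, v in groups.items()}
    if all_const and len(set(means.values())) == 1:
        # degenerate: identical constant groups
        f_stat, p_val = 0.0, 1.0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            f_stat, p_val = stats.f_oneway(*groups.values())
        if np.isnan(f_stat):
            f_stat, p_val = 0.0, 1.0

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    data = np.concatenate([groups[m] for m in models])
    labels = np.concatenate([[m] * groups[m].size for m in models])
    if np.ptp(data) == 0:
        pairs = list(itertools.combinations(models, 2))
        tukey = pd.DataFrame({"model_a": [a for a, _ in pairs],
                              "model_b": [b for _, b in pairs],
                              "meandiff": 0.0, "p_adj": 1.0, "reject": False})
    else:
        res = pairwise_tukeyhsd(data, labels, alpha=alpha)
        tukey = pd.DataFrame(res.summary().data[1:],
                             columns=[c.strip() for c in res.summary().data[0]])
        tukey = tukey.rename(columns={"group1": "model_a", "group2": "model_b",
                                      "p-adj": "p_adj"})
        tukey = tukey[["model_a", "model_b", "meandiff", "p_adj", "reject"]]
        tukey["reject"] = tukey["reject"].astype(bool)

    ranges = pd.DataFrame({m: {"min": groups[m].min(), "max": groups[m].max()}
                           for m in models}).T
    overlap = pd.DataFrame(False, index=models, columns=models)
    for a, b in itertools.combinations(models, 2):
        ov = (ranges.loc[a, "min"] <= ranges.loc[b, "max"]
              and ranges.loc[b, "min"] <= ranges.loc[a, "max"])
        overlap.loc[a, b] = overlap.loc[b, a] = bool(ov)

    distinguishing = _distinguishing(models, tukey, overlap)
    return ComparisonReport(metric, net_type, float(f_stat), float(p_val),
                            tukey, ranges, overlap, distinguishing)


def _distinguishing(models, tukey, overlap) -> bool:
    """Cross-group pairs (cluster vs CSR vs Gibbs) must be Tukey-significant
    and have disjoint ranges."""
    reject = {}
    for _, row in tukey.iterrows():
        reject[frozenset((row["model_a"], row["model_b"]))] = bool(row["reject"])
    seen_cross_pair = False
    for a, b in itertools.combinations(models, 2):
        if _group_of(a) == _group_of(b):
            continue
        seen_cross_pair = True
        if overlap.loc[a, b] or not reject.get(frozenset((a, b)), False):
            return False
    return seen_cross_pair


def classify_metric(batch: SimulationBatch, metric: str,
                    net_type: str = "CS", alpha: float = 0.05) -> str:
    """Verdict for one metric: ``"distinguishing"`` or ``"non-distinguishing"``.

    Distinguishing means every cross-group model pair (cluster vs CSR vs
    Gibbs) is significant under Tukey HSD *and* has non-overlapping ranges.
    """
    if len(batch.models) < 2:
        raise ParameterError("verdict undefined for a single-model batch")
    report = compare_models(batch, metric, net_type=net_type, alpha=alpha)
    return "distinguishing" if report.distinguishing else "non-distinguishing"


@dataclass
class EmpiricalComparison:
    """An observed stem map located within the null metric distributions."""

    observed: dict                 # net_type -> MetricSet
    table: pd.DataFrame            # model, net_type, metric, percentile, in_range
    batch: SimulationBatch
    kappa_hat: float
    crown_fit: CrownDistribution


def empirical_vs_null(trees, n_sim: int = 199, seed: int = 0,
                      net_types: Sequence[str] = ("CS", "CL", "WCL"),
                      window: Optional[Window] = None,
                      metrics: Sequence[str] = ("k", "C", "D", "L"),
                      model_configs: Optional[dict] = None) -> EmpiricalComparison:
    """Compare an observed stem map against null batteries fitted to it.

    ``kappa`` is estimated as the observed tree density (total intensity:
    cluster models simulate parents at ``kappa / mu``) and the crown-radius
    distribution by a gamma maximum-likelihood fit, then each null model is
    simulated on the observed window.
    """
    table = as_tree_table(trees)
    if window is None:
        if isinstance(trees, MarkedPattern):
            window = trees.window
        else:
            window = Window.from_points(table["x"].to_numpy(), table["y"].to_numpy())
    kappa_hat = len(table) / window.area
    crown_fit = fit_crown_gamma(table["crown_radius"].to_numpy())
    if model_configs is None:
        model_configs = {name: NullModelConfig(model=name, kappa=kappa_hat)
                         for name in MODEL_ORDER}
    batch = run_null_battery(model_configs, crown_fit, net_types=net_types,
                             n_sim=n_sim, seed=seed, window=window)
    observed = {net: metric_set(_NET_BUILDERS[net](table)) for net in net_types}
    rows = []
    for net in net_types:
        for metric in metrics:
            obs_val = getattr(observed[net], metric)
            if obs_val is None:
                continue
            for model in batch.models:
                sims = batch.values(metric, net, model)
                sims = sims[np.isfinite(sims)]
                pct = float(stats.percentileofscore(sims, obs_val, kind="mean"))
                rows.append({
                    "model": model, "net_type": net, "metric": metric,
                    "observed": float(obs_val), "percentile": pct,
                    "in_range": bool(sims.min() <= obs_val <= sims.max()),
                })
    return EmpiricalComparison(observed, pd.DataFrame(rows), batch,
                               kappa_hat, crown_fit)


@dataclass
class SweepResult:
    """Stacked batteries over a one-at-a-time parameter sweep."""

    batches: list                  # of (parameter, value, SimulationBatch)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for param, value, batch in self.batches:
            df = batch.to_frame()
            df.insert(0, "parameter", param)
            df.insert(1, "value", value)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


_SWEEPABLE = {"kappa", "mu", "r_d", "r_g", "p"}


def sensitivity_sweep(parameter_grid: dict,
                      base_configs: Optional[dict] = None,
                      crown_dist: Optional[CrownDistribution] = None,
                      net_types: Sequence[str] = ("CS", "CL", "WCL"),
                      n_sim: int = 199, seed: int = 0,
                      window: Optional[Window] = None,
                      path_length: bool = True) -> SweepResult:
    """One-at-a-time sensitivity analysis over model parameters.

    ``parameter_grid`` maps a parameter name (kappa, mu, r_d, r_g, p) to the
    values to try; each grid point overrides that parameter in every model
    it applies to and runs a full battery.
    """
    base_configs = default_configs() if base_configs is None else base_configs
    batches = []
    for param, grid in parameter_grid.items():
        if param not in _SWEEPABLE:
            raise ParameterError(f"cannot sweep parameter {param!r}")
        for value in grid:
            configs = {name: cfg.with_(**{param: value})
                       for name, cfg in base_configs.items()}
            batch = run_null_battery(configs, crown_dist, net_types=net_types,
                                     n_sim=n_sim, seed=seed, window=window,
                                     path_length=path_length)
            batches.append((param, value, batch))
    return SweepResult(batches)
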
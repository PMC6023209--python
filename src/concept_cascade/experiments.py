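"""Experiment grid runner: replicate networks, aggregation, t-tests.

For every replicate a fresh network is generated, the target concept
receives a uniformly random seed set, the controllable concept's seeds are
chosen by the configured heuristic after the burn-in, and the cascade runs
to quiescence.  One cascade is run per generated network; the reported
statistic is the mean (and sample SD) of the final number of
target-concept activations, seeds included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import graphs as gr
from .cascade import run_icm, run_ltm
from .graphs import Graph
from .heuristics import DEFAULT_HOP_LIMIT, DEFAULT_THETA, HEURISTIC_NAMES, get_selector
from .interaction import ICM, LTM, ConceptSystem

__all__ = [
    "ExperimentConfig",
    "ResultTable",
    "run_grid",
    "pairwise_ttests",
    "write_results_csv",
    "write_replicates_csv",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "model", "family", "n", "param", "k", "r", "burn_in",
    "heuristic", "replicates", "mean", "sd",
]


@dataclass
class ExperimentConfig:
    """One cell (or row of cells sharing networks) of the parameter grid."""

    model: str = ICM
    family: str = "small_world"  # small_world | scale_free | edge_list
    n: int = 25_000
    clustering_exponent: float = 0.25
    long_range_per_node: int = 1
    m: int = 4
    edge_list_path: Optional[str] = None
    seed_set_size: int = 100  # both concepts use the same k
    r: float = 2.0
    p: float = 0.1
    burn_in: int = 0
    heuristics: Tuple[str, ...] = ("mpg",)
    replicates: int = 100
    master_seed: int = 0
    theta: float = DEFAULT_THETA
    hop_limit: int = DEFAULT_HOP_LIMIT
    threshold_mean: float = 0.8
    threshold_sd: float = 0.05
    lam: int = 2
    max_steps: int = 10_000

    def __post_init__(self):
        if isinstance(self.heuristics, str):
            self.heuristics = (self.heuristics,)
        else:
            self.heuristics = tuple(self.heuristics)
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        for h in self.heuristics:
            if h not in HEURISTIC_NAMES:
                raise ValueError(f"unknown heuristic {h!r}")
        if self.model not in (ICM, LTM):
            raise ValueError(f"unknown model {self.model!r}")
        if self.family not in ("small_world", "scale_free", "edge_list"):
            raise ValueError(f"unknown network family {self.family!r}")

    @property
    def family_param(self) -> Union[float, int, str]:
        if self.family == "small_world":
            return self.clustering_exponent
        if self.family == "scale_free":
            return self.m
        return self.edge_list_path or ""

    @classmethod
    def from_dict(cls, d: Dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known - {"heuristic"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "heuristic" in d and "heuristics" not in d:
            d["heuristics"] = d.pop("heuristic")
        else:
            d.pop("heuristic", None)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ResultTable:
    """Aggregated grid results plus the retained per-replicate values."""

    rows: pd.DataFrame
    replicate_values: Dict[str, np.ndarray]
    config: Optional[ExperimentConfig] = None

    def mean(self, heuristic: str) -> float:
        return float(np.mean(self.replicate_values[heuristic]))

    def sd(self, heuristic: str) -> float:
        vals = self.replicate_values[heuristic]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def _generate_network(cfg: ExperimentConfig, rep: int) -> Graph:
    base = cfg.master_seed ^ rep
    if cfg.family == "small_world":
        g = gr.generate_small_world(
            cfg.n, cfg.clustering_exponent, cfg.long_range_per_node,
            rng_seed=(base, 0),
        )
    elif cfg.family == "scale_free":
        g = gr.generate_scale_free(cfg.n, cfg.m, rng_seed=(base, 0))
    else:
        if not cfg.edge_list_path:
            raise ValueError("edge_list family requires edge_list_path")
        g = gr.load_edge_list(cfg.edge_list_path)
    if cfg.model == LTM:
        gr.assign_ltm_attributes(
            g, ["t", "s"], cfg.threshold_mean, cfg.threshold_sd,
            rng_seed=(base, 3),
        )
    return g


def run_grid(config: ExperimentConfig) -> ResultTable:
    """Run the configured cell for every heuristic over shared replicates.

    Per replicate ``i`` the RNG streams are derived from
    ``master_seed XOR i`` with separate sub-streams for network generation,
    target-seed drawing and each heuristic's cascade, so the full grid is
    bit-reproducible under a fixed master seed and all heuristics see the
    same networks and target seeds.
    """
    cfg = config
    cs_run = ConceptSystem(r=cfg.r, p=cfg.p, model_tag=cfg.model)
    prune = cfg.theta if cfg.model == ICM else cfg.hop_limit
    values: Dict[str, List[float]] = {h: [] for h in cfg.heuristics}
    runner = run_icm if cfg.model == ICM else run_ltm
    for rep in range(cfg.replicates):
        base = cfg.master_seed ^ rep
        g = _generate_network(cfg, rep)
        rng_t = np.random.default_rng((base, 1))
        target_seeds = rng_t.choice(g.n_nodes, size=cfg.seed_set_size, replace=False)
        for j, h in enumerate(cfg.heuristics):
            selector = get_selector(h, cfg.seed_set_size, prune=prune, lam=cfg.lam)
            result = runner(
                g, cs_run, target_seeds,
                controllable_seed_selector=selector,
                burn_in=cfg.burn_in,
                rng_seed=(base, 2, j),
                max_steps=cfg.max_steps,
            )
            values[h].append(result.final_active_count[cs_run.target_id])
        logger.info(
            "replicate %d/%d done: %s", rep + 1, cfg.replicates,
            {h: values[h][-1] for h in cfg.heuristics},
        )

    rows = []
    reps: Dict[str, np.ndarray] = {}
    for h in cfg.heuristics:
        arr = np.asarray(values[h], dtype=np.float64)
        reps[h] = arr
        rows.append({
            "model": cfg.model,
            "family": cfg.family,
            "n": cfg.n,
            "param": cfg.family_param,
            "k": cfg.seed_set_size,
            "r": cfg.r,
            "burn_in": cfg.burn_in,
            "heuristic": h,
            "replicates": len(arr),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        })
    return ResultTable(
        rows=pd.DataFrame(rows, columns=RESULT_COLUMNS),
        replicate_values=reps,
        config=cfg,
    )


def pairwise_ttests(
    samples: Union[ResultTable, Dict[str, Sequence[float]]]
) -> pd.DataFrame:
    """Welch two-sample two-tailed t-tests on each heuristic pairing.

    Returns a symmetric matrix of p-values with unit diagonal.  Degenerate
    zero-variance pairs yield p = 1 for equal means and p = 0 otherwise.
    """
    if isinstance(samples, ResultTable):
        samples = samples.replicate_values
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two heuristics to compare")
    arrays = {h: np.asarray(samples[h], dtype=np.float64) for h in names}
    for h, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"heuristic {h!r} has fewer than 2 replicate values")
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x, y = arrays[a], arrays[b]
            if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
                p = 1.0 if x.mean() == y.mean() else 0.0
            else:
                p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
            mat.loc[a, b] = p
            mat.loc[b, a] = p
    return mat


def write_results_csv(rt: ResultTable, path) -> None:
    rt.rows.to_csv(path, index=False)


def write_replicates_csv(rt: ResultTable, path) -> None:
    records = []
    for h, vals in rt.replicate_values.items():
        for i, v in enumerate(vals):
            records.append({
                "heuristic": h,
                "replicate": i,
                "final_target_activations": v,
            })
    pd.DataFrame(
        records, columns=["heuristic", "replicate", "final_target_activations"]
    ).to_csv(path, index=False)


def read_replicates_csv(path) -> Dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {
        h: grp["final_target_activations"].to_numpy(dtype=np.float64)
        for h, grp in df.groupby("heuristic", sort=True)
    }
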
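"""Replicate-level experiment runner.

Sweeps a grid of generating conditions (f, gamma, k, s, N), simulates
``n_replicates`` ascertained datasets per cell, applies the requested
estimators/statistics, and returns both tidy per-replicate values and
cross-replicate summaries (mean, SD, exclusion counts). Per-replicate seeds
are derived from (master seed, cell index, replicate index) via
``numpy.random.SeedSequence`` spawn keys so every cell is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from .likelihood import maximize_ld_lod
from .models import AscertainmentModel, Dataset, ReplicateSummary, TraitModel
from .simulate import simulate_dataset, simulate_null_dataset
from .tbf import maximize_tbf, tbf_gen

__all__ = ["ExperimentConfig", "ExperimentResult", "run_replicates", "threshold_exceedance"]

KNOWN_STATISTICS = (
    "f_tilde",
    "f_tilde_star",
    "f_hat",
    "ld_mod",
    "le_lod_max",
    "tbf_gen",
    "f_tbf",
    "tbf_max",
)

_NEEDS_MOD = {"f_hat", "ld_mod", "le_lod_max"}
_NEEDS_TBF_MAX = {"f_tbf", "tbf_max"}


@dataclass
class ExperimentConfig:
    """Parameter grid and run settings for a replicate experiment.

    Each of ``f``, ``gamma``, ``k``, ``s``, ``N`` may be a scalar or a list;
    the grid is their Cartesian product. ``null`` switches every cell to the
    no-linkage/no-LD generator.
    """

    f: Sequence[float] | float = 0.5
    gamma: Sequence[float] | float = 0.0
    k: Sequence[float] | float = 1.0
    s: Sequence[int] | int = 2
    N: Sequence[int] | int = 20
    statistics: Sequence[str] = ("f_tilde", "f_tilde_star")
    n_replicates: int = 1000
    seed: int = 0
    null: bool = False
    pooled: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.statistics) - set(KNOWN_STATISTICS)
        if unknown:
            raise ValueError(f"unknown statistics {sorted(unknown)}; known: {KNOWN_STATISTICS}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def cells(self) -> list[dict]:
        def aslist(v) -> list:
            return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v]

        grid = product(aslist(self.f), aslist(self.gamma), aslist(self.k), aslist(self.s), aslist(self.N))
        return [
            {"f": float(f), "gamma": float(g), "k": float(k), "s": int(s), "N": int(n)}
            for f, g, k, s, n in grid
        ]


@dataclass
class ExperimentResult:
    """Tidy per-replicate values plus per-cell ReplicateSummary objects."""

    replicates: pd.DataFrame
    summaries: list[ReplicateSummary] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        cols = ["f", "gamma", "k", "s", "N", "statistic"]
        df = self.replicates
        agg = (
            df[df["ok"]]
            .groupby(cols, dropna=False)["value"]
            .agg(mean="mean", sd=lambda v: v.std(ddof=1), n_replicates="count")
            .reset_index()
        )
        excl = df.groupby(cols, dropna=False)["n_noncontributing"].sum().reset_index()
        return agg.merge(excl, on=cols, how="left")


def _replicate_statistics(
    dataset: Dataset, statistics: Iterable[str], trait: TraitModel, pooled: bool
) -> dict[str, tuple[float, int]]:
    """Map statistic name -> (value, n_noncontributing) for one dataset."""
    out: dict[str, tuple[float, int]] = {}
    stats = list(statistics)
    if "f_tilde" in stats:
        r = est.f_tilde(dataset, pooled=pooled)
        out["f_tilde"] = (r.estimate, r.n_noncontributing)
    if "f_tilde_star" in stats:
        r = est.f_tilde_star(dataset, pooled=pooled)
        out["f_tilde_star"] = (r.estimate, r.n_noncontributing)
    if _NEEDS_MOD.intersection(stats):
        fit = maximize_ld_lod(dataset)
        if "f_hat" in stats:
            out["f_hat"] = (fit.f_hat, 0)
        if "ld_mod" in stats:
            out["ld_mod"] = (fit.ld_mod, 0)
        if "le_lod_max" in stats:
            out["le_lod_max"] = (fit.le_lod_max, 0)
    if "tbf_gen" in stats:
        out["tbf_gen"] = (tbf_gen(dataset, trait), 0)
    if _NEEDS_TBF_MAX.intersection(stats):
        fit = maximize_tbf(dataset)
        if "f_tbf" in stats:
            out["f_tbf"] = (fit.f_tbf, 0)
        if "tbf_max" in stats:
            out["tbf_max"] = (fit.tbf_max, 0)
    return out


def run_replicates(config: ExperimentConfig) -> ExperimentResult:
    """Run the full grid; never aborts on a failing replicate (flags it instead)."""
    rows: list[dict] = []
    summaries: list[ReplicateSummary] = []
    simulate = simulate_null_dataset if config.null else simulate_dataset
    for cell_idx, cell in enumerate(config.cells()):
        trait = TraitModel(f=cell["f"], gamma=cell["gamma"])
        asc = AscertainmentModel(k=cell["k"])
        cell_values: dict[str, list[float]] = {name: [] for name in config.statistics}
        cell_excl: dict[str, int] = {name: 0 for name in config.statistics}
        for rep in range(config.n_replicates):
            seed_seq = np.random.SeedSequence(entropy=config.seed, spawn_key=(cell_idx, rep))
            rng = np.random.default_rng(seed_seq)
            try:
                dataset = simulate(trait, asc, cell["s"], cell["N"], rng)
                values = _replicate_statistics(dataset, config.statistics, trait, config.pooled)
                ok = True
            except Exception as exc:  # flagged, never aborts the grid
                values = {name: (float("nan"), 0) for name in config.statistics}
                ok = False
            for name in config.statistics:
                value, n_excl = values[name]
                rows.append(
                    {**cell, "replicate": rep, "statistic": name, "value": value,
                     "n_noncontributing": n_excl, "ok": ok and not np.isnan(value)}
                )
                if ok and not np.isnan(value):
                    cell_values[name].append(value)
                else:
                    cell_excl[name] += 1
        for name in config.statistics:
            summaries.append(
                ReplicateSummary(
                    estimate_name=f"{name}[f={cell['f']},gamma={cell['gamma']},k={cell['k']},s={cell['s']},N={cell['N']}]",
                    values=np.array(cell_values[name]),
                    n_noncontributing=cell_excl[name],
                )
            )
    columns = ["f", "gamma", "k", "s", "N", "replicate", "statistic", "value", "n_noncontributing", "ok"]
    frame = pd.DataFrame(rows, columns=columns)
    return ExperimentResult(replicates=frame, summaries=summaries)


def threshold_exceedance(values, threshold: float) -> int:
    """Number of values at or above ``threshold`` (empty input gives 0)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return 0
    return int(np.count_nonzero(arr >= threshold))
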
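"""Factorial grid runner, aggregation and result writers.

The benchmark crosses six manipulated factors (number of known groups,
total sample size, known-group size ratio, subgroup size ratio,
known-group separation delta, subgroup separation/overlap), draws a
paired training / cross-validation sample per replicate, fits every
requested classifier on the training sample (known-group labels only -
the latent subgroup labels are never shown to a method), and records
overall and by-group misclassification for both roles in a tidy table.

Seeding is hierarchical and counter-based: each (cell, replicate) gets a
child seed derived from ``SeedSequence((master_seed, cell_index,
replicate_index))``, so cells are independent, the grid is
embarrassingly parallel in principle, and the same master seed always
reproduces the same result table bit for bit.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifiers import FITTERS, MethodConfig, predict
from .metrics import misclassification_by_group, misclassification_overall
from .simdata import SimulationDesign, simulate_pair

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentGrid",
    "SummaryTable",
    "run_grid",
    "summarize",
    "report",
    "load_grid",
    "population_bayes_rate",
    "UNEQUAL_GROUP_RATIOS",
]

#: unequal known-group ratio by number of groups
UNEQUAL_GROUP_RATIOS = {2: (0.75, 0.25), 3: (0.60, 0.20, 0.20)}
#: unequal subgroup ratio (within every known group)
UNEQUAL_SUBGROUP_RATIO = (0.75, 0.25)

#: study sample sizes by number of groups
DEFAULT_TOTAL_N = {2: (100, 200, 500), 3: (150, 300, 750)}
DEFAULT_DELTAS = (0.2, 0.5, 0.8)
DEFAULT_OVERLAPS = (0.0, 0.05, 0.10, 0.15, 0.20)


@dataclass
class ExperimentGrid:
    """Full factorial design: every combination of the factor levels."""

    n_groups: int = 3
    total_ns: tuple[int, ...] = ()
    nratios: tuple[str, ...] = ("equal", "unequal")
    sratios: tuple[str, ...] = ("equal", "unequal")
    deltas: tuple[float, ...] = DEFAULT_DELTAS
    overlaps: tuple[float, ...] = DEFAULT_OVERLAPS
    methods: tuple[str, ...] = ("lda", "lr", "mixda", "cart", "gam")
    replicates: int = 1000
    master_seed: int = 20140520
    method_config: MethodConfig = field(default_factory=MethodConfig)

    def __post_init__(self) -> None:
        if not self.total_ns:
            self.total_ns = DEFAULT_TOTAL_N[self.n_groups]
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        for name in ("total_ns", "nratios", "sratios", "deltas", "overlaps", "methods"):
            if not getattr(self, name):
                raise ValueError(f"factor list {name!r} must be nonempty")
        unknown = set(self.methods) - set(FITTERS)
        if unknown:
            raise ValueError(f"unknown method name(s): {sorted(unknown)}")
        for r in tuple(self.nratios) + tuple(self.sratios):
            if r not in ("equal", "unequal"):
                raise ValueError(f"ratios must be 'equal' or 'unequal', got {r!r}")

    @property
    def cells(self) -> list[dict]:
        """Factor settings of every design cell, in deterministic order."""
        out = []
        i = 0
        for n in self.total_ns:
            for nratio in self.nratios:
                for sratio in self.sratios:
                    for delta in self.deltas:
                        for s in self.overlaps:
                            out.append(
                                dict(
                                    cell=i,
                                    total_n=n,
                                    nratio=nratio,
                                    sratio=sratio,
                                    delta=delta,
                                    overlap=s,
                                )
                            )
                            i += 1
        return out

    def design_for(self, cell: dict) -> SimulationDesign:
        gp = (
            tuple([1.0 / self.n_groups] * self.n_groups)
            if cell["nratio"] == "equal"
            else UNEQUAL_GROUP_RATIOS[self.n_groups]
        )
        sp = (0.5, 0.5) if cell["sratio"] == "equal" else UNEQUAL_SUBGROUP_RATIO
        return SimulationDesign(
            n_groups=self.n_groups,
            total_n=cell["total_n"],
            group_proportions=gp,
            subgroup_proportions=sp,
            group_separation_delta=cell["delta"],
            subgroup_separation=cell["overlap"],
        )


def child_seed(master_seed: int, cell_index: int, replicate_index: int) -> int:
    """Deterministic per-replicate seed, independent across the grid."""
    ss = np.random.SeedSequence((master_seed, cell_index, replicate_index))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _rate_row(pred, truth, n_groups):
    overall = misclassification_overall(pred, truth)
    by_group = misclassification_by_group(pred, truth)
    row = {"overall": overall}
    for g in range(1, n_groups + 1):
        row[f"rate_g{g}"] = by_group.get(g, np.nan)
        row[f"n_g{g}"] = int(np.sum(np.asarray(truth) == g))
    return row


def run_grid(grid: ExperimentGrid, progress: bool = False) -> pd.DataFrame:
    """Run the full factorial experiment and return tidy replicate results.

    One output row per (design cell, replicate, method, role) with the
    overall and by-group misclassification rates.  A method failing on
    one replicate is logged and recorded as missing (NaN rates) without
    aborting the rest of the cell.
    """
    records: list[dict] = []
    cells = grid.cells
    for cell in cells:
        design = grid.design_for(cell)
        if progress:
            logger.info("cell %d/%d: %s", cell["cell"] + 1, len(cells), cell)
        for rep in range(grid.replicates):
            seed = child_seed(grid.master_seed, cell["cell"], rep)
            train, cv = simulate_pair(design, seed)
            base = {
                "n_groups": grid.n_groups,
                **{k: cell[k] for k in ("cell", "total_n", "nratio", "sratio", "delta", "overlap")},
                "replicate": rep,
                "seed": seed,
            }
            for method in grid.methods:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        model = FITTERS[method](train, grid.method_config)
                    fits = {
                        role: _rate_row(predict(model, ds.X)[0], ds.y_group, grid.n_groups)
                        for role, ds in (("train", train), ("cv", cv))
                    }
                except Exception:
                    logger.exception(
                        "method %s failed on cell %d replicate %d; recorded as missing",
                        method, cell["cell"], rep,
                    )
                    nan_row = {"overall": np.nan}
                    for g in range(1, grid.n_groups + 1):
                        nan_row[f"rate_g{g}"] = np.nan
                        nan_row[f"n_g{g}"] = 0
                    fits = {"train": nan_row, "cv": dict(nan_row)}
                for role, row in fits.items():
                    records.append({**base, "method": method, "role": role, **row})
    return pd.DataFrame.from_records(records)


def population_bayes_rate(design: SimulationDesign, n: int = 100_000, seed: int = 0) -> float:
    """Monte Carlo estimate of the Bayes-optimal misclassification rate.

    Classifies a large fresh sample with the *population* mixture rule
    (true subgroup means, true mixing proportions, true covariance, class
    priors equal to the design's group proportions) — the best any
    classifier can do on this design, a useful floor when judging fitted
    methods.
    """
    from .classifiers.mixda import MIXDAModel
    from .simdata import make_population

    pop = make_population(design)
    sample, _ = simulate_pair(design.replace(total_n=n), seed)
    model = MIXDAModel(
        classes=np.arange(1, design.n_groups + 1),
        means=pop.subgroup_means,
        mixing=np.tile(np.asarray(design.subgroup_proportions), (design.n_groups, 1)),
        covariance=pop.covariance,
        priors=np.asarray(design.group_proportions),
        loglik_path=[],
        converged=True,
    )
    labels = model.predict(sample.X)
    return float(np.mean(labels != sample.y_group))


@dataclass
class SummaryTable:
    """Cell means of misclassification rates plus per-method marginals.

    ``table`` is tidy: one row per (grouping-factor cell, method) with
    the mean rate; ``marginals`` holds min / max / median / mean / IQR of
    the cell means per method.
    """

    by: tuple[str, ...]
    role: str
    value: str
    table: pd.DataFrame
    marginals: pd.DataFrame

    def pivot(self) -> pd.DataFrame:
        """Wide rendering: grouping factors as rows, methods as columns."""
        return self.table.pivot_table(
            index=list(self.by), columns="method", values="rate"
        )


def summarize(
    results: pd.DataFrame,
    by: tuple[str, ...] = ("overlap",),
    role: str = "cv",
    value: str = "overall",
) -> SummaryTable:
    """Aggregate replicate results into factor-wise mean rates.

    Collapsed factors are averaged with equal weight per replicate (every
    cell of the full cross has the same replicate count, so this matches
    per-observation pooling up to rounding).  Cells where every replicate
    of a method failed are reported as missing rows, not dropped silently.
    """
    if results.empty:
        raise ValueError("results table is empty")
    sub = results[results["role"] == role]
    if sub.empty:
        raise ValueError(f"no rows with role {role!r}")
    grouped = sub.groupby([*by, "method"], sort=True)[value]
    table = grouped.mean().rename("rate").reset_index()
    n_missing = int(table["rate"].isna().sum())
    if n_missing:
        logger.warning("%d summary cells have no successful replicates", n_missing)
    # marginal spread statistics per method over the grouped cells
    stats = []
    for method, rates in table.groupby("method")["rate"]:
        r = rates.dropna().to_numpy()
        stats.append(
            {
                "method": method,
                "min": r.min() if len(r) else np.nan,
                "max": r.max() if len(r) else np.nan,
                "median": float(np.median(r)) if len(r) else np.nan,
                "mean": float(np.mean(r)) if len(r) else np.nan,
                "iqr": float(np.subtract(*np.percentile(r, [75, 25]))) if len(r) else np.nan,
            }
        )
    return SummaryTable(
        by=tuple(by), role=role, value=value, table=table, marginals=pd.DataFrame(stats)
    )


def report(
    summary: SummaryTable, out_dir: str | Path, prefix: str, text: bool = False
) -> list[Path]:
    """Write a summary as CSV (always) and optionally as aligned text."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    table_path = out_dir / f"{prefix}_table.csv"
    summary.table.to_csv(table_path, index=False)
    paths.append(table_path)
    marg_path = out_dir / f"{prefix}_marginals.csv"
    summary.marginals.to_csv(marg_path, index=False)
    paths.append(marg_path)
    if text:
        txt_path = out_dir / f"{prefix}_table.txt"
        txt_path.write_text(summary.pivot().round(3).to_string() + "\n")
        paths.append(txt_path)
    return paths


def load_grid(path: str | Path) -> ExperimentGrid:
    """Read an experiment grid from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if "methods_config" in data or "method_config" in data:
        cfg = data.pop("method_config", data.pop("methods_config", None))
        data["method_config"] = MethodConfig.from_dict(cfg)
    list_fields = ("total_ns", "nratios", "sratios", "deltas", "overlaps", "methods")
    kwargs = {}
    for key, val in data.items():
        kwargs[key] = tuple(val) if key in list_fields else val
    return ExperimentGrid(**kwargs)
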
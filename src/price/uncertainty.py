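"""Probabilistic sensitivity analysis (PSA).

Uncertain model inputs are described by independent parametric
distributions (point mass, gamma in shape/rate form, normal in mean/sd
form, beta, uniform), optionally truncated to an interval by rejection.
Joint parameter draws are propagated through a tree builder, and the
cost-effectiveness metrics are recomputed per draw, yielding Monte-Carlo
distributions of expected cost, expected effectiveness and effective cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .effectiveness import UtilityParams, cost_effectiveness_report
from .exceptions import NonPositiveEffectivenessError, PriceError, TruncationError

FAMILIES = ("point", "gamma", "normal", "beta", "uniform")

#: Rejection-sampling retry cap per value under truncation.
RESAMPLE_CAP = 1000


@dataclass(frozen=True)
class DistributionSpec:
    """One uncertain parameter.

    ``parameters`` is family-specific: gamma -> ``shape``/``rate``; normal
    -> ``mean``/``sd``; beta -> ``a``/``b``; uniform -> ``low``/``high``;
    point -> ``value``.  ``truncation`` optionally bounds draws to
    ``[low, high]`` by rejection.
    """

    family: str
    parameters: dict
    truncation: Optional[tuple] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        pos = {"gamma": ("shape", "rate"), "normal": ("sd",), "beta": ("a", "b")}
        for key in pos.get(self.family, ()):
            if self.parameters.get(key, 1.0) <= 0:
                raise ValueError(f"{self.family} parameter {key!r} must be positive")
        if self.family == "uniform" and not self.parameters["low"] < self.parameters["high"]:
            raise ValueError("uniform requires low < high")
        if self.truncation is not None and not self.truncation[0] < self.truncation[1]:
            raise ValueError("truncation requires low < high")

    def mean(self) -> float:
        """Closed-form mean of the untruncated distribution."""
        q = self.parameters
        return {
            "point": lambda: q["value"],
            "gamma": lambda: q["shape"] / q["rate"],
            "normal": lambda: q["mean"],
            "beta": lambda: q["a"] / (q["a"] + q["b"]),
            "uniform": lambda: 0.5 * (q["low"] + q["high"]),
        }[self.family]()

    def _draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        q = self.parameters
        if self.family == "point":
            return np.full(n, float(q["value"]))
        if self.family == "gamma":
            return rng.gamma(shape=q["shape"], scale=1.0 / q["rate"], size=n)
        if self.family == "normal":
            return rng.normal(loc=q["mean"], scale=q["sd"], size=n)
        if self.family == "beta":
            return rng.beta(q["a"], q["b"], size=n)
        return rng.uniform(q["low"], q["high"], size=n)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        draws = self._draw(rng, n)
        if self.truncation is None:
            return draws
        lo, hi = self.truncation
        for _ in range(RESAMPLE_CAP):
            bad = (draws < lo) | (draws > hi)
            if not bad.any():
                return draws
            draws[bad] = self._draw(rng, int(bad.sum()))
        raise TruncationError(
            f"truncation to [{lo}, {hi}] rejected a value {RESAMPLE_CAP} times for {self.family}")


def point(value: float) -> DistributionSpec:
    return DistributionSpec("point", {"value": value})


def gamma(shape: float, rate: float, truncation=None) -> DistributionSpec:
    return DistributionSpec("gamma", {"shape": shape, "rate": rate}, truncation)


def normal(mean: float, sd: float, truncation=None) -> DistributionSpec:
    return DistributionSpec("normal", {"mean": mean, "sd": sd}, truncation)


def beta(a: float, b: float) -> DistributionSpec:
    return DistributionSpec("beta", {"a": a, "b": b})


def uniform(low: float, high: float) -> DistributionSpec:
    return DistributionSpec("uniform", {"low": low, "high": high})


def spec_from_dict(raw: dict) -> DistributionSpec:
    """Build a spec from a plain mapping (YAML/JSON spec files)."""
    trunc = raw.get("truncation")
    return DistributionSpec(raw["family"], dict(raw["params"]),
                            tuple(trunc) if trunc is not None else None)


def sample_parameters(specs: dict, n: int, seed) -> pd.DataFrame:
    """``n`` independent joint draws of all parameters, one column each."""
    if n < 1:
        raise ValueError(f"draw count must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({name: spec.sample(rng, n) for name, spec in specs.items()})


@dataclass
class PSAResult:
    """Per-draw metric table plus a recomputable summary."""

    table: pd.DataFrame
    summary: pd.DataFrame
    n_undefined_effective_cost: int = 0
    metrics: tuple = ("expected_cost", "expected_effectiveness", "effective_cost")


def _summarize(table: pd.DataFrame, metrics) -> pd.DataFrame:
    rows = {}
    for m in metrics:
        col = table[m].dropna()
        rows[m] = {
            "mean": col.mean(),
            "sd": col.std(ddof=1) if len(col) > 1 else 0.0,
            "p2.5": col.quantile(0.025),
            "p97.5": col.quantile(0.975),
        }
    return pd.DataFrame(rows).T


def probabilistic_sensitivity(
    tree_builder: Callable[[dict], "object"],
    specs: dict,
    utility: UtilityParams,
    n: int,
    seed,
) -> PSAResult:
    """Rebuild the tree and recompute metrics for every parameter draw.

    Draws whose expected effectiveness is not positive are retained with
    ``effective_cost`` set to NaN and excluded from the effective-cost
    summary; their count is reported.  Fully deterministic for a fixed
    ``seed``.  A builder failure aborts the run, citing the draw index and
    the offending parameters.
    """
    from .cost_engine import becc_expected_cost
    from .effectiveness import expected_effectiveness as _expected_effectiveness

    draws = sample_parameters(specs, n, seed)
    records, undefined = [], 0
    for i, draw in enumerate(draws.to_dict(orient="records")):
        try:
            tree = tree_builder(draw)
        except Exception as exc:
            raise PriceError(f"tree builder failed on draw {i} ({draw}): {exc}") from exc
        try:
            report = cost_effectiveness_report(tree, utility)
            rec = {"expected_cost": report.expected_cost,
                   "expected_effectiveness": report.expected_effectiveness,
                   "effective_cost": report.effective_cost}
        except NonPositiveEffectivenessError:
            undefined += 1
            rec = {"expected_cost": becc_expected_cost(tree).expected_cost,
                   "expected_effectiveness": _expected_effectiveness(
                       tree, utility).expected_effectiveness,
                   "effective_cost": float("nan")}
        records.append({"draw": i, **draw, **rec})
    table = pd.DataFrame(records)
    return PSAResult(
        table=table,
        summary=_summarize(table, PSAResult.metrics),
        n_undefined_effective_cost=undefined,
    )
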
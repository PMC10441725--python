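"""One-way, two-way and probabilistic sensitivity analyses.

One-way analysis perturbs each parameter to +/- a fraction of baseline
(default 20%) and records the ICER excursion; entries sorted by span give
the tornado diagram.  Two-way analysis classifies a grid of two parameters
as cost-effective or not at a willingness-to-pay threshold.  The PSA draws
every parameter from its assigned distribution family and re-evaluates the
full model per draw; the cost-effectiveness acceptability curve (CEAC) is
the fraction of draws with positive net monetary benefit across a WTP grid.

Distribution reconstruction: the source prints a family and a (low, high)
range per parameter but no variance, so beta and gamma distributions are
moment-matched to the mean with SE = (high - low) / (2 * 1.96) — the range
read as a 95% interval; normal draws are truncated to [low, high]; uniform
draws cover [low, high]; "fixed" always returns the mean.  The fitted
survival parameters are held fixed (no distribution is reported for them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .economics import compare, evaluate_strategy, net_monetary_benefit
from .errors import PsaSpecError
from .parameters import AnalysisInputs, PsaParameterSpec, get_param, set_param

#: parameters that live on the utility scale and are capped at 1 when varied
_UTILITY_MARKERS = ("utility_pfs", "utility_pd")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class PsaDraw:
    delta_cost: float
    delta_qaly: float
    params: dict


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability_cost_effective: float


def _is_utility(path: str) -> bool:
    return any(m in path for m in _UTILITY_MARKERS) and "disutilit" not in path


def _icer(inputs: AnalysisInputs) -> float:
    ce = compare(
        evaluate_strategy(inputs, "intervention"),
        evaluate_strategy(inputs, "comparator"),
    )
    return ce.icer_per_qaly


def _apply(inputs: AnalysisInputs, name: str, value) -> AnalysisInputs:
    for path in name.split("|"):
        inputs = set_param(inputs, path.strip(), value)
    return inputs


def one_way(
    inputs: AnalysisInputs,
    parameters: Sequence[str] | None = None,
    fraction: float = 0.20,
) -> list[TornadoEntry]:
    """Tornado entries, sorted by ICER span, largest first.

    ``parameters`` defaults to every non-fixed PSA parameter of the inputs,
    with the shared PFS utility replaced by the two arm-specific PFS
    utilities (the published one-way analysis varied each arm's PFS utility
    separately).  Utility-scale excursions are capped at 1.0.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if parameters is None:
        parameters = ["intervention.utility_pfs", "comparator.utility_pfs"] + [
            s.name for s in inputs.psa_specs
            if s.family != "fixed" and s.name != "econ.utility_pfs"
        ]
    entries = []
    for name in parameters:
        base = get_param(inputs, name.split("|")[0].strip())
        low, high = base * (1.0 - fraction), base * (1.0 + fraction)
        if _is_utility(name):
            high = min(high, 1.0)
        entries.append(TornadoEntry(
            parameter=name,
            low_value=low,
            high_value=high,
            icer_at_low=_icer(_apply(inputs, name, low)),
            icer_at_high=_icer(_apply(inputs, name, high)),
        ))
    entries.sort(key=lambda e: -e.span)
    return entries


def tornado_table(entries: Iterable[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter,
        "low_value": e.low_value,
        "high_value": e.high_value,
        "icer_at_low_usd_per_qaly": e.icer_at_low,
        "icer_at_high_usd_per_qaly": e.icer_at_high,
        "span_usd_per_qaly": e.span,
    } for e in entries])


def two_way(
    inputs: AnalysisInputs,
    param_x: str,
    grid_x: Sequence[float],
    param_y: str,
    grid_y: Sequence[float],
    wtp: float | None = None,
) -> pd.DataFrame:
    """Cost-effectiveness classification over a two-parameter grid.

    Returns a tidy frame with one row per (x, y) cell; ``cost_effective``
    is true when the net monetary benefit at ``wtp`` is non-negative
    (equivalently ICER <= wtp for a trade-off, and always true under
    dominance).
    """
    if wtp is None:
        wtp = inputs.econ.wtp_per_qaly
    rows = []
    for x in grid_x:
        inp_x = _apply(inputs, param_x, float(x))
        for y in grid_y:
            inp = _apply(inp_x, param_y, float(y))
            ce = compare(
                evaluate_strategy(inp, "intervention"),
                evaluate_strategy(inp, "comparator"),
            )
            nmb = net_monetary_benefit(ce.delta_cost, ce.delta_qaly, wtp)
            rows.append({
                param_x: float(x), param_y: float(y),
                "icer_usd_per_qaly": ce.icer_per_qaly,
                "cost_effective": bool(nmb >= 0.0),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def _draw_one(spec: PsaParameterSpec, rng: np.random.Generator) -> float:
    m, lo, hi = spec.mean, spec.low, spec.high
    if spec.family == "fixed":
        return m
    if spec.family == "uniform":
        return float(rng.uniform(lo, hi))
    se = (hi - lo) / (2.0 * 1.96)
    if se <= 0:
        return m
    if spec.family == "normal":
        for _ in range(1000):
            x = rng.normal(m, se)
            if lo <= x <= hi:
                return float(x)
        return m
    if spec.family == "gamma":
        shape = (m / se) ** 2
        return float(rng.gamma(shape, m / shape))
    if spec.family == "beta":
        var = se * se
        if var >= m * (1.0 - m):
            raise PsaSpecError(
                f"{spec.name}: SE {se:.4g} too large for a beta with mean {m}"
            )
        nu = m * (1.0 - m) / var - 1.0
        return float(rng.beta(m * nu, (1.0 - m) * nu))
    raise PsaSpecError(f"{spec.name}: unknown family {spec.family!r}")


def draw_parameters(
    specs: Sequence[PsaParameterSpec], rng: np.random.Generator | int
) -> dict[str, float]:
    """One joint parameter draw, keyed by spec name; reproducible under seed."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return {spec.name: _draw_one(spec, rng) for spec in specs}


def run_psa(
    inputs: AnalysisInputs,
    n_iterations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> list[PsaDraw]:
    """Monte-Carlo PSA: each iteration samples every parameter with a named
    distribution and runs the full model.  Deterministic under the seed."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = []
    for _ in range(n_iterations):
        sampled = draw_parameters(inputs.psa_specs, rng)
        inp = inputs
        for name, value in sampled.items():
            inp = _apply(inp, name, value)
        ce = compare(
            evaluate_strategy(inp, "intervention"),
            evaluate_strategy(inp, "comparator"),
        )
        draws.append(PsaDraw(ce.delta_cost, ce.delta_qaly, sampled))
    return draws


def psa_table(draws: Iterable[PsaDraw]) -> pd.DataFrame:
    """Scatter-ready PSA table: one row per draw with sampled parameters."""
    return pd.DataFrame([
        {"delta_cost_usd": d.delta_cost, "delta_qaly": d.delta_qaly, **d.params}
        for d in draws
    ])


def ceac(
    draws: Sequence[PsaDraw],
    wtp_grid: Sequence[float] | None = None,
) -> list[CEACPoint]:
    """Probability of positive NMB at each willingness-to-pay value."""
    if len(draws) == 0:
        raise ValueError("ceac requires at least one PSA draw")
    if wtp_grid is None:
        wtp_grid = np.arange(0, 300_001, 2_000)
    dc = np.array([d.delta_cost for d in draws])
    dq = np.array([d.delta_qaly for d in draws])
    return [
        CEACPoint(float(w), float(np.mean(w * dq - dc > 0.0)))
        for w in wtp_grid
    ]


def ceac_table(points: Iterable[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame([{
        "wtp_usd_per_qaly": p.wtp,
        "probability_cost_effective": p.probability_cost_effective,
    } for p in points])


def wtp_at_probability(curve: Sequence[CEACPoint], target: float) -> float:
    """WTP at which the acceptability curve first crosses ``target``.

    Linear interpolation between the bracketing grid points; raises if the
    curve never spans the target probability.
    """
    pts = sorted(curve, key=lambda p: p.wtp)
    for a, b in zip(pts, pts[1:]):
        pa, pb = a.probability_cost_effective, b.probability_cost_effective
        if (pa - target) * (pb - target) <= 0.0 and pa != pb:
            return a.wtp + (target - pa) * (b.wtp - a.wtp) / (pb - pa)
        if pa == target == pb:
            return a.wtp
    raise ValueError(
        f"acceptability curve does not span probability {target} on its WTP grid"
    )
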
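"""Right-censored pseudo individual-patient data and Kaplan-Meier curves.

The decision model's survival stage was originally fed with patient-level
data reconstructed from published Kaplan-Meier figures.  Those figures are
not machine-readable here, so this module generates samples with the same
statistical structure: event times drawn by inverse-transform sampling from
any supported parametric law, censored by the earlier of an administrative
study cutoff and an exponential dropout time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .survival import IPDRecord, SurvivalSpec, quantile

IPD_COLUMNS = ("time_months", "event")


@dataclass(frozen=True)
class CensoringSpec:
    """Administrative cutoff (months) plus per-month exponential dropout."""

    admin_censor_time: float = np.inf
    dropout_rate: float = 0.0

    def __post_init__(self):
        if not self.admin_censor_time > 0:
            raise ValueError("admin_censor_time must be positive")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be non-negative")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: step times, survival and at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_months": self.times,
            "survival": self.survival,
            "at_risk": self.at_risk,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_ipd(
    spec: SurvivalSpec,
    n: int,
    censoring: CensoringSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> list[IPDRecord]:
    """Draw ``n`` right-censored records from ``spec``.

    Event times come from the closed-form quantile function applied to
    uniform draws; the censoring time of each subject is the smaller of the
    administrative cutoff and an exponential dropout draw.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    censoring = censoring or CensoringSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    event_times = np.array([quantile(spec, ui) for ui in u])
    if censoring.dropout_rate > 0:
        dropout = rng.exponential(1.0 / censoring.dropout_rate, size=n)
    else:
        dropout = np.full(n, np.inf)
    censor_times = np.minimum(dropout, censoring.admin_censor_time)
    times = np.minimum(event_times, censor_times)
    events = event_times <= censor_times
    # guard against a zero quantile draw at u ~ 1
    times = np.maximum(times, 1e-12)
    return [IPDRecord(float(t), bool(e)) for t, e in zip(times, events)]


def km_estimate(ipd: list[IPDRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator (deaths before censorings at ties)."""
    if not ipd:
        raise ValueError("km_estimate requires a non-empty sample")
    times = [r.time for r in ipd]
    events = [r.event for r in ipd]
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    t = np.asarray(sf.index, dtype=float)
    return KMCurve(
        times=t,
        survival=np.asarray(sf.values, dtype=float),
        at_risk=np.asarray(table["at_risk"].reindex(sf.index).values, dtype=float),
    )


def write_ipd(ipd: list[IPDRecord], path) -> None:
    """Two-column delimited text with header: time_months, event (0/1)."""
    df = pd.DataFrame({
        "time_months": [r.time for r in ipd],
        "event": [int(r.event) for r in ipd],
    })
    df.to_csv(path, sep="\t", index=False)


def read_ipd(path) -> list[IPDRecord]:
    df = pd.read_csv(Path(path), sep=None, engine="python")
    missing = [c for c in IPD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"IPD file lacks required column(s): {missing}")
    return [
        IPDRecord(float(t), bool(int(e)))
        for t, e in zip(df["time_months"], df["event"])
    ]
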
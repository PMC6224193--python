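"""Deprivation scenarios and the three in-silico experiments.

Three conditions are compared on the same network realization:

* BL     — baseline, all weights at their Table-level values;
* TC     — thalamocortical depression only: thalamic drive onto excitatory
           cells scaled by delta_e, onto inhibitory cells by delta_i;
* TC+IC  — TC plus intracortical potentiation: recurrent excitatory drive
           onto inhibitory cells additionally scaled by pi.

Background drive and recurrent inhibitory weights are never scaled.  All
comparisons are paired: the three scenarios share connectivity, initial
conditions and the external input seed, so rate differences reflect only
the weight changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from dataclasses import replace as dc_replace
from typing import Optional

import numpy as np
import pandas as pd

from .config import derive_seed
from .factors import ScenarioFactors
from .network import (
    Connectivity,
    InputSpec,
    NetworkSpec,
    NeuronParams,
    PathwayMultipliers,
    build_connectivity,
    simulate,
)

__all__ = [
    "SCENARIOS",
    "SweepRanges",
    "RateTargets",
    "ConditionResult",
    "GridResult",
    "MonteCarloResult",
    "apply_scenario",
    "run_condition_comparison",
    "monte_carlo_sweep",
    "grid_scan",
]

SCENARIOS = ("BL", "TC", "TC_IC")


class PercentUndefinedError(RuntimeError):
    """Baseline rate is zero; raw rates are attached as ``.rates``."""

    def __init__(self, msg: str, rates: dict):
        super().__init__(msg)
        self.rates = rates


@dataclass(frozen=True)
class SweepRanges:
    """Uniform sampling ranges for the Monte-Carlo robustness sweep."""

    j_range: tuple = (0.1, 0.4)  # nS
    g_rc_range: tuple = (7.0, 10.0)
    R_lgn_range: tuple = (5.0, 15.0)  # Hz
    R_bkg_range: tuple = (5.0, 15.0)  # Hz

    def __post_init__(self) -> None:
        for name in ("j_range", "g_rc_range", "R_lgn_range", "R_bkg_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < min <= max")


@dataclass(frozen=True)
class RateTargets:
    """In-vivo firing-rate targets for baseline matching.

    The reference measurements exist only as a figure, so the numeric
    targets are mandatory user input — there are no defaults.
    """

    target_rate_e: float
    target_rate_i: float
    tolerance: float = 0.10
    match: str = "both"  # both | e | i

    def __post_init__(self) -> None:
        if self.target_rate_e <= 0 or self.target_rate_i <= 0:
            raise ValueError("rate targets must be positive")
        if not 0 < self.tolerance <= 1:
            raise ValueError("tolerance must lie in (0, 1]")
        if self.match not in ("both", "e", "i"):
            raise ValueError("match must be 'both', 'e' or 'i'")

    def matches(self, rate_e: float, rate_i: float) -> bool:
        ok_e = abs(rate_e - self.target_rate_e) <= self.tolerance * self.target_rate_e
        ok_i = abs(rate_i - self.target_rate_i) <= self.tolerance * self.target_rate_i
        if self.match == "e":
            return ok_e
        if self.match == "i":
            return ok_i
        return ok_e and ok_i


def apply_scenario(
    input_spec: InputSpec,
    spec: NetworkSpec,
    factors: ScenarioFactors,
    scenario: str,
) -> PathwayMultipliers:
    """Per-pathway weight multipliers for one scenario.

    BL leaves everything at 1; TC scales thalamic drive (delta_e onto E,
    delta_i onto I); TC_IC additionally scales recurrent E->I by pi.
    """
    if scenario == "BL":
        return PathwayMultipliers()
    if scenario == "TC":
        return PathwayMultipliers(tc_e=factors.delta_e, tc_i=factors.delta_i)
    if scenario == "TC_IC":
        return PathwayMultipliers(
            tc_e=factors.delta_e, tc_i=factors.delta_i, ei=factors.pi_fb
        )
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


@dataclass
class ConditionResult:
    """Paired-seed rates for BL / TC / TC+IC and percent-of-baseline."""

    rates: dict  # scenario -> (rate_e, rate_i)
    percent_of_bl: dict  # scenario -> (pct_e, pct_i)
    results: dict = field(default_factory=dict)  # scenario -> SimResult
    meta: dict = field(default_factory=dict)


def run_condition_comparison(
    neuron: NeuronParams,
    spec: NetworkSpec,
    input_spec: InputSpec,
    factors: ScenarioFactors,
    duration: float = 9000.0,
    seed: int = 0,
    dt: float = 0.1,
    transient_discard: float = 500.0,
    conn: Optional[Connectivity] = None,
    keep_results: bool = True,
) -> ConditionResult:
    """Simulate BL, TC and TC+IC on one shared network realization.

    Connectivity, initial voltages and external Poisson drive use seeds
    derived from ``seed``, identical across the three scenarios, so the
    comparison is paired.
    """
    if conn is None:
        conn = build_connectivity(spec, derive_seed(seed, "connectivity"))
    sim_seed = derive_seed(seed, "simulate")
    rates: dict = {}
    results: dict = {}
    for scen in SCENARIOS:
        mult = apply_scenario(input_spec, spec, factors, scen)
        res = simulate(
            neuron,
            spec,
            input_spec,
            conn,
            duration=duration,
            seed=sim_seed,
            weight_overrides=mult,
            dt=dt,
            transient_discard=transient_discard,
        )
        rates[scen] = (res.rate_e, res.rate_i)
        if keep_results:
            results[scen] = res
    bl_e, bl_i = rates["BL"]
    if bl_e == 0 or bl_i == 0:
        raise PercentUndefinedError(
            "percent-undefined: baseline rate is zero", rates
        )
    percent = {
        s: (100.0 * re / bl_e, 100.0 * ri / bl_i) for s, (re, ri) in rates.items()
    }
    return ConditionResult(
        rates=rates,
        percent_of_bl=percent,
        results=results,
        meta={"seed": seed, "duration_ms": duration, "dt_ms": dt, "factors": factors},
    )


@dataclass
class MonteCarloResult:
    """Outcome of the random-network robustness sweep."""

    table: pd.DataFrame  # one row per network x scenario x population
    params: pd.DataFrame  # one row per draw: sampled parameters + BL rates
    matched_ids: list
    summary: pd.DataFrame  # distribution summaries of percent-of-BL
    bl_rate_histogram: Optional[dict] = None  # diagnostic when nothing matched


def monte_carlo_sweep(
    ranges: SweepRanges,
    n_draws: int,
    targets: RateTargets,
    factors: ScenarioFactors,
    neuron: NeuronParams = NeuronParams(),
    base_spec: NetworkSpec = NetworkSpec(),
    base_input: InputSpec = InputSpec(),
    duration: float = 3000.0,
    master_seed: int = 0,
    dt: float = 0.1,
    transient_discard: float = 500.0,
) -> MonteCarloResult:
    """Random-network sweep: draw (j, g_rc, R_lgn, R_bkg), keep networks whose
    baseline rates match the targets, then apply TC and TC+IC to each.

    Each draw's parameters and seeds derive deterministically from
    ``master_seed``.  Percent-of-BL uses each network's own baseline as
    denominator.
    """
    if n_draws < 0:
        raise ValueError("n_draws must be >= 0")
    rows, prows = [], []
    matched: list[int] = []
    root = np.random.SeedSequence(master_seed)
    children = root.spawn(max(n_draws, 1))
    for k in range(n_draws):
        rng = np.random.default_rng(children[k])
        j = rng.uniform(*ranges.j_range)
        g_rc = rng.uniform(*ranges.g_rc_range)
        r_lgn = rng.uniform(*ranges.R_lgn_range)
        r_bkg = rng.uniform(*ranges.R_bkg_range)
        state = children[k].generate_state(2)
        conn_seed = int(state[0] % (2**31 - 1))
        sim_seed = int(state[1] % (2**31 - 1))

        spec_k = dc_replace(base_spec, j=j, g_rc=g_rc)
        input_k = dc_replace(base_input, R_lgn=r_lgn, R_bkg=r_bkg)
        conn = build_connectivity(spec_k, conn_seed)
        scen_rates = {}
        bl = simulate(
            neuron, spec_k, input_k, conn, duration, sim_seed,
            weight_overrides=apply_scenario(input_k, spec_k, factors, "BL"),
            dt=dt, transient_discard=transient_discard,
        )
        scen_rates["BL"] = (bl.rate_e, bl.rate_i)
        is_match = targets.matches(bl.rate_e, bl.rate_i)
        prows.append(
            {
                "network_id": k,
                "j_nS": j,
                "g_rc": g_rc,
                "R_lgn_Hz": r_lgn,
                "R_bkg_Hz": r_bkg,
                "bl_rate_e": bl.rate_e,
                "bl_rate_i": bl.rate_i,
                "matched": is_match,
            }
        )
        if not is_match:
            continue
        matched.append(k)
        for scen in ("TC", "TC_IC"):
            res = simulate(
                neuron, spec_k, input_k, conn, duration, sim_seed,
                weight_overrides=apply_scenario(input_k, spec_k, factors, scen),
                dt=dt, transient_discard=transient_discard,
            )
            scen_rates[scen] = (res.rate_e, res.rate_i)
        for scen, (re_, ri_) in scen_rates.items():
            for pop, rate, bl_rate in (("E", re_, bl.rate_e), ("I", ri_, bl.rate_i)):
                rows.append(
                    {
                        "network_id": k,
                        "scenario": scen,
                        "population": pop,
                        "rate_hz": rate,
                        "percent_of_bl": 100.0 * rate / bl_rate if bl_rate > 0 else np.nan,
                    }
                )

    table = pd.DataFrame(
        rows, columns=["network_id", "scenario", "population", "rate_hz", "percent_of_bl"]
    )
    params = pd.DataFrame(
        prows,
        columns=[
            "network_id", "j_nS", "g_rc", "R_lgn_Hz", "R_bkg_Hz",
            "bl_rate_e", "bl_rate_i", "matched",
        ],
    )
    if table.empty:
        summary = pd.DataFrame(
            columns=["scenario", "population", "median", "iqr_lo", "iqr_hi", "mean", "n"]
        )
    else:
        summary = (
            table.groupby(["scenario", "population"])["percent_of_bl"]
            .agg(
                median="median",
                iqr_lo=lambda s: s.quantile(0.25),
                iqr_hi=lambda s: s.quantile(0.75),
                mean="mean",
                n="count",
            )
            .reset_index()
        )
    hist = None
    if n_draws > 0 and not matched:
        counts_e, edges_e = np.histogram(params["bl_rate_e"], bins=20)
        counts_i, edges_i = np.histogram(params["bl_rate_i"], bins=20)
        hist = {
            "rate_e": (counts_e.tolist(), edges_e.tolist()),
            "rate_i": (counts_i.tolist(), edges_i.tolist()),
        }
    return MonteCarloResult(
        table=table, params=params, matched_ids=matched, summary=summary,
        bl_rate_histogram=hist,
    )


@dataclass
class GridResult:
    """(rho_EI, pi) grid of steady-state rates relative to the (1, 1) cell."""

    rho_values: np.ndarray
    pi_values: np.ndarray
    rate_e: np.ndarray  # (n_rho, n_pi) Hz
    rate_i: np.ndarray
    percent_of_bl_e: np.ndarray
    percent_of_bl_i: np.ndarray
    meta: dict = field(default_factory=dict)


def grid_scan(
    rho_values,
    pi_values,
    neuron: NeuronParams = NeuronParams(),
    spec: NetworkSpec = NetworkSpec(),
    input_spec: InputSpec = InputSpec(),
    delta_e_fixed: float = 0.9,
    duration: float = 9000.0,
    seed: int = 0,
    dt: float = 0.1,
    transient_discard: float = 500.0,
) -> GridResult:
    """Scan combinations of feedforward shift rho_EI and feedback potentiation pi.

    Thalamic depression onto excitatory cells is fixed at ``delta_e_fixed``
    (the measured value); each grid cell sets delta_i = delta_e / rho and
    applies the TC+IC multipliers.  All cells share connectivity and input
    seeds, and rates are expressed as percent of the (rho=1, pi=1) cell,
    which is therefore 100 by construction.
    """
    rho = np.asarray(list(rho_values), dtype=float)
    piv = np.asarray(list(pi_values), dtype=float)
    if np.any(rho < 1.0) or np.any(piv < 1.0):
        import warnings

        warnings.warn(
            "rho/pi below 1 are outside the declared [1, 1.5] range; computing anyway",
            stacklevel=2,
        )
    conn = build_connectivity(spec, derive_seed(seed, "connectivity"))
    sim_seed = derive_seed(seed, "simulate")

    def run_cell(r: float, p: float):
        mult = PathwayMultipliers(
            tc_e=delta_e_fixed, tc_i=delta_e_fixed / r, ei=p
        )
        res = simulate(
            neuron, spec, input_spec, conn, duration, sim_seed,
            weight_overrides=mult, dt=dt, transient_discard=transient_discard,
        )
        return res.rate_e, res.rate_i

    ref_e, ref_i = run_cell(1.0, 1.0)
    rate_e = np.empty((rho.size, piv.size))
    rate_i = np.empty((rho.size, piv.size))
    for a, r in enumerate(rho):
        for b, p in enumerate(piv):
            if r == 1.0 and p == 1.0:
                rate_e[a, b], rate_i[a, b] = ref_e, ref_i
            else:
                rate_e[a, b], rate_i[a, b] = run_cell(float(r), float(p))
    pct_e = 100.0 * rate_e / ref_e if ref_e > 0 else np.full_like(rate_e, np.nan)
    pct_i = 100.0 * rate_i / ref_i if ref_i > 0 else np.full_like(rate_i, np.nan)
    return GridResult(
        rho_values=rho,
        pi_values=piv,
        rate_e=rate_e,
        rate_i=rate_i,
        percent_of_bl_e=pct_e,
        percent_of_bl_i=pct_i,
        meta={
            "delta_e_fixed": delta_e_fixed,
            "seed": seed,
            "duration_ms": duration,
            "reference": "grid cell (rho=1, pi=1)",
        },
    )
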
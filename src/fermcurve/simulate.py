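"""Ground-truth generator for fermentation screens.

Emulates the reference screen design — 13 carbohydrate candidates, the
19-point sampling schedule over 205 h, biological triplicates, six measured
patterns (viable counts, acetate, propionate, butyrate, total SCFA,
dissolved ammonia) — with known logistic/Gompertz truths, a growth–decline
viable-count pattern joined at a tipping point, and additive Gaussian noise
truncated at zero (measured quantities are non-negative).

The default truths span the qualitative regimes seen in such screens:
simple sugars ferment fast but fail to sustain the population (high growth
rate, early tipping point, early decline); oligosaccharides sit in between;
polymeric beta-glucans ferment slowly but sustain growth past the end of the
observation window (negative decline lag).  The numbers are the package's
own realistic choices, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curve_models import CurveParams, model_value
from .screen_data import SampleSeries, ScreenDataset, default_schedule

__all__ = [
    "AdditiveTruth",
    "CandidateTruth",
    "SimSpec",
    "ScreenSimulation",
    "default_sim_spec",
    "simulate_metabolite_curve",
    "simulate_growth_curve",
    "simulate_screen",
]

METABOLITE_ANALYTES = ("acetate", "propionate", "butyrate", "nh3")
_UNITS = {"cfu": "CFU/mL", "acetate": "mM", "propionate": "mM",
          "butyrate": "mM", "total_scfa": "mM", "nh3": "mg/mL"}


@dataclass(frozen=True)
class AdditiveTruth:
    """True two-branch viable-count pattern joined at tipping point tx."""

    growth: CurveParams
    decline: CurveParams
    tx: float
    growth_model: str = "logistic"
    decline_model: str = "logistic"


@dataclass(frozen=True)
class CandidateTruth:
    """True curve per metabolite analyte plus the viable-count pattern."""

    metabolites: dict[str, tuple[CurveParams, str]]
    cfu: AdditiveTruth


@dataclass
class SimSpec:
    """Simulation design: candidates, schedule, replication, noise, seed."""

    candidates: dict[str, CandidateTruth]
    schedule: list[float] = field(default_factory=default_schedule)
    n_replicates: int = 3
    noise_sd: float = 0.05  # additive Gaussian sd as a fraction of A
    t_end: float = 205.0
    seed: int | None = None
    cfu_noise: str = "gaussian"  # or "lognormal"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("seed is mandatory for stochastic output")


# per-candidate truth table: metabolite curves as (A, mu, lam) — units mM
# and mM/h for SCFAs, mg/mL for NH3 — plus the viable-count pattern as
# (A in CFU/mL, tx in h, growth rise time r_g, decline rise time r_d).
# Rise time r = A/mu is the tangent-rule time to traverse the sigmoid; the
# branch lags follow lam_g = tx - 1.35 r_g and lam_d = (205 - tx) - 1.35 r_d
# so each branch sits just shy of capacity at the tipping point and the
# noiseless pattern peaks exactly at tx (broad plateaus would make tx
# unidentifiable under measurement noise).  Slow decliners (large r_d) get a
# negative decline lag: the population has not reached zero by 205 h.
_DEFAULT_TRUTHS: dict[str, dict] = {
    #           acetate           propionate        butyrate           nh3                    cfu(A, tx, r_g, r_d)
    "Glucose":   dict(ace=(45, 2.8, 3),  pro=(10, 0.7, 4),  but=(4, 0.30, 5),   nh3=(0.30, 0.012, 8),  cfu=(8.0e8, 36, 9, 12)),
    "Lactose":   dict(ace=(60, 3.0, 4),  pro=(9, 0.6, 5),   but=(5, 0.35, 6),   nh3=(0.45, 0.015, 10), cfu=(7.0e8, 48, 11, 14)),
    "Sucrose":   dict(ace=(30, 1.8, 3),  pro=(8, 0.5, 4),   but=(3, 0.25, 5),   nh3=(0.80, 0.028, 18), cfu=(1.0e9, 48, 10, 13)),
    "Xylitol":   dict(ace=(28, 1.2, 6),  pro=(9, 0.5, 8),   but=(4, 0.22, 9),   nh3=(0.55, 0.018, 12), cfu=(6.0e8, 55, 13, 16)),
    "FOS":       dict(ace=(40, 2.0, 6),  pro=(14, 0.9, 8),  but=(6, 0.40, 9),   nh3=(0.40, 0.020, 20), cfu=(8.5e8, 55, 12, 18)),
    "GOS":       dict(ace=(55, 2.5, 5),  pro=(10, 0.6, 7),  but=(6, 0.35, 8),   nh3=(0.28, 0.010, 15), cfu=(7.5e8, 61, 14, 18)),
    "XOS":       dict(ace=(38, 1.6, 12), pro=(11, 0.7, 13), but=(12, 0.60, 14), nh3=(0.50, 0.016, 16), cfu=(6.5e8, 61, 13, 20)),
    "Inulin":    dict(ace=(36, 2.2, 14), pro=(18, 1.1, 15), but=(8, 0.45, 15),  nh3=(0.60, 0.018, 22), cfu=(6.0e8, 79, 18, 100)),
    "Glycogen":  dict(ace=(33, 1.4, 10), pro=(9, 0.5, 11),  but=(5, 0.30, 12),  nh3=(0.20, 0.008, 14), cfu=(7.0e8, 73, 16, 24)),
    "Starch":    dict(ace=(35, 1.5, 11), pro=(10, 0.6, 12), but=(6, 0.35, 13),  nh3=(0.75, 0.026, 25), cfu=(1.0e9, 79, 16, 26)),
    "Oat_bG":    dict(ace=(25, 1.0, 13), pro=(8, 0.45, 14), but=(9, 0.50, 15),  nh3=(0.26, 0.009, 18), cfu=(7.0e8, 85, 20, 50)),
    "Barley_bG": dict(ace=(50, 2.4, 13), pro=(12, 0.8, 14), but=(14, 0.70, 15), nh3=(0.48, 0.015, 20), cfu=(5.5e8, 97, 22, 90)),
    "Ptr_bG":    dict(ace=(32, 1.3, 14), pro=(10, 0.6, 15), but=(10, 0.55, 16), nh3=(0.52, 0.016, 19), cfu=(6.0e8, 85, 18, 45)),
}

_KEY_TO_ANALYTE = {"ace": "acetate", "pro": "propionate", "but": "butyrate",
                   "nh3": "nh3"}

_LAG_FACTOR = 1.35  # branch lag offset in rise times; see table comment


def _default_cfu_truth(A: float, tx: float, r_g: float, r_d: float,
                       growth_model: str, decline_model: str,
                       t_end: float = 205.0) -> AdditiveTruth:
    growth = CurveParams(A, A / r_g, tx - _LAG_FACTOR * r_g)
    decline = CurveParams(A, A / r_d, (t_end - tx) - _LAG_FACTOR * r_d)
    return AdditiveTruth(growth=growth, decline=decline, tx=float(tx),
                         growth_model=growth_model,
                         decline_model=decline_model)


def default_sim_spec(seed: int | None = None, n_candidates: int = 13,
                     noise_sd: float = 0.05,
                     n_replicates: int = 3) -> SimSpec:
    """The reference 13-candidate simulation design.

    Metabolite models alternate between logistic and Gompertz across
    candidates so model selection is exercised in both directions.
    """
    names = list(_DEFAULT_TRUTHS)[:n_candidates]
    if n_candidates > len(_DEFAULT_TRUTHS):
        raise ValueError(f"at most {len(_DEFAULT_TRUTHS)} default candidates")
    candidates = {}
    for i, name in enumerate(names):
        row = _DEFAULT_TRUTHS[name]
        model = "logistic" if i % 2 == 0 else "gompertz"
        metabolites = {
            _KEY_TO_ANALYTE[k]: (CurveParams(*row[k]), model)
            for k in ("ace", "pro", "but", "nh3")
        }
        cfu = _default_cfu_truth(
            *row["cfu"], growth_model=model,
            decline_model="logistic" if i % 3 else "gompertz")
        candidates[name] = CandidateTruth(metabolites=metabolites, cfu=cfu)
    return SimSpec(candidates=candidates, noise_sd=noise_sd,
                   n_replicates=n_replicates, seed=seed)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_metabolite_curve(
    params: CurveParams,
    model: str,
    schedule=None,
    noise_sd: float = 0.0,
    seed=None,
    candidate_id: str = "sim",
    replicate: int = 1,
    analyte: str = "acetate",
) -> SampleSeries:
    """One noisy metabolite production series at the scheduled times.

    Additive Gaussian noise with sd = ``noise_sd * A``, truncated at zero;
    deterministic given the seed.
    """
    t = np.asarray(default_schedule() if schedule is None else schedule,
                   dtype=float)
    y = model_value(model, params, t)
    if noise_sd > 0:
        y = y + _rng(seed).normal(0.0, noise_sd * params.A, size=len(t))
        y = np.maximum(y, 0.0)
    return SampleSeries(candidate_id, replicate, analyte, t, y,
                        _UNITS.get(analyte, ""))


def simulate_growth_curve(
    growth: CurveParams,
    decline: CurveParams,
    tx: float,
    t_end: float = 205.0,
    schedule=None,
    noise_sd: float = 0.0,
    seed=None,
    growth_model: str = "logistic",
    decline_model: str = "logistic",
    noise: str = "gaussian",
    candidate_id: str = "sim",
    replicate: int = 1,
) -> SampleSeries:
    """One noisy viable-count series from the two-branch pattern.

    Below tx the growth branch applies; above tx the time-mirrored decline
    branch; exactly at tx the larger of the two, so the tipping point is the
    literal maximum of the noiseless pattern.  ``noise`` is additive
    Gaussian (sd = noise_sd * max capacity, truncated at 0) or
    multiplicative lognormal (sigma = noise_sd).
    """
    if not (0 < tx < t_end):
        raise ValueError(f"tx must lie in (0, {t_end}), got {tx}")
    t = np.asarray(default_schedule() if schedule is None else schedule,
                   dtype=float)
    g = model_value(growth_model, growth, t)
    d = model_value(decline_model, decline, t_end - t)
    y = np.where(t < tx, g, d)
    y = np.where(t == tx, np.maximum(g, d), y)
    if noise_sd > 0:
        rng = _rng(seed)
        if noise == "lognormal":
            y = y * np.exp(rng.normal(0.0, noise_sd, size=len(t)))
        elif noise == "gaussian":
            amp = noise_sd * max(growth.A, decline.A)
            y = np.maximum(y + rng.normal(0.0, amp, size=len(t)), 0.0)
        else:
            raise ValueError(f"unknown noise model {noise!r}")
    return SampleSeries(candidate_id, replicate, "cfu", t, y, _UNITS["cfu"])


@dataclass
class ScreenSimulation:
    """A simulated dataset together with its generating truth table."""

    dataset: ScreenDataset
    truth: pd.DataFrame
    spec: SimSpec


def _series_seed(spec_seed, i: int, j: int, k: int):
    base = 0 if spec_seed is None else int(spec_seed)
    return np.random.SeedSequence(entropy=base, spawn_key=(i, j, k))


def simulate_screen(spec: SimSpec) -> ScreenSimulation:
    """Simulate a full screen: six measured patterns per candidate x
    replicate, with the total-SCFA series derived as the sum of the three
    simulated component series (so its noise is the propagated component
    noise).  Bit-for-bit reproducible from (spec, seed)."""
    series = []
    truth_rows = []
    for i, (cand, truth) in enumerate(spec.candidates.items()):
        for k, analyte in enumerate(METABOLITE_ANALYTES):
            params, model = truth.metabolites[analyte]
            truth_rows.append({"candidate": cand, "analyte": analyte,
                               "model": model, "A": params.A, "mu": params.mu,
                               "lam": params.lam})
        cfu = truth.cfu
        truth_rows.append({
            "candidate": cand, "analyte": "cfu",
            "model": f"{cfu.growth_model}+{cfu.decline_model}",
            "MaxCFU": cfu.growth.A, "GroRate": cfu.growth.mu,
            "Lag": cfu.growth.lam, "tx": cfu.tx,
            "DeclineMaxCFU": cfu.decline.A, "DeclineRate": cfu.decline.mu,
            "DeclineLag": cfu.decline.lam,
        })
        for j in range(1, spec.n_replicates + 1):
            components = {}
            for k, analyte in enumerate(METABOLITE_ANALYTES):
                params, model = truth.metabolites[analyte]
                s = simulate_metabolite_curve(
                    params, model, spec.schedule, spec.noise_sd,
                    seed=_series_seed(spec.seed, i, j, k),
                    candidate_id=cand, replicate=j, analyte=analyte)
                components[analyte] = s
                series.append(s)
            total = (components["acetate"].values
                     + components["propionate"].values
                     + components["butyrate"].values)
            series.append(SampleSeries(cand, j, "total_scfa",
                                       np.asarray(spec.schedule, dtype=float),
                                       total, _UNITS["total_scfa"]))
            series.append(simulate_growth_curve(
                cfu.growth, cfu.decline, cfu.tx, spec.t_end, spec.schedule,
                spec.noise_sd, seed=_series_seed(spec.seed, i, j, 99),
                growth_model=cfu.growth_model, decline_model=cfu.decline_model,
                noise=spec.cfu_noise, candidate_id=cand, replicate=j))
    dataset = ScreenDataset(series=series, t_end=spec.t_end,
                            schedule=list(spec.schedule))
    return ScreenSimulation(dataset=dataset,
                            truth=pd.DataFrame(truth_rows), spec=spec)
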
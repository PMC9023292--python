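"""Early-translation Michaelis-Menten kinetics and the volume correlation.

The elementary scheme has three rate constants: tRNA arrival at an empty
A site (``k_arr``, the association rate constant times tRNA
availability), dissociation of the bound tRNA (``k_minus``) and peptide
bond formation (``k_pep``).  A bound tRNA either reacts, with
probability ``p = k_pep / (k_minus + k_pep)``, or leaves; after a
successful reaction the deacylated tRNA is released from the P site at
the same ``k_minus``.  The mean time per incorporated codon under this
renewal scheme is

    T(k-) = (1/p) * (1/k_arr + 1/(k_minus + k_pep)) + 1/k_minus
          = (k_minus + k_pep) / (k_pep * k_arr) + 1/k_pep + 1/k_minus,

which diverges both as k- -> 0 (the spent tRNA never leaves the P site)
and as k- -> infinity (peptide bond formation never succeeds), with a
unique interior optimum at k-* = sqrt(k_arr * k_pep).  When arrival is
not limiting relative to the chemistry (k_arr = k_pep) the optimum is
exactly k- = k_pep: a tRNA that reacts about half the time and then
leaves quickly maximizes the translation rate.  The modern scheme
appends a committed accommodation step of mean duration 1/k_acc and a
PTC-levelled uniform peptide-bond constant k'_pep.

Dissociation constants map exponentially onto duplex free energies,
``k- = k0_off * exp(dG0 / RT)``, and the peptide-bond constant is
expected to decrease with amino-acid side-chain volume; the "volume
correlation" between -dG0 and van der Waals volume is the genetic-code
trace of the ancestral k- ~ k_pep matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KineticParams",
    "ModernParams",
    "ElongationResult",
    "EnergyVolumeTables",
    "CorrelationResult",
    "SimulatedElongation",
    "p_pep",
    "mean_elongation_time",
    "elongation_result",
    "optimal_k_minus",
    "optimal_k_minus_numeric",
    "k_minus_from_dg",
    "k_pep_from_volume",
    "volume_correlation",
    "modern_mean_time",
    "modern_rate",
    "simulate_elongation",
]


def _check_positive(**rates: float) -> None:
    for name, value in rates.items():
        if not (math.isfinite(value) and value > 0):
            raise ValueError(f"{name} must be strictly positive and finite, got {value}")


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the elementary translation scheme (all 1/s)."""

    k_arr: float
    k_minus: float
    k_pep: float

    def __post_init__(self) -> None:
        _check_positive(k_arr=self.k_arr, k_minus=self.k_minus, k_pep=self.k_pep)


@dataclass(frozen=True)
class ModernParams:
    """Elementary scheme plus committed accommodation (k_acc) and a
    PTC-levelled uniform peptide-bond constant (k_pep_prime, defaults to
    k_pep; k_acc is expected to be of the same order as k_pep_prime)."""

    k_arr: float
    k_minus: float
    k_pep: float
    k_acc: float
    k_pep_prime: float | None = None

    def __post_init__(self) -> None:
        _check_positive(
            k_arr=self.k_arr, k_minus=self.k_minus, k_pep=self.k_pep, k_acc=self.k_acc
        )
        if self.k_pep_prime is not None:
            _check_positive(k_pep_prime=self.k_pep_prime)

    @property
    def effective_k_pep(self) -> float:
        return self.k_pep if self.k_pep_prime is None else self.k_pep_prime


@dataclass(frozen=True)
class ElongationResult:
    """Derived quantities of one scheme evaluation."""

    p_pep: float
    mean_time: float
    rate: float


def p_pep(k_minus: float, k_pep: float) -> float:
    """Probability that a bound tRNA forms a peptide bond before leaving."""
    _check_positive(k_minus=k_minus, k_pep=k_pep)
    return k_pep / (k_minus + k_pep)


def mean_elongation_time(params: KineticParams) -> float:
    """Mean time per incorporated codon under the renewal scheme (s)."""
    p = p_pep(params.k_minus, params.k_pep)
    cycle = 1.0 / params.k_arr + 1.0 / (params.k_minus + params.k_pep)
    return cycle / p + 1.0 / params.k_minus


def elongation_result(params: KineticParams) -> ElongationResult:
    t = mean_elongation_time(params)
    return ElongationResult(
        p_pep=p_pep(params.k_minus, params.k_pep), mean_time=t, rate=1.0 / t
    )


def optimal_k_minus(k_arr: float, k_pep: float) -> float:
    """Dissociation constant maximizing the translation rate.

    Closed form sqrt(k_arr * k_pep); reduces to k- = k_pep when arrival
    matches the chemistry (k_arr = k_pep).
    """
    _check_positive(k_arr=k_arr, k_pep=k_pep)
    return math.sqrt(k_arr * k_pep)


def optimal_k_minus_numeric(k_arr: float, k_pep: float) -> float:
    """Numeric argmin of the mean elongation time over log k- (cross-check)."""
    _check_positive(k_arr=k_arr, k_pep=k_pep)

    def objective(log_km: float) -> float:
        return mean_elongation_time(KineticParams(k_arr, math.exp(log_km), k_pep))

    center = 0.5 * (math.log(k_arr) + math.log(k_pep))
    res = optimize.minimize_scalar(
        objective,
        bracket=(center - 8.0, center, center + 8.0),
        method="brent",
        options={"xtol": 1e-12},
    )
    return math.exp(res.x)


def modern_mean_time(params: ModernParams) -> float:
    """Mean time per codon with a committed accommodation step.

    Accommodation happens once, after the successful selection cycle and
    before peptide bond formation, with no return to the free pool, so
    it adds exactly 1/k_acc to the renewal mean; as k_acc -> infinity
    the early scheme is recovered.
    """
    base = KineticParams(params.k_arr, params.k_minus, params.effective_k_pep)
    return mean_elongation_time(base) + 1.0 / params.k_acc


def modern_rate(params: ModernParams) -> ElongationResult:
    t = modern_mean_time(params)
    return ElongationResult(
        p_pep=p_pep(params.k_minus, params.effective_k_pep),
        mean_time=t,
        rate=1.0 / t,
    )


# ---------------------------------------------------------------------------
# Energy / volume mappings


@dataclass(frozen=True)
class EnergyVolumeTables:
    """Anticodon-codon duplex free energies and side-chain volumes.

    ``dg0`` is in kcal/mol (more negative = more stable duplex);
    ``volume`` in cubic angstroms.  ``rt`` defaults to 0.616 kcal/mol
    (310 K).  The prefactors set the absolute scale of the exponential
    mappings; only ratios are meaningful.
    """

    dg0: Mapping[str, float]
    volume: Mapping[str, float]
    rt: float = 0.616
    k0_off: float = 1.0
    k0_pep: float = 1.0

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError(f"RT must be positive, got {self.rt}")
        if not self.dg0 or not self.volume:
            raise ValueError("dg0 and volume tables must be non-empty")

    def shared_species(self) -> list[str]:
        return sorted(set(self.dg0) & set(self.volume))


def k_minus_from_dg(dg0: float, tables: EnergyVolumeTables) -> float:
    """Dissociation constant from duplex free energy: k0_off * exp(dG0/RT)."""
    return tables.k0_off * math.exp(dg0 / tables.rt)


def k_pep_from_volume(volume: float, tables: EnergyVolumeTables, beta: float = 0.01) -> float:
    """Peptide-bond constant from side-chain volume: k0_pep * exp(-beta*V).

    ``beta`` (1/A^3) sets how steeply bulkier side chains slow the
    uncatalyzed reaction; only the monotone-decreasing form matters here.
    """
    if volume < 0:
        raise ValueError("volume must be non-negative")
    return tables.k0_pep * math.exp(-beta * volume)


@dataclass(frozen=True)
class CorrelationResult:
    """Rank and linear correlation between -dG0 and side-chain volume."""

    spearman_rho: float
    pearson_r: float
    n: int
    excluded: tuple[str, ...]
    degenerate: bool = False


def volume_correlation(
    tables: EnergyVolumeTables, exclusions: Sequence[str] = ()
) -> CorrelationResult:
    """Correlate duplex stability (-dG0) with van der Waals volume.

    Species in ``exclusions`` (the code's apparent outliers such as
    asn/arg/trp) are dropped from the statistic and reported separately.
    Zero variance on either axis flags the result as degenerate with NaN
    correlations.
    """
    excluded = tuple(s for s in exclusions if s in set(tables.dg0) | set(tables.volume))
    keys = [k for k in tables.shared_species() if k not in set(exclusions)]
    if len(keys) < 3:
        raise ValueError(
            f"need at least 3 shared species after exclusions, have {len(keys)}"
        )
    stab = np.array([-tables.dg0[k] for k in keys])
    vol = np.array([tables.volume[k] for k in keys])
    if np.ptp(stab) == 0 or np.ptp(vol) == 0:
        return CorrelationResult(
            spearman_rho=float("nan"),
            pearson_r=float("nan"),
            n=len(keys),
            excluded=excluded,
            degenerate=True,
        )
    rho = stats.spearmanr(stab, vol).statistic
    r = stats.pearsonr(stab, vol).statistic
    return CorrelationResult(
        spearman_rho=float(rho), pearson_r=float(r), n=len(keys), excluded=excluded
    )


# ---------------------------------------------------------------------------
# Stochastic cross-check


@dataclass(frozen=True)
class SimulatedElongation:
    mean_time: float
    sem: float
    n_events: int
    seed: int


def simulate_elongation(
    params: KineticParams, n_events: int = 100_000, seed: int = 0
) -> SimulatedElongation:
    """Event-level stochastic simulation of the renewal scheme.

    Each incorporation runs cycles of exponential arrival and bound
    residence; the exit channel (reaction vs dissociation) is drawn from
    the competing exponentials, and a final P-site release at k_minus
    closes the event.  Serves as an independent check of the closed-form
    mean (agreement expected within a few SEM).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    k_exit = params.k_minus + params.k_pep
    p = params.k_pep / k_exit
    times = np.empty(n_events)
    for i in range(n_events):
        t = 0.0
        while True:
            t += rng.exponential(1.0 / params.k_arr)
            t += rng.exponential(1.0 / k_exit)
            if rng.random() < p:
                break
        t += rng.exponential(1.0 / params.k_minus)
        times[i] = t
    mean = float(times.mean())
    sem = float(times.std(ddof=1) / math.sqrt(n_events))
    return SimulatedElongation(mean_time=mean, sem=sem, n_events=n_events, seed=seed)
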
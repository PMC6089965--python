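"""Molecule-counting statistics for zeptomolar standard solutions.

At zeptomolar (zM, 1e-21 mol/l) concentrations a 100 µl aliquot holds only
a handful of molecules, so the number actually sampled is a Poisson random
variable whose mean λ follows from the nominal molarity by Avogadro
conversion.  This module converts concentrations to expected molecule
numbers, propagates the two uncertainty sources of a serial-dilution
protocol (per-step dilution error and Poisson sampling error), and
accumulates dose over sequential incubations of the same sensing gate.

Units: concentrations in zM, volumes in µl, molecule numbers dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Avogadro constant, mol^-1.  Fixed at 4 significant digits: every printed
#: conversion in the assay literature this package targets uses this value,
#: and CODATA refinements are invisible at the reported precision.
N_AVOGADRO = 6.022e23

__all__ = [
    "N_AVOGADRO",
    "StandardSolution",
    "DilutionSeries",
    "DoseCount",
    "molecules_expected",
    "poisson_probability",
    "sampling_sigma_molarity",
    "total_concentration_error",
    "build_dilution_series",
    "cumulative_dose",
    "series_to_frame",
    "round_to_sig",
]


def molecules_expected(concentration_zm: float, volume_ul: float) -> float:
    """Expected number of molecules λ in a sampled aliquot.

    Parameters
    ----------
    concentration_zm : float
        Nominal concentration in zeptomolar (1 zM = 1e-21 mol/l).
    volume_ul : float
        Sampled volume in microlitres.

    Returns
    -------
    float
        λ = C·1e-21 · V·1e-6 · N_A, the Poisson mean of the sampled count.
    """
    if concentration_zm < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration_zm}")
    if volume_ul <= 0:
        raise ValueError(f"volume must be > 0, got {volume_ul}")
    return concentration_zm * 1e-21 * volume_ul * 1e-6 * N_AVOGADRO


def molarity_from_molecules(lam: float, volume_ul: float) -> float:
    """Inverse Avogadro conversion: molecule number -> concentration in zM."""
    if volume_ul <= 0:
        raise ValueError(f"volume must be > 0, got {volume_ul}")
    if lam < 0:
        raise ValueError(f"molecule number must be >= 0, got {lam}")
    return lam / (volume_ul * 1e-6 * N_AVOGADRO) * 1e21


def poisson_probability(k: int, lam: float) -> float:
    """P(K = k) for K ~ Poisson(lam): e^-λ λ^k / k!.

    ``poisson_probability(0, lam)`` is the probability that the sampled
    aliquot contains no molecule at all — the quantity that decides whether
    a sub-single-molecule incubation can register a response.
    """
    if lam < 0:
        raise ValueError(f"Poisson mean must be >= 0, got {lam}")
    if k < 0 or int(k) != k:
        raise ValueError(f"count must be a non-negative integer, got {k}")
    return float(stats.poisson.pmf(int(k), lam))


def sampling_sigma_molarity(concentration_zm: float, volume_ul: float) -> float:
    """Poisson sampling SD of a standard solution, expressed in zM.

    The sampled count has SD sqrt(λ); converting back to molarity gives the
    concentration-equivalent one-standard-deviation sampling uncertainty.
    Relative to the nominal concentration this is 1/sqrt(λ), so it dominates
    the error budget at the most dilute standards.
    """
    lam = molecules_expected(concentration_zm, volume_ul)
    return molarity_from_molecules(math.sqrt(lam), volume_ul)


def total_concentration_error(dilution_sigma_zm: float, poisson_sigma_zm: float) -> float:
    """Combine dilution and Poisson uncertainties in quadrature (both in zM)."""
    if dilution_sigma_zm < 0 or poisson_sigma_zm < 0:
        raise ValueError("uncertainties must be >= 0")
    return math.hypot(dilution_sigma_zm, poisson_sigma_zm)


@dataclass(frozen=True)
class StandardSolution:
    """One standard solution of a serial-dilution protocol.

    Attributes
    ----------
    concentration : float
        Nominal concentration in zM.
    volume : float
        Sampled (incubation) volume in µl.
    dilution_sigma : float
        One SD of the concentration from the dilution protocol, in zM.
    """

    concentration: float
    volume: float
    dilution_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.volume <= 0:
            raise ValueError("volume must be > 0")
        if self.dilution_sigma < 0:
            raise ValueError("dilution_sigma must be >= 0")

    @property
    def lam(self) -> float:
        """Expected molecule number in the sampled volume."""
        return molecules_expected(self.concentration, self.volume)

    @property
    def poisson_sigma(self) -> float:
        """Poisson sampling SD in zM."""
        return sampling_sigma_molarity(self.concentration, self.volume)

    @property
    def total_sigma(self) -> float:
        """Quadrature combination of dilution and Poisson SDs, in zM."""
        return total_concentration_error(self.dilution_sigma, self.poisson_sigma)


@dataclass(frozen=True)
class DilutionSeries:
    """An ordered set of standard solutions from one serial-dilution run."""

    steps: tuple[StandardSolution, ...]
    per_step_cv: float = 0.0

    def __init__(self, steps: Sequence[StandardSolution], per_step_cv: float = 0.0):
        if per_step_cv < 0:
            raise ValueError("per_step_cv must be >= 0")
        steps = tuple(steps)
        if len(steps) == 0:
            raise ValueError("a dilution series needs at least one step")
        conc = [s.concentration for s in steps]
        diffs = np.diff(conc)
        if len(diffs) and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("concentrations must be strictly monotone")
        object.__setattr__(self, "steps", steps)
        object.__setattr__(self, "per_step_cv", per_step_cv)

    def __len__(self) -> int:
        return len(self.steps)

    def measurement_order(self) -> tuple[StandardSolution, ...]:
        """Steps sorted most-dilute-first, the order a gate is incubated in."""
        return tuple(sorted(self.steps, key=lambda s: s.concentration))


@dataclass(frozen=True)
class DoseCount:
    """Expected molecule number with its SD (pure Poisson: sigma² = lam)."""

    lam: float
    sigma: float

    def __post_init__(self) -> None:
        if self.lam < 0 or self.sigma < 0:
            raise ValueError("lam and sigma must be >= 0")


def build_dilution_series(
    c0_zm: float,
    factor: float,
    n_steps: int,
    per_step_cv: float = 0.015,
    volume_ul: float = 100.0,
) -> DilutionSeries:
    """Serial dilution from stock ``c0_zm`` by ``factor`` per step.

    Step ``i`` (1-based) has concentration c0/factor^i.  Each dilution step
    contributes an independent multiplicative error of relative SD
    ``per_step_cv``, so after i steps the accumulated dilution SD is
    c_i · cv · sqrt(i).  The default cv of 1.5% reproduces permille-level
    uncertainties at the concentrated end of an eleven-decade series while
    leaving the dilute end Poisson-dominated.
    """
    if c0_zm <= 0:
        raise ValueError("stock concentration must be > 0")
    if factor <= 1:
        raise ValueError("dilution factor must be > 1")
    if n_steps < 1:
        raise ValueError("need at least one dilution step")
    if per_step_cv < 0:
        raise ValueError("per_step_cv must be >= 0")
    steps = []
    for i in range(1, n_steps + 1):
        c = c0_zm / factor**i
        steps.append(
            StandardSolution(
                concentration=c,
                volume=volume_ul,
                dilution_sigma=c * per_step_cv * math.sqrt(i),
            )
        )
    return DilutionSeries(steps, per_step_cv=per_step_cv)


def cumulative_dose(series: DilutionSeries, upto: int) -> DoseCount:
    """Total expected molecule number over incubations 0..upto inclusive.

    Incubations proceed most-dilute-first (one gate sees every standard in
    turn), so the dose at a given standard is the sum of λ over all
    standards sampled so far.  The Poisson SD of the cumulative count is
    sqrt of the cumulative mean.  ``upto = -1`` denotes the empty prefix.
    """
    ordered = series.measurement_order()
    if upto < -1 or upto >= len(ordered):
        raise IndexError(f"upto={upto} out of range for {len(ordered)} steps")
    lam = sum(s.lam for s in ordered[: upto + 1])
    return DoseCount(lam=lam, sigma=math.sqrt(lam))


def series_to_frame(series: DilutionSeries) -> pd.DataFrame:
    """Tabulate a dilution series in measurement order.

    Columns: step, conc_zM, dilution_sigma_zM, poisson_sigma_zM,
    total_sigma_zM, lam, cum_lam.  ``step`` is the 1-based dilution index
    (1 = most concentrated), rows run most-dilute-first.
    """
    by_conc_desc = sorted(series.steps, key=lambda s: -s.concentration)
    index_of = {id(s): i + 1 for i, s in enumerate(by_conc_desc)}
    rows = []
    cum = 0.0
    for s in series.measurement_order():
        cum += s.lam
        rows.append(
            {
                "step": index_of[id(s)],
                "conc_zM": s.concentration,
                "dilution_sigma_zM": s.dilution_sigma,
                "poisson_sigma_zM": s.poisson_sigma,
                "total_sigma_zM": s.total_sigma,
                "lam": s.lam,
                "cum_lam": cum,
            }
        )
    return pd.DataFrame(rows)


def round_to_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (reporting convention for m ± s)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig - 1}e}")
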
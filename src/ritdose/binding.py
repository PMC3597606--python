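"""Radioligand binding assay analysis.

Three assay readouts are covered:

* **Cell-binding curves** — bound fraction vs cell number at fixed tracer,
  analyzed by the Lindmo double-inverse extrapolation to infinite antigen
  excess, yielding the immunoreactive fraction r.
* **Homologous competition curves** — bound signal vs unlabeled-competitor
  concentration with the same antibody hot and cold; a one-site model yields
  IC50, and Kd = IC50 − [hot ligand].
* **Internalization time courses** — four-compartment counts (internalized,
  membrane-bound, medium protein-bound, medium free) reduced to fractions of
  total activity per time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "CellBindingCurve",
    "CompetitionCurve",
    "InternalizationTimecourse",
    "BindingFitResult",
    "FitFailure",
    "lindmo_fit",
    "homologous_competition_fit",
    "internalization_fractions",
    "KD_FLOOR_NM",
]

#: Kd is floored here (with a flag) when IC50 does not exceed the hot-ligand
#: concentration, which can happen on noisy curves near the assay resolution.
KD_FLOOR_NM = 1e-6

IC50_BOUNDS_NM = (1e-6, 1e4)

COMPARTMENTS = ("internalized", "membrane_bound", "medium_protein_bound", "medium_non_protein_bound")


class FitFailure(RuntimeError):
    """A binding fit could not produce a physically meaningful estimate."""


@dataclass(frozen=True)
class CellBindingCurve:
    """Bound fraction vs cell number at fixed tracer concentration."""

    cells_per_tube: np.ndarray
    bound_fraction: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells_per_tube", np.asarray(self.cells_per_tube, float))
        object.__setattr__(self, "bound_fraction", np.asarray(self.bound_fraction, float))
        c, b = self.cells_per_tube, self.bound_fraction
        if c.shape != b.shape or c.ndim != 1:
            raise ValueError("cells_per_tube and bound_fraction must be 1-D and aligned")
        if c.size < 3:
            raise ValueError(f"need >= 3 points, got {c.size}")
        if not np.all(c > 0):
            raise ValueError("cells_per_tube must be strictly positive")
        if np.any(b < 0) or np.any(b > 1):
            raise ValueError("bound_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CompetitionCurve:
    """Bound signal vs unlabeled competitor concentration (same antibody)."""

    competitor_conc_nM: np.ndarray
    bound_signal: np.ndarray
    labeled_conc_nM: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "competitor_conc_nM", np.asarray(self.competitor_conc_nM, float))
        object.__setattr__(self, "bound_signal", np.asarray(self.bound_signal, float))
        c, s = self.competitor_conc_nM, self.bound_signal
        if c.shape != s.shape or c.ndim != 1:
            raise ValueError("competitor_conc_nM and bound_signal must be 1-D and aligned")
        if c.size < 5:
            raise ValueError(f"need >= 5 points, got {c.size}")
        if np.any(c < 0) or np.any(s < 0):
            raise ValueError("concentrations and signals must be >= 0")
        if not np.any(c == 0):
            raise ValueError("need at least one zero-competitor point")
        pos = c[c > 0]
        if pos.size == 0 or pos.max() / pos.min() < 100:
            raise ValueError("positive concentrations must span >= 2 orders of magnitude")
        if not self.labeled_conc_nM > 0:
            raise ValueError("labeled_conc_nM must be > 0")


@dataclass(frozen=True)
class InternalizationTimecourse:
    """Four-compartment activity counts over incubation time.

    ``counts`` has shape (n_times, 4) ordered as internalized, membrane-bound,
    medium protein-bound, medium non-protein-bound.
    """

    times_h: np.ndarray
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_h", np.asarray(self.times_h, float))
        object.__setattr__(self, "counts", np.asarray(self.counts, float))
        t, c = self.times_h, self.counts
        if c.ndim != 2 or c.shape != (t.size, 4):
            raise ValueError("counts must have shape (n_times, 4)")
        if np.any(t < 0):
            raise ValueError("times must be >= 0 h")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class BindingFitResult:
    """Fit estimates with diagnostics; exactly one of r / Kd blocks is set."""

    immunoreactive_fraction: Optional[float] = None
    ic50_nM: Optional[float] = None
    kd_nM: Optional[float] = None
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    n_points: int = 0
    flags: tuple = ()

    def to_dict(self) -> dict:
        return {
            "immunoreactive_fraction": self.immunoreactive_fraction,
            "ic50_nM": self.ic50_nM,
            "kd_nM": self.kd_nM,
            "stderr": dict(self.stderr),
            "rss": self.rss,
            "n_points": self.n_points,
            "flags": list(self.flags),
        }


def lindmo_fit(curve: CellBindingCurve, weighted: bool = True) -> BindingFitResult:
    """Immunoreactive fraction by Lindmo double-inverse extrapolation.

    Regresses y = total/bound = 1/r + (K/r)·(1/cells) on x = 1/cells and
    extrapolates to infinite cell (antigen) excess: r = 1/intercept. The
    default weighting ∝ bound² counteracts the variance inflation the
    reciprocal transform causes at low bound fractions; ``weighted=False``
    gives the plain unweighted regression.

    Raises
    ------
    ValueError
        If any bound fraction is non-positive (its reciprocal is undefined).
    FitFailure
        If the fitted intercept is non-positive.
    """
    b = curve.bound_fraction
    if np.any(b <= 0):
        raise ValueError("all bound fractions must be > 0 for the double-inverse transform")
    x = 1.0 / curve.cells_per_tube
    y = 1.0 / b
    w = b**2 if weighted else np.ones_like(b)

    X = np.column_stack([np.ones_like(x), x])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    beta = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ beta
    rss = float(np.sum(w * resid**2))
    dof = max(x.size - 2, 1)
    cov = np.linalg.inv(xtwx) * (rss / dof)
    intercept, slope = float(beta[0]), float(beta[1])
    if intercept <= 0:
        raise FitFailure(
            f"Lindmo intercept {intercept:.4g} <= 0 (slope {slope:.4g}); "
            "curve does not extrapolate to a positive bound plateau"
        )
    r = 1.0 / intercept
    se_intercept = float(np.sqrt(cov[0, 0]))
    se_r = se_intercept / intercept**2  # delta method
    flags = ()
    if r > 1.0:
        flags = ("immunoreactive_fraction_above_1",)
    return BindingFitResult(
        immunoreactive_fraction=r,
        stderr={"immunoreactive_fraction": se_r, "intercept": se_intercept},
        rss=rss,
        n_points=int(x.size),
        flags=flags,
    )


def _one_site(c: np.ndarray, b0: float, ns: float, ic50: float) -> np.ndarray:
    return ns + (b0 - ns) / (1.0 + c / ic50)


def homologous_competition_fit(curve: CompetitionCurve) -> BindingFitResult:
    """One-site homologous competition fit: IC50 and Kd = IC50 − [hot].

    Fits B(c) = NS + (B0 − NS)/(1 + c/IC50) by bounded least squares with
    multiple IC50 starting values, then applies the homologous correction
    (labeled and unlabeled ligand are the same antibody, so the hot-ligand
    concentration shifts the half-inhibition point additively). Both the raw
    IC50 and the corrected Kd are reported.
    """
    c = curve.competitor_conc_nM
    s = curve.bound_signal
    b0_guess = float(s[c == 0].mean())
    ns_guess = float(s.min())

    best = None
    pos = np.sort(c[c > 0])
    starts = np.geomspace(max(pos[0], IC50_BOUNDS_NM[0] * 10), pos[-1], 6)
    for ic50_0 in starts:
        try:
            popt, pcov = curve_fit(
                _one_site,
                c,
                s,
                p0=[max(b0_guess, 1e-6), max(ns_guess, 0.0), ic50_0],
                bounds=([0.0, 0.0, IC50_BOUNDS_NM[0]], [np.inf, np.inf, IC50_BOUNDS_NM[1]]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((s - _one_site(c, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise FitFailure("one-site competition fit did not converge from any start")
    rss, popt, pcov = best
    b0, ns, ic50 = (float(v) for v in popt)
    perr = np.sqrt(np.diag(pcov))

    flags = []
    # plateau coverage: highest competitor should push binding near NS
    if c.max() < 10 * ic50:
        flags.append("upper_plateau_not_covered")
    kd = ic50 - curve.labeled_conc_nM
    if kd <= 0:
        kd = KD_FLOOR_NM
        flags.append("kd_floored_ic50_below_labeled_conc")
    return BindingFitResult(
        ic50_nM=ic50,
        kd_nM=kd,
        stderr={"ic50_nM": float(perr[2]), "b0": float(perr[0]), "ns": float(perr[1])},
        rss=rss,
        n_points=int(c.size),
        flags=tuple(flags),
    )


def internalization_fractions(tc: InternalizationTimecourse) -> np.ndarray:
    """Per-time-point fractions of total activity for the four compartments.

    Returns an array of shape (n_times, 4), each row summing to 1, ordered as
    ``COMPARTMENTS``.
    """
    totals = tc.counts.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(
            f"zero total activity at t = {tc.times_h[zero[0]]:g} h; fractions undefined"
        )
    return tc.counts / totals[:, None]
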
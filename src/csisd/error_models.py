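"""Closed-form mathematics of the chemical-shift error models.

The inferential treatment of shift restraints replaces an empirical restraint
weight with an explicit probability model for the prediction error
Δδ = δ_pred − δ_exp of each nucleus class j, governed by an unknown positive
scale (σ_j for a Gaussian error law, γ_j for a Cauchy law).  The joint
posterior over structure and scales factorises over classes, and its negative
logarithm is a hybrid energy: a data-misfit term per class plus the physical
energy E(X) in units of k_B·T.

Four model families are provided:

``gaussian_jeffreys``
    Gaussian likelihood with the uninformative 1/σ Jeffreys prior.  Energy
    per class: (n_j+1)·ln σ_j + χ²_j/(2σ_j²).
``gaussian_conjugate``
    Gaussian likelihood with an Inverse-Gamma(α, β) prior on σ², the weakly
    informative choice that keeps the scale away from zero.  Energy per
    class: (n_j+2α+2)·ln σ_j + (2β+χ²_j)/(2σ_j²).
``gaussian_marginal``
    Gaussian likelihood with σ integrated out under the Jeffreys prior;
    no scale parameters remain.  Energy per class: (n_j/2)·ln χ²_j.
``cauchy_jeffreys``
    Cauchy likelihood (Student's t with ν=1, heavy-tailed and hence robust
    to outlier predictions) with the same 1/γ prior.  Energy per class:
    (n_j+1)·ln γ_j + Σ_i ln(1 + (Δδ_ij/γ_j)²).

Convention: hybrid-energy operations drop all additive constants (this is
what a Monte Carlo sampler needs); log-likelihood operations keep the full
normalisation so that unit integrals are testable.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Optional, Tuple

import numpy as np

from .shift_data import NUCLEI, DeviationSummary, SummaryOnlyError

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

FAMILIES: Tuple[str, ...] = (
    "gaussian_jeffreys",
    "gaussian_conjugate",
    "gaussian_marginal",
    "cauchy_jeffreys",
)

#: Per-class error scales fitted on the CamShift training set (ppm):
#: RMSD-style maximum-likelihood σ for the Gaussian model ...
TRAINING_SET_SIGMA: Dict[str, float] = {
    "CA": 1.22, "HA": 0.26, "N": 2.78, "H": 0.56, "C": 1.12, "CB": 1.19,
}
#: ... and maximum-likelihood half-widths γ for the Cauchy model.
TRAINING_SET_GAMMA: Dict[str, float] = {
    "CA": 0.70, "HA": 0.19, "N": 1.87, "H": 0.31, "C": 0.74, "CB": 0.77,
}

#: Named fixed-weight presets for ``weights_mode="fixed"``.
FIXED_WEIGHT_PRESETS: Dict[str, Dict[str, float]] = {
    "camshift-trainingset-gaussian": TRAINING_SET_SIGMA,
    "camshift-trainingset-cauchy": TRAINING_SET_GAMMA,
}


class DivergenceError(ValueError):
    """The marginal likelihood integral is undefined (χ² = 0 with n ≥ 1)."""


@dataclass(frozen=True)
class UncertaintyState:
    """The vector of positive per-class scales (σ_j or γ_j, in ppm).

    Energy and likelihood operations require strictly positive scales; a MAP
    estimator may legitimately return a zero scale in the degenerate χ²=0
    Jeffreys case, which is why construction tolerates zero.
    """

    scales: Mapping[str, float]

    def __post_init__(self) -> None:
        for j, s in self.scales.items():
            if j not in NUCLEI:
                raise ValueError(f"unknown nucleus class {j!r}")
            if not math.isfinite(s) or s < 0:
                raise ValueError(f"scale for {j} must be finite and >= 0, got {s}")

    def __getitem__(self, nucleus: str) -> float:
        return self.scales[nucleus]

    def __contains__(self, nucleus: str) -> bool:
        return nucleus in self.scales


#: Contract for the physical-energy term E(X): any callable mapping a
#: structure surrogate to a finite energy in k_B·T units.
PhysicalEnergy = Callable[[object], float]


def zero_physical_energy(structure: object = None) -> float:
    """The default E(X) ≡ 0 (no force field in play)."""
    return 0.0


@dataclass(frozen=True)
class ModelSpec:
    """Which error model and prior to use, and whether scales are sampled.

    ``alpha``/``beta`` are the Inverse-Gamma hyperparameters of the conjugate
    family (default 0.001 each, a near-uninformative choice); ``kBT`` is the
    energy scale in reduced units; with ``weights_mode="fixed"`` the scales in
    ``fixed_scales`` are constants rather than sampled parameters.
    """

    family: str
    alpha: float = 1e-3
    beta: float = 1e-3
    kBT: float = 1.0
    weights_mode: str = "sampled"
    fixed_scales: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "gaussian_conjugate" and (self.alpha <= 0 or self.beta <= 0):
            raise ValueError("alpha and beta must be > 0 for the conjugate prior")
        if self.kBT <= 0:
            raise ValueError("kBT must be > 0")
        if self.weights_mode not in ("fixed", "sampled"):
            raise ValueError(f"unknown weights_mode {self.weights_mode!r}")
        if self.weights_mode == "fixed":
            if self.family == "gaussian_marginal":
                raise ValueError("gaussian_marginal has no scale parameters to fix")
            if self.fixed_scales is None:
                raise ValueError("weights_mode='fixed' requires fixed_scales")
        if self.family == "gaussian_marginal" and self.fixed_scales is not None:
            raise ValueError("gaussian_marginal has no scale parameters")

    @property
    def has_scales(self) -> bool:
        return self.family != "gaussian_marginal"

    @classmethod
    def with_preset(cls, family: str, preset: str, **kwargs) -> "ModelSpec":
        """A fixed-weight ModelSpec using a named packaged preset."""
        return cls(
            family=family,
            weights_mode="fixed",
            fixed_scales=dict(FIXED_WEIGHT_PRESETS[preset]),
            **kwargs,
        )


def _check_scales(dev: DeviationSummary, theta: UncertaintyState) -> None:
    for j in dev.classes_with_data():
        if j not in theta:
            raise ValueError(f"no scale supplied for populated class {j}")
        if theta[j] <= 0:
            raise ValueError(f"scale for class {j} must be > 0, got {theta[j]}")


def _require_deviations(dev: DeviationSummary) -> None:
    if dev.summary_only:
        raise SummaryOnlyError(
            "Cauchy operations need the individual deviations: the Cauchy "
            "likelihood does not reduce to a function of chi-square, so a "
            "summary-only DeviationSummary cannot be used"
        )


# ---------------------------------------------------------------------------
# Gaussian family
# ---------------------------------------------------------------------------

def log_likelihood_gaussian(dev: DeviationSummary, theta: UncertaintyState) -> float:
    """Full Gaussian log-likelihood Σ_j [−n_j·ln(σ_j√2π) − χ²_j/(2σ_j²)].

    Normalisation constants are kept.  Depends on the data only through
    (n_j, χ²_j), so summary-only input is accepted.
    """
    _check_scales(dev, theta)
    total = 0.0
    for j in dev.classes_with_data():
        s = theta[j]
        total += -dev.n(j) * (math.log(s) + _LOG_SQRT_2PI) - dev.chi_square(j) / (2.0 * s * s)
    return total


def neg_log_posterior_gaussian_jeffreys(
    dev: DeviationSummary,
    theta: UncertaintyState,
    e_phys: float = 0.0,
    kBT: float = 1.0,
) -> float:
    """Hybrid energy (in kBT units) of the Gaussian/Jeffreys posterior.

    Σ_j [(n_j+1)·ln σ_j + χ²_j/(2σ_j²)] + E_phys/kBT, constants dropped.
    """
    _check_scales(dev, theta)
    total = 0.0
    for j in dev.classes_with_data():
        s = theta[j]
        total += (dev.n(j) + 1) * math.log(s) + dev.chi_square(j) / (2.0 * s * s)
    return total + e_phys / kBT


def map_sigma_jeffreys(dev: DeviationSummary) -> UncertaintyState:
    """MAP scales under the Jeffreys prior: σ_j² = χ²_j / (n_j + 1).

    Classes with n_j = 0 are omitted.  A class with χ² = 0 yields σ = 0 —
    the degenerate mode this prior is known for — with a warning.
    """
    scales: Dict[str, float] = {}
    for j in dev.classes_with_data():
        chi2 = dev.chi_square(j)
        if chi2 == 0.0:
            warnings.warn(
                f"class {j}: chi-square is zero, Jeffreys MAP sigma degenerates to 0",
                RuntimeWarning,
                stacklevel=2,
            )
        scales[j] = math.sqrt(chi2 / (dev.n(j) + 1))
    return UncertaintyState(scales)


def neg_log_posterior_gaussian_conjugate(
    dev: DeviationSummary,
    theta: UncertaintyState,
    alpha: float = 1e-3,
    beta: float = 1e-3,
    e_phys: float = 0.0,
    kBT: float = 1.0,
) -> float:
    """Hybrid energy of the Gaussian posterior with Inverse-Gamma(α, β) prior.

    Σ_j [(n_j+2α+2)·ln σ_j + (2β+χ²_j)/(2σ_j²)] + E_phys/kBT.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    _check_scales(dev, theta)
    total = 0.0
    for j in dev.classes_with_data():
        s = theta[j]
        total += (dev.n(j) + 2 * alpha + 2) * math.log(s) + (
            2 * beta + dev.chi_square(j)
        ) / (2.0 * s * s)
    return total + e_phys / kBT


def map_sigma_conjugate(
    dev: DeviationSummary, alpha: float = 1e-3, beta: float = 1e-3
) -> UncertaintyState:
    """MAP scales under the conjugate prior: σ_j² = (2β+χ²_j)/(2α+2+n_j).

    Strictly positive even at χ² = 0 whenever β > 0 — the property that makes
    this prior usable where the Jeffreys MAP collapses.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    scales = {
        j: math.sqrt((2 * beta + dev.chi_square(j)) / (2 * alpha + 2 + dev.n(j)))
        for j in dev.classes_with_data()
    }
    return UncertaintyState(scales)


def neg_log_marginal_gaussian(
    dev: DeviationSummary, e_phys: float = 0.0, kBT: float = 1.0
) -> float:
    """Hybrid energy with σ integrated out: Σ_j (n_j/2)·ln χ²_j + E_phys/kBT.

    Raises :class:`DivergenceError` when any populated class has χ² = 0,
    where the marginalisation integral diverges.
    """
    total = 0.0
    for j in dev.classes_with_data():
        chi2 = dev.chi_square(j)
        if chi2 <= 0.0:
            raise DivergenceError(
                f"class {j}: chi-square is zero, the sigma-marginal is undefined"
            )
        total += 0.5 * dev.n(j) * math.log(chi2)
    return total + e_phys / kBT


# ---------------------------------------------------------------------------
# Cauchy family
# ---------------------------------------------------------------------------

def log_likelihood_cauchy(dev: DeviationSummary, theta: UncertaintyState) -> float:
    """Full Cauchy log-likelihood Σ_j [−n_j·ln(πγ_j) − Σ_i ln(1+(Δδ_ij/γ_j)²)]."""
    _require_deviations(dev)
    _check_scales(dev, theta)
    total = 0.0
    for j in dev.classes_with_data():
        g = theta[j]
        d = dev.deviations[j]
        # np.sum is pairwise, keeping accumulation error small at large n
        total += -dev.n(j) * math.log(math.pi * g) - float(np.sum(np.log1p((d / g) ** 2)))
    return total


def neg_log_posterior_cauchy(
    dev: DeviationSummary,
    theta: UncertaintyState,
    e_phys: float = 0.0,
    kBT: float = 1.0,
) -> float:
    """Hybrid energy of the Cauchy/Jeffreys posterior.

    Σ_j [(n_j+1)·ln γ_j + Σ_i ln(1+(Δδ_ij/γ_j)²)] + E_phys/kBT.
    """
    _require_deviations(dev)
    _check_scales(dev, theta)
    total = 0.0
    for j in dev.classes_with_data():
        g = theta[j]
        d = dev.deviations[j]
        total += (dev.n(j) + 1) * math.log(g) + float(np.sum(np.log1p((d / g) ** 2)))
    return total + e_phys / kBT


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def total_hybrid_energy(
    dev: DeviationSummary,
    theta: Optional[UncertaintyState],
    model: ModelSpec,
    e_phys: Optional[PhysicalEnergy] = None,
    structure: object = None,
) -> float:
    """Family-matched hybrid energy in kBT units.

    ``theta`` must be present exactly when the family has scale parameters
    and ``weights_mode`` is ``"sampled"``; with fixed weights the scales come
    from ``model.fixed_scales``.  ``e_phys`` is the pluggable physical-energy
    callable E(X), evaluated on ``structure`` (default: constant zero).
    """
    e_fn = e_phys if e_phys is not None else zero_physical_energy
    e_val = float(e_fn(structure))
    if not math.isfinite(e_val):
        raise ValueError("physical energy must be finite")
    if model.family == "gaussian_marginal":
        if theta is not None:
            raise ValueError("gaussian_marginal takes no UncertaintyState")
        return neg_log_marginal_gaussian(dev, e_phys=e_val, kBT=model.kBT)
    if model.weights_mode == "fixed":
        if theta is not None:
            raise ValueError("theta must be omitted when weights_mode='fixed'")
        theta = UncertaintyState(model.fixed_scales)
    elif theta is None:
        raise ValueError(f"family {model.family} requires an UncertaintyState")
    if model.family == "gaussian_jeffreys":
        return neg_log_posterior_gaussian_jeffreys(dev, theta, e_phys=e_val, kBT=model.kBT)
    if model.family == "gaussian_conjugate":
        return neg_log_posterior_gaussian_conjugate(
            dev, theta, alpha=model.alpha, beta=model.beta, e_phys=e_val, kBT=model.kBT
        )
    return neg_log_posterior_cauchy(dev, theta, e_phys=e_val, kBT=model.kBT)
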
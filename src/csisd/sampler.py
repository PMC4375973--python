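"""Metropolis–Hastings sampling of chemical-shift uncertainty parameters.

The only move in uncertainty space is the multiplicative ξ-move,
ξ' = ξ·exp(z) with z ~ Normal(0, σ_μ²), i.e. a symmetric random walk in
ln ξ.  Because the proposal is multiplicative, detailed balance with
respect to a density written in ξ requires the Hastings factor ξ'/ξ; the
log-correction equals the drawn z and is applied inside the acceptance
test, so the chain's stationary density in ξ is exp(−E(ξ)).

The coordinate ξ is the one whose density the hybrid energy actually is.
For the Jeffreys families the energy is the negative log posterior density
of the scale itself (the 1/σ prior lives in σ-measure), so ξ = σ or γ.
For the conjugate Gaussian family the Inverse-Gamma prior — and therefore
the printed posterior exponent — lives in σ²-measure, so there ξ = σ² and
one ξ-move multiplies the variance by exp(z) (the scale by exp(z/2)).
With that convention the conjugate chain's stationary law is exactly
σ_j² ~ Inverse-Gamma(α+n_j/2, β+χ²_j/2), which the exact sampler
:func:`gibbs_exact_conjugate` reproduces independently and the test suite
compares by a Kolmogorov–Smirnov test; mishandling either the Hastings
factor or the measure makes that test fail, which is what makes it
diagnostic.

Two chain drivers are provided:

:func:`sample_uncertainties_frozen`
    The deviations are fixed ("frozen" structure) and only the scales are
    sampled, one randomly chosen class per step.

:func:`sample_joint_toy`
    The predicted shifts themselves are also sampled by a Gaussian random
    walk — a maximally flexible structure surrogate.  This is the setting in
    which the Gaussian/Jeffreys model exhibits its known pathology: the
    chain ratchets χ² toward zero, dragging σ with it, whereas the conjugate
    and Cauchy models remain stationary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np

from .error_models import ModelSpec, UncertaintyState
from .shift_data import (
    NUCLEI,
    DeviationSummary,
    ShiftRecord,
    ShiftTable,
    SummaryOnlyError,
    compute_deviations,
)

#: σ below which a scale is considered collapsed (ppm).
SIGMA_COLLAPSE_PPM = 0.01
#: χ² below which the misfit is considered collapsed (ppm²).
CHI2_COLLAPSE_PPM2 = 1e-3
#: max |Δ mean ln(scale)| between disjoint halves for "stationary".
LOG_SCALE_DRIFT_MAX = 0.2

_RNG_BLOCK = 1_000_000  # random draws are consumed in fixed-size blocks


class ConfigError(ValueError):
    """Sampler configuration is inconsistent with the requested run."""


@dataclass(frozen=True)
class SamplerConfig:
    """Chain length, proposal width, seeding and averaging conventions.

    ``burn_in_fraction`` 0.9 means statistics are taken over the final 10 %
    of the chain (the convention of averaging the last 10⁶ of 10⁷ steps).
    ``sigma_mu`` = 0.1 gives rapid, stable convergence for both the Gaussian
    and Cauchy families.
    """

    n_steps: int
    seed: int
    sigma_mu: float = 0.1
    burn_in_fraction: float = 0.9
    report_stride: int = 1

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ConfigError("n_steps must be >= 1")
        if self.sigma_mu <= 0:
            raise ConfigError("sigma_mu must be > 0")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ConfigError("burn_in_fraction must lie in [0, 1)")
        if self.report_stride < 1:
            raise ConfigError("report_stride must be >= 1")


@dataclass
class ChainTrace:
    """Recorded scale/energy trajectories plus acceptance bookkeeping."""

    classes: List[str]
    steps: np.ndarray                      # 1-based step index of each record
    scales: Dict[str, np.ndarray]          # per class, one value per record
    energy: np.ndarray                     # total hybrid energy per record
    proposals: Dict[str, int]
    accepts: Dict[str, int]
    config: SamplerConfig
    kind: str = "frozen"
    chi_squares: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        n_rec = self.config.n_steps // self.config.report_stride
        if len(self.steps) != n_rec or len(self.energy) != n_rec:
            raise ValueError("record count inconsistent with n_steps/report_stride")
        for key in self.accepts:
            if self.accepts[key] > self.proposals.get(key, 0):
                raise ValueError(f"accepts exceed proposals for {key}")

    def post_burn_in_mask(self) -> np.ndarray:
        cut = self.config.burn_in_fraction * self.config.n_steps
        mask = self.steps > cut
        if not mask.any():
            raise ConfigError("post-burn-in window contains no recorded samples")
        return mask


def xi_move(xi: float, sigma_mu: float, rng_draw: float) -> float:
    """Multiplicative scale proposal ξ' = ξ·exp(z), z a N(0, σ_μ²) draw.

    ``rng_draw`` is the *standard* normal variate; it is scaled by σ_μ here
    so the proposal's law is explicit at the call site.
    """
    if xi <= 0:
        raise ValueError("xi must be > 0")
    return xi * math.exp(sigma_mu * rng_draw)


def mh_acceptance(
    neg_log_post_current: float,
    neg_log_post_proposed: float,
    hastings_log_correction: float,
    rng_uniform: float,
) -> bool:
    """Metropolis–Hastings test: accept w.p. min(1, exp(ΔE⁻ + correction)).

    ΔE⁻ = current − proposed energy; a proposed energy of +inf is always
    rejected.  For the ξ-move the correction is ln(ξ'/ξ).
    """
    if math.isinf(neg_log_post_proposed) and neg_log_post_proposed > 0:
        return False
    log_ratio = neg_log_post_current - neg_log_post_proposed + hastings_log_correction
    if log_ratio >= 0.0:
        return True
    return math.log(rng_uniform) < log_ratio


# ---------------------------------------------------------------------------
# Frozen-mode sampling
# ---------------------------------------------------------------------------

def _gaussian_coeffs(dev: DeviationSummary, model: ModelSpec, j: str) -> Tuple[float, float]:
    """(A, B) with per-class energy A·ln s + B/s²."""
    n, chi2 = dev.n(j), dev.chi_square(j)
    if model.family == "gaussian_jeffreys":
        return (n + 1.0, 0.5 * chi2)
    return (n + 2.0 * model.alpha + 2.0, model.beta + 0.5 * chi2)


def _cauchy_term(dev: DeviationSummary, j: str):
    n = dev.n(j)
    d = dev.deviations[j]

    def term(g: float) -> float:
        return (n + 1.0) * math.log(g) + float(np.sum(np.log1p((d / g) ** 2)))

    return term


def _validate_sampling_model(dev: DeviationSummary, model: ModelSpec) -> None:
    if not model.has_scales:
        raise ValueError("gaussian_marginal has no scale parameters to sample")
    if model.weights_mode != "sampled":
        raise ValueError("sampling requires weights_mode='sampled'")
    if model.family == "cauchy_jeffreys" and dev.summary_only:
        raise SummaryOnlyError(
            "the Cauchy posterior needs individual deviations; a summary-only "
            "DeviationSummary cannot be sampled under cauchy_jeffreys"
        )


def sample_uncertainties_frozen(
    dev: DeviationSummary,
    model: ModelSpec,
    config: SamplerConfig,
    initial: Optional[Mapping[str, float]] = None,
) -> ChainTrace:
    """Sample the per-class scales with the deviations held fixed.

    Each step picks one populated class uniformly at random and applies one
    ξ-move with Metropolis–Hastings acceptance.  Scales start at 1 ppm unless
    ``initial`` overrides.  Returns the recorded trace; posterior summaries
    over the post-burn-in window come from :func:`posterior_summary`.
    """
    _validate_sampling_model(dev, model)
    classes = dev.classes_with_data()
    if not classes:
        raise ValueError("no populated nucleus class to sample")
    k = len(classes)
    cur = np.array([float((initial or {}).get(j, 1.0)) for j in classes])
    if (cur <= 0).any():
        raise ValueError("initial scales must be > 0")

    gaussian = model.family in ("gaussian_jeffreys", "gaussian_conjugate")
    # ξ is the variance for the conjugate family (see module docstring)
    step_frac = 0.5 if model.family == "gaussian_conjugate" else 1.0
    if gaussian:
        A = np.array([_gaussian_coeffs(dev, model, j)[0] for j in classes])
        B = np.array([_gaussian_coeffs(dev, model, j)[1] for j in classes])
        terms = None
        cur_term = [A[c] * math.log(cur[c]) + B[c] / (cur[c] * cur[c]) for c in range(k)]
    else:
        terms = [_cauchy_term(dev, j) for j in classes]
        cur_term = [terms[c](cur[c]) for c in range(k)]

    n_steps, stride, sig = config.n_steps, config.report_stride, config.sigma_mu
    n_rec = n_steps // stride
    rec_steps = np.empty(n_rec, dtype=np.int64)
    rec_scales = np.empty((n_rec, k))
    rec_energy = np.empty(n_rec)
    proposals = {j: 0 for j in classes}
    accepts = {j: 0 for j in classes}

    rng = np.random.default_rng(config.seed)
    rec = 0
    t = 0
    while t < n_steps:
        block = min(_RNG_BLOCK, n_steps - t)
        # fixed draw order per block: class picks, proposal z's, uniforms
        cls_idx = rng.integers(0, k, block)
        zs = rng.normal(0.0, sig, block)
        us = rng.random(block)
        for b in range(block):
            c = cls_idx[b]
            z = zs[b]
            s_new = cur[c] * math.exp(step_frac * z)
            if gaussian:
                new_term = A[c] * math.log(s_new) + B[c] / (s_new * s_new)
            else:
                new_term = terms[c](s_new)
            # Hastings log-correction for the multiplicative proposal is z
            log_ratio = cur_term[c] - new_term + z
            proposals[classes[c]] += 1
            if log_ratio >= 0.0 or math.log(us[b]) < log_ratio:
                cur[c] = s_new
                cur_term[c] = new_term
                accepts[classes[c]] += 1
            t += 1
            if t % stride == 0:
                rec_steps[rec] = t
                rec_scales[rec] = cur
                rec_energy[rec] = sum(cur_term)
                rec += 1

    trace = ChainTrace(
        classes=classes,
        steps=rec_steps,
        scales={j: rec_scales[:, c].copy() for c, j in enumerate(classes)},
        energy=rec_energy,
        proposals=proposals,
        accepts=accepts,
        config=config,
        kind="frozen",
    )
    trace.post_burn_in_mask()  # fail fast on an empty averaging window
    return trace


def gibbs_exact_conjugate(
    dev: DeviationSummary,
    alpha: float,
    beta: float,
    n_draws: int,
    seed: int,
) -> Dict[str, np.ndarray]:
    """Exact i.i.d. σ draws from the conjugate-Gaussian scale posterior.

    For each populated class, σ² ~ Inverse-Gamma(α + n_j/2, β + χ²_j/2);
    draws are returned on the σ scale (square to recover σ²).  Serves as the
    independent oracle for the ξ-move chain's stationary distribution.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    rng = np.random.default_rng(seed)
    out: Dict[str, np.ndarray] = {}
    for j in dev.classes_with_data():
        shape = alpha + 0.5 * dev.n(j)
        rate = beta + 0.5 * dev.chi_square(j)
        out[j] = np.sqrt(rate / rng.gamma(shape, 1.0, n_draws))
    return out


# ---------------------------------------------------------------------------
# Joint toy sampling (flexible predictions)
# ---------------------------------------------------------------------------

def sample_joint_toy(
    experimental: ShiftTable,
    model: ModelSpec,
    toy_moves: float,
    config: SamplerConfig,
    initial_offset: float = 1.0,
    e_phys=None,
) -> ChainTrace:
    """Jointly sample scales and the predicted shifts themselves.

    The structure surrogate is the predicted-shift vector: it starts at the
    experimental shifts plus Normal(0, ``initial_offset``²) noise, and odd
    steps perturb one predicted shift by Normal(0, ``toy_moves``²) while
    even steps apply a ξ-move to one class's scale.  This is the maximally
    flexible setting in which the Gaussian/Jeffreys model can drive χ² —
    and with it σ — arbitrarily close to zero, freezing the surrogate.

    Records per-class scale and χ² trajectories.
    """
    init_rng = np.random.default_rng([config.seed, 0])
    pred_records = [
        ShiftRecord(
            r.residue_index,
            r.residue_type,
            r.nucleus,
            r.shift + initial_offset * init_rng.standard_normal(),
        )
        for r in experimental
    ]
    predicted = ShiftTable(pred_records, label="toy-predicted")
    dev = compute_deviations(experimental, predicted)
    return _sample_joint_toy_deviations(dev, model, toy_moves, config, e_phys=e_phys)


def _sample_joint_toy_deviations(
    dev: DeviationSummary,
    model: ModelSpec,
    toy_moves: float,
    config: SamplerConfig,
    initial: Optional[Mapping[str, float]] = None,
    e_phys=None,
) -> ChainTrace:
    """Joint toy chain on an explicit initial deviation set (see above).

    ``e_phys``, if given, is a callable mapping the surrogate state (a dict
    of per-class deviation arrays) to an energy in kBT units; it enters the
    acceptance test of every shift move.  Default: constant zero.
    """
    _validate_sampling_model(dev, model)
    if dev.summary_only:
        raise SummaryOnlyError("joint toy sampling needs individual deviations")
    if toy_moves <= 0:
        raise ValueError("toy_moves must be > 0")
    classes = dev.classes_with_data()
    k = len(classes)
    devs = [dev.deviations[j].astype(float).copy() for j in classes]
    ns = [len(d) for d in devs]
    chi2 = [float(np.sum(d * d)) for d in devs]
    cur = [float((initial or {}).get(j, 1.0)) for j in classes]
    fam = model.family
    two_a2 = 2.0 * model.alpha + 2.0
    two_b = 2.0 * model.beta

    def scale_term(c: int, s: float) -> float:
        if fam == "gaussian_jeffreys":
            return (ns[c] + 1.0) * math.log(s) + chi2[c] / (2.0 * s * s)
        if fam == "gaussian_conjugate":
            return (ns[c] + two_a2) * math.log(s) + (two_b + chi2[c]) / (2.0 * s * s)
        return (ns[c] + 1.0) * math.log(s) + float(np.sum(np.log1p((devs[c] / s) ** 2)))

    cur_term = [scale_term(c, cur[c]) for c in range(k)]
    step_frac = 0.5 if fam == "gaussian_conjugate" else 1.0

    n_steps, stride, sig = config.n_steps, config.report_stride, config.sigma_mu
    n_rec = n_steps // stride
    rec_steps = np.empty(n_rec, dtype=np.int64)
    rec_scales = np.empty((n_rec, k))
    rec_chi2 = np.empty((n_rec, k))
    rec_energy = np.empty(n_rec)
    proposals = {f"xi/{j}": 0 for j in classes}
    proposals.update({f"shift/{j}": 0 for j in classes})
    accepts = dict(proposals)

    rng = np.random.default_rng(config.seed)
    rec = 0
    t = 0
    while t < n_steps:
        block = min(_RNG_BLOCK, n_steps - t)
        cls_idx = rng.integers(0, k, block)
        zs = rng.normal(0.0, 1.0, block)  # reused as z (xi) or eps (shift) scale-free
        us = rng.random(block)
        elem_us = rng.random(block)
        for b in range(block):
            c = cls_idx[b]
            if t % 2 == 0:
                # ξ-move on class c's scale (variance for the conjugate family)
                z = sig * zs[b]
                s_new = cur[c] * math.exp(step_frac * z)
                new_term = scale_term(c, s_new)
                log_ratio = cur_term[c] - new_term + z
                proposals[f"xi/{classes[c]}"] += 1
                if log_ratio >= 0.0 or math.log(us[b]) < log_ratio:
                    cur[c] = s_new
                    cur_term[c] = new_term
                    accepts[f"xi/{classes[c]}"] += 1
            else:
                # symmetric random-walk move on one deviation of class c
                i = int(elem_us[b] * ns[c])
                eps = toy_moves * zs[b]
                d_old = devs[c][i]
                d_new = d_old + eps
                s = cur[c]
                if fam == "cauchy_jeffreys":
                    delta = math.log1p((d_new / s) ** 2) - math.log1p((d_old / s) ** 2)
                else:
                    dchi = d_new * d_new - d_old * d_old
                    delta = dchi / (2.0 * s * s)
                data_delta = delta
                if e_phys is not None:
                    e_old = e_phys({j: devs[cc] for cc, j in enumerate(classes)})
                    devs[c][i] = d_new
                    e_new = e_phys({j: devs[cc] for cc, j in enumerate(classes)})
                    devs[c][i] = d_old
                    delta += e_new - e_old
                proposals[f"shift/{classes[c]}"] += 1
                if delta <= 0.0 or math.log(us[b]) < -delta:
                    devs[c][i] = d_new
                    chi2[c] += d_new * d_new - d_old * d_old
                    cur_term[c] += data_delta
                    accepts[f"shift/{classes[c]}"] += 1
            t += 1
            if t % stride == 0:
                rec_steps[rec] = t
                for cc in range(k):
                    rec_scales[rec, cc] = cur[cc]
                    rec_chi2[rec, cc] = chi2[cc]
                rec_energy[rec] = sum(cur_term)
                rec += 1

    trace = ChainTrace(
        classes=classes,
        steps=rec_steps,
        scales={j: rec_scales[:, c].copy() for c, j in enumerate(classes)},
        energy=rec_energy,
        proposals=proposals,
        accepts=accepts,
        config=config,
        kind="joint_toy",
        chi_squares={j: rec_chi2[:, c].copy() for c, j in enumerate(classes)},
    )
    trace.post_burn_in_mask()
    return trace


# ---------------------------------------------------------------------------
# Summaries, diagnostics and trace I/O
# ---------------------------------------------------------------------------

def posterior_summary(
    trace: ChainTrace, n_batches: int = 50
) -> Dict[str, Dict[str, float]]:
    """Mean, s.d. and batch-means s.e. of each scale over the averaging window.

    The s.e. uses batch means (default 50 batches), which remains honest
    under the chain's autocorrelation.
    """
    mask = trace.post_burn_in_mask()
    out: Dict[str, Dict[str, float]] = {}
    for j in trace.classes:
        x = trace.scales[j][mask]
        n = x.size
        mean = float(x.mean())
        sd = float(x.std(ddof=1)) if n > 1 else 0.0
        nb = min(n_batches, n)
        batches = np.array_split(x, nb)
        bm = np.array([b.mean() for b in batches])
        se = float(bm.std(ddof=1) / math.sqrt(nb)) if nb > 1 else 0.0
        out[j] = {"mean": mean, "sd": sd, "se": se, "n": float(n)}
    return out


@dataclass(frozen=True)
class PathologyReport:
    """Per-class collapse/stationarity verdicts from a joint toy trace."""

    collapsed: Dict[str, bool]
    stationary: Dict[str, bool]
    min_sigma: Dict[str, float]
    min_chi2: Dict[str, float]
    log_scale_drift: Dict[str, float]

    @property
    def any_collapsed(self) -> bool:
        return any(self.collapsed.values())

    @property
    def all_stationary(self) -> bool:
        return all(self.stationary.values())


def assess_pathology(
    trace: ChainTrace,
    sigma_threshold: float = SIGMA_COLLAPSE_PPM,
    chi2_threshold: float = CHI2_COLLAPSE_PPM2,
    drift_threshold: float = LOG_SCALE_DRIFT_MAX,
) -> PathologyReport:
    """Diagnose scale collapse vs stationarity for a joint toy chain.

    A class has *collapsed* when its recorded σ falls below
    ``sigma_threshold`` and its χ² below ``chi2_threshold`` anywhere in the
    trace.  A class is *stationary* when the mean of ln(scale) over the two
    halves of the post-burn-in window differs by less than
    ``drift_threshold``.
    """
    if trace.chi_squares is None:
        raise ValueError("pathology assessment needs a joint toy trace with chi-squares")
    mask = trace.post_burn_in_mask()
    collapsed, stationary, min_sig, min_chi, drift = {}, {}, {}, {}, {}
    for j in trace.classes:
        s = trace.scales[j]
        c2 = trace.chi_squares[j]
        min_sig[j] = float(s.min())
        min_chi[j] = float(c2.min())
        collapsed[j] = min_sig[j] < sigma_threshold and min_chi[j] < chi2_threshold
        ln_s = np.log(s[mask])
        half = ln_s.size // 2
        d = abs(float(ln_s[:half].mean()) - float(ln_s[half:].mean()))
        drift[j] = d
        stationary[j] = d < drift_threshold
    return PathologyReport(collapsed, stationary, min_sig, min_chi, drift)


def write_trace(trace: ChainTrace, path: Union[str, Path]) -> None:
    """Write a trace as ``step<TAB>class<TAB>scale_ppm<TAB>energy_kBT``.

    A ``<path>.meta`` sidecar records the configuration and acceptance rates
    as key-value lines.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("step\tclass\tscale_ppm\tenergy_kBT\n")
        for r in range(len(trace.steps)):
            for j in trace.classes:
                fh.write(
                    f"{trace.steps[r]}\t{j}\t{trace.scales[j][r]!r}\t{trace.energy[r]!r}\n"
                )
    cfg = trace.config
    with Path(str(path) + ".meta").open("w", encoding="utf-8") as fh:
        fh.write(f"kind\t{trace.kind}\n")
        fh.write(f"n_steps\t{cfg.n_steps}\n")
        fh.write(f"seed\t{cfg.seed}\n")
        fh.write(f"sigma_mu\t{cfg.sigma_mu}\n")
        fh.write(f"burn_in_fraction\t{cfg.burn_in_fraction}\n")
        fh.write(f"report_stride\t{cfg.report_stride}\n")
        for key in sorted(trace.proposals):
            prop = trace.proposals[key]
            acc = trace.accepts.get(key, 0)
            rate = acc / prop if prop else float("nan")
            fh.write(f"acceptance/{key}\t{acc}/{prop}\t{rate:.4f}\n")
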
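"""Pure-state mixture decomposition of contact-decay curves.

Chromosomes behave as mixtures of regions folded in the three stable phases
of the strings-and-binders polymer (coil, disordered globule, ordered
globule). The average contact probability P(s) of such a mixture is a convex
combination of the P(s) of the pure states, so the observed decay can be
decomposed by constrained least squares into the fractions of each state.

Pure-state curves are obtained by simulating a homopolymer in each regime
(no binding; strong binding at moderate binder concentration; strong binding
at high concentration), verified by phase classification, and cached to disk
keyed by the simulation parameters.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, nnls
from sklearn.base import BaseEstimator

from .contacts import ContactCurve
from .observables import classify_phase, contact_curve, contact_map_from_ensemble

__all__ = [
    "PureStateCurves",
    "MixtureFitResult",
    "PURE_REGIMES",
    "estimate_pure_curves",
    "fit_mixture",
    "PureStateMixture",
]

STATE_NAMES = ("coil", "disordered_globule", "ordered_globule")

# Capture radius used for P(s) decay analyses. Calibrated so that the coil
# regime reproduces the established self-avoiding-walk contact-decay
# exponent (~ -2.1) in the accessible separation range; see docs/methods.md.
DECAY_CONTACT_THRESHOLD = 2.5


@dataclass(frozen=True)
class PureStateCurves:
    """The three pure-state P(s) curves on a common separation grid."""

    coil: ContactCurve
    disordered_globule: ContactCurve
    ordered_globule: ContactCurve
    n_beads: int
    provenance: dict

    def as_matrix(self) -> np.ndarray:
        """(n_separations, 3) matrix of the three curves."""
        return np.column_stack(
            [self.coil.probabilities, self.disordered_globule.probabilities, self.ordered_globule.probabilities]
        )

    @property
    def separations(self) -> np.ndarray:
        return self.coil.separations

    def interp_at(self, fractions_of_chain: np.ndarray) -> np.ndarray:
        """(len(q), 3) pure-state values at fractional separations s/N, by
        log-log interpolation."""
        s = np.asarray(fractions_of_chain) * self.n_beads
        s = np.clip(s, self.separations.min(), self.separations.max())
        return np.column_stack(
            [c.interp_log(s) for c in (self.coil, self.disordered_globule, self.ordered_globule)]
        )


@dataclass(frozen=True)
class MixtureFitResult:
    f_coil: float
    f_disordered: float
    f_ordered: float
    scale: float
    chi_squared: float
    residuals: ContactCurve

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.f_coil, self.f_disordered, self.f_ordered])

    def __post_init__(self) -> None:
        f = np.array([self.f_coil, self.f_disordered, self.f_ordered])
        if f.min() < -1e-12 or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("state fractions must be non-negative and sum to 1")


def estimate_pure_curves(
    n_beads: int = 64,
    seeds: list[int] | None = None,
    cache_dir: str | None = None,
    contact_threshold: float = DECAY_CONTACT_THRESHOLD,
    check_phases: bool = True,
    tau_total: float | None = None,
) -> PureStateCurves:
    """Simulate the three pure regimes and return their P(s) curves.

    Each regime is simulated as a homopolymer ensemble (one replica per
    seed) under the reference protocol of :mod:`sbskit.phases`, its phase
    verified against the intended label, and the pooled equilibrium contact
    map reduced to P(s). Results are cached on disk keyed by all
    parameters; ``cache_dir=None`` defaults to ``~/.cache/sbskit``, an empty
    string disables caching.
    """
    from .phases import run_phase_corner

    if seeds is None:
        seeds = [11, 12, 13, 14]

    if cache_dir is None:
        cache_dir = os.path.join(os.path.expanduser("~"), ".cache", "sbskit")
    key = repr((n_beads, tuple(seeds), contact_threshold, tau_total, "phase-protocols-v1"))
    digest = hashlib.sha1(key.encode()).hexdigest()[:16]
    cache_path = os.path.join(cache_dir, f"pure_curves_{digest}.npz") if cache_dir else None
    if cache_path and os.path.exists(cache_path):
        z = np.load(cache_path)
        curves = {name: ContactCurve(z["s"], z[name], label=name) for name in STATE_NAMES}
        return PureStateCurves(
            curves["coil"],
            curves["disordered_globule"],
            curves["ordered_globule"],
            n_beads,
            {"cache": cache_path},
        )

    curves = {}
    for name in STATE_NAMES:
        trajs = []
        for s in seeds:
            traj, binders = run_phase_corner(name, n_beads, seed=int(s), tau_total=tau_total)
            trajs.append(traj)
        if check_phases:
            phase = classify_phase(trajs[0], binders)
            if phase.label != name:
                raise RuntimeError(
                    f"pure-state regime {name!r} classified as {phase.label!r} "
                    f"(nu={phase.nu_estimate:.3f}, q6={phase.binder_order_parameter:.3f}); "
                    "adjust regime parameters or run longer"
                )
        cmap = contact_map_from_ensemble(trajs, threshold=contact_threshold)
        curves[name] = ContactCurve(
            contact_curve(cmap).separations, contact_curve(cmap).probabilities, label=name
        )

    if cache_path:
        os.makedirs(cache_dir, exist_ok=True)
        np.savez(
            cache_path,
            s=curves["coil"].separations,
            **{name: curves[name].probabilities for name in STATE_NAMES},
        )
    return PureStateCurves(
        curves["coil"],
        curves["disordered_globule"],
        curves["ordered_globule"],
        n_beads,
        {"seeds": list(seeds), "protocols": "sbskit.phases.PHASE_PROTOCOLS"},
    )


class PureStateMixture(BaseEstimator):
    """Decompose an observed P(s) into pure-state fractions.

    Non-negative weights with an overall free positive scale (raw Hi-C
    decays are count-valued, not probability-valued) are fitted by least
    squares on log P: Hi-C-like noise is multiplicative, so log residuals
    are the homoskedastic ones, and the decomposition is far better
    conditioned there than in linear space. A weighted non-negative linear
    least-squares solution seeds the optimisation. Separations are compared
    as fractions of chain length, with log-log interpolation of the pure
    curves, and residuals are weighted by 1/s so every decade of genomic
    separation contributes equally. Recovered weights are normalized to
    fractions on the simplex.

    Attributes (after ``fit``)
    --------------------------
    fractions_ : ndarray (3,) -- coil, disordered, ordered; sums to 1.
    scale_ : float -- fitted overall amplitude.
    chi_squared_ : float -- sum of (obs - model)^2 / model over the fit range.
    result_ : MixtureFitResult
    """

    def __init__(self, pure: PureStateCurves = None, s_min: float = 2.0, s_max: float | None = None):
        self.pure = pure
        self.s_min = s_min
        self.s_max = s_max

    def fit(self, X: ContactCurve, y=None):
        if self.pure is None:
            raise ValueError("PureStateMixture needs pure-state curves (pure=...)")
        obs = X
        n_obs = float(obs.separations.max() + 1)
        s_max = self.s_max if self.s_max is not None else n_obs / 2.0
        sel = (obs.separations >= self.s_min) & (obs.separations <= s_max) & (obs.probabilities > 0)
        if sel.sum() < 4:
            raise ValueError(f"only {int(sel.sum())} usable separations in fit range; need >= 4")
        s = obs.separations[sel]
        y_obs = obs.probabilities[sel]
        basis = self.pure.interp_at(s / n_obs)  # (m, 3)
        ok = (basis > 0).all(axis=1)
        s, y_obs, basis = s[ok], y_obs[ok], basis[ok]
        if len(s) < 4:
            raise ValueError("fewer than 4 separations where all pure curves are positive")
        w = 1.0 / s  # uniform weight per log-s interval

        coeffs0, _ = nnls(basis * w[:, None], y_obs * w)
        coeffs0 = np.maximum(coeffs0, 1e-8 * max(coeffs0.max(), 1e-30))
        log_y = np.log(y_obs)

        def _objective(log_c):
            return float(np.sum(w * (np.log(basis @ np.exp(log_c)) - log_y) ** 2))

        res = minimize(
            _objective,
            np.log(coeffs0),
            method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-14, maxiter=5000),
        )
        coeffs = np.exp(res.x)
        total = coeffs.sum()
        if not np.isfinite(total) or total <= 0:
            raise RuntimeError("degenerate mixture fit: non-positive total weight")
        fractions = coeffs / total
        model = basis @ coeffs
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = float(np.sum((y_obs - model) ** 2 / np.where(model > 0, model, np.nan)))
        residuals = ContactCurve(s, y_obs - model, label="residual")
        self.fractions_ = fractions
        self.scale_ = float(total)
        self.chi_squared_ = chi2
        self.result_ = MixtureFitResult(
            float(fractions[0]), float(fractions[1]), float(fractions[2]), float(total), chi2, residuals
        )
        return self


def fit_mixture(
    observed: ContactCurve,
    pure: PureStateCurves,
    fit_range: tuple[float, float] | None = None,
) -> MixtureFitResult:
    """Functional wrapper around :class:`PureStateMixture`."""
    if fit_range is None:
        est = PureStateMixture(pure=pure)
    else:
        est = PureStateMixture(pure=pure, s_min=fit_range[0], s_max=fit_range[1])
    est.fit(observed)
    return est.result_
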
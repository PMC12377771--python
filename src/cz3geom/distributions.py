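"""Gamma ("k-gamma") distribution fitting and distributional summaries.

Compartment areas and aspect ratios in packed cellular materials follow
gamma distributions

    p(x; k, lam) = lam**k * x**(k-1) * exp(-lam * x) / Gamma(k),

whose shape parameter k acts as an order parameter: at fixed mean, large k
means a narrow, nearly Gaussian (crystalline) distribution while small k
means a broad, disordered one.  Fitting k per spheroid therefore tracks how
ordered the compartment mesh is through the life cycle.

The maximum-likelihood estimate solves  log(k) - psi(k) = log(mean) -
mean(log x)  by Newton iteration on the digamma equation, started from the
moment-matched value k0 = mean^2 / var.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "GammaFit",
    "standardize",
    "fit_gamma_mle",
    "histogram_profile",
    "hemisphere_fits",
    "moment_summaries",
]

_STANDARDIZE_MODES = ("none", "mean_scale", "offset_min", "offset_then_scale")


class DegenerateSampleError(ValueError):
    """Sample has zero variance or too few values to fit."""


@dataclass(frozen=True)
class GammaFit:
    """Maximum-likelihood gamma fit of a standardized sample.

    ``k`` is the unitless shape, ``lam`` the rate in inverse units of the
    standardized variable.  ``k_moment`` is the moment-matched initial value
    (kept for comparison), ``mode`` records how the sample was standardized.
    """

    k: float
    lam: float
    log_likelihood: float
    n: int
    mode: str
    converged: bool
    k_moment: float
    iterations: int


def standardize(
    values: Sequence[float], mode: str = "mean_scale", x0: float = 0.0
) -> tuple[np.ndarray, dict]:
    """Map raw metric values onto the positive support of the gamma family.

    Modes: ``none`` (identity), ``mean_scale`` (x / <x>), ``offset_min``
    (x - x0, e.g. alpha - 1 for aspect ratios whose minimum is 1) and
    ``offset_then_scale`` (offset then divide by the post-offset mean).
    Returns the transformed array and a transform record with enough
    information to invert the mapping.
    """
    if mode not in _STANDARDIZE_MODES:
        raise ValueError(f"unknown standardization mode {mode!r}")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if mode == "none":
        out, rec = x.copy(), {"mode": mode}
    elif mode == "mean_scale":
        mu = float(np.mean(x))
        if mu <= 0:
            raise ValueError("mean_scale requires a positive mean")
        out, rec = x / mu, {"mode": mode, "scale": mu}
    elif mode == "offset_min":
        out, rec = x - x0, {"mode": mode, "offset": x0}
    else:  # offset_then_scale
        shifted = x - x0
        mu = float(np.mean(shifted))
        if mu <= 0:
            raise ValueError("offset_then_scale requires positive post-offset mean")
        out, rec = shifted / mu, {"mode": mode, "offset": x0, "scale": mu}
    bad = int(np.sum(out <= 0))
    if bad:
        raise ValueError(
            f"{bad} standardized value(s) non-positive under mode {mode!r}"
        )
    return out, rec


def fit_gamma_mle(
    values: Sequence[float], *, tol: float = 1e-10, max_iter: int = 100
) -> GammaFit:
    """Maximum-likelihood gamma fit by Newton iteration on the shape.

    Deterministic given the sample: the score equation
    ``log k - psi(k) = log(mean) - mean(log x)`` is solved from the
    moment-matched start ``k0 = mean^2/var``; the rate is ``lam = k/mean``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError(f"need >= 10 values, got {x.size}")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("values must be positive and finite")
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    if var <= 0:
        raise DegenerateSampleError("degenerate sample: zero variance")

    s = math.log(mean) - float(np.mean(np.log(x)))
    k = mean * mean / var  # moment-matched start
    k0 = k
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f = math.log(k) - special.digamma(k) - s
        if abs(f) < tol:
            converged = True
            break
        fp = 1.0 / k - special.polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:  # damped bisection toward zero
            k_new = k / 2.0
        k = k_new
    else:
        f = math.log(k) - special.digamma(k) - s
        converged = abs(f) < tol
    if not converged:
        raise RuntimeError(
            f"gamma MLE did not converge in {max_iter} iterations "
            f"(k={k:.6g}, score={f:.3e})"
        )
    lam = k / mean
    ll = float(np.sum(stats.gamma.logpdf(x, a=k, scale=1.0 / lam)))
    return GammaFit(
        k=float(k), lam=float(lam), log_likelihood=ll, n=int(x.size),
        mode="raw", converged=converged, k_moment=float(k0), iterations=it,
    )


def histogram_profile(values: Sequence[float], n_bins: int = 100) -> dict:
    """Equal-width histogram over [min, max] plus the empirical mean.

    Mirrors the per-stage metric histograms with a vertical mean marker.
    A constant sample collapses to a single-bin histogram with a flag.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return {
            "edges": np.array([lo, hi]),
            "counts": np.array([x.size]),
            "mean": lo,
            "degenerate": True,
        }
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    return {
        "edges": edges,
        "counts": counts,
        "mean": float(np.mean(x)),
        "degenerate": False,
    }


def hemisphere_fits(
    pa_coords,
    values=None,
    *,
    metric: str = "a_cz3",
    mode: str = "mean_scale",
    x0: float = 0.0,
    min_n: int = 10,
) -> dict:
    """Separate gamma fits for the posterior and anterior hemispheres.

    Compartments with normalized posterior->anterior coordinate < 0.5 form
    the posterior sample, the rest the anterior one; each is standardized
    and fitted independently.  A hemisphere with fewer than ``min_n``
    compartments is reported as None.

    Accepts either explicit ``(pa_coords, values)`` arrays or a
    ``SpheroidRecord`` (with ``metric`` naming the FeatureRecord field).
    """
    from .spheroid import SpheroidRecord, pa_coordinate

    if isinstance(pa_coords, SpheroidRecord):
        rec = pa_coords
        feats = [f for f in rec.features if "boundary" not in f.flags]
        values = [getattr(f, metric) for f in feats]
        pa_coords = pa_coordinate(rec, np.array([f.x_cz3 for f in feats]))
    u = np.asarray(pa_coords, dtype=float)
    x = np.asarray(values, dtype=float)
    if u.shape != x.shape:
        raise ValueError("pa_coords and values must align")
    out: dict[str, Optional[GammaFit]] = {}
    for name, sel in (("posterior", u < 0.5), ("anterior", u >= 0.5)):
        sub = x[sel & np.isfinite(x)]
        if sub.size < min_n:
            out[name] = None
            continue
        std, _ = standardize(sub, mode=mode, x0=x0)
        out[name] = fit_gamma_mle(std)
    return out


def moment_summaries(values: Sequence[float]) -> dict:
    """Sample mean, SD and (bias-corrected) skewness."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 values")
    sd = float(np.std(x, ddof=1))
    out = {
        "mean": float(np.mean(x)),
        "sd": sd,
        "skewness": None,
        "skewness_bias_corrected": True,
        "n": int(x.size),
    }
    if sd > 0:
        out["skewness"] = float(stats.skew(x, bias=False))
    return out
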
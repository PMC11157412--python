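"""Laser-power dose-response fitting and fiber-optic geometry.

Per-trial laser powers are normalized to the animal's maximum and binned at
5 % width; the binned response (locomotor speed or angular velocity) is fit
with a four-parameter logistic

    y = bottom + (top - bottom) / (1 + exp(-(x - x0) / k))

with multi-start least squares.  The fit correlation R = sqrt(1 - SSres /
SStot) and its F-test significance follow the convention of common
nonlinear-regression packages, and a pointwise 95 % confidence band comes
from the parameter covariance (delta method).

The optics half of the module evaluates the light cone exiting an implanted
multimode fiber into brain tissue (full divergence 2*arcsin(NA/n)) and a
geometric-spread-plus-scattering irradiance attenuation model with depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponse", "OpticsParams", "normalize_and_bin", "fit_sigmoid",
    "logistic4", "cone_angle", "irradiance_profile",
]


def logistic4(x, bottom, top, x0, k):
    """Four-parameter logistic (sigmoid) response curve."""
    return bottom + (top - bottom) / (1.0 + np.exp(-(np.asarray(x, dtype=float) - x0) / k))


@dataclass
class DoseResponse:
    """Binned power-response data and, once fitted, the sigmoid fit."""
    power_pct: np.ndarray          # per-trial normalized power (% of max)
    response: np.ndarray
    bin_pct: float
    bin_edges: np.ndarray          # right-closed bins over (0, 100]
    bin_centers: np.ndarray        # populated bins only
    bin_mean: np.ndarray
    bin_sem: np.ndarray
    bin_n: np.ndarray
    # fit results
    converged: bool | None = None
    params: dict | None = None     # bottom, top, x0, k
    covariance: np.ndarray | None = None
    r: float | None = None
    p_value: float | None = None
    ci_band: tuple | None = None   # (x_grid, lower, upper)
    diagnostics: dict = field(default_factory=dict)


@dataclass
class OpticsParams:
    """Implanted-fiber optics: numerical aperture, core radius, tissue
    refractive index, and tissue scattering coefficient (mouse brain at
    ~473 nm)."""
    na: float = 0.22
    core_radius_mm: float = 0.1
    n_tissue: float = 1.36
    scatter_per_mm: float = 11.2

    def __post_init__(self):
        if not (0 <= self.na < self.n_tissue):
            raise ValueError("need 0 <= NA < n_tissue")
        if not self.core_radius_mm > 0:
            raise ValueError("core_radius_mm must be positive")
        if self.scatter_per_mm < 0:
            raise ValueError("scatter_per_mm must be non-negative")


# ---------------------------------------------------------------------------

def normalize_and_bin(power_values, responses, bin_pct: float = 5.0) -> DoseResponse:
    """Normalize powers to % of their maximum and bin the responses.

    Bins are right-closed intervals of width ``bin_pct`` partitioning
    (0, 100]; per-bin mean and SEM of the response are reported for the
    populated bins.  Normalization is idempotent: values already in % of a
    100 maximum are unchanged.
    """
    power = np.asarray(power_values, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if power.size == 0:
        raise ValueError("need at least one trial")
    if power.shape != resp.shape:
        raise ValueError("power and response lengths differ")
    pmax = power.max()
    if pmax <= 0:
        raise ValueError("all powers are zero; cannot normalize")
    pct = 100.0 * power / pmax
    n_bins = int(np.ceil(100.0 / bin_pct))
    edges = np.linspace(0.0, n_bins * bin_pct, n_bins + 1)
    # right-closed: value v falls in (edges[i], edges[i+1]]
    idx = np.clip(np.ceil(pct / bin_pct).astype(int) - 1, 0, n_bins - 1)
    centers, means, sems, ns = [], [], [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        vals = resp[sel]
        centers.append((edges[b] + edges[b + 1]) / 2.0)
        means.append(vals.mean())
        ns.append(int(sel.sum()))
        sems.append(vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1
                    else np.nan)
    return DoseResponse(power_pct=pct, response=resp, bin_pct=bin_pct,
                        bin_edges=edges, bin_centers=np.array(centers),
                        bin_mean=np.array(means), bin_sem=np.array(sems),
                        bin_n=np.array(ns))


N_SIGMOID_PARAMS = 4


def fit_sigmoid(dose: DoseResponse, ci_points: int = 101) -> DoseResponse:
    """Fit the binned dose-response with a four-parameter logistic.

    Initialization is multi-start: x0 seeded at each quartile of the binned
    x values, best final sum of squares wins.  R = sqrt(1 - SSres/SStot);
    p from the regression F statistic; the 95 % confidence band is the
    pointwise delta-method band from the parameter covariance.  R is
    invariant under affine rescaling of y.  Non-convergence from every start
    returns a result flagged ``converged=False`` with diagnostics rather
    than raising.
    """
    x, y = dose.bin_centers, dose.bin_mean
    n = len(x)
    if n < N_SIGMOID_PARAMS:
        raise ValueError(f"need >= {N_SIGMOID_PARAMS} populated bins to fit "
                         f"a {N_SIGMOID_PARAMS}-parameter sigmoid (have {n})")
    span = max(x.max() - x.min(), 1.0)
    best = None
    errors = []
    for q in (0.25, 0.5, 0.75):
        x0_init = np.quantile(x, q)
        p0 = (y.min(), y.max(), x0_init, span / 10.0)
        try:
            popt, pcov = optimize.curve_fit(logistic4, x, y, p0=p0,
                                            maxfev=20000)
        except (RuntimeError, optimize.OptimizeWarning) as exc:
            errors.append(str(exc))
            continue
        sse = float(np.sum((y - logistic4(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        dose.converged = False
        dose.diagnostics = {"errors": errors}
        return dose
    sse, popt, pcov = best
    sst = float(np.sum((y - y.mean()) ** 2))
    dose.converged = True
    dose.params = dict(zip(("bottom", "top", "x0", "k"), map(float, popt)))
    dose.covariance = pcov
    dose.r = float(np.sqrt(max(0.0, 1.0 - sse / sst))) if sst > 0 else np.nan
    dof = n - N_SIGMOID_PARAMS
    if dof > 0 and sse > 0:
        f = ((sst - sse) / (N_SIGMOID_PARAMS - 1)) / (sse / dof)
        dose.p_value = float(stats.f.sf(f, N_SIGMOID_PARAMS - 1, dof))
    else:
        dose.p_value = 0.0 if sse == 0 else np.nan

    grid = np.linspace(x.min(), x.max(), ci_points)
    if np.all(np.isfinite(pcov)) and dof > 0:
        jac = _logistic4_jacobian(grid, *popt)
        var = np.einsum("ij,jk,ik->i", jac, pcov, jac)
        halfwidth = stats.t.ppf(0.975, dof) * np.sqrt(np.maximum(var, 0.0))
        yhat = logistic4(grid, *popt)
        dose.ci_band = (grid, yhat - halfwidth, yhat + halfwidth)
    dose.diagnostics = {"sse": sse, "sst": sst, "n_bins": n}
    return dose


def _logistic4_jacobian(x, bottom, top, x0, k):
    z = (np.asarray(x, dtype=float) - x0) / k
    sig = 1.0 / (1.0 + np.exp(-z))
    dsig = sig * (1.0 - sig)
    return np.stack([1.0 - sig,
                     sig,
                     -(top - bottom) * dsig / k,
                     -(top - bottom) * dsig * z / k], axis=-1)


# ---------------------------------------------------------------------------
# Fiber optics
# ---------------------------------------------------------------------------

def cone_angle(optics: OpticsParams | None = None, na: float | None = None,
               n_tissue: float | None = None) -> float:
    """Full divergence angle (deg) of the light cone in tissue.

    The emission half-angle in a medium of index n is arcsin(NA / n), so the
    full cone angle is 2*arcsin(NA / n).  Monotone increasing in NA,
    decreasing in n.
    """
    if optics is None:
        optics = OpticsParams()
    na = optics.na if na is None else na
    n_tissue = optics.n_tissue if n_tissue is None else n_tissue
    if na >= n_tissue:
        raise ValueError("NA must be smaller than the tissue index")
    return float(np.degrees(2.0 * np.arcsin(na / n_tissue)))


def irradiance_profile(optics: OpticsParams | None = None,
                       depths_mm=np.linspace(0.0, 2.0, 41)):
    """Transmitted irradiance fraction vs depth under geometric spread plus
    scattering.

    With the conical-spread length scale rho = r * sqrt((n/NA)^2 - 1), the
    transmitted fraction at depth z is

        T(z) = rho^2 / ((S*z + 1) * (z + rho)^2),

    normalized so T(0) = 1; the fraction lost is 1 - T(z).  T is strictly
    decreasing in z and lies in (0, 1].  Returns ``(depths, transmitted,
    lost)``.
    """
    if optics is None:
        optics = OpticsParams()
    z = np.asarray(depths_mm, dtype=float)
    if np.any(z < 0):
        raise ValueError("depths must be non-negative")
    rho = optics.core_radius_mm * np.sqrt(
        (optics.n_tissue / optics.na) ** 2 - 1.0)
    transmitted = rho ** 2 / ((optics.scatter_per_mm * z + 1.0)
                              * (z + rho) ** 2)
    lost = 1.0 - transmitted
    return z, transmitted, lost
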
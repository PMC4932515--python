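"""SAXS scoring: Debye profiles, the reduced chi discrepancy, ensemble targets.

The discrepancy between a model curve :math:`I_m(q)` and target data
:math:`I_t(q)` with per-point errors :math:`\\sigma(q)` over K points is

.. math::

    \\chi = \\sqrt{\\frac{1}{K} \\sum_q
        \\left[\\frac{\\mu I_m(q) - I_t(q)}{\\sigma(q)}\\right]^2 }

with the scale factor :math:`\\mu` fitted in closed form unless fixed.
Theoretical curves come from an in-vacuo Debye double sum over scattering
centers; hydration-shell and excluded-volume corrections are deliberately
not modeled (see docs/methods.md), so absolute chi values are not
comparable with CRYSOL's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structmodel import Conformation

logger = logging.getLogger(__name__)

__all__ = [
    "ScatteringProfile",
    "FormFactorModel",
    "debye_profile",
    "optimal_scale",
    "chi",
    "ensemble_average_profile",
    "read_saxs_dat",
    "write_saxs_dat",
    "interpolate_profile",
]

#: Relative floor applied to sigma: values below SIGMA_FLOOR * max(I) are
#: clamped so simulated targets with vanishing spread stay usable in chi.
SIGMA_FLOOR = 1e-6

#: chi normalization constant: 1/K (reduced form). Set to K-1 semantics by
#: passing ddof=1 to chi() if a (K-1) convention is ever needed.
CHI_DDOF = 0

# electrons per neutral atom, for the optional all-atom weighting mode
_ELECTRONS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "SE": 34, "FE": 26,
    "ZN": 30, "MG": 12, "CA": 20, "MN": 25, "NA": 11, "K": 19, "CL": 17,
}


@dataclass
class ScatteringProfile:
    """A 1-D scattering curve on a strictly increasing q grid (Å⁻¹)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    n_curves: int | None = None  # ensemble size when built by averaging

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.intensity.shape != self.q.shape:
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if len(self.q) == 0:
            raise ValueError("empty profile")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.q[0] < 0:
            raise ValueError("q must be non-negative")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensities")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length differs from q")
            if np.any(self.sigma < 0):
                raise ValueError("negative sigma")

    @property
    def K(self) -> int:
        return len(self.q)

    def truncated(self, q_max: float) -> "ScatteringProfile":
        """Restrict to q <= q_max (the usable low-angle fitting range)."""
        mask = self.q <= q_max
        if not mask.any():
            raise ValueError(f"no points with q <= {q_max}")
        return ScatteringProfile(
            self.q[mask],
            self.intensity[mask],
            None if self.sigma is None else self.sigma[mask],
            self.n_curves,
        )


@dataclass(frozen=True)
class FormFactorModel:
    """Maps atoms to scattering weights.

    ``mode="ca_bead"`` places one unit-weight dummy bead per Cα (the default
    coarse representation, adequate for low-q shape fitting);
    ``mode="element"`` uses every atom with a constant per-element electron
    count.  Weights are q-independent in both modes.
    """

    mode: str = "ca_bead"

    def weights(self, conf: Conformation) -> tuple[np.ndarray, np.ndarray]:
        """Return (coords, weights) of the scattering centers."""
        if self.mode == "ca_bead":
            mask = np.array([a.name == "CA" for a in conf.atoms])
            if not mask.any():
                raise ValueError("no CA atoms for ca_bead form-factor mode")
            return conf.coords[mask], np.ones(int(mask.sum()))
        if self.mode == "element":
            w = np.array(
                [_ELECTRONS.get(a.element.upper(), 6.0) for a in conf.atoms],
                dtype=float,
            )
            return conf.coords, w
        raise ValueError(f"unknown form-factor mode {self.mode!r}")


def debye_profile(
    conf: Conformation,
    q: np.ndarray,
    ff: FormFactorModel | None = None,
) -> ScatteringProfile:
    """Rotationally averaged intensity by the Debye double sum.

    I(q) = sum_ij f_i f_j sin(q r_ij) / (q r_ij), with sinc -> 1 at q = 0
    and on the diagonal.  O(n^2) in scattering centers per q point and fully
    deterministic.
    """
    from scipy.spatial.distance import pdist

    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("negative q")
    ff = ff or FormFactorModel()
    coords, w = ff.weights(conf)
    if len(coords) == 0:
        raise ValueError("no scattering centers")
    # diagonal (i == j) terms
    intensity = np.full(len(q), float(np.sum(w**2)))
    if len(coords) > 1:
        d = pdist(coords)
        iu = np.triu_indices(len(coords), k=1)
        wprod = w[iu[0]] * w[iu[1]]
        # np.sinc(x) = sin(pi x)/(pi x); handles q*d == 0 analytically
        sinc = np.sinc(np.outer(q, d) / np.pi)
        intensity = intensity + 2.0 * sinc @ wprod
    return ScatteringProfile(q, intensity)


def _common_grid_check(model: ScatteringProfile, target: ScatteringProfile) -> None:
    if model.K != target.K or not np.allclose(model.q, target.q, rtol=0, atol=1e-12):
        raise ValueError(
            "model and target are on different q grids; interpolate first"
        )


def _usable_sigma(target: ScatteringProfile) -> np.ndarray:
    if target.sigma is None:
        raise ValueError("target profile has no sigma; chi is undefined")
    floor = SIGMA_FLOOR * float(np.max(np.abs(target.intensity)))
    if floor == 0.0:
        floor = SIGMA_FLOOR
    sigma = target.sigma.copy()
    low = sigma < floor
    if low.any():
        logger.warning("flooring %d sigma values below %.3g", int(low.sum()), floor)
        sigma[low] = floor
    return sigma


def optimal_scale(model: ScatteringProfile, target: ScatteringProfile) -> float:
    """Closed-form scale factor minimizing the chi residual.

    mu = [sum I_t I_m / sigma^2] / [sum I_m^2 / sigma^2].
    """
    _common_grid_check(model, target)
    sigma = _usable_sigma(target)
    w = 1.0 / sigma**2
    denom = float(np.sum(w * model.intensity**2))
    if denom == 0.0:
        raise ValueError("model intensity is identically zero")
    return float(np.sum(w * target.intensity * model.intensity) / denom)


def chi(
    model: ScatteringProfile,
    target: ScatteringProfile,
    mu: float | None = None,
) -> float:
    """Reduced discrepancy between a model curve and target SAXS data.

    ``mu`` defaults to the closed-form optimal scale.  chi >= 0, and
    chi == 0 iff the scaled model reproduces the target exactly.
    """
    _common_grid_check(model, target)
    sigma = _usable_sigma(target)
    if mu is None:
        mu = optimal_scale(model, target)
    resid = (mu * model.intensity - target.intensity) / sigma
    return float(np.sqrt(np.sum(resid**2) / (model.K - CHI_DDOF)))


def ensemble_average_profile(
    profiles: list[ScatteringProfile], ddof: int = 1
) -> ScatteringProfile:
    """Average L curves into a simulated target: per-q mean and sample SD.

    The per-q standard deviation of the ensemble becomes the target's
    sigma(q); ``ddof=1`` (sample SD) by default.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles (sigma undefined otherwise)")
    q0 = profiles[0].q
    for p in profiles[1:]:
        if p.K != len(q0) or not np.allclose(p.q, q0, rtol=0, atol=1e-12):
            raise ValueError("profiles are on inconsistent q grids")
    stack = np.array([p.intensity for p in profiles])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=ddof)
    if np.any(sd < SIGMA_FLOOR * max(float(np.max(np.abs(mean))), 1e-300)):
        logger.warning("ensemble sigma is ~0 at some q; it will be floored in chi")
    return ScatteringProfile(q0, mean, sd, n_curves=len(profiles))


def read_saxs_dat(path, q_unit: str = "A^-1") -> ScatteringProfile:
    """Read a whitespace-delimited SAXS text file (q, I[, sigma]).

    Lines starting with ``#`` and non-numeric header/footer lines are
    skipped.  ``q_unit="nm^-1"`` converts the q column to Å⁻¹ on input.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                values = [float(x) for x in parts]
            except ValueError:
                continue  # header or footer text
            if len(values) < 2:
                raise ValueError(f"{path}: need at least 2 columns, got {line!r}")
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    data = np.array([r[:ncol] for r in rows])
    q = data[:, 0]
    if q_unit == "nm^-1":
        q = q / 10.0
    elif q_unit != "A^-1":
        raise ValueError(f"unknown q unit {q_unit!r}")
    sigma = data[:, 2] if ncol >= 3 else None
    return ScatteringProfile(q, data[:, 1], sigma)


def write_saxs_dat(profile: ScatteringProfile, path) -> None:
    """Write a profile as 3-column (or 2-column) text at fixed precision."""
    with open(path, "w") as fh:
        fh.write("# q(A^-1) I(q)" + (" sigma\n" if profile.sigma is not None else "\n"))
        for i in range(profile.K):
            row = f"{profile.q[i]:.6e} {profile.intensity[i]:.6e}"
            if profile.sigma is not None:
                row += f" {profile.sigma[i]:.6e}"
            fh.write(row + "\n")


def interpolate_profile(
    profile: ScatteringProfile, q_new: np.ndarray
) -> ScatteringProfile:
    """Linear interpolation of I (and sigma) onto a new grid; no extrapolation."""
    q_new = np.asarray(q_new, dtype=float)
    if q_new.min() < profile.q[0] - 1e-12 or q_new.max() > profile.q[-1] + 1e-12:
        raise ValueError(
            f"q_new range [{q_new.min():g}, {q_new.max():g}] outside profile "
            f"range [{profile.q[0]:g}, {profile.q[-1]:g}]"
        )
    intensity = np.interp(q_new, profile.q, profile.intensity)
    sigma = (
        None
        if profile.sigma is None
        else np.interp(q_new, profile.q, profile.sigma)
    )
    return ScatteringProfile(q_new, intensity, sigma, profile.n_curves)
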
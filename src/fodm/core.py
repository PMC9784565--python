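"""The fuzzy-oil-drop model and its membrane-modified extension.

The model compares three per-residue hydrophobicity distributions over a
protein chain, each normalized to sum to 1:

* **T** (theoretical): a 3D Gaussian fitted to the molecule's shape,
  evaluated at each residue's effective atom — the idealized micelle with a
  hydrophobic core (maximal at the centre, near zero at the surface).
* **O** (observed): the hydrophobicity each residue actually collects from
  pairwise contacts with its neighbours, aggregated with Levitt's smooth
  cutoff function.
* **R** (reference): uniform, 1/N per residue — no differentiation at all.

Agreement is measured with Kullback–Leibler divergence (base 2), and
summarized by the relative distance

    RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R)),

with RD < 0.5 indicating a micelle-like hydrophobic core. For proteins in a
non-polar environment (a membrane), the expected distribution is instead the
blend

    M ∝ T + K·(T_MAX − T),

which interpolates from the Gaussian drop (K = 0) through uniform (K = 1)
toward the inverted drop (hydrophobicity exposed at the surface) as K grows.
The environment-modulation parameter K is fitted by minimizing D_KL(O|M(K))
over a grid; water-soluble proteins sit near K = 0, membrane proteins above
K ≈ 0.9.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ComputationError, InputError
from .structure_io import EffectiveAtomCloud, ResId

__all__ = [
    "GaussianEnvelope",
    "HydroProfile",
    "FodStatus",
    "FodConfig",
    "ChainResult",
    "orient",
    "fit_gaussian_envelope",
    "theoretical_profile",
    "levitt_weight",
    "observed_profile",
    "uniform_profile",
    "modified_profile",
    "kl_divergence",
    "rd",
    "fit_k",
    "chain_status",
]

logger = logging.getLogger(__name__)

#: Floor applied to interaction-derived (O) and blended (M) profile values
#: when they appear in the denominator of a divergence, to avoid log(0) on
#: degenerate synthetic inputs. T is analytically strictly positive.
EPS_FLOOR = 1e-12

#: Normalization tolerance for profiles.
NORM_TOL = 1e-9


@dataclass(frozen=True)
class GaussianEnvelope:
    """Axis-aligned 3D Gaussian fitted to an oriented molecule.

    ``center`` and ``rotation`` record the frame that maps original
    coordinates into the oriented frame (rows of ``rotation`` are the
    principal axes); ``sigma`` holds (σx, σy, σz) in Å.
    """

    center: np.ndarray
    rotation: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, float))
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ComputationError("envelope rotation is not orthonormal")
        if not np.all(self.sigma > 0) or not np.all(np.isfinite(self.sigma)):
            raise ComputationError("envelope sigmas must be positive and finite")


@dataclass
class HydroProfile:
    """A normalized per-residue hydrophobicity distribution."""

    kind: str  # one of "T", "O", "R", "M"
    values: np.ndarray
    index: tuple[ResId, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.index = tuple(self.index)
        if self.values.shape != (len(self.index),):
            raise InputError("profile values and index length differ")
        if np.any(self.values < 0):
            raise ComputationError(f"{self.kind} profile has negative values")
        if abs(self.values.sum() - 1.0) > NORM_TOL:
            raise ComputationError(
                f"{self.kind} profile does not sum to 1 (sum={self.values.sum()!r})"
            )

    def __len__(self) -> int:
        return len(self.index)


@dataclass(frozen=True)
class FodStatus:
    """RD / K / divergence summary for a chain, fragment or residue set."""

    rd: float
    k: float
    dkl_ot: float
    dkl_or: float
    dkl_om_at_k: float
    n_residues: int


@dataclass(frozen=True)
class FodConfig:
    """Model parameterization.

    cutoff
        Levitt interaction cutoff c in Å (no contact beyond it).
    pad
        Extra margin added on each side of the molecule's extent before the
        ±3σ envelope rule is applied.
    k_grid
        (k_min, k_max, step) for the K scan; step 0.1 matches the precision
        K is conventionally reported at.
    interaction
        "symmetric": pair term (H_i + H_j); "self": neighbour term H_i only.
    """

    cutoff: float = 9.0
    pad: float = 0.0
    k_grid: tuple[float, float, float] = (0.0, 10.0, 0.1)
    interaction: str = "symmetric"


@dataclass
class ChainResult:
    """Everything chain_status computes: the summary plus all profiles."""

    status: FodStatus
    t: HydroProfile
    o: HydroProfile
    r: HydroProfile
    m: HydroProfile
    envelope: GaussianEnvelope
    k_curve: "np.ndarray"  # (n_grid, 2): K value, D_KL(O|M(K))


def orient(cloud: EffectiveAtomCloud) -> tuple[EffectiveAtomCloud, np.ndarray, np.ndarray]:
    """Move the cloud into its canonical frame.

    Returns the oriented cloud plus (center, rotation): effective atoms are
    translated so their centroid is the origin and rotated onto the principal
    axes of their covariance, largest variance along x. Axis signs are fixed
    deterministically from the data: an axis is flipped if the third moment
    of the projections onto it is negative (falling back to a positive
    largest-magnitude eigenvector component for sign-symmetric clouds), and
    the third axis is the cross product of the first two so the rotation is
    proper. The sign rule depends only on the point set, so the oriented
    output is identical for any rigidly moved copy of the input and T is
    well-defined regardless of the input frame.
    """
    pos = cloud.positions
    center = pos.mean(axis=0)
    centered = pos - center
    cov = centered.T @ centered / len(cloud)
    if np.allclose(cov, 0.0, atol=1e-12):
        raise ComputationError("cannot orient: all effective atoms coincide")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T  # rows = principal axes, x = largest variance
    for i in range(2):
        proj = centered @ axes[i]
        skew = np.sum(proj**3)
        if abs(skew) > 1e-9 * max(np.sum(proj**2), 1.0) ** 1.5:
            flip = skew < 0
        else:  # sign-symmetric projections: fall back to component rule
            flip = axes[i, int(np.argmax(np.abs(axes[i])))] < 0
        if flip:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    oriented = centered @ axes.T
    return cloud.replace_positions(oriented), center, axes


def fit_gaussian_envelope(
    oriented: EffectiveAtomCloud,
    pad: float = 0.0,
    center: np.ndarray | None = None,
    rotation: np.ndarray | None = None,
) -> GaussianEnvelope:
    """Size the Gaussian drop: σ = (extent + 2·pad) / 6 per axis, so the
    molecule (plus padding) spans ±3σ. Sigmas are floored at 1e-3 Å."""
    pos = oriented.positions
    extent = pos.max(axis=0) - pos.min(axis=0)
    sigma = np.maximum((extent + 2.0 * pad) / 6.0, 1e-3)
    return GaussianEnvelope(
        center=np.zeros(3) if center is None else center,
        rotation=np.eye(3) if rotation is None else rotation,
        sigma=sigma,
    )


def theoretical_profile(
    oriented: EffectiveAtomCloud, envelope: GaussianEnvelope
) -> HydroProfile:
    """Evaluate the 3D Gaussian at each effective atom and normalize."""
    pos = oriented.positions
    # log-space for numerical safety with far-flung points
    log_t = -0.5 * np.sum((pos / envelope.sigma) ** 2, axis=1)
    t = np.exp(log_t - log_t.max())
    return HydroProfile("T", t / t.sum(), tuple(oriented.res_ids))


def levitt_weight(r: float | np.ndarray, c: float) -> float | np.ndarray:
    """Levitt's smooth contact function: 1 at r = 0, 0 at r ≥ c.

    For r ≤ c:  1 − ½(7x² − 9x⁴ + 5x⁶ − x⁸) with x = r/c.
    """
    if c <= 0:
        raise InputError(f"cutoff must be positive, got {c}")
    x = np.asarray(r, dtype=float) / c
    w = 1.0 - 0.5 * (7 * x**2 - 9 * x**4 + 5 * x**6 - x**8)
    w = np.where(x <= 1.0, w, 0.0)
    if np.ndim(r) == 0:
        return float(w)
    return w


def observed_profile(
    cloud: EffectiveAtomCloud, cutoff: float = 9.0, interaction: str = "symmetric"
) -> HydroProfile:
    """Hydrophobicity each residue collects from its neighbourhood.

    The raw value is Õ_j = Σ_i (H_i + H_j)·w(r_ij, c) over all residues
    including i = j (the self term has weight 1 and contributes 2·H_j), then
    normalized. Distances are Euclidean between effective atoms, so O is
    invariant under rigid motion. ``interaction="self"`` uses the
    neighbour-only form Σ_i H_i·w(r_ij, c) instead.
    """
    dist = cdist(cloud.positions, cloud.positions)
    w = levitt_weight(dist, cutoff)
    h = cloud.h
    if interaction == "symmetric":
        raw = w @ h + h * w.sum(axis=1)
    elif interaction == "self":
        raw = w @ h
    else:
        raise InputError(f"unknown interaction form {interaction!r}")
    total = raw.sum()
    if total <= 0:
        raise ComputationError("degenerate observed distribution (all zero)")
    return HydroProfile("O", raw / total, tuple(cloud.res_ids))


def uniform_profile(n: int, index: tuple[ResId, ...] | None = None) -> HydroProfile:
    """The reference distribution: 1/n everywhere."""
    if n < 1:
        raise InputError(f"uniform profile needs n >= 1, got {n}")
    if index is None:
        index = tuple(("R", i + 1, "") for i in range(n))
    vals = np.full(n, 1.0 / n)
    # compensate the tail element so the sum is exactly 1 in float arithmetic
    vals[-1] = 1.0 - vals[:-1].sum()
    return HydroProfile("R", vals, index)


def modified_profile(
    t: HydroProfile, k: float, t_max: float | None = None
) -> HydroProfile:
    """Membrane-modified expectation M ∝ T + K·(T_MAX − T), normalized.

    ``t_max`` defaults to the maximum of the profile in hand (fragment-local
    when applied to a restricted profile); pass a global maximum to override.
    """
    if k < 0:
        raise InputError(f"K must be non-negative, got {k}")
    tmax = float(t.values.max()) if t_max is None else float(t_max)
    # exact algebraic identities, kept free of renormalization round-off
    if k == 0.0:
        return HydroProfile("M", t.values.copy(), t.index)
    if k == 1.0 and t_max is None:
        n = len(t)
        vals = np.full(n, 1.0 / n)
        vals[-1] = 1.0 - vals[:-1].sum()
        return HydroProfile("M", vals, t.index)
    raw = t.values + k * (tmax - t.values)
    total = raw.sum()
    if total <= 0:
        raise ComputationError("degenerate modified distribution")
    return HydroProfile("M", raw / total, t.index)


def kl_divergence(
    p: HydroProfile | np.ndarray,
    q: HydroProfile | np.ndarray,
    q_floor: float = 0.0,
) -> float:
    """Kullback–Leibler divergence Σ p_i log2(p_i/q_i) in bits.

    Terms with p_i = 0 contribute 0. ``q_floor`` > 0 floors the denominator
    (used for interaction-derived profiles that can carry exact zeros on
    synthetic inputs); floor events are logged.
    """
    pv = p.values if isinstance(p, HydroProfile) else np.asarray(p, float)
    qv = q.values if isinstance(q, HydroProfile) else np.asarray(q, float)
    if pv.shape != qv.shape:
        raise InputError(f"profile length mismatch: {pv.shape} vs {qv.shape}")
    if q_floor > 0:
        n_floored = int(np.sum(qv < q_floor))
        if n_floored:
            logger.info("kl_divergence: floored %d q values at %g", n_floored, q_floor)
        qv = np.maximum(qv, q_floor)
    mask = pv > 0
    if np.any(qv[mask] <= 0):
        raise ComputationError("q has zero mass where p is positive")
    return float(np.sum(pv[mask] * np.log2(pv[mask] / qv[mask])))


def rd(o: HydroProfile, t: HydroProfile, r: HydroProfile) -> float:
    """Relative distance RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R)) in [0, 1]."""
    d_ot = kl_divergence(o, t)
    d_or = kl_divergence(o, r)
    denom = d_ot + d_or
    if denom == 0.0:
        warnings.warn("RD undefined (O = T = R); returning 0", stacklevel=2)
        return 0.0
    return d_ot / denom


def k_grid_points(grid: tuple[float, float, float]) -> np.ndarray:
    k_min, k_max, step = grid
    n = int(round((k_max - k_min) / step)) + 1
    if n < 1 or step <= 0:
        raise InputError(f"empty or invalid K grid {grid}")
    # round to the grid's decimal precision so reported K values are clean
    return np.round(k_min + step * np.arange(n), 10)


def fit_k(
    o: HydroProfile,
    t: HydroProfile,
    grid: tuple[float, float, float] = (0.0, 10.0, 0.1),
    t_max: float | None = None,
) -> tuple[float, np.ndarray]:
    """Scan the K grid for the blend M(T, K) closest to O in D_KL.

    Returns (K*, curve) where curve is an (n, 2) array of (K, D_KL(O|M(K))).
    Ties break toward smaller K (the least environmental modification).
    """
    ks = k_grid_points(grid)
    curve = np.empty((len(ks), 2))
    for i, k in enumerate(ks):
        m = modified_profile(t, float(k), t_max=t_max)
        curve[i] = (k, kl_divergence(o, m, q_floor=EPS_FLOOR))
    best = int(np.argmin(curve[:, 1]))  # argmin takes the first = smallest K
    return float(curve[best, 0]), curve


def chain_status(cloud: EffectiveAtomCloud, config: FodConfig = FodConfig()) -> ChainResult:
    """Run the whole pipeline on one chain.

    Orients the cloud, fits the Gaussian envelope, builds T, O and R,
    computes RD, and fits K; returns the summary together with all four
    profiles (M at the fitted K) for reporting.
    """
    oriented, center, rotation = orient(cloud)
    envelope = fit_gaussian_envelope(oriented, pad=config.pad,
                                     center=center, rotation=rotation)
    t = theoretical_profile(oriented, envelope)
    o = observed_profile(oriented, cutoff=config.cutoff,
                         interaction=config.interaction)
    r = uniform_profile(len(cloud), t.index)
    rd_val = rd(o, t, r)
    k_star, curve = fit_k(o, t, grid=config.k_grid)
    m = modified_profile(t, k_star)
    status = FodStatus(
        rd=rd_val,
        k=k_star,
        dkl_ot=kl_divergence(o, t),
        dkl_or=kl_divergence(o, r),
        dkl_om_at_k=float(curve[np.argmin(curve[:, 1]), 1]),
        n_residues=len(cloud),
    )
    return ChainResult(status, t, o, r, m, envelope, curve)
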
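"""Synthetic inputs with known ground truth.

Three generators cover the regimes the model distinguishes, so the whole
pipeline is testable without any structure download:

* a micelle-like droplet — hydrophobicity falling from centre to surface, so
  the observed profile tracks the Gaussian expectation (RD < 0.5, K small);
* an inverted, membrane-like droplet — hydrophobicity rising toward the
  surface, optionally with a central cavity mimicking a transport channel
  (RD > 0.5, K large);
* an observed profile manufactured from a given T at a known K, for
  parameter-recovery checks.

Synthetic residues carry their hydrophobicity directly (residue names are
"UNK"), exercising the pipeline below the scale-lookup layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HydroProfile, modified_profile
from .errors import InputError
from .structure_io import EffectiveAtomCloud

__all__ = [
    "SyntheticSpec",
    "make_gaussian_micelle",
    "make_inverted_micelle",
    "make_profile_with_k",
    "toy_fixture",
]

#: Default generator geometry: anisotropic sigmas (Å) giving a globular
#: droplet of roughly protein-like extent for n ≈ 200 residues.
DEFAULT_SIGMAS = (14.0, 11.0, 8.0)

#: Default central cavity radius (Å) for the inverted (channel-like) mode.
DEFAULT_CAVITY = 6.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cloud; ``k_true`` is required exactly for
    the known-K mode."""

    n_residues: int = 200
    mode: str = "micelle"  # micelle | inverted | known_k
    k_true: float | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise InputError("synthetic clouds need n_residues >= 10")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if (self.mode == "known_k") != (self.k_true is not None):
            raise InputError("k_true is required iff mode == 'known_k'")


def _cloud_from(positions: np.ndarray, h: np.ndarray) -> EffectiveAtomCloud:
    n = len(h)
    ids = [("S", i + 1, "") for i in range(n)]
    return EffectiveAtomCloud(ids, ["UNK"] * n, positions, h)


def _rank_map(radii: np.ndarray, increasing: bool) -> np.ndarray:
    # map radius ranks onto [0, 1]; ties broken by index (stable argsort)
    n = len(radii)
    order = np.argsort(radii, kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(n)
    frac = ranks / (n - 1)
    return frac if increasing else 1.0 - frac


def _positions(rng, n, sigmas, cavity_radius=0.0):
    sig = np.asarray(sigmas, float)
    pos = rng.normal(scale=sig, size=(n, 3))
    if cavity_radius > 0:
        # excluded volume: push interior points radially out to the cavity
        # shell, keeping the draw paired with the cavity-free cloud
        r = np.linalg.norm(pos, axis=1)
        inside = r < cavity_radius
        pos[inside] *= (cavity_radius / r[inside])[:, None]
    return pos


def _apply_noise(rng, h, noise_sd):
    if noise_sd > 0:
        h = np.clip(h + rng.normal(scale=noise_sd, size=h.shape), 0.0, 1.0)
    return h


def make_gaussian_micelle(
    spec: SyntheticSpec, sigmas: tuple[float, float, float] = DEFAULT_SIGMAS
) -> EffectiveAtomCloud:
    """Micelle-like droplet: positions from an anisotropic 3D Gaussian,
    hydrophobicity decreasing with (Mahalanobis) distance from the centre so
    the observed distribution follows the theoretical one."""
    if spec.mode != "micelle":
        raise InputError(f"spec mode is {spec.mode!r}, expected 'micelle'")
    rng = np.random.default_rng(spec.seed)
    pos = _positions(rng, spec.n_residues, sigmas)
    radii = np.linalg.norm(pos / np.asarray(sigmas), axis=1)
    h = _apply_noise(rng, _rank_map(radii, increasing=False), spec.noise_sd)
    return _cloud_from(pos, h)


def make_inverted_micelle(
    spec: SyntheticSpec,
    sigmas: tuple[float, float, float] = DEFAULT_SIGMAS,
    cavity_radius: float = DEFAULT_CAVITY,
) -> EffectiveAtomCloud:
    """Membrane-like droplet: hydrophobicity increasing toward the surface,
    with an optional empty central cavity (no residues within
    ``cavity_radius``) mimicking the free space of a transport channel."""
    if spec.mode != "inverted":
        raise InputError(f"spec mode is {spec.mode!r}, expected 'inverted'")
    rng = np.random.default_rng(spec.seed)
    pos = _positions(rng, spec.n_residues, sigmas, cavity_radius=cavity_radius)
    radii = np.linalg.norm(pos / np.asarray(sigmas), axis=1)
    h = _apply_noise(rng, _rank_map(radii, increasing=True), spec.noise_sd)
    return _cloud_from(pos, h)


def make_profile_with_k(
    t: HydroProfile, k_true: float, noise_sd: float = 0.0, seed: int = 0
) -> HydroProfile:
    """An 'observed' profile manufactured from T at a known K:
    O = normalize(max(0, M(T, k_true) + Gaussian noise))."""
    if k_true < 0:
        raise InputError("k_true must be >= 0")
    m = modified_profile(t, k_true)
    vals = m.values.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = np.maximum(vals + rng.normal(scale=noise_sd, size=vals.shape), 0.0)
    total = vals.sum()
    if total <= 0:
        raise InputError("noise destroyed the profile (all zero)")
    return HydroProfile("O", vals / total, t.index)


#: Fixed 10-residue cloud used by the hand-audited oracle tests:
#: anisotropic spread, varied hydrophobicities, nothing symmetric.
_TOY_POSITIONS = np.array([
    [-12.0,  3.0, -1.0],
    [ -8.5, -4.0,  2.5],
    [ -5.0,  1.5, -3.0],
    [ -2.0, -1.0,  1.0],
    [  0.5,  2.0,  0.0],
    [  2.5, -2.5, -1.5],
    [  5.0,  0.5,  2.0],
    [  7.5,  3.5, -2.0],
    [ 10.0, -1.5,  1.5],
    [ 13.0,  1.0, -0.5],
])
_TOY_H = np.array([0.10, 0.35, 0.80, 0.95, 1.00, 0.90, 0.70, 0.40, 0.20, 0.05])


def toy_fixture() -> EffectiveAtomCloud:
    """A fixed, hard-coded 10-residue cloud for oracle comparisons; every
    call returns an identical object."""
    return _cloud_from(_TOY_POSITIONS.copy(), _TOY_H.copy())
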
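"""Paired-phase chest phantom generator with closed-form expected indices.

The phantom is two ellipsoidal "lungs" of Gaussian parenchymal density
embedded in uniform soft tissue. Expiration is modelled by shrinking the
lung geometry isotropically to a target expiratory/inspiratory volume
ratio and by shifting the density of non-trapped parenchyma upward by a
fixed amount (the lung densifies as air leaves); a blob-clustered fraction
of voxels keeps its inspiratory density (air trapping, mosaic pattern).

Because the indices under study never require voxel registration, no
deformation model is used: the expiratory lattice is a geometric subset of
the inspiratory one, and each expiratory voxel reuses the inspiratory
density draw at the same position, plus the expiratory shift for
non-trapped voxels and fresh acquisition noise. With zero noise and no
trapping this makes the expiratory value at a matched voxel exactly the
inspiratory value plus the shift.

Every expected index has a closed form (two-component Gaussian mixture),
so a generated phantom doubles as a ground-truth oracle for the
densitometry pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import norm

from .densitometry import (
    HAA_THRESHOLDS_HU,
    LAA_THRESHOLDS_HU,
    DensitometryResult,
    DensityVolume,
    LungMask,
    Phase,
)

__all__ = ["PhantomSpec", "generate_phantom", "analytic_expectations"]


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of a single top-level seed."""
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode()),))
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a paired-phase chest phantom.

    Attributes
    ----------
    grid_shape, voxel_spacing
        Lattice size (voxels) and voxel edge lengths (mm); first axis is
        subject left-right.
    left_center, left_semiaxes, right_center, right_semiaxes
        Inspiratory lung ellipsoids in voxel coordinates; must lie strictly
        inside the grid and must not overlap.
    expiratory_volume_ratio
        Target expiratory/inspiratory lung volume ratio in (0, 1]; the
        expiratory semi-axes are the inspiratory ones scaled by its cube
        root.
    mu_ins, sigma_parenchyma
        Mean and SD of inspiratory parenchymal density (HU) at the
        reference age.
    delta_exp
        Expiratory density increase (HU, >= 0) for non-trapped parenchyma.
    trapped_fraction, n_trapped_blobs
        Fraction of parenchymal voxels that keep their inspiratory density
        on expiration, clustered around ``n_trapped_blobs`` random seed
        points (mosaic attenuation).
    noise_sigma
        SD of additive acquisition noise (HU), drawn independently per
        phase.
    body_hu
        Uniform soft-tissue background density.
    age_years, hu_per_year, reference_age_years
        Age drives the effective inspiratory mean linearly:
        ``mu = mu_ins + hu_per_year * (age_years - reference_age_years)``.
        Default slope -15 HU/year reflects parenchymal density decrease
        with lung growth in children.
    seed
        Top-level seed; geometry, density and noise use named substreams.
    """

    grid_shape: Tuple[int, int, int] = (48, 48, 60)
    voxel_spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    left_center: Tuple[float, float, float] = (14.0, 24.0, 30.0)
    left_semiaxes: Tuple[float, float, float] = (9.0, 13.0, 20.0)
    right_center: Tuple[float, float, float] = (34.0, 24.0, 30.0)
    right_semiaxes: Tuple[float, float, float] = (9.0, 13.0, 20.0)
    expiratory_volume_ratio: float = 0.6
    mu_ins: float = -880.0
    sigma_parenchyma: float = 30.0
    delta_exp: float = 130.0
    trapped_fraction: float = 0.0
    n_trapped_blobs: int = 8
    noise_sigma: float = 5.0
    body_hu: float = 40.0
    age_years: float = 10.0
    hu_per_year: float = -15.0
    reference_age_years: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.trapped_fraction <= 1.0):
            raise ValueError("trapped_fraction must lie in [0, 1]")
        if not (0.0 < self.expiratory_volume_ratio <= 1.0):
            raise ValueError("expiratory_volume_ratio must lie in (0, 1]")
        if self.sigma_parenchyma <= 0:
            raise ValueError("sigma_parenchyma must be positive")
        if self.delta_exp < 0:
            raise ValueError("delta_exp must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_trapped_blobs < 1:
            raise ValueError("n_trapped_blobs must be a positive integer")
        if any(n < 2 for n in self.grid_shape) or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("grid_shape must be >= 2 per axis with positive spacing")
        if self.mu_effective + self.delta_exp >= self.body_hu:
            raise ValueError("lung density plus expiratory shift must stay below body_hu")
        for name, c, a in [
            ("left", self.left_center, self.left_semiaxes),
            ("right", self.right_center, self.right_semiaxes),
        ]:
            if any(ai <= 0 for ai in a):
                raise ValueError(f"{name} semi-axes must be positive")
            for ci, ai, ni in zip(c, a, self.grid_shape):
                if ci - ai < 0.5 or ci + ai > ni - 1.5:
                    raise ValueError(
                        f"{name} lung ellipsoid extends outside the grid "
                        f"(center {c}, semi-axes {a}, shape {self.grid_shape})"
                    )
        # non-overlap along the left-right axis (ellipsoids share y/z extent)
        gap = (self.right_center[0] - self.right_semiaxes[0]) - (
            self.left_center[0] + self.left_semiaxes[0]
        )
        if gap <= 0:
            raise ValueError("lung ellipsoids overlap along the left-right axis")

    @property
    def mu_effective(self) -> float:
        """Inspiratory parenchymal mean after the age trend."""
        return self.mu_ins + self.hu_per_year * (self.age_years - self.reference_age_years)

    @property
    def sigma_total(self) -> float:
        """Marginal SD of a parenchymal voxel (density + noise)."""
        return math.hypot(self.sigma_parenchyma, self.noise_sigma)


def _ellipsoid_mask(
    shape: Tuple[int, int, int],
    center: Tuple[float, float, float],
    semiaxes: Tuple[float, float, float],
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return r2 <= 1.0


def _lung_labels(spec: PhantomSpec, scale: float) -> np.ndarray:
    left = _ellipsoid_mask(
        spec.grid_shape, spec.left_center, tuple(a * scale for a in spec.left_semiaxes)
    )
    right = _ellipsoid_mask(
        spec.grid_shape, spec.right_center, tuple(a * scale for a in spec.right_semiaxes)
    )
    if (left & right).any():
        raise ValueError("lung ellipsoids overlap")
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[left] = 1
    labels[right] = 2
    return labels


def _trapped_subset(
    coords_mm: np.ndarray, seeds_mm: np.ndarray, fraction: float
) -> np.ndarray:
    """Boolean flags for the blob-clustered trapped subset of one lattice.

    The ``fraction`` quantile of voxels nearest (in mm) to any blob seed is
    trapped; ties are broken by lattice order so the result is exact and
    deterministic: exactly floor(fraction * n) voxels are flagged.
    """
    n = coords_mm.shape[0]
    k = int(math.floor(fraction * n))
    flags = np.zeros(n, dtype=bool)
    if k == 0:
        return flags
    d = cdist(coords_mm, seeds_mm).min(axis=1)
    flags[np.argsort(d, kind="stable")[:k]] = True
    return flags


def generate_phantom(
    spec: PhantomSpec,
) -> Tuple[DensityVolume, DensityVolume, LungMask, LungMask, DensitometryResult]:
    """Generate one paired-phase phantom plus its expected index panel.

    Returns ``(ins_volume, exp_volume, ins_mask, exp_mask, expected)``
    where ``expected`` holds the closed-form index values from
    :func:`analytic_expectations`. Identical spec (including seed) yields
    bit-identical volumes.
    """
    ins_labels = _lung_labels(spec, 1.0)
    if not ins_labels.any():
        raise ValueError("degenerate phantom: inspiratory lung contains no voxels")
    scale = spec.expiratory_volume_ratio ** (1.0 / 3.0)
    exp_labels = _lung_labels(spec, scale)
    if not exp_labels.any():
        raise ValueError("degenerate phantom: expiratory lung contains no voxels")
    # the shrunken lattice must be a subset of the inspiratory one so that
    # expiratory voxels can reuse the inspiratory density draw
    assert not (exp_labels.astype(bool) & ~ins_labels.astype(bool)).any()

    rng_geom = _substream(spec.seed, "geometry")
    rng_dens = _substream(spec.seed, "density")
    rng_noise = _substream(spec.seed, "noise")

    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    ins_idx = np.argwhere(ins_labels > 0)
    exp_idx = np.argwhere(exp_labels > 0)

    # blob seed points: uniform over the inspiratory lung voxels
    seeds_mm = ins_idx[rng_geom.choice(len(ins_idx), size=spec.n_trapped_blobs)] * spacing

    mu = spec.mu_effective
    draws = np.full(spec.grid_shape, np.nan)
    draws[tuple(ins_idx.T)] = rng_dens.normal(mu, spec.sigma_parenchyma, size=len(ins_idx))

    ins_values = np.full(spec.grid_shape, spec.body_hu, dtype=np.float64)
    ins_values[tuple(ins_idx.T)] = draws[tuple(ins_idx.T)]
    if spec.noise_sigma > 0:
        ins_values[tuple(ins_idx.T)] += rng_noise.normal(
            0.0, spec.noise_sigma, size=len(ins_idx)
        )

    trapped_exp = _trapped_subset(exp_idx * spacing, seeds_mm, spec.trapped_fraction)
    exp_values = np.full(spec.grid_shape, spec.body_hu, dtype=np.float64)
    shift = np.where(trapped_exp, 0.0, spec.delta_exp)
    exp_values[tuple(exp_idx.T)] = draws[tuple(exp_idx.T)] + shift
    if spec.noise_sigma > 0:
        exp_values[tuple(exp_idx.T)] += rng_noise.normal(
            0.0, spec.noise_sigma, size=len(exp_idx)
        )

    ins_vol = DensityVolume(ins_values, spec.voxel_spacing, Phase.INSPIRATORY)
    exp_vol = DensityVolume(exp_values, spec.voxel_spacing, Phase.EXPIRATORY)
    return (
        ins_vol,
        exp_vol,
        LungMask(ins_labels),
        LungMask(exp_labels),
        analytic_expectations(spec),
    )


def _mixture_below(t: float, mu: float, delta: float, p: float, sigma: float) -> float:
    """P(X < t) for the expiratory two-component mixture, as a percentage.

    A trapped voxel (weight p) keeps N(mu, sigma^2); a non-trapped voxel
    (weight 1-p) is N(mu + delta, sigma^2).
    """
    return 100.0 * (
        p * norm.cdf((t - mu) / sigma) + (1.0 - p) * norm.cdf((t - mu - delta) / sigma)
    )


def analytic_expectations(spec: PhantomSpec) -> DensitometryResult:
    """Closed-form expected index panel for a phantom spec.

    Volumes use the continuous ellipsoid volume (4/3 pi abc), MLDs the
    mixture means, and each threshold fraction a two-component Gaussian-CDF
    mixture evaluated at the threshold with the marginal SD
    sqrt(sigma_parenchyma^2 + noise_sigma^2). Edge/partial-volume effects
    of voxelization are ignored; the documented discretization bound on
    E/I volume is one voxel shell (100 x surface voxels / total voxels).
    """
    voxel_mm3 = float(np.prod(spec.voxel_spacing))
    v_ins = (
        4.0
        / 3.0
        * math.pi
        * (math.prod(spec.left_semiaxes) + math.prod(spec.right_semiaxes))
        * voxel_mm3
        / 1000.0
    )
    v_exp = v_ins * spec.expiratory_volume_ratio
    mu = spec.mu_effective
    p = spec.trapped_fraction
    exp_mld = mu + (1.0 - p) * spec.delta_exp
    sigma = spec.sigma_total
    laa: Dict[float, float] = {
        float(t): _mixture_below(t, mu, spec.delta_exp, p, sigma) for t in LAA_THRESHOLDS_HU
    }
    haa: Dict[float, float] = {
        float(t): 100.0 - _mixture_below(t, mu, spec.delta_exp, p, sigma)
        for t in HAA_THRESHOLDS_HU
    }
    return DensitometryResult(
        ins_volume_ml=v_ins,
        exp_volume_ml=v_exp,
        ins_mld_hu=mu,
        exp_mld_hu=exp_mld,
        mldd_hu=exp_mld - mu,
        ei_volume_pct=100.0 * spec.expiratory_volume_ratio,
        ei_mld_pct=100.0 * exp_mld / mu,
        laa_pct=laa,
        haa_pct=haa,
    )


def bo_like_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Convenience spec resembling an air-trapping (BO-like) lung."""
    base = PhantomSpec(
        seed=seed, trapped_fraction=0.5, expiratory_volume_ratio=0.73, delta_exp=130.0
    )
    return replace(base, **overrides) if overrides else base
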
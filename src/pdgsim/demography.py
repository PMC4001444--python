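"""Demographic rates: mortality, fecundity, dispersal, mating and recruitment.

The stand lives on a 200 x 1000 m domain mapped onto a 700-1700 m
elevational gradient (elevation = 700 + y) and divided into 500 cells of
20 x 20 m for seed dispersal.

Dispersal (pollen and seed) uses the exponential-power kernel family

    p(r) = b / (2 pi a^2 Gamma(2/b)) * exp(-(r/a)^b),

parameterised by its mean dispersal distance ``delta = a Gamma(3/b) /
Gamma(2/b)`` and shape ``b``; ``b = 1`` recovers the pure exponential with
``delta = 2 a``.  Distances to the domain borders are handled by first-order
mirror images of the source across the four edges, so border trees do not
lose progeny.

Mating: a seed is selfed with fixed probability ``s``; otherwise the father
is drawn with probability proportional to ``p_P(r) * DBH^gamma_m``
(distance-decayed pollen arrival times size-dependent male fertility).

Recruitment: the seed rain of mother ``j`` on cell ``i`` is ``tau_ij = F_j *
p_S(r_ij)`` at the cell centre; the number of recruits per (mother, cell) is
Poisson with mean ``tau_ij * S``.  Recruits enter at age 40 with Gaussian
height and diameter, are placed uniformly within their cell (or around the
mother if she sits in the same cell), and then undergo density-dependent
thinning: no surviving pair of crowns (discs of the tree's crown-projection
area) may overlap by more than 30% of the smaller crown.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import gamma as gamma_fn

__all__ = [
    "Domain",
    "Grid",
    "DispersalKernel",
    "MortalityMode",
    "CauseOfDeath",
    "MortalityThresholds",
    "AllometryParams",
    "mortality_check",
    "primary_seed_production",
    "effective_fecundity",
    "kernel_density",
    "density_with_images",
    "pollen_contributions",
    "sample_fathers",
    "seed_rain",
    "recruit_counts",
    "place_recruit",
    "circle_overlap_area",
    "crown_overlap_thinning",
    "dbh_growth",
    "height_from_dbh",
    "crown_area_from_dbh",
    "stem_carbon",
]


@dataclass(frozen=True)
class Domain:
    """Rectangular simulation domain; elevation rises linearly along y."""

    x_extent: float = 200.0
    y_extent: float = 1000.0
    elevation_base: float = 700.0
    elevation_top: float = 1700.0

    def elevation(self, y: np.ndarray | float) -> np.ndarray | float:
        return self.elevation_base + (
            (self.elevation_top - self.elevation_base) / self.y_extent
        ) * np.asarray(y, float)

    def contains(self, x, y) -> np.ndarray | bool:
        return (
            (np.asarray(x) >= 0)
            & (np.asarray(x) <= self.x_extent)
            & (np.asarray(y) >= 0)
            & (np.asarray(y) <= self.y_extent)
        )


@dataclass(frozen=True)
class Grid:
    """Square-cell grid over the domain (default 10 x 50 = 500 cells of 400 m2)."""

    domain: Domain = Domain()
    cell_size: float = 20.0

    @property
    def nx(self) -> int:
        return int(round(self.domain.x_extent / self.cell_size))

    @property
    def ny(self) -> int:
        return int(round(self.domain.y_extent / self.cell_size))

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = (np.arange(self.nx) + 0.5) * self.cell_size
        cy = (np.arange(self.ny) + 0.5) * self.cell_size
        gx, gy = np.meshgrid(cx, cy, indexing="xy")
        return gx.ravel(), gy.ravel()

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        ix = np.clip((np.asarray(x) / self.cell_size).astype(int), 0, self.nx - 1)
        iy = np.clip((np.asarray(y) / self.cell_size).astype(int), 0, self.ny - 1)
        return iy * self.nx + ix

    def cell_origin(self, cell: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        cell = np.asarray(cell)
        return (cell % self.nx) * self.cell_size, (cell // self.nx) * self.cell_size


class DispersalKernel:
    """Exponential-power dispersal kernel with given mean distance and shape."""

    def __init__(self, mean_distance: float, shape: float):
        if mean_distance <= 0 or shape <= 0:
            raise ValueError("mean distance and shape must be positive")
        self.mean_distance = float(mean_distance)
        self.shape = float(shape)
        # delta = a * Gamma(3/b) / Gamma(2/b)
        self.scale = self.mean_distance * gamma_fn(2.0 / shape) / gamma_fn(3.0 / shape)
        self._norm = shape / (2.0 * np.pi * self.scale**2 * gamma_fn(2.0 / shape))

    def density(self, r: np.ndarray | float) -> np.ndarray | float:
        """Probability density per unit area at distance ``r`` from the source."""
        r = np.asarray(r, float)
        if np.any(r < 0):
            raise ValueError("distance must be non-negative")
        return self._norm * np.exp(-((r / self.scale) ** self.shape))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample dispersal distances: ``a * G^(1/b)`` with G ~ Gamma(2/b)."""
        g = rng.gamma(2.0 / self.shape, 1.0, n)
        return self.scale * g ** (1.0 / self.shape)


def kernel_density(r: np.ndarray | float, kernel: DispersalKernel) -> np.ndarray | float:
    return kernel.density(r)


def density_with_images(
    kernel: DispersalKernel,
    source_x: np.ndarray,
    source_y: np.ndarray,
    target_x: np.ndarray | float,
    target_y: np.ndarray | float,
    domain: Domain,
) -> np.ndarray:
    """Kernel density from sources to targets under reflecting borders.

    The density is summed over the source and its four first-order mirror
    images across the domain edges; shapes of source and target broadcast.
    """
    sx = np.asarray(source_x, float)
    sy = np.asarray(source_y, float)
    tx = np.asarray(target_x, float)
    ty = np.asarray(target_y, float)
    images = (
        (sx, sy),
        (-sx, sy),
        (2.0 * domain.x_extent - sx, sy),
        (sx, -sy),
        (sx, 2.0 * domain.y_extent - sy),
    )
    dens = 0.0
    for ix, iy in images:
        r = np.hypot(tx - ix, ty - iy)
        dens = dens + kernel.density(r)
    return dens


class MortalityMode(IntEnum):
    NONE = 0
    BOTH = 1
    TYPE_I_ONLY = 2
    TYPE_II_ONLY = 3


class CauseOfDeath(IntEnum):
    NONE = 0
    TYPE_I = 1   # end-of-year reserves below the critical level
    TYPE_II = 2  # pre-budburst reserve deficit beyond the critical level


@dataclass(frozen=True)
class MortalityThresholds:
    cum_cr_crit: float = 45.0   # gC m-2, Type I
    bb_crit: float = 160.0      # gC m-2, Type II


def mortality_check(
    cum_cr: np.ndarray | float,
    bb_deficit: np.ndarray | float,
    thresholds: MortalityThresholds | None = None,
    mode: MortalityMode = MortalityMode.BOTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Carbon-starvation survival check.

    Type I death if end-of-year reserves fall below ``cum_cr_crit``;
    Type II death if the pre-budburst deficit exceeds ``bb_crit``.  The mode
    masks either check.  When both fire in the same year, Type I is the
    recorded cause.  Returns ``(alive, cause)`` arrays.
    """
    th = thresholds or MortalityThresholds()
    cum_cr = np.atleast_1d(np.asarray(cum_cr, float))
    bb = np.atleast_1d(np.asarray(bb_deficit, float))
    type1 = cum_cr < th.cum_cr_crit
    type2 = np.nan_to_num(bb, nan=-np.inf) > th.bb_crit
    if mode in (MortalityMode.NONE, MortalityMode.TYPE_II_ONLY):
        type1 = np.zeros_like(type1)
    if mode in (MortalityMode.NONE, MortalityMode.TYPE_I_ONLY):
        type2 = np.zeros_like(type2)
    cause = np.where(type1, CauseOfDeath.TYPE_I, np.where(type2, CauseOfDeath.TYPE_II, 0))
    return ~(type1 | type2), cause.astype(np.int8)


def primary_seed_production(
    b_res: np.ndarray | float,
    crown_area: np.ndarray | float,
    s_b_res: float = 100.0,
    r_sp: float = 0.05,
    seed_cost: float = 0.45,
) -> tuple[np.ndarray, np.ndarray]:
    """Seed count when reserves exceed the reproduction threshold.

    ``N_S = floor(R_SP * B_res * C_P / c)`` for ``B_res > sB_res``, else 0.
    Returns ``(n_seeds, reserve_debit)`` where the debit is the per-area
    carbon actually spent, ``N_S * c / C_P`` (gC m-2).
    """
    if s_b_res <= 0 or r_sp <= 0 or seed_cost <= 0:
        raise ValueError("s_b_res, r_sp and seed_cost must be positive")
    b = np.atleast_1d(np.asarray(b_res, float))
    cp = np.broadcast_to(np.asarray(crown_area, float), b.shape)
    n_seeds = np.where(
        (b > s_b_res) & (cp > 0), np.floor(r_sp * b * cp / seed_cost), 0.0
    ).astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        debit = np.where(cp > 0, n_seeds * seed_cost / np.where(cp > 0, cp, 1.0), 0.0)
    return n_seeds, debit


def effective_fecundity(
    n_seeds: np.ndarray | float,
    r_es: float = 0.33,
    r_ss: float = 0.15,
    r_sg: float = 0.485,
) -> np.ndarray | float:
    """Expected recruits at germination: ``N_S (1 - r_ES) r_SS r_SG``."""
    for name, r in (("r_es", r_es), ("r_ss", r_ss), ("r_sg", r_sg)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    return np.asarray(n_seeds, float) * (1.0 - r_es) * r_ss * r_sg


def pollen_contributions(
    j: int,
    x: np.ndarray,
    y: np.ndarray,
    dbh: np.ndarray,
    kernel: DispersalKernel,
    gamma_m: float = 0.82,
    domain: Domain | None = None,
) -> np.ndarray:
    """Normalised outcross paternity probabilities for seed tree ``j``.

    Weight of candidate ``k != j`` is ``p_P(r_jk) * DBH_k^gamma_m`` with
    distances under reflecting borders; the self weight is zero (selfing is
    a separate fixed-rate gate).
    """
    dom = domain or Domain()
    dens = density_with_images(kernel, x, y, x[j], y[j], dom)
    w = dens * np.asarray(dbh, float) ** gamma_m
    w[j] = 0.0
    total = w.sum()
    if total <= 0.0:
        raise ValueError("no candidate fathers with positive weight")
    return w / total


def sample_fathers(
    j: int,
    probs: np.ndarray,
    n: int,
    selfing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fathers of ``n`` seeds of mother ``j``: self with probability ``s``,
    otherwise drawn from the outcross paternity distribution."""
    fathers = rng.choice(probs.size, size=n, p=probs)
    if selfing_rate > 0.0:
        fathers[rng.random(n) < selfing_rate] = j
    return fathers


def seed_rain(
    mother_x: float,
    mother_y: float,
    fecundity: float,
    grid: Grid,
    kernel: DispersalKernel,
) -> np.ndarray:
    """Seed-rain intensity ``tau_i = F_j p_S(r_ij)`` at every cell centre."""
    if fecundity < 0:
        raise ValueError("fecundity must be non-negative")
    cx, cy = grid.centers()
    return fecundity * density_with_images(kernel, mother_x, mother_y, cx, cy, grid.domain)


def recruit_counts(tau: np.ndarray, cell_area: float, rng: np.random.Generator) -> np.ndarray:
    """Per-cell recruit numbers: Poisson with mean ``tau * S``."""
    return rng.poisson(np.asarray(tau, float) * cell_area)


def place_recruit(
    cell: int,
    grid: Grid,
    rng: np.random.Generator,
    mother_xy: tuple[float, float] | None = None,
    mother_sd: float = 5.0,
) -> tuple[float, float]:
    """Position of a recruit: uniform in its cell, or Gaussian around the
    mother (sd ``mother_sd``) when she stands in the same cell, clipped to
    the domain."""
    ox, oy = grid.cell_origin(cell)
    if mother_xy is not None and grid.cell_of(np.array([mother_xy[0]]), np.array([mother_xy[1]]))[0] == cell:
        x = rng.normal(mother_xy[0], mother_sd)
        y = rng.normal(mother_xy[1], mother_sd)
        x = float(np.clip(x, 0.0, grid.domain.x_extent))
        y = float(np.clip(y, 0.0, grid.domain.y_extent))
        return x, y
    return (
        float(ox + rng.uniform(0.0, grid.cell_size)),
        float(oy + rng.uniform(0.0, grid.cell_size)),
    )


def circle_overlap_area(d: float, r1: float, r2: float) -> float:
    """Intersection area of two discs with centre distance ``d``."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return np.pi * min(r1, r2) ** 2
    a1 = r1**2 * np.arccos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * np.arccos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    corr = 0.5 * np.sqrt(
        max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
    )
    return a1 + a2 - corr


def crown_overlap_thinning(
    x: np.ndarray,
    y: np.ndarray,
    crown_area: np.ndarray,
    rng: np.random.Generator,
    max_overlap: float = 0.3,
) -> np.ndarray:
    """Density-dependent thinning: boolean keep-mask with no pair of
    surviving crowns overlapping by more than ``max_overlap`` of the smaller
    crown's area.

    Crowns are discs centred on the stems.  All violating pairs are found,
    visited in random order, and for each pair still fully alive one member
    is removed uniformly at random.  Removal cannot create new overlap, so
    one pass suffices; the result is audited by construction.
    """
    n = x.size
    keep = np.ones(n, bool)
    if n < 2:
        return keep
    radius = np.sqrt(np.asarray(crown_area, float) / np.pi)
    tree = cKDTree(np.column_stack([x, y]))
    pairs = tree.query_pairs(r=2.0 * radius.max(), output_type="ndarray")
    if pairs.size == 0:
        return keep
    i, jj = pairs[:, 0], pairs[:, 1]
    d = np.hypot(x[i] - x[jj], y[i] - y[jj])
    candidate = d < radius[i] + radius[jj]
    violating = []
    for a, b, dd in zip(i[candidate], jj[candidate], d[candidate]):
        inter = circle_overlap_area(dd, radius[a], radius[b])
        small = np.pi * min(radius[a], radius[b]) ** 2
        if small > 0 and inter > max_overlap * small:
            violating.append((a, b))
    if not violating:
        return keep
    order = rng.permutation(len(violating))
    for k in order:
        a, b = violating[k]
        if keep[a] and keep[b]:
            keep[[a, b][rng.integers(2)]] = False
    return keep


@dataclass(frozen=True)
class AllometryParams:
    """Configurable power-law allometries and the stem carbon model.

    Stem volume is a cylinder times a form factor; wood carbon density is
    dry-wood density times carbon fraction.  Height (m) and crown projection
    (m2) are power laws of DBH (cm); defaults give a 13.8 cm recruit a
    height of ~9 m and a crown of ~14 m2.
    """

    wood_density: float = 550_000.0  # g dry mass per m3
    carbon_frac: float = 0.5
    form_factor: float = 0.5
    height_coef: float = 1.86
    height_exp: float = 0.6
    crown_coef: float = 0.6
    crown_exp: float = 1.2

    @property
    def carbon_density(self) -> float:
        return self.wood_density * self.carbon_frac  # gC per m3


def height_from_dbh(dbh_cm: np.ndarray | float, allom: AllometryParams) -> np.ndarray | float:
    return allom.height_coef * np.asarray(dbh_cm, float) ** allom.height_exp


def crown_area_from_dbh(dbh_cm: np.ndarray | float, allom: AllometryParams) -> np.ndarray | float:
    return allom.crown_coef * np.asarray(dbh_cm, float) ** allom.crown_exp


def stem_carbon(
    dbh_cm: np.ndarray | float, height_m: np.ndarray | float, allom: AllometryParams
) -> np.ndarray | float:
    """Stem carbon (gC) of a cylindrical stem with a form factor."""
    d_m = np.asarray(dbh_cm, float) / 100.0
    volume = allom.form_factor * np.pi / 4.0 * d_m**2 * np.asarray(height_m, float)
    return volume * allom.carbon_density


def dbh_growth(
    dbh_cm: np.ndarray | float,
    height_m: np.ndarray | float,
    wood_carbon: np.ndarray | float,
    allom: AllometryParams | None = None,
) -> np.ndarray | float:
    """New DBH after adding ``wood_carbon`` (gC) to the stem.

    The volume increment is converted at fixed height by inverting the
    cylindrical allometry, so the diameter increment is concave in carbon.
    """
    allom = allom or AllometryParams()
    wc = np.asarray(wood_carbon, float)
    if np.any(wc < 0):
        raise ValueError("wood carbon must be non-negative")
    d_m = np.asarray(dbh_cm, float) / 100.0
    h = np.asarray(height_m, float)
    dv = wc / allom.carbon_density
    new_d_m = np.sqrt(d_m**2 + dv / (allom.form_factor * np.pi / 4.0 * h))
    return new_d_m * 100.0
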
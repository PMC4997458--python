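"""Synthetic panels, rasters, and population surfaces with known ground truth.

The generator draws every component of the hierarchy the model fits — an ICAR
+ unstructured (BYM) spatial log-magnitude field with planted contiguous
hotspot clusters, a common linear log-trend with yearly random departures,
unit-level local trend departures, and the two-level Normal observation noise
— so parameter-recovery tests can compare posteriors against exact truth.

The default scenario emulates a 17-year national annual panel: overall level
exp(alpha) = 30 μg/m³, a gentle common upward trend, and three contiguous
hotspot clusters pushing local magnitudes exp(S) up to about 2.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .adjacency import AdjacencyStructure
from .geodata import RasterGrid, ZoneLabels
from .panel import SpaceTimePanel

__all__ = [
    "HotspotSpec",
    "TruthConfig",
    "SyntheticTruth",
    "simulate_icar_field",
    "make_truth",
    "simulate_panel",
    "simulate_population",
    "simulate_concentration_rasters",
    "block_zones",
    "DEFAULT_YEARS",
]

DEFAULT_YEARS = tuple(range(1998, 2015))  # 17 annual surfaces


@dataclass(frozen=True)
class HotspotSpec:
    """A planted contiguous bump added to a per-unit field on a lattice.

    ``center`` is (row, col) in unit-lattice coordinates; ``radius`` is in
    cells; ``amplitude`` is the log-scale peak height. ``shape`` is either a
    Gaussian falloff exp(-d^2 / 2 r^2) (truncated at 3r) or a flat disc.
    """

    center: tuple[int, int]
    radius: float
    amplitude: float
    shape: str = "gauss"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("hotspot radius must be >= 1 cell")
        if not math.isfinite(self.amplitude):
            raise ValueError("hotspot amplitude must be finite")
        if self.shape not in ("gauss", "disc"):
            raise ValueError("shape must be 'gauss' or 'disc'")

    def evaluate(self, coords: np.ndarray) -> np.ndarray:
        """Bump values at the given (n, 2) array of unit coordinates."""
        d = np.hypot(coords[:, 0] - self.center[0], coords[:, 1] - self.center[1])
        if self.shape == "disc":
            return np.where(d <= self.radius, self.amplitude, 0.0)
        out = self.amplitude * np.exp(-0.5 * (d / self.radius) ** 2)
        return np.where(d <= 3 * self.radius, out, 0.0)


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth settings of the default synthetic scenario.

    Units and scales: ``alpha`` is the overall log level (default ln 30, i.e.
    30 μg/m³); ``b0`` the common log trend per year (default 0.01 ≈ +0.3
    μg/m³/yr at that level); the BYM fields split their variance 1:1 between
    structured and unstructured parts; ``sigma0``/``sigma1`` are the two
    observation-noise sds in μg/m³ (default 5% and ~3% of the level);
    ``sigma_eps`` is the log-scale over-dispersion sd (off by default).
    """

    alpha: float = math.log(30.0)
    b0: float = 0.01
    s_struct_sd: float = 0.1
    s_unstruct_sd: float = 0.1
    b1_struct_sd: float = 0.002
    b1_unstruct_sd: float = 0.002
    v_sd: float = 0.03
    sigma0: float = 1.5
    sigma1: float = 1.0
    sigma_eps: float = 0.0
    s_hotspots: tuple[HotspotSpec, ...] = (
        HotspotSpec(center=(2, 2), radius=2.0, amplitude=0.8),
        HotspotSpec(center=(7, 7), radius=2.0, amplitude=0.65),
        HotspotSpec(center=(2, 7), radius=1.5, amplitude=0.5),
    )
    b1_hotspots: tuple[HotspotSpec, ...] = ()
    years: tuple[int, ...] = DEFAULT_YEARS


@dataclass
class SyntheticTruth:
    """Exact parameter values behind a simulated panel.

    Constraints: ``S`` and ``b1`` have mean 0 and ``v`` is orthogonal to
    (1, t*); the means/slopes removed in enforcing them have been folded into
    ``alpha`` and ``b0``, so the stored values are exactly the identified
    quantities a fit should recover.
    """

    alpha: float
    b0: float
    S: np.ndarray
    b1: np.ndarray
    v: np.ndarray
    years: np.ndarray
    sigma0: float
    sigma1: float
    sigma_eps: float
    seed: int

    @property
    def tstar(self) -> np.ndarray:
        t = self.years.astype(float)
        return t - t.mean()

    @property
    def n_units(self) -> int:
        return self.S.size

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "b0": self.b0,
            "S": self.S.tolist(),
            "b1": self.b1.tolist(),
            "v": self.v.tolist(),
            "years": self.years.tolist(),
            "sigma0": self.sigma0,
            "sigma1": self.sigma1,
            "sigma_eps": self.sigma_eps,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            alpha=d["alpha"], b0=d["b0"],
            S=np.array(d["S"]), b1=np.array(d["b1"]), v=np.array(d["v"]),
            years=np.array(d["years"], dtype=int),
            sigma0=d["sigma0"], sigma1=d["sigma1"], sigma_eps=d["sigma_eps"],
            seed=d["seed"],
        )


def simulate_icar_field(
    adj: AdjacencyStructure, sd: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Exact draw from the zero-mean intrinsic CAR distribution.

    The ICAR precision is (D - W) / sd^2; the draw is built spectrally on the
    eigenvectors with nonzero eigenvalue, which imposes a sum-to-zero
    constraint within each connected component (isolated units get 0).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = adj.n_units
    if sd == 0:
        return np.zeros(n)
    lam, vec = np.linalg.eigh(adj.laplacian())
    tol = 1e-8 * max(1.0, float(lam[-1]))
    keep = lam > tol
    coef = rng.standard_normal(int(keep.sum())) * sd / np.sqrt(lam[keep])
    return vec[:, keep] @ coef


def _unit_coords(adj: AdjacencyStructure, lattice_shape: tuple[int, int] | None) -> np.ndarray:
    if lattice_shape is None:
        raise ValueError("hotspots need a unit lattice shape (nrows, ncols)")
    nr, nc = lattice_shape
    if nr * nc != adj.n_units:
        raise ValueError("lattice shape inconsistent with number of units")
    idx = np.arange(adj.n_units)
    return np.column_stack([idx // nc, idx % nc]).astype(float)


def make_truth(
    adj: AdjacencyStructure,
    config: TruthConfig = TruthConfig(),
    seed: int = 0,
    lattice_shape: tuple[int, int] | None = None,
) -> SyntheticTruth:
    """Draw ground-truth fields with the BYM structure and planted hotspots.

    ``S`` = ICAR draw + iid Normal draw + hotspot bumps, then centered; ``b1``
    likewise; ``v`` is iid Normal residualized against (1, t*). Every mean or
    slope removed by the constraints is folded into ``alpha``/``b0`` so the
    generating process is unchanged by the centering.
    """
    rng = np.random.default_rng(seed)
    years = np.asarray(config.years, dtype=int)
    t = years.astype(float)
    tstar = t - t.mean()

    def bym(struct_sd, unstruct_sd, hotspots):
        x = simulate_icar_field(adj, struct_sd, rng)
        x = x + rng.standard_normal(adj.n_units) * unstruct_sd
        if hotspots:
            coords = _unit_coords(adj, lattice_shape)
            for h in hotspots:
                x = x + h.evaluate(coords)
        return x

    S = bym(config.s_struct_sd, config.s_unstruct_sd, config.s_hotspots)
    b1 = bym(config.b1_struct_sd, config.b1_unstruct_sd, config.b1_hotspots)
    v = rng.standard_normal(years.size) * config.v_sd

    alpha = config.alpha + float(S.mean())
    S = S - S.mean()
    b0 = config.b0 + float(b1.mean())
    b1 = b1 - b1.mean()
    a = float(v.mean())
    slope = float(v @ tstar / np.sum(tstar**2))
    v = v - a - slope * tstar
    alpha += a
    b0 += slope

    return SyntheticTruth(
        alpha=alpha, b0=b0, S=S, b1=b1, v=v, years=years,
        sigma0=config.sigma0, sigma1=config.sigma1, sigma_eps=config.sigma_eps,
        seed=seed,
    )


def truth_eta(truth: SyntheticTruth) -> np.ndarray:
    """Noise-free (n, T) log linear predictor of the truth."""
    ts = truth.tstar
    return (
        truth.alpha
        + truth.S[:, None]
        + truth.b0 * ts[None, :]
        + truth.v[None, :]
        + truth.b1[:, None] * ts[None, :]
    )


def simulate_panel(
    truth: SyntheticTruth,
    years: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> SpaceTimePanel:
    """Draw one observed panel from the two-level Normal hierarchy.

    For each (i, t): eta = alpha + S_i + b0 t* + v_t + b1_i t* + eps_it with
    eps ~ N(0, sigma_eps^2); theta = exp(eta); mu ~ N(theta, sigma1^2);
    y ~ N(mu, sigma0^2).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if years is not None and not np.array_equal(np.asarray(years), truth.years):
        raise ValueError("years must match the truth's years")
    n, T = truth.n_units, truth.years.size
    eta = truth_eta(truth)
    if truth.sigma_eps > 0:
        eta = eta + rng.standard_normal((n, T)) * truth.sigma_eps
    theta = np.exp(eta)
    mu = theta + rng.standard_normal((n, T)) * truth.sigma1
    y = mu + rng.standard_normal((n, T)) * truth.sigma0
    return SpaceTimePanel(values=y, years=truth.years)


def block_zones(
    unit_rows: int, unit_cols: int, cells_per_unit: int = 3
) -> ZoneLabels:
    """Label raster partitioning a cell lattice into square blocks of units.

    Unit (r, c) of the ``unit_rows x unit_cols`` lattice owns the
    ``cells_per_unit x cells_per_unit`` block of cells at that position; unit
    ids are row-major 1..n, matching :func:`stbhm.adjacency.queen_lattice`.
    """
    unit_idx = np.arange(unit_rows * unit_cols).reshape(unit_rows, unit_cols) + 1
    return ZoneLabels(labels=np.kron(unit_idx, np.ones((cells_per_unit, cells_per_unit), dtype=int)))


def simulate_population(
    zones: ZoneLabels,
    truth: SyntheticTruth,
    total: float = 1e8,
    seed: int | np.random.Generator = 0,
    coefficient: float = 1.0,
    noise_sd: float = 0.0,
) -> RasterGrid:
    """Population surface concentrated where the pollution magnitude is high.

    Cell density is proportional to exp(coefficient * S_unit) (log-linear in
    the local log-magnitude), optionally jittered by lognormal cell noise, and
    normalized to sum to ``total`` persons. Cells outside the study area
    (label 0) get zero population and are masked.
    """
    if total <= 0:
        raise ValueError("total population must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = zones.labels
    if zones.n_units != truth.n_units:
        raise ValueError("zones and truth disagree on the number of units")
    density = np.zeros(labels.shape, dtype=float)
    inside = labels > 0
    density[inside] = np.exp(coefficient * truth.S[labels[inside] - 1])
    if noise_sd > 0:
        density[inside] *= np.exp(rng.standard_normal(int(inside.sum())) * noise_sd)
    density *= total / density.sum()
    return RasterGrid(values=density, missing_mask=~inside, year=None)


def simulate_concentration_rasters(
    truth: SyntheticTruth,
    zones: ZoneLabels,
    seed: int | np.random.Generator = 0,
    cell_sd: float | None = None,
    missing_rate: float = 0.0,
) -> list[RasterGrid]:
    """Annual cell-level concentration grids consistent with the truth.

    Each cell of unit i in year t draws N(theta_it, cell_sd^2) (default
    cell_sd = sigma0), clipped at 0; cells outside the study area are masked,
    and ``missing_rate`` punches additional random holes (for exercising the
    focal-mean imputation).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = truth.sigma0 if cell_sd is None else cell_sd
    theta = np.exp(truth_eta(truth))
    labels = zones.labels
    inside = labels > 0
    grids = []
    for k, year in enumerate(truth.years):
        vals = np.zeros(labels.shape)
        vals[inside] = theta[labels[inside] - 1, k]
        vals = vals + rng.standard_normal(labels.shape) * sd
        vals = np.clip(vals, 0.0, None)
        mask = ~inside
        if missing_rate > 0:
            holes = rng.random(labels.shape) < missing_rate
            mask = mask | holes
        vals = np.where(mask, 0.0, vals)
        grids.append(RasterGrid(values=vals, missing_mask=mask, year=int(year)))
    return grids
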
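"""Well-tempered metadynamics on toy two-dimensional CV-space landscapes.

The all-atom system (an RNA hairpin opening while protein-bound) is replaced
by overdamped Langevin dynamics of the two collective variables themselves —
backbone RMSD (angstrom) and stem coordination number (dimensionless) —
moving on an analytic potential. The biasing mathematics is exactly the
well-tempered protocol:

* a Gaussian hill is deposited every ``pace`` steps at the current CV point;
* its height is tempered by the bias already accumulated there,
  ``w = w0 * exp(-V(s, t) / (kB * dT))`` with ``dT = (gamma - 1) * T``;
* the bias is a separable sum of the deposited Gaussians.

Default hill parameters: w0 = 1.0 kJ/mol deposited every 0.2 ps of toy time,
widths (0.5 A, 10) for the two CVs, bias factor gamma = 15, T = 300 K.

The sampler is parametrised by per-CV mobilities mu (drift = mu * F * dt,
noise std = sqrt(2 mu kB T dt)), so the zero-temperature limit is plain
gradient descent; at 300 K the default mobilities correspond to diffusion
constants (0.5 A^2/ps, 50 /ps). Bias forces during propagation come from a
fine internal grid (spacing sigma/5, nearest-node lookup) updated at each
deposition, while hill heights are computed from the exact analytic bias at
the deposition point — so a hills log can be re-verified to machine
precision independently of the grid. Dynamics reflect at the domain-box
walls; leaving the box by more than 10 hill widths aborts with a
diagnostic. Runs are bit-reproducible per seed.

Hills logs read and write the PLUMED-style HILLS text dialect
(``#! FIELDS time cv1 cv2 sigma_cv1 sigma_cv2 height biasf``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from numba import njit

__all__ = [
    "KB_KJ",
    "KJ_PER_KCAL",
    "MetadParams",
    "LangevinSettings",
    "ToyPotential",
    "HillsLog",
    "MetadynamicsError",
    "wt_hill_height",
    "evaluate_bias",
    "MetadSampler",
    "run_wt_metadynamics",
]

KB_KJ = 0.008314462618  # Boltzmann constant, kJ / (mol K)
KJ_PER_KCAL = 4.184


class MetadynamicsError(RuntimeError):
    """Raised when the CV trajectory diverges from the domain box."""


@dataclass(frozen=True)
class MetadParams:
    """Well-tempered hill-deposition parameters.

    w0 in kJ/mol; ``pace`` in integrator steps (100 steps of the default
    2 fs-equivalent dt = one hill per 0.2 ps of toy time); widths are the
    Gaussian sigmas along (CV1 in angstrom, CV2 dimensionless); gamma is the
    bias factor (> 1); temperature in kelvin.
    """

    w0: float = 1.0
    pace: int = 100
    widths: tuple[float, float] = (0.5, 10.0)
    bias_factor: float = 15.0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.w0 <= 0:
            raise ValueError("w0 must be positive")
        if self.pace < 1:
            raise ValueError("pace must be >= 1")
        if self.widths[0] <= 0 or self.widths[1] <= 0:
            raise ValueError("hill widths must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        if self.temperature < 0:
            raise ValueError("temperature must be nonnegative")

    @property
    def delta_t(self) -> float:
        """Well-tempered boost temperature (gamma - 1) * T, kelvin."""
        return (self.bias_factor - 1.0) * self.temperature


@dataclass(frozen=True)
class LangevinSettings:
    """Overdamped-Langevin propagation settings.

    dt in ps; mobility per CV in (CV unit)^2 / (kJ/mol) / ps; seed drives
    the numpy Philox-family generator; ``start`` defaults to the potential's
    suggested start (or domain centre). ``trace_stride`` thins the returned
    CV trace.
    """

    dt: float = 0.002
    mobility: tuple[float, float] = (0.802, 80.2)
    seed: int = 0
    start: tuple[float, float] | None = None
    trace_stride: int = 10


# --- Toy potentials ---------------------------------------------------------


@dataclass(frozen=True)
class ToyPotential:
    """Analytic CV-space potential on a rectangular domain.

    kinds: ``"flat"``; ``"harmonic"`` (params kx, ky, cx, cy);
    ``"double_well"`` (params: centers, sigmas, depths of two Gaussian
    wells, kJ/mol). Energies in kJ/mol.
    """

    kind: str
    params: dict = field(default_factory=dict)
    domain: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 10.0), (0.0, 100.0))
    start: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "harmonic", "double_well"):
            raise ValueError(f"unknown potential kind {self.kind!r}")

    @classmethod
    def flat(cls, domain=((0.0, 4.0), (0.0, 40.0))) -> "ToyPotential":
        return cls("flat", {}, domain)

    @classmethod
    def harmonic(
        cls, kx: float, ky: float, cx: float = 0.0, cy: float = 0.0, domain=None
    ) -> "ToyPotential":
        if domain is None:
            # +/- 4 thermal sigmas at 300 K
            sx = math.sqrt(KB_KJ * 300.0 / kx)
            sy = math.sqrt(KB_KJ * 300.0 / ky)
            domain = ((cx - 4 * sx, cx + 4 * sx), (cy - 4 * sy, cy + 4 * sy))
        return cls("harmonic", {"kx": kx, "ky": ky, "cx": cx, "cy": cy}, domain, (cx, cy))

    @classmethod
    def hairpin_landscape(
        cls,
        delta_g_kcal: float = 9.86,
        depth_hairpin_kj: float = 20.0,
        center_hairpin: tuple[float, float] = (3.0, 95.0),
        center_open: tuple[float, float] = (11.0, 25.0),
        sigma_hairpin: tuple[float, float] = (2.0, 20.0),
        sigma_open: tuple[float, float] = (2.5, 22.0),
        domain: tuple = ((0.0, 18.0), (0.0, 150.0)),
    ) -> "ToyPotential":
        """Two-Gaussian-well stand-in for the hairpin/stem-open landscape.

        The hairpin basin sits at low RMSD / high coordination number, the
        stem-open basin at high RMSD / low CN. ``delta_g_kcal`` > 0 makes
        the open well deeper (open state favored) by that free-energy gap;
        well separations are large enough that the minima depths equal the
        well depths to within ~1e-4 kJ/mol.

        Well widths are deliberately broad relative to the default hill
        widths (0.5, 10): the well-tempered bias is built from finite-width
        Gaussians and can only represent features it can resolve, so a
        faithful depth readout requires feature widths at least ~2x the
        hill widths on each axis.
        """
        depth_open = depth_hairpin_kj + delta_g_kcal * KJ_PER_KCAL
        return cls(
            "double_well",
            {
                "centers": (center_hairpin, center_open),
                "sigmas": (sigma_hairpin, sigma_open),
                "depths": (depth_hairpin_kj, depth_open),
            },
            domain,
            start=center_hairpin,
        )

    def _pack(self) -> tuple[int, np.ndarray]:
        """Encode for the jitted inner loop."""
        if self.kind == "flat":
            return 0, np.zeros(1)
        if self.kind == "harmonic":
            p = self.params
            return 1, np.array([p["kx"], p["ky"], p["cx"], p["cy"]], float)
        p = self.params
        (c1, c2), (s1, s2), (d1, d2) = p["centers"], p["sigmas"], p["depths"]
        return 2, np.array(
            [c1[0], c1[1], s1[0], s1[1], d1, c2[0], c2[1], s2[0], s2[1], d2], float
        )

    def energy(self, x, y):
        """Potential energy (kJ/mol), vectorised."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if self.kind == "flat":
            return np.zeros(np.broadcast(x, y).shape)
        if self.kind == "harmonic":
            p = self.params
            return 0.5 * p["kx"] * (x - p["cx"]) ** 2 + 0.5 * p["ky"] * (y - p["cy"]) ** 2
        v = np.zeros(np.broadcast(x, y).shape)
        for (cx, cy), (sx, sy), depth in zip(
            self.params["centers"], self.params["sigmas"], self.params["depths"]
        ):
            v = v - depth * np.exp(
                -((x - cx) ** 2) / (2 * sx**2) - ((y - cy) ** 2) / (2 * sy**2)
            )
        return v

    def gradient(self, x, y):
        """(dV/dx, dV/dy), vectorised."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if self.kind == "flat":
            z = np.zeros(np.broadcast(x, y).shape)
            return z, z.copy()
        if self.kind == "harmonic":
            p = self.params
            return p["kx"] * (x - p["cx"]), p["ky"] * (y - p["cy"])
        gx = np.zeros(np.broadcast(x, y).shape)
        gy = np.zeros_like(gx)
        for (cx, cy), (sx, sy), depth in zip(
            self.params["centers"], self.params["sigmas"], self.params["depths"]
        ):
            g = np.exp(-((x - cx) ** 2) / (2 * sx**2) - ((y - cy) ** 2) / (2 * sy**2))
            gx = gx + depth * g * (x - cx) / sx**2
            gy = gy + depth * g * (y - cy) / sy**2
        return gx, gy


# --- Hills log --------------------------------------------------------------


@dataclass
class HillsLog:
    """Time-ordered record of deposited Gaussian hills."""

    time: np.ndarray
    cv1: np.ndarray
    cv2: np.ndarray
    sigma1: np.ndarray
    sigma2: np.ndarray
    height: np.ndarray
    bias_factor: float
    w0: float | None = None

    def __post_init__(self) -> None:
        arrays = [self.time, self.cv1, self.cv2, self.sigma1, self.sigma2, self.height]
        arrays = [np.asarray(a, float) for a in arrays]
        (self.time, self.cv1, self.cv2, self.sigma1, self.sigma2, self.height) = arrays
        n = self.time.size
        if any(a.shape != (n,) for a in arrays):
            raise ValueError("hills arrays must have equal length")
        if n and np.any(np.diff(self.time) <= 0):
            raise ValueError("hill times must be strictly increasing")
        if np.any(self.height <= 0):
            raise ValueError("hill heights must be positive")
        if self.w0 is not None and np.any(self.height > self.w0 * (1 + 1e-12)):
            raise ValueError("hill heights must not exceed w0")

    def __len__(self) -> int:
        return self.time.size

    def head(self, n: int) -> "HillsLog":
        return HillsLog(
            self.time[:n], self.cv1[:n], self.cv2[:n],
            self.sigma1[:n], self.sigma2[:n], self.height[:n],
            self.bias_factor, self.w0,
        )

    def until_time(self, t: float) -> "HillsLog":
        return self.head(int(np.searchsorted(self.time, t, side="right")))

    @classmethod
    def concat(cls, a: "HillsLog", b: "HillsLog") -> "HillsLog":
        if a.bias_factor != b.bias_factor:
            raise ValueError("cannot concatenate logs with different bias factors")
        return cls(
            np.concatenate([a.time, b.time]), np.concatenate([a.cv1, b.cv1]),
            np.concatenate([a.cv2, b.cv2]), np.concatenate([a.sigma1, b.sigma1]),
            np.concatenate([a.sigma2, b.sigma2]), np.concatenate([a.height, b.height]),
            a.bias_factor, a.w0,
        )

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("#! FIELDS time cv1 cv2 sigma_cv1 sigma_cv2 height biasf\n")
            for k in range(len(self)):
                fh.write(
                    f"{self.time[k]:.6f} {self.cv1[k]:.10g} {self.cv2[k]:.10g} "
                    f"{self.sigma1[k]:.6g} {self.sigma2[k]:.6g} "
                    f"{self.height[k]:.12g} {self.bias_factor:.6g}\n"
                )

    @classmethod
    def read(cls, path: str | Path) -> "HillsLog":
        rows = []
        biasf = None
        with Path(path).open() as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = [float(tok) for tok in line.split()]
                rows.append(parts[:6])
                biasf = parts[6]
        if not rows:
            raise ValueError(f"{path}: no hills records")
        arr = np.array(rows)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4], arr[:, 5], biasf)


def wt_hill_height(bias_at_center: float, params: MetadParams) -> float:
    """Tempered hill height ``w0 * exp(-V / (kB * (gamma - 1) * T))``."""
    if bias_at_center < 0:
        raise ValueError("bias must be nonnegative")
    if params.temperature <= 0:
        raise ValueError("hill tempering requires a positive temperature")
    return params.w0 * math.exp(-bias_at_center / (KB_KJ * params.delta_t))


def evaluate_bias(point, hills: HillsLog):
    """Deposited bias (kJ/mol) at one point or an array of points.

    ``point`` is (cv1, cv2) or arrays broadcastable against the hills. An
    empty log yields 0.
    """
    x = np.asarray(point[0], float)
    y = np.asarray(point[1], float)
    if len(hills) == 0:
        return np.zeros(np.broadcast(x, y).shape) if x.ndim or y.ndim else 0.0
    xs = x[..., None]
    ys = y[..., None]
    g = hills.height * np.exp(
        -((xs - hills.cv1) ** 2) / (2 * hills.sigma1**2)
        - ((ys - hills.cv2) ** 2) / (2 * hills.sigma2**2)
    )
    out = g.sum(axis=-1)
    if out.ndim == 0:
        return float(out)
    return out


# --- Jitted propagation -----------------------------------------------------


@njit(cache=False)
def _propagate(
    x, y, n_steps,
    pot_kind, pot_params,
    fx_grid, fy_grid, x0g, y0g, dxg, dyg, nxg, nyg,
    xmin, xmax, ymin, ymax,
    mu1, mu2, dt, noise1, noise2, normals,
    trace, trace_stride, trace_offset, step_offset,
):
    """Advance n_steps of overdamped Langevin under potential + grid bias.

    Returns (x, y, status); status 1 flags divergence. ``normals`` holds
    pre-drawn standard normals of shape (n_steps, 2).
    """
    esc_x = 10.0 * (xmax - xmin)
    esc_y = 10.0 * (ymax - ymin)
    for s in range(n_steps):
        # analytic potential gradient
        if pot_kind == 0:
            gx = 0.0
            gy = 0.0
        elif pot_kind == 1:
            gx = pot_params[0] * (x - pot_params[2])
            gy = pot_params[1] * (y - pot_params[3])
        else:
            dx1 = x - pot_params[0]
            dy1 = y - pot_params[1]
            e1 = math.exp(
                -dx1 * dx1 / (2.0 * pot_params[2] * pot_params[2])
                - dy1 * dy1 / (2.0 * pot_params[3] * pot_params[3])
            )
            dx2 = x - pot_params[5]
            dy2 = y - pot_params[6]
            e2 = math.exp(
                -dx2 * dx2 / (2.0 * pot_params[7] * pot_params[7])
                - dy2 * dy2 / (2.0 * pot_params[8] * pot_params[8])
            )
            gx = pot_params[4] * e1 * dx1 / (pot_params[2] * pot_params[2]) + pot_params[
                9
            ] * e2 * dx2 / (pot_params[7] * pot_params[7])
            gy = pot_params[4] * e1 * dy1 / (pot_params[3] * pot_params[3]) + pot_params[
                9
            ] * e2 * dy2 / (pot_params[8] * pot_params[8])
        # bias force from the nearest grid node
        i = int(round((x - x0g) / dxg))
        j = int(round((y - y0g) / dyg))
        if i < 0:
            i = 0
        elif i >= nxg:
            i = nxg - 1
        if j < 0:
            j = 0
        elif j >= nyg:
            j = nyg - 1
        fx = fx_grid[i, j] - gx
        fy = fy_grid[i, j] - gy
        x = x + mu1 * fx * dt + noise1 * normals[s, 0]
        y = y + mu2 * fy * dt + noise2 * normals[s, 1]
        # reflecting walls
        if x < xmin:
            x = 2.0 * xmin - x
        elif x > xmax:
            x = 2.0 * xmax - x
        if y < ymin:
            y = 2.0 * ymin - y
        elif y > ymax:
            y = 2.0 * ymax - y
        if (
            x < xmin - esc_x or x > xmax + esc_x
            or y < ymin - esc_y or y > ymax + esc_y
            or x != x or y != y
        ):
            return x, y, 1
        step = step_offset + s + 1
        if step % trace_stride == 0:
            k = trace_offset + step // trace_stride - (step_offset // trace_stride) - 1
            if 0 <= k < trace.shape[0]:
                trace[k, 0] = x
                trace[k, 1] = y
    return x, y, 0


class MetadSampler:
    """Resumable well-tempered metadynamics run on a toy potential.

    Call :meth:`run` repeatedly to extend the simulation; :attr:`hills` and
    :meth:`trace` expose the accumulated state. State depends only on the
    constructor arguments and the total number of steps run, so chunked and
    single-shot runs of equal length are identical.
    """

    _CAPACITY = 65536

    def __init__(
        self,
        potential: ToyPotential,
        params: MetadParams,
        settings: LangevinSettings,
        grid_spacing_frac: float = 0.2,
        exact_heights: bool = True,
    ) -> None:
        """``exact_heights`` selects how the tempering bias V(s, t) at the
        deposition point is obtained: analytically over all prior hills
        (exact, O(n) per hill — heights re-derivable from the log to
        machine precision) or bilinearly from the internal bias grid
        (O(1) per hill, relative error ~1e-3 of a hill height; use for
        runs with very many hills)."""
        self.potential = potential
        self.params = params
        self.settings = settings
        self.exact_heights = exact_heights
        (xmin, xmax), (ymin, ymax) = potential.domain
        if settings.start is not None:
            self._x, self._y = float(settings.start[0]), float(settings.start[1])
        elif potential.start is not None:
            self._x, self._y = float(potential.start[0]), float(potential.start[1])
        else:
            self._x, self._y = 0.5 * (xmin + xmax), 0.5 * (ymin + ymax)
        if not (xmin <= self._x <= xmax and ymin <= self._y <= ymax):
            raise ValueError("start point outside the domain box")
        self._rng = np.random.default_rng(settings.seed)
        self._step = 0
        # bias-force grid at sigma * grid_spacing_frac resolution
        s1, s2 = params.widths
        self._dxg = s1 * grid_spacing_frac
        self._dyg = s2 * grid_spacing_frac
        self._x0g, self._y0g = xmin, ymin
        self._nxg = int(math.ceil((xmax - xmin) / self._dxg)) + 1
        self._nyg = int(math.ceil((ymax - ymin) / self._dyg)) + 1
        self._fx = np.zeros((self._nxg, self._nyg))
        self._fy = np.zeros((self._nxg, self._nyg))
        self._vb = np.zeros((self._nxg, self._nyg))  # bias values, for grid heights
        self._xg = xmin + self._dxg * np.arange(self._nxg)
        self._yg = ymin + self._dyg * np.arange(self._nyg)
        # hills storage (grown on demand)
        self._cap = self._CAPACITY
        self._h_t = np.empty(self._cap)
        self._h_x = np.empty(self._cap)
        self._h_y = np.empty(self._cap)
        self._h_w = np.empty(self._cap)
        self._n_hills = 0
        self._trace_chunks: list[np.ndarray] = []
        self._pot_kind, self._pot_params = potential._pack()

    # -- state views --------------------------------------------------------

    @property
    def n_steps(self) -> int:
        return self._step

    @property
    def position(self) -> tuple[float, float]:
        return self._x, self._y

    @property
    def hills(self) -> HillsLog:
        n = self._n_hills
        s1, s2 = self.params.widths
        return HillsLog(
            self._h_t[:n].copy(), self._h_x[:n].copy(), self._h_y[:n].copy(),
            np.full(n, s1), np.full(n, s2), self._h_w[:n].copy(),
            self.params.bias_factor, self.params.w0,
        )

    def trace(self) -> np.ndarray:
        """(n, 2) thinned CV trace accumulated so far."""
        if not self._trace_chunks:
            return np.empty((0, 2))
        return np.concatenate(self._trace_chunks, axis=0)

    def bias_at(self, x: float, y: float) -> float:
        """Exact analytic bias at a point (independent of the force grid)."""
        n = self._n_hills
        if n == 0:
            return 0.0
        s1, s2 = self.params.widths
        g = self._h_w[:n] * np.exp(
            -((x - self._h_x[:n]) ** 2) / (2 * s1 * s1)
            - ((y - self._h_y[:n]) ** 2) / (2 * s2 * s2)
        )
        return float(g.sum())

    # -- propagation --------------------------------------------------------

    def _grow(self) -> None:
        self._cap *= 2
        for name in ("_h_t", "_h_x", "_h_y", "_h_w"):
            old = getattr(self, name)
            new = np.empty(self._cap)
            new[: self._n_hills] = old[: self._n_hills]
            setattr(self, name, new)

    def _grid_bias_at(self, x: float, y: float) -> float:
        """Bilinear interpolation of the accumulated bias-value grid."""
        fx = (x - self._x0g) / self._dxg
        fy = (y - self._y0g) / self._dyg
        i = min(max(int(fx), 0), self._nxg - 2)
        j = min(max(int(fy), 0), self._nyg - 2)
        tx = min(max(fx - i, 0.0), 1.0)
        ty = min(max(fy - j, 0.0), 1.0)
        v = self._vb
        return float(
            v[i, j] * (1 - tx) * (1 - ty)
            + v[i + 1, j] * tx * (1 - ty)
            + v[i, j + 1] * (1 - tx) * ty
            + v[i + 1, j + 1] * tx * ty
        )

    def _deposit(self) -> None:
        if self.params.temperature <= 0:
            raise MetadynamicsError("hill deposition requires a positive temperature")
        if self._n_hills >= self._cap:
            self._grow()
        x, y = self._x, self._y
        v_here = self.bias_at(x, y) if self.exact_heights else self._grid_bias_at(x, y)
        w = wt_hill_height(v_here, self.params)
        k = self._n_hills
        self._h_t[k] = self._step * self.settings.dt
        self._h_x[k] = x
        self._h_y[k] = y
        self._h_w[k] = w
        self._n_hills = k + 1
        # add the hill's force to the grid on a +/- 5 sigma patch
        s1, s2 = self.params.widths
        i0 = max(0, int((x - 5 * s1 - self._x0g) / self._dxg))
        i1 = min(self._nxg, int((x + 5 * s1 - self._x0g) / self._dxg) + 2)
        j0 = max(0, int((y - 5 * s2 - self._y0g) / self._dyg))
        j1 = min(self._nyg, int((y + 5 * s2 - self._y0g) / self._dyg) + 2)
        dxv = self._xg[i0:i1] - x
        dyv = self._yg[j0:j1] - y
        gx = np.exp(-(dxv**2) / (2 * s1 * s1))
        gy = np.exp(-(dyv**2) / (2 * s2 * s2))
        # F = -grad(V_bias): for V = w * Gx * Gy, -dV/dx = w * (dx/s1^2) Gx Gy
        self._fx[i0:i1, j0:j1] += w * ((dxv / (s1 * s1)) * gx)[:, None] * gy[None, :]
        self._fy[i0:i1, j0:j1] += w * gx[:, None] * ((dyv / (s2 * s2)) * gy)[None, :]
        self._vb[i0:i1, j0:j1] += w * gx[:, None] * gy[None, :]

    def run(self, n_steps: int) -> None:
        """Advance the simulation by ``n_steps`` integrator steps."""
        st = self.settings
        (xmin, xmax), (ymin, ymax) = self.potential.domain
        kbt = KB_KJ * self.params.temperature
        noise1 = math.sqrt(2.0 * st.mobility[0] * kbt * st.dt)
        noise2 = math.sqrt(2.0 * st.mobility[1] * kbt * st.dt)
        pace = self.params.pace
        remaining = n_steps
        n_trace = n_steps // st.trace_stride + 2
        trace = np.full((n_trace, 2), np.nan)
        t_off = 0
        while remaining > 0:
            # steps until the next deposition boundary
            until = pace - (self._step % pace)
            chunk = min(until, remaining)
            normals = self._rng.standard_normal((chunk, 2))
            x, y, status = _propagate(
                self._x, self._y, chunk,
                self._pot_kind, self._pot_params,
                self._fx, self._fy, self._x0g, self._y0g,
                self._dxg, self._dyg, self._nxg, self._nyg,
                xmin, xmax, ymin, ymax,
                st.mobility[0], st.mobility[1], st.dt, noise1, noise2, normals,
                trace, st.trace_stride, t_off, self._step,
            )
            if status != 0:
                raise MetadynamicsError(
                    f"CV trajectory diverged at step {self._step}: "
                    f"position ({x:.3g}, {y:.3g}) left the domain box "
                    f"{self.potential.domain} by more than 10 widths; "
                    "reduce dt or the mobilities"
                )
            self._x, self._y = x, y
            prev_step = self._step
            self._step += chunk
            t_off += self._step // st.trace_stride - prev_step // st.trace_stride
            remaining -= chunk
            if self._step % pace == 0:
                self._deposit()
        self._trace_chunks.append(trace[:t_off])


def run_wt_metadynamics(
    potential: ToyPotential,
    params: MetadParams,
    settings: LangevinSettings,
    n_steps: int,
) -> tuple[HillsLog, np.ndarray]:
    """One-shot convenience wrapper: returns (hills log, thinned CV trace)."""
    sampler = MetadSampler(potential, params, settings)
    sampler.run(n_steps)
    return sampler.hills, sampler.trace()
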
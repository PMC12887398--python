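"""Free-energy-surface reconstruction and basin analysis.

From a well-tempered hills log, the bias on a (RMSD, coordination-number)
grid is the separable Gaussian sum of the deposited hills, and the free
energy follows the standard well-tempered estimator

    F(s) = -[gamma / (gamma - 1)] * V(s),

reported in kcal/mol and shifted so the global minimum is zero. Because the
instantaneous estimate carries hill-sized ripples, :func:`reconstruct_fes`
optionally averages the bias over checkpoints spanning the last half of the
deposition history (the estimator's additive constant is uniform over the
grid, so averaging preserves relative free energies).

Basins are local minima of the gridded surface (8-neighbour rule), merged by
topographic persistence: two minima separated by a saddle lower than
``min_barrier`` above the shallower minimum belong to one basin. Each node
is then assigned to a surviving basin by steepest descent (ties broken by
node index, so the analysis is deterministic). The basin-to-basin free
energy difference is, by default, the difference of basin minima — the way
a single number is read off a 2D PMF plot — with a Boltzmann-integrated
alternative behind a flag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metad import (
    KB_KJ,
    KJ_PER_KCAL,
    HillsLog,
    LangevinSettings,
    MetadParams,
    MetadSampler,
    ToyPotential,
)

__all__ = [
    "FESGrid",
    "Basin",
    "BasinReport",
    "grid_from_hills",
    "sum_hills",
    "bias_to_fes",
    "reconstruct_fes",
    "find_basins",
    "label_stem_basins",
    "basin_delta_g",
    "convergence_diagnostic",
    "recover_delta_g",
]

KB_KCAL = KB_KJ / KJ_PER_KCAL


@dataclass
class FESGrid:
    """2D free-energy surface over (cv1 = RMSD [A], cv2 = CN) in kcal/mol."""

    cv1_axis: np.ndarray
    cv2_axis: np.ndarray
    free_energy: np.ndarray  # shape (n1, n2), min-shifted to 0
    bias_factor: float

    def __post_init__(self) -> None:
        self.cv1_axis = np.asarray(self.cv1_axis, float)
        self.cv2_axis = np.asarray(self.cv2_axis, float)
        self.free_energy = np.asarray(self.free_energy, float)
        if self.free_energy.shape != (self.cv1_axis.size, self.cv2_axis.size):
            raise ValueError("free_energy shape must match the axes")
        if not np.all(np.isfinite(self.free_energy)):
            raise ValueError("free energy must be finite everywhere")

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("#! FIELDS cv1 cv2 free_energy_kcal\n")
            fh.write(f"#! SET bias_factor {self.bias_factor}\n")
            for i, x in enumerate(self.cv1_axis):
                for j, y in enumerate(self.cv2_axis):
                    fh.write(f"{x:.6f} {y:.6f} {self.free_energy[i, j]:.8f}\n")

    @classmethod
    def read(cls, path: str | Path) -> "FESGrid":
        xs, ys, fs = [], [], []
        biasf = float("nan")
        with Path(path).open() as fh:
            for line in fh:
                if line.startswith("#"):
                    if "bias_factor" in line:
                        biasf = float(line.split()[-1])
                    continue
                if not line.strip():
                    continue
                x, y, f = (float(t) for t in line.split()[:3])
                xs.append(x)
                ys.append(y)
                fs.append(f)
        cv1 = np.unique(xs)
        cv2 = np.unique(ys)
        grid = np.asarray(fs).reshape(cv1.size, cv2.size)
        return cls(cv1, cv2, grid, biasf)


def grid_from_hills(
    hills: HillsLog, shape: tuple[int, int] = (200, 200), pad_widths: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Axes covering the hill centers padded by ``pad_widths`` hill sigmas."""
    if len(hills) == 0:
        raise ValueError("empty hills log")
    s1 = float(hills.sigma1.max())
    s2 = float(hills.sigma2.max())
    x = np.linspace(hills.cv1.min() - pad_widths * s1, hills.cv1.max() + pad_widths * s1, shape[0])
    y = np.linspace(hills.cv2.min() - pad_widths * s2, hills.cv2.max() + pad_widths * s2, shape[1])
    return x, y


def sum_hills(
    hills: HillsLog,
    grid: tuple[np.ndarray, np.ndarray],
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Deposited bias (kJ/mol) on a grid; linear in the log.

    Exploits the separability of the (axis-aligned) hills: the bias is a
    product of per-axis Gaussian factor matrices contracted over hills,
    evaluated as one matrix product. Optional per-hill ``weights`` scale the
    heights (used for checkpoint-averaged reconstruction).

    The grid must cover every hill center to +/- 5 sigma; spacing coarser
    than sigma/2 triggers a warning.
    """
    x, y = (np.asarray(grid[0], float), np.asarray(grid[1], float))
    if len(hills) == 0:
        return np.zeros((x.size, y.size))
    s1 = hills.sigma1
    s2 = hills.sigma2
    if (
        x[0] > hills.cv1.min() - 5 * s1.max() + 1e-9
        or x[-1] < hills.cv1.max() + 5 * s1.max() - 1e-9
        or y[0] > hills.cv2.min() - 5 * s2.max() + 1e-9
        or y[-1] < hills.cv2.max() + 5 * s2.max() - 1e-9
    ):
        raise ValueError("grid must cover the hill centers +/- 5 widths")
    if x.size > 1 and np.max(np.diff(x)) > s1.min() / 2 + 1e-12:
        warnings.warn("cv1 grid spacing coarser than sigma/2", stacklevel=2)
    if y.size > 1 and np.max(np.diff(y)) > s2.min() / 2 + 1e-12:
        warnings.warn("cv2 grid spacing coarser than sigma/2", stacklevel=2)
    h = hills.height if weights is None else hills.height * np.asarray(weights, float)
    gx = np.exp(-((x[:, None] - hills.cv1[None, :]) ** 2) / (2 * s1[None, :] ** 2))  # (nx, k)
    gy = np.exp(-((y[:, None] - hills.cv2[None, :]) ** 2) / (2 * s2[None, :] ** 2))  # (ny, k)
    return (gx * h[None, :]) @ gy.T


def bias_to_fes(
    bias_grid_kj: np.ndarray,
    gamma: float,
    grid: tuple[np.ndarray, np.ndarray],
) -> FESGrid:
    """Well-tempered estimator F = -[gamma/(gamma-1)] V, kcal/mol, min at 0."""
    if gamma <= 1:
        raise ValueError("bias factor must exceed 1")
    f_kj = -(gamma / (gamma - 1.0)) * np.asarray(bias_grid_kj, float)
    f_kcal = f_kj / KJ_PER_KCAL
    f_kcal = f_kcal - f_kcal.min()
    return FESGrid(grid[0], grid[1], f_kcal, gamma)


def reconstruct_fes(
    hills: HillsLog,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    shape: tuple[int, int] = (200, 200),
    time_average: bool = True,
    avg_fraction: float = 0.5,
    n_checkpoints: int = 11,
) -> FESGrid:
    """Hills log -> free-energy surface.

    With ``time_average`` the bias is averaged over ``n_checkpoints``
    deposition counts evenly spanning the last ``avg_fraction`` of the log,
    which damps the hill-sized ripples of the instantaneous estimate. The
    averaged bias is still a weighted hill sum, so this costs one
    :func:`sum_hills` call with per-hill weights equal to the fraction of
    checkpoints that include each hill.
    """
    if grid is None:
        grid = grid_from_hills(hills, shape=shape)
    n = len(hills)
    weights = None
    if time_average and n >= 4:
        first = int(np.ceil((1.0 - avg_fraction) * n))
        first = min(max(first, 1), n)
        counts = np.unique(np.linspace(first, n, n_checkpoints).round().astype(int))
        # hill k (1-based) is inside checkpoints with count >= k
        k = np.arange(1, n + 1)
        weights = (counts[None, :] >= k[:, None]).sum(axis=1) / counts.size
    bias = sum_hills(hills, grid, weights=weights)
    return bias_to_fes(bias, hills.bias_factor, grid)


# --- Basin analysis ---------------------------------------------------------


@dataclass
class Basin:
    """One watershed basin of the FES."""

    label: str
    min_index: tuple[int, int]
    min_location: tuple[float, float]
    min_free_energy: float
    region: np.ndarray = field(repr=False)  # boolean mask on the grid

    @property
    def size(self) -> int:
        return int(self.region.sum())


_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def find_basins(fes: FESGrid, min_barrier: float = 1.0) -> list[Basin]:
    """Persistence-merged local minima with steepest-descent watersheds.

    Local minima are grid nodes below all 8 neighbours (boundary nodes use
    the neighbours that exist; plateau ties resolved by flood order, lowest
    flat index first). Minima whose separating saddle rises less than
    ``min_barrier`` (kcal/mol) above the shallower minimum are merged into
    the deeper one. Returns basins sorted by minimum free energy. A surface
    without interior minima yields an empty list.
    """
    F = fes.free_energy
    n1, n2 = F.shape
    flat = F.ravel()
    order = np.argsort(flat, kind="stable")

    parent = {}  # flat index of component root (a minimum) -> root
    comp_min = {}  # root -> (min F, flat index)

    def find(r):
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    assigned = np.full(n1 * n2, -1, dtype=np.int64)  # component root per node
    minima: list[int] = []
    for idx in order:
        i, j = divmod(int(idx), n2)
        roots = set()
        for di, dj in _NEIGHBOURS:
            ni, nj = i + di, j + dj
            if 0 <= ni < n1 and 0 <= nj < n2:
                a = assigned[ni * n2 + nj]
                if a >= 0:
                    roots.add(find(int(a)))
        if not roots:
            # new local minimum
            parent[int(idx)] = int(idx)
            comp_min[int(idx)] = (float(flat[idx]), int(idx))
            minima.append(int(idx))
            assigned[idx] = idx
            continue
        # deepest neighbouring component wins the node
        deepest = min(roots, key=lambda r: (comp_min[r][0], comp_min[r][1]))
        for r in roots:
            if r == deepest:
                continue
            persistence = float(flat[idx]) - comp_min[r][0]
            if persistence < min_barrier:
                parent[r] = deepest  # merge shallow basin away
        assigned[idx] = deepest

    survivors = sorted({find(m) for m in minima})
    basins: list[Basin] = []

    # steepest-descent watershed assignment to surviving minima
    descent_target = np.full(n1 * n2, -1, dtype=np.int64)

    def descend(start: int) -> int:
        path = []
        idx = start
        while descent_target[idx] < 0:
            path.append(idx)
            i, j = divmod(idx, n2)
            best = idx
            best_val = flat[idx]
            for di, dj in _NEIGHBOURS:
                ni, nj = i + di, j + dj
                if 0 <= ni < n1 and 0 <= nj < n2:
                    nidx = ni * n2 + nj
                    val = flat[nidx]
                    if val < best_val or (val == best_val and nidx < best):
                        best_val = val
                        best = nidx
            if best == idx:  # local minimum
                descent_target[idx] = find(idx) if idx in parent else idx
                break
            idx = best
        target = descent_target[idx]
        for p in path:
            descent_target[p] = target
        return int(target)

    for idx in range(n1 * n2):
        descend(idx)

    for rank, root in enumerate(sorted(survivors, key=lambda r: comp_min[r][0])):
        region = (descent_target == root).reshape(n1, n2)
        i, j = divmod(comp_min[root][1], n2)
        basins.append(
            Basin(
                label=f"basin{rank}",
                min_index=(i, j),
                min_location=(float(fes.cv1_axis[i]), float(fes.cv2_axis[j])),
                min_free_energy=comp_min[root][0],
                region=region,
            )
        )
    return basins


def label_stem_basins(basins: list[Basin]) -> dict[str, Basin]:
    """Identify the hairpin (high CN) and stem-open (low CN) basins.

    Of the two lowest-free-energy basins, the one whose minimum sits at the
    larger coordination number (cv2) is the hairpin.
    """
    if len(basins) < 2:
        raise ValueError("need at least two basins to label hairpin and open states")
    lead = sorted(basins, key=lambda b: b.min_free_energy)[:2]
    hairpin = max(lead, key=lambda b: b.min_location[1])
    open_ = min(lead, key=lambda b: b.min_location[1])
    if hairpin is open_:
        raise ValueError("basins are not separated along the coordination number")
    return {"hairpin": hairpin, "open": open_}


@dataclass
class BasinReport:
    """Two-basin free-energy readout."""

    delta_g: float  # kcal/mol, F_min(hairpin) - F_min(open); > 0 => open favored
    barrier: float  # kcal/mol above the lower minimum
    convention: str
    hairpin_min: tuple[float, float]
    open_min: tuple[float, float]
    hairpin_f: float
    open_f: float

    def to_dict(self) -> dict:
        return {
            "delta_g_kcal": self.delta_g,
            "barrier_kcal": self.barrier,
            "convention": self.convention,
            "hairpin_min": list(self.hairpin_min),
            "open_min": list(self.open_min),
            "hairpin_free_energy_kcal": self.hairpin_f,
            "open_free_energy_kcal": self.open_f,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _saddle_between(fes: FESGrid, a: Basin, b: Basin) -> float:
    """Lowest crossing level between two basin regions (flood level)."""
    F = fes.free_energy
    n1, n2 = F.shape
    flat = F.ravel()
    order = np.argsort(flat, kind="stable")
    a_min = a.min_index[0] * n2 + a.min_index[1]
    b_min = b.min_index[0] * n2 + b.min_index[1]
    seeds = {a_min: 0, b_min: 1}

    labels = np.full(n1 * n2, -1, dtype=np.int64)
    next_label = 2
    parents: dict[int, int] = {0: 0, 1: 1}

    def find(r: int) -> int:
        while parents[r] != r:
            parents[r] = parents[parents[r]]
            r = parents[r]
        return r

    for idx in order:
        i, j = divmod(int(idx), n2)
        roots = set()
        for di, dj in _NEIGHBOURS:
            ni, nj = i + di, j + dj
            if 0 <= ni < n1 and 0 <= nj < n2:
                lab = labels[ni * n2 + nj]
                if lab >= 0:
                    roots.add(find(int(lab)))
        if int(idx) in seeds:
            labels[idx] = seeds[int(idx)]
            roots.add(seeds[int(idx)])
        if not roots:
            labels[idx] = next_label
            parents[next_label] = next_label
            next_label += 1
            continue
        first = min(roots)
        for r in roots:
            parents[find(r)] = find(first)
        if labels[idx] < 0:
            labels[idx] = first
        if find(0) == find(1):
            return float(flat[idx])
    return float("inf")


def basin_delta_g(
    fes: FESGrid,
    basin_hairpin: Basin,
    basin_open: Basin,
    method: str = "minima",
    temperature: float = 300.0,
) -> BasinReport:
    """Free-energy gap between the hairpin and stem-open basins.

    ``method="minima"`` (default): difference of the basin minimum free
    energies, F_min(hairpin) - F_min(open); positive means the open state is
    favored. ``method="integral"``: Boltzmann-integrated basin free
    energies, F_basin = -kB T ln sum_region exp(-F / kB T) (cell areas are
    uniform on the grid and cancel in the difference).
    """
    if method not in ("minima", "integral"):
        raise ValueError(f"unknown method {method!r}")
    if method == "minima":
        fh = basin_hairpin.min_free_energy
        fo = basin_open.min_free_energy
    else:
        kbt = KB_KCAL * temperature
        F = fes.free_energy

        def integral(b: Basin) -> float:
            vals = F[b.region]
            ref = vals.min()
            return float(ref - kbt * np.log(np.sum(np.exp(-(vals - ref) / kbt))))

        fh = integral(basin_hairpin)
        fo = integral(basin_open)
    saddle = _saddle_between(fes, basin_hairpin, basin_open)
    lower = min(basin_hairpin.min_free_energy, basin_open.min_free_energy)
    barrier = saddle - lower if np.isfinite(saddle) else float("inf")
    return BasinReport(
        delta_g=float(fh - fo),
        barrier=float(barrier),
        convention=f"F_{method}(hairpin) - F_{method}(open); positive favors open",
        hairpin_min=basin_hairpin.min_location,
        open_min=basin_open.min_location,
        hairpin_f=float(fh),
        open_f=float(fo),
    )


def convergence_diagnostic(
    hills: HillsLog,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    min_barrier: float = 1.0,
) -> dict:
    """Last-half versus full comparison of the reconstructed surface.

    Reconstructs the FES from the full log and from the log truncated at
    half the final deposition time, and reports the RMS difference (after
    aligning the additive offsets) over the region the half-time log has
    already sampled — nodes where its bias exceeds 5% of its maximum;
    comparing in newly explored territory would conflate convergence with
    coverage. When both surfaces resolve two basins, the change in the
    hairpin/open delta G is reported as well.
    """
    if len(hills) < 8:
        raise ValueError("too few hills for a convergence diagnostic")
    if grid is None:
        grid = grid_from_hills(hills)
    half = hills.until_time(hills.time[-1] / 2.0)
    fes_full = reconstruct_fes(hills, grid=grid)
    fes_half = reconstruct_fes(half, grid=grid)
    bias_half = sum_hills(half, grid)
    region = bias_half > 0.05 * bias_half.max()
    diff = fes_full.free_energy - fes_half.free_energy
    diff = diff - diff[region].mean()
    out = {
        "fes_rms_kcal": float(np.sqrt(np.mean(diff[region] ** 2))),
        "delta_g_change_kcal": None,
    }
    try:
        dg_full = basin_delta_g(fes_full, **_two_basins(fes_full, min_barrier)).delta_g
        dg_half = basin_delta_g(fes_half, **_two_basins(fes_half, min_barrier)).delta_g
        out["delta_g_change_kcal"] = float(dg_full - dg_half)
    except ValueError:
        pass
    return out


def _two_basins(fes: FESGrid, min_barrier: float) -> dict:
    named = label_stem_basins(find_basins(fes, min_barrier=min_barrier))
    return {"basin_hairpin": named["hairpin"], "basin_open": named["open"]}


def recover_delta_g(
    potential: ToyPotential | None = None,
    params: MetadParams | None = None,
    settings: LangevinSettings | None = None,
    chunk_steps: int = 200_000,
    max_chunks: int = 12,
    tol_kcal: float = 0.25,
    min_barrier: float = 1.0,
    grid_shape: tuple[int, int] = (200, 200),
) -> dict:
    """Run well-tempered metadynamics until the basin delta G stabilises.

    Extends the simulation in chunks; after each chunk the FES is
    reconstructed (checkpoint-averaged) and the hairpin/open delta G
    compared between the half-time and full logs. The run stops once the
    change falls below ``tol_kcal`` (and at least two chunks have run), or
    at ``max_chunks``. Returns a report dict with the delta G, convergence
    history, and the objects needed for further analysis.
    """
    potential = potential or ToyPotential.hairpin_landscape()
    params = params or MetadParams()
    settings = settings or LangevinSettings(seed=1)
    sampler = MetadSampler(potential, params, settings)
    history: list[dict] = []
    converged = False
    report = None
    fes = None
    for chunk in range(1, max_chunks + 1):
        sampler.run(chunk_steps)
        hills = sampler.hills
        if len(hills) < 8:
            continue
        grid = grid_from_hills(hills, shape=grid_shape)
        fes = reconstruct_fes(hills, grid=grid)
        try:
            kwargs = _two_basins(fes, min_barrier)
            report = basin_delta_g(fes, **kwargs)
        except ValueError:
            history.append({"chunk": chunk, "delta_g": None, "half_full_change": None})
            continue
        half = hills.until_time(hills.time[-1] / 2.0)
        change = None
        if len(half) >= 8:
            try:
                fes_half = reconstruct_fes(half, grid=grid)
                dg_half = basin_delta_g(fes_half, **_two_basins(fes_half, min_barrier)).delta_g
                change = report.delta_g - dg_half
            except ValueError:
                change = None
        history.append(
            {"chunk": chunk, "delta_g": report.delta_g, "half_full_change": change}
        )
        if chunk >= 2 and change is not None and abs(change) < tol_kcal:
            converged = True
            break
    return {
        "delta_g_kcal": report.delta_g if report else None,
        "report": report,
        "fes": fes,
        "hills": sampler.hills,
        "converged": converged,
        "history": history,
        "n_steps": sampler.n_steps,
        "n_hills": len(sampler.hills),
    }
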
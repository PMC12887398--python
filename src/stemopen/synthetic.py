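"""Seeded generators for every pipeline input.

Each generator encodes exactly the statistical structure the matching
analysis stage assumes, so the whole pipeline is testable without any
experimental download:

* titrations — two-state binding with ligand depletion plus i.i.d. Gaussian
  read noise;
* melts — two-state van't Hoff transition on linear baselines with a
  multiplicative thermal-quenching ramp;
* NMR shift tables — fast-exchange population averaging, with perturbations
  confined to a chosen residue set;
* hairpin conformers — deterministic parametric closed/open geometries of
  the 15-mer (backbone atoms + a base-centroid pseudo-atom per residue),
  built for controllable contact/separation structure rather than realistic
  A-form geometry;
* a toy landscape + seeded sampler for hills schedules lives in
  :mod:`stemopen.metad`.

Every generator is a pure function of its arguments and the seed in its
:class:`NoiseSpec`; sd = 0 outputs lie exactly on the model curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .binding import BindingTruth, TitrationSeries, fraction_bound, predict_observable
from .melt import MeltCurve, MeltTruth, melt_model
from .csp import ShiftTable
from .structure import CENTROID_ATOM, Conformer, N_RESIDUES

import pandas as pd

__all__ = [
    "NoiseSpec",
    "ShiftPerturbationSpec",
    "HairpinGeometry",
    "BindingTruth",
    "MeltTruth",
    "gen_titration",
    "gen_melt",
    "gen_melt_dose_series",
    "gen_apo_shifts",
    "gen_shift_tables",
    "gen_hairpin_conformer",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian i.i.d. read noise: standard deviation in observable units."""

    sd: float = 0.0
    seed: int = 0
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.kind != "gaussian":
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("noise sd must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.sd == 0:
            return np.asarray(values, float).copy()
        return values + self.rng().normal(0.0, self.sd, size=np.shape(values))


def gen_titration(
    truth: BindingTruth,
    titrant_concs: Sequence[float] | np.ndarray,
    noise: NoiseSpec = NoiseSpec(),
) -> TitrationSeries:
    """Synthetic titration on the ligand-depletion isotherm."""
    concs = np.asarray(titrant_concs, dtype=float)
    if np.any(concs < 0):
        raise ValueError("titrant concentrations must be nonnegative")
    if np.any(np.diff(concs) < 0):
        raise ValueError("titrant concentrations must be sorted")
    obs = noise.apply(predict_observable(truth, concs))
    return TitrationSeries(
        concs,
        obs,
        truth.probe_total,
        truth.obs_kind,
        meta={
            "true_kd": truth.kd,
            "true_obs_free": truth.obs_free,
            "true_obs_bound": truth.obs_bound,
            "noise_sd": noise.sd,
            "noise_seed": noise.seed,
        },
    )


def gen_melt(
    truth: MeltTruth,
    temps: Sequence[float] | np.ndarray,
    noise: NoiseSpec = NoiseSpec(),
    condition: str = "0",
) -> MeltCurve:
    """Synthetic melt curve on the two-state model (heating scans map the
    instrument's 1 degC/min ramp onto the supplied temperature grid)."""
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError("empty temperature grid")
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperatures must be sorted ascending")
    signal = noise.apply(melt_model(temps, truth))
    return MeltCurve(temps, signal, condition)


def gen_melt_dose_series(
    truth: MeltTruth,
    doses_nm: Sequence[float],
    kd_nm: float,
    probe_total_nm: float,
    temps: Sequence[float] | np.ndarray,
    noise: NoiseSpec = NoiseSpec(),
) -> list[MeltCurve]:
    """Melt curves across protein doses: the hairpin-opening protein removes
    a fraction fb(dose) of the folded population, scaling the transition
    amplitude by 1 - fb while leaving Tm unchanged."""
    curves = []
    for i, dose in enumerate(doses_nm):
        fb = fraction_bound(dose, probe_total_nm, kd_nm)
        bf = truth.baseline_folded
        bu = truth.baseline_unfolded
        scaled = MeltTruth(
            tm=truth.tm,
            dh_vh=truth.dh_vh,
            baseline_folded=bf,
            baseline_unfolded=(
                bf[0] + (1.0 - fb) * (bu[0] - bf[0]),
                bf[1] + (1.0 - fb) * (bu[1] - bf[1]),
            ),
            quench_slope=truth.quench_slope,
        )
        sub_noise = NoiseSpec(noise.sd, noise.seed + i) if noise.sd else noise
        curves.append(gen_melt(scaled, temps, sub_noise, condition=f"{dose:g}"))
    return curves


# --- NMR shift tables -------------------------------------------------------


@dataclass(frozen=True)
class ShiftPerturbationSpec:
    """Ground truth of a fast-exchange titration of a protein by RNA.

    ``dh_bound``/``dn_bound`` are the fully-bound ppm offsets for each
    perturbed residue (zero implied for every other residue); ``ratios``
    are the RNA:protein molar ratios of the titration points;
    ``protein_total`` and ``kd`` are in uM.
    """

    perturbed_residues: tuple[int, ...] = (84, 85, 86, 100, 101)
    dh_bound: tuple[float, ...] = (0.18, -0.22, 0.15, 0.25, -0.20)
    dn_bound: tuple[float, ...] = (0.9, -1.2, 0.8, 1.5, -1.0)
    ratios: tuple[float, ...] = (0.6, 1.2, 1.9, 2.5, 3.8, 5.0, 10.1)
    protein_total: float = 68.0
    kd: float = 0.024

    def __post_init__(self) -> None:
        n = len(self.perturbed_residues)
        if len(self.dh_bound) != n or len(self.dn_bound) != n:
            raise ValueError("offset lists must match perturbed_residues")
        if any(b <= a for a, b in zip(self.ratios, self.ratios[1:])):
            raise ValueError("ratios must be strictly increasing")
        if self.protein_total <= 0 or self.kd <= 0:
            raise ValueError("protein_total and kd must be positive")


def gen_apo_shifts(
    residues: Sequence[int] | None = None,
    seed: int = 0,
) -> ShiftTable:
    """Plausible apo amide shift table (synthetic stand-in for a published
    assignment set): 1H uniform in 7.2-9.4 ppm, 15N in 105-130 ppm."""
    if residues is None:
        residues = range(2, 167)  # residue 1 has no amide
    residues = sorted(int(r) for r in residues)
    rng = np.random.default_rng(seed)
    aa = "ACDEFGHIKLMNQRSTVWY"
    data = pd.DataFrame(
        {
            "residue_id": residues,
            "residue_name": [aa[rng.integers(len(aa))] for _ in residues],
            "dH_ppm": rng.uniform(7.2, 9.4, len(residues)).round(4),
            "dN_ppm": rng.uniform(105.0, 130.0, len(residues)).round(4),
        }
    )
    return ShiftTable(data, state="apo")


def gen_shift_tables(
    spec: ShiftPerturbationSpec,
    apo: ShiftTable,
    noise: NoiseSpec = NoiseSpec(),
) -> list[ShiftTable]:
    """Fast-exchange titration tables: one per ratio, plus the apo table.

    At each titration point the observed shift is the population average
    delta = (1 - fb) * delta_apo + fb * delta_bound, with the protein bound
    fraction fb from the ligand-depletion isotherm at that point's total RNA
    concentration (ratio * protein_total). Noise (if any) is added to both
    dimensions independently per table.
    """
    apo_idx = apo.indexed()
    missing = [r for r in spec.perturbed_residues if r not in apo_idx.index]
    if missing:
        raise ValueError(f"perturbed residues {missing} absent from the apo table")
    rng = noise.rng()
    tables = [apo]
    dh_off = pd.Series(0.0, index=apo_idx.index)
    dn_off = pd.Series(0.0, index=apo_idx.index)
    for r, dh, dn in zip(spec.perturbed_residues, spec.dh_bound, spec.dn_bound):
        dh_off[r] = dh
        dn_off[r] = dn
    for ratio in spec.ratios:
        rna_total = ratio * spec.protein_total
        fb = fraction_bound(rna_total, spec.protein_total, spec.kd)
        df = apo.data.copy()
        df["dH_ppm"] = apo_idx["dH_ppm"].to_numpy() + fb * dh_off.to_numpy()
        df["dN_ppm"] = apo_idx["dN_ppm"].to_numpy() + fb * dn_off.to_numpy()
        if noise.sd:
            df["dH_ppm"] += rng.normal(0, noise.sd, len(df))
            df["dN_ppm"] += rng.normal(0, noise.sd, len(df))
        tables.append(ShiftTable(df, state=f"{ratio:g}"))
    return tables


# --- Hairpin conformers -----------------------------------------------------


@dataclass(frozen=True)
class HairpinGeometry:
    """Parameters of the deterministic toy hairpin geometry (angstrom)."""

    contact_distance: float = 3.0  # closed-state inter-strand centre spacing
    rise: float = 6.0  # per-residue rise along the stem axis
    loop_radius: float = 6.0
    open_separation: float = 30.0  # open-state displacement of the 3' strand


# fixed intra-residue atom offsets (same template every residue), angstrom
_ATOM_TEMPLATE: tuple[tuple[str, str, tuple[float, float, float]], ...] = (
    ("P", "P", (-0.80, 0.60, 0.00)),
    ("O5'", "O", (-0.40, -0.60, 0.40)),
    ("C5'", "C", (0.00, 0.50, -0.50)),
    ("C4'", "C", (0.30, -0.40, 0.30)),
    ("C3'", "C", (0.60, 0.30, -0.30)),
    ("O3'", "O", (0.90, -0.20, 0.20)),
    (CENTROID_ATOM, "C", (0.00, 0.00, 0.00)),
)


def _residue_centers(state: str, geom: HairpinGeometry) -> np.ndarray:
    d = geom.contact_distance
    rise = geom.rise
    centers = np.zeros((N_RESIDUES, 3))
    # 5' stem strand: residues 1-4 along +z
    for i in range(1, 5):
        centers[i - 1] = (0.0, 0.0, (i - 1) * rise)
    # loop residues 5-11 on an arc above the stem
    arc_c = np.array([d / 2.0, 0.0, 3 * rise + geom.loop_radius])
    for k, i in enumerate(range(5, 12)):
        theta = math.pi * (1.0 - (k + 1) / 8.0)
        centers[i - 1] = arc_c + np.array(
            [-(geom.loop_radius + d / 2.0) * math.cos(theta), 0.0,
             geom.loop_radius * math.sin(theta)]
        )
    if state == "closed":
        # 3' strand: residue 16-i pairs residue i at the contact distance
        for i in range(1, 5):
            centers[(16 - i) - 1] = (d, 0.0, (i - 1) * rise)
    else:
        # stem dissociated: 3' strand swung far out along +x
        for i in range(1, 5):
            centers[(16 - i) - 1] = (
                geom.open_separation + (4 - i) * rise,
                0.0,
                2 * rise,
            )
    return centers


def gen_hairpin_conformer(
    state: str, geometry: HairpinGeometry = HairpinGeometry()
) -> Conformer:
    """Idealised closed (stem paired) or open (stem dissociated) conformer.

    Closed: residues 1-4 pair 15-12 with inter-group heavy-atom contacts
    near ``contact_distance``; open: the 3' stem groups sit more than
    ``open_separation`` - 2 A from the 5' groups. Geometry is deterministic
    and exactly reproducible; the loop is arbitrary but fixed.
    """
    if state not in ("closed", "open"):
        raise ValueError(f"unknown hairpin state {state!r}; expected 'closed' or 'open'")
    centers = _residue_centers(state, geometry)
    names: list[str] = []
    rids: list[int] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    for i in range(1, N_RESIDUES + 1):
        for name, element, offset in _ATOM_TEMPLATE:
            if name == "P" and i == 1:
                continue  # 5' terminus carries no phosphate
            names.append(name)
            rids.append(i)
            elements.append(element)
            coords.append(centers[i - 1] + np.array(offset))
    return Conformer(names, np.array(rids), elements, np.array(coords), label=state)
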
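"""Amide chemical-shift-perturbation (CSP) mapping for a protein titration.

The combined perturbation of an amide group between two states is

    CSP = sqrt(ddH^2 + ddN^2 / 36),

where ddH and ddN are the 1H and 15N shift changes in ppm; the 1/36 factor
(i.e. dividing the nitrogen axis by 6) compensates the wider 15N dispersion,
making the CSP the Euclidean norm of (ddH, ddN/6).

Residues are flagged as perturbed by a mean + n*SD threshold over all CSPs,
iterated once after removing the first-pass outliers so that a few strongly
shifted residues do not inflate the background statistics. Missing residues
(prolines, unassigned amides, exchange-broadened peaks) propagate as missing
rather than zero — zero would masquerade as "unperturbed".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ShiftTable",
    "CSPResult",
    "compute_csp",
    "track_titration",
    "flag_perturbed",
]

_COLUMNS = ["residue_id", "residue_name", "dH_ppm", "dN_ppm"]


@dataclass
class ShiftTable:
    """Per-residue amide shifts for one titration state.

    ``data`` columns: residue_id (int), residue_name (str), dH_ppm, dN_ppm.
    ``state`` labels the point: "apo" or the RNA:protein molar ratio.
    """

    data: pd.DataFrame
    state: str = "apo"

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"shift table missing columns {missing}")
        self.data = self.data[_COLUMNS].copy()
        self.data["residue_id"] = self.data["residue_id"].astype(int)
        if self.data["residue_id"].duplicated().any():
            dup = self.data.loc[self.data["residue_id"].duplicated(), "residue_id"].tolist()
            raise ValueError(f"duplicate residue ids {dup}")
        if self.data[["dH_ppm", "dN_ppm"]].isna().any().any():
            raise ValueError("both dH and dN must be present for every listed residue")

    @property
    def residues(self) -> set[int]:
        return set(self.data["residue_id"].tolist())

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("residue_id")

    def write_csv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("residue_id,residue_name,dH_ppm,dN_ppm,state\n")
            for _, row in self.data.iterrows():
                fh.write(
                    f"{int(row.residue_id)},{row.residue_name},"
                    f"{row.dH_ppm:.6f},{row.dN_ppm:.6f},{self.state}\n"
                )

    @classmethod
    def read_csv(cls, path: str | Path) -> "ShiftTable":
        df = pd.read_csv(path)
        state = str(df["state"].iloc[0]) if "state" in df.columns and len(df) else "apo"
        return cls(df[_COLUMNS], state=state)


@dataclass
class CSPResult:
    """Per-residue CSP magnitudes relative to a reference state."""

    csp: pd.Series  # indexed by residue_id, ppm
    flagged: set[int]
    threshold: float
    reference_state: str
    comparison_state: str
    missing: set[int] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        df = self.csp.rename("csp_ppm").to_frame()
        df["flagged"] = [r in self.flagged for r in df.index]
        return df


def _csp_magnitude(ddh: np.ndarray, ddn: np.ndarray) -> np.ndarray:
    return np.sqrt(ddh**2 + ddn**2 / 36.0)


def compute_csp(
    apo: ShiftTable,
    bound: ShiftTable,
    rule: str = "mean_sd",
    n_sigma: float = 1.0,
) -> CSPResult:
    """CSP of every residue common to both tables, with perturbed-set flagging.

    Residues present in only one table are reported in ``missing`` (never
    imputed as zero). Flagging follows :func:`flag_perturbed`.
    """
    a = apo.indexed()
    b = bound.indexed()
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("shift tables share no residues")
    ddh = (b.loc[common, "dH_ppm"] - a.loc[common, "dH_ppm"]).to_numpy()
    ddn = (b.loc[common, "dN_ppm"] - a.loc[common, "dN_ppm"]).to_numpy()
    csp = pd.Series(_csp_magnitude(ddh, ddn), index=common, name="csp_ppm").sort_index()
    missing = (apo.residues | bound.residues) - set(common.tolist())
    result = CSPResult(
        csp=csp,
        flagged=set(),
        threshold=float("nan"),
        reference_state=apo.state,
        comparison_state=bound.state,
        missing=missing,
    )
    result.flagged = flag_perturbed(result, rule=rule, n_sigma=n_sigma)
    return result


def flag_perturbed(
    result: "CSPResult | pd.Series",
    rule: str = "mean_sd",
    n_sigma: float = 1.0,
) -> set[int]:
    """Residues whose CSP exceeds the background threshold.

    Rule ``"mean_sd"``: threshold = mean + n_sigma*SD over all CSPs,
    recomputed once after removing the residues flagged in the first pass
    (one outlier-rejection iteration). Deterministic and order-independent.
    If every CSP is equal the SD is zero and nothing exceeds the mean, so
    the flagged set is empty. The final threshold is written back onto a
    CSPResult input.
    """
    if rule != "mean_sd":
        raise ValueError(f"unknown flagging rule {rule!r}")
    csp = result.csp if isinstance(result, CSPResult) else result
    if len(csp) < 5:
        raise ValueError("need at least 5 residues to estimate a background")
    values = csp.to_numpy(dtype=float)

    def threshold_of(v: np.ndarray) -> float:
        return float(np.mean(v) + n_sigma * np.std(v, ddof=0))

    thr = threshold_of(values)
    keep = values <= thr
    if keep.any() and not keep.all():
        thr = threshold_of(values[keep])
    flagged = set(csp.index[values > thr].tolist())
    if isinstance(result, CSPResult):
        result.threshold = thr
    return flagged


def track_titration(
    tables: Sequence[ShiftTable],
    monotone_tol: float = 0.0,
) -> pd.DataFrame:
    """CSP trajectories versus the apo state across a titration series.

    ``tables`` must contain exactly one table with state ``"apo"``; the rest
    are titration points whose states parse as molar ratios and are sorted
    ascending. Returns a DataFrame (rows: residue_id, columns: ratio) of CSP
    values; per-residue monotonicity diagnostics (is the trajectory
    nondecreasing within ``monotone_tol`` ppm?) are stored in
    ``df.attrs["monotone"]`` as a boolean Series.
    """
    apo = [t for t in tables if t.state == "apo"]
    if len(apo) != 1:
        raise ValueError("exactly one apo table required")
    apo_table = apo[0]
    points = [t for t in tables if t is not apo_table]
    if not points:
        raise ValueError("no titration points supplied")
    try:
        ratios = [float(t.state) for t in points]
    except ValueError as exc:
        raise ValueError("titration states must parse as molar ratios") from exc
    order = np.argsort(ratios)

    cols = {}
    for i in order:
        res = compute_csp(apo_table, points[i])
        cols[ratios[i]] = res.csp
    df = pd.DataFrame(cols).sort_index()
    traj = df.to_numpy()
    monotone = (np.diff(traj, axis=1) >= -monotone_tol).all(axis=1)
    # plain dict: pandas propagates .attrs through operations and requires
    # them to be equality-comparable
    df.attrs["monotone"] = dict(zip(df.index.tolist(), monotone.tolist()))
    return df


def write_csp_table(result: CSPResult, path: str | Path) -> None:
    """CSP bar-table: residue, CSP, flag — the plottable Fig-style output."""
    with Path(path).open("w") as fh:
        fh.write(f"# reference_state = {result.reference_state}\n")
        fh.write(f"# comparison_state = {result.comparison_state}\n")
        fh.write(f"# threshold_ppm = {result.threshold:.6f}\n")
        if result.missing:
            fh.write(f"# missing_residues = {sorted(result.missing)}\n")
        fh.write("residue_id,csp_ppm,flagged\n")
        for rid, val in result.csp.items():
            fh.write(f"{rid},{val:.6f},{int(rid in result.flagged)}\n")
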
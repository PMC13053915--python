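"""Readers and writers for the package's tabular dialects.

All tables are tab-separated text.  Dialects:

decay series      residue_id, delay_s, intensity, sigma
CPMG dispersion   residue_id, nu_cpmg_hz, intensity, sigma
                  (nu_cpmg_hz = 0 marks reference planes; duplicates allowed)
NOE pairs         residue_id, experiment (sat|ref), intensity, sigma
fitted rates      residue_id, observable, value, sigma, quality, model
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exchange import DispersionCurve
from .relax import DecaySeries, NoePair, compute_r2eff

__all__ = [
    "read_decay_series",
    "read_dispersion_curves",
    "read_noe_pairs",
    "write_table",
]

FLOAT_FMT = "%.8g"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _read(path: str | Path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_decay_series(path: str | Path) -> list[DecaySeries]:
    """Load per-residue relaxation decay series from one table."""
    df = _read(path, {"residue_id", "delay_s", "intensity", "sigma"})
    out = []
    for rid, grp in df.groupby("residue_id", sort=True):
        out.append(
            DecaySeries(
                residue_id=int(rid),
                delays=grp["delay_s"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                sigma_i=float(grp["sigma"].iloc[0]),
            )
        )
    return out


def read_dispersion_curves(
    path: str | Path, t_relax: float
) -> list[DispersionCurve]:
    """Load CPMG intensity tables and convert planes to R2eff.

    Reference planes (nu = 0) are averaged per residue; their uncertainty
    enters every R2eff through first-order propagation.  Planes with
    non-positive intensity are dropped.
    """
    df = _read(path, {"residue_id", "nu_cpmg_hz", "intensity", "sigma"})
    curves = []
    for rid, grp in df.groupby("residue_id", sort=True):
        refs = grp[grp["nu_cpmg_hz"] == 0]
        planes = grp[grp["nu_cpmg_hz"] > 0]
        if refs.empty:
            raise ValueError(f"residue {rid}: no reference plane (nu = 0)")
        i0 = float(refs["intensity"].mean())
        sigma_i0 = float(refs["sigma"].iloc[0]) / np.sqrt(len(refs))
        if i0 <= 0:
            continue
        nu, r2, sig = [], [], []
        for row in planes.itertuples():
            if row.intensity <= 0:
                continue  # plane lost to noise
            est = compute_r2eff(row.intensity, i0, t_relax, row.sigma, sigma_i0)
            nu.append(row.nu_cpmg_hz)
            r2.append(est.value)
            sig.append(est.sigma)
        if nu:
            curves.append(DispersionCurve(int(rid), np.array(nu),
                                          np.array(r2), np.array(sig)))
    return curves


def read_noe_pairs(path: str | Path) -> list[NoePair]:
    df = _read(path, {"residue_id", "experiment", "intensity", "sigma"})
    pairs = []
    for rid, grp in df.groupby("residue_id", sort=True):
        sat = grp[grp["experiment"] == "sat"]
        ref = grp[grp["experiment"] == "ref"]
        if sat.empty or ref.empty:
            raise ValueError(f"residue {rid}: need both sat and ref rows")
        pairs.append(
            NoePair(
                residue_id=int(rid),
                i_sat=float(sat["intensity"].iloc[0]),
                i_ref=float(ref["intensity"].iloc[0]),
                sigma_sat=float(sat["sigma"].iloc[0]),
                sigma_ref=float(ref["sigma"].iloc[0]),
            )
        )
    return pairs
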
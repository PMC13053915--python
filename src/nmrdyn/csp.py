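"""Chemical-shift perturbation analysis of assigned 1H-15N peak lists.

Matches peaks between two ligand states by residue assignment, computes the
combined-shift perturbation, flags residues whose peaks disappear (exchange
broadening) or appear, and derives the k-sigma significance threshold.

The CSP statistic is

    CSP = sqrt( (d_dH)^2 + (d_dN)^2 / n_weight )

with the 15N difference down-weighted by ``n_weight`` (default 10, i.e. the
nitrogen axis compressed by sqrt(10)).  Some groups instead use
(d_dN / alpha)^2; both dialects are expressible through ``n_weight``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "CspRecord",
    "match_peaks",
    "compute_csp",
    "significance_threshold",
    "read_peaklist",
    "read_sparky_list",
    "write_peaklist",
    "csp_table",
]


@dataclass
class Peak:
    residue_id: int
    residue_name: str
    delta_h: float  # ppm
    delta_n: float  # ppm
    intensity: float = 1.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.residue_id < 1:
            raise ValueError("residue_id must be >= 1")
        if not (np.isfinite(self.delta_h) and np.isfinite(self.delta_n)):
            raise ValueError("chemical shifts must be finite")


@dataclass
class CspRecord:
    residue_id: int
    status: str  # "matched" | "disappeared" | "appeared"
    csp: float | None = None  # ppm, defined only for matched
    significant: bool = False


def compute_csp(
    dh_a: float, dn_a: float, dh_b: float, dn_b: float, n_weight: float = 10.0
) -> float:
    """Combined 1H/15N shift perturbation between two states (ppm)."""
    if n_weight <= 0:
        raise ValueError("n_weight must be positive")
    ddh = dh_a - dh_b
    ddn = dn_a - dn_b
    return float(np.sqrt(ddh * ddh + ddn * ddn / n_weight))


def match_peaks(list_a: list[Peak], list_b: list[Peak]) -> list[CspRecord]:
    """Pair peaks by residue assignment and call disappearances.

    Residues present only in state A are "disappeared" (broadened beyond
    detection on binding), present only in B "appeared".  Duplicate
    assignments within one list are an input error.
    """
    a_by_id = {p.residue_id: p for p in list_a}
    b_by_id = {p.residue_id: p for p in list_b}
    if len(a_by_id) != len(list_a) or len(b_by_id) != len(list_b):
        raise ValueError("duplicate residue_id within a peak list")
    records = []
    for rid in sorted(set(a_by_id) | set(b_by_id)):
        if rid in a_by_id and rid in b_by_id:
            pa, pb = a_by_id[rid], b_by_id[rid]
            records.append(CspRecord(rid, "matched",
                                     compute_csp(pa.delta_h, pa.delta_n,
                                                 pb.delta_h, pb.delta_n)))
        elif rid in a_by_id:
            records.append(CspRecord(rid, "disappeared"))
        else:
            records.append(CspRecord(rid, "appeared"))
    return records


def significance_threshold(csps, k: float = 2.0, trim: bool = False) -> float:
    """k-sigma threshold over the CSP distribution (ppm).

    ``trim=True`` iteratively excludes values beyond the current threshold
    until convergence (a common variant); the default uses all matched
    residues, no exclusion.
    """
    csps = np.asarray([c for c in csps if c is not None and np.isfinite(c)])
    if len(csps) < 5:
        raise ValueError("need >= 5 matched records for a threshold")
    if k <= 0:
        raise ValueError("k must be positive")
    if not trim:
        return float(k * np.std(csps, ddof=1))
    kept = csps
    for _ in range(100):
        thr = k * np.std(kept, ddof=1)
        new = csps[csps <= thr]
        if len(new) < 5 or len(new) == len(kept):
            break
        kept = new
    return float(k * np.std(kept, ddof=1))


def csp_table(
    records: list[CspRecord], k: float = 2.0, trim: bool = False
) -> pd.DataFrame:
    """Flag significant CSPs and assemble the per-residue table."""
    matched = [r.csp for r in records if r.status == "matched"]
    thr = significance_threshold(matched, k=k, trim=trim)
    rows = []
    for r in records:
        sig = r.status == "matched" and thr > 0 and r.csp > thr
        r.significant = bool(sig)
        rows.append({"residue_id": r.residue_id, "status": r.status,
                     "csp_ppm": r.csp if r.csp is not None else np.nan,
                     "significant": bool(sig)})
    df = pd.DataFrame(rows)
    df.attrs["threshold_ppm"] = thr
    return df


# ---------------------------------------------------------------- file I/O

_PEAK_COLUMNS = ["residue_id", "residue_name", "delta_h_ppm", "delta_n_ppm",
                 "intensity", "sigma"]


def read_peaklist(path: str | Path) -> list[Peak]:
    """Read the package's tab-separated peak-list dialect."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak list {path} missing columns: {sorted(missing)}")
    return [
        Peak(int(r.residue_id), str(r.residue_name), float(r.delta_h_ppm),
             float(r.delta_n_ppm), float(r.intensity), float(r.sigma))
        for r in df.itertuples()
    ]


def write_peaklist(peaks: list[Peak], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"residue_id": p.residue_id, "residue_name": p.residue_name,
             "delta_h_ppm": p.delta_h, "delta_n_ppm": p.delta_n,
             "intensity": p.intensity, "sigma": p.sigma}
            for p in peaks
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


# e.g. "V102N-H", "E328NH", "LEU75N-H": residue letters, number, atom names
_SPARKY_ASSIGN = re.compile(r"^([A-Za-z]{1,3}?)(\d+)[A-Za-z0-9\-]*$")


def read_sparky_list(path: str | Path) -> list[Peak]:
    """Read a Sparky-style assigned peak list.

    Expected layout: header line, then one peak per line,
    ``assignment  w1(15N)  w2(1H)  [height]``, with assignments like
    ``V102N-H``.  Unassigned peaks (``?-?``) are skipped.
    """
    peaks = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) < 3 or parts[0].lower() in ("assignment",):
            continue
        m = _SPARKY_ASSIGN.match(parts[0])
        if not m:
            continue
        resname, resid = m.group(1), int(m.group(2))
        w1, w2 = float(parts[1]), float(parts[2])
        height = float(parts[3]) if len(parts) > 3 else 1.0
        peaks.append(Peak(resid, resname.upper(), delta_h=w2, delta_n=w1,
                          intensity=height))
    if not peaks:
        raise ValueError(f"no assigned peaks parsed from {path}")
    return peaks
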
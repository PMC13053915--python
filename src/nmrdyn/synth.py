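"""Synthetic two-state NMR dynamics study with planted ground truth.

Generates everything the analysis pipeline consumes — a toy structure,
assigned peak lists, R1/R2 decay series, constant-time CPMG dispersion
tables, and hetNOE pairs for an "apo" and a "bound" state — from a single
seeded ground truth.

The planted perturbation emulates the qualitative signature of allosteric
ligand binding to a kinase-like target: effects largest at a contiguous
ligand site, decaying exponentially with Cα distance from it, plus a sparse
set of distal "network" residues that feel the full effect regardless of
distance; a subset of residues acquires µs-ms two-site exchange (giving
CPMG-detectable Rex above or below the 7.5 1/s reporting rule) and another
subset broadens beyond detection in the bound state (disappeared peaks).

Defaults (the study conditions): 120 residues, ligand site 95-105, eight
distal network residues, distance decay length 10 Å, intensity noise 1.5%
of the reference intensity, shift noise 0.002/0.010 ppm (1H/15N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .csp import Peak, compute_csp, write_peaklist
from .exchange import CpmgSchedule, ExchangeParams, model_rex, carver_richards
from .io import write_table
from .structure import ResidueSite

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "SyntheticStudy",
    "build_toy_structure",
    "make_ground_truth",
    "plant_allostery",
    "emit_study",
    "DEFAULT_SCHEDULE",
]

#: constant-time CPMG schedule of the synthetic study: 18 frequencies in
#: duplicate at t_relax = 40 ms (maximum 2 kHz refocusing)
DEFAULT_SCHEDULE = CpmgSchedule(
    t_relax=0.04,
    nu_cpmg=tuple(
        np.repeat(
            [25, 50, 75, 100, 125, 150, 200, 250, 300, 400, 500, 600, 700,
             850, 1000, 1250, 1500, 2000], 2
        ).astype(float)
    ),
)

# each delay measured in duplicate (the standard error-estimation scheme)
R1_DELAYS = tuple(np.repeat([0.02, 0.06, 0.12, 0.20, 0.35, 0.50, 0.80, 1.20], 2))
R2_DELAYS = tuple(np.repeat([0.004, 0.008, 0.017, 0.034, 0.051, 0.068, 0.085,
                             0.12], 2))


@dataclass(frozen=True)
class StudyDesign:
    """Planted-effect layout and noise model of the synthetic study."""

    n_res: int = 120
    ligand_site: tuple[int, ...] = tuple(range(95, 106))
    network_residues: tuple[int, ...] = (12, 20, 27, 35, 42, 50, 58, 66)
    #: network members that also acquire exchange in the bound state
    exchange_network: tuple[int, ...] = (12, 27, 42, 58)
    #: pocket-proximal residues that acquire exchange in the bound state
    exchange_pocket: tuple[int, ...] = (91, 93, 94, 98, 106, 107, 108, 109)
    #: residues with weak exchange (Rex below the reporting rule) in both states
    exchange_weak: tuple[int, ...] = (30, 55, 115)
    disappeared: tuple[int, ...] = (96, 100, 102, 104)
    decay_length: float = 10.0  # Å
    # full-size (d = 0) effects, bound minus apo
    effect_dh: float = 0.12  # ppm
    effect_dn: float = -0.50  # ppm
    effect_r1: float = -0.20  # 1/s
    effect_r2: float = 2.5  # 1/s
    effect_noe: float = -0.08
    # two-site exchange process shared by the affected residues
    exchange_p_b: float = 0.05
    exchange_k_ex: float = 1500.0  # 1/s
    #: per-residue |delta_omega| range for strong exchangers (rad/s)
    dw_strong: tuple[float, float] = (700.0, 1100.0)
    dw_weak: tuple[float, float] = (200.0, 280.0)
    # noise model
    noise_intensity: float = 0.015  # fraction of reference intensity
    noise_shift_h: float = 0.002  # ppm
    noise_shift_n: float = 0.010  # ppm
    rex_cutoff: float = 7.5  # 1/s, reporting rule the design is built around


@dataclass
class GroundTruth:
    """Per-residue, per-state true values every emitted file derives from."""

    design: StudyDesign
    sites: list[ResidueSite]
    states: dict[str, pd.DataFrame]  # per state: indexed by residue_id
    schedule: CpmgSchedule

    def exchange_params(self, state: str, residue_id: int) -> ExchangeParams | None:
        row = self.states[state].loc[residue_id]
        if np.isnan(row["dw"]):
            return None
        return ExchangeParams(p_b=row["p_b"], k_ex=row["k_ex"],
                              delta_omega=row["dw"], r2_a=row["r2_0"])

    def rex_above_cutoff(self, state: str) -> set[int]:
        tab = self.states[state]
        return set(tab.index[tab["rex"] > self.design.rex_cutoff])

    def true_csps(self) -> pd.Series:
        """True CSP (apo vs bound) for residues observable in both states."""
        apo, bound = self.states["apo"], self.states["bound"]
        shared = [r for r in apo.index
                  if r in bound.index and r not in self.design.disappeared]
        return pd.Series(
            {
                r: compute_csp(apo.loc[r, "delta_h"], apo.loc[r, "delta_n"],
                               bound.loc[r, "delta_h"], bound.loc[r, "delta_n"])
                for r in shared
            }
        )

    def significant_csp_set(self, k: float = 2.0) -> set[int]:
        csps = self.true_csps()
        thr = k * csps.std(ddof=1)
        return set(csps.index[csps > thr])


@dataclass
class SyntheticStudy:
    out_dir: Path
    rng_seed: int
    design: StudyDesign
    schedule: CpmgSchedule
    truth: GroundTruth
    files: dict[str, Path] = field(default_factory=dict)


def build_toy_structure(
    n_res: int,
    rng: np.random.Generator,
    b_base: float = 20.0,
    b_noise: float = 2.0,
    b_increments: dict[int, float] | None = None,
) -> list[ResidueSite]:
    """Ideal α-helix Cα trace: rise 1.5 Å/residue, 100°/residue, radius 2.3 Å."""
    if n_res < 20:
        raise ValueError("need n_res >= 20")
    sites = []
    for i in range(n_res):
        rid = i + 1
        theta = np.deg2rad(100.0 * i)
        coord = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
        b = b_base + rng.normal(0.0, b_noise)
        if b_increments:
            b += b_increments.get(rid, 0.0)
        sites.append(ResidueSite(rid, "A", coord, round(float(b), 2)))
    return sites


_AA3 = ("ALA", "VAL", "LEU", "ILE", "PHE", "SER", "THR", "ASP", "GLU", "LYS",
        "ARG", "ASN", "GLN", "GLY", "MET", "TYR", "TRP", "HIS")


def make_ground_truth(
    design: StudyDesign = StudyDesign(),
    schedule: CpmgSchedule = DEFAULT_SCHEDULE,
    rng_seed: int = 0,
) -> GroundTruth:
    """Draw apo baselines and plant the bound-state perturbation."""
    rng = np.random.default_rng(rng_seed)
    b_inc = {r: 8.0 for r in design.ligand_site}
    b_inc.update({r: 6.0 for r in design.network_residues})
    sites = build_toy_structure(design.n_res, rng, b_increments=b_inc)

    n = design.n_res
    rids = np.arange(1, n + 1)
    apo = pd.DataFrame(index=rids)
    apo.index.name = "residue_id"
    apo["residue_name"] = rng.choice(_AA3, size=n)
    apo["delta_h"] = rng.normal(8.3, 0.45, n).round(4)
    apo["delta_n"] = rng.normal(119.0, 3.5, n).round(3)
    apo["r1"] = np.clip(rng.normal(1.30, 0.10, n), 0.8, None).round(4)
    apo["r2_0"] = np.clip(rng.normal(12.0, 1.5, n), 6.0, None).round(3)
    noe = np.clip(rng.normal(0.82, 0.03, n), None, 0.93)
    # flexible termini: fast ps-ns motion depresses the NOE
    noe[:3] = (0.35, 0.55, 0.70)
    noe[-3:] = (0.70, 0.55, 0.35)
    apo["noe"] = noe.round(4)
    for col in ("p_b", "k_ex", "dw"):
        apo[col] = np.nan
    # weak exchangers are present already in the apo state
    for rid in design.exchange_weak:
        apo.loc[rid, ["p_b", "k_ex"]] = (design.exchange_p_b, design.exchange_k_ex)
        apo.loc[rid, "dw"] = round(rng.uniform(*design.dw_weak), 1)

    gt = GroundTruth(design=design, sites=sites,
                     states={"apo": apo}, schedule=schedule)
    return plant_allostery(gt, rng)


def plant_allostery(gt: GroundTruth, rng: np.random.Generator) -> GroundTruth:
    """Derive the bound state: distance-decaying local effects plus the
    full-size distal network, exchange for the configured subsets, and
    peak disappearance."""
    design = gt.design
    apo = gt.states["apo"]
    coords = {s.residue_id: s.ca_coord for s in gt.sites}
    missing = [r for r in design.network_residues if r not in coords]
    if missing:
        raise ValueError(f"network residues outside structure: {missing}")

    site_xyz = np.array([coords[r] for r in design.ligand_site])
    bound = apo.copy()
    for rid in apo.index:
        d = float(np.min(np.linalg.norm(site_xyz - coords[rid], axis=1)))
        w = 1.0 if rid in design.network_residues else np.exp(-d / design.decay_length)
        bound.loc[rid, "delta_h"] = apo.loc[rid, "delta_h"] + design.effect_dh * w
        bound.loc[rid, "delta_n"] = apo.loc[rid, "delta_n"] + design.effect_dn * w
        bound.loc[rid, "r1"] = apo.loc[rid, "r1"] + design.effect_r1 * w
        bound.loc[rid, "r2_0"] = apo.loc[rid, "r2_0"] + design.effect_r2 * w
        bound.loc[rid, "noe"] = apo.loc[rid, "noe"] + design.effect_noe * w

    strong = tuple(design.exchange_pocket) + tuple(design.exchange_network)
    for rid in strong:
        bound.loc[rid, ["p_b", "k_ex"]] = (design.exchange_p_b, design.exchange_k_ex)
        bound.loc[rid, "dw"] = round(rng.uniform(*design.dw_strong), 1)

    for state_tab in (apo, bound):
        rex = np.zeros(len(state_tab))
        for i, rid in enumerate(state_tab.index):
            p = gt_params(state_tab, rid)
            if p is not None:
                rex[i] = model_rex(p, gt.schedule)
        state_tab["rex"] = rex.round(4)
    bound["disappeared"] = [r in design.disappeared for r in bound.index]
    apo["disappeared"] = False
    gt.states["bound"] = bound
    return gt


def gt_params(tab: pd.DataFrame, rid: int) -> ExchangeParams | None:
    row = tab.loc[rid]
    if np.isnan(row["dw"]):
        return None
    return ExchangeParams(p_b=float(row["p_b"]), k_ex=float(row["k_ex"]),
                          delta_omega=float(row["dw"]), r2_a=float(row["r2_0"]))


def _write_pdb(sites: list[ResidueSite], names: pd.Series, path: Path) -> None:
    lines = []
    for i, s in enumerate(sites):
        name = names.get(s.residue_id, "ALA")
        lines.append(
            f"ATOM  {i + 1:>5} {'CA':^4}{name:>4} {s.chain_id}{s.residue_id:>4}"
            f"    {s.ca_coord[0]:8.3f}{s.ca_coord[1]:8.3f}{s.ca_coord[2]:8.3f}"
            f"{1.00:6.2f}{s.b_factor:6.2f}          {'C':>2}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def emit_study(
    gt: GroundTruth,
    out_dir: str | Path,
    rng_seed: int = 1,
    noise: float | None = None,
) -> SyntheticStudy:
    """Write every measurement file for both states, plus the structure,
    the ground-truth table and a manifest.  Deterministic per seed."""
    design = gt.design
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)
    noise = design.noise_intensity if noise is None else noise
    schedule = gt.schedule
    study = SyntheticStudy(out, rng_seed, design, schedule, gt)

    for state, tab in gt.states.items():
        observed = tab.index[~tab["disappeared"]]

        peaks = [
            Peak(int(r), str(tab.loc[r, "residue_name"]),
                 float(tab.loc[r, "delta_h"] + rng.normal(0, design.noise_shift_h)
                       if noise > 0 else tab.loc[r, "delta_h"]),
                 float(tab.loc[r, "delta_n"] + rng.normal(0, design.noise_shift_n)
                       if noise > 0 else tab.loc[r, "delta_n"]),
                 intensity=1.0, sigma=noise)
            for r in observed
        ]
        path = out / f"peaks_{state}.tsv"
        write_peaklist(peaks, path)
        study.files[f"peaks_{state}"] = path

        for obs, delays in (("r1", R1_DELAYS), ("r2", R2_DELAYS)):
            rows = []
            for r in observed:
                rate = tab.loc[r, obs if obs == "r1" else "r2_0"]
                if obs == "r2":
                    p = gt_params(tab, r)
                    if p is not None:
                        # 2 kHz refocusing leaves a small residual exchange term
                        rate = carver_richards(p, 2000.0, t_relax=schedule.t_relax)
                for t in delays:
                    ideal = np.exp(-rate * t)
                    val = ideal + (rng.normal(0, noise) if noise > 0 else 0.0)
                    rows.append({"residue_id": r, "delay_s": t,
                                 "intensity": val, "sigma": max(noise, 1e-8)})
            path = out / f"{obs}_decay_{state}.tsv"
            write_table(pd.DataFrame(rows), path)
            study.files[f"{obs}_decay_{state}"] = path

        rows = []
        for r in observed:
            p = gt_params(tab, r)
            if p is None:
                r2eff = np.full(len(schedule.nu_cpmg), tab.loc[r, "r2_0"])
            else:
                r2eff = np.asarray(
                    carver_richards(p, np.array(schedule.nu_cpmg),
                                    t_relax=schedule.t_relax)
                )
            ideal = np.exp(-r2eff * schedule.t_relax)
            for _ in range(2):  # duplicate reference planes
                val = 1.0 + (rng.normal(0, noise) if noise > 0 else 0.0)
                rows.append({"residue_id": r, "nu_cpmg_hz": 0.0,
                             "intensity": val, "sigma": max(noise, 1e-8)})
            for nu, inten in zip(schedule.nu_cpmg, ideal):
                val = inten + (rng.normal(0, noise) if noise > 0 else 0.0)
                rows.append({"residue_id": r, "nu_cpmg_hz": nu,
                             "intensity": val, "sigma": max(noise, 1e-8)})
        path = out / f"cpmg_{state}.tsv"
        write_table(pd.DataFrame(rows), path)
        study.files[f"cpmg_{state}"] = path

        rows = []
        for r in observed:
            ref = 1.0 + (rng.normal(0, noise) if noise > 0 else 0.0)
            sat = tab.loc[r, "noe"] + (rng.normal(0, noise) if noise > 0 else 0.0)
            rows.append({"residue_id": r, "experiment": "sat",
                         "intensity": sat, "sigma": max(noise, 1e-8)})
            rows.append({"residue_id": r, "experiment": "ref",
                         "intensity": ref, "sigma": max(noise, 1e-8)})
        path = out / f"noe_{state}.tsv"
        write_table(pd.DataFrame(rows), path)
        study.files[f"noe_{state}"] = path

    pdb = out / "structure.pdb"
    _write_pdb(gt.sites, gt.states["apo"]["residue_name"], pdb)
    study.files["structure"] = pdb

    truth_path = out / "ground_truth.tsv"
    truth = pd.concat(
        {s: t.drop(columns=["residue_name"]) for s, t in gt.states.items()},
        names=["state"],
    ).reset_index()
    write_table(truth, truth_path)
    study.files["ground_truth"] = truth_path

    manifest = {
        "rng_seed": int(rng_seed),
        "noise_intensity": float(noise),
        "noise_shift_h": design.noise_shift_h,
        "noise_shift_n": design.noise_shift_n,
        "t_relax": schedule.t_relax,
        "nu_cpmg": [float(x) for x in schedule.nu_cpmg],
        "n_res": design.n_res,
        "ligand_site": list(design.ligand_site),
        "network_residues": list(design.network_residues),
        "disappeared": list(design.disappeared),
        "decay_length": design.decay_length,
        "files": {k: str(v.name) for k, v in study.files.items()},
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    study.files["manifest"] = out / "manifest.yaml"
    return study
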
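"""Validation experiments: the quantitative checks behind the package.

Each function runs a self-contained, seeded experiment — oracle
cross-checks of the exchange model, Monte-Carlo calibration of the
estimators, dispersion parameter recovery, end-to-end rule fidelity on the
synthetic study, and the clustering oracle — and returns plain numbers.
The test suite asserts on them and the acceptance script reports them; both
call this one implementation.

Problem sizes are chosen to resolve the quantities being checked while
keeping each experiment in the minutes range on one CPU: 10^4 draws for
sigma calibration, 1000 replicates for fit bias, 200 replicates for
dispersion recovery, 100 random site sets for the clustering oracle.
"""

from __future__ import annotations

import tempfile
from itertools import combinations
from pathlib import Path

import numpy as np

from .compare import REX_CUTOFF
from .exchange import (
    CpmgSchedule,
    ExchangeParams,
    carver_richards,
    luz_meiboom,
    model_rex,
    propagate_cpmg,
    simulate_dispersion,
)
from .pipeline import RunConfig, run_pipeline
from .relax import (
    DecaySeries,
    compute_r2eff,
    fit_dispersion_global,
    fit_monoexponential,
)
from .structure import ResidueSite, cluster_residues
from .synth import DEFAULT_SCHEDULE, StudyDesign, emit_study, make_ground_truth

__all__ = [
    "oracle_agreement",
    "fast_exchange_agreement",
    "degenerate_flatness",
    "estimator_calibration",
    "dispersion_recovery",
    "rule_fidelity",
    "clustering_oracle",
]

REGIME_GRID = {"slow": 200.0, "intermediate": 600.0, "fast": 6000.0}


def oracle_agreement(n_freq: int = 20, t_relax: float = 0.04) -> dict:
    """Closed form vs numerical propagator over three exchange regimes.

    Returns the maximum relative R2eff deviation over a slow/intermediate/
    fast k_ex grid at ``n_freq`` schedule-compatible frequencies.
    """
    step = 1.0 / (2.0 * t_relax)  # pulse-count-compatible frequency spacing
    nus = np.arange(1, n_freq + 1) * step * 2
    nus = nus[nus <= 2000.0]
    worst = 0.0
    for kex in REGIME_GRID.values():
        params = ExchangeParams(p_b=0.03, k_ex=kex, delta_omega=600.0, r2_a=10.0)
        prop = np.array([propagate_cpmg(params, t_relax, nu) for nu in nus])
        closed = np.asarray(carver_richards(params, nus, t_relax=t_relax))
        worst = max(worst, float(np.max(np.abs(closed / prop - 1.0))))
    return {"max_rel_dev": worst, "n": len(nus) * len(REGIME_GRID)}


def fast_exchange_agreement(t_relax: float = 0.04) -> dict:
    """Three-way agreement in the fast-exchange limit (k_ex >= 10 |dw|),
    plus the worked zero-frequency exchange term pA pB dw^2 / kex."""
    params = ExchangeParams(p_b=0.05, k_ex=2000.0, delta_omega=200.0, r2_a=10.0)
    nus = np.array([50.0, 100.0, 250.0, 500.0, 1000.0, 2000.0])
    prop = np.array([propagate_cpmg(params, t_relax, nu) for nu in nus])
    cr = np.asarray(carver_richards(params, nus))
    lm = np.asarray(luz_meiboom(params, nus))
    pair_dev = max(
        float(np.max(np.abs(a / b - 1.0)))
        for a, b in combinations((prop, cr, lm), 2)
    )
    worked = ExchangeParams(p_b=0.05, k_ex=2000.0, delta_omega=600.0, r2_a=10.0)
    rex0 = worked.p_a * worked.p_b * worked.delta_omega**2 / worked.k_ex
    return {"max_pairwise_dev": pair_dev, "rex_zero_freq": float(rex0),
            "n": len(nus)}


def degenerate_flatness(t_relax: float = 0.04) -> dict:
    """Flat-dispersion error for p_b = 0 and for delta_omega = 0."""
    nus = (25.0, 100.0, 500.0, 2000.0)
    no_minor = ExchangeParams(p_b=0.0, k_ex=1000.0, delta_omega=700.0, r2_a=10.0)
    same_shift = ExchangeParams(p_b=0.1, k_ex=1000.0, delta_omega=0.0, r2_a=12.0)
    dev = 0.0
    for params, flat in ((no_minor, 10.0), (same_shift, 12.0)):
        for nu in nus:
            dev = max(dev, abs(propagate_cpmg(params, t_relax, nu) - flat))
    return {"max_abs_dev": dev, "n": 2 * len(nus)}


def estimator_calibration(
    seed: int, n_draws: int = 10_000, n_rep: int = 1000
) -> dict:
    """Monte-Carlo calibration of the two analytic error models.

    (i) compute_r2eff: ratio of the propagated sigma to the empirical sd of
    R2eff over ``n_draws`` intensity-noise draws at 1.5% noise;
    (ii) fit_monoexponential: relative bias of the mean fitted rate over
    ``n_rep`` replicates at 5% intensity noise, 8 delays, R = 15 1/s.
    """
    rng = np.random.default_rng(seed)
    t_relax, r2_true, noise = 0.04, 15.0, 0.015
    i_true = np.exp(-r2_true * t_relax)
    i = i_true + rng.normal(0.0, noise, n_draws)
    i0 = 1.0 + rng.normal(0.0, noise, n_draws)
    r2 = -np.log(i / i0) / t_relax
    empirical_sd = float(r2.std(ddof=1))
    propagated = compute_r2eff(i_true, 1.0, t_relax, noise, noise).sigma
    sigma_ratio = propagated / empirical_sd

    delays = np.array([0.005, 0.012, 0.022, 0.035, 0.05, 0.07, 0.1, 0.15])
    rate_true, fnoise = 15.0, 0.05
    fitted = np.empty(n_rep)
    for k in range(n_rep):
        y = np.exp(-rate_true * delays) + rng.normal(0.0, fnoise, len(delays))
        series = DecaySeries(0, delays, y, fnoise)
        _, rate = fit_monoexponential(series)
        fitted[k] = rate.value
    bias = float(np.nanmean(fitted) / rate_true - 1.0)
    return {"sigma_ratio": sigma_ratio, "monoexp_rel_bias": bias,
            "n": n_draws + n_rep}


#: the dispersion-recovery group: four residues sharing one exchange process
RECOVERY_PB = 0.05
RECOVERY_KEX = 1500.0
RECOVERY_DWS = (800.0, 1200.0, 1600.0, 2000.0)


def dispersion_recovery(seed: int, n_rep: int = 200) -> dict:
    """Parameter recovery of the grouped two-site fit at 1.5% noise.

    Each replicate simulates four dispersion curves sharing (p_b, k_ex)
    with site-specific delta_omega, fits them jointly, and scores: fraction
    of fits with k_ex within 15%, with p_b dw^2 within 10%, and the
    fraction whose 1-sigma Rex interval covers the true Rex.
    """
    schedule = DEFAULT_SCHEDULE
    truths = [ExchangeParams(RECOVERY_PB, RECOVERY_KEX, dw, 10.0)
              for dw in RECOVERY_DWS]
    true_rex = [model_rex(t, schedule) for t in truths]
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 10, size=n_rep)
    n_fit = kex_ok = phi_ok = covered = 0
    for rep_seed in seeds:
        curves = []
        for i, t in enumerate(truths):
            c = simulate_dispersion(t, schedule, 0.015, int(rep_seed) + i)
            c.residue_id = i
            curves.append(c)
        for i, fit in enumerate(fit_dispersion_global(curves, schedule)):
            if fit.model != "two_site":
                continue
            n_fit += 1
            if abs(fit.params.k_ex / RECOVERY_KEX - 1.0) < 0.15:
                kex_ok += 1
            phi = fit.params.p_b * fit.params.delta_omega**2
            if abs(phi / (RECOVERY_PB * RECOVERY_DWS[i] ** 2) - 1.0) < 0.10:
                phi_ok += 1
            if abs(fit.rex.value - true_rex[i]) < fit.rex.sigma:
                covered += 1
    return {
        "kex_within_15pct": kex_ok / n_fit,
        "phi_within_10pct": phi_ok / n_fit,
        "rex_1sigma_coverage": covered / n_fit,
        "n": n_fit,
    }


def _score_sets(got: set, truth: set, universe: set) -> tuple[float, float]:
    sens = len(got & truth) / len(truth) if truth else 1.0
    neg = universe - truth
    spec = len(neg - got) / len(neg) if neg else 1.0
    return sens, spec


def rule_fidelity(seed: int, work_dir: str | Path | None = None) -> dict:
    """End-to-end reporting rules on the default synthetic study.

    Runs the full pipeline twice — at zero noise and at the study's default
    noise — and scores the Rex > 7.5 1/s set, the 2-sigma-significant CSP
    set, the disappeared-peak set and the cluster memberships against the
    planted ground truth.
    """
    tmp_ctx = tempfile.TemporaryDirectory() if work_dir is None else None
    base = Path(tmp_ctx.name if tmp_ctx else work_dir)
    try:
        gt = make_ground_truth(StudyDesign(), DEFAULT_SCHEDULE, rng_seed=seed)
        truth_rex = gt.rex_above_cutoff("bound")
        truth_csp = gt.significant_csp_set()
        truth_dis = set(gt.design.disappeared)
        bound = gt.states["bound"]
        universe = set(bound.index[~bound["disappeared"]])

        out = {}
        for label, noise in (("zero_noise", 0.0), ("default_noise", None)):
            emit_study(gt, base / f"study_{label}", rng_seed=seed, noise=noise)
            res = run_pipeline(RunConfig(input_dir=str(base / f"study_{label}"),
                                         out_dir=str(base / f"out_{label}")))
            rex_sens, rex_spec = _score_sets(res.rex_sets["bound"], truth_rex,
                                             universe)
            csp_sens, csp_spec = _score_sets(res.significant["csp"], truth_csp,
                                             universe)
            got_dis = set(
                res.csp_table.loc[res.csp_table["status"] == "disappeared",
                                  "residue_id"].astype(int)
            )
            clusters_truth = {
                frozenset(cl.members)
                for cl in cluster_residues(truth_csp, gt.sites, cutoff=8.0)
            }
            got_clusters = {
                frozenset(int(m) for m in row.members.split(","))
                for row in res.clusters.itertuples()
                if row.observable == "csp"
            }
            out[label] = {
                "rex_sensitivity": rex_sens, "rex_specificity": rex_spec,
                "csp_sensitivity": csp_sens, "csp_specificity": csp_spec,
                "disappeared_exact": got_dis == truth_dis,
                "clusters_exact": got_clusters == clusters_truth,
                "n_rex_above_cutoff": len(res.rex_sets["bound"]),
                "n_csp_significant": len(res.significant["csp"]),
            }
        out["n_residues"] = gt.design.n_res
        out["rex_cutoff"] = REX_CUTOFF
        return out
    finally:
        if tmp_ctx:
            tmp_ctx.cleanup()


def _brute_force_components(coords: np.ndarray, cutoff: float) -> list[set[int]]:
    """Independent oracle: exhaustive BFS on the thresholded distance graph."""
    n = len(coords)
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        comp, queue = {start}, [start]
        while queue:
            u = queue.pop()
            for v in range(n):
                if v not in comp and np.linalg.norm(coords[u] - coords[v]) <= cutoff:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        comps.append(comp)
    return comps


def clustering_oracle(seed: int, n_sets: int = 100, cutoff: float = 8.0) -> dict:
    """Single-linkage clusters vs brute-force connected components on
    random synthetic site sets; returns the number of mismatching sets."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_sets):
        n = int(rng.integers(2, 40))
        coords = rng.uniform(0.0, 40.0, size=(n, 3))
        sites = [ResidueSite(i + 1, "A", coords[i], 20.0) for i in range(n)]
        got = {
            frozenset(cl.members)
            for cl in cluster_residues(set(range(1, n + 1)), sites, cutoff)
        }
        expected = {
            frozenset(i + 1 for i in comp)
            for comp in _brute_force_components(coords, cutoff)
        }
        if got != expected:
            mismatches += 1
    return {"mismatching_sets": mismatches, "n": n_sets}
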
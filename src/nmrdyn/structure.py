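"""Mapping per-residue scores onto a protein structure.

Reads Cα sites and B-factors from PDB files (via gemmi), normalises
B-factors to per-chain z-scores, groups significant residues into spatial
clusters (single-linkage on the Cα-Cα distance graph, default 8 Å cutoff),
and writes per-residue scores into the temperature-factor column of a PDB
copy for visualisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ResidueSite",
    "Cluster",
    "read_structure",
    "normalize_bfactors",
    "cluster_residues",
    "write_score_structure",
]

#: sentinel written to the B-factor column for residues without a score
UNSCORED_SENTINEL = -1.0


@dataclass
class ResidueSite:
    residue_id: int
    chain_id: str
    ca_coord: np.ndarray  # (3,) Å
    b_factor: float

    def __post_init__(self) -> None:
        self.ca_coord = np.asarray(self.ca_coord, dtype=float)
        if self.ca_coord.shape != (3,) or not np.all(np.isfinite(self.ca_coord)):
            raise ValueError("ca_coord must be a finite 3-vector")


@dataclass
class Cluster:
    members: frozenset[int]
    observable: str
    diameter: float  # largest within-cluster Cα-Cα distance (Å)


def read_structure(path: str | Path, chain: str = "A") -> list[ResidueSite]:
    """One site per residue with a Cα atom, in author numbering.

    Altlocs resolve to the highest-occupancy conformer; residues with
    insertion codes are rejected (renumber upstream rather than guess).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chain_obj = model.find_chain(chain)
    if chain_obj is None:
        raise ValueError(f"chain {chain!r} not found in {path}")
    sites = []
    for res in chain_obj:
        if res.seqid.icode not in ("", " "):
            raise ValueError(
                f"residue {res.seqid.num}{res.seqid.icode} has an insertion "
                "code; renumber the structure before mapping"
            )
        cas = [a for a in res if a.name == "CA"]
        if not cas:
            continue
        ca = max(cas, key=lambda a: a.occ)
        sites.append(
            ResidueSite(
                residue_id=res.seqid.num, chain_id=chain,
                ca_coord=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
                b_factor=float(ca.b_iso),
            )
        )
    if not sites:
        raise ValueError(f"no Cα records in chain {chain!r} of {path}")
    return sites


def normalize_bfactors(sites: list[ResidueSite]) -> dict[int, float]:
    """Per-residue B-factor z-scores over the chain."""
    if len(sites) < 5:
        raise ValueError("need >= 5 sites to normalise")
    b = np.array([s.b_factor for s in sites])
    sd = b.std(ddof=0)
    if sd == 0:
        raise ValueError("zero B-factor variance; z-scores undefined")
    z = (b - b.mean()) / sd
    return {s.residue_id: float(v) for s, v in zip(sites, z)}


def cluster_residues(
    significant: set[int],
    sites: list[ResidueSite],
    cutoff: float = 8.0,
    observable: str = "",
) -> list[Cluster]:
    """Single-linkage spatial clusters of significant residues.

    Two residues are linked iff their Cα-Cα distance is <= cutoff (Å);
    clusters are the connected components of that graph.  Significant
    residues without coordinates are excluded with a warning.
    """
    by_id = {s.residue_id: s for s in sites}
    missing = significant - set(by_id)
    if missing:
        warnings.warn(
            f"significant residues without coordinates excluded: {sorted(missing)}"
        )
    ids = sorted(significant & set(by_id))
    if not ids:
        return []
    coords = np.array([by_id[i].ca_coord for i in ids])
    if len(ids) == 1:
        return [Cluster(frozenset(ids), observable, 0.0)]
    dmat = squareform(pdist(coords))
    adj = csr_matrix(dmat <= cutoff)
    n_comp, labels = connected_components(adj, directed=False)
    clusters = []
    for c in range(n_comp):
        idx = np.where(labels == c)[0]
        members = frozenset(ids[i] for i in idx)
        diameter = float(dmat[np.ix_(idx, idx)].max()) if len(idx) > 1 else 0.0
        clusters.append(Cluster(members, observable, diameter))
    clusters.sort(key=lambda cl: min(cl.members))
    return clusters


def write_score_structure(
    sites: list[ResidueSite],
    scores: dict[int, float],
    template: str | Path,
    out: str | Path,
    chain: str = "A",
) -> None:
    """Write a PDB copy with per-residue scores in the B-factor column.

    Scores use the fixed-width %6.2f temperature-factor field; residues
    without a score receive the sentinel -1.00.  Scores outside the
    representable range are linearly rescaled (and a warning issued) so the
    column never overflows.
    """
    scores = dict(scores)
    finite = [v for v in scores.values() if np.isfinite(v)]
    scale = 1.0
    if finite and (max(finite) > 999.99 or min(finite) < -99.99):
        scale = min(999.99 / max(abs(v) for v in finite), 1.0)
        warnings.warn(f"scores rescaled by {scale:.3g} to fit the B-factor column")
    st = gemmi.read_structure(str(template))
    for model in st:
        ch = model.find_chain(chain)
        if ch is None:
            continue
        for res in ch:
            val = scores.get(res.seqid.num, UNSCORED_SENTINEL)
            if not np.isfinite(val):
                val = UNSCORED_SENTINEL
            for atom in res:
                atom.b_iso = round(val * scale, 2)
    st.write_pdb(str(out))
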
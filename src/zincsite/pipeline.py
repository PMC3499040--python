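"""End-to-end feature extraction: structures + profiles -> FeatureMatrix.

Feature columns use the field's V1..V9 window nomenclature: V5 is always
the centered residue, so e.g. ``Ex_CN_V5`` is the coordination number of
the sample residue itself and ``Net_closen_cent_V9`` the closeness
centrality of the residue four positions downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import exposure as expo
from . import network as net
from .dataset import FeatureMatrix, assemble_matrix
from .pssm import (WINDOW_WIDTH, PSSMProfile, chain_composition,
                   conservation_scores, window_pssm, window_values)
from .structure import (HetContext, ProteinChain, ZincIon, classify_zinc_sites,
                        label_binding_residues, make_sample_set, parse_structure)

#: short column tags for the contact-graph metrics
NET_TAGS = {"degree": "degree", "clustering": "cluster_coef",
            "closeness": "closen_cent", "betweenness": "between_cent",
            "eccentricity": "eccentric", "status": "status",
            "ego_density": "density"}

EXPOSURE_TAGS = {"sasa_total": "SASA", "all_polar_abs": "All_polar_abs",
                 "hbond_count": "Hbplus", "hseau": "Ex_HSEAU",
                 "hsead": "Ex_HSEAD", "hsebu": "Ex_HSEBU", "hsebd": "Ex_HSEBD",
                 "cn": "Ex_CN", "rd": "Ex_RD", "rda": "Ex_RDa"}


@dataclass
class Structure:
    """One parsed structure: polymer chains, zinc ions, het context."""
    chains: list[ProteinChain]
    zincs: list[ZincIon]
    het: HetContext

    @classmethod
    def from_pdb_text(cls, text: str) -> "Structure":
        chains, zincs, het = parse_structure(text)
        return cls(chains, zincs, het)


def collect_samples(structures: list[Structure], cutoff: float = 3.0,
                    co_cat_metal_radius: float = 5.0,
                    co_cat_shell_radius: float = 3.0):
    """Label all structures and pool (residue, label) CHED samples."""
    samples = []
    sites_all = []
    for st in structures:
        binding = label_binding_residues(st.chains, st.zincs, cutoff=cutoff)
        sites = classify_zinc_sites(st.zincs, binding, st.het,
                                    co_cat_metal_radius=co_cat_metal_radius,
                                    co_cat_shell_radius=co_cat_shell_radius)
        samples.extend(make_sample_set(st.chains, sites))
        sites_all.extend(sites)
    return samples, sites_all


def _window_frame(per_pos: np.ndarray, chain: ProteinChain, tag: str,
                  width: int) -> dict[str, dict[str, float]]:
    cols: dict[str, dict[str, float]] = {}
    for res in chain.residues:
        vals, _ = window_values(per_pos, res.seq_index, width)
        cols[res.key] = {f"{tag}_V{n + 1}": vals[n] for n in range(width)}
    return cols


def sequence_feature_frame(chains: list[ProteinChain],
                           profiles: dict[str, PSSMProfile],
                           width: int = WINDOW_WIDTH) -> pd.DataFrame:
    """Windowed PSSM log-odds, conservation windows and chain composition."""
    rows = {}
    for chain in chains:
        profile = profiles.get(chain.chain_id)
        if profile is None:
            raise ValueError(f"no PSSM profile for chain {chain.chain_id!r}")
        cons = conservation_scores(profile)
        comp = chain_composition(chain)
        for res in chain.residues:
            enc = window_pssm(profile, res.seq_index, width)
            row = dict(zip(enc.names, enc.values))
            cvals, _ = window_values(cons, res.seq_index, width)
            row.update({f"Conservation_score_V{n + 1}": cvals[n] for n in range(width)})
            row.update(comp)
            rows[res.key] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def exposure_feature_frame(structures: list[Structure],
                           width: int = WINDOW_WIDTH,
                           n_sphere_points: int = expo.N_SPHERE_POINTS) -> pd.DataFrame:
    """Windowed SASA/polar/H-bond/HSE/depth features, per structure context."""
    rows = {}
    for st in structures:
        records = expo.compute_exposure(st.chains, n_sphere_points=n_sphere_points)
        for chain in st.chains:
            length = len(chain)
            for attr, tag in EXPOSURE_TAGS.items():
                per_pos = np.zeros(length)
                for res in chain.residues:
                    rec = records.get(res.key)
                    if rec is not None:
                        per_pos[res.seq_index - 1] = getattr(rec, attr)
                for key, cols in _window_frame(per_pos, chain, tag, width).items():
                    rows.setdefault(key, {}).update(cols)
    return pd.DataFrame.from_dict(rows, orient="index")


def network_feature_frame(chains: list[ProteinChain],
                          width: int = WINDOW_WIDTH,
                          cutoff: float = net.CONTACT_CUTOFF) -> pd.DataFrame:
    """Windowed contact-graph node metrics plus the chain graph density."""
    rows = {}
    for chain in chains:
        graph = net.build_contact_graph(chain, cutoff=cutoff)
        metrics = net.node_metrics(graph)
        gdens = net.graph_density(graph)
        for name, tag in NET_TAGS.items():
            per_pos = net.metrics_array(metrics[name], len(chain))
            for key, cols in _window_frame(per_pos, chain, f"Net_{tag}", width).items():
                rows.setdefault(key, {}).update(cols)
        for res in chain.residues:
            rows.setdefault(res.key, {})["Net_graph_density"] = gdens
    return pd.DataFrame.from_dict(rows, orient="index")


def build_feature_matrix(
    structures: list[Structure],
    profiles: dict[str, PSSMProfile],
    width: int = WINDOW_WIDTH,
    passthrough: pd.DataFrame | None = None,
    cutoff: float = 3.0,
    n_sphere_points: int = expo.N_SPHERE_POINTS,
) -> FeatureMatrix:
    """Label, extract all native feature families and assemble the matrix."""
    samples, _ = collect_samples(structures, cutoff=cutoff)
    chains = [c for st in structures for c in st.chains]
    frames = [
        sequence_feature_frame(chains, profiles, width),
        exposure_feature_frame(structures, width, n_sphere_points=n_sphere_points),
        network_feature_frame(chains, width),
    ]
    return assemble_matrix(samples, frames, passthrough=passthrough)


def protein_truth(matrix: FeatureMatrix) -> dict[str, bool]:
    """chain_id -> does the chain contain any functional-zinc residue."""
    truth: dict[str, bool] = {}
    for key, label in matrix.y.items():
        cid = matrix.chain_id[key]
        truth[cid] = truth.get(cid, False) or label == 1
    return truth
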
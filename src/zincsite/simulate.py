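"""Ground-truthed synthetic structures, profiles and decoy features.

The generator emulates the statistical shape of a zinc-binding structural
benchmark without downloading anything: self-avoiding random-walk Calpha
backbones (3.8 A steps) with minimal backbone and side-chain atoms, planted
tetrahedral-ish zinc sites whose CHED donor atoms sit 2.0-2.3 A from the
ion, background CHED decoys, and PSI-BLAST-style profiles whose
binding-site columns are more conserved than background columns. Every
planted coordinating residue is recorded in a ground-truth table, so
downstream labeling, feature extraction and selection can be checked
exactly.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .dataset import FeatureMatrix
from .pssm import DEFAULT_AA_ORDER, PSSMProfile, write_pssm

STEP_LENGTH = 3.8          # consecutive Calpha spacing, A
CLASH_DISTANCE = 4.0       # min spacing of non-consecutive Calpha, A
ZINC_CLEARANCE = 3.2       # min distance of any decoy atom to a planted zinc, A

_DONOR_ATOM = {"CYS": "SG", "HIS": "NE2", "GLU": "OE1", "ASP": "OD1"}
_ONE_TO_THREE = {"A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
                 "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
                 "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
                 "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL"}
_NON_CHED = "ARNQGILKMFPSTWYV"


class FixtureError(RuntimeError):
    pass


@dataclass
class FixtureSpec:
    """Study conditions emulated by the generator.

    Defaults follow the composition of curated zinc benchmarks: sites of
    arity 3-4 (the functional classes), donor-zinc distances inside the 3 A
    labeling threshold, and a CHED background rich enough that negatives
    outnumber positives several-fold before any subsampling.
    """
    n_chains: int = 8
    chain_length: tuple[int, int] = (40, 60)
    n_sites: int = 1
    site_arity: int = 4
    coord_range: tuple[float, float] = (2.0, 2.3)
    background_ched_freq: float = 0.30
    conservation_contrast: float = 0.9   # profile mass on the true residue at site columns
    n_noise_features: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.coord_range
        if not (0.0 < lo <= hi < 3.0):
            raise ValueError("coordination range must lie inside (0, 3.0) A")
        if self.chain_length[0] < 9:
            raise ValueError("chains must be at least one window (9 residues) long")
        if self.site_arity not in (3, 4):
            raise ValueError("site arity must be 3 or 4")


@dataclass
class SyntheticFixture:
    spec: FixtureSpec
    pdb_texts: dict[str, str]
    pssm_texts: dict[str, str]
    profiles: dict[str, PSSMProfile]
    sequences: dict[str, str]
    truth: pd.DataFrame          # chain_id, seq_index, res_type, site_id
    manifest: dict = field(default_factory=dict)

    def positive_keys(self) -> set[str]:
        return {f"{r.chain_id}:{r.seq_index}" for r in self.truth.itertuples()}

    def write(self, outdir) -> None:
        from pathlib import Path
        import json
        outdir = Path(outdir)
        (outdir / "structures").mkdir(parents=True, exist_ok=True)
        (outdir / "pssms").mkdir(parents=True, exist_ok=True)
        for cid, text in self.pdb_texts.items():
            (outdir / "structures" / f"{cid}.pdb").write_text(text)
        for cid, text in self.pssm_texts.items():
            (outdir / "pssms" / f"{cid}.pssm").write_text(text)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _chain_ids(n: int) -> list[str]:
    letters = string.ascii_uppercase
    ids = list(letters)
    ids += [a + b for a in letters for b in letters]
    return ids[:n]


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _self_avoiding_walk(n: int, rng: np.random.Generator,
                        max_restarts: int = 50) -> np.ndarray:
    for _ in range(max_restarts):
        pos = [np.zeros(3)]
        ok = True
        for _i in range(1, n):
            placed = False
            for _try in range(200):
                cand = pos[-1] + STEP_LENGTH * _random_unit(rng)
                if len(pos) < 2 or np.all(
                        np.linalg.norm(np.array(pos[:-1]) - cand, axis=1) >= CLASH_DISTANCE):
                    pos.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pos)
    raise FixtureError("could not grow a self-avoiding backbone; loosen the spec")


def _backbone_atoms(ca: np.ndarray, prev_ca: np.ndarray | None,
                    next_ca: np.ndarray | None,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    toward_prev = (prev_ca - ca) if prev_ca is not None else _random_unit(rng)
    toward_next = (next_ca - ca) if next_ca is not None else _random_unit(rng)
    toward_prev = toward_prev / np.linalg.norm(toward_prev)
    toward_next = toward_next / np.linalg.norm(toward_next)
    n = ca + 1.45 * toward_prev
    c = ca + 1.52 * toward_next
    o = c + 1.23 * _random_unit(rng)
    return {"N": n, "CA": ca, "C": c, "O": o}


_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C",
               "SG": "S", "NE2": "N", "OE1": "O", "OD1": "O"}


def _build_chain_atoms(sequence: str, cas: np.ndarray,
                       rng: np.random.Generator) -> list[dict[str, np.ndarray]]:
    atoms: list[dict[str, np.ndarray]] = []
    n = len(sequence)
    for i, letter in enumerate(sequence):
        ca = cas[i]
        rec = _backbone_atoms(ca, cas[i - 1] if i > 0 else None,
                              cas[i + 1] if i < n - 1 else None, rng)
        res3 = _ONE_TO_THREE[letter]
        if res3 != "GLY":
            rec["CB"] = ca + 1.53 * _random_unit(rng)
        donor = _DONOR_ATOM.get(res3)
        if donor:
            base = rec.get("CB", ca)
            rec[donor] = base + 1.6 * _random_unit(rng)
        atoms.append(rec)
    return atoms


def _plant_site(atoms: list[dict[str, np.ndarray]], sequence: str,
                site_indices: list[int], cas: np.ndarray,
                spec: FixtureSpec, rng: np.random.Generator,
                existing_zincs: list[np.ndarray]) -> np.ndarray:
    """Place one zinc and re-pose the site residues' donor atoms around it."""
    site_set = set(site_indices)
    centroid = cas[site_indices].mean(axis=0)
    for _try in range(300):
        zn = centroid + rng.normal(scale=1.5, size=3)
        if any(np.linalg.norm(zn - z) < 8.0 for z in existing_zincs):
            continue
        # decoy atoms must stay clear of the labeling cutoff
        clear = True
        for i, rec in enumerate(atoms):
            if i in site_set:
                continue
            for xyz in rec.values():
                if np.linalg.norm(xyz - zn) < ZINC_CLEARANCE:
                    clear = False
                    break
            if not clear:
                break
        # backbone of site residues must not coordinate a *different* zinc
        if clear:
            for i in site_indices:
                for xyz in atoms[i].values():
                    if any(np.linalg.norm(xyz - z) < ZINC_CLEARANCE for z in existing_zincs):
                        clear = False
                        break
        if not clear:
            continue
        lo, hi = spec.coord_range
        for i in site_indices:
            donor = _DONOR_ATOM[_ONE_TO_THREE[sequence[i]]]
            atoms[i][donor] = zn + rng.uniform(lo, hi) * _random_unit(rng)
            # keep the rest of the residue outside the shell of any other zinc
        return zn
    raise FixtureError("could not place a zinc clear of decoy residues; loosen the spec")


def _to_pdb(chain_id: str, sequence: str,
            atoms: list[dict[str, np.ndarray]], zincs: list[np.ndarray]) -> str:
    st = gemmi.Structure()
    st.name = chain_id
    model = gemmi.Model("1")
    chain = gemmi.Chain(chain_id)
    for i, letter in enumerate(sequence):
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE[letter]
        res.seqid = gemmi.SeqId(i + 1, " ")
        res.het_flag = "A"
        for aname, xyz in atoms[i].items():
            atom = gemmi.Atom()
            atom.name = aname
            atom.element = gemmi.Element(_ELEMENT_OF[aname])
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    # zinc ions on a separate het chain
    if zincs:
        zchain = gemmi.Chain("Z" if chain_id != "Z" else "Y")
        for k, zn in enumerate(zincs):
            res = gemmi.Residue()
            res.name = "ZN"
            res.seqid = gemmi.SeqId(k + 1, " ")
            res.het_flag = "H"
            atom = gemmi.Atom()
            atom.name = "ZN"
            atom.element = gemmi.Element("ZN")
            atom.pos = gemmi.Position(*zn)
            atom.occ = 1.0
            res.add_atom(atom)
            zchain.add_residue(res)
        model.add_chain(zchain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def generate_structures(spec: FixtureSpec, rng: np.random.Generator | None = None):
    """Generate PDB texts plus the ground-truth coordinating-residue table."""
    rng = rng or np.random.default_rng(spec.seed)
    pdb_texts: dict[str, str] = {}
    sequences: dict[str, str] = {}
    truth_rows: list[dict] = []
    for cid in _chain_ids(spec.n_chains):
        length = int(rng.integers(spec.chain_length[0], spec.chain_length[1] + 1))
        cas = _self_avoiding_walk(length, rng)
        # pick site residues first, spaced along the chain
        site_indices_all: list[list[int]] = []
        used: set[int] = set()
        for _s in range(spec.n_sites):
            for _try in range(200):
                idx = sorted(rng.choice(length, size=spec.site_arity, replace=False))
                if any(abs(a - b) < 2 for a, b in zip(idx, idx[1:])):
                    continue
                if used.intersection(idx):
                    continue
                site_indices_all.append([int(i) for i in idx])
                used.update(idx)
                break
            else:
                raise FixtureError("could not choose site residues; loosen the spec")
        letters = []
        for i in range(length):
            if i in used:
                letters.append(rng.choice(list("CHED")))
            elif rng.random() < spec.background_ched_freq:
                letters.append(rng.choice(list("CHED")))
            else:
                letters.append(rng.choice(list(_NON_CHED)))
        sequence = "".join(letters)
        atoms = _build_chain_atoms(sequence, cas, rng)
        zincs: list[np.ndarray] = []
        for s, idx in enumerate(site_indices_all):
            zn = _plant_site(atoms, sequence, idx, cas, spec, rng, zincs)
            zincs.append(zn)
            for i in idx:
                truth_rows.append({"chain_id": cid, "seq_index": i + 1,
                                   "res_type": _ONE_TO_THREE[sequence[i]],
                                   "site_id": f"{cid}-site{s}"})
        pdb_texts[cid] = _to_pdb(cid, sequence, atoms, zincs)
        sequences[cid] = sequence
    truth = pd.DataFrame(truth_rows,
                         columns=["chain_id", "seq_index", "res_type", "site_id"])
    return pdb_texts, sequences, truth


# ---------------------------------------------------------------------------
# profiles

def _largest_remainder(p: np.ndarray, total: int = 100) -> np.ndarray:
    scaled = p * total
    floors = np.floor(scaled).astype(int)
    rest = total - floors.sum()
    order = np.argsort(-(scaled - floors), kind="stable")
    floors[order[:rest]] += 1
    return floors


def generate_pssms(sequences: dict[str, str], truth: pd.DataFrame,
                   spec: FixtureSpec, rng: np.random.Generator | None = None):
    """Profiles whose binding-site columns are peaked on the true residue.

    Binding columns put ``conservation_contrast`` of the probability mass on
    the residue actually present; background columns are drawn near-uniform
    from a flat Dirichlet. Percentages are written as integers (the
    PSI-BLAST convention), so round-trips are exact to 2 decimals.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    binding = {(r.chain_id, r.seq_index) for r in truth.itertuples()}
    aa_index = {aa: k for k, aa in enumerate(DEFAULT_AA_ORDER)}
    profiles: dict[str, PSSMProfile] = {}
    texts: dict[str, str] = {}
    for cid, seq in sequences.items():
        L = len(seq)
        freqs = np.zeros((L, 20))
        for i, letter in enumerate(seq):
            j = aa_index[letter]
            if (cid, i + 1) in binding:
                p = np.full(20, (1.0 - spec.conservation_contrast) / 19.0)
                p[j] = spec.conservation_contrast
            else:
                p = rng.dirichlet(np.full(20, 8.0))
            freqs[i] = _largest_remainder(p) / 100.0
        with np.errstate(divide="ignore"):
            lo = np.round(2.0 * np.log2(np.maximum(freqs, 1e-3) / 0.05))
        log_odds = np.clip(lo, -9, 11).astype(int)
        profile = PSSMProfile(residue_letters=seq, aa_order=tuple(DEFAULT_AA_ORDER),
                              log_odds=log_odds, frequencies=freqs)
        profiles[cid] = profile
        texts[cid] = write_pssm(profile)
    return profiles, texts


# ---------------------------------------------------------------------------
# decoy features

def generate_noise_features(matrix: FeatureMatrix, n: int,
                            seed: int = 0) -> FeatureMatrix:
    """Append ``n`` label-independent standard-normal columns (noise_0001...)."""
    rng = np.random.default_rng(seed)
    noise = pd.DataFrame(
        rng.standard_normal((matrix.n_samples, n)),
        index=matrix.X.index,
        columns=[f"noise_{i + 1:04d}" for i in range(n)])
    X = pd.concat([matrix.X, noise], axis=1)
    prov = dict(matrix.provenance)
    prov.update({c: "native" for c in noise.columns})
    return FeatureMatrix(X, matrix.y, matrix.residue_type, matrix.chain_id, prov)


def planted_matrix(n_pos: int = 20, ratio: int = 6, n_informative: int = 5,
                   n_noise: int = 15, effect_size: float = 1.0,
                   seed: int = 0) -> FeatureMatrix:
    """Feature matrix with planted label-shifted columns plus pure noise.

    Informative columns (planted_1..) are standard normal with the positive
    class shifted by ``effect_size``; noise columns are label-independent.
    Used to test that selection retains signal and discards decoys.
    """
    rng = np.random.default_rng(seed)
    n_neg = ratio * n_pos
    n = n_pos + n_neg
    y = np.array([1] * n_pos + [-1] * n_neg)
    X = rng.standard_normal((n, n_informative))
    X[y == 1] += effect_size
    keys = [f"S:{i + 1}" for i in range(n)]
    frame = pd.DataFrame(X, index=pd.Index(keys, name="sample_key"),
                         columns=[f"planted_{j + 1}" for j in range(n_informative)])
    matrix = FeatureMatrix(
        frame, pd.Series(y, index=frame.index, name="label"),
        pd.Series(rng.choice(list("CHED"), size=n), index=frame.index,
                  name="residue_type"),
        pd.Series("S", index=frame.index, name="chain_id"))
    return generate_noise_features(matrix, n_noise, seed=seed + 1)


# ---------------------------------------------------------------------------
# front door

def generate_fixture(spec: FixtureSpec) -> SyntheticFixture:
    """Structures + profiles + ground truth from one seeded generator."""
    rng = np.random.default_rng(spec.seed)
    pdb_texts, sequences, truth = generate_structures(spec, rng)
    profiles, pssm_texts = generate_pssms(sequences, truth, spec, rng)
    manifest = {"spec": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in vars(spec).items()},
                "n_positive": int(len(truth))}
    return SyntheticFixture(spec=spec, pdb_texts=pdb_texts, pssm_texts=pssm_texts,
                            profiles=profiles, sequences=sequences, truth=truth,
                            manifest=manifest)
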
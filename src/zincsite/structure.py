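"""Coordinate model, zinc labeling and zinc-site classification.

Parses PDB-format structures into a lightweight coordinate model, labels
CHED residues (Cys, His, Glu, Asp — the residue types that dominate zinc
coordination) as zinc-binding when any non-hydrogen atom lies within a
distance cutoff of a zinc ion, classifies each zinc ion by the number of
coordinating residues (Zn1..Zn4+, plus a co-catalytic rule for zincs acting
together with a second metal), and derives the positive/negative residue
sample set used downstream for classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gemmi
import numpy as np
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

#: residue types that coordinate the vast majority of protein zinc sites
CHED_TYPES = frozenset({"CYS", "HIS", "GLU", "ASP"})

#: non-zinc metals considered when testing the co-catalytic rule
CO_CATALYTIC_METALS = frozenset({"MG", "MN", "FE", "CO", "NI", "CU", "CA", "CD"})

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(ValueError):
    """Raised for malformed or empty structure input."""


@dataclass(eq=False)
class Atom:
    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name!r}: empty element symbol")


@dataclass(eq=False)
class Residue:
    chain_id: str
    seq_index: int          # 1-based position within the chain
    res_type: str           # 3-letter code
    atoms: list[Atom]

    @property
    def is_ched(self) -> bool:
        return self.res_type in CHED_TYPES

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.res_type, "X")

    @property
    def key(self) -> str:
        return f"{self.chain_id}:{self.seq_index}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass(eq=False)
class ProteinChain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(eq=False)
class ZincIon:
    ion_id: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"zinc {self.ion_id}: non-finite coordinates")


@dataclass(eq=False)
class HetContext:
    """Non-zinc metal ions and water oxygens needed for co-catalytic detection."""
    metals: list[tuple[str, str, np.ndarray]] = field(default_factory=list)  # (id, element, xyz)
    waters: list[np.ndarray] = field(default_factory=list)


ZNX_CLASSES = ("Zn1", "Zn2", "Zn3", "Zn4plus", "co_catalytic")
FUNCTIONAL_CLASSES = frozenset({"Zn3", "Zn4plus", "co_catalytic"})


@dataclass(eq=False)
class ZincSite:
    ion: ZincIon
    coordinating_residues: list[Residue]
    znx_class: str

    @property
    def is_functional(self) -> bool:
        return self.znx_class in FUNCTIONAL_CLASSES


# ---------------------------------------------------------------------------
# parsing

def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved lexicographically by altloc code
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "A"))


def parse_structure(pdb_text: str) -> tuple[list[ProteinChain], list[ZincIon], HetContext]:
    """Parse PDB-format text (first MODEL only) into the coordinate model.

    Hydrogens are discarded; alternate locations are resolved to the
    highest-occupancy conformer (ties keep the lexicographically first
    altloc code). Zinc ions are recognised by element or residue name "ZN".
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"malformed PDB input: {exc}") from exc
    if len(st) == 0:
        raise StructureError("no ATOM records found in input")
    model = st[0]

    chains: list[ProteinChain] = []
    zincs: list[ZincIon] = []
    het = HetContext()
    n_polymer_atoms = 0

    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            name = gres.name.strip().upper()
            element_of = {a.name: a.element.name.upper() for a in gres}
            if name == "ZN" or (gres.het_flag == "H" and any(
                    e == "ZN" for e in element_of.values())):
                for a in gres:
                    if a.element.name.upper() == "ZN":
                        zincs.append(ZincIon(
                            ion_id=f"{gchain.name}:{gres.seqid.num}:ZN",
                            coords=[a.pos.x, a.pos.y, a.pos.z]))
                continue
            if name in WATER_NAMES:
                for a in gres:
                    if a.element.name.upper() == "O":
                        het.waters.append(np.array([a.pos.x, a.pos.y, a.pos.z]))
                continue
            if gres.het_flag == "H" and name in CO_CATALYTIC_METALS:
                for a in gres:
                    het.metals.append((f"{gchain.name}:{gres.seqid.num}:{name}",
                                       a.element.name.upper(),
                                       np.array([a.pos.x, a.pos.y, a.pos.z])))
                continue
            if gres.het_flag == "H" and name not in _THREE_TO_ONE:
                # other het groups are irrelevant to labeling
                continue
            # polymer residue: resolve altlocs, drop hydrogens
            by_name: dict[str, list[gemmi.Atom]] = {}
            for a in gres:
                if a.element.is_hydrogen:
                    continue
                by_name.setdefault(a.name, []).append(a)
            atoms = []
            for aname, alts in by_name.items():
                ga = _pick_altloc(alts)
                atoms.append(Atom(name=aname, element=ga.element.name.upper() or "X",
                                  coords=[ga.pos.x, ga.pos.y, ga.pos.z]))
            if not atoms:
                continue
            residues.append(Residue(chain_id=gchain.name,
                                    seq_index=len(residues) + 1,
                                    res_type=name, atoms=atoms))
            n_polymer_atoms += len(atoms)
        if residues:
            chains.append(ProteinChain(chain_id=gchain.name, residues=residues))

    if n_polymer_atoms == 0:
        raise StructureError("no ATOM records found in input")
    return chains, zincs, het


# ---------------------------------------------------------------------------
# labeling

def label_binding_residues(
    chains: Iterable[ProteinChain],
    zincs: Iterable[ZincIon],
    cutoff: float = 3.0,
) -> dict[Residue, set[ZincIon]]:
    """Map each residue to the zinc ions it binds.

    A residue binds a zinc ion when the minimum distance over its
    non-hydrogen atoms to the ion is <= ``cutoff`` (boundary inclusive).
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    zincs = list(zincs)
    binding: dict[Residue, set[ZincIon]] = {}
    if not zincs:
        return binding
    all_atoms: list[tuple[Residue, np.ndarray]] = []
    for chain in chains:
        for res in chain.residues:
            for atom in res.atoms:
                all_atoms.append((res, atom.coords))
    if not all_atoms:
        return binding
    coords = np.array([c for _, c in all_atoms])
    tree = cKDTree(coords)
    for zn in zincs:
        # small epsilon keeps the <= boundary robust to kd-tree rounding
        for idx in tree.query_ball_point(zn.coords, cutoff + 1e-9):
            res = all_atoms[idx][0]
            if np.linalg.norm(all_atoms[idx][1] - zn.coords) <= cutoff:
                binding.setdefault(res, set()).add(zn)
    return binding


def _min_residue_distance(res: Residue, point: np.ndarray) -> float:
    return float(np.min(np.linalg.norm(res.coord_array() - point, axis=1)))


def classify_zinc_sites(
    zincs: Iterable[ZincIon],
    binding_map: Mapping[Residue, set[ZincIon]],
    het_context: HetContext | None = None,
    co_cat_metal_radius: float = 5.0,
    co_cat_shell_radius: float = 3.0,
) -> list[ZincSite]:
    """Classify each zinc ion by its number of coordinating residues.

    1/2/3 residues give Zn1/Zn2/Zn3; four or more give Zn4plus. A zinc is
    reclassified co-catalytic when a second metal ion lies within
    ``co_cat_metal_radius`` and either a water oxygen sits in the zinc's
    coordination shell (``co_cat_shell_radius``) or one of the zinc's
    coordinating residues also reaches into the second metal's shell
    (a bridging side chain). Zincs with no coordinating residues are
    dropped with a warning.
    """
    het = het_context or HetContext()
    by_zinc: dict[ZincIon, list[Residue]] = {}
    for res, ions in binding_map.items():
        for ion in ions:
            by_zinc.setdefault(ion, []).append(res)
    sites: list[ZincSite] = []
    for zn in zincs:
        residues = sorted(by_zinc.get(zn, []), key=lambda r: (r.chain_id, r.seq_index))
        if not residues:
            log.warning("zinc %s has no coordinating residues within cutoff; dropped", zn.ion_id)
            continue
        n = len(residues)
        znx = ("Zn1", "Zn2", "Zn3")[n - 1] if n <= 3 else "Zn4plus"
        if _is_co_catalytic(zn, residues, het, co_cat_metal_radius, co_cat_shell_radius):
            znx = "co_catalytic"
        sites.append(ZincSite(ion=zn, coordinating_residues=residues, znx_class=znx))
    return sites


def _is_co_catalytic(zn: ZincIon, residues: list[Residue], het: HetContext,
                     metal_radius: float, shell_radius: float) -> bool:
    near_metals = [m for m in het.metals
                   if np.linalg.norm(m[2] - zn.coords) <= metal_radius]
    if not near_metals:
        return False
    for w in het.waters:
        if np.linalg.norm(w - zn.coords) <= shell_radius:
            return True
    for _, _, mcoords in near_metals:
        for res in residues:
            if _min_residue_distance(res, mcoords) <= shell_radius:
                return True
    return False


def make_sample_set(
    chains: Iterable[ProteinChain],
    sites: Iterable[ZincSite],
) -> list[tuple[Residue, int]]:
    """Return (residue, label) pairs for every CHED residue.

    Label is +1 when the residue coordinates at least one functional zinc
    (Zn3, Zn4plus or co-catalytic), else -1. Non-CHED residues are excluded.
    """
    positives: set[int] = set()
    for site in sites:
        if site.is_functional:
            positives.update(id(r) for r in site.coordinating_residues)
    samples: list[tuple[Residue, int]] = []
    for chain in chains:
        for res in chain.residues:
            if res.is_ched:
                samples.append((res, 1 if id(res) in positives else -1))
    return samples


def write_labeling_report(
    path,
    binding_map: Mapping[Residue, set[ZincIon]],
    samples: Iterable[tuple[Residue, int]],
) -> None:
    """Tab-delimited labeling report: key fields, label, zinc ids, min distance."""
    with open(path, "w") as fh:
        fh.write("chain_id\tseq_index\tres_type\tlabel\tzinc_ids\tmin_distance_A\n")
        for res, label in samples:
            ions = sorted(binding_map.get(res, ()), key=lambda z: z.ion_id)
            if ions:
                dmin = min(_min_residue_distance(res, z.coords) for z in ions)
                ids = ",".join(z.ion_id for z in ions)
                fh.write(f"{res.chain_id}\t{res.seq_index}\t{res.res_type}\t{label}"
                         f"\t{ids}\t{dmin:.3f}\n")
            else:
                fh.write(f"{res.chain_id}\t{res.seq_index}\t{res.res_type}\t{label}\t\t\n")
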
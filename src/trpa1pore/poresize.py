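"""Organic-cation sizing and excluded-volume pore-diameter estimation.

The minimum open-pore diameter of a channel can be bracketed by measuring
which organic cations carry inward current.  Each cation is assigned a
"vertex diameter": embed the ion in 3-D, identify the terminal heavy atom
of every substituent arm (the vertices), and average, over all vertex
pairs, the internuclear distance plus both van der Waals radii.  Cations
are classified permeant or impermeant from their current relative to Na+
at -80 mV; the largest permeant diameter is a lower bound on the pore
diameter.

Terminal vertices carry their hydrogens pointing outward, so united-atom
(group) van der Waals radii are used for them - 2.0 A for CH3/CH2 and
H-bearing nitrogen, 1.7 A for hydroxyl oxygen (Bondi-style group values) -
rather than bare heavy-atom radii, which would ignore roughly one C-H bond
length of bulk at every arm tip.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

#: united-atom van der Waals radii (A) for terminal heavy-atom groups
GROUP_RADII_A = {"C": 2.0, "N": 2.0, "O": 1.7, "P": 2.1, "S": 2.0}

#: default ETKDG embedding seed; a panel parameter, fixed for reproducibility
DEFAULT_EMBED_SEED = 7

#: relative current below this fraction of the Na+ reference is leak
DEFAULT_LEAK_THRESHOLD = 0.02


@dataclass(frozen=True)
class CationSpec:
    """One test cation: identity, connectivity and measured relative current.

    ``relative_current`` is the inward current at -80 mV relative to Na+;
    ``blocker`` marks cations that bind in the pore and block outward
    current, for which the relative current understates permeability.
    """

    name: str
    smiles: str
    charge: int = 1
    relative_current: float | None = None
    blocker: bool = False


@dataclass(frozen=True)
class CutoffEstimate:
    """Lower-bound pore diameter from a permeation panel."""

    cutoff_A: float
    largest_permeant: str
    smallest_impermeant: str | None
    smallest_impermeant_A: float | None
    ordering_violated: bool


def embed_cation(spec: CationSpec, seed: int = DEFAULT_EMBED_SEED) -> Chem.Mol:
    """Deterministic 3-D embedding: ETKDG with a fixed seed, then MMFF94.

    The same seed always yields the same conformer, making the diameters
    reproducible panel constants.
    """
    mol = Chem.MolFromSmiles(spec.smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES for {spec.name}: {spec.smiles!r}")
    if Chem.GetFormalCharge(mol) != spec.charge:
        raise ValueError(f"{spec.name}: SMILES charge != declared charge")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"3-D embedding failed for {spec.name}")
    AllChem.MMFFOptimizeMolecule(mol)
    return mol


def vertex_atom_indices(mol: Chem.Mol) -> list[int]:
    """Terminal heavy atoms of each substituent arm (heavy-graph degree <= 1)."""
    verts = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() <= 1:
            continue
        heavy_neighbors = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)
        if heavy_neighbors <= 1:
            verts.append(atom.GetIdx())
    return verts


def cation_diameter(
    spec: CationSpec,
    radii_A: dict[str, float] | None = None,
    seed: int = DEFAULT_EMBED_SEED,
    mol: Chem.Mol | None = None,
) -> float:
    """Vertex-method molecular diameter in angstroms.

    For every unordered pair of vertex atoms the internuclear distance plus
    both group radii is computed; the diameter is the mean over pairs.  A
    single-vertex (monatomic-like) species gets twice its group radius.
    """
    radii = GROUP_RADII_A if radii_A is None else radii_A
    if mol is None:
        mol = embed_cation(spec, seed=seed)
    verts = vertex_atom_indices(mol)
    if not verts:
        raise ValueError(f"{spec.name}: no vertex atoms found")

    def radius(idx: int) -> float:
        symbol = mol.GetAtomWithIdx(idx).GetSymbol()
        try:
            return radii[symbol]
        except KeyError:
            raise KeyError(f"no van der Waals radius for element {symbol!r}") from None

    if len(verts) == 1:
        return 2.0 * radius(verts[0])
    pos = mol.GetConformer().GetPositions()
    dists = [
        float(np.linalg.norm(pos[i] - pos[j])) + radius(i) + radius(j)
        for i, j in itertools.combinations(verts, 2)
    ]
    return float(np.mean(dists))


# --------------------------------------------------------------------------
# the wild-type test panel
#
# Relative currents for the wild-type channel are synthetic panel values
# chosen to reproduce the published permeant/impermeant classification
# (permeant: MEA ... THP; impermeant: NMDG, TPA, TBA); only the
# classification, not the current magnitudes, enters the cutoff estimate.

WT_PANEL: tuple[CationSpec, ...] = (
    CationSpec("MEA", "C[NH3+]", relative_current=0.85),
    CationSpec("DMA", "C[NH2+]C", relative_current=0.70),
    CationSpec("TMA3", "C[NH+](C)C", relative_current=0.55),
    CationSpec("TMA4", "C[N+](C)(C)C", relative_current=0.45),
    CationSpec("TMP", "C[P+](C)(C)C", relative_current=0.40),
    CationSpec("TEA3", "CC[NH+](CC)CC", relative_current=0.15),
    CationSpec("TEA4", "CC[N+](CC)(CC)CC", relative_current=0.05),
    CationSpec("THP", "OC[P+](CO)(CO)CO", relative_current=0.10),
    CationSpec("NMDG", "C[NH2+]C[C@@H](O)[C@H](O)[C@H](O)[C@H](O)CO",
               relative_current=0.005),
    CationSpec("TPA", "CCC[N+](CCC)(CCC)CCC", relative_current=0.008, blocker=True),
    CationSpec("TBA", "CCCC[N+](CCCC)(CCCC)CCCC", relative_current=0.006, blocker=True),
)


def panel_diameters(
    panel: tuple[CationSpec, ...] = WT_PANEL, seed: int = DEFAULT_EMBED_SEED
) -> pd.DataFrame:
    """Vertex diameters for a whole panel, one row per cation."""
    rows = [
        {"name": s.name, "diameter_A": cation_diameter(s, seed=seed)} for s in panel
    ]
    return pd.DataFrame(rows)


def classify_permeation(
    panel: tuple[CationSpec, ...] = WT_PANEL,
    leak_threshold: float = DEFAULT_LEAK_THRESHOLD,
) -> pd.DataFrame:
    """Permeant/impermeant classification from relative currents.

    A cation is permeant when its current relative to the Na+ reference
    exceeds ``leak_threshold``; the blocker flag is carried through because
    permeant blockers understate their permeability.
    """
    missing = [s.name for s in panel if s.relative_current is None]
    if missing:
        raise ValueError(f"no relative current for: {missing}")
    rows = [
        {
            "name": s.name,
            "relative_current": s.relative_current,
            "blocker": s.blocker,
            "classification": (
                "permeant" if s.relative_current > leak_threshold else "impermeant"
            ),
        }
        for s in panel
    ]
    return pd.DataFrame(rows)


def estimate_cutoff(
    permeation: pd.DataFrame, diameters: pd.DataFrame
) -> CutoffEstimate:
    """Lower-bound pore diameter: the largest permeant vertex diameter.

    Also reports the smallest impermeant diameter bracketing the cutoff and
    flags panels where an impermeant cation is smaller than the largest
    permeant one (classification noise).
    """
    merged = permeation.merge(diameters, on="name")
    perm = merged[merged["classification"] == "permeant"]
    imperm = merged[merged["classification"] == "impermeant"]
    if perm.empty:
        raise ValueError("no permeant cation in the panel; cutoff undefined")
    top = perm.loc[perm["diameter_A"].idxmax()]
    if imperm.empty:
        return CutoffEstimate(
            cutoff_A=float(top["diameter_A"]),
            largest_permeant=str(top["name"]),
            smallest_impermeant=None,
            smallest_impermeant_A=None,
            ordering_violated=False,
        )
    bottom = imperm.loc[imperm["diameter_A"].idxmin()]
    return CutoffEstimate(
        cutoff_A=float(top["diameter_A"]),
        largest_permeant=str(top["name"]),
        smallest_impermeant=str(bottom["name"]),
        smallest_impermeant_A=float(bottom["diameter_A"]),
        ordering_violated=bool(bottom["diameter_A"] < top["diameter_A"]),
    )
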
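"""Extended Topochemical Atom (ETA) descriptors.

ETA indices are 2D topochemical descriptors built from three atomic
quantities on the hydrogen-suppressed molecular graph:

* alpha — a core-count term, ``alpha = [(Z - Zv)/Zv] * 1/(PN - 1)`` with
  ``alpha(H) = 0``;
* epsilon — an electronegativity measure, ``epsilon = -alpha + 0.3 * Zv``;
* beta — the valence-electron-mobile (VEM) count: per-bond sigma
  contributions (0.5 for bonded atoms of similar electronegativity, 0.75
  for dissimilar), pi contributions (1.0 similar / 1.5 dissimilar per pi
  bond, 2.0 per aromatic ring bond) and a 0.5 increment for a lone-pair
  atom conjugated to a pi system.

Composite indices compare the molecule against two auxiliary graphs: the
*reference alkane* (all heteroatoms replaced by carbon, all bonds single)
and the *saturated carbon skeleton* (heteroatoms kept, carbon-carbon
multiple bonds made single).  The functionality and branching content of
a molecule is then read off from differences such as

* ``dEpsilon_C = epsilon_3 - epsilon_4`` (<= 0; 0 iff no heteroatoms),
* ``dEpsilon_D = epsilon_5 - epsilon_2`` (>= 0; > 0 iff H on N/O/S),
* ``dAlpha_B  = max(0, 0.5 - mean(alpha))`` (polar-surface measure),
* ``BetaP_s   = sum(beta_s) / Nv`` (sigma VEM content per vertex),
* ``EtaP_F    = (eta_R - eta) / Nv`` (functionality index relative to size),

where ``eta = sum_{i<j} sqrt(gamma_i * gamma_j) / d_ij`` over heavy-atom
pairs at topological distance ``d_ij`` and ``gamma = alpha / beta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .chemio import Atom, Bond, Molecule, MoleculeError

# Adopted ETA constants, kept in one place so the scheme is editable.
SIGMA_SIMILAR = 0.5          # sigma contribution, similar electronegativity
SIGMA_DISSIMILAR = 0.75      # sigma contribution, dissimilar electronegativity
PI_SIMILAR = 1.0             # per pi bond, similar electronegativity
PI_DISSIMILAR = 1.5          # per pi bond, dissimilar electronegativity
AROMATIC_NS = 2.0            # non-sigma contribution per aromatic ring bond
LONE_PAIR_DELTA = 0.5        # lone-pair atom conjugated to a pi system
EPSILON_SIMILARITY_THRESHOLD = 0.3  # |d(epsilon)| <= threshold counts as similar
REFERENCE_ALPHA_PER_VERTEX = 0.5    # mean alpha of any alkane carbon skeleton

# Typical covalent valences used when re-filling hydrogens on derived graphs.
_STANDARD_VALENCE = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1,
    "Si": 4, "P": 3, "S": 2, "Cl": 1, "Br": 1, "I": 1,
}

#: The five descriptors of the final larvicidal-activity model.
MODEL_DESCRIPTORS = (
    "ETA_dEpsilon_D",
    "ETA_EtaP_F",
    "ETA_dAlpha_B",
    "ETA_BetaP_s",
    "ETA_dEpsilon_C",
)

#: Descriptors validated against hand-derived values and the scheme's stated
#: fragments; everything else in the block is computed with the same
#: machinery but carries an "unvalidated" flag in output metadata.
VALIDATED_DESCRIPTORS = frozenset(
    MODEL_DESCRIPTORS
    + ("ETA_Alpha", "ETA_AlphaP", "ETA_dAlpha_A", "ETA_Beta_s", "ETA_Beta",
       "ETA_Epsilon_1", "ETA_Epsilon_2", "ETA_Epsilon_3", "ETA_Epsilon_4",
       "ETA_Epsilon_5")
)


@dataclass(frozen=True)
class AtomEtaValues:
    """Atomic ETA quantities for one heavy atom (or hydrogen)."""

    alpha: float
    epsilon: float
    beta_s: float
    beta_ns: float

    @property
    def beta(self) -> float:
        return self.beta_s + self.beta_ns

    @property
    def gamma(self) -> float:
        if self.beta <= 0:
            raise ValueError("gamma undefined for beta <= 0")
        return self.alpha / self.beta


def atomic_alpha(atom: Atom) -> float:
    """Core count ``alpha = [(Z - Zv)/Zv] / (PN - 1)``; 0 for hydrogen."""
    if atom.is_hydrogen:
        return 0.0
    if atom.PN < 2:
        raise MoleculeError(f"alpha undefined for period-1 heavy atom {atom.element}")
    return ((atom.Z - atom.Zv) / atom.Zv) / (atom.PN - 1)


def atomic_epsilon(atom: Atom) -> float:
    """Electronegativity measure ``epsilon = -alpha + 0.3 * Zv``."""
    return -atomic_alpha(atom) + 0.3 * atom.Zv


def _similar(a: Atom, b: Atom) -> bool:
    return abs(atomic_epsilon(a) - atomic_epsilon(b)) <= EPSILON_SIMILARITY_THRESHOLD


def sigma_contribution(a: Atom, b: Atom) -> float:
    """Per-bond sigma VEM contribution: 0.5 similar / 0.75 dissimilar."""
    return SIGMA_SIMILAR if _similar(a, b) else SIGMA_DISSIMILAR


def pi_contribution(a: Atom, b: Atom) -> float:
    """Per-pi-bond VEM contribution: 1.0 similar / 1.5 dissimilar."""
    return PI_SIMILAR if _similar(a, b) else PI_DISSIMILAR


def _lone_pairs(atom: Atom, mol: Molecule) -> int:
    used = sum(b.order for _, b in mol.neighbors(atom.index))
    return max(0, (atom.Zv - used)) // 2


def _conjugated_lone_pair(atom: Atom, mol: Molecule) -> bool:
    """Lone-pair atom adjacent to (or part of) a pi system.

    The atom's own multiple bond does not count: a carbonyl oxygen gets a pi
    contribution, not the lone-pair increment.
    """
    if atom.is_hydrogen or atom.element == "C" or _lone_pairs(atom, mol) < 1:
        return False
    for nb, bond in mol.heavy_neighbors(atom.index):
        if bond.aromatic:
            return True
        for _, nb_bond in mol.heavy_neighbors(nb.index):
            other = nb_bond.j if nb_bond.i == nb.index else nb_bond.i
            if other == atom.index:
                continue
            if nb_bond.aromatic or nb_bond.order >= 2:
                return True
    return False


def atom_beta(atom: Atom, mol: Molecule) -> AtomEtaValues:
    """Atomic VEM count split into sigma and non-sigma parts.

    Hydrogen-suppressed bookkeeping: bonds to hydrogen contribute nothing.
    Every heavy-heavy bond carries one sigma contribution; additional pi
    contributions accrue per extra bond order, aromatic ring bonds add 2.0,
    and a conjugated lone pair adds 0.5 once.
    """
    beta_s = 0.0
    beta_ns = 0.0
    if not atom.is_hydrogen:
        for nb, bond in mol.heavy_neighbors(atom.index):
            beta_s += sigma_contribution(atom, nb)
            if bond.aromatic:
                beta_ns += AROMATIC_NS
            elif bond.order >= 2:
                beta_ns += (bond.order - 1) * pi_contribution(atom, nb)
        if _conjugated_lone_pair(atom, mol):
            beta_ns += LONE_PAIR_DELTA
    return AtomEtaValues(
        alpha=atomic_alpha(atom),
        epsilon=atomic_epsilon(atom),
        beta_s=beta_s,
        beta_ns=beta_ns,
    )


# ---------------------------------------------------------------------------
# Derived graphs
# ---------------------------------------------------------------------------

def _hydrogen_filled(mol_id: str, elements: list[str], heavy_bonds: list[tuple[int, int, int]]) -> Molecule:
    """Build a Molecule from a heavy skeleton, re-filling hydrogens to the
    standard valence of each element."""
    from .chemio import _element_info  # shared element table

    atoms: list[Atom] = []
    for i, el in enumerate(elements):
        zv, pn = _element_info(el)
        z = {"H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Si": 14,
             "P": 15, "S": 16, "Cl": 17, "Br": 35, "I": 53}[el]
        atoms.append(Atom(index=i, element=el, Z=z, Zv=zv, PN=pn, is_hydrogen=False))
    bonds = [Bond(i, j, o) for i, j, o in heavy_bonds]
    order_sum = {i: 0 for i in range(len(elements))}
    for i, j, o in heavy_bonds:
        order_sum[i] += o
        order_sum[j] += o
    next_idx = len(elements)
    for i, el in enumerate(elements):
        n_h = max(0, _STANDARD_VALENCE[el] - order_sum[i])
        for _ in range(n_h):
            atoms.append(Atom(index=next_idx, element="H", Z=1, Zv=1, PN=1, is_hydrogen=True))
            bonds.append(Bond(i, next_idx, 1))
            next_idx += 1
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds)


def reference_alkane(mol: Molecule) -> Molecule:
    """All heteroatoms replaced by carbon; all bonds single; H re-filled."""
    heavy = mol.heavy_atoms()
    remap = {a.index: i for i, a in enumerate(heavy)}
    bonds = [(remap[b.i], remap[b.j], 1) for b in mol.heavy_bonds()]
    return _hydrogen_filled(f"{mol.id}|ref_alkane", ["C"] * len(heavy), bonds)


def saturated_skeleton(mol: Molecule) -> Molecule:
    """Heteroatoms kept; carbon-carbon multiple bonds demoted to single."""
    heavy = mol.heavy_atoms()
    remap = {a.index: i for i, a in enumerate(heavy)}
    elements = [a.element for a in heavy]
    bonds = []
    atom_by_idx = {a.index: a for a in heavy}
    for b in mol.heavy_bonds():
        cc = atom_by_idx[b.i].element == "C" and atom_by_idx[b.j].element == "C"
        order = 1 if cc else b.order
        bonds.append((remap[b.i], remap[b.j], order))
    return _hydrogen_filled(f"{mol.id}|sat_skeleton", elements, bonds)


def _strip_donor_hydrogens(mol: Molecule) -> list[Atom]:
    """Atoms of the molecule with hydrogens bonded to N, O or S removed."""
    donors = {"N", "O", "S"}
    kept = []
    for a in mol.atoms:
        if a.is_hydrogen:
            nb_idx = mol.neighbors(a.index)[0][0]
            if mol.atoms[nb_idx].element in donors:
                continue
        kept.append(a)
    return kept


# ---------------------------------------------------------------------------
# Epsilon variants and composites
# ---------------------------------------------------------------------------

def _mean_epsilon(atoms: list[Atom]) -> float:
    return sum(atomic_epsilon(a) for a in atoms) / len(atoms)


def epsilon_variants(mol: Molecule) -> tuple[float, float, float, float, float]:
    """The five mean-electronegativity variants (epsilon_1 ... epsilon_5)."""
    eps1 = _mean_epsilon(mol.heavy_atoms())
    eps2 = _mean_epsilon(mol.atoms)
    eps3 = _mean_epsilon(reference_alkane(mol).atoms)
    eps4 = _mean_epsilon(saturated_skeleton(mol).atoms)
    eps5 = _mean_epsilon(_strip_donor_hydrogens(mol))
    return eps1, eps2, eps3, eps4, eps5


def _eta_index(mol: Molecule, local: bool = False) -> float:
    """Composite eta: sum over heavy-atom pairs of sqrt(gamma_i gamma_j)/d_ij.

    ``local=True`` restricts to bonded pairs (d = 1).  Single-heavy-atom
    molecules return 0.
    """
    heavy = mol.heavy_atoms()
    if len(heavy) < 2:
        return 0.0
    gamma = {a.index: atom_beta(a, mol).gamma for a in heavy}
    if local:
        return sum(math.sqrt(gamma[b.i] * gamma[b.j]) for b in mol.heavy_bonds())
    g = mol.heavy_graph()
    total = 0.0
    dist = dict(nx.all_pairs_shortest_path_length(g))
    idxs = [a.index for a in heavy]
    for ii, i in enumerate(idxs):
        for j in idxs[ii + 1:]:
            total += math.sqrt(gamma[i] * gamma[j]) / dist[i][j]
    return total


def eta_composite(mol: Molecule) -> dict[str, float]:
    """Full composite ETA descriptor block for one molecule.

    Returns a name -> value mapping using the descriptor-software column
    convention (``ETA_dEpsilon_D``, ``ETA_EtaP_F``, ...), plus the raw
    counts ``Nv``, ``N``, ``NR`` and ``Nss``.
    """
    heavy = mol.heavy_atoms()
    if not heavy:
        raise MoleculeError(f"{mol.id}: no heavy atoms")
    nv = len(heavy)
    n_all = mol.n_atoms()
    ref = reference_alkane(mol)
    sat = saturated_skeleton(mol)

    eps1, eps2, eps3, eps4, eps5 = epsilon_variants(mol)

    per_atom = {a.index: atom_beta(a, mol) for a in heavy}
    alpha_sum = sum(v.alpha for v in per_atom.values())
    beta_s_sum = sum(v.beta_s for v in per_atom.values())
    beta_ns_sum = sum(v.beta_ns for v in per_atom.values())
    beta_sum = beta_s_sum + beta_ns_sum
    mean_alpha = alpha_sum / nv

    eta = _eta_index(mol)
    eta_r = _eta_index(ref)
    eta_local = _eta_index(mol, local=True)
    eta_f = eta_r - eta

    # Branching/shape read off alpha shares by heavy-atom degree.
    degree = {a.index: len(mol.heavy_neighbors(a.index)) for a in heavy}
    def _alpha_share(target_degree: int) -> float:
        s = sum(per_atom[i].alpha for i in degree if degree[i] == target_degree)
        return s / alpha_sum if alpha_sum > 0 else 0.0

    eps_sum_all = sum(atomic_epsilon(a) for a in mol.atoms)

    values: dict[str, float] = {
        "Nv": float(nv),
        "N": float(n_all),
        "NR": float(ref.n_atoms()),
        "Nss": float(sat.n_atoms()),
        "ETA_Alpha": alpha_sum,
        "ETA_AlphaP": mean_alpha,
        "ETA_dAlpha_A": max(0.0, mean_alpha - REFERENCE_ALPHA_PER_VERTEX),
        "ETA_dAlpha_B": max(0.0, REFERENCE_ALPHA_PER_VERTEX - mean_alpha),
        "ETA_Epsilon_1": eps1,
        "ETA_Epsilon_2": eps2,
        "ETA_Epsilon_3": eps3,
        "ETA_Epsilon_4": eps4,
        "ETA_Epsilon_5": eps5,
        "ETA_dEpsilon_A": eps1 - eps3,
        "ETA_dEpsilon_B": eps1 - eps4,
        "ETA_dEpsilon_C": eps3 - eps4,
        "ETA_dEpsilon_D": eps5 - eps2,
        "ETA_Beta_s": beta_s_sum,
        "ETA_BetaP_s": beta_s_sum / nv,
        "ETA_Beta_ns": beta_ns_sum,
        "ETA_BetaP_ns": beta_ns_sum / nv,
        "ETA_Beta": beta_sum,
        "ETA_BetaP": beta_sum / nv,
        "ETA_Eta": eta,
        "ETA_EtaP": eta / nv,
        "ETA_Eta_R": eta_r,
        "ETA_Eta_F": eta_f,
        "ETA_EtaP_F": eta_f / nv,
        "ETA_Eta_L": eta_local,
        "ETA_EtaP_L": eta_local / nv,
        "ETA_Shape_P": _alpha_share(1),
        "ETA_Shape_Y": _alpha_share(3),
        "ETA_Shape_X": _alpha_share(4),
        "ETA_Psi_1": alpha_sum / eps_sum_all if eps_sum_all > 0 else 0.0,
    }
    for name, v in values.items():
        if not math.isfinite(v):
            raise MoleculeError(f"{mol.id}: non-finite descriptor {name}")
    return values


def compute_descriptor_table(mols: list[Molecule]) -> pd.DataFrame:
    """Descriptor matrix for a molecule set, one row per compound id."""
    rows = {m.id: eta_composite(m) for m in mols}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df
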
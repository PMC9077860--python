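"""Synthetic molecule sets and activities for pipeline testing.

The generator emulates the statistical shape of a small plant-derived
larvicide dataset: 40-80 monoterpene/phenylpropanoid-like organics
(C/H/O/Cl, <= 25 heavy atoms, carbocyclic and aromatic cores, a mix of
hydroxy/methoxy/chloro/ester/alkyl/alkenyl substituents), with activity
built as a linear function of a small subset of ETA descriptors plus
Gaussian noise.  Only that linear signal-plus-noise structure is
emulated — no real structure-activity relationship is implied.

``fixtures()`` additionally ships curated SMILES for the named study
compounds used throughout the descriptor discussion (camphene,
limonene, resorcinol, the thymyl/carvacryl esters, ...), keyed by their
study compound numbers.  The SMILES are curated from the systematic
names; stereochemistry is irrelevant to the 2D descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemio import Molecule, canonical_smiles, from_rdkit
from .eta import compute_descriptor_table
from .preprocess import DescriptorTable

# Curated named compounds (study numbering).  Enantiomer pairs (50/54)
# intentionally share one graph: topological descriptors are stereo-blind.
FIXTURE_SMILES: dict[str, tuple[str, str]] = {
    "1": ("CC1(C)C2CCC(C2)C1=C", "(-)-camphene"),
    "3": ("CC(C)C12CCC(C)(CC1)O2", "1,4-cineole"),
    "4": ("CC12CCC(CC1)C(C)(C)O2", "1,8-cineole"),
    "8": ("Cc1ccc(C(C)C)cc1OC(=O)C(Cl)(Cl)Cl", "carvacryl trichloroacetate"),
    "10": ("Cc1ccc(C(C)C)cc1OC(=O)c1ccccc1", "carvacryl benzoate"),
    "14": ("Cc1ccc(C(C)C)c(OC(=O)CCl)c1", "thymyl chloroacetate"),
    "15": ("Cc1ccc(C(C)C)c(OC(=O)C(Cl)(Cl)Cl)c1", "thymyl trichloroacetate"),
    "23": ("OCC1C(CO)C2CC1C=C2", "5-norbornene-2-endo-3-endo-dimethanol"),
    "26": ("COc1cc(CC=C)ccc1OCC(=O)O", "2-[2-methoxy-4-(2-propen-1-yl)phenoxy]acetic acid"),
    "35": ("COc1cc(CCCO)ccc1O", "4-hydroxy-3-methoxy-benzenepropanol"),
    "44": ("CC12OC1CC(C(=C)C)CC2=O", "1,2-carvone oxide"),
    "49": ("Oc1cccc(O)c1", "resorcinol"),
    "50": ("CC1=CCC(CC1)C(=C)C", "R-limonene"),
    "54": ("CC1=CCC(CC1)C(=C)C", "S-limonene"),
    "59": ("CC1=CCC2CC1C2(C)C", "3-carene"),
}

_CORES = {  # (SMILES, weight)
    "cyclohexane": ("C1CCCCC1", 0.4),
    "benzene": ("c1ccccc1", 0.4),
    "decalin": ("C1CCC2CCCCC2C1", 0.2),
}

# substituent fragments; attachment point is atom 0 of the fragment SMILES
_SUBSTITUENTS = {  # name: (SMILES, heteroatoms?, weight)
    "methyl": ("C", False, 0.20),
    "isopropyl": ("C(C)C", False, 0.15),
    "vinyl": ("C=C", False, 0.10),
    "allyl": ("CC=C", False, 0.10),
    "hydroxy": ("O", True, 0.13),
    "methoxy": ("OC", True, 0.12),
    "chloro": ("Cl", True, 0.08),
    "acetoxy": ("OC(C)=O", True, 0.12),
}

MAX_HEAVY_ATOMS = 25


@dataclass
class SyntheticSpec:
    """Conditions for synthetic molecule/activity generation."""

    n_compounds: int = 60
    max_substituents: int = 3
    true_subset: tuple[str, ...] = ("ETA_dEpsilon_D", "ETA_EtaP_F", "ETA_BetaP_s")
    true_coefficients: tuple[float, ...] = (-1.0, 0.8, -0.6)
    noise_sd: float | None = None   # absolute noise SD; exclusive with snr
    snr: float | None = 9.0         # signal:noise variance ratio
    seed: int = 0
    core_weights: dict[str, float] = field(
        default_factory=lambda: {k: w for k, (_, w) in _CORES.items()}
    )
    substituent_weights: dict[str, float] = field(
        default_factory=lambda: {k: w for k, (_, _, w) in _SUBSTITUENTS.items()}
    )

    def __post_init__(self) -> None:
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.true_subset) != len(self.true_coefficients):
            raise ValueError("true_subset and true_coefficients lengths differ")


def _attach(core: Chem.RWMol, frag_smiles: str, site: int) -> None:
    frag = Chem.MolFromSmiles(frag_smiles)
    offset = core.GetNumAtoms()
    for a in frag.GetAtoms():
        na = Chem.Atom(a.GetAtomicNum())
        core.AddAtom(na)
    for b in frag.GetBonds():
        core.AddBond(offset + b.GetBeginAtomIdx(), offset + b.GetEndAtomIdx(), b.GetBondType())
    core.AddBond(site, offset, Chem.BondType.SINGLE)


def generate_molecules(spec: SyntheticSpec) -> list[Molecule]:
    """Seeded grammar-based construction of valence-correct molecules.

    Cores (cyclohexane / benzene / decalin) receive 0-``max_substituents``
    substituents at random carbons with a free hydrogen; duplicates (by
    canonical SMILES) are discarded and generation continues until
    ``n_compounds`` distinct molecules exist.
    """
    rng = np.random.default_rng(spec.seed)
    core_names = list(spec.core_weights)
    core_p = np.array([spec.core_weights[c] for c in core_names], float)
    core_p /= core_p.sum()
    sub_names = list(spec.substituent_weights)
    sub_p = np.array([spec.substituent_weights[s] for s in sub_names], float)
    sub_p /= sub_p.sum()

    seen: set[str] = set()
    out: list[Molecule] = []
    attempts = 0
    while len(out) < spec.n_compounds and attempts < spec.n_compounds * 200:
        attempts += 1
        core_name = core_names[int(rng.choice(len(core_names), p=core_p))]
        rw = Chem.RWMol(Chem.MolFromSmiles(_CORES[core_name][0]))
        n_sub = int(rng.integers(0, spec.max_substituents + 1))
        for _ in range(n_sub):
            sites = [
                a.GetIdx() for a in rw.GetAtoms()
                if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1 and a.GetIdx() < rw.GetNumAtoms()
            ]
            if not sites:
                break
            site = int(sites[int(rng.integers(len(sites)))])
            frag = sub_names[int(rng.choice(len(sub_names), p=sub_p))]
            _attach(rw, _SUBSTITUENTS[frag][0], site)
            try:
                Chem.SanitizeMol(rw)
            except Exception:
                break
        try:
            Chem.SanitizeMol(rw)
        except Exception:
            continue
        if rw.GetNumHeavyAtoms() > MAX_HEAVY_ATOMS:
            continue
        smi = Chem.MolToSmiles(rw)
        if smi in seen:
            continue
        seen.add(smi)
        out.append(from_rdkit(Chem.MolFromSmiles(smi), f"syn{len(out) + 1:03d}"))
    if len(out) < spec.n_compounds:
        raise RuntimeError("grammar failed to produce enough distinct molecules")
    return out


def generate_activity(mols: list[Molecule], spec: SyntheticSpec) -> pd.Series:
    """Linear activity ``y = sum_j c_j z_j + noise`` on autoscaled descriptors.

    With ``spec.snr`` set, the noise SD is chosen so that the realized
    signal-to-noise variance ratio matches; ``spec.noise_sd`` fixes it
    absolutely instead.
    """
    table = compute_descriptor_table(mols)
    missing = [c for c in spec.true_subset if c not in table.columns]
    if missing:
        raise ValueError(f"true_subset names not computable: {missing}")
    Z = table[list(spec.true_subset)].to_numpy(dtype=float)
    sd = Z.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Z - Z.mean(axis=0)) / sd
    signal = Z @ np.asarray(spec.true_coefficients, float)
    if spec.noise_sd is not None:
        noise_sd = spec.noise_sd
    elif spec.snr is not None and spec.snr > 0:
        noise_sd = float(signal.std(ddof=1)) / np.sqrt(spec.snr)
    else:
        noise_sd = 0.0
    rng = np.random.default_rng(spec.seed + 7_919)
    y = signal + rng.normal(0.0, noise_sd, size=len(signal))
    return pd.Series(y, index=table.index, name="pLC50")


def generate_dataset(spec: SyntheticSpec) -> tuple[list[Molecule], DescriptorTable]:
    """Molecules plus their full descriptor table joined with activity."""
    mols = generate_molecules(spec)
    y = generate_activity(mols, spec)
    table = compute_descriptor_table(mols)
    return mols, DescriptorTable(table, y)


# ---------------------------------------------------------------------------
# Selection-recovery study
# ---------------------------------------------------------------------------

def recovery_pool(
    spec: SyntheticSpec,
    pool_size: int = 30,
    truth_corr_cut: float = 0.7,
    corr_cut: float = 0.95,
) -> DescriptorTable:
    """Descriptor pool for the GA selection-recovery study.

    Recovery of a known true subset is only a well-posed question when the
    distractors are not near-proxies of the truth, so the pool is built as:
    the true-subset columns; every other computed descriptor whose
    correlation with each truth column stays below ``truth_corr_cut``
    (near-duplicate distractor pairs at |r| >= ``corr_cut`` pruned,
    keeping the higher-variance member); and seeded standard-normal noise
    columns (``NOISE_01`` ...) padding the pool to ``pool_size``.
    """
    mols = generate_molecules(spec)
    table = compute_descriptor_table(mols)
    y = generate_activity(mols, spec)
    truth = list(spec.true_subset)

    X = table.copy()
    sds = X.std(ddof=1)
    X = X[[c for c in X.columns if sds[c] >= 1e-4]]
    corr = X.corr().abs()
    proxies = [c for c in X.columns
               if c not in truth and corr.loc[c, truth].max() >= truth_corr_cut]
    X = X.drop(columns=proxies)

    corr = X.corr().abs()
    cols = list(X.columns)
    var = X.var(ddof=1)
    dropped: set[str] = set()
    for a_pos, a in enumerate(cols):
        if a in dropped:
            continue
        for b in cols[a_pos + 1:]:
            if b in dropped:
                continue
            if corr.loc[a, b] >= corr_cut:
                if a in truth:
                    victim = b
                elif b in truth:
                    victim = a
                else:
                    victim = a if var[a] < var[b] else b
                dropped.add(victim)
                if victim == a:
                    break
    X = X.drop(columns=sorted(dropped, key=cols.index))

    rng = np.random.default_rng(spec.seed + 17)
    i = 1
    while X.shape[1] < pool_size:
        X[f"NOISE_{i:02d}"] = rng.normal(size=len(X))
        i += 1
    return DescriptorTable(X.iloc[:, :pool_size], y)


def recovery_trial(seed: int, pool_size: int = 30) -> dict:
    """One seeded end-to-end selection-recovery run.

    Generates the dataset, builds the recovery pool, divides train/test by
    k-medoids, runs the GA under double cross-validation and reports
    whether the top model contains the true subset plus its external
    predictivity.
    """
    from .preprocess import divide
    from .select import DcvConfig, dcv_report, run_ga

    spec = SyntheticSpec(seed=seed)
    pool = recovery_pool(spec, pool_size=pool_size)
    division = divide(pool, seed=seed)
    train = pool.subset_rows(division.train_ids)
    test = pool.subset_rows(division.test_ids)
    candidates = run_ga(train, DcvConfig(seed=seed))
    report = dcv_report(candidates, train, test, top_m=1)[0]
    return {
        "seed": seed,
        "true_subset": list(spec.true_subset),
        "selected": report["descriptors"],
        "contains_truth": set(spec.true_subset) <= set(report["descriptors"]),
        "q2_f1": report["q2_f1"],
        "fitness": report["fitness"],
    }


def fixtures() -> dict[str, Molecule]:
    """Named study compounds keyed by their compound number."""
    out = {}
    for num, (smi, name) in FIXTURE_SMILES.items():
        out[num] = from_rdkit(Chem.MolFromSmiles(smi), num, name=name)
    return out
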
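"""Molecular descriptor engine.

Two families feed the QSAR design matrix:

* 2D (topological) descriptors computed on the hydrogen-suppressed graph:
  Broto–Moreau / centered / averaged autocorrelations, Moran and Geary
  coefficients, Burden-matrix eigenvalues, electrotopological state (E-state)
  atom types, the nitrogen-rooted weighted path sum (WTPT-5), Galvez
  topological charge indices and the Mannhold logP estimate.

* 3D radial distribution function (RDF) descriptors: for every grid radius r
  and every unordered atom pair (i, j),

      RDF(r) = sum_{i<j} p_i * p_j * exp(-B * (r - r_ij)^2),

  with p the partial charges, r_ij the Euclidean distance and B a fuzziness
  parameter. The pair sum is partitioned by charge-sign pattern into three
  sets — (a) one positive and one negative charge, (b) both positive,
  (c) both negative — of one descriptor per grid point each.

Every descriptor here is defined exactly by the formulas in this module (no
external descriptor package is involved), so the test suite can check each
one against an independent brute-force implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .chem_io import ChemError, Molecule, MoleculeRecord

# ---------------------------------------------------------------------------
# Atomic property tables
# ---------------------------------------------------------------------------

#: Version tag for the element-level property tables below.
PROPERTY_TABLE_VERSION = "2026.1"

#: Per-element properties: standard atomic mass (u), Bondi van der Waals
#: volume (A^3), Sanderson electronegativity (dimensionless), dipole
#: polarizability (A^3), first ionization potential (eV).
ELEMENT_PROPERTIES: dict[str, dict[str, float]] = {
    #        mass     vdw_vol  sanderson  polariz.  ion.pot
    "H": {"m": 1.008, "v": 7.24, "e": 2.592, "p": 0.667, "i": 13.598},
    "C": {"m": 12.011, "v": 20.58, "e": 2.746, "p": 1.760, "i": 11.260},
    "N": {"m": 14.007, "v": 15.60, "e": 3.194, "p": 1.100, "i": 14.534},
    "O": {"m": 15.999, "v": 14.71, "e": 3.654, "p": 0.802, "i": 13.618},
    "S": {"m": 32.06, "v": 24.43, "e": 2.957, "p": 2.900, "i": 10.360},
    "P": {"m": 30.974, "v": 24.43, "e": 2.515, "p": 3.630, "i": 10.487},
    "F": {"m": 18.998, "v": 13.31, "e": 4.000, "p": 0.557, "i": 17.423},
    "Cl": {"m": 35.45, "v": 22.45, "e": 3.475, "p": 2.180, "i": 12.968},
    "Br": {"m": 79.904, "v": 26.52, "e": 3.219, "p": 3.050, "i": 11.814},
    "I": {"m": 126.904, "v": 32.52, "e": 2.778, "p": 5.350, "i": 10.451},
}

#: Valence electron counts.
VALENCE_ELECTRONS = {
    "H": 1, "C": 4, "N": 5, "O": 6, "S": 6, "P": 5,
    "F": 7, "Cl": 7, "Br": 7, "I": 7,
}

#: Principal quantum number of the valence shell.
PRINCIPAL_QUANTUM = {
    "H": 1, "C": 2, "N": 2, "O": 2, "F": 2,
    "S": 3, "P": 3, "Cl": 3, "Br": 4, "I": 5,
}

#: Intrinsic-state value of an sp3 carbon, used as the carbon reference when
#: Burden diagonals are weighted by I-state.
ISTATE_CARBON_REF = 2.0

#: Weight codes: element-level m/v/e/p/i, per-atom c (partial charge) and
#: s (intrinsic E-state value).
WEIGHT_CODES = ("m", "v", "e", "p", "i", "c", "s")
WEIGHT_NAMES = {
    "m": "mass",
    "v": "van_der_waals_volume",
    "e": "sanderson_electronegativity",
    "p": "polarizability",
    "i": "first_ionization_potential",
    "c": "partial_charge",
    "s": "intrinsic_state",
}

AUTOCORR_VARIANTS = ("ATS", "ATSC", "AATS", "AATSC", "Moran", "Geary")


class DescriptorError(ChemError):
    pass


# ---------------------------------------------------------------------------
# Graph substrate
# ---------------------------------------------------------------------------

def topo_distance_matrix(mol: Molecule) -> np.ndarray:
    """Shortest-path length matrix over heavy atoms (H-suppressed graph).

    Returns an (n_heavy, n_heavy) integer matrix indexed in heavy-atom order.
    Disconnected heavy-atom graphs are an error: standardize first.
    """
    heavy = mol.heavy_indices()
    g = mol.graph(heavy_only=True)
    n = len(heavy)
    pos = {a: k for k, a in enumerate(heavy)}
    D = np.full((n, n), -1, dtype=int)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            D[pos[src], pos[dst]] = d
    if np.any(D < 0):
        raise DescriptorError(
            f"molecule {mol.id!r}: heavy-atom graph is disconnected; standardize first"
        )
    return D


def _heavy_weights(mol: Molecule, weight: str) -> np.ndarray:
    """Per-heavy-atom weight vector for a weight code or name."""
    code = weight if weight in WEIGHT_CODES else {
        v: k for k, v in WEIGHT_NAMES.items()
    }.get(weight)
    if code is None:
        raise DescriptorError(f"unknown weight: {weight!r}")
    heavy = mol.heavy_indices()
    if code == "c":
        vals = []
        for i in heavy:
            q = mol.atoms[i].partial_charge
            if q is None:
                raise DescriptorError(
                    f"molecule {mol.id!r}: partial charges not assigned "
                    f"(needed for charge weighting)"
                )
            vals.append(q)
        return np.array(vals, dtype=float)
    if code == "s":
        return intrinsic_states(mol)
    return np.array(
        [ELEMENT_PROPERTIES[mol.atoms[i].element][code] for i in heavy], dtype=float
    )


# ---------------------------------------------------------------------------
# Autocorrelation descriptors
# ---------------------------------------------------------------------------

def autocorrelation(
    mol: Molecule,
    weight: str,
    lag: int,
    variant: str,
    _D: np.ndarray | None = None,
) -> float:
    """Topological autocorrelation of one weighting at one lag.

    With P_d the unordered heavy-atom pairs at topological distance d,
    Delta = |P_d|, w_bar the mean weight and n the heavy-atom count:

    * ATS_d   = sum_{P_d} w_i w_j                       (Broto–Moreau)
    * ATSC_d  = the same with centered weights w - w_bar
    * AATS_d  = ATS_d / Delta,  AATSC_d = ATSC_d / Delta
    * Moran_d = [sum_{P_d}(w_i-w_bar)(w_j-w_bar)/Delta] / [sum_i(w_i-w_bar)^2/n]
    * Geary_d = [sum_{P_d}(w_i-w_j)^2/(2 Delta)] / [sum_i(w_i-w_bar)^2/(n-1)]

    Returns NaN when no pair exists at the lag, or when the Moran/Geary
    denominator has zero variance.
    """
    if lag < 1:
        raise DescriptorError("lag must be >= 1")
    if variant not in AUTOCORR_VARIANTS:
        raise DescriptorError(f"unknown autocorrelation variant: {variant!r}")
    D = topo_distance_matrix(mol) if _D is None else _D
    w = _heavy_weights(mol, weight)
    n = len(w)
    ii, jj = np.where(np.triu(D == lag, k=1))
    delta = len(ii)
    if delta == 0:
        return float("nan")
    wc = w - w.mean()
    if variant == "ATS":
        return float(np.sum(w[ii] * w[jj]))
    if variant == "ATSC":
        return float(np.sum(wc[ii] * wc[jj]))
    if variant == "AATS":
        return float(np.sum(w[ii] * w[jj]) / delta)
    if variant == "AATSC":
        return float(np.sum(wc[ii] * wc[jj]) / delta)
    denom_var = float(np.sum(wc**2))
    if denom_var == 0.0:
        return float("nan")
    if variant == "Moran":
        return float((np.sum(wc[ii] * wc[jj]) / delta) / (denom_var / n))
    # Geary
    if n < 2:
        return float("nan")
    return float(
        (np.sum((w[ii] - w[jj]) ** 2) / (2 * delta)) / (denom_var / (n - 1))
    )


# ---------------------------------------------------------------------------
# Burden eigenvalues
# ---------------------------------------------------------------------------

def burden_matrix(mol: Molecule, weight: str) -> np.ndarray:
    """Symmetric Burden connectivity matrix over heavy atoms.

    Diagonal: atom weight relative to carbon's value. Off-diagonal for bonded
    pairs: 0.1 x conventional bond order (aromatic = 1.5), plus 0.01 if either
    atom has heavy-atom degree 1; all non-bonded pairs: 0.001.
    """
    heavy = mol.heavy_indices()
    pos = {a: k for k, a in enumerate(heavy)}
    n = len(heavy)
    if weight == "s" or WEIGHT_NAMES.get("s") == weight:
        diag = intrinsic_states(mol) / ISTATE_CARBON_REF
    else:
        code = weight if weight in WEIGHT_CODES else {
            v: k for k, v in WEIGHT_NAMES.items()
        }.get(weight)
        if code is None or code == "c":
            raise DescriptorError(
                f"Burden weighting requires an element-level property or "
                f"intrinsic state, got {weight!r}"
            )
        ref = ELEMENT_PROPERTIES["C"][code]
        diag = np.array(
            [ELEMENT_PROPERTIES[mol.atoms[i].element][code] / ref for i in heavy]
        )
    B = np.full((n, n), 0.001)
    np.fill_diagonal(B, diag)
    degree = np.zeros(n, dtype=int)
    for b in mol.bonds:
        if b.a1 in pos and b.a2 in pos:
            degree[pos[b.a1]] += 1
            degree[pos[b.a2]] += 1
    for b in mol.bonds:
        if b.a1 in pos and b.a2 in pos:
            i, j = pos[b.a1], pos[b.a2]
            val = 0.1 * b.conventional_order()
            if degree[i] == 1 or degree[j] == 1:
                val += 0.01
            B[i, j] = B[j, i] = val
    return B


def burden_spectrum(mol: Molecule, weight: str) -> np.ndarray:
    """Sorted (ascending) eigenvalues of the Burden matrix."""
    return np.linalg.eigvalsh(burden_matrix(mol, weight))


def spmin(mol: Molecule, weight: str, k: int) -> float:
    """k-th smallest Burden eigenvalue; NaN if k exceeds the atom count."""
    ev = burden_spectrum(mol, weight)
    return float(ev[k - 1]) if 1 <= k <= len(ev) else float("nan")


def spmax(mol: Molecule, weight: str, k: int) -> float:
    """k-th largest Burden eigenvalue; NaN if k exceeds the atom count."""
    ev = burden_spectrum(mol, weight)
    return float(ev[-k]) if 1 <= k <= len(ev) else float("nan")


# ---------------------------------------------------------------------------
# Electrotopological state
# ---------------------------------------------------------------------------

def intrinsic_states(mol: Molecule) -> np.ndarray:
    """Kier–Hall intrinsic state I per heavy atom.

    I = ((2/L)^2 * delta_v + 1) / delta, with L the principal quantum number,
    delta_v = (valence electrons) - (bonded hydrogens) and delta the
    heavy-atom connectivity. An isolated heavy atom (delta = 0) yields NaN.
    """
    heavy = mol.heavy_indices()
    out = np.empty(len(heavy))
    for k, i in enumerate(heavy):
        a = mol.atoms[i]
        delta = sum(1 for j in mol.neighbors(i) if not mol.atoms[j].is_hydrogen)
        delta_v = VALENCE_ELECTRONS[a.element] - mol.h_count(i)
        if delta == 0:
            out[k] = np.nan
            continue
        L = PRINCIPAL_QUANTUM[a.element]
        out[k] = ((2.0 / L) ** 2 * delta_v + 1.0) / delta
    return out


def estate_values(mol: Molecule) -> np.ndarray:
    """E-state index S per heavy atom.

    S_i = I_i + sum_{j != i} (I_i - I_j) / (d_ij + 1)^2 over heavy atoms,
    with d the topological distance.
    """
    I = intrinsic_states(mol)
    D = topo_distance_matrix(mol)
    n = len(I)
    S = I.copy()
    for i in range(n):
        for j in range(n):
            if i != j:
                S[i] += (I[i] - I[j]) / (D[i, j] + 1.0) ** 2
    return S


def hydrogen_estate_values(mol: Molecule) -> np.ndarray:
    """Hydrogen E-state per heavy atom (NaN where no hydrogen is attached).

    Uses the Kier–Hall atom-level electronegativity KHE = (delta_v - delta)/L^2
    in place of the intrinsic state:
    HS_i = KHE_i + sum_{j != i} (KHE_i - KHE_j) / (d_ij + 1)^2.
    """
    heavy = mol.heavy_indices()
    D = topo_distance_matrix(mol)
    n = len(heavy)
    khe = np.empty(n)
    has_h = np.zeros(n, dtype=bool)
    for k, i in enumerate(heavy):
        a = mol.atoms[i]
        delta = sum(1 for j in mol.neighbors(i) if not mol.atoms[j].is_hydrogen)
        delta_v = VALENCE_ELECTRONS[a.element] - mol.h_count(i)
        khe[k] = (delta_v - delta) / PRINCIPAL_QUANTUM[a.element] ** 2
        has_h[k] = mol.h_count(i) > 0
    HS = khe.copy()
    for i in range(n):
        for j in range(n):
            if i != j:
                HS[i] += (khe[i] - khe[j]) / (D[i, j] + 1.0) ** 2
    HS[~has_h] = np.nan
    return HS


def _single_bonded(mol: Molecule, i: int) -> bool:
    return all(
        b.order == 1 for b in mol.bonds if b.a1 == i or b.a2 == i
    )


def _match_atomtype(mol: Molecule, pattern: str) -> list[int]:
    """Heavy-atom indices (positions in heavy order) matching an atom type."""
    heavy = mol.heavy_indices()
    pos = {a: k for k, a in enumerate(heavy)}
    matches = []
    for i in heavy:
        a = mol.atoms[i]
        hdeg = sum(1 for j in mol.neighbors(i) if not mol.atoms[j].is_hydrogen)
        h = mol.h_count(i)
        if pattern == "ssssC":
            ok = a.element == "C" and h == 0 and hdeg == 4 and _single_bonded(mol, i)
        elif pattern == "ssCH2":
            ok = a.element == "C" and h == 2 and hdeg == 2 and _single_bonded(mol, i)
        elif pattern == "HCsats":
            ok = (
                a.element == "C"
                and h > 0
                and _single_bonded(mol, i)
                and all(
                    _single_bonded(mol, j)
                    for j in mol.neighbors(i)
                    if not mol.atoms[j].is_hydrogen
                )
            )
        elif pattern == "wHBa":
            ok = (
                a.element in ("O", "S")
                and h == 0
                and hdeg == 2
                and _single_bonded(mol, i)
            )
        else:
            raise DescriptorError(f"unknown atom-type pattern: {pattern!r}")
        if ok:
            matches.append(pos[i])
    return matches


def estate_atomtype(mol: Molecule, type_pattern: str, agg: str = "sum") -> float:
    """Aggregate E-state over atoms matching an atom-type pattern.

    Patterns: ``ssssC`` (quaternary carbon), ``ssCH2`` (methylene with two
    heavy single bonds), ``HCsats`` (hydrogens on saturated carbons in a
    saturated environment; uses the hydrogen E-state), ``wHBa`` (weak
    hydrogen-bond acceptors: ether-type divalent O and divalent S).
    Returns NaN when no atom matches.
    """
    if agg not in ("sum", "max", "min"):
        raise DescriptorError(f"unknown aggregation: {agg!r}")
    matches = _match_atomtype(mol, type_pattern)
    if not matches:
        return float("nan")
    values = (
        hydrogen_estate_values(mol) if type_pattern == "HCsats" else estate_values(mol)
    )
    sel = values[matches]
    return float({"sum": np.sum, "max": np.max, "min": np.min}[agg](sel))


# ---------------------------------------------------------------------------
# Weighted paths, charge indices, logP
# ---------------------------------------------------------------------------

def weighted_path_nitrogen(mol: Molecule) -> float:
    """Sum of Randic path weights over simple paths starting at nitrogens.

    Each nitrogen contributes 1 (its self term) plus, for every simple path of
    length >= 1 starting there, the product over path bonds of
    1/sqrt(deg_i * deg_j), degrees taken in the H-suppressed graph. Molecules
    without nitrogen score 0.
    """
    g = mol.graph(heavy_only=True)
    deg = dict(g.degree())
    total = 0.0
    for start in g.nodes:
        if mol.atoms[start].element != "N":
            continue
        total += 1.0
        # iterative DFS over simple paths rooted at `start`
        stack: list[tuple[int, set[int], float]] = [(start, {start}, 1.0)]
        while stack:
            node, visited, w = stack.pop()
            for nb in g.neighbors(node):
                if nb in visited:
                    continue
                w2 = w / np.sqrt(deg[node] * deg[nb])
                total += w2
                stack.append((nb, visited | {nb}, w2))
    return float(total)


def topological_charge_index(mol: Molecule, k: int) -> tuple[float, float]:
    """Galvez topological charge indices (GGI_k, JGI_k).

    M = A.Q with A the heavy-atom adjacency matrix and Q_ij = 1/d_ij^2 for
    i != j (topological distances), Q_ii = 0. The charge-transfer term is
    CT_ij = M_ij - M_ji; GGI_k sums |CT_ij| over pairs at distance k and
    JGI_k = GGI_k/(n-1). Returns (NaN, NaN) when no pair sits at distance k.
    """
    D = topo_distance_matrix(mol)
    n = D.shape[0]
    if n < 2:
        raise DescriptorError("topological charge index needs >= 2 heavy atoms")
    A = (D == 1).astype(float)
    with np.errstate(divide="ignore"):
        Q = np.where(D > 0, 1.0 / np.maximum(D, 1) ** 2, 0.0)
    np.fill_diagonal(Q, 0.0)
    M = A @ Q
    CT = M - M.T
    mask = np.triu(D == k, k=1)
    if not mask.any():
        return float("nan"), float("nan")
    ggi = float(np.abs(CT)[mask].sum())
    return ggi, ggi / (n - 1)


def mannhold_logp(mol: Molecule) -> float:
    """Mannhold logP: 1.46 + 0.11*(nC) - 0.11*(non-carbon heavy atoms)."""
    nc = sum(1 for a in mol.atoms if a.element == "C")
    nhet = sum(1 for a in mol.atoms if not a.is_hydrogen and a.element != "C")
    return 1.46 + 0.11 * nc - 0.11 * nhet


# ---------------------------------------------------------------------------
# 3D RDF descriptors
# ---------------------------------------------------------------------------

@dataclass
class RDFConfig:
    """Grid and weighting for the charge-partitioned RDF descriptors.

    The grid is r_g = (r_max/n_bins)*g for g = 1..n_bins — with the defaults,
    128 points at 0.1 A spacing from 0.1 to 12.8 A (r = 0 is excluded: a pair
    distance of zero is chemically meaningless). ``fuzziness`` is the Gaussian
    exponent B in 1/A^2. ``absolute`` switches the pair products |p_i p_j| on
    for sensitivity checks; by default the signed products are kept, so the
    mixed-sign set (a) is non-positive and the like-sign sets (b), (c)
    non-negative. ``heavy_only`` drops hydrogens from the pair sum.
    """

    n_bins: int = 128
    r_max: float = 12.8
    fuzziness: float = 100.0
    heavy_only: bool = False
    absolute: bool = False

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.r_max <= 0 or self.fuzziness <= 0:
            raise DescriptorError("RDF grid parameters must be positive")

    @property
    def spacing(self) -> float:
        return self.r_max / self.n_bins

    @property
    def grid(self) -> np.ndarray:
        return self.spacing * np.arange(1, self.n_bins + 1)


RDF_SETS = ("a", "b", "c")


def rdf_descriptors(mol: Molecule, cfg: RDFConfig | None = None) -> np.ndarray:
    """Charge-sign-partitioned RDF vector, shape (3*n_bins,): sets a, b, c.

    Set membership by charge signs of the pair: a = (+,-), b = (+,+),
    c = (-,-). Atoms with exactly zero partial charge belong to no set.
    Requires assigned partial charges and 3D coordinates.
    """
    cfg = cfg or RDFConfig()
    idx = mol.heavy_indices() if cfg.heavy_only else list(range(len(mol.atoms)))
    q = []
    for i in idx:
        pc = mol.atoms[i].partial_charge
        if pc is None:
            raise DescriptorError(
                f"molecule {mol.id!r}: partial charges not assigned (required for RDF)"
            )
        q.append(pc)
    q = np.array(q)
    X = mol.coords_array()[idx]
    if len(idx) > 1 and np.allclose(X, X[0]):
        raise DescriptorError(
            f"molecule {mol.id!r}: no 3D coordinates (all atoms coincide)"
        )
    grid = cfg.grid
    out = np.zeros((3, cfg.n_bins))
    n = len(idx)
    if n >= 2:
        iu, ju = np.triu_indices(n, k=1)
        rij = np.linalg.norm(X[iu] - X[ju], axis=1)
        prod = q[iu] * q[ju]
        signs_i, signs_j = np.sign(q[iu]), np.sign(q[ju])
        sets = {
            "a": (signs_i * signs_j) < 0,
            "b": (signs_i > 0) & (signs_j > 0),
            "c": (signs_i < 0) & (signs_j < 0),
        }
        for s_idx, s in enumerate(RDF_SETS):
            m = sets[s]
            if not m.any():
                continue
            p = np.abs(prod[m]) if cfg.absolute else prod[m]
            gauss = np.exp(-cfg.fuzziness * (grid[None, :] - rij[m, None]) ** 2)
            out[s_idx] = p @ gauss
    return out.ravel()


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

@dataclass
class FeaturizeConfig:
    """Which descriptor families to compute and how to handle missing values."""

    autocorrelation: bool = True
    burden: bool = True
    estate: bool = True
    weighted_paths: bool = True
    charge_indices: bool = True
    logp: bool = True
    rdf: bool = True
    rdf_config: RDFConfig = field(default_factory=RDFConfig)
    lags: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    burden_k: int = 5
    #: 'zero' replaces missing values with 0 (recorded in the mask);
    #: 'strict' raises naming the molecule and descriptor.
    missing_policy: str = "zero"

    def __post_init__(self) -> None:
        if self.missing_policy not in ("zero", "strict"):
            raise DescriptorError(f"unknown missing policy: {self.missing_policy!r}")


#: E-state atom-type columns shipped by default: (name, pattern, aggregation).
ESTATE_COLUMNS = (
    ("SssssC", "ssssC", "sum"),
    ("maxssssC", "ssssC", "max"),
    ("SssCH2", "ssCH2", "sum"),
    ("minHCsats", "HCsats", "min"),
    ("SwHBa", "wHBa", "sum"),
)

BURDEN_WEIGHTS = ("m", "v", "e", "p", "i", "s")


@dataclass
class DescriptorMatrix:
    """Named design matrix with a missing-value mask and a column manifest."""

    values: pd.DataFrame
    missing_mask: pd.DataFrame
    manifest: list[dict]

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path, manifest_path=None) -> None:
        self.values.to_csv(path, index_label="id")
        if manifest_path is not None:
            with open(manifest_path, "w") as fh:
                json.dump(self.manifest, fh, indent=1)

    @classmethod
    def from_csv(cls, path, manifest_path=None) -> "DescriptorMatrix":
        values = pd.read_csv(path, index_col="id")
        manifest = []
        if manifest_path is not None:
            with open(manifest_path) as fh:
                manifest = json.load(fh)
        mask = values.isna()
        return cls(values=values.fillna(0.0), missing_mask=mask, manifest=manifest)


def _column_plan(cfg: FeaturizeConfig) -> list[dict]:
    """Deterministic column order: the manifest before any value is computed."""
    plan: list[dict] = []
    if cfg.autocorrelation:
        for variant in AUTOCORR_VARIANTS:
            for w in WEIGHT_CODES:
                for lag in cfg.lags:
                    plan.append(
                        {
                            "name": f"{variant}{lag}{w}",
                            "family": "autocorrelation",
                            "variant": variant,
                            "weight": WEIGHT_NAMES[w],
                            "lag": lag,
                        }
                    )
    if cfg.burden:
        for acc in ("SpMin", "SpMax"):
            for k in range(1, cfg.burden_k + 1):
                for w in BURDEN_WEIGHTS:
                    plan.append(
                        {
                            "name": f"{acc}{k}_Bh{w}",
                            "family": "burden",
                            "accessor": acc.lower(),
                            "k": k,
                            "weight": WEIGHT_NAMES[w],
                        }
                    )
    if cfg.estate:
        for name, pattern, agg in ESTATE_COLUMNS:
            plan.append(
                {"name": name, "family": "estate", "pattern": pattern, "agg": agg}
            )
    if cfg.weighted_paths:
        plan.append({"name": "WTPT-5", "family": "weighted_path"})
    if cfg.charge_indices:
        for k in (1, 2, 3):
            plan.append({"name": f"JGI{k}", "family": "topological_charge", "k": k})
    if cfg.logp:
        plan.append({"name": "MLogP", "family": "constitutional"})
    if cfg.rdf:
        grid = cfg.rdf_config.grid
        for s in RDF_SETS:
            for g in range(1, cfg.rdf_config.n_bins + 1):
                plan.append(
                    {
                        "name": f"RDF{s}_{g}",
                        "family": "rdf",
                        "set": s,
                        "bin": g,
                        "r": round(float(grid[g - 1]), 6),
                    }
                )
    return plan


def expected_column_count(cfg: FeaturizeConfig) -> int:
    """Closed-form column count for a configuration (manifest formula)."""
    n = 0
    if cfg.autocorrelation:
        n += len(AUTOCORR_VARIANTS) * len(WEIGHT_CODES) * len(cfg.lags)
    if cfg.burden:
        n += 2 * cfg.burden_k * len(BURDEN_WEIGHTS)
    if cfg.estate:
        n += len(ESTATE_COLUMNS)
    if cfg.weighted_paths:
        n += 1
    if cfg.charge_indices:
        n += 3
    if cfg.logp:
        n += 1
    if cfg.rdf:
        n += 3 * cfg.rdf_config.n_bins
    return n


def _featurize_one(mol: Molecule, cfg: FeaturizeConfig, plan: list[dict]) -> np.ndarray:
    row = np.empty(len(plan))
    pos = 0
    D = topo_distance_matrix(mol) if (cfg.autocorrelation or cfg.estate) else None
    if cfg.autocorrelation:
        for variant in AUTOCORR_VARIANTS:
            for w in WEIGHT_CODES:
                for lag in cfg.lags:
                    row[pos] = autocorrelation(mol, w, lag, variant, _D=D)
                    pos += 1
    if cfg.burden:
        spectra = {w: burden_spectrum(mol, w) for w in BURDEN_WEIGHTS}
        for acc in ("min", "max"):
            for k in range(1, cfg.burden_k + 1):
                for w in BURDEN_WEIGHTS:
                    ev = spectra[w]
                    if k > len(ev):
                        row[pos] = np.nan
                    else:
                        row[pos] = ev[k - 1] if acc == "min" else ev[-k]
                    pos += 1
    if cfg.estate:
        for _, pattern, agg in ESTATE_COLUMNS:
            row[pos] = estate_atomtype(mol, pattern, agg)
            pos += 1
    if cfg.weighted_paths:
        row[pos] = weighted_path_nitrogen(mol)
        pos += 1
    if cfg.charge_indices:
        for k in (1, 2, 3):
            row[pos] = topological_charge_index(mol, k)[1]
            pos += 1
    if cfg.logp:
        row[pos] = mannhold_logp(mol)
        pos += 1
    if cfg.rdf:
        nrdf = 3 * cfg.rdf_config.n_bins
        row[pos : pos + nrdf] = rdf_descriptors(mol, cfg.rdf_config)
        pos += nrdf
    assert pos == len(plan)
    return row


def featurize(
    records: Sequence[MoleculeRecord | Molecule],
    config: FeaturizeConfig | None = None,
) -> DescriptorMatrix:
    """Compute the configured descriptor families for every molecule.

    Column order is deterministic (autocorrelations, Burden eigenvalue
    accessors, E-state atom types, WTPT-5, JGI_1..3, Mannhold logP, then the
    three RDF sets) and recorded in the manifest. Missing values are replaced
    by 0 and flagged in the mask under the default policy; the strict policy
    raises, naming the molecule and descriptor.
    """
    cfg = config or FeaturizeConfig()
    plan = _column_plan(cfg)
    names = [p["name"] for p in plan]
    mols = [r.molecule if isinstance(r, MoleculeRecord) else r for r in records]
    rows = np.empty((len(mols), len(plan)))
    for ri, mol in enumerate(mols):
        rows[ri] = _featurize_one(mol, cfg, plan)
        if cfg.missing_policy == "strict" and np.any(np.isnan(rows[ri])):
            bad = names[int(np.flatnonzero(np.isnan(rows[ri]))[0])]
            raise DescriptorError(
                f"molecule {mol.id!r}: descriptor {bad!r} is missing under strict policy"
            )
    mask = np.isnan(rows)
    rows = np.where(mask, 0.0, rows)
    ids = [m.id for m in mols]
    values = pd.DataFrame(rows, index=ids, columns=names)
    missing = pd.DataFrame(mask, index=ids, columns=names)
    return DescriptorMatrix(values=values, missing_mask=missing, manifest=plan)
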
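"""Synthetic molecule libraries with a planted structure–activity rule.

The generator emulates the statistical shape of a small-molecule activity
set — drug-like sizes (10–60 heavy atoms), C/N/O/S/halogen composition,
seven scaffold families standing in for structural clusters I–VII, 3D
coordinates, PEOE partial charges and a mild class imbalance — without any
claim of chemical realism. Activity is planted by a rule that deliberately
couples a 2D feature with a 3D feature:

    active  <=>  a quaternary carbon is present
                 AND a strong (+,-) charge pair sits inside a stated
                 distance window (default 4.5–5.5 A),

then flipped with a small noise probability. The quaternary carbon is
readable through the ssssC E-state atom types, the charge-pair geometry
through the mixed-sign RDF set (a) bins covering the window — so recovering
the rule exercises both halves of the descriptor engine.

The charge thresholds defining a "strong" pair (default >= +0.45 e and
<= -0.70 e) are chosen against the PEOE charge scale so that only a
carbonate-type carbon qualifies on the positive side and only alkoxide-type
oxygens on the negative side. Every generated molecule carries exactly one
planted carbonate group and one gem-diolate cluster (two O- on a single
carbon; growth never attaches O/N to a carbon that already bears one, so no
grown group approaches those charges): each molecule therefore has exactly
two strong (+,-) pairs — the carbonate carbon against the two clustered
diolate oxygens — and the rule hinges on where that one anchor separation
lands. The pair product (~0.45 e^2) dwarfs every other mixed-sign product,
so an in-window anchor writes an unmistakable spike into the matching RDF
set (a) bins. Inactive molecules are a mix
of "no motif" (the majority) and geometric near-misses — motif and strong
pairs present, but none inside the window — so the 2D motif alone cannot
fully separate the classes and the window bins stay load-bearing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit.Chem import AllChem

from .chem_io import (
    Atom,
    Bond,
    ChemError,
    Molecule,
    MoleculeRecord,
    add_hydrogens,
    from_rdkit,
    to_rdkit,
    write_sdf,
)
from .charges import ChargeConfig, assign_partial_charges
from .descriptors import _match_atomtype
from .qsar import ACTIVE, INACTIVE, ActivityRecord, label_activity


class SyntheticError(ChemError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PlantedRule:
    """Parameters of the planted structure–activity rule."""

    motif: str = "ssssC"
    window: tuple[float, float] = (4.5, 5.5)  # Angstrom
    min_positive_charge: float = 0.45  # e: carbonate-type carbons only
    max_negative_charge: float = -0.70  # e: alkoxide/diolate oxygens only
    flip_prob: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.flip_prob < 0.5):
            raise SyntheticError("flip probability must lie in [0, 0.5)")
        if self.window[0] >= self.window[1]:
            raise SyntheticError("distance window must be increasing")


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults define the standard study conditions.

    ``active_fraction`` = 0.45 reproduces a roughly 1:1.22 two-class
    imbalance before label noise. The element palette and heavy-atom range
    bracket ordinary drug-like organics.
    """

    n_molecules: int = 141
    heavy_atom_range: tuple[int, int] = (10, 60)
    elements: tuple[str, ...] = ("C", "N", "O", "S", "Cl", "Br")
    active_fraction: float = 0.45
    rule: PlantedRule = field(default_factory=PlantedRule)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.active_fraction < 1.0):
            raise SyntheticError("active_fraction must lie strictly in (0, 1)")
        lo, hi = self.heavy_atom_range
        if lo < 8 or hi < lo:
            raise SyntheticError(
                f"infeasible heavy-atom range {self.heavy_atom_range} "
                "(need at least 8 atoms for the scaffold templates)"
            )


#: Scaffold family -> structural-cluster label (role mirroring only).
FAMILY_CLUSTERS = {
    "acyclic": "I",
    "o_heterocycle": "II",
    "n_heterocycle": "III",
    "fused_ring": "IV",
    "diketopiperazine_like": "V",
    "two_ring_linker": "VI",
    "macrocycle": "VII",
}
FAMILIES = tuple(FAMILY_CLUSTERS)

_VALENCE_CAP = {"C": 4, "N": 3, "O": 2, "S": 2, "Cl": 1, "Br": 1}
#: growth palette weights; heteroatoms are sparse (and grown oxygens are
#: carbonyls) so that no grown group approaches the planted anchors' charge
#: magnitudes and the anchor pairs stay the only large mixed-sign products
_ELEMENT_WEIGHTS = {"C": 0.84, "N": 0.02, "O": 0.02, "S": 0.05, "Cl": 0.05, "Br": 0.02}
_CARBONYL_PROB = 1.0

#: share of inactive molecules built as geometric near-misses (motif and
#: strong pairs present, none inside the window); the rest carry no motif
NEAR_MISS_FRACTION = 0.125

#: number of heavy-atom-count strata used to size-match the motif pools
_N_SIZE_BINS = 4

#: rule-positive molecules are accepted with an anchor pair inside this
#: centrally trimmed sub-window, concentrating the planted spikes on a few
#: adjacent RDF grid points; the labeling rule itself uses the full window
CENTRAL_WINDOW_TRIM = 0.15  # fraction trimmed off each window edge



# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

class _Builder:
    """Mutable valence-aware molecular graph under construction."""

    def __init__(self) -> None:
        self.elements: list[str] = []
        self.bonds: list[tuple[int, int, int]] = []
        self.charges: dict[int, int] = {}
        self._order_sum: list[int] = []

    def add_atom(self, element: str) -> int:
        self.elements.append(element)
        self._order_sum.append(0)
        return len(self.elements) - 1

    def add_bond(self, i: int, j: int, order: int = 1) -> None:
        self.bonds.append((i, j, order))
        self._order_sum[i] += order
        self._order_sum[j] += order

    def free(self, i: int) -> int:
        cap = _VALENCE_CAP[self.elements[i]] + self.charges.get(i, 0)
        return cap - self._order_sum[i]

    def heavy_single_neighbors(self, i: int) -> int:
        return sum(1 for a, b, o in self.bonds if o == 1 and i in (a, b))

    @property
    def n(self) -> int:
        return len(self.elements)

    def to_molecule(self, mol_id: str) -> Molecule:
        atoms = [
            Atom(e, np.zeros(3), formal_charge=self.charges.get(i, 0))
            for i, e in enumerate(self.elements)
        ]
        bonds = [Bond(a, b, o) for a, b, o in self.bonds]
        return Molecule(id=mol_id, atoms=atoms, bonds=bonds, source="synthetic")


def _template(family: str, rng: np.random.Generator) -> _Builder:
    b = _Builder()
    if family == "acyclic":
        k = int(rng.integers(6, 10))
        prev = b.add_atom("C")
        for _ in range(k - 1):
            cur = b.add_atom("C")
            b.add_bond(prev, cur, 1)
            prev = cur
    elif family in ("o_heterocycle", "n_heterocycle"):
        het = "O" if family == "o_heterocycle" else "N"
        ring = [b.add_atom(het if i == 0 else "C") for i in range(6)]
        for i in range(6):
            b.add_bond(ring[i], ring[(i + 1) % 6], 1)
    elif family == "fused_ring":
        atoms = [b.add_atom("C") for _ in range(10)]
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0),
                 (0, 6), (6, 7), (7, 8), (8, 9), (9, 5)]
        for i, j in edges:
            b.add_bond(atoms[i], atoms[j], 1)
    elif family == "diketopiperazine_like":
        elems = ["C", "N", "C", "C", "N", "C"]
        ring = [b.add_atom(e) for e in elems]
        for i in range(6):
            b.add_bond(ring[i], ring[(i + 1) % 6], 1)
        for carbonyl_at in (0, 3):
            o = b.add_atom("O")
            b.add_bond(ring[carbonyl_at], o, 2)
    elif family == "two_ring_linker":
        r1 = [b.add_atom("C") for _ in range(6)]
        r2 = [b.add_atom("C") for _ in range(6)]
        for ring in (r1, r2):
            for i in range(6):
                b.add_bond(ring[i], ring[(i + 1) % 6], 1)
        ca, cb, ox = b.add_atom("C"), b.add_atom("C"), b.add_atom("O")
        b.add_bond(r1[0], ca, 1)
        b.add_bond(ca, cb, 1)
        b.add_bond(cb, r2[0], 1)
        b.add_bond(cb, ox, 2)
    elif family == "macrocycle":
        k = int(rng.integers(12, 16))
        ring = [b.add_atom("O" if i == 0 else "C") for i in range(k)]
        for i in range(k):
            b.add_bond(ring[i], ring[(i + 1) % k], 1)
    else:  # pragma: no cover
        raise SyntheticError(f"unknown scaffold family: {family!r}")
    return b


def _attachment_sites(b: _Builder, allow_quaternary: bool) -> list[int]:
    sites = []
    for i in range(b.n):
        if b.free(i) < 1:
            continue
        if b.elements[i] != "C":
            continue  # grow only from carbons: no heteroatom-heteroatom chains
        if not allow_quaternary and b.heavy_single_neighbors(i) >= 3:
            continue
        sites.append(i)
    return sites


def _has_on_neighbor(b: _Builder, i: int) -> bool:
    return any(
        b.elements[j if a == i else a] in ("O", "N")
        for a, j, _ in b.bonds
        if i in (a, j)
    )


def _grow(
    b: _Builder,
    rng: np.random.Generator,
    target_heavy: int,
    elements: tuple[str, ...],
    allow_quaternary: bool,
) -> bool:
    """Random valence-respecting growth up to ``target_heavy`` atoms.

    Oxygen and nitrogen never attach to a carbon that already bears an O/N
    neighbor: this keeps the planted ester the only ester-grade polar group,
    so the charge-pair rule has a well-defined anchor.
    """
    weights = np.array([_ELEMENT_WEIGHTS[e] for e in elements])
    weights = weights / weights.sum()
    while b.n < target_heavy:
        sites = _attachment_sites(b, allow_quaternary)
        if not sites:
            return False
        parent = int(sites[rng.integers(len(sites))])
        elem = str(rng.choice(elements, p=weights))
        if elem in ("O", "N") and _has_on_neighbor(b, parent):
            elem = "C"
        child = b.add_atom(elem)
        if elem == "O" and b.free(parent) >= 2 and rng.random() < _CARBONYL_PROB:
            b.add_bond(parent, child, 2)  # ketone-type carbonyl
        else:
            b.add_bond(parent, child, 1)
    return True


def _insert_quaternary(b: _Builder, rng: np.random.Generator) -> bool:
    """Attach a neopentyl-like quaternary carbon (central C with 4 C bonds)."""
    sites = [i for i in range(b.n) if b.elements[i] == "C" and b.free(i) >= 1]
    if not sites:
        return False
    parent = int(sites[rng.integers(len(sites))])
    center = b.add_atom("C")
    b.add_bond(parent, center, 1)
    for _ in range(3):
        methyl = b.add_atom("C")
        b.add_bond(center, methyl, 1)
    return True


def _polar_sites(b: _Builder) -> list[int]:
    # secondary carbons only: attaching a fourth single-bonded heavy neighbor
    # would create an unintended quaternary (ssssC) center
    return [
        i
        for i in range(b.n)
        if b.elements[i] == "C"
        and b.free(i) >= 1
        and not _has_on_neighbor(b, i)
        and b.heavy_single_neighbors(i) <= 2
    ]


def _insert_carbonate(b: _Builder, rng: np.random.Generator) -> int | None:
    """Attach one carbonate fragment -O-C(=O)-O-C (the strong-positive anchor).

    Returns the index of the carbonate carbon, or None if no site exists.
    """
    sites = _polar_sites(b)
    if not sites:
        return None
    parent = int(sites[rng.integers(len(sites))])
    o_link = b.add_atom("O")
    b.add_bond(parent, o_link, 1)
    c = b.add_atom("C")
    b.add_bond(o_link, c, 1)
    o_double = b.add_atom("O")
    b.add_bond(c, o_double, 2)
    o_single = b.add_atom("O")
    b.add_bond(c, o_single, 1)
    tail = b.add_atom("C")
    b.add_bond(o_single, tail, 1)
    return c


def _insert_gem_diolate(b: _Builder, rng: np.random.Generator) -> bool:
    """Attach a gem-diolate -CH(O-)(O-) cluster (the strong-negative anchor).

    The two alkoxide oxygens sit ~2.3 A apart on one carbon, so their
    distances to the carbonate carbon move together and the anchor has a
    single well-defined separation. (A dianionic diolate is not a realistic
    solution species; it is a deliberately synthetic strongly-polar probe.)
    """
    sites = _polar_sites(b)
    if not sites:
        return False
    parent = int(sites[rng.integers(len(sites))])
    hub = b.add_atom("C")
    b.add_bond(parent, hub, 1)
    for _ in range(2):
        o_minus = b.add_atom("O")
        b.add_bond(hub, o_minus, 1)
        b.charges[o_minus] = -1
    return True


def _build_candidate(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    family: str,
    with_motif: bool,
    target_heavy: int | None = None,
) -> Molecule | None:
    lo, hi = cfg.heavy_atom_range
    target = int(rng.integers(lo, hi + 1)) if target_heavy is None else target_heavy
    b = _template(family, rng)
    if with_motif and not _insert_quaternary(b, rng):
        return None
    # one carbonate + one gem-diolate: two strong (+,-) anchor pairs whose
    # distances move together
    if _insert_carbonate(b, rng) is None or not _insert_gem_diolate(b, rng):
        return None
    if not _grow(b, rng, max(target, b.n), cfg.elements, allow_quaternary=with_motif):
        return None
    return b.to_molecule("candidate")


# ---------------------------------------------------------------------------
# 3D embedding
# ---------------------------------------------------------------------------

#: Geometry bounds checked after embedding (Angstrom).
HEAVY_BOND_RANGE = (1.2, 1.9)
HYDROGEN_BOND_RANGE = (0.85, 1.3)
NONBONDED_MIN = 1.5

_EMBED_RETRIES = 4


def embed_3d(mol: Molecule, seed: int) -> Molecule:
    """Deterministic distance-geometry 3D coordinates (ETKDG).

    Retries with perturbed seeds up to a small budget, then raises. The same
    molecule with the same seed always yields identical coordinates.
    """
    rd = to_rdkit(mol, sanitize=True)
    params = AllChem.ETKDGv3()
    params.useRandomCoords = False
    conf_id = -1
    for attempt in range(_EMBED_RETRIES):
        params.randomSeed = int((seed + attempt * 7919) % (2**31 - 1)) + 1
        conf_id = AllChem.EmbedMolecule(rd, params)
        if conf_id == 0:
            break
        if attempt == _EMBED_RETRIES - 2:
            params.useRandomCoords = True
    if conf_id != 0:
        raise SyntheticError(
            f"3D embedding failed for molecule {mol.id!r} after "
            f"{_EMBED_RETRIES} attempts"
        )
    out = from_rdkit(rd, mol_id=mol.id, source=mol.source)
    out.properties = dict(mol.properties)
    return out


def geometry_violations(mol: Molecule) -> list[str]:
    """Bond-length and steric-clash violations against the stated bounds."""
    X = mol.coords_array()
    bonded = set()
    problems = []
    for b in mol.bonds:
        bonded.add((min(b.a1, b.a2), max(b.a1, b.a2)))
        d = float(np.linalg.norm(X[b.a1] - X[b.a2]))
        is_h = mol.atoms[b.a1].is_hydrogen or mol.atoms[b.a2].is_hydrogen
        lo, hi = HYDROGEN_BOND_RANGE if is_h else HEAVY_BOND_RANGE
        if not (lo <= d <= hi):
            problems.append(f"bond {b.a1}-{b.a2}: {d:.2f} A outside [{lo}, {hi}]")
    n = len(mol.atoms)
    iu, ju = np.triu_indices(n, k=1)
    dists = np.linalg.norm(X[iu] - X[ju], axis=1)
    for i, j, d in zip(iu, ju, dists):
        if (int(i), int(j)) not in bonded and d < NONBONDED_MIN:
            problems.append(f"non-bonded pair {i}-{j}: {d:.2f} A < {NONBONDED_MIN}")
    return problems


# ---------------------------------------------------------------------------
# Planted activity
# ---------------------------------------------------------------------------

def _strong_pair_distances(mol: Molecule, rule: PlantedRule) -> np.ndarray:
    """Distances of all strong (+,-) pairs; empty when none exists."""
    q = np.array(
        [a.partial_charge if a.partial_charge is not None else np.nan for a in mol.atoms]
    )
    if np.any(np.isnan(q)):
        raise SyntheticError(
            f"molecule {mol.id!r}: partial charges must be assigned before "
            "evaluating the planted rule"
        )
    pos = np.flatnonzero(q >= rule.min_positive_charge)
    neg = np.flatnonzero(q <= rule.max_negative_charge)
    if len(pos) == 0 or len(neg) == 0:
        return np.empty(0)
    X = mol.coords_array()
    return np.linalg.norm(X[pos][:, None, :] - X[neg][None, :, :], axis=-1).ravel()


def _strong_pair_state(mol: Molecule, rule: PlantedRule) -> tuple[bool, bool]:
    """(any strong (+,-) pair exists, any such pair lies inside the window)."""
    d = _strong_pair_distances(mol, rule)
    if d.size == 0:
        return False, False
    lo, hi = rule.window
    return True, bool(np.any((d >= lo) & (d <= hi)))


def rule_holds(mol: Molecule, rule: PlantedRule | None = None) -> bool:
    """Noise-free planted rule: motif present AND strong (+,-) pair in window."""
    rule = rule or PlantedRule()
    if not _match_atomtype(mol, rule.motif):
        return False
    return _strong_pair_state(mol, rule)[1]


def plant_activity(mol: Molecule, rule: PlantedRule | None = None, seed: int = 0) -> str:
    """Planted class label: the noise-free rule, flipped with ``flip_prob``."""
    rule = rule or PlantedRule()
    base = ACTIVE if rule_holds(mol, rule) else INACTIVE
    if rule.flip_prob > 0 and np.random.default_rng(seed).random() < rule.flip_prob:
        return INACTIVE if base == ACTIVE else ACTIVE
    return base


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

def generate_library(
    cfg: SyntheticConfig | None = None,
    sdf_path=None,
    activity_csv_path=None,
) -> list[MoleculeRecord]:
    """Generate a labeled, embedded, charged molecule library.

    Deterministic at a fixed seed (byte-identical SDF output). The noise-free
    rule outcome is balanced to the configured active fraction by rejection
    sampling; the noise flips are applied on top, and the stored activity
    endpoint (a percent-inhibition value) is drawn consistently with the
    final label so that re-labeling the CSV reproduces the classes. Each
    record carries the cluster label of its scaffold family and the
    properties ``rule_active`` (pre-noise) and ``flipped``.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_molecules
    n_pos = int(round(cfg.active_fraction * n))
    n_neg = n - n_pos
    # three pools: rule-positive, geometric near-miss, motif-free; the
    # near-miss share (NEAR_MISS_FRACTION of inactives) keeps the geometric
    # half of the rule load-bearing without dominating the error budget
    n_near = int(round(NEAR_MISS_FRACTION * n_neg))
    lo, hi = cfg.heavy_atom_range
    size_edges = np.linspace(lo, hi + 1, _N_SIZE_BINS + 1)

    def _quota(total: int) -> np.ndarray:
        base, extra = divmod(total, _N_SIZE_BINS)
        return base + (np.arange(_N_SIZE_BINS) < extra).astype(int)

    # rule-positives and near-misses fill matched heavy-atom-size quotas, so
    # molecular size (the dominant driver of RDF background intensity) never
    # correlates with the geometric half of the rule
    need = {"pos": _quota(n_pos), "near": _quota(n_near)}
    need_free = n_neg - n_near
    accepted: list[tuple[Molecule, str, bool]] = []  # (mol, family, rule_true)
    surplus: list[tuple[Molecule, str, bool]] = []
    attempts, max_attempts = 0, 80 * n
    while (
        int(need["pos"].sum() + need["near"].sum()) + need_free > 0
        and attempts < max_attempts
    ):
        attempts += 1
        if attempts == 30 * n:  # narrow ranges can leave strata unfillable
            need = {k: np.array([int(v.sum())]) for k, v in need.items()}
            size_edges = np.array([lo, hi + 1], dtype=float)
        motif_quota = int(need["pos"].sum() + need["near"].sum())
        with_motif = motif_quota >= need_free
        if with_motif:
            open_bins = np.flatnonzero((need["pos"] + need["near"]) > 0)
            sbin = int(open_bins[rng.integers(len(open_bins))])
            target = int(
                rng.integers(int(size_edges[sbin]), int(size_edges[sbin + 1]))
            )
        else:
            target = int(rng.integers(lo, hi + 1))
        family = FAMILIES[int(rng.integers(len(FAMILIES)))]
        cand = _build_candidate(rng, cfg, family, with_motif, target_heavy=target)
        if cand is None:
            continue
        cand = add_hydrogens(cand)
        try:
            cand = embed_3d(cand, seed=int(rng.integers(0, 2**31 - 1)))
            cand = assign_partial_charges(cand, ChargeConfig())
        except ChemError:
            continue
        # route by the candidate's actual state, not the requested build:
        # templates and planted groups can occasionally produce (or miss)
        # the motif, and labels must always agree with the rule
        motif_present = bool(_match_atomtype(cand, cfg.rule.motif))
        d = _strong_pair_distances(cand, cfg.rule)
        wlo, whi = cfg.rule.window
        trim = CENTRAL_WINDOW_TRIM * (whi - wlo)
        n_in_window = int(np.sum((d >= wlo) & (d <= whi)))
        n_central = int(np.sum((d >= wlo + trim) & (d <= whi - trim)))
        if motif_present and n_central >= 1:
            pool = "pos"
        elif motif_present and n_in_window >= 1:
            continue  # rule-positive but off-center: keep the spikes focused
        elif motif_present and d.size > 0:
            pool = "near"
        elif not motif_present:
            pool = "free"
        else:
            continue  # motif without any strong pair: not a clean near-miss
        rule_true = pool == "pos"
        if pool == "free":
            if need_free > 0:
                accepted.append((cand, family, rule_true))
                need_free -= 1
            elif len(surplus) < n:
                surplus.append((cand, family, rule_true))
            continue
        heavy = sum(1 for a in cand.atoms if not a.is_hydrogen)
        sbin = int(
            np.clip(
                np.searchsorted(size_edges, heavy, side="right") - 1,
                0,
                len(size_edges) - 2,
            )
        )
        if need[pool][sbin] > 0:
            accepted.append((cand, family, rule_true))
            need[pool][sbin] -= 1
        elif len(surplus) < n:
            surplus.append((cand, family, rule_true))
    for item in surplus:  # pragma: no cover - quota fallback
        if len(accepted) >= n:
            break
        accepted.append(item)
    if len(accepted) < n:
        raise SyntheticError(
            f"generated only {len(accepted)}/{n} molecules in {attempts} attempts"
        )
    records: list[MoleculeRecord] = []
    for idx, (mol, family, rule_true) in enumerate(accepted):
        flip = bool(rng.random() < cfg.rule.flip_prob)
        base = ACTIVE if rule_true else INACTIVE
        label = (
            (INACTIVE if base == ACTIVE else ACTIVE) if flip else base
        )
        mol = mol.copy()
        mol.id = f"SYN{idx:05d}"
        if label == ACTIVE:
            value = float(rng.uniform(53.0, 100.0))
        else:
            value = float(rng.uniform(0.0, 52.0))
        activity = ActivityRecord(
            endpoint_type="percent_inhibition", value=round(value, 2), units="%"
        )
        label_activity(activity)
        assert activity.activity_class == label
        mol.properties.update(
            {
                "activity_class": label,
                "percent_inhibition": f"{value:.2f}",
                "cluster": FAMILY_CLUSTERS[family],
                "rule_active": str(rule_true),
                "flipped": str(flip),
            }
        )
        records.append(
            MoleculeRecord(
                molecule=mol, activity=activity, cluster=FAMILY_CLUSTERS[family]
            )
        )
    if sdf_path is not None:
        write_sdf(records, sdf_path)
    if activity_csv_path is not None:
        pd.DataFrame(
            {
                "id": [r.molecule.id for r in records],
                "endpoint_type": ["percent_inhibition"] * n,
                "endpoint_value": [r.activity.value for r in records],
                "units": ["%"] * n,
                "activity_class": [r.activity.activity_class for r in records],
                "cluster": [r.cluster for r in records],
            }
        ).to_csv(activity_csv_path, index=False)
    return records
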
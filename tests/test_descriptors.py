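"""Descriptor engine: hand-derived values, brute-force oracles, invariants."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem.EState import EStateIndices

from foulqsar.chem_io import Atom, Bond, Molecule, add_hydrogens, from_smiles, to_rdkit
from foulqsar.descriptors import (
    AUTOCORR_VARIANTS,
    DescriptorError,
    ELEMENT_PROPERTIES,
    FeaturizeConfig,
    RDFConfig,
    autocorrelation,
    burden_matrix,
    burden_spectrum,
    estate_atomtype,
    estate_values,
    expected_column_count,
    featurize,
    mannhold_logp,
    rdf_descriptors,
    topo_distance_matrix,
    topological_charge_index,
    weighted_path_nitrogen,
)

from conftest import embedded_molecule


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive re-implementations)
# ---------------------------------------------------------------------------

def bfs_distances(mol):
    """Breadth-first shortest paths on the heavy-atom graph, no networkx."""
    heavy = mol.heavy_indices()
    pos = {a: k for k, a in enumerate(heavy)}
    adj = {i: [] for i in heavy}
    for b in mol.bonds:
        if b.a1 in pos and b.a2 in pos:
            adj[b.a1].append(b.a2)
            adj[b.a2].append(b.a1)
    n = len(heavy)
    D = np.full((n, n), -1, dtype=int)
    for src in heavy:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for dst, d in dist.items():
            D[pos[src], pos[dst]] = d
    return D


def autocorr_oracle(mol, weights, lag, variant):
    """Direct double-loop pair sum over heavy atoms."""
    D = bfs_distances(mol)
    w = np.asarray(weights, dtype=float)
    n = len(w)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if D[i, j] == lag]
    if not pairs:
        return float("nan")
    wbar = w.mean()
    delta = len(pairs)
    ats = sum(w[i] * w[j] for i, j in pairs)
    atsc = sum((w[i] - wbar) * (w[j] - wbar) for i, j in pairs)
    if variant == "ATS":
        return ats
    if variant == "ATSC":
        return atsc
    if variant == "AATS":
        return ats / delta
    if variant == "AATSC":
        return atsc / delta
    var = sum((x - wbar) ** 2 for x in w)
    if var == 0:
        return float("nan")
    if variant == "Moran":
        return (atsc / delta) / (var / n)
    return (sum((w[i] - w[j]) ** 2 for i, j in pairs) / (2 * delta)) / (var / (n - 1))


def rdf_oracle(mol, cfg):
    """Triple loop over pairs and grid points."""
    idx = [i for i in range(len(mol.atoms))]
    out = np.zeros((3, cfg.n_bins))
    grid = [cfg.spacing * g for g in range(1, cfg.n_bins + 1)]
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            qi = mol.atoms[a].partial_charge
            qj = mol.atoms[b].partial_charge
            if qi == 0 or qj == 0:
                continue
            if qi * qj < 0:
                s = 0
            elif qi > 0:
                s = 1
            else:
                s = 2
            rij = float(np.linalg.norm(mol.atoms[a].coords - mol.atoms[b].coords))
            for g, r in enumerate(grid):
                out[s, g] += qi * qj * np.exp(-cfg.fuzziness * (r - rij) ** 2)
    return out.ravel()


def wtpt_oracle(mol):
    """Exhaustive DFS path enumeration from nitrogen atoms."""
    heavy = mol.heavy_indices()
    adj = {i: [] for i in heavy}
    for b in mol.bonds:
        if b.a1 in adj and b.a2 in adj:
            adj[b.a1].append(b.a2)
            adj[b.a2].append(b.a1)
    deg = {i: len(adj[i]) for i in heavy}
    total = 0.0

    def dfs(node, visited, weight):
        nonlocal total
        for nb in adj[node]:
            if nb in visited:
                continue
            w2 = weight / np.sqrt(deg[node] * deg[nb])
            total += w2
            dfs(nb, visited | {nb}, w2)

    for start in heavy:
        if mol.atoms[start].element == "N":
            total += 1.0
            dfs(start, {start}, 1.0)
    return total


def charge_index_oracle(mol, k):
    D = bfs_distances(mol)
    n = D.shape[0]
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            for m in range(n):
                if D[i, m] == 1 and m != j and D[m, j] > 0:
                    M[i, j] += 1.0 / D[m, j] ** 2
    total = 0.0
    found = False
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] == k:
                total += abs(M[i, j] - M[j, i])
                found = True
    if not found:
        return float("nan"), float("nan")
    return total, total / (n - 1)


# ---------------------------------------------------------------------------
# Hand-derived examples
# ---------------------------------------------------------------------------

class TestHandValues:
    def test_estate_ethane(self):
        mol = add_hydrogens(from_smiles("CC", "ethane"))
        assert estate_values(mol) == pytest.approx([2.0, 2.0])

    def test_estate_propane(self):
        mol = add_hydrogens(from_smiles("CCC", "propane"))
        S = estate_values(mol)
        assert sorted(S) == pytest.approx([1.25, 2.125, 2.125])

    def test_estate_matches_rdkit(self):
        for smi in ("CCO", "CC(C)CC=O", "c1ccccc1O", "CC(C)(C)CN"):
            mol = add_hydrogens(from_smiles(smi, smi))
            ours = estate_values(mol)
            rd = Chem.RemoveHs(to_rdkit(mol))
            theirs = EStateIndices(rd)
            assert ours == pytest.approx(list(theirs), abs=1e-8)

    def test_estate_atomtypes(self):
        neopentane = add_hydrogens(from_smiles("CC(C)(C)C", "neopentane"))
        quat = estate_atomtype(neopentane, "ssssC", "max")
        assert np.isfinite(quat)
        propane = add_hydrogens(from_smiles("CCC", "propane"))
        assert estate_atomtype(propane, "ssCH2", "sum") == pytest.approx(1.25)
        benzene = add_hydrogens(from_smiles("c1ccccc1", "benzene"))
        assert np.isnan(estate_atomtype(benzene, "ssCH2", "sum"))

    def test_charge_index_propane(self):
        mol = add_hydrogens(from_smiles("CCC", "propane"))
        ggi, jgi = topological_charge_index(mol, 1)
        assert (ggi, jgi) == pytest.approx((0.5, 0.25))

    def test_charge_index_two_atoms(self):
        mol = add_hydrogens(from_smiles("CC", "ethane"))
        assert topological_charge_index(mol, 1) == pytest.approx((0.0, 0.0))

    def test_mannhold(self):
        benzene = add_hydrogens(from_smiles("c1ccccc1", "benzene"))
        assert mannhold_logp(benzene) == pytest.approx(2.12)
        water_like = Molecule("o", [Atom("O", np.zeros(3))], [])
        assert mannhold_logp(water_like) == pytest.approx(1.35)
        con = add_hydrogens(from_smiles("CO", "methanol"))
        assert mannhold_logp(con) == pytest.approx(1.46)

    def test_wtpt_no_nitrogen_is_zero(self):
        mol = add_hydrogens(from_smiles("CCO", "ethanol"))
        assert weighted_path_nitrogen(mol) == 0.0

    def test_wtpt_methylamine(self):
        mol = add_hydrogens(from_smiles("CN", "methylamine"))
        assert weighted_path_nitrogen(mol) == pytest.approx(2.0)

    def test_burden_two_atom_closed_form(self):
        mol = add_hydrogens(from_smiles("CC", "ethane"))
        # relative mass diagonal 1.0; single bond, both terminal: 0.11
        assert burden_spectrum(mol, "m") == pytest.approx([0.89, 1.11])

    def test_burden_single_atom(self):
        mol = Molecule("n", [Atom("N", np.zeros(3))], [])
        ref = ELEMENT_PROPERTIES["N"]["m"] / ELEMENT_PROPERTIES["C"]["m"]
        assert burden_spectrum(mol, "m") == pytest.approx([ref])

    def test_autocorr_path_ats(self):
        mol = add_hydrogens(from_smiles("CCC", "propane"))
        # unit weights via uniform element (all C): ATS1 with weight=mass/mass
        val = autocorrelation(mol, "m", 1, "ATS")
        assert val == pytest.approx(2 * ELEMENT_PROPERTIES["C"]["m"] ** 2)

    def test_atsc_uniform_weights_zero(self):
        mol = add_hydrogens(from_smiles("CCCCC", "pentane"))
        for lag in (1, 2, 3):
            assert autocorrelation(mol, "m", lag, "ATSC") == pytest.approx(0.0, abs=1e-9)

    def test_topo_distances(self):
        path3 = add_hydrogens(from_smiles("CCC", "p3"))
        D = topo_distance_matrix(path3)
        assert D.max() == 2
        ring6 = add_hydrogens(from_smiles("C1CCCCC1", "c6"))
        assert topo_distance_matrix(ring6).max() == 3


# ---------------------------------------------------------------------------
# Oracle sweeps over random synthetic molecules
# ---------------------------------------------------------------------------

class TestOracles:
    def test_autocorrelations_match_bruteforce(self, small_library):
        for rec in small_library[:50]:
            mol = rec.molecule
            heavy = mol.heavy_indices()
            w = np.array(
                [ELEMENT_PROPERTIES[mol.atoms[i].element]["m"] for i in heavy]
            )
            for variant in AUTOCORR_VARIANTS:
                for lag in (1, 3, 5, 8):
                    ours = autocorrelation(mol, "m", lag, variant)
                    ref = autocorr_oracle(mol, w, lag, variant)
                    if np.isnan(ref):
                        assert np.isnan(ours)
                    else:
                        assert ours == pytest.approx(ref, rel=1e-10, abs=1e-10)

    def test_topo_distances_match_bfs(self, small_library):
        for rec in small_library[:50]:
            D = topo_distance_matrix(rec.molecule)
            assert np.array_equal(D, bfs_distances(rec.molecule))

    def test_rdf_matches_bruteforce(self, small_library):
        cfg = RDFConfig(n_bins=32, r_max=6.4)  # reduced grid keeps O(n^2 g) oracle fast
        for rec in small_library[:20]:
            ours = rdf_descriptors(rec.molecule, cfg)
            ref = rdf_oracle(rec.molecule, cfg)
            assert np.abs(ours - ref).max() <= 1e-8 * max(1.0, np.abs(ref).max())

    def test_wtpt_matches_exhaustive_dfs(self, small_library):
        for rec in small_library[:25]:
            ours = weighted_path_nitrogen(rec.molecule)
            assert ours == pytest.approx(wtpt_oracle(rec.molecule), rel=1e-10, abs=1e-10)

    def test_charge_index_matches_bruteforce(self, small_library):
        for rec in small_library[:15]:
            for k in (1, 2, 3):
                ours = topological_charge_index(rec.molecule, k)
                ref = charge_index_oracle(rec.molecule, k)
                for a, b in zip(ours, ref):
                    if np.isnan(b):
                        assert np.isnan(a)
                    else:
                        assert a == pytest.approx(b, rel=1e-9, abs=1e-10)


# ---------------------------------------------------------------------------
# Structural invariants
# ---------------------------------------------------------------------------

class TestInvariants:
    def test_aats_times_delta_equals_ats(self, small_library):
        mol = small_library[0].molecule
        D = topo_distance_matrix(mol)
        for lag in (1, 2, 4):
            delta = int(np.triu(D == lag, k=1).sum())
            ats = autocorrelation(mol, "v", lag, "ATS")
            aats = autocorrelation(mol, "v", lag, "AATS")
            assert aats * delta == pytest.approx(ats, rel=1e-12)

    def test_ats_quadratic_scaling_and_moran_affine_invariance(self, small_library):
        mol = small_library[1].molecule
        heavy = mol.heavy_indices()
        w = np.array([ELEMENT_PROPERTIES[mol.atoms[i].element]["p"] for i in heavy])
        a, b = 2.5, -1.3
        base_ats = autocorr_oracle(mol, w, 2, "ATS")
        assert autocorr_oracle(mol, a * w, 2, "ATS") == pytest.approx(
            a**2 * base_ats, rel=1e-10
        )
        for variant in ("Moran", "Geary"):
            v0 = autocorr_oracle(mol, w, 2, variant)
            v1 = autocorr_oracle(mol, a * w + b, 2, variant)
            assert v1 == pytest.approx(v0, rel=1e-9)

    def test_burden_permutation_invariance(self, small_library, rng):
        from foulqsar.chem_io import Bond as B

        mol = small_library[2].molecule
        ev = burden_spectrum(mol, "e")
        perm = rng.permutation(len(mol.atoms))
        inv = np.argsort(perm)
        shuffled = Molecule(
            id=mol.id,
            atoms=[mol.atoms[i] for i in perm],
            bonds=[B(int(inv[b.a1]), int(inv[b.a2]), b.order) for b in mol.bonds],
        )
        assert np.abs(burden_spectrum(shuffled, "e") - ev).max() <= 1e-10

    def test_burden_matrix_structure(self):
        mol = add_hydrogens(from_smiles("CC(C)C", "isobutane"))
        B = burden_matrix(mol, "m")
        assert B.shape == (4, 4)
        assert B[0, 2] == pytest.approx(0.001)  # non-bonded
        # bonded terminal: 0.1 + 0.01
        central = 1  # isobutane heavy order: C C(C)(C) -> index of degree-3 atom
        degs = (B != 0.001).sum(axis=0)
        assert np.isclose(B, 0.11).any()

    def test_rdf_rigid_motion_invariance(self, small_library, rng):
        mol = small_library[3].molecule
        base = rdf_descriptors(mol)
        # random rotation (QR) + translation
        Qm, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.normal(scale=5.0, size=3)
        moved = mol.copy()
        for a in moved.atoms:
            a.coords = Qm @ a.coords + shift
        assert np.abs(rdf_descriptors(moved) - base).max() <= 1e-10

    def test_rdf_sign_structure(self, small_library):
        cfg = RDFConfig()
        for rec in small_library[:10]:
            v = rdf_descriptors(rec.molecule, cfg).reshape(3, -1)
            assert np.all(v[0] <= 1e-12)  # mixed-sign set
            assert np.all(v[1] >= -1e-12)  # (+,+)
            assert np.all(v[2] >= -1e-12)  # (-,-)

    def test_rdf_two_atom_closed_form(self):
        a1 = Atom("C", [0.0, 0.0, 0.0])
        a1.partial_charge = 0.5
        a2 = Atom("O", [1.0, 0.0, 0.0])
        a2.partial_charge = -0.5
        mol = Molecule("pair", [a1, a2], [Bond(0, 1, 1)])
        v = rdf_descriptors(mol).reshape(3, -1)
        grid = RDFConfig().grid
        g = int(np.argmin(np.abs(grid - 1.0)))
        assert v[0, g] == pytest.approx(-0.25)
        assert np.abs(v[1]).max() == 0.0
        assert np.abs(v[2]).max() == 0.0

    def test_rdf_single_atom_all_zero(self):
        a = Atom("C", np.zeros(3))
        a.partial_charge = 0.3
        mol = Molecule("single", [a], [])
        assert np.all(rdf_descriptors(mol) == 0.0)

    def test_rdf_locality(self, small_library):
        """An atom far beyond r_max + kernel reach cannot move any bin."""
        cfg = RDFConfig()
        mol = small_library[4].molecule.copy()
        base = rdf_descriptors(mol, cfg)
        reach = cfg.r_max + 3.0 / np.sqrt(2 * cfg.fuzziness)
        far = mol.copy()
        # push one atom far outside every pair's kernel reach
        far.atoms[0].coords = far.atoms[0].coords + np.array([10 * reach, 0, 0])
        moved = rdf_descriptors(far, cfg)
        # bins only lose that atom's pair terms; remaining values match the
        # molecule with the atom's pairs removed -> compare vs explicit removal
        trimmed = mol.copy()
        trimmed.atoms[0].partial_charge = 0.0
        ref = rdf_descriptors(trimmed, cfg)
        assert np.abs(moved - ref).max() <= 1e-6 * max(1.0, np.abs(ref).max())

    def test_rdf_missing_charges_error(self):
        mol = add_hydrogens(from_smiles("CCO", "ethanol"))
        with pytest.raises(DescriptorError, match="charges"):
            rdf_descriptors(mol)


# ---------------------------------------------------------------------------
# Featurize
# ---------------------------------------------------------------------------

class TestFeaturize:
    def test_rdf_only_shape(self, small_library):
        cfg = FeaturizeConfig(
            autocorrelation=False, burden=False, estate=False,
            weighted_paths=False, charge_indices=False, logp=False,
        )
        dm = featurize(small_library[:2], cfg)
        assert dm.values.shape == (2, 384)

    def test_column_count_matches_manifest_formula(self, small_library):
        cfg = FeaturizeConfig()
        dm = featurize(small_library[:3], cfg)
        assert dm.values.shape[1] == expected_column_count(cfg) == len(dm.manifest)

    def test_deterministic(self, small_library):
        dm1 = featurize(small_library[:5])
        dm2 = featurize(small_library[:5])
        assert dm1.values.equals(dm2.values)

    def test_no_nitrogen_wtpt_zero_not_missing(self):
        mol = embedded_molecule("CCCOC", "noN")
        dm = featurize([mol])
        assert dm.values.loc["noN", "WTPT-5"] == 0.0
        assert not dm.missing_mask.loc["noN", "WTPT-5"]

    def test_missing_policy(self):
        benzene = embedded_molecule("c1ccccc1", "benzene")
        dm = featurize([benzene])
        assert dm.missing_mask.loc["benzene", "SssCH2"]
        assert dm.values.loc["benzene", "SssCH2"] == 0.0
        strict = FeaturizeConfig(missing_policy="strict")
        with pytest.raises(DescriptorError, match="benzene"):
            featurize([benzene], strict)

    def test_csv_round_trip(self, small_library, tmp_path):
        dm = featurize(small_library[:4])
        path = tmp_path / "m.csv"
        mpath = tmp_path / "m.json"
        dm.to_csv(path, manifest_path=mpath)
        from foulqsar.descriptors import DescriptorMatrix

        again = DescriptorMatrix.from_csv(path, manifest_path=mpath)
        assert np.allclose(again.values.to_numpy(), dm.values.to_numpy(), atol=1e-9)
        assert [m["name"] for m in again.manifest] == [m["name"] for m in dm.manifest]
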
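import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pdbinder.structure_model import AtomRec, ResidueRecord

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


# --------------------------------------------------------------------------
# Residue construction helpers
# --------------------------------------------------------------------------

def make_residue(chain: str, num: int, aa: str, ca, rng=None,
                 icode: str = "") -> ResidueRecord:
    """A residue with N/CA/C/CB (no CB for GLY) around the given CA."""
    ca = np.asarray(ca, dtype=float)
    if rng is None:
        offs = {"N": [1.3, 0.5, 0.0], "C": [-1.3, 0.5, 0.0], "CB": [0.0, -1.0, 1.1]}
    else:
        def rand_off():
            v = rng.normal(size=3)
            return 1.5 * v / np.linalg.norm(v)
        offs = {"N": rand_off(), "C": rand_off(), "CB": rand_off()}
    atoms = [AtomRec("N", "N", ca + offs["N"]), AtomRec("CA", "C", ca),
             AtomRec("C", "C", ca + offs["C"])]
    if aa != "GLY":
        atoms.append(AtomRec("CB", "C", ca + offs["CB"]))
    return ResidueRecord(chain_id=chain, seq_num=num, insertion_code=icode,
                         aa_type=aa, atoms=atoms)


@pytest.fixture
def make_res():
    return make_residue


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------

def _euler_matrix(a: float, b: float, c: float) -> np.ndarray:
    ca_, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rz = np.array([[ca_, -sa, 0], [sa, ca_, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rx = np.array([[1, 0, 0], [0, cc, -sc], [0, sc, cc]])
    return rz @ ry @ rx


def grid_search_rmsd(a: np.ndarray, b: np.ndarray, tol: float = 1e-4) -> float:
    """Minimal superposition RMSD by iteratively refined search over Euler
    angles (proper rotations only).  Independent of the analytic solver."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    n = len(a)

    def rmsd_at(angles):
        r = _euler_matrix(*angles)
        return np.sqrt(np.sum((ac - bc @ r.T) ** 2) / n)

    coarse = []
    step0 = np.pi / 12
    grid = np.arange(0, 2 * np.pi, step0)
    for x in grid:
        # z-y-x (Tait-Bryan) angles: pitch in [-pi/2, pi/2] covers SO(3)
        for y in np.arange(-np.pi / 2, np.pi / 2 + 1e-9, step0):
            for z in grid:
                coarse.append((rmsd_at((x, y, z)), (x, y, z)))
    coarse.sort(key=lambda t: t[0])

    best = coarse[0][0]
    for _, start in coarse[:15]:  # refine from several basins
        angles, value = start, rmsd_at(start)
        step = step0
        while step > tol:
            step /= 2.0
            cx, cy, cz = angles
            for x in cx + step * np.arange(-2, 3):
                for y in cy + step * np.arange(-2, 3):
                    for z in cz + step * np.arange(-2, 3):
                        v = rmsd_at((x, y, z))
                        if v < value:
                            value, angles = v, (x, y, z)
        best = min(best, value)
    return float(best)


def brute_force_matches(query, lib, cfg):
    """Exhaustive reference matcher over every triplet pair and every
    identical-type permutation; returns {(query keys, library keys): rmsd}."""
    from itertools import combinations, permutations

    from pdbinder.motif_matcher import kabsch_rmsd
    from pdbinder.structure_model import ensure_representations

    def triplets(residues):
        complete, _ = ensure_representations(residues, cfg.representation)
        out = []
        for combo in combinations(sorted(complete, key=lambda r: r.key), 3):
            cas = [r.ca for r in combo]
            edges = sum(np.linalg.norm(cas[i] - cas[j]) < cfg.neighbor_max
                        for i in range(3) for j in range(i + 1, 3))
            if edges >= 2:
                out.append(combo)
        return out

    result = {}
    q_triplets = triplets(query)
    for chain_key, (cluster, lib_res) in lib.chains().items():
        for lt in triplets(lib_res):
            flags = {r.is_binding for r in lt}
            if len(flags) != 1:
                continue
            for qt in q_triplets:
                best = None
                for perm in permutations(lt):
                    if tuple(r.aa_type for r in perm) != tuple(r.aa_type for r in qt):
                        continue
                    rmsd = kabsch_rmsd(np.concatenate([r.rep_coords for r in qt]),
                                       np.concatenate([r.rep_coords for r in perm]))
                    if rmsd < cfg.rmsd_max and (best is None or rmsd < best):
                        best = rmsd
                if best is not None:
                    key = (tuple(r.key for r in qt), tuple(r.key for r in lt))
                    result[key] = best
    return result
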
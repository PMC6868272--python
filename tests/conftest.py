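import numpy as np
import pytest

from felhip.pedigree import Pedigree, PedigreeRecord


def random_pedigree(rng: np.random.Generator, n_founders: int = 10,
                    n_extra: int = 30) -> Pedigree:
    """Random mating pedigree for tests: founders then sequential offspring.

    Sires and dams are drawn from disjoint pools (an individual never plays
    both roles); some offspring have one or both parents unknown.
    """
    males = [f"M{i}" for i in range(n_founders // 2)]
    females = [f"F{i}" for i in range(n_founders - n_founders // 2)]
    recs = [PedigreeRecord(m, None, None, "male") for m in males]
    recs += [PedigreeRecord(f, None, None, "female") for f in females]
    for k in range(n_extra):
        sex = "male" if rng.random() < 0.5 else "female"
        iid = f"X{k}"
        sire = rng.choice(males) if rng.random() < 0.9 else None
        dam = rng.choice(females) if rng.random() < 0.9 else None
        recs.append(PedigreeRecord(iid, sire, dam, sex))
        (males if sex == "male" else females).append(iid)
    return Pedigree(recs)


def coancestry_oracle(ped: Pedigree) -> np.ndarray:
    """Brute-force kinship f(i,j) by the textbook recursion (memoized).

    f(i,i) = ½(1 + f(s_i, d_i)); for i < j (topological order),
    f(i,j) = ½[f(i, s_j) + f(i, d_j)]; unknown parents contribute 0.
    Independent of the tabular method used by the package.
    """
    n = len(ped)
    f = {}

    def kin(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        if (i, j) in f:
            return f[(i, j)]
        if i == j:
            val = 0.5 * (1.0 + kin(ped.sire[i], ped.dam[i]))
        else:
            val = 0.5 * (kin(i, ped.sire[j]) + kin(i, ped.dam[j]))
        f[(i, j)] = val
        return val

    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            out[i, j] = out[j, i] = kin(i, j)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
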
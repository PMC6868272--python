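"""Published summary counts from the PawPeds Maine Coon hip programme.

The PawPeds health programme (Sweden) published per-sex counts of left,
right and maximum hip scores for 5038 Maine Coon cats screened 2000-2019.
Those printed counts are a directly usable input: they reproduce the
headline prevalence and laterality figures without access to the underlying
database, and serve as a fixed reference dataset for this package.
"""

from __future__ import annotations

import numpy as np

from .demography import HipRecord, ScoreTable

# counts per score grade 0..3
MAINE_COON_COUNTS = {
    "male": {                       # n = 1751
        "left": [1217, 312, 165, 57],
        "right": [1197, 331, 157, 66],
        "max": [1085, 372, 217, 77],
    },
    "female": {                     # n = 3287
        "left": [2309, 605, 287, 86],
        "right": [2279, 630, 282, 96],
        "max": [2068, 723, 370, 126],
    },
}

SURVEY_YEARS = (2000, 2019)


def maine_coon_score_table() -> ScoreTable:
    """The published per-sex score counts as a :class:`ScoreTable`."""
    return ScoreTable.from_counts(MAINE_COON_COUNTS)


def _joint_from_marginals(left: np.ndarray, right: np.ndarray,
                          maxc: np.ndarray) -> np.ndarray:
    """An integer 4x4 joint (left, right) table consistent with all three
    published marginals (left, right and per-cat maximum), found by integer
    programming.  Any feasible joint reproduces every max-score-based
    summary and the inclusion-exclusion laterality exactly.
    """
    from scipy.optimize import Bounds, LinearConstraint, milp

    idx = {(l, r): k for k, (l, r) in
           enumerate((l, r) for l in range(4) for r in range(4))}
    n_var = 16
    rows, rhs = [], []
    for l in range(4):            # row sums = left marginal
        v = np.zeros(n_var)
        for r in range(4):
            v[idx[(l, r)]] = 1
        rows.append(v)
        rhs.append(left[l])
    for r in range(4):            # column sums = right marginal
        v = np.zeros(n_var)
        for l in range(4):
            v[idx[(l, r)]] = 1
        rows.append(v)
        rhs.append(right[r])
    for s in range(4):            # max-score counts
        v = np.zeros(n_var)
        for (l, r), k in idx.items():
            if max(l, r) == s:
                v[k] = 1
        rows.append(v)
        rhs.append(maxc[s])
    A = np.vstack(rows)
    b = np.asarray(rhs, float)
    res = milp(c=np.zeros(n_var),
               constraints=LinearConstraint(A, b, b),
               integrality=np.ones(n_var),
               bounds=Bounds(0, np.inf))
    if not res.success:
        raise RuntimeError("no integer joint table consistent with the "
                           "published marginals")
    J = np.zeros((4, 4), dtype=int)
    for (l, r), k in idx.items():
        J[l, r] = int(round(res.x[k]))
    return J


def maine_coon_records() -> list[HipRecord]:
    """Reconstruct 5038 individual records from the published counts.

    Per sex, an integer joint (left, right) distribution consistent with the
    printed left, right and maximum marginals is solved for; each cell then
    yields that many records.  Ages and years are nominal placeholders (the
    published table does not stratify by them) -- use these records for
    count-based summaries only.
    """
    records = []
    k = 0
    for sex, sides in MAINE_COON_COUNTS.items():
        J = _joint_from_marginals(np.array(sides["left"]),
                                  np.array(sides["right"]),
                                  np.array(sides["max"]))
        for l in range(4):
            for r in range(4):
                for _ in range(J[l, r]):
                    records.append(HipRecord(
                        id=f"cat{k}", sex=sex, age_days=520, year=2010,
                        left=l, right=r))
                    k += 1
    return records
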
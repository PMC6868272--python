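"""Phenotype records and descriptive epidemiology of hip-score data.

Covers the cross-sectional side of a hip-screening programme: loading
per-cat assessment records (left and right hip graded 0-3), tabulating
score distributions by sex, prevalence (any radiographic sign, i.e. maximum
score ≥ 1), laterality among affected cats (one vs both hips), and the
year-trend multinomial model of category proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .multinomial import MultinomialFit, fit_multinomial

SCORES = (0, 1, 2, 3)
SEXES = ("female", "male")


@dataclass(frozen=True)
class HipRecord:
    """One cat's hip-screening assessment."""

    id: str
    sex: str
    age_days: int
    year: int
    left: int
    right: int
    body_mass_kg: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be female/male, got {self.sex!r}")
        if self.age_days <= 0:
            raise ValueError(f"non-positive age for {self.id!r}")
        for side, s in (("left", self.left), ("right", self.right)):
            if s not in SCORES:
                raise ValueError(
                    f"{side} score {s!r} outside 0-3 for {self.id!r}")
        if self.body_mass_kg is not None and not self.body_mass_kg > 0:
            raise ValueError(f"non-positive body mass for {self.id!r}")

    @property
    def max_score(self) -> int:
        """Worse of the two hips -- the analysis's main response."""
        return max(self.left, self.right)

    @property
    def affected(self) -> bool:
        return self.max_score >= 1


def load_records(path) -> list[HipRecord]:
    """Read phenotype CSV: id,sex,age_days,year,left,right[,mass_kg].

    The maximum score is always computed, never read from the file.
    Invalid rows raise ``ValueError`` naming the row number.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    needed = ["id", "sex", "age_days", "year", "left", "right"]
    missing = [c for c in needed if c not in cols]
    if missing:
        raise ValueError(f"phenotype file missing column(s): {missing}")
    mass_col = cols.get("mass_kg") or cols.get("body_mass_kg")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        r = row._asdict()
        mass = r.get(mass_col) if mass_col else None
        if mass is not None and pd.isna(mass):
            mass = None
        try:
            out.append(HipRecord(
                id=str(r[cols["id"]]),
                sex=str(r[cols["sex"]]).strip().lower(),
                age_days=int(r[cols["age_days"]]),
                year=int(r[cols["year"]]),
                left=int(r[cols["left"]]),
                right=int(r[cols["right"]]),
                body_mass_kg=float(mass) if mass is not None else None,
            ))
        except (ValueError, TypeError) as e:
            raise ValueError(f"invalid phenotype row {i}: {e}") from e
    return out


def records_to_frame(records: Iterable[HipRecord]) -> pd.DataFrame:
    rows = [{
        "id": r.id, "sex": r.sex, "age_days": r.age_days, "year": r.year,
        "left": r.left, "right": r.right, "max_score": r.max_score,
        "mass_kg": r.body_mass_kg,
    } for r in records]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# score tables and prevalence


@dataclass
class ScoreTable:
    """Per-sex counts of left / right / maximum scores by category.

    ``counts`` is indexed by score 0-3 with a (sex, side) column MultiIndex;
    sides are ``left``, ``right`` and ``max``.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        for sex in self.counts.columns.levels[0]:
            sub = self.counts[sex]
            tot = sub.sum(axis=0)
            if tot.nunique() > 1:
                raise ValueError(
                    f"inconsistent column totals for sex {sex!r}: {dict(tot)}")
            if (sub < 0).any().any():
                raise ValueError("negative counts")

    @classmethod
    def from_counts(cls, per_sex: dict[str, dict[str, Sequence[int]]]
                    ) -> "ScoreTable":
        """Build from ``{sex: {side: [c0, c1, c2, c3]}}``."""
        frames = {}
        for sex, sides in per_sex.items():
            frames[sex] = pd.DataFrame(
                {side: list(c) for side, c in sides.items()},
                index=list(SCORES))
        df = pd.concat(frames, axis=1)
        return cls(df)

    def total(self, sex: str | None = None) -> int:
        if sex is not None:
            return int(self.counts[sex]["max"].sum())
        return int(sum(self.counts[s]["max"].sum()
                       for s in self.counts.columns.levels[0]))

    def proportions(self) -> pd.DataFrame:
        out = self.counts.astype(float).copy()
        for sex in self.counts.columns.levels[0]:
            out[sex] = self.counts[sex] / self.counts[sex].sum(axis=0)
        return out

    def pooled(self, side: str = "max") -> pd.Series:
        sexes = self.counts.columns.levels[0]
        return sum(self.counts[s][side] for s in sexes)


@dataclass
class ScoreSummary:
    """Score table plus headline epidemiological quantities."""

    table: ScoreTable
    n: int
    prevalence_percent: float
    max_share_percent: dict[int, float]
    per_sex_prevalence_percent: dict[str, float] = field(default_factory=dict)


def summarize_scores(records: Sequence[HipRecord]) -> ScoreSummary:
    """Tabulate per-sex score distributions and overall prevalence.

    Prevalence is the percentage of cats whose maximum (worse-hip) score is
    at least 1; per-category shares are percentages of all surveyed cats.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    per_sex: dict[str, dict[str, list[int]]] = {}
    for sex in sorted({r.sex for r in records}):
        sub = [r for r in records if r.sex == sex]
        per_sex[sex] = {
            "left": list(np.bincount([r.left for r in sub], minlength=4)),
            "right": list(np.bincount([r.right for r in sub], minlength=4)),
            "max": list(np.bincount([r.max_score for r in sub], minlength=4)),
        }
    table = ScoreTable.from_counts(per_sex)
    n = len(records)
    n_aff = sum(r.affected for r in records)
    pooled_max = table.pooled("max")
    shares = {s: 100.0 * pooled_max[s] / n for s in SCORES}
    per_sex_prev = {
        sex: 100.0 * (1.0 - table.counts[sex]["max"][0]
                      / table.counts[sex]["max"].sum())
        for sex in per_sex
    }
    return ScoreSummary(table=table, n=n,
                        prevalence_percent=100.0 * n_aff / n,
                        max_share_percent=shares,
                        per_sex_prevalence_percent=per_sex_prev)


# ---------------------------------------------------------------------------
# laterality


def laterality_from_records(records: Sequence[HipRecord]) -> dict:
    """Unilateral vs bilateral involvement among affected cats.

    Unilateral means exactly one hip scored > 0.  Also returns a
    severity-by-laterality cross-tab (maximum score x unilateral/bilateral).
    """
    affected = [r for r in records if r.affected]
    if not affected:
        raise ValueError("no affected cats (max score >= 1)")
    uni = [r for r in affected if (r.left > 0) != (r.right > 0)]
    bil = [r for r in affected if (r.left > 0) and (r.right > 0)]
    cross = pd.DataFrame(0, index=[1, 2, 3], columns=["unilateral", "bilateral"])
    for r in uni:
        cross.loc[r.max_score, "unilateral"] += 1
    for r in bil:
        cross.loc[r.max_score, "bilateral"] += 1
    return {
        "n_affected": len(affected),
        "unilateral_frac": len(uni) / len(affected),
        "bilateral_frac": len(bil) / len(affected),
        "severity_by_laterality": cross,
    }


def laterality_from_marginals(table: ScoreTable) -> dict:
    """Laterality reconstructed from marginal counts by inclusion-exclusion.

    A cat is affected on the left, right, or either side; since
    ``|L∪R| = |max>0|``, the bilateral count is
    ``|L>0| + |R>0| − |max>0|``.  Computed per sex, then pooled.
    """
    per_sex = {}
    tot_aff = tot_bil = 0
    for sex in table.counts.columns.levels[0]:
        sub = table.counts[sex]
        aff_l = int(sub["left"][1:].sum())
        aff_r = int(sub["right"][1:].sum())
        aff = int(sub["max"][1:].sum())
        bil = aff_l + aff_r - aff
        uni = aff - bil
        if bil < 0 or uni < 0:
            raise ValueError(
                f"inconsistent marginals for sex {sex!r}: "
                f"implied bilateral={bil}, unilateral={uni}")
        per_sex[sex] = {"unilateral_frac": uni / aff if aff else np.nan,
                        "bilateral_frac": bil / aff if aff else np.nan}
        tot_aff += aff
        tot_bil += bil
    if tot_aff == 0:
        raise ValueError("no affected cats in table")
    return {
        "unilateral_frac": (tot_aff - tot_bil) / tot_aff,
        "bilateral_frac": tot_bil / tot_aff,
        "per_sex": per_sex,
        "n_affected": tot_aff,
    }


# ---------------------------------------------------------------------------
# year-trend multinomial model


def fit_multinomial_trend(records: Sequence[HipRecord], *,
                          base_year: int = 2000,
                          include_sex: bool = True,
                          ridge: float = 0.0) -> "TrendModel":
    """Multinomial logistic model of maximum-score category vs programme year.

    Year enters as a continuous covariate (years since ``base_year``); sex
    as a binary main effect.  Reference category is score 0.  The fit is by
    Newton iterations on the multinomial log-likelihood with step-halving;
    complete separation triggers a warning and a ridge-penalised refit.
    """
    df = records_to_frame(records)
    y = df["max_score"].to_numpy()
    cols = [np.ones(len(df)), (df["year"] - base_year).to_numpy(float)]
    names = ["intercept", "years_since_base"]
    if include_sex:
        cols.append((df["sex"] == "male").to_numpy(float))
        names.append("sex_male")
    X = np.column_stack(cols)
    fit = fit_multinomial(y, X, ridge=ridge)
    return TrendModel(fit=fit, base_year=base_year, include_sex=include_sex,
                      coef_names=names)


@dataclass
class TrendModel:
    fit: MultinomialFit
    base_year: int
    include_sex: bool
    coef_names: list[str]

    def predict_proportions(self, years: Sequence[int],
                            sex: str = "female") -> pd.DataFrame:
        """Per-category probability surface over calendar years (one sex)."""
        t = np.asarray(years, float) - self.base_year
        cols = [np.ones_like(t), t]
        if self.include_sex:
            cols.append(np.full_like(t, 1.0 if sex == "male" else 0.0))
        P = self.fit.predict_proba(np.column_stack(cols))
        return pd.DataFrame(P, index=list(years),
                            columns=[f"score_{k}" for k in range(P.shape[1])])


def proportional_odds_diagnostic(records: Sequence[HipRecord], *,
                                 base_year: int = 2000) -> dict:
    """Likelihood-ratio comparison: cumulative-logit vs multinomial model.

    A cumulative (proportional-odds) model constrains the covariate effects
    to be equal across category splits; the multinomial model frees them.
    Twice the log-likelihood gap is compared to χ² with the difference in
    parameter count.  A small P-value indicates the proportional-odds
    assumption is violated.
    """
    from scipy.stats import chi2
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    df = records_to_frame(records)
    exog = pd.DataFrame({
        "years": df["year"] - base_year,
        "sex_male": (df["sex"] == "male").astype(float),
    })
    ordfit = OrderedModel(df["max_score"], exog, distr="logit").fit(
        method="bfgs", disp=False)
    mnl = fit_multinomial_trend(records, base_year=base_year)
    lr = 2.0 * (mnl.fit.loglik - ordfit.llf)
    df_diff = mnl.fit.n_params - len(ordfit.params)
    return {
        "lr_stat": float(lr),
        "df": int(df_diff),
        "p_value": float(chi2.sf(max(lr, 0.0), df_diff)),
        "loglik_multinomial": float(mnl.fit.loglik),
        "loglik_cumulative": float(ordfit.llf),
    }
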
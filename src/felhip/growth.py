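"""Sex-specific growth curves and age-adjusted residual body mass.

Body mass in cats depends strongly on sex and age, so mass enters the
downstream analyses as a *residual*: observed minus the mass expected for
the cat's sex and age on a fitted growth curve.  A Gompertz curve
``m(a) = A · exp(−b · exp(−c·a))`` (asymptotic adult mass A, shape b,
rate c per day) is fitted per sex by nonlinear least squares; if that fails
to converge the fit falls back to a quadratic polynomial in log age, which
is flagged in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .demography import HipRecord, records_to_frame

MEAN_ASSESSMENT_AGE_DAYS = 520.0


def gompertz(age_days, a_sat, b, c):
    return a_sat * np.exp(-b * np.exp(-c * np.asarray(age_days, float)))


@dataclass
class SexCurve:
    params: dict
    form: str               # "gompertz" or "log_poly"
    resid_sd: float
    n: int
    age_range: tuple[float, float]

    def predict(self, age_days) -> np.ndarray:
        age = np.asarray(age_days, float)
        if self.form == "gompertz":
            return gompertz(age, self.params["a_sat"], self.params["b"],
                            self.params["c"])
        la = np.log(age)
        return (self.params["c0"] + self.params["c1"] * la
                + self.params["c2"] * la ** 2)


@dataclass
class GrowthModel:
    """Per-sex growth curves with residual standard deviations."""

    curves: dict[str, SexCurve] = field(default_factory=dict)

    def predict(self, sex: str, age_days) -> np.ndarray:
        if sex not in self.curves:
            raise KeyError(f"no fitted curve for sex {sex!r}")
        curve = self.curves[sex]
        age = np.atleast_1d(np.asarray(age_days, float))
        lo, hi = curve.age_range
        if (age < lo).any() or (age > hi).any():
            warnings.warn(
                f"age outside the fitted range [{lo:.0f}, {hi:.0f}] d for "
                f"{sex}; extrapolating")
        return np.atleast_1d(curve.predict(age))

    def to_dict(self) -> dict:
        return {sex: {"form": c.form, "params": c.params,
                      "resid_sd": c.resid_sd, "n": c.n,
                      "age_range": list(c.age_range)}
                for sex, c in self.curves.items()}


def fit_growth_curve(records: Sequence[HipRecord] | pd.DataFrame,
                     *, min_per_sex: int = 10) -> GrowthModel:
    """Fit a Gompertz mass-age curve per sex by nonlinear least squares.

    Needs at least ``min_per_sex`` massed records per sex spanning at least
    a two-fold age range.  Non-convergence of the Gompertz fit falls back to
    a quadratic polynomial in log age (``form == "log_poly"``).
    """
    df = records if isinstance(records, pd.DataFrame) \
        else records_to_frame(records)
    df = df.dropna(subset=["mass_kg"])
    model = GrowthModel()
    for sex, sub in df.groupby("sex"):
        age = sub["age_days"].to_numpy(float)
        mass = sub["mass_kg"].to_numpy(float)
        if len(sub) < min_per_sex:
            raise ValueError(
                f"only {len(sub)} massed records for sex {sex!r}; "
                f"need >= {min_per_sex}")
        if age.max() < 2 * age.min():
            raise ValueError(
                f"age range for sex {sex!r} spans less than two-fold")
        try:
            p0 = (np.quantile(mass, 0.9), 3.0, 0.01)
            popt, _ = curve_fit(
                gompertz, age, mass, p0=p0, maxfev=20_000,
                bounds=([0.1, 1e-3, 1e-5], [30.0, 50.0, 1.0]))
            pred = gompertz(age, *popt)
            curve = SexCurve(
                params={"a_sat": float(popt[0]), "b": float(popt[1]),
                        "c": float(popt[2])},
                form="gompertz",
                resid_sd=float(np.std(mass - pred)),
                n=len(sub), age_range=(float(age.min()), float(age.max())))
        except RuntimeError:
            warnings.warn(f"Gompertz fit did not converge for sex {sex!r}; "
                          "falling back to a quadratic in log age")
            la = np.log(age)
            coefs = np.polyfit(la, mass, 2)
            pred = np.polyval(coefs, la)
            curve = SexCurve(
                params={"c0": float(coefs[2]), "c1": float(coefs[1]),
                        "c2": float(coefs[0])},
                form="log_poly",
                resid_sd=float(np.std(mass - pred)),
                n=len(sub), age_range=(float(age.min()), float(age.max())))
        model.curves[sex] = curve
    return model


def residual_mass(model: GrowthModel, record: HipRecord) -> float:
    """Observed minus expected mass (kg); NaN when mass is missing."""
    if record.body_mass_kg is None:
        return float("nan")
    pred = model.predict(record.sex, record.age_days)
    return float(record.body_mass_kg - pred[0])


def residual_mass_frame(model: GrowthModel,
                        records: Sequence[HipRecord] | pd.DataFrame
                        ) -> pd.DataFrame:
    """Phenotype frame with a ``residual_mass`` column appended."""
    df = (records if isinstance(records, pd.DataFrame)
          else records_to_frame(records)).copy()
    out = np.full(len(df), np.nan)
    for sex in df["sex"].unique():
        mask = (df["sex"] == sex) & df["mass_kg"].notna()
        if mask.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pred = model.predict(sex, df.loc[mask, "age_days"].to_numpy())
            out[mask.to_numpy()] = df.loc[mask, "mass_kg"].to_numpy() - pred
    df["residual_mass"] = out
    return df


def predict_mass(model: GrowthModel, sex: str,
                 age_days: float = MEAN_ASSESSMENT_AGE_DAYS) -> float:
    """Expected mass (kg) at an age, default the programme's mean (520 d)."""
    return float(model.predict(sex, age_days)[0])
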
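"""Binomial-GLM occurrence modelling with AIC selection (Method B core).

Presence/absence of the gull on an observation day is modelled by logistic
regression on standardized covariates: the seasonal ordinal date, trajectory
covariates (lagged parcel latitude Lat24/48/72 and bearing Deg24/48/72),
sea-ice extents, and observation duration. Model building follows a
two-stage AIC procedure: first each three-member covariate family (ice,
latitude, bearing) is screened to one winner (member + duration models
compared by AIC), then all subsets of {date, ice winner, latitude winner,
bearing winner, duration} are fitted and ranked by AIC.

All covariates are z-scored with training-set means and standard deviations;
the scaling constants are frozen into the model artifact so a forecast input
(including the fixed 60-minute duration) is standardized exactly as the
training data were.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import DegenerateCovariateError, FormatError

ICE_FAMILY = ("ice_whole", "ice_north", "ice_south")
LAT_FAMILY = ("lat24", "lat48", "lat72")
DEG_FAMILY = ("deg24", "deg48", "deg72")
RESPONSE = "presence"
DEFAULT_FORECAST_DURATION_MIN = 60.0


@dataclass
class Scaling:
    """Per-covariate training mean and standard deviation."""

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in self.mean:
            if col in out.columns:
                out[col] = (out[col] - self.mean[col]) / self.sd[col]
        return out

    def transform_value(self, term: str, value: float) -> float:
        return (value - self.mean[term]) / self.sd[term]


def scale(
    covariates: pd.DataFrame, scaling: Scaling | None = None
) -> tuple[pd.DataFrame, Scaling]:
    """Z-score every numeric covariate column (response excluded).

    With ``scaling=None`` the constants are fitted from the data and
    returned; otherwise the stored constants are reused (prediction path).
    A zero-variance covariate raises :class:`DegenerateCovariateError`.
    """
    if scaling is not None:
        return scaling.transform(covariates), scaling
    scaling = Scaling()
    for col in covariates.columns:
        if col == RESPONSE or not pd.api.types.is_numeric_dtype(covariates[col]):
            continue
        if pd.api.types.is_bool_dtype(covariates[col]):
            continue
        m = float(covariates[col].mean())
        s = float(covariates[col].std(ddof=1))
        if not np.isfinite(s) or s <= 0:
            raise DegenerateCovariateError(f"covariate {col!r} has zero variance")
        scaling.mean[col] = m
        scaling.sd[col] = s
    return scaling.transform(covariates), scaling


@dataclass
class OccurrenceModel:
    """Fitted logistic model on scaled covariates.

    ``k`` counts the estimated coefficients including the intercept and
    ``aic = -2 * log_likelihood + 2 * k`` holds exactly.
    """

    terms: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    log_likelihood: float
    k: int
    aic: float
    scaling: Scaling
    converged: bool = True

    def __post_init__(self) -> None:
        assert abs(self.aic - (-2.0 * self.log_likelihood + 2.0 * self.k)) < 1e-8

    def linear_predictor(self, scaled: dict[str, float]) -> float:
        eta = self.coefficients["intercept"]
        for t in self.terms:
            eta += self.coefficients[t] * scaled[t]
        return eta


def _design(scaled: pd.DataFrame, terms) -> np.ndarray:
    cols = [np.ones(len(scaled))]
    for t in terms:
        if t not in scaled.columns:
            raise FormatError(f"term {t!r} not among covariates")
        cols.append(np.asarray(scaled[t], dtype=float))
    return np.column_stack(cols)


def _check_rank(x: np.ndarray, terms) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [
            (["intercept"] + list(terms))[i]
            for i in range(x.shape[1])
            if diag[i] < 1e-8 * diag.max()
        ]
        raise FormatError(f"singular design; collinear terms: {bad}")


def fit_glm(
    scaled_covariates: pd.DataFrame,
    terms,
    scaling: Scaling | None = None,
) -> OccurrenceModel:
    """Maximum-likelihood logistic regression (IRLS via statsmodels).

    ``scaled_covariates`` must already be standardized; pass the fitted
    :class:`Scaling` so predictions can standardize new inputs. Perfect
    separation yields a flagged (``converged=False``) model rather than an
    exception; a singular design raises naming the collinear terms.
    """
    terms = list(terms)
    y = np.asarray(scaled_covariates[RESPONSE], dtype=float)
    if len(np.unique(y)) < 2:
        raise FormatError("need at least one record of each response class")
    x = _design(scaled_covariates, terms)
    _check_rank(x, terms)
    converged = True
    with warnings.catch_warnings():
        warnings.filterwarnings("error", message=".*[Pp]erfect.*separation.*")
        try:
            res = sm.GLM(y, x, family=sm.families.Binomial()).fit(
                tol=1e-10, maxiter=200
            )
            params = res.params
            llf = float(res.llf)
        except (PerfectSeparationError, Warning):
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, x, family=sm.families.Binomial()).fit(
                    tol=1e-8, maxiter=50
                )
            params = res.params
            llf = float(res.llf)
    k = len(terms) + 1
    coefs = {"intercept": float(params[0])}
    coefs.update({t: float(params[i + 1]) for i, t in enumerate(terms)})
    return OccurrenceModel(
        terms=terms,
        coefficients=coefs,
        log_likelihood=llf,
        k=k,
        aic=-2.0 * llf + 2.0 * k,
        scaling=scaling if scaling is not None else Scaling(),
        converged=converged,
    )


def screen_categories(
    covariates: pd.DataFrame,
    families: dict[str, tuple] | None = None,
) -> dict[str, str]:
    """Stage-one screening: pick one member per covariate family by AIC.

    Each candidate model is member + duration; the lowest-AIC member wins
    (strict comparison, so an exact tie keeps the earlier family member).
    Families whose members are absent from the data are skipped.
    """
    if families is None:
        families = {"ice": ICE_FAMILY, "lat": LAT_FAMILY, "deg": DEG_FAMILY}
    scaled, scaling = scale(covariates)
    winners: dict[str, str] = {}
    for fam_name, members in families.items():
        present = [m for m in members if m in covariates.columns]
        if not present:
            continue
        best, best_aic = None, np.inf
        for m in present:
            model = fit_glm(scaled, [m, "duration_min"], scaling)
            if model.aic < best_aic:
                best, best_aic = m, model.aic
        winners[fam_name] = best
    return winners


def select_model(
    covariates: pd.DataFrame,
    candidate_terms=None,
) -> tuple[pd.DataFrame, OccurrenceModel]:
    """Stage-two selection: fit every subset of the candidate terms and rank
    by AIC.

    Default candidates are {date_ordinal, ice winner, lat winner, deg winner,
    duration_min} with winners from :func:`screen_categories`. Returns the
    ranked table (terms, df, logLik, AIC, dAIC) and the best model; ties are
    broken toward fewer terms.
    """
    if candidate_terms is None:
        winners = screen_categories(covariates)
        candidate_terms = ["date_ordinal"] + [
            winners[f] for f in ("ice", "lat", "deg") if f in winners
        ] + ["duration_min"]
    candidate_terms = [t for t in candidate_terms if t in covariates.columns]
    scaled, scaling = scale(covariates)

    rows = []
    models = []
    subsets = []
    for size in range(len(candidate_terms) + 1):
        subsets.extend(itertools.combinations(candidate_terms, size))
    for terms in subsets:
        try:
            model = fit_glm(scaled, list(terms), scaling)
        except FormatError:
            continue  # unrankable (e.g. collinear) candidate
        models.append(model)
        rows.append(
            {
                "terms": "+".join(terms) if terms else "(intercept)",
                "df": model.k,
                "logLik": model.log_likelihood,
                "AIC": model.aic,
                "converged": model.converged,
                **{t: model.coefficients[t] for t in terms},
                "intercept": model.coefficients["intercept"],
            }
        )
    table = pd.DataFrame(rows)
    order = np.argsort(table["AIC"].values, kind="stable")
    table = table.iloc[order].reset_index(drop=True)
    table["dAIC"] = table["AIC"] - table["AIC"].iloc[0]
    best = models[int(order[0])]
    return table, best


def predict(
    model: OccurrenceModel,
    lat24: float | None = None,
    date_ordinal: float | None = None,
    duration_min: float = DEFAULT_FORECAST_DURATION_MIN,
    **other: float,
) -> float:
    """Occurrence probability for covariates on their ORIGINAL scale.

    Inputs are standardized with the model's stored training scaling, then
    pushed through the inverse-logit link. Terms the model does not contain
    may be omitted; terms it does contain must be supplied.
    """
    supplied = dict(other)
    if lat24 is not None:
        supplied["lat24"] = lat24
    if date_ordinal is not None:
        supplied["date_ordinal"] = date_ordinal
    supplied.setdefault("duration_min", duration_min)
    scaled = {}
    for t in model.terms:
        if t not in supplied:
            raise FormatError(f"model term {t!r} missing from inputs")
        scaled[t] = model.scaling.transform_value(t, float(supplied[t]))
    eta = model.linear_predictor(scaled)
    return float(1.0 / (1.0 + np.exp(-eta)))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_occurrence(model: OccurrenceModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "terms": model.terms,
                "coefficients": model.coefficients,
                "log_likelihood": model.log_likelihood,
                "k": model.k,
                "aic": model.aic,
                "converged": model.converged,
                "scaling": {"mean": model.scaling.mean, "sd": model.scaling.sd},
            },
            fh,
            indent=2,
        )


def load_occurrence(path) -> OccurrenceModel:
    with open(path) as fh:
        d = json.load(fh)
    return OccurrenceModel(
        terms=list(d["terms"]),
        coefficients={k: float(v) for k, v in d["coefficients"].items()},
        log_likelihood=float(d["log_likelihood"]),
        k=int(d["k"]),
        aic=float(d["aic"]),
        scaling=Scaling(
            mean={k: float(v) for k, v in d["scaling"]["mean"].items()},
            sd={k: float(v) for k, v in d["scaling"]["sd"].items()},
        ),
        converged=bool(d["converged"]),
    )
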
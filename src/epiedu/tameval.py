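"""Technology-acceptance evaluation: survey simulation with a planted
structural model, reliability (Cronbach's α, AVE), composite path analysis,
hierarchical moderation regression, format-preference chi-square, and the
binary logistic regression of perceived effectiveness.

The simulator plants a TAM structure: PEOU is standard normal; PU loads on
PEOU; behavioural intention (BI) loads on PU and PEOU with eHealth-literacy
(eHL) moderation; Likert items load on their construct and are discretized
at equiprobable standard-normal quintiles.  The binary effectiveness
outcome follows a logistic model over demographic indicators with
configurable odds ratios.  Every planted coefficient is therefore
recoverable by the fitting half of this module, which is how the battery is
validated.

Path analysis is composite-based: construct scores are item means,
z-scored, with OLS standardized betas and t-values (a fully specified
stand-in for a PLS-SEM at the composite level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .errors import SeparationError, ValidationError
from .topicmodel import Chi2Result, pearson_chi2

PATHS = ("PEOU->PU", "PU->BI", "PEOU->BI", "eHLxPU->BI", "eHLxPEOU->BI")
LOGIT_VARS = ("age60plus", "college_edu", "high_ehl", "official_source")

DEFAULT_PATH_COEFS = {
    "PEOU->PU": 0.38,
    "PU->BI": 0.42,
    "PEOU->BI": 0.31,
    "eHLxPU->BI": 0.18,
    "eHLxPEOU->BI": 0.22,
}

DEFAULT_ODDS_RATIOS = {
    "age60plus": 0.76,
    "college_edu": 1.52,
    "high_ehl": 1.87,
    "official_source": 2.05,
}

#: equiprobable quintile cut-points of the standard normal
_LIKERT_CUTS = norm.ppf([0.2, 0.4, 0.6, 0.8])

FORMATS = ("video_audio", "infographic", "text", "interactive")

#: preferred-format probabilities per age band: older respondents lean
#: heavily to video/audio, younger ones to infographic/text
_FORMAT_PREFS = {
    "18-30": (0.15, 0.40, 0.25, 0.20),
    "31-59": (0.30, 0.30, 0.25, 0.15),
    "60+": (0.65, 0.10, 0.15, 0.10),
}


@dataclass
class SurveyConfig:
    n_respondents: int = 305
    path_coefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATH_COEFS))
    logit_odds_ratios: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ODDS_RATIOS))
    items_pu: int = 6
    items_peou: int = 6
    items_bi: int = 5
    items_eheals: int = 8
    items_topic_knowledge: int = 10  # filler items completing the 35-item form
    loading: float = 0.8
    discretize: bool = True
    logit_intercept: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_respondents < 1:
            raise ValidationError("n_respondents must be >= 1")
        for path in PATHS:
            if path not in self.path_coefs:
                raise ValidationError(f"missing path coefficient {path!r}")
            if abs(self.path_coefs[path]) >= 1:
                raise ValidationError(f"|coefficient| for {path!r} must be < 1")
        for v in LOGIT_VARS:
            if v not in self.logit_odds_ratios:
                raise ValidationError(f"missing odds ratio {v!r}")
            if self.logit_odds_ratios[v] <= 0:
                raise ValidationError("odds ratios must be positive")
        if not (0 < self.loading <= 1):
            raise ValidationError("loading must be in (0, 1]")

    def residual_sd_bi(self) -> float:
        """Residual scale making the latent BI exactly unit variance."""
        b = self.path_coefs
        rho = b["PEOU->PU"]
        main = (b["PU->BI"] ** 2 + b["PEOU->BI"] ** 2
                + 2 * b["PU->BI"] * b["PEOU->BI"] * rho)
        inter = 0.25 * (b["eHLxPU->BI"] ** 2 + b["eHLxPEOU->BI"] ** 2
                        + 2 * b["eHLxPU->BI"] * b["eHLxPEOU->BI"] * rho)
        var = 1.0 - main - inter
        if var <= 0:
            raise ValidationError(
                "path coefficients imply explained variance >= 1")
        return math.sqrt(var)


@dataclass
class SurveyResponse:
    respondent_id: str
    age_years: int
    age_band: str
    gender: str
    education: str
    pu_items: list
    peou_items: list
    bi_items: list
    ehl_items: list
    ehl_group: str
    effectiveness: int
    official_source_trust: int
    preferred_format: str


@dataclass
class ReliabilityReport:
    cronbach_alpha: dict[str, float]
    ave: dict[str, float]


@dataclass
class PathResults:
    betas: dict[str, float]
    t_values: dict[str, float]
    composites: pd.DataFrame


@dataclass
class ModerationResults:
    step1_betas: dict[str, float]
    step2_betas: dict[str, float]
    r2_step1: float
    r2_step2: float
    delta_r2: float


@dataclass
class LogitResults:
    coef: dict[str, float]
    odds_ratio: dict[str, float]
    se: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    loglik_trace: list[float]


def response_rate(n_valid: int, n_recruited: int) -> float:
    """Valid-response percentage, to one decimal place."""
    if n_recruited < 1 or not (0 <= n_valid <= n_recruited):
        raise ValidationError("need 0 <= n_valid <= n_recruited, n_recruited >= 1")
    return round(100.0 * n_valid / n_recruited, 1)


def _likert(values: np.ndarray, discretize: bool) -> np.ndarray:
    if not discretize:
        return values
    return np.digitize(values, _LIKERT_CUTS) + 1


def _items_for(latent: np.ndarray, n_items: int, loading: float,
               discretize: bool, rng: np.random.Generator) -> np.ndarray:
    resid = math.sqrt(max(0.0, 1.0 - loading ** 2))
    raw = loading * latent[:, None] + resid * rng.standard_normal(
        (latent.shape[0], n_items))
    return _likert(raw, discretize)


def simulate_survey(config: SurveyConfig) -> list[SurveyResponse]:
    """Simulate respondents with the planted TAM structure; deterministic
    for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    b = config.path_coefs

    # demographics: age bands 25/55/20, higher education ~62.6%
    band_idx = rng.choice(3, size=n, p=(0.25, 0.55, 0.20))
    lo = np.array([18, 31, 60])[band_idx]
    hi = np.array([31, 60, 77])[band_idx]
    ages = (lo + rng.random(n) * (hi - lo)).astype(int)
    bands = np.array(["18-30", "31-59", "60+"])[band_idx]
    gender = np.where(rng.random(n) < 0.482, "male", "female")
    edu = rng.choice(
        ["below_high_school", "high_school", "college", "postgraduate"],
        size=n, p=(0.20, 0.174, 0.50, 0.126))

    ehl = rng.integers(0, 2, size=n)  # planted high-eHL indicator
    mc = ehl - 0.5

    peou = rng.standard_normal(n)
    pu = b["PEOU->PU"] * peou + math.sqrt(
        1 - b["PEOU->PU"] ** 2) * rng.standard_normal(n)
    bi = (b["PU->BI"] * pu + b["PEOU->BI"] * peou
          + b["eHLxPU->BI"] * mc * pu + b["eHLxPEOU->BI"] * mc * peou
          + config.residual_sd_bi() * rng.standard_normal(n))

    pu_items = _items_for(pu, config.items_pu, config.loading,
                          config.discretize, rng)
    peou_items = _items_for(peou, config.items_peou, config.loading,
                            config.discretize, rng)
    bi_items = _items_for(bi, config.items_bi, config.loading,
                          config.discretize, rng)
    # eHEALS: strongly group-separated so the median split recovers the plant
    ehl_latent = (2.0 * ehl - 1.0) + 0.1 * rng.standard_normal(n)
    ehl_items = _items_for(ehl_latent, config.items_eheals, 0.8,
                           config.discretize, rng)

    official = (rng.random(n) < 0.7).astype(int)
    logors = {v: math.log(config.logit_odds_ratios[v]) for v in LOGIT_VARS}
    x_age = (bands == "60+").astype(int)
    x_col = np.isin(edu, ["college", "postgraduate"]).astype(int)
    eta = (config.logit_intercept + logors["age60plus"] * x_age
           + logors["college_edu"] * x_col + logors["high_ehl"] * ehl
           + logors["official_source"] * official)
    eff = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    fmt = np.empty(n, dtype=object)
    for band, probs in _FORMAT_PREFS.items():
        mask = bands == band
        if mask.any():
            fmt[mask] = rng.choice(FORMATS, size=int(mask.sum()), p=probs)

    responses = [
        SurveyResponse(
            respondent_id=f"R{i:05d}",
            age_years=int(ages[i]), age_band=str(bands[i]),
            gender=str(gender[i]), education=str(edu[i]),
            pu_items=pu_items[i].tolist(),
            peou_items=peou_items[i].tolist(),
            bi_items=bi_items[i].tolist(),
            ehl_items=ehl_items[i].tolist(),
            ehl_group="",  # set by ehl_split below
            effectiveness=int(eff[i]),
            official_source_trust=int(official[i]),
            preferred_format=str(fmt[i]),
        )
        for i in range(n)
    ]
    return ehl_split(responses)


def ehl_split(responses: Sequence[SurveyResponse]) -> list[SurveyResponse]:
    """Median split on eHEALS totals: high iff total > sample median (ties
    at the median fall to medium_low).  Order-invariant."""
    totals = np.array([float(np.sum(r.ehl_items)) for r in responses])
    med = float(np.median(totals))
    for r, t in zip(responses, totals):
        r.ehl_group = "high" if t > med else "medium_low"
    return list(responses)


def to_dataframe(responses: Sequence[SurveyResponse]) -> pd.DataFrame:
    rows = []
    for r in responses:
        row = {
            "respondent_id": r.respondent_id, "age_years": r.age_years,
            "age_band": r.age_band, "gender": r.gender,
            "education": r.education, "ehl_group": r.ehl_group,
            "effectiveness": r.effectiveness,
            "official_source_trust": r.official_source_trust,
            "preferred_format": r.preferred_format,
        }
        for name, items in (("pu", r.pu_items), ("peou", r.peou_items),
                            ("bi", r.bi_items), ("ehl", r.ehl_items)):
            for j, v in enumerate(items, 1):
                row[f"{name}_{j}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def from_dataframe(df: pd.DataFrame) -> list[SurveyResponse]:
    def cols(prefix):
        names = [c for c in df.columns
                 if c.startswith(prefix + "_") and
                 c.rsplit("_", 1)[1].isdigit()]
        return sorted(names, key=lambda c: int(c.rsplit("_", 1)[1]))

    out = []
    for _, row in df.iterrows():
        out.append(SurveyResponse(
            respondent_id=str(row["respondent_id"]),
            age_years=int(row["age_years"]), age_band=str(row["age_band"]),
            gender=str(row["gender"]), education=str(row["education"]),
            pu_items=[row[c] for c in cols("pu")],
            peou_items=[row[c] for c in cols("peou")],
            bi_items=[row[c] for c in cols("bi")],
            ehl_items=[row[c] for c in cols("ehl")],
            ehl_group=str(row["ehl_group"]),
            effectiveness=int(row["effectiveness"]),
            official_source_trust=int(row["official_source_trust"]),
            preferred_format=str(row["preferred_format"]),
        ))
    return out


def cronbach_alpha(items_matrix) -> float:
    """α = k/(k−1) (1 − Σ item variances / total-score variance), with
    sample (n−1) variances."""
    x = np.asarray(items_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 2:
        raise ValidationError("need >= 2 items and >= 2 respondents")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValidationError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def ave(loadings) -> float:
    """Average variance extracted: mean of squared standardized loadings."""
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise ValidationError("loadings are empty")
    if (np.abs(lam) > 1).any():
        raise ValidationError("standardized loadings must lie in [-1, 1]")
    return float(np.mean(lam ** 2))


def _composites(responses: Sequence[SurveyResponse]) -> pd.DataFrame:
    df = pd.DataFrame({
        "PU": [float(np.mean(r.pu_items)) for r in responses],
        "PEOU": [float(np.mean(r.peou_items)) for r in responses],
        "BI": [float(np.mean(r.bi_items)) for r in responses],
        "ehl_high": [1.0 if r.ehl_group == "high" else 0.0 for r in responses],
    })
    for c in ("PU", "PEOU", "BI"):
        sd = df[c].std(ddof=0)
        if sd == 0:
            raise ValidationError(f"construct {c} has zero variance")
        df[c] = (df[c] - df[c].mean()) / sd
    return df


def reliability_report(responses: Sequence[SurveyResponse]) -> ReliabilityReport:
    """Cronbach's α per construct, and AVE from item-composite correlations
    as the standardized loadings."""
    mats = {
        "PU": np.array([r.pu_items for r in responses], dtype=float),
        "PEOU": np.array([r.peou_items for r in responses], dtype=float),
        "BI": np.array([r.bi_items for r in responses], dtype=float),
        "eHL": np.array([r.ehl_items for r in responses], dtype=float),
    }
    alphas, aves = {}, {}
    for name, m in mats.items():
        alphas[name] = cronbach_alpha(m)
        comp = m.mean(axis=1)
        lam = [float(np.corrcoef(m[:, j], comp)[0, 1]) for j in range(m.shape[1])]
        aves[name] = ave(lam)
    return ReliabilityReport(cronbach_alpha=alphas, ave=aves)


def fit_paths(responses: Sequence[SurveyResponse]) -> PathResults:
    """Composite standardized path regressions for the five TAM paths."""
    if len(responses) < 30:
        raise ValidationError("need at least 30 respondents")
    df = _composites(responses)
    mc = df["ehl_high"] - df["ehl_high"].mean()

    x1 = sm.add_constant(df[["PEOU"]])
    m1 = sm.OLS(df["PU"], x1).fit()

    x2 = pd.DataFrame({
        "PU": df["PU"], "PEOU": df["PEOU"],
        "eHLxPU": mc * df["PU"], "eHLxPEOU": mc * df["PEOU"],
    })
    m2 = sm.OLS(df["BI"], sm.add_constant(x2)).fit()

    betas = {
        "PEOU->PU": float(m1.params["PEOU"]),
        "PU->BI": float(m2.params["PU"]),
        "PEOU->BI": float(m2.params["PEOU"]),
        "eHLxPU->BI": float(m2.params["eHLxPU"]),
        "eHLxPEOU->BI": float(m2.params["eHLxPEOU"]),
    }
    tvals = {
        "PEOU->PU": float(m1.tvalues["PEOU"]),
        "PU->BI": float(m2.tvalues["PU"]),
        "PEOU->BI": float(m2.tvalues["PEOU"]),
        "eHLxPU->BI": float(m2.tvalues["eHLxPU"]),
        "eHLxPEOU->BI": float(m2.tvalues["eHLxPEOU"]),
    }
    return PathResults(betas=betas, t_values=tvals, composites=df)


def moderation_hierarchy(responses: Sequence[SurveyResponse]) -> ModerationResults:
    """Hierarchical regression: step 1 main effects, step 2 adds the eHL
    interactions; reports betas and ΔR² (>= 0 by nesting)."""
    if len(responses) < 30:
        raise ValidationError("need at least 30 respondents")
    df = _composites(responses)
    mc = df["ehl_high"] - df["ehl_high"].mean()
    step1 = pd.DataFrame({"PU": df["PU"], "PEOU": df["PEOU"], "eHL": mc})
    m1 = sm.OLS(df["BI"], sm.add_constant(step1)).fit()
    step2 = step1.assign(eHLxPU=mc * df["PU"], eHLxPEOU=mc * df["PEOU"])
    m2 = sm.OLS(df["BI"], sm.add_constant(step2)).fit()
    return ModerationResults(
        step1_betas={k: float(v) for k, v in m1.params.items() if k != "const"},
        step2_betas={k: float(v) for k, v in m2.params.items() if k != "const"},
        r2_step1=float(m1.rsquared), r2_step2=float(m2.rsquared),
        delta_r2=float(m2.rsquared - m1.rsquared),
    )


def _check_separation(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> None:
    if y.min() == y.max():
        raise SeparationError("(outcome constant)")
    for j, name in enumerate(names):
        x = X[:, j]
        if x.min() == x.max():
            continue
        if x[y == 1].min() > x[y == 0].max() or \
           x[y == 1].max() < x[y == 0].min():
            raise SeparationError(name)


def logistic_irls(
    X: np.ndarray, y: np.ndarray, names: Sequence[str],
    tol: float = 1e-8, max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Maximum-likelihood logistic fit by iteratively reweighted least
    squares.  Returns (coef, standard errors, log-likelihood trace)."""
    _check_separation(X, y, names)
    n, p = X.shape
    beta = np.zeros(p)
    trace: list[float] = []
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        trace.append(float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu))))
        w = mu * (1 - mu)
        if w.min() < 1e-12:
            raise SeparationError("(diverging fit — quasi-separation)")
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    trace.append(float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu))))
    w = mu * (1 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, np.sqrt(np.diag(cov)), trace


def logit_effectiveness(responses: Sequence[SurveyResponse]) -> LogitResults:
    """Logistic regression of the binary effectiveness outcome on the
    demographic indicator set (age 60+, college education, high eHL,
    official-source trust)."""
    y = np.array([r.effectiveness for r in responses], dtype=float)
    X = np.column_stack([
        np.ones(len(responses)),
        [1.0 if r.age_band == "60+" else 0.0 for r in responses],
        [1.0 if r.education in ("college", "postgraduate") else 0.0
         for r in responses],
        [1.0 if r.ehl_group == "high" else 0.0 for r in responses],
        [float(r.official_source_trust) for r in responses],
    ])
    names = ("const",) + LOGIT_VARS
    beta, se, trace = logistic_irls(X, y, names)
    zvals = beta / se
    pvals = 2 * norm.sf(np.abs(zvals))
    return LogitResults(
        coef=dict(zip(names, beta.tolist())),
        odds_ratio={k: math.exp(v) for k, v in zip(names, beta)},
        se=dict(zip(names, se.tolist())),
        z=dict(zip(names, zvals.tolist())),
        p=dict(zip(names, pvals.tolist())),
        loglik_trace=trace,
    )


def format_preference_chi2(responses: Sequence[SurveyResponse]) -> Chi2Result:
    """Pearson chi-square on the age-band × preferred-format table."""
    bands = sorted({r.age_band for r in responses})
    fmts = sorted({r.preferred_format for r in responses})
    table = np.zeros((len(bands), len(fmts)))
    bi = {b: i for i, b in enumerate(bands)}
    fi = {f: i for i, f in enumerate(fmts)}
    for r in responses:
        table[bi[r.age_band], fi[r.preferred_format]] += 1
    return pearson_chi2(table)
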
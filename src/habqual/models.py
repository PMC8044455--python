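"""Environmental response models for gridded and tree-centric variables.

Count-like responses (per-tree seed production in latas, per-cell tree
density, per-cell seed production in lata multiples) are fitted as
quasi-Poisson log-linear models: the mean is Poisson-log-linear and the
variance is phi times the mean, with the dispersion phi estimated as
Pearson chi^2 / residual df. Continuous responses (per-tree and per-cell
AGB, the aggregation index) use Gaussian identity-link models.

Each environmental variable is fitted univariately (the published
response tables report per-variable slopes despite collinearity).
Within-concession correlation is handled by concession-clustered
sandwich standard errors; the quasi-scaled SE (raw SE x sqrt(phi)) is
reported alongside. Fitted slopes discretize into arrow codes via
:func:`habqual.arrows.arrow_from_pvalue`.

Variable importance uses an explicit permutation loop around a bagged
tree ensemble: the importance of a covariate is the mean increase in
held-out loss (MSE, or Poisson deviance for counts) when that column is
permuted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist
from scipy.stats import norm
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from .arrows import ArrowCode, arrow_from_pvalue

__all__ = [
    "FitResult",
    "fit_response",
    "fit_all",
    "estimate_dispersion",
    "round_half_up",
    "permutation_importance",
    "residual_correlogram",
    "FAMILY_BY_RESPONSE",
]

#: family used for each canonical response variable
FAMILY_BY_RESPONSE = {
    "sp_t": "quasipoisson",
    "density": "quasipoisson",
    "sp_a": "quasipoisson",
    "agb_t": "gaussian",
    "aggregation": "gaussian",
    "agb_a": "gaussian",
}


@dataclass(frozen=True)
class FitResult:
    """Univariate fit of one covariate against one response.

    ``se`` is the inference SE (cluster-robust when groups were supplied,
    else the quasi-scaled SE); ``se_quasi`` always equals
    ``se_raw * sqrt(phi)``.
    """

    covariate: str
    response: str
    family: str
    coef: float
    se_raw: float
    se_quasi: float
    se: float
    p_value: float
    phi: float
    n_obs: int
    n_groups: int

    @property
    def sign(self) -> int:
        return 0 if self.coef == 0 else (1 if self.coef > 0 else -1)

    @property
    def arrow(self) -> ArrowCode:
        return arrow_from_pvalue(self.sign, self.p_value)


def round_half_up(x):
    """Round to integer with .5 going up (count responses given in
    continuous units, e.g. cell seed mass divided into lata multiples)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def estimate_dispersion(glm_results) -> float:
    """Dispersion phi = Pearson chi^2 / residual df. For a Gaussian fit
    this is the residual variance estimate."""
    return float(glm_results.pearson_chi2 / glm_results.df_resid)


def fit_response(
    table: pd.DataFrame,
    response: str,
    covariate: str,
    family: str | None = None,
    groups: str | None = "concession_id",
) -> FitResult | None:
    """Fit one response against one covariate (with intercept).

    ``family`` defaults from :data:`FAMILY_BY_RESPONSE`. ``groups`` names
    the clustering column (set ``None`` for independent errors). Rows
    with a missing response or covariate are dropped. Returns ``None``
    with a warning for a zero-variance covariate.
    """
    family = family or FAMILY_BY_RESPONSE.get(response, "gaussian")
    cols = [response, covariate] + ([groups] if groups else [])
    data = table[cols].dropna(subset=[response, covariate])
    y = data[response].to_numpy(dtype=float)
    x = data[covariate].to_numpy(dtype=float)
    if len(data) < 3 or np.std(x) == 0:
        warnings.warn(f"covariate {covariate!r}: zero variance or too few rows")
        return None

    if family == "quasipoisson" and not np.allclose(y, np.round(y)):
        warnings.warn(
            f"response {response!r}: non-integer counts rounded half-up for "
            "the quasi-Poisson fit"
        )
        y = round_half_up(y)

    X = sm.add_constant(x)
    fam = sm.families.Poisson() if family == "quasipoisson" else sm.families.Gaussian()
    model = sm.GLM(y, X, family=fam)
    res = model.fit()
    phi = estimate_dispersion(res)
    coef = float(res.params[1])
    se_raw = float(res.bse[1])
    se_quasi = se_raw * np.sqrt(phi)

    n_groups = 0
    if groups:
        g = data[groups].to_numpy()
        n_groups = len(np.unique(g))
        if n_groups >= 2:
            res_c = model.fit(cov_type="cluster", cov_kwds={"groups": g})
            se = float(res_c.bse[1])
        else:
            se = se_quasi
    else:
        se = se_quasi
    p = 2.0 * norm.sf(abs(coef) / se) if se > 0 else float("nan")
    return FitResult(
        covariate, response, family, coef, se_raw, se_quasi, se, float(p),
        phi, int(len(data)), int(n_groups),
    )


def fit_all(
    table: pd.DataFrame,
    response: str,
    covariates: list[str],
    family: str | None = None,
    groups: str | None = "concession_id",
) -> pd.DataFrame:
    """Univariate fits of every covariate; one row per successful fit,
    with the arrow discretization attached."""
    rows = []
    for cov in covariates:
        fr = fit_response(table, response, cov, family=family, groups=groups)
        if fr is None:
            continue
        rows.append(
            dict(
                covariate=fr.covariate, response=fr.response, family=fr.family,
                coef=fr.coef, se_raw=fr.se_raw, se_quasi=fr.se_quasi, se=fr.se,
                p_value=fr.p_value, phi=fr.phi, n_obs=fr.n_obs,
                n_groups=fr.n_groups, arrow=fr.arrow.symbol,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation variable importance

def _poisson_deviance(y, mu):
    mu = np.maximum(mu, 1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.mean(term - (y - mu)))


def permutation_importance(
    X: pd.DataFrame,
    y,
    task: str = "regression",
    n_repeats: int = 10,
    seed: int = 0,
    test_size: float = 0.25,
    learner=None,
) -> pd.DataFrame:
    """Held-out permutation importance around a bagged tree ensemble.

    The learner (default: a random-forest regressor, insensitive to
    covariate collinearity) is fitted on a train split; the importance of
    covariate j is the mean over ``n_repeats`` of (held-out loss with
    column j permuted) - (baseline held-out loss). Loss is MSE for
    ``task="regression"`` and mean Poisson deviance for ``task="counts"``.
    Deterministic given ``seed``; output sorted by descending importance.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    if learner is None:
        learner = RandomForestRegressor(
            n_estimators=200, random_state=seed, n_jobs=1, min_samples_leaf=5
        )
    Xtr, Xte, ytr, yte = train_test_split(
        X.to_numpy(dtype=float), y, test_size=test_size, random_state=seed
    )
    learner.fit(Xtr, ytr)

    def loss(Xm):
        pred = learner.predict(Xm)
        if task == "counts":
            return _poisson_deviance(yte, pred)
        return float(np.mean((yte - pred) ** 2))

    base = loss(Xte)
    rows = []
    for j, name in enumerate(X.columns):
        deltas = []
        for _ in range(n_repeats):
            Xp = Xte.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas.append(loss(Xp) - base)
        rows.append((name, float(np.mean(deltas)), float(np.std(deltas))))
    out = pd.DataFrame(rows, columns=["covariate", "importance", "importance_sd"])
    out = out.sort_values("importance", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# residual spatial autocorrelation

def residual_correlogram(
    residuals,
    coords,
    bin_edges,
    n_perm: int = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """Distance-binned Moran's I correlogram of model residuals.

    ``coords`` are (n, 2) positions in the same units as ``bin_edges``.
    For each bin, binary neighbour weights select pairs whose separation
    falls in [lo, hi); Moran's I is reported with its null expectation
    -1/(n-1) and a one-sided permutation p-value for positive
    autocorrelation (>= 199 permutations). Empty bins yield NaN.
    """
    z = np.asarray(residuals, dtype=float)
    z = z - z.mean()
    n = len(z)
    denom = float(np.sum(z**2))
    d = pdist(np.asarray(coords, dtype=float))
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(z) for _ in range(n_perm)]

    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        mask = (d >= lo) & (d < hi)
        npairs = int(mask.sum())
        if npairs == 0:
            rows.append((lo, hi, np.nan, -1.0 / (n - 1), np.nan, 0))
            continue
        ii, jj = iu[0][mask], iu[1][mask]

        def moran(v):
            cross = float(np.sum(v[ii] * v[jj]))
            return (n / npairs) * cross / denom_v(v)

        def denom_v(v):
            return float(np.sum((v - v.mean()) ** 2))

        i_obs = moran(z)
        i_perm = np.array([moran(p) for p in perms])
        p_pos = (1.0 + np.sum(i_perm >= i_obs)) / (n_perm + 1.0)
        rows.append((lo, hi, i_obs, -1.0 / (n - 1), p_pos, npairs))
    return pd.DataFrame(
        rows, columns=["bin_lo", "bin_hi", "moran_i", "expected", "p_pos", "n_pairs"]
    )
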
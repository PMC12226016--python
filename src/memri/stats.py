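"""Mixed-effects and many-to-one inference for membrane-potential studies.

The in vitro analysis regresses each MR parameter on the measured
membrane-potential change dVm with a per-batch random intercept (REML),
reporting the intercept a, the fractional slope b/a matching the
a (1 + s dVm) parameterization, and the Wald p-value of the slope.  A
group-specific slope deviation tests whether potassium- and
barium-induced depolarization act differently, and Dunnett's test
compares every condition to the shared control with familywise error
control.  The in vivo analysis fits dT2 against epoch, arm and their
interaction with a per-rat random intercept and reports the per-epoch
modulation-minus-control contrast.

Mixed models are fitted with REML (statsmodels MixedLM); Wald tests use
the large-sample normal reference.  When the residual variation is
numerically zero (noise-free synthetic data) the fit degenerates to
ordinary least squares, which is then exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DomainError
from .synthetic import RESPONSES, InVivoSeries, StudyDataset

__all__ = [
    "FractionalSlopeFit", "DunnettResult",
    "fit_fractional_slope", "test_group_interaction",
    "dunnett_vs_control", "fit_invivo_interaction",
    "dunnett_pvalue",
]


@dataclass(frozen=True)
class FractionalSlopeFit:
    """Random-intercept regression of a response on dVm, reported in the
    fractional form response = intercept * (1 + fractional_slope * dVm)."""

    response: str
    intercept: float
    fractional_slope: float    # per mV; raw slope / intercept
    raw_slope: float
    slope_p: float
    random_intercept_sd: float
    residual_sd: float
    n_obs: int
    n_groups: int


@dataclass
class DunnettResult:
    """Many-to-one comparisons against the control condition.

    table columns: label, diff (response units), t, p_adj, tier
    ('' / '*' / '**' / '***' at 0.05 / 0.01 / 0.001).
    """

    response: str
    control_label: str
    table: pd.DataFrame


def _is_deterministic(y, X):
    """True when an OLS fit reproduces y to numerical precision."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    scale = max(float(np.var(y)), 1e-300)
    return float(np.var(resid)) < 1e-16 * scale, beta


def _mixed_slope(df, value_col):
    """Random-intercept fit of value ~ dVm; returns the pieces of a
    FractionalSlopeFit.  Falls back to exact OLS when residuals vanish."""
    y = df[value_col].to_numpy(float)
    X = np.column_stack([np.ones(len(df)), df["delta_vm"].to_numpy(float)])
    deterministic, beta = _is_deterministic(y, X)
    if deterministic:
        return beta[0], beta[1], 0.0, 0.0, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=df["batch_id"].to_numpy())
        res = model.fit(reml=True)
    fe = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    if not np.all(np.isfinite(se)):
        raise DomainError("mixed model is unidentifiable on these data")
    p_slope = float(2.0 * sps.norm.sf(abs(fe[1] / se[1])))
    re_var = float(np.asarray(res.cov_re)[0, 0])
    return (float(fe[0]), float(fe[1]), p_slope,
            float(np.sqrt(max(re_var, 0.0))),
            float(np.sqrt(res.scale)))


def fit_fractional_slope(dataset: StudyDataset,
                         response: str) -> FractionalSlopeFit:
    """REML random-intercept regression of an MR parameter on dVm."""
    if response not in RESPONSES:
        raise DomainError(f"response must be one of {RESPONSES}")
    df = dataset.params
    if df["batch_id"].nunique() < 2:
        raise DomainError("need at least 2 batches")
    if df["delta_vm"].nunique() < 2:
        raise DomainError("need at least 2 distinct delta_vm values")
    a, b, p, re_sd, resid_sd = _mixed_slope(df, response)
    if a <= 0:
        raise DomainError("fitted intercept is nonpositive; fractional "
                          "parameterization undefined")
    return FractionalSlopeFit(
        response=response, intercept=a, fractional_slope=b / a,
        raw_slope=b, slope_p=p, random_intercept_sd=re_sd,
        residual_sd=resid_sd, n_obs=len(df),
        n_groups=df["batch_id"].nunique())


def test_group_interaction(dataset: StudyDataset,
                           responses=RESPONSES) -> dict[str, float]:
    """Wald p-value of a barium-specific slope deviation per response.

    Model: response ~ dVm + dVm : 1[barium], random intercept per batch.
    The control condition sits on the potassium branch (indicator 0).
    """
    df = dataset.params.copy()
    groups = set(df["group"])
    if "barium" not in groups or "potassium" not in groups:
        raise DomainError("interaction test needs both potassium and "
                          "barium conditions")
    df["is_ba"] = (df["group"] == "barium").astype(float)
    out = {}
    for resp in responses:
        y = df[resp].to_numpy(float)
        X = np.column_stack([np.ones(len(df)),
                             df["delta_vm"].to_numpy(float),
                             df["delta_vm"].to_numpy(float)
                             * df["is_ba"].to_numpy(float)])
        deterministic, _ = _is_deterministic(y, X)
        if deterministic:
            out[resp] = 1.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=df["batch_id"].to_numpy()
                             ).fit(reml=True)
        fe = np.asarray(res.fe_params, dtype=float)
        se = np.asarray(res.bse_fe, dtype=float)
        out[resp] = float(2.0 * sps.norm.sf(abs(fe[2] / se[2])))
    return out


def dunnett_pvalue(t_obs: float, lambdas, df: int) -> float:
    """Two-sided adjusted p-value P(max_i |T_i| >= |t_obs|) for the
    many-to-one contrast family.

    The contrasts share the control-group mean, so their correlation has
    the one-factor form rho_ij = lambda_i lambda_j with
    lambda_i = sqrt(n_i / (n_i + n_0)); the familywise tail probability
    reduces to a double integral over the shared factor and the pooled
    scale, evaluated here by Gauss-Hermite x Gauss-Legendre quadrature.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    t = abs(float(t_obs))
    if t == 0.0:
        return 1.0
    # z nodes: Gauss-Hermite for the N(0,1) common factor
    zh, wh = np.polynomial.hermite_e.hermegauss(96)
    wh = wh / np.sqrt(2.0 * np.pi)
    # w nodes: Gauss-Legendre in probability space of W = chi_df/sqrt(df)
    u, wu = np.polynomial.legendre.leggauss(64)
    u = 0.5 * (u + 1.0)
    wu = 0.5 * wu
    w = sps.chi(df).ppf(u) / np.sqrt(df)

    s = np.sqrt(1.0 - lambdas ** 2)
    # product over comparisons of P(|D_i| <= t W | Z = z)
    zz = zh[:, None, None]
    ww = w[None, :, None]
    lam = lambdas[None, None, :]
    ss = s[None, None, :]
    upper = (t * ww - lam * zz) / ss
    lower = (-t * ww - lam * zz) / ss
    inner = np.prod(sps.norm.cdf(upper) - sps.norm.cdf(lower), axis=2)
    prob_max_le = float(wh @ inner @ wu)
    return float(np.clip(1.0 - prob_max_le, 0.0, 1.0))


def _tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def dunnett_vs_control(dataset: StudyDataset,
                       response: str) -> DunnettResult:
    """Dunnett many-to-one comparison of every condition to the control."""
    if response not in RESPONSES:
        raise DomainError(f"response must be one of {RESPONSES}")
    df = dataset.params
    control = df[df["group"] == "control"]
    if control.empty:
        raise DomainError("no control condition in dataset")
    control_label = control["label"].iloc[0]
    others = [lab for lab in df["label"].unique() if lab != control_label]
    if len(others) < 1:
        raise DomainError("need at least one non-control condition")

    by = df.groupby("label")[response]
    means, counts = by.mean(), by.size()
    sse = float(((df[response] - df["label"].map(means)) ** 2).sum())
    dof = len(df) - df["label"].nunique()
    if dof <= 0:
        raise DomainError("no residual degrees of freedom")
    s2 = sse / dof
    n0 = int(counts[control_label])
    lambdas = np.array([np.sqrt(counts[lab] / (counts[lab] + n0))
                        for lab in others])
    rows = []
    for j, lab in enumerate(others):
        diff = float(means[lab] - means[control_label])
        se = np.sqrt(s2 * (1.0 / counts[lab] + 1.0 / n0))
        tstat = diff / se if se > 0 else 0.0
        p_adj = dunnett_pvalue(tstat, lambdas, dof)
        rows.append({"label": lab, "diff": diff, "t": float(tstat),
                     "p_adj": p_adj, "tier": _tier(p_adj)})
    return DunnettResult(response=response, control_label=control_label,
                         table=pd.DataFrame(rows))


def fit_invivo_interaction(series: InVivoSeries) -> pd.DataFrame:
    """Per-epoch modulation-minus-control dT2 contrasts.

    Mixed model: delta_t2 ~ C(epoch) * arm with a per-rat random
    intercept; the contrast at epoch e is beta_arm + beta_arm:epoch_e
    (the arm difference at that epoch).  Returns a frame with columns
    epoch, contrast_ms, se, p for every epoch past the first where both
    arms are observed.
    """
    df = series.data
    arms = set(df["arm"])
    if arms != {"modulation", "control"}:
        raise DomainError("both a modulation and a control arm are "
                          "required")
    if df["epoch"].nunique() < 2:
        raise DomainError("need at least 2 epochs")
    df = df.copy()
    df["is_mod"] = (df["arm"] == "modulation").astype(float)
    epochs = sorted(df["epoch"].unique())
    cols = [np.ones(len(df)), df["is_mod"].to_numpy()]
    names = ["const", "arm"]
    for e in epochs[1:]:
        ind = (df["epoch"] == e).astype(float).to_numpy()
        cols += [ind, ind * df["is_mod"].to_numpy()]
        names += [f"epoch{e}", f"arm:epoch{e}"]
    X = np.column_stack(cols)
    y = df["delta_t2_ms"].to_numpy(float)

    deterministic, beta = _is_deterministic(y, X)
    if deterministic:
        params, cov = beta, np.zeros((len(beta), len(beta)))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=df["rat_id"].to_numpy()
                             ).fit(reml=True)
        params = np.asarray(res.fe_params, dtype=float)
        cov = np.asarray(res.cov_params())[:len(names), :len(names)]
    rows = []
    for e in epochs[1:]:
        both = df[df["epoch"] == e]["arm"].nunique() == 2
        if not both:
            continue
        c = np.zeros(len(names))
        c[names.index("arm")] = 1.0
        c[names.index(f"arm:epoch{e}")] = 1.0
        est = float(c @ params)
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        p = float(2.0 * sps.norm.sf(abs(est) / se)) if se > 0 else 0.0
        rows.append({"epoch": e, "contrast_ms": est, "se": se, "p": p})
    return pd.DataFrame(rows)
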
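"""Two-equation longitudinal mediation model with design-based study weights.

Equation A regresses the post-baseline mediator on intervention dummies, baseline
mediator and outcome, and demographic covariates; equation B regresses the
post-baseline outcome on the same terms plus the post-baseline mediator. The model is
recursive with uncorrelated errors, so equation-wise weighted least squares is the
full-model estimator; inference comes from the stratified bootstrap, not from the WLS
standard errors. The indirect effect of arm k is a_k * b_med (intervention→mediator
path times mediator→outcome path), the total effect is the direct effect plus the
indirect effect, and effects are additionally reported standardized with respect to the
outcome (divided by the weighted SD of the equation's dependent variable).

Participants are weighted by the inverse square root of their study's sample size so
that very large trials do not dominate the pooled estimate; the weights are a
design-based device for clustered data, and a cluster-robust sandwich standard error is
provided purely as a diagnostic cross-check of the bootstrap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .data_model import Arm, IPDDataset, ModelSpec, TX_TERMS

__all__ = [
    "WeightVector",
    "EquationFit",
    "MediationFit",
    "EffectEstimates",
    "TERM_COLUMNS",
    "compute_weights",
    "design_matrix",
    "fit_equation",
    "fit_mediation",
    "compute_effects",
    "standardize_effects",
    "cluster_robust_se",
]

#: regression term -> dataset column (treatment dummies and intercept are generated)
TERM_COLUMNS = {
    "BL_ALCPROB": "bl_outcome",
    "BL_PBS": "bl_mediator",
    "MALE": "male",
    "FIRSTYR": "firstyr",
    "NONWHITE": "nonwhite",
    "POST_PBS": "post_mediator",
}

DEPENDENT = {"A": "post_mediator", "B": "post_outcome"}

_RANK_RTOL = 1e-10  # smallest/largest singular value below this -> rank deficient


@dataclass(frozen=True)
class WeightVector:
    """Per-participant analysis weights.

    Under the ``inv_sqrt_n`` scheme every participant in study s receives
    w_s ∝ 1/sqrt(n_s), rescaled so the weights sum to the number of participants;
    ``uniform`` gives everyone weight 1. WLS point estimates are invariant to the
    overall scale, so normalization only affects reported diagnostics.
    """

    w: np.ndarray
    scheme: Literal["inv_sqrt_n", "uniform"]
    normalized: bool = True

    def __post_init__(self) -> None:
        if np.any(self.w <= 0):
            raise ValueError("weights must be strictly positive")


def compute_weights(ds: IPDDataset, scheme: Literal["inv_sqrt_n", "uniform"] = "inv_sqrt_n") -> WeightVector:
    """Design-based weights for clustering by study.

    ``inv_sqrt_n``: w_i = 1/sqrt(n_s) for participant i in study s, normalized to
    sum to N; ``uniform``: all ones.
    """
    n = ds.n
    if scheme == "uniform":
        return WeightVector(np.ones(n), "uniform")
    sizes = ds.df["study"].map(ds.study_sizes).to_numpy(dtype=float)
    raw = 1.0 / np.sqrt(sizes)
    return WeightVector(raw * (n / raw.sum()), "inv_sqrt_n")


def design_matrix(ds: IPDDataset, terms: tuple[str, ...]) -> np.ndarray:
    """Assemble the n x p design matrix for the given ordered term tuple."""
    df = ds.df
    n = len(df)
    cols = []
    arm_vals = np.asarray([a.value for a in df["arm"]])
    for t in terms:
        if t == "intercept":
            cols.append(np.ones(n))
        elif t in TX_TERMS:
            cols.append((arm_vals == t.removeprefix("TX_")).astype(float))
        else:
            cols.append(df[TERM_COLUMNS[t]].to_numpy(dtype=float))
    return np.column_stack(cols)


@dataclass
class EquationFit:
    """One fitted regression equation of the mediation model."""

    equation: Literal["A", "B"]
    coefficients: dict[str, float]
    residual_variance: float
    sd_dependent: float
    r_squared: float
    n_used: int


@dataclass
class MediationFit:
    """The fitted pair of mediation equations (same rows, same weights)."""

    eqA: EquationFit
    eqB: EquationFit
    spec: ModelSpec
    weights: WeightVector


@dataclass
class EffectEstimates:
    """Per-arm mediation effects, raw and standardized with respect to the outcome.

    For each arm k evaluated in the model: ``a[k]`` is the intervention→mediator
    path, ``direct[k]`` the intervention→outcome path adjusting for the mediator,
    ``indirect[k] = a[k] * b_med`` and ``total[k] = direct[k] + indirect[k]``.
    ``b_med`` is the mediator→outcome path per unit of the mediator.

    Standardized fields divide outcome-equation quantities by the weighted SD of
    the post-baseline outcome (``std_direct``, ``std_indirect``, ``std_total``,
    ``std_b_med_per_unit``) and mediator-equation quantities by the weighted SD of
    the post-baseline mediator (``std_a``); ``std_b_med_per_sd`` expresses the
    mediator→outcome path per SD of the mediator.
    """

    a: dict[Arm, float]
    direct: dict[Arm, float]
    indirect: dict[Arm, float]
    total: dict[Arm, float]
    b_med: float
    std_a: dict[Arm, float] = field(default_factory=dict)
    std_direct: dict[Arm, float] = field(default_factory=dict)
    std_indirect: dict[Arm, float] = field(default_factory=dict)
    std_total: dict[Arm, float] = field(default_factory=dict)
    std_b_med_per_unit: float = float("nan")
    std_b_med_per_sd: float = float("nan")

    @property
    def arms(self) -> tuple[Arm, ...]:
        return tuple(self.a)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, terms: tuple[str, ...]):
    """Weighted least squares with an explicit rank check.

    Returns (beta, weighted SSE, weighted SST, weighted SD of y).
    """
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    sv = np.linalg.svd(Xw, compute_uv=False)
    if sv[-1] < _RANK_RTOL * sv[0]:
        # identify terms involved in the near-null space for the error message
        _, _, vt = np.linalg.svd(Xw)
        bad = [terms[j] for j in np.nonzero(np.abs(vt[-1]) > 1e-6)[0]]
        raise np.linalg.LinAlgError(f"design matrix rank deficient; collinear terms: {bad}")
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = y - X @ beta
    sse = float(w @ resid**2)
    ybar = float(w @ y / w.sum())
    sst = float(w @ (y - ybar) ** 2)
    sd_y = float(np.sqrt(sst / w.sum()))
    return beta, sse, sst, sd_y


def fit_equation(
    ds: IPDDataset,
    spec: ModelSpec,
    equation: Literal["A", "B"],
    weights: WeightVector,
) -> EquationFit:
    """Fit one mediation equation by weighted least squares.

    Requires complete data on the used fields (call after imputation, or on
    complete data). Residual variance uses the n − p divisor; R² comes from
    weighted sums of squares around the weighted mean.

    Raises
    ------
    numpy.linalg.LinAlgError
        If the design matrix is rank deficient (names the collinear terms).
    ValueError
        If any used field has missing values.
    """
    terms = spec.eqA_terms if equation == "A" else spec.eqB_terms
    X = design_matrix(ds, terms)
    y = ds.df[DEPENDENT[equation]].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError(f"equation {equation}: missing values among used fields; impute first")
    w = weights.w
    beta, sse, sst, sd_y = _wls(X, y, w, terms)
    n, p = X.shape
    return EquationFit(
        equation=equation,
        coefficients={t: float(b) for t, b in zip(terms, beta)},
        residual_variance=sse / (n - p),
        sd_dependent=sd_y,
        r_squared=1.0 - sse / sst,
        n_used=n,
    )


def fit_mediation(ds: IPDDataset, spec: ModelSpec, weights: WeightVector) -> MediationFit:
    """Fit both mediation equations on the same rows with the same weights."""
    return MediationFit(
        eqA=fit_equation(ds, spec, "A", weights),
        eqB=fit_equation(ds, spec, "B", weights),
        spec=spec,
        weights=weights,
    )


def compute_effects(fit: MediationFit) -> EffectEstimates:
    """Indirect, direct, and total effects from the fitted coefficient pair.

    indirect_k = a_k * b_med (product of coefficients); total_k = direct_k +
    indirect_k. Only arms present in the model spec get entries.
    """
    b_med = fit.eqB.coefficients["POST_PBS"]
    a, direct, indirect, total = {}, {}, {}, {}
    for t in TX_TERMS:
        if t not in fit.spec.eqA_terms:
            continue
        arm = Arm[t.removeprefix("TX_")]
        a[arm] = fit.eqA.coefficients[t]
        direct[arm] = fit.eqB.coefficients[t]
        indirect[arm] = a[arm] * b_med
        total[arm] = direct[arm] + indirect[arm]
    return EffectEstimates(a=a, direct=direct, indirect=indirect, total=total, b_med=b_med)


def standardize_effects(fit: MediationFit, effects: EffectEstimates) -> EffectEstimates:
    """Fill the outcome-standardized effect fields in place (and return them).

    Mediator-equation quantities are divided by the weighted SD of the
    post-baseline mediator, outcome-equation quantities by the weighted SD of the
    post-baseline outcome. The standardized indirect effect is indirect / sd_B
    (equivalently (a/sd_A) x (b_med sd_A/sd_B)), so total = direct + indirect is
    preserved on the standardized scale.
    """
    sd_a, sd_b = fit.eqA.sd_dependent, fit.eqB.sd_dependent
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("cannot standardize: zero SD of a dependent variable")
    for arm in effects.arms:
        effects.std_a[arm] = effects.a[arm] / sd_a
        effects.std_direct[arm] = effects.direct[arm] / sd_b
        effects.std_indirect[arm] = effects.indirect[arm] / sd_b
        effects.std_total[arm] = effects.total[arm] / sd_b
    effects.std_b_med_per_unit = effects.b_med / sd_b
    effects.std_b_med_per_sd = effects.b_med * sd_a / sd_b
    return effects


def cluster_robust_se(fit: MediationFit, ds: IPDDataset) -> dict[str, dict[str, float]]:
    """Cluster-robust (sandwich) standard errors with clusters = studies.

    A diagnostic cross-check against the bootstrap intervals, not the primary
    inference. Returns ``{"A": {term: se}, "B": {term: se}}``.

    Raises
    ------
    ValueError
        With fewer than two studies (no between-cluster variation to estimate).
    """
    import statsmodels.api as sm

    studies = ds.df["study"]
    if studies.nunique() < 2:
        raise ValueError("cluster-robust SEs require at least two studies")
    out: dict[str, dict[str, float]] = {}
    for eq, terms in (("A", fit.spec.eqA_terms), ("B", fit.spec.eqB_terms)):
        X = design_matrix(ds, terms)
        y = ds.df[DEPENDENT[eq]].to_numpy(dtype=float)
        res = sm.WLS(y, X, weights=fit.weights.w).fit(
            cov_type="cluster", cov_kwds={"groups": studies.to_numpy()}
        )
        out[eq] = {t: float(se) for t, se in zip(terms, res.bse)}
    return out
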
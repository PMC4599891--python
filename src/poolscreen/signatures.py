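"""Expression signatures: zero-transformation, occurrence/fold filtering,
two-class signature creation and projection, and signature regression.

The signature pipeline turns a knockdown expression experiment into a
projector: expression is first zero-transformed (each gene expressed as
log2 change versus the mean of scramble-control samples), marker genes are
ranked by a two-class signal-to-noise ratio, the top markers' training
submatrix is factorized by SVD, and a ridge-penalized probit maps factor
scores to the probability that a profile resembles the knockdown (train1)
class. Projected probabilities of two signatures across a cohort can then
be compared by simple linear regression.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ZeroTransformedMatrix",
    "SignatureModel",
    "RegressionResult",
    "zero_transform",
    "fold_filter",
    "create_signature",
    "project_signature",
    "signature_regression",
]


@dataclass
class ZeroTransformedMatrix:
    """Genes × samples log2 matrix centered on control-sample means."""

    values: pd.DataFrame
    control_ids: list

    @property
    def genes(self):
        return self.values.index


def zero_transform(expr: pd.DataFrame, control_ids) -> ZeroTransformedMatrix:
    """Subtract each gene's mean over the control (scramble) samples.

    Input must already be on log2 scale; each row of the result is the
    log2 change of that gene relative to the average control level, so
    row means over the control columns are exactly zero.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("need at least one control sample")
    missing = [c for c in control_ids if c not in expr.columns]
    if missing:
        raise ValueError(f"control ids absent from matrix: {missing}")
    centered = expr.sub(expr[control_ids].mean(axis=1), axis=0)
    return ZeroTransformedMatrix(values=centered, control_ids=control_ids)


def fold_filter(
    zt: ZeroTransformedMatrix,
    fold: float = 1.7,
    min_arrays: int = 6,
    scale: str = "fold",
    strict: bool = False,
) -> pd.DataFrame:
    """Keep genes changed at least ``fold`` in at least ``min_arrays`` samples.

    ``scale="fold"`` (default) reads the threshold as a linear fold change,
    i.e. |log2 value| ≥ log2(fold); ``scale="log2"`` reads it directly in
    log2 units. The occurrence comparison is inclusive (≥) unless
    ``strict``.
    """
    if scale not in ("fold", "log2"):
        raise ValueError("scale must be 'fold' or 'log2'")
    if scale == "fold" and fold <= 1:
        raise ValueError("fold must be > 1 on the fold scale")
    if scale == "log2" and fold <= 0:
        raise ValueError("threshold must be > 0 on the log2 scale")
    if min_arrays < 1:
        raise ValueError("min_arrays must be >= 1")
    if min_arrays > zt.values.shape[1]:
        raise ValueError("min_arrays exceeds number of samples")
    thr = math.log2(fold) if scale == "fold" else fold
    absvals = zt.values.abs().to_numpy()
    counts = (absvals > thr).sum(axis=1) if strict else (absvals >= thr).sum(axis=1)
    return zt.values.loc[counts >= min_arrays]


# ---------------------------------------------------------------------------
# Signature creation / projection


@dataclass
class SignatureModel:
    """Trained two-class expression projector.

    Selected marker genes, their training means (centering statistics),
    the top-k left singular vectors of the centered training submatrix,
    and ridge-probit coefficients on the factor scores. ``project`` maps
    any profile over the marker genes to P(class = train1).
    """

    genes: list
    train_means: pd.Series
    basis: np.ndarray  # len(genes) × k
    coef: np.ndarray  # intercept + k slopes
    snr: pd.Series
    n_sig: int
    k_factors: int
    ridge: float
    train0_ids: list
    train1_ids: list
    sd_floor_hits: int = 0
    meta: dict = field(default_factory=dict)

    def project(self, test_matrix: pd.DataFrame, center: str = "train") -> pd.Series:
        return project_signature(self, test_matrix, center=center)

    def to_json(self, path) -> None:
        payload = {
            "genes": list(self.genes),
            "train_means": [float(x) for x in self.train_means],
            "basis": self.basis.tolist(),
            "coef": self.coef.tolist(),
            "snr": [float(x) for x in self.snr],
            "n_sig": self.n_sig,
            "k_factors": self.k_factors,
            "ridge": self.ridge,
            "train0_ids": list(self.train0_ids),
            "train1_ids": list(self.train1_ids),
            "sd_floor_hits": self.sd_floor_hits,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            genes=d["genes"],
            train_means=pd.Series(d["train_means"], index=d["genes"]),
            basis=np.asarray(d["basis"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            snr=pd.Series(d["snr"], index=d["genes"]),
            n_sig=d["n_sig"],
            k_factors=d["k_factors"],
            ridge=d["ridge"],
            train0_ids=d["train0_ids"],
            train1_ids=d["train1_ids"],
            sd_floor_hits=d["sd_floor_hits"],
        )


def _ridge_probit(F: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    """Penalized-ML probit of y∈{0,1} on factor scores F (n × k).

    Minimizes −loglik + (ridge/2)·||slopes||²; the intercept is not
    penalized. Small dimension (k+1), solved by BFGS with analytic
    gradient.
    """
    n, k = F.shape
    X = np.column_stack([np.ones(n), F])
    q = 2.0 * y - 1.0

    def negloglik(beta):
        z = q * (X @ beta)
        ll = special.log_ndtr(z).sum()
        pen = 0.5 * ridge * np.dot(beta[1:], beta[1:])
        return -ll + pen

    def grad(beta):
        z = q * (X @ beta)
        # d/dz log Phi(z) = phi(z)/Phi(z), computed in log space for stability
        w = np.exp(stats.norm.logpdf(z) - special.log_ndtr(z)) * q
        g = -(X.T @ w)
        g[1:] += ridge * beta[1:]
        return g

    res = optimize.minimize(negloglik, np.zeros(k + 1), jac=grad, method="BFGS")
    return res.x


def create_signature(
    zt: ZeroTransformedMatrix | pd.DataFrame,
    train0_ids,
    train1_ids,
    n_sig: int = 100,
    k_factors: int = 2,
    ridge: float = 1e-3,
) -> SignatureModel:
    """Train a two-class signature from zero-transformed expression.

    Genes are ranked by the absolute signal-to-noise ratio
    (mean1 − mean0) / (sd0 + sd1) between the train1 (knockdown) and
    train0 (control) samples; the top ``n_sig`` are retained. The selected
    training submatrix (centered on per-gene training means) is factorized
    by SVD; class membership is fitted on the top ``k_factors`` factor
    scores by ridge-penalized probit (the ridge keeps the fit finite on
    perfectly separable tiny training sets). Deterministic given inputs.
    """
    mat = zt.values if isinstance(zt, ZeroTransformedMatrix) else zt
    train0_ids, train1_ids = list(train0_ids), list(train1_ids)
    if len(train0_ids) < 2 or len(train1_ids) < 2:
        raise ValueError("need at least 2 samples per class")
    missing = [s for s in train0_ids + train1_ids if s not in mat.columns]
    if missing:
        raise ValueError(f"training samples absent from matrix: {missing}")
    n_train = len(train0_ids) + len(train1_ids)
    if k_factors > n_train - 1:
        raise ValueError("k_factors must be <= n_train - 1")

    x0 = mat[train0_ids].to_numpy(float)
    x1 = mat[train1_ids].to_numpy(float)
    m0, m1 = x0.mean(axis=1), x1.mean(axis=1)
    s0, s1 = x0.std(axis=1, ddof=1), x1.std(axis=1, ddof=1)
    denom = s0 + s1
    floor = 1e-6
    n_floored = int((denom < floor).sum())
    if n_floored:
        warnings.warn(f"{n_floored} gene(s) with near-zero within-class sd floored")
    snr = (m1 - m0) / np.maximum(denom, floor)
    snr = pd.Series(snr, index=mat.index)

    order = snr.abs().sort_values(ascending=False, kind="stable")
    selected = list(order.index[:n_sig])

    sub = mat.loc[selected, train0_ids + train1_ids]
    train_means = sub.mean(axis=1)
    centered = sub.sub(train_means, axis=0).to_numpy(float)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    k = min(k_factors, len(S))
    basis = U[:, :k]
    scores = (S[:k, None] * Vt[:k, :]).T  # n_train × k sample factor scores
    y = np.r_[np.zeros(len(train0_ids)), np.ones(len(train1_ids))]
    coef = _ridge_probit(scores, y, ridge)

    return SignatureModel(
        genes=selected,
        train_means=train_means,
        basis=basis,
        coef=coef,
        snr=snr.loc[selected],
        n_sig=n_sig,
        k_factors=k,
        ridge=ridge,
        train0_ids=train0_ids,
        train1_ids=train1_ids,
        sd_floor_hits=n_floored,
    )


def project_signature(
    model: SignatureModel, test_matrix: pd.DataFrame, center: str = "train"
) -> pd.Series:
    """Project profiles through a trained signature → P(train1 class).

    Test profiles are restricted to the signature genes, centered, mapped
    through the factor basis and the probit link. ``center="train"``
    (default) subtracts the training gene means and assumes the test data
    are on the training scale (zero-transformed against the same
    controls). ``center="test"`` subtracts each gene's mean over the test
    samples themselves — the appropriate choice for an external cohort
    that has no scramble-control samples and therefore cannot be
    zero-transformed onto the training scale. Genes outside the signature
    never influence the result.
    """
    if center not in ("train", "test"):
        raise ValueError("center must be 'train' or 'test'")
    missing = [g for g in model.genes if g not in test_matrix.index]
    if missing:
        raise ValueError(f"test matrix lacks signature genes: {missing[:10]}")
    x = test_matrix.loc[model.genes].to_numpy(float)
    if center == "train":
        centered = x - model.train_means.to_numpy(float)[:, None]
    else:
        centered = x - x.mean(axis=1, keepdims=True)
    scores = model.basis.T @ centered  # k × n_samples
    eta = model.coef[0] + model.coef[1:] @ scores
    prob = special.ndtr(eta)
    return pd.Series(prob, index=test_matrix.columns, name="probability")


# ---------------------------------------------------------------------------
# Signature regression


@dataclass
class RegressionResult:
    """OLS of one signature's probabilities on another's."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slope": None if np.isnan(self.slope) else float(self.slope),
                    "intercept": None if np.isnan(self.intercept) else float(self.intercept),
                    "r_squared": None if np.isnan(self.r_squared) else float(self.r_squared),
                    "p_value": None if np.isnan(self.p_value) else float(self.p_value),
                    "n": self.n,
                },
                fh,
                indent=2,
            )


def signature_regression(prob_a: pd.Series, prob_b: pd.Series) -> RegressionResult:
    """Simple linear regression of ``prob_b`` on ``prob_a`` over shared samples.

    Returns the slope with its t-test p-value; zero variance in the
    predictor leaves the slope undefined (NaN).
    """
    common = prob_a.index.intersection(prob_b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    x = prob_a.loc[common].to_numpy(float)
    y = prob_b.loc[common].to_numpy(float)
    if np.var(x) == 0:
        return RegressionResult(
            slope=float("nan"),
            intercept=float("nan"),
            r_squared=float("nan"),
            p_value=float("nan"),
            n=len(common),
        )
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(common),
    )
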
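"""Polynomial regression of quantum use efficiency on waveband fractions.

The response is the calibrated quantum use efficiency c_ε (optionally
normalized by RI, the treatment's integrated irradiance divided by that of
the pure-red 180 µmol m⁻² s⁻¹ reference, 32.8 W m⁻²).  Features are built
from the four waveband fraction ratios F_B, F_G, F_R, F_FR, which must sum
to one:

    c_ε = a₀ + Σᵢ [aᵢFᵢ + bᵢFᵢ² + cᵢFᵢ³ + dᵢFᵢ⁴] + Σ_{i<j} e_ij FᵢFⱼ

Term families (powers 1-4 plus the six pairwise interactions, 22 terms in
all) are selected through a :class:`TermSet`; the studied model sizes are 4,
8, 12, 14 and 16 coefficients.  Fitting is ordinary least squares with
optional ridge or lasso penalties; models are scored by R², MAPE and the
Gaussian-likelihood information criteria AIC/BIC on a train/test split.

Feature ordering is power-major: the four first-order fractions in
blue/green/red/far-red order, then the squares, cubes and quartics in the
same band order, then the interactions BG, BR, BFR, GR, GFR, RFR.  No
standardization is applied, so fitted weights are directly comparable to the
packaged published coefficient set (see :func:`published_model`).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

from .errors import ConstraintError, OutOfDomainWarning, SingularDesignError
from .spectra import BAND_ORDER

__all__ = [
    "TermSet",
    "ModelMetrics",
    "RegressionModel",
    "PolynomialEfficiencyModel",
    "build_features",
    "fit",
    "r2_score",
    "mape",
    "information_criteria",
    "select_model",
    "structural_rank",
    "published_model",
    "CANDIDATE_TERM_SETS",
    "REFERENCE_IRRADIANCE_W_M2",
]

#: Integrated irradiance of the pure-red reference treatment (W m⁻²),
#: used to form RI = I / I_ref.
REFERENCE_IRRADIANCE_W_M2 = 32.8

#: Interaction pair ordering (indices into the blue/green/red/far-red vector).
INTERACTION_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

_CLOSURE_TOL = 1e-6


@dataclass(frozen=True)
class TermSet:
    """Which polynomial term families enter the design matrix.

    ``powers`` is a subset of (1, 2, 3, 4); ``interactions`` adds the six
    pairwise products FᵢFⱼ.  The intercept is implicit and not counted in
    ``n_features``.
    """

    powers: tuple[int, ...] = (1,)
    interactions: bool = False

    def __post_init__(self):
        powers = tuple(sorted(set(self.powers)))
        if not powers and not self.interactions:
            raise ValueError("term set selects no features")
        if any(p not in (1, 2, 3, 4) for p in powers):
            raise ValueError("powers must be drawn from 1..4")
        object.__setattr__(self, "powers", powers)

    @property
    def n_features(self) -> int:
        return 4 * len(self.powers) + (6 if self.interactions else 0)

    @property
    def tag(self) -> str:
        names = {1: "fi", 2: "se", 3: "th", 4: "fo"}
        parts = [names[p] for p in self.powers]
        if self.interactions:
            parts.append("nl")
        return "+".join(parts)

    def feature_names(self) -> list[str]:
        short = ("B", "G", "R", "FR")
        names = [f"F_{b}^{p}" if p > 1 else f"F_{b}" for p in self.powers for b in short]
        if self.interactions:
            names += [f"F_{short[i]}*F_{short[j]}" for i, j in INTERACTION_PAIRS]
        return names


#: The model sizes studied: 4, 8, 12, 14 and 16 weight coefficients.
CANDIDATE_TERM_SETS = (
    TermSet((1,)),
    TermSet((1, 2)),
    TermSet((1, 2, 3)),
    TermSet((1, 2), interactions=True),
    TermSet((1, 2, 3, 4)),
)


def _validate_fractions(fractions) -> np.ndarray:
    vec = np.asarray(fractions, dtype=float)
    if vec.shape != (4,):
        raise ConstraintError(f"expected a 4-vector in {BAND_ORDER} order")
    if np.any(vec < 0) or np.any(vec > 1):
        raise ConstraintError("fractions must lie in [0, 1]")
    if abs(vec.sum() - 1.0) > _CLOSURE_TOL:
        raise ConstraintError(
            f"fractions must sum to 1 (got {vec.sum():.8f}); closure constraint violated"
        )
    return vec


def build_features(fractions, terms: TermSet) -> np.ndarray:
    """Feature vector for one fraction 4-vector under a term set.

    The input must satisfy the closure constraint (sum to one, each entry in
    [0, 1]); ordering is power-major as described in the module docstring.
    """
    vec = _validate_fractions(fractions)
    blocks = [vec**p for p in terms.powers]
    if terms.interactions:
        blocks.append(np.array([vec[i] * vec[j] for i, j in INTERACTION_PAIRS]))
    return np.concatenate(blocks)


def design_matrix(fraction_rows: np.ndarray, terms: TermSet) -> np.ndarray:
    """Stack :func:`build_features` over rows of fraction 4-vectors."""
    rows = np.asarray(fraction_rows, dtype=float)
    return np.vstack([build_features(row, terms) for row in rows])


def r2_score(y, y_hat) -> float:
    """Coefficient of determination R² = 1 − SS_res / SS_tot."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for zero-variance targets")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def mape(y, y_hat, guard: float = 1e-12) -> float:
    """Mean absolute percentage error with a small-denominator guard.

    mean(|y − ŷ| / max(guard, |y|)); returned as a fraction, not percent.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("need two equal-length non-empty vectors")
    return float(np.mean(np.abs(y - y_hat) / np.maximum(guard, np.abs(y))))


def gaussian_log_likelihood(residuals) -> float:
    """Gaussian log-likelihood with the MLE variance σ̂² = SS_res / n."""
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if n == 0:
        raise ValueError("empty residual vector")
    sigma2 = float(np.mean(r**2))
    if sigma2 <= 0.0:
        raise ValueError("zero residual variance: likelihood degenerate")
    return -0.5 * n * (math.log(2.0 * math.pi) + math.log(sigma2) + 1.0)


def information_criteria(residuals, k: int, mode: str = "conventional") -> tuple[float, float]:
    """(AIC, BIC) from a residual vector and the number of features ``k``.

    ``mode="conventional"`` uses AIC = 2(k+1) − 2LL and
    BIC = ln(n)(k+1) − 2LL, counting the intercept.  ``mode="as_printed"``
    swaps the two penalty terms — a compatibility mode for published tables
    that interchange the definitions.
    """
    r = np.asarray(residuals, dtype=float)
    n = r.size
    ll = gaussian_log_likelihood(r)
    akaike_pen = 2.0 * (k + 1)
    bayes_pen = math.log(n) * (k + 1)
    if mode == "conventional":
        return akaike_pen - 2.0 * ll, bayes_pen - 2.0 * ll
    if mode == "as_printed":
        return bayes_pen - 2.0 * ll, akaike_pen - 2.0 * ll
    raise ValueError(f"unknown information-criterion mode {mode!r}")


@dataclass(frozen=True)
class ModelMetrics:
    """Fit quality on one data partition."""

    r2: float
    mape: float
    aic: float
    bic: float
    n: int
    k: int
    ic_mode: str = "conventional"


@dataclass(frozen=True)
class PolynomialEfficiencyModel:
    """A polynomial c_ε predictor over waveband fraction ratios.

    When ``normalize == "ri"`` the polynomial evaluates c_ε/RI and the
    prediction is multiplied by RI = I / i_ref; with ``normalize == "none"``
    the polynomial gives c_ε directly and irradiance is ignored.
    ``domain`` maps band names to the (min, max) fraction range observed in
    training; predictions outside it trigger :class:`OutOfDomainWarning`.
    """

    terms: TermSet
    intercept: float
    coefficients: np.ndarray
    normalize: str = "none"
    i_ref_w_m2: float = REFERENCE_IRRADIANCE_W_M2
    domain: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self):
        coefs = np.asarray(self.coefficients, dtype=float)
        if coefs.shape != (self.terms.n_features,):
            raise ValueError(
                f"coefficient vector length {coefs.size} does not match "
                f"term set ({self.terms.n_features} features)"
            )
        if self.normalize not in ("none", "ri"):
            raise ValueError("normalize must be 'none' or 'ri'")
        object.__setattr__(self, "coefficients", coefs)

    def polynomial_value(self, fractions) -> float:
        """Raw polynomial value (c_ε, or c_ε/RI when RI-normalized)."""
        return self.intercept + float(build_features(fractions, self.terms) @ self.coefficients)

    def predict(self, fractions, irradiance_w_m2: float | None = None) -> float:
        """Predicted c_ε (g J⁻¹) for one fraction 4-vector.

        ``irradiance_w_m2`` (I_PAR+FR, W m⁻²) is required for RI-normalized
        models.  Emits :class:`OutOfDomainWarning` when a fraction lies
        outside the training domain.
        """
        vec = _validate_fractions(fractions)
        if self.domain is not None:
            for name, value in zip(BAND_ORDER, vec):
                lo, hi = self.domain.get(name, (0.0, 1.0))
                if not lo <= value <= hi:
                    warnings.warn(
                        f"{name} fraction {value:.3f} outside training domain "
                        f"[{lo:.3f}, {hi:.3f}]; extrapolating",
                        OutOfDomainWarning,
                        stacklevel=2,
                    )
        value = self.polynomial_value(vec)
        if self.normalize == "ri":
            if irradiance_w_m2 is None:
                raise ValueError("RI-normalized model requires the total irradiance")
            value *= irradiance_w_m2 / self.i_ref_w_m2
        return value

    def predict_many(self, fraction_rows, irradiance_w_m2=None) -> np.ndarray:
        rows = np.asarray(fraction_rows, dtype=float)
        if irradiance_w_m2 is None:
            irr = [None] * len(rows)
        else:
            irr = np.broadcast_to(np.asarray(irradiance_w_m2, dtype=float), (len(rows),))
        return np.array([self.predict(row, i) for row, i in zip(rows, irr)])

    def to_dict(self) -> dict:
        d = {
            "terms": {"powers": list(self.terms.powers), "interactions": self.terms.interactions},
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "feature_names": self.terms.feature_names(),
            "normalize": self.normalize,
            "i_ref_w_m2": self.i_ref_w_m2,
        }
        if self.domain is not None:
            d["domain"] = {k: list(v) for k, v in self.domain.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PolynomialEfficiencyModel":
        terms = TermSet(tuple(d["terms"]["powers"]), bool(d["terms"]["interactions"]))
        domain = d.get("domain")
        if domain is not None:
            domain = {k: tuple(v) for k, v in domain.items()}
        return cls(
            terms=terms,
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            normalize=d.get("normalize", "none"),
            i_ref_w_m2=float(d.get("i_ref_w_m2", REFERENCE_IRRADIANCE_W_M2)),
            domain=domain,
        )


@dataclass(frozen=True)
class RegressionModel:
    """A fitted polynomial model plus its training metadata and metrics."""

    model: PolynomialEfficiencyModel
    train_idx: np.ndarray
    test_idx: np.ndarray
    penalty: str = "none"
    penalty_weight: float = 0.0
    metrics: Mapping[str, ModelMetrics] = field(default_factory=dict)

    @property
    def terms(self) -> TermSet:
        return self.model.terms

    def to_json(self, path) -> None:
        payload = self.model.to_dict()
        payload["training"] = {
            "train_idx": np.asarray(self.train_idx).tolist(),
            "test_idx": np.asarray(self.test_idx).tolist(),
            "penalty": self.penalty,
            "penalty_weight": self.penalty_weight,
        }
        payload["metrics"] = {
            part: vars(m).copy() for part, m in self.metrics.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _solve_ridge(design: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge on an intercept-augmented design (intercept unpenalized).

    Solved through the pseudo-inverse so a zero penalty on a
    closure-degenerate design still returns the minimum-norm solution.
    """
    k = design.shape[1]
    penalty = lam * np.eye(k)
    penalty[0, 0] = 0.0
    return np.linalg.lstsq(design.T @ design + penalty, design.T @ y, rcond=None)[0]


@lru_cache(maxsize=None)
def structural_rank(terms: TermSet) -> int:
    """Rank of the intercept-augmented design on generic closed compositions.

    Because the fractions sum to one, some columns are linearly dependent no
    matter the data: the intercept equals the sum of the first-order block,
    and with both squares and interactions present F_i = F_i² + Σ_j F_iF_j.
    This is the number of identifiable coefficients; it is what a training
    set must reach for the fit to be determined (e.g. 16, not 17, for the
    quartic set)."""
    rng = np.random.default_rng(0)
    fractions = rng.dirichlet(np.ones(4), size=terms.n_features + 12)
    design = np.column_stack(
        [np.ones(len(fractions)), design_matrix(fractions, terms)]
    )
    return int(np.linalg.matrix_rank(design))


def fit(
    fraction_rows,
    targets,
    terms: TermSet,
    irradiance_w_m2=None,
    normalize: str = "none",
    penalty: str = "none",
    penalty_weight: float = 0.0,
    train_idx: Sequence[int] | None = None,
    test_idx: Sequence[int] | None = None,
    ic_mode: str = "conventional",
    i_ref_w_m2: float = REFERENCE_IRRADIANCE_W_M2,
) -> RegressionModel:
    """Fit a polynomial c_ε model on a train partition and score both partitions.

    Parameters
    ----------
    fraction_rows : (n, 4) array
        Waveband fraction vectors (each summing to one).
    targets : (n,) array
        Calibrated c_ε values, g J⁻¹.
    irradiance_w_m2 : (n,) array, optional
        Total integrated irradiance per sample; required when
        ``normalize="ri"``, in which case the regression is fitted on
        c_ε / RI and predictions are rescaled by RI.
    penalty : {"none", "ridge", "lasso"}
        ``none`` is a minimum-norm least-squares solve; ridge is closed form
        with an unpenalized intercept; lasso uses coordinate descent.

    Notes
    -----
    Closed compositions make some coefficient combinations unidentifiable
    (the intercept equals the sum of the first-order features when the
    fractions sum to exactly one), so on exactly-closed data the unpenalized
    solution is the minimum-norm representative; predictions are unaffected.
    The training partition must contain at least :func:`structural_rank`
    rows, and a rank below that signals genuinely degenerate data.
    """
    rows = np.asarray(fraction_rows, dtype=float)
    y = np.asarray(targets, dtype=float)
    n = len(rows)
    if y.shape != (n,):
        raise ValueError("targets must match the number of fraction rows")
    if normalize == "ri":
        if irradiance_w_m2 is None:
            raise ValueError("normalize='ri' requires per-sample irradiance")
        ri = np.asarray(irradiance_w_m2, dtype=float) / i_ref_w_m2
        y_fit = y / ri
    elif normalize == "none":
        y_fit = y
    else:
        raise ValueError("normalize must be 'none' or 'ri'")

    if train_idx is None:
        train_idx = np.arange(n)
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx if test_idx is not None else [], dtype=int)

    features = design_matrix(rows, terms)
    design = np.column_stack([np.ones(n), features])
    k = terms.n_features
    x_tr, y_tr = design[train_idx], y_fit[train_idx]

    if penalty == "none":
        needed = structural_rank(terms)
        if len(train_idx) < needed:
            raise SingularDesignError(
                f"{len(train_idx)} training rows cannot determine the "
                f"{needed} identifiable coefficients of term set {terms.tag!r}"
            )
        # Minimum-norm solve: duplicate compositions (replicated treatments)
        # and the closure dependency leave the predictor well defined even
        # when individual coefficients are not.
        beta, _, _, _ = np.linalg.lstsq(x_tr, y_tr, rcond=None)
    elif penalty == "ridge":
        beta = _solve_ridge(x_tr, y_tr, penalty_weight)
    elif penalty == "lasso":
        est = Lasso(alpha=penalty_weight, fit_intercept=True, tol=1e-10, max_iter=100_000)
        est.fit(x_tr[:, 1:], y_tr)
        beta = np.concatenate([[est.intercept_], est.coef_])
    else:
        raise ValueError("penalty must be 'none', 'ridge' or 'lasso'")

    model = PolynomialEfficiencyModel(
        terms=terms,
        intercept=float(beta[0]),
        coefficients=beta[1:],
        normalize=normalize,
        i_ref_w_m2=i_ref_w_m2,
        domain={
            name: (float(rows[:, i].min()), float(rows[:, i].max()))
            for i, name in enumerate(BAND_ORDER)
        },
    )

    metrics = {}
    for part, idx in (("train", train_idx), ("test", test_idx)):
        if len(idx) < 2:
            continue
        y_hat = design[idx] @ beta
        residuals = y_fit[idx] - y_hat
        try:
            aic, bic = information_criteria(residuals, k, mode=ic_mode)
        except ValueError:  # exact interpolation: likelihood degenerate
            aic = bic = float("-inf")
        metrics[part] = ModelMetrics(
            r2=r2_score(y_fit[idx], y_hat),
            mape=mape(y_fit[idx], y_hat),
            aic=aic,
            bic=bic,
            n=len(idx),
            k=k,
            ic_mode=ic_mode,
        )
    return RegressionModel(
        model=model,
        train_idx=train_idx,
        test_idx=test_idx,
        penalty=penalty,
        penalty_weight=penalty_weight,
        metrics=metrics,
    )


def select_model(
    candidates: Sequence[TermSet],
    fraction_rows,
    targets,
    irradiance_w_m2=None,
    normalize: str = "none",
    penalty: str = "none",
    penalty_weight: float = 0.0,
    train_idx=None,
    test_idx=None,
) -> tuple[pd.DataFrame, list[RegressionModel]]:
    """Fit every candidate term set and rank the results.

    Ranking is by test R² (descending), ties broken by lower test BIC; when
    no test partition exists the train metrics are used.  Returns the ranked
    metric table and the fitted models in the same order.
    """
    if not candidates:
        raise ValueError("need at least one candidate term set")
    fitted = []
    rows = []
    for terms in candidates:
        m = fit(
            fraction_rows,
            targets,
            terms,
            irradiance_w_m2=irradiance_w_m2,
            normalize=normalize,
            penalty=penalty,
            penalty_weight=penalty_weight,
            train_idx=train_idx,
            test_idx=test_idx,
        )
        part = "test" if "test" in m.metrics else "train"
        score = m.metrics[part]
        rows.append(
            {
                "terms": terms.tag,
                "k": terms.n_features,
                "r2_train": m.metrics["train"].r2,
                "mape_train": m.metrics["train"].mape,
                "r2_test": m.metrics["test"].r2 if "test" in m.metrics else np.nan,
                "mape_test": m.metrics["test"].mape if "test" in m.metrics else np.nan,
                "aic": score.aic,
                "bic": score.bic,
            }
        )
        fitted.append(m)
    table = pd.DataFrame(rows)
    rank_r2 = table["r2_test"].fillna(table["r2_train"])
    order = np.lexsort((table["bic"].to_numpy(), -rank_r2.to_numpy()))
    table = table.iloc[order].reset_index(drop=True)
    return table, [fitted[i] for i in order]


def published_model() -> PolynomialEfficiencyModel:
    """The packaged RI-normalized quartic c_ε model.

    A 16-coefficient polynomial in the four irradiance fraction ratios,
    fitted on the 20-treatment LED dataset with the RI normalization; its
    coefficients ship with the package as a JSON model file.
    """
    path = resources.files("spectragrow.data").joinpath("published_efficiency_model.json")
    with path.open() as fh:
        return PolynomialEfficiencyModel.from_dict(json.load(fh))
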
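"""Box-Behnken design, desirability aggregation, quadratic fit, optimization.

The extraction process is optimized over three factors (first liquid-solid
ratio, first extraction time, second extraction time) with a three-level
Box-Behnken design: 12 edge-midpoint runs plus center replicates.  Multiple
responses are rescaled to [0,1] desirabilities d_i = (Y_i - Ymin)/(Ymax -
Ymin) and combined into one overall desirability OD = (d_1 d_2 ... d_k)^(1/k)
(geometric mean).  A full second-order polynomial in coded units is fitted by
ordinary least squares, checked by ANOVA with a lack-of-fit test against the
pure error of the center replicates, and maximized over the coded cube
[-1, 1]^3 by exact stationary-point analysis of every face of the cube.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, DomainError, FitError, ParameterError

TERM_NAMES = ["b0", "b1", "b2", "b3", "b12", "b13", "b23", "b11", "b22", "b33"]


@dataclass(frozen=True)
class FactorSpec:
    """An experimental factor with its coded-unit transform.

    coded x = (actual - center) / step, so the design levels -1/0/+1 map to
    center - step, center, center + step in actual units.
    """

    name: str
    center: float
    step: float

    def __post_init__(self):
        if self.step <= 0:
            raise ParameterError(f"factor {self.name}: step must be > 0")

    @property
    def low(self) -> float:
        return self.center - self.step

    @property
    def high(self) -> float:
        return self.center + self.step

    def encode(self, actual: float) -> float:
        return (actual - self.center) / self.step

    def decode(self, coded: float) -> float:
        return self.center + coded * self.step


#: Factors of the decoction extraction design: first liquid-solid ratio
#: (mL/g), first extraction time (min), second extraction time (min).
EXTRACTION_FACTORS = (
    FactorSpec("liquid_solid_ratio", 8.0, 1.0),
    FactorSpec("first_extraction_time_min", 45.0, 15.0),
    FactorSpec("second_extraction_time_min", 30.0, 10.0),
)


@dataclass
class BBDesign:
    factors: tuple[FactorSpec, FactorSpec, FactorSpec]
    runs: np.ndarray  # coded levels, n x 3
    n_center: int

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    def actual(self) -> np.ndarray:
        return np.column_stack(
            [f.decode(self.runs[:, j]) for j, f in enumerate(self.factors)]
        )

    @property
    def center_mask(self) -> np.ndarray:
        return np.all(self.runs == 0, axis=1)


def bbd_design(
    factors=EXTRACTION_FACTORS,
    n_center: int = 5,
    seed: int | None = None,
) -> BBDesign:
    """Three-factor Box-Behnken design: 12 edge midpoints + center replicates.

    Run order is deterministic (sorted); pass ``seed`` to randomize it.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise ParameterError("bbd_design supports exactly 3 factors")
    if n_center < 1:
        raise ParameterError("n_center must be >= 1 (pure error undefined otherwise)")
    runs = []
    for i, j in itertools.combinations(range(3), 2):
        for a, b in itertools.product((-1.0, 1.0), repeat=2):
            row = [0.0, 0.0, 0.0]
            row[i], row[j] = a, b
            runs.append(row)
    runs.sort()
    runs.extend([[0.0, 0.0, 0.0]] * n_center)
    runs = np.asarray(runs)
    if seed is not None:
        rng = np.random.default_rng(seed)
        runs = runs[rng.permutation(len(runs))]
    return BBDesign(factors, runs, n_center)


@dataclass(frozen=True)
class DesirabilityConfig:
    """Bounds for the linear larger-is-better desirability transform."""

    ymin: float
    ymax: float
    bounds_source: str = "observed"  # "observed" or "supplied"

    def __post_init__(self):
        if not self.ymax > self.ymin:
            raise ParameterError("desirability requires ymax > ymin")


def desirability(y, cfg: DesirabilityConfig | None = None) -> np.ndarray:
    """Per-response desirability d = (Y - Ymin)/(Ymax - Ymin).

    With no config the bounds are the observed min/max of ``y``; externally
    supplied bounds clip the result to [0, 1].
    """
    y = np.asarray(y, dtype=float)
    if cfg is None:
        cfg = DesirabilityConfig(float(y.min()), float(y.max()), "observed")
    d = (y - cfg.ymin) / (cfg.ymax - cfg.ymin)
    if cfg.bounds_source == "supplied":
        d = np.clip(d, 0.0, 1.0)
    return d


def overall_desirability(ds: list[np.ndarray]) -> np.ndarray:
    """Geometric mean of the per-response desirabilities, run by run."""
    if len(ds) < 1:
        raise ParameterError("need at least one desirability vector")
    D = np.column_stack([np.asarray(d, dtype=float) for d in ds])
    if np.any(D < 0):
        raise DomainError("desirabilities must be non-negative")
    return np.prod(D, axis=1) ** (1.0 / D.shape[1])


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """Full second-order model matrix in coded units.

    Columns: 1, x1, x2, x3, x1x2, x1x3, x2x3, x1^2, x2^2, x3^2.
    """
    x = np.asarray(coded, dtype=float)
    x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2]
    return np.column_stack(
        [np.ones(len(x)), x1, x2, x3, x1 * x2, x1 * x3, x2 * x3, x1**2, x2**2, x3**2]
    )


@dataclass
class QuadraticModel:
    """Fitted second-order response model in coded units."""

    coef: dict[str, float]
    design: BBDesign
    y: np.ndarray
    fitted: np.ndarray
    residual_df: int
    r_squared: float
    sigma2: float          # residual mean square
    coef_se: dict[str, float]

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coef[t] for t in TERM_NAMES])

    def predict_coded(self, coded) -> np.ndarray:
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        return model_matrix(coded) @ self.beta

    def predict(self, actual) -> np.ndarray:
        """Predict at points given in actual units (warns outside the ranges)."""
        actual = np.atleast_2d(np.asarray(actual, dtype=float))
        coded = np.column_stack(
            [f.encode(actual[:, j]) for j, f in enumerate(self.design.factors)]
        )
        if np.any(np.abs(coded) > 1 + 1e-9):
            warnings.warn("prediction outside the design factor ranges", stacklevel=2)
        return self.predict_coded(coded)


def fit_quadratic(design: BBDesign, y) -> QuadraticModel:
    """Ordinary least squares fit of the full quadratic in coded units."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != design.n_runs:
        raise DataError("response length does not match the number of runs")
    X = model_matrix(design.runs)
    n, p = X.shape
    if n <= p or np.linalg.matrix_rank(X) < p:
        raise FitError("model matrix is rank deficient (need >10 distinct runs)")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    df_resid = n - p
    sigma2 = rss / df_resid
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return QuadraticModel(
        coef=dict(zip(TERM_NAMES, beta)),
        design=design,
        y=y,
        fitted=fitted,
        residual_df=df_resid,
        r_squared=1.0 - rss / tss if tss > 0 else 1.0,
        sigma2=sigma2,
        coef_se=dict(zip(TERM_NAMES, se)),
    )


_F_CAP = 1e12  # reported when a denominator mean square underflows to ~0


def anova(model: QuadraticModel) -> pd.DataFrame:
    """ANOVA of the fitted quadratic: model, terms, lack of fit, pure error.

    Term F statistics are the squared coefficient t statistics (equivalent to
    type-III tests; the coded BBD columns are orthogonal so this matches the
    type-I decomposition for the linear and interaction terms).  Pure error
    comes from the center-point replicates; the lack-of-fit F compares the
    remaining residual against it.  Noiseless data give near-zero denominators:
    F is then capped and flagged by p = 0.
    """
    y = model.y
    fitted = model.fitted
    n = len(y)
    df_model = len(TERM_NAMES) - 1
    df_resid = model.residual_df
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_resid = float(np.sum((y - fitted) ** 2))
    ss_model = ss_total - ss_resid
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    rows = []

    def f_and_p(ms_num, df_num, ms_den, df_den):
        if ms_den is None or not np.isfinite(ms_den) or df_den <= 0:
            return np.nan, np.nan
        if ms_den <= 1e-300:
            return _F_CAP, 0.0
        F = ms_num / ms_den
        if not np.isfinite(F) or F >= _F_CAP:
            return _F_CAP, 0.0
        return F, float(stats.f.sf(F, df_num, df_den))

    F, p = f_and_p(ss_model / df_model, df_model, ms_resid, df_resid)
    rows.append(("model", ss_model, df_model, ss_model / df_model, F, p))

    # per-term tests from coefficient t statistics
    for term in TERM_NAMES[1:]:
        b, se = model.coef[term], model.coef_se[term]
        if se <= 1e-300:
            F, p = _F_CAP, 0.0
        else:
            t = b / se
            F = t * t
            p = float(2 * stats.t.sf(abs(t), df_resid))
            if F >= _F_CAP:
                F, p = _F_CAP, 0.0
        rows.append((term, F * model.sigma2, 1, F * model.sigma2, F, p))

    center = model.design.center_mask
    n_center = int(center.sum())
    if n_center >= 2:
        yc = y[center]
        ss_pe = float(np.sum((yc - yc.mean()) ** 2))
        df_pe = n_center - 1
        ss_lof = max(ss_resid - ss_pe, 0.0)
        df_lof = df_resid - df_pe
        if df_lof > 0:
            ms_pe = ss_pe / df_pe
            F, p = f_and_p(ss_lof / df_lof, df_lof, ms_pe, df_pe)
            rows.append(("lack_of_fit", ss_lof, df_lof, ss_lof / df_lof, F, p))
        rows.append(("pure_error", ss_pe, df_pe, ss_pe / df_pe if df_pe else np.nan,
                     np.nan, np.nan))
    rows.append(("residual", ss_resid, df_resid,
                 ms_resid, np.nan, np.nan))
    rows.append(("total", ss_total, n - 1, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["source", "SS", "df", "MS", "F", "p"])


@dataclass
class OptimizationResult:
    argmax_coded: np.ndarray
    argmax_actual: np.ndarray
    predicted: float


def optimize(model: QuadraticModel, factors=None) -> OptimizationResult:
    """Global maximum of the fitted quadratic over the coded cube [-1,1]^3.

    A quadratic restricted to any face of the cube is again a quadratic, so
    the global maximum is attained at a stationary point of one of the 27
    coordinate patterns (each coordinate free, at -1, or at +1).  All
    feasible pattern solutions are enumerated and the best is returned -- an
    exact, deterministic search.
    """
    factors = model.design.factors if factors is None else tuple(factors)
    b = model.coef
    # gradient of q(x) = b0 + sum bi xi + sum bij xi xj + sum bii xi^2:
    # dq/dxi = bi + 2 bii xi + sum_{j != i} bij xj
    H = np.array(
        [
            [2 * b["b11"], b["b12"], b["b13"]],
            [b["b12"], 2 * b["b22"], b["b23"]],
            [b["b13"], b["b23"], 2 * b["b33"]],
        ]
    )
    g = np.array([b["b1"], b["b2"], b["b3"]])

    best_x, best_val = None, -np.inf
    for pattern in itertools.product((None, -1.0, 1.0), repeat=3):
        free = [i for i, v in enumerate(pattern) if v is None]
        x = np.array([0.0 if v is None else v for v in pattern])
        if free:
            A = H[np.ix_(free, free)]
            rhs = -(g[free] + H[np.ix_(free, [i for i in range(3) if i not in free])]
                    @ x[[i for i in range(3) if i not in free]])
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            if np.any(np.abs(sol) > 1 + 1e-12):
                continue
            x[free] = np.clip(sol, -1.0, 1.0)
        val = float(model.predict_coded(x)[0])
        if val > best_val:
            best_val, best_x = val, x.copy()

    actual = np.array([f.decode(xi) for f, xi in zip(factors, best_x)])
    return OptimizationResult(best_x, actual, best_val)


def surface_grid(
    model: QuadraticModel,
    pair: tuple[int, int] = (0, 1),
    fixed_level: float = 0.0,
    n: int = 51,
) -> pd.DataFrame:
    """Predicted-response grid over two factors for contour export.

    The remaining factor is held at ``fixed_level`` (coded units).  Grid
    coordinates are reported in actual units.
    """
    i, j = pair
    if i == j or not {i, j} <= {0, 1, 2}:
        raise ParameterError("pair must be two distinct factor indices in 0..2")
    (k,) = set(range(3)) - {i, j}
    levels = np.linspace(-1.0, 1.0, n)
    gi, gj = np.meshgrid(levels, levels, indexing="ij")
    coded = np.zeros((n * n, 3))
    coded[:, i] = gi.ravel()
    coded[:, j] = gj.ravel()
    coded[:, k] = fixed_level
    pred = model.predict_coded(coded)
    fi, fj = model.design.factors[i], model.design.factors[j]
    return pd.DataFrame(
        {
            fi.name: fi.decode(coded[:, i]),
            fj.name: fj.decode(coded[:, j]),
            "predicted": pred,
        }
    )


def infer_factors(levels: pd.DataFrame, names=None) -> tuple[FactorSpec, ...]:
    """Derive FactorSpecs from a run table given in actual units.

    Each column must take exactly three equally spaced levels (low, center,
    high); center and step are read off those levels.
    """
    specs = []
    for idx, col in enumerate(levels.columns):
        vals = np.unique(levels[col].to_numpy(dtype=float))
        if len(vals) != 3 or not np.isclose(vals[1] - vals[0], vals[2] - vals[1]):
            raise DataError(
                f"column {col}: expected 3 equally spaced levels, got {vals}"
            )
        name = names[idx] if names else str(col)
        specs.append(FactorSpec(name, float(vals[1]), float(vals[1] - vals[0])))
    return tuple(specs)


def read_run_table(source, factor_cols=("X1", "X2", "X3")):
    """Load a design run table from CSV (or DataFrame); auto-detect coding.

    Columns ``X1, X2, X3`` hold factor levels, coded (-1/0/+1) or actual; the
    remaining numeric columns are responses.  Returns (BBDesign, responses
    DataFrame).
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in factor_cols if c not in df.columns]
    if missing:
        raise DataError(f"run table missing factor columns {missing}")
    levels = df[list(factor_cols)]
    uniq = set(np.unique(levels.to_numpy(dtype=float)))
    if uniq <= {-1.0, 0.0, 1.0}:
        factors = tuple(FactorSpec(c, 0.0, 1.0) for c in factor_cols)
        coded = levels.to_numpy(dtype=float)
    else:
        factors = infer_factors(levels)
        coded = np.column_stack(
            [f.encode(levels[c].to_numpy(dtype=float)) for f, c in zip(factors, factor_cols)]
        )
    n_center = int(np.sum(np.all(coded == 0, axis=1)))
    design = BBDesign(factors, coded, n_center)
    responses = df.drop(columns=[c for c in df.columns if c in factor_cols or c == "run"])
    return design, responses
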
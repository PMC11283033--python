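"""Presence-background maximum-entropy suitability modeling.

The model is the Gibbs distribution over background cells

    p(b) = exp(eta(b)) / Z,    eta(x) = sum_j beta_j f_j(x),
    Z = sum_background exp(eta(b)),

with features f_j built from predictor variables (linear, quadratic,
pairwise-product and hinge classes, each rescaled to [0, 1] over the
training data).  Coefficients maximize the L1-penalized presence
log-likelihood

    (1/m) sum_presences eta(x_i) - log Z - sum_j lambda_j |beta_j|,

solved by a deterministic proximal-Newton scheme (full gradient and feature
covariance, an inner soft-threshold coordinate descent on the quadratic
subproblem, backtracking line search) starting from beta = 0.  At the
optimum the moment condition |E_model[f_j] - mean_presence[f_j]| <= lambda_j
holds for every feature — the defining property of penalized maximum
entropy.

Suitability is reported on the cloglog scale,

    cloglog(x) = 1 - exp(-exp(H) * raw(x)),   raw(x) = exp(eta(x) - log Z),

where H is the entropy of the fitted background distribution; a featureless
model therefore predicts 1 - 1/e everywhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .rasters import Raster, RasterStack

logger = logging.getLogger("invasionrisk")

#: sample-size schedule for default regularization multipliers, per feature
#: class: (presence-count knots, multiplier knots), linearly interpolated.
REG_SCHEDULE = {
    "linear": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 17, 30], [1.3, 0.8, 0.5, 0.25]),
    "product": ([0, 10, 17, 30], [2.6, 1.6, 1.0, 0.43]),
    "hinge": ([0, 1], [0.5, 0.5]),
}

#: presence-count thresholds for the default feature-class schedule
def default_classes(n_presence: int) -> tuple[str, ...]:
    """Feature classes enabled by presence count (the canonical schedule)."""
    if n_presence >= 80:
        return ("linear", "quadratic", "product", "hinge")
    if n_presence >= 15:
        return ("linear", "quadratic", "hinge")
    if n_presence >= 10:
        return ("linear", "quadratic")
    return ("linear",)


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------

@dataclass
class FeatureDef:
    variables: tuple[str, ...]
    kind: str                  # linear | quadratic | product | hinge
    knot: float | None = None
    orientation: int = 0       # hinge: +1 => max(0, x-k), -1 => max(0, k-x)

    @property
    def label(self) -> str:
        if self.kind == "hinge":
            side = "fwd" if self.orientation > 0 else "rev"
            return f"hinge_{side}({self.variables[0]}@{self.knot:g})"
        if self.kind == "product":
            return f"product({self.variables[0]},{self.variables[1]})"
        return f"{self.kind}({self.variables[0]})"


@dataclass
class FeatureSet:
    """Feature definitions plus the training statistics needed to apply them.

    ``clamp`` maps each source variable to its training (min, max); inputs
    are clamped to this box before feature evaluation.  ``scale`` maps each
    feature to its raw (min, max) used for the [0, 1] rescale.  ``means``
    holds the training mean of each source variable (for response curves).
    """

    definitions: list[FeatureDef]
    clamp: dict[str, tuple[float, float]]
    scale: list[tuple[float, float]]
    means: dict[str, float]

    @property
    def variables(self) -> list[str]:
        return list(self.clamp)

    @property
    def labels(self) -> list[str]:
        return [d.label for d in self.definitions]

    def evaluate(self, table: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        """Expand a variable table into the rescaled feature matrix."""
        cols = {}
        for v in self.clamp:
            if v not in table.columns:
                raise KeyError(f"variable '{v}' missing from input table")
            x = table[v].to_numpy(dtype=float)
            if clamp:
                lo, hi = self.clamp[v]
                x = np.clip(x, lo, hi)
            cols[v] = x
        out = np.empty((len(table), len(self.definitions)))
        for j, (d, (flo, fhi)) in enumerate(zip(self.definitions, self.scale)):
            if d.kind == "linear":
                raw = cols[d.variables[0]]
            elif d.kind == "quadratic":
                raw = cols[d.variables[0]] ** 2
            elif d.kind == "product":
                raw = cols[d.variables[0]] * cols[d.variables[1]]
            elif d.kind == "hinge":
                x = cols[d.variables[0]]
                raw = np.maximum(0.0, d.orientation * (x - d.knot))
            else:  # pragma: no cover
                raise ValueError(f"unknown feature kind {d.kind}")
            span = fhi - flo
            out[:, j] = (raw - flo) / span if span > 0 else 0.0
        return out


def build_features(table: pd.DataFrame, classes=("linear", "quadratic"),
                   n_hinge_knots: int = 5,
                   variables: list[str] | None = None):
    """Build a FeatureSet from a training table and return (fs, matrix).

    Constant variables contribute only their (degenerate) linear feature;
    their quadratic/product/hinge features are dropped with a warning.
    Hinge knots are evenly spaced strictly inside each variable's range,
    both orientations.
    """
    if len(table) < 2:
        raise ValueError("training table needs at least 2 rows")
    if variables is None:
        variables = [c for c in table.columns
                     if not c.startswith("_") and c not in ("lon", "lat", "is_presence")]
    classes = set(classes)
    clamp = {}
    means = {}
    constant = set()
    for v in variables:
        x = table[v].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            raise ValueError(f"non-finite values in variable '{v}'")
        clamp[v] = (float(x.min()), float(x.max()))
        means[v] = float(x.mean())
        if x.min() == x.max():
            constant.add(v)
            logger.warning("build_features: variable '%s' is constant; "
                           "dropping its nonlinear features", v)

    defs: list[FeatureDef] = []
    if "linear" in classes:
        defs += [FeatureDef((v,), "linear") for v in variables]
    if "quadratic" in classes:
        defs += [FeatureDef((v,), "quadratic") for v in variables if v not in constant]
    if "product" in classes:
        for a in range(len(variables)):
            for b in range(a + 1, len(variables)):
                va, vb = variables[a], variables[b]
                if va in constant or vb in constant:
                    continue
                defs.append(FeatureDef((va, vb), "product"))
    if "hinge" in classes:
        for v in variables:
            if v in constant:
                continue
            lo, hi = clamp[v]
            knots = np.linspace(lo, hi, n_hinge_knots + 2)[1:-1]
            for k in knots:
                defs.append(FeatureDef((v,), "hinge", knot=float(k), orientation=+1))
                defs.append(FeatureDef((v,), "hinge", knot=float(k), orientation=-1))

    fs = FeatureSet(definitions=defs, clamp=clamp,
                    scale=[(0.0, 1.0)] * len(defs), means=means)
    raw = fs.evaluate(table, clamp=False)
    scale = []
    for j in range(raw.shape[1]):
        lo, hi = float(raw[:, j].min()), float(raw[:, j].max())
        scale.append((lo, hi) if hi > lo else (lo, lo))
    fs.scale = scale
    return fs, fs.evaluate(table, clamp=False)


# ---------------------------------------------------------------------------
# Background sampling
# ---------------------------------------------------------------------------

def sample_background(stack: RasterStack, n: int = 10_000, seed: int = 0,
                      presences=None) -> pd.DataFrame:
    """Sample background cells plus (optionally) the presence cells.

    Up to ``n`` distinct jointly valid cells are drawn uniformly without
    replacement (all cells if there are fewer).  If ``presences`` is given,
    their values are extracted and appended with ``is_presence = 1``; the
    background rows carry ``is_presence = 0``.  The background represents the
    available environment, presences included.
    """
    from .rasters import extract
    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("no valid cells to sample background from")
    rng = np.random.default_rng(seed)
    take = min(n, rows.size)
    idx = rng.choice(rows.size, size=take, replace=False)
    r, c = rows[idx], cols[idx]
    lon, lat = stack.header.cell_center(r, c)
    bg = stack.table(r, c)
    bg.insert(0, "lat", lat)
    bg.insert(0, "lon", lon)
    bg["_row"], bg["_col"] = r, c
    bg["is_presence"] = 0
    if presences is not None:
        pres = extract(stack, presences)
        pres["is_presence"] = 1
        bg = pd.concat([bg, pres], ignore_index=True)
    return bg


def default_lambdas(fs: FeatureSet, presence_matrix: np.ndarray,
                    multiplier: float = 1.0) -> np.ndarray:
    """Default per-feature L1 penalties from the sample-size schedule.

    lambda_j = multiplier * r_class(m) * sd_presence(f_j) / sqrt(m), with the
    sd floored at a small constant so rarely-varying features still get a
    nonzero penalty.
    """
    m = presence_matrix.shape[0]
    lam = np.empty(len(fs.definitions))
    for j, d in enumerate(fs.definitions):
        ss, mult = REG_SCHEDULE[d.kind]
        r = float(np.interp(m, ss, mult))
        sd = float(presence_matrix[:, j].std())
        lam[j] = multiplier * r * max(sd, 0.01) / np.sqrt(max(m, 1))
    return lam


# ---------------------------------------------------------------------------
# Model and fitting
# ---------------------------------------------------------------------------

@dataclass
class MaxentModel:
    features: FeatureSet
    beta: np.ndarray
    lam: np.ndarray
    log_z: float
    entropy: float
    converged: bool = True
    n_iter: int = 0
    background: pd.DataFrame | None = field(default=None, repr=False)

    def eta(self, table: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        return self.features.evaluate(table, clamp=clamp) @ self.beta

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "definitions": [
                {"variables": list(d.variables), "kind": d.kind,
                 "knot": d.knot, "orientation": d.orientation}
                for d in self.features.definitions
            ],
            "clamp": {k: list(v) for k, v in self.features.clamp.items()},
            "scale": [list(s) for s in self.features.scale],
            "means": self.features.means,
            "beta": self.beta.tolist(),
            "lambda": self.lam.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
        }
        with open(str(path), "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MaxentModel":
        with open(str(path)) as fh:
            doc = json.load(fh)
        fs = FeatureSet(
            definitions=[FeatureDef(tuple(d["variables"]), d["kind"],
                                    d["knot"], d["orientation"])
                         for d in doc["definitions"]],
            clamp={k: (v[0], v[1]) for k, v in doc["clamp"].items()},
            scale=[(s[0], s[1]) for s in doc["scale"]],
            means=doc["means"],
        )
        return cls(features=fs, beta=np.array(doc["beta"]),
                   lam=np.array(doc["lambda"]), log_z=doc["log_z"],
                   entropy=doc["entropy"])


def _objective(beta, f_pres, f_bg, lam):
    """Penalized presence log-likelihood (to be maximized)."""
    eta_bg = f_bg @ beta
    mx = eta_bg.max()
    log_z = mx + np.log(np.exp(eta_bg - mx).sum())
    return float((f_pres @ beta).mean() - log_z - np.abs(beta) @ lam)


def fit(presence_features: np.ndarray, background_features: np.ndarray,
        features: FeatureSet, lam: np.ndarray | float = 0.0,
        tol: float = 1e-10, max_iter: int = 500,
        background: pd.DataFrame | None = None) -> MaxentModel:
    """Fit the penalized maximum-entropy model.

    Proximal Newton from beta = 0: each outer iteration builds the quadratic
    model of the log-likelihood (gradient = presence means minus model
    expectations; Hessian = feature covariance under the model), solves the
    L1-penalized subproblem by cyclic soft-threshold coordinate descent, and
    backtracks on the exact penalized objective.  Deterministic; no seed.

    Raises if features are non-finite or the relative objective change fails
    to reach ``tol`` within ``max_iter`` iterations.
    """
    f_pres = np.asarray(presence_features, dtype=float)
    f_bg = np.asarray(background_features, dtype=float)
    if f_pres.ndim != 2 or f_pres.shape[0] < 1:
        raise ValueError("need at least one presence row")
    if f_bg.shape[0] < 2:
        raise ValueError("need at least two background rows")
    if not (np.isfinite(f_pres).all() and np.isfinite(f_bg).all()):
        raise ValueError("non-finite feature values")
    n_feat = f_pres.shape[1]
    lam = np.full(n_feat, float(lam)) if np.isscalar(lam) else np.asarray(lam, float)
    if (lam < 0).any():
        raise ValueError("penalties must be nonnegative")

    pres_mean = f_pres.mean(axis=0)
    beta = np.zeros(n_feat)
    obj = _objective(beta, f_pres, f_bg, lam)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta_bg = f_bg @ beta
        w = np.exp(eta_bg - eta_bg.max())
        p = w / w.sum()
        e_f = p @ f_bg
        grad = pres_mean - e_f                      # d loglik / d beta
        centered = f_bg - e_f
        hess = centered.T @ (centered * p[:, None])  # covariance of features
        hess[np.diag_indices_from(hess)] += 1e-9     # ridge for degenerate features

        # inner CD: minimize 1/2 d'Hd - grad'd + sum lam |beta+d|
        d = np.zeros(n_feat)
        hd = np.zeros(n_feat)  # H @ d
        diag = np.diag(hess).copy()
        for _sweep in range(100):
            max_step = 0.0
            for j in range(n_feat):
                gj = grad[j] - hd[j] + diag[j] * d[j]
                bj = beta[j]
                target = bj + gj / diag[j]
                new = np.sign(target) * max(abs(target) - lam[j] / diag[j], 0.0) - bj
                delta = new - d[j]
                if delta != 0.0:
                    hd += hess[:, j] * delta
                    d[j] = new
                    max_step = max(max_step, abs(delta))
            if max_step < 1e-12:
                break

        step = 1.0
        improved = False
        for _bt in range(40):
            cand = beta + step * d
            cand_obj = _objective(cand, f_pres, f_bg, lam)
            if cand_obj > obj - 1e-15:
                improved = cand_obj > obj
                new_obj = cand_obj
                break
            step *= 0.5
        else:
            new_obj = obj
            cand = beta
        rel = abs(new_obj - obj) / max(abs(obj), 1.0)
        beta, obj = cand, new_obj
        if rel < tol and it > 1:
            converged = True
            break
        if not improved and it > 1:
            converged = True  # stationary: no ascent direction remains
            break
    if not converged:
        raise RuntimeError(
            f"maxent fit did not converge in {max_iter} iterations "
            f"(last relative objective change {rel:.3e})")

    eta_bg = f_bg @ beta
    mx = eta_bg.max()
    log_z = mx + np.log(np.exp(eta_bg - mx).sum())
    p = np.exp(eta_bg - log_z)
    entropy = float(-(p * np.log(np.maximum(p, 1e-300))).sum())
    return MaxentModel(features=features, beta=beta, lam=lam, log_z=log_z,
                       entropy=entropy, converged=converged, n_iter=it,
                       background=background)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_raw(model: MaxentModel, table: pd.DataFrame) -> np.ndarray:
    """Raw (Gibbs) weights exp(eta - logZ); sums to 1 over the training background."""
    return np.exp(model.eta(table) - model.log_z)


def predict_cloglog(model: MaxentModel, table: pd.DataFrame) -> np.ndarray:
    """Suitability in (0, 1): 1 - exp(-exp(H) * raw)."""
    return 1.0 - np.exp(-np.exp(model.entropy) * predict_raw(model, table))


def predict_raster(model: MaxentModel, stack: RasterStack) -> Raster:
    """Cloglog suitability over every jointly valid cell of a stack."""
    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    table = stack.table(rows, cols)
    vals = np.full((stack.header.nrows, stack.header.ncols), np.nan)
    vals[rows, cols] = predict_cloglog(model, table)
    return Raster(values=vals, header=stack.header, name="suitability")


def ensemble_predict(models: list[MaxentModel], stack: RasterStack):
    """Per-cell mean and sd of the cloglog predictions of several models."""
    if not models:
        raise ValueError("empty model list")
    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    table = stack.table(rows, cols)
    preds = np.stack([predict_cloglog(m, table) for m in models])
    mean = np.full((stack.header.nrows, stack.header.ncols), np.nan)
    sd = np.full_like(mean, np.nan)
    mean[rows, cols] = preds.mean(axis=0)
    sd[rows, cols] = preds.std(axis=0, ddof=0)
    return (Raster(values=mean, header=stack.header, name="suitability_mean"),
            Raster(values=sd, header=stack.header, name="suitability_sd"))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling.

    The probability that a random presence scores above a random background
    point, ties counting one half.
    """
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([pres, bg]))
    r_pres = ranks[: pres.size].sum()
    u = r_pres - pres.size * (pres.size + 1) / 2.0
    return float(u / (pres.size * bg.size))


@dataclass
class EvaluationReport:
    fold_aucs: list[float]
    fold_sizes: list[int]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=0))


def kfold_evaluate(presence_table: pd.DataFrame, background_table: pd.DataFrame,
                   features_kw: dict | None = None, k: int = 10, seed: int = 0,
                   lam_multiplier: float = 1.0, tol: float = 1e-10):
    """k-fold cross-validation of the suitability model.

    Presences are split into k near-equal seeded folds; each model is fitted
    on the remaining folds against the full background and scored by AUC of
    the held-out presences versus the background.  Returns the report and
    the k fitted models.
    """
    m = len(presence_table)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > m:
        raise ValueError(f"k={k} exceeds the {m} presences")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    folds = [perm[i::k] for i in range(k)]
    features_kw = dict(features_kw or {})
    features_kw.setdefault("classes", default_classes(m))

    fold_aucs, models = [], []
    for fold in folds:
        train_mask = np.ones(m, dtype=bool)
        train_mask[fold] = False
        train = presence_table.iloc[train_mask].reset_index(drop=True)
        test = presence_table.iloc[fold].reset_index(drop=True)
        joint = pd.concat([train, background_table], ignore_index=True)
        fs, joint_mat = build_features(joint, **features_kw)
        f_pres = joint_mat[: len(train)]
        f_bg = joint_mat[len(train):]
        lam = default_lambdas(fs, f_pres, multiplier=lam_multiplier)
        model = fit(f_pres, f_bg, fs, lam=lam, tol=tol)
        pres_scores = predict_cloglog(model, test)
        bg_scores = predict_cloglog(model, background_table)
        fold_aucs.append(auc(pres_scores, bg_scores))
        models.append(model)
    report = EvaluationReport(fold_aucs=fold_aucs,
                              fold_sizes=[len(f) for f in folds])
    logger.info("kfold_evaluate: k=%d mean_auc=%.4f sd_auc=%.4f",
                k, report.mean_auc, report.sd_auc)
    return report, models


# ---------------------------------------------------------------------------
# Permutation importance and response curves
# ---------------------------------------------------------------------------

@dataclass
class ImportanceTable:
    importance: dict[str, float]   # percent, sums to 100 when any drop > 0
    auc_drop: dict[str, float]
    baseline_auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": list(self.importance),
            "importance_pct": list(self.importance.values()),
            "auc_drop": [self.auc_drop[v] for v in self.importance],
        }).sort_values("importance_pct", ascending=False, ignore_index=True)


def permutation_importance(model: MaxentModel, presence_table: pd.DataFrame,
                           background_table: pd.DataFrame, seed: int = 0,
                           n_repeats: int = 3) -> ImportanceTable:
    """Variable importance as the normalized AUC drop under shuffling.

    Each source variable's column is shuffled jointly across presence and
    background rows (seeded, averaged over ``n_repeats``), features are
    re-evaluated, and the drop from the baseline training AUC is recorded,
    clipped at zero.  Drops are normalized to percentages summing to 100;
    if every drop is zero the importances are all zero (warned).
    """
    rng = np.random.default_rng(seed)
    n_pres = len(presence_table)
    joint = pd.concat([presence_table, background_table], ignore_index=True)
    base_scores = predict_cloglog(model, joint)
    baseline = auc(base_scores[:n_pres], base_scores[n_pres:])

    drops = {}
    for var in model.features.variables:
        rep = []
        for _ in range(n_repeats):
            shuffled = joint.copy()
            shuffled[var] = rng.permutation(shuffled[var].to_numpy())
            scores = predict_cloglog(model, shuffled)
            rep.append(baseline - auc(scores[:n_pres], scores[n_pres:]))
        drops[var] = max(0.0, float(np.mean(rep)))
    total = sum(drops.values())
    if total <= 0:
        logger.warning("permutation_importance: all AUC drops are zero")
        importance = {v: 0.0 for v in drops}
    else:
        importance = {v: 100.0 * d / total for v, d in drops.items()}
    return ImportanceTable(importance=importance, auc_drop=drops,
                           baseline_auc=baseline)


def response_curve(model: MaxentModel, variable: str, n_points: int = 100):
    """Cloglog suitability as one variable sweeps its training range.

    All other variables are held at their training means.  Returns
    ``(grid_values, cloglog_values)``.
    """
    if variable not in model.features.clamp:
        raise KeyError(f"variable '{variable}' is not used by the model")
    lo, hi = model.features.clamp[variable]
    xs = np.linspace(lo, hi, n_points)
    table = pd.DataFrame({v: np.full(n_points, model.features.means[v])
                          for v in model.features.variables})
    table[variable] = xs
    return xs, predict_cloglog(model, table)
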
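"""Feature assembly, linear-SVM training and the relatedness scorer.

The Multi-Features Relatedness (MFR) score of a gene pair is
``sigmoid(w . x + b)`` where x is the pair's 12-feature vector (scaled to
[0, 1] per feature by a min-max transform fitted on training data) and
(w, b) come from a soft-margin linear SVM fitted on labeled pairs.  Linear
baselines (logistic regression, LDA) and the CXP coexpression average are
provided for comparison, along with the published 12-weight scorer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .errors import MFRError, MissingFeatureError, UndefinedCorrelationError
from .expression import ExpressionFeatureConfig, cmi, mean_expression, mi, pcc, ppc, src
from .io import (
    COEXPRESSION_FEATURES,
    EXPRESSION_FEATURES,
    FEATURE_NAMES,
    AnnotationMap,
    ExpressionMatrix,
    HomologyProfileSet,
    Ontology,
    PairDataset,
    PairRecord,
)
from .knowledge import (
    GoSimilarity,
    ReactomeSimilarity,
    homology_similarity,
    localization_similarity,
    regulatory_similarity,
)

#: Weights of the 12 features as printed for the trained reference model.
PUBLISHED_WEIGHTS = {
    "exp1": -0.810,
    "exp2": -0.807,
    "PCC": -0.017,
    "SRC": 0.840,
    "MI": 4.875,
    "PPC": 2.414,
    "CMI": -0.055,
    "goSim": 0.972,
    "lcSim": 1.198,
    "hgSim": 0.433,
    "rxSim": 0.544,
    "trSim": 0.668,
}


def sigmoid(t: float | np.ndarray) -> float | np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(t, dtype=float)))


class ImputationPolicy(str, Enum):
    """What to do with pairs whose features cannot all be computed."""

    DROP = "drop"
    IMPUTE_HALF = "impute_half"  # missing features become 0.5 in scaled space


# ---------------------------------------------------------------------------
# Feature scaling
# ---------------------------------------------------------------------------

@dataclass
class FeatureScaler:
    """Per-feature min-max transform to [0, 1], fitted on training data.

    Constant features map to 0.5 (flagged with a warning at fit time).
    """

    min_: np.ndarray
    max_: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        span = self.max_ - self.min_
        out = np.empty_like(x, dtype=float)
        const = span == 0
        with np.errstate(invalid="ignore"):
            out[..., ~const] = (x[..., ~const] - self.min_[~const]) / span[~const]
        out[..., const] = 0.5
        return out

    def inverse(self, x: np.ndarray) -> np.ndarray:
        span = self.max_ - self.min_
        return np.asarray(x, dtype=float) * span + self.min_

    @staticmethod
    def identity(n_features: int = len(FEATURE_NAMES)) -> "FeatureScaler":
        return FeatureScaler(np.zeros(n_features), np.ones(n_features))


def fit_scaler(dataset: PairDataset | np.ndarray) -> FeatureScaler:
    """Fit the min-max scaler on a dataset's feature matrix (NaN-tolerant)."""
    x = dataset.feature_matrix() if isinstance(dataset, PairDataset) else np.asarray(dataset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanmin(x, axis=0)
        hi = np.nanmax(x, axis=0)
    lo = np.where(np.isnan(lo), 0.0, lo)
    hi = np.where(np.isnan(hi), 1.0, hi)
    if (hi == lo).any():
        idx = np.flatnonzero(hi == lo)
        names = [FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else str(i) for i in idx]
        warnings.warn(f"constant feature column(s) {names}; scaled to 0.5", stacklevel=2)
    return FeatureScaler(lo, hi)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class MFRModel:
    """Linear scorer: score(x) = sigmoid(w . scale(x) + b)."""

    weights: np.ndarray
    bias: float
    scaler: FeatureScaler | None = None
    hyperparameters: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    # training-time artifacts for KKT verification (not serialized)
    support_vectors_: np.ndarray | None = None
    dual_coef_: np.ndarray | None = None
    support_idx_: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(FEATURE_NAMES),):
            raise MFRError(f"weight vector must have {len(FEATURE_NAMES)} entries")

    def decision_value(self, features: np.ndarray) -> np.ndarray:
        """w . scale(x) + b, with NaN features imputed at 0.5 in scaled space."""
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if self.scaler is not None:
            scaled = self.scaler.transform(x)
        else:
            scaled = x.copy()
        missing = np.isnan(scaled)
        if missing.any():
            scaled = np.where(missing, 0.5, scaled)
        return scaled @ self.weights + self.bias

    def score(self, features: np.ndarray, policy: ImputationPolicy = ImputationPolicy.DROP):
        """Relatedness score(s) in (0, 1).

        Under the drop policy a NaN feature raises; under impute_half it is
        replaced with 0.5 after scaling.
        """
        x = np.asarray(features, dtype=float)
        single = x.ndim == 1
        x2 = np.atleast_2d(x)
        if policy == ImputationPolicy.DROP and np.isnan(x2).any():
            raise MissingFeatureError("missing feature under the drop policy")
        out = sigmoid(self.decision_value(x2))
        return float(out[0]) if single else out


def score(model: MFRModel, features, policy: ImputationPolicy = ImputationPolicy.DROP):
    """Functional alias for :meth:`MFRModel.score`."""
    return model.score(features, policy)


def published_weights_model(bias: float = 0.0) -> MFRModel:
    """The reference scorer with the 12 printed weights, identity scaler.

    The bias term was never printed for the reference model, so it defaults
    to 0 and is configurable.
    """
    w = np.array([PUBLISHED_WEIGHTS[n] for n in FEATURE_NAMES])
    return MFRModel(
        weights=w,
        bias=float(bias),
        scaler=FeatureScaler.identity(),
        metadata={"source": "published-weights"},
    )


def train_mfr(
    train: PairDataset | tuple[np.ndarray, np.ndarray],
    C: float = 1.0,
    tol: float = 1e-4,
    seed: int = 0,
    scaler: FeatureScaler | None = None,
) -> MFRModel:
    """Fit the soft-margin linear SVM (LIBSVM/SMO) on labeled pair features.

    Features are min-max scaled (scaler fitted here unless provided); the
    returned model carries the collapsed primal weights w = sum(alpha_i y_i
    x_i), the solver bias, and the support vectors/duals for KKT checks.
    """
    if isinstance(train, PairDataset):
        x, y = train.feature_matrix(), train.labels
    else:
        x, y = train
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise MFRError("training data must contain both labels")
    if scaler is None:
        scaler = fit_scaler(x)
    xs = scaler.transform(x)
    xs = np.where(np.isnan(xs), 0.5, xs)
    svc = SVC(kernel="linear", C=C, tol=tol, random_state=seed)
    svc.fit(xs, y)
    w = svc.coef_[0]
    b = float(svc.intercept_[0])
    return MFRModel(
        weights=w,
        bias=b,
        scaler=scaler,
        hyperparameters={"C": C, "tol": tol},
        metadata={"seed": seed, "n_train": int(len(y))},
        support_vectors_=svc.support_vectors_,
        dual_coef_=svc.dual_coef_[0],
        support_idx_=svc.support_,
    )


def kkt_violations(model: MFRModel, x_scaled: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Measure violations of the SVM KKT conditions on the training set.

    Returns the absolute dual-balance residual |sum alpha_i y_i|, the box
    violation max(0, alpha - C, -alpha), the worst complementary-slackness
    gap over support vectors with 0 < alpha < C (|y f(x) - 1|), and the
    worst margin violation over non-support points (max(0, 1 - y f(x))).
    """
    if model.dual_coef_ is None:
        raise MFRError("model carries no dual information (not freshly trained)")
    c = float(model.hyperparameters.get("C", 1.0))
    dual = model.dual_coef_  # alpha_i * y_i for support vectors
    alphas = np.abs(dual)
    f = x_scaled @ model.weights + model.bias
    ysigned = np.where(y > 0, 1.0, -1.0)
    margins = ysigned * f
    is_sv = np.zeros(len(y), dtype=bool)
    sv_alpha = np.zeros(len(y))
    is_sv[model.support_idx_] = True
    sv_alpha[model.support_idx_] = alphas
    free = is_sv & (sv_alpha < c - 1e-8)
    return {
        "dual_balance": abs(float(dual.sum())),
        "box": float(max(0.0, alphas.max(initial=0.0) - c, -alphas.min(initial=0.0))),
        "slackness": float(np.abs(margins[free] - 1.0).max(initial=0.0)),
        "margin": float(np.maximum(0.0, 1.0 - margins[~is_sv]).max(initial=0.0)),
    }


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def _xy(train) -> tuple[np.ndarray, np.ndarray, FeatureScaler]:
    if isinstance(train, PairDataset):
        x, y = train.feature_matrix(), train.labels
    else:
        x, y = train
        x, y = np.asarray(x, float), np.asarray(y, int)
    scaler = fit_scaler(x)
    xs = np.where(np.isnan(scaler.transform(x)), 0.5, scaler.transform(x))
    return xs, y, scaler


def train_logit(train, C: float = 1.0, seed: int = 0) -> MFRModel:
    """L2-penalized maximum-likelihood logistic regression baseline."""
    xs, y, scaler = _xy(train)
    clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    clf.fit(xs, y)
    return MFRModel(
        weights=clf.coef_[0],
        bias=float(clf.intercept_[0]),
        scaler=scaler,
        hyperparameters={"C": C},
        metadata={"method": "logit"},
    )


def train_lda(train) -> MFRModel:
    """LDA baseline (pooled covariance); ridge-regularized when singular."""
    xs, y, scaler = _xy(train)
    try:
        clf = LinearDiscriminantAnalysis(solver="svd")
        clf.fit(xs, y)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(xs, y)
    return MFRModel(
        weights=clf.coef_[0],
        bias=float(clf.intercept_[0]),
        scaler=scaler,
        metadata={"method": "lda"},
    )


def cxp_score(features: np.ndarray, scaler: FeatureScaler | None = None):
    """CXP baseline: mean of the five scaled coexpression measures.

    ``features`` is one 12-vector or an (n, 12) matrix in canonical order;
    any missing coexpression value makes the score missing (NaN).
    """
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if scaler is not None:
        x2 = scaler.transform(x2)
    idx = [FEATURE_NAMES.index(n) for n in COEXPRESSION_FEATURES]
    out = x2[:, idx].mean(axis=1)  # NaN propagates by design
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

@dataclass
class PairFeatureResources:
    """Bundle of every input needed to compute the 12 features for a pair."""

    expression: ExpressionMatrix
    ontology: Ontology
    bp_annotations: AnnotationMap
    cc_annotations: AnnotationMap
    homology: HomologyProfileSet
    pathway_graph: nx.Graph
    regulatory_pairs: set[tuple[str, str]]
    config: ExpressionFeatureConfig = field(default_factory=ExpressionFeatureConfig)

    def __post_init__(self) -> None:
        self._go = GoSimilarity(self.ontology, self.bp_annotations)
        self._rx = ReactomeSimilarity(self.pathway_graph)
        if not self.config.conditioning_panel:
            # default panel: most-variable genes; the scored pair is excluded
            # at use time.  Capped so the sample count stays above panel+2.
            variances = self.expression.values.var(axis=1)
            order = np.argsort(variances, kind="stable")[::-1]
            cap = min(self.config.max_panel, max(1, self.expression.n_samples - 4))
            self.config.conditioning_panel = [
                self.expression.gene_ids[i] for i in order[: cap + 2]
            ]

    def panel_for(self, gene_i: str, gene_j: str) -> np.ndarray:
        genes = [g for g in self.config.conditioning_panel if g not in (gene_i, gene_j)]
        genes = genes[: self.config.max_panel]
        return np.array([self.expression.row(g) for g in genes])


def assemble_features(
    pair: tuple[str, str],
    resources: PairFeatureResources,
    policy: ImputationPolicy = ImputationPolicy.DROP,
    max_missing_knowledge: int = 2,
) -> dict[str, float] | None:
    """Compute the 12-feature dict for a pair, or None if dropped.

    Expression features are mandatory: a pair with either gene absent from
    the expression matrix (or an undefined correlation) is dropped under
    the drop policy. Knowledge features may be missing; under drop the pair
    survives only if at most ``max_missing_knowledge`` of the five are
    missing, under impute_half missing values are recorded as NaN and
    become 0.5 in scaled space at scoring time.
    """
    gene_i, gene_j = pair
    if gene_i not in resources.expression or gene_j not in resources.expression:
        return None  # exp1/exp2 undefined: always dropped
    expr = resources.expression
    x, y = expr.row(gene_i), expr.row(gene_j)
    feats: dict[str, float] = {}
    try:
        feats["exp1"] = mean_expression(expr, gene_i)
        feats["exp2"] = mean_expression(expr, gene_j)
        feats["PCC"] = pcc(x, y)
        feats["SRC"] = src(x, y)
        feats["MI"] = mi(x, y, resources.config)
        panel = resources.panel_for(gene_i, gene_j)
        feats["PPC"] = ppc(x, y, panel)
        feats["CMI"] = cmi(x, y, panel, resources.config)
    except (UndefinedCorrelationError, MFRError):
        if policy == ImputationPolicy.DROP:
            return None
        for name in EXPRESSION_FEATURES:
            feats.setdefault(name, np.nan)
    knowledge_calls = {
        "goSim": lambda: resources._go(gene_i, gene_j),
        "lcSim": lambda: localization_similarity(resources.cc_annotations, gene_i, gene_j),
        "hgSim": lambda: homology_similarity(resources.homology, gene_i, gene_j),
        "rxSim": lambda: resources._rx(gene_i, gene_j),
        "trSim": lambda: float(
            regulatory_similarity(resources.regulatory_pairs, gene_i, gene_j)
        ),
    }
    n_missing = 0
    for name, call in knowledge_calls.items():
        try:
            feats[name] = float(call())
        except MissingFeatureError:
            feats[name] = np.nan
            n_missing += 1
    if policy == ImputationPolicy.DROP and n_missing > max_missing_knowledge:
        return None
    return {n: feats[n] for n in FEATURE_NAMES}


def assemble_dataset(
    pairs: list[tuple[str, str, int]],
    resources: PairFeatureResources,
    policy: ImputationPolicy = ImputationPolicy.DROP,
    provenance: str = "",
) -> PairDataset:
    """Assemble features for labeled pairs, applying the drop policy."""
    records = []
    for gene_a, gene_b, label in pairs:
        feats = assemble_features((gene_a, gene_b), resources, policy)
        if feats is None:
            continue
        records.append(PairRecord(gene_a, gene_b, label, feats, provenance))
    return PairDataset(records, provenance)
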
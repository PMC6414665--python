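"""Expression preprocessing and the seven expression-based gene-pair features.

For a gene pair (i, j) the features are the two average expression levels
(exp1, exp2) and five coexpression measures: Pearson correlation (PCC,
linear), Spearman rank correlation (SRC) and mutual information (MI,
non-linear), partial Pearson correlation (PPC, linear association after
projecting out a conditioning gene panel) and conditional mutual
information (CMI, its non-linear counterpart). MI and CMI use a plug-in
estimator on equal-frequency discretized expression levels, base-2
logarithm, so values are in bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import SizeError, UndefinedCorrelationError
from .io import ExpressionMatrix


@dataclass
class ExpressionFeatureConfig:
    """Knobs for the coexpression measures.

    mi_bins : number of discretization bins for MI/CMI (>= 2).
    discretization : "equal-frequency" (default) or "equal-width".
    conditioning_panel : gene ids used as the conditioning set for PPC/CMI;
        the pair being scored is always excluded at use time.
    max_panel : cap on conditioning genes actually used per pair.  PPC
        projects on the selected panel jointly; CMI conditions on the
        single most-correlated panel gene (first-order CMI) by default.
    cmi_panel_cap : number of panel genes jointly binned for CMI.
    pseudocount : added before log2 during normalization.
    """

    mi_bins: int = 8
    discretization: str = "equal-frequency"
    conditioning_panel: list[str] = field(default_factory=list)
    max_panel: int = 10
    cmi_panel_cap: int = 1
    log_base: float = 2.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")
        if self.discretization not in ("equal-frequency", "equal-width"):
            raise ValueError(f"unknown discretization {self.discretization!r}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def log2_quantile_normalize(
    matrix: ExpressionMatrix, pseudocount: float | None = 1.0
) -> ExpressionMatrix:
    """log2-transform then quantile-normalize the sample columns.

    After normalization every sample column has exactly the same sorted
    value vector (the across-sample mean of the column-sorted log2 values).
    Ties within a column receive the average of the mean-vector entries at
    the tied ranks.
    """
    x = np.asarray(matrix.values, dtype=float)
    if pseudocount is not None:
        x = x + pseudocount
    if (x <= 0).any():
        raise UndefinedCorrelationError(
            "non-positive expression value with pseudocount disabled; log2 undefined"
        )
    logged = np.log2(x)
    n_genes, n_samples = logged.shape
    order = np.argsort(logged, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(logged, order, axis=0)
    mean_quantiles = sorted_vals.mean(axis=1)
    out = np.empty_like(logged)
    for j in range(n_samples):
        col = logged[:, j]
        ranks = stats.rankdata(col, method="average") - 1.0  # 0-based, ties averaged
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (mean_quantiles[lo] + mean_quantiles[hi])
    return ExpressionMatrix(
        list(matrix.gene_ids), list(matrix.sample_ids), out, normalized=True
    )


def mean_expression(matrix: ExpressionMatrix, gene: str) -> float:
    """Average expression level of ``gene`` over all samples."""
    return float(np.mean(matrix.row(gene)))


# ---------------------------------------------------------------------------
# Pairwise measures
# ---------------------------------------------------------------------------

def _check_pair(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SizeError(f"expected equal-length 1-D vectors, got {x.shape} and {y.shape}")
    if x.size < min_n:
        raise SizeError(f"need at least {min_n} samples, got {x.size}")
    return x, y


def pcc(x, y) -> float:
    """Pearson product-moment correlation."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance; Pearson correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def src(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance; Spearman correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def discretize(v: np.ndarray, config: ExpressionFeatureConfig) -> np.ndarray:
    """Map a sample vector to integer bin labels in [0, mi_bins).

    Equal-frequency binning assigns bin ``floor((rank - 0.5) * B / n)`` on
    mid-ranks, so tied values always share a bin and counts are exactly
    balanced whenever n is a multiple of B and values are distinct.
    """
    v = np.asarray(v, dtype=float)
    n, b = v.size, config.mi_bins
    if n < b:
        raise SizeError(f"{n} samples cannot fill {b} bins")
    if config.discretization == "equal-width":
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.zeros(n, dtype=int)
        bins = np.minimum(((v - lo) / (hi - lo) * b).astype(int), b - 1)
        return bins
    ranks = stats.rankdata(v, method="average")  # mid-ranks: ties share a bin
    return np.minimum(((ranks - 0.5) * b / n).astype(int), b - 1)


def _mi_from_labels(xb: np.ndarray, yb: np.ndarray) -> float:
    """Plug-in MI (bits) of two integer-labeled variables."""
    n = xb.size
    joint: dict[tuple[int, int], int] = {}
    for a, b in zip(xb.tolist(), yb.tolist()):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    px: dict[int, int] = {}
    py: dict[int, int] = {}
    for (a, b), c in joint.items():
        px[a] = px.get(a, 0) + c
        py[b] = py.get(b, 0) + c
    mi_val = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi_val += p_ab * np.log2(p_ab * n * n / (px[a] * py[b]))
    return max(mi_val, 0.0)


def mi(x, y, config: ExpressionFeatureConfig | None = None) -> float:
    """Plug-in mutual information of the discretized pair, in bits."""
    config = config or ExpressionFeatureConfig()
    x, y = _check_pair(x, y, min_n=config.mi_bins)
    return _mi_from_labels(discretize(x, config), discretize(y, config))


def ppc(x, y, panel: np.ndarray) -> float:
    """Full-order partial Pearson correlation of x and y given the panel.

    Both vectors are residualized by least squares on [1, Z] (Z the panel
    vectors as columns); rank-deficient panels fall back to the
    pseudoinverse solution, which ``lstsq`` provides.
    """
    x, y = _check_pair(x, y)
    z = np.atleast_2d(np.asarray(panel, dtype=float))
    if z.shape[1] != x.size:
        z = z.T
    if z.shape[1] != x.size:
        raise SizeError("panel vectors must have the same sample length as x and y")
    if x.size <= z.shape[0] + 2:
        raise SizeError(
            f"sample count {x.size} must exceed panel size {z.shape[0]} + 2"
        )
    design = np.column_stack([np.ones(x.size), z.T])
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise UndefinedCorrelationError("empty residual variance after projection")
    return float(stats.pearsonr(rx, ry).statistic)


def cmi(x, y, panel: np.ndarray, config: ExpressionFeatureConfig | None = None) -> float:
    """Plug-in conditional mutual information I(X;Y|Z) in bits.

    The conditioning variable Z is the joint discretization of at most
    ``config.cmi_panel_cap`` panel genes (default 1: the panel gene most
    correlated with either member of the pair).
    """
    config = config or ExpressionFeatureConfig()
    x, y = _check_pair(x, y, min_n=config.mi_bins)
    z = np.atleast_2d(np.asarray(panel, dtype=float))
    if z.shape[1] != x.size:
        z = z.T
    if z.shape[0] > config.cmi_panel_cap:
        # keep the panel genes most (absolutely) correlated with the pair
        strength = []
        for row in z:
            s = 0.0
            for v in (x, y):
                if np.ptp(row) > 0 and np.ptp(v) > 0:
                    s = max(s, abs(np.corrcoef(row, v)[0, 1]))
            strength.append(s)
        keep = np.argsort(strength, kind="stable")[::-1][: config.cmi_panel_cap]
        z = z[np.sort(keep)]
    z_labels = np.zeros(x.size, dtype=int)
    for row in z:
        z_labels = z_labels * config.mi_bins + discretize(row, config)
    xb, yb = discretize(x, config), discretize(y, config)
    n = x.size
    out = 0.0
    for zv in np.unique(z_labels):
        mask = z_labels == zv
        pz = mask.sum() / n
        out += pz * _mi_from_labels(xb[mask], yb[mask])
    return max(out, 0.0)
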
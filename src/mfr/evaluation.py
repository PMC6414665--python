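"""ROC/AUC, B-match precision, cross-validation and dataset assembly.

AUC is computed with the average-rank Mann–Whitney formula, which is
identical (including tie handling) to trapezoidal integration of the ROC
curve with tied scores grouped. The cross-validation harness follows an
81/9/10 design: 10% of pairs are held out for a single test evaluation,
and the remaining 90% is split 10-fold so each round trains on 81% of the
full dataset and develops on 9%; the box constraint C is picked by mean
development AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import MFRError, SizeError, ValidationError
from .io import FEATURE_NAMES, PairDataset, PairRecord
from .model import ImputationPolicy, train_mfr


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC; ties handled by the average-rank convention."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise MFRError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores, method="average")
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    # curve: sweep thresholds over unique scores, descending, ties grouped
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    boundaries = np.flatnonzero(np.diff(sorted_scores)) if len(scores) > 1 else np.array([], int)
    idx = np.r_[boundaries, len(scores) - 1]
    tp = np.cumsum(sorted_labels == 1)[idx]
    fp = np.cumsum(sorted_labels == 0)[idx]
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    return RocResult(fpr=fpr, tpr=tpr, auc=float(auc))


def ppv(top_set: set, truth_set: set) -> float:
    """Precision TP / (TP + FP) of a predicted top set against truth."""
    if not top_set:
        raise MFRError("PPV undefined for an empty top set")
    tp = len(top_set & truth_set)
    return tp / len(top_set)


# ---------------------------------------------------------------------------
# B-match precision
# ---------------------------------------------------------------------------

@dataclass
class BMatchCriteria:
    """Thresholds for the two matched-pair definitions.

    A pair is a B0 match if (PCC > t or SRC > t) and goSim > t and
    lcSim > t at t = 0.5; B1 uses t = 0.3, so B0 matches are a subset of
    B1 matches.
    """

    b0_threshold: float = 0.5
    b1_threshold: float = 0.3

    def mask(self, features: np.ndarray, threshold: float) -> np.ndarray:
        idx = {n: FEATURE_NAMES.index(n) for n in ("PCC", "SRC", "goSim", "lcSim")}
        f = np.atleast_2d(np.asarray(features, dtype=float))
        expr_high = (f[:, idx["PCC"]] > threshold) | (f[:, idx["SRC"]] > threshold)
        know_high = (f[:, idx["goSim"]] > threshold) & (f[:, idx["lcSim"]] > threshold)
        return expr_high & know_high

    def b0(self, features: np.ndarray) -> np.ndarray:
        return self.mask(features, self.b0_threshold)

    def b1(self, features: np.ndarray) -> np.ndarray:
        return self.mask(features, self.b1_threshold)


def top_fraction_count(n: int, fraction: float) -> int:
    """floor(fraction * n), but at least 1."""
    return max(1, int(np.floor(fraction * n)))


def b_match_ppv(
    scores,
    feature_table: np.ndarray,
    criteria: BMatchCriteria | None = None,
) -> tuple[float, float]:
    """PPV of the top-5% pairs against B0 labels and top-10% against B1.

    ``feature_table`` is an (n, 12) matrix in canonical feature order
    (unscaled; the B thresholds apply to raw feature values).
    """
    criteria = criteria or BMatchCriteria()
    scores = np.asarray(scores, dtype=float)
    features = np.atleast_2d(np.asarray(feature_table, dtype=float))
    n = len(scores)
    if n < 20:
        raise SizeError(f"need at least 20 pairs for top-5% precision, got {n}")
    order = np.argsort(-scores, kind="stable")
    b0 = criteria.b0(features)
    b1 = criteria.b1(features)
    k5 = top_fraction_count(n, 0.05)
    k10 = top_fraction_count(n, 0.10)
    ppv_b0 = float(b0[order[:k5]].mean())
    ppv_b1 = float(b1[order[:k10]].mean())
    return ppv_b0, ppv_b1


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class CvPlan:
    folds: int = 10
    test_fraction: float = 0.10
    repeats: int = 1
    seed: int = 0


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Indices of n_folds label-stratified folds."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(int(j))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def crossval(
    dataset: PairDataset | tuple[np.ndarray, np.ndarray],
    plan: CvPlan | None = None,
    grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
    with_b_match: bool = False,
) -> dict:
    """81/9/10 cross-validation with C selection by mean development AUC.

    Returns a report dict: per-C mean/sd development AUC, the selected C,
    and the single held-out test AUC (plus B-match PPVs when requested).
    Deterministic given (dataset, plan.seed).
    """
    plan = plan or CvPlan()
    if isinstance(dataset, PairDataset):
        x, y = dataset.feature_matrix(), dataset.labels
    else:
        x, y = dataset
        x, y = np.asarray(x, float), np.asarray(y, int)
    rng = np.random.default_rng(plan.seed)
    # hold out the test split, stratified
    test_folds = _stratified_folds(y, round(1 / plan.test_fraction), rng)
    test_idx = test_folds[0]
    dev_pool = np.sort(np.concatenate(test_folds[1:]))
    x_pool, y_pool = x[dev_pool], y[dev_pool]
    folds = _stratified_folds(y_pool, plan.folds, rng)
    results: dict[float, list[float]] = {c: [] for c in grid}
    for k in range(plan.folds):
        dev = folds[k]
        tr = np.sort(np.concatenate([folds[m] for m in range(plan.folds) if m != k]))
        if len(np.unique(y_pool[dev])) < 2 or len(np.unique(y_pool[tr])) < 2:
            warnings.warn("single-class fold encountered; re-stratifying", stacklevel=2)
            continue
        for c in grid:
            model = train_mfr((x_pool[tr], y_pool[tr]), C=c, seed=plan.seed)
            dev_scores = model.score(x_pool[dev], policy=ImputationPolicy.IMPUTE_HALF)
            results[c].append(roc_auc(dev_scores, y_pool[dev]).auc)
    mean_dev = {c: float(np.mean(v)) for c, v in results.items() if v}
    best_c = max(mean_dev, key=lambda c: (mean_dev[c], -c))
    final = train_mfr((x_pool, y_pool), C=best_c, seed=plan.seed)
    test_scores = final.score(x[test_idx], policy=ImputationPolicy.IMPUTE_HALF)
    report = {
        "grid": {str(c): {"mean_dev_auc": mean_dev[c], "sd_dev_auc": float(np.std(results[c]))}
                 for c in mean_dev},
        "selected_C": best_c,
        "dev_auc": mean_dev[best_c],
        "test_auc": roc_auc(test_scores, y[test_idx]).auc,
        "n_test": int(len(test_idx)),
        "seed": plan.seed,
    }
    if with_b_match:
        b0, b1 = b_match_ppv(test_scores, x[test_idx])
        report["ppv_b0_top5"] = b0
        report["ppv_b1_top10"] = b1
    return report


# ---------------------------------------------------------------------------
# Dataset assembly (coexpression ranks + pathways + regulatory pairs)
# ---------------------------------------------------------------------------

@dataclass
class DatasetSpec:
    """How labeled pairs are assembled from ranking/pathway/regulatory sources.

    top_n : rank cutoff for coexpression positives (each gene contributes
        its top_n coexpression partners).
    middle_window : size of the centered window of each gene's ranked list
        whose members become discoexpressed negatives.
    min_shared_pathways : pathway-comembership threshold for positives.
    """

    top_n: int = 50
    middle_window: int = 80
    min_shared_pathways: int = 3
    balance: bool = True


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def coexpression_pairs(
    mr_lists: dict[str, list[str]], spec: DatasetSpec
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Positives = each gene's top-n ranked partners; negatives = a centered
    middle window of the ranked list. A pair qualifying as both is positive."""
    pos: set[tuple[str, str]] = set()
    neg: set[tuple[str, str]] = set()
    for gene, ranked in mr_lists.items():
        for partner in ranked[: spec.top_n]:
            pos.add(_canon(gene, partner))
        mid = len(ranked) // 2
        half = spec.middle_window // 2
        lo = max(0, mid - half)
        for partner in ranked[lo: lo + spec.middle_window]:
            neg.add(_canon(gene, partner))
    return pos, neg - pos


def pathway_pairs(
    pathway_map: dict[str, set[str]], spec: DatasetSpec, rng: np.random.Generator
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Positives: genes sharing >= min_shared_pathways pathways; negatives:
    random same-universe pairs from different pathways, balanced."""
    genes = sorted({g for s in pathway_map.values() for g in s})
    membership = {g: {p for p, s in pathway_map.items() if g in s} for g in genes}
    pos: set[tuple[str, str]] = set()
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if len(membership[a] & membership[b]) >= spec.min_shared_pathways:
                pos.add(_canon(a, b))
    neg: set[tuple[str, str]] = set()
    max_tries = 50 * max(1, len(pos))
    tries = 0
    while len(neg) < len(pos) and tries < max_tries:
        tries += 1
        a, b = rng.choice(genes, size=2, replace=False)
        pair = _canon(str(a), str(b))
        if membership[pair[0]] & membership[pair[1]]:
            continue
        if pair not in pos:
            neg.add(pair)
    if spec.balance and len(neg) < len(pos):
        raise MFRError(
            f"insufficient negative candidates: needed {len(pos)}, found {len(neg)}"
        )
    return pos, neg


def regulatory_pair_dataset(
    regulatory: set[tuple[str, str]], rng: np.random.Generator
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Positives: recorded regulator->target pairs; negatives: random
    permutation of regulators against targets, disjoint from positives and
    balanced to the positive count."""
    pos = {_canon(a, b) for a, b in regulatory if a != b}
    regulators = sorted({a for a, _ in regulatory})
    targets = sorted({b for _, b in regulatory})
    neg: set[tuple[str, str]] = set()
    max_tries = 200 * max(1, len(pos))
    tries = 0
    while len(neg) < len(pos) and tries < max_tries:
        tries += 1
        a = regulators[rng.integers(len(regulators))]
        b = targets[rng.integers(len(targets))]
        if a == b:
            continue
        pair = _canon(a, b)
        if pair in pos or pair in neg:
            continue
        neg.add(pair)
    if len(neg) < len(pos):
        raise MFRError(
            f"insufficient permutation negatives: needed {len(pos)}, found {len(neg)}"
        )
    return pos, neg


@dataclass
class DatasetResources:
    """Sources feeding :func:`build_pair_dataset`."""

    mr_lists: dict[str, list[str]] | None = None
    pathway_map: dict[str, set[str]] | None = None
    regulatory: set[tuple[str, str]] | None = None


def build_pair_dataset(
    resources: DatasetResources, spec: DatasetSpec | None = None, seed: int = 0
) -> PairDataset:
    """Assemble the labeled pair dataset from whichever sources are present.

    Positives follow each sub-dataset rule; negatives come from middle-rank
    windows, different-pathway sampling, and regulator/target permutation.
    Negatives never collide with positives of any sub-dataset; only the
    negative sampling consumes randomness, so two seeds share positives.
    """
    spec = spec or DatasetSpec()
    rng = np.random.default_rng(seed)
    records: list[PairRecord] = []
    all_pos: set[tuple[str, str]] = set()
    sources: list[tuple[str, set, set]] = []
    if resources.mr_lists:
        p, n = coexpression_pairs(resources.mr_lists, spec)
        sources.append(("coexpression", p, n))
    if resources.pathway_map:
        p, n = pathway_pairs(resources.pathway_map, spec, rng)
        sources.append(("pathway", p, n))
    if resources.regulatory:
        p, n = regulatory_pair_dataset(resources.regulatory, rng)
        sources.append(("regulatory", p, n))
    if not sources:
        raise MFRError("no dataset sources provided")
    for name, p, _ in sources:
        all_pos |= p
    seen: set[tuple[str, str]] = set()
    for name, p, n in sources:
        for a, b in sorted(p):
            if (a, b) not in seen:
                records.append(PairRecord(a, b, 1, provenance=name))
                seen.add((a, b))
        for a, b in sorted(n - all_pos):
            if (a, b) not in seen:
                records.append(PairRecord(a, b, 0, provenance=name))
                seen.add((a, b))
    try:
        return PairDataset(records)
    except ValidationError as exc:  # pragma: no cover - defensive
        raise MFRError(f"dataset assembly produced duplicates: {exc}") from exc
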
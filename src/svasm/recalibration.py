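"""Variant quality score recalibration and the inbreeding-coefficient filter.

Recalibration is a two-class Bayesian classification over up to nine
technical features associated with assembly error, global alignment error
and local alignment artifacts.  A Gaussian mixture (1..8 clusters, chosen
by BIC) is fitted to a positive training set (e.g. double-hit variants) and
a negative training set; every variant is then scored by the base-10
log-odds of arising from the positive versus the negative model,

    Score(x) = -lg(1 - P_pos(x)) + lg(1 - P_neg(x)),

where P_pos is the prior-weighted two-class-normalized positive
probability (priors 0.6/0.4 for known variants, 0.4/0.6 for novel ones)
and P_neg = 1 - P_pos.  The PASS threshold maximizes Youden's J on the
training ROC.

Loci with excessive hetero-/homozygosity among unrelated individuals are
filtered on the inbreeding coefficient F = 1 - N_het / (2*p*q*N), removing
variants with F < -0.4 or F > 0.7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "RecalModel",
    "InbreedingStats",
    "extract_features",
    "read_feature_tsv",
    "fit_class_mixture",
    "fit_recal_model",
    "score_from_probabilities",
    "score_variant",
    "choose_threshold",
    "cross_validate",
    "inbreeding_f",
    "inbreeding_coefficient",
    "filter_by_inbreeding",
]

FEATURE_NAMES = (
    "gap_ratio",
    "alt_depth",
    "neither_depth",
    "misalign_prob",
    "align_score",
    "local_identity",
    "scaffold_position",
    "proper_read_ratio",
    "improper_read_ratio",
)

PRIOR_POSITIVE_KNOWN = 0.6
PRIOR_POSITIVE_NOVEL = 0.4

_CLAMP = 1e-10


@dataclass
class FeatureVector:
    """The nine technical features of one variant; missing values are NaN."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature(s) {sorted(unknown)}")
        if all(math.isnan(v) for v in self.values.values()) or not self.values:
            raise ValueError("all features missing")
        for name in ("gap_ratio", "proper_read_ratio", "improper_read_ratio"):
            v = self.values.get(name, 0.0)
            if not math.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")

    def as_array(self, features: Sequence[str]) -> np.ndarray:
        return np.array([self.values.get(name, float("nan")) for name in features])


def extract_features(
    variant,
    scaffold_seq: str | None = None,
    scaffold_pos: int | None = None,
    block=None,
    read_summary: dict | None = None,
    window: int = 500,
) -> FeatureVector:
    """Assemble the feature vector from whatever evidence is available.

    gap_ratio is the N-base fraction of the scaffold within ``window`` bp of
    the variant; misalign_prob derives from the carrying alignment's mapping
    quality (10^(-MQ/10)); local identity and alignment score come from the
    enclosing block; read-level features from ``read_summary`` (keys
    alt_depth, neither_depth, proper_read_ratio, improper_read_ratio).
    Unavailable features are NaN.
    """
    nan = float("nan")
    values = dict.fromkeys(FEATURE_NAMES, nan)
    if scaffold_seq is not None and scaffold_pos is not None:
        lo = max(scaffold_pos - window, 0)
        hi = min(scaffold_pos + window, len(scaffold_seq))
        local = scaffold_seq[lo:hi]
        values["gap_ratio"] = local.count("N") / len(local) if local else 0.0
        values["scaffold_position"] = scaffold_pos / max(len(scaffold_seq), 1)
    if block is not None:
        values["align_score"] = float(block.score)
        cols = sum(1 for a, b in zip(block.ref_row, block.query_row))
        matches = sum(
            1 for a, b in zip(block.ref_row, block.query_row) if a == b != "-"
        )
        values["local_identity"] = matches / cols if cols else nan
        mapq = getattr(block, "mapq", None)
        if mapq is not None:
            values["misalign_prob"] = 10.0 ** (-mapq / 10.0)
    if read_summary:
        for key in (
            "alt_depth",
            "neither_depth",
            "proper_read_ratio",
            "improper_read_ratio",
            "misalign_prob",
        ):
            if key in read_summary:
                values[key] = float(read_summary[key])
    return FeatureVector(values)


def read_feature_tsv(path) -> pd.DataFrame:
    """Feature table: variant_id plus any subset of the nine feature columns."""
    table = pd.read_csv(path, sep="\t")
    if "variant_id" not in table.columns:
        raise ValueError("feature table must have a variant_id column")
    unknown = set(table.columns) - {"variant_id", "label", *FEATURE_NAMES}
    if unknown:
        raise ValueError(f"unknown feature column(s) {sorted(unknown)}")
    return table


def fit_class_mixture(
    X: np.ndarray, max_clusters: int = 8, seed: int = 0
) -> GaussianMixture:
    """Gaussian mixture for one training class; cluster count 1..max chosen
    by the Bayesian information criterion."""
    X = np.asarray(X, dtype=float)
    if len(X) < 10:
        raise ValueError("need at least 10 training points per class")
    max_clusters = min(max_clusters, len(X))
    best = None
    best_bic = np.inf
    for k in range(1, max_clusters + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            random_state=seed,
            reg_covar=1e-6,
            n_init=1,
        ).fit(X)
        bic = gm.bic(X)
        if bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    return best


@dataclass
class RecalModel:
    positive: GaussianMixture
    negative: GaussianMixture
    features: tuple[str, ...]
    threshold: float = float("nan")
    auc: float = float("nan")
    roc: pd.DataFrame | None = field(default=None, repr=False)


def fit_recal_model(
    positive_X: np.ndarray,
    negative_X: np.ndarray,
    features: Sequence[str] = FEATURE_NAMES,
    max_clusters: int = 8,
    seed: int = 0,
) -> RecalModel:
    return RecalModel(
        positive=fit_class_mixture(positive_X, max_clusters, seed),
        negative=fit_class_mixture(negative_X, max_clusters, seed),
        features=tuple(features),
    )


def score_from_probabilities(p_positive: float, p_negative: float) -> float:
    """Score = -lg(1 - P_positive) + lg(1 - P_negative), probabilities
    clamped away from 1 so the score stays finite."""
    p_pos = min(max(p_positive, _CLAMP), 1.0 - _CLAMP)
    p_neg = min(max(p_negative, _CLAMP), 1.0 - _CLAMP)
    return -math.log10(1.0 - p_pos) + math.log10(1.0 - p_neg)


def score_variant(
    x: np.ndarray | FeatureVector, model: RecalModel, is_known: bool = False
) -> float:
    """Recalibrated quality score of one variant; higher = more likely true.

    The class likelihoods are combined with the known/novel priors into the
    two-class-normalized positive probability before applying the log-odds
    formula, keeping the score finite and monotone in the Bayes factor.
    """
    if isinstance(x, FeatureVector):
        x = x.as_array(model.features)
    x = np.asarray(x, dtype=float).reshape(1, -1)
    p01 = PRIOR_POSITIVE_KNOWN if is_known else PRIOR_POSITIVE_NOVEL
    p02 = 1.0 - p01
    log_lpos = float(model.positive.score_samples(x)[0])
    log_lneg = float(model.negative.score_samples(x)[0])
    # normalized on the log scale for numerical stability
    a = math.log(p01) + log_lpos
    b = math.log(p02) + log_lneg
    mx = max(a, b)
    p_pos = math.exp(a - mx) / (math.exp(a - mx) + math.exp(b - mx))
    return score_from_probabilities(p_pos, 1.0 - p_pos)


def choose_threshold(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, pd.DataFrame, float]:
    """ROC over all score cutoffs; the PASS threshold maximizes Youden's J
    (TPR - FPR), keeping most positives while minimizing negatives.

    Returns (threshold, ROC table, AUC).  Ties take the highest threshold.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both positive and negative labels")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    roc = pd.DataFrame({"threshold": thresholds, "tpr": tpr, "fpr": fpr})
    j = tpr - fpr
    best = int(np.argmax(j))  # roc_curve thresholds descend: first max is highest
    threshold = float(thresholds[best])
    return threshold, roc, float(_sk_auc(fpr, tpr))


def classify(scores: np.ndarray, threshold: float) -> np.ndarray:
    """PASS (True) for scores at or above the threshold, FALSE otherwise."""
    return np.asarray(scores) >= threshold


def cross_validate(
    X: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    max_clusters: int = 8,
    seed: int = 0,
) -> float:
    """Stratified k-fold estimate of the held-out misclassification rate at
    the per-fold chosen threshold."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(int)
    if k < 2:
        raise ValueError("k must be >= 2")
    min_class = int(np.bincount(labels).min())
    if min_class < k:
        import warnings

        warnings.warn(f"reducing folds from {k} to {min_class}")
        k = min_class
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    errors = []
    for train, test in folds.split(X, labels):
        model = fit_recal_model(
            X[train][labels[train] == 1],
            X[train][labels[train] == 0],
            max_clusters=max_clusters,
            seed=seed,
        )
        train_scores = np.array([score_variant(x, model) for x in X[train]])
        threshold, _, _ = choose_threshold(train_scores, labels[train])
        test_scores = np.array([score_variant(x, model) for x in X[test]])
        predicted = classify(test_scores, threshold)
        errors.append(float(np.mean(predicted != (labels[test] == 1))))
    return float(np.mean(errors))


# --- inbreeding coefficient ----------------------------------------------


@dataclass(frozen=True)
class InbreedingStats:
    p: float  # reference allele frequency
    q: float  # alternative allele frequency
    n: int  # unrelated individuals with non-missing genotypes
    n_het: int
    f: float


_DOSE = {"RR": 0, "RA": 1, "AA": 2}


def inbreeding_f(n: int, n_het: int, p: float) -> float:
    """F = 1 - N_het / (2*p*q*N) with q = 1 - p."""
    q = 1.0 - p
    return 1.0 - (n_het / (2.0 * p * q * n))


def inbreeding_coefficient(genotypes: Sequence[str]) -> InbreedingStats | None:
    """F = 1 - N_het / (2*p*q*N) over unrelated individuals at one locus.

    Genotypes in {RR, RA, AA}; missing entries are dropped.  Returns None
    for monomorphic loci (p*q = 0), which the filter skips.
    """
    doses = [_DOSE[g] for g in genotypes if g in _DOSE]
    n = len(doses)
    if n < 2:
        raise ValueError("need at least 2 unrelated genotyped individuals")
    alt = sum(doses)
    q = alt / (2 * n)
    p = 1.0 - q
    if p <= 0.0 or q <= 0.0:
        return None
    n_het = sum(1 for d in doses if d == 1)
    return InbreedingStats(p, q, n, n_het, inbreeding_f(n, n_het, p))


def filter_by_inbreeding(
    records,
    genotypes_per_record: Sequence[Sequence[str]],
    low: float = -0.4,
    high: float = 0.7,
):
    """Flag records whose F falls strictly outside [low, high].

    Returns the records with their filter field updated and InbCoeff INFO
    set where F is defined.
    """
    for rec, genotypes in zip(records, genotypes_per_record):
        stats = inbreeding_coefficient(genotypes)
        if stats is None:
            continue
        rec.info["InbCoeff"] = round(stats.f, 6)
        if stats.f < low or stats.f > high:
            rec.filter = (
                "INBCOEFF"
                if rec.filter in (".", "PASS", "")
                else rec.filter + ";INBCOEFF"
            )
    return records
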
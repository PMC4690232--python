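"""Population genotyping of bi-allelic structural variants.

Each individual contributes a two-dimensional observation d_i per variant:
the fraction of reads uniquely supporting the reference allele (R
intensity) and the alternative allele (A intensity).  Across a population
these observations cluster into three genotype states (RR, RA, AA) and are
modelled with a three-state Gaussian mixture fitted by EM under linear
constraints: the state centers must stay inside a box around the expected
centers RR=(1, 0), RA=(0.5, 0.5), AA=(0, 1) scaled by a factor m, and must
keep their canonical ordering along the A-intensity axis.  m is scanned
over {0.8, 0.9, 1.0, 1.1, 1.2} (five rounds of training) and the best m is
chosen by the rank-sum of the constraint bias and the trio Mendelian error
rate.

Genotypes are the posterior argmax; the genotype quality is the
Phred-scaled probability that the call is wrong, GQ = -10*log10(1 - p),
capped at 99.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal

from .io_formats import Trio

__all__ = [
    "STATES",
    "AlleleIntensity",
    "GenotypeModel",
    "GenotypeCall",
    "compute_intensities",
    "read_intensity_tsv",
    "state_likelihood",
    "posterior",
    "fit_em",
    "phred_gq",
    "call_genotype",
    "mendelian_error_rate",
    "select_scaling_factor",
    "SCALING_GRID",
]

STATES = ("RR", "RA", "AA")
SCALING_GRID = (0.8, 0.9, 1.0, 1.1, 1.2)

#: expected (r_intensity, a_intensity) centers for RR, RA, AA
EXPECTED_CENTERS = np.array([[1.0, 0.001], [0.5, 0.5], [0.001, 1.0]])

_CENTER_BOX = 0.3  # |mu - m*expected| <= 0.3 per coordinate
_VAR_FLOOR = 1e-4


@dataclass(frozen=True)
class AlleleIntensity:
    """Normalized allele support for one individual at one variant."""

    r_intensity: float
    a_intensity: float
    depth: int

    @property
    def missing(self) -> bool:
        return self.depth == 0

    def vector(self) -> np.ndarray:
        return np.array([self.r_intensity, self.a_intensity])


MISSING = AlleleIntensity(float("nan"), float("nan"), 0)


@dataclass
class GenotypeModel:
    weights: np.ndarray  # (3,)
    means: np.ndarray  # (3, 2)
    covariances: np.ndarray  # (3, 2, 2)
    scaling: float = 1.0
    log_likelihood: float = float("-inf")
    n_iter: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(float(np.sum(self.weights)), 1.0, abs_tol=1e-6):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("negative mixture weight")
        a = self.means[:, 1]
        if not (a[0] < a[1] < a[2]):
            raise ValueError("state centers must be ordered on the A intensity")


@dataclass
class GenotypeCall:
    gt: str  # RR | RA | AA | missing
    gq: int
    posteriors: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    likelihoods: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))


def compute_intensities(r_count: int, a_count: int, depth: int) -> AlleleIntensity:
    """Intensities from unique read counts; depth 0 is a missing observation.

    Reads supporting neither allele contribute to depth only, so the two
    intensities need not sum to one.
    """
    if r_count < 0 or a_count < 0 or depth < 0:
        raise ValueError("negative read count")
    if depth == 0:
        return MISSING
    return AlleleIntensity(r_count / depth, a_count / depth, depth)


def read_intensity_tsv(path) -> dict[str, dict[str, AlleleIntensity]]:
    """Read a (variant_id, sample, r_count, a_count, depth) TSV into
    intensities keyed by variant then sample."""
    table = pd.read_csv(path, sep="\t")
    required = {"variant_id", "sample", "r_count", "a_count", "depth"}
    if not required.issubset(table.columns):
        raise ValueError(f"intensity table must have columns {sorted(required)}")
    out: dict[str, dict[str, AlleleIntensity]] = {}
    for row in table.itertuples():
        out.setdefault(str(row.variant_id), {})[str(row.sample)] = compute_intensities(
            int(row.r_count), int(row.a_count), int(row.depth)
        )
    return out


def intensities_from_sam(path, variant_ids) -> dict[str, dict[str, AlleleIntensity]]:
    """Count uniquely mapped reads per allele from a SAM file whose contigs
    are named ``<variant>|ref|<sample>`` and ``<variant>|alt|<sample>``."""
    import pysam

    counts: dict[tuple[str, str], list[int]] = {}
    with pysam.AlignmentFile(str(path), "r") as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            vid, allele, sample = read.reference_name.split("|")
            key = (vid, sample)
            counts.setdefault(key, [0, 0, 0])
            counts[key][2] += 1
            if read.mapping_quality == 0:
                continue  # not unique
            counts[key][0 if allele == "ref" else 1] += 1
    out: dict[str, dict[str, AlleleIntensity]] = {v: {} for v in variant_ids}
    for (vid, sample), (r, a, depth) in counts.items():
        out.setdefault(vid, {})[sample] = compute_intensities(r, a, depth)
    return out


def state_likelihood(d: AlleleIntensity, model: GenotypeModel, j: int) -> float:
    """Weighted state density w_j * N(d | mu_j, Sigma_j)."""
    if d.missing:
        raise ValueError("missing observation")
    cov = model.covariances[j]
    if np.linalg.det(cov) <= 0:
        raise np.linalg.LinAlgError("singular state covariance")
    return float(
        model.weights[j] * multivariate_normal.pdf(d.vector(), model.means[j], cov)
    )


def posterior(d: AlleleIntensity, model: GenotypeModel) -> np.ndarray:
    """Genotype posterior: state likelihoods normalized over the 3 states."""
    lik = np.array([state_likelihood(d, model, j) for j in range(3)])
    total = lik.sum()
    if total <= 0.0:
        warnings.warn("all state likelihoods underflow; uniform posterior")
        return np.full(3, 1.0 / 3.0)
    return lik / total


def _project_means(means: np.ndarray, scaling: float) -> np.ndarray:
    """Enforce the linear constraints: box around the scaled expected
    centers, then ordering on the A-intensity coordinate."""
    expected = scaling * EXPECTED_CENTERS
    out = np.clip(means, expected - _CENTER_BOX, expected + _CENTER_BOX)
    a = out[:, 1]
    eps = 1e-4
    # pool adjacent violators, then separate ties minimally within the box
    for j in (1, 2):
        if a[j] <= a[j - 1]:
            a[j] = a[j - 1] + eps
    hi = expected[2, 1] + _CENTER_BOX
    for j in (2, 1, 0):
        cap = hi - eps * (2 - j)
        if a[j] > cap:
            a[j] = cap
    out[:, 1] = a
    return out


def _log_density(D: np.ndarray, model: GenotypeModel) -> np.ndarray:
    """(N, 3) matrix of log(w_j) + log N(d_i | mu_j, Sigma_j)."""
    logd = np.empty((len(D), 3))
    for j in range(3):
        logd[:, j] = multivariate_normal.logpdf(
            D, model.means[j], model.covariances[j]
        ) + np.log(max(model.weights[j], 1e-300))
    return logd


def fit_em(
    D,
    m: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    diagonal: bool = True,
) -> GenotypeModel:
    """Fit the constrained three-state mixture to the non-missing
    observations ``D`` (sequence of AlleleIntensity or (N, 2) array).

    Weights start at (1/3, 1/3, 1/3) and the centers at the expected
    centers scaled by ``m``.  The M-step projects the centers back into the
    constraint set; a state that loses all responsibility mass keeps its
    initial center.
    """
    if isinstance(D, np.ndarray):
        X = D
    else:
        X = np.array([d.vector() for d in D if not d.missing])
    if len(X) < 3:
        raise ValueError("need at least 3 non-missing observations")
    init_means = _project_means(m * EXPECTED_CENTERS.copy(), m)
    model = GenotypeModel(
        weights=np.full(3, 1.0 / 3.0),
        means=init_means,
        covariances=np.array([np.eye(2) * 0.01 for _ in range(3)]),
        scaling=m,
    )
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        logd = _log_density(X, model)
        mx = logd.max(axis=1, keepdims=True)
        dens = np.exp(logd - mx)
        total = dens.sum(axis=1, keepdims=True)
        resp = dens / total
        ll = float(np.sum(np.log(total.ravel()) + mx.ravel()))
        nk = resp.sum(axis=0)
        weights = nk / nk.sum()
        means = model.means.copy()
        covs = model.covariances.copy()
        for j in range(3):
            if nk[j] < 1e-8:
                warnings.warn(f"state {STATES[j]} lost responsibility mass")
                continue
            mu = resp[:, j] @ X / nk[j]
            means[j] = mu
            diff = X - mu
            cov = (resp[:, j, None] * diff).T @ diff / nk[j]
            if diagonal:
                cov = np.diag(np.diag(cov))
            cov[np.diag_indices_from(cov)] = np.maximum(
                cov[np.diag_indices_from(cov)], _VAR_FLOOR
            )
            covs[j] = cov
        means = _project_means(means, m)
        model = GenotypeModel(weights, means, covs, m, ll, it)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return model


def phred_gq(p_best: float) -> int:
    """Phred-scale genotype quality -10*log10(1 - p), rounded, capped at 99."""
    p_wrong = max(1.0 - p_best, 1e-10)
    return min(int(round(-10.0 * math.log10(p_wrong))), 99)


def call_genotype(d: AlleleIntensity, model: GenotypeModel) -> GenotypeCall:
    """Posterior-argmax genotype with Phred-scale quality, capped at 99.

    Ties break to the earlier state in the fixed order RR < RA < AA.
    """
    if d.missing:
        return GenotypeCall("missing", 0)
    post = posterior(d, model)
    lik = np.array([state_likelihood(d, model, j) for j in range(3)])
    best = int(np.argmax(post))
    return GenotypeCall(STATES[best], phred_gq(float(post[best])), post, lik)


_ALT_DOSE = {"RR": 0, "RA": 1, "AA": 2, "missing": None}
_DOSE_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def _consistent(child: int, father: int, mother: int) -> bool:
    return any(
        sorted((fa, mo)) == list(_DOSE_ALLELES[child])
        for fa in _DOSE_ALLELES[father]
        for mo in _DOSE_ALLELES[mother]
    )


def mendelian_error_rate(
    genotypes: dict[str, dict[str, str]], trios: list[Trio]
) -> float:
    """Fraction of trio-complete loci where the child genotype is impossible
    given the parents (e.g. RR x RR parents cannot produce an RA child).

    ``genotypes`` maps variant id -> sample -> genotype in {RR, RA, AA,
    missing}.
    """
    for trio in trios:
        for member in (trio.child, trio.father, trio.mother):
            if not any(member in calls for calls in genotypes.values()):
                raise ValueError(f"pedigree id {member} absent from genotypes")
    checked = errors = 0
    for calls in genotypes.values():
        for trio in trios:
            doses = [
                _ALT_DOSE.get(calls.get(member, "missing"))
                for member in (trio.child, trio.father, trio.mother)
            ]
            if any(d is None for d in doses):
                continue
            checked += 1
            if not _consistent(*doses):
                errors += 1
    return errors / checked if checked else 0.0


def _constraint_bias(model: GenotypeModel) -> float:
    """L1 distance of the fitted centers from the scaled expected centers."""
    return float(
        np.abs(model.means - model.scaling * EXPECTED_CENTERS).sum()
    )


def select_scaling_factor(
    intensities: dict[str, dict[str, AlleleIntensity]],
    trios: list[Trio] | None = None,
    grid: tuple[float, ...] = SCALING_GRID,
) -> tuple[float, dict[float, GenotypeModel]]:
    """Five rounds of training over the scaling grid; the best m minimizes
    the rank-sum of constraint bias and trio Mendelian error rate (bias
    alone when no trios are given).  Ties break toward m closest to 1."""
    X = np.array(
        [
            d.vector()
            for per_sample in intensities.values()
            for d in per_sample.values()
            if not d.missing
        ]
    )
    models: dict[float, GenotypeModel] = {}
    biases: dict[float, float] = {}
    mendel: dict[float, float] = {}
    for m in grid:
        model = fit_em(X, m)
        models[m] = model
        biases[m] = _constraint_bias(model)
        if trios:
            calls = {
                vid: {
                    sample: call_genotype(d, model).gt
                    for sample, d in per_sample.items()
                }
                for vid, per_sample in intensities.items()
            }
            mendel[m] = mendelian_error_rate(calls, trios)

    def ranks(values: dict[float, float]) -> dict[float, int]:
        ordered = sorted(grid, key=lambda m: values[m])
        return {m: i for i, m in enumerate(ordered)}

    score = ranks(biases)
    if trios:
        mranks = ranks(mendel)
        score = {m: score[m] + mranks[m] for m in grid}
    best = min(grid, key=lambda m: (score[m], abs(m - 1.0), m))
    return best, models
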
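"""Incoherence and cohesion over ensembles of replicate distributions.

An :class:`Ensemble` holds two or more replicate :class:`Sample` outcomes
of the same experiment or simulation — continuous observations or
categorical counts.  From it this module computes

* **incoherence** ``I = sqrt((1/H~) * sum_k w_k (H~ - H_k)^2)`` — the
  weighted spread of per-replicate entropies ``H_k`` around the entropy
  ``H~`` of the pooled (point-wise mean) distribution.  A non-ergodic
  system, whose replicates settle into different outcome distributions,
  has high incoherence.

* **cohesion** ``C = (1 - H(G))^2`` where ``H(G)`` is the density-variance
  entropy of the set of all normalised pairwise Jensen–Shannon divergences.
  Cohesion is 1 when every replicate produced the same distribution and
  falls towards 0 as the divergences spread out — i.e. when the replicates
  do not organise into a small number of clean scenarios.

The Jensen–Shannon divergence is used (rather than Kullback–Leibler)
because replicates of a system near a tipping point can have disjoint
supports, for which KL is undefined or infinite.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

from .entropy import (
    BinScheme,
    DensityVarianceParams,
    density_variance_entropy,
    discretise,
    shannon_entropy,
)

__all__ = [
    "Sample",
    "Ensemble",
    "DivergenceSet",
    "EnsembleReport",
    "KindMismatchError",
    "pooled_distribution",
    "incoherence",
    "pairwise_jsd",
    "divergence_set",
    "cohesion",
    "analyse_ensemble",
    "default_dv_params",
]

LN2 = math.log(2.0)

Weighting = Literal["equal", "proportional"]
Estimator = Literal["histogram", "density_variance"]


class KindMismatchError(TypeError):
    """Samples of different data kinds were combined."""


_DEFAULT_PARAMS: DensityVarianceParams | None = None


def default_dv_params() -> DensityVarianceParams:
    """Calibrated default density-variance parameters (cached)."""
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = DensityVarianceParams().calibrated()
    return _DEFAULT_PARAMS


@dataclass(frozen=True)
class Sample:
    """One replicate's outcome distribution.

    Exactly one of ``observations`` (continuous data) or ``counts``
    (categorical data, mapping category label to a non-negative count)
    is set.  ``label`` carries optional ground-truth metadata (e.g. the
    generating letter of a synthetic message burst) and plays no part in
    any computation.
    """

    id: str
    observations: tuple[float, ...] | None = None
    counts: dict[str, float] | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if (self.observations is None) == (self.counts is None):
            raise ValueError("a sample holds either observations or counts")
        if self.observations is not None:
            obs = tuple(float(x) for x in self.observations)
            if len(obs) == 0:
                raise ValueError(f"sample {self.id!r} has no observations")
            object.__setattr__(self, "observations", obs)
        else:
            counts = {str(k): float(v) for k, v in self.counts.items()}
            if any(v < 0 for v in counts.values()):
                raise ValueError(f"sample {self.id!r} has negative counts")
            if sum(counts.values()) <= 0:
                raise ValueError(f"sample {self.id!r} has no positive count")
            object.__setattr__(self, "counts", counts)

    @property
    def kind(self) -> str:
        return "continuous" if self.observations is not None else "categorical"

    @property
    def n(self) -> float:
        if self.observations is not None:
            return float(len(self.observations))
        return float(sum(self.counts.values()))


@dataclass(frozen=True)
class Ensemble:
    """Two or more replicate samples of one data kind plus a weighting.

    ``weighting="equal"`` gives every sample weight 1/K (and every pair
    1/2 each); ``"proportional"`` weights by observation count n/N, the
    natural choice when replicates re-sample one underlying population.
    For continuous data all samples share one bin scheme, derived from
    the pooled observations (Freedman–Diaconis) unless supplied.
    """

    samples: tuple[Sample, ...]
    weighting: Weighting = "equal"
    bins: BinScheme | None = None

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        if len(samples) < 2:
            raise ValueError("an ensemble needs at least 2 samples")
        kinds = {s.kind for s in samples}
        if len(kinds) != 1:
            raise KindMismatchError(f"mixed sample kinds: {sorted(kinds)}")
        if self.weighting not in ("equal", "proportional"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        object.__setattr__(self, "samples", samples)
        if self.kind == "continuous" and self.bins is None:
            pooled = np.concatenate([np.asarray(s.observations) for s in samples])
            object.__setattr__(self, "bins", BinScheme.from_observations(pooled))

    @property
    def kind(self) -> str:
        return self.samples[0].kind

    @property
    def size(self) -> int:
        return len(self.samples)

    @property
    def categories(self) -> tuple[str, ...]:
        if self.kind != "categorical":
            raise KindMismatchError("categories only defined for categorical data")
        cats: set[str] = set()
        for s in self.samples:
            cats.update(s.counts)
        return tuple(sorted(cats))

    def weights(self) -> np.ndarray:
        if self.weighting == "equal":
            w = np.full(self.size, 1.0 / self.size)
        else:
            n = np.array([s.n for s in self.samples])
            w = n / n.sum()
        return w

    def probability_vectors(self) -> np.ndarray:
        """(K, B) matrix of per-sample probability vectors on the shared
        bin scheme (continuous) or sorted category union (categorical)."""
        if self.kind == "continuous":
            return np.vstack(
                [discretise(np.asarray(s.observations), self.bins) for s in self.samples]
            )
        cats = self.categories
        mat = np.zeros((self.size, len(cats)))
        index = {c: j for j, c in enumerate(cats)}
        for i, s in enumerate(self.samples):
            for c, v in s.counts.items():
                mat[i, index[c]] = v
            mat[i] /= mat[i].sum()
        return mat


def pooled_distribution(
    vectors: np.ndarray, weights: Sequence[float] | None = None
) -> np.ndarray:
    """Weighted point-wise mean of probability vectors (the mixture whose
    entropy is H~)."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    k = vectors.shape[0]
    w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return w @ vectors


def _scaled_observations(ensemble: Ensemble) -> list[np.ndarray]:
    """Ensemble observations affinely mapped onto [0, 1] by the global
    range, the domain the calibrated density-variance estimator expects."""
    data = [np.asarray(s.observations, dtype=float) for s in ensemble.samples]
    lo = min(d.min() for d in data)
    hi = max(d.max() for d in data)
    span = hi - lo if hi > lo else 1.0
    return [(d - lo) / span for d in data]


def _dv_entropies(
    ensemble: Ensemble, raw_k: float
) -> tuple[np.ndarray, float, list[np.ndarray]]:
    """Per-sample and pooled density-variance entropies of a continuous
    ensemble (pooling by concatenating the observations)."""
    if ensemble.kind != "continuous":
        raise KindMismatchError("density-variance entropies need continuous data")
    params = DensityVarianceParams(k=raw_k).calibrated()
    scaled = _scaled_observations(ensemble)
    h_k = np.array([density_variance_entropy(d, params) for d in scaled])
    h_pool = density_variance_entropy(np.concatenate(scaled), params)
    return h_k, h_pool, scaled


def incoherence(
    ensemble: Ensemble,
    base: float | None = None,
    rooted: bool = True,
    estimator: Estimator = "histogram",
    raw_k: float = 100.0,
) -> float:
    """Weighted entropy-spread statistic I of an ensemble.

    The rooted form (default) is the RMS of entropy deviations scaled by
    ``1/sqrt(H~)``; ``rooted=False`` returns its square.  A pooled
    distribution with zero entropy (all mass in one bin in every sample)
    makes the ratio degenerate: I is then 0 by convention, with a warning.

    With ``estimator="density_variance"`` (continuous data) the sample and
    pooled entropies are density-variance estimates on range-scaled data;
    they are already normalised, so ``base`` does not apply.
    """
    w = ensemble.weights()
    if estimator == "density_variance":
        h_k, h_pool, _ = _dv_entropies(ensemble, raw_k)
    else:
        vectors = ensemble.probability_vectors()
        h_k = np.array([shannon_entropy(v, base) for v in vectors])
        h_pool = shannon_entropy(pooled_distribution(vectors, w), base)
    if h_pool <= 0.0:
        warnings.warn("pooled entropy is zero; incoherence degenerates to 0")
        return 0.0
    i2 = float((w * (h_pool - h_k) ** 2).sum() / h_pool)
    return math.sqrt(i2) if rooted else i2


def _jsd_vectors(pa: np.ndarray, pb: np.ndarray, wa: float, wb: float) -> float:
    """Eq-style JSD in nats between two probability vectors."""
    mix = wa * pa + wb * pb
    d = shannon_entropy(mix) - wa * shannon_entropy(pa) - wb * shannon_entropy(pb)
    if d < -1e-9:
        raise RuntimeError(f"internal inconsistency: JSD = {d}")
    return max(d, 0.0)


def pairwise_jsd(
    a: Sample,
    b: Sample,
    weighting: Weighting = "equal",
    bins: BinScheme | None = None,
) -> float:
    """Jensen–Shannon divergence ``d_ab = w_a (H~ab - H_a) + w_b (H~ab - H_b)``
    in nats.  Symmetric, non-negative, and bounded by the entropy of the
    weight vector (ln 2 at equal weights)."""
    if a.kind != b.kind:
        raise KindMismatchError(f"cannot compare {a.kind} with {b.kind} data")
    pair = Ensemble((a, b), weighting=weighting, bins=bins)
    pa, pb = pair.probability_vectors()
    wa, wb = pair.weights()
    return _jsd_vectors(pa, pb, wa, wb)


@dataclass(frozen=True)
class DivergenceSet:
    """All unordered pairwise divergences of an ensemble.

    ``raw`` values are in nats for the histogram estimator and in
    normalised entropy units for the density-variance estimator;
    ``normalised`` values always lie in [0, 1] (divided by ``normaliser``,
    the theoretical maximum — ln 2 for equal pairwise weights)."""

    pairs: tuple[tuple[str, str], ...]
    raw: tuple[float, ...]
    normalised: tuple[float, ...]
    normaliser: float

    def __post_init__(self) -> None:
        if not (len(self.pairs) == len(self.raw) == len(self.normalised)):
            raise ValueError("pairs/raw/normalised lengths differ")
        if any(v < 0 or v > 1 + 1e-9 for v in self.normalised):
            raise ValueError("normalised divergences must lie in [0, 1]")


def _continuous_dv_divergences(
    ensemble: Ensemble, raw_k: float
) -> tuple[tuple[tuple[str, str], ...], tuple[float, ...]]:
    """Pairwise divergences using the density-variance entropy as the
    continuous estimator H in the divergence formula.

    Observations are affinely mapped onto [0, 1] by the ensemble's global
    range so the calibrated estimator applies; each divergence is the
    pooled-pair entropy minus the mean of the individual entropies.
    Suited to very small per-sample counts, where histogram estimates are
    dominated by sampling noise.
    """
    params = DensityVarianceParams(k=raw_k).calibrated()
    h_arr, _, scaled = _dv_entropies(ensemble, raw_k)
    h = list(h_arr)
    pairs = []
    raw = []
    for i, j in combinations(range(ensemble.size), 2):
        pooled = np.concatenate([scaled[i], scaled[j]])
        d = density_variance_entropy(pooled, params) - 0.5 * (h[i] + h[j])
        pairs.append((ensemble.samples[i].id, ensemble.samples[j].id))
        raw.append(max(d, 0.0))
    return tuple(pairs), tuple(raw)


def divergence_set(
    ensemble: Ensemble,
    estimator: Estimator = "histogram",
    raw_k: float = 1.0,
) -> DivergenceSet:
    """All K(K-1)/2 pairwise Jensen–Shannon divergences of an ensemble.

    ``estimator="histogram"`` (default) computes divergences between the
    shared-bin probability vectors and normalises by ln 2, the theoretical
    maximum for equal pairwise weights.  ``estimator="density_variance"``
    (continuous data only) plugs the density-variance entropy into the
    divergence formula; those divergences are already on a normalised
    entropy scale, so the normaliser is 1.
    """
    if estimator == "density_variance":
        if ensemble.kind != "continuous":
            raise KindMismatchError("density-variance estimator needs continuous data")
        pairs, raw = _continuous_dv_divergences(ensemble, raw_k)
        normalised = tuple(min(v, 1.0) for v in raw)
        return DivergenceSet(pairs, raw, normalised, 1.0)

    vectors = ensemble.probability_vectors()
    if ensemble.weighting == "equal":
        pair_w = {(i, j): (0.5, 0.5) for i, j in combinations(range(ensemble.size), 2)}
    else:
        n = np.array([s.n for s in ensemble.samples])
        pair_w = {
            (i, j): (n[i] / (n[i] + n[j]), n[j] / (n[i] + n[j]))
            for i, j in combinations(range(ensemble.size), 2)
        }
    pairs = []
    raw = []
    for (i, j), (wa, wb) in pair_w.items():
        pairs.append((ensemble.samples[i].id, ensemble.samples[j].id))
        raw.append(_jsd_vectors(vectors[i], vectors[j], wa, wb))
    normalised = tuple(min(max(v / LN2, 0.0), 1.0) for v in raw)
    return DivergenceSet(tuple(pairs), tuple(raw), normalised, LN2)


def cohesion(
    ensemble: Ensemble,
    params: DensityVarianceParams | None = None,
    estimator: Estimator = "histogram",
    raw_k: float = 1.0,
) -> float:
    """Cohesion ``C = (1 - H(G))^2`` of an ensemble.

    ``H(G)`` is the density-variance entropy of the normalised divergence
    set.  Identical replicates give divergences all at 0, hence H(G)=0 and
    C=1 exactly; divergences spread evenly over [0, 1] give H(G)=1 and
    C=0.
    """
    if params is None:
        params = default_dv_params()
    dset = divergence_set(ensemble, estimator=estimator, raw_k=raw_k)
    h_g = density_variance_entropy(np.asarray(dset.normalised), params)
    return (1.0 - h_g) ** 2


@dataclass
class EnsembleReport:
    """Everything the metrics stack computes for one ensemble."""

    sample_ids: list[str]
    h_k: list[float]
    h_pooled: float
    incoherence: float
    incoherence_unrooted: float
    incoherence_variant: str
    divergences_raw: list[float]
    divergences_normalised: list[float]
    divergence_pairs: list[tuple[str, str]]
    h_g: float
    cohesion: float
    estimator: str
    weighting: str
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sample_ids": list(self.sample_ids),
            "H_k": list(self.h_k),
            "H_pooled": self.h_pooled,
            "incoherence": self.incoherence,
            "incoherence_unrooted": self.incoherence_unrooted,
            "incoherence_variant": self.incoherence_variant,
            "divergences_raw": list(self.divergences_raw),
            "divergences_normalised": list(self.divergences_normalised),
            "divergence_pairs": [list(p) for p in self.divergence_pairs],
            "H_G": self.h_g,
            "cohesion": self.cohesion,
            "estimator": self.estimator,
            "weighting": self.weighting,
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleReport":
        return cls(
            sample_ids=list(d["sample_ids"]),
            h_k=list(d["H_k"]),
            h_pooled=d["H_pooled"],
            incoherence=d["incoherence"],
            incoherence_unrooted=d["incoherence_unrooted"],
            incoherence_variant=d["incoherence_variant"],
            divergences_raw=list(d["divergences_raw"]),
            divergences_normalised=list(d["divergences_normalised"]),
            divergence_pairs=[tuple(p) for p in d["divergence_pairs"]],
            h_g=d["H_G"],
            cohesion=d["cohesion"],
            estimator=d["estimator"],
            weighting=d["weighting"],
            params=dict(d.get("params", {})),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def analyse_ensemble(
    ensemble: Ensemble,
    params: DensityVarianceParams | None = None,
    estimator: Estimator = "histogram",
    raw_k: float = 1.0,
    base: float | None = None,
) -> EnsembleReport:
    """Compute the full report: per-sample and pooled entropies, both
    incoherence variants, the divergence set, its density-variance entropy
    and the cohesion."""
    if params is None:
        params = default_dv_params()
    w = ensemble.weights()
    if estimator == "density_variance":
        h_arr, h_pool, _ = _dv_entropies(ensemble, raw_k)
        h_k = list(h_arr)
    else:
        vectors = ensemble.probability_vectors()
        h_k = [shannon_entropy(v, base) for v in vectors]
        h_pool = shannon_entropy(pooled_distribution(vectors, w), base)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        i_root = incoherence(
            ensemble, base=base, rooted=True, estimator=estimator, raw_k=raw_k
        )
    dset = divergence_set(ensemble, estimator=estimator, raw_k=raw_k)
    h_g = density_variance_entropy(np.asarray(dset.normalised), params)
    return EnsembleReport(
        sample_ids=[s.id for s in ensemble.samples],
        h_k=h_k,
        h_pooled=h_pool,
        incoherence=i_root,
        incoherence_unrooted=i_root**2,
        incoherence_variant="rooted",
        divergences_raw=list(dset.raw),
        divergences_normalised=list(dset.normalised),
        divergence_pairs=list(dset.pairs),
        h_g=h_g,
        cohesion=(1.0 - h_g) ** 2,
        estimator=estimator,
        weighting=ensemble.weighting,
        params={
            "k": params.k,
            "n_ref": params.n_ref,
            "support": list(params.support),
            "v0": params.v0,
            "v1": params.v1,
            "entropy_base": base,
            "raw_k": raw_k if estimator == "density_variance" else None,
        },
    )
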
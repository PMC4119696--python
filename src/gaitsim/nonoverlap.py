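"""Similarity for nonoverlapped (disjoint-support) point distributions.

Distance-based fuzzy similarity measures degenerate when the two compared
distributions have disjoint supports: the pointwise minimum vanishes
everywhere, so the score collapses to ``1 − mean(all values)`` — a quantity
that cannot tell apart different partitions of the same value multiset
(:func:`conventional_on_disjoint` demonstrates this).

The measure implemented by :func:`sim_nonoverlap` fixes this by comparing each
sample's *complement mass* — its normalized Hamming distance to the all-ones
vector — so the score depends on how the values are split between the two
classes, not just on their union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import EmptyInputError
from .fuzzy import AxiomReport

__all__ = [
    "SingletonSample",
    "ReferencePool",
    "complement_mass",
    "sim_nonoverlap",
    "conventional_on_disjoint",
    "sample_axiom_report",
]


@dataclass(frozen=True)
class SingletonSample:
    """A labeled multiset of membership heights, each in ``[0, 1]``.

    Values are an ordered multiset: duplicates are allowed and counted with
    multiplicity.
    """

    label: str
    values: tuple

    def __post_init__(self) -> None:
        values = tuple(float(v) for v in self.values)
        if len(values) == 0:
            raise EmptyInputError(f"sample {self.label!r} must be non-empty")
        arr = np.asarray(values)
        if not np.all(np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError(f"sample {self.label!r} values must lie in [0, 1]")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values)


@dataclass(frozen=True)
class ReferencePool:
    """The multiset union of every sample under comparison.

    Recorded for provenance: each sample is contained in the pool, so the
    intersection of a sample with the pool is the sample itself, and all
    arithmetic below operates on the samples' own values.
    """

    values: tuple

    @classmethod
    def from_samples(cls, *samples: SingletonSample) -> "ReferencePool":
        pooled: list[float] = []
        for s in samples:
            pooled.extend(s.values)
        return cls(tuple(pooled))

    def contains(self, sample: SingletonSample) -> bool:
        """Multiset containment check."""
        pool = list(self.values)
        for v in sample.values:
            if v in pool:
                pool.remove(v)
            else:
                return False
        return True


def complement_mass(sample: SingletonSample) -> float:
    """Normalized distance of the sample's values to the all-ones vector.

    ``(1/|sample|) · Σ (1 − v_i)`` — the ``s_a`` quantity of the nonoverlap
    measure. Normalization is by the sample's *own* cardinality, so samples of
    unequal size remain comparable on the ``[0, 1]`` scale.
    """
    return float(np.mean(1.0 - sample.as_array()))


def sim_nonoverlap(a: SingletonSample, b: SingletonSample) -> float:
    """Similarity between two disjoint-support samples.

    ``1 − |complement_mass(a) − complement_mass(b)|``; symmetric, in
    ``[0, 1]``, and equal to 1 for identical samples.
    """
    return 1.0 - abs(complement_mass(a) - complement_mass(b))


def conventional_on_disjoint(a: SingletonSample, b: SingletonSample) -> float:
    """The conventional distance-based score on disjoint supports.

    With disjoint supports the pointwise minimum is identically zero and the
    pointwise maximum at each point is the lone defined value, so the
    min/max-based measure reduces to ``1 − (1/N) Σ v`` over all ``N = |a|+|b|``
    values of both samples. The result depends only on the pooled values —
    repartitioning them between the two classes cannot change it, which is
    exactly the discrimination failure motivating :func:`sim_nonoverlap`.
    """
    pooled = np.concatenate([a.as_array(), b.as_array()])
    # fsum is exactly rounded, hence invariant to how the values are
    # partitioned between the two samples — the invariance being demonstrated
    # must not be broken by float summation order
    return 1.0 - math.fsum(pooled) / pooled.size


def sample_axiom_report(
    measure: Callable[[SingletonSample, SingletonSample], float] = sim_nonoverlap,
    trials: int = 1000,
    seed: int = 0,
    tolerance: float = 1e-12,
    max_size: int = 8,
) -> AxiomReport:
    """Empirical S1–S4 axiom check for a sample-pair measure.

    Mirrors :func:`gaitsim.fuzzy.axiom_report` in the singleton-sample domain:

    - **S1** symmetry on random sample pairs (sizes may differ);
    - **S2** an all-ones sample versus its all-zeros complement scores 0
      (the crisp set / complement pair in this domain: a point that is fully
      present versus fully absent);
    - **S3** ``s(C, C) = 1``;
    - **S4** for same-size triples nested pointwise ``A ≤ B ≤ C``,
      ``s(A,B) ≥ s(A,C)`` and ``s(B,C) ≥ s(A,C)``.
    """
    if not callable(measure):
        raise TypeError("measure must be callable")
    rng = np.random.default_rng(seed)
    report = AxiomReport(trials=trials, seed=seed, tolerance=tolerance)

    for t in range(trials):
        na = int(rng.integers(1, max_size + 1))
        nb = int(rng.integers(1, max_size + 1))
        a = SingletonSample("a", tuple(rng.random(na)))
        b = SingletonSample("b", tuple(rng.random(nb)))
        s_ab = measure(a, b)
        s_ba = measure(b, a)
        if abs(s_ab - s_ba) > tolerance:
            report.record("S1", f"trial {t}: s(a,b)={s_ab!r} != s(b,a)={s_ba!r}")

        n = int(rng.integers(1, max_size + 1))
        ones = SingletonSample("D", (1.0,) * n)
        zeros = SingletonSample("Dc", (0.0,) * n)
        s_dc = measure(ones, zeros)
        if abs(s_dc) > tolerance:
            report.record("S2", f"trial {t}: s(ones, zeros)={s_dc!r}")

        c = SingletonSample("c", tuple(rng.random(n)))
        s_cc = measure(c, c)
        if abs(s_cc - 1.0) > tolerance:
            report.record("S3", f"trial {t}: s(C,C)={s_cc!r}")

        vc = rng.random(n)
        vb = vc * rng.random(n)
        va = vb * rng.random(n)
        sa = SingletonSample("A", tuple(va))
        sb = SingletonSample("B", tuple(vb))
        sc = SingletonSample("C", tuple(vc))
        s_ac = measure(sa, sc)
        if measure(sa, sb) < s_ac - tolerance:
            report.record("S4", f"trial {t}: s(A,B) < s(A,C) for nested A≤B≤C")
        if measure(sb, sc) < s_ac - tolerance:
            report.record("S4", f"trial {t}: s(B,C) < s(A,C) for nested A≤B≤C")

    return report
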
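"""Fuzzy sets on a shared discrete support and distance-based similarity measures.

A :class:`FuzzySet` assigns each element of an ordered finite support a
membership degree in ``[0, 1]``. All binary operations require both operands
to carry the *identical* identifier sequence; mismatches raise
:class:`~gaitsim.errors.SupportMismatchError` instead of aligning silently,
because the normalized Hamming distance presumes a shared universe of
discourse.

Four distance-based similarity measures are provided:

``sim_bounds_sum``
    ``d(A∩B, [0]) + d(A∪B, [1])``
``sim_minmax``
    ``1 − d(A∩B, A∪B)``
``sim_containment``
    ``1 − d(A, A∩B) − d(B, A∩B)``
``sim_bounds_complement``
    ``2 − d(A∩B, [1]) − d(A∪B, [0])``

where ``d`` is the normalized Hamming distance and ``[0]``/``[1]`` are the
constant zero/one sets. All four are algebraically equal to
``1 − hamming_distance(A, B)``; they are kept as distinct formulas so the
equivalence can be *verified* (see the test suite) rather than assumed.

:func:`axiom_report` empirically checks any candidate measure against the four
similarity-measure axioms (symmetry; zero on a crisp set versus its
complement; maximal self-similarity; monotonicity under nesting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import EmptyInputError, SupportMismatchError

__all__ = [
    "FuzzySet",
    "CrispSet",
    "hamming_distance",
    "intersect",
    "union_of",
    "complement",
    "zero_set",
    "one_set",
    "sim_bounds_sum",
    "sim_minmax",
    "sim_containment",
    "sim_bounds_complement",
    "DISTANCE_MEASURES",
    "AxiomReport",
    "axiom_report",
]


@dataclass(frozen=True)
class FuzzySet:
    """A finite fuzzy set: an ordered support plus one membership per element.

    Parameters
    ----------
    support
        Ordered sequence of unique, hashable element identifiers.
    memberships
        Real vector in ``[0, 1]``, one entry per support element.
    """

    support: tuple
    memberships: np.ndarray

    def __post_init__(self) -> None:
        support = tuple(self.support)
        if len(support) == 0:
            raise EmptyInputError("fuzzy set requires a non-empty support")
        if len(set(support)) != len(support):
            raise ValueError("support identifiers must be unique")
        mu = np.array(self.memberships, dtype=float, copy=True)
        if mu.ndim != 1 or mu.size != len(support):
            raise ValueError(
                f"memberships must be a 1-d vector of length {len(support)}, "
                f"got shape {mu.shape}"
            )
        if not np.all(np.isfinite(mu)):
            raise ValueError("memberships must be finite")
        if mu.min() < 0.0 or mu.max() > 1.0:
            raise ValueError("memberships must lie in [0, 1]")
        mu.flags.writeable = False
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "memberships", mu)

    def __len__(self) -> int:
        return len(self.support)

    @classmethod
    def from_memberships(cls, memberships: Sequence[float]) -> "FuzzySet":
        """Build a set on the default support ``x1..xn``."""
        mu = np.asarray(memberships, dtype=float)
        support = tuple(f"x{i + 1}" for i in range(mu.size))
        return cls(support, mu)

    def is_crisp(self, tol: float = 0.0) -> bool:
        mu = self.memberships
        return bool(np.all((np.abs(mu) <= tol) | (np.abs(mu - 1.0) <= tol)))


class CrispSet(FuzzySet):
    """A fuzzy set whose memberships are all exactly 0 or 1 (an ordinary set)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.is_crisp():
            raise ValueError("crisp set memberships must be exactly 0 or 1")


def _check_shared_support(a: FuzzySet, b: FuzzySet) -> None:
    if a.support != b.support:
        raise SupportMismatchError(
            "operands must share an identical support sequence; "
            f"got {a.support!r} vs {b.support!r}"
        )


def hamming_distance(a: FuzzySet, b: FuzzySet) -> float:
    """Normalized Hamming distance: mean absolute membership difference.

    Returns a value in ``[0, 1]``; 0 iff the membership vectors are identical.
    """
    _check_shared_support(a, b)
    return float(np.mean(np.abs(a.memberships - b.memberships)))


def intersect(a: FuzzySet, b: FuzzySet) -> FuzzySet:
    """Pointwise minimum of the two membership vectors."""
    _check_shared_support(a, b)
    return FuzzySet(a.support, np.minimum(a.memberships, b.memberships))


def union_of(a: FuzzySet, b: FuzzySet) -> FuzzySet:
    """Pointwise maximum of the two membership vectors."""
    _check_shared_support(a, b)
    return FuzzySet(a.support, np.maximum(a.memberships, b.memberships))


def complement(a: FuzzySet) -> FuzzySet:
    """Pointwise ``1 − μ``."""
    return FuzzySet(a.support, 1.0 - a.memberships)


def zero_set(support: Iterable) -> FuzzySet:
    """Constant-zero fuzzy set on *support*."""
    support = tuple(support)
    return FuzzySet(support, np.zeros(len(support)))


def one_set(support: Iterable) -> FuzzySet:
    """Constant-one fuzzy set on *support*."""
    support = tuple(support)
    return FuzzySet(support, np.ones(len(support)))


def sim_bounds_sum(a: FuzzySet, b: FuzzySet) -> float:
    """``d(A∩B, [0]) + d(A∪B, [1])``."""
    inter = intersect(a, b)
    uni = union_of(a, b)
    return hamming_distance(inter, zero_set(a.support)) + hamming_distance(
        uni, one_set(a.support)
    )


def sim_minmax(a: FuzzySet, b: FuzzySet) -> float:
    """``1 − d(A∩B, A∪B)``."""
    return 1.0 - hamming_distance(intersect(a, b), union_of(a, b))


def sim_containment(a: FuzzySet, b: FuzzySet) -> float:
    """``1 − d(A, A∩B) − d(B, A∩B)``."""
    inter = intersect(a, b)
    return 1.0 - hamming_distance(a, inter) - hamming_distance(b, inter)


def sim_bounds_complement(a: FuzzySet, b: FuzzySet) -> float:
    """``2 − d(A∩B, [1]) − d(A∪B, [0])``."""
    inter = intersect(a, b)
    uni = union_of(a, b)
    return (
        2.0
        - hamming_distance(inter, one_set(a.support))
        - hamming_distance(uni, zero_set(a.support))
    )


#: The four equivalent distance-based measures, keyed by formula name.
DISTANCE_MEASURES: dict[str, Callable[[FuzzySet, FuzzySet], float]] = {
    "bounds_sum": sim_bounds_sum,
    "minmax": sim_minmax,
    "containment": sim_containment,
    "bounds_complement": sim_bounds_complement,
}


_AXIOMS = ("S1", "S2", "S3", "S4")
_MAX_STORED = 20  # per axiom; counts keep growing past this


@dataclass
class AxiomReport:
    """Outcome of an empirical axiom check.

    Attributes
    ----------
    trials
        Number of random draws per axiom.
    seed, tolerance
        Inputs echoed for reproducibility.
    counts
        Violation count per axiom id (``S1``..``S4``).
    examples
        Up to 20 stored human-readable violation descriptions per axiom.
    """

    trials: int
    seed: int
    tolerance: float
    counts: dict[str, int] = field(default_factory=lambda: {a: 0 for a in _AXIOMS})
    examples: dict[str, list[str]] = field(
        default_factory=lambda: {a: [] for a in _AXIOMS}
    )

    def record(self, axiom: str, message: str) -> None:
        self.counts[axiom] += 1
        if len(self.examples[axiom]) < _MAX_STORED:
            self.examples[axiom].append(message)

    @property
    def total_violations(self) -> int:
        return sum(self.counts.values())

    @property
    def ok(self) -> bool:
        return self.total_violations == 0

    def summary(self) -> str:
        lines = [
            f"axiom check: {self.trials} trials, tolerance {self.tolerance:g}, "
            f"seed {self.seed}"
        ]
        for axiom in _AXIOMS:
            status = "ok" if self.counts[axiom] == 0 else f"{self.counts[axiom]} violations"
            lines.append(f"  {axiom}: {status}")
            for msg in self.examples[axiom][:3]:
                lines.append(f"    e.g. {msg}")
        return "\n".join(lines)


def axiom_report(
    measure: Callable[[FuzzySet, FuzzySet], float],
    trials: int = 1000,
    seed: int = 0,
    tolerance: float = 1e-12,
    self_similarity_target: float | None = 1.0,
    max_support: int = 8,
) -> AxiomReport:
    """Empirically test *measure* against the four similarity axioms.

    Per trial a fresh support of size 1..*max_support* is drawn and the
    following are checked:

    - **S1** symmetry on a random pair;
    - **S2** zero on a random crisp set versus its pointwise complement;
    - **S3** maximal self-similarity — tested as ``s(C, C) == target`` when
      *self_similarity_target* is given (all measures shipped here attain 1);
      when ``None``, tested as ``s(C, C) ≥`` every sampled pair value, which is
      the weaker reading appropriate for arbitrary user-supplied measures;
    - **S4** nesting monotonicity on a constructed triple ``A ⊂ B ⊂ C`` with
      ``μ_C`` uniform, ``μ_B = μ_C·u``, ``μ_A = μ_B·v`` (guaranteeing
      containment by construction).
    """
    if not callable(measure):
        raise TypeError("measure must be callable")
    rng = np.random.default_rng(seed)
    report = AxiomReport(trials=trials, seed=seed, tolerance=tolerance)
    sampled_max = -np.inf
    min_self = np.inf

    for t in range(trials):
        n = int(rng.integers(1, max_support + 1))
        support = tuple(range(n))

        a = FuzzySet(support, rng.random(n))
        b = FuzzySet(support, rng.random(n))
        s_ab = measure(a, b)
        s_ba = measure(b, a)
        sampled_max = max(sampled_max, s_ab, s_ba)
        if abs(s_ab - s_ba) > tolerance:
            report.record("S1", f"trial {t}: s(A,B)={s_ab!r} != s(B,A)={s_ba!r}")

        d = FuzzySet(support, rng.integers(0, 2, n).astype(float))
        s_dc = measure(d, complement(d))
        if abs(s_dc) > tolerance:
            report.record("S2", f"trial {t}: s(D,D^c)={s_dc!r} for crisp D")

        c = FuzzySet(support, rng.random(n))
        s_cc = measure(c, c)
        min_self = min(min_self, s_cc)
        if self_similarity_target is not None and abs(
            s_cc - self_similarity_target
        ) > tolerance:
            report.record("S3", f"trial {t}: s(C,C)={s_cc!r}")

        mu_c = rng.random(n)
        mu_b = mu_c * rng.random(n)
        mu_a = mu_b * rng.random(n)
        sa = FuzzySet(support, mu_a)
        sb = FuzzySet(support, mu_b)
        sc = FuzzySet(support, mu_c)
        s_ac = measure(sa, sc)
        if measure(sa, sb) < s_ac - tolerance:
            report.record("S4", f"trial {t}: s(A,B) < s(A,C) for nested A⊂B⊂C")
        if measure(sb, sc) < s_ac - tolerance:
            report.record("S4", f"trial {t}: s(B,C) < s(A,C) for nested A⊂B⊂C")

    if self_similarity_target is None and sampled_max > min_self + tolerance:
        report.record(
            "S3",
            f"sampled pair value {sampled_max!r} exceeds minimal "
            f"self-similarity {min_self!r}",
        )
    return report
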
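"""Core value types for two-sample Mendelian randomization.

The package works entirely at the summary-statistic level: a variant's
association with a trait is a (beta, se, p) triple expressed per copy of a
named effect allele. These small frozen dataclasses carry that information
between the I/O, harmonization, selection and estimation layers and enforce
the invariants every downstream computation relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import ValidationError

NUCLEOTIDES = frozenset("ACGT")

#: Watson-Crick complement, used for strand reconciliation during harmonization.
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with a single trait.

    Parameters
    ----------
    rsid : str
        Variant identifier; the matching key between exposure and outcome
        tables (positions are carried as metadata only).
    effect_allele, other_allele : str
        Uppercase single-nucleotide alleles; ``beta`` is per copy of
        ``effect_allele``.
    beta : float
        Association estimate. For an exposure table this is the per-allele
        change in the exposure (here: genetically predicted serum
        testosterone); for a disease outcome it is a log odds ratio.
    se : float
        Standard error of ``beta``; must be positive.
    pvalue : float
        Two-sided association p-value in (0, 1].
    position : int, optional
        1-based base-pair coordinate.
    eaf : float, optional
        Effect-allele frequency in [0, 1].
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    position: Optional[int] = None
    eaf: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("rsid must be a non-empty string")
        for name in ("effect_allele", "other_allele"):
            allele = getattr(self, name)
            if allele not in NUCLEOTIDES:
                raise ValidationError(
                    f"{self.rsid}: {name} {allele!r} must be one of A/C/G/T (uppercase)"
                )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are identical")
        if not np.isfinite(self.beta):
            raise ValidationError(f"{self.rsid}: beta must be finite")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"{self.rsid}: se must be finite and > 0")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(f"{self.rsid}: pvalue must lie in (0, 1]")
        if self.position is not None and self.position < 1:
            raise ValidationError(f"{self.rsid}: position is 1-based and must be >= 1")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.rsid}: eaf must lie in [0, 1]")

    def is_palindromic(self) -> bool:
        """True for A/T or C/G pairs, whose strand cannot be told from alleles."""
        return self.other_allele == COMPLEMENT[self.effect_allele]

    def flipped(self) -> "VariantAssociation":
        """The same association expressed per copy of the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass(frozen=True)
class HarmonizedVariant:
    """One variant's allele-aligned exposure/outcome association pair."""

    rsid: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    effect_allele: str
    other_allele: str
    position: Optional[int] = None
    pvalue_x: Optional[float] = None
    flipped: bool = False  # outcome beta's sign was flipped during alignment


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Allele-aligned per-variant exposure/outcome pairs ready for estimation.

    Both betas of every variant refer to the exposure table's effect allele.
    ``drop_log`` maps each discarded rsid to a reason code
    (``unmatched_outcome``, ``palindromic``, ``triallelic``,
    ``allele_mismatch``).
    """

    variants: tuple
    n_dropped: int = 0
    drop_log: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rsids = [v.rsid for v in self.variants]
        if len(set(rsids)) != len(rsids):
            raise ValidationError("duplicate rsids in harmonized instrument")
        for v in self.variants:
            if v.se_x <= 0 or v.se_y <= 0:
                raise ValidationError(f"{v.rsid}: standard errors must be > 0")
        if self.n_dropped != len(self.drop_log):
            raise ValidationError("n_dropped disagrees with drop_log length")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def rsids(self) -> tuple:
        return tuple(v.rsid for v in self.variants)

    @property
    def beta_x(self) -> np.ndarray:
        return np.array([v.beta_x for v in self.variants], dtype=float)

    @property
    def se_x(self) -> np.ndarray:
        return np.array([v.se_x for v in self.variants], dtype=float)

    @property
    def beta_y(self) -> np.ndarray:
        return np.array([v.beta_y for v in self.variants], dtype=float)

    @property
    def se_y(self) -> np.ndarray:
        return np.array([v.se_y for v in self.variants], dtype=float)

    def subset(self, rsids: Sequence[str]) -> "HarmonizedInstrument":
        """Restrict to ``rsids`` (order taken from the instrument)."""
        keep = set(rsids)
        missing = keep - set(self.rsids)
        if missing:
            raise ValidationError(f"rsids not in instrument: {sorted(missing)}")
        return HarmonizedInstrument(
            variants=tuple(v for v in self.variants if v.rsid in keep),
            n_dropped=self.n_dropped,
            drop_log=dict(self.drop_log),
        )

    def to_association_tables(self):
        """Re-expand into (exposure, outcome) association tables.

        Both sides share the exposure orientation, so harmonizing the result
        against itself is a no-op (idempotence of harmonization).
        """
        exposure, outcome = [], []
        for v in self.variants:
            exposure.append(
                VariantAssociation(
                    rsid=v.rsid,
                    effect_allele=v.effect_allele,
                    other_allele=v.other_allele,
                    beta=v.beta_x,
                    se=v.se_x,
                    pvalue=v.pvalue_x
                    if v.pvalue_x is not None
                    else _two_sided_p(v.beta_x, v.se_x),
                    position=v.position,
                )
            )
            outcome.append(
                VariantAssociation(
                    rsid=v.rsid,
                    effect_allele=v.effect_allele,
                    other_allele=v.other_allele,
                    beta=v.beta_y,
                    se=v.se_y,
                    pvalue=_two_sided_p(v.beta_y, v.se_y),
                    position=v.position,
                )
            )
        return exposure, outcome


def _two_sided_p(beta: float, se: float) -> float:
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return max(float(p), np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise signed linkage-disequilibrium correlations over a variant set.

    Stored as signed r (the correlation-aware estimator needs signs); pruning
    thresholds apply to r squared. Must be symmetric with unit diagonal,
    entries in [-1, 1] and positive semi-definite within tolerance.
    """

    rsids: tuple
    r: np.ndarray

    def __post_init__(self) -> None:
        rsids = tuple(self.rsids)
        object.__setattr__(self, "rsids", rsids)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        n = len(rsids)
        if len(set(rsids)) != n:
            raise ValidationError("duplicate rsids in LD matrix")
        if r.shape != (n, n):
            raise ValidationError(f"LD matrix shape {r.shape} does not match {n} rsids")
        if n and np.max(np.abs(r - r.T)) > 1e-8:
            raise ValidationError("LD matrix is asymmetric beyond tolerance 1e-8")
        if n and np.max(np.abs(np.diag(r) - 1.0)) > 1e-8:
            raise ValidationError("LD matrix diagonal must be 1")
        if n and np.max(np.abs(r)) > 1.0 + 1e-12:
            raise ValidationError("LD correlations must lie in [-1, 1]")
        if n and np.linalg.eigvalsh((r + r.T) / 2.0).min() < -1e-6 * max(1, n):
            raise ValidationError("LD matrix is not positive semi-definite")
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(rsids)})

    @classmethod
    def identity(cls, rsids: Sequence[str]) -> "LDMatrix":
        return cls(rsids=tuple(rsids), r=np.eye(len(rsids)))

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def r_of(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.r_of(a, b) ** 2

    def submatrix(self, rsids: Sequence[str]) -> "LDMatrix":
        missing = [s for s in rsids if s not in self._index]
        if missing:
            raise ValidationError(f"rsids not in LD matrix: {missing}")
        idx = [self._index[s] for s in rsids]
        return LDMatrix(rsids=tuple(rsids), r=self.r[np.ix_(idx, idx)])


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate, on the log-odds scale plus odds scale.

    The estimate is the change in log odds of the outcome per unit of
    genetically predicted exposure; ``odds_ratio`` and its bounds are the
    exact exponentials of the log-scale quantities.
    """

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    n_variants: int

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValidationError("se must be > 0")
        if not (0 < self.pvalue <= 1):
            raise ValidationError("pvalue must lie in (0, 1]")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValidationError("confidence bounds must bracket the estimate")

    @classmethod
    def from_normal(
        cls,
        method: str,
        estimate: float,
        se: float,
        n_variants: int,
        pvalue: Optional[float] = None,
    ) -> "MREstimate":
        """Build from (estimate, se) with normal-quantile CI.

        The 95% multiplier is the exact 0.975 normal quantile (1.959964...).
        ``pvalue`` may be supplied to use a reference other than the normal
        (e.g. a t distribution for MR-Egger).
        """
        z975 = float(stats.norm.ppf(0.975))
        lo = estimate - z975 * se
        hi = estimate + z975 * se
        if pvalue is None:
            pvalue = _two_sided_p(estimate, se)
        # exp may overflow to inf for absurdly large log-odds; that is the
        # correct odds-scale answer, not a warning-worthy event
        with np.errstate(over="ignore"):
            return cls(
                method=method,
                estimate=float(estimate),
                se=float(se),
                ci_low=lo,
                ci_high=hi,
                pvalue=float(pvalue),
                odds_ratio=float(np.exp(estimate)),
                or_ci_low=float(np.exp(lo)),
                or_ci_high=float(np.exp(hi)),
                n_variants=int(n_variants),
            )


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger regression output: causal slope plus pleiotropy intercept.

    The intercept estimates the average directional pleiotropic effect per
    variant (log-odds units); a two-sided intercept p-value below the chosen
    level indicates directional pleiotropy.
    """

    slope: MREstimate
    intercept_estimate: float
    intercept_se: float
    intercept_pvalue: float

    def __post_init__(self) -> None:
        if not (self.intercept_se > 0):
            raise ValidationError("intercept_se must be > 0")
        if not (0 < self.intercept_pvalue <= 1):
            raise ValidationError("intercept_pvalue must lie in (0, 1]")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of greedy p-value-ranked LD pruning.

    ``selected`` is in selection order (ascending p subject to the pruning
    constraint); ``removed`` maps each pruned rsid to the stronger selected
    variant that excluded it.
    """

    selected: tuple
    removed: Mapping[str, str]
    r2_threshold: float
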
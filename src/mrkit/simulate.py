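"""Synthetic two-sample GWAS summary statistics with known ground truth.

The estimators consume only summary data, so simulation happens directly at
the summary level: for variant j with minor-allele frequency p_j and true
per-allele exposure effect gamma_j, the observed exposure association is
drawn as beta_x_j ~ N(gamma_j, se_x_j) with the standard GWAS sampling
variance se_x_j = 1/sqrt(2 p_j (1-p_j) n_exposure) for a unit-variance
trait, and the outcome association as
beta_y_j ~ N(theta * gamma_j + alpha_j, se_y_j) with the analogous
se_y_j built from n_outcome. theta is the true causal effect (log-odds per
exposure unit) and alpha_j a per-variant horizontal-pleiotropy effect —
zero for valid instruments, drawn with mean zero (balanced) or a nonzero
mean (directional) for an ``invalid_fraction`` of variants.

Defaults mirror the study conditions this generator stands in for: a
20-variant instrument with per-allele exposure effects of magnitude
0.03-0.18 estimated in ~3200 men, against outcome GWAS of ~10^5 samples.

Everything is driven by an explicit integer seed; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import ParameterError
from .types import LDMatrix, VariantAssociation

#: Non-palindromic allele pairs cycled through when labelling variants.
_ALLELE_PAIRS = (("T", "C"), ("A", "G"), ("C", "T"), ("G", "A"), ("T", "G"), ("C", "A"))


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for synthetic two-sample summary statistics.

    Attributes
    ----------
    n_variants : int
        Instrument size.
    theta : float
        True causal effect, log-odds of outcome per unit exposure.
    gamma_dist : tuple
        Distribution of true per-variant exposure effects, either
        ``("uniform", low, high)`` or ``("normal", mean, sd)``.
    maf_dist : tuple
        Distribution of allele frequencies; bounds must stay in (0, 0.5].
    n_exposure, n_outcome : int
        Effective sample sizes; they set the SE magnitudes via
        1/sqrt(2 p (1-p) n).
    pleiotropy_mode : str
        ``"none"``, ``"balanced"`` (alpha mean 0) or ``"directional"``
        (alpha mean = ``pleiotropy_mean``).
    pleiotropy_mean, pleiotropy_sd : float
        Parameters of the normal pleiotropy distribution.
    invalid_fraction : float
        Share of variants receiving a pleiotropic effect, in [0, 1].
    ld_blocks : tuple, optional
        ``(n_blocks, block_size, within_r)``; when set, sampling noise is
        correlated within blocks (block-constant signed r) and
        ``n_variants`` must equal ``n_blocks * block_size``.
    seed : int
        Required; drives every random draw.
    """

    seed: int
    n_variants: int = 20
    theta: float = 0.2
    gamma_dist: Tuple = ("uniform", 0.03, 0.18)
    maf_dist: Tuple = ("uniform", 0.05, 0.5)
    n_exposure: int = 3225
    n_outcome: int = 100_000
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.02
    invalid_fraction: float = 0.0
    ld_blocks: Optional[Tuple[int, int, float]] = None

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ParameterError("n_variants must be >= 1")
        if self.n_exposure < 1 or self.n_outcome < 1:
            raise ParameterError("sample sizes must be >= 1")
        if not (0 <= self.invalid_fraction <= 1):
            raise ParameterError("invalid_fraction must lie in [0, 1]")
        if self.pleiotropy_mode not in {"none", "balanced", "directional"}:
            raise ParameterError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_sd < 0:
            raise ParameterError("pleiotropy_sd must be >= 0")
        kind = self.maf_dist[0]
        if kind != "uniform":
            raise ParameterError("maf_dist must be ('uniform', low, high)")
        low, high = self.maf_dist[1], self.maf_dist[2]
        if not (0 < low <= high <= 0.5):
            raise ParameterError("maf bounds must lie within (0, 0.5]")
        if self.gamma_dist[0] not in {"uniform", "normal"}:
            raise ParameterError("gamma_dist must be ('uniform', a, b) or ('normal', m, s)")
        if self.ld_blocks is not None:
            nb, bs, r = self.ld_blocks
            if nb < 1 or bs < 1:
                raise ParameterError("ld_blocks counts must be >= 1")
            if not (0 <= r < 1):
                raise ParameterError("within-block r must lie in [0, 1)")
            if nb * bs != self.n_variants:
                raise ParameterError("ld_blocks must tile n_variants exactly")


def _draw(rng: np.random.Generator, spec: Tuple, size: int) -> np.ndarray:
    kind = spec[0]
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size)
    return rng.normal(spec[1], spec[2], size)


def _block_ld(n_blocks: int, block_size: int, within_r: float) -> np.ndarray:
    block = np.full((block_size, block_size), within_r)
    np.fill_diagonal(block, 1.0)
    r = np.zeros((n_blocks * block_size,) * 2)
    for b in range(n_blocks):
        lo = b * block_size
        r[lo : lo + block_size, lo : lo + block_size] = block
    return r


def simulate_two_sample(config: SimulationConfig):
    """Draw one synthetic two-sample summary-statistic data set.

    Returns
    -------
    (exposure, outcome, truth)
        Two lists of :class:`VariantAssociation` sharing rsids and alleles
        (non-palindromic by construction, already orientation-consistent),
        and a truth record with keys ``theta``, ``gamma``, ``alpha``,
        ``maf``, ``invalid``, ``se_x``, ``se_y`` and, when ``ld_blocks``
        is set, ``ld`` (an :class:`LDMatrix`).

    Identical configs (same seed) yield bitwise-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    j = config.n_variants
    maf = _draw(rng, config.maf_dist, j)
    gamma = _draw(rng, config.gamma_dist, j)
    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_outcome)

    alpha = np.zeros(j)
    n_invalid = int(round(config.invalid_fraction * j))
    invalid = np.zeros(j, dtype=bool)
    if config.pleiotropy_mode != "none" and n_invalid > 0:
        idx = rng.choice(j, size=n_invalid, replace=False)
        invalid[idx] = True
        mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        alpha[idx] = rng.normal(mean, config.pleiotropy_sd, n_invalid)

    ld = None
    if config.ld_blocks is not None:
        nb, bs, wr = config.ld_blocks
        corr = _block_ld(nb, bs, wr)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(j))
        noise_x = chol @ rng.standard_normal(j)
        noise_y = chol @ rng.standard_normal(j)
    else:
        noise_x = rng.standard_normal(j)
        noise_y = rng.standard_normal(j)
    beta_x = gamma + se_x * noise_x
    beta_y = config.theta * gamma + alpha + se_y * noise_y

    exposure, outcome = [], []
    for k in range(j):
        ea, oa = _ALLELE_PAIRS[k % len(_ALLELE_PAIRS)]
        common = dict(
            rsid=f"rs{k + 1}",
            effect_allele=ea,
            other_allele=oa,
            position=(k + 1) * 1000,
            eaf=float(maf[k]),
        )
        exposure.append(
            VariantAssociation(
                beta=float(beta_x[k]),
                se=float(se_x[k]),
                pvalue=_p(beta_x[k], se_x[k]),
                **common,
            )
        )
        outcome.append(
            VariantAssociation(
                beta=float(beta_y[k]),
                se=float(se_y[k]),
                pvalue=_p(beta_y[k], se_y[k]),
                **common,
            )
        )
    truth = {
        "theta": config.theta,
        "gamma": gamma,
        "alpha": alpha,
        "maf": maf,
        "invalid": invalid,
        "se_x": se_x,
        "se_y": se_y,
    }
    if config.ld_blocks is not None:
        truth["ld"] = LDMatrix(rsids=tuple(v.rsid for v in exposure), r=corr)
    return exposure, outcome, truth


def _p(beta: float, se: float) -> float:
    return max(float(2.0 * stats.norm.sf(abs(beta) / se)), np.nextafter(0.0, 1.0))


def simulate_ld_candidates(
    n_blocks: int, block_size: int, within_r: float, seed: int
):
    """Candidate associations plus a block-diagonal LD matrix for pruning.

    Within each block every pair has signed correlation ``within_r``;
    across blocks the correlation is zero. Candidate (beta, se) pairs are
    drawn with consistent p-values, so at any r² threshold below
    ``within_r**2`` greedy stepwise selection must return exactly the
    minimum-p variant of each block — a ground truth the pruning tests
    exploit.

    Returns
    -------
    (candidates, ld) : (list of VariantAssociation, LDMatrix)
    """
    if not (0 <= within_r < 1):
        raise ParameterError("within_r must lie in [0, 1)")
    if n_blocks < 1 or block_size < 1:
        raise ParameterError("n_blocks and block_size must be >= 1")
    rng = np.random.default_rng(seed)
    j = n_blocks * block_size
    se = rng.uniform(0.01, 0.03, j)
    z = rng.uniform(2.0, 9.0, j)
    sign = rng.choice([-1.0, 1.0], j)
    beta = sign * z * se
    candidates = []
    for k in range(j):
        ea, oa = _ALLELE_PAIRS[k % len(_ALLELE_PAIRS)]
        candidates.append(
            VariantAssociation(
                rsid=f"rs{k + 1}",
                effect_allele=ea,
                other_allele=oa,
                beta=float(beta[k]),
                se=float(se[k]),
                pvalue=_p(beta[k], se[k]),
                position=(k + 1) * 1000,
            )
        )
    ld = LDMatrix(
        rsids=tuple(c.rsid for c in candidates),
        r=_block_ld(n_blocks, block_size, within_r),
    )
    return candidates, ld
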
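"""Greedy p-value-ranked stepwise LD pruning.

Instrument construction from a candidate association list: repeatedly take
the remaining candidate with the smallest p-value, discard every remaining
candidate in linkage disequilibrium with it (r squared strictly greater
than the threshold, default 0.40), and repeat until no candidates remain.
The survivors have low pairwise correlation and can be treated as
approximately independent instruments by the estimators.

Ties on p-value are broken by lexicographically smaller rsid so the
procedure is deterministic and invariant to input order.
"""

from __future__ import annotations

from typing import Sequence

from .exceptions import ParameterError, ValidationError
from .types import LDMatrix, SelectionResult, VariantAssociation

DEFAULT_R2_THRESHOLD = 0.40


def stepwise_select(
    candidates: Sequence[VariantAssociation],
    ld: LDMatrix,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> SelectionResult:
    """Prune candidates by greedy p-value-ranked stepwise selection.

    Parameters
    ----------
    candidates : sequence of VariantAssociation
        Non-empty candidate list; every rsid must appear in ``ld``.
    ld : LDMatrix
        Signed pairwise LD correlations; the pruning rule uses r squared.
    r2_threshold : float
        Pairs with r² strictly greater than this are considered in LD; the
        weaker member is removed. Must lie in (0, 1]. Pairs at exactly the
        threshold are retained.

    Returns
    -------
    SelectionResult
        ``selected`` in selection order (the first entry always attains the
        minimum p-value among all candidates); ``removed`` maps each pruned
        rsid to the selected variant that excluded it.
    """
    if not candidates:
        raise ParameterError("candidate list must be non-empty")
    if not (0 < r2_threshold <= 1):
        raise ParameterError(f"r2_threshold must lie in (0, 1], got {r2_threshold}")
    missing = [c.rsid for c in candidates if c.rsid not in ld]
    if missing:
        raise ValidationError(f"candidates absent from LD matrix: {missing}")
    ids = [c.rsid for c in candidates]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate rsids among candidates")

    remaining = sorted(candidates, key=lambda c: (c.pvalue, c.rsid))
    selected: list = []
    removed: dict = {}
    while remaining:
        top, rest = remaining[0], remaining[1:]
        selected.append(top.rsid)
        keep = []
        for cand in rest:
            if ld.r2(top.rsid, cand.rsid) > r2_threshold:
                removed[cand.rsid] = top.rsid
            else:
                keep.append(cand)
        remaining = keep
    return SelectionResult(
        selected=tuple(selected), removed=removed, r2_threshold=r2_threshold
    )
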
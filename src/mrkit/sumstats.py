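"""Summary-statistic I/O and allele harmonization.

Association tables are tab-delimited with a header row. The canonical
columns are ``rsid``, ``position``, ``effect_allele``, ``other_allele``,
``beta``, ``se``, ``pvalue`` and optionally ``eaf``; files using other
header names are read through a *dialect* mapping of canonical name ->
file column name. LD matrices are either a square labelled TSV (row labels
equal to column labels) or long-format triples ``rsid_a  rsid_b  r``.

Harmonization aligns an outcome table onto the exposure table's effect
alleles so that every (beta_x, beta_y) pair refers to the same allele:
matching alleles are kept, swapped alleles flip the outcome beta's sign,
strand-complement alleles are complemented first, and palindromic (A/T,
C/G) variants — whose strand cannot be resolved from alleles alone — are
dropped by default.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    HarmonizationError,
    ParameterError,
    SchemaError,
    ValidationError,
)
from .types import (
    COMPLEMENT,
    HarmonizedInstrument,
    HarmonizedVariant,
    LDMatrix,
    VariantAssociation,
)

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pvalue")
OPTIONAL_COLUMNS = ("position", "eaf")

#: Header names recognized for the long (triple) LD format.
_LONG_LD_HEADERS = {
    ("rsid_a", "rsid_b", "r"),
    ("snp_a", "snp_b", "r"),
}


def read_associations(
    path, dialect: Optional[Mapping[str, str]] = None
) -> list:
    """Read a variant-association TSV into :class:`VariantAssociation` records.

    Parameters
    ----------
    path : path-like
        Tab-delimited file with a header row.
    dialect : mapping, optional
        Canonical column name -> column name used in the file, for tables
        whose headers differ from the canonical ones. Unmapped canonical
        names are looked up verbatim.

    Returns
    -------
    list of VariantAssociation
        One record per valid data row, input order preserved. Rows with a
        missing or unparsable required field are rejected and logged with
        their row number and reason; alleles are uppercased.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SchemaError
        If a required column cannot be resolved.
    ValidationError
        If the retained rows contain duplicate rsids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"association table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    dialect = dict(dialect or {})
    colmap = {}
    for canon in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        name = dialect.get(canon, canon)
        if name in df.columns:
            colmap[canon] = name
        elif canon in REQUIRED_COLUMNS:
            raise SchemaError(f"{path}: required column '{name}' (for '{canon}') missing")

    records = []
    n_rejected = 0
    for i, row in df.iterrows():
        try:
            records.append(_parse_row(row, colmap))
        except (ValidationError, ValueError) as exc:
            n_rejected += 1
            log.warning("%s row %d rejected: %s", path, i + 2, exc)  # +2: header, 1-based
    if n_rejected:
        log.warning("%s: rejected %d of %d data rows", path, n_rejected, len(df))

    seen: dict = {}
    dups = []
    for rec in records:
        if rec.rsid in seen:
            dups.append(rec.rsid)
        seen[rec.rsid] = True
    if dups:
        raise ValidationError(f"{path}: duplicate rsids {sorted(set(dups))}")
    return records


def _parse_row(row, colmap) -> VariantAssociation:
    def get(canon, required=True):
        if canon not in colmap:
            return None
        val = row[colmap[canon]]
        if pd.isna(val) or str(val).strip() in {"", "NA", "NaN", "nan", "."}:
            if required:
                raise ValueError(f"missing value in column '{colmap[canon]}'")
            return None
        return str(val).strip()

    pos = get("position", required=False)
    eaf = get("eaf", required=False)
    return VariantAssociation(
        rsid=get("rsid"),
        effect_allele=get("effect_allele").upper(),
        other_allele=get("other_allele").upper(),
        beta=float(get("beta")),
        se=float(get("se")),
        pvalue=float(get("pvalue")),
        position=int(pos) if pos is not None else None,
        eaf=float(eaf) if eaf is not None else None,
    )


def write_associations(records: Sequence[VariantAssociation], path) -> None:
    """Write association records to TSV with the canonical columns."""
    rows = []
    for r in records:
        rows.append(
            {
                "rsid": r.rsid,
                "position": r.position,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "eaf": r.eaf,
            }
        )
    df = pd.DataFrame(rows, columns=["rsid", "position", "effect_allele",
                                     "other_allele", "beta", "se", "pvalue", "eaf"])
    if df["eaf"].isna().all():
        df = df.drop(columns=["eaf"])
    if len(df) and df["position"].isna().all():
        df = df.drop(columns=["position"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ld_matrix(path) -> LDMatrix:
    """Read an LD matrix from a square labelled TSV or long-format triples.

    The long format is detected by its header, which must be exactly
    ``rsid_a, rsid_b, r`` (or ``snp_a, snp_b, r``); anything else is parsed
    as a square matrix whose first column holds the row labels. In long
    format the matrix is symmetrized, the diagonal is set to 1 and absent
    off-diagonal pairs default to 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"LD matrix not found: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if tuple(h.strip().lower() for h in header) in _LONG_LD_HEADERS:
        return _read_ld_long(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise ValidationError(f"{path}: row labels do not match column labels")
    return LDMatrix(rsids=tuple(rows), r=df.to_numpy(dtype=float))


def _read_ld_long(path: Path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    a_col, b_col = df.columns[0], df.columns[1]
    rsids = list(dict.fromkeys(list(df[a_col]) + list(df[b_col])))
    index = {s: i for i, s in enumerate(rsids)}
    r = np.eye(len(rsids))
    for _, row in df.iterrows():
        i, j = index[row[a_col]], index[row[b_col]]
        val = float(row["r"])
        if i != j:
            r[i, j] = r[j, i] = val
        elif abs(val - 1.0) > 1e-8:
            raise ValidationError(f"{path}: diagonal entry for {row[a_col]} must be 1")
    return LDMatrix(rsids=tuple(rsids), r=r)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    """Write an LD matrix as a square labelled TSV."""
    df = pd.DataFrame(ld.r, index=list(ld.rsids), columns=list(ld.rsids))
    df.to_csv(path, sep="\t", float_format="%.15g")


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindromic_policy: str = "drop",
) -> HarmonizedInstrument:
    """Align outcome associations onto the exposure effect alleles.

    Variants are matched by rsid. For each match the outcome record is
    reconciled with the exposure alleles:

    * same effect/other alleles — outcome beta kept as-is;
    * swapped alleles — outcome beta sign-flipped;
    * strand complement (or swapped complement) — complemented first, then
      the same rule applied;
    * palindromic variants (A/T or C/G on either side) — handled per
      ``palindromic_policy``: ``"drop"`` (default) discards them,
      ``"keep"`` assumes both tables report the same strand;
    * anything irreconcilable (including triallelic-looking allele sets) —
      dropped with a reason code, never silently kept.

    Returns
    -------
    HarmonizedInstrument
        Retained pairs in exposure order, expressed per exposure effect
        allele, plus a per-rsid drop log.

    Raises
    ------
    HarmonizationError
        If no variant survives (estimation would be impossible).
    ParameterError
        If ``palindromic_policy`` is unknown.
    """
    if palindromic_policy not in {"drop", "keep"}:
        raise ParameterError(
            f"palindromic_policy must be 'drop' or 'keep', got {palindromic_policy!r}"
        )
    for name, table in (("exposure", exposure), ("outcome", outcome)):
        ids = [v.rsid for v in table]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate rsids in {name} table")

    outcome_by_rsid = {v.rsid: v for v in outcome}
    kept = []
    drop_log: dict = {}
    for exp in exposure:
        out = outcome_by_rsid.get(exp.rsid)
        if out is None:
            drop_log[exp.rsid] = "unmatched_outcome"
            continue
        if exp.is_palindromic() or out.is_palindromic():
            if palindromic_policy == "drop":
                drop_log[exp.rsid] = "palindromic"
                continue
            aligned = _align_same_strand(exp, out)
        else:
            aligned = _align_same_strand(exp, out)
            if aligned is None:
                aligned = _align_same_strand(exp, _complemented(out))
        if aligned is None:
            shared = {exp.effect_allele, exp.other_allele} & {
                out.effect_allele,
                out.other_allele,
            }
            drop_log[exp.rsid] = "triallelic" if len(shared) == 1 else "allele_mismatch"
            continue
        beta_y, flipped = aligned
        kept.append(
            HarmonizedVariant(
                rsid=exp.rsid,
                beta_x=exp.beta,
                se_x=exp.se,
                beta_y=beta_y,
                se_y=out.se,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                position=exp.position,
                pvalue_x=exp.pvalue,
                flipped=flipped,
            )
        )
    if not kept:
        raise HarmonizationError(
            f"no variants survived harmonization (dropped {len(drop_log)}: "
            f"{dict(drop_log)})"
        )
    return HarmonizedInstrument(
        variants=tuple(kept), n_dropped=len(drop_log), drop_log=drop_log
    )


def _align_same_strand(exp, out):
    """Match outcome alleles to exposure alleles assuming the same strand.

    Returns (beta_y, flipped) or None when the allele pairs differ.
    """
    if (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele):
        return out.beta, False
    if (out.effect_allele, out.other_allele) == (exp.other_allele, exp.effect_allele):
        return -out.beta, True
    return None


def _complemented(v: VariantAssociation) -> VariantAssociation:
    from dataclasses import replace

    return replace(
        v,
        effect_allele=COMPLEMENT[v.effect_allele],
        other_allele=COMPLEMENT[v.other_allele],
    )
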
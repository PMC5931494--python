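"""Delimited-text input with row-level validation.

One dialect everywhere: tab-separated, UTF-8, "." decimal point, ``NA`` for
missing values.  Summary tables may carry either (beta_outcome, se_outcome)
or (or, ci_low, ci_high); the latter is converted through
:func:`vitdmr.mr.ci_to_se`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mr import ci_to_se


class TableValidationError(ValueError):
    """Raised when a summary table is malformed beyond the tolerated fraction."""


REQUIRED_COLUMNS = ("study_id", "snp_id", "effect_allele", "other_allele")


def read_summary_table(
    path,
    max_bad_fraction: float = 0.1,
):
    """Read a per-study per-SNP summary table with validation.

    Returns (table, errors) where ``errors`` is a list of
    ``(line_number, message)`` for rejected rows.  Rows carrying
    ``or``/``ci_low``/``ci_high`` instead of ``beta_outcome``/``se_outcome``
    are converted.  If more than ``max_bad_fraction`` of data rows are bad,
    a :class:`TableValidationError` is raised.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"malformed header: missing columns {missing}")
    has_beta = {"beta_outcome", "se_outcome"}.issubset(df.columns)
    has_or = {"or", "ci_low", "ci_high"}.issubset(df.columns)
    if not (has_beta or has_or):
        raise TableValidationError(
            "need either beta_outcome/se_outcome or or/ci_low/ci_high columns"
        )

    errors: list[tuple[int, str]] = []
    rows = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        r = dict(row)
        try:
            if has_beta and pd.notna(row.get("beta_outcome")):
                b = float(row["beta_outcome"])
                s = float(row["se_outcome"])
                if not s > 0:
                    raise ValueError(f"se_outcome must be > 0, got {s}")
            elif has_or:
                orv = float(row["or"])
                lo = float(row["ci_low"])
                hi = float(row["ci_high"])
                s = ci_to_se(orv, lo, hi)
                if s == 0:
                    raise ValueError("degenerate CI (zero width)")
                b = float(np.log(orv))
            else:
                raise ValueError("no usable effect columns in row")
            r["beta_outcome"] = b
            r["se_outcome"] = s
            rows.append(r)
        except (ValueError, TypeError) as exc:
            errors.append((line, str(exc)))
    n_data = len(df)
    if n_data > 0 and len(errors) / n_data > max_bad_fraction:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:5])
        raise TableValidationError(
            f"{len(errors)}/{n_data} rows rejected (> {max_bad_fraction:.0%}): {detail}"
        )
    return pd.DataFrame(rows), errors


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table in the package dialect (12 significant digits)."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")
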
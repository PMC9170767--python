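"""Signed log-p differential-expression values for genes and nodes.

Differential expression enters the pathway display as a single signed
number per gene or node:

    value = log2(p) * (-10) * regulation

where *regulation* is +1 for up-regulated targets (positive fold change)
and -1 for down-regulated ones.  Small p-values give large magnitudes
(p = 0.05 maps to about 43.2), and the regulation sign points the color
gradient up or down.  Targets with p at or above the significance cutoff
(strictly below alpha counts as significant; default alpha 0.05) are set
to value 0 — visually neutral.

The supported route for serious DE results is :func:`import_de_table`
(e.g. a voom/limma table with p-values and fold changes).  The built-in
:func:`builtin_de` is a deliberately simple two-group reference — Welch's
t-test on log2 counts-per-million — useful for synthetic data and smoke
tests; it is not equivalent to a moderated model and is not presented as
one.  No multiple-testing correction is applied by default; an optional
Benjamini–Hochberg adjustment is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .expression import CountMatrix, ExpressionError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

#: p-values below this are clamped before the log transform, preventing
#: infinities; the display scale saturates far earlier anyway
P_FLOOR = 1e-300


class DEError(Exception):
    """Invalid differential-expression input."""


@dataclass
class DERecord:
    """One target's differential-expression summary.

    ``value`` is the signed log-p display value; it is zero when the
    record is not significant, and its sign equals ``regulation`` when it
    is.
    """

    target: str
    pvalue: float
    regulation: int
    value: float = 0.0
    significant: bool = False


def signed_log_p(pvalue: float, regulation: int) -> float:
    """Transform a p-value into the signed display value.

    ``log2(p) * (-10) * regulation`` with p clamped below at ``P_FLOOR``.
    Raises :class:`DEError` outside (0, 1] or for a regulation sign other
    than +1/-1.
    """
    if not (0.0 < pvalue <= 1.0):
        raise DEError(f"p-value {pvalue!r} outside (0, 1]")
    if regulation not in (1, -1):
        raise DEError(f"regulation must be +1 or -1, got {regulation!r}")
    return math.log2(max(pvalue, P_FLOOR)) * (-10.0) * regulation


def apply_threshold(
    records: list[DERecord], alpha: float = DEFAULT_ALPHA
) -> list[DERecord]:
    """Set the signed log-p value on significant records, zero otherwise.

    Significance is strict: p must be *below* alpha.  Returns new records;
    the input list is not mutated.
    """
    if not (0.0 < alpha < 1.0):
        raise DEError(f"alpha {alpha!r} outside (0, 1)")
    out = []
    for rec in records:
        if rec.pvalue < alpha:
            out.append(replace(
                rec,
                value=signed_log_p(rec.pvalue, rec.regulation),
                significant=True,
            ))
        else:
            out.append(replace(rec, value=0.0, significant=False))
    return out


def builtin_de(
    counts: CountMatrix, alpha: float = DEFAULT_ALPHA
) -> list[DERecord]:
    """Simple two-group reference test on a (gene- or node-level) matrix.

    Counts are library-size scaled to counts per million, log2 transformed
    with pseudocount 1, and compared between groups with Welch's unequal-
    variance t-test.  Regulation is the sign of (case mean - control mean)
    on the log scale; rows with identical group means get regulation +1
    and, having p = 1, are never significant.  Deterministic for fixed
    input.
    """
    case = counts.samples_in("case")
    control = counts.samples_in("control")
    if len(case) < 2 or len(control) < 2:
        raise DEError(
            f"each group needs >= 2 samples (case={len(case)}, "
            f"control={len(control)})"
        )
    libsize = counts.counts.sum(axis=0)
    if (libsize <= 0).any():
        raise DEError("sample(s) with zero total counts")
    logcpm = np.log2(counts.counts.div(libsize, axis=1) * 1e6 + 1.0)
    a = logcpm[case].to_numpy()
    b = logcpm[control].to_numpy()
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    diffs = a.mean(axis=1) - b.mean(axis=1)
    records = [
        DERecord(
            target=target,
            pvalue=float(min(max(p, P_FLOOR), 1.0)),
            regulation=-1 if d < 0 else 1,
        )
        for target, p, d in zip(logcpm.index, pvals, diffs)
    ]
    return apply_threshold(records, alpha)


def import_de_table(
    tsv_path, alpha: float = DEFAULT_ALPHA
) -> list[DERecord]:
    """Load an external DE table (columns: target, pvalue, fold_change).

    ``logFC`` is accepted in place of ``fold_change`` — only the sign is
    used either way.  Rows with fold change exactly 0 have no defined
    regulation and are skipped with a warning.
    """
    df = pd.read_csv(tsv_path, sep="\t")
    fc_col = next((c for c in ("fold_change", "logFC") if c in df.columns),
                  None)
    missing = [c for c in ("target", "pvalue") if c not in df.columns]
    if missing or fc_col is None:
        need = missing + ([] if fc_col else ["fold_change (or logFC)"])
        raise DEError(f"{tsv_path}: missing column(s): {', '.join(need)}")
    records = []
    for row in df.itertuples(index=False):
        fc = float(getattr(row, fc_col))
        if fc == 0.0:
            logger.warning(
                "%s: target %s has fold change 0 (regulation undefined); "
                "row skipped", tsv_path, row.target,
            )
            continue
        pvalue = float(row.pvalue)
        if not (0.0 < pvalue <= 1.0):
            raise DEError(
                f"{tsv_path}: target {row.target}: p-value {pvalue} "
                "outside (0, 1]"
            )
        records.append(DERecord(
            target=str(row.target),
            pvalue=pvalue,
            regulation=1 if fc > 0 else -1,
        ))
    return apply_threshold(records, alpha)


def export_de_table(records: list[DERecord], path) -> None:
    pd.DataFrame(
        [
            {
                "target": r.target, "pvalue": r.pvalue,
                "regulation": r.regulation, "value": r.value,
                "significant": r.significant,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def bh_adjust(records: list[DERecord],
              alpha: float = DEFAULT_ALPHA) -> list[DERecord]:
    """Optional Benjamini–Hochberg variant of :func:`apply_threshold`.

    Replaces each record's p-value with its BH-adjusted value before
    thresholding.  Off by default; the unadjusted strict cutoff is the
    package's standard behavior.
    """
    if not records:
        return []
    adj = stats.false_discovery_control([r.pvalue for r in records])
    adjusted = [replace(r, pvalue=float(min(p, 1.0)))
                for r, p in zip(records, adj)]
    return apply_threshold(adjusted, alpha)
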